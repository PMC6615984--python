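"""Iterative reciprocal alignment: cis discovery, scoring and matching rounds.

Starting from the pairs matched by annotated sample ID, each round
re-tests the cis-associations on the currently matched pairs, rebuilds
the similarity matrix and re-runs the chosen matcher; corrected
matches sharpen the cis barcode, which in turn sharpens the matches.
Rounds repeat until the set of alignment decisions stops changing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cis import CisAssociationSet, CisCandidateMap, test_cis_associations
from .core import OmicsMatrix
from .prob_matcher import MatchDecisionConfig, promodmatcher_align
from .rank_matcher import modmatcher_align
from .results import AlignmentResult
from .similarity import similarity_matrix

__all__ = ["IterationOutcome", "iterate_alignment"]

logger = logging.getLogger(__name__)


@dataclass
class IterationOutcome:
    """Final alignment plus the cis-association set it rests on."""

    result: AlignmentResult
    cis: CisAssociationSet
    n_iterations: int
    converged: bool
    history: list[dict] = field(default_factory=list)


def iterate_alignment(
    matA: OmicsMatrix,
    matB: OmicsMatrix,
    candidates: CisCandidateMap,
    matcher: str = "probabilistic",
    config: MatchDecisionConfig | None = None,
    alpha: float = 0.05,
    min_n: int = 10,
    min_overlap: int | None = None,
    max_iter: int = 20,
    seed: int = 0,
) -> IterationOutcome:
    """Run rounds of {cis test -> similarity -> match} until stable.

    ``matcher`` is ``"probabilistic"`` or ``"rank"``.  The loop stops
    when the alignment statuses repeat an earlier state (converged) or
    ``max_iter`` is reached (flagged non-converged).  The initial
    matched set is the samples shared by ID between the two matrices.
    """
    if matcher not in ("probabilistic", "rank"):
        raise ValueError(f"unknown matcher {matcher!r}")
    if config is None:
        config = MatchDecisionConfig(seed=seed, max_iter=max_iter)
    shared = [s for s in matA.sample_ids if matB.has_sample(s)]
    if not shared:
        raise ValueError("no shared sample IDs to seed the alignment")
    matched: list[tuple[str, str]] = [(s, s) for s in shared]

    prev_state: frozenset | None = None
    history: list[dict] = []
    result: AlignmentResult | None = None
    cis: CisAssociationSet | None = None
    converged = False
    n_iter = 0

    for it in range(1, max_iter + 1):
        n_iter = it
        cis = test_cis_associations(matA, matB, candidates, matched, alpha=alpha, min_n=min_n)
        S = similarity_matrix(matA, matB, cis, min_overlap=min_overlap)
        if matcher == "rank":
            result = modmatcher_align(S)
        else:
            result = promodmatcher_align(
                S, config, matA, matB, cis, matched=matched, min_overlap=min_overlap
            )
        result.table["iteration"] = it
        state = result.status_key()
        summ = result.summary()
        history.append(
            {
                "iteration": it,
                "n_cis_significant": cis.n_significant,
                "self_aligned": summ["self_aligned"],
                "cross_aligned": summ["cross_aligned"],
            }
        )
        logger.info(
            "iteration %d: %d significant cis pairs, %d self-aligned, %d cross-aligned",
            it, cis.n_significant, summ["self_aligned"], summ["cross_aligned"],
        )
        if state == prev_state:
            converged = True
            break
        prev_state = state
        new_matched = result.aligned_pairs()
        if len(new_matched) < min_n:
            logger.warning("fewer than %d aligned pairs; stopping", min_n)
            break
        matched = new_matched

    result.converged = converged
    result.data_type_a = matA.data_type
    result.data_type_b = matB.data_type
    return IterationOutcome(result=result, cis=cis, n_iterations=n_iter, converged=converged, history=history)
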