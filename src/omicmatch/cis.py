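"""Candidate cis feature pairs and significant cis-associations.

A cis-association is a statistical dependence between two omics
features at the same locus (SNP-transcript, methylation
probe-transcript, CNV segment-transcript, miRNA-host gene, protein-its
mRNA).  The set of significant cis-associations acts as an intrinsic
per-sample barcode: candidate pairs are built from genomic proximity or
explicit biological maps, then tested by Spearman correlation with
Benjamini-Hochberg control over all tested pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicAnnotation, OmicsMatrix

__all__ = [
    "CisCandidateMap",
    "CisAssociationSet",
    "map_candidates_by_proximity",
    "map_candidates_by_identity",
    "test_cis_associations",
    "bh_adjust",
    "spearman_rho_p",
]


@dataclass
class CisCandidateMap:
    """Unique candidate (featureA, featureB) pairs plus their provenance."""

    pairs: list[tuple[str, str]]
    provenance: str = "explicit"

    def __post_init__(self):
        seen = set()
        uniq = []
        for p in self.pairs:
            p = (str(p[0]), str(p[1]))
            if p not in seen:
                seen.add(p)
                uniq.append(p)
        self.pairs = uniq

    def __len__(self):
        return len(self.pairs)


@dataclass
class CisAssociationSet:
    """Spearman test results for candidate pairs, with BH q-values.

    ``table`` columns: feature_a, feature_b, rho, p, q, n_used,
    significant.  ``dropped`` records pairs that could not be tested
    and why (zero variance, insufficient overlap, unknown feature).
    """

    table: pd.DataFrame
    alpha: float = 0.05
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["feature_a", "feature_b", "reason"]))

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.table[self.table["significant"]]
        return list(zip(sig["feature_a"], sig["feature_b"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _check_chrom_conventions(chromsA: set[str], chromsB: set[str]) -> None:
    if chromsA & chromsB:
        return
    strip = lambda cs: {c[3:] if c.lower().startswith("chr") else c for c in cs}
    if strip(chromsA) & strip(chromsB):
        raise ValueError(
            "chromosome naming conventions differ between the two annotations "
            "(e.g. 'chr1' vs '1'); harmonize them explicitly before mapping"
        )


def map_candidates_by_proximity(
    annotA: GenomicAnnotation,
    annotB: GenomicAnnotation,
    window_bp: int = 1_000_000,
    mode: str = "window",
) -> CisCandidateMap:
    """Pair features of two data types by genomic proximity.

    ``mode="window"`` pairs every same-chromosome feature pair within
    ``window_bp`` (inclusive) of each other; ``mode="nearest_tss"``
    assigns each A feature only to the B feature with the nearest
    position, still subject to the window, with distance ties broken
    toward the lexicographically smaller B feature id.
    """
    if len(annotA) == 0 or len(annotB) == 0:
        raise ValueError("annotations must be non-empty")
    if mode not in ("window", "nearest_tss"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_chrom_conventions(annotA.chromosomes, annotB.chromosomes)
    dfA, dfB = annotA.table, annotB.table
    pairs: list[tuple[str, str]] = []
    for chrom, ga in dfA.groupby("chrom"):
        gb = dfB[dfB["chrom"] == chrom]
        if gb.empty:
            continue
        gb = gb.sort_values(["position", "feature_id"], kind="stable")
        posB = gb["position"].to_numpy()
        idsB = gb["feature_id"].to_numpy()
        for fa, pa in zip(ga["feature_id"], ga["position"]):
            lo = np.searchsorted(posB, pa - window_bp, side="left")
            hi = np.searchsorted(posB, pa + window_bp, side="right")
            if lo >= hi:
                continue
            if mode == "window":
                pairs.extend((fa, fb) for fb in idsB[lo:hi])
            else:
                cand = np.arange(lo, hi)
                dist = np.abs(posB[cand] - pa)
                dmin = dist.min()
                tied = idsB[cand[dist == dmin]]
                pairs.append((fa, min(tied)))
    return CisCandidateMap(pairs, provenance="proximity" if mode == "window" else "nearest_tss")


def map_candidates_by_identity(
    id_map: list[tuple[str, str]] | pd.DataFrame,
    featA_ids=None,
    featB_ids=None,
    provenance: str = "explicit",
) -> tuple[CisCandidateMap, list[tuple[str, str, str]]]:
    """Build a candidate map from an explicit two-column pair table.

    Covers biology-driven one-to-one maps (miRNA to host gene, protein
    to its mRNA).  If feature-id universes are given, unresolvable rows
    are skipped and reported as ``(featureA, featureB, reason)``
    triples rather than raising.
    """
    if isinstance(id_map, pd.DataFrame):
        rows = [(str(a), str(b)) for a, b in zip(id_map.iloc[:, 0], id_map.iloc[:, 1])]
    else:
        rows = [(str(a), str(b)) for a, b in id_map]
    skipped: list[tuple[str, str, str]] = []
    kept: list[tuple[str, str]] = []
    setA = set(map(str, featA_ids)) if featA_ids is not None else None
    setB = set(map(str, featB_ids)) if featB_ids is not None else None
    for a, b in rows:
        if setA is not None and a not in setA:
            skipped.append((a, b, "unknown A feature"))
        elif setB is not None and b not in setB:
            skipped.append((a, b, "unknown B feature"))
        else:
            kept.append((a, b))
    return CisCandidateMap(kept, provenance=provenance), skipped


# ---------------------------------------------------------------------------
# Spearman machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _exact_null_rho(n: int) -> np.ndarray:
    """Null distribution of Spearman rho over all n! rank permutations."""
    base = np.arange(1, n + 1, dtype=float)
    c = base - base.mean()
    denom = float(c @ c)
    vals = [float(c @ (np.asarray(p, dtype=float) - base.mean())) / denom
            for p in itertools.permutations(base)]
    return np.sort(np.asarray(vals))


def spearman_rho_p(x: np.ndarray, y: np.ndarray, exact_below: int = 10) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Uses the t-approximation for ``n >= exact_below``; below that, the
    exact permutation null is enumerated when both vectors are
    tie-free (with ties the t-approximation is used throughout).
    """
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _pearson(rx, ry)
    if math.isnan(rho):
        return float("nan"), float("nan")
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n < exact_below and not ties and n >= 3:
        null = _exact_null_rho(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return float(rho), p
    return float(rho), _t_pvalue(np.asarray([rho]), n)[0]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = math.sqrt(float(a @ a) * float(b @ b))
    if den == 0:
        return float("nan")
    return float(a @ b) / den


def _t_pvalue(rho: np.ndarray, n) -> np.ndarray:
    """Two-sided p for Spearman rho via the t-approximation, df = n - 2."""
    n = np.asarray(n, dtype=float)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    return np.minimum(p, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.asarray([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_cis_associations(
    matA: OmicsMatrix,
    matB: OmicsMatrix,
    candidates: CisCandidateMap,
    matched_sample_pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    min_n: int = 10,
) -> CisAssociationSet:
    """Test candidate cis pairs by Spearman correlation over matched samples.

    For each candidate pair the correlation is computed over
    pairwise-complete matched samples; pairs with fewer than ``min_n``
    usable samples or a constant vector are dropped with a reason.  BH
    adjustment runs over all tested pairs and ``significant`` means
    ``q < alpha``.
    """
    if not matched_sample_pairs:
        raise ValueError("matched_sample_pairs must be non-empty")
    if len(candidates) == 0:
        raise ValueError("candidate map is empty")
    if len(matched_sample_pairs) < min_n:
        raise ValueError(
            f"only {len(matched_sample_pairs)} matched samples; need at least min_n={min_n}"
        )
    colA = [matA.sample_index(a) for a, _ in matched_sample_pairs]
    colB = [matB.sample_index(b) for _, b in matched_sample_pairs]
    n_m = len(colA)

    rows = []
    dropped = []
    testable: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    for fa, fb in candidates.pairs:
        if not matA.has_feature(fa):
            dropped.append((fa, fb, "unknown A feature"))
            continue
        if not matB.has_feature(fb):
            dropped.append((fa, fb, "unknown B feature"))
            continue
        x = matA.values[matA.feature_index(fa)][colA]
        y = matB.values[matB.feature_index(fb)][colB]
        ok = ~(np.isnan(x) | np.isnan(y))
        n_used = int(ok.sum())
        if n_used < min_n:
            dropped.append((fa, fb, "insufficient overlap"))
            continue
        xv, yv = x[ok], y[ok]
        if np.all(xv == xv[0]) or np.all(yv == yv[0]):
            dropped.append((fa, fb, "zero variance"))
            continue
        testable.append((fa, fb, xv, yv))

    if testable and all(t[2].size == n_m for t in testable) and n_m >= 10:
        # fast path: no missingness anywhere, vectorize ranks + Pearson
        X = np.vstack([t[2] for t in testable])
        Y = np.vstack([t[3] for t in testable])
        rX = stats.rankdata(X, axis=1)
        rY = stats.rankdata(Y, axis=1)
        rX -= rX.mean(axis=1, keepdims=True)
        rY -= rY.mean(axis=1, keepdims=True)
        den = np.sqrt((rX**2).sum(axis=1) * (rY**2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            rho = (rX * rY).sum(axis=1) / den
        pvals = _t_pvalue(rho, n_m)
        for (fa, fb, _, _), r, p in zip(testable, rho, pvals):
            rows.append((fa, fb, float(r), float(p), n_m))
    else:
        for fa, fb, xv, yv in testable:
            r, p = spearman_rho_p(xv, yv)
            rows.append((fa, fb, r, p, xv.size))

    table = pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho", "p", "n_used"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["q"] < alpha
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    table = table[["feature_a", "feature_b", "rho", "p", "q", "n_used", "significant"]]
    dropped_df = pd.DataFrame(dropped, columns=["feature_a", "feature_b", "reason"])
    return CisAssociationSet(table=table, alpha=alpha, dropped=dropped_df)
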