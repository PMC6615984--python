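"""Patient-centric integration of pairwise alignments and error-source calls.

Pairwise alignments say that two profiles do or do not belong to the
same individual; they cannot by themselves say which data type carries
a labeling error.  Collecting all pairwise outcomes into a graph with
one node per (patient, data type) localizes the error: a swap of two
patients' profiles within data type T shows up as reciprocal cross
edges from the T profiles to the other patient's profiles, while the
remaining data types of both patients stay mutually self-aligned.  A
single mislabeled profile cross-aligns away without any reciprocal
partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import OmicsMatrix
from .results import CROSS_ALIGNED, SELF_ALIGNED, AlignmentResult

__all__ = [
    "PatientAlignmentGraph",
    "build_patient_view",
    "infer_error_source",
    "apply_correction",
    "correction_gain",
]

CORRECT = "correct"
MISLABELED = "mislabeled"
SWAPPED = "swapped_with"
UNRESOLVED = "unresolved"


@dataclass
class PatientAlignmentGraph:
    """Graph over (patient_id, data_type) nodes with alignment-status edges."""

    graph: nx.Graph
    verdicts: dict = field(default_factory=dict)

    def nodes(self):
        return list(self.graph.nodes)

    def edges_table(self) -> pd.DataFrame:
        rows = [
            (a[0], a[1], b[0], b[1], d["status"], d.get("score"))
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["patient_a", "type_a", "patient_b", "type_b", "status", "score"])

    def verdicts_table(self) -> pd.DataFrame:
        rows = []
        for (pat, dt), v in sorted(self.verdicts.items()):
            if isinstance(v, tuple) and v[0] == SWAPPED:
                rows.append((pat, dt, SWAPPED, v[1][0], v[2]))
            elif isinstance(v, tuple):
                rows.append((pat, dt, v[0], v[1] if v[1] else "", v[2] if len(v) > 2 else 0))
            else:
                rows.append((pat, dt, v, "", 0))
        return pd.DataFrame(rows, columns=["patient", "data_type", "verdict", "partner", "evidence"])

    def to_dot(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("graph patient_view {\n")
            for a, b, d in self.graph.edges(data=True):
                color = {"self": "red", "cross": "blue"}.get(d["status"], "gray")
                fh.write(f'  "{a[0]}|{a[1]}" -- "{b[0]}|{b[1]}" [color={color}];\n')
            fh.write("}\n")


def build_patient_view(results: list[AlignmentResult]) -> PatientAlignmentGraph:
    """Merge pairwise alignment results into one patient-centric graph.

    Each result must carry ``data_type_a``/``data_type_b`` labels.
    Self edges connect the two data-type nodes of one patient; cross
    edges connect the aligned partner nodes; unaligned candidate pairs
    are kept as ``unaligned`` edges (absence of evidence is itself
    informative).
    """
    g = nx.Graph()
    for res in results:
        ta, tb = res.data_type_a, res.data_type_b
        if not ta or not tb:
            raise ValueError("alignment results need data_type_a/data_type_b labels")
        for _, row in res.table.iterrows():
            status = {SELF_ALIGNED: "self", CROSS_ALIGNED: "cross"}.get(row["status"], "unaligned")
            u = (row["sample_a"], ta)
            v = (row["sample_b"], tb)
            if g.has_edge(u, v):
                if g.edges[u, v]["status"] != status:
                    raise ValueError(f"conflicting duplicate edge between {u} and {v}")
                continue
            g.add_edge(u, v, status=status, score=row.get("score"))
    return PatientAlignmentGraph(graph=g)


def _cross_partners(g: nx.Graph, node):
    return [(nbr, d) for nbr, d in g.adj[node].items() if d["status"] == "cross"]


def _has_self_edge(g: nx.Graph, node) -> bool:
    return any(d["status"] == "self" for _, d in g.adj[node].items())


def _non_t_consistent(g: nx.Graph, patient, t_exclude) -> bool:
    """All edges among the patient's non-T profiles are self, and at
    least one such corroborating self edge exists."""
    own = [n for n in g.nodes if n[0] == patient and n[1] != t_exclude]
    n_self = 0
    for k, u in enumerate(own):
        for v in own[k + 1 :]:
            if g.has_edge(u, v):
                if g.edges[u, v]["status"] != "self":
                    return False
                n_self += 1
    return n_self >= 1


def infer_error_source(view: PatientAlignmentGraph, min_support: int = 1) -> dict:
    """Classify each profile node as correct / mislabeled / swapped / unresolved.

    A swap of data type T between patients i and j needs reciprocal
    cross edges (i,T)<->(j,T') and (j,T)<->(i,T') for at least
    ``min_support`` data types T', plus self-consistency of both
    patients' remaining profiles.  A single profile is mislabeled when
    it cross-aligns away with no reciprocal pattern while its patient's
    other profiles agree with each other.  Everything ambiguous falls
    into the safe ``unresolved`` sink.
    """
    g = view.graph
    verdicts: dict = {}

    # swap candidates
    cross_nodes = [n for n in g.nodes if _cross_partners(g, n)]
    for node in cross_nodes:
        if node in verdicts:
            continue
        pat_i, t = node
        if _has_self_edge(g, node):
            # a profile corroborated by any self-alignment is not the swapped one
            continue
        # opposite patients this T profile points to
        partners = {nbr[0] for nbr, _ in _cross_partners(g, node)}
        for pat_j in partners:
            other = (pat_j, t)
            if other not in g.nodes or _has_self_edge(g, other):
                continue
            support = 0
            for t_prime in {n[1] for n in g.nodes} - {t}:
                fwd = g.has_edge(node, (pat_j, t_prime)) and g.edges[node, (pat_j, t_prime)]["status"] == "cross"
                rev = g.has_edge(other, (pat_i, t_prime)) and g.edges[other, (pat_i, t_prime)]["status"] == "cross"
                if fwd and rev:
                    support += 1
            if support >= min_support and _non_t_consistent(g, pat_i, t) and _non_t_consistent(g, pat_j, t):
                verdicts[node] = (SWAPPED, other, support)
                verdicts[other] = (SWAPPED, node, support)
                break

    # single-profile mislabelings
    for node in cross_nodes:
        if node in verdicts:
            continue
        pat_i, t = node
        partners = _cross_partners(g, node)
        # reciprocal pattern would have been claimed as a swap above; require none
        reciprocal = any(
            _cross_partners(g, (nbr[0], t)) for nbr, _ in partners if (nbr[0], t) in g.nodes
        )
        if reciprocal or _has_self_edge(g, node):
            verdicts[node] = (UNRESOLVED, None, 0)
            continue
        if not _non_t_consistent(g, pat_i, t):
            verdicts[node] = (UNRESOLVED, None, 0)
            continue
        target_patients = {nbr[0] for nbr, _ in partners}
        partner = target_patients.pop() if len(target_patients) == 1 else None
        verdicts[node] = (MISLABELED, (partner, t) if partner else None, len(partners))

    # everything else
    for node in g.nodes:
        if node in verdicts:
            continue
        statuses = {d["status"] for _, d in g.adj[node].items()}
        if statuses <= {"self"} and statuses:
            verdicts[node] = (CORRECT, None, len(g.adj[node]))
        elif not statuses:
            verdicts[node] = (UNRESOLVED, None, 0)
        else:
            # touched by unaligned or cross evidence it cannot explain
            verdicts[node] = (UNRESOLVED, None, 0)

    view.verdicts = verdicts
    return verdicts


def apply_correction(
    matrices: dict[str, OmicsMatrix],
    verdicts: dict,
    apply_swaps: bool = True,
    apply_mislabels: bool = True,
) -> tuple[dict[str, OmicsMatrix], list[dict]]:
    """Apply swap/mislabel corrections to the implicated matrices.

    Swap verdicts exchange the two sample columns within the implicated
    data type; mislabeled profiles are relabeled to the inferred
    partner when unambiguous, else dropped.  Unresolved profiles are
    never touched.  Relabeling is all-or-nothing per data type: a
    collision with an existing label aborts that data type's
    corrections with an error.
    """
    out = {t: m.copy() for t, m in matrices.items()}
    log: list[dict] = []

    if apply_swaps:
        done: set[frozenset] = set()
        for node, v in verdicts.items():
            if not (isinstance(v, tuple) and v[0] == SWAPPED):
                continue
            (pat_i, t) = node
            (pat_j, t2) = v[1]
            if t != t2:
                continue
            key = frozenset([node, v[1]])
            if key in done:
                continue
            done.add(key)
            m = out.get(t)
            if m is None or not (m.has_sample(pat_i) and m.has_sample(pat_j)):
                continue
            ci, cj = m.sample_index(pat_i), m.sample_index(pat_j)
            m.values[:, [ci, cj]] = m.values[:, [cj, ci]]
            log.append({"action": "swap", "data_type": t, "samples": (pat_i, pat_j)})

    if apply_mislabels:
        # validate all relabels per data type before applying any
        per_type: dict[str, list] = {}
        for node, v in verdicts.items():
            if isinstance(v, tuple) and v[0] == MISLABELED:
                per_type.setdefault(node[1], []).append((node, v[1]))
        for t, items in per_type.items():
            m = out.get(t)
            if m is None:
                continue
            relabels = {}
            drops = []
            for (pat, _), partner in items:
                if not m.has_sample(pat):
                    continue
                if partner is None:
                    drops.append(pat)
                else:
                    relabels[pat] = partner[0]
            for old, new in relabels.items():
                if m.has_sample(new) or new in relabels.values() and list(relabels.values()).count(new) > 1:
                    raise ValueError(
                        f"relabel target collision in data type {t!r}: {old} -> {new}; nothing applied"
                    )
            ids = [relabels.get(s, s) for s in m.sample_ids]
            m2 = OmicsMatrix(m.values, m.feature_ids, ids, m.data_type)
            if drops:
                keep = [s for s in m2.sample_ids if s not in drops]
                m2 = m2.subset_samples(keep)
            out[t] = m2
            for old, new in relabels.items():
                log.append({"action": "relabel", "data_type": t, "old": old, "new": new})
            for s in drops:
                log.append({"action": "drop", "data_type": t, "sample": s})

    return out, log


def correction_gain(
    matA: OmicsMatrix,
    matB: OmicsMatrix,
    cis_pairs,
    pairs_before: list[tuple[str, str]],
    pairs_after: list[tuple[str, str]],
    n_resample: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cis-pair correlation before vs after label correction.

    The "after" correlation uses the aligned pairs; the "before"
    correlation is the mean over ``n_resample`` random subsets of the
    initially matched pairs of the same size, removing the sample-size
    advantage of the larger initial set.
    """
    from .cis import spearman_rho_p

    if n_resample < 1:
        raise ValueError("n_resample must be >= 1")
    if len(pairs_after) > len(pairs_before):
        raise ValueError("pairs_after cannot exceed pairs_before")
    rng = np.random.default_rng(seed)
    pairs = cis_pairs.pairs if hasattr(cis_pairs, "pairs") else list(cis_pairs)
    n_after = len(pairs_after)

    def _cols(pair_list):
        ia = [matA.sample_index(a) for a, _ in pair_list]
        ib = [matB.sample_index(b) for _, b in pair_list]
        return ia, ib

    ia_after, ib_after = _cols(pairs_after)
    subsets = [rng.choice(len(pairs_before), size=n_after, replace=False) for _ in range(n_resample)]

    rows = []
    for fa, fb in pairs:
        if not (matA.has_feature(fa) and matB.has_feature(fb)):
            continue
        xa = matA.feature_row(fa)
        xb = matB.feature_row(fb)
        x_after = xa[ia_after]
        y_after = xb[ib_after]
        ok = ~(np.isnan(x_after) | np.isnan(y_after))
        rho_after, _ = spearman_rho_p(x_after[ok], y_after[ok]) if ok.sum() >= 3 else (np.nan, np.nan)
        accs = []
        for idx in subsets:
            sub = [pairs_before[k] for k in idx]
            ia, ib = _cols(sub)
            x = xa[ia]
            y = xb[ib]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() >= 3:
                r, _ = spearman_rho_p(x[ok], y[ok])
                accs.append(r)
        rho_before = float(np.nanmean(accs)) if accs else np.nan
        rows.append((fa, fb, rho_before, rho_after, rho_after - rho_before))
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho_before_mean", "rho_after", "gain"])
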