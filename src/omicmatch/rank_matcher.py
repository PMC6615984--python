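"""Rank-based matcher: top-k self-alignment plus reciprocal-best cross-alignment.

A candidate self pair (same annotated sample ID in both data types) is
confirmed when its similarity score ranks within the top 5% of both its
row and its column (top 20 when the respective dimension exceeds 400
samples).  Profiles left over are then cross-aligned when a score is
the unique maximum of both its row and its column — reciprocal-best
evidence that two differently-labeled profiles share an individual.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .results import CROSS_ALIGNED, SELF_ALIGNED, UNALIGNED, AlignmentResult
from .similarity import SimilarityMatrix

__all__ = ["modmatcher_align", "top_k_threshold"]


def top_k_threshold(n: int) -> int:
    """Self-alignment rank threshold: ceil(5% of n), capped at 20 for n > 400."""
    return math.ceil(0.05 * n) if n <= 400 else 20


def _best_tied_rank(vec: np.ndarray, value: float) -> int:
    """1 + number of entries strictly greater (ties share the best rank)."""
    return 1 + int(np.sum(vec[~np.isnan(vec)] > value))


def modmatcher_align(S: SimilarityMatrix) -> AlignmentResult:
    """Two-phase rank alignment of a similarity matrix.

    Returns one row per candidate self pair (IDs present in both data
    types) plus one row per cross-aligned pair found among the
    leftovers.
    """
    n_a, n_b = S.shape
    if n_a < 2 or n_b < 2:
        raise ValueError("similarity matrix must be at least 2 x 2")
    k_row = top_k_threshold(n_b)
    k_col = top_k_threshold(n_a)
    col_pos = {s: j for j, s in enumerate(S.col_ids)}
    candidates = [(i, col_pos[s]) for i, s in enumerate(S.row_ids) if s in col_pos]

    rows = []
    self_rows: set[int] = set()
    self_cols: set[int] = set()
    for i, j in candidates:
        s = S.scores[i, j]
        if np.isnan(s):
            rows.append((S.row_ids[i], S.col_ids[j], UNALIGNED, np.nan, np.nan, np.nan, np.nan, 0, "undefined score"))
            continue
        r_row = _best_tied_rank(S.scores[i, :], s)
        r_col = _best_tied_rank(S.scores[:, j], s)
        if r_row <= k_row and r_col <= k_col:
            rows.append((S.row_ids[i], S.col_ids[j], SELF_ALIGNED, s, np.nan, r_row, r_col, 0, ""))
            self_rows.add(i)
            self_cols.add(j)
        else:
            rows.append((S.row_ids[i], S.col_ids[j], UNALIGNED, s, np.nan, r_row, r_col, 0, "below top-k"))

    # reciprocal-best cross-alignment among the unaligned leftovers
    free_rows = [i for i in range(n_a) if i not in self_rows]
    free_cols = [j for j in range(n_b) if j not in self_cols]
    with np.errstate(invalid="ignore"):
        row_max = np.nanmax(np.where(np.isnan(S.scores), -np.inf, S.scores), axis=1)
        col_max = np.nanmax(np.where(np.isnan(S.scores), -np.inf, S.scores), axis=0)
    cross = []
    for i in free_rows:
        for j in free_cols:
            s = S.scores[i, j]
            if np.isnan(s) or S.row_ids[i] == S.col_ids[j]:
                continue
            if s >= row_max[i] and s >= col_max[j]:
                # require uniqueness of the maximum in both directions
                if np.sum(S.scores[i, :] == s) == 1 and np.sum(S.scores[:, j] == s) == 1:
                    cross.append((i, j, s))
    used_a: set[int] = set()
    used_b: set[int] = set()
    for i, j, s in sorted(cross, key=lambda t: -t[2]):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        rows.append((S.row_ids[i], S.col_ids[j], CROSS_ALIGNED, s, np.nan, 1, 1, 0, ""))

    table = pd.DataFrame(
        rows,
        columns=["sample_a", "sample_b", "status", "score", "p_value", "rank_row", "rank_col", "iteration", "reason"],
    )
    return AlignmentResult(table=table, method="rank")
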