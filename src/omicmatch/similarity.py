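"""Normal rank transformation and the profile-similarity score matrix.

Each significant cis feature is rank-transformed to a standard-normal
scale, which removes platform-specific dynamic ranges; the similarity
between sample i of data type A and sample j of data type B is then the
Pearson correlation between the two length-N transformed cis-feature
vectors.  Matched samples produce high scores, unrelated samples
scores near zero, so the matrix acts as an intrinsic barcode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .cis import CisAssociationSet
from .core import OmicsMatrix

__all__ = ["SimilarityMatrix", "normal_rank_transform", "similarity_matrix", "pairwise_pearson"]


@dataclass
class SimilarityMatrix:
    """N_A x N_B profile-pair similarity scores over significant cis pairs.

    Undefined entries (fewer than ``min_overlap`` pairwise-complete cis
    features, or a zero-variance column) are ``NaN`` and flagged in
    ``undefined``.
    """

    scores: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    n_cis: int

    @property
    def undefined(self) -> np.ndarray:
        return np.isnan(self.scores)

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def row_index(self, sample_id: str) -> int:
        return self.row_ids.index(sample_id)

    def col_index(self, sample_id: str) -> int:
        return self.col_ids.index(sample_id)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.scores, index=self.row_ids, columns=self.col_ids).to_csv(path, sep="\t")


def normal_rank_transform(v: np.ndarray) -> np.ndarray:
    """Map a vector to standard-normal scores by rank.

    Non-missing entries become ``Phi^-1((rank - 0.5)/n)`` with average
    ranks for ties (n = non-missing count); missing entries stay
    missing.  A constant vector maps to all zeros.
    """
    v = np.asarray(v, dtype=float)
    out = np.full(v.shape, np.nan)
    obs = ~np.isnan(v)
    n = int(obs.sum())
    if n < 2:
        raise ValueError("normal rank transform needs at least 2 non-missing values")
    ranks = rankdata(v[obs], method="average")
    out[obs] = norm.ppf((ranks - 0.5) / n)
    return out


def _rank_transform_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise normal rank transform of a features x samples block."""
    out = np.empty_like(X)
    if not np.isnan(X).any():
        n = X.shape[1]
        ranks = rankdata(X, axis=1, method="average")
        out[:] = norm.ppf((ranks - 0.5) / n)
        return out
    for i in range(X.shape[0]):
        out[i] = normal_rank_transform(X[i])
    return out


def pairwise_pearson(X: np.ndarray, Y: np.ndarray, min_overlap: int = 1) -> np.ndarray:
    """Column-by-column Pearson correlation with pairwise-complete rows.

    ``X`` is N x p, ``Y`` is N x q; returns the p x q correlation matrix
    between columns, using for each column pair only the rows where both
    values are present.  Entries with fewer than ``min_overlap``
    complete rows, or zero variance over the overlap, are ``NaN``.
    """
    MX = ~np.isnan(X)
    MY = ~np.isnan(Y)
    X0 = np.nan_to_num(X)
    Y0 = np.nan_to_num(Y)
    n = MX.T.astype(float) @ MY.astype(float)
    sx = X0.T @ MY
    sy = MX.T.astype(float) @ Y0
    sxx = (X0**2).T @ MY
    syy = MX.T.astype(float) @ (Y0**2)
    sxy = X0.T @ Y0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        S = cov / np.sqrt(vx * vy)
    S[(n < min_overlap) | (vx <= 0) | (vy <= 0)] = np.nan
    return np.clip(S, -1.0, 1.0, out=S)


def build_transformed_cis_blocks(
    matA: OmicsMatrix, matB: OmicsMatrix, cis: CisAssociationSet
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-transformed N x samples blocks for the significant cis pairs.

    Row n of each block holds the transformed values of the A-side
    (resp. B-side) feature of the n-th significant pair; features that
    participate in several pairs are transformed once and reused.  The
    B-side row is multiplied by the sign of the pair's cis correlation,
    so that anti-correlated associations (methylation-expression and
    negative-effect loci) contribute signal rather than canceling
    positively-correlated pairs.  The transform is taken over all
    samples of each matrix so that samples outside the matched set
    remain scoreable.
    """
    sig = cis.table[cis.table["significant"]]
    if sig.empty:
        raise ValueError("no intrinsic barcode: zero significant cis pairs")
    pairs = list(zip(sig["feature_a"], sig["feature_b"]))
    signs = np.where(sig["rho"].to_numpy() < 0, -1.0, 1.0)
    featsA = sorted({a for a, _ in pairs})
    featsB = sorted({b for _, b in pairs})
    rtA = _rank_transform_rows(matA.values[[matA.feature_index(f) for f in featsA]])
    rtB = _rank_transform_rows(matB.values[[matB.feature_index(f) for f in featsB]])
    ia = {f: i for i, f in enumerate(featsA)}
    ib = {f: i for i, f in enumerate(featsB)}
    A = rtA[[ia[a] for a, _ in pairs]]
    B = rtB[[ib[b] for _, b in pairs]] * signs[:, None]
    return A, B


def default_min_overlap(n_cis: int) -> int:
    """Guard against non-random missingness: max(10, half the cis pairs)."""
    return max(10, math.ceil(0.5 * n_cis))


def similarity_matrix(
    matA: OmicsMatrix,
    matB: OmicsMatrix,
    cis: CisAssociationSet,
    min_overlap: int | None = None,
) -> SimilarityMatrix:
    """Profile-similarity scores S(A_i, B_j) over significant cis pairs.

    S(A_i, B_j) is the Pearson correlation between the normal
    rank-transformed cis-feature vector of sample i (A side) and of
    sample j (B side), over pairwise-complete cis features.
    """
    A, B = build_transformed_cis_blocks(matA, matB, cis)
    n_cis = A.shape[0]
    if min_overlap is None:
        min_overlap = default_min_overlap(n_cis)
    S = pairwise_pearson(A, B, min_overlap=min_overlap)
    return SimilarityMatrix(S, list(matA.sample_ids), list(matB.sample_ids), n_cis)
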