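"""Preprocessing filters and normalization for profile matrices.

The filters mirror the standard curation steps applied to consortium
level-3 data before identity matching: drop features measured in too
few samples (missingness is never imputed), log-transform and quantile
normalize expression-like data, and drop features whose values carry
essentially no information (near-monomorphic genotypes, constant
continuous features).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

from .core import OmicsMatrix

__all__ = [
    "filter_missing_features",
    "log2_quantile_normalize",
    "quantile_normalize",
    "filter_low_information",
]


def filter_missing_features(m: OmicsMatrix, max_missing_fraction: float = 0.25) -> OmicsMatrix:
    """Drop features missing in more than ``max_missing_fraction`` of samples.

    The boundary is strict: a feature missing in exactly the threshold
    fraction is retained.  Idempotent.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = np.mean(np.isnan(m.values), axis=1)
    keep = frac <= max_missing_fraction
    if not keep.any():
        warnings.warn("all features removed by missingness filter", stacklevel=2)
    return m.subset_features(keep)


def quantile_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Quantile-normalize samples (columns) to a common reference distribution.

    The reference is the across-sample mean of the per-sample sorted
    values; when non-missing counts differ between samples the sorted
    values are interpolated onto a common quantile grid first.  Tied
    values within a sample receive the mean of the reference values
    over the rank span they occupy, so the transform is monotone within
    each column.  Missing entries are excluded and stay missing.
    """
    X = m.values
    n_feat, n_samp = X.shape
    obs = ~np.isnan(X)
    n_obs = obs.sum(axis=0)
    if (n_obs < 1).any():
        raise ValueError("every sample needs at least one non-missing value")
    grid = (np.arange(n_feat) + 0.5) / n_feat
    # reference quantile function on the common grid
    acc = np.zeros(n_feat)
    for j in range(n_samp):
        col = np.sort(X[obs[:, j], j])
        k = col.size
        if k == n_feat:
            acc += col
        else:
            p = (np.arange(k) + 0.5) / k
            acc += np.interp(grid, p, col)
    ref = acc / n_samp

    out = np.full_like(X, np.nan)
    for j in range(n_samp):
        idx = np.flatnonzero(obs[:, j])
        col = X[idx, j]
        k = col.size
        order = np.argsort(col, kind="stable")
        slot_p = (np.arange(k) + 0.5) / k
        slot_vals = ref if k == n_feat else np.interp(slot_p, grid, ref)
        assigned = np.empty(k)
        assigned[order] = slot_vals
        # ties: mean of the reference values over the tied rank span
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < k:
            sums = np.bincount(inv, weights=assigned)
            cnts = np.bincount(inv)
            assigned = (sums / cnts)[inv]
        out[idx, j] = assigned
    return m.with_values(out)


def log2_quantile_normalize(m: OmicsMatrix, pseudocount: float = 1.0, apply_log: bool = True) -> OmicsMatrix:
    """``log2(value + pseudocount)`` then quantile normalization.

    Use ``pseudocount=1`` for count-like data; set ``apply_log=False``
    for data that is already on a log scale.
    """
    X = m.values
    if apply_log:
        with np.errstate(invalid="ignore"):
            if np.nanmin(X + pseudocount) < 0:
                raise ValueError("negative values under log2; disable the log step or add a pseudocount")
        X = np.log2(X + pseudocount)
    return quantile_normalize(m.with_values(X))


def filter_low_information(m: OmicsMatrix, kind: str = "continuous", maf_min: float = 0.05) -> OmicsMatrix:
    """Drop features that carry almost no information.

    For ``kind="genotype"`` values must be allele dosages in {0,1,2}
    (missing allowed); loci with minor allele frequency <= ``maf_min``
    are removed — rare variants behave as constants and would let a
    handful of samples dominate the match.  For ``kind="continuous"``,
    zero-variance features are removed.
    """
    X = m.values
    if kind == "genotype":
        finite = X[~np.isnan(X)]
        if not np.all(np.isin(finite, [0.0, 1.0, 2.0])):
            raise ValueError("genotype matrices must contain dosages 0/1/2 (or missing)")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(X, axis=1) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        keep = maf > maf_min
    elif kind == "continuous":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            var = np.nanvar(X, axis=1)
        keep = var > 0
        keep &= ~np.isnan(var)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return m.subset_features(keep)
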