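"""Core containers: omics profile matrices and genomic feature annotations.

An :class:`OmicsMatrix` holds one data type (expression, methylation,
CNV, miRNA, protein, genotype ...) as a features x samples matrix of
floats.  Missing measurements are stored as ``NaN``; the boolean missing
mask is derived from that, so there is a single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicsMatrix", "GenomicAnnotation"]


def _find_duplicates(ids) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class OmicsMatrix:
    """Features x samples profile matrix for one omics data type.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_features, n_samples)``.  ``NaN``
        marks missing measurements.
    feature_ids, sample_ids
        Unique row / column identifiers.
    data_type
        Free-text label (e.g. ``"RNAseq"``, ``"miRNA"``); used when
        integrating alignment results across data types.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    data_type: str = ""
    _fidx: dict = field(default=None, repr=False, compare=False)
    _sidx: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        dupf = _find_duplicates(self.feature_ids)
        if dupf:
            raise ValueError(f"duplicate feature IDs: {dupf}")
        dups = _find_duplicates(self.sample_ids)
        if dups:
            raise ValueError(f"duplicate sample IDs: {dups}")
        self._fidx = {f: i for i, f in enumerate(self.feature_ids)}
        self._sidx = {s: j for j, s in enumerate(self.sample_ids)}

    # -- basic geometry -------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the measurement is missing."""
        return np.isnan(self.values)

    # -- lookups --------------------------------------------------------
    def feature_index(self, feature_id: str) -> int:
        return self._fidx[feature_id]

    def sample_index(self, sample_id: str) -> int:
        return self._sidx[sample_id]

    def has_feature(self, feature_id: str) -> bool:
        return feature_id in self._fidx

    def has_sample(self, sample_id: str) -> bool:
        return sample_id in self._sidx

    def feature_row(self, feature_id: str) -> np.ndarray:
        return self.values[self._fidx[feature_id]]

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self._sidx[sample_id]]

    # -- derivation -----------------------------------------------------
    def with_values(self, values: np.ndarray) -> "OmicsMatrix":
        return OmicsMatrix(values, list(self.feature_ids), list(self.sample_ids), self.data_type)

    def subset_features(self, keep: np.ndarray) -> "OmicsMatrix":
        """Return a copy restricted to the boolean/index row selection."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        feats = [self.feature_ids[i] for i in idx]
        return OmicsMatrix(self.values[idx].copy(), feats, list(self.sample_ids), self.data_type)

    def subset_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        idx = [self._sidx[s] for s in sample_ids]
        return OmicsMatrix(self.values[:, idx].copy(), list(self.feature_ids), list(sample_ids), self.data_type)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.values.copy(), list(self.feature_ids), list(self.sample_ids), self.data_type)

    # -- pandas bridge --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, data_type: str = "") -> "OmicsMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str)), data_type)


@dataclass
class GenomicAnnotation:
    """Genomic coordinates for the features of one data type.

    Stored as a table with columns ``feature_id``, ``chrom``,
    ``position`` (1-based TSS or probe coordinate) and ``strand``
    (``+``/``-``/``unknown``).  Strand is retained for format fidelity
    but plays no role in distance computations.
    """

    table: pd.DataFrame

    REQUIRED = ("feature_id", "chrom", "position", "strand")

    def __post_init__(self):
        df = self.table.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        df["feature_id"] = df["feature_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["position"] = df["position"].astype(int)
        if (df["position"] < 1).any():
            bad = df.loc[df["position"] < 1, "feature_id"].tolist()
            raise ValueError(f"positions must be >= 1 (violations: {bad[:5]})")
        dups = df["feature_id"][df["feature_id"].duplicated()].unique().tolist()
        if dups:
            raise ValueError(f"duplicate feature IDs in annotation: {dups}")
        bad_strand = ~df["strand"].isin(["+", "-", "unknown"])
        if bad_strand.any():
            raise ValueError("strand must be one of '+', '-', 'unknown'")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> set[str]:
        return set(self.table["chrom"].unique())
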