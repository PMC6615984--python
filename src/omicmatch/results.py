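"""Alignment outcome container shared by the rank and probabilistic matchers."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["SELF_ALIGNED", "CROSS_ALIGNED", "UNALIGNED", "AlignmentResult"]

SELF_ALIGNED = "self_aligned"
CROSS_ALIGNED = "cross_aligned"
UNALIGNED = "unaligned"

_COLUMNS = [
    "sample_a",
    "sample_b",
    "status",
    "score",
    "p_value",
    "rank_row",
    "rank_col",
    "iteration",
    "reason",
]


@dataclass
class AlignmentResult:
    """Per-pair alignment decisions for one Type A vs Type B comparison.

    ``table`` has one row per evaluated pair: every candidate self pair
    (shared sample ID) with status ``self_aligned`` or ``unaligned``,
    plus one row per ``cross_aligned`` pair discovered.  ``method`` is
    ``"rank"`` or ``"probabilistic"``.
    """

    table: pd.DataFrame
    method: str
    data_type_a: str = ""
    data_type_b: str = ""
    converged: bool = True
    cutoff_self: float | None = None
    cutoff_cross: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        for c in _COLUMNS:
            if c not in self.table.columns:
                self.table[c] = pd.NA
        self.table = self.table[_COLUMNS].reset_index(drop=True)
        # mutual exclusivity / single partner per direction
        aligned = self.table[self.table["status"].isin([SELF_ALIGNED, CROSS_ALIGNED])]
        if aligned["sample_a"].duplicated().any() or aligned["sample_b"].duplicated().any():
            raise ValueError("a sample may appear in at most one alignment per direction")

    # -- views ----------------------------------------------------------
    def aligned_pairs(self) -> list[tuple[str, str]]:
        """(sample_a, sample_b) for all self- and cross-aligned pairs."""
        sub = self.table[self.table["status"].isin([SELF_ALIGNED, CROSS_ALIGNED])]
        return list(zip(sub["sample_a"], sub["sample_b"]))

    def self_aligned_ids(self) -> list[str]:
        sub = self.table[self.table["status"] == SELF_ALIGNED]
        return list(sub["sample_a"])

    def cross_pairs(self) -> list[tuple[str, str]]:
        sub = self.table[self.table["status"] == CROSS_ALIGNED]
        return list(zip(sub["sample_a"], sub["sample_b"]))

    def status_key(self) -> frozenset:
        """Hashable snapshot of all decisions, used for convergence checks."""
        return frozenset(zip(self.table["sample_a"], self.table["sample_b"], self.table["status"]))

    def summary(self) -> dict:
        n_cand = int((self.table["sample_a"] == self.table["sample_b"]).sum())
        n_self = len(self.self_aligned_ids())
        return {
            "method": self.method,
            "candidate_self_pairs": n_cand,
            "self_aligned": n_self,
            "self_aligned_fraction": n_self / n_cand if n_cand else float("nan"),
            "cross_aligned": len(self.cross_pairs()),
            "converged": self.converged,
        }

    def to_tsv(self, path, config_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if config_comment:
                fh.write(f"# {config_comment}\n")
            fh.write(f"# method={self.method} data_type_a={self.data_type_a} "
                     f"data_type_b={self.data_type_b} converged={self.converged}\n")
            if self.cutoff_self is not None:
                fh.write(f"# cutoff_self={self.cutoff_self:.6g} cutoff_cross={self.cutoff_cross:.6g}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, data_type_a: str = "", data_type_b: str = "") -> "AlignmentResult":
        meta = {"method": "unknown", "converged": True}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_a": str, "sample_b": str})
        return cls(
            table=df,
            method=str(meta.get("method", "unknown")),
            data_type_a=data_type_a or str(meta.get("data_type_a", "")),
            data_type_b=data_type_b or str(meta.get("data_type_b", "")),
            converged=str(meta.get("converged", "True")) == "True",
        )
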