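"""Reading and writing profile matrices, annotations and pair tables.

Profile matrices are delimited text with the sample IDs in the header
row and the feature IDs in the first column (the layout large
consortium portals distribute level-3 data in, after reformatting).
Parsing is strict: duplicated IDs and ragged rows are hard errors, and
the set of tokens treated as missing is explicit and configurable.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .core import GenomicAnnotation, OmicsMatrix

__all__ = [
    "DEFAULT_MISSING_TOKENS",
    "read_profile_matrix",
    "write_profile_matrix",
    "read_annotation",
    "write_annotation",
    "read_pair_table",
]

#: tokens mapped to the missing mask on read; portal dialects vary
DEFAULT_MISSING_TOKENS = frozenset({"NA", "NaN", ""})


def read_profile_matrix(
    path,
    delimiter: str = "\t",
    missing_tokens=DEFAULT_MISSING_TOKENS,
    data_type: str = "",
    transposed: bool = False,
) -> OmicsMatrix:
    """Read a features x samples profile matrix from delimited text.

    Parameters
    ----------
    path
        File with sample IDs in the first row and feature IDs in the
        first column.  Lines starting with ``#`` are ignored.
    delimiter
        Field separator.
    missing_tokens
        Cell values mapped to missing (``NaN``).
    transposed
        Set when the file is samples x features; the matrix is
        transposed after reading.  Orientation is never guessed.

    Raises
    ------
    ValueError
        On duplicated sample or feature IDs (naming the duplicates),
        ragged rows (naming the line number) or unparseable cells.
    """
    path = Path(path)
    rows: list[list[str]] = []
    line_nos: list[int] = []
    with open(path, newline="") as fh:
        for ln, rec in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not rec or (rec[0].startswith("#") and len(rec) == 1):
                continue
            if rec and rec[0].startswith("#"):
                continue
            rows.append(rec)
            line_nos.append(ln)
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    sample_ids = [c.strip() for c in header[1:]]
    width = len(header)
    feature_ids: list[str] = []
    values: list[list[float]] = []
    for rec, ln in zip(rows[1:], line_nos[1:]):
        if len(rec) != width:
            raise ValueError(
                f"{path}: ragged row at line {ln}: expected {width} fields, got {len(rec)}"
            )
        feature_ids.append(rec[0].strip())
        vals = []
        for tok in rec[1:]:
            tok = tok.strip()
            if tok in missing_tokens:
                vals.append(float("nan"))
            else:
                try:
                    vals.append(float(tok))
                except ValueError as exc:
                    raise ValueError(f"{path}: line {ln}: cannot parse value {tok!r}") from exc
        values.append(vals)
    m = OmicsMatrix(values, feature_ids, sample_ids, data_type)
    if transposed:
        m = OmicsMatrix(m.values.T.copy(), m.sample_ids, m.feature_ids, data_type)
    return m


def write_profile_matrix(m: OmicsMatrix, path, delimiter: str = "\t", missing_token: str = "NA") -> None:
    """Write a profile matrix; exact inverse of :func:`read_profile_matrix`.

    Floats are serialized with 17 significant digits so the read-back
    matrix is bit-identical.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["feature_id", *m.sample_ids])
        for i, fid in enumerate(m.feature_ids):
            row = [fid]
            for v in m.values[i]:
                row.append(missing_token if v != v else format(v, ".17g"))
            w.writerow(row)


def read_annotation(path, delimiter: str = "\t") -> GenomicAnnotation:
    """Read a 4-column annotation table (feature_id, chrom, position, strand)."""
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str)
    cols = list(df.columns)
    if len(cols) < 4:
        raise ValueError(f"{path}: annotation needs 4 columns, got {cols}")
    df = df.rename(columns=dict(zip(cols[:4], GenomicAnnotation.REQUIRED)))
    return GenomicAnnotation(df[list(GenomicAnnotation.REQUIRED)])


def write_annotation(annot: GenomicAnnotation, path, delimiter: str = "\t") -> None:
    annot.table.to_csv(path, sep=delimiter, index=False)


def read_pair_table(path, delimiter: str = "\t") -> list[tuple[str, str]]:
    """Read a two-column feature-pair table (featureA_id, featureB_id)."""
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str, header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: pair table needs two columns")
    first = (str(df.iloc[0, 0]).lower(), str(df.iloc[0, 1]).lower())
    if first in {("featurea_id", "featureb_id"), ("feature_a", "feature_b")}:
        df = df.iloc[1:]
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
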