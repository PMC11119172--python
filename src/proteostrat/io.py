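"""Readers and writers for the plain-text formats the pipeline exchanges.

Quantification matrices travel as wide TSV/CSV (first column = protein
group id, header = sample ids, empty field = not detected); a MaxQuant
proteinGroups dialect ingests only the "LFQ intensity <sample>" columns.
Annotations, Ig mappings, labels and every report are TSV.  All readers
and writers round-trip exactly.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import RAW, IgMapping, QuantMatrix, SampleAnnotation

MAXQUANT_LFQ_PREFIX = "LFQ intensity "


def _sep_for(path: Path, dialect: str) -> str:
    if dialect == "csv" or (dialect == "auto" and str(path).endswith(".csv")):
        return ","
    return "\t"


def read_quant_matrix(
    path,
    dialect: str = "auto",
    missing_markers: tuple[str, ...] = ("", "NA", "NaN"),
    zero_as_missing: bool = True,
    lfq_prefix: str = MAXQUANT_LFQ_PREFIX,
) -> QuantMatrix:
    """Read a raw-scale quantification matrix.

    ``dialect``: "auto" (TSV unless *.csv), "tsv", "csv", or "maxquant"
    (proteinGroups-style table; only columns prefixed ``lfq_prefix`` are
    ingested and sample names are the prefix-stripped suffixes).  Zero is
    a missing marker for raw LFQ input by default (undetected proteins are
    exported as 0 by common quantification software).
    """
    path = Path(path)
    sep = _sep_for(path, dialect if dialect != "maxquant" else "auto")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(missing_markers),
                         keep_default_na=False, dtype=str)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse table: {exc}") from exc
    if dialect == "maxquant":
        lfq_cols = [c for c in df.columns if c.startswith(lfq_prefix)]
        if not lfq_cols:
            raise ValueError(f"{path}: no columns prefixed {lfq_prefix!r}")
        df = df[lfq_cols]
        df.columns = [c[len(lfq_prefix):] for c in lfq_cols]
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate protein ids {dupes}")
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        bad = None
        for col in df.columns:
            conv = pd.to_numeric(df[col], errors="coerce")
            broken = conv.isna() & df[col].notna()
            if broken.any():
                bad = (df.index[broken][0], col, df[col][broken].iloc[0])
                break
        if bad:
            raise ValueError(
                f"{path}: non-numeric cell at ({bad[0]!r}, {bad[1]!r}): {bad[2]!r}"
            ) from exc
        raise
    if zero_as_missing:
        values = values.mask(values == 0)
    return QuantMatrix(values, scale=RAW)


def write_quant_matrix(m: QuantMatrix, path) -> None:
    path = Path(path)
    out = m.data.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_annotation(path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleAnnotation(df)


def write_annotation(ann: SampleAnnotation, path) -> None:
    out = ann.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_ig_mapping(path) -> IgMapping:
    """Two-column TSV: raw_code <tab> unified_code (header optional)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            if parts[0] == "raw_code" and lineno == 1:
                continue
            mapping[parts[0]] = parts[1]
    return IgMapping(mapping)


def write_ig_mapping(mapping: IgMapping, path) -> None:
    with open(path, "w") as fh:
        fh.write("raw_code\tunified_code\n")
        for raw, unified in mapping.items():
            fh.write(f"{raw}\t{unified}\n")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    s.name = "cluster"
    return s


def write_labels(labels: pd.Series, path) -> None:
    out = labels.to_frame("cluster")
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
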