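"""Preprocessing of raw LFQ matrices into analysis-ready datasets.

Order of transforms is fixed and flag-enforced:

1. ``unify_immunoglobulins`` — sum split Ig accession codes on the RAW scale;
2. ``log2_transform`` — variance-stabilising log2;
3. ``filter_by_missingness`` — drop proteins missing in more than 10% of samples;
4. ``sampmin_impute`` — replace remaining missing cells by 0.95 x the
   per-sample minimum (left-censoring imputation).

Sub-dataset extraction (diagnosis: CONTROL+SCOPD; exacerbation:
SCOPD+AECOPD) happens before filtering/imputation so each sub-dataset is
filtered and imputed on its own samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import LOG2, RAW, IgMapping, QuantMatrix, SampleAnnotation


def log2_transform(m: QuantMatrix) -> QuantMatrix:
    """log2-transform every present value; missing cells stay missing."""
    m.require(scale=RAW, stage="log2_transform")
    vals = m.data.to_numpy()
    present = ~np.isnan(vals)
    if (vals[present] <= 0).any():
        i, j = np.argwhere(present & ~(vals > 0))[0]
        raise ValueError(
            f"nonpositive value at ({m.data.index[i]!r}, {m.data.columns[j]!r})"
        )
    return m.with_data(
        pd.DataFrame(np.log2(vals), index=m.data.index, columns=m.data.columns),
        scale=LOG2,
    )


def unify_immunoglobulins(m: QuantMatrix, mapping: IgMapping) -> QuantMatrix:
    """Sum rows of split immunoglobulin codes into unified groups (raw scale).

    A unified cell is the sum of present constituent values and is missing
    only when every constituent is missing.  Unified rows take the position
    of their first constituent; unmapped rows pass through unchanged.
    """
    m.require(scale=RAW, ig_unified=False, stage="unify_immunoglobulins")
    absent = [c for c in mapping.raw_to_unified if c not in set(m.protein_ids)]
    if absent:
        warnings.warn(
            f"ig mapping references {len(absent)} codes absent from the matrix",
            stacklevel=2,
        )
    unified_ids = [mapping.unified(pid) for pid in m.protein_ids]
    grouped = m.data.groupby(
        pd.Index(unified_ids, name=m.data.index.name), sort=False
    ).sum(min_count=1)
    return m.with_data(grouped, ig_unified=True)


def filter_by_missingness(
    m: QuantMatrix, max_missing_frac: float = 0.10
) -> tuple[QuantMatrix, list]:
    """Keep proteins whose missing fraction is <= ``max_missing_frac``.

    The strict "more than 10% missing" rule: a protein missing in exactly
    10% of samples is retained.  Row order is preserved; dropped protein
    ids are returned.
    """
    if not (0.0 <= max_missing_frac <= 1.0):
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = m.missing_mask().mean(axis=1)
    keep = frac <= max_missing_frac
    dropped = list(m.data.index[~keep])
    return m.with_data(m.data.loc[keep]), dropped


def sampmin_impute(m: QuantMatrix, mode: str = "literal") -> QuantMatrix:
    """SampMin imputation: missing cells take 0.95 x their sample's minimum.

    Applied on the log2 scale.  ``mode="literal"`` multiplies the log2
    minimum by 0.95 (the formula read verbatim on the analysis scale);
    ``mode="raw"`` applies 0.95 to the raw-scale minimum, i.e. imputes
    min + log2(0.95) on the log2 scale.  Per-protein minima are available
    via ``mode="literal-protein"`` / ``mode="raw-protein"``.
    """
    m.require(scale=LOG2, imputed=False, stage="sampmin_impute")
    if mode not in ("literal", "raw", "literal-protein", "raw-protein"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    per_protein = mode.endswith("-protein")
    axis = 1 if per_protein else 0
    mins = m.data.min(axis=axis, skipna=True)
    dead = mins.index[m.data.notna().sum(axis=axis) == 0].tolist()
    if dead:
        kind = "protein" if per_protein else "sample"
        raise ValueError(f"{kind}(s) with no present values: {dead}")
    if mode.startswith("literal"):
        fill = 0.95 * mins
    else:
        fill = mins + np.log2(0.95)
    if per_protein:
        filled = m.data.T.fillna(fill).T
    else:
        filled = m.data.fillna(fill)
    return m.with_data(filled, imputed=True)


def make_subdatasets(
    m: QuantMatrix,
    ann: SampleAnnotation,
    diagnosis_groups: tuple[str, str] = ("CONTROL", "SCOPD"),
    exacerbation_groups: tuple[str, str] = ("SCOPD", "AECOPD"),
) -> tuple[QuantMatrix, QuantMatrix]:
    """Extract the two clinical sub-datasets by clinical group membership.

    Returns ``(diagnosis, exacerbation)`` matrices; protein rows are left
    untouched (filtering/imputation run per sub-dataset afterwards).
    Column order follows the annotation order.
    """
    ann.check_covers(m)

    def subset(groups: tuple[str, str], label: str) -> QuantMatrix:
        for g in groups:
            if not (ann.groups == g).any():
                raise ValueError(f"{label} sub-dataset: group {g!r} has no samples")
        cols = [s for s in ann.sample_ids if ann.groups[s] in groups and s in m.data.columns]
        return m.with_data(m.data[cols])

    return (
        subset(diagnosis_groups, "diagnosis"),
        subset(exacerbation_groups, "exacerbation"),
    )
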