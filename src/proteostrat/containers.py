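"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`QuantMatrix`, a wide protein-group x sample
intensity table with explicit missingness (NaN) and two provenance flags:
the intensity scale (``raw`` linear LFQ vs ``log2``) and whether split
immunoglobulin codes have been unified.  Stages check these flags so the
mandated order of transforms (unify on raw -> log2 -> filter -> impute)
cannot be violated silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

# Canonical clinical group labels of the COPD cohort design.
CONTROL = "CONTROL"
SCOPD = "SCOPD"
AECOPD = "AECOPD"

RAW = "raw"
LOG2 = "log2"


class PipelineOrderError(RuntimeError):
    """A transform was applied to a matrix in the wrong state."""


@dataclass
class QuantMatrix:
    """Protein-group x sample quantification matrix.

    Parameters
    ----------
    data
        DataFrame indexed by protein-group id, columns = sample ids,
        values = intensities, ``NaN`` = not detected.
    scale
        ``"raw"`` (linear LFQ) or ``"log2"``.
    ig_unified
        True once split immunoglobulin codes have been summed into
        unified groups.
    imputed
        True once missing cells have been filled; differential-abundance
        stages refuse imputed input.
    """

    data: pd.DataFrame
    scale: str = RAW
    ig_unified: bool = False
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        present = ~np.isnan(vals)
        if self.scale == RAW and present.any() and (vals[present] <= 0).any():
            r, c = np.argwhere(present & ~(vals > 0))[0]
            raise ValueError(
                "raw-scale intensities must be positive; offending cell "
                f"({self.data.index[r]!r}, {self.data.columns[c]!r})"
            )
        if self.scale == LOG2 and present.any() and not np.isfinite(vals[present]).all():
            raise ValueError("log2-scale values must be finite where present")
        self.data.index.name = "protein_id"
        self.data.columns.name = None

    # -- convenience -------------------------------------------------------

    @property
    def protein_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def with_data(self, data: pd.DataFrame, **flags) -> "QuantMatrix":
        """Copy carrying provenance flags forward, overriding via `flags`."""
        return replace(self, data=data, **flags)

    def require(self, *, scale: str | None = None, ig_unified: bool | None = None,
                imputed: bool | None = None, stage: str = "operation") -> None:
        """Raise PipelineOrderError unless the matrix is in the given state."""
        if scale is not None and self.scale != scale:
            raise PipelineOrderError(
                f"{stage} requires a {scale}-scale matrix, got {self.scale}"
            )
        if ig_unified is not None and self.ig_unified != ig_unified:
            raise PipelineOrderError(
                f"{stage} requires ig_unified={ig_unified}, got {self.ig_unified}"
            )
        if imputed is not None and self.imputed != imputed:
            raise PipelineOrderError(
                f"{stage} requires imputed={imputed}, got {self.imputed}"
            )


@dataclass
class SampleAnnotation:
    """Per-sample clinical group and covariates.

    ``table`` is indexed by sample id and must carry a ``group`` column;
    any further columns (age, sex, bmi, ...) are treated as covariates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValueError("annotation table needs a 'group' column")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in annotation")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.table.columns if c != "group"]

    def samples_in(self, *groups: str) -> list:
        mask = self.table["group"].isin(groups)
        return list(self.table.index[mask])

    def check_covers(self, m: QuantMatrix) -> None:
        missing = set(m.sample_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)}")


@dataclass
class IgMapping:
    """Map raw accession codes to unified immunoglobulin group codes.

    Codes absent from the map pass through unchanged (the map is total on
    the codes it covers, identity elsewhere).
    """

    raw_to_unified: Mapping[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.raw_to_unified)

    def unified(self, raw_code: str) -> str:
        return self.raw_to_unified.get(raw_code, raw_code)

    def items(self):
        return self.raw_to_unified.items()
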