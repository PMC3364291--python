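"""Core in-memory containers: the expression matrix and the sample table.

Every stage of the screen transforms an :class:`ExpressionMatrix` (a
probe × sample table of intensities, raw or log2, with optional per-cell
detection p-values) guided by a :class:`SampleTable` of per-sample
covariates from which the two age groups are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Age (years) separating the "young" from the "old" group.  Chosen where
#: cortical glucose uptake and synapse density reach adult levels.
AGE_CUTOFF_YEARS = 15.0

SEX_LEVELS = ("male", "female", "unknown")

_SAMPLE_COLUMNS = ("subject_id", "age_years", "sex", "dev_delay", "region")


class DuplicateIdError(ValueError):
    """Duplicate probe or sample identifiers."""


class ShapeMismatchError(ValueError):
    """Companion table does not align with the expression matrix."""


class UnknownSexCodeError(ValueError):
    """Sex code outside {male, female, unknown}."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe × sample expression values with provenance.

    Parameters
    ----------
    values
        DataFrame, probes in rows (unique index), samples in columns
        (unique header).
    detection_p
        Optional same-shape DataFrame of per-cell detection p-values in
        [0, 1]; ``None`` once the matrix has been transformed past the
        detection-filter stage.
    scale
        ``"raw"`` (background-corrected intensities) or ``"log2"``.
    provenance
        Ordered record of the transforms applied so far.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    scale: str = "raw"
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate probe ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.scale == "raw" and arr.size and not np.isfinite(arr).all():
            raise ValueError("raw-scale expression values must be finite")
        if self.detection_p is not None:
            dp = self.detection_p
            if not dp.index.equals(self.values.index) or not dp.columns.equals(
                self.values.columns
            ):
                raise ShapeMismatchError(
                    "detection_p index/columns do not match expression values"
                )
            d = dp.to_numpy()
            if d.size and ((d < 0) | (d > 1)).any():
                raise ValueError("detection p-values must lie in [0, 1]")

    # -- convenience -------------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def evolve(
        self,
        values: pd.DataFrame,
        step: str,
        *,
        detection_p: pd.DataFrame | None = None,
        scale: str | None = None,
        keep_detection: bool = False,
    ) -> "ExpressionMatrix":
        """Return a new matrix with ``step`` appended to the provenance."""
        return ExpressionMatrix(
            values=values,
            detection_p=detection_p if not keep_detection else self.detection_p,
            scale=self.scale if scale is None else scale,
            provenance=self.provenance + (step,),
        )


@dataclass(frozen=True)
class SampleTable:
    """Per-sample covariates, indexed by sample id.

    Columns: ``subject_id`` (groups technical replicate arrays of one
    biological sample), ``age_years``, ``sex`` (male/female/unknown),
    ``dev_delay`` (bool), ``region`` (free text).
    """

    data: pd.DataFrame
    age_cutoff: float = AGE_CUTOFF_YEARS

    def __post_init__(self) -> None:
        missing = [c for c in _SAMPLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        if self.data.index.duplicated().any():
            raise DuplicateIdError("duplicate sample ids in sample table")
        bad_sex = set(self.data["sex"].astype(str)) - set(SEX_LEVELS)
        if bad_sex:
            raise UnknownSexCodeError(
                f"unknown sex codes {sorted(bad_sex)}; expected one of {SEX_LEVELS}"
            )
        if (self.data["age_years"].to_numpy(dtype=float) < 0).any():
            raise ValueError("age_years must be non-negative")
        if self.age_cutoff <= 0:
            raise ValueError("age cutoff must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(pd.unique(self.data["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def age_group(self) -> pd.Series:
        """'young' (< cutoff) or 'old' (>= cutoff), per sample."""
        young = self.data["age_years"] < self.age_cutoff
        return pd.Series(
            np.where(young, "young", "old"), index=self.data.index, name="age_group"
        )

    def group_sample_ids(self) -> tuple[list[str], list[str]]:
        """Sample ids in the young and old groups, in table order."""
        grp = self.age_group
        return (
            list(grp.index[grp == "young"]),
            list(grp.index[grp == "old"]),
        )

    def subset(self, sample_ids: list[str]) -> "SampleTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ShapeMismatchError(f"samples not in table: {missing[:5]}")
        return replace(self, data=self.data.loc[sample_ids])

    def align_to(self, matrix: ExpressionMatrix) -> "SampleTable":
        """Reorder to the matrix columns, erroring on any absent sample."""
        missing = [s for s in matrix.sample_ids if s not in self.data.index]
        if missing:
            raise ShapeMismatchError(
                f"matrix samples missing from metadata: {missing[:5]}"
            )
        return replace(self, data=self.data.loc[matrix.sample_ids])
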