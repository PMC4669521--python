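"""In-memory containers for methylation matrices and cohort metadata.

The central object is :class:`MethylationMatrix`: a sites x samples table of
beta values (fraction of methylated alleles, in [0, 1]) with NaN marking
missing entries and an optional auxiliary layer of the same shape holding
per-value detection p-values (BeadChip) or confidence scores (EpiTYPER).
Sites are rows — the 450K convention, where matrices are tall and skinny.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["MethylationMatrix", "CohortMetadata"]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class MethylationMatrix:
    """Sites x samples beta values with missing mask and optional aux layer.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by site id, columns by sample id. Float values in
        [0, 1]; NaN encodes missing.
    aux : pandas.DataFrame, optional
        Same shape/labels as ``values``; detection p-values or confidence
        scores, depending on platform.
    unit_interval : bool
        Enforce values in [0, 1]. Disable for raw instrument-scale
        (pre-calibration) measurements, which may leave the unit interval.
    """

    values: pd.DataFrame
    aux: Optional[pd.DataFrame] = None
    unit_interval: bool = True

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "site ids")
        _check_unique(self.values.columns, "sample ids")
        finite = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = ((finite < 0) | (finite > 1)) if self.unit_interval else np.zeros_like(finite, bool)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0,1] at site {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {finite[i, j]}"
            )
        if self.aux is not None:
            self.aux = self.aux.astype(float)
            if self.aux.shape != self.values.shape:
                raise ValidationError(
                    f"aux shape {self.aux.shape} != values shape {self.values.shape}"
                )
            if not self.aux.index.equals(self.values.index) or not self.aux.columns.equals(
                self.values.columns
            ):
                raise ValidationError("aux layer labels do not match values")

    # -- basic geometry ----------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where a value is missing."""
        return self.values.isna()

    def missing_fraction_by_site(self) -> pd.Series:
        return self.values.isna().mean(axis=1)

    def missing_fraction_by_sample(self) -> pd.Series:
        return self.values.isna().mean(axis=0)

    # -- manipulation ------------------------------------------------------
    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(
            self.values.copy(),
            None if self.aux is None else self.aux.copy(),
            unit_interval=self.unit_interval,
        )

    def with_values(
        self, values: pd.DataFrame, unit_interval: Optional[bool] = None
    ) -> "MethylationMatrix":
        """Return a new matrix with replaced values, keeping aux aligned."""
        aux = None
        if self.aux is not None:
            aux = self.aux.loc[values.index, values.columns].copy()
        if unit_interval is None:
            unit_interval = self.unit_interval
        return MethylationMatrix(values, aux, unit_interval=unit_interval)

    def subset(
        self,
        sites: Optional[Sequence[str]] = None,
        samples: Optional[Sequence[str]] = None,
    ) -> "MethylationMatrix":
        v = self.values
        if sites is not None:
            v = v.loc[list(sites)]
        if samples is not None:
            v = v[list(samples)]
        return self.with_values(v.copy())

    def equals(self, other: "MethylationMatrix") -> bool:
        if not self.values.equals(other.values):
            return False
        if (self.aux is None) != (other.aux is None):
            return False
        return self.aux is None or self.aux.equals(other.aux)


@dataclass
class CohortMetadata:
    """Per-sample metadata: age (years), sex, cohort label, twin-pair id."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "age", "sex", "cohort", "pair_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["age"] = t["age"].astype(float)
        if t["sample_id"].duplicated().any():
            dupes = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        if (t["age"] <= 0).any() or not np.isfinite(t["age"]).all():
            bad = t.loc[~(t["age"] > 0), "sample_id"].tolist()
            raise ValidationError(f"non-positive or non-finite age for samples: {bad[:5]}")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def ages_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Ages aligned to ``sample_ids`` by id (never by position)."""
        lookup = self.table.set_index("sample_id")["age"]
        missing = [s for s in sample_ids if s not in lookup.index]
        if missing:
            raise ValidationError(f"samples absent from metadata: {missing[:5]}")
        return lookup.loc[list(sample_ids)].to_numpy(dtype=float)
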