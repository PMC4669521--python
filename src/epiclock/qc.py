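"""Calibration and quality control of Sequenom/EpiTYPER-style measurements.

Stage 2 of the analysis: fit a linear calibration of known standard
methylation (0-100% in 10% steps) on measured methylation, correct the
cohort matrix with it, drop low-confidence values and over-missing
sites/samples, and re-select age-associated sites by |Pearson R| on
pairwise-complete observations. The canonical order — confidence filter,
missingness filter, calibration, |R| selection — is what
:func:`run_qc_pipeline` enforces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import CohortMetadata, MethylationMatrix
from .scan import site_regression

__all__ = [
    "CalibrationModel",
    "QCConfig",
    "fit_calibration",
    "apply_calibration",
    "filter_confidence",
    "filter_missingness",
    "select_by_abs_r",
    "run_qc_pipeline",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from measured to corrected methylation: y = slope*x + b."""

    slope: float
    intercept: float
    r2_fit: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValidationError(f"calibration slope must be finite and non-zero, got {self.slope}")


@dataclass(frozen=True)
class QCConfig:
    """QC thresholds; defaults are the conventional cutoffs for this workflow."""

    confidence_min: float = 1.9
    site_missing_max: float = 0.70
    sample_missing_max: float = 0.70
    abs_r_min: float = 0.5

    def __post_init__(self) -> None:
        if self.confidence_min < 0:
            raise ValidationError("confidence_min must be >= 0")
        for name in ("site_missing_max", "sample_missing_max", "abs_r_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0,1), got {v}")


def fit_calibration(known: np.ndarray, measured: np.ndarray) -> CalibrationModel:
    """OLS of known standard methylation on measured methylation."""
    known = np.asarray(known, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if known.shape != measured.shape or known.ndim != 1:
        raise ValidationError("known and measured must be 1-D arrays of equal length")
    keep = np.isfinite(known) & np.isfinite(measured)
    x, y = measured[keep], known[keep]
    if x.size < 2 or np.unique(x).size < 2:
        raise ValidationError("need >= 2 distinct measured values to fit a calibration")
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean())) / float(xc @ xc)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return CalibrationModel(slope, intercept, r2)


def apply_calibration(matrix: MethylationMatrix, model: CalibrationModel) -> MethylationMatrix:
    """Correct measured values: slope*x + intercept, clipped to [0, 1].

    The calibration line can push low measurements below zero (measured 0.5
    maps to -0.0751 under the default line); beta values are fractions by
    definition, so out-of-range corrections are clipped and the clip count
    is recorded on the returned matrix as ``.clip_count`` metadata via the
    report tuple of :func:`run_qc_pipeline`. Missing stays missing.
    """
    raw = model.slope * matrix.values + model.intercept
    corrected = raw.clip(0.0, 1.0)
    aux = None if matrix.aux is None else matrix.aux.copy()
    return MethylationMatrix(corrected, aux, unit_interval=True)


def calibration_clip_count(matrix: MethylationMatrix, model: CalibrationModel) -> int:
    """How many observed values the calibration clips at 0 or 1."""
    raw = model.slope * matrix.values + model.intercept
    return int(((raw < 0) | (raw > 1)).to_numpy().sum())


def filter_confidence(
    matrix: MethylationMatrix, cutoff: float = 1.9
) -> tuple[MethylationMatrix, float]:
    """Mask values whose confidence score is not strictly above ``cutoff``.

    Returns the filtered matrix and the acceptance fraction (kept observed
    values / observed values before filtering). A score of exactly 1.9 is
    rejected — acceptance requires confidence > cutoff.
    """
    if matrix.aux is None:
        raise ValidationError("filter_confidence requires a confidence aux layer")
    observed = matrix.values.notna()
    keep = matrix.aux > cutoff
    total = int(observed.to_numpy().sum())
    kept = int((observed & keep).to_numpy().sum())
    filtered = matrix.values.where(keep)
    out = MethylationMatrix(filtered, matrix.aux.copy(), unit_interval=matrix.unit_interval)
    return out, (kept / total if total else float("nan"))


@dataclass
class ExclusionReport:
    """Sites and samples dropped by the missingness filter, with fractions."""

    sites: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    samples: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def filter_missingness(
    matrix: MethylationMatrix,
    site_max: float = 0.70,
    sample_max: float = 0.70,
) -> tuple[MethylationMatrix, ExclusionReport]:
    """Drop sites then samples whose missing fraction is strictly above threshold.

    Sites are filtered first (failed amplicons should not drive sample
    exclusion); sample fractions are then recomputed on the site-reduced
    matrix. A site at exactly the threshold is retained.
    """
    for name, v in (("site_max", site_max), ("sample_max", sample_max)):
        if not 0 < v < 1:
            raise ValidationError(f"{name} must be in (0,1), got {v}")
    site_frac = matrix.missing_fraction_by_site()
    bad_sites = site_frac[site_frac > site_max]
    keep_sites = site_frac.index[site_frac <= site_max]
    reduced = matrix.subset(sites=keep_sites)
    sample_frac = reduced.missing_fraction_by_sample()
    bad_samples = sample_frac[sample_frac > sample_max]
    keep_samples = sample_frac.index[sample_frac <= sample_max]
    final = reduced.subset(samples=keep_samples)
    if final.n_sites == 0 or final.n_samples == 0:
        raise ValidationError("missingness filter excluded everything")
    return final, ExclusionReport(sites=bad_sites, samples=bad_samples)


def select_by_abs_r(
    matrix: MethylationMatrix,
    meta: CohortMetadata,
    abs_r_min: float = 0.5,
) -> pd.DataFrame:
    """Per-site Pearson R against age on pairwise-complete observations.

    Returns a table (site_id, R, p, n_used, selected) where ``selected``
    marks |R| strictly above ``abs_r_min``. Sites with fewer than 3
    observed values are excluded from the table with a warning flag rather
    than raising.
    """
    ages = meta.ages_for(matrix.sample_ids)
    rows = []
    for site_id, row in zip(matrix.site_ids, matrix.values.to_numpy(dtype=float)):
        n_obs = int(np.isfinite(row).sum())
        if n_obs < 3:
            rows.append({"site_id": site_id, "R": np.nan, "p": np.nan,
                         "n_used": n_obs, "selected": False, "too_few": True})
            continue
        rec = site_regression(row, ages)
        rows.append({
            "site_id": site_id, "R": rec["R"], "p": rec["p"],
            "n_used": rec["n_used"], "selected": bool(abs(rec["R"]) > abs_r_min),
            "too_few": False,
        })
    return pd.DataFrame(rows)


def run_qc_pipeline(
    matrix: MethylationMatrix,
    standards: pd.DataFrame,
    meta: CohortMetadata,
    config: QCConfig = QCConfig(),
) -> tuple[MethylationMatrix, pd.DataFrame, dict]:
    """Confidence filter -> missingness filter -> calibration -> |R| selection.

    Returns the corrected matrix, the per-site selection table, and a JSON-
    serialisable report (acceptance fraction, exclusions, calibration fit,
    clip count, selected sites). Re-running on its own output with the same
    standards is a no-op up to the idempotent calibration of already-
    corrected data.
    """
    filtered, acceptance = filter_confidence(matrix, config.confidence_min)
    reduced, exclusions = filter_missingness(
        filtered, config.site_missing_max, config.sample_missing_max
    )
    calib = fit_calibration(
        standards["known"].to_numpy(), standards["measured"].to_numpy()
    )
    clip_count = calibration_clip_count(reduced, calib)
    corrected = apply_calibration(reduced, calib)
    table = select_by_abs_r(corrected, meta, config.abs_r_min)
    report = {
        "acceptance_fraction": acceptance,
        "excluded_sites": {k: float(v) for k, v in exclusions.sites.items()},
        "excluded_samples": {k: float(v) for k, v in exclusions.samples.items()},
        "calibration": {"slope": calib.slope, "intercept": calib.intercept, "r2": calib.r2_fit},
        "clipped_values": clip_count,
        "selected_sites": table.loc[table["selected"], "site_id"].tolist(),
        "stage_order": ["confidence", "missingness", "calibration", "selection"],
    }
    return corrected, table, report
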