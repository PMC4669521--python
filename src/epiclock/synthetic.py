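"""Synthetic methylome generator.

Emulates the statistical structure the downstream analysis assumes: a twin
discovery cohort and an unrelated validation cohort; CpG sites whose beta
value drifts linearly with age inside [0, 1]; non-associated background
sites; Gaussian measurement noise clipped to the unit interval; value-level
missingness; EpiTYPER-style confidence scores; and a linear platform
distortion whose inverse is the calibration line fitted downstream
(corrected = 2.285 * measured - 1.2176).

Randomness: one global integer seed propagated to named sub-streams
(cohort, betas, mask, standards, confidence), so each stage is reproducible
on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import CohortMetadata, MethylationMatrix

__all__ = [
    "CohortSpec",
    "SiteSpec",
    "PlatformDistortion",
    "generate_cohort",
    "generate_betas",
    "distort_measurements",
    "generate_standards",
    "attach_confidence",
    "simulate_discovery",
    "simulate_validation",
    "simulate_panel",
    "DEFAULT_DISTORTION",
]

_STREAMS = {"cohort": 1, "betas": 2, "mask": 3, "standards": 4, "confidence": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class CohortSpec:
    """A cohort to simulate: size, age interval, twin structure, seed."""

    n_samples: int
    age_range: tuple[float, float]
    twin_pairs: int = 0
    seed: int = 0
    sex: str = "F"
    cohort: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError(f"n_samples must be >= 2, got {self.n_samples}")
        lo, hi = self.age_range
        if lo > hi:  # degenerate (lo == hi) interval is allowed
            raise ValidationError(f"age_range lower must be <= upper, got {self.age_range}")
        if lo <= 0:
            raise ValidationError(f"age_range must be positive, got {self.age_range}")
        if self.twin_pairs < 0 or 2 * self.twin_pairs > self.n_samples:
            raise ValidationError(
                f"twin_pairs must satisfy 0 <= 2*twin_pairs <= n_samples, got {self.twin_pairs}"
            )


@dataclass(frozen=True)
class SiteSpec:
    """Sites to simulate: how many, how many age-associated, effect sizes.

    ``slope_range`` is a signed interval in beta units per year;
    ``baseline_range`` is the interval the age-0 intercept b0 is drawn from.
    Generated values follow clip(b0 + slope*age + eps, 0, 1) with
    eps ~ Normal(0, noise_sd); background sites have slope 0.
    """

    n_sites: int
    n_associated: int
    slope_range: tuple[float, float] = (0.015, 0.022)
    baseline_range: tuple[float, float] = (0.02, 0.15)
    noise_sd: float = 0.03
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError(f"n_sites must be >= 1, got {self.n_sites}")
        if not 0 <= self.n_associated <= self.n_sites:
            raise ValidationError(
                f"n_associated must be in [0, n_sites], got {self.n_associated}"
            )
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError(f"missing_rate must be in [0,1), got {self.missing_rate}")
        lo, hi = self.baseline_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError(f"baseline_range must lie within [0,1], got {self.baseline_range}")
        if self.slope_range[0] > self.slope_range[1]:
            raise ValidationError(f"slope_range reversed: {self.slope_range}")


@dataclass(frozen=True)
class PlatformDistortion:
    """Linear measurement distortion plus the standard series it is fit on.

    ``slope``/``intercept`` are on the *corrected* scale: a true fraction y
    is observed as measured x = (y - intercept) / slope (+ noise), so the
    downstream calibration OLS of known on measured recovers exactly
    (slope, intercept). Defaults invert the calibration line
    y = 2.285 x - 1.2176 fitted on 0..100% standards in 10% steps.
    """

    slope: float = 2.285
    intercept: float = -1.2176
    standard_levels: tuple[float, ...] = tuple(np.round(np.arange(0, 1.01, 0.1), 10))
    standard_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValidationError("distortion slope must be non-zero")
        levels = np.asarray(self.standard_levels, dtype=float)
        if np.any(levels < 0) or np.any(levels > 1):
            raise ValidationError("standard_levels must lie in [0,1]")
        if len(levels) >= 2 and np.any(np.diff(levels) <= 0):
            raise ValidationError("standard_levels must be strictly increasing")


DEFAULT_DISTORTION = PlatformDistortion()


def generate_cohort(spec: CohortSpec) -> CohortMetadata:
    """Draw a cohort: uniform ages on the age interval, twins sharing ages.

    The first ``2 * twin_pairs`` samples form consecutive pairs with
    identical ages and a shared ``pair_id``; the remainder are unrelated.
    """
    rng = _rng(spec.seed, "cohort")
    lo, hi = spec.age_range
    n_free = spec.n_samples - spec.twin_pairs  # one draw per pair + singletons
    draws = rng.uniform(lo, hi, size=n_free) if hi > lo else np.full(n_free, float(lo))
    ages = np.empty(spec.n_samples)
    pair_ids: list[Optional[str]] = [None] * spec.n_samples
    for p in range(spec.twin_pairs):
        ages[2 * p] = ages[2 * p + 1] = draws[p]
        pair_ids[2 * p] = pair_ids[2 * p + 1] = f"P{p + 1:02d}"
    ages[2 * spec.twin_pairs :] = draws[spec.twin_pairs :]
    table = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:03d}" for i in range(spec.n_samples)],
            "age": ages,
            "sex": spec.sex,
            "cohort": spec.cohort,
            "pair_id": pair_ids,
        }
    )
    return CohortMetadata(table)


def generate_betas(
    cohort: CohortMetadata,
    sites: SiteSpec,
    seed: int = 0,
    site_prefix: str = "cg",
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Simulate a beta matrix over a cohort; return it with its truth table.

    The first ``n_associated`` sites get a slope drawn uniformly from
    ``slope_range`` and an intercept from ``baseline_range``; the rest are
    flat. Twin pairs share the site line (baseline and slope are site
    properties) but receive independent noise. The truth table records
    site_id, associated flag, slope and baseline for recovery tests.
    """
    if cohort.n_samples == 0:
        raise ValidationError("cohort is empty")
    rng_b = _rng(seed, "betas")
    rng_m = _rng(seed, "mask")
    ages = cohort.table["age"].to_numpy()
    n_sites, n_samples = sites.n_sites, cohort.n_samples

    slopes = np.zeros(n_sites)
    slopes[: sites.n_associated] = rng_b.uniform(
        sites.slope_range[0], sites.slope_range[1], size=sites.n_associated
    )
    baselines = rng_b.uniform(
        sites.baseline_range[0], sites.baseline_range[1], size=n_sites
    )
    clean = baselines[:, None] + slopes[:, None] * ages[None, :]
    noise = (
        rng_b.normal(0.0, sites.noise_sd, size=(n_sites, n_samples))
        if sites.noise_sd > 0
        else 0.0
    )
    betas = np.clip(clean + noise, 0.0, 1.0)
    if sites.missing_rate > 0:
        mask = rng_m.random((n_sites, n_samples)) < sites.missing_rate
        betas = np.where(mask, np.nan, betas)

    width = max(5, len(str(n_sites)))
    site_ids = [f"{site_prefix}{i + 1:0{width}d}" for i in range(n_sites)]
    values = pd.DataFrame(betas, index=site_ids, columns=cohort.sample_ids)
    truth = pd.DataFrame(
        {
            "site_id": site_ids,
            "associated": np.arange(n_sites) < sites.n_associated,
            "slope": slopes,
            "baseline": baselines,
        }
    )
    return MethylationMatrix(values), truth


def distort_measurements(
    matrix: MethylationMatrix, d: PlatformDistortion, seed: int = 0
) -> MethylationMatrix:
    """Map true fractions to the measured scale: (true - b) / a plus noise.

    The inverse of the calibration that :func:`epiclock.qc.fit_calibration`
    recovers; a zero-noise round trip is exact. Measured values are *not*
    clipped — the instrument scale may legitimately leave [0, 1].
    """
    rng = _rng(seed, "standards")
    measured = (matrix.values - d.intercept) / d.slope
    if d.standard_noise_sd > 0:
        measured = measured + rng.normal(0.0, d.standard_noise_sd, size=measured.shape)
    aux = None if matrix.aux is None else matrix.aux.copy()
    return MethylationMatrix(measured, aux, unit_interval=False)


def generate_standards(d: PlatformDistortion, seed: int = 0) -> pd.DataFrame:
    """Measure the methylation-standard dilution series under a distortion.

    Returns a two-column frame (known, measured), one row per standard
    level (0%, 10%, ..., 100% by default).
    """
    levels = np.asarray(d.standard_levels, dtype=float)
    if len(levels) < 2:
        raise ValidationError("need at least 2 standard levels")
    rng = _rng(seed, "standards")
    measured = (levels - d.intercept) / d.slope
    if d.standard_noise_sd > 0:
        measured = measured + rng.normal(0.0, d.standard_noise_sd, size=len(levels))
    return pd.DataFrame({"known": levels, "measured": measured})


def attach_confidence(
    matrix: MethylationMatrix,
    seed: int = 0,
    low_fraction: float = 0.05,
    high_loc: float = 4.0,
    low_loc: float = 1.0,
    scale: float = 0.5,
) -> MethylationMatrix:
    """Attach EpiTYPER-style confidence scores (0 = low, 5 = high) as aux.

    A ``low_fraction`` of values get scores centred near ``low_loc`` (below
    the conventional >1.9 acceptance cutoff); the rest near ``high_loc``.
    Scores are clipped to [0, 5].
    """
    rng = _rng(seed, "confidence")
    shape = matrix.values.shape
    low = rng.random(shape) < low_fraction
    scores = rng.normal(np.where(low, low_loc, high_loc), scale, size=shape)
    conf = pd.DataFrame(
        np.clip(scores, 0.0, 5.0), index=matrix.values.index, columns=matrix.values.columns
    )
    return MethylationMatrix(matrix.values.copy(), conf)


def simulate_discovery(
    seed: int = 0,
    n_sites: int = 10_000,
    n_associated: int = 500,
    n_samples: int = 16,
    twin_pairs: int = 8,
    age_range: tuple[float, float] = (21.0, 32.0),
    noise_sd: float = 0.03,
    detection_p_bad_fraction: float = 0.01,
) -> tuple[CohortMetadata, MethylationMatrix, pd.DataFrame]:
    """The discovery-scan scenario: a small twin cohort on a genome-scale array.

    Half the planted sites gain methylation with age, half lose it; slope
    magnitudes (0.015-0.022 beta/yr) against noise_sd 0.03 put planted sites
    in a population-R^2 > 0.7 regime over this narrow age window. Baseline
    windows are sign-specific so trends are not flattened by clipping. The
    aux layer carries detection p-values, a small fraction of which exceed
    the conventional 0.01 masking threshold.
    """
    cohort = generate_cohort(
        CohortSpec(n_samples, age_range, twin_pairs=twin_pairs, seed=seed, cohort="twins")
    )
    n_pos = n_associated // 2
    n_neg = n_associated - n_pos
    hi_age = age_range[1]
    pos_spec = SiteSpec(
        n_sites - n_neg,
        n_pos,
        slope_range=(0.015, 0.022),
        baseline_range=(0.02, max(0.03, 0.97 - 0.022 * hi_age)),
        noise_sd=noise_sd,
    )
    neg_spec = SiteSpec(
        n_neg,
        n_neg,
        slope_range=(-0.022, -0.015),
        baseline_range=(min(0.97, 0.03 + 0.022 * hi_age), 0.97),
        noise_sd=noise_sd,
    )
    m_pos, t_pos = generate_betas(cohort, pos_spec, seed=seed, site_prefix="cg")
    m_neg, t_neg = generate_betas(cohort, neg_spec, seed=seed + 1, site_prefix="ng")
    values = pd.concat([m_pos.values, m_neg.values])
    truth = pd.concat([t_pos, t_neg], ignore_index=True)

    rng = _rng(seed, "confidence")
    detp = np.where(
        rng.random(values.shape) < detection_p_bad_fraction,
        rng.uniform(0.011, 0.5, size=values.shape),
        rng.uniform(0.0, 0.009, size=values.shape),
    )
    aux = pd.DataFrame(detp, index=values.index, columns=values.columns)
    return cohort, MethylationMatrix(values, aux), truth


def simulate_validation(
    seed: int = 0,
    n_samples: int = 50,
    age_range: tuple[float, float] = (20.0, 80.0),
    n_sites: int = 95,
    n_associated: int = 11,
    noise_sd: float = 0.05,
    missing_rate: float = 0.15,
    n_dropout_sites: int = 5,
    dropout_site_rate: float = 0.78,
    n_dropout_samples: int = 1,
    dropout_sample_rate: float = 0.83,
    distortion: PlatformDistortion = DEFAULT_DISTORTION,
    associated_site_ids: Optional[Sequence[str]] = None,
) -> tuple[CohortMetadata, MethylationMatrix, pd.DataFrame]:
    """The Sequenom validation scenario: 50 unrelated adults, 95 amplicon CpGs.

    Eleven sites (6 positive, 5 negative) carry gentler slopes
    (0.004-0.008 beta/yr) appropriate for a 60-year age span. Values are
    pushed through the platform distortion onto the measured scale, given
    confidence scores, and peppered with missingness; a handful of sites and
    one sample additionally get heavy dropout so the >70% missingness filter
    has real work to do. If ``associated_site_ids`` is given, the planted
    sites are renamed to those ids (mimicking re-assay of discovery hits).
    """
    cohort = generate_cohort(
        CohortSpec(n_samples, age_range, twin_pairs=0, seed=seed, cohort="validation")
    )
    n_pos = (n_associated + 1) // 2
    n_neg = n_associated - n_pos
    hi_age = age_range[1]
    pos_spec = SiteSpec(
        n_sites - n_neg,
        n_pos,
        slope_range=(0.004, 0.008),
        baseline_range=(0.05, max(0.06, 0.95 - 0.008 * hi_age)),
        noise_sd=noise_sd,
    )
    neg_spec = SiteSpec(
        n_neg,
        n_neg,
        slope_range=(-0.008, -0.004),
        baseline_range=(min(0.94, 0.05 + 0.008 * hi_age), 0.95),
        noise_sd=noise_sd,
    )
    m_pos, t_pos = generate_betas(cohort, pos_spec, seed=seed + 10, site_prefix="Xp")
    m_neg, t_neg = generate_betas(cohort, neg_spec, seed=seed + 11, site_prefix="Xn")
    values = pd.concat([m_pos.values, m_neg.values])
    truth = pd.concat([t_pos, t_neg], ignore_index=True)

    # amplicon-style site names X21..; planted ids optionally overridden
    rename = {old: f"X{i + 21}" for i, old in enumerate(values.index)}
    if associated_site_ids is not None:
        planted = truth.loc[truth["associated"], "site_id"].tolist()
        for old, new in zip(planted, associated_site_ids):
            rename[old] = str(new)
    values = values.rename(index=rename)
    truth["site_id"] = truth["site_id"].map(rename)

    # onto the measured scale, then confidence + missingness
    measured = (values - distortion.intercept) / distortion.slope
    if distortion.standard_noise_sd > 0:
        rng_d = _rng(seed, "standards")
        measured = measured + rng_d.normal(0.0, distortion.standard_noise_sd, measured.shape)
    rng_m = _rng(seed, "mask")
    miss = rng_m.random(measured.shape) < missing_rate
    site_idx = rng_m.choice(n_sites, size=min(n_dropout_sites, n_sites), replace=False)
    for i in site_idx:
        miss[i] |= rng_m.random(n_samples) < dropout_site_rate
    sample_idx = rng_m.choice(n_samples, size=min(n_dropout_samples, n_samples), replace=False)
    for j in sample_idx:
        miss[:, j] |= rng_m.random(n_sites) < dropout_sample_rate
    measured = measured.where(~miss)

    rng_c = _rng(seed, "confidence")
    low = rng_c.random(measured.shape) < 0.05
    conf = pd.DataFrame(
        np.clip(rng_c.normal(np.where(low, 1.0, 4.0), 0.5), 0.0, 5.0),
        index=measured.index,
        columns=measured.columns,
    )
    # measured scale can leave [0,1]; calibration downstream restores fractions
    matrix = MethylationMatrix(measured, conf, unit_interval=False)
    return cohort, matrix, truth


def simulate_panel(
    seed: int = 0,
    n_samples: int = 49,
    n_sites: int = 11,
    age_range: tuple[float, float] = (20.0, 80.0),
    slope_range: tuple[float, float] = (0.004, 0.008),
    noise_sd: float = 0.05,
    accel_scale: float = 5.0,
    accel_df: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """The model-comparison scenario: a clean marker panel with realistic spread.

    Returns (features, ages) for ``n_samples`` adults and ``n_sites`` CpGs
    (split positive/negative slope). Methylation tracks *biological* age:
    chronological age plus a per-sample "age acceleration" offset drawn
    from a heavy-tailed scaled Student-t (``accel_scale * t(accel_df)``,
    default sd about 8.7 years). The offset is shared across a sample's
    sites, so some individuals deviate coherently from their chronological
    age — the inter-individual divergence age cohorts actually show, and
    the reason an epsilon-insensitive loss pays off over squared error.
    Values are clipped to [0, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))
    ages = rng.uniform(age_range[0], age_range[1], n_samples)
    accel = accel_scale * rng.standard_t(accel_df, size=n_samples)
    eage = ages + accel
    n_pos = (n_sites + 1) // 2
    lo_a, hi_a = age_range
    X = np.empty((n_samples, n_sites))
    for j in range(n_sites):
        sign = 1.0 if j < n_pos else -1.0
        s = sign * rng.uniform(slope_range[0], slope_range[1])
        if sign > 0:
            b0 = rng.uniform(0.05, max(0.06, 0.95 - slope_range[1] * hi_a))
        else:
            b0 = rng.uniform(min(0.94, 0.05 + slope_range[1] * hi_a), 0.95)
        X[:, j] = np.clip(b0 + s * eage + rng.normal(0.0, noise_sd, n_samples), 0.0, 1.0)
    return X, ages
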