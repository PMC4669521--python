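"""Genome-scale age-association scan of beta values.

Stage 1 of the analysis: mask values with poor detection p, impute the
gaps with a row-KNN scheme, regress each site's beta on age (OLS with a
Student t test on the slope), adjust p-values by Benjamini-Hochberg, and
select age-associated sites with two filters — a loose one (P < 0.01 and
R^2 > 0.5) and a strict one (FDR q < 0.01). A Fisher exact test checks
whether the selected sites are enriched in CpG islands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .matrix import CohortMetadata, MethylationMatrix

__all__ = [
    "ScanConfig",
    "mask_low_detection",
    "knn_impute",
    "site_regression",
    "scan_associations",
    "bh_fdr",
    "select_sites",
    "island_enrichment",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan thresholds; defaults are the conventional cutoffs for this workflow."""

    detection_p_max: float = 0.01
    knn_k: int = 10
    p_max: float = 0.01
    r2_min: float = 0.5
    fdr_max: float = 0.01

    def __post_init__(self) -> None:
        for name in ("detection_p_max", "p_max", "r2_min", "fdr_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        if self.knn_k < 1:
            raise ValidationError(f"knn_k must be >= 1, got {self.knn_k}")


def mask_low_detection(matrix: MethylationMatrix, threshold: float = 0.01) -> MethylationMatrix:
    """Set values whose detection p-value exceeds ``threshold`` to missing.

    The comparison is strict (> threshold); a value detected at exactly the
    threshold is kept.
    """
    if matrix.aux is None:
        raise ValidationError("mask_low_detection requires a detection-p aux layer")
    masked = matrix.values.where(~(matrix.aux > threshold))
    return MethylationMatrix(masked, matrix.aux.copy(), unit_interval=matrix.unit_interval)


def knn_impute(matrix: MethylationMatrix, k: int = 10) -> MethylationMatrix:
    """Impute missing values from the k nearest sites (rows).

    Nearness between two site rows is Euclidean distance over their mutually
    observed samples, scaled by sqrt(n_columns / n_shared) so that sparsely
    overlapping rows are not spuriously close. A missing cell is filled with
    the mean of that sample's values at the k nearest sites observed in that
    sample; distance ties break by input row order. Observed values are
    never altered.
    """
    X = matrix.values.to_numpy(dtype=float).copy()
    n_sites, n_samples = X.shape
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k >= n_sites:
        raise ValidationError(f"k={k} must be < number of sites ({n_sites})")
    obs = ~np.isnan(X)
    empty = np.flatnonzero(~obs.any(axis=1))
    if empty.size:
        ids = [matrix.values.index[i] for i in empty]
        raise ValidationError(f"sites with zero observed values: {ids[:10]}")
    rows_missing = np.flatnonzero(~obs.all(axis=1))
    if rows_missing.size == 0:
        return matrix.copy()

    X0 = np.where(obs, X, 0.0)
    filled = X.copy()
    for i in rows_missing:
        # distances from row i to all rows over mutually observed samples
        shared = obs & obs[i]  # (n_sites, n_samples)
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, X0 - X0[i], 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d2 = (diff**2).sum(axis=1) * (n_samples / n_shared)
        d2[i] = np.inf
        d2[n_shared == 0] = np.inf
        order = np.argsort(d2, kind="stable")  # stable => ties by row order
        for j in np.flatnonzero(~obs[i]):
            donors = [r for r in order if obs[r, j] and np.isfinite(d2[r])][:k]
            if not donors:
                raise ValidationError(
                    f"no neighbour with an observed value for site "
                    f"{matrix.values.index[i]!r}, sample {matrix.values.columns[j]!r}"
                )
            filled[i, j] = X[donors, j].mean()
    out = pd.DataFrame(filled, index=matrix.values.index, columns=matrix.values.columns)
    aux = None if matrix.aux is None else matrix.aux.copy()
    return MethylationMatrix(out, aux, unit_interval=matrix.unit_interval)


def site_regression(beta_row: np.ndarray, ages: np.ndarray) -> dict:
    """OLS of one site's beta on age with the Student t test on the slope.

    Returns slope, intercept, Pearson R, R^2, t = R*sqrt((n-2)/(1-R^2)),
    two-sided p from the t distribution with n-2 df, and n_used. Pairs with
    a missing member are dropped. Zero-variance beta (or age) is reported
    as R=0, p=1, slope=0 and flagged ``degenerate`` so record tables stay
    total and filterable.
    """
    beta_row = np.asarray(beta_row, dtype=float)
    ages = np.asarray(ages, dtype=float)
    keep = np.isfinite(beta_row) & np.isfinite(ages)
    x, y = ages[keep], beta_row[keep]
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 paired observations, got {n}")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return {
            "slope": 0.0, "intercept": float(y.mean()), "R": 0.0, "R2": 0.0,
            "t": 0.0, "p": 1.0, "n_used": int(n), "degenerate": True,
        }
    xc, yc = x - x.mean(), y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * x.mean())
    r = float(xc @ yc / np.sqrt(sxx * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t, p = np.inf if r > 0 else -np.inf, 0.0  # underflow convention
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return {
        "slope": slope, "intercept": intercept, "R": r, "R2": r * r,
        "t": float(t), "p": p, "n_used": int(n), "degenerate": False,
    }


def scan_associations(matrix: MethylationMatrix, meta: CohortMetadata) -> pd.DataFrame:
    """Per-site regression of beta on age across a whole matrix.

    Vectorised over complete rows (the common case after imputation); rows
    with residual missingness fall back to the per-site path. Output table
    columns: site_id, slope, intercept, R, R2, t, p, q, n_used; q is the
    Benjamini-Hochberg adjusted p.
    """
    ages = meta.ages_for(matrix.sample_ids)
    X = matrix.values.to_numpy(dtype=float)
    n_sites, n = X.shape
    if n < 3:
        raise ValidationError(f"need >= 3 samples, got {n}")
    complete = np.isfinite(X).all(axis=1)

    out = np.empty((n_sites, 7))
    if complete.any():
        Y = X[complete]
        xc = ages - ages.mean()
        sxx = float(xc @ xc)
        if sxx == 0:
            raise ValidationError("ages have zero variance")
        yc = Y - Y.mean(axis=1, keepdims=True)
        syy = (yc**2).sum(axis=1)
        sxy = yc @ xc
        slope = sxy / sxx
        intercept = Y.mean(axis=1) - slope * ages.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            r = sxy / np.sqrt(sxx * syy)
        degen = syy == 0
        r = np.clip(np.where(degen, 0.0, r), -1.0, 1.0)
        slope = np.where(degen, 0.0, slope)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1 - r * r))
        p = np.where(
            np.abs(r) == 1.0, 0.0, 2 * stats.t.sf(np.abs(np.where(np.abs(r) == 1, 0, t)), df=n - 2)
        )
        p = np.where(degen, 1.0, p)
        out[complete] = np.column_stack(
            [slope, intercept, r, r**2, t, p, np.full(Y.shape[0], n)]
        )
    for i in np.flatnonzero(~complete):
        rec = site_regression(X[i], ages)
        out[i] = [rec["slope"], rec["intercept"], rec["R"], rec["R2"], rec["t"], rec["p"], rec["n_used"]]

    table = pd.DataFrame(
        out, columns=["slope", "intercept", "R", "R2", "t", "p", "n_used"]
    )
    table.insert(0, "site_id", matrix.site_ids)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["n_used"] = table["n_used"].astype(int)
    return table


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted scale, mapped back to
    the input order; monotone and order-preserving.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class SiteSelection:
    """Result of threshold-based site selection from a scan table."""

    loose: list[str]
    strict: list[str]
    loose_positive: int
    loose_negative: int
    strict_positive: int
    strict_negative: int


def select_sites(records: pd.DataFrame, config: ScanConfig = ScanConfig()) -> SiteSelection:
    """Apply the loose (p < p_max and R^2 > r2_min) and strict (q < fdr_max)
    filters; inequalities are strict, exactly as printed. Lists are sorted
    by site id; positive/negative counts split on the slope sign.
    """
    needed = {"site_id", "p", "R2", "q", "slope"}
    missing = needed - set(records.columns)
    if missing:
        raise ValidationError(f"records table missing columns: {sorted(missing)}")
    loose_mask = (records["p"] < config.p_max) & (records["R2"] > config.r2_min)
    strict_mask = records["q"] < config.fdr_max
    loose = records.loc[loose_mask]
    strict = records.loc[strict_mask]
    return SiteSelection(
        loose=sorted(loose["site_id"]),
        strict=sorted(strict["site_id"]),
        loose_positive=int((loose["slope"] > 0).sum()),
        loose_negative=int((loose["slope"] < 0).sum()),
        strict_positive=int((strict["slope"] > 0).sum()),
        strict_negative=int((strict["slope"] < 0).sum()),
    )


def island_enrichment(
    selected_sites: Sequence[str],
    annotation: Mapping[str, bool],
    universe: Sequence[str],
) -> tuple[np.ndarray, float]:
    """CpG-island enrichment of selected sites by two-sided Fisher exact test.

    The 2x2 table has rows {selected, universe minus selected} and columns
    {island, non-island}; the p-value is the hypergeometric two-sided tail.
    Every site in the universe must be annotated; the universe must contain
    every selected site.
    """
    selected = set(map(str, selected_sites))
    universe_set = set(map(str, universe))
    if not selected:
        raise ValidationError("empty selection")
    if not selected <= universe_set:
        raise ValidationError(f"selected sites outside universe: {sorted(selected - universe_set)[:5]}")
    unannotated = [s for s in universe_set if s not in annotation]
    if unannotated:
        raise ValidationError(f"unannotated sites: {sorted(unannotated)[:5]}")
    rest = universe_set - selected
    a = sum(bool(annotation[s]) for s in selected)
    b = len(selected) - a
    c = sum(bool(annotation[s]) for s in rest)
    d = len(rest) - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)
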