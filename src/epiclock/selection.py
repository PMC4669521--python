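"""Leave-one-out cross-validation and exhaustive CpG-subset selection.

The study's validation logic: every candidate model is scored by
leave-one-out (LOO) MAD — fit on n-1 samples, predict the held-out one —
and, to find a small marker panel, *every* subset of the candidate sites is
scored this way, recording the minimal LOO MAD per subset size. The
contrast between resubstitution (training-set) MAD and LOO MAD is the
over-fitting diagnostic this exercise exists for, so both are recorded for
every subset.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .models import BaseAgeModel, mad

__all__ = [
    "PredictionReport",
    "SubsetSearchResult",
    "loo_cv",
    "exhaustive_subset_search",
    "choose_final_subset",
]

logger = logging.getLogger(__name__)

MAX_EXHAUSTIVE_FEATURES = 20


@dataclass
class PredictionReport:
    """Per-sample observed/predicted ages and the summary MAD (years)."""

    table: pd.DataFrame  # columns: observed, predicted, residual
    mad: float


@dataclass
class SubsetSearchResult:
    """Full exhaustive-search record.

    ``table`` has one row per evaluated subset (size, subset tuple,
    loo_mad, fit_mad); ``minima`` one row per requested size with the
    minimal LOO MAD and its arg-min subset (lexicographically smallest on
    ties).
    """

    table: pd.DataFrame
    minima: pd.DataFrame
    family: str
    hyperparameters: dict = field(default_factory=dict)


def _clone(model: BaseAgeModel) -> BaseAgeModel:
    return type(model)(**model.get_params())


def loo_cv(
    model: BaseAgeModel,
    features: np.ndarray,
    ages: np.ndarray,
    base_seed: Optional[int] = None,
) -> PredictionReport:
    """Leave-one-out cross-validation of a model on (features, ages).

    For each sample i the model is re-fit on the other n-1 samples and
    predicts sample i. Deterministic families give deterministic reports;
    a stochastic family (BPNN) is reseeded per fold as base_seed + fold
    index when it exposes a ``seed`` parameter.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(ages, dtype=float)
    n = y.size
    if X.shape[0] != n:
        raise ValidationError(f"features rows ({X.shape[0]}) != ages ({n})")
    if n < 3:
        raise ValidationError(f"need >= 3 samples for leave-one-out, got {n}")
    preds = np.empty(n)
    has_seed = "seed" in model.get_params()
    for i in range(n):
        fold = _clone(model)
        if has_seed and base_seed is not None:
            fold.set_params(seed=base_seed + i)
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            fold.fit(X[keep], y[keep])
        except Exception as exc:
            raise ValidationError(f"fold {i} failed to fit: {exc}") from exc
        preds[i] = fold.predict(X[i : i + 1])[0]
    table = pd.DataFrame(
        {"observed": y, "predicted": preds, "residual": preds - y}
    )
    return PredictionReport(table=table, mad=mad(preds, y))


def exhaustive_subset_search(
    features: pd.DataFrame,
    ages: np.ndarray,
    model: BaseAgeModel,
    sizes: Sequence[int],
    base_seed: Optional[int] = None,
    allow_large: bool = False,
) -> SubsetSearchResult:
    """Score every site subset of each requested size by LOO MAD.

    ``features`` is a samples x sites DataFrame whose columns name the
    sites. Returns the full (subset, loo_mad, fit_mad) table plus per-size
    minima; ties on minimal MAD break toward the lexicographically smallest
    site-id tuple (site order within a subset follows the input column
    order, so tuples are comparable).
    """
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(
            np.asarray(features, dtype=float),
            columns=[f"x{j}" for j in range(np.asarray(features).shape[1])],
        )
    y = np.asarray(ages, dtype=float)
    p = features.shape[1]
    if p > MAX_EXHAUSTIVE_FEATURES and not allow_large:
        raise ValidationError(
            f"{p} features would require {2**p - 1} subsets; pass allow_large=True "
            f"to override the {MAX_EXHAUSTIVE_FEATURES}-feature guard"
        )
    sizes = sorted(set(int(k) for k in sizes))
    if not sizes or sizes[0] < 1 or sizes[-1] > p:
        raise ValidationError(f"sizes must be within 1..{p}, got {sizes}")

    site_ids = list(features.columns)
    Xall = features.to_numpy(dtype=float)
    rows = []
    for k in sizes:
        logger.info("subset search: size %d (%d subsets)", k, math.comb(p, k))
        for combo in itertools.combinations(range(p), k):
            X = Xall[:, combo]
            report = loo_cv(model, X, y, base_seed=base_seed)
            fit_model = _clone(model)
            if base_seed is not None and "seed" in fit_model.get_params():
                fit_model.set_params(seed=base_seed)
            fit_mad = fit_model.fit_predict_mad(X, y)
            rows.append(
                {
                    "size": k,
                    "subset": tuple(site_ids[j] for j in combo),
                    "loo_mad": report.mad,
                    "fit_mad": fit_mad,
                }
            )
    table = pd.DataFrame(rows)
    minima_rows = []
    for k in sizes:
        block = table[table["size"] == k]
        best = block["loo_mad"].min()
        winners = block.loc[block["loo_mad"] == best, "subset"]
        argmin = min(winners)  # lexicographic tie-break
        minima_rows.append(
            {
                "size": k,
                "min_loo_mad": float(best),
                "subset": argmin,
                "fit_mad": float(
                    block.loc[block["subset"] == argmin, "fit_mad"].iloc[0]
                ),
            }
        )
    minima = pd.DataFrame(minima_rows)
    return SubsetSearchResult(
        table=table,
        minima=minima,
        family=type(model).__name__,
        hyperparameters=model.get_params(),
    )


def choose_final_subset(
    result: SubsetSearchResult, tolerance: float = 0.05
) -> tuple[int, tuple[str, ...]]:
    """Pick the final marker panel from per-size minima.

    Default policy: the smallest size whose minimal LOO MAD is within
    ``tolerance`` years of the global minimum over all sizes — the formal
    version of trading a site or two for negligible accuracy loss.
    """
    minima = result.minima
    if minima.empty:
        raise ValidationError("empty subset-search result")
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    global_min = minima["min_loo_mad"].min()
    ok = minima[minima["min_loo_mad"] <= global_min + tolerance]
    row = ok.loc[ok["size"].idxmin()]
    return int(row["size"]), tuple(row["subset"])
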