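"""Prediction assessment: PCC, MSE, fit slope, repeated subsampling.

The evaluation protocol guards against selection bias by repeatedly
drawing fixed-size subsamples without replacement and averaging the
metrics:

* SNV vs non-SNV comparison — a single subsample size
  N = floor(0.5 * min(|SNV|, |non-SNV|)) is applied to the whole
  dataset and to both strata, with 100 independent draws each;
* chemical-category comparison — a category is assessed only if it
  holds at least ceil(f * |dataset|) records (f = 0.10 by default,
  0.50 for small protein-DNA sets); the subsample size is then
  K = floor(0.5 * |category|).

Reported values are the across-draw mean and sample standard deviation
of the Pearson correlation, mean squared error and ordinary
least-squares slope of predicted on experimental ddG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .dataset_io import Dataset, MutationRecord, PredictionSet
from .energetics import STABILIZING_DIRECTION, split_snv
from .genetic_code import InputError, SNVLookup
from .mutation_typing import (
    DEFAULT_SCHEME,
    PropertyScheme,
    SubstitutionCategory,
    stratify_by_category,
)

__all__ = [
    "SamplingPlan",
    "AssessmentResult",
    "pearson",
    "mse",
    "fit_slope",
    "align_prediction_sign",
    "snv_sample_size",
    "class_inclusion_threshold",
    "paired_arrays",
    "subsample_metrics",
    "assess_snv_vs_nonsnv",
    "assess_by_category",
]


class UndefinedResultError(ValueError):
    """A metric is undefined for the given input (e.g. zero variance)."""


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation between experimental and predicted ddG."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("pearson requires two equal-length 1-D vectors")
    if x.size < 3:
        raise InputError(f"pearson requires >= 3 points, got {x.size}")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedResultError("pearson undefined for zero-variance input")
    return float(dx @ dy) / math.sqrt(sxx * syy)


def mse(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Mean squared error, (kcal/mol)^2."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise InputError("mse requires two equal-length non-empty vectors")
    diff = y_true - y_pred
    return float(diff @ diff) / y_true.size


def fit_slope(x: Sequence[float], y: Sequence[float]) -> float:
    """OLS slope of predicted (y) on experimental (x), intercept included.

    A slope below 1 means the predictor systematically underestimates
    the magnitude of the energy change.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise InputError("fit_slope requires two equal-length vectors of >= 2 points")
    dx = x - x.mean()
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise UndefinedResultError("fit_slope undefined for zero x-variance")
    return float(dx @ (y - y.mean())) / sxx


def align_prediction_sign(preds: PredictionSet, dataset_kind: str) -> PredictionSet:
    """Express predictions in the dataset's native sign convention.

    Folding datasets are stabilizing-positive, binding datasets
    destabilizing-positive.  The operation is idempotent: the returned
    set declares ``convention="dataset"``.
    """
    if dataset_kind not in STABILIZING_DIRECTION:
        raise InputError(f"unknown dataset kind {dataset_kind!r}")
    native = ("stabilizing_positive" if STABILIZING_DIRECTION[dataset_kind] > 0
              else "destabilizing_positive")
    if preds.convention == "dataset" or preds.convention == native:
        return replace(preds, values=dict(preds.values), convention="dataset")
    if preds.convention in ("stabilizing_positive", "destabilizing_positive"):
        return replace(
            preds,
            values={k: -v for k, v in preds.values.items()},
            convention="dataset",
        )
    raise InputError(
        f"prediction set {preds.predictor!r} has undeclared sign convention "
        f"{preds.convention!r}; declare one of dataset/stabilizing_positive/"
        f"destabilizing_positive"
    )


def snv_sample_size(n_snv: int, n_non_snv: int, fraction: float = 0.5) -> int:
    """Shared subsample size N = floor(fraction * min(n_snv, n_non_snv))."""
    if n_snv < 1 or n_non_snv < 1:
        raise InputError(
            f"both strata must be non-empty (SNV={n_snv}, non-SNV={n_non_snv})"
        )
    return math.floor(fraction * min(n_snv, n_non_snv))


def class_inclusion_threshold(n_total: int, fraction: float) -> int:
    """Minimum category size for assessment: ceil(fraction * n_total)."""
    if not 0 < fraction <= 1:
        raise InputError(f"fraction must be in (0, 1], got {fraction}")
    return math.ceil(fraction * n_total)


@dataclass
class SamplingPlan:
    """Parameters of the repeated-subsampling protocol."""

    n_draws: int = 100
    fraction: float = 0.5
    inclusion_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise InputError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.n_draws < 1:
            raise InputError(f"n_draws must be >= 1, got {self.n_draws}")


@dataclass
class AssessmentResult:
    """Across-draw mean +/- SD of PCC, MSE and fit slope for one stratum."""

    stratum: str
    pool_size: int
    subsample_size: int
    n_draws: int
    pcc_mean: float
    pcc_sd: float
    mse_mean: float
    mse_sd: float
    slope_mean: float
    slope_sd: float

    def as_row(self) -> dict:
        return {
            "stratum": self.stratum, "pool_size": self.pool_size,
            "N": self.subsample_size, "n_draws": self.n_draws,
            "PCC": self.pcc_mean, "PCC_sd": self.pcc_sd,
            "MSE": self.mse_mean, "MSE_sd": self.mse_sd,
            "slope": self.slope_mean, "slope_sd": self.slope_sd,
        }


def paired_arrays(
    records: Sequence[MutationRecord], preds: PredictionSet
) -> tuple[np.ndarray, np.ndarray]:
    """Experimental / predicted vectors for a record pool.

    Records without a prediction abort with an error naming the missing
    ids — silent dropping would distort the strata.
    """
    missing = [r.record_id for r in records if r.record_id not in preds.values]
    if missing:
        raise InputError(
            f"prediction set {preds.predictor!r} lacks {len(missing)} record(s): "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    x = np.array([r.ddg_exp for r in records], dtype=float)
    y = np.array([preds.values[r.record_id] for r in records], dtype=float)
    return x, y


def subsample_metrics(
    x: np.ndarray,
    y: np.ndarray,
    subsample_size: int,
    plan: SamplingPlan,
    stratum: str = "",
    rng: np.random.Generator | None = None,
) -> AssessmentResult:
    """Repeatedly draw ``subsample_size`` pairs without replacement and
    average PCC, MSE and slope over the draws (sample SD across draws)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not 3 <= subsample_size <= n:
        raise InputError(
            f"stratum {stratum!r}: need pool size >= N >= 3 "
            f"(pool {n}, N {subsample_size})"
        )
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    pccs = np.empty(plan.n_draws)
    mses = np.empty(plan.n_draws)
    slopes = np.empty(plan.n_draws)
    for i in range(plan.n_draws):
        idx = rng.choice(n, size=subsample_size, replace=False)
        xs, ys = x[idx], y[idx]
        pccs[i] = pearson(xs, ys)
        mses[i] = mse(xs, ys)
        slopes[i] = fit_slope(xs, ys)
    ddof = 1 if plan.n_draws > 1 else 0
    return AssessmentResult(
        stratum=stratum, pool_size=n, subsample_size=subsample_size,
        n_draws=plan.n_draws,
        pcc_mean=float(pccs.mean()), pcc_sd=float(pccs.std(ddof=ddof)),
        mse_mean=float(mses.mean()), mse_sd=float(mses.std(ddof=ddof)),
        slope_mean=float(slopes.mean()), slope_sd=float(slopes.std(ddof=ddof)),
    )


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-stratum substreams from one master seed, so strata
    stay comparable across runs."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def assess_snv_vs_nonsnv(
    dataset: Dataset,
    preds: PredictionSet,
    lookup: SNVLookup,
    plan: SamplingPlan | None = None,
) -> dict[str, AssessmentResult]:
    """Assess the whole dataset and its SNV / non-SNV strata with a shared
    subsample size N = floor(fraction * min(|SNV|, |non-SNV|))."""
    plan = plan or SamplingPlan()
    preds = align_prediction_sign(preds, dataset.dataset_kind)
    strata = split_snv(dataset, lookup)
    n_snv, n_non = len(strata["SNV"]), len(strata["non-SNV"])
    N = snv_sample_size(n_snv, n_non, plan.fraction)
    pools = {"whole": list(dataset.records), "SNV": strata["SNV"],
             "non-SNV": strata["non-SNV"]}
    for label, pool in pools.items():
        if len(pool) < N:
            raise InputError(
                f"stratum {label!r} ({len(pool)} records) smaller than N={N}"
            )
    rngs = _spawn_rngs(plan.seed, len(pools))
    out = {}
    for (label, pool), rng in zip(pools.items(), rngs):
        x, y = paired_arrays(pool, preds)
        out[label] = subsample_metrics(x, y, N, plan, stratum=label, rng=rng)
    return out


def assess_by_category(
    dataset: Dataset,
    preds: PredictionSet,
    scheme: PropertyScheme = DEFAULT_SCHEME,
    axis: str | None = None,
    plan: SamplingPlan | None = None,
) -> tuple[dict[SubstitutionCategory, AssessmentResult], list[SubstitutionCategory]]:
    """Assess qualifying substitution categories on one axis (or all axes).

    A category qualifies when its size reaches
    ceil(inclusion_fraction * |dataset|); each qualifying category is
    subsampled at K = floor(fraction * |category|).  Returns the results
    and the list of skipped (under-threshold) categories.
    """
    plan = plan or SamplingPlan()
    preds = align_prediction_sign(preds, dataset.dataset_kind)
    axes = [axis] if axis is not None else list(scheme.axes)
    threshold = class_inclusion_threshold(len(dataset), plan.inclusion_fraction)
    categories: dict[SubstitutionCategory, list[MutationRecord]] = {}
    for ax in axes:
        categories.update(stratify_by_category(dataset, scheme, ax))
    ordered = sorted(categories, key=lambda c: (c.axis, c.wt_label, c.mut_label))
    qualifying = [c for c in ordered if len(categories[c]) >= threshold]
    skipped = [c for c in ordered if len(categories[c]) < threshold]
    rngs = _spawn_rngs(plan.seed, len(qualifying))
    results = {}
    for cat, rng in zip(qualifying, rngs):
        pool = categories[cat]
        K = math.floor(plan.fraction * len(pool))
        x, y = paired_arrays(pool, preds)
        results[cat] = subsample_metrics(x, y, K, plan, stratum=str(cat), rng=rng)
    return results, skipped
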