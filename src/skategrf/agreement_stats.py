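"""Agreement verification between plate-measured and posture-estimated GRF.

Implements the statistics used to validate a direction estimator against
force-plate truth at 10%-of-stride checkpoints (5%..95%): RMSE, ordinary
least squares of true on estimated values, ICC(2,1) (two-way random
effects, absolute agreement, single measure), Bland-Altman bias /
precision / limits of agreement, fixed- and proportional-error detection,
the 0.08 BW correction trigger, and leave-one-participant-out validation
of the fitted linear correction.

Paired data are carried as a long-format DataFrame with columns
``participant, trial, motion, component, pct, true_bw, est_bw`` (components
"X", "Y", "Z"; forces in BW units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .direction_estimator import COMPONENTS, CorrectionModel
from .errors import (
    DegenerateSignalError,
    FitError,
    InsufficientDataError,
    InvalidParameterError,
)

DEFAULT_GRID = tuple(range(5, 100, 10))  # 5, 15, ..., 95 % of stride

#: ICC banding (Koo & Li): half-open on the left edge of each band.
ICC_BANDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"))

REPORT_COLUMNS = [
    "component", "pct", "n", "true_mean", "true_sd", "est_mean", "est_sd",
    "slope", "intercept", "icc", "icc_category", "icc_degenerate",
    "bias", "precision", "loa_low", "loa_high", "ci_low", "ci_high",
    "fixed_error", "proportional_error", "prop_slope", "prop_ci_low", "prop_ci_high",
]


@dataclass
class AgreementReport:
    """Per-grid-point, per-component agreement table plus trigger state."""

    table: pd.DataFrame
    threshold: float = 0.08

    @property
    def max_abs_bias(self) -> float:
        biases = self.table["bias"].dropna()
        return float(np.abs(biases).max()) if len(biases) else float("nan")


def rmse(true_series: np.ndarray, est_series: np.ndarray) -> float:
    """Root mean square error between paired series (BW units)."""
    t = np.asarray(true_series, dtype=float).ravel()
    e = np.asarray(est_series, dtype=float).ravel()
    if t.shape != e.shape:
        raise InvalidParameterError("series lengths differ")
    if t.size == 0:
        raise InsufficientDataError("empty series")
    return float(np.sqrt(np.mean((t - e) ** 2)))


def regression_true_on_est(true_vals: np.ndarray, est_vals: np.ndarray) -> tuple[float, float]:
    """OLS with the true value as response and the estimate as predictor."""
    x = np.asarray(est_vals, dtype=float)
    y = np.asarray(true_vals, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need >= 3 pairs for regression")
    if np.var(x) <= 0:
        raise FitError("zero variance in estimates")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


@dataclass
class ICCResult:
    value: float
    category: str
    agreement: bool
    degenerate: bool = False


def icc_2_1(data: np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``data`` is an n x 2 matrix (trials x methods, no missing cells).
    Computed from the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Zero between-trial variance makes the coefficient ill-defined; the
    result is then flagged degenerate (value 0) rather than raised.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise InvalidParameterError("expected an n x 2 matrix (trials x methods)")
    n, k = data.shape
    if n < 3:
        raise InsufficientDataError("ICC needs >= 3 trials")
    if not np.all(np.isfinite(data)):
        raise InvalidParameterError("ICC input contains non-finite cells")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-15:
        return ICCResult(0.0, "poor", False, degenerate=True)
    value = float((msr - mse) / denom)
    category = "poor"
    for cut, name in ICC_BANDS:
        if value >= cut:
            category = name
            break
    return ICCResult(value, category, agreement=value >= 0.5)


@dataclass
class BlandAltman:
    bias: float
    precision: float
    loa_low: float
    loa_high: float
    ci_low: float
    ci_high: float
    fixed_error: bool


def bias_precision_loa(diffs: np.ndarray) -> BlandAltman:
    """Bland-Altman summary of estimate-minus-true differences.

    bias = mean, precision = sample sd (n-1), LoA = bias +/- 1.96*precision,
    95% CI of the bias via the t distribution; fixed error when that CI
    excludes zero.
    """
    d = np.asarray(diffs, dtype=float).ravel()
    if d.size < 2:
        raise InsufficientDataError("Bland-Altman needs >= 2 differences")
    bias = float(d.mean())
    precision = float(d.std(ddof=1))
    half = 1.96 * precision
    tcrit = stats.t.ppf(0.975, d.size - 1)
    ci_half = tcrit * precision / np.sqrt(d.size)
    ci_low, ci_high = bias - ci_half, bias + ci_half
    return BlandAltman(
        bias=bias,
        precision=precision,
        loa_low=bias - half,
        loa_high=bias + half,
        ci_low=ci_low,
        ci_high=ci_high,
        fixed_error=not (ci_low <= 0.0 <= ci_high),
    )


@dataclass
class ProportionalError:
    flag: bool
    slope: float
    ci_low: float
    ci_high: float
    p_value: float


def proportional_error(
    means: np.ndarray,
    diffs: np.ndarray,
    participant: np.ndarray,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> ProportionalError:
    """Detect proportional error on the Bland-Altman plot.

    A significant Pearson correlation between pairwise means (x) and
    differences (y) flags a proportional error. The slope of diffs on means
    gets a participant-clustered bootstrap CI (repeated trials per skater
    are not independent, so whole participants are resampled).
    """
    m = np.asarray(means, dtype=float).ravel()
    d = np.asarray(diffs, dtype=float).ravel()
    part = np.asarray(participant).ravel()
    if m.size < 4:
        raise InsufficientDataError("proportional-error test needs >= 4 points")
    if np.var(m) <= 0:
        raise DegenerateSignalError("zero variance in means: correlation undefined")
    if np.ptp(d) <= 1e-12 * max(1.0, np.max(np.abs(d))):
        # constant differences: correlation undefined, no proportional trend
        return ProportionalError(False, 0.0, 0.0, 0.0, 1.0)

    r, p = stats.pearsonr(m, d)
    slope = float(np.polyfit(m, d, 1)[0])

    clusters = np.unique(part)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    by_cluster = {c: np.nonzero(part == c)[0] for c in clusters}
    for b in range(n_boot):
        pick = rng.choice(clusters, size=clusters.size, replace=True)
        idx = np.concatenate([by_cluster[c] for c in pick])
        var = np.var(m[idx])
        if var <= 0:
            boot[b] = np.nan
            continue
        boot[b] = np.cov(m[idx], d[idx])[0, 1] / var * (len(idx) - 1) / len(idx)
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    return ProportionalError(bool(p < alpha), slope, float(lo), float(hi), float(p))


def timepoint_report(
    dataset: pd.DataFrame,
    grid: tuple[int, ...] = DEFAULT_GRID,
    threshold: float = 0.08,
    seed: int = 0,
) -> AgreementReport:
    """Full per-checkpoint verification table over components x grid points.

    Cells with too few trials for a statistic are left NaN (ICC needs >= 3,
    Bland-Altman >= 2, the proportional test >= 4) and the run continues.
    """
    rows = []
    for comp in COMPONENTS:
        sub_c = dataset[dataset["component"] == comp]
        for pct in grid:
            cell = sub_c[sub_c["pct"] == pct]
            t, e = cell["true_bw"].to_numpy(float), cell["est_bw"].to_numpy(float)
            n = len(cell)
            row: dict = {"component": comp, "pct": pct, "n": n}
            if n == 0:
                rows.append(row)
                continue
            row.update(
                true_mean=t.mean(), est_mean=e.mean(),
                true_sd=t.std(ddof=1) if n > 1 else np.nan,
                est_sd=e.std(ddof=1) if n > 1 else np.nan,
            )
            if n >= 3 and np.var(e) > 0:
                row["slope"], row["intercept"] = regression_true_on_est(t, e)
            if n >= 3:
                icc = icc_2_1(np.column_stack([t, e]))
                row.update(icc=icc.value, icc_category=icc.category,
                           icc_degenerate=icc.degenerate)
            if n >= 2:
                ba = bias_precision_loa(e - t)
                row.update(bias=ba.bias, precision=ba.precision,
                           loa_low=ba.loa_low, loa_high=ba.loa_high,
                           ci_low=ba.ci_low, ci_high=ba.ci_high,
                           fixed_error=ba.fixed_error)
            if n >= 4 and np.var((t + e) / 2) > 0:
                pe = proportional_error(
                    (t + e) / 2, e - t, cell["participant"].to_numpy(), seed=seed
                )
                row.update(proportional_error=pe.flag, prop_slope=pe.slope,
                           prop_ci_low=pe.ci_low, prop_ci_high=pe.ci_high)
            rows.append(row)
    table = pd.DataFrame(rows).reindex(columns=REPORT_COLUMNS)
    return AgreementReport(table=table, threshold=threshold)


def correction_trigger(report: AgreementReport, threshold: float = 0.08) -> bool:
    """True iff any component at any checkpoint has |bias| >= threshold (BW).

    The comparison is inclusive: a bias of exactly 8% of body weight fires.
    """
    biases = report.table["bias"].dropna() if "bias" in report.table else pd.Series(dtype=float)
    if biases.empty:
        warnings.warn("empty agreement report: trigger vacuously False", stacklevel=2)
        return False
    return bool((biases.abs() >= threshold - 1e-12).any())


def _fit_from_long(train: pd.DataFrame, fitted_for: str | None = None) -> CorrectionModel:
    slopes, intercepts = np.empty(3), np.empty(3)
    for j, comp in enumerate(COMPONENTS):
        sub = train[train["component"] == comp]
        if len(sub) < 3:
            raise InsufficientDataError(f"component {comp}': <3 training pairs")
        slopes[j], intercepts[j] = regression_true_on_est(
            sub["true_bw"].to_numpy(float), sub["est_bw"].to_numpy(float)
        )
    return CorrectionModel(slopes, intercepts, fitted_for=fitted_for)


def lopo_validate(
    dataset: pd.DataFrame,
    grid: tuple[int, ...] = DEFAULT_GRID,
    threshold: float = 0.08,
    seed: int = 0,
) -> dict:
    """Leave-one-participant-out validation of the linear correction.

    For every held-out participant the correction is fitted on the pooled
    remaining data (true on estimate, per component) and applied to the
    held-out estimates; pre/post RMSE and an out-of-sample agreement report
    are computed on held-out data only.
    """
    participants = dataset["participant"].unique()
    if len(participants) < 2:
        raise InsufficientDataError("LOPO needs >= 2 participants")

    folds: dict = {}
    corrected_frames = []
    for p in participants:
        held = dataset[dataset["participant"] == p]
        train = dataset[dataset["participant"] != p]
        if held.empty:
            warnings.warn(f"participant {p!r} has no trials: skipped", stacklevel=2)
            continue
        model = _fit_from_long(train)
        held = held.copy()
        comp_idx = held["component"].map({c: j for j, c in enumerate(COMPONENTS)})
        held["est_corrected"] = (
            held["est_bw"].to_numpy(float) * model.slopes[comp_idx]
            + model.intercepts[comp_idx]
        )
        pre = {c: rmse(g["true_bw"], g["est_bw"]) for c, g in held.groupby("component")}
        post = {c: rmse(g["true_bw"], g["est_corrected"]) for c, g in held.groupby("component")}
        folds[p] = {"model": model, "rmse_pre": pre, "rmse_post": post}
        corrected_frames.append(held.assign(est_bw=held["est_corrected"]))

    pooled = pd.concat(corrected_frames, ignore_index=True)
    report = timepoint_report(pooled, grid=grid, threshold=threshold, seed=seed)
    agg_pre = {c: rmse(g["true_bw"], g["est_bw"]) for c, g in dataset.groupby("component")}
    agg_post = {c: rmse(g["true_bw"], g["est_corrected"]) for c, g in pooled.groupby("component")}
    return {
        "folds": folds,
        "report": report,
        "rmse_pre": agg_pre,
        "rmse_post": agg_post,
    }
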