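"""Gait-cycle evaluation metrics and composite ranking scores.

Predicted and reference trajectories are compared on the normalized gait
cycle (heel strike to next ipsilateral heel strike), resampled to a fixed
grid of 100 nodes at 1..100 %GC.  Agreement is summarized by Pearson's r and
RMSE; temporal localization of disagreement uses one-dimensional statistical
parametric mapping (SPM): a node-wise two-group one-way-ANOVA F trajectory
with a family-wise critical threshold.

Four dimensionless scores rank competing input combinations:

    miscorrelation score = ((1 - r_pos) + (1 - r_mom)) / 2
    RMSE score           = (rmse_pos/peak_pos + rmse_mom/peak_mom) / 2,
                           peaks taken over the whole cohort of combinations
    SPM score            = (frac_pos + frac_mom) / 2,
                           frac = fraction of %GC nodes significantly different
    overall error score  = miscorrelation x RMSE x SPM   (lower is better)

The family-wise SPM threshold is a permutation max-statistic critical value
(seeded, assumption-light); a parametric node-wise F threshold with no
family-wise correction is available as a labeled fallback.  Random-field
theory thresholds are not implemented and no equivalence with them is
claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    CycleError,
    DegenerateCohortError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "N_GC_NODES",
    "SPMResult",
    "EvaluationRecord",
    "ScoreRecord",
    "resample_to_gait_cycle",
    "resample_series_cycles",
    "trial_agreement",
    "spm_f_test",
    "miscorrelation_score",
    "rmse_score",
    "spm_score",
    "overall_error_score",
    "residual_qq",
    "round_report",
]

N_GC_NODES = 100


def round_report(x: float, decimals: int = 4) -> float:
    """Report rounding: 4 decimals, round-half-even; internals stay full precision."""
    return float(np.round(x, decimals))


@dataclass
class SPMResult:
    """Node-wise F trajectory with its family-wise critical value."""

    f_trajectory: np.ndarray
    f_critical: float
    alpha: float
    method: str

    def __post_init__(self):
        self.f_trajectory = np.asarray(self.f_trajectory, dtype=float)
        if len(self.f_trajectory) != N_GC_NODES:
            raise ValidationError(f"F trajectory must have {N_GC_NODES} nodes")
        if np.any(self.f_trajectory < 0):
            raise ValidationError("F values must be nonnegative")

    @property
    def significant_nodes(self) -> list[int]:
        """%GC nodes (1..100) where F exceeds the critical value."""
        return [i + 1 for i in np.flatnonzero(self.f_trajectory > self.f_critical)]

    @property
    def fraction(self) -> float:
        return len(self.significant_nodes) / N_GC_NODES


@dataclass
class EvaluationRecord:
    """Per-combination validation metrics (mean +- SD across validation trials)."""

    combo_name: str
    r_pos_mean: float
    r_pos_sd: float
    r_mom_mean: float
    r_mom_sd: float
    rmse_pos_mean: float
    rmse_pos_sd: float
    rmse_mom_mean: float
    rmse_mom_sd: float
    spm_frac_pos: float
    spm_frac_mom: float

    def __post_init__(self):
        for r in (self.r_pos_mean, self.r_mom_mean):
            if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
                raise ValidationError("mean correlations must lie in [-1, 1]")
        if self.rmse_pos_mean < 0 or self.rmse_mom_mean < 0:
            raise ValidationError("RMSEs must be >= 0")
        for f in (self.spm_frac_pos, self.spm_frac_mom):
            if not 0 <= f <= 1:
                raise ValidationError("SPM fractions must lie in [0, 1]")


@dataclass
class ScoreRecord:
    """The composite ranking scores of one combination."""

    combo_name: str
    miscorrelation_score: float
    rmse_score: float
    spm_score: float
    overall_error_score: float

    def __post_init__(self):
        for v in (self.miscorrelation_score, self.rmse_score, self.spm_score):
            if v < 0:
                raise ValidationError("scores must be >= 0")
        expected = self.miscorrelation_score * self.rmse_score * self.spm_score
        if self.overall_error_score != expected:
            raise ValidationError("overall_error_score must equal the exact product")


def resample_to_gait_cycle(
    series: np.ndarray, events: Sequence[int], cycle_index: int
) -> np.ndarray:
    """One gait cycle resampled onto the 100-node %GC grid (nodes 1..100).

    The span runs from heel strike ``events[cycle_index]`` to the next one;
    values are linearly interpolated at 1..100 % of the cycle duration.
    """
    series = np.asarray(series, dtype=float)
    events = np.asarray(events, dtype=int)
    if not 0 <= cycle_index < len(events) - 1:
        raise CycleError(f"cycle_index {cycle_index} has no complete event-to-event span")
    start, end = events[cycle_index], events[cycle_index + 1]
    if end >= len(series) or end - start + 1 < 4:
        raise CycleError("cycle span incomplete or shorter than 4 samples")
    nodes = start + (np.arange(1, N_GC_NODES + 1) / N_GC_NODES) * (end - start)
    span_idx = np.arange(start, end + 1)
    return np.interp(nodes, span_idx, series[span_idx])


def resample_series_cycles(
    times: np.ndarray,
    values: np.ndarray,
    event_times: np.ndarray,
    cycles: Sequence[int],
) -> np.ndarray:
    """%GC curves of several cycles from an arbitrarily clocked series.

    Used for predictions, whose rows live on the feature-window clock rather
    than the mechanical clock.  Cycles whose span is not fully covered by
    ``times`` raise a CycleError.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    out = []
    for k in cycles:
        t0, t1 = event_times[k], event_times[k + 1]
        if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
            raise CycleError(f"cycle {k} span [{t0:g}, {t1:g}] not covered by the series")
        nodes = t0 + (np.arange(1, N_GC_NODES + 1) / N_GC_NODES) * (t1 - t0)
        out.append(np.interp(nodes, times, values))
    return np.array(out)


def trial_agreement(pred: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    """(Pearson r, RMSE) between predicted and reference series.

    RMSE carries the target's units.  A constant reference makes r undefined;
    an UndefinedCorrelationError carrying the RMSE is raised.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or len(pred) < 3:
        raise ValidationError("pred and actual must be equal-length vectors of length >= 3")
    rmse = float(np.sqrt(np.mean((pred - actual) ** 2)))
    if np.ptp(actual) == 0:
        raise UndefinedCorrelationError(rmse)
    r = float(stats.pearsonr(pred, actual).statistic)
    return r, rmse


def _f_two_group(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Node-wise one-way ANOVA F for two groups of curves (equals t^2)."""
    n_a, n_b = len(a), len(b)
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    grand = (n_a * mean_a + n_b * mean_b) / (n_a + n_b)
    ss_between = n_a * (mean_a - grand) ** 2 + n_b * (mean_b - grand) ** 2
    ss_within = ((a - mean_a) ** 2).sum(axis=0) + ((b - mean_b) ** 2).sum(axis=0)
    df_within = n_a + n_b - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / (ss_within / df_within)
    return np.where(np.isfinite(f), f, 0.0)


def spm_f_test(
    actual_curves: np.ndarray,
    pred_curves: np.ndarray,
    alpha: float = 0.05,
    method: str = "permutation",
    n_permutations: int = 1000,
    seed: int = 0,
) -> SPMResult:
    """1-D SPM two-group F test over the %GC grid.

    ``method='permutation'`` (default): the family-wise critical value F* is
    the (1 - alpha) quantile of the max-over-nodes F under seeded random
    permutations of the group labels.  ``method='parametric_pointwise'`` uses
    the node-wise F(1, n_a+n_b-2) critical value with no family-wise
    correction (labeled fallback; liberal).
    """
    a = np.atleast_2d(np.asarray(actual_curves, dtype=float))
    b = np.atleast_2d(np.asarray(pred_curves, dtype=float))
    if a.shape[1] != N_GC_NODES or b.shape[1] != N_GC_NODES:
        raise ValidationError(f"curves must have {N_GC_NODES} nodes")
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least 2 curves per group")
    f_obs = _f_two_group(a, b)

    if method == "permutation":
        pooled = np.vstack([a, b])
        n_a = len(a)
        rng = np.random.default_rng(seed)
        max_f = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(len(pooled))
            max_f[i] = _f_two_group(pooled[perm[:n_a]], pooled[perm[n_a:]]).max()
        f_crit = float(np.quantile(max_f, 1.0 - alpha))
    elif method == "parametric_pointwise":
        f_crit = float(stats.f.ppf(1.0 - alpha, 1, len(a) + len(b) - 2))
    else:
        raise ValidationError(f"unknown SPM method: {method!r}")

    return SPMResult(f_trajectory=f_obs, f_critical=f_crit, alpha=alpha, method=method)


def miscorrelation_score(r_pos_mean: float, r_mom_mean: float) -> float:
    """Mean deviation of the two correlation means from one."""
    for r in (r_pos_mean, r_mom_mean):
        if not -1.0 <= r <= 1.0:
            raise ValidationError("correlation means must lie in [-1, 1]")
    return ((1.0 - r_pos_mean) + (1.0 - r_mom_mean)) / 2.0


def rmse_score(records: Sequence[EvaluationRecord]) -> list[float]:
    """Peak-normalized RMSE score of every record in a cohort.

    Each record's position and moment RMSE is normalized to its cohort peak
    (the maximum over all provided records), then the two ratios are averaged.
    The cohort must be the complete set of combinations being ranked.
    """
    if not records:
        raise ValidationError("need at least one record")
    peak_pos = max(r.rmse_pos_mean for r in records)
    peak_mom = max(r.rmse_mom_mean for r in records)
    if peak_pos == 0 or peak_mom == 0:
        raise DegenerateCohortError("cohort RMSE peak is zero")
    return [
        (r.rmse_pos_mean / peak_pos + r.rmse_mom_mean / peak_mom) / 2.0 for r in records
    ]


def spm_score(frac_pos: float, frac_mom: float) -> float:
    """Mean of the significant-node fractions of the two targets."""
    for f in (frac_pos, frac_mom):
        if not 0.0 <= f <= 1.0:
            raise ValidationError("SPM fractions must lie in [0, 1]")
    return (frac_pos + frac_mom) / 2.0


def overall_error_score(m: float, e: float, s: float) -> float:
    """Product of miscorrelation, RMSE and SPM scores; lower is better."""
    if m < 0 or e < 0 or s < 0:
        raise ValidationError("scores must be >= 0")
    return m * e * s


def residual_qq(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Normal Q-Q pairs for the prediction residuals (diagnostic).

    Returns [n x 2] pairs (theoretical standard-normal quantile, sorted
    residual), with Blom plotting positions (i - 3/8) / (n + 1/4).
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or len(pred) < 3:
        raise ValidationError("pred and actual must be equal-length vectors of length >= 3")
    resid = np.sort(pred - actual)
    n = len(resid)
    positions = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    return np.column_stack([stats.norm.ppf(positions), resid])
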