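"""Optimal-level selection, additive prediction and confirmation.

After the factor-response and ANOVA stages, the Taguchi procedure picks
the level with the highest mean S/N for each factor, predicts the S/N at
that combination with the additive model

    predicted = grand_mean + sum_f (level_mean(f, l*_f) - grand_mean)

restricted to the factors that survived ANOVA (including insignificant
factors overestimates the total effect), and checks the prediction with
a confirmation experiment. The prediction carries a confidence interval

    CI = t_{alpha/2, fe} * sqrt( MSe * (1/me + 1/mr) )

where MSe and fe come from the pooled error, mr is the confirmation
sample size and me = n_runs / (1 + sum of the dofs of the factors used
in the prediction) is the equivalent sample size. A confirmation S/N
inside the CI marks the study reliable. S/N gains translate to quality
loss through the half-per-3-dB rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .doe_design import FACTOR_CODES
from .taguchi_stats import ResponseTable

__all__ = [
    "Prediction",
    "ConfirmationResult",
    "CalibrationReport",
    "select_optimal",
    "predict_snr",
    "equivalent_sample_size",
    "confirmation_ci",
    "quality_loss_ratio",
    "calibration_report",
    "compare_confirmation",
]


@dataclass(frozen=True)
class Prediction:
    """Additive-model prediction of the S/N at selected factor levels."""

    selected_levels: dict[str, int]
    included_factors: tuple[str, ...]
    predicted_snr: float
    ci_half_width: float
    alpha: float
    me: float
    mr: int

    def __post_init__(self) -> None:
        if not set(self.included_factors) <= set(self.selected_levels):
            raise ValueError("included_factors must have selected levels")
        if self.ci_half_width < 0:
            raise ValueError("ci_half_width must be non-negative")
        if self.me <= 0 or self.mr < 1:
            raise ValueError("need me > 0 and mr >= 1")


@dataclass(frozen=True)
class ConfirmationResult:
    """Predicted vs confirmed S/N, CI verdict, and quality-loss ratio."""

    predicted_snr: float
    confirmed_snr: float
    deviation: float
    within_ci: bool
    quality_loss_ratio: float


@dataclass(frozen=True)
class CalibrationReport:
    """Ordinary least-squares linearity summary of measured vs commanded."""

    slope: float
    intercept: float
    r_squared: float
    sd_of_residuals: float
    cv_percent: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


def select_optimal(response: ResponseTable) -> dict[str, int]:
    """Per factor, the 1-based level index with the highest mean S/N.

    Ties break toward the lowest level index.
    """
    out = {}
    for f in FACTOR_CODES:
        means = response.level_means[f]
        out[f] = int(np.argmax(means)) + 1  # argmax takes first maximum
    return out


def predict_snr(
    response: ResponseTable,
    levels: Mapping[str, int],
    included_factors: Sequence[str],
) -> float:
    """Additive-model S/N at the given levels, using only the included factors."""
    included = tuple(included_factors)
    if not included:
        raise ValueError("included_factors must be non-empty")
    unknown = set(included) - set(FACTOR_CODES)
    if unknown:
        raise ValueError(f"unknown factors {sorted(unknown)}")
    g = response.grand_mean
    return g + sum(
        response.level_means[f][levels[f] - 1] - g for f in included
    )


def equivalent_sample_size(
    n_runs: int, included_factor_dofs: Sequence[int]
) -> float:
    """Effective replication of the additive prediction: n / (1 + sum dof)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    return n_runs / (1 + sum(included_factor_dofs))


def confirmation_ci(
    mse: float, fe: int, me: float, mr: int, alpha: float = 0.01
) -> float:
    """Half-width of the two-sided confirmation CI in dB.

    t_{alpha/2, fe} * sqrt( mse * (1/me + 1/mr) ).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if mse < 0:
        raise ValueError("mse must be non-negative")
    if fe < 1 or me <= 0 or mr < 1:
        raise ValueError("need fe >= 1, me > 0, mr >= 1")
    t_crit = float(sps.t.ppf(1 - alpha / 2, fe))
    return t_crit * math.sqrt(mse * (1.0 / me + 1.0 / mr))


def quality_loss_ratio(snr_optimal: float, snr_original: float) -> float:
    """Quality-loss ratio of the half-per-3-dB rule: 0.5^(gain / 3).

    Every 3 dB of S/N gain halves the expected quality loss; a gain of 0
    leaves it unchanged (ratio 1).
    """
    for v in (snr_optimal, snr_original):
        if not math.isfinite(v):
            raise ValueError("S/N values must be finite")
    return 0.5 ** ((snr_optimal - snr_original) / 3.0)


def calibration_report(x, y) -> CalibrationReport:
    """OLS linearity of measured y against commanded x.

    r_squared = 1 - RSS/TSS; residual SD uses divisor n - 2; CV% is
    100 * residual SD / mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("x is constant: slope undefined")
    fit = sps.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    sd = math.sqrt(rss / (len(x) - 2))
    cv = 100.0 * sd / float(y.mean()) if y.mean() else math.nan
    return CalibrationReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        sd_of_residuals=sd,
        cv_percent=cv,
    )


def compare_confirmation(
    predicted: float, confirmed: float, ci_half_width: float,
    quality_loss: float = math.nan,
) -> ConfirmationResult:
    """Deviation of the confirmed S/N from the prediction vs the CI."""
    deviation = abs(predicted - confirmed)
    return ConfirmationResult(
        predicted_snr=predicted,
        confirmed_snr=confirmed,
        deviation=deviation,
        within_ci=bool(deviation <= ci_half_width),
        quality_loss_ratio=quality_loss,
    )
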