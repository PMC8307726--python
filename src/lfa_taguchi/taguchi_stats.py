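"""Dynamic-characteristic S/N ratios, factor response analysis and ANOVA.

The reader's quality characteristic is dynamic: the measured band
grayscale y should be proportional to the commanded input level x. Each
run's quality is summarized by the zero-point proportional fit
``y = beta * x`` and its dispersion S_d, combined into the
signal-to-noise ratio

    S/N = -10 * log10(S_d^2 / beta^2)   [dB]

A larger S/N means a steeper, tighter calibration. Per-factor, per-level
means of the nine run S/N values form the response table; the range
(max - min) of a factor's level means ranks its influence, and a pooled
one-way ANOVA on the level means assigns each factor a confidence level.
Factors whose effect cannot be distinguished from noise are pooled into
the error term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .doe_design import FACTOR_CODES, DesignMatrix

__all__ = [
    "RunSeries",
    "DynamicSNResult",
    "ResponseTable",
    "AnovaRow",
    "AnovaTable",
    "fit_zero_intercept",
    "dynamic_sd",
    "snr_dynamic",
    "snr_for_series",
    "response_table",
    "anova",
    "f_tail",
    "reconstruct_runs",
    "read_run_series",
]

Divisor = Literal["n", "n-1", "n-2"]


@dataclass(frozen=True)
class RunSeries:
    """Calibration series of one run: commanded x and measured y."""

    run_id: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D and the same length")
        if len(x) < 3:
            raise ValueError("need at least 3 calibration points")
        if not np.any(x != 0):
            raise ValueError("x must not be all zero")


@dataclass(frozen=True)
class DynamicSNResult:
    """Slope, dispersion and S/N of one run's calibration fit."""

    beta: float
    sd: float
    snr: float

    @property
    def degenerate(self) -> bool:
        """True for a perfect proportional fit (S_d = 0, S/N = +inf)."""
        return not math.isfinite(self.snr)


def fit_zero_intercept(x, y) -> float:
    """Least-squares slope through the origin: beta = sum(xy) / sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("cannot fit a slope: x is all zero")
    return float(x @ y) / sxx


_DIVISORS = {"n": 0, "n-1": 1, "n-2": 2}


def dynamic_sd(x, y, beta: float, divisor: Divisor = "n-1") -> float:
    """Dispersion of y about the proportional fit beta*x.

    S_d = sqrt( sum((y - beta*x)^2) / d ) with d = n, n-1 (default) or
    n-2 depending on the chosen divisor convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 points")
    d = n - _DIVISORS[divisor]
    if d < 1:
        raise ValueError(f"divisor {divisor!r} needs more than {n} points")
    resid = y - beta * x
    return float(np.sqrt(resid @ resid / d))


def snr_dynamic(beta: float, sd: float) -> float:
    """Dynamic S/N in dB: -10*log10(sd^2 / beta^2).

    A perfect fit (sd = 0) returns +inf, flagged downstream as a
    degenerate result rather than an error.
    """
    if beta == 0:
        raise ValueError("S/N undefined for beta = 0")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0.0:
        return math.inf
    return -10.0 * math.log10(sd**2 / beta**2)


def snr_for_series(series: RunSeries, divisor: Divisor = "n-1") -> DynamicSNResult:
    """Fit one run's series and return (beta, S_d, S/N)."""
    beta = fit_zero_intercept(series.x, series.y)
    sd = dynamic_sd(series.x, series.y, beta, divisor)
    return DynamicSNResult(beta=beta, sd=sd, snr=snr_dynamic(beta, sd))


@dataclass(frozen=True)
class ResponseTable:
    """Per-factor, per-level mean S/N with range and rank.

    ``level_means[f][l]`` is the mean S/N (dB) of the three runs holding
    factor f at 1-based level l+1. Rank 1 marks the factor with the
    largest range; ties break in factor order A < B < C < D.
    """

    level_means: dict[str, tuple[float, float, float]]
    grand_mean: float
    range_r: dict[str, float] = field(default_factory=dict)
    rank: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.level_means) != set(FACTOR_CODES):
            raise ValueError(f"level_means must cover factors {FACTOR_CODES}")
        ranges = {
            f: max(means) - min(means) for f, means in self.level_means.items()
        }
        order = sorted(FACTOR_CODES, key=lambda f: (-ranges[f], f))
        object.__setattr__(self, "range_r", ranges)
        object.__setattr__(
            self, "rank", {f: order.index(f) + 1 for f in FACTOR_CODES}
        )

    @classmethod
    def from_level_means(
        cls,
        level_means: dict[str, Sequence[float]],
        grand_mean: float | None = None,
    ) -> "ResponseTable":
        """Build from a printed/stored table; grand mean defaults to the
        average of all twelve level means."""
        lm = {f: tuple(float(v) for v in vs) for f, vs in level_means.items()}
        if grand_mean is None:
            grand_mean = float(np.mean([v for vs in lm.values() for v in vs]))
        return cls(level_means=lm, grand_mean=grand_mean)

    def factor_ss(self, code: str) -> float:
        """Sum of squares of one factor: 3 * sum((level mean - grand)^2)."""
        return 3.0 * sum(
            (m - self.grand_mean) ** 2 for m in self.level_means[code]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in FACTOR_CODES:
            for l in range(3):
                rows.append(
                    {
                        "factor": f,
                        "level": l + 1,
                        "mean_snr": self.level_means[f][l],
                        "range": self.range_r[f],
                        "rank": self.rank[f],
                    }
                )
        return pd.DataFrame(rows)


def response_table(design: DesignMatrix, run_snrs: Sequence[float]) -> ResponseTable:
    """Factor-response analysis of the nine run S/N values."""
    snrs = np.asarray(run_snrs, dtype=float)
    if snrs.shape != (9,):
        raise ValueError(f"need exactly 9 run S/N values, got {snrs.shape}")
    level_means = {}
    for j, code in enumerate(FACTOR_CODES):
        level_means[code] = tuple(
            float(snrs[design.rows[:, j] == l].mean()) for l in (1, 2, 3)
        )
    return ResponseTable(
        level_means=level_means, grand_mean=float(snrs.mean())
    )


def f_tail(f_value: float, d1: int, d2: int) -> float:
    """Upper-tail probability of the F(d1, d2) distribution."""
    if f_value < 0:
        raise ValueError("F value must be non-negative")
    if d1 < 1 or d2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(sps.f.sf(f_value, d1, d2))


@dataclass(frozen=True)
class AnovaRow:
    factor: str
    ss: float
    dof: int
    var: float
    f: float | None
    probability: float | None
    confidence: float | None
    significant: bool
    pooled: bool


@dataclass(frozen=True)
class AnovaTable:
    rows: tuple[AnovaRow, ...]
    ss_error: float
    dof_error: int
    mse: float
    ss_total: float
    dof_total: int

    @property
    def significant_factors(self) -> tuple[str, ...]:
        return tuple(r.factor for r in self.rows if r.significant)

    @property
    def pooled_factors(self) -> tuple[str, ...]:
        return tuple(r.factor for r in self.rows if r.pooled)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "factor": r.factor,
                    "ss": r.ss,
                    "dof": r.dof,
                    "var": r.var,
                    "f": r.f,
                    "probability": r.probability,
                    "confidence": r.confidence,
                    "significant": r.significant,
                    "pooled": r.pooled,
                }
                for r in self.rows
            ]
        )


def anova(
    response: ResponseTable,
    pool: set[str] | frozenset[str] | Literal["auto"] = "auto",
    confidence_threshold: float = 0.95,
) -> AnovaTable:
    """Pooled ANOVA of the run S/N values via the response table.

    Each factor contributes ss = 3*sum((level mean - grand mean)^2) on 2
    degrees of freedom (a saturated L9 leaves no residual error, so the
    error term comes from pooling weak factors). ``pool`` is either an
    explicit set of factor codes or "auto": pool the two smallest-ss
    factors, then keep pooling the smallest remaining factor until every
    unpooled factor reaches the confidence threshold or only the
    largest-ss factor remains.
    """
    ss = {f: response.factor_ss(f) for f in FACTOR_CODES}
    if pool == "auto":
        by_ss = sorted(FACTOR_CODES, key=lambda f: (ss[f], f))
        pooled = set(by_ss[:2])  # keep dof_error >= 4
        while len(pooled) < 3:
            rows = _anova_rows(ss, pooled, confidence_threshold)
            weak = [
                r.factor
                for r in rows
                if not r.pooled and r.confidence < confidence_threshold
            ]
            if not weak:
                break
            pooled.add(min(weak, key=lambda f: (ss[f], f)))
    else:
        pooled = set(pool)
        unknown = pooled - set(FACTOR_CODES)
        if unknown:
            raise ValueError(f"unknown factor codes {sorted(unknown)}")
    if len(pooled) == 4:
        raise ValueError("cannot pool all four factors: nothing left to test")
    if len(pooled) == 0:
        raise ValueError("a saturated L9 needs at least one pooled factor")
    rows = _anova_rows(ss, pooled, confidence_threshold)
    ss_e = sum(ss[f] for f in pooled)
    dof_e = 2 * len(pooled)
    return AnovaTable(
        rows=tuple(rows),
        ss_error=ss_e,
        dof_error=dof_e,
        mse=ss_e / dof_e,
        ss_total=sum(ss.values()),
        dof_total=8,
    )


def _anova_rows(
    ss: dict[str, float], pooled: set[str], threshold: float
) -> list[AnovaRow]:
    ss_e = sum(ss[f] for f in pooled)
    dof_e = 2 * len(pooled)
    mse = ss_e / dof_e if dof_e else math.nan
    rows = []
    for f in FACTOR_CODES:
        var = ss[f] / 2.0
        if f in pooled:
            rows.append(
                AnovaRow(f, ss[f], 2, var, None, None, None, False, True)
            )
        else:
            if mse == 0:
                raise ValueError("pooled error is zero: F ratios undefined")
            fv = var / mse
            p = f_tail(fv, 2, dof_e)
            rows.append(
                AnovaRow(
                    f, ss[f], 2, var, fv, p, 1.0 - p, (1.0 - p) >= threshold,
                    False,
                )
            )
    return rows


def reconstruct_runs(
    design: DesignMatrix, level_means: dict[str, Sequence[float]]
) -> np.ndarray:
    """Recover the 9 run S/N values implied by a table of level means.

    Each run's S/N enters four level-mean equations (one per factor), so
    the twelve equations in nine unknowns have full column rank for an
    L9; the least-squares solution is the unique 9-vector consistent
    with an exact table, and the minimum-residual reconstruction when the
    table was rounded for printing.
    """
    m = np.zeros((12, 9))
    b = np.zeros(12)
    i = 0
    for j, code in enumerate(FACTOR_CODES):
        for l in (1, 2, 3):
            m[i, design.rows[:, j] == l] = 1.0 / 3.0
            b[i] = level_means[code][l - 1]
            i += 1
    if np.linalg.matrix_rank(m) < 9:
        raise ValueError("level-mean system is rank deficient")
    sol, *_ = np.linalg.lstsq(m, b, rcond=None)
    return sol


def read_run_series(path) -> list[RunSeries]:
    """Read run series from a CSV with columns run_id,input_level,measured."""
    df = pd.read_csv(path)
    required = {"run_id", "input_level", "measured"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"series CSV missing columns {sorted(missing)}")
    out = []
    for run_id, grp in df.groupby("run_id", sort=False):
        out.append(
            RunSeries(
                run_id=str(run_id),
                x=grp["input_level"].to_numpy(float),
                y=grp["measured"].to_numpy(float),
            )
        )
    return out
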