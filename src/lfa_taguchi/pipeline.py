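"""End-to-end study orchestration.

``run_study`` composes the whole chain — simulate strips, image them
through the camera model, measure C/T grayscales, fit per-run dynamic
S/N, build the response table and pooled ANOVA, select and predict the
optimum, and run seeded confirmation experiments — and writes a report
directory of CSVs plus a JSON summary. Everything is deterministic given
the config's base seed.

Seed plumbing: run r of the L9 uses per-run seed ``base_seed + r``; the
image for input level k within a run adds ``1009 * k``. Confirmation
replicates use run indices 20+ (original design) and 30+ (optimal) so no
image shares a noise stream with the screening runs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import doe_design, optimize_confirm, strip_quant, synthetic_strip
from . import taguchi_stats as ts
from .config import StudyConfig
from .doe_design import FACTOR_CODES
from .strip_quant import LineMeasurement, ROISpec
from .synthetic_strip import CameraSettings, StripGeometry, StripSpec

__all__ = ["StageError", "StudyReport", "run_study", "simulate_run", "summarize_confirmation"]

logger = logging.getLogger("lfa_taguchi")

_ORIGINAL_RUN_BASE = 20
_OPTIMAL_RUN_BASE = 30
_LEVEL_SEED_STRIDE = 1009


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and run."""


@dataclass(frozen=True)
class StudyReport:
    """In-memory result of a full study (also serialized to out_dir)."""

    plan: list[doe_design.RunPlan]
    measurements: list[LineMeasurement]
    run_results: list[ts.DynamicSNResult]
    response: ts.ResponseTable
    anova: ts.AnovaTable
    optimal_levels: dict[str, int]
    prediction: optimize_confirm.Prediction
    confirmation: optimize_confirm.ConfirmationResult
    original_confirmed_snr: float
    calibration_original: optimize_confirm.CalibrationReport
    calibration_optimal: optimize_confirm.CalibrationReport
    degenerate: bool

    def summary_dict(self) -> dict:
        conf = self.confirmation
        return {
            "optimal_levels": self.optimal_levels,
            "significant_factors": list(self.anova.significant_factors),
            "pooled_factors": list(self.anova.pooled_factors),
            "mse": self.anova.mse,
            "dof_error": self.anova.dof_error,
            "predicted_snr_db": self.prediction.predicted_snr,
            "ci_half_width_db": self.prediction.ci_half_width,
            "alpha": self.prediction.alpha,
            "me": self.prediction.me,
            "mr": self.prediction.mr,
            "confirmed_snr_db": conf.confirmed_snr,
            "original_confirmed_snr_db": self.original_confirmed_snr,
            "deviation_db": conf.deviation,
            "within_ci": conf.within_ci,
            # ratio of quality loss after/before, 0.5^(gain_dB / 3)
            "quality_loss_ratio": conf.quality_loss_ratio,
            "quality_loss_ratio_formula": "0.5 ** ((snr_optimal - snr_original) / 3)",
            "degenerate_perfect_fit": self.degenerate,
            "calibration": {
                "original": vars(self.calibration_original),
                "optimal": vars(self.calibration_optimal),
            },
        }


def _default_roi(geo: StripGeometry) -> ROISpec:
    top = max(0, geo.c_top - 20)
    bottom = min(geo.height, geo.t_top + geo.t_height + 20)
    return ROISpec(x0=0, y0=top, x1=geo.width, y1=bottom)


def simulate_run(
    settings: dict[str, float],
    config: StudyConfig,
    run_index: int,
    run_id: str,
) -> tuple[list[LineMeasurement], ts.RunSeries]:
    """Simulate and measure one run's full calibration series.

    Renders one strip per commanded input level, images it with the
    run's camera settings (seeded per image), and measures the C/T lines
    at the known band rows.
    """
    geo = StripGeometry(**config.geometry.model_dump())
    roi = _default_roi(geo)
    run_seed = config.base_seed + run_index
    measurements = []
    for k, level in enumerate(config.input_levels):
        spec = StripSpec(
            t_target_gray=int(level),
            c_target_gray=config.c_target_gray,
            fixed_red=config.fixed_red,
            geometry=geo,
        )
        cam = CameraSettings(
            **settings,
            noise_sd=config.noise_sd,
            seed=run_seed + _LEVEL_SEED_STRIDE * k,
        )
        image = synthetic_strip.apply_camera(
            synthetic_strip.render_strip(spec), cam
        )
        m = strip_quant.measure_lines(
            image.pixels,
            roi,
            bands=(geo.c_rows, geo.t_rows),
            run_id=run_id,
            input_level=float(level),
        )
        measurements.append(m)
    series = ts.RunSeries(
        run_id=run_id,
        x=np.array([m.input_level for m in measurements]),
        y=np.array([m.t_gray for m in measurements]),
    )
    return measurements, series


def summarize_confirmation(
    replicate_series: Sequence[ts.RunSeries],
    divisor: str = "n-1",
) -> tuple[float, list[ts.DynamicSNResult], bool]:
    """Mean S/N over confirmation replicates, flagging perfect fits.

    Returns (mean S/N dB, per-replicate results, degenerate flag). A
    replicate with S_d = 0 has infinite S/N; the mean is then +inf and
    the degenerate flag is set rather than raising.
    """
    results = [ts.snr_for_series(s, divisor) for s in replicate_series]
    snrs = [r.snr for r in results]
    degenerate = any(not math.isfinite(s) for s in snrs)
    mean_snr = math.inf if degenerate else float(np.mean(snrs))
    return mean_snr, results, degenerate


def _confirmation_series(
    config: StudyConfig,
    factors: list[doe_design.FactorSpec],
    level_indices: Sequence[int],
    run_base: int,
    label: str,
) -> tuple[list[LineMeasurement], list[ts.RunSeries]]:
    settings = doe_design.settings_for_levels(factors, level_indices)
    all_measurements: list[LineMeasurement] = []
    series = []
    for rep in range(config.confirmation_replicates):
        ms, s = simulate_run(
            settings, config, run_base + rep, f"{label}-rep{rep + 1}"
        )
        all_measurements.extend(ms)
        series.append(s)
    return all_measurements, series


def _mean_series_by_level(series: Sequence[ts.RunSeries]) -> tuple[np.ndarray, np.ndarray]:
    """Per-level mean of replicate measurements (the confirmation table row)."""
    x = series[0].x
    y = np.mean([s.y for s in series], axis=0)
    return x, y


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Run the complete robust-design study; optionally write a report dir."""
    factors = config.factor_specs()
    design = doe_design.l9_array()
    plan = doe_design.make_plan(factors, design, config.input_levels)
    logger.info("plan: 9 runs x %d input levels", len(config.input_levels))

    all_measurements: list[LineMeasurement] = []
    run_results: list[ts.DynamicSNResult] = []
    for i, rp in enumerate(plan):
        try:
            ms, series = simulate_run(rp.settings, config, i, f"run{rp.run_id}")
            res = ts.snr_for_series(series, config.sd_divisor)
        except Exception as exc:  # noqa: BLE001 - stage context added
            raise StageError(f"simulate/measure stage, run {rp.run_id}: {exc}") from exc
        logger.info(
            "run %d: beta=%.4f sd=%.3f snr=%.2f dB", rp.run_id, res.beta, res.sd, res.snr
        )
        all_measurements.extend(ms)
        run_results.append(res)

    snrs = [r.snr for r in run_results]
    if any(not math.isfinite(s) for s in snrs):
        raise StageError(
            "analysis stage: a screening run has a perfect proportional fit "
            "(S/N = +inf); factor analysis is undefined"
        )
    response = ts.response_table(design, snrs)
    pool = config.pooling if config.pooling == "auto" else set(config.pooling)
    anova_table = ts.anova(response, pool)
    logger.info(
        "anova: significant=%s pooled=%s mse=%.3f",
        anova_table.significant_factors, anova_table.pooled_factors, anova_table.mse,
    )

    optimal = optimize_confirm.select_optimal(response)
    included = anova_table.significant_factors or tuple(
        f for f in FACTOR_CODES if f not in anova_table.pooled_factors
    )
    predicted = optimize_confirm.predict_snr(response, optimal, included)
    me = optimize_confirm.equivalent_sample_size(9, [2] * len(included))
    mr = config.confirmation_replicates
    ci = optimize_confirm.confirmation_ci(
        anova_table.mse, anova_table.dof_error, me, mr, config.alpha
    )
    prediction = optimize_confirm.Prediction(
        selected_levels=optimal,
        included_factors=included,
        predicted_snr=predicted,
        ci_half_width=ci,
        alpha=config.alpha,
        me=me,
        mr=mr,
    )

    # Confirmation: triplicate runs at the original and the optimal settings.
    optimal_indices = [optimal[f] for f in FACTOR_CODES]
    orig_ms, orig_series = _confirmation_series(
        config, factors, config.original_levels, _ORIGINAL_RUN_BASE, "original"
    )
    opt_ms, opt_series = _confirmation_series(
        config, factors, optimal_indices, _OPTIMAL_RUN_BASE, "optimal"
    )
    all_measurements.extend(orig_ms)
    all_measurements.extend(opt_ms)
    orig_snr, _, orig_degen = summarize_confirmation(orig_series, config.sd_divisor)
    opt_snr, _, opt_degen = summarize_confirmation(opt_series, config.sd_divisor)
    degenerate = orig_degen or opt_degen
    qlr = (
        math.nan
        if degenerate
        else optimize_confirm.quality_loss_ratio(opt_snr, orig_snr)
    )
    confirmation = optimize_confirm.compare_confirmation(
        predicted, opt_snr, ci, quality_loss=qlr
    )
    logger.info(
        "confirmation: predicted=%.2f confirmed=%.2f (original %.2f) within_ci=%s",
        predicted, opt_snr, orig_snr, confirmation.within_ci,
    )

    cal_orig = optimize_confirm.calibration_report(*_mean_series_by_level(orig_series))
    cal_opt = optimize_confirm.calibration_report(*_mean_series_by_level(opt_series))

    report = StudyReport(
        plan=plan,
        measurements=all_measurements,
        run_results=run_results,
        response=response,
        anova=anova_table,
        optimal_levels=optimal,
        prediction=prediction,
        confirmation=confirmation,
        original_confirmed_snr=orig_snr,
        calibration_original=cal_orig,
        calibration_optimal=cal_opt,
        degenerate=degenerate,
    )
    if out_dir is not None:
        write_report(report, config, Path(out_dir))
    return report


def write_report(report: StudyReport, config: StudyConfig, out_dir: Path) -> None:
    """Serialize the study to a report directory (CSVs + JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doe_design.plan_to_csv(report.plan, out_dir / "plan.csv")
    strip_quant.write_measurements(report.measurements, out_dir / "measurements.csv")
    pd.DataFrame(
        [
            {
                "run_id": rp.run_id,
                "beta": r.beta,
                "sd": r.sd,
                "snr_db": r.snr,
            }
            for rp, r in zip(report.plan, report.run_results)
        ]
    ).to_csv(out_dir / "snr.csv", index=False)
    report.response.to_frame().to_csv(out_dir / "response_table.csv", index=False)
    report.anova.to_frame().to_csv(out_dir / "anova.csv", index=False)
    config.to_yaml(out_dir / "config.yaml")
    summary = report.summary_dict()
    summary["grand_mean_snr_db"] = report.response.grand_mean
    with open(out_dir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("report written to %s", out_dir)
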