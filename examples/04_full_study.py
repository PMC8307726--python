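"""The complete robust-design study in one call.

Simulate -> measure -> S/N -> response/ANOVA -> select optimum ->
additive prediction with a confirmation CI -> triplicate confirmation
runs at the original and optimal settings -> quality-loss ratio and
calibration linearity. Writes a report directory of CSVs plus JSON.
"""

import json
from pathlib import Path

from lfa_taguchi import StudyConfig, run_study

out = Path("scratch/example_study")
report = run_study(StudyConfig(base_seed=42), out_dir=out)

summary = report.summary_dict()
print(json.dumps({k: summary[k] for k in (
    "optimal_levels", "significant_factors", "predicted_snr_db",
    "ci_half_width_db", "confirmed_snr_db", "original_confirmed_snr_db",
    "within_ci", "quality_loss_ratio",
)}, indent=2))
print(f"\nfull report in {out}/: plan.csv, measurements.csv, snr.csv, "
      "response_table.csv, anova.csv, report.json")

# The optimum holds contrast at its highest level (slope closest to 1)
# and avoids the clipping 280-lux illuminance; the confirmed S/N at the
# optimum exceeds the original settings' S/N by >10 dB on this synthetic
# system, the deviation from the additive prediction stays inside the CI,
# and the quality-loss ratio (0.5^(gain/3)) drops well below 1.
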