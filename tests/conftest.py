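"""Shared fixtures: the reference study's published summary tables.

The reference study reports only summary statistics (per-level mean S/N,
ANOVA sums of squares, confirmation slopes/dispersions), not its raw
images, so these tables are the anchor inputs for regression tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from lfa_taguchi import l9_array

# Per-level mean S/N (dB) of the reference study's factor response table.
REFERENCE_LEVEL_MEANS = {
    "A": (-15.2, -11.7, -13.1),
    "B": (-17.7, -11.0, -11.3),
    "C": (-12.9, -13.9, -13.1),
    "D": (-12.4, -13.5, -14.0),
}

# Confirmation rows: 11 commanded levels and the measured grayscale means,
# plus the published (slope, dispersion, S/N) summaries.
REFERENCE_INPUT_LEVELS = (125, 150, 200, 240, 245, 250, 251, 252, 253, 254, 255)
REFERENCE_ORIGINAL_MEASURED = (
    117.85, 140.91, 200.59, 239.81, 243.31, 248.93, 248.61, 249.19,
    249.81, 250.64, 250.04,
)
REFERENCE_OPTIMAL_MEASURED = (
    117.68, 141.76, 200.83, 241.71, 245.05, 248.37, 248.21, 249.35,
    250.05, 253.29, 255.28,
)
REFERENCE_ORIGINAL_BETA_SD = (0.9998, 4.41)
REFERENCE_OPTIMAL_BETA_SD = (0.9925, 3.48)
REFERENCE_MSE = 1.33
REFERENCE_DOF_ERROR = 4


@pytest.fixture(scope="session")
def design():
    return l9_array()


@pytest.fixture(scope="session")
def reference_level_means():
    return {k: tuple(v) for k, v in REFERENCE_LEVEL_MEANS.items()}


@pytest.fixture(scope="session")
def reconstructed_snrs(design, reference_level_means):
    """The 9-run S/N vector implied by the reference level means."""
    from lfa_taguchi import reconstruct_runs

    return reconstruct_runs(design, reference_level_means)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210629)
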