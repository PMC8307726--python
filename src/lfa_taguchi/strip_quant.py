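"""Densitometry of lateral-flow strip images.

A captured cassette image contains two colored bands — the control line
(C line) and the test line (T line). Their grayscale intensities are the
measured response of the reader: the darker the band, the lower the
grayscale. This module converts RGB pixels to luma, extracts a per-row
intensity profile inside a region of interest (ROI), locates the two
bands, and reports each band's mean grayscale.

Conventions: images are ``H x W x 3`` uint8 arrays, row index increases
downward, rectangles are 0-based half-open. Grayscale is ITU-R BT.601
luma (0.299 R + 0.587 G + 0.114 B), kept unrounded for internal math.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LUMA_WEIGHTS",
    "ROISpec",
    "LineMeasurement",
    "BandDetectionError",
    "rgb_to_gray",
    "gray_image",
    "band_profile",
    "detect_bands",
    "measure_lines",
    "read_measurements",
    "write_measurements",
]

#: BT.601 luma weights for (R, G, B).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class BandDetectionError(RuntimeError):
    """Raised when fewer than two bands can be located in the ROI."""


@dataclass(frozen=True)
class ROISpec:
    """Half-open pixel rectangle ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate ROI {self}")
        if min(self.x0, self.y0) < 0:
            raise ValueError(f"negative ROI coordinates {self}")

    def check_within(self, shape: tuple[int, ...]) -> None:
        h, w = shape[0], shape[1]
        if self.x1 > w or self.y1 > h:
            raise ValueError(f"ROI {self} exceeds image bounds {h}x{w}")


@dataclass(frozen=True)
class LineMeasurement:
    """Grayscale readout of one strip image.

    ``input_level`` is the commanded grayscale of the T line (the signal
    x of the calibration); ``c_gray``/``t_gray`` are the measured band
    means (the response y).
    """

    run_id: str
    input_level: float
    c_gray: float
    t_gray: float

    def __post_init__(self) -> None:
        for name in ("c_gray", "t_gray"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name}={v} outside [0, 255]")

    @property
    def t_over_c(self) -> float:
        """T/C ratio; informational only, not used in the S/N chain."""
        return self.t_gray / self.c_gray if self.c_gray else math.nan


def rgb_to_gray(r, g, b):
    """BT.601 luma of channel values in [0, 255] (scalars or arrays)."""
    r, g, b = (np.asarray(c, dtype=float) for c in (r, g, b))
    for name, c in zip("rgb", (r, g, b)):
        if np.any(c < 0) or np.any(c > 255):
            raise ValueError(f"channel {name} outside [0, 255]")
    wr, wg, wb = LUMA_WEIGHTS
    out = wr * r + wg * g + wb * b
    return float(out) if out.ndim == 0 else out


def gray_image(pixels: np.ndarray) -> np.ndarray:
    """Luma plane of an ``H x W x 3`` image as float64."""
    px = np.asarray(pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {px.shape}")
    return rgb_to_gray(px[..., 0], px[..., 1], px[..., 2])


def band_profile(pixels: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Per-row mean grayscale inside the ROI (length ``y1 - y0``)."""
    px = np.asarray(pixels)
    roi.check_within(px.shape)
    gray = gray_image(px[roi.y0 : roi.y1, roi.x0 : roi.x1])
    return gray.mean(axis=1)


def _smooth(profile: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(profile) < window:
        return profile
    kernel = np.ones(window) / window
    # reflect-pad so the smoothed profile keeps its length
    pad = window // 2
    padded = np.pad(profile, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: len(profile)]


def detect_bands(
    profile: np.ndarray,
    smooth_window: int = 3,
    threshold_offset: float = 10.0,
) -> list[tuple[int, int]]:
    """Locate dark bands in a row profile.

    The profile is smoothed with a moving average, the background level is
    the median of the smoothed profile, and bands are maximal runs of rows
    more than ``threshold_offset`` grayscale units below background. Run
    edges are then trimmed against the unsmoothed profile, so transition
    rows the moving average dragged below threshold do not dilute the
    band. Returns half-open ``(start, stop)`` row ranges relative to the
    profile, in row order.
    """
    raw = np.asarray(profile, dtype=float)
    prof = _smooth(raw, smooth_window)
    threshold = float(np.median(prof)) - threshold_offset
    below = prof < threshold
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(below)))
    bands = []
    for s, e in runs:
        while s < e and raw[s] >= threshold:
            s += 1
        while e > s and raw[e - 1] >= threshold:
            e -= 1
        if s < e:
            bands.append((s, e))
    return bands


def measure_lines(
    pixels: np.ndarray,
    roi: ROISpec,
    bands: tuple[tuple[int, int], tuple[int, int]] | None = None,
    run_id: str = "",
    input_level: float = math.nan,
    smooth_window: int = 3,
    threshold_offset: float = 10.0,
) -> LineMeasurement:
    """Measure C- and T-line grayscales inside the ROI.

    With ``bands=None`` the two deepest dark bands are auto-detected from
    the row profile; the band nearer the sample end (smaller row index) is
    taken as the C line. ``bands`` may instead give explicit absolute
    image-row ranges ``((c0, c1), (t0, t1))`` — required when a band is
    too faint to clear the detection threshold (e.g. a T line within 10
    gray units of the background).

    The reported grayscale per line is the mean of the per-row profile
    over the band rows. Deterministic: identical input, identical output.
    """
    profile = band_profile(pixels, roi)
    if bands is None:
        found = detect_bands(profile, smooth_window, threshold_offset)
        if len(found) < 2:
            raise BandDetectionError(
                f"expected 2 bands below threshold, found {len(found)}"
            )
        if len(found) > 2:
            # keep the two deepest bands, then restore row order
            found = sorted(
                found, key=lambda se: profile[se[0] : se[1]].min()
            )[:2]
            found.sort()
        (c0, c1), (t0, t1) = found
    else:
        (c0, c1), (t0, t1) = (
            (b[0] - roi.y0, b[1] - roi.y0) for b in bands
        )
        for s, e in ((c0, c1), (t0, t1)):
            if not (0 <= s < e <= len(profile)):
                raise ValueError("band rows outside the ROI")
    return LineMeasurement(
        run_id=run_id,
        input_level=input_level,
        c_gray=float(profile[c0:c1].mean()),
        t_gray=float(profile[t0:t1].mean()),
    )


_CSV_COLUMNS = ["run_id", "input_level", "c_gray", "t_gray"]


def write_measurements(measurements: Sequence[LineMeasurement], path) -> None:
    """Write measurements as CSV with header run_id,input_level,c_gray,t_gray."""
    df = pd.DataFrame(
        [
            {
                "run_id": m.run_id,
                "input_level": m.input_level,
                "c_gray": m.c_gray,
                "t_gray": m.t_gray,
            }
            for m in measurements
        ],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_measurements(path) -> list[LineMeasurement]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns {sorted(missing)}")
    return [
        LineMeasurement(
            run_id=str(row.run_id),
            input_level=float(row.input_level),
            c_gray=float(row.c_gray),
            t_gray=float(row.t_gray),
        )
        for row in df.itertuples()
    ]
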