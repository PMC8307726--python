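"""Synthetic lateral-flow strips and a parametric camera model.

Real rapid tests develop colloidal-gold bands whose color varies with
analyte concentration, which makes them a poor calibration target. The
simulated strips used here instead fix the red channel and set G = B to
whatever value makes the band hit a commanded grayscale target, so the
commanded level is an exact, known input signal. A simple camera /
illumination model then maps control-factor settings (illuminance,
contrast, saturation, tone) plus sensor noise onto the rendered strip,
standing in for a physical darkroom, LED board and USB camera.

The camera model is a simulator contract, not a claim about any real
device: gain scales with illuminance relative to 240 lux, contrast and
saturation are linear remaps that are the identity at 0.5, tone is an
additive offset that vanishes at 0.5, and noise is i.i.d. Gaussian.
Neutral settings (240 lux, 0.5, 0.5, 0.5, no noise) are a strict no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import imageio.v3 as iio
import numpy as np

from .strip_quant import LUMA_WEIGHTS, rgb_to_gray

__all__ = [
    "NEUTRAL_ILLUMINANCE",
    "StripGeometry",
    "StripSpec",
    "CameraSettings",
    "StripImage",
    "UnreachableGrayError",
    "solve_gb_for_gray",
    "render_strip",
    "apply_camera",
    "write_png",
    "read_image",
]

#: Illuminance (lux) at which the camera gain is exactly 1.
NEUTRAL_ILLUMINANCE = 240.0


class UnreachableGrayError(ValueError):
    """Commanded grayscale cannot be reached with the fixed red channel."""


@dataclass(frozen=True)
class StripGeometry:
    """Pixel layout of the cassette window.

    Bands are horizontal stripes spanning the full width; rows are given
    as 0-based half-open ranges. Defaults give a 400x120 portrait window
    with the C band above the T band.
    """

    width: int = 120
    height: int = 400
    c_top: int = 60
    c_height: int = 20
    t_top: int = 140
    t_height: int = 20
    background_gray: int = 255

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        c0, c1 = self.c_top, self.c_top + self.c_height
        t0, t1 = self.t_top, self.t_top + self.t_height
        for name, (a, b) in (("C", (c0, c1)), ("T", (t0, t1))):
            if not (0 <= a < b <= self.height):
                raise ValueError(f"{name} band rows [{a},{b}) outside image")
        if max(c0, t0) < min(c1, t1):
            raise ValueError("C and T bands overlap")
        if not 0 <= self.background_gray <= 255:
            raise ValueError("background_gray outside [0, 255]")

    @property
    def c_rows(self) -> tuple[int, int]:
        return (self.c_top, self.c_top + self.c_height)

    @property
    def t_rows(self) -> tuple[int, int]:
        return (self.t_top, self.t_top + self.t_height)


@dataclass(frozen=True)
class StripSpec:
    """A simulated strip: commanded band grayscales plus geometry."""

    t_target_gray: int
    c_target_gray: int = 125
    fixed_red: int = 255
    geometry: StripGeometry = field(default_factory=StripGeometry)

    def __post_init__(self) -> None:
        for name in ("t_target_gray", "c_target_gray", "fixed_red"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")


@dataclass(frozen=True)
class CameraSettings:
    """Control-factor settings of the simulated camera.

    illuminance is factor A (lux), contrast factor B, saturation factor C
    and tone factor D; the last three are unitless in [0, 1] with 0.5 the
    neutral point. noise_sd is the additive Gaussian sensor noise in
    grayscale units; seed makes the noise reproducible.
    """

    illuminance: float = NEUTRAL_ILLUMINANCE
    contrast: float = 0.5
    saturation: float = 0.5
    tone: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.illuminance <= 0:
            raise ValueError("illuminance must be positive")
        for name in ("contrast", "saturation", "tone"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class StripImage:
    """An 8-bit RGB image plus the provenance of a synthetic render."""

    pixels: np.ndarray
    spec: StripSpec | None = None
    settings: CameraSettings | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixels, got {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError("pixels must be uint8")


def solve_gb_for_gray(t_target_gray: int, fixed_red: int) -> int:
    """Channel value v for G = B so that (R, v, v) hits a grayscale target.

    With BT.601 luma and the red channel fixed, gray = w_R*R + (w_G+w_B)*v,
    so v = round((target - w_R*R) / (w_G + w_B)). The target is reachable
    only if it lies between w_R*R (v = 0) and w_R*R + (w_G+w_B)*255.
    """
    for name, v in (("t_target_gray", t_target_gray), ("fixed_red", fixed_red)):
        if not 0 <= v <= 255:
            raise ValueError(f"{name}={v} outside [0, 255]")
    wr = LUMA_WEIGHTS[0]
    wgb = LUMA_WEIGHTS[1] + LUMA_WEIGHTS[2]
    v = round((t_target_gray - wr * fixed_red) / wgb)
    if not 0 <= v <= 255:
        lo, hi = wr * fixed_red, wr * fixed_red + wgb * 255
        raise UnreachableGrayError(
            f"grayscale {t_target_gray} unreachable with R={fixed_red}: "
            f"reachable range is [{lo:.1f}, {hi:.1f}]"
        )
    return v


def render_strip(spec: StripSpec) -> StripImage:
    """Render a noise-free strip: uniform background plus C and T bands.

    Background pixels are (bg, bg, bg); band pixels are (fixed_red, v, v)
    with v solved per band target. Deterministic.
    """
    geo = spec.geometry
    bg = geo.background_gray
    px = np.full((geo.height, geo.width, 3), bg, dtype=np.uint8)
    for (r0, r1), target in ((geo.c_rows, spec.c_target_gray),
                             (geo.t_rows, spec.t_target_gray)):
        v = solve_gb_for_gray(target, spec.fixed_red)
        px[r0:r1, :] = (spec.fixed_red, v, v)
    return StripImage(pixels=px, spec=spec)


def apply_camera(image: StripImage, settings: CameraSettings) -> StripImage:
    """Image the strip through the parametric camera model.

    Fixed transform order on float pixels:
      1. gain  g = illuminance / 240, per channel;
      2. contrast  p' = 128 + (0.5 + contrast) * (p - 128);
      3. saturation: chroma (p - luma) scaled by (0.5 + saturation);
      4. tone: additive offset 40 * (tone - 0.5);
      5. Gaussian noise, sd = noise_sd, from a generator seeded with
         ``settings.seed``;
      6. clip to [0, 255] and quantize to uint8.
    Identical image + settings give a bit-identical result.
    """
    p = np.asarray(image.pixels, dtype=float)
    p = p * (settings.illuminance / NEUTRAL_ILLUMINANCE)
    p = 128.0 + (0.5 + settings.contrast) * (p - 128.0)
    luma = (np.array(LUMA_WEIGHTS) * p).sum(axis=2, keepdims=True)
    p = luma + (0.5 + settings.saturation) * (p - luma)
    p = p + 40.0 * (settings.tone - 0.5)
    if settings.noise_sd > 0:
        rng = np.random.default_rng(settings.seed)
        p = p + rng.normal(0.0, settings.noise_sd, size=p.shape)
    p = np.clip(np.rint(p), 0, 255).astype(np.uint8)
    return StripImage(pixels=p, spec=image.spec, settings=settings)


def write_png(image: StripImage, path) -> None:
    """Write the image as 8-bit RGB PNG."""
    iio.imwrite(path, image.pixels, extension=".png")


def read_image(path) -> StripImage:
    """Read a PNG or TIFF image back as a StripImage (no metadata)."""
    px = np.asarray(iio.imread(path))
    if px.ndim == 2:  # grayscale file: replicate channels
        px = np.stack([px] * 3, axis=-1)
    if px.shape[2] == 4:  # drop alpha
        px = px[..., :3]
    return StripImage(pixels=px.astype(np.uint8))


def settings_from_mapping(mapping: Mapping[str, float], **overrides) -> CameraSettings:
    """Build CameraSettings from a plain mapping (e.g. a plan row or YAML)."""
    merged = {**dict(mapping), **overrides}
    return CameraSettings(**merged)
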