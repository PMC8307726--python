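"""L9(3^4) orthogonal-array experimental design.

Four 3-level control factors (A illuminance, B contrast, C saturation,
D tone) are screened in nine runs using the standard L9 orthogonal
array: every level of every factor appears three times, and for any two
factors each of the nine ordered level pairs occurs exactly once. This
balance is what lets per-level means of the run S/N ratios isolate each
factor's effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FACTOR_CODES",
    "DEFAULT_INPUT_LEVELS",
    "FactorSpec",
    "DesignMatrix",
    "RunPlan",
    "l9_array",
    "default_factors",
    "make_plan",
    "factors_from_yaml",
    "plan_to_csv",
]

FACTOR_CODES = ("A", "B", "C", "D")

#: Commanded T-line grayscale levels of the calibration series.
DEFAULT_INPUT_LEVELS = (125, 150, 200, 240, 245, 250, 251, 252, 253, 254, 255)

# Canonical L9: first column 1,1,1,2,2,2,3,3,3 with the standard
# Latin-square completion of the remaining three columns.
_L9 = np.array(
    [
        [1, 1, 1, 1],
        [1, 2, 2, 2],
        [1, 3, 3, 3],
        [2, 1, 2, 3],
        [2, 2, 3, 1],
        [2, 3, 1, 2],
        [3, 1, 3, 2],
        [3, 2, 1, 3],
        [3, 3, 2, 1],
    ],
    dtype=int,
)


@dataclass(frozen=True)
class FactorSpec:
    """A named control factor with exactly three ascending physical levels."""

    code: str
    name: str
    unit: str
    levels: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.code not in FACTOR_CODES:
            raise ValueError(f"factor code must be one of {FACTOR_CODES}")
        if len(self.levels) != 3:
            raise ValueError("a factor needs exactly 3 levels")
        if len(set(self.levels)) != 3:
            raise ValueError("factor levels must be distinct")
        if list(self.levels) != sorted(self.levels):
            raise ValueError("factor levels must be ascending")

    def level(self, index: int) -> float:
        """Physical value at 1-based level index."""
        if index not in (1, 2, 3):
            raise ValueError(f"level index {index} not in 1..3")
        return self.levels[index - 1]


@dataclass(frozen=True)
class DesignMatrix:
    """9 runs x 4 columns of level indices in {1, 2, 3}."""

    rows: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=int)
        object.__setattr__(self, "rows", rows)
        if rows.shape != (9, 4):
            raise ValueError(f"expected 9x4 design, got {rows.shape}")
        self.audit()

    def audit(self) -> None:
        """Brute-force balance and orthogonality check."""
        rows = self.rows
        for j in range(4):
            counts = np.bincount(rows[:, j], minlength=4)[1:4]
            if not np.all(counts == 3):
                raise ValueError(f"column {j} unbalanced: counts {counts}")
        for j, k in combinations(range(4), 2):
            pairs = {tuple(p) for p in rows[:, [j, k]]}
            if pairs != set(product((1, 2, 3), repeat=2)):
                raise ValueError(f"columns ({j},{k}) not orthogonal")

    def level_index(self, run: int, factor: int) -> int:
        return int(self.rows[run, factor])


@dataclass(frozen=True)
class RunPlan:
    """One experimental run: physical camera settings plus signal levels."""

    run_id: int
    settings: dict[str, float]  # illuminance, contrast, saturation, tone
    input_levels: tuple[int, ...]


def l9_array() -> DesignMatrix:
    """The canonical L9(3^4) orthogonal array."""
    return DesignMatrix(rows=_L9.copy())


def default_factors() -> tuple[FactorSpec, FactorSpec, FactorSpec, FactorSpec]:
    """The study's four control factors and their screening levels."""
    return (
        FactorSpec("A", "Illuminance", "lux", (200.0, 240.0, 280.0)),
        FactorSpec("B", "Contrast", "", (0.13, 0.33, 0.53)),
        FactorSpec("C", "ColorSaturation", "", (0.35, 0.5, 0.65)),
        FactorSpec("D", "Tone", "", (0.35, 0.5, 0.65)),
    )


_SETTING_KEYS = ("illuminance", "contrast", "saturation", "tone")


def settings_for_levels(
    factors: Sequence[FactorSpec], level_indices: Sequence[int]
) -> dict[str, float]:
    """Map 1-based level indices (A, B, C, D order) to physical settings."""
    if len(factors) != 4 or len(level_indices) != 4:
        raise ValueError("need 4 factors and 4 level indices")
    return {
        key: fac.level(idx)
        for key, fac, idx in zip(_SETTING_KEYS, factors, level_indices)
    }


def make_plan(
    factors: Sequence[FactorSpec],
    design: DesignMatrix | None = None,
    input_levels: Sequence[int] = DEFAULT_INPUT_LEVELS,
) -> list[RunPlan]:
    """Bind the design matrix to physical factor levels: the 9-run plan."""
    if len(factors) != 4:
        raise ValueError(f"need exactly 4 factors, got {len(factors)}")
    if tuple(f.code for f in factors) != FACTOR_CODES:
        raise ValueError("factors must be given in A, B, C, D order")
    if len(input_levels) == 0:
        raise ValueError("input_levels must not be empty")
    if design is None:
        design = l9_array()
    return [
        RunPlan(
            run_id=i + 1,
            settings=settings_for_levels(factors, design.rows[i]),
            input_levels=tuple(int(v) for v in input_levels),
        )
        for i in range(9)
    ]


def factors_from_yaml(path) -> list[FactorSpec]:
    """Read factors from YAML: a list of {code, name, unit, levels} blocks."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [
        FactorSpec(
            code=item["code"],
            name=item["name"],
            unit=item.get("unit", ""),
            levels=tuple(item["levels"]),
        )
        for item in data
    ]


def plan_to_csv(plan: Sequence[RunPlan], path) -> None:
    """Write the run plan as CSV: run_id,illuminance_lux,contrast,saturation,tone."""
    df = pd.DataFrame(
        [
            {
                "run_id": rp.run_id,
                "illuminance_lux": rp.settings["illuminance"],
                "contrast": rp.settings["contrast"],
                "saturation": rp.settings["saturation"],
                "tone": rp.settings["tone"],
            }
            for rp in plan
        ]
    )
    df.to_csv(path, index=False)
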