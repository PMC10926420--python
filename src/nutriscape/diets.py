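"""Diet definitions and tube-based intake accounting.

A liquid diet is characterised by its protein:carbohydrate mass ratio
(in "parts", e.g. 1:4) and the combined nutrient concentration in g/L.
Consumption is measured as the drop in liquid column length of a graduated
pipette tip, converted to microlitres by a linear calibration, corrected
for evaporation using control tubes kept without flies, and finally
converted to milligrams of protein and carbohydrate via the diet's
nutrient densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Diet",
    "TubeMeasurement",
    "Calibration",
    "InvalidDietError",
    "MissingControlsError",
    "nutrient_densities",
    "volume_consumed",
    "evaporation_correction",
    "intake_mg",
    "experiment1_diet_grid",
    "experiment2_diet_pairs",
    "read_diet_grid",
    "read_tube_measurements",
]


class InvalidDietError(ValueError):
    """Raised when a diet definition violates its invariants."""


class MissingControlsError(KeyError):
    """Raised when no evaporation-control tubes match a fly's diet/interval."""


@dataclass(frozen=True)
class Diet:
    """A liquid diet defined by P:C mass parts and total nutrient concentration.

    Parameters
    ----------
    p_parts, c_parts : float
        Mass parts of protein and carbohydrate (e.g. 1 and 4 for a 1:4 diet).
    concentration : float
        Combined protein + carbohydrate concentration in g/L.
    label : str
        Human-readable name, e.g. ``"1:4 (180)"``.
    """

    p_parts: float
    c_parts: float
    concentration: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.p_parts < 0 or self.c_parts < 0 or self.p_parts + self.c_parts <= 0:
            raise InvalidDietError(
                f"diet {self.label!r}: p_parts + c_parts must be positive "
                f"(got {self.p_parts}, {self.c_parts})"
            )
        if self.concentration <= 0:
            raise InvalidDietError(
                f"diet {self.label!r}: concentration must be positive g/L "
                f"(got {self.concentration})"
            )
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.p_parts:g}:{self.c_parts:g} ({self.concentration:g})"
            )

    @property
    def protein_mg_per_uL(self) -> float:
        return self.p_parts / (self.p_parts + self.c_parts) * self.concentration / 1000.0

    @property
    def carb_mg_per_uL(self) -> float:
        return self.c_parts / (self.p_parts + self.c_parts) * self.concentration / 1000.0

    @property
    def ratio(self) -> float:
        """Numeric P:C ratio (p_parts / c_parts); ``inf`` on a pure-protein diet."""
        if self.c_parts == 0:
            return float("inf")
        return self.p_parts / self.c_parts


@dataclass(frozen=True)
class Calibration:
    """Linear length-to-volume calibration: volume_uL = slope * length_mm + intercept.

    The default convention anchors a full tube (``full_length_mm``) to the
    100 uL of diet initially dispensed, i.e. slope = 100 / full_length_mm and
    intercept = 0.
    """

    slope: float  # uL per mm
    intercept: float = 0.0  # uL

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive (got {self.slope})")

    @classmethod
    def anchored(cls, full_length_mm: float, full_volume_uL: float = 100.0) -> "Calibration":
        """Calibration for which a full tube of ``full_length_mm`` reads ``full_volume_uL``."""
        return cls(slope=full_volume_uL / full_length_mm, intercept=0.0)


@dataclass(frozen=True)
class TubeMeasurement:
    """One tube read over one measurement interval.

    ``final_length_mm > initial_length_mm`` is tolerated (measurement noise);
    the resulting negative consumption is floored at zero only after
    evaporation correction.
    """

    tube_id: str
    diet: Diet
    interval_start_day: int
    interval_end_day: int
    initial_length_mm: float
    final_length_mm: float
    role: str = "fly"  # "fly" | "control"

    def __post_init__(self) -> None:
        if self.interval_end_day <= self.interval_start_day:
            raise ValueError(
                f"tube {self.tube_id}: interval_end_day must exceed interval_start_day"
            )


def nutrient_densities(diet: Diet) -> tuple[float, float]:
    """Protein and carbohydrate densities of a diet in mg/uL.

    The two densities split concentration/1000 in proportion to the mass
    parts, so they always sum to the total nutrient density (mass balance).
    """
    return diet.protein_mg_per_uL, diet.carb_mg_per_uL


def volume_consumed(m: TubeMeasurement, cal: Calibration) -> float:
    """Volume drop of a tube in uL from its length change.

    Negative values (final length above initial) are returned as-is and
    logged; they are corrected downstream by the evaporation step's floor.
    """
    vol = cal.slope * (m.initial_length_mm - m.final_length_mm)
    if vol < 0:
        logger.warning(
            "tube %s: negative raw volume %.2f uL (lengths %.1f -> %.1f mm)",
            m.tube_id, vol, m.initial_length_mm, m.final_length_mm,
        )
    return vol


def evaporation_correction(
    consumed_uL: float,
    controls: Sequence[TubeMeasurement],
    cal: Calibration,
    *,
    diet: Diet | None = None,
    interval: tuple[int, int] | None = None,
) -> float:
    """Subtract the mean control-tube loss from a fly's consumed volume.

    Controls are the tubes of the same diet kept in the climate room without
    flies over the same interval. The corrected volume is floored at zero:
    evaporation cannot make true consumption negative.
    """
    if diet is not None or interval is not None:
        controls = [
            c for c in controls
            if (diet is None or c.diet == diet)
            and (interval is None
                 or (c.interval_start_day == interval[0] and c.interval_end_day == interval[1]))
        ]
    if len(controls) == 0:
        where = f" for diet {diet.label!r}" if diet is not None else ""
        if interval is not None:
            where += f" over days {interval[0]}-{interval[1]}"
        raise MissingControlsError(f"no evaporation controls{where}")
    mean_loss = sum(volume_consumed(c, cal) for c in controls) / len(controls)
    return max(0.0, consumed_uL - mean_loss)


def intake_mg(corrected_uL: float, diet: Diet) -> tuple[float, float]:
    """Convert a corrected consumed volume into (protein_mg, carb_mg)."""
    if corrected_uL < 0:
        raise ValueError(f"corrected volume must be non-negative (got {corrected_uL})")
    p, c = nutrient_densities(diet)
    return corrected_uL * p, corrected_uL * c


# ---------------------------------------------------------------------------
# The experimental diet grids
# ---------------------------------------------------------------------------

RATIOS: tuple[tuple[float, float], ...] = ((0, 1), (1, 8), (1, 4), (1, 2), (1, 1))
CONCENTRATIONS: tuple[float, ...] = (45.0, 180.0, 360.0)


def experiment1_diet_grid() -> list[Diet]:
    """The 15-diet no-choice grid: P:C in {0:1, 1:8, 1:4, 1:2, 1:1} x {45, 180, 360} g/L."""
    return [
        Diet(p, c, conc)
        for conc in CONCENTRATIONS
        for (p, c) in RATIOS
    ]


def experiment2_diet_pairs() -> list[tuple[Diet, Diet]]:
    """The four complementary diet pairs of the choice experiment."""
    d11_180 = Diet(1, 1, 180.0)
    d11_360 = Diet(1, 1, 360.0)
    d01_180 = Diet(0, 1, 180.0)
    d01_360 = Diet(0, 1, 360.0)
    return [
        (d11_180, d01_180),  # pair 1
        (d11_180, d01_360),  # pair 2
        (d11_360, d01_180),  # pair 3
        (d11_360, d01_360),  # pair 4
    ]


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def read_diet_grid(path) -> dict[str, Diet]:
    """Read a diet grid CSV with columns label, p_parts, c_parts, concentration_g_per_L."""
    df = pd.read_csv(path)
    required = {"label", "p_parts", "c_parts", "concentration_g_per_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"diet grid {path}: missing columns {sorted(missing)}")
    return {
        str(r.label): Diet(float(r.p_parts), float(r.c_parts),
                           float(r.concentration_g_per_L), str(r.label))
        for r in df.itertuples()
    }


def write_diet_grid(diets: Iterable[Diet], path) -> None:
    pd.DataFrame(
        [
            {"label": d.label, "p_parts": d.p_parts, "c_parts": d.c_parts,
             "concentration_g_per_L": d.concentration}
            for d in diets
        ]
    ).to_csv(path, index=False)


def read_tube_measurements(path, diets: dict[str, Diet]) -> list[TubeMeasurement]:
    """Read a tube measurement CSV.

    Columns: tube_id, diet_label, interval_start_day, interval_end_day,
    initial_length_mm, final_length_mm, role (fly | control).
    """
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        label = str(r.diet_label)
        if label not in diets:
            raise KeyError(f"tube {r.tube_id}: unknown diet label {label!r}")
        out.append(
            TubeMeasurement(
                tube_id=str(r.tube_id),
                diet=diets[label],
                interval_start_day=int(r.interval_start_day),
                interval_end_day=int(r.interval_end_day),
                initial_length_mm=float(r.initial_length_mm),
                final_length_mm=float(r.final_length_mm),
                role=str(r.role),
            )
        )
    return out
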