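"""Synthetic fly-level datasets with the structure of the two feeding experiments.

Experiment I (no-choice): each fly is confined to a single diet, so its
realized (protein, carbohydrate) intake lies on that diet's nutritional
rail; lifespan and egg production respond to the per-day intake through a
configurable quadratic response surface. Experiment II (choice): each fly
feeds from a complementary diet pair and regulates its cumulative intake
towards a target point in nutrient space over a fixed 16-day window.

The default design sizes, diet grids and intake targets reproduce the
published experimental conditions (1200 flies on 15 diets; 280 flies on 4
diet pairs with the upward-selected line at three replicates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diets import Diet, experiment1_diet_grid, experiment2_diet_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "TrueSurface",
    "Experiment1Design",
    "Experiment2Design",
    "default_surfaces",
    "default_intake_targets",
    "generate_experiment1",
    "generate_experiment2",
]


@dataclass(frozen=True)
class TrueSurface:
    """A quadratic trait surface over per-day protein/carbohydrate intake.

    trait(P, C) = intercept + beta_P*P + beta_C*C
                  + gamma_PP*P^2 + gamma_CC*C^2 + gamma_PC*P*C

    Units: trait units per mg/day for the linear gradients, per (mg/day)^2
    for the quadratic and correlational terms. A concave surface
    (gamma_PP < 0, gamma_CC < 0 and gamma_PP*gamma_CC > gamma_PC^2/4) has a
    unique finite maximum.
    """

    intercept: float
    beta_P: float
    beta_C: float
    gamma_PP: float = 0.0
    gamma_CC: float = 0.0
    gamma_PC: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def value(self, P, C):
        """Surface value at intake (P, C) mg/day (vectorised)."""
        P = np.asarray(P, dtype=float)
        C = np.asarray(C, dtype=float)
        return (
            self.intercept
            + self.beta_P * P
            + self.beta_C * C
            + self.gamma_PP * P**2
            + self.gamma_CC * C**2
            + self.gamma_PC * P * C
        )

    @property
    def is_concave(self) -> bool:
        return (
            self.gamma_PP < 0
            and self.gamma_CC < 0
            and self.gamma_PP * self.gamma_CC > self.gamma_PC**2 / 4
        )

    def peak(self) -> tuple[float, float]:
        """Stationary point (argmax if concave); raises on a degenerate Hessian."""
        H = 2 * np.array([[self.gamma_PP, self.gamma_PC / 2],
                          [self.gamma_PC / 2, self.gamma_CC]])
        if abs(np.linalg.det(H)) < 1e-14:
            raise ValueError("surface has no unique stationary point")
        x = np.linalg.solve(H, -np.array([self.beta_P, self.beta_C]))
        return float(x[0]), float(x[1])

    @classmethod
    def from_peak(
        cls,
        peak_P: float,
        peak_C: float,
        peak_value: float,
        gamma_PP: float,
        gamma_CC: float,
        gamma_PC: float = 0.0,
        noise_sd: float = 0.0,
    ) -> "TrueSurface":
        """Concave surface with its maximum at (peak_P, peak_C) of height peak_value."""
        G = np.array([[gamma_PP, gamma_PC / 2], [gamma_PC / 2, gamma_CC]])
        x = np.array([peak_P, peak_C])
        beta = -2 * G @ x
        intercept = peak_value + float(x @ G @ x)
        return cls(intercept, float(beta[0]), float(beta[1]),
                   gamma_PP, gamma_CC, gamma_PC, noise_sd)


def default_surfaces() -> dict[tuple[str, str, str], TrueSurface]:
    """Default true surfaces for (line, sex, trait).

    Lifespan surfaces are concave and carbohydrate-dominant, with peaks at
    the low-protein high-carbohydrate intakes reported for each line and
    sex (e.g. control females near 0.2 mg/day protein, 24 mg/day
    carbohydrate). Daily egg production (DEP) peaks at a more
    protein-biased blend in control females; in upward-selected females it
    rises linearly with protein and has no interior peak. Lifetime egg
    production (LEP) surfaces are carried for configuration completeness;
    egg counts are generated from the DEP surface and lifespan, so the LEP
    landscape emerges as their product.
    """
    s: dict[tuple[str, str, str], TrueSurface] = {}
    # lifespan (days); peaks from the reported per-trait optima
    s[("CT", "F", "LS")] = TrueSurface.from_peak(0.21, 24.2, 80.0, -0.08, -0.060, -0.010, noise_sd=8.0)
    s[("US", "F", "LS")] = TrueSurface.from_peak(2.80, 24.9, 65.0, -0.06, -0.050, 0.000, noise_sd=8.0)
    s[("CT", "M", "LS")] = TrueSurface.from_peak(0.07, 27.3, 75.0, -0.06, -0.050, -0.010, noise_sd=8.0)
    s[("US", "M", "LS")] = TrueSurface.from_peak(0.09, 31.7, 60.0, -0.05, -0.040, -0.008, noise_sd=8.0)
    # daily egg production (eggs/day)
    s[("CT", "F", "DEP")] = TrueSurface.from_peak(1.6, 16.7, 14.0, -0.60, -0.020, 0.0, noise_sd=3.0)
    s[("US", "F", "DEP")] = TrueSurface(2.0, 0.6, 0.0, noise_sd=3.0)
    # lifetime egg production (eggs); configuration-level description only
    s[("CT", "F", "LEP")] = TrueSurface.from_peak(0.01, 25.8, 850.0, -8.0, -0.9, 0.0, noise_sd=150.0)
    s[("US", "F", "LEP")] = TrueSurface(120.0, 12.0, 2.0, noise_sd=150.0)
    return s


@dataclass(frozen=True)
class Experiment1Design:
    """Design of the no-choice experiment.

    Defaults give 15 diets x 2 lines x 4 replicates x 2 sexes x 5 flies
    = 1200 flies.
    """

    lines: tuple[str, ...] = ("CT", "US")
    replicates_per_line: tuple[tuple[str, int], ...] = (("CT", 4), ("US", 4))
    sexes: tuple[str, ...] = ("F", "M")
    flies_per_cell: int = 5
    diets: tuple[Diet, ...] = tuple(experiment1_diet_grid())
    seed: int = 0
    # intake model: mean daily volume at the reference concentration, a
    # compensatory-feeding exponent (dilute diets are consumed in larger
    # volumes), and lognormal between-fly variability of the daily volume
    mean_volume_uL_day: float = 55.0
    reference_concentration: float = 180.0
    compensation: float = 0.45
    volume_sigma: float = 0.35
    # overall consumption differs between lines (upward-selected flies eat
    # more) and sexes (males eat more than females)
    line_volume_factor: tuple[tuple[str, float], ...] = (("CT", 1.0), ("US", 1.15))
    sex_volume_factor: tuple[tuple[str, float], ...] = (("F", 1.0), ("M", 1.1))
    replicate_sd: float = 1.0          # additive normal replicate shift, trait units
    nonnatural_death_fraction: float = 0.02
    dish_interval_days: int = 6
    egg_dispersion: float = 8.0        # negative-binomial size parameter per dish

    def __post_init__(self) -> None:
        if self.flies_per_cell < 1 or len(self.diets) < 1:
            raise ValueError("all design counts must be >= 1")
        reps = dict(self.replicates_per_line)
        if any(reps.get(l, 0) < 1 for l in self.lines):
            raise ValueError("every line needs >= 1 replicate")

    @property
    def n_flies(self) -> int:
        reps = dict(self.replicates_per_line)
        return sum(
            len(self.diets) * reps[line] * len(self.sexes) * self.flies_per_cell
            for line in self.lines
        )


def _mean_daily_volume(design: Experiment1Design, diet: Diet) -> float:
    return design.mean_volume_uL_day * (
        design.reference_concentration / diet.concentration
    ) ** design.compensation


def generate_experiment1(
    design: Experiment1Design | None = None,
    surfaces: dict[tuple[str, str, str], TrueSurface] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the no-choice experiment: one fly per row.

    Each fly draws a constant daily feeding volume (lognormal around a
    diet-specific mean, so realized intakes spread along the diet's rail),
    its lifespan from a gamma distribution whose mean is the lifespan
    surface at its realized per-day intake, and — for females — egg counts
    per 6-day oviposition dish from a negative binomial whose daily mean is
    the DEP surface value. A small fraction of flies is flagged as
    non-natural deaths for the exclusion step.

    Returns a DataFrame with one row per fly. The ``dish_counts`` column
    holds the per-dish egg counts as a list (empty for males).
    """
    design = design or Experiment1Design()
    surfaces = surfaces if surfaces is not None else default_surfaces()
    for line in design.lines:
        for sex in design.sexes:
            if (line, sex, "LS") not in surfaces:
                raise KeyError(f"missing lifespan surface for ({line}, {sex})")
        for trait in ("LEP", "DEP"):
            if "F" in design.sexes and (line, "F", trait) not in surfaces:
                raise KeyError(f"missing {trait} surface for ({line}, F)")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    reps = dict(design.replicates_per_line)

    rows = []
    fly_counter = 0
    for line in design.lines:
        # replicate shifts shared by all flies of a replicate within a line
        rep_shift = {
            r: rng.normal(0.0, design.replicate_sd) for r in range(1, reps[line] + 1)
        }
        for replicate in range(1, reps[line] + 1):
            for sex in design.sexes:
                for diet in design.diets:
                    pdens, cdens = diet.protein_mg_per_uL, diet.carb_mg_per_uL
                    mean_vol = (
                        _mean_daily_volume(design, diet)
                        * dict(design.line_volume_factor).get(line, 1.0)
                        * dict(design.sex_volume_factor).get(sex, 1.0)
                    )
                    for _ in range(design.flies_per_cell):
                        fly_counter += 1
                        sig = design.volume_sigma
                        vol = mean_vol * rng.lognormal(-sig**2 / 2, sig) if sig > 0 else mean_vol
                        P_day, C_day = vol * pdens, vol * cdens

                        ls_surface = surfaces[(line, sex, "LS")]
                        mean_ls = float(ls_surface.value(P_day, C_day)) + rep_shift[replicate]
                        mean_ls = max(mean_ls, 2.0)
                        if ls_surface.noise_sd > 0:
                            shape = (mean_ls / ls_surface.noise_sd) ** 2
                            lifespan = float(rng.gamma(shape, mean_ls / shape))
                        else:
                            lifespan = mean_ls
                        lifespan_days = max(1, int(round(lifespan)))

                        dish_counts: list[int] = []
                        if sex == "F":
                            dep = surfaces[(line, "F", "DEP")]
                            daily_mean = max(float(dep.value(P_day, C_day)), 0.0)
                            day = 0
                            while day < lifespan_days:
                                span = min(design.dish_interval_days, lifespan_days - day)
                                mu = daily_mean * span
                                if mu <= 0:
                                    dish_counts.append(0)
                                elif dep.noise_sd > 0:
                                    k = design.egg_dispersion
                                    dish_counts.append(
                                        int(rng.negative_binomial(k, k / (k + mu)))
                                    )
                                else:
                                    dish_counts.append(int(round(mu)))
                                day += span

                        death_cause = (
                            "non_natural"
                            if rng.random() < design.nonnatural_death_fraction
                            else "natural"
                        )
                        rows.append({
                            "fly_id": f"E1-{fly_counter:05d}",
                            "line": line,
                            "replicate": replicate,
                            "sex": sex,
                            "diet_label": diet.label,
                            "p_parts": diet.p_parts,
                            "c_parts": diet.c_parts,
                            "concentration": diet.concentration,
                            "volume_uL_day": vol,
                            "P_mg_day": P_day,
                            "C_mg_day": C_day,
                            "lifespan_days": lifespan_days,
                            "P_mg_total": P_day * lifespan_days,
                            "C_mg_total": C_day * lifespan_days,
                            "eggs_total": int(sum(dish_counts)),
                            "dish_counts": dish_counts,
                            "death_cause": death_cause,
                        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment II — dietary choice
# ---------------------------------------------------------------------------

def default_intake_targets() -> dict[tuple[str, str], tuple[float, float]]:
    """Default regulated cumulative intake targets (mg over 16 days) per (line, sex).

    These are the mean total protein and carbohydrate intakes reported for
    each line and sex of the choice experiment.
    """
    return {
        ("CT", "F"): (15.65, 57.33),
        ("CT", "M"): (15.46, 55.45),
        ("US", "F"): (19.93, 64.39),
        ("US", "M"): (20.06, 64.55),
    }


@dataclass(frozen=True)
class Experiment2Design:
    """Design of the choice experiment.

    Defaults give 4 diet pairs x (4 CT + 3 US replicates) x 2 sexes x
    5 flies = 280 flies over a 16-day window read every 4 days.
    """

    lines: tuple[str, ...] = ("CT", "US")
    replicates_per_line: tuple[tuple[str, int], ...] = (("CT", 4), ("US", 3))
    sexes: tuple[str, ...] = ("F", "M")
    flies_per_cell: int = 5
    diet_pairs: tuple[tuple[Diet, Diet], ...] = tuple(experiment2_diet_pairs())
    duration_days: int = 16
    interval_days: int = 4
    seed: int = 0
    volume_sigma: float = 0.25     # lognormal per-interval, per-tube variability
    replicate_sd: float = 2.0      # additive replicate shift on cumulative C (mg)

    def __post_init__(self) -> None:
        if self.duration_days % self.interval_days:
            raise ValueError("duration_days must be a multiple of interval_days")
        if self.flies_per_cell < 1 or len(self.diet_pairs) < 1:
            raise ValueError("all design counts must be >= 1")

    @property
    def n_intervals(self) -> int:
        return self.duration_days // self.interval_days

    @property
    def n_flies(self) -> int:
        reps = dict(self.replicates_per_line)
        return sum(
            len(self.diet_pairs) * reps[line] * len(self.sexes) * self.flies_per_cell
            for line in self.lines
        )


def solve_pair_volumes(
    diet_a: Diet, diet_b: Diet, target_P: float, target_C: float
) -> tuple[float, float, bool]:
    """Tube volumes (uL) from a diet pair whose mixed intake hits a target (mg).

    Solves the 2x2 mixing system density_matrix @ (vA, vB) = (P, C). When
    the exact solution needs a negative volume the target is unreachable
    from the pair's rails; the nearest reachable point (non-negative least
    squares) is used instead and the fallback is reported.
    """
    A = np.array([
        [diet_a.protein_mg_per_uL, diet_b.protein_mg_per_uL],
        [diet_a.carb_mg_per_uL, diet_b.carb_mg_per_uL],
    ])
    b = np.array([target_P, target_C])
    exact = True
    if abs(np.linalg.det(A)) > 1e-12:
        v = np.linalg.solve(A, b)
    else:
        v, *_ = np.linalg.lstsq(A, b, rcond=None)
        exact = False
    if np.any(v < -1e-9):
        from scipy.optimize import nnls

        v, _ = nnls(A, b)
        exact = False
        logger.info(
            "target (%.2f, %.2f) mg not reachable from pair %s vs %s; "
            "using nearest reachable point",
            target_P, target_C, diet_a.label, diet_b.label,
        )
    return float(max(v[0], 0.0)), float(max(v[1], 0.0)), exact


def generate_experiment2(
    design: Experiment2Design | None = None,
    targets: dict[tuple[str, str], tuple[float, float]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the choice experiment: one fly per row with per-interval volumes.

    For each fly the expected cumulative intake over the 16 days equals its
    (line, sex) target point where the diet-pair geometry permits; interval
    volumes add mean-one lognormal noise per tube. No fly dies before the
    end of the window.

    Columns include per-interval volumes ``vol_a_i<k>`` / ``vol_b_i<k>``,
    the tube totals, and cumulative ``P_mg`` / ``C_mg``.
    """
    design = design or Experiment2Design()
    targets = targets if targets is not None else default_intake_targets()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    reps = dict(design.replicates_per_line)
    nint = design.n_intervals

    rows = []
    fly_counter = 0
    for line in design.lines:
        rep_shift = {
            r: rng.normal(0.0, design.replicate_sd) for r in range(1, reps[line] + 1)
        }
        for replicate in range(1, reps[line] + 1):
            for sex in design.sexes:
                try:
                    tP, tC = targets[(line, sex)]
                except KeyError:
                    raise KeyError(f"missing intake target for ({line}, {sex})") from None
                for pair_idx, (diet_a, diet_b) in enumerate(design.diet_pairs, start=1):
                    # replicate effect perturbs the carbohydrate target
                    vA, vB, _ = solve_pair_volumes(
                        diet_a, diet_b, tP, max(tC + rep_shift[replicate], 0.0)
                    )
                    for _ in range(design.flies_per_cell):
                        fly_counter += 1
                        sig = design.volume_sigma
                        if sig > 0:
                            noise_a = rng.lognormal(-sig**2 / 2, sig, nint)
                            noise_b = rng.lognormal(-sig**2 / 2, sig, nint)
                        else:
                            noise_a = noise_b = np.ones(nint)
                        va = vA / nint * noise_a
                        vb = vB / nint * noise_b
                        P = float(va.sum() * diet_a.protein_mg_per_uL
                                  + vb.sum() * diet_b.protein_mg_per_uL)
                        C = float(va.sum() * diet_a.carb_mg_per_uL
                                  + vb.sum() * diet_b.carb_mg_per_uL)
                        row = {
                            "fly_id": f"E2-{fly_counter:05d}",
                            "line": line,
                            "replicate": replicate,
                            "sex": sex,
                            "pair": pair_idx,
                            "diet_a": diet_a.label,
                            "diet_b": diet_b.label,
                            "p_parts_a": diet_a.p_parts, "c_parts_a": diet_a.c_parts,
                            "concentration_a": diet_a.concentration,
                            "p_parts_b": diet_b.p_parts, "c_parts_b": diet_b.c_parts,
                            "concentration_b": diet_b.concentration,
                        }
                        for k in range(nint):
                            row[f"vol_a_i{k + 1}"] = float(va[k])
                            row[f"vol_b_i{k + 1}"] = float(vb[k])
                        row["vol_a_total_uL"] = float(va.sum())
                        row["vol_b_total_uL"] = float(vb.sum())
                        row["P_mg"] = P
                        row["C_mg"] = C
                        rows.append(row)
    return pd.DataFrame(rows)
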