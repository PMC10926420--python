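"""Turn raw fly records into analysis-ready traits and standardized intakes.

Lifespans differ widely across diets, so intakes are expressed per day
lived; traits (lifespan LS, lifetime egg production LEP, daily egg
production DEP) and intakes are z-standardized to mean 0 and sample
standard deviation 1 within each analysis group; flies that escaped or
died non-naturally are excluded before any model fitting.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "per_day_intake",
    "derive_egg_traits",
    "apply_exclusions",
    "z_transform",
    "prepare_experiment1",
    "DegenerateGroupError",
]


class DegenerateGroupError(ValueError):
    """A standardization group is constant or has fewer than two values."""


def per_day_intake(total_P_mg, total_C_mg, lifespan_days):
    """Divide cumulative nutrient intakes by days lived (vectorised).

    Zero or negative lifespans cannot be divided by; those records must be
    excluded upstream.
    """
    lifespan = np.asarray(lifespan_days, dtype=float)
    if np.any(lifespan <= 0):
        raise ValueError("lifespan_days must be positive; exclude zero-lifespan records")
    return (
        np.asarray(total_P_mg, dtype=float) / lifespan,
        np.asarray(total_C_mg, dtype=float) / lifespan,
    )


def derive_egg_traits(dish_counts: Sequence[int], lifespan_days: float) -> tuple[float, float]:
    """Lifetime (LEP) and daily (DEP) egg production from per-dish counts.

    LEP is the sum over oviposition dishes; DEP = LEP / lifespan, so
    DEP * LS == LEP holds by construction.
    """
    counts = np.asarray(list(dish_counts), dtype=float)
    if counts.size and (np.any(counts < 0) or np.any(counts != np.round(counts))):
        raise ValueError("dish counts must be non-negative integers")
    if lifespan_days <= 0:
        raise ValueError("lifespan_days must be positive")
    lep = float(counts.sum())
    return lep, lep / lifespan_days


def apply_exclusions(
    records: pd.DataFrame, cause_col: str = "death_cause", keep: str = "natural"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove flies flagged as escaped or non-natural deaths.

    Returns (kept, exclusion_log); the log has one row per removed fly with
    its id and reason. kept + excluded always partition the input.
    """
    flagged = records[cause_col] != keep
    log = records.loc[flagged, ["fly_id", cause_col]].rename(columns={cause_col: "reason"})
    kept = records.loc[~flagged].copy()
    if kept.empty:
        logger.warning("all %d records excluded", len(records))
    return kept, log.reset_index(drop=True)


def z_transform(values, group_keys=None):
    """Standardize to mean 0, sample sd 1 (n-1 denominator), optionally by group.

    ``group_keys`` may be a Series/array of labels aligned with ``values``.
    A constant group (sd == 0) or a group with fewer than two values cannot
    be standardized and raises :class:`DegenerateGroupError` naming it.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    if group_keys is None:
        groups = pd.Series(0, index=s.index)
    else:
        groups = pd.Series(np.asarray(group_keys), index=s.index)
    out = pd.Series(np.nan, index=s.index)
    for key, idx in s.groupby(groups).groups.items():
        g = s.loc[idx]
        if len(g) < 2:
            raise DegenerateGroupError(f"group {key!r} has fewer than 2 values")
        sd = g.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateGroupError(f"group {key!r} is constant; cannot standardize")
        out.loc[idx] = (g - g.mean()) / sd
    return out.to_numpy()


def prepare_experiment1(
    flies: pd.DataFrame,
    *,
    standardize_within: Iterable[str] = ("line", "sex"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the analysis table for the no-choice experiment.

    Applies exclusions, derives per-day intakes and egg traits, and adds
    z-standardized columns (zP, zC, zLS, zLEP, zDEP) computed within each
    ``standardize_within`` group (default: each line x sex dataset, the
    grouping used for the per-group response-surface fits; comparisons
    restandardize over their own pooled set).
    """
    kept, log = apply_exclusions(flies)
    if kept.empty:
        raise ValueError("no records remain after exclusions")
    df = kept.copy()
    df["P_mg_day"], df["C_mg_day"] = per_day_intake(
        df["P_mg_total"], df["C_mg_total"], df["lifespan_days"]
    )
    df["LS"] = df["lifespan_days"].astype(float)
    if "dish_counts" in df.columns:
        traits = [derive_egg_traits(d, ls) for d, ls in zip(df["dish_counts"], df["LS"])]
        df["LEP"] = [t[0] for t in traits]
        df["DEP"] = [t[1] for t in traits]
    elif "eggs_total" in df.columns:
        df["LEP"] = df["eggs_total"].astype(float)
        df["DEP"] = df["LEP"] / df["LS"]

    group = df[list(standardize_within)].astype(str).agg("|".join, axis=1)
    df["zP"] = z_transform(df["P_mg_day"], group)
    df["zC"] = z_transform(df["C_mg_day"], group)
    df["zLS"] = z_transform(df["LS"], group)
    if "LEP" in df.columns:
        # egg traits exist for females only; standardize within female groups
        for trait in ("LEP", "DEP"):
            zcol = "z" + trait
            df[zcol] = np.nan
            fem = df["sex"] == "F"
            if fem.any():
                df.loc[fem, zcol] = z_transform(df.loc[fem, trait], group[fem])
    return df, log
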