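"""Dietary-choice analysis: random-feeding null, regulated intake points,
and between-group regulation comparisons.

Flies offered a complementary diet pair can compose any nutrient blend
between the two rails. Feeding "at random" — equal volumes from each tube
— defines the null intake; a one-sample t-test of observed minus expected
intake against zero per nutrient detects active regulation. The regulated
intake point of a group is its mean cumulative (protein, carbohydrate)
intake pooled across all diet pairs, summarised as a 1:x P:C ratio.
Whether two groups defend different points is tested by a mixed model of
carbohydrate intake on protein intake, group and their interaction, with
replicate as a random intercept: a significant interaction means the
groups' regulated blends differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .diets import Diet

__all__ = [
    "expected_random_intake",
    "random_feeding_test",
    "characterize_preference",
    "regulated_intake_point",
    "RegulatedIntakePoint",
    "RegulationModel",
    "RegulationResults",
]


def expected_random_intake(
    total_volume_uL: float, diet_a: Diet, diet_b: Diet
) -> tuple[float, float]:
    """Nutrients (mg) a fly would ingest eating equal volumes from each tube.

    Half the total consumed volume is assigned to each diet of the pair and
    converted through that diet's nutrient densities. Zero consumption
    gives (0, 0).
    """
    if total_volume_uL < 0:
        raise ValueError("total volume must be non-negative")
    v = total_volume_uL / 2.0
    P = v * (diet_a.protein_mg_per_uL + diet_b.protein_mg_per_uL)
    C = v * (diet_a.carb_mg_per_uL + diet_b.carb_mg_per_uL)
    return P, C


def _expected_columns(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Expected (P, C) per fly from the diet-pair columns of a choice table."""
    need = {"p_parts_a", "c_parts_a", "concentration_a",
            "p_parts_b", "c_parts_b", "concentration_b",
            "vol_a_total_uL", "vol_b_total_uL"}
    missing = need - set(records.columns)
    if missing:
        raise KeyError(f"choice records missing columns {sorted(missing)}")
    eP = np.empty(len(records))
    eC = np.empty(len(records))
    for k, r in enumerate(records.itertuples()):
        da = Diet(r.p_parts_a, r.c_parts_a, r.concentration_a)
        db = Diet(r.p_parts_b, r.c_parts_b, r.concentration_b)
        eP[k], eC[k] = expected_random_intake(
            r.vol_a_total_uL + r.vol_b_total_uL, da, db
        )
    return eP, eC


def random_feeding_test(records: pd.DataFrame) -> pd.DataFrame:
    """One-sample t-tests of observed minus random-expected intake, per nutrient.

    ``records`` should hold one group (one line x sex x diet pair). Returns
    a two-row DataFrame (protein, carbohydrate) with mean difference, t, p
    (two-sided). If every difference is exactly zero the test is degenerate
    and returns t = 0, p = 1; a nonzero constant difference has no valid t
    and raises.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 flies for a t-test")
    eP, eC = _expected_columns(records)
    rows = []
    for nutrient, obs, exp in (
        ("protein", records["P_mg"].to_numpy(float), eP),
        ("carbohydrate", records["C_mg"].to_numpy(float), eC),
    ):
        diff = obs - exp
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff, 0.0):
                rows.append({"nutrient": nutrient, "mean_diff": 0.0, "t": 0.0, "p": 1.0})
                continue
            raise ValueError(
                f"{nutrient}: constant nonzero difference, t-test undefined"
            )
        t, p = stats.ttest_1samp(diff, 0.0)
        rows.append({"nutrient": nutrient, "mean_diff": float(diff.mean()),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows).set_index("nutrient")


def characterize_preference(records: pd.DataFrame, alpha: float = 0.05) -> str:
    """Classify a group's feeding strategy against the random-feeding null.

    Returns "protein-preferring", "carbohydrate-preferring" or "random"
    from the sign of the significant observed-minus-expected differences.
    """
    res = random_feeding_test(records)
    sig = res[res["p"] < alpha]
    if sig.empty:
        return "random"
    if "protein" in sig.index and sig.loc["protein", "mean_diff"] > 0:
        return "protein-preferring"
    return "carbohydrate-preferring"


@dataclass(frozen=True)
class RegulatedIntakePoint:
    """Mean cumulative intake a group defends, pooled across diet pairs."""

    mean_P: float
    mean_C: float
    n: int
    infinite_ratio: bool = False

    @property
    def C_to_P_ratio(self) -> float:
        if self.infinite_ratio:
            return float("inf")
        return self.mean_C / self.mean_P

    @property
    def label(self) -> str:
        """P:C ratio as printed, e.g. ``"1:3.6"`` (1 dp)."""
        if self.infinite_ratio:
            return "0:1"
        return f"1:{self.C_to_P_ratio:.1f}"

    def __str__(self) -> str:
        return (
            f"regulated intake point: P = {self.mean_P:.2f} mg, "
            f"C = {self.mean_C:.2f} mg (n = {self.n}, ratio {self.label})"
        )


def regulated_intake_point(records: pd.DataFrame) -> RegulatedIntakePoint:
    """Mean cumulative P and C over all flies of a group, across all diet pairs."""
    if len(records) == 0:
        raise ValueError("no records")
    mean_P = float(records["P_mg"].mean())
    mean_C = float(records["C_mg"].mean())
    return RegulatedIntakePoint(
        mean_P=mean_P, mean_C=mean_C, n=len(records),
        infinite_ratio=(mean_P == 0),
    )


@dataclass
class RegulationResults:
    """Tests of whether two groups defend the same regulated intake point."""

    chi2: pd.Series
    pvalues: pd.Series
    params: pd.Series
    n: int
    group_col: str
    groups: tuple

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chi2": self.chi2, "df": 1, "p": self.pvalues,
        })

    def summary(self) -> str:
        lines = [
            f"Regulated-intake comparison ({self.group_col}: "
            f"{self.groups[0]} vs {self.groups[1]}), n = {self.n}",
            f"{'term':<22}{'chi2':>10}{'df':>4}{'p':>10}",
        ]
        for t in self.chi2.index:
            lines.append(f"{t:<22}{self.chi2[t]:>10.2f}{1:>4}{self.pvalues[t]:>10.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "group": self.group_col,
            "chi2": {t: float(v) for t, v in self.chi2.items()},
            "p": {t: float(v) for t, v in self.pvalues.items()},
        }


class RegulationModel:
    """Mixed model C_mg ~ P_mg * group with a replicate random intercept.

    ``group_col`` is typically ``"line"`` (between selection regimes) or
    ``"sex"`` (within a line). Likelihood-ratio chi-squares (ML fits, df 1
    each) are reported for the protein covariate, the group factor, and
    their interaction; a significant interaction indicates the regulated
    intake point differs between the groups.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        group_col: str = "line",
        *,
        replicate_col: str = "replicate",
    ):
        groups = tuple(pd.unique(data[group_col]))
        if len(groups) != 2:
            raise ValueError(
                f"{group_col!r} must have exactly 2 levels, found {groups}"
            )
        self.data = data.reset_index(drop=True)
        self.group_col = group_col
        self.replicate_col = replicate_col
        self.groups = groups
        # replicates are populations nested within selection line: CT
        # replicate 1 and US replicate 1 are unrelated, so the random
        # intercept groups on the line x replicate combination
        if "line" in self.data.columns:
            self._re_groups = (
                self.data["line"].astype(str) + ":"
                + self.data[replicate_col].astype(str)
            )
        else:
            self._re_groups = self.data[replicate_col]

    def _llf(self, formula: str) -> tuple[float, object]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM.from_formula(
                formula, groups=self._re_groups, data=self.data
            ).fit(reml=False)
        return float(res.llf), res

    def fit(self) -> RegulationResults:
        g = self.group_col
        llf_full, res_full = self._llf(f"C_mg ~ P_mg * C({g})")
        llf_add, _ = self._llf(f"C_mg ~ P_mg + C({g})")
        llf_noP, _ = self._llf(f"C_mg ~ C({g})")
        llf_nog, _ = self._llf("C_mg ~ P_mg")

        def lr(a, b):
            stat = max(0.0, 2.0 * (a - b))
            return stat, float(stats.chi2.sf(stat, df=1))

        chi2, p = {}, {}
        chi2["protein"], p["protein"] = lr(llf_add, llf_noP)
        chi2[g], p[g] = lr(llf_add, llf_nog)
        key = f"{g}_x_protein"
        chi2[key], p[key] = lr(llf_full, llf_add)

        params = pd.Series(
            np.asarray(res_full.params)[: len(res_full.model.exog_names)],
            index=res_full.model.exog_names,
        )
        return RegulationResults(
            chi2=pd.Series(chi2), pvalues=pd.Series(p), params=params,
            n=len(self.data), group_col=g, groups=self.groups,
        )
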