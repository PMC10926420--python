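"""Sequential comparison of two nutritional landscapes by partial F-tests.

Two groups of flies (two selection lines, two sexes, or the same flies
scored for two traits) are pooled with a dummy variable coding the group.
Six nested fixed-effects models are then built:

1. linear nutrient effects (P, C)
2. model 1 + their interactions with the group dummy
3. model 2 + quadratic effects (P^2, C^2)
4. model 3 + quadratic x group interactions
5. model 4 + the correlational effect (P*C)
6. model 5 + its group interaction

The linear, quadratic and correlational blocks are tested by partial
F-tests on (1 vs 2), (3 vs 4) and (5 vs 6) using residual sums of squares
from the ordinary least-squares fits; replicate enters as a fixed 4-level
covariate. By default every model also carries the group main effect so
that a mean difference between the arms cannot masquerade as a gradient
difference; with ``group_main_effect=False`` (the historical
parameterization, which omits it) 600 flies give denominator degrees of
freedom 592, 588 and 586 for the three blocks. When a block is
significant, univariate follow-ups test each nutrient's group interaction
separately by a likelihood-ratio chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import z_transform

logger = logging.getLogger(__name__)

__all__ = ["partial_f", "LandscapeComparison", "ComparisonResults"]

BLOCKS = ("linear", "quadratic", "correlational")


def partial_f(ssr: float, ssc: float, df1: int, df2: int) -> tuple[float, float]:
    """Partial F-statistic and p-value for nested model residual sums of squares.

    ``ssr`` is the residual SS of the reduced model, ``ssc`` of the model
    with the extra block of ``df1`` parameters; ``df2`` is the residual
    degrees of freedom of the larger model.

    F = ((SSr - SSc)/DF1) / (SSc/DF2), p from the upper tail of F(DF1, DF2).
    """
    if df1 < 1 or df2 < 1:
        raise ValueError("DF1 and DF2 must be positive integers")
    if ssc <= 0:
        raise ValueError("SSc must be positive")
    if ssc > ssr * (1 + 1e-12):
        raise ValueError(
            f"SSc ({ssc}) exceeds SSr ({ssr}): models are misordered or not nested"
        )
    F = max(0.0, (ssr - ssc) / df1 / (ssc / df2))
    return F, float(stats.f.sf(F, df1, df2))


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _gauss_llf(n: int, rss: float) -> float:
    # profile Gaussian log-likelihood of an OLS fit, up to the usual constants
    return -0.5 * n * np.log(rss / n)


@dataclass
class ComparisonResults:
    """Sequential partial-F comparison of two landscapes."""

    table: pd.DataFrame                 # index: block; SSr SSc DF1 DF2 F p
    followups: dict[str, pd.DataFrame]  # block -> per-nutrient chi2/p
    n: int
    group_labels: tuple[str, str]
    alpha: float

    def summary(self) -> str:
        lines = [
            f"Landscape comparison: {self.group_labels[0]} vs {self.group_labels[1]} "
            f"(n = {self.n} stacked observations)",
            f"{'block':<15}{'SSr':>10}{'SSc':>10}{'DF1':>5}{'DF2':>5}{'F':>8}{'p':>10}",
        ]
        for b, r in self.table.iterrows():
            lines.append(
                f"{b:<15}{r.SSr:>10.3f}{r.SSc:>10.3f}{int(r.DF1):>5}{int(r.DF2):>5}"
                f"{r.F:>8.2f}{r.p:>10.4g}"
            )
        for block, fu in self.followups.items():
            for nut, r in fu.iterrows():
                lines.append(
                    f"  follow-up [{block}] {nut}: chi2 = {r.chi2:.2f}, p = {r.p:.4g}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "groups": list(self.group_labels),
            "blocks": {
                b: {k: (int(v) if k in ("DF1", "DF2") else float(v))
                    for k, v in r.items()}
                for b, r in self.table.iterrows()
            },
            "followups": {
                b: {nut: {"chi2": float(r.chi2), "p": float(r.p)}
                    for nut, r in fu.iterrows()}
                for b, fu in self.followups.items()
            },
        }


class LandscapeComparison:
    """Build the stacked dataset and the six sequential models.

    Either compare one trait between two groups of flies::

        LandscapeComparison(ct_females, us_females, trait="LS")

    or two traits within the same flies (the records are stacked twice and
    the dummy codes the trait type)::

        LandscapeComparison(ct_females, traits=("LS", "DEP"))

    Intakes are z-standardized over the pooled stacked set (the comparison
    needs a common nutrient scale). The response is standardized over the
    pooled set too when one trait is compared between two groups
    (``response_scope="pooled"``, the default there; the partial F-tests
    are then exactly calibrated because F is invariant to a common affine
    rescaling). When two differently scaled traits are compared, each
    trait must be z-scored on its own (``response_scope="arm"``); the
    within-arm rescaling makes the quadratic-block test mildly
    conservative, which is inherent to comparing traits on z-scales.
    """

    def __init__(
        self,
        records_a: pd.DataFrame,
        records_b: pd.DataFrame | None = None,
        *,
        trait: str | None = None,
        traits: tuple[str, str] | None = None,
        group_labels: tuple[str, str] | None = None,
        intake_cols: tuple[str, str] = ("P_mg_day", "C_mg_day"),
        replicate_col: str = "replicate",
        replicate_fixed: bool = True,
        response_scope: str = "auto",
        group_main_effect: bool = True,
        alpha: float = 0.05,
    ):
        if response_scope not in ("auto", "pooled", "arm"):
            raise ValueError("response_scope must be 'auto', 'pooled' or 'arm'")
        if (records_b is None) == (traits is None):
            raise ValueError("provide either records_b with trait=, or traits=(t1, t2)")
        pcol, ccol = intake_cols
        if records_b is not None:
            if trait is None:
                raise ValueError("trait= is required for a two-group comparison")
            if len(records_a) == 0 or len(records_b) == 0:
                raise ValueError("both groups must be nonempty")
            parts = []
            for g, (rec, lbl) in enumerate(
                zip((records_a, records_b), group_labels or ("A", "B"))
            ):
                parts.append(pd.DataFrame({
                    "y": rec[trait].to_numpy(float),
                    "P": rec[pcol].to_numpy(float),
                    "C": rec[ccol].to_numpy(float),
                    "rep": rec[replicate_col].to_numpy(),
                    "g": g,
                    "arm": lbl,
                }))
            self.group_labels = tuple(group_labels or ("A", "B"))
        else:
            if len(records_a) == 0:
                raise ValueError("records must be nonempty")
            parts = []
            for g, t in enumerate(traits):
                parts.append(pd.DataFrame({
                    "y": records_a[t].to_numpy(float),
                    "P": records_a[pcol].to_numpy(float),
                    "C": records_a[ccol].to_numpy(float),
                    "rep": records_a[replicate_col].to_numpy(),
                    "g": g,
                    "arm": t,
                }))
            self.group_labels = traits
        df = pd.concat(parts, ignore_index=True).dropna()
        if df["g"].nunique() < 2:
            raise ValueError("comparison needs two nonempty arms")
        if response_scope == "auto":
            response_scope = "arm" if records_b is None else "pooled"
        # common nutrient scale over the pooled set
        df["zP"] = z_transform(df["P"])
        df["zC"] = z_transform(df["C"])
        df["zy"] = (z_transform(df["y"], df["arm"]) if response_scope == "arm"
                    else z_transform(df["y"]))
        self.data = df
        self.replicate_fixed = replicate_fixed
        self.group_main_effect = group_main_effect
        self.alpha = alpha

    # -- model matrices -----------------------------------------------------

    def _base_columns(self) -> tuple[np.ndarray, np.ndarray]:
        df = self.data
        cols = [np.ones(len(df))]
        if self.group_main_effect:
            # a chance (or real) mean difference between arms must be
            # absorbed here, not by the interaction blocks under test;
            # dropping it reproduces the historically printed df2 instead
            cols.append(df["g"].to_numpy(float))
        if self.replicate_fixed:
            dummies = pd.get_dummies(df["rep"], drop_first=True, dtype=float)
            cols.extend(dummies.to_numpy().T)
        return np.column_stack(cols), df["g"].to_numpy(float)

    def _model_matrices(self) -> dict[int, np.ndarray]:
        df = self.data
        base, g = self._base_columns()
        zP, zC = df["zP"].to_numpy(), df["zC"].to_numpy()
        zP2, zC2, zPC = zP**2, zC**2, zP * zC
        m = {}
        m[1] = np.column_stack([base, zP, zC])
        m[2] = np.column_stack([m[1], zP * g, zC * g])
        m[3] = np.column_stack([m[2], zP2, zC2])
        m[4] = np.column_stack([m[3], zP2 * g, zC2 * g])
        m[5] = np.column_stack([m[4], zPC])
        m[6] = np.column_stack([m[5], zPC * g])
        for k, X in m.items():
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(
                    f"model {k} design matrix is rank deficient; "
                    "unbalanced factor levels prevent interaction estimation"
                )
        return m

    # -- fitting ------------------------------------------------------------

    def fit(self) -> ComparisonResults:
        df = self.data
        y = df["zy"].to_numpy()
        n = len(df)
        m = self._model_matrices()
        rss = {k: _ols_rss(X, y) for k, X in m.items()}

        pairs = {"linear": (1, 2), "quadratic": (3, 4), "correlational": (5, 6)}
        rows = []
        for block, (r_idx, c_idx) in pairs.items():
            df1 = m[c_idx].shape[1] - m[r_idx].shape[1]
            df2 = n - m[c_idx].shape[1]
            F, p = partial_f(rss[r_idx], rss[c_idx], df1, df2)
            rows.append({"block": block, "SSr": rss[r_idx], "SSc": rss[c_idx],
                         "DF1": df1, "DF2": df2, "F": F, "p": p})
        table = pd.DataFrame(rows).set_index("block")

        followups = {}
        for block in BLOCKS:
            if table.loc[block, "p"] < self.alpha:
                followups[block] = self.univariate_followup(block, warn=False)
        return ComparisonResults(
            table=table, followups=followups, n=n,
            group_labels=self.group_labels, alpha=self.alpha,
        )

    def univariate_followup(self, block: str, warn: bool = True) -> pd.DataFrame:
        """Test each nutrient's group interaction in a block separately.

        Likelihood-ratio chi-square (df 1) between the block's larger model
        and that model with the single interaction column removed.
        """
        if block not in BLOCKS:
            raise ValueError(f"unknown block {block!r}")
        if warn:
            logger.warning(
                "univariate follow-up requested for block %r without a "
                "significance check", block,
            )
        y = self.data["zy"].to_numpy()
        n = len(y)
        m = self._model_matrices()
        full_idx = {"linear": 2, "quadratic": 4, "correlational": 6}[block]
        X_full = m[full_idx]
        rss_full = _ols_rss(X_full, y)
        # interaction columns are the trailing block of the larger model
        n_inter = {"linear": 2, "quadratic": 2, "correlational": 1}[block]
        nutrients = {
            "linear": ("protein", "carbohydrate"),
            "quadratic": ("protein", "carbohydrate"),
            "correlational": ("protein_x_carbohydrate",),
        }[block]
        rows = []
        for j, nut in enumerate(nutrients):
            drop = X_full.shape[1] - n_inter + j
            keep = [i for i in range(X_full.shape[1]) if i != drop]
            rss_r = _ols_rss(X_full[:, keep], y)
            stat = max(0.0, 2.0 * (_gauss_llf(n, rss_full) - _gauss_llf(n, rss_r)))
            rows.append({"nutrient": nut, "chi2": stat,
                         "p": float(stats.chi2.sf(stat, df=1))})
        return pd.DataFrame(rows).set_index("nutrient")
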