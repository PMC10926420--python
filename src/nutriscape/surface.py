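"""Response-surface estimation of nutrient effects on life-history traits.

The central model is a second-order (Lande–Arnold-style) response surface:
the trait is regressed on the linear (P, C), quadratic (P^2, C^2) and
correlational (P*C) terms of per-day protein and carbohydrate intake, with
replicate population as a random intercept. Estimation is by maximum
likelihood (not REML) so that nested fixed-effect terms can be compared by
likelihood-ratio chi-square tests, one per term, as in the coefficient
tables of nutritional-geometry studies. A negative quadratic coefficient
indicates a peak along that nutrient axis, a positive one a trough; the
correlational term measures how the nutrients' effects covary.

When the replicate variance estimates at its boundary (zero) the mixed fit
degenerates; the model then falls back to ordinary least squares with
replicate as fixed dummies, which has the same fixed-effects structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ResponseSurfaceModel",
    "SurfaceFitResults",
    "TotalConsumptionModel",
    "TotalConsumptionResults",
    "RankDeficientDesignError",
]

TERMS_LINEAR = ("beta_P", "beta_C")
TERMS_FULL = ("beta_P", "beta_C", "gamma_PP", "gamma_CC", "gamma_PC")

_VARIANCE_BOUNDARY = 1e-8
_COND_LIMIT = 1e10


class RankDeficientDesignError(np.linalg.LinAlgError):
    """The nutrient design matrix is (numerically) rank deficient."""


def _design_matrix(P: np.ndarray, C: np.ndarray, variant: str) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(P), P, C]
    names = ["intercept", "beta_P", "beta_C"]
    if variant == "full":
        cols += [P**2, C**2, P * C]
        names += ["gamma_PP", "gamma_CC", "gamma_PC"]
    X = np.column_stack(cols)
    return X, names


@dataclass
class SurfaceFitResults:
    """Fitted nutrient-effect coefficients with per-term likelihood-ratio tests."""

    params: pd.Series
    bse: pd.Series
    chi2: pd.Series
    pvalues: pd.Series
    llf: float
    n: int
    variant: str                      # "linear" | "full"
    random_effect_var: float
    method: str                       # "mixed_ml" | "ols_fallback"
    trait: str = ""

    @property
    def terms(self) -> tuple[str, ...]:
        return TERMS_FULL if self.variant == "full" else TERMS_LINEAR

    def coef_table(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            rows.append({
                "term": t,
                "coefficient": self.params[t],
                "se": self.bse[t],
                "chi2": self.chi2.get(t, np.nan),
                "p": self.pvalues.get(t, np.nan),
            })
        return pd.DataFrame(rows).set_index("term")

    def summary(self) -> str:
        head = (
            f"Response-surface fit ({self.variant}) for {self.trait or 'trait'}\n"
            f"n = {self.n}, method = {self.method}, "
            f"replicate variance = {self.random_effect_var:.4g}, "
            f"logLik = {self.llf:.3f}\n"
        )
        tbl = self.coef_table()
        lines = [head, f"{'term':<10}{'coef':>10}{'se':>9}{'chi2':>10}{'p':>10}"]
        for t, r in tbl.iterrows():
            lines.append(
                f"{t:<10}{r.coefficient:>10.3f}{r.se:>9.3f}{r.chi2:>10.2f}{r.p:>10.4g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "variant": self.variant,
            "method": self.method,
            "n": self.n,
            "llf": self.llf,
            "random_effect_var": self.random_effect_var,
            "coefficients": {t: float(self.params[t]) for t in self.terms},
            "se": {t: float(self.bse[t]) for t in self.terms},
            "chi2": {t: float(self.chi2.get(t, np.nan)) for t in self.terms},
            "p": {t: float(self.pvalues.get(t, np.nan)) for t in self.terms},
        }


class ResponseSurfaceModel:
    """Trait ~ nutrients response surface with a replicate random intercept.

    Parameters
    ----------
    data : DataFrame
        One row per fly after exclusions.
    trait : str
        Response column (typically a z-standardized trait, e.g. ``"zLS"``).
    variant : {"full", "linear"}
        Whether quadratic and correlational terms are included.
    intake_cols : (str, str)
        Protein and carbohydrate intake columns (typically ``("zP", "zC")``
        for standardized fits, or raw mg/day columns).
    replicate_col : str
        Grouping column for the random intercept.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        trait: str,
        *,
        variant: str = "full",
        intake_cols: tuple[str, str] = ("zP", "zC"),
        replicate_col: str = "replicate",
    ):
        if variant not in ("full", "linear"):
            raise ValueError("variant must be 'full' or 'linear'")
        cols = [trait, *intake_cols, replicate_col]
        df = data[cols].dropna()
        if len(df) < 10:
            raise ValueError(f"need >= 10 records, got {len(df)}")
        if df[replicate_col].nunique() < 2:
            raise ValueError("need >= 2 replicates for a random intercept")
        self.data = df.reset_index(drop=True)
        self.trait = trait
        self.variant = variant
        self.intake_cols = intake_cols
        self.replicate_col = replicate_col

        P = self.data[intake_cols[0]].to_numpy(float)
        C = self.data[intake_cols[1]].to_numpy(float)
        self.exog, self.exog_names = _design_matrix(P, C, variant)
        self.endog = self.data[trait].to_numpy(float)
        self.groups = self.data[replicate_col].to_numpy()
        cond = np.linalg.cond(self.exog)
        if (np.linalg.matrix_rank(self.exog) < self.exog.shape[1]
                or cond > _COND_LIMIT):
            raise RankDeficientDesignError(
                f"nutrient design matrix is rank deficient or ill-conditioned "
                f"(condition number {cond:.3g}); are all flies on a single rail?"
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str, **kw) -> "ResponseSurfaceModel":
        return cls(data, trait, **kw)

    # -- estimation ---------------------------------------------------------

    def _loglike(self, exog: np.ndarray, method: str | None = None):
        """ML log-likelihood of the mixed model (or its OLS fallback).

        ``method`` pins the estimator so that nested models in a
        likelihood-ratio pair are always fitted the same way.
        """
        if method in (None, "mixed_ml"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                try:
                    res = MixedLM(self.endog, exog, groups=self.groups).fit(reml=False)
                    re_var = float(np.asarray(res.cov_re)[0, 0])
                    bse = np.asarray(res.bse)  # fails on a singular Hessian
                    ok = (np.isfinite(res.llf) and np.all(np.isfinite(bse))
                          and re_var > _VARIANCE_BOUNDARY)
                    if ok or method == "mixed_ml":
                        return float(res.llf), res, "mixed_ml", max(re_var, 0.0)
                except (np.linalg.LinAlgError, ValueError):
                    if method == "mixed_ml":
                        raise
        # boundary / failed mixed fit: OLS with replicate fixed dummies
        dummies = pd.get_dummies(pd.Series(self.groups), drop_first=True, dtype=float)
        X = np.column_stack([exog, dummies.to_numpy()])
        res = sm.OLS(self.endog, X).fit()
        return float(res.llf), res, "ols_fallback", 0.0

    def fit(self) -> SurfaceFitResults:
        llf, res, method, re_var = self._loglike(self.exog)
        k = len(self.exog_names)
        params = pd.Series(np.asarray(res.params)[:k], index=self.exog_names)
        bse = pd.Series(np.asarray(res.bse)[:k], index=self.exog_names)

        chi2, pvals = {}, {}
        nutrient_terms = [n for n in self.exog_names if n != "intercept"]
        llf_ols_full = None
        for term in nutrient_terms:
            keep = [i for i, n in enumerate(self.exog_names) if n != term]
            try:
                llf_r, *_ = self._loglike(self.exog[:, keep], method=method)
                llf_f = llf
            except (np.linalg.LinAlgError, ValueError):
                # degenerate reduced mixed fit: use the OLS pair for this term
                if llf_ols_full is None:
                    llf_ols_full, *_ = self._loglike(self.exog, method="ols_fallback")
                llf_r, *_ = self._loglike(self.exog[:, keep], method="ols_fallback")
                llf_f = llf_ols_full
            stat = max(0.0, 2.0 * (llf_f - llf_r))
            chi2[term] = stat
            pvals[term] = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0

        return SurfaceFitResults(
            params=params,
            bse=bse,
            chi2=pd.Series(chi2),
            pvalues=pd.Series(pvals),
            llf=llf,
            n=len(self.endog),
            variant=self.variant,
            random_effect_var=re_var,
            method=method,
            trait=self.trait,
        )


# ---------------------------------------------------------------------------
# Total consumption model
# ---------------------------------------------------------------------------

@dataclass
class TotalConsumptionResults:
    """Fixed-effect tests for the overall food-consumption model."""

    params: pd.Series
    chi2: pd.Series
    pvalues: pd.Series
    llf: float
    n: int
    method: str

    def summary(self) -> str:
        lines = [
            f"Total consumption model (sqrt scale), n = {self.n}, method = {self.method}",
            f"{'term':<22}{'chi2':>10}{'p':>10}",
        ]
        for t in self.chi2.index:
            lines.append(f"{t:<22}{self.chi2[t]:>10.2f}{self.pvalues[t]:>10.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "method": self.method,
            "chi2": {t: float(v) for t, v in self.chi2.items()},
            "p": {t: float(v) for t, v in self.pvalues.items()},
            "coefficients": {t: float(v) for t, v in self.params.items()},
        }


class TotalConsumptionModel:
    """sqrt(total per-day consumption) ~ line * sex + concentration + ratio.

    Replicate enters as a random intercept. Main effects are tested by
    likelihood-ratio chi-squares from the additive model; the line x sex
    interaction against the additive model (marginality-respecting drops).
    The P:C ratio covariate is the numeric mass ratio p_parts / c_parts.
    """

    def __init__(self, data: pd.DataFrame, *, replicate_col: str = "replicate"):
        for col in ("line", "sex", "P_mg_day", "C_mg_day", "concentration", replicate_col):
            if col not in data.columns:
                raise KeyError(f"missing column {col!r}")
        if data["line"].nunique() < 2 or data["sex"].nunique() < 2:
            raise ValueError("total-consumption model needs both lines and both sexes")
        df = data.copy()
        total = df["P_mg_day"].to_numpy(float) + df["C_mg_day"].to_numpy(float)
        if np.any(total < 0):
            raise ValueError("negative total consumption")
        df["sqrt_total"] = np.sqrt(total)
        if "ratio" not in df.columns:
            df["ratio"] = df["p_parts"] / df["c_parts"]
        # replicate populations are nested within line
        df["_re_group"] = df["line"].astype(str) + ":" + df[replicate_col].astype(str)
        self.data = df
        self.replicate_col = replicate_col

    def _fit_formula(self, formula: str, use_ols: bool = False) -> tuple[float, object]:
        import statsmodels.formula.api as smf

        if use_ols:
            res = smf.ols(formula + " + C(_re_group)", data=self.data).fit()
            return float(res.llf), res
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = MixedLM.from_formula(
                formula, groups=self.data["_re_group"], data=self.data
            )
            res = m.fit(reml=False)
            np.asarray(res.bse)  # raises on a singular Hessian
        return float(res.llf), res

    def fit(self) -> TotalConsumptionResults:
        full_f = "sqrt_total ~ C(line) * C(sex) + concentration + ratio"
        additive_f = "sqrt_total ~ C(line) + C(sex) + concentration + ratio"
        use_ols = False
        try:
            llf_full, res_full = self._fit_formula(full_f)
        except (np.linalg.LinAlgError, ValueError):
            # degenerate mixed fit: replicate enters as fixed dummies instead
            use_ols = True
            llf_full, res_full = self._fit_formula(full_f, use_ols=True)
        llf_add, _ = self._fit_formula(additive_f, use_ols)

        drops = {
            "line": "sqrt_total ~ C(sex) + concentration + ratio",
            "sex": "sqrt_total ~ C(line) + concentration + ratio",
            "concentration": "sqrt_total ~ C(line) + C(sex) + ratio",
            "ratio": "sqrt_total ~ C(line) + C(sex) + concentration",
        }
        chi2, pvals = {}, {}
        for term, formula in drops.items():
            llf_r, _ = self._fit_formula(formula, use_ols)
            stat = max(0.0, 2.0 * (llf_add - llf_r))
            chi2[term] = stat
            pvals[term] = float(stats.chi2.sf(stat, df=1))
        stat = max(0.0, 2.0 * (llf_full - llf_add))
        chi2["line:sex"] = stat
        pvals["line:sex"] = float(stats.chi2.sf(stat, df=1))

        params = pd.Series(
            np.asarray(res_full.params)[: len(res_full.model.exog_names)],
            index=res_full.model.exog_names,
        )
        return TotalConsumptionResults(
            params=params,
            chi2=pd.Series(chi2),
            pvalues=pd.Series(pvals),
            llf=llf_full,
            n=len(self.data),
            method="ols_fallback" if use_ols else "mixed_ml",
        )
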