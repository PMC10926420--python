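import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nutriscape.compare import LandscapeComparison, partial_f

from conftest import simulate_surface_data


class TestPartialF:
    # published comparison-table rows that are internally consistent with
    # the partial-F formula: (SSr, SSc, DF1, DF2) -> F at 2 dp
    CONSISTENT_ROWS = [
        (195.573, 194.732, 2, 592, 1.28),
        (168.699, 166.744, 2, 592, 3.47),
        (143.904, 142.843, 2, 588, 2.18),
        (139.673, 139.558, 1, 586, 0.48),
        (206.340, 205.036, 2, 588, 1.87),
        (201.366, 201.260, 1, 586, 0.31),
        (100.026, 98.955, 2, 588, 3.18),
        (155.836, 155.815, 1, 586, 0.08),
    ]

    @pytest.mark.parametrize("ssr,ssc,df1,df2,expected", CONSISTENT_ROWS)
    def test_published_rows_reproduced(self, ssr, ssc, df1, df2, expected):
        F, p = partial_f(ssr, ssc, df1, df2)
        assert round(F, 2) == pytest.approx(expected)
        assert 0 <= p <= 1

    def test_equal_ss_gives_zero_f_unit_p(self):
        F, p = partial_f(100.0, 100.0, 2, 500)
        assert F == 0.0 and p == 1.0

    def test_misordered_models_rejected(self):
        with pytest.raises(ValueError, match="misordered"):
            partial_f(100.0, 101.0, 2, 500)

    def test_p_matches_f_distribution(self):
        F, p = partial_f(120.0, 100.0, 2, 50)
        assert p == pytest.approx(stats.f.sf(F, 2, 50))


def two_group_data(rng, n_per=100, beta_a=(0.1, 0.8), beta_b=None,
                   gamma_a=(0.0, 0.0, 0.0), gamma_b=None, noise_sd=1.0):
    beta_b = beta_b or beta_a
    gamma_b = gamma_b or gamma_a
    a = simulate_surface_data(rng, n=n_per, beta=beta_a, gamma=gamma_a, noise_sd=noise_sd)
    b = simulate_surface_data(rng, n=n_per, beta=beta_b, gamma=gamma_b, noise_sd=noise_sd)
    a = a.rename(columns={"y": "LS"})
    b = b.rename(columns={"y": "LS"})
    return a, b


class TestSequentialCompare:
    def test_brute_force_ols_oracle(self):
        # on a small dataset the block F equals the F computed by explicitly
        # fitting both OLS models and comparing residual sums of squares
        rng = np.random.default_rng(0)
        a, b = two_group_data(rng, n_per=25, noise_sd=1.0)
        cmp_ = LandscapeComparison(a, b, trait="LS")
        res = cmp_.fit()
        y = cmp_.data["zy"].to_numpy()
        m = cmp_._model_matrices()
        for block, (ri, ci) in {"linear": (1, 2), "quadratic": (3, 4),
                                "correlational": (5, 6)}.items():
            for idx, col in ((ri, "SSr"), (ci, "SSc")):
                X = m[idx]
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = float(((y - X @ beta) ** 2).sum())
                assert rss == pytest.approx(res.table.loc[block, col], abs=1e-10)
            df1 = m[ci].shape[1] - m[ri].shape[1]
            df2 = len(y) - m[ci].shape[1]
            ssr, ssc = res.table.loc[block, ["SSr", "SSc"]]
            F_expected = ((ssr - ssc) / df1) / (ssc / df2)
            assert res.table.loc[block, "F"] == pytest.approx(F_expected, abs=1e-10)

    def test_df2_sequence_at_600_flies(self):
        # 600 stacked observations with a 4-level replicate covariate:
        # the default models carry the group main effect (591, 587, 585);
        # omitting it reproduces the historical 592, 588, 586 sequence
        rng = np.random.default_rng(1)
        a, b = two_group_data(rng, n_per=300)
        res = LandscapeComparison(a, b, trait="LS").fit()
        assert list(res.table["DF1"]) == [2, 2, 1]
        assert list(res.table["DF2"]) == [591, 587, 585]
        legacy = LandscapeComparison(a, b, trait="LS", group_main_effect=False).fit()
        assert list(legacy.table["DF2"]) == [592, 588, 586]

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = two_group_data(rng, n_per=60)
        f_ab = LandscapeComparison(a, b, trait="LS").fit().table["F"]
        f_ba = LandscapeComparison(b, a, trait="LS").fit().table["F"]
        assert f_ab.to_numpy() == pytest.approx(f_ba.to_numpy(), abs=1e-9)

    def test_trait_mode_stacks_same_flies(self):
        rng = np.random.default_rng(3)
        a, _ = two_group_data(rng, n_per=80)
        a["DEP"] = a["LS"] * 0.5 + rng.normal(0, 1, len(a))
        res = LandscapeComparison(a, traits=("LS", "DEP")).fit()
        assert res.n == 160
        assert set(res.table.index) == {"linear", "quadratic", "correlational"}

    def test_linear_difference_detected_other_blocks_nominal(self):
        # groups differing only in the carbohydrate gradient: the linear
        # block must show high power while quadratic/correlational stay near
        # the nominal level
        n_sig = {"linear": 0, "quadratic": 0, "correlational": 0}
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(500 + seed)
            a, b = two_group_data(rng, n_per=300, beta_a=(0.1, 0.4),
                                  beta_b=(0.1, 1.0), noise_sd=0.5)
            res = LandscapeComparison(a, b, trait="LS").fit()
            for blk in n_sig:
                n_sig[blk] += res.table.loc[blk, "p"] < 0.05
        assert n_sig["linear"] >= 0.9 * n_seeds
        assert n_sig["quadratic"] <= 0.2 * n_seeds
        assert n_sig["correlational"] <= 0.2 * n_seeds

    def test_monotone_f_in_group_difference(self):
        medians = []
        for delta in (0.0, 0.3, 0.6):
            fs = []
            for seed in range(10):
                rng = np.random.default_rng(900 + seed)
                a, b = two_group_data(rng, n_per=150, beta_a=(0.1, 0.5),
                                      beta_b=(0.1, 0.5 + delta), noise_sd=0.7)
                fs.append(LandscapeComparison(a, b, trait="LS").fit()
                          .table.loc["linear", "F"])
            medians.append(np.median(fs))
        assert medians[0] <= medians[1] <= medians[2]

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(4)
        a, b = two_group_data(rng, n_per=30)
        with pytest.raises(ValueError):
            LandscapeComparison(a, b.iloc[:0], trait="LS")


class TestUnivariateFollowup:
    def test_carbohydrate_only_difference_attributed(self):
        # difference only in the carbohydrate gradient: its follow-up should
        # be significant while protein stays at the nominal level
        hits_c, hits_p = 0, 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(2000 + seed)
            a, b = two_group_data(rng, n_per=200, beta_a=(0.1, 0.4),
                                  beta_b=(0.1, 0.9), noise_sd=0.6)
            fu = LandscapeComparison(a, b, trait="LS").univariate_followup(
                "linear", warn=False
            )
            hits_c += fu.loc["carbohydrate", "p"] < 0.05
            hits_p += fu.loc["protein", "p"] < 0.05
        assert hits_c >= 0.85 * n_seeds
        assert hits_p <= 0.25 * n_seeds

    def test_null_pvalues_roughly_uniform(self):
        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(3000 + seed)
            a, b = two_group_data(rng, n_per=60, noise_sd=1.0)
            fu = LandscapeComparison(a, b, trait="LS").univariate_followup(
                "linear", warn=False
            )
            pvals.extend(fu["p"].tolist())
        # Kolmogorov-Smirnov against uniform: should not reject wildly
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.001

    def test_unknown_block_rejected(self):
        rng = np.random.default_rng(5)
        a, b = two_group_data(rng, n_per=30)
        with pytest.raises(ValueError):
            LandscapeComparison(a, b, trait="LS").univariate_followup("cubic")
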