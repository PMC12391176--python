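"""Group comparisons, mixed model, and backward-stepwise clinical models."""

import warnings

import numpy as np
import pandas as pd
import pytest

from pinprick_tfr import stats
from pinprick_tfr.core import ParameterError
from pinprick_tfr.synth import generate_feature_table

warnings.filterwarnings("ignore", category=UserWarning)


def _sample_with_moments(rng, n, mean, sd):
    """Exact-moment sample: standardized draws rescaled to (mean, sd)."""
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestCohensD:
    def test_hand_computed_group_contrast(self, rng):
        """Healthy 2.73 +- 1.36 vs sensorimotor 1.44 +- 0.59 (n = 10 each):
        the (n-1)-weighted pooled-SD convention gives d = 1.2306."""
        a = _sample_with_moments(rng, 10, 2.73, 1.36)
        b = _sample_with_moments(rng, 10, 1.44, 0.59)
        sp = np.sqrt((9 * 1.36**2 + 9 * 0.59**2) / 18)
        assert stats.cohens_d(a, b) == pytest.approx((2.73 - 1.44) / sp, rel=1e-9)
        assert stats.cohens_d(a, b) == pytest.approx(1.2306, abs=1e-4)

    def test_zero_for_identical_groups(self, rng):
        a = _sample_with_moments(rng, 12, 1.0, 0.5)
        assert stats.cohens_d(a, a) == 0.0


class TestAnova:
    @staticmethod
    def _table(groups, values):
        return pd.DataFrame({"group": groups, "np_amplitude": values})

    def test_f_matches_sums_of_squares_oracle(self, rng):
        """Three groups of five: F computed independently from SS formulas."""
        vals = {"a": [4.1, 5.2, 3.9, 4.8, 5.0],
                "b": [6.3, 6.9, 7.1, 6.0, 6.6],
                "c": [5.1, 4.7, 5.5, 5.3, 4.9]}
        table = self._table(sum(([g] * 5 for g in vals), []),
                            sum(vals.values(), []))
        res = stats.anova_amplitude(table, posthoc=False)
        all_vals = np.concatenate(list(vals.values()))
        grand = all_vals.mean()
        ss_between = sum(5 * (np.mean(v) - grand) ** 2 for v in vals.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                        for v in vals.values())
        f_oracle = (ss_between / 2) / (ss_within / 12)
        assert res.terms.loc[0, "F"] == pytest.approx(f_oracle, rel=1e-10)
        assert res.terms.loc[0, "df1"] == 2 and res.terms.loc[0, "df2"] == 12

    def test_two_group_f_equals_t_squared(self, rng):
        from scipy.stats import ttest_ind

        a = rng.normal(2.0, 1.0, 12)
        b = rng.normal(3.0, 1.0, 9)
        table = self._table(["x"] * 12 + ["y"] * 9, np.concatenate([a, b]))
        res = stats.anova_amplitude(table, posthoc=False)
        t = ttest_ind(a, b).statistic
        assert res.terms.loc[0, "F"] == pytest.approx(t**2, rel=1e-10)

    def test_posthoc_runs_regardless_of_omnibus(self, rng):
        table = self._table(["x"] * 8 + ["y"] * 8, rng.standard_normal(16))
        res = stats.anova_amplitude(table)  # null data, omnibus n.s.
        assert res.posthoc is not None and len(res.posthoc) == 1

    def test_small_group_rejected_by_name(self):
        table = self._table(["a", "a", "b"], [1.0, 2.0, 3.0])
        with pytest.raises(ParameterError, match="b"):
            stats.anova_amplitude(table)

    def test_residual_outlier_removal(self, rng):
        vals = np.concatenate([rng.normal(2, 0.2, 10), rng.normal(3, 0.2, 10)])
        vals[0] = 50.0
        table = self._table(["a"] * 10 + ["b"] * 10, vals)
        res = stats.anova_amplitude(table, remove_outliers=True, posthoc=False)
        assert len(res.notes["outliers_removed"]) == 1


class TestTukey:
    def test_identical_group_means_not_rejected(self, rng):
        base = rng.standard_normal(10)
        table = pd.DataFrame({
            "group": ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
            "v": np.concatenate([base, base, base])})
        tk = stats.tukey_posthoc(table, "v", "group")
        assert (tk["p_adj"] > 0.9).all()
        assert np.allclose(tk["cohens_d"], 0.0)

    def test_separated_groups_detected_with_direction(self, rng):
        table = pd.DataFrame({
            "group": ["a"] * 10 + ["b"] * 10,
            "v": np.concatenate([rng.normal(0, 0.5, 10), rng.normal(3, 0.5, 10)])})
        tk = stats.tukey_posthoc(table, "v", "group")
        assert tk.loc[0, "p_adj"] < 0.01 and tk.loc[0, "cohens_d"] > 2


class TestBackwardSelection:
    def test_marginality_never_violated_and_deterministic(self, rng):
        """A main effect is kept while its interaction is in the model, and
        reruns give identical selection paths."""
        n = 60
        df = pd.DataFrame({"x": rng.standard_normal(n),
                           "z": rng.integers(0, 2, n).astype(float)})
        df["y"] = 2.0 * df.x * df.z + rng.standard_normal(n) * 0.5

        import statsmodels.formula.api as smf

        def fit_fn(terms):
            rhs = " + ".join(terms) if terms else "1"
            return smf.ols(f"y ~ {rhs}", data=df).fit()

        paths = []
        for _ in range(2):
            fit, terms, dropped = stats.backward_select(fit_fn, ["x", "z", "x:z"])
            paths.append((tuple(terms), tuple(dropped)))
            assert "x:z" in terms  # generating interaction retained
            # marginality: mains present while interaction is
            assert "x" in terms and "z" in terms
        assert paths[0] == paths[1]

    def test_pure_noise_usually_reduces_to_intercept(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(20):
            df = pd.DataFrame(rng.standard_normal((40, 4)),
                              columns=["y", "a", "b", "c"])

            def fit_fn(terms, df=df):
                rhs = " + ".join(terms) if terms else "1"
                return smf.ols(f"y ~ {rhs}", data=df).fit()

            _, terms, _ = stats.backward_select(fit_fn, ["a", "b", "c"])
            hits += not terms
        assert hits >= 14  # ~(1 - alpha)^3 ~ 86% of null seeds


class TestMixedModel:
    @staticmethod
    def _long(rng, n_per_group=10, interaction=0.0, re_sd=0.5):
        rows = []
        p = 0
        for g in ("healthy", "motor", "sensorimotor"):
            for _ in range(n_per_group):
                u = rng.normal(0, re_sd)
                for f in ("delta", "theta", "alpha", "beta1", "beta2"):
                    eff = 0.5 if f in ("delta", "theta") else -0.5
                    if interaction and f == "alpha" and g == "sensorimotor":
                        eff += interaction
                    rows.append({"participant": f"p{p}", "group": g,
                                 "feature": f, "power": eff + u + rng.normal(0, 0.3)})
                p += 1
        return pd.DataFrame(rows)

    def test_zero_random_variance_matches_ols(self, rng):
        import statsmodels.formula.api as smf

        df = self._long(rng, re_sd=0.0)
        res = stats.mixed_model_power(df)
        ols = smf.ols("power ~ " + res.formula.split("~")[1], data=df).fit()
        fe = res.fit.fe_params if hasattr(res.fit, "fe_params") else res.fit.params
        np.testing.assert_allclose(np.asarray(fe), np.asarray(ols.params), atol=0.05)

    def test_generated_interaction_retained(self):
        rng = np.random.default_rng(21)
        kept = 0
        for _ in range(10):
            res = stats.mixed_model_power(self._long(rng, interaction=1.5))
            kept += "C(group):C(feature)" in set(res.terms["term"])
        assert kept >= 9

    def test_null_interaction_usually_dropped(self):
        rng = np.random.default_rng(22)
        dropped = 0
        for _ in range(10):
            res = stats.mixed_model_power(self._long(rng, interaction=0.0))
            dropped += "C(group):C(feature)" not in set(res.terms["term"])
        assert dropped >= 8

    def test_posthoc_contrasts_cover_all_cells(self, rng):
        res = stats.mixed_model_power(self._long(rng))
        assert set(res.posthoc["feature"]) == {"delta", "theta", "alpha",
                                               "beta1", "beta2"}
        assert len(res.posthoc) == 5 * 3  # 3 group pairs per feature


class TestClinicalRegression:
    def test_generating_terms_recovered_with_direction(self):
        ft = generate_feature_table(25, 25, seed=0)["features"]
        res = stats.clinical_regression(ft, "fma")
        terms = res.terms.set_index("term")
        assert "beta1" in terms.index
        assert terms.loc["beta1", "estimate"] < 0
        assert 0 < res.adj_r2 <= 1

    def test_change_model_uses_t2_minus_t1(self):
        ft = generate_feature_table(25, 25, seed=1)["features"]
        res = stats.clinical_regression(ft, "fma", change=True)
        assert res.kind == "clinical_change"
        assert "beta2" in set(res.terms["term"])  # generating change term

    def test_pure_noise_outcome_usually_empty_model(self):
        rng = np.random.default_rng(5)
        empty = 0
        for _ in range(15):
            ft = generate_feature_table(25, 25, seed=int(rng.integers(1e6)))["features"]
            ft["fma_t1"] = rng.standard_normal(len(ft))
            res = stats.clinical_regression(ft, "fma")
            empty += len(res.terms) == 0
        assert empty >= 6  # ~0.95^13 ~ 51% of null seeds

    def test_too_few_observations_rejected(self):
        ft = generate_feature_table(5, 5, seed=0)["features"]
        with pytest.raises(ParameterError):
            stats.clinical_regression(ft, "fma")

    def test_report_renders(self):
        ft = generate_feature_table(25, 25, seed=0)["features"]
        res = stats.clinical_regression(ft, "fma")
        text = stats.report(res)
        assert "adjusted R2" in text and "fma_t1" in text
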