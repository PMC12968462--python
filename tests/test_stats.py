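import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from netreconf.stats import (
    correlate_metrics_fatigue,
    default_blocks,
    encode_dmt,
    group_comparison_ancova,
    hierarchical_regression,
)


def _pheno(rng, n_ms=40, n_hc=20):
    n = n_ms + n_hc
    idx = [f"s{i}" for i in range(n)]
    return pd.DataFrame({
        "group": ["pwMS"] * n_ms + ["HC"] * n_hc,
        "age": rng.normal(38, 10, n),
        "sex": rng.integers(0, 2, n),
        "education": rng.normal(15, 3, n),
        "fatigue_total": rng.uniform(20, 90, n),
        "fatigue_motor": rng.uniform(10, 45, n),
        "fatigue_cognitive": rng.uniform(10, 45, n),
    }, index=idx)


class TestCorrelations:
    def test_perfect_association(self):
        rng = np.random.default_rng(0)
        pheno = _pheno(rng)
        summ = pd.DataFrame({"global_flexibility": pheno["fatigue_total"] * 0.001},
                            index=pheno.index)
        rep = correlate_metrics_fatigue(summ, pheno, metric_cols=["global_flexibility"],
                                        fatigue_cols=["fatigue_total"], family_size=1)
        ms = rep[(rep.group == "pwMS")].iloc[0]
        assert ms["r"] == pytest.approx(1.0)
        assert ms["p_raw"] < 1e-12

    def test_hand_computed_five_pairs(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 5.0])
        pheno = pd.DataFrame({"group": ["pwMS"] * 5, "fatigue_total": y},
                             index=list("abcde"))
        summ = pd.DataFrame({"global_promiscuity": x}, index=list("abcde"))
        rep = correlate_metrics_fatigue(summ, pheno, metric_cols=["global_promiscuity"],
                                        fatigue_cols=["fatigue_total"], family_size=1)
        assert rep.iloc[0]["r"] == pytest.approx(0.8)

    def test_bonferroni_multiplication_and_cap(self):
        rng = np.random.default_rng(1)
        pheno = _pheno(rng)
        summ = pd.DataFrame({"m": rng.normal(size=len(pheno))}, index=pheno.index)
        rep = correlate_metrics_fatigue(summ, pheno, metric_cols=["m"],
                                        fatigue_cols=["fatigue_total"], family_size=4)
        for _, row in rep.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, row["p_raw"] * 4))

    def test_family_size_one_leaves_p_unchanged(self):
        rng = np.random.default_rng(2)
        pheno = _pheno(rng)
        summ = pd.DataFrame({"m": rng.normal(size=len(pheno))}, index=pheno.index)
        rep = correlate_metrics_fatigue(summ, pheno, metric_cols=["m"],
                                        fatigue_cols=["fatigue_total"], family_size=1)
        assert (rep["p_adj"] == rep["p_raw"]).all()

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        pheno = _pheno(rng)
        summ = pd.DataFrame({"m": rng.normal(size=len(pheno))}, index=pheno.index)
        r1 = correlate_metrics_fatigue(summ, pheno, metric_cols=["m"], family_size=1)
        summ2 = summ * 37.0 + 5.0
        r2 = correlate_metrics_fatigue(summ2, pheno, metric_cols=["m"], family_size=1)
        np.testing.assert_allclose(r1["r"], r2["r"], atol=1e-12)

    def test_zero_variance_flagged(self):
        pheno = _pheno(np.random.default_rng(4))
        summ = pd.DataFrame({"m": 0.5}, index=pheno.index)
        rep = correlate_metrics_fatigue(summ, pheno, metric_cols=["m"], family_size=1)
        assert (rep["flag"] == "zero_variance").all()
        assert rep["r"].isna().all()


class TestAncova:
    def test_covariate_free_equals_t_test_squared(self):
        rng = np.random.default_rng(5)
        pheno = _pheno(rng)
        summ = pd.DataFrame({"m": rng.normal(size=len(pheno))}, index=pheno.index)
        rep = group_comparison_ancova(summ, pheno, metric_cols=["m"], covariates=(),
                                      family_size=1)
        ms = summ["m"][pheno.group == "pwMS"]
        hc = summ["m"][pheno.group == "HC"]
        t, p = sps.ttest_ind(ms, hc)
        assert rep.loc["m", "F"] == pytest.approx(t ** 2)
        assert rep.loc["m", "p_raw"] == pytest.approx(p)

    def test_collinear_covariate_named(self):
        rng = np.random.default_rng(6)
        pheno = _pheno(rng)
        pheno["age2"] = pheno["age"] * 2.0
        summ = pd.DataFrame({"m": rng.normal(size=len(pheno))}, index=pheno.index)
        with pytest.raises(ValueError, match="age"):
            group_comparison_ancova(summ, pheno, metric_cols=["m"],
                                    covariates=("age", "age2"), family_size=1)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(7)
        pheno = _pheno(rng, n_ms=30, n_hc=0)
        summ = pd.DataFrame({"m": rng.normal(size=len(pheno))}, index=pheno.index)
        with pytest.raises(ValueError):
            group_comparison_ancova(summ, pheno, metric_cols=["m"])

    def test_type_one_error_roughly_nominal(self):
        # quick calibration check; the full 500-replicate version lives in
        # the acceptance suite
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 150
        for _ in range(reps):
            pheno = _pheno(rng, n_ms=40, n_hc=40)
            summ = pd.DataFrame({"m": rng.normal(size=len(pheno))}, index=pheno.index)
            rep = group_comparison_ancova(summ, pheno, metric_cols=["m"], family_size=1)
            rejections += rep.loc["m", "p_raw"] < 0.05
        assert 0.01 <= rejections / reps <= 0.11


class TestHierarchicalRegression:
    def _data(self, rng, n=155, beta=0.2):
        dmt_cats = ["none", "interferon", "fingolimod"]
        df = pd.DataFrame({
            "age": rng.normal(39, 10, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.normal(14, 3, n),
            "edss": rng.choice([0, 1, 1.5, 2, 3, 4], n),
            "disease_duration": np.abs(rng.normal(10, 8, n)),
            "dmt_category": rng.choice(dmt_cats, n),
            "nbv": rng.normal(1512, 79, n),
            "t2_ll": np.exp(rng.normal(np.log(3.5), 0.6, n)),
            "metric": rng.normal(0.07, 0.01, n),
        }, index=[f"s{i}" for i in range(n)])
        z = (df["metric"] - df["metric"].mean()) / df["metric"].std(ddof=0)
        noise = rng.standard_normal(n)
        df["fatigue_total"] = 50 + 19 * (beta * z + np.sqrt(1 - beta ** 2) * noise)
        dmt = encode_dmt(df["dmt_category"])
        data = pd.concat([df.drop(columns="dmt_category"), dmt], axis=1)
        blocks = [("demographics", ["age", "sex", "education"]),
                  ("clinical", ["edss", "disease_duration", *dmt.columns]),
                  ("structural", ["nbv", "t2_ll"])]
        return data, blocks

    def test_single_block_matches_simple_regression(self):
        rng = np.random.default_rng(9)
        data, _ = self._data(rng)
        res = hierarchical_regression(data, "fatigue_total", "metric",
                                      blocks=[("demographics", ["age"])])
        import statsmodels.api as sm

        simple = sm.OLS(data["fatigue_total"], sm.add_constant(data[["age"]])).fit()
        assert res["steps"][0]["r2"] == pytest.approx(simple.rsquared)

    def test_r2_monotone_in_blocks(self):
        rng = np.random.default_rng(10)
        data, blocks = self._data(rng)
        res = hierarchical_regression(data, "fatigue_total", "metric", blocks)
        r2s = [s["r2"] for s in res["steps"]]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_orthogonal_predictor_beta_near_zero(self):
        rng = np.random.default_rng(11)
        data, blocks = self._data(rng, beta=0.0)
        res = hierarchical_regression(data, "fatigue_total", "metric", blocks)
        assert abs(res["beta"]) < 2.5 * res["beta_se"]

    def test_known_effect_recovered(self):
        rng = np.random.default_rng(12)
        betas = []
        for _ in range(40):
            data, blocks = self._data(rng, beta=0.2)
            res = hierarchical_regression(data, "fatigue_total", "metric", blocks)
            betas.append(res["beta"])
        assert np.mean(betas) == pytest.approx(0.2, abs=2.5 * np.std(betas) / np.sqrt(40))

    def test_too_many_parameters_rejected(self):
        rng = np.random.default_rng(13)
        data, blocks = self._data(rng, n=12)
        with pytest.raises(ValueError, match="12"):
            hierarchical_regression(data, "fatigue_total", "metric", blocks)

    def test_listwise_deletion_counted(self):
        rng = np.random.default_rng(14)
        data, blocks = self._data(rng)
        data.loc[data.index[:7], "edss"] = np.nan
        res = hierarchical_regression(data, "fatigue_total", "metric", blocks)
        assert res["n_dropped"] == 7 and res["n"] == len(data) - 7

    def test_default_blocks_use_dmt_dummies(self):
        rng = np.random.default_rng(15)
        pheno = pd.DataFrame({"dmt_category": ["none", "interferon"]})
        blocks = default_blocks(pheno)
        names = dict(blocks)
        assert "dmt_interferon" in names["clinical"]
        assert names["structural"] == ["nbv", "t2_ll"]
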