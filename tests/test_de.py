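"""CPM, expressed sets, size factors, NB Wald DE and the ddCt calculator."""

import numpy as np
import pandas as pd
import pytest

from tsrnakit.de import (DDCtInput, NormalizationError, apply_thresholds, cpm,
                         ddct, de_test, expressed_sets, size_factors)
from tsrnakit.simulate import nb_draw

GROUPS = ["Ctrl"] * 5 + ["Cd"] * 5


def _null_counts(seed, n_species=2000, n=5, disp=0.1, mean_log=np.log(200)):
    rng = np.random.default_rng(seed)
    means = rng.lognormal(mean=mean_log, sigma=1.0, size=n_species)
    counts = nb_draw(rng, np.tile(means[:, None], (1, 2 * n)), disp)
    cols = [f"Ctrl_{i}" for i in range(n)] + [f"Cd_{i}" for i in range(n)]
    return pd.DataFrame(counts, columns=cols)


class TestCpm:
    def test_counts_per_million_scale(self):
        counts = pd.DataFrame({"S1": [20, 10**6 - 20]})
        assert cpm(counts)["S1"].iloc[0] == pytest.approx(20.0)

    def test_columns_sum_to_one_million(self):
        counts = _null_counts(0, n_species=500)
        sums = cpm(counts).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_scale_invariance_per_sample(self):
        counts = _null_counts(1, n_species=100)
        doubled = counts.copy()
        doubled["Ctrl_0"] *= 2
        pd.testing.assert_series_equal(cpm(counts)["Ctrl_0"],
                                       cpm(doubled)["Ctrl_0"])

    def test_zero_total_sample_is_an_error_naming_it(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(NormalizationError, match="empty"):
            cpm(counts)


class TestExpressedSets:
    def test_threshold_is_inclusive(self):
        cpm_df = pd.DataFrame({"C1": [20.0], "C2": [20.0],
                               "T1": [20.0], "T2": [20.0]}, index=["x"])
        sets = expressed_sets(cpm_df, ["Ctrl", "Ctrl", "Cd", "Cd"])
        assert sets["common"] == {"x"}

    def test_silent_species_in_no_set(self):
        cpm_df = pd.DataFrame({"C1": [0.0, 100.0], "T1": [0.0, 100.0],
                               "C2": [0.0, 100.0], "T2": [0.0, 100.0]},
                              index=["silent", "loud"])
        sets = expressed_sets(cpm_df, ["Ctrl", "Cd", "Ctrl", "Cd"])
        assert "silent" not in set().union(*sets.values())

    def test_venn_is_a_partition(self):
        rng = np.random.default_rng(5)
        cpm_df = pd.DataFrame(rng.uniform(0, 60, size=(200, 4)),
                              columns=["C1", "C2", "T1", "T2"])
        groups = ["Ctrl", "Ctrl", "Cd", "Cd"]
        sets = expressed_sets(cpm_df, groups)
        union = set().union(*sets.values())
        assert sum(len(s) for s in sets.values()) == len(union)
        mean_c = cpm_df[["C1", "C2"]].mean(axis=1)
        mean_t = cpm_df[["T1", "T2"]].mean(axis=1)
        expressed_any = set(cpm_df.index[(mean_c >= 20) | (mean_t >= 20)])
        assert union == expressed_any


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"A": [5, 9, 30], "B": [5, 9, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_has_double_the_factor_of_its_peers(self):
        col = _null_counts(2, n_species=300)["Ctrl_0"]
        counts = pd.DataFrame({"A": col, "B": col, "C": col * 2})
        f = size_factors(counts)
        assert f["C"] / f["A"] == pytest.approx(2.0, rel=1e-9)
        assert f["A"] == pytest.approx(f["B"], rel=1e-12)

    def test_matches_median_of_ratios_formula(self):
        counts = _null_counts(3, n_species=200, n=3)
        got = size_factors(counts).to_numpy()
        arr = counts.to_numpy(float)
        keep = arr[(arr > 0).all(axis=1)]
        log_gm = np.log(keep).mean(axis=1)
        want = [np.median(keep[:, j] / np.exp(log_gm))
                for j in range(arr.shape[1])]
        assert np.allclose(got, want)

    def test_all_zero_row_fallback_warns(self):
        counts = pd.DataFrame({"A": [0, 3], "B": [2, 0]})
        with pytest.warns(UserWarning):
            f = size_factors(counts)
        assert (f > 0).all()


class TestDeTest:
    def test_null_type_one_error_near_nominal(self):
        counts = _null_counts(7)
        res = de_test(counts, GROUPS)
        rate = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_null_pvalues_approximately_uniform(self):
        from scipy.stats import kstest
        res = de_test(_null_counts(8), GROUPS)
        assert kstest(res["pvalue"], "uniform").statistic < 0.05

    def test_equal_groups_give_zero_lfc(self):
        counts = pd.DataFrame(np.tile([[100]], (3, 10)),
                              columns=[f"s{i}" for i in range(10)])
        res = de_test(counts, GROUPS)
        assert np.allclose(res["log2FC"], 0.0)

    def test_all_zero_species_reported_ns(self):
        counts = _null_counts(9, n_species=20)
        counts.iloc[0] = 0
        res = de_test(counts, GROUPS)
        assert res.iloc[0]["pvalue"] == 1.0
        assert res.iloc[0]["regulation"] == "NS"
        assert not res.iloc[0]["tested"]

    def test_group_role_swap_negates_lfc_exactly(self):
        """Assigning the condition labels to the opposite samples reverses
        the contrast: log2FC negates exactly, p-values are unchanged."""
        counts = _null_counts(10, n_species=100)
        res1 = de_test(counts, GROUPS)
        swapped = counts[list(counts.columns[5:]) + list(counts.columns[:5])]
        res2 = de_test(swapped, GROUPS)
        assert np.allclose(res1["log2FC"], -res2["log2FC"])
        assert np.allclose(res1["pvalue"], res2["pvalue"])

    def test_bh_adjustment_properties(self):
        res = de_test(_null_counts(11, n_species=500), GROUPS)
        assert (res["padj"] >= res["pvalue"] - 1e-12).all()
        assert (res["padj"] <= 1.0).all()
        ordered = res.sort_values("pvalue")
        assert ordered["padj"].is_monotonic_increasing

    def test_planted_effects_recovered_with_sign(self):
        """9 up + 5 down at |log2FC|=2, depth 1e5, 5 vs 5: >=12/14 recovered
        sign-correct in at least 90% of 20 seeds."""
        passes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ns, n, depth = 300, 5, 1e5
            ab = rng.lognormal(0, 1, ns)
            ab /= ab.sum()
            lfc_true = np.zeros(ns)
            idx = rng.choice(ns, 14, replace=False)
            lfc_true[idx[:9]], lfc_true[idx[9:]] = 2.0, -2.0
            m1 = depth * ab * 2 ** (-lfc_true / 2)
            m2 = depth * ab * 2 ** (lfc_true / 2)
            means = np.hstack([np.tile(m1[:, None], (1, n)),
                               np.tile(m2[:, None], (1, n))])
            counts = pd.DataFrame(nb_draw(rng, means, 0.1),
                                  columns=[f"s{i}" for i in range(2 * n)])
            res = de_test(counts, GROUPS)
            sig = (res["log2FC"].abs() > 1.5) & (res["pvalue"] < 0.05)
            ok = sum(1 for j in idx
                     if sig.iloc[j]
                     and np.sign(res["log2FC"].iloc[j]) == np.sign(lfc_true[j]))
            passes += ok >= 12
        assert passes >= 18

    def test_independent_nb_glm_agrees_on_strong_effects(self):
        """Cross-check against statsmodels' NB GLM per species: the Wald
        screen and an independently fitted model call the same strong
        effects with the same signs."""
        import statsmodels.api as sm
        rng = np.random.default_rng(21)
        ns, n = 40, 5
        ab = np.full(ns, 1 / ns)
        lfc_true = np.zeros(ns)
        lfc_true[:4], lfc_true[4:8] = 3.0, -3.0
        m1 = 5e4 * ab * 2 ** (-lfc_true / 2)
        m2 = 5e4 * ab * 2 ** (lfc_true / 2)
        means = np.hstack([np.tile(m1[:, None], (1, n)),
                           np.tile(m2[:, None], (1, n))])
        counts = pd.DataFrame(nb_draw(rng, means, 0.05),
                              columns=[f"s{i}" for i in range(2 * n)])
        res = de_test(counts, GROUPS)
        X = sm.add_constant(np.repeat([0.0, 1.0], n))
        for j in range(8):
            glm = sm.GLM(counts.iloc[j].to_numpy(), X,
                         family=sm.families.NegativeBinomial(alpha=0.05)).fit()
            lfc_glm = glm.params[1] / np.log(2)
            assert np.sign(lfc_glm) == np.sign(res["log2FC"].iloc[j])
            assert abs(lfc_glm - res["log2FC"].iloc[j]) < 0.5
            assert glm.pvalues[1] < 0.05 and res["pvalue"].iloc[j] < 0.05


class TestThresholds:
    def test_boundary_lfc_excluded(self):
        res = pd.DataFrame({"log2FC": [1.5, 1.51, -1.5, -1.6],
                            "pvalue": [0.01] * 4, "padj": [0.01] * 4})
        kept = apply_thresholds(res)
        assert list(kept["log2FC"]) == [1.51, -1.6]
        assert list(kept["regulation"]) == ["Up", "Down"]

    def test_boundary_pvalue_excluded(self):
        res = pd.DataFrame({"log2FC": [2.0, 2.0],
                            "pvalue": [0.05, 0.049], "padj": [0.05, 0.049]})
        assert len(apply_thresholds(res)) == 1


class TestDdct:
    @pytest.mark.parametrize("ddct_value,expected", [
        (0.0, 1.0), (1.0, 0.5), (-2.0, 4.0),
    ])
    def test_closed_form(self, ddct_value, expected):
        inp = DDCtInput(ct_target_treated=20.0 + ddct_value,
                        ct_reference_treated=15.0,
                        ct_target_control=20.0, ct_reference_control=15.0)
        assert ddct(inp) == pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct(DDCtInput(np.nan, 15.0, 20.0, 15.0))
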