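import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chronostat import (
    compare_rhythms,
    factorial_anova,
    fold_change,
    group_mean_correlation,
    group_summaries,
)
from chronostat.errors import (
    InsufficientDataError,
    UnbalancedDesignWarning,
    UndefinedRatioError,
)
from conftest import make_samples
from oracles import oneway_anova_f


class TestCompareRhythms:
    def test_identical_datasets_give_zero_statistic(self, rng):
        a = make_samples(1.0, 0.5, 10.0, noise_sd=0.2, rng=rng)
        for param in ("joint", "acrophase", "amplitude"):
            res = compare_rhythms(a, a.copy(), parameter=param)
            assert res.statistic == pytest.approx(0.0, abs=1e-8)
            assert res.p_value == pytest.approx(1.0, abs=1e-8)

    def test_six_hour_shift_detected(self, rng):
        a = make_samples(1.0, 0.5, 6.0, noise_sd=0.05, rng=rng)
        b = a.copy()
        b["zt_h"] = (b["zt_h"] + 6.0) % 24.0  # same data, rhythm shifted 6 h
        res = compare_rhythms(a, b, parameter="acrophase")
        assert res.p_value < 0.001
        assert abs(res.estimate) == pytest.approx(6.0, abs=0.5)
        joint = compare_rhythms(a, b, parameter="joint")
        assert joint.p_value < 0.001

    def test_symmetric_under_group_swap(self, rng):
        a = make_samples(1.0, 0.6, 9.0, noise_sd=0.25, rng=rng)
        b = make_samples(1.2, 0.4, 14.0, noise_sd=0.25, rng=rng)
        for param in ("joint", "acrophase", "amplitude"):
            ab = compare_rhythms(a, b, parameter=param)
            ba = compare_rhythms(b, a, parameter=param)
            assert ab.statistic == pytest.approx(ba.statistic, rel=1e-9)
            assert ab.p_value == pytest.approx(ba.p_value, rel=1e-9)

    def test_acrophase_difference_uses_shortest_arc(self, rng):
        a = make_samples(1.0, 0.5, 23.0, noise_sd=0.05, rng=rng)
        b = make_samples(1.0, 0.5, 1.0, noise_sd=0.05, rng=rng)
        res = compare_rhythms(a, b, parameter="acrophase")
        assert abs(res.estimate) <= 12.0
        assert res.estimate == pytest.approx(-2.0, abs=0.5)

    def test_degenerate_group_propagates(self, rng):
        a = make_samples(1.0, 0.5, 10.0, noise_sd=0.2, rng=rng)
        flat = make_samples(1.0, 0.0, 0.0)
        from chronostat.errors import DegenerateDesignError
        with pytest.raises(DegenerateDesignError):
            compare_rhythms(a, flat, parameter="acrophase")


class TestFactorialAnova:
    def test_one_factor_matches_textbook_oracle(self, rng):
        groups = [rng.normal(m, 1.0, 10) for m in (0.0, 0.5, 1.5)]
        df = pd.DataFrame({
            "strain": np.repeat(["a", "b", "c"], 10),
            "value": np.concatenate(groups)})
        table = factorial_anova(df, ("strain",))
        f_oracle, df_b, df_w = oneway_anova_f(groups)
        row = table[table["term"] == "strain"].iloc[0]
        assert row["F"] == pytest.approx(f_oracle, rel=1e-10)
        assert row["df"] == df_b
        assert table.attrs["ss_type"] == 1  # balanced

    def test_zero_between_group_variance(self, rng):
        vals = rng.normal(0, 1, 10)
        df = pd.DataFrame({"sex": ["m"] * 10 + ["f"] * 10,
                           "value": np.concatenate([vals, vals])})
        table = factorial_anova(df, ("sex",))
        row = table[table["term"] == "sex"].iloc[0]
        assert row["F"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_full_factorial_terms_present(self, rng):
        df = pd.concat([
            make_samples(1.0, 0.7, 10.0, noise_sd=0.25, rng=rng,
                         strain=s, sex=x)
            for s in ("B6D2F1", "B6CBAF1") for x in ("male", "female")],
            ignore_index=True)
        table = factorial_anova(df, ("zt", "strain", "sex"))
        terms = set(table["term"])
        assert {"zt_h", "strain", "sex", "zt_h:strain:sex", "Residual"} <= terms
        zt_row = table[table["term"] == "zt_h"].iloc[0]
        assert zt_row["p_value"] < 1e-6  # strong shared rhythm

    def test_unbalanced_design_uses_type_three(self, rng):
        df = pd.DataFrame({
            "strain": ["a"] * 12 + ["b"] * 5,
            "sex": (["m"] * 6 + ["f"] * 6) + (["m"] * 3 + ["f"] * 2),
            "value": rng.normal(0, 1, 17)})
        table = factorial_anova(df, ("strain", "sex"))
        assert table.attrs["ss_type"] == 3

    def test_empty_cells_warn_with_names(self, rng):
        df = pd.DataFrame({
            "strain": ["a"] * 10 + ["b"] * 5,
            "sex": ["m"] * 5 + ["f"] * 5 + ["m"] * 5,
            "value": rng.normal(0, 1, 15)})
        with pytest.warns(UnbalancedDesignWarning, match=r"\('b', 'f'\)"):
            factorial_anova(df, ("strain", "sex"))

    def test_zt_effect_power_and_nuisance_type_i(self, rng):
        """ZT term is detected nearly always; a null strain factor near 5%."""
        n_rep, zt_hits, strain_hits = 120, 0, 0
        for _ in range(n_rep):
            df = pd.concat([
                make_samples(1.0, 0.72, 10.0, noise_sd=0.25, rng=rng, strain=s)
                for s in ("a", "b")], ignore_index=True)
            table = factorial_anova(df, ("zt", "strain"))
            p = table.set_index("term")["p_value"]
            zt_hits += p["zt_h"] < 0.05
            strain_hits += p["strain"] < 0.05
        assert zt_hits / n_rep > 0.8
        assert strain_hits / n_rep < 0.15


class TestGroupMeanCorrelation:
    def _cells(self, values):
        idx = [(s, x, z) for s in ("a", "b") for x in ("m", "f")
               for z in (0.0, 6.0, 12.0, 18.0)]
        return pd.DataFrame([{"strain": s, "sex": x, "zt_h": z, "mean": v}
                             for (s, x, z), v in zip(idx, values)])

    def test_perfect_linear_relation(self, rng):
        x = self._cells(rng.uniform(1, 5, 16))
        y = x.copy()
        y["mean"] = 2.0 * y["mean"]
        r, p, n = group_mean_correlation(x, y)
        assert r == pytest.approx(1.0)
        assert n == 16
        y["mean"] = -x["mean"]
        r, _, _ = group_mean_correlation(x, y)
        assert r == pytest.approx(-1.0)

    def test_null_p_values_are_uniform(self, rng):
        """Under independence the p-value is U(0,1): KS check on 400 sims."""
        from scipy import stats
        pvals = []
        for _ in range(400):
            x = self._cells(rng.normal(0, 1, 16))
            y = self._cells(rng.normal(0, 1, 16))
            _, p, _ = group_mean_correlation(x, y)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_insufficient_pairs_rejected(self):
        x = self._cells(np.arange(16.0)).head(2)
        with pytest.raises(InsufficientDataError):
            group_mean_correlation(x, x)


class TestFoldChange:
    def test_printed_style_six_fold(self):
        s = pd.DataFrame({"zt_h": [0.0, 12.0], "mean": [1.0, 6.0]})
        assert fold_change(s) == (12.0, 0.0, 6.0)

    def test_constant_means(self):
        s = pd.DataFrame({"zt_h": [0.0, 6.0, 12.0], "mean": [2.0, 2.0, 2.0]})
        peak, trough, ratio = fold_change(s)
        assert ratio == 1.0
        assert peak == trough == 0.0

    def test_direct_max_min(self):
        s = pd.DataFrame({"zt_h": [0.0, 6.0, 12.0, 18.0],
                          "mean": [2.0, 4.0, 8.0, 4.0]})
        assert fold_change(s) == (12.0, 0.0, 4.0)

    def test_nonpositive_trough_undefined(self):
        s = pd.DataFrame({"zt_h": [0.0, 12.0], "mean": [0.0, 6.0]})
        with pytest.raises(UndefinedRatioError):
            fold_change(s)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        s = pd.DataFrame({"zt_h": [0.0, 6.0, 12.0], "mean": [1.0, 3.0, 2.0]})
        scaled = s.copy()
        scaled["mean"] *= scale
        assert fold_change(scaled)[2] == pytest.approx(fold_change(s)[2], rel=1e-9)


def test_group_summaries_sem_definition(rng):
    df = make_samples(1.0, 0.5, 10.0, noise_sd=0.3, rng=rng)
    summ = group_summaries(df)
    one = df[df["zt_h"] == 0.0]["value"]
    row = summ[summ["zt_h"] == 0.0].iloc[0]
    assert row["mean"] == pytest.approx(one.mean())
    assert row["sem"] == pytest.approx(one.std(ddof=1) / np.sqrt(len(one)))
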