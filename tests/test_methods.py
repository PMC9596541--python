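"""Replicate F_ST test, error-variance test, and their FDR scans."""

import numpy as np
import pandas as pd
import pytest

from poolbsa.diff import (
    PoolContrast,
    intersect_methods,
    method1_fdr,
    method1_fdr_scan,
    method1_stats,
    method1_test,
    method2_fdr,
    method2_fdr_scan,
    method2_stats,
    method2_test,
)


class TestMethod1:
    def test_strong_contrast_significant_in_all_six(self, pools):
        # frequencies of the strongest reported SNP contrast, replicated
        freqs = [[0.27, 0.27, 0.27, 0.95, 0.95, 0.95]]
        df = method1_test(freqs, pools, p_level=0.001)
        assert (df["p"] <= 0.001).all()
        assert df["marker_significant"].all()

    def test_equal_frequencies_not_significant(self, pools):
        df = method1_test([[0.5] * 6], pools, p_level=0.05)
        assert (df["fst"] == 0).all()
        assert not df["marker_significant"].any()

    def test_one_failing_comparison_blocks_marker(self, pools):
        # E3 sits at the late-group mean: its comparison cannot be significant
        freqs = [[0.1, 0.1, 0.9, 0.9, 0.9, 0.9]]
        df = method1_test(freqs, pools, p_level=0.001)
        assert (df["p"] > 0.001).any()
        assert not df["marker_significant"].any()

    def test_direction_must_oppose_between_groups(self, pools):
        # early pools scatter on both sides of the late mean
        freqs = np.array([[0.1, 0.9, 0.1, 0.5, 0.5, 0.5]])
        st = method1_stats(freqs, pools)
        assert not st["direction_ok"][0]

    def test_contrast_weights_are_summed_gametes(self, pools):
        st = method1_test([[0.27, 0.27, 0.27, 0.95, 0.95, 0.95]], pools)
        # focal early pool of 18 vs 104 late gametes -> 2N = 140
        assert st.loc[st["pool"] == "E1", "two_n"].iloc[0] == 140
        assert st.loc[st["pool"] == "E2", "two_n"].iloc[0] == 138

    def test_null_direction_rule_symmetry_and_oracle(self, pools, rng):
        # under iid null pools the two direction patterns are equally
        # likely, and the rule matches a brute-force re-derivation; note
        # the six directions share the two group means, so consistency is
        # far more common than independent signs would suggest — which is
        # why the rule is paired with six-fold significance
        freqs = rng.random((40_000, 6))
        st = method1_stats(freqs, pools)
        gam = np.array([p.n_gametes for p in pools], dtype=float)
        mean_e = freqs[:, :3] @ gam[:3] / gam[:3].sum()
        mean_l = freqs[:, 3:] @ gam[3:] / gam[3:].sum()
        e_high = (freqs[:, :3] > mean_l[:, None]).all(axis=1) & (
            freqs[:, 3:] < mean_e[:, None]
        ).all(axis=1)
        e_low = (freqs[:, :3] < mean_l[:, None]).all(axis=1) & (
            freqs[:, 3:] > mean_e[:, None]
        ).all(axis=1)
        np.testing.assert_array_equal(st["direction_ok"], e_high | e_low)
        p_up, p_down = e_high.mean(), e_low.mean()
        se = np.sqrt((p_up + p_down) / len(freqs))
        assert abs(p_up - p_down) <= 3 * se

    def test_missing_frequency_skips_marker(self, pools):
        freqs = np.array([[0.2, np.nan, 0.2, 0.8, 0.8, 0.8]])
        st = method1_stats(freqs, pools)
        assert not st["valid"][0]
        assert np.isnan(st["max_p"][0])


class TestMethod2:
    def test_identical_group_means_give_zero(self, pools):
        res = method2_test([[0.3] * 6], pools)
        assert res["z2"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_hand_computed_statistic(self, pools):
        # replicates exactly 0.2 vs 0.8: V2 = 0, V1 each = 0.16/104
        res = method2_test([[0.2, 0.2, 0.2, 0.8, 0.8, 0.8]], pools)
        assert res["v2_early"].iloc[0] == pytest.approx(0.0, abs=1e-15)
        assert res["v1_early"].iloc[0] == pytest.approx(0.16 / 104)
        assert res["z2"].iloc[0] == pytest.approx(0.36 / (2 * 0.16 / 104), rel=1e-9)
        assert res["z2"].iloc[0] == pytest.approx(117.0, abs=0.1)

    def test_fixed_opposite_alleles_degenerate(self, pools):
        res = method2_test([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]], pools)
        assert np.isinf(res["z2"].iloc[0])
        assert res["p"].iloc[0] == 0.0
        assert res["degenerate"].iloc[0]

    def test_matches_bruteforce_definition(self, pools, rng):
        gam = np.array([p.n_gametes for p in pools], dtype=float)
        freqs = rng.random((50, 6))
        res = method2_stats(freqs, pools)
        for m in range(50):
            qe = np.average(freqs[m, :3], weights=gam[:3])
            ql = np.average(freqs[m, 3:], weights=gam[3:])
            v1e, v1l = qe * (1 - qe) / 104, ql * (1 - ql) / 104
            v2e = np.var(freqs[m, :3], ddof=1) / 3
            v2l = np.var(freqs[m, 3:], ddof=1) / 3
            expect = (ql - qe) ** 2 / (v1e + v1l + v2e + v2l)
            assert res["z2"][m] == pytest.approx(expect, rel=1e-12)


class TestFdrScans:
    def test_method1_fdr_arithmetic(self):
        assert method1_fdr(10_000, 0.05, 5) == pytest.approx(0.0625)

    def test_method2_fdr_arithmetic(self):
        assert method2_fdr(100_000, 1e-5, 20) == pytest.approx(0.05)
        # all markers significant -> FDR = P
        assert method2_fdr(500, 0.01, 500) == pytest.approx(0.01)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            method2_fdr_scan(np.array([0.5]), p_grid=np.array([]))

    def test_no_discoveries_returns_empty_set(self):
        p = np.full(100, 0.9)
        with pytest.warns(UserWarning):
            res = method2_fdr_scan(p, target_fdr=0.05)
        assert res["d"] == 0 and not res["significant"].any()

    def test_scan_chooses_largest_qualifying_level(self):
        # 1000 markers: 30 at p=1e-6, rest uniform-ish large
        p = np.concatenate([np.full(30, 1e-6), np.linspace(0.2, 1, 970)])
        res = method2_fdr_scan(p, target_fdr=0.05)
        assert res["d"] == 30
        # chosen level admits all 30 while keeping l*P/d <= 0.05
        assert res["p_level"] >= 1e-6
        assert res["fdr"] <= 0.05

    def test_method1_scan_requires_direction(self):
        max_p = np.full(100, 1e-9)
        direction = np.zeros(100, dtype=bool)
        with pytest.warns(UserWarning):
            res = method1_fdr_scan(max_p, direction, target_fdr=0.05)
        assert res["d"] == 0


class TestIntersect:
    def test_basic_intersection(self):
        res = intersect_methods({"a": {"x", "y", "z"}, "b": {"y", "z"}, "c": {"z"}})
        assert res["consensus"] == {"z"}
        assert res["per_method"] == {"a": 3, "b": 2, "c": 1}

    def test_empty_set_empties_consensus(self):
        res = intersect_methods({"a": {"x"}, "b": set()})
        assert res["consensus"] == set()


class TestModelInterface:
    def test_fit_and_summary(self, pools, rng):
        n = 300
        freqs = rng.random((n, 6))
        freqs[0] = [0.05, 0.06, 0.05, 0.95, 0.94, 0.96]  # planted contrast
        df = pd.DataFrame(freqs, columns=[p.pool_id for p in pools],
                          index=[f"m{i}" for i in range(n)])
        model = PoolContrast(df, pools)
        res = model.fit(method="error_variance", fdr=0.05)
        assert "m0" in res.significant
        text = res.summary()
        assert "Error-variance" in text and "Markers tested" in text

    def test_missing_pool_column_rejected(self, pools):
        df = pd.DataFrame({"E1": [0.5]})
        with pytest.raises(ValueError):
            PoolContrast(df, pools)

    def test_two_group_fst_summary(self, pools):
        df = pd.DataFrame(
            [[0.96, 0.96, 0.96, 0.14, 0.14, 0.14]],
            columns=[p.pool_id for p in pools], index=["m"],
        )
        res = PoolContrast(df, pools).fit("error_variance")
        assert res.two_group_fst().iloc[0] == pytest.approx(0.6792, abs=1e-3)
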