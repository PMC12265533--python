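"""Confidence binning, rates/K, ROC construction, RM statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmcda.behavior import (
    DegenerateTestError,
    RejectedResponseError,
    bin_confidence,
    build_roc,
    compute_rates,
    pairwise_tests,
    rm_anova,
    roc_from_counts,
)


class TestBinConfidence:
    @pytest.mark.parametrize(
        "angle,expected",
        [
            (-30.0, 6),    # center of surely-old
            (0.0, 5),      # center of probably-old
            (30.0, 4),     # center of guess-old
            (150.0, 3),    # center of guess-new
            (180.0, 2),    # center of probably-new
            (210.0, 1),    # center of surely-new
            (330.0, 6),    # wrap-around form of -30
        ],
    )
    def test_region_centers(self, angle, expected):
        assert bin_confidence(angle) == expected

    @pytest.mark.parametrize(
        "angle,expected",
        [(15.0, 4), (-15.0, 5), (195.0, 1), (165.0, 2)],
    )
    def test_boundaries_assign_lower_bin(self, angle, expected):
        assert bin_confidence(angle) == expected

    @pytest.mark.parametrize("angle", [90.0, 60.0, 120.0, 270.0, 250.0])
    def test_gap_angles_rejected(self, angle):
        with pytest.raises(RejectedResponseError):
            bin_confidence(angle)


def _trials_with_rates(hits, n_old, fas, n_new, participant=0):
    rows = []
    for status, pos, n in (("old", hits, n_old), ("new", fas, n_new)):
        rows += [{"participant": participant, "probe_status": status,
                  "old_response": i < pos} for i in range(n)]
    return pd.DataFrame(rows)


class TestComputeRates:
    def test_printed_capacity_value(self):
        # H = 0.72, FA = 0.13 at set size 6 -> K = 6 * 0.59 = 3.54
        trials = _trials_with_rates(72, 100, 13, 100)
        out = compute_rates(trials, set_size=6)
        assert out.loc[0, "hit_rate"] == 0.72
        assert out.loc[0, "fa_rate"] == 0.13
        assert out.loc[0, "K"] == pytest.approx(3.54, abs=1e-12)

    def test_equal_rates_give_zero_capacity(self):
        out = compute_rates(_trials_with_rates(40, 100, 40, 100), set_size=6)
        assert out.loc[0, "K"] == 0.0

    def test_perfect_observer_reaches_set_size(self):
        out = compute_rates(_trials_with_rates(50, 50, 0, 50), set_size=5)
        assert out.loc[0, "K"] == 5.0

    def test_below_chance_capacity_not_truncated(self):
        out = compute_rates(_trials_with_rates(10, 100, 30, 100), set_size=5)
        assert out.loc[0, "K"] == pytest.approx(-1.0)

    def test_k_identity_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_old, n_new = rng.integers(3, 60, 2)
            h, fa = rng.integers(0, n_old + 1), rng.integers(0, n_new + 1)
            out = compute_rates(_trials_with_rates(h, n_old, fa, n_new), set_size=6)
            assert out.loc[0, "K"] == pytest.approx(
                6 * (out.loc[0, "hit_rate"] - out.loc[0, "fa_rate"]), abs=1e-12
            )

    def test_empty_cell_raises(self):
        trials = pd.DataFrame(
            {"participant": [0, 0], "probe_status": ["old", "old"], "old_response": [1, 0]}
        )
        with pytest.raises(ValueError, match="lacks old or new"):
            compute_rates(trials, set_size=6)


class TestROC:
    def test_hand_cumulated_points(self):
        # old counts listed bin 6 -> 1
        old_by_bin6_first = [40, 20, 10, 10, 10, 30]
        old = np.array(old_by_bin6_first[::-1])
        new = np.array([20] * 6)
        curve = roc_from_counts(old, new)
        np.testing.assert_allclose(curve.hr, [1 / 3, 1 / 2, 7 / 12, 2 / 3, 3 / 4])
        np.testing.assert_allclose(curve.far, [1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6])

    def test_all_top_bin_saturates(self):
        curve = roc_from_counts([0, 0, 0, 0, 0, 30], [0, 0, 0, 0, 0, 10])
        np.testing.assert_allclose(curve.hr, 1.0)
        np.testing.assert_allclose(curve.far, 1.0)

    def test_identical_counts_lie_on_diagonal(self):
        counts = [5, 8, 2, 9, 4, 7]
        curve = roc_from_counts(counts, counts)
        np.testing.assert_allclose(curve.hr, curve.far)

    def test_monotone_on_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            curve = roc_from_counts(rng.integers(0, 20, 6) + 1, rng.integers(0, 20, 6) + 1)
            assert np.all(np.diff(curve.hr) >= 0) and np.all(np.diff(curve.far) >= 0)

    def test_zero_class_raises(self):
        with pytest.raises(ValueError):
            roc_from_counts([0] * 6, [1] * 6)

    def test_build_roc_groups_by_participant_condition(self):
        rng = np.random.default_rng(2)
        rows = []
        for pid in (0, 1):
            for cond in ("A", "B"):
                for status in ("old", "new"):
                    for _ in range(30):
                        rows.append({"participant": pid, "condition": cond,
                                     "probe_status": status,
                                     "response": rng.integers(1, 7)})
        curves = build_roc(pd.DataFrame(rows))
        assert set(curves) == {(0, "A"), (0, "B"), (1, "A"), (1, "B")}
        assert curves[(0, "A")].counts.sum() == 60


# --------------------------------------------------------------------------- #
# brute-force sums-of-squares oracles

def _oneway_rm_oracle(table):
    """table: subjects x levels."""
    n_s, n_a = table.shape
    grand = table.mean()
    ss_a = n_s * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((table - table.mean(0) - table.mean(1)[:, None] + grand) ** 2).sum()
    df_a, df_e = n_a - 1, (n_a - 1) * (n_s - 1)
    f = (ss_a / df_a) / (ss_err / df_e)
    p = stats.f.sf(f, df_a, df_e)
    return f, df_a, df_e, p, ss_a / (ss_a + ss_err)


def _twoway_rm_oracle(cube):
    """cube: subjects x A levels x B levels; returns dict per effect."""
    n_s, n_a, n_b = cube.shape
    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)
    out = {}
    # main effect A against the A x subject interaction
    ss_a = n_s * n_b * ((m_a - grand) ** 2).sum()
    ss_as = n_b * ((m_sa - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
    out["A"] = (ss_a, n_a - 1, ss_as, (n_a - 1) * (n_s - 1))
    ss_b = n_s * n_a * ((m_b - grand) ** 2).sum()
    ss_bs = n_a * ((m_sb - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
    out["B"] = (ss_b, n_b - 1, ss_bs, (n_b - 1) * (n_s - 1))
    ss_ab = n_s * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (
        cube
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = (resid**2).sum()
    out["A * B"] = (ss_ab, (n_a - 1) * (n_b - 1), ss_abs, (n_a - 1) * (n_b - 1) * (n_s - 1))
    stats_out = {}
    for eff, (ss, df1, ss_e, df2) in out.items():
        f = (ss / df1) / (ss_e / df2)
        stats_out[eff] = (f, df1, df2, stats.f.sf(f, df1, df2), ss / (ss + ss_e))
    return stats_out


def _long(table, factor="cond"):
    n_s, n_a = table.shape
    rows = [
        {"participant": s, factor: f"L{a}", "y": table[s, a]}
        for s in range(n_s)
        for a in range(n_a)
    ]
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_identical_columns_give_zero_f(self):
        table = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova(_long(table), dv="y", within="cond", subject="participant")
        assert res.loc[0, "F"] == pytest.approx(0.0, abs=1e-12)

    def test_two_levels_equal_squared_paired_t(self):
        rng = np.random.default_rng(5)
        table = rng.normal(size=(6, 2))
        res = rm_anova(_long(table), dv="y", within="cond", subject="participant")
        t, _ = stats.ttest_rel(table[:, 0], table[:, 1])
        assert res.loc[0, "F"] == pytest.approx(t**2)

    def test_oneway_matches_ss_oracle(self):
        rng = np.random.default_rng(6)
        table = rng.normal(size=(5, 3)) + rng.normal(size=(5, 1))
        res = rm_anova(_long(table), dv="y", within="cond", subject="participant")
        f, df1, df2, p, np2 = _oneway_rm_oracle(table)
        assert res.loc[0, "F"] == pytest.approx(f, rel=1e-10)
        assert (res.loc[0, "df1"], res.loc[0, "df2"]) == (df1, df2)
        assert res.loc[0, "p"] == pytest.approx(p, rel=1e-10)
        assert res.loc[0, "np2"] == pytest.approx(np2, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_twoway_matches_ss_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cube = rng.normal(size=(6, 2, 3)) + rng.normal(size=(6, 1, 1))
        rows = [
            {"participant": s, "A": f"a{a}", "B": f"b{b}", "y": cube[s, a, b]}
            for s in range(6) for a in range(2) for b in range(3)
        ]
        res = rm_anova(pd.DataFrame(rows), dv="y", within=["A", "B"], subject="participant")
        oracle = _twoway_rm_oracle(cube)
        for eff, key in (("A", "A"), ("B", "B"), ("A * B", "A * B")):
            row = res[res["effect"] == eff].iloc[0]
            f, df1, df2, p, np2 = oracle[key]
            assert row["F"] == pytest.approx(f, rel=1e-10)
            assert (row["df1"], row["df2"]) == (df1, df2)
            assert row["p"] == pytest.approx(p, rel=1e-10)
            assert row["np2"] == pytest.approx(np2, rel=1e-8)

    def test_missing_cell_rejected(self):
        df = _long(np.zeros((4, 3))).drop(index=0)
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(df, dv="y", within="cond", subject="participant")


class TestPairwise:
    def test_identical_vectors_give_null_result(self):
        table = np.tile(np.arange(4.0)[:, None], (1, 2))
        res = pairwise_tests(_long(table), dv="y", within="cond", subject="participant")
        assert res.loc[0, "t"] == 0.0
        assert res.loc[0, "p_corr"] == 1.0
        assert res.loc[0, "cohen_d"] == 0.0

    def test_three_levels_bonferroni_capped(self):
        rng = np.random.default_rng(7)
        table = rng.normal(size=(8, 3))
        res = pairwise_tests(_long(table), dv="y", within="cond", subject="participant")
        assert len(res) == 3
        for _, row in res.iterrows():
            assert row["p_corr"] == min(1.0, row["p_unc"] * 3)

    def test_matches_direct_formula(self):
        a = np.array([3.1, 2.9, 3.4, 3.8, 2.5])
        b = np.array([2.7, 2.8, 3.0, 3.1, 2.2])
        table = np.stack([a, b], axis=1)
        res = pairwise_tests(_long(table), dv="y", within="cond", subject="participant")
        d = a - b
        t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.loc[0, "t"] == pytest.approx(t_direct)
        assert res.loc[0, "cohen_d"] == pytest.approx(t_direct / np.sqrt(len(d)))

    def test_constant_nonzero_difference_is_degenerate(self):
        table = np.stack([np.arange(4.0), np.arange(4.0) + 1.0], axis=1)
        with pytest.raises(DegenerateTestError):
            pairwise_tests(_long(table), dv="y", within="cond", subject="participant")
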