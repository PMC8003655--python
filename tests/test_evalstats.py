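"""Dice, volumes, Welch ANOVA / Games-Howell oracles, histograms, aggregation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from gliomaft.evalstats import (
    EvalRecord,
    aggregate,
    dice,
    games_howell,
    histogram_profile,
    pearson_r,
    read_records,
    tumor_volume_ml,
    welch_anova,
    write_records,
)
from gliomaft.phantoms import TumorParams, make_base_phantom
from gliomaft.volio import VoiMask, Volume4Ch, merge_voi, zscore_normalize


def mask_of(arr, spacing=(1.0, 1.0, 1.0)):
    return VoiMask(np.asarray(arr, dtype=np.uint8), spacing=spacing)


# --------------------------------------------------------------------- Dice


class TestDice:
    def test_identical_masks_score_one(self, rng):
        m = mask_of(rng.random((6, 6, 6)) < 0.4)
        assert dice(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((4, 4, 4)); a[0] = 1
        b = np.zeros((4, 4, 4)); b[2] = 1
        assert dice(mask_of(a), mask_of(b)) == 0.0

    def test_forced_value_four_six_three(self):
        a = np.zeros((10, 1, 1)); a[:4] = 1
        b = np.zeros((10, 1, 1)); b[1:7] = 1
        assert dice(mask_of(a), mask_of(b)) == pytest.approx(0.6)

    def test_both_empty_rejected(self):
        z = mask_of(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            dice(z, z)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(mask_of(np.ones((3, 3, 3))), mask_of(np.ones((4, 3, 3))))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_property(self, seed):
        g = np.random.default_rng(seed)
        a, b = mask_of(g.random((5, 5, 5)) < 0.5), mask_of(g.random((5, 5, 5)) < 0.5)
        if a.voxel_count + b.voxel_count == 0:
            return
        assert dice(a, b) == dice(b, a)
        assert 0.0 <= dice(a, b) <= 1.0


class TestTumorVolume:
    def test_empty_mask_zero(self):
        assert tumor_volume_ml(mask_of(np.zeros((5, 5, 5)))) == 0.0

    def test_thousand_unit_voxels_is_one_ml(self):
        arr = np.zeros((10, 10, 10)); arr.ravel()[:1000] = 1
        assert tumor_volume_ml(mask_of(arr)) == pytest.approx(1.0)

    def test_anisotropic_spacing_counting_oracle(self, rng):
        arr = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        m = mask_of(arr, spacing=(1.0, 1.0, 5.0))
        assert tumor_volume_ml(m) == pytest.approx(arr.sum() * 5.0 / 1000.0)


# --------------------------------------------------------------- Welch ANOVA


def welch_anova_direct(groups):
    """Independent direct evaluation of the Welch formulas."""
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    w = n / v
    mw = (w * m).sum() / w.sum()
    f_num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    tmp = ((1 - w / w.sum()) ** 2 / (n - 1)).sum() / (k**2 - 1)
    f = f_num / (1 + 2 * (k - 2) * tmp)
    df2 = 1.0 / (3 * tmp)
    p = sps.f.sf(f, k - 1, df2)
    return f, k - 1.0, df2, p


class TestWelchAnova:
    def test_two_groups_equal_welch_t_test(self):
        for seed in range(20):
            g = np.random.default_rng(seed)
            a = g.normal(0, 1, g.integers(5, 15))
            b = g.normal(0.5, 2, g.integers(5, 15))
            f, df1, df2, p = welch_anova([a, b])
            t = sps.ttest_ind(a, b, equal_var=False)
            assert f == pytest.approx(t.statistic**2, abs=1e-8, rel=1e-8)
            assert p == pytest.approx(t.pvalue, abs=1e-8)

    def test_identical_groups_give_f_zero_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        f, _, _, p = welch_anova([g, g, g])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_fixed_arrays_match_direct_formula(self):
        groups = [[1, 2, 3, 4], [2, 3, 4, 5], [5, 6, 7, 9]]
        f, df1, df2, p = welch_anova(groups)
        fe, df1e, df2e, pe = welch_anova_direct(groups)
        assert f == pytest.approx(fe, rel=1e-10)
        assert df1 == df1e
        assert df2 == pytest.approx(df2e, rel=1e-10)
        assert p == pytest.approx(pe, rel=1e-10)

    def test_equal_variance_two_groups_reduce_to_classical_f(self):
        # with equal sample variances and sizes the Welch statistic
        # coincides with the classical pooled-variance F (two groups;
        # for k > 2 Welch's denominator correction keeps them apart)
        groups = [[1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]]
        f, *_ = welch_anova(groups)
        classical = sps.f_oneway(*groups)
        assert f == pytest.approx(classical.statistic, abs=1e-6)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="fewer"):
            welch_anova([[1.0], [1.0, 2.0, 3.0]])


def games_howell_direct(groups):
    """Independent direct evaluation of the Games-Howell formulas."""
    k = len(groups)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = np.asarray(groups[i], float), np.asarray(groups[j], float)
            na, nb = len(a), len(b)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            se2 = va / na + vb / nb
            t = (a.mean() - b.mean()) / np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            q = np.abs(t) * np.sqrt(2.0)
            p = sps.studentized_range.sf(q, k, df)
            out[(i, j)] = (a.mean() - b.mean(), p)
    return out


class TestGamesHowell:
    def test_two_identical_groups_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        table = games_howell([g, list(g)])
        assert table["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert table["mean_diff"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_pair_count_combinatorics(self, rng):
        groups = [rng.normal(i, 1, 6) for i in range(4)]
        assert len(games_howell(groups)) == 4 * 3 // 2

    def test_fixed_groups_match_direct_formula(self):
        groups = [[1, 2, 3, 4], [2, 3, 4, 5], [5, 6, 7, 9]]
        table = games_howell(groups, labels=["g0", "g1", "g2"])
        direct = games_howell_direct(groups)
        for row in table.itertuples():
            i, j = int(row.group_a[1]), int(row.group_b[1])
            diff, p = direct[(i, j)]
            assert row.mean_diff == pytest.approx(diff, rel=1e-10)
            assert row.p_adj == pytest.approx(p, rel=1e-6, abs=1e-10)

    @settings(derandomize=True, max_examples=15)
    @given(st.integers(0, 2**32 - 1))
    def test_adjusted_p_at_least_pairwise_welch_p(self, seed):
        g = np.random.default_rng(seed)
        groups = [g.normal(g.normal(), 1 + g.random(), int(g.integers(4, 9)))
                  for _ in range(3)]
        table = games_howell(groups, labels=["0", "1", "2"])
        for row in table.itertuples():
            a = groups[int(row.group_a)]
            b = groups[int(row.group_b)]
            welch_p = sps.ttest_ind(a, b, equal_var=False).pvalue
            assert row.p_adj >= welch_p - 1e-12

    def test_dict_input_keeps_labels(self):
        table = games_howell({"x": [1.0, 2, 3], "y": [4.0, 5, 7]})
        assert set(table["group_a"]) | set(table["group_b"]) == {"x", "y"}


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_fixed_vectors_match_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        expect = np.cov(x, y, ddof=0)[0, 1] / (x.std() * y.std())
        assert pearson_r(x, y) == pytest.approx(expect, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def normalized_case():
    case = make_base_phantom(
        (24, 24, 24),
        TumorParams(center=(11.5, 11.5, 11.5), radii=(4.0,) * 3, rim_width=1.5),
        seed=1,
    )
    vol = zscore_normalize(case.volume)
    voi = merge_voi(case.labels)
    return vol, voi


class TestHistogramProfile:
    def test_counts_conserve_support(self, normalized_case):
        vol, voi = normalized_case
        prof = histogram_profile(vol, voi, channel=1)
        sup = np.any(vol.data != 0, axis=0)
        assert prof.channel_counts.sum(axis=1).tolist() == [int(sup.sum())] * 4

    def test_full_support_voi_fraction_one(self, normalized_case):
        vol, _ = normalized_case
        sup = np.any(vol.data != 0, axis=0)
        prof = histogram_profile(vol, VoiMask(sup.astype(np.uint8)), channel=1)
        assert prof.voi_fraction == pytest.approx(1.0)

    def test_bright_tumor_voi_median_above_support_median(self, normalized_case):
        # the T2-hyperintense lesion should sit on the right of the histogram
        vol, voi = normalized_case
        prof = histogram_profile(vol, voi, channel=1)
        sup = np.any(vol.data != 0, axis=0)
        assert prof.voi_defined
        assert prof.voi_median_z > np.median(vol.data[1][sup])

    def test_empty_voi_flagged(self, normalized_case):
        vol, _ = normalized_case
        prof = histogram_profile(vol, VoiMask(np.zeros(vol.shape, np.uint8)), channel=1)
        assert not prof.voi_defined
        assert prof.voi_fraction == 0.0
        assert np.isnan(prof.voi_median_z)


class TestAggregateAndRecords:
    def records(self):
        return [
            EvalRecord("c1", "A", "source", 0.8, 10.0, "gbm"),
            EvalRecord("c2", "A", "source", 0.6, 20.0, "astro"),
            EvalRecord("c1", "A", "target", 0.9, 10.0, "gbm"),
        ]

    def test_single_record_sd_zero(self):
        table = aggregate([self.records()[0]], by="model_type")
        assert table.iloc[0]["sd_dice"] == 0.0 and table.iloc[0]["n"] == 1

    def test_hand_checked_group_means(self):
        table = aggregate(self.records(), by="model_type").set_index("model_type")
        assert table.loc["source", "mean_dice"] == pytest.approx(0.7)
        assert table.loc["source", "sd_dice"] == pytest.approx(np.std([0.8, 0.6], ddof=1))
        assert table.loc["target", "mean_dice"] == pytest.approx(0.9)

    def test_counts_conserved(self):
        table = aggregate(self.records(), by="metadata_label")
        assert table["n"].sum() == 3

    def test_invalid_group_key_rejected(self):
        with pytest.raises(ValueError):
            aggregate(self.records(), by="dice")

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "records.csv"
        write_records(self.records(), path)
        back = read_records(path)
        assert back == self.records()

    def test_record_validation(self):
        with pytest.raises(ValueError):
            EvalRecord("c", "A", "source", 1.2, 0.0)
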