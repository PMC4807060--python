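"""Tests for the gait symmetry pipeline: reader, preprocessing, features,
tolerance selection and the rank statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xfuzzen import (
    EntropyParams,
    GaitRecord,
    asi,
    mann_whitney_u,
    min_max_normalize,
    read_gait_file,
    remove_outliers,
    remove_outliers_paired,
    select_r,
    symmetry_features,
)
from xfuzzen.gait import default_gait_r_grid
from xfuzzen.simulate import synthetic_cohort

from _reference import exact_mannwhitney_p


class TestReader:
    def test_three_column_roundtrip(self, tmp_path):
        rows = np.column_stack(
            [np.arange(10.0), np.linspace(1.0, 1.1, 10), np.linspace(1.2, 1.3, 10)]
        )
        f = tmp_path / "subj.txt"
        np.savetxt(f, rows, fmt="%.6f")
        rec = read_gait_file(f)
        assert rec.n_strides == 10
        np.testing.assert_allclose(rec.left_stride, rows[:, 1], atol=1e-6)
        np.testing.assert_allclose(rec.right_stride, rows[:, 2], atol=1e-6)

    def test_trailing_nan_trimmed_to_common_length(self, tmp_path):
        f = tmp_path / "subj.csv"
        f.write_text("t,left,right\n0,1.0,1.1\n1,1.2,1.3\n2,1.1,\n")
        rec = read_gait_file(f, column_map={"left": "left", "right": "right"})
        assert rec.n_strides == 2

    def test_missing_column_named_in_error(self, tmp_path):
        f = tmp_path / "subj.csv"
        f.write_text("a,b\n1,2\n3,4\n")
        with pytest.raises(ValueError, match="nope"):
            read_gait_file(f, column_map={"left": "nope", "right": "b"})
        with pytest.raises(ValueError, match="out of range"):
            read_gait_file(f, column_map={"left": 5, "right": 1})

    def test_empty_file(self, tmp_path):
        f = tmp_path / "empty.txt"
        f.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_gait_file(f)


class TestOutlierRemoval:
    def test_clean_series_untouched(self, rng):
        series = rng.normal(1.1, 0.01, 100)  # nothing near 3 SD of the median
        series = np.clip(series, 1.07, 1.13)
        kept, removed = remove_outliers(series)
        assert removed.size == 0
        np.testing.assert_array_equal(kept, series)

    def test_injected_turnarounds_removed_exactly(self, rng):
        clean = rng.normal(1.1, 0.05, 200)
        clean = np.clip(clean, 1.1 - 3 * 0.05, 1.1 + 3 * 0.05)
        series = clean.copy()
        idx = [10, 50, 99, 150, 180]
        series[idx] = 4.0
        kept, removed = remove_outliers(series)
        assert sorted(removed.tolist()) == idx
        assert kept.size == 195

    def test_constant_series_plus_spike(self):
        series = np.full(30, 1.1)
        series[7] = 5.0
        kept, removed = remove_outliers(series)
        assert removed.tolist() == [7]
        np.testing.assert_array_equal(kept, np.full(29, 1.1))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            remove_outliers(np.ones(5))

    def test_paired_removal_preserves_alignment(self, rng):
        left = rng.normal(1.1, 0.02, 100)
        right = left + rng.normal(0, 0.005, 100)
        left[10] = 4.0   # left-only outlier
        right[20] = 4.0  # right-only outlier
        l2, r2, removed = remove_outliers_paired(left, right)
        assert sorted(removed.tolist()) == [10, 20]
        assert l2.size == r2.size == 98
        # pairing preserved: the same positions were dropped on both sides
        keep = np.setdiff1d(np.arange(100), [10, 20])
        np.testing.assert_array_equal(l2, left[keep])
        np.testing.assert_array_equal(r2, right[keep])


class TestAsiAndFeatures:
    def test_asi_worked_example(self):
        assert asi(1.0, 1.2) == pytest.approx(100 * 0.2 / 1.1)

    @given(
        tl=st.floats(0.5, 2.0),
        tr=st.floats(0.5, 2.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_asi_antisymmetry_and_scale_invariance(self, tl, tr, scale):
        assert asi(tl, tr) == pytest.approx(-asi(tr, tl), abs=1e-9)
        assert asi(scale * tl, scale * tr) == pytest.approx(asi(tl, tr), rel=1e-9)

    def test_identical_limbs_give_zero_asi_and_self_entropy(self, rng):
        series = np.clip(rng.normal(1.1, 0.02, 160), 1.05, 1.16)
        rec = GaitRecord("s1", "CO", series, series.copy())
        feats = symmetry_features(rec, EntropyParams(m=1, r=0.004), N_use=150)
        assert feats.asi == pytest.approx(0.0, abs=1e-12)
        assert feats.T_L == pytest.approx(feats.T_R)
        # cross entropy of a series with itself == its self-(fuzzy)entropy
        from xfuzzen import TimeSeriesPair, cross_fuzzy_entropy

        self_val = cross_fuzzy_entropy(
            TimeSeriesPair(series[:150], series[:150]), EntropyParams(m=1, r=0.004)
        ).value
        assert feats.cfuzzyen == pytest.approx(self_val)

    def test_too_few_strides_names_subject(self, rng):
        series = np.clip(rng.normal(1.1, 0.02, 60), 1.05, 1.16)
        rec = GaitRecord("shorty", "PD", series, series.copy())
        with pytest.raises(ValueError, match="shorty"):
            symmetry_features(rec, N_use=150)


class TestMannWhitney:
    def test_exact_separated_groups(self):
        U, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)  # enumeration over C(6,3) assignments
        assert p == pytest.approx(exact_mannwhitney_p([1, 2, 3], [4, 5, 6]))

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_agrees_with_enumeration_on_random_groups(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, 5).tolist()
            b = rng.normal(0.5, 1, 6).tolist()
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(exact_mannwhitney_p(a, b), abs=1e-9)

    def test_rank_invariance_under_monotone_transform(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        _, p1 = mann_whitney_u(a, b)
        _, p2 = mann_whitney_u(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestMinMaxNormalize:
    def test_example(self):
        np.testing.assert_allclose(min_max_normalize([2, 4, 6]), [0, 0.5, 1])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30, unique=True))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_range_and_order_preserved(self, values):
        out = min_max_normalize(values)
        assert out.min() == 0.0 and out.max() == 1.0
        # weakly order-preserving (distinct inputs may collapse in float)
        assert np.all(np.diff(out[np.argsort(values)]) >= 0)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="zero range"):
            min_max_normalize([3.0, 3.0, 3.0])


class TestSelectR:
    def test_degenerate_grid_returns_that_r(self):
        records = synthetic_cohort(seed=1)
        best_r, table = select_r(records, r_grid=np.array([0.004]))
        assert best_r == 0.004
        assert len(table) == 1

    def test_default_grid_is_the_fine_screen(self):
        grid = default_gait_r_grid()
        assert grid.size == 19
        assert grid[0] == pytest.approx(1e-4)
        assert grid[-1] == pytest.approx(0.01)
        assert default_gait_r_grid(include_coarse_tail=True).size == 28

    def test_separated_groups_reach_significance(self):
        records = synthetic_cohort(seed=2)
        best_r, table = select_r(records)
        assert table.p_value.min() < 0.01
        assert best_r in set(table.r)

    def test_null_cohort_usually_insignificant(self):
        # both groups from the same generator: the minimum p over the grid
        # should not be spuriously tiny in most replicates
        hits = 0
        for seed in range(5):
            records = synthetic_cohort(
                seed=100 + seed, pd_coupling=0.9, co_coupling=0.9,
                pd_noise_sd=0.03, co_noise_sd=0.03,
            )
            _, table = select_r(records)
            if table.p_value.min() < 0.001:
                hits += 1
        assert hits <= 1

    def test_single_group_rejected(self):
        records = [r for r in synthetic_cohort(seed=3) if r.group == "PD"]
        with pytest.raises(ValueError, match="two groups"):
            select_r(records)


def test_feature_pipeline_deterministic():
    from xfuzzen import feature_table

    records = synthetic_cohort(seed=4)
    a = feature_table(records)
    b = feature_table(records)
    assert a.equals(b)


def test_group_direction_recovered_across_seeds():
    """PD-like pairs carry higher C-FuzzyEn than control-like pairs, and the
    tolerance screen finds a significant separation, in >= 9/10 cohorts."""
    from xfuzzen import feature_table

    direction_ok = 0
    signif_ok = 0
    for seed in range(10):
        records = synthetic_cohort(seed=seed)
        table = feature_table(records)
        mean_pd = table[table.group == "PD"].cfuzzyen.mean()
        mean_co = table[table.group == "CO"].cfuzzyen.mean()
        if mean_pd > mean_co:
            direction_ok += 1
        _, screen = select_r(records)
        if screen.p_value.min() < 0.05:
            signif_ok += 1
    assert direction_ok >= 9
    assert signif_ok >= 9
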