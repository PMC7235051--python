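"""Circumplex projection identities, depression scoring, and two-way
imputation closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadconflict.scoring import (
    DEFAULT_ITEM_OCTANT_MAP,
    OCTANT_ANGLES_DEG,
    NormTable,
    OctantProfile,
    dimensional_scores,
    fit_imputation_model,
    imputation_stability,
    score_depression,
    score_octants,
    score_parents,
    standardize_octants,
    twoway_impute,
)

ANGLES = np.deg2rad(np.asarray(OCTANT_ANGLES_DEG))


class TestOctantScoring:
    def test_constant_items_give_constant_octants(self):
        prof = score_octants(np.full(32, 2.0))
        np.testing.assert_array_equal(prof.octant_scores, np.full(8, 2.0))

    def test_single_octant_block(self):
        items = np.zeros(32)
        items[:4] = 4.0  # PA block under the default map
        prof = score_octants(items)
        np.testing.assert_array_equal(prof.octant_scores, [4, 0, 0, 0, 0, 0, 0, 0])

    def test_octant_mean_is_arithmetic(self):
        items = np.zeros(32)
        items[4:8] = [0, 1, 2, 3]  # BC block
        assert score_octants(items).octant_scores[1] == 1.5

    def test_missing_items_rejected(self):
        items = np.full(32, 1.0)
        items[0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            score_octants(items)

    def test_malformed_map_rejected(self):
        bad = dict(DEFAULT_ITEM_OCTANT_MAP)
        bad[0] = "LM"  # now LM has 5 items, PA has 3
        with pytest.raises(ValueError, match="4 items"):
            score_octants(np.zeros(32), bad)


class TestStandardization:
    def test_raw_at_norm_mean_is_zero(self):
        norms = NormTable(np.linspace(1, 2, 8), np.full(8, 0.5))
        z = standardize_octants(OctantProfile(np.linspace(1, 2, 8)), norms)
        np.testing.assert_allclose(z.octant_scores, 0.0)

    def test_one_sd_above_is_one(self):
        norms = NormTable(np.full(8, 1.0), np.full(8, 0.4))
        z = standardize_octants(OctantProfile(np.full(8, 1.4)), norms)
        np.testing.assert_allclose(z.octant_scores, 1.0)

    def test_z_arithmetic(self):
        norms = NormTable(np.full(8, 1.5), np.full(8, 0.75))
        prof = np.full(8, 1.5)
        prof[0] = 3.0
        z = standardize_octants(OctantProfile(prof), norms)
        assert z.octant_scores[0] == pytest.approx(2.0)

    def test_nonpositive_norm_sd_rejected(self):
        with pytest.raises(ValueError):
            NormTable(np.zeros(8), np.zeros(8))


class TestDimensionalScores:
    def test_constant_profile_is_pure_elevation(self):
        dims = dimensional_scores(OctantProfile(np.full(8, 1.7)))
        assert dims.agency == pytest.approx(0.0, abs=1e-12)
        assert dims.communion == pytest.approx(0.0, abs=1e-12)
        assert dims.elevation == pytest.approx(1.7)

    def test_sine_profile_scores_unit_agency(self):
        dims = dimensional_scores(OctantProfile(np.sin(ANGLES)))
        assert dims.agency == pytest.approx(1.0, abs=1e-12)
        assert dims.communion == pytest.approx(0.0, abs=1e-12)
        assert dims.elevation == pytest.approx(0.0, abs=1e-12)

    def test_cosine_profile_scores_unit_communion(self):
        dims = dimensional_scores(OctantProfile(np.cos(ANGLES)))
        assert dims.communion == pytest.approx(1.0, abs=1e-12)
        assert dims.agency == pytest.approx(0.0, abs=1e-12)

    def test_rotation_identity_on_grid(self):
        # z_i = A cos(angle_i - delta) -> agency = A sin(delta), communion = A cos(delta)
        for amp in np.linspace(0.5, 3.0, 10):
            for delta in np.linspace(0, 2 * np.pi, 10, endpoint=False):
                dims = dimensional_scores(OctantProfile(amp * np.cos(ANGLES - delta)))
                assert abs(dims.agency - amp * np.sin(delta)) < 1e-10
                assert abs(dims.communion - amp * np.cos(delta)) < 1e-10

    @given(st.floats(-3, 3), st.lists(st.floats(-2, 2), min_size=8, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_shift_moves_only_elevation(self, c, z):
        base = dimensional_scores(OctantProfile(np.asarray(z)))
        shifted = dimensional_scores(OctantProfile(np.asarray(z) + c))
        assert shifted.agency == pytest.approx(base.agency, abs=1e-9)
        assert shifted.communion == pytest.approx(base.communion, abs=1e-9)
        assert shifted.elevation == pytest.approx(base.elevation + c, abs=1e-9)


class TestDepression:
    @pytest.mark.parametrize(
        "items, expected",
        [
            (np.full(17, 1.0), 1.0),
            (np.full(17, 5.0), 5.0),
            (np.r_[np.full(9, 1.0), np.full(8, 3.0)], 33 / 17),
        ],
    )
    def test_mean_item_score(self, items, expected):
        assert score_depression(items) == pytest.approx(expected)

    def test_missing_rejected(self):
        items = np.full(17, 2.0)
        items[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            score_depression(items)


class TestTwowayImputation:
    def test_hand_worked_example(self):
        m = np.array([[1.0, 2.0], [3.0, np.nan]])
        out = twoway_impute(m)
        # PM_2 = 3, IM_2 = 2, OM = 2 -> 3 + 2 - 2 = 3
        assert out[1, 1] == pytest.approx(3.0)

    def test_constant_matrix_imputes_constant(self):
        m = np.full((5, 6), 2.0)
        m[1, 2] = m[4, 0] = np.nan
        out = twoway_impute(m)
        np.testing.assert_allclose(out, 2.0)

    def test_additive_matrix_reconstructed_exactly(self):
        # additive r_i + c_j with the deleted cell's row/column effects equal
        # to the mean of the remaining ones: the single-pass two-way fit is
        # exact there (it is not for arbitrary additive cells, whose row and
        # item means shift when the cell is removed)
        r = np.array([0.0, 1.0, 2.0, 1.0])
        c = np.array([1.0, 2.0, 3.0, 2.0])
        m = r[:, None] + c[None, :]
        deleted = m.copy()
        deleted[3, 3] = np.nan
        out = twoway_impute(deleted)
        assert out[3, 3] == pytest.approx(m[3, 3], abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 5, (6, 8)).astype(float)
        m[rng.random((6, 8)) < 0.2] = np.nan
        if np.all(np.isnan(m).sum(axis=1) < 8) and np.all(np.isnan(m).sum(axis=0) < 6):
            out = twoway_impute(m)
            pr = rng.permutation(6)
            pc = rng.permutation(8)
            out_perm = twoway_impute(m[pr][:, pc])
            np.testing.assert_allclose(out_perm, out[pr][:, pc], atol=1e-12)

    def test_stochastic_mode_deterministic_under_seed(self):
        m = np.full((4, 5), 2.0) + np.arange(5)
        m[0, 1] = m[2, 3] = np.nan
        a = twoway_impute(m, stochastic=True, seed=42)
        b = twoway_impute(m, stochastic=True, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_round_to_scale_clips(self):
        m = np.array([[0.0, 4.0, 4.0], [4.0, 4.0, np.nan]])
        out = twoway_impute(m, round_to_scale=True, scale_points=range(5))
        assert out[1, 2] in set(range(5))

    def test_fully_missing_row_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError):
            twoway_impute(m)


class TestImputationStability:
    def test_no_missing_rows_have_zero_sd(self):
        rng = np.random.default_rng(1)
        m = rng.integers(1, 6, (6, 17)).astype(float)
        m[0, 3] = np.nan
        sds = imputation_stability(m, np.mean, n_imputations=20, seed=2)
        assert sds[0] > 0
        np.testing.assert_array_equal(sds[1:], 0.0)

    def test_zero_residual_gives_zero_sd(self):
        # centered additive cell: the two-way fit reproduces every observed
        # cell, so the stochastic noise scale is 0 and all scores are stable
        r = np.arange(5.0)
        c = np.arange(7.0)
        m = r[:, None] + c[None, :]
        m[2, 3] = np.nan  # r_2 = mean(other rows), c_3 = mean(other cols)
        assert fit_imputation_model(m).residual_sd == pytest.approx(0.0, abs=1e-12)
        sds = imputation_stability(m, np.mean, n_imputations=20, seed=3)
        np.testing.assert_allclose(sds, 0.0, atol=1e-12)

    def test_single_missing_item_error_propagation(self):
        rng = np.random.default_rng(5)
        m = np.clip(np.round(rng.normal(3, 1, (40, 17))), 1, 5)
        m[0, 0] = np.nan
        rsd = fit_imputation_model(m).residual_sd
        sds = imputation_stability(m, np.mean, n_imputations=400, seed=6)
        # the mean over 17 items inherits sigma_r / 17 from one noisy cell
        assert sds[0] == pytest.approx(rsd / 17, rel=0.2)

    def test_too_few_imputations_rejected(self):
        with pytest.raises(ValueError):
            imputation_stability(np.ones((2, 2)), np.mean, n_imputations=1)


def test_score_parents_flags_whole_scale_missingness(small_study, small_norms):
    ds, _ = small_study
    table = score_parents(ds, small_norms, seed=1)
    assert set(table.index) == {p.parent_id for p in ds.parents}
    for p in ds.parents:
        row = table.loc[p.parent_id]
        if np.all(np.isnan(p.scl_items)):
            assert row["scl_missing"] and np.isnan(row["depression"])
        else:
            assert np.isfinite(row["depression"])
        if np.all(np.isnan(p.iipc_items)):
            assert row["iipc_missing"] and np.isnan(row["agency"])
        else:
            assert np.isfinite(row["agency"])
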