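import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree

from driftknn.knn_drift import (
    CostParams,
    DriftModel,
    cost_landscape,
    drift_correct_knn,
    fit_inter,
    fit_intra,
    inter_cost,
    intra_cost,
    project_to_t0,
    thresholded_nnd_sum,
)
from driftknn.localization_io import LocalizationTable

from conftest import brute_force_nnd_sum, make_table


class TestThresholdedNNDSum:
    def test_close_pair_sums_both_distances(self):
        pts = np.array([[0.0, 0.0], [0.5, 0.0]])
        assert thresholded_nnd_sum(pts, pts, l=1.0, exclude_self=True) == pytest.approx(1.0)

    def test_far_pair_saturates_at_threshold(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0]])
        assert thresholded_nnd_sum(pts, pts, l=1.0, exclude_self=True) == pytest.approx(2.0)

    def test_single_point_self_mode_saturates(self):
        pts = np.array([[1.0, 1.0]])
        assert thresholded_nnd_sum(pts, pts, l=0.7, exclude_self=True) == pytest.approx(0.7)

    def test_empty_query_is_zero(self):
        empty = np.empty((0, 2))
        ref = np.array([[0.0, 0.0]])
        assert thresholded_nnd_sum(empty, ref, l=1.0) == 0.0

    def test_coincident_points_count_at_zero_distance(self):
        # self-exclusion is by identity, not by distance
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [3.0, 3.0]])
        got = thresholded_nnd_sum(pts, pts, l=0.5, exclude_self=True)
        assert got == pytest.approx(0.0 + 0.0 + 0.5)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(2, 60), st.sampled_from([2, 3]),
           st.booleans(), st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, n, ndim, self_mode, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 3, (n, ndim))
        ref = pts if self_mode else rng.uniform(0, 3, (n + 5, ndim))
        l = float(rng.uniform(0.1, 2.0))
        got = thresholded_nnd_sum(pts, pts if self_mode else ref, l,
                                  exclude_self=self_mode)
        expect = brute_force_nnd_sum(pts, ref, l, exclude_self=self_mode)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_reference_tree_reuse_is_equivalent(self, rng):
        ref = rng.uniform(0, 5, (80, 2))
        q = rng.uniform(0, 5, (40, 2))
        tree = cKDTree(ref)
        assert thresholded_nnd_sum(q, tree, 1.0) == pytest.approx(
            thresholded_nnd_sum(q, ref, 1.0))

    @settings(deadline=None, max_examples=15)
    @given(st.integers(1, 50), st.integers(0, 2**31 - 1))
    def test_cost_bounds(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (n, 2))
        l = float(rng.uniform(0.1, 3.0))
        c = thresholded_nnd_sum(pts, pts, l, exclude_self=True)
        assert 0.0 <= c <= n * l + 1e-12


class TestProjection:
    def test_zero_coeffs_identity(self, rng):
        pos = rng.uniform(0, 10, (20, 2))
        frames = rng.integers(0, 100, 20)
        np.testing.assert_array_equal(project_to_t0(pos, frames, np.zeros((2, 1))), pos)

    def test_linear_projection(self):
        pos = np.array([[10.0, 20.0]])
        out = project_to_t0(pos, np.array([100]), np.array([[0.003], [0.004]]))
        np.testing.assert_allclose(out, [[10.0 - 0.3, 20.0 - 0.4]])

    def test_quadratic_matches_polyval_oracle(self, rng):
        coeffs = rng.normal(0, 1e-3, (3, 2))  # 3D, degree 2
        pos = rng.uniform(0, 10, (50, 3))
        frames = rng.integers(0, 500, 50)
        out = project_to_t0(pos, frames, coeffs)
        for dim in range(3):
            # polyval with constant term 0: [a2, a1, 0]
            drift = np.polyval([coeffs[dim, 1], coeffs[dim, 0], 0.0], frames)
            np.testing.assert_allclose(out[:, dim], pos[:, dim] - drift, atol=1e-12)


def _duplicated_blink_data(rng, n_emitters=60, n_frames=200, rate=(0.003, 0.004),
                           blinks=3):
    """Noiseless emitters each blinking `blinks` times under exact linear drift."""
    emitters = rng.uniform(2, 8, (n_emitters, 2))
    frames = rng.integers(0, n_frames, (n_emitters, blinks))
    pos = np.repeat(emitters, blinks, axis=0)
    f = frames.ravel()
    pos = pos + f[:, None] * np.asarray(rate)
    return pos, f


class TestIntraCost:
    def test_zero_at_true_coefficients(self, rng):
        rate = np.array([0.003, 0.004])
        pos, f = _duplicated_blink_data(rng, rate=rate)
        assert intra_cost(pos, f, rate[:, None], 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_higher_at_zero_coefficients(self, rng):
        rate = np.array([0.003, 0.004])
        pos, f = _duplicated_blink_data(rng, rate=rate)
        c_true = intra_cost(pos, f, rate[:, None], 1.0)
        c_zero = intra_cost(pos, f, np.zeros((2, 1)), 1.0)
        assert c_zero > c_true

    def test_single_blink_emitters_saturate(self, rng):
        # isolated emitters far apart: every projected NN distance > l
        pos = np.arange(20, dtype=float)[:, None] * np.array([10.0, 10.0])
        f = np.zeros(20, int)
        assert intra_cost(pos, f, np.zeros((2, 1)), 1.0) == pytest.approx(20.0)


class TestFitIntra:
    def test_recovers_linear_rate(self, rng):
        rate = np.array([0.003, 0.004])
        pos, f = _duplicated_blink_data(rng, n_emitters=150, rate=rate)
        pos = pos + rng.normal(0, 0.05, pos.shape)  # 5 nm scatter at 100 nm px
        coeffs, diag = fit_intra(pos, f, degree=1, l_intra=1.0)
        np.testing.assert_allclose(coeffs[:, 0], rate, atol=5e-4)
        assert diag.final_cost <= diag.initial_cost

    def test_zero_drift_gives_near_zero_coeffs(self, rng):
        pos, f = _duplicated_blink_data(rng, rate=(0.0, 0.0))
        pos = pos + rng.normal(0, 0.05, pos.shape)
        coeffs, _ = fit_intra(pos, f, degree=1, l_intra=1.0)
        assert np.all(np.abs(coeffs) <= 1e-3)

    def test_quadratic_fit_beats_true_coefficients(self, rng):
        true = np.array([[2e-3, -5e-6], [1e-3, 3e-6]])  # (ndim, degree 2)
        emitters = rng.uniform(2, 8, (80, 2))
        f = rng.integers(0, 200, 240)
        pos = np.repeat(emitters, 3, axis=0)
        drift = (true[None, :, 0] * f[:, None] + true[None, :, 1] * f[:, None] ** 2)
        pos = pos + drift + rng.normal(0, 0.03, pos.shape)
        coeffs, diag = fit_intra(pos, f, degree=2, l_intra=1.0)
        c_fit = intra_cost(pos, f, coeffs, 1.0)
        c_true = intra_cost(pos, f, true, 1.0)
        assert c_fit <= c_true + 1e-6

    def test_degenerate_dataset_returns_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            coeffs, diag = fit_intra(np.array([[1.0, 1.0]]), np.array([0]), 1, 1.0)
        assert np.all(coeffs == 0.0) and diag.converged


class TestInterCost:
    def test_displaced_copy_zero_at_negative_displacement(self, rng):
        ref = rng.uniform(0, 10, (100, 2))
        s = np.array([0.8, -0.5])
        tree = cKDTree(ref)
        assert inter_cost(tree, ref + s, -s, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_large_displacement_saturates(self, rng):
        ref = rng.uniform(0, 2, (30, 2))
        tree = cKDTree(ref)
        got = inter_cost(tree, ref + np.array([50.0, 0.0]), np.zeros(2), 2.0)
        assert got == pytest.approx(30 * 2.0)

    @settings(deadline=None, max_examples=15)
    @given(st.integers(1, 40), st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(0, 4, (n + 3, 3))
        tgt = rng.uniform(0, 4, (n, 3))
        shift = rng.normal(0, 0.5, 3)
        got = inter_cost(cKDTree(ref), tgt, shift, 2.0)
        expect = brute_force_nnd_sum(tgt + shift, ref, 2.0)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_empty_target_is_zero(self, rng):
        tree = cKDTree(rng.uniform(0, 1, (5, 2)))
        assert inter_cost(tree, np.empty((0, 2)), np.zeros(2), 2.0) == 0.0


class TestFitInter:
    def test_recovers_displacement(self, rng):
        ref = rng.uniform(0, 20, (300, 2))
        s = np.array([0.6, -0.9])
        shift, diag = fit_inter(cKDTree(ref), ref + s, np.zeros(2), 2.0)
        np.testing.assert_allclose(shift, -s, atol=1e-3)
        assert diag.final_cost <= diag.initial_cost

    def test_identical_sets_give_zero_shift(self, rng):
        ref = rng.uniform(0, 20, (200, 2))
        shift, _ = fit_inter(cKDTree(ref), ref.copy(), np.zeros(2), 2.0)
        np.testing.assert_allclose(shift, 0.0, atol=1e-6)

    def test_outlier_beyond_threshold_contributes_exactly_l(self, rng):
        ref = rng.uniform(0, 5, (5, 2))
        outlier = np.array([[100.0, 100.0]])
        target = np.vstack([ref, outlier])
        shift, diag = fit_inter(cKDTree(ref), target, np.zeros(2), 2.0)
        np.testing.assert_allclose(shift, 0.0, atol=1e-3)
        assert diag.final_cost == pytest.approx(2.0, abs=1e-3)


def _multi_dataset_table(rng, n_datasets=3, n_frames=300, rate_px=(0.002, 0.003),
                         shifts=None, n_emitters=120, sigma=0.05):
    """Emitters re-blinking across datasets; linear intra drift continues
    globally, producing known inter offsets when shifts is None."""
    emitters = rng.uniform(5, 45, (n_emitters, 2))
    rows_pos, rows_f, rows_d = [], [], []
    rate = np.asarray(rate_px)
    for d in range(n_datasets):
        k = rng.integers(2, 5, n_emitters)
        for i in range(n_emitters):
            f = rng.integers(0, n_frames, k[i])
            gf = d * n_frames + f
            p = emitters[i] + gf[:, None] * rate
            rows_pos.append(p)
            rows_f.append(f)
            rows_d.append(np.full(k[i], d))
    pos = np.vstack(rows_pos) + rng.normal(0, sigma, (sum(len(f) for f in rows_f), 2))
    return make_table(x=pos[:, 0], y=pos[:, 1],
                      frame=np.concatenate(rows_f),
                      dataset=np.concatenate(rows_d))


class TestDriftCorrectKNN:
    def test_zero_drift_correction_is_tiny(self, rng):
        # well-constrained data (many emitters, low scatter) so residual
        # corrections reflect fit noise, not statistical starvation
        t = _multi_dataset_table(rng, rate_px=(0.0, 0.0), n_emitters=400,
                                 sigma=0.02)
        corrected, model = drift_correct_knn(t)
        delta = np.abs(corrected.coords() - t.coords())
        assert delta.max() <= 0.02

    def test_recovers_continuous_drift_across_datasets(self, rng):
        rate = (0.002, 0.003)
        t = _multi_dataset_table(rng, rate_px=rate)
        corrected, model = drift_correct_knn(t, registration_used=False)
        # intra rates per dataset approximate the global rate
        np.testing.assert_allclose(model.intra_coeffs[:, 0, 0], rate[0], atol=4e-4)
        np.testing.assert_allclose(model.intra_coeffs[:, 1, 0], rate[1], atol=4e-4)
        # inter shifts approximate the accumulated drift at dataset starts
        for d in range(1, model.n_datasets):
            expect = np.array(rate) * d * 300
            np.testing.assert_allclose(model.inter_shift[d], expect, atol=0.05)

    def test_corrected_equals_observed_minus_model(self, rng):
        t = _multi_dataset_table(rng)
        corrected, model = drift_correct_knn(t)
        drift = model.drift_at(t.datasets(), t.frames())
        np.testing.assert_allclose(corrected.coords(), t.coords() - drift,
                                   atol=1e-9)

    def test_shift_equivariance(self, rng):
        t = _multi_dataset_table(rng, n_datasets=2)
        _, m1 = drift_correct_knn(t)
        shifted = t.with_coords(t.coords() + np.array([123.4, -56.7]))
        _, m2 = drift_correct_knn(shifted)
        np.testing.assert_allclose(m1.intra_coeffs, m2.intra_coeffs, atol=1e-6)
        np.testing.assert_allclose(m1.inter_shift, m2.inter_shift, atol=1e-4)

    def test_monotone_improvement_every_fit(self, rng):
        t = _multi_dataset_table(rng, n_datasets=3)
        _, model = drift_correct_knn(t)
        for d, diag in model.diagnostics["intra"].items():
            assert diag["final_cost"] <= diag["initial_cost"] + 1e-12
        for d, diag in model.diagnostics["inter"].items():
            assert diag["final_cost"] <= diag["initial_cost"] + 1e-12

    def test_resegmentation_override_round_trips_indices(self, rng):
        t = _multi_dataset_table(rng, n_datasets=2, n_frames=400)
        corrected, model = drift_correct_knn(
            t, frames_per_dataset_override=200, original_frames_per_dataset=400)
        np.testing.assert_array_equal(corrected.frames(), t.frames())
        np.testing.assert_array_equal(corrected.datasets(), t.datasets())
        assert model.n_datasets == 4

    def test_model_json_round_trip(self, rng, tmp_path):
        t = _multi_dataset_table(rng, n_datasets=2)
        _, model = drift_correct_knn(t)
        path = tmp_path / "model.json"
        model.to_json(path, pixel_size_nm=100.0)
        back = DriftModel.from_json(path)
        np.testing.assert_allclose(back.intra_coeffs, model.intra_coeffs)
        np.testing.assert_allclose(back.inter_shift, model.inter_shift)
        assert back.intra_degree == model.intra_degree


class TestCostLandscape:
    def test_bounds_hold_everywhere(self, rng):
        t = _multi_dataset_table(rng, n_datasets=1, n_emitters=40)
        axis = np.linspace(-0.004, 0.004, 9)
        ls = cost_landscape(t, "intra", [axis, axis])
        n = (t.datasets() == 0).sum()
        assert np.all(ls.cost >= 0) and np.all(ls.cost <= n * 1.0 + 1e-9)

    def test_inter_minimum_at_negative_displacement(self, rng):
        base = rng.uniform(0, 20, (200, 2))
        s = np.array([0.5, -0.25])
        t = make_table(x=np.concatenate([base[:, 0], base[:, 0] + s[0]]),
                       y=np.concatenate([base[:, 1], base[:, 1] + s[1]]),
                       frame=np.zeros(400, int),
                       dataset=np.repeat([0, 1], 200))
        axis = np.linspace(-1.0, 1.0, 17)  # grid step 0.125
        ls = cost_landscape(t, "inter", [axis, axis])
        np.testing.assert_allclose(ls.argmin(), -s, atol=0.125)

    def test_intra_minimum_matches_optimizer(self, rng):
        rate = np.array([0.002, -0.0015])
        pos, f = _duplicated_blink_data(rng, n_emitters=100, rate=rate)
        pos = pos + rng.normal(0, 0.03, pos.shape)
        t = make_table(x=pos[:, 0], y=pos[:, 1], frame=f,
                       dataset=np.zeros(len(f), int))
        coeffs, _ = fit_intra(pos, f, 1, 1.0)
        axis = np.linspace(-0.004, 0.004, 17)  # cell 5e-4
        ls = cost_landscape(t, "intra", [axis, axis])
        np.testing.assert_allclose(ls.argmin(), coeffs[:, 0], atol=5e-4)
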