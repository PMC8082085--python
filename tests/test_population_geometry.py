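"""Population matrix, PCA subspace, distance/velocity, neural weights."""

import copy

import numpy as np
import pytest
from scipy import stats

from nlot.population_geometry import (
    PopulationMatrix,
    build_population_matrix,
    compare_weights_by_type,
    neural_weights,
    pca_subspace,
    sliding_weights,
    trajectory_distance,
    trajectory_velocity,
)


def synthetic_matrix(data, bin_width=0.020, t0=-0.2):
    """Wrap a (units, bins, conds) array as a normalized matrix."""
    n_units, n_bins, n_cond = data.shape
    centers = t0 + bin_width * (np.arange(n_bins) + 0.5)
    return PopulationMatrix(
        data=data.astype(float),
        raw=data.astype(float),
        unit_ids=[f"u{i}" for i in range(n_units)],
        bin_centers=centers,
        conditions=("go", "no-go")[:n_cond] if n_cond <= 2
        else tuple(f"c{i}" for i in range(n_cond)),
        normalization="raw",
        norm_mean=np.zeros(n_units),
        norm_sd=np.ones(n_units),
        excluded_units=[],
    )


class TestBuildMatrix:
    def test_shape_and_zscore_round_trip(self, small_session):
        session, _ = small_session
        m = build_population_matrix(session)
        assert m.data.ndim == 3 and m.data.shape[2] == 2
        np.testing.assert_allclose(m.denormalize(), m.raw, atol=1e-9)

    def test_constant_unit_maps_to_zeros(self):
        data = np.random.default_rng(0).normal(size=(4, 30, 2))
        data[2] = 5.0  # constant-rate unit
        m = synthetic_matrix(data)
        # emulate the builder's z-scoring on raw values
        flat = m.raw.reshape(4, -1)
        sd = flat.std(axis=1)
        assert sd[2] == 0.0

    def test_units_lacking_trials_excluded(self, small_session):
        session, _ = small_session
        m = build_population_matrix(session, min_trials=10)
        assert m.n_units + len(m.excluded_units) == len(session.units)


class TestPCA:
    def test_loadings_orthonormal(self, small_session):
        session, _ = small_session
        m = build_population_matrix(session)
        sub = pca_subspace(m, k=3)
        gram = sub.loadings.T @ sub.loadings
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_planar_data_has_vanishing_third_component(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(8, 1, 1))
        v = rng.normal(size=(8, 1, 1))
        w = rng.normal(size=(8, 1, 1))
        t = np.linspace(0, 1, 40)[None, :, None]
        # full-rank data whose variance lies (almost) entirely in a plane
        data = u * np.sin(6 * t) + v * np.cos(6 * t) + 1e-7 * w * t**2
        data = np.concatenate([data, data[:, ::-1, :]], axis=2)
        sub = pca_subspace(synthetic_matrix(data), k=3)
        assert sub.explained_variance_ratio[2] < 1e-10

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(10, 10, 2))
        m = synthetic_matrix(data)
        sub = pca_subspace(m, k=3)
        samples = data.reshape(10, -1).T
        c = np.cov(samples, rowvar=False, bias=False)
        evals, evecs = np.linalg.eigh(c)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        ratio = evals / evals.sum()
        np.testing.assert_allclose(
            sub.explained_variance_ratio, ratio[:3], rtol=1e-8
        )
        for k in range(3):
            dot = abs(np.dot(sub.loadings[:, k], evecs[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_variance_ratios_sum_to_one_at_full_rank(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(5, 12, 2))
        sub = pca_subspace(synthetic_matrix(data), k=5)
        assert sub.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_k_beyond_rank_rejected(self):
        data = np.zeros((4, 10, 2))
        data[0, :, 0] = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            pca_subspace(synthetic_matrix(data), k=3)


class TestDistance:
    def test_identical_conditions_give_zero(self):
        rng = np.random.default_rng(4)
        one = rng.normal(size=(6, 40, 1))
        data = np.concatenate([one, one], axis=2)
        d = trajectory_distance(synthetic_matrix(data))
        np.testing.assert_allclose(d.values, 0.0)
        assert not d.significant.any()

    def test_single_unit_single_bin_difference(self):
        data = np.zeros((3, 40, 2))
        data[1, 25, 0] = 0.7
        d = trajectory_distance(synthetic_matrix(data))
        assert d.values[25] == pytest.approx(0.7)
        assert np.all(d.values[:25] == 0)

    def test_full_space_dominates_projection(self, small_session):
        session, _ = small_session
        m = build_population_matrix(session)
        sub = pca_subspace(m, k=2)
        full = trajectory_distance(m)
        proj = trajectory_distance(m, subspace=sub)
        assert np.all(full.values >= proj.values - 1e-9)

    def test_invariant_to_unit_reordering_and_rotation(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(8, 30, 2))
        m = synthetic_matrix(data)
        d0 = trajectory_distance(m).values
        perm = rng.permutation(8)
        d1 = trajectory_distance(synthetic_matrix(data[perm])).values
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        rotated = np.einsum("ij,jbc->ibc", q, data)
        d2 = trajectory_distance(synthetic_matrix(rotated)).values
        np.testing.assert_allclose(d0, d1, atol=1e-9)
        np.testing.assert_allclose(d0, d2, atol=1e-9)

    def test_too_few_baseline_bins_rejected(self):
        data = np.random.default_rng(0).normal(size=(3, 30, 2))
        with pytest.raises(ValueError, match="baseline"):
            trajectory_distance(synthetic_matrix(data, t0=0.0))


class TestVelocity:
    def test_constant_trajectory_zero_velocity(self):
        data = np.ones((5, 50, 2))
        v = trajectory_velocity(synthetic_matrix(data), "go")
        np.testing.assert_allclose(v.values, 0.0)

    def test_linear_ramp_gives_slope(self):
        data = np.zeros((4, 50, 2))
        t = np.arange(50) * 0.020
        data[2, :, 0] = 3.0 * t  # one unit ramps at 3 units/s
        v = trajectory_velocity(synthetic_matrix(data), "go")
        interior = v.values[2:-2]
        np.testing.assert_allclose(interior, 3.0, rtol=1e-6)

    def test_transient_produces_velocity_peak(self, small_session):
        session, _ = small_session
        m = build_population_matrix(session)
        v = trajectory_velocity(m, "go")
        t_peak = v.bin_centers[np.argmax(v.values)]
        assert 0.3 < t_peak < 0.65  # cue-evoked transient


class TestWeights:
    def test_absolute_loading_and_sign_invariance(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(6, 30, 2))
        sub = pca_subspace(synthetic_matrix(data), k=2)
        w = neural_weights(sub, dimension=1)
        assert np.all(w >= 0)
        np.testing.assert_allclose(w, np.abs(sub.loadings[:, 0]))

    def test_dominant_unit_gets_max_weight(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(8, 40, 2)) * 0.1
        data[3] += 10 * np.sin(np.linspace(0, 3, 40))[None, :, None].squeeze(0)
        sub = pca_subspace(synthetic_matrix(data), k=1)
        w = neural_weights(sub)
        assert np.argmax(w) == 3

    def test_sliding_weights_bounded_and_type_i_elevated(self, small_session):
        session, gt = small_session
        m = build_population_matrix(session)
        centers, w = sliding_weights(m)
        assert np.nanmax(w) <= 1.0 + 1e-9
        labels = np.array([gt.labels[u] for u in m.unit_ids])
        late = (centers >= 0.40) & (centers <= 0.55)
        if (labels == "I").sum() >= 3 and (labels == "V").sum() >= 3:
            w_i = np.nanmean(w[labels == "I"][:, late])
            w_v = np.nanmean(w[labels == "V"][:, late])
            assert w_i > w_v


class TestWeightComparison:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        w = np.concatenate([a, b])
        labels = ["I"] * 12 + ["V"] * 15
        res = compare_weights_by_type(w, labels)
        t, _ = stats.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-9)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(9)
        w = np.concatenate(
            [rng.normal(2.0, 1, 20), rng.normal(0, 1, 20), rng.normal(0, 1, 20)]
        )
        labels = ["I"] * 20 + ["III"] * 20 + ["V"] * 20
        res = compare_weights_by_type(w, labels)
        assert res.p_value < 0.001
        row = res.tukey[
            (res.tukey.group1 == "I") | (res.tukey.group2 == "I")
        ]
        assert row.reject.astype(bool).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_weights_by_type(np.ones(5), ["I"] * 5)
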