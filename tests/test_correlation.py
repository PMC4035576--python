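"""Cross-correlation matrix and essential-dynamics PCA."""

import numpy as np
import pytest

from mdpost.correlation import (
    cross_correlation_matrix,
    mode_displacement_profile,
    pca_decompose,
    pca_from_trajectory,
    positional_covariance,
    variance_fraction,
)
from mdpost.structure import Trajectory
from mdpost.synthetic import generate_gnm_ensemble, gnm_site_covariance

from .conftest import frozen_trajectory, make_ca_chain


def _two_site_trajectory(displacements_a, displacements_b):
    top = make_ca_chain(2)
    coords = np.repeat(top.coords[None], len(displacements_a), axis=0)
    coords[:, 0] += np.asarray(displacements_a)
    coords[:, 1] += np.asarray(displacements_b)
    return Trajectory(coords, 10.0, top)


class TestCrossCorrelation:
    def test_identical_motion_gives_plus_one(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal((50, 3))
        traj = _two_site_trajectory(d, d)
        m = cross_correlation_matrix(traj, superpose=False)
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_opposite_motion_gives_minus_one(self):
        rng = np.random.default_rng(1)
        d = rng.standard_normal((50, 3))
        traj = _two_site_trajectory(d, -d)
        m = cross_correlation_matrix(traj, superpose=False)
        assert m.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_sites_decorrelate_at_large_n(self):
        rng = np.random.default_rng(2)
        n = 100_000
        traj = _two_site_trajectory(
            rng.standard_normal((n, 3)), rng.standard_normal((n, 3))
        )
        m = cross_correlation_matrix(traj, superpose=False)
        assert abs(m.values[0, 1]) < 0.02  # ~ 1/sqrt(3n) sampling error

    def test_bounds_and_unit_diagonal(self, gnm_spec_20):
        traj = generate_gnm_ensemble(gnm_spec_20)
        m = cross_correlation_matrix(traj, superpose=False)
        assert np.all(m.values <= 1.0) and np.all(m.values >= -1.0)
        np.testing.assert_allclose(np.diag(m.values), 1.0, atol=1e-10)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)

    def test_zero_variance_atom_named_in_error(self):
        rng = np.random.default_rng(3)
        traj = _two_site_trajectory(np.zeros((20, 3)), rng.standard_normal((20, 3)))
        with pytest.raises(ValueError, match="A1:CA"):
            cross_correlation_matrix(traj, superpose=False)


class TestPositionalCovariance:
    def test_frozen_trajectory_gives_zero_matrix(self):
        traj = frozen_trajectory(make_ca_chain(5), 10)
        np.testing.assert_allclose(positional_covariance(traj), 0.0, atol=1e-12)

    def test_gnm_covariance_within_5pct_frobenius(self, gnm_spec_20):
        spec = gnm_spec_20
        spec.n_frames = 100_000
        traj = generate_gnm_ensemble(spec)
        cov = positional_covariance(traj, superpose=False)
        analytic = np.kron(gnm_site_covariance(spec), np.eye(3))
        err = np.linalg.norm(cov - analytic) / np.linalg.norm(analytic)
        assert err < 0.05

    def test_duplicated_frames_leave_covariance_unchanged(self, gnm_spec_20):
        spec = gnm_spec_20
        spec.n_frames = 200
        traj = generate_gnm_ensemble(spec)
        doubled = Trajectory(
            np.concatenate([traj.coordinates, traj.coordinates]), 10.0, traj.topology
        )
        np.testing.assert_allclose(
            positional_covariance(doubled, superpose=False),
            positional_covariance(traj, superpose=False),
            atol=1e-12,
        )

    def test_single_frame_rejected(self):
        traj = frozen_trajectory(make_ca_chain(4), 1)
        with pytest.raises(ValueError, match="2 frames"):
            positional_covariance(traj)


class TestPCA:
    def test_diagonal_covariance_eigenvalues(self):
        cov = np.diag([4.0, 1.0, 0.5, 0.25, 0.1, 0.05])
        res = pca_decompose(cov)
        assert res.eigenvalues[0] == pytest.approx(4.0)
        assert np.all(np.diff(res.eigenvalues) <= 0)

    def test_eigenvalue_sum_equals_trace(self, gnm_spec_20):
        spec = gnm_spec_20
        spec.n_frames = 1000
        cov = positional_covariance(generate_gnm_ensemble(spec), superpose=False)
        res = pca_decompose(cov)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(cov), rel=1e-8)

    def test_orthonormal_eigenvectors(self, gnm_spec_20):
        spec = gnm_spec_20
        spec.n_frames = 500
        cov = positional_covariance(generate_gnm_ensemble(spec), superpose=False)
        v = pca_decompose(cov).eigenvectors
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)

    def test_sign_convention_deterministic(self):
        cov = np.diag([3.0, 2.0, 1.0])
        v = pca_decompose(cov).eigenvectors
        for k in range(3):
            assert v[np.argmax(np.abs(v[:, k])), k] > 0

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pca_decompose(bad)

    def test_leading_subspace_matches_analytic_gnm_modes(self, gnm_spec_20):
        """Each per-axis GNM mode appears three-fold degenerate in 3N space,
        so recovery is checked as overlap of the leading 3-dim subspaces."""
        spec = gnm_spec_20
        spec.n_frames = 100_000
        cov = positional_covariance(generate_gnm_ensemble(spec), superpose=False)
        emp = pca_decompose(cov).eigenvectors[:, :3]
        analytic = pca_decompose(np.kron(gnm_site_covariance(spec), np.eye(3)))
        ana = analytic.eigenvectors[:, :3]
        # mean principal-angle cosine of the two subspaces
        overlap = np.linalg.norm(emp.T @ ana) / np.sqrt(3.0)
        assert overlap > 0.99


class TestVarianceFraction:
    def test_all_modes_give_100_percent(self):
        res = pca_decompose(np.diag([3.0, 1.0, 0.0]))
        assert variance_fraction(res, 3) == pytest.approx(100.0)

    def test_simple_arithmetic(self):
        res = pca_decompose(np.diag([3.0, 1.0, 0.0, 0.0]))
        assert variance_fraction(res, 1) == pytest.approx(75.0)

    def test_k_out_of_range_rejected(self):
        res = pca_decompose(np.diag([3.0, 1.0]))
        with pytest.raises(ValueError):
            variance_fraction(res, 0)
        with pytest.raises(ValueError):
            variance_fraction(res, 3)


class TestModeProfile:
    def test_localized_mode(self):
        cov = np.zeros((6, 6))
        cov[3, 3] = 2.0  # all variance on residue 2, x-axis
        res = pca_decompose(cov)
        profile = mode_displacement_profile(res, 0)
        np.testing.assert_allclose(profile, [0.0, 1.0], atol=1e-12)

    def test_unit_norm_unscaled(self, gnm_spec_20):
        spec = gnm_spec_20
        spec.n_frames = 500
        res = pca_from_trajectory(generate_gnm_ensemble(spec), superpose=False)
        profile = mode_displacement_profile(res, 0)
        assert np.linalg.norm(profile) == pytest.approx(1.0, rel=1e-10)

    def test_eigenvalue_scaling_flag(self):
        cov = np.diag([4.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        res = pca_decompose(cov)
        unscaled = mode_displacement_profile(res, 0)
        scaled = mode_displacement_profile(res, 0, scale_by_eigenvalue=True)
        np.testing.assert_allclose(scaled, 2.0 * unscaled)

    def test_invalid_mode_rejected(self):
        res = pca_decompose(np.diag([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            mode_displacement_profile(res, 5)
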