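import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import chemomodes as cm
from chemomodes.ensemble_modes import align_basis, fit_frames, save_basis, load_basis
from chemomodes.errors import ValidationError


def _posed_copies(xyz, n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        rot = Rotation.from_quat(rng.normal(size=4)).as_matrix()
        out.append(xyz @ rot.T + rng.uniform(-1, 1, 3))
    return np.stack(out)


class TestIterativeMean:
    def test_identical_shapes_in_different_poses(self, template):
        e = cm.Ensemble(list(template.labels), _posed_copies(template.xyz, 5, 0))
        mean, fitted = cm.iterative_mean(e)
        assert cm.rmsd(mean.reshape(-1, 3), template.xyz, fit=True) < 1e-6

    def test_two_frames_mean_is_midpoint(self, template, truth):
        v = truth.mode_vectors[:, 0]
        xa = template.coords + 0.3 * v
        xb = template.coords - 0.3 * v
        e = cm.Ensemble(list(template.labels), np.stack([xa, xb]).reshape(2, -1, 3))
        mean, fitted = cm.iterative_mean(e)
        np.testing.assert_allclose(mean, fitted.frames.mean(axis=0), atol=1e-15)
        assert cm.rmsd(mean.reshape(-1, 3), template.xyz, fit=True) < 1e-6

    def test_mean_recovers_template_under_noise(self):
        spec = cm.SyntheticSpec(n_frames=2000, mode_std_nm=(0.0, 0.0),
                                noise_sigma_nm=0.01, seed=5)
        e, truth = cm.make_ensemble(spec)
        mean, _ = cm.iterative_mean(e)
        assert cm.rmsd(mean.reshape(-1, 3), truth.template.xyz, fit=True) < 0.002


class TestCovariance:
    def test_rank_one_case(self, template, truth):
        v = truth.mode_vectors[:, 1]
        a = 0.2
        frames = np.stack([template.coords + a * v, template.coords - a * v])
        e = cm.Ensemble(list(template.labels), frames.reshape(2, -1, 3))
        c = cm.covariance(e, template.coords)
        np.testing.assert_allclose(c, a**2 * np.outer(v, v), atol=1e-12)
        w = np.linalg.eigvalsh(c)
        assert w[-1] == pytest.approx(a**2, rel=1e-9)

    def test_identical_frames_give_zero(self, template):
        e = cm.Ensemble(list(template.labels), np.repeat(template.xyz[None], 3, axis=0))
        assert np.abs(cm.covariance(e, template.coords)).max() == 0.0


class TestPcaModes:
    def test_rank_one_eigenvector_recovery(self, truth):
        v = truth.mode_vectors[:, 0]
        basis = cm.pca_modes(0.04 * np.outer(v, v))
        assert cm.overlap(basis.mode(1), v) == pytest.approx(1.0, abs=1e-10)
        assert basis.eigenvalues[0] == pytest.approx(0.04, rel=1e-10)

    def test_eigenvalue_sum_equals_trace(self, recovery_run):
        fitted = recovery_run["fitted"]
        mean = recovery_run["basis"].mean  # aligned copy: use raw covariance instead
        c = cm.covariance(fitted, fitted.frames.mean(axis=0))
        basis = cm.pca_modes(c)
        assert basis.eigenvalues.sum() == pytest.approx(np.trace(c), rel=1e-8)

    def test_orthonormal_eigenvectors(self, recovery_run):
        v = recovery_run["basis"].eigenvectors[:, :20]
        np.testing.assert_allclose(v.T @ v, np.eye(20), atol=1e-8)

    def test_sign_convention(self, recovery_run):
        fitted = recovery_run["fitted"]
        basis = cm.pca_modes(cm.covariance(fitted, fitted.frames.mean(axis=0)))
        v = basis.eigenvectors
        idx = np.argmax(np.abs(v), axis=0)
        assert np.all(v[idx, np.arange(v.shape[1])] > 0)

    def test_asymmetric_input_raises(self):
        c = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValidationError):
            cm.pca_modes(c)

    def test_spectrum_decays_after_mode_two(self, recovery_run):
        # the planted ensemble has two collective modes; mode 3 carries only
        # site noise (~sigma^2 = 1e-4 nm^2 per direction)
        w = recovery_run["basis"].eigenvalues
        assert w[2] / w[1] < 0.1

    def test_matches_sklearn_pca(self, template, truth):
        sklearn = pytest.importorskip("sklearn.decomposition")
        spec = cm.SyntheticSpec(n_frames=400, rigid_jitter=False, seed=8)
        e, _ = cm.make_ensemble(spec)
        mean, fitted = cm.iterative_mean(e)
        basis = cm.pca_modes(cm.covariance(fitted, mean))
        ref = sklearn.PCA(n_components=5, svd_solver="full").fit(fitted.frames)
        m = e.n_frames
        np.testing.assert_allclose(
            basis.eigenvalues[:5] * m / (m - 1), ref.explained_variance_, rtol=1e-6)


class TestProjectAndExtrapolate:
    def test_mean_projects_to_zero(self, planted_basis, template):
        pe = cm.project_structure(template, planted_basis)
        np.testing.assert_allclose(pe, 0.0, atol=1e-9)

    def test_displaced_frame_projects_exactly(self, planted_basis, template, truth):
        s = template.with_xyz((template.coords + 0.5 * truth.mode_vectors[:, 1]).reshape(-1, 3))
        pe = cm.project_structure(s, planted_basis)
        assert pe[0] == pytest.approx(0.0, abs=1e-9)
        assert pe[1] == pytest.approx(0.5, abs=1e-9)

    def test_extrapolate_project_round_trip(self, planted_basis):
        s = cm.extrapolate(planted_basis, 2, 0.37)
        pe = cm.project_structure(s, planted_basis)
        assert pe[1] == pytest.approx(0.37, abs=1e-9)

    def test_extrapolate_linearity(self, planted_basis):
        a, b = 0.2, -0.7
        lhs = cm.extrapolate(planted_basis, 1, a + b).coords
        rhs = cm.extrapolate(planted_basis, 1, a).coords + b * planted_basis.mode(1)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_out_of_range_mode_raises(self, planted_basis):
        with pytest.raises(IndexError):
            cm.extrapolate(planted_basis, 3, 0.1)

    def test_fitted_projections_have_zero_mean(self, recovery_run):
        basis, _ = cm.pca_from_ensemble(recovery_run["ensemble"])
        table = cm.project(recovery_run["ensemble"], basis, k=5)
        # projecting about the ensemble's own converged mean
        assert np.abs(table.values.mean(axis=0)).max() < 1e-9

    def test_projection_correlation_recovers_planted(self, recovery_run, planted_basis):
        table = cm.project(recovery_run["ensemble"], planted_basis, k=2)
        r = np.corrcoef(table.pe(1), table.pe(2))[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)


class TestBasisUtilities:
    def test_align_basis_preserves_eigenvalues_and_orthonormality(self, recovery_run, template):
        b = recovery_run["basis"]
        b2 = align_basis(b, template.xyz)
        np.testing.assert_allclose(b2.eigenvalues, b.eigenvalues)
        v = b2.eigenvectors[:, :10]
        np.testing.assert_allclose(v.T @ v, np.eye(10), atol=1e-8)

    def test_orient_modes_flips_sign(self, planted_basis, truth):
        ref = -truth.mode_vectors[:, 1]
        flipped = cm.orient_modes(planted_basis, {2: ref})
        assert flipped.metadata["sign_flips"] == [2]
        assert float(flipped.mode(2) @ ref) > 0

    def test_save_load_round_trip(self, planted_basis, tmp_path):
        p = tmp_path / "basis.tsv"
        save_basis(planted_basis, p)
        back = load_basis(p)
        np.testing.assert_allclose(back.mean, planted_basis.mean, atol=1e-9)
        np.testing.assert_allclose(back.eigenvectors, planted_basis.eigenvectors, atol=1e-9)
        assert back.labels == planted_basis.labels
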