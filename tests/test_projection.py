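"""PCA contributions, mode coherence, 2D projections and cloud distances."""

import numpy as np
import pytest

import rrscan as rr
from rrscan.projection import ProjectionCloud
from rrscan.quasiharmonic import QHSpectrum
from rrscan import constants


def _spectrum_with_lambdas(lams, dim=None, temperature=300.0):
    lams = np.asarray(lams, dtype=float)  # descending variance
    dim = dim or len(lams)
    omega = np.sqrt(constants.kbt_internal(temperature) / lams)
    freq = np.asarray(constants.omega_to_wavenumber(omega))
    modes = np.eye(dim)[:, : len(lams)]
    return QHSpectrum(freq, modes, lams, temperature, 0)


def _random_orthonormal(rng, d, k):
    q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    return q[:, :k]


class TestPcaContributions:
    def test_fraction_arithmetic(self):
        spec = _spectrum_with_lambdas([4.0, 3.0, 2.0, 1.0])
        fractions, cumulative, n90 = rr.pca_contributions(spec)
        np.testing.assert_allclose(fractions, [0.4, 0.3, 0.2, 0.1])
        np.testing.assert_allclose(cumulative, [0.4, 0.7, 0.9, 1.0])
        assert n90 == 3

    def test_equal_lambdas_threshold_count(self):
        m = 10
        spec = _spectrum_with_lambdas(np.full(m, 2.0))
        _, _, n90 = rr.pca_contributions(spec)
        assert n90 == int(np.ceil(0.9 * m))

    def test_fractions_sum_to_one_and_cumulative_monotone(self, toy_spectrum):
        fractions, cumulative, _ = rr.pca_contributions(toy_spectrum)
        assert fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(cumulative) >= -1e-15)


class TestProjectFrames:
    def test_mean_structure_projects_to_zero(self, toy_model, toy_spectrum):
        mean = toy_model.mean_structure
        ens = rr.FrameEnsemble(mean[None], frame_interval=1.0, aligned_to="m")
        proj = rr.project_frames(ens, toy_spectrum, [0, 1], toy_model.topology,
                                 mean_structure=mean)
        np.testing.assert_allclose(proj, 0.0, atol=1e-10)

    def test_displacement_along_mode_projects_cleanly(self, toy_model, toy_spectrum):
        mean = toy_model.mean_structure.reshape(-1)
        inv_sqrt_m = 1.0 / np.sqrt(np.repeat(toy_model.topology.atom_masses, 3))
        c = 2.5
        frame = mean + c * inv_sqrt_m * toy_spectrum.modes[:, 0]
        ens = rr.FrameEnsemble(frame.reshape(1, -1, 3), frame_interval=1.0,
                               aligned_to="m")
        proj = rr.project_frames(ens, toy_spectrum, [0, 1, 2], toy_model.topology,
                                 mean_structure=mean)
        np.testing.assert_allclose(proj[0], [c, 0.0, 0.0], atol=1e-9)

    def test_projection_variance_matches_lambda(self, toy_model):
        # round trip: sampled ensemble variance along mode k equals λ_k
        spec = toy_model.spectrum()
        ens = rr.sample_frames(toy_model, 10000, seed=60)
        proj = rr.project_frames(ens, spec, [0, 1, 2], toy_model.topology,
                                 mean_structure=toy_model.mean_structure)
        var = proj.var(axis=0)
        np.testing.assert_allclose(var, spec.variances[:3], rtol=0.05)

    def test_dimension_mismatch_rejected(self, toy_model, toy_spectrum):
        ens = rr.FrameEnsemble(np.zeros((2, 5, 3)), frame_interval=1.0,
                               aligned_to="m")
        with pytest.raises(ValueError, match="dimension"):
            rr.project_frames(ens, toy_spectrum, [0], toy_model.topology)


class TestModeOverlap:
    def test_identical_mode_gives_one(self, rng):
        v = _random_orthonormal(rng, 20, 1)
        rep = rr.mode_overlap(v, v)
        assert rep.unsigned_mean[0] == pytest.approx(1.0)

    def test_orthogonal_modes_give_zero(self, rng):
        q = _random_orthonormal(rng, 20, 2)
        rep = rr.mode_overlap(q[:, :1], q[:, 1:])
        assert rep.dot_matrix[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_sign_flip_invariance_of_unsigned_summaries(self, rng):
        a = _random_orthonormal(rng, 30, 3)
        b = _random_orthonormal(rng, 30, 3)
        r1 = rr.mode_overlap(a, b)
        r2 = rr.mode_overlap(a * np.array([1, -1, 1]), b * np.array([-1, 1, 1]))
        np.testing.assert_allclose(r1.unsigned_mean, r2.unsigned_mean, atol=1e-12)

    def test_non_normalized_rejected(self, rng):
        a = _random_orthonormal(rng, 10, 2)
        with pytest.raises(ValueError, match="unit-norm"):
            rr.mode_overlap(a * 2.0, a)

    def test_random_unit_vector_overlap_statistics(self):
        # E|u·v| for random unit vectors in dimension d is sqrt(2/(π d))
        rng = np.random.default_rng(500)
        d, trials = 50, 2000
        dots = []
        for _ in range(trials):
            u = rng.standard_normal(d)
            v = rng.standard_normal(d)
            dots.append(abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        expected = np.sqrt(2.0 / (np.pi * d))
        assert np.mean(dots) == pytest.approx(expected, rel=0.1)


class TestCoherence:
    def _block_spectra(self, model, n_blocks, frames, seed0):
        specs = []
        for b in range(n_blocks):
            ens = rr.sample_frames(model, frames, seed=seed0 + b)
            cov = rr.covariance_matrix(ens)
            specs.append(rr.qh_modes(cov, model.topology, 300.0))
        return specs

    def test_identical_blocks_have_unit_pc1_overlap(self, toy_model):
        ens = rr.sample_frames(toy_model, 3000, seed=70)
        cov = rr.covariance_matrix(ens)
        spec = rr.qh_modes(cov, toy_model.topology, 300.0)
        rep = rr.coherence_check([spec, spec, spec], spec, k_modes=3)
        np.testing.assert_allclose(rep.unsigned_mean, 1.0, atol=1e-9)
        np.testing.assert_allclose(np.abs(rep.pc1_pair_matrix), 1.0, atol=1e-9)

    def test_spectral_gap_makes_pc1_coherent(self, toy_model):
        # the toy ENM has a distinct softest mode: PC1 reproduces across
        # independent blocks while higher modes agree less
        blocks = self._block_spectra(toy_model, 5, 3000, 80)
        full = self._block_spectra(toy_model, 1, 15000, 99)[0]
        rep = rr.coherence_check(blocks, full, k_modes=5)
        assert rep.unsigned_mean[0] > 0.9
        assert rep.pc1_offdiag_mean > 0.8

    def test_degenerate_spectrum_gives_incoherent_pc1(self):
        # isotropic Gaussian: every direction is PC1, so block overlaps sit
        # near the random-vector baseline, far below a coherent mode
        rng = np.random.default_rng(90)
        n = 10
        top = rr.Topology(np.arange(1, n + 1), np.full(n, 12.0), np.ones(n, int))
        specs = []
        for b in range(4):
            x = rng.standard_normal((2000, n, 3)) * 0.3
            ens = rr.FrameEnsemble(x, frame_interval=1.0, aligned_to="m")
            cov = rr.covariance_matrix(ens)
            specs.append(rr.qh_modes(cov, top, 300.0, n_external=0))
        rep = rr.coherence_check(specs[:3], specs[3], k_modes=1)
        assert rep.unsigned_mean[0] < 0.5

    def test_blocks_with_differing_atoms_rejected(self, toy_model, toy_spectrum):
        small = _spectrum_with_lambdas([1.0, 0.5], dim=6)
        with pytest.raises(ValueError, match="atom sets|blocks"):
            rr.coherence_check([toy_spectrum, small], toy_spectrum)


class TestProject2d:
    def test_frames_along_axis_a_stay_on_x_axis(self, toy_model):
        d = 3 * toy_model.topology.n_atoms
        axis_a = np.eye(d)[0]
        axis_b = np.eye(d)[1]
        mean = toy_model.mean_structure.reshape(-1)
        inv_sqrt_m = 1.0 / np.sqrt(np.repeat(toy_model.topology.atom_masses, 3))
        frames = mean + np.outer(np.linspace(-1, 1, 9), inv_sqrt_m * axis_a)
        ens = rr.FrameEnsemble(frames.reshape(9, -1, 3), frame_interval=1.0,
                               aligned_to="m")
        cloud = rr.project_2d(ens, axis_a, axis_b, mean, toy_model.topology)
        np.testing.assert_allclose(cloud.points[:, 1], 0.0, atol=1e-10)
        np.testing.assert_allclose(cloud.points[:, 0], np.linspace(-1, 1, 9),
                                   atol=1e-10)

    def test_centroid_at_common_mean_is_origin(self, toy_model):
        spec = toy_model.spectrum()
        ens = rr.sample_frames(toy_model, 4000, seed=101)
        cloud = rr.project_2d(ens, spec.modes[:, 0], spec.modes[:, 1],
                              toy_model.mean_structure, toy_model.topology)
        se = np.sqrt(spec.variances[:2] / 4000)
        assert np.all(np.abs(cloud.centroid) < 4 * se)

    def test_axes_not_reorthogonalized(self, toy_model):
        d = 3 * toy_model.topology.n_atoms
        a = np.eye(d)[0]
        b = (a + np.eye(d)[1]) / np.sqrt(2)
        ens = rr.FrameEnsemble(toy_model.mean_structure[None], frame_interval=1.0,
                               aligned_to="m")
        cloud = rr.project_2d(ens, a, b, toy_model.mean_structure, toy_model.topology)
        assert cloud.axis_dot == pytest.approx(1 / np.sqrt(2))


class TestDistributionDistance:
    def test_identical_clouds_zero(self, rng):
        pts = rng.standard_normal((100, 2))
        a = ProjectionCloud(pts, "u")
        assert rr.distribution_distance(a, a) == 0.0

    def test_pythagorean_shift(self, rng):
        pts = rng.standard_normal((100, 2))
        a = ProjectionCloud(pts, "u")
        b = ProjectionCloud(pts + [3.0, 4.0], "b")
        assert rr.distribution_distance(a, b) == pytest.approx(5.0)

    def test_symmetry_and_translation_invariance(self, rng):
        a = ProjectionCloud(rng.standard_normal((200, 2)), "u")
        b = ProjectionCloud(rng.standard_normal((200, 2)) + 1.5, "b")
        d1 = rr.distribution_distance(a, b)
        assert d1 == pytest.approx(rr.distribution_distance(b, a))
        shift = np.array([10.0, -7.0])
        a2 = ProjectionCloud(a.points + shift, "u")
        b2 = ProjectionCloud(b.points + shift, "b")
        assert rr.distribution_distance(a2, b2) == pytest.approx(d1)

    def test_gaussian_mean_separation_recovered(self, rng):
        mu_a, mu_b = np.array([0.0, 0.0]), np.array([1.2, -0.7])
        f = 10000
        a = ProjectionCloud(rng.standard_normal((f, 2)) + mu_a, "u")
        b = ProjectionCloud(rng.standard_normal((f, 2)) + mu_b, "b")
        se = np.sqrt(2.0 / f)  # per-axis SE of the centroid difference
        expected = np.linalg.norm(mu_b - mu_a)
        assert rr.distribution_distance(a, b) == pytest.approx(expected, abs=3 * 2 * se)

    def test_imposed_mode_shift_recovered(self, toy_model):
        # synthetic two-state pair: mean shifted by δ along PC1 (mass-weighted)
        spec = toy_model.spectrum()
        delta = 1.5
        shifted = rr.two_state_shift(toy_model, spec.modes[:, 0], delta)
        f = 10000
        ens_a = rr.sample_frames(toy_model, f, seed=110)
        ens_b = rr.sample_frames(shifted, f, seed=111)
        mean = toy_model.mean_structure
        clouds = [rr.project_2d(e, spec.modes[:, 0], spec.modes[:, 1], mean,
                                toy_model.topology, s)
                  for e, s in ((ens_a, "unbound"), (ens_b, "bound"))]
        se = np.sqrt(2 * (spec.variances[0] + spec.variances[1]) / f)
        got = rr.distribution_distance(*clouds)
        assert got == pytest.approx(delta, abs=3 * se)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ProjectionCloud(np.zeros((0, 2)), "u")

    def test_density_mode_separates_two_tight_clusters(self, rng):
        a = ProjectionCloud(0.05 * rng.standard_normal((2000, 2)), "u")
        b = ProjectionCloud(0.05 * rng.standard_normal((2000, 2)) + [2.0, 0.0], "b")
        d = rr.distribution_distance(a, b, method="density_mode")
        assert d == pytest.approx(2.0, abs=0.3)
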