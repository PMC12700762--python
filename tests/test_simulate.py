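import numpy as np
import pytest

from patchap.mesh import patch_basis
from patchap.simulate import (
    NoiseSpec,
    SimulationConfig,
    colored_noise_cov,
    correlated_timecourses,
    draw_noise,
    make_synthetic_head,
    patch_source_matrix,
    sample_ground_truth,
    sensor_data,
    simulate_trial,
)


class TestSyntheticHead:
    def test_icosphere_vertex_counts(self, head23):
        assert head23.mesh_sim.n_vertices == 162   # 10*4^2 + 2
        assert head23.mesh_inv.n_vertices == 642   # 10*4^3 + 2

    def test_unit_column_norms(self, head23):
        assert np.allclose(np.linalg.norm(head23.A_sim, axis=0), 1.0)
        assert np.allclose(np.linalg.norm(head23.A_inv, axis=0), 1.0)

    def test_seed_reproducibility(self):
        h1 = make_synthetic_head(levels=(1, 2), m=16, seed=5)
        h2 = make_synthetic_head(levels=(1, 2), m=16, seed=5)
        assert np.array_equal(h1.A_sim, h2.A_sim)
        assert np.array_equal(h1.A_inv, h2.A_inv)
        h3 = make_synthetic_head(levels=(1, 2), m=16, seed=6)
        assert not np.array_equal(h1.A_sim, h3.A_sim)

    def test_coarse_topographies_approximated_not_contained(self, head23):
        # each coarse vertex coincides geometrically with a fine vertex;
        # its topography must resemble (but not equal) the fine one, since
        # the two meshes smooth the shared field differently
        from scipy.spatial import cKDTree

        nearest = cKDTree(head23.mesh_inv.vertices).query(
            head23.mesh_sim.vertices
        )[1]
        dots = np.einsum(
            "mi,mi->i", head23.A_sim, head23.A_inv[:, nearest]
        )  # both column sets are unit norm
        assert np.all(dots > 0.9)
        assert np.all(dots < 1.0 - 1e-9)

    def test_equal_levels_warns(self):
        with pytest.warns(UserWarning, match="inverse crime"):
            make_synthetic_head(levels=(1, 1), m=8, seed=0)


class TestGroundTruthPlacement:
    def test_disjoint_patches(self, head23):
        patches = sample_ground_truth(head23.mesh_sim, 3, (2, 2, 2), seed=4)
        sets = [set(p.members.tolist()) for p in patches]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])

    def test_reproducible(self, head23):
        a = sample_ground_truth(head23.mesh_sim, 2, (1, 3), seed=9)
        b = sample_ground_truth(head23.mesh_sim, 2, (1, 3), seed=9)
        assert [p.seed for p in a] == [p.seed for p in b]

    def test_impossible_placement_raises(self, icosahedron):
        with pytest.raises(RuntimeError):
            sample_ground_truth(icosahedron, 4, (2, 2, 2, 2), seed=0,
                                max_retries=20)


class TestCorrelatedTimecourses:
    @pytest.mark.parametrize("rho", [0.1, 0.5, 0.9])
    def test_empirical_correlation_converges(self, rho):
        X = correlated_timecourses(3, 10_000, rho, seed=2)
        corr = np.corrcoef(X)
        off = corr[np.triu_indices(3, 1)]
        assert np.all(np.abs(off - rho) < 0.05)

    def test_unit_variance_rows(self):
        X = correlated_timecourses(4, 500, 0.3, seed=1)
        assert np.allclose(X.std(axis=1), 1.0)

    def test_full_coherence(self):
        X = correlated_timecourses(3, 100, 1.0, seed=0)
        assert np.allclose(np.corrcoef(X), 1.0)

    def test_cholesky_mixing_factor_by_hand(self):
        # for n=2, rho=0.5 the mixing factor is [[1, 0], [0.5, sqrt(0.75)]]
        L = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert np.allclose(L, [[1.0, 0.0], [0.5, np.sqrt(0.75)]])

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            correlated_timecourses(2, 100, 1.5)


class TestPatchSourceMatrix:
    def test_point_source_carries_base_course(self, head23):
        mesh = head23.mesh_sim
        patches = [mesh.patch(10, 0)]
        base = correlated_timecourses(1, 50, 0.0, seed=3)
        K = mesh.smoothing_operator(0.15)
        S = patch_source_matrix(patches, [1], base, K, q=0, seed=0)
        assert np.count_nonzero(S.any(axis=1)) == 1
        # unit-norm 1x1 mixing can only flip the sign
        assert np.allclose(np.abs(S[10]), np.abs(base[0]))

    def test_rank_two_block_has_rank_two(self, head23):
        mesh = head23.mesh_sim
        patches = [mesh.patch(40, 2)]
        base = correlated_timecourses(1, 100, 0.0, seed=4)
        K = mesh.smoothing_operator(0.15)
        S = patch_source_matrix(patches, [2], base, K, q=0, seed=1)
        block = S[patches[0].members]
        s = np.linalg.svd(block, compute_uv=False)
        assert s[1] > 1e-8 * s[0] and s[2] < 1e-10 * s[0]

    def test_matches_generative_equation(self, head23):
        """S equals K^q E Sdot for an independently assembled product."""
        mesh = head23.mesh_sim
        patches = [mesh.patch(7, 1), mesh.patch(100, 0)]
        base = correlated_timecourses(2, 30, 0.5, seed=5)
        K = mesh.smoothing_operator(0.15)
        S = patch_source_matrix(patches, [2, 1], base, K, q=2, seed=2)
        S0 = patch_source_matrix(patches, [2, 1], base, K, q=0, seed=2)
        Kd = K.toarray()
        assert np.allclose(S, Kd @ Kd @ S0, atol=1e-12)
        # q=0 support is exactly the patch members
        outside = np.setdiff1d(
            np.arange(mesh.n_vertices),
            np.concatenate([p.members for p in patches]),
        )
        assert np.allclose(S0[outside], 0.0)


class TestColoredNoise:
    def test_diagonal_construction(self):
        cov = colored_noise_cov("diagonal", 0.5, 4)
        assert np.allclose(np.diag(cov), [1.5, 0.5, 1.5, 0.5])
        assert np.allclose(cov - np.diag(np.diag(cov)), 0.0)

    def test_banded_construction(self):
        cov = colored_noise_cov("banded", 0.4, 5)
        assert np.allclose(np.diag(cov, 1), 0.2)
        assert np.allclose(np.diag(cov, 2), 0.0)

    def test_cholesky_construction(self):
        cov = colored_noise_cov("cholesky", 0.4, 6)
        assert np.isclose(cov[0, 1], 0.4) and np.isclose(cov[0, 2], 0.16)
        assert np.allclose(cov, cov.T)

    def test_unit_mean_diagonal(self):
        for kind, gamma in (("diagonal", 0.3), ("banded", 0.6),
                            ("cholesky", 0.4), ("white", 0.0)):
            cov = colored_noise_cov(kind, gamma, 9)
            assert np.isclose(np.mean(np.diag(cov)), 1.0)

    @pytest.mark.parametrize("kind,gamma", [("diagonal", 1.2),
                                            ("banded", 0.0),
                                            ("cholesky", 0.7)])
    def test_gamma_ranges(self, kind, gamma):
        with pytest.raises(ValueError):
            NoiseSpec(kind=kind, gamma=gamma)

    def test_cholesky_empirical_correlation(self):
        gamma = 0.4
        cov = colored_noise_cov("cholesky", gamma, 12)
        noise = draw_noise(cov, 10_000, seed=6)
        emp = np.corrcoef(noise)
        idx = np.arange(12)
        target = gamma ** np.abs(idx[:, None] - idx[None, :])
        assert np.max(np.abs(emp - target)) < 0.05


class TestSensorData:
    def test_snr_exact(self, head23):
        rng = np.random.default_rng(0)
        S = np.zeros((162, 80))
        S[5] = rng.standard_normal(80)
        for snr in (-5.0, 0.0, 5.0):
            Y, realized = sensor_data(head23.A_sim, S, snr, NoiseSpec(), seed=1)
            assert abs(realized - snr) < 0.05
        Y0, _ = sensor_data(head23.A_sim, S, 0.0, NoiseSpec(), seed=1)
        clean = head23.A_sim @ S
        assert np.isclose(np.linalg.norm(clean), np.linalg.norm(Y0 - clean))

    def test_zero_signal_rejected(self, head23):
        with pytest.raises(ValueError):
            sensor_data(head23.A_sim, np.zeros((162, 10)), 0.0, NoiseSpec())

    def test_white_noise_cov_is_isotropic(self):
        cov = colored_noise_cov("white", 0.0, 20)
        noise = draw_noise(cov, 20_000, seed=2)
        emp = noise @ noise.T / 20_000
        assert np.max(np.abs(emp - np.diag(np.diag(emp)))) < 0.05


def test_simulate_trial_reproducible(head23):
    cfg = SimulationConfig(n_sources=2, extents=(1, 2), ranks=(1, 2),
                           rho=0.5, snr_db=0.0, samples=60, seed=42)
    Y1, t1 = simulate_trial(cfg, head23)
    Y2, t2 = simulate_trial(cfg, head23)
    assert np.array_equal(Y1, Y2)
    assert np.array_equal(t1.S, t2.S)
    assert abs(t1.realized_snr_db - 0.0) < 0.05
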