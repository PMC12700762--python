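import numpy as np
import pytest

from patchap.dictionary import SmoothingSpec, build_dictionary
from patchap.localize import (
    DataCovariance,
    estimate_num_sources,
    localizer_value,
    orthonormal_projector,
    patch_ap,
    scan_candidates,
)

SMOOTH = SmoothingSpec(alpha=0.15, order=2)


def small_dictionary(head, l_max=3, rank_mode="patch"):
    return build_dictionary(head.A_inv, head.mesh_inv, SMOOTH, l_max, rank_mode)


def brute_force_best(Q, C, dictionary):
    """Independent exhaustive maximization of the localizer over atoms,
    computed with explicit pinv-based projections."""
    best_key, best_val = None, -np.inf
    for atom in dictionary:
        W = Q @ atom.U
        if np.linalg.svd(W, compute_uv=False)[-1] < 1e-8:
            continue
        Pi = W @ np.linalg.pinv(W.T @ W) @ W.T
        val = np.trace(Pi @ C)
        key = (atom.seed, atom.extent)
        if val > best_val + 1e-9 or (
            np.isclose(val, best_val, rtol=1e-12)
            and (key[1], key[0]) < (best_key[1], best_key[0])
        ):
            best_key, best_val = key, val
    return best_key, best_val


class TestProjector:
    def test_basis_vector(self):
        Pi, Q = orthonormal_projector(np.eye(4)[:, :1])
        assert np.allclose(Pi, np.diag([1.0, 0, 0, 0]))
        assert np.allclose(Q, np.diag([0.0, 1, 1, 1]))

    def test_idempotent_and_annihilating(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((10, 3))
        Pi, Q = orthonormal_projector(M)
        assert np.allclose(Pi @ Pi, Pi, atol=1e-12)
        assert np.allclose(Q @ M, 0.0, atol=1e-10)
        assert np.isclose(np.trace(Pi), 3.0)

    def test_rank_deficient_fallback(self):
        M = np.column_stack([np.ones(5), 2 * np.ones(5)])
        Pi, _ = orthonormal_projector(M)
        assert np.isclose(np.trace(Pi), 1.0)

    def test_empty_matrix_gives_identity_complement(self):
        Pi, Q = orthonormal_projector(np.zeros((6, 0)))
        assert np.allclose(Pi, 0.0) and np.allclose(Q, np.eye(6))


class TestLocalizerValue:
    def test_unit_vector_quadratic_form(self, head_small):
        d = small_dictionary(head_small)
        atom = d.atom(3, 0)
        rng = np.random.default_rng(0)
        B = rng.standard_normal((32, 32))
        C = B @ B.T
        u = atom.U[:, 0]
        val = localizer_value(atom, np.eye(32), C)
        assert np.isclose(val, u @ C @ u)

    def test_identity_covariance_gives_rank(self, head_small):
        d = small_dictionary(head_small)
        atom = d.atom(5, 2)
        val = localizer_value(atom, np.eye(32), np.eye(32))
        assert np.isclose(val, atom.rank)

    def test_own_topography_covariance(self, head_small):
        d = small_dictionary(head_small)
        atom = d.atom(9, 0)
        u = atom.U[:, 0]
        assert np.isclose(localizer_value(atom, np.eye(32), np.outer(u, u)), 1.0)


class TestScan:
    def test_planted_atom_wins(self, head_small):
        d = small_dictionary(head_small)
        atom = d.atom(17, 2)
        rng = np.random.default_rng(4)
        X = rng.standard_normal((atom.rank, 80))
        Y = atom.U @ X
        key, _ = scan_candidates(np.eye(32), Y @ Y.T, d)
        assert key == (17, 2)

    def test_agrees_with_brute_force(self, head_small):
        d = small_dictionary(head_small)
        rng = np.random.default_rng(8)
        for _ in range(5):
            B = rng.standard_normal((32, 40))
            C = B @ B.T
            key, val = scan_candidates(np.eye(32), C, d)
            bkey, bval = brute_force_best(np.eye(32), C, d)
            assert key == bkey
            assert np.isclose(val, bval)

    def test_sequential_scan_finds_second_atom(self, head23):
        d = build_dictionary(head23.A_inv, head23.mesh_inv, SMOOTH,
                             l_max=1, rank_mode="patch")
        # a pair of near-orthogonal-topography atoms on opposite sides
        rng = np.random.default_rng(3)
        pair = None
        while pair is None:
            i, j = rng.choice(head23.mesh_inv.n_vertices, 2, replace=False)
            a1, a2 = d.atom(int(i), 1), d.atom(int(j), 1)
            coh = np.linalg.svd(a1.U.T @ a2.U, compute_uv=False)[0]
            if coh < 0.2:
                pair = ((int(i), 1), (int(j), 1))
        m = head23.A_inv.shape[0]
        Y = np.hstack([a1.U, a2.U]) @ rng.standard_normal((a1.rank + a2.rank, 60))
        C = Y @ Y.T
        key1, _ = scan_candidates(np.eye(m), C, d)
        _, Q = orthonormal_projector(d.atom(*key1).U)
        key2, _ = scan_candidates(Q, C, d)
        assert {key1, key2} == set(pair)


class TestPatchAP:
    def test_single_noiseless_source_recovered_exactly(self, head_small):
        d = small_dictionary(head_small)
        atom = d.atom(21, 3)
        rng = np.random.default_rng(5)
        Y = atom.U @ rng.standard_normal((atom.rank, 100))
        cov = DataCovariance.from_data(Y)
        res = patch_ap(cov, d, 1)
        assert res.seeds == [21] and res.extents == [3]
        assert np.isclose(res.objective_trace[-1], np.trace(cov.C))
        assert res.converged

    def test_objective_monotone_under_noise(self, head_small):
        d = small_dictionary(head_small)
        rng = np.random.default_rng(9)
        for _ in range(10):
            B = rng.standard_normal((32, 60))
            res = patch_ap(DataCovariance.from_data(B), d, 2)
            trace = np.array(res.objective_trace)
            assert np.all(np.diff(trace) >= -1e-8 * trace.max())

    def test_non_psd_rejected(self, head_small):
        d = small_dictionary(head_small)
        C = -np.eye(32)
        with pytest.raises(ValueError):
            patch_ap(C, d, 1)

    def test_n_sources_validation(self, head_small):
        d = small_dictionary(head_small)
        with pytest.raises(ValueError):
            patch_ap(np.eye(32), d, 0)


class TestAPReduction:
    """Point dictionary + extent 0 must reproduce classical single-dipole
    alternating projections, verified against an independent scan written
    directly on the raw leadfield columns."""

    @staticmethod
    def independent_ap(A, C, n_sources, max_sweeps=15):
        m, k = A.shape

        def best(Q, exclude_span):
            vals = np.full(k, -np.inf)
            for p in range(k):
                w = Q @ A[:, p]
                nrm = np.linalg.norm(w)
                if nrm < 1e-8 * np.linalg.norm(A[:, p]):
                    continue
                vals[p] = (w @ C @ w) / (w @ w)
            return int(np.argmax(vals))

        found = []
        for _ in range(n_sources):
            if found:
                M = A[:, found]
                Q = np.eye(m) - M @ np.linalg.pinv(M.T @ M) @ M.T
            else:
                Q = np.eye(m)
            found.append(best(Q, found))
        for _ in range(max_sweeps):
            changed = False
            for n in range(n_sources):
                others = [p for i, p in enumerate(found) if i != n]
                if others:
                    M = A[:, others]
                    Q = np.eye(m) - M @ np.linalg.pinv(M.T @ M) @ M.T
                else:
                    Q = np.eye(m)
                p = best(Q, others)
                if p != found[n]:
                    found[n] = p
                    changed = True
            if not changed:
                break
        return found

    def test_matches_independent_ap(self, head_small):
        # q = 0: the point atoms are exactly the (normalized) raw columns
        d = build_dictionary(head_small.A_inv, head_small.mesh_inv,
                             SmoothingSpec(alpha=0.15, order=0),
                             l_max=0, rank_mode="point")
        A = head_small.A_inv
        rng = np.random.default_rng(12)
        for _ in range(5):
            B = rng.standard_normal((32, 50))
            C = B @ B.T
            res = patch_ap(DataCovariance(C=C), d, 2)
            expected = self.independent_ap(A, C, 2)
            assert res.seeds == expected
            assert res.extents == [0, 0] and res.ranks == [1, 1]


class TestNumSources:
    def test_constructed_spectrum(self):
        C = np.diag([40.0, 30.0, 20.0, 9.0, 0.5, 0.5])
        assert estimate_num_sources(C, 0.95) == 4

    def test_rank_one(self):
        u = np.arange(1.0, 6.0)
        assert estimate_num_sources(np.outer(u, u), 0.95) == 1

    def test_threshold_one_gives_numerical_rank(self):
        rng = np.random.default_rng(1)
        B = rng.standard_normal((8, 3))
        assert estimate_num_sources(B @ B.T, 1.0) == 3

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            estimate_num_sources(np.zeros((4, 4)))
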