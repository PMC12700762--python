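"""Self-contained synthetic data: meshes, leadfields, patch sources, noise.

Everything the inversion pipeline consumes can be generated here without
external downloads.  The synthetic head is a pair of nested icosphere
meshes (coarse for simulation, fine for inversion — distinct forward
models mitigate the inverse crime) carrying smooth random gain fields that
mimic the long-range spatial correlation of real sensor leadfields.  Patch
sources are placed disjointly at controlled extent and within-patch rank,
their time courses mixed to a target inter-source correlation by Cholesky
mixing, projected to the sensors, and corrupted by white or colored noise
scaled to an exact SNR.

Every operation is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .dictionary import smoothed_leadfield
from .mesh import TriangleMesh, patch_basis

__all__ = [
    "NoiseSpec",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticHead",
    "make_synthetic_head",
    "sample_ground_truth",
    "correlated_timecourses",
    "patch_source_matrix",
    "colored_noise_cov",
    "draw_noise",
    "sensor_data",
    "simulate_trial",
]

NOISE_KINDS = ("white", "diagonal", "banded", "cholesky")

# angular concentration of the random gain field's kernel features; width
# ~1/sqrt(kappa) rad, chosen so the field's correlation scale exceeds the
# diameter of an extent-5 patch and the leadfield's effective rank is in
# the range of real 128-channel arrays
FIELD_KAPPA = 6.0
FIELD_N_FEATURES = 384
HEAD_RADIUS_MM = 100.0
HEAD_SMOOTH_POWER = 3
HEAD_SMOOTH_ALPHA = 0.15


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor-noise covariance family.

    kind "white": identity.  "diagonal": alternating 1+gamma / 1-gamma
    diagonal (unequal channel noise power, SD of power = gamma, no
    cross-channel correlation).  "banded": identity plus gamma/2 on the
    first off-diagonals (neighboring-channel artifacts).  "cholesky":
    C_ij = gamma^|i-j|, exponentially decaying global correlation.
    """

    kind: str = "white"
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {NOISE_KINDS}")
        if self.kind in ("diagonal", "banded") and not 0.0 < self.gamma < 1.0:
            raise ValueError(f"{self.kind} noise requires 0 < gamma < 1")
        if self.kind == "cholesky" and not 0.0 < self.gamma < 0.5:
            raise ValueError("cholesky noise requires 0 < gamma < 0.5")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative description of one synthetic trial."""

    n_sources: int = 1
    extents: tuple = (2,)
    ranks: tuple = (2,)
    rho: float = 0.5
    snr_db: float = 0.0
    smooth_order: int = 2
    alpha: float = 0.15
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    samples: int = 200
    channels: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "extents", tuple(int(l) for l in self.extents))
        object.__setattr__(self, "ranks", tuple(int(r) for r in self.ranks))
        if len(self.extents) != self.n_sources or len(self.ranks) != self.n_sources:
            raise ValueError("extents and ranks must list one entry per source")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What was actually simulated, on the simulation mesh."""

    patches: tuple
    base_timecourses: np.ndarray   # n_sources x T
    S: np.ndarray                  # k_sim x T smooth source matrix
    clean: np.ndarray              # m x T noiseless sensor data
    realized_snr_db: float


@dataclass(frozen=True)
class SyntheticHead:
    """Dual-resolution source spaces with matched random gain fields."""

    mesh_sim: TriangleMesh
    mesh_inv: TriangleMesh
    A_sim: np.ndarray
    A_inv: np.ndarray


def _icosphere(level: int) -> TriangleMesh:
    m = trimesh.creation.icosphere(subdivisions=level, radius=HEAD_RADIUS_MM)
    return TriangleMesh(vertices=np.asarray(m.vertices), faces=np.asarray(m.faces))


def _gain_field(W: np.ndarray, centers: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Evaluate the shared random von-Mises-Fisher feature field on a mesh,
    then apply per-mesh diffusion smoothing and column normalization."""
    unit = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    phi = np.exp(FIELD_KAPPA * (centers @ unit.T - 1.0))  # n_feat x k
    A = W @ phi
    K = mesh.smoothing_operator(HEAD_SMOOTH_ALPHA)
    A = smoothed_leadfield(A, K, HEAD_SMOOTH_POWER)
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0.0):
        raise RuntimeError("degenerate gain field column")
    return A / norms


def make_synthetic_head(levels=(3, 4), m: int = 128, seed: int = 0) -> SyntheticHead:
    """Nested icosphere meshes plus smooth random leadfields.

    ``levels`` are icosphere subdivision levels (10*4^n + 2 vertices); the
    coarse mesh simulates, the fine mesh inverts.  Both leadfields sample
    the same underlying random gain field, so coarse-mesh topographies are
    approximated — not exactly contained — in the fine dictionary.  Equal
    levels are allowed for unit tests but commit the inverse crime.
    """
    lo, hi = int(levels[0]), int(levels[1])
    if lo > hi:
        raise ValueError("simulation level must not exceed inversion level")
    if lo == hi:
        import warnings

        warnings.warn("equal mesh levels: simulation and inversion share a "
                      "forward model (inverse crime)")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((m, FIELD_N_FEATURES))
    centers = rng.standard_normal((FIELD_N_FEATURES, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    mesh_sim = _icosphere(lo)
    mesh_inv = _icosphere(hi)
    A_sim = _gain_field(W, centers, mesh_sim)
    A_inv = _gain_field(W, centers, mesh_inv)
    return SyntheticHead(mesh_sim=mesh_sim, mesh_inv=mesh_inv,
                         A_sim=A_sim, A_inv=A_inv)


def sample_ground_truth(
    mesh_sim: TriangleMesh, n_sources: int, extents, seed: int = 0,
    max_retries: int = 200,
):
    """Disjoint random patch placement: seeds drawn uniformly without
    replacement, redrawn until member sets are pairwise disjoint."""
    extents = [int(l) for l in extents]
    if len(extents) != n_sources:
        raise ValueError("one extent per source required")
    rng = np.random.default_rng(seed)
    k = mesh_sim.n_vertices
    for _ in range(max_retries):
        seeds = rng.choice(k, size=n_sources, replace=False)
        patches = [mesh_sim.patch(int(s), l) for s, l in zip(seeds, extents)]
        used: set = set()
        ok = True
        for p in patches:
            members = set(p.members.tolist())
            if used & members:
                ok = False
                break
            used |= members
        if ok:
            return tuple(patches)
    raise RuntimeError(
        f"could not place {n_sources} disjoint patches in {max_retries} draws"
    )


def correlated_timecourses(n: int, T: int, rho: float, seed: int = 0) -> np.ndarray:
    """n unit-variance processes with pairwise correlation rho.

    Independent Gaussian rows are mixed by the Cholesky factor of
    rho*11' + (1-rho)*I and re-standardized to unit sample variance
    (row scaling leaves correlations untouched).
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if T < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, T))
    Ctarget = rho * np.ones((n, n)) + (1.0 - rho) * np.eye(n)
    if rho == 1.0:
        X = np.tile(Z[:1], (n, 1))
    else:
        X = np.linalg.cholesky(Ctarget) @ Z
    X = X - X.mean(axis=1, keepdims=True)
    return X / X.std(axis=1, keepdims=True)


def patch_source_matrix(
    patches, ranks, base_tcs: np.ndarray, K_sim, q: int, seed: int = 0,
) -> np.ndarray:
    """Smooth full-mesh source matrix S = K^q E Sdot from patch components.

    Within patch i of rank r_i the local courses are Sdot_i = W_i Z_i: row 1
    of Z_i is the source's inter-source-correlated base course, higher rows
    are independent unit-variance processes, and W_i is a random d_i x r_i
    mixing matrix with unit-norm rows.  Only the first component carries the
    inter-source correlation.
    """
    patches = list(patches)
    ranks = [int(r) for r in ranks]
    base_tcs = np.asarray(base_tcs, dtype=float)
    if len(patches) != len(ranks) or base_tcs.shape[0] != len(patches):
        raise ValueError("patches, ranks and base courses must align")
    rng = np.random.default_rng(seed)
    k = K_sim.shape[0]
    T = base_tcs.shape[1]
    S = np.zeros((k, T))
    for patch, r, base in zip(patches, ranks, base_tcs):
        d = patch.size
        if r > d:
            import warnings

            warnings.warn(f"rank {r} clipped to patch size {d}")
            r = d
        Z = np.empty((r, T))
        Z[0] = base
        if r > 1:
            extra = rng.standard_normal((r - 1, T))
            extra = extra - extra.mean(axis=1, keepdims=True)
            Z[1:] = extra / extra.std(axis=1, keepdims=True)
        W = rng.standard_normal((d, r))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        E = patch_basis(patch.members, k)
        S += np.asarray(E @ (W @ Z))
    for _ in range(int(q)):
        S = K_sim @ S
    return np.asarray(S)


def colored_noise_cov(kind: str, gamma: float, m: int) -> np.ndarray:
    """Channel-noise covariance, normalized to unit mean diagonal so gamma
    changes correlation structure rather than total power."""
    spec = NoiseSpec(kind=kind, gamma=gamma)  # validates ranges
    if kind == "white":
        cov = np.eye(m)
    elif kind == "diagonal":
        diag = np.ones(m)
        diag[0::2] += spec.gamma
        diag[1::2] -= spec.gamma
        cov = np.diag(diag)
    elif kind == "banded":
        cov = np.eye(m)
        off = np.full(m - 1, spec.gamma / 2.0)
        cov += np.diag(off, 1) + np.diag(off, -1)
    else:  # cholesky
        idx = np.arange(m)
        cov = spec.gamma ** np.abs(idx[:, None] - idx[None, :])
    return cov / np.mean(np.diag(cov))


def draw_noise(cov: np.ndarray, T: int, seed: int = 0) -> np.ndarray:
    """m x T Gaussian noise with channel covariance ``cov``."""
    rng = np.random.default_rng(seed)
    m = cov.shape[0]
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(m))
    return L @ rng.standard_normal((m, T))


def sensor_data(A_sim: np.ndarray, S: np.ndarray, snr_db: float,
                noise_spec: NoiseSpec, seed: int = 0):
    """Y = A S + noise, with the noise globally rescaled so the realized
    SNR 10*log10(||AS||_F^2 / ||noise||_F^2) equals ``snr_db`` exactly."""
    clean = np.asarray(A_sim) @ np.asarray(S)
    signal_energy = np.linalg.norm(clean) ** 2
    if signal_energy <= 0.0:
        raise ValueError("zero clean signal: SNR undefined")
    cov = colored_noise_cov(noise_spec.kind, noise_spec.gamma, clean.shape[0])
    noise = draw_noise(cov, clean.shape[1], seed=seed)
    scale = np.sqrt(signal_energy / np.linalg.norm(noise) ** 2
                    / 10.0 ** (snr_db / 10.0))
    noise = scale * noise
    realized = 10.0 * np.log10(signal_energy / np.linalg.norm(noise) ** 2)
    return clean + noise, float(realized)


def simulate_trial(config: SimulationConfig, head: SyntheticHead):
    """One complete trial: (Y, GroundTruth) on the head's simulation mesh.

    Sub-seeds for placement, time courses, mixing and noise are derived
    deterministically from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    s_place, s_base, s_mix, s_noise = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    ]
    patches = sample_ground_truth(
        head.mesh_sim, config.n_sources, config.extents, seed=s_place
    )
    base = correlated_timecourses(
        config.n_sources, config.samples, config.rho, seed=s_base
    )
    K_sim = head.mesh_sim.smoothing_operator(config.alpha)
    S = patch_source_matrix(
        patches, config.ranks, base, K_sim, config.smooth_order, seed=s_mix
    )
    Y, realized = sensor_data(
        head.A_sim, S, config.snr_db, config.noise, seed=s_noise
    )
    truth = GroundTruth(
        patches=patches,
        base_timecourses=base,
        S=S,
        clean=head.A_sim @ S,
        realized_snr_db=realized,
    )
    return Y, truth
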