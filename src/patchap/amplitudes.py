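"""Amplitude reconstruction for localized patches.

Given the localized atoms, the reduced-rank activation time courses are the
least-squares fit of the data onto the concatenated topographies
``U(P,L)``; each patch's per-dipole time courses follow by pseudo-inverting
its ``diag(sigma) V'`` factor; the full-mesh estimate scatters those onto
the mesh through the patch bases and applies the diffusion smoother.

The smoothing power applied at the last step is configurable
(``smooth_power_mode``): "as_printed" raises K to each patch's estimated
rank; "generative" raises K to the smoothing order q used by the forward
patch model.  The two coincide for rank-2 patches under the default q = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .dictionary import PatchAtom
from .localize import LocalizationResult, PINV_RTOL
from .mesh import Patch, patch_basis

__all__ = [
    "ReducedTimecourses",
    "SourceEstimate",
    "reduced_timecourses",
    "patch_timecourses",
    "full_source_estimate",
    "estimate_amplitudes",
]


@dataclass(frozen=True)
class ReducedTimecourses:
    """Stacked reduced-rank activations, partitioned by source rank."""

    data: np.ndarray      # r_total x T
    ranks: tuple

    def block(self, i: int) -> np.ndarray:
        start = sum(self.ranks[:i])
        return self.data[start : start + self.ranks[i]]


@dataclass(frozen=True)
class SourceEstimate:
    """Full-mesh amplitude estimate (k vertices x T samples)."""

    data: np.ndarray
    t_start: float = 0.0
    t_step: float = 1.0

    @property
    def n_vertices(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_times(self) -> int:
        return int(self.data.shape[1])


def reduced_timecourses(U_combined: np.ndarray, Y: np.ndarray,
                        ranks=None) -> ReducedTimecourses:
    """Least-squares activations: S = (U'U)^-1 U' Y.

    The residual Y - U S is orthogonal to span(U).  Rank-deficient U falls
    back to the pseudo-inverse (minimum-norm solution).
    """
    U = np.asarray(U_combined, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if U.shape[0] != Y.shape[0]:
        raise ValueError("channel dimensions of U and Y disagree")
    S, _, rank, _ = np.linalg.lstsq(U, Y, rcond=PINV_RTOL)
    if rank < U.shape[1]:
        import warnings

        warnings.warn("combined topography matrix is rank deficient; "
                      "minimum-norm activations returned")
    if ranks is None:
        ranks = (U.shape[1],)
    return ReducedTimecourses(data=S, ranks=tuple(int(r) for r in ranks))


def patch_timecourses(atom: PatchAtom, S_reduced: np.ndarray) -> np.ndarray:
    """Per-dipole patch time courses: (diag(sigma) V')^+ applied blockwise.

    Maps the atom's reduced coordinates back to its member dipoles as the
    minimum-norm d x T solution.
    """
    S_reduced = np.asarray(S_reduced, dtype=float)
    if S_reduced.shape[0] != atom.rank:
        raise ValueError("reduced block row count does not match atom rank")
    if np.any(atom.sigma <= atom.sigma[0] * PINV_RTOL):
        import warnings

        warnings.warn("near-zero singular values; effective rank reduced")
    SV = np.diag(atom.sigma) @ atom.V.T      # r x d
    return np.linalg.pinv(SV, rcond=PINV_RTOL) @ S_reduced


def full_source_estimate(
    patches,
    S_blocks,
    K: sp.spmatrix,
    ranks=None,
    smooth_power_mode: str = "as_printed",
    q: int | None = None,
    t_start: float = 0.0,
    t_step: float = 1.0,
) -> SourceEstimate:
    """Scatter per-dipole patch courses onto the mesh and smooth.

    S_hat = sum_i K^{s_i} E_i Sdot_i, with s_i the patch's estimated rank
    ("as_printed") or the generative smoothing order q ("generative").
    Additive across patches.
    """
    if smooth_power_mode not in ("as_printed", "generative"):
        raise ValueError("smooth_power_mode must be 'as_printed' or 'generative'")
    if smooth_power_mode == "generative" and q is None:
        raise ValueError("generative mode requires the smoothing order q")
    patches = list(patches)
    S_blocks = [np.asarray(b, dtype=float) for b in S_blocks]
    if len(patches) != len(S_blocks):
        raise ValueError("one time-course block per patch required")
    k = K.shape[0]
    T = S_blocks[0].shape[1]
    out = np.zeros((k, T))
    for i, (patch, block) in enumerate(zip(patches, S_blocks)):
        p = patch.patch if isinstance(patch, PatchAtom) else patch
        if not isinstance(p, Patch):
            raise ValueError("patches must be Patch or PatchAtom objects")
        if p.members.max() >= k:
            raise ValueError("patch does not fit the smoothing mesh")
        if block.shape[0] != p.size:
            raise ValueError("block rows must equal the patch size")
        E = patch_basis(p.members, k)
        scattered = np.asarray(E @ block)
        if smooth_power_mode == "generative":
            power = int(q)
        else:
            if ranks is None:
                raise ValueError("as_printed mode requires per-patch ranks")
            power = int(ranks[i])
        for _ in range(power):
            scattered = K @ scattered
        out += scattered
    return SourceEstimate(data=out, t_start=t_start, t_step=t_step)


def estimate_amplitudes(
    result: LocalizationResult,
    Y: np.ndarray,
    K: sp.spmatrix,
    smooth_power_mode: str = "as_printed",
    q: int | None = None,
    t_start: float = 0.0,
    t_step: float = 1.0,
) -> SourceEstimate:
    """Full pipeline from a localization result to a mesh-level estimate."""
    atoms = result.atoms
    if not atoms:
        raise ValueError("localization result carries no atoms")
    U = np.hstack([a.U for a in atoms])
    reduced = reduced_timecourses(U, Y, ranks=[a.rank for a in atoms])
    blocks = [
        patch_timecourses(a, reduced.block(i)) for i, a in enumerate(atoms)
    ]
    return full_source_estimate(
        [a.patch for a in atoms],
        blocks,
        K,
        ranks=[a.rank for a in atoms],
        smooth_power_mode=smooth_power_mode,
        q=q,
        t_start=t_start,
        t_step=t_step,
    )
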