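"""Alternating-projection localization over the patch dictionary.

The estimator maximizes tr(Pi_{U(P,L)} C), the data-covariance energy
captured by the joint column space of the selected atoms' topographies,
over seeds P and extents L.  Alternating projections turn this N-source
problem into a sequence of single-source scans: with every other source's
topography fixed and projected out by Q, the winning atom maximizes

    tr( U' Q C Q U (U' Q U)^-1 ),

the oblique projection of C onto the atom's topography after removing the
fixed sources.  A greedy initialization pass (source n scanned with the
first n-1 already projected out) is followed by refinement sweeps in which
each source is re-scanned against all the others until no (seed, extent)
changes.  The classical single-dipole AP scanner is the special case of a
point dictionary (extent 0, rank 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import CandidateDictionary, PatchAtom

__all__ = [
    "DataCovariance",
    "LocalizationResult",
    "orthonormal_projector",
    "localizer_value",
    "scan_candidates",
    "patch_ap",
    "estimate_num_sources",
]

# relative cutoff on singular values when inverting U'QU
PINV_RTOL = 1e-12
# atoms whose projected topography QU has smallest singular value below this
# (relative to ||U|| = 1) are excluded from that scan step
EXCLUDE_TOL = 1e-8


@dataclass(frozen=True)
class DataCovariance:
    """C = Y Y', the localizer's sufficient statistic."""

    C: np.ndarray
    sample_count: int = 0

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(C, C.T, atol=1e-8 * max(1.0, np.abs(C).max())):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "C", 0.5 * (C + C.T))

    @classmethod
    def from_data(cls, Y: np.ndarray) -> "DataCovariance":
        Y = np.asarray(Y, dtype=float)
        return cls(C=Y @ Y.T, sample_count=Y.shape[1])


@dataclass
class LocalizationResult:
    """Estimated seeds/extents/ranks plus the objective trace of the fit."""

    seeds: list
    extents: list
    ranks: list
    objective_trace: list
    sweeps_used: int
    converged: bool
    atoms: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "seeds": [int(s) for s in self.seeds],
            "extents": [int(l) for l in self.extents],
            "ranks": [int(r) for r in self.ranks],
            "objective_trace": [float(v) for v in self.objective_trace],
            "sweeps_used": int(self.sweeps_used),
            "converged": bool(self.converged),
        }


def orthonormal_projector(M: np.ndarray | None):
    """Orthogonal projector onto span(M) and its complement.

    Returns (Pi, Q) with Pi = M (M'M)^+ M' computed through an SVD
    orthonormalization (rank-deficient M falls back to the pseudo-inverse
    cutoff) and Q = I - Pi.  M with zero columns gives Pi = 0, Q = I.
    """
    if M is None or M.size == 0 or M.shape[1] == 0:
        m = 0 if M is None else M.shape[0]
        if m == 0:
            raise ValueError("cannot build a projector without row dimension")
        return np.zeros((m, m)), np.eye(m)
    M = np.asarray(M, dtype=float)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    keep = s > s[0] * PINV_RTOL if s.size else np.zeros(0, dtype=bool)
    B = U[:, keep]
    Pi = B @ B.T
    return Pi, np.eye(M.shape[0]) - Pi


def localizer_value(atom: PatchAtom, Q: np.ndarray, C: np.ndarray) -> float:
    """tr( U'QCQU (U'QU)^-1 ) for a single atom; equals tr(Pi_{QU} C)."""
    U = atom.U if isinstance(atom, PatchAtom) else np.asarray(atom)
    W = Q @ U
    smin = np.linalg.svd(W, compute_uv=False)[-1]
    if smin < EXCLUDE_TOL:
        raise np.linalg.LinAlgError(
            "atom lies in the span of the fixed sources"
        )
    G = W.T @ W          # = U'QU for idempotent Q
    Mnum = W.T @ C @ W
    return float(np.trace(np.linalg.solve(G, Mnum)))


def _scan_group(r: int, U_stack: np.ndarray, Q: np.ndarray, C: np.ndarray):
    """Vectorized localizer values for all atoms of one rank; NaN = excluded."""
    n, m, _ = U_stack.shape
    Um = U_stack.transpose(1, 0, 2).reshape(m, n * r)
    W = (Q @ Um).reshape(m, n, r)
    CW = (C @ W.reshape(m, n * r)).reshape(m, n, r)
    G = np.einsum("mnr,mns->nrs", W, W)
    Mn = np.einsum("mnr,mns->nrs", W, CW)
    if r == 1:
        g = G[:, 0, 0]
        vals = np.full(n, np.nan)
        ok = np.sqrt(np.maximum(g, 0.0)) >= EXCLUDE_TOL
        vals[ok] = Mn[ok, 0, 0] / g[ok]
        return vals
    if r == 2:
        g00, g01, g11 = G[:, 0, 0], G[:, 0, 1], G[:, 1, 1]
        det = g00 * g11 - g01**2
        trG = g00 + g11
        disc = np.sqrt(np.maximum(trG**2 - 4.0 * det, 0.0))
        smin = np.sqrt(np.maximum(0.5 * (trG - disc), 0.0))
        ok = smin >= EXCLUDE_TOL
        vals = np.full(n, np.nan)
        num = (
            g11[ok] * Mn[ok, 0, 0]
            + g00[ok] * Mn[ok, 1, 1]
            - g01[ok] * (Mn[ok, 0, 1] + Mn[ok, 1, 0])
        )
        vals[ok] = num / det[ok]
        return vals
    # ranks > 2 are not produced by the standard rules; loop fallback
    vals = np.full(n, np.nan)
    for i in range(n):
        Wi = W[:, i, :]
        if np.linalg.svd(Wi, compute_uv=False)[-1] < EXCLUDE_TOL:
            continue
        vals[i] = np.trace(np.linalg.solve(Wi.T @ Wi, Wi.T @ C @ Wi))
    return vals


def scan_candidates(
    Q: np.ndarray, C: np.ndarray, dictionary: CandidateDictionary
):
    """Best atom over the dictionary: returns ((seed, extent), value).

    Ties are broken toward the smaller extent, then the smaller seed index.
    Atoms whose projected topography is numerically inside the fixed
    sources' span are excluded for this step.
    """
    if len(dictionary) == 0:
        raise ValueError("empty dictionary")
    all_keys, all_vals = [], []
    for r, keys, U_stack in dictionary.scan_groups():
        all_keys.extend(keys)
        all_vals.append(_scan_group(r, U_stack, Q, C))
    vals = np.concatenate(all_vals)
    if np.all(np.isnan(vals)):
        raise ValueError("all atoms excluded from this scan step")
    seeds = np.array([k[0] for k in all_keys])
    extents = np.array([k[1] for k in all_keys])
    vals_for_sort = np.where(np.isnan(vals), -np.inf, vals)
    best = np.lexsort((seeds, extents, -vals_for_sort))[0]
    return (int(seeds[best]), int(extents[best])), float(vals[best])


def _objective(atoms: list, C: np.ndarray) -> float:
    """tr(Pi_{[U_1 ... U_N]} C) for the current atom selection."""
    U = np.hstack([a.U for a in atoms])
    Pi, _ = orthonormal_projector(U)
    return float(np.trace(Pi @ C))


def patch_ap(
    C,
    dictionary: CandidateDictionary,
    n_sources: int,
    max_sweeps: int = 15,
    tol: float = 0.0,
) -> LocalizationResult:
    """Alternating-projection fit of ``n_sources`` patches to a covariance.

    Phase 1 initializes greedily: source n is scanned with sources
    1..n-1 projected out.  Phase 2 sweeps over sources, re-scanning each
    against all current others, until a sweep changes no (seed, extent) or
    ``max_sweeps`` is reached.  The captured-energy objective tr(Pi C) is
    nondecreasing across updates because each scan solves its single-source
    subproblem exactly and the incumbent atom is among the candidates.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    cov = C if isinstance(C, DataCovariance) else DataCovariance(C=np.asarray(C))
    Cm = cov.C
    eigmin = np.linalg.eigvalsh(Cm)[0]
    if eigmin < -1e-8 * max(1.0, np.abs(Cm).max()):
        raise ValueError("covariance is not positive semidefinite")
    total_rank_available = sum(a.rank for a in dictionary)
    if n_sources > len(dictionary) or n_sources * 1 > total_rank_available:
        raise ValueError("more sources requested than the dictionary supports")

    trace: list[float] = []
    found: list[tuple[int, int]] = []

    # Phase 1: greedy initialization; not-yet-estimated sources are absent
    for _ in range(n_sources):
        fixed = [dictionary.atom(*key) for key in found]
        if fixed:
            _, Q = orthonormal_projector(np.hstack([a.U for a in fixed]))
        else:
            Q = np.eye(Cm.shape[0])
        try:
            key, _ = scan_candidates(Q, Cm, dictionary)
        except ValueError:
            if not found:
                raise
            import warnings

            warnings.warn(
                f"degenerate fit: only {len(found)} of {n_sources} requested "
                "sources have independent topographies; truncating"
            )
            n_sources = len(found)
            break
        found.append(key)
        trace.append(_objective([dictionary.atom(*k) for k in found], Cm))

    # Phase 2: refinement sweeps
    converged = False
    sweeps = 0
    for _ in range(max_sweeps):
        sweeps += 1
        changed = False
        for n in range(n_sources):
            others = [dictionary.atom(*k) for i, k in enumerate(found) if i != n]
            if others:
                _, Q = orthonormal_projector(np.hstack([a.U for a in others]))
            else:
                Q = np.eye(Cm.shape[0])
            key, _ = scan_candidates(Q, Cm, dictionary)
            if key != found[n]:
                found[n] = key
                changed = True
            trace.append(_objective([dictionary.atom(*k) for k in found], Cm))
        if not changed:
            converged = True
            break
        if tol > 0 and len(trace) > n_sources and (
            trace[-1] - trace[-1 - n_sources] <= tol
        ):
            converged = True
            break

    atoms = [dictionary.atom(*k) for k in found]
    return LocalizationResult(
        seeds=[k[0] for k in found],
        extents=[k[1] for k in found],
        ranks=[a.rank for a in atoms],
        objective_trace=trace,
        sweeps_used=sweeps,
        converged=converged,
        atoms=atoms,
    )


def estimate_num_sources(C, threshold: float = 0.95) -> int:
    """Smallest N whose top-N eigenvalues reach ``threshold`` of the total.

    The 95% cumulative-eigenvalue heuristic used to pick the number of
    sources when it is not known a priori.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    Cm = C.C if isinstance(C, DataCovariance) else np.asarray(C, dtype=float)
    eig = np.linalg.eigvalsh(Cm)[::-1]
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    if total <= 0.0:
        raise ValueError("covariance has no energy")
    if threshold == 1.0:
        return int(np.count_nonzero(eig > eig[0] * 1e-12))
    frac = np.cumsum(eig) / total
    return int(np.searchsorted(frac, threshold - 1e-15) + 1)
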