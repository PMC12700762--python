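"""Canonical Monte-Carlo experiments on the synthetic head.

These are the package's reference study conditions, scaled down from the
original-scale protocol (500 trials on 5124/8196-dipole BEM meshes) to run
on one CPU in minutes: the rank-2 energy survey uses 100 random patches on
the default 642/2562-vertex head; the method-ordering experiment uses 50
trials on a 162/642-vertex head.  Problem sizes are stated in
docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .dictionary import SmoothingSpec, cumulative_energy_profile, smoothed_leadfield
from .simulate import NoiseSpec, SimulationConfig, make_synthetic_head, simulate_trial
from .workflow import METHODS, localize_trial

__all__ = ["rank2_energy_experiment", "ordering_experiment"]


def rank2_energy_experiment(
    seed: int,
    n_patches: int = 100,
    levels=(3, 4),
    m: int = 128,
    alpha: float = 0.15,
    q: int = 2,
    l_max: int = 5,
) -> dict:
    """Mean cumulative squared-singular-value energy at two components of
    smoothed patch leadfields, over random seeds x extents 0..l_max.

    Returns {"mean_energy_pct", "per_extent_pct", "n"} with n the number of
    (patch, extent) pairs surveyed.  The survey runs on the inversion
    (dictionary) mesh of the synthetic head.
    """
    head = make_synthetic_head(levels=levels, m=m, seed=seed)
    mesh = head.mesh_inv
    K = mesh.smoothing_operator(alpha)
    Aq = smoothed_leadfield(head.A_inv, K, q)
    rng = np.random.default_rng(seed)
    seeds = rng.choice(mesh.n_vertices, size=n_patches, replace=False)
    values = []
    per_extent = {l: [] for l in range(l_max + 1)}
    for s in seeds:
        for l in range(l_max + 1):
            patch = mesh.patch(int(s), l)
            profile = cumulative_energy_profile(Aq[:, patch.members])
            v = float(profile[min(1, profile.size - 1)])
            values.append(v)
            per_extent[l].append(v)
    return {
        "mean_energy_pct": 100.0 * float(np.mean(values)),
        "per_extent_pct": {l: 100.0 * float(np.mean(v))
                           for l, v in per_extent.items()},
        "n": len(values),
    }


def ordering_experiment(
    seed: int,
    n_trials: int = 50,
    levels=(2, 3),
    m: int = 128,
    snr_db: float = 0.0,
    rho: float = 0.5,
    q: int = 2,
    extent: int = 2,
    rank: int = 2,
    samples: int = 200,
    l_max: int = 5,
    methods=METHODS,
) -> dict:
    """Mean EMD per method for one rank-2 extended source.

    The headline comparison: a single rank-``rank`` patch of the given
    extent at the given SNR, localized by the patch scanner, its rank-1
    (flex) and point-dipole reductions, and the ridge minimum norm.
    Returns {"mean_emd_mm": {method: mm}, "n": n_trials}.
    """
    head = make_synthetic_head(levels=levels, m=m, seed=seed)
    results = {method: [] for method in methods}
    ss = np.random.SeedSequence(seed)
    trial_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_trials)]
    for trial_seed in trial_seeds:
        config = SimulationConfig(
            n_sources=1, extents=(extent,), ranks=(rank,), rho=rho,
            snr_db=snr_db, smooth_order=q, noise=NoiseSpec(),
            samples=samples, channels=m, seed=trial_seed,
        )
        Y, truth = simulate_trial(config, head)
        for method in methods:
            results[method].append(
                localize_trial(Y, truth, head, method, config, l_max=l_max)
            )
    return {
        "mean_emd_mm": {method: float(np.mean(v)) for method, v in results.items()},
        "n": n_trials,
    }
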