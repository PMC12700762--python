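"""End-to-end orchestration: simulate -> localize -> evaluate -> sweep.

Every entry point is a pure function of its configuration and master seed;
per-trial seeds are derived deterministically, so whole experiments are
bit-reproducible.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .amplitudes import estimate_amplitudes
from .dictionary import SmoothingSpec, build_dictionary
from .evaluation import (
    choose_ridge_gcv,
    emd,
    minimum_norm_baseline,
    source_distribution,
)
from .localize import DataCovariance, estimate_num_sources, patch_ap
from .mesh import TriangleMesh
from .simulate import (
    NoiseSpec,
    SimulationConfig,
    SyntheticHead,
    make_synthetic_head,
    simulate_trial,
)

logger = logging.getLogger("patchap")

__all__ = ["RunConfig", "run_localize", "run_sweep", "simulate_to_dir",
            "localize_trial", "METHODS"]

#: inversion variants compared in sweeps: the patch scanner, its rank-1
#: ("flex") and point-dipole ("ap") reductions, and the ridge minimum norm
METHODS = ("patch_ap", "flex_ap", "ap", "mne")


@dataclass
class RunConfig:
    """Parameters of one localization run on data from disk."""

    leadfield_file: str
    data_file: str
    mesh_vertices_file: str
    mesh_faces_file: str
    alpha: float = 0.15
    q: int = 2
    l_max: int = 5
    rank_mode: str = "patch"
    n_sources: int | None = None
    num_sources_threshold: float = 0.95
    max_sweeps: int = 15
    smooth_power_mode: str = "as_printed"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**io.load_yaml(path))


def run_localize(config: RunConfig, out_dir) -> dict:
    """Localize + reconstruct amplitudes; writes result JSON and the
    full-mesh estimate next to a log of every parameter used."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("leadfield_file", "data_file", "mesh_vertices_file",
                 "mesh_faces_file"):
        if not Path(getattr(config, name)).exists():
            raise FileNotFoundError(f"{name}: {getattr(config, name)}")
    A = io.load_matrix_tsv(config.leadfield_file)
    Y = io.load_matrix_tsv(config.data_file)
    mesh = io.load_mesh_tsv(config.mesh_vertices_file, config.mesh_faces_file)
    if A.shape[1] != mesh.n_vertices:
        raise ValueError(
            f"leadfield_file has {A.shape[1]} columns for a "
            f"{mesh.n_vertices}-vertex mesh"
        )
    if A.shape[0] != Y.shape[0]:
        raise ValueError("leadfield_file and data_file channel counts differ")

    label = "AP" if (config.rank_mode == "point" and config.l_max == 0) else "PATCH-AP"
    cov = DataCovariance.from_data(Y)
    n_sources = config.n_sources
    auto_n = n_sources is None
    if auto_n:
        n_sources = estimate_num_sources(cov, config.num_sources_threshold)
        logger.info("n_sources auto-estimated as %d (threshold %.2f)",
                    n_sources, config.num_sources_threshold)
    smoothing = SmoothingSpec(alpha=config.alpha, order=config.q)
    dictionary = build_dictionary(A, mesh, smoothing, config.l_max,
                                  config.rank_mode)
    result = patch_ap(cov, dictionary, n_sources, max_sweeps=config.max_sweeps)
    K = mesh.smoothing_operator(config.alpha)
    estimate = estimate_amplitudes(
        result, Y, K, smooth_power_mode=config.smooth_power_mode, q=config.q
    )
    payload = result.to_dict()
    payload["n_sources_auto"] = auto_n
    payload["method"] = label
    payload["parameters"] = {
        "alpha": config.alpha, "q": config.q, "l_max": config.l_max,
        "rank_mode": config.rank_mode, "max_sweeps": config.max_sweeps,
        "smooth_power_mode": config.smooth_power_mode,
        "n_sources": int(n_sources), "seed": config.seed,
    }
    io.save_json(payload, out / "result.json")
    io.save_matrix_tsv(
        estimate.data, out / "estimate.tsv",
        sidecar={"mesh_vertices": str(config.mesh_vertices_file),
                 "t_start": estimate.t_start, "t_step": estimate.t_step,
                 "units": "arbitrary"},
    )
    logger.info("%s run: %s", label, payload["parameters"])
    return payload


def simulate_to_dir(config: SimulationConfig, head: SyntheticHead, out_dir) -> None:
    """Write one simulated trial (meshes, leadfields, data, truth) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Y, truth = simulate_trial(config, head)
    io.save_mesh_tsv(head.mesh_sim, out / "mesh_sim_vertices.tsv",
                     out / "mesh_sim_faces.tsv")
    io.save_mesh_tsv(head.mesh_inv, out / "mesh_inv_vertices.tsv",
                     out / "mesh_inv_faces.tsv")
    io.save_matrix_tsv(head.A_sim, out / "leadfield_sim.tsv",
                       sidecar={"channels": head.A_sim.shape[0],
                                "sources": head.A_sim.shape[1],
                                "units": "normalized"})
    io.save_matrix_tsv(head.A_inv, out / "leadfield_inv.tsv",
                       sidecar={"channels": head.A_inv.shape[0],
                                "sources": head.A_inv.shape[1],
                                "units": "normalized"})
    io.save_matrix_tsv(Y, out / "sensor_data.tsv")
    io.save_matrix_tsv(truth.S, out / "source_matrix.tsv")
    io.save_json(
        {
            "seeds": [int(p.seed) for p in truth.patches],
            "extents": [int(p.extent) for p in truth.patches],
            "ranks": list(config.ranks),
            "rho": config.rho,
            "snr_db": config.snr_db,
            "realized_snr_db": truth.realized_snr_db,
            "noise": {"kind": config.noise.kind, "gamma": config.noise.gamma},
            "smooth_order": config.smooth_order,
            "alpha": config.alpha,
            "seed": config.seed,
        },
        out / "ground_truth.json",
    )


def localize_trial(Y, truth, head: SyntheticHead, method: str,
                   config: SimulationConfig, l_max: int = 5,
                   max_sweeps: int = 15):
    """Invert one simulated trial with one method; returns its EMD in mm."""
    truth_dist = source_distribution(truth.S, head.mesh_sim.vertices)
    n = config.n_sources
    if method == "mne":
        lam = choose_ridge_gcv(head.A_inv, Y)
        est = minimum_norm_baseline(head.A_inv, Y, lam)
    else:
        rank_mode = {"patch_ap": "patch", "flex_ap": "flex", "ap": "point"}[method]
        mode_lmax = 0 if method == "ap" else l_max
        # classical AP scans the raw leadfield columns: no smoothing
        order = 0 if method == "ap" else config.smooth_order
        smoothing = SmoothingSpec(alpha=config.alpha, order=order)
        dictionary = build_dictionary(head.A_inv, head.mesh_inv, smoothing,
                                      mode_lmax, rank_mode)
        cov = DataCovariance.from_data(Y)
        result = patch_ap(cov, dictionary, n, max_sweeps=max_sweeps)
        K_inv = head.mesh_inv.smoothing_operator(config.alpha)
        est = estimate_amplitudes(result, Y, K_inv, q=config.smooth_order).data
    est_dist = source_distribution(est, head.mesh_inv.vertices)
    return emd(truth_dist, est_dist)


def _trial_seed(master_seed: int, trial_index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(trial_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(experiment: dict, out_path=None) -> pd.DataFrame:
    """Monte-Carlo grid sweep; returns (and optionally writes) a tidy table.

    ``experiment`` keys: snr_db, rho, q, noise (list of {kind, gamma}),
    rank_combos (list of rank lists), extents (per-combo extents, optional,
    default 2 each), n_reps, seed, levels, channels, samples, methods,
    l_max.  Each trial row records the per-method EMD and runtime.
    """
    grid = {
        "snr_db": experiment.get("snr_db", [0.0]),
        "rho": experiment.get("rho", [0.5]),
        "q": experiment.get("q", [2]),
        "noise": experiment.get("noise", [{"kind": "white", "gamma": 0.0}]),
        "rank_combo": experiment.get("rank_combos", [[2]]),
    }
    n_reps = int(experiment.get("n_reps", 50))
    master_seed = int(experiment["seed"])
    levels = tuple(experiment.get("levels", (2, 3)))
    channels = int(experiment.get("channels", 128))
    samples = int(experiment.get("samples", 200))
    methods = list(experiment.get("methods", METHODS))
    l_max = int(experiment.get("l_max", 5))
    max_sweeps = int(experiment.get("max_sweeps", 15))
    default_extent = int(experiment.get("extent", 2))

    head = make_synthetic_head(levels=levels, m=channels, seed=master_seed)
    rows = []
    trial_index = 0
    for snr_db, rho, q, noise, ranks in itertools.product(
        grid["snr_db"], grid["rho"], grid["q"], grid["noise"],
        grid["rank_combo"],
    ):
        for rep in range(n_reps):
            seed = _trial_seed(master_seed, trial_index)
            trial_index += 1
            config = SimulationConfig(
                n_sources=len(ranks),
                extents=tuple([default_extent] * len(ranks)),
                ranks=tuple(ranks),
                rho=float(rho),
                snr_db=float(snr_db),
                smooth_order=int(q),
                noise=NoiseSpec(kind=noise["kind"],
                                gamma=float(noise.get("gamma", 0.0))),
                samples=samples,
                channels=channels,
                seed=seed,
            )
            try:
                Y, truth = simulate_trial(config, head)
            except RuntimeError as exc:  # non-placeable patches: flag row
                for method in methods:
                    rows.append({
                        "trial": trial_index - 1, "rep": rep, "method": method,
                        "snr_db": snr_db, "rho": rho, "q": q,
                        "noise": noise["kind"],
                        "rank_combo": ",".join(map(str, ranks)),
                        "emd_mm": np.nan, "runtime_s": np.nan,
                        "error": str(exc),
                    })
                continue
            for method in methods:
                start = time.perf_counter()
                value = localize_trial(Y, truth, head, method, config,
                                       l_max=l_max, max_sweeps=max_sweeps)
                rows.append({
                    "trial": trial_index - 1, "rep": rep, "method": method,
                    "snr_db": snr_db, "rho": rho, "q": q,
                    "noise": noise["kind"],
                    "rank_combo": ",".join(map(str, ranks)),
                    "emd_mm": value,
                    "runtime_s": time.perf_counter() - start,
                    "error": "",
                })
    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table
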