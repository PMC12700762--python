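# patchap

Patch-based alternating-projection source localization for MEG/EEG.

## The problem

M/EEG source imaging must recover where on the cortex neural activity
originated from a handful of sensor channels. Dipole-fitting scanners
(MUSIC, RAP-MUSIC, alternating projections) model activity as a few point
dipoles and miss spatially extended sources; distributed imaging (minimum
norm, sLORETA) smears focal sources across the surface. Real cortical
patches sit in between: spatially extended, locally coherent, but not
fully coherent — their activity is well described by a *low-rank* patch
model rather than by a single dipole or a rank-1 patch.

`patchap` implements a patch-based alternating-projection scanner
(PATCH-AP) that localizes both focal and extended sources. Candidate
sources are patches (seed vertex `p`, graph-distance extent `l`) on a
triangulated source space. Each candidate's leadfield is spatially
smoothed by a graph diffusion operator and compressed to low rank:

    K = I − αL,          L = D − A   (combinatorial mesh Laplacian)
    g(p,l) = A_gain K^q E(p,l),      g ≈ U Σ Vᵀ   (rank r: 1 if l=0, else 2)

With `C = Y Yᵀ` the data covariance, sources are found by maximizing the
covariance energy captured by the selected atoms' topographies,

    max_{P,L}  tr( Π_{U(P,L)} C ),

via alternating projections: each source is re-scanned in turn with all
others projected out by `Q = I − Π_others`, using the localizer

    (p̂,l̂) = argmax  tr( UᵀQCQU (UᵀQU)⁻¹ ),

with a greedy initialization pass followed by refinement sweeps. Classical
single-dipole AP is the special case `l = 0`, rank 1, no smoothing.
Amplitudes are then reconstructed by least squares on the selected
topographies and scattered back to the mesh through the patch bases and
the diffusion smoother.

The package also ships everything needed to study the method end to end
without external data: a synthetic dual-resolution spherical head
(distinct simulation/inversion forward models, avoiding the inverse
crime), patch sources with controlled extent/rank/inter-source
correlation/SNR, white and colored sensor noise, an exact Earth Mover's
Distance (EMD) metric in millimeters, a hemispheric symmetry correlation,
and a ridge minimum-norm baseline.

## Worked example

```python
from patchap import (make_synthetic_head, SimulationConfig, simulate_trial,
                     build_dictionary, SmoothingSpec, DataCovariance, patch_ap,
                     estimate_amplitudes, source_distribution, emd)

head = make_synthetic_head(levels=(2, 3), m=128, seed=1)   # 162 / 642 vertices
config = SimulationConfig(n_sources=2, extents=(2, 2), ranks=(1, 2),
                          rho=0.5, snr_db=0.0, samples=200, seed=1)
Y, truth = simulate_trial(config, head)

dictionary = build_dictionary(head.A_inv, head.mesh_inv,
                              SmoothingSpec(alpha=0.15, order=2), l_max=5)
result = patch_ap(DataCovariance.from_data(Y), dictionary, n_sources=2)
print(result.seeds, result.extents, result.ranks, result.sweeps_used)

K = head.mesh_inv.smoothing_operator(0.15)
estimate = estimate_amplitudes(result, Y, K, q=2)
score = emd(source_distribution(truth.S, head.mesh_sim.vertices),
            source_distribution(estimate.data, head.mesh_inv.vertices))
print(f"EMD vs ground truth: {score:.1f} mm")
```

Output:

```
true seeds/extents: [(61, 2), (141, 2)] realized SNR -0.00 dB
estimated seeds: [597, 548] extents: [5, 5] ranks: [2, 2] (converged in 2 sweeps)
EMD vs ground truth: 20.4 mm
```

The two patches are simulated on the 162-vertex mesh and localized on the
642-vertex mesh (vertex spacing ≈ 15–30 mm on a 100 mm sphere), so the
estimated seeds land 14–16 mm from the true ones — about one mesh edge —
and the EMD of ~20 mm reflects both that displacement and the spatial
spread of the reconstructed patches at 0 dB SNR.

A command-line interface covers the same workflow on files:

```sh
patchap simulate --config sim.yaml --out trial/
patchap localize --config run.yaml --out fit/
patchap evaluate --truth trial/ --estimate fit/ --out metrics.json
patchap sweep    --config experiment.yaml --out results.tsv
```

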