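# Methods

## Source model

The source space is a triangulated surface with `k` vertices (candidate
fixed-orientation dipoles, coordinates in mm). Spatial structure enters
only through the vertex-adjacency graph: `A` (binary adjacency), `D`
(degree), the combinatorial Laplacian `L = D − A`, and the diffusion
smoother `K = I − αL`. A patch is a seed vertex plus all vertices within
`l` graph hops (`l = 0` is a point source); members are ordered by
(hop distance, vertex index) so every downstream factorization is
reproducible. Extent is deliberately combinatorial (BFS hops, not metric
radius): the smoothing and basis machinery is purely graph-based, and
physical patch areas are mesh-dependent. `TriangleMesh.patch_area_mm2`
reports areas but no calibration from hops to cm² is attempted.

A candidate atom is the smoothed patch leadfield `g(p,l) = A_gain K^q E`
with its truncated SVD. The rank rule — 1 for points, 2 for extended
patches — rests on an empirical property of realistic gain matrices:
after order-2 smoothing, two singular components capture ≥ 95% of the
squared singular-value energy of patch leadfields up to extent 5 (the
acceptance survey measures 97.2% on the default synthetic head, n = 600
patch×extent pairs). `rank_mode` exposes the fully-coherent rank-1
variant ("flex") and the point-dipole variant ("point") as reductions;
the point dictionary with `q = 0` reproduces classical AP exactly, which
the tests verify against an independent implementation.

## Localizer

With `C = Y Yᵀ` (unwhitened; the simulations use no whitening and a
pre-whitening hook can be applied to `Y` upstream), the fit maximizes
`tr(Π_{U(P,L)} C)`. Alternating projections: greedy initialization
(source n scanned with sources 1..n−1 projected out; later sources are
simply absent from the fixed set), then refinement sweeps until no
(seed, extent) changes, capped at `max_sweeps = 15` (observed: ≤ 3).
Each scan is exact for its single-source subproblem and the incumbent
atom is always among the candidates, so the objective is nondecreasing —
asserted over 100 noisy runs in the tests.

Numerical choices: projectors are built by SVD orthonormalization with a
relative cutoff of 1e−12; atoms whose projected topography `QU` has
smallest singular value below 1e−8 (topographies are unit-normalized) are
excluded from that scan step, since their localizer value is dominated by
round-off. Ties are broken toward smaller extent, then smaller seed index
(parsimony). Scans are vectorized over atoms with closed-form 1×1 and 2×2
solves. If fewer than the requested number of sources have numerically
independent topographies, the fit truncates with a degenerate-fit warning
rather than failing. `estimate_num_sources` implements the 95%
cumulative-eigenvalue heuristic; note that on raw noisy covariances it
counts noise dimensions too, so it is most meaningful on averaged or
whitened data.

The smoothing default is `α = 0.15`, `q = 2`, `l_max = 5`. `α` must stay
below `1/max_degree` (1/6 on icosphere meshes) for `K` to be a proper
nonnegative averaging operator with spectral radius ≤ 1; 0.15 is chosen
close to that stability limit so each application diffuses strongly.
Larger `α` values are accepted by the API (the model only requires
`0 < α < 1`) but act as sharpeners on degree-6 graphs and are not
recommended.

## Amplitude reconstruction

Reduced activations are the least-squares fit `S̈ = (UᵀU)⁻¹UᵀY` on the
concatenated topographies; per-dipole patch courses apply the
pseudo-inverse of `diag(σ)Vᵀ` blockwise; the mesh-level estimate is
`Ŝ = Σᵢ K^{sᵢ} Eᵢ Ṡᵢ`. The exponent `sᵢ` is configurable because the two
natural choices disagree in general: the patch model generates sources
with `K^q`, while the reconstruction operator is specified per estimated
rank `r̂ᵢ`. `smooth_power_mode="as_printed"` (default) uses `r̂ᵢ`;
`"generative"` uses `q`. Under the defaults (`q = 2`, rank-2 patches) the
two coincide for extended sources. Both are kept because neither is
uniquely implied by the model; no attempt is made to adjudicate.

## Synthetic data generator

The synthetic head is a pair of nested icospheres (radius 100 mm):
default subdivision levels (3, 4) = 642/2562 vertices, with the coarse
mesh used for simulation and the fine mesh for inversion so that the two
forward models differ (inverse-crime mitigation). The gain field is a
smooth random field shared by both meshes: an m×384 standard-normal
coefficient matrix applied to von-Mises–Fisher kernel features
(concentration κ = 6) evaluated at the vertices, then smoothed per mesh
by `K³` (α = 0.15) and column-normalized. κ = 6 makes the field's angular
correlation scale exceed the diameter of an extent-5 patch — the defining
property of real far-field leadfields, whose columns at neighboring
vertices are strongly correlated — while keeping the global effective
rank of the leadfield comparable to real 128-channel arrays. Because the
two meshes smooth the shared field differently, coarse topographies are
approximated, not contained, in the fine dictionary (tested: nearest-
column dot products in (0.9, 1)).

Sources: disjoint random patches (overlap is redrawn, capped); base time
courses are unit-variance Gaussian white processes (the localizer sees
only `C`, so the waveform family is immaterial; a windowed sinusoid can
be substituted for demos) mixed to pairwise correlation ρ by the Cholesky
factor of `ρ11ᵀ + (1−ρ)I`. Within a rank-r patch, local courses are
`W Z` with `Z` row 1 the correlated base course, rows 2..r independent
processes, and `W` a random unit-row mixing matrix — one admissible
choice for "rank-r patch activity"; only the first component carries the
inter-source correlation. The full source matrix is `S = K^q E Ṡ`.
Sensor data add white or colored noise (diagonal, banded, or
exponentially decaying `γ^|i−j|` channel covariance, each normalized to
unit mean diagonal so γ shifts structure, not power), globally rescaled
so the realized SNR matches the target exactly.

What the generator does *not* emulate: realistic BEM/FEM head
conductivity, sensor geometry, cortical folding and orientation
constraints, trial/epoch structure, or non-Gaussian artifacts. Passing
tests therefore demonstrate the method's behavior under its own model
assumptions plus forward-model mismatch from the dual meshes — not
performance on real recordings, for which a measured leadfield can be
supplied through the standard matrix formats.

## Evaluation

Estimates are reduced to unit-mass spatial distributions (per-vertex RMS
over the analysis window, zero-clipped, normalized; a single-sample mode
exists). EMD between distributions — possibly supported on different
meshes, compared directly in their shared embedding without resampling —
is the exact optimal-transport cost in mm (computed through
`scipy.stats.wasserstein_distance_nd`; tests cross-check an explicit
transportation LP). The symmetry correlation is the Pearson correlation
of the two hemispheres' mean absolute activity courses (NaN when a
hemisphere is silent); synthetic hemispheres are labeled by the sign of
the x-coordinate, and labels are an input for real meshes. The
minimum-norm baseline is `Aᵀ(AAᵀ + λI)⁻¹Y` with λ selected by GCV over a
10-point logarithmic grid.

Leadfield columns are not norm-equalized before dictionary construction
(the model uses the gain matrix as-is); on real leadfields this may bias
the scan toward superficial sources, and depth weighting is out of scope.

## Problem sizes and defaults

Scaled-down study conditions (the package's defaults, chosen so every
suite runs on one CPU in minutes): rank-2 energy survey — 100 patches ×
extents 0–5 on the 642/2562-vertex head; Monte-Carlo ordering experiment —
50 trials, one rank-2 extent-2 source, 0 dB SNR, ρ = 0.5, q = 2, on the
162/642-vertex head, comparing the patch scanner, flex, point (classical
AP, unsmoothed) and the GCV minimum norm; oracle-equivalence and
AP-reduction checks — 42-vertex meshes where brute force is exact;
monotonicity — 100 noisy two-source runs. Default simulation: 128
channels, 200 samples, white noise. All experiments are pure functions of
a single integer seed (per-trial seeds derived via `SeedSequence`).

## Known limitations

- Patch rank is capped at 2 in the scan; higher-rank activity is
  approximated and stress-test generators allow rank ≤ 3 to probe this.
- The greedy + refinement scheme guarantees monotone objective ascent,
  not global optimality; with very coarse meshes and two focal sources a
  single straddling extended atom can trap the refinement (visible in
  tests only below ~200 vertices).
- The 95% eigenvalue source-count heuristic over-counts on raw noisy
  covariances.
- EMD cost grows with support sizes (an exact LP); full-mesh estimates on
  meshes ≳ 10⁴ vertices should be thresholded first.
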