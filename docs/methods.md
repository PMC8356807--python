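# Methods

This note records the model implemented by `wmdss`, the choices made
where the design was genuinely open, and what the synthetic validation
does and does not establish.

## ODF model

A diffusion ODF is a nonnegative, antipodally symmetric function on the
unit sphere per voxel. Two representations are supported.

*Analytic fields* (`wmdss.odf.AnalyticODFField`) are sums of Watson-like
lobes `w · exp(κ((â·r̂)² − 1))` plus an isotropic floor. Each lobe is
normalized to peak value `w` on its axis, is antipodally symmetric by
construction, and its concentration κ sets the angular width. The
default κ = 5 gives an angular FWHM of ≈45°, matching the sharpness of a
typical single-fiber *diffusion ODF* (which is broad, with modest
peak-to-trough contrast) rather than a fiber orientation density (FOD),
which would be far sharper. The floor under a fiber lobe is 0.1 of the
lobe peak. Because the edge-weight normalization is scale-invariant per
voxel, only these *ratios* matter; absolute ODF normalization (e.g.
whether an upstream reconstruction min-subtracts) is absorbed.

*Tabulated fields* hold per-voxel samples over a fixed direction set
(4D NIfTI + plain-text direction file). Evaluation uses the projective
angular distance (so antipodal symmetry is automatic) with either
nearest-direction lookup or Shepard inverse-angular-distance weights
over the 3 closest tabulated directions; an exact hit returns the
stored sample under both schemes. The 3-neighbor support is the smallest
that brackets a query direction inside a spherical triangle of the
sampling mesh.

## Graph construction

Vertices are mask voxels; edges follow the 3-conn (26 offsets) or
pruned 5-conn (98 offsets) lattice neighborhood, the latter excluding
outer-layer offsets collinear with inner ones since they duplicate an
orientation already represented.

The directed measure toward each neighbor is the mean of the voxel's
ODF over the spherical cap of solid angle Ω = 4π/|N| around the
neighbor direction (half-angle arccos(1 − Ω/2π): 22.62° for 3-conn,
11.59° for 5-conn). Cone means are sampled by intersecting a level-4
icosphere (2562 near-uniform directions) with the cap; the cap's
expected sample count is ≈26 and the sampled mean agrees with dense
numerical integration of the cap integral to better than 2% (verified
in the tests). If a cap captured no dense sample, the center direction
itself would be used (cannot occur at the default resolution).

Per voxel, cone means are normalized as q = p̃ / (2·max p̃) over the
*existing* neighbors, so q ∈ [0, 0.5] with the argmax neighbor at
exactly 0.5; boundary voxels normalize over their available neighbors.
A voxel whose cone means are all zero is treated as isotropic in the
limit (q = 0.5 to all neighbors), which avoids spurious disconnection.
The symmetric weight w = qᵢⱼ + qⱼᵢ ∈ [0, 1] is sharpened by the sigmoid
h(x; α, β), computed in log space (via the logistic function of
β·[log((1−α)x) − log(α(1−x))]) so that β = 50 does not overflow.
Sub-threshold weights underflow to ~1e−40 but remain nonzero and are
stored, honoring the connectivity argument for preferring a sigmoid
over a hard threshold; weights below double-precision range (≈1e−308)
necessarily become 0. If the weighted graph is nonetheless
disconnected (possible for fragmented masks), it is restricted to its
largest connected component with a warning, which also guarantees
strictly positive degrees for the normalized Laplacian.

Voxel grids are assumed isotropic (lattice offsets are used as
directions); `voxel_size_mm` (default 1.25) only enters the Gaussian
baseline's mm→voxel conversion.

## Spectral filtering

The normalized Laplacian L = I − D^(−1/2)AD^(−1/2) has spectrum in
[0, 2]; smoothing applies k(λ) = e^(−τλ) spectrally. Rather than
estimating λ_max per graph, the Chebyshev approximation interval is
fixed to [0, 2], which always contains the spectrum — this trades a
marginally wider fit for skipping a power-iteration preprocessing pass.
Coefficients are the truncated Chebyshev *series* (Gauss–Chebyshev
quadrature with 1000 nodes), which is near-minimax; at the default
order 15 the sup-norm error is ~1e−15 for τ = 1 and ~4e−7 for τ = 8,
and the matrix polynomial applied through the three-term recurrence
matches exact eigendecomposition filtering to relative ℓ₂ error below
1e−6 on 500-vertex graphs for τ ∈ {1, 4, 8}. Heat-kernel gains are ≤ 1,
so filtering never expands signal energy (up to approximation error),
and k(0) = 1 preserves the degree-weighted mean. Filter application is
linear, costs one sparse matvec per degree, and shares the recurrence
across kernels and time frames. After filtering, out-of-mask voxels are
zeroed by default (the filter is only defined on the graph); a flag
preserves the input values instead.

## Phantoms

*Circular phantoms.* The activation is a circle of radius 10/20/30
voxels in a plane through the volume center, rasterized as a tube of
cross-sectional area 1 voxel² (tube radius 1/√π ≈ 0.564), so the truth
voxel count tracks the circumference 2πr. Orientations come from the
level-3 icosphere (642 vertices, canonical icosahedron at cyclic
permutations of (0, ±1, ±φ)) restricted to the closed nonnegative
octant (0 ≤ θ, φ ≤ π/2 with θ the polar angle from +z, φ the azimuth
from +x), which yields 93 orientations. The ODF map represents strong
diffusion along the circle: by default *every* voxel carries a
single-lobe ODF along the tangent of the concentric circle through it
(voxels within 1 voxel of the axis, where the tangent is ill-defined,
are isotropic). Restricting tangent lobes to the activation voxels with
an isotropic background (available as `background="isotropic"`) was
found to be a degenerate design: an isotropic neighbor reciprocates any
direction with q = 0.5, so activation voxels acquire strong dead-end
edges into the background just off the thin tube, which drains signal
at large τ and penalizes the finer 5-conn neighborhood; the
volume-filling tangent field removes this artifact. The default volume
is 64³ voxels at 1.25 mm (radius-30 circles need ≥ 72³; the generator
enforces a 2-voxel fit margin); activation amplitude is 1.

*Streamline phantoms.* A synthetic tractogram stands in for
deterministic tractography: streamlines are grown by a direction random
walk (step 0.5 voxel, per-step angular perturbation 0.08 rad), giving
smooth, slowly curving polylines strictly inside the volume. Traversed
voxels get a tangent-aligned lobe (a second lobe where two streamlines
cross at > 30°); elsewhere the field is isotropic. Activations select
streamlines with probability proportional to length (favoring long
bundles, mimicking the non-uniform spread of real tractograms), pick a
focal vertex uniformly, and decay as exp(−s²/2σ∥²)·exp(−d²/2σ⊥²) with s
the arclength from the focus and d the distance from the curve
(defaults σ∥ = 6, σ⊥ = 1.5 voxels); truth is the voxel-wise maximum
over activations, in [0, 1], exactly 1 at each focal voxel.

*Time series.* 100 frames of five 20-frame blocks (off-on-off-on-off);
active frames carry `amplitude × truth`. Noise is additive white
Gaussian (σ = 1 by default, 10 realizations), seeded hierarchically so
realization i of seed s is reproducible in isolation. Physiological
drift and temporal autocorrelation are deliberately not modeled.

## Evaluation

The Gaussian baseline multiplies the volume by the WM mask *before*
convolving (σ_vox = FWHM/(2√(2 ln 2)·voxel size); zero padding at the
borders, no renormalization by the smoothed mask) — so mask-boundary
voxels are attenuated, as in the reference procedure. ROC analysis
thresholds the statistic at 300 uniform levels spanning its in-mask
range (detection = value ≥ level, one-sided), computes TPR/FPR against
the binary truth over the whole phantom mask, and integrates
trapezoidally with (0,0)/(1,1) endpoints; diffuse streamline truths are
binarized at 10% of their maximum (configurable); a constant statistic
is assigned AUC 0.5 with a warning. The GLM regresses each voxel's time
series on the canonical double-gamma HRF convolved with the block
design (TR 1 s for phantoms) plus an intercept, by OLS (phantom noise
is white); an optional global AR(1) mode estimates a single ρ from
pooled residual lag-1 autocorrelation and refits on Cochrane–Orcutt
transformed data. Detections use one-sided positive t-tests with
Benjamini–Hochberg FDR at q = 0.05 over in-mask voxels; detection maps
are compared with the Dice coefficient, with both-empty pairs flagged
undefined and excluded.

## Problem sizes

The full protocol (93 orientations × 10 realizations, 64³ volumes, all
radii) is straightforward but long; the shipped experiments use
reduced, seeded configurations chosen for stable medians: the Gaussian
FWHM sweep runs radius-20 phantoms in 48³ with 5 orientations × 5
realizations (its 2-mm peak is stable across seeds), and the
DSS3/DSS5/GSS comparison runs radius-10 phantoms in 32³ with 5 × 5.
Medians over 3 × 3 samples were dominated by sampling noise at the
τ = 2 boundary of the DSS5-vs-DSS3 comparison and are not used.

## Limitations

* Phantom ODFs are single- or two-lobe Watson models; real ODFs have
  richer shapes, and real data add registration error, physiological
  noise, and partial-volume effects that white Gaussian noise does not
  emulate. Passing phantom tests shows the pipeline ranks anisotropic
  activations correctly under the stated noise model, not that the same
  margins hold on acquired data.
* Noiseless adaptive smoothing is not exactly AUC 1: the graph filter
  spreads a little activation mass along the fiber beyond the
  1-voxel-thick truth tube (measured 0.9997 on radius-10 rings).
* The graph is undirected; asymmetric FODs, tractogram-derived graphs,
  and tensor-based weights are out of scope, as are ODF reconstruction
  and sharpening (inputs are taken as given).
* Anisotropic voxel grids are rejected rather than resampled.
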