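# wmdss — diffusion-informed spatial smoothing of white-matter fMRI

The BOLD signal in brain white matter (WM) is weak and spatially
anisotropic: its correlation structure follows the local axonal fiber
orientation. Conventional fMRI pipelines smooth with isotropic Gaussian
kernels, which mix signal across fiber boundaries and wash out slender,
streamline-shaped activations. `wmdss` implements an adaptive
alternative: spectral heat-kernel filters defined on a voxel-wise WM
graph whose edge weights encode the diffusion orientation distribution
function (ODF) at every voxel, so that a single spectral filter profile
becomes a spatially varying smoother that follows the fiber geometry.

It is aimed at neuroimaging researchers who have co-registered WM masks,
diffusion ODFs, and fMRI data, and at anyone studying graph signal
processing on voxel lattices. All validation inputs (phantoms, noise,
block-design time series) are generated by the package itself.

## Method

**Graph.** Each WM voxel is a vertex. Voxels are connected under the
3-conn (3×3×3 lattice, 26 neighbors) or pruned 5-conn (5×5×5, 98
neighbors; outer-layer directions parallel to inner ones are excluded)
neighborhood. For voxel *i* and neighbor direction r̂ᵢⱼ, the ODF
O᷈ᵢ is discretized as the mean over the cone of solid angle 4π/|N|
around r̂ᵢⱼ,

    p̃(i, r̂ᵢⱼ) = (1/Nₜ) Σₖ Oᵢ(r̂ᵢⱼᵏ),

normalized per voxel to qᵢⱼ = p̃ / (2 maxⱼ p̃) ∈ [0, 0.5], symmetrized
as wᵢⱼ = qᵢⱼ + qⱼᵢ ∈ [0, 1], and passed through a tunable sigmoid

    h(x) = ((1−α)x)^β / (((1−α)x)^β + ((1−x)α)^β),

(α the threshold with h(α) = ½, β the steepness; defaults α = 0.9,
β = 50) to give edge weights aᵢⱼ = h(wᵢⱼ) that retain only the main
diffusion directions while never disconnecting the graph.

**Filtering.** With the normalized Laplacian L = I − D^(−1/2) A D^(−1/2)
(spectrum in [0, 2]), smoothing applies the heat kernel k(λ) = e^(−τλ)
to the graph signal of each fMRI frame. The filter is evaluated as an
order-15 truncated Chebyshev expansion of k on [0, 2] via the three-term
recurrence on L — no eigendecomposition, one sparse matvec per
polynomial degree, shared across any number of kernels and frames. τ
plays the role that FWHM plays for Gaussian smoothing.

**Validation.** Circular phantoms (activation rings of radius 10/20/30
voxels at 1.25 mm in 93 near-uniform orientations, with tangent-aligned
ODF fields) and synthetic streamline phantoms with diffuse activations
are corrupted with white Gaussian noise and denoised with DSS
(diffusion-informed smoothing) and GSS (WM-masked isotropic Gaussian
smoothing). Detection quality is scored by 300-level ROC thresholding
(AUC), optionally after a GLM with the canonical double-gamma HRF, with
Benjamini–Hochberg FDR detection maps compared by Dice coefficient.

## Worked example

```python
import numpy as np
from wmdss import (make_circular_phantom, build_wm_graph, SpectralKernel,
                   filter_volume, add_noise, gaussian_smooth_masked, roc_auc)

phantom = make_circular_phantom(normal=[0, 0, 1], radius_vox=10, shape=(32, 32, 32))
graph = build_wm_graph(phantom.odf_field, phantom.mask, ndef="5-conn")
print(f"graph: {graph.n_vertices} vertices, {graph.adjacency.nnz // 2} edges")

noisy = add_noise(phantom.truth, sigma=1.0, n_realizations=1, seed=0)[0]
dss = filter_volume(graph, noisy, SpectralKernel.heat(tau=4.0))
gss = gaussian_smooth_masked(noisy, fwhm_mm=2.0, voxel_size_mm=1.25)

for name, vol in [("DSS (tau=4)", dss), ("GSS (2 mm)", gss)]:
    auc = roc_auc(vol, phantom.truth > 0, phantom.mask).auc
    print(f"{name}: AUC = {auc:.3f}")
```

prints

```
graph: 32768 vertices, 1436788 edges
DSS (tau=4): AUC = 0.916
GSS (2 mm): AUC = 0.839
```

i.e. on a noisy ring-shaped activation (noise σ equal to the activation
amplitude), smoothing along the fiber geometry separates active from
inactive voxels markedly better than the best isotropic Gaussian.

The same pipeline is available from the shell:

```sh
wmdss simulate circular --radius 20 --normal 0 0 1 --seed 7 --out phantom/
wmdss build-graph --odf phantom/odf_samples.nii.gz --dirs phantom/odf_directions.txt \
    --mask phantom/mask.nii.gz --neighborhood 5 --alpha 0.9 --out graph.npz
wmdss filter --graph graph.npz --in phantom/truth.nii.gz --tau 4 --out smoothed.nii.gz
wmdss evaluate --radius 10 --n-orientations 3 --n-realizations 3 --out eval/
```

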