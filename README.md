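# stwarp

Diffeomorphic metric mapping alignment for spatial transcriptomics (ST)
data.

Comparing ST sections across replicates, samples, or technologies requires
putting them in a common space first, and affine transforms alone cannot
absorb the local distortions, tears, and partial matches that tissue
sections accumulate. `stwarp` aligns sections by treating cell positions as
a spatial measure, smoothing them into a density image, and solving a
**large deformation diffeomorphic metric mapping** (LDDMM) problem: the map

```
phi(x) = A · phi_1^v(x)
```

composes an affine transform `A` with the time-1 flow `phi_1^v` of a
time-varying velocity field `v_t`. The parameters minimize

```
E = R(v) + M(phi · I_S, I_T) [+ landmark term]

R(v) = 1/(2 sigma_R^2) ∫ ‖(id − a²Δ)^p v_t‖²_{L²} dt
M    = 1/(2 sigma_M^2) Σ_x W(x) ‖f_θ(I_S ∘ phi⁻¹)(x) − I_T(x)‖² dx²
```

where `R` keeps the velocity field smooth (so the flow is a true
diffeomorphism — invertible, neighbor-preserving, safe to apply to raw
cell coordinates), `W(x)` are per-pixel posteriors of a three-component
Gaussian mixture (matching / background / artifact) that lets missing or
contaminated tissue drop out of the match, and `f_θ` is a per-channel
polynomial contrast function absorbing cell-density and modality
differences. Optimization is steepest gradient descent with exact
reverse-mode gradients; velocity gradients are smoothed by
`(id − a²Δ)^(−2p)` before each step (natural gradient). The same objective
solves 2D–2D alignment, alignment of a cell table to an H&E image, and 3D
volume–to–2D slice alignment with voxel annotation lift-over (e.g. against
a 50 µm mouse-brain common coordinate framework).

## Worked example

`examples/01_rasterize_and_align.py` generates a ~3000-cell synthetic
coronal section, deforms it with a known smooth 60 µm warp, and solves the
alignment on a 64×64 raster at 30 µm:

```
source: 3000 cells -> 64x64 pixels at 30 µm
held-out RMSE before alignment: 74.1 µm
held-out RMSE after alignment:  19.5 µm  (74% of the deformation recovered)
map invertibility error: 0.370 µm (diffeomorphism contract: < 3 µm = 0.1 pixel)
```

The held-out RMSE is measured on cells the optimizer never sees as
correspondences — only the two density images are compared — so the 74%
reduction means the solved map genuinely recovered the hidden deformation,
and the sub-micrometer forward∘inverse error certifies the map is
invertible at working precision. The other examples cover partial-tissue
robustness (`02`), 3D atlas alignment and label lift-over (`03`),
expression correspondence scoring (`04`), and region-composition entropy
analysis (`05`); each prints what its numbers mean.

A thin CLI mirrors the library (`stwarp simulate | rasterize | align2d |
align3d | liftover | apply | evaluate`), with optimizer flags under their
standard names (`sigmaM`, `sigmaR`, `sigmaP`, `sigmaA`, `sigmaB`, `a`,
`p`, `niter`, `diffeo_start`, `nt`, `epL`, `epT`, `epV`, `muB`, `muA`,
`dx`) and a provenance log written with every run.

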