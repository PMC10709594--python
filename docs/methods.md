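# Methods

## Model

A source section is aligned onto a target by the map `phi(x) = A ·
phi_1^v(x)`: the flow `phi_1^v` of a time-varying velocity field composed
with an affine transform, acting in homogeneous coordinates. Cell
positions are first converted to an image by convolving the point measure
with a normalized Gaussian kernel and sampling at pixel centers
(`raster.rasterize`); the kernel bandwidth is exposed directly and
defaults to the pixel size `dx` (taking the square root of a Gaussian
varifold kernel only rescales the bandwidth, so a single interpretable
parameter suffices). The raster is an exact separable evaluation, not a
binned approximation: it is linear in per-cell weights, conserves total
mass to the kernel truncation (padding is 4 bandwidths), and is
equivariant under whole-pixel shifts.

The objective is

    E = R(v) + M(phi · I_S, I_T) + (optional) landmark term

with

    R(v)  = 1/(2 σR²) Σ_t Δt ‖(id − a²Δ)^p v_t‖²_{L²}
    M     = 1/(2 σM²) Σ_x W_match(x) ‖f_θ(I_S ∘ ψ)(x) − I_T(x)‖² dx^d
    P     = 1/(2 σP²) Σ_i ‖A·phi_1^v(p_i) − q_i‖²

where `ψ = (phi_1^v)⁻¹ ∘ A⁻¹` is the target-to-source map used to pull
the source image back onto the target grid. `R` is evaluated in the
frequency domain through the symbol of the discrete periodic Laplacian;
an explicit finite-difference operator matrix reproduces it to 1e-6
relative (tested). `W(x)` are E-step posteriors of a three-component
Gaussian mixture over target pixel intensity: matching (mean = the
contrast-mapped source prediction, sd σM), background (mean muB, sd σB),
artifact (mean muA, sd σA), with equal priors and per-channel density
products for multichannel targets. σB and σA are fixed, not re-estimated.
When muB/muA are not given they default to the darkest/brightest decile
means of the target. `f_θ` is a per-target-channel polynomial in the
warped source intensity (degree 1 by default; degree 3 is appropriate for
RGB histology targets), refit each iteration by weighted least squares
with the matching posterior as weights; rank deficiency (e.g. constant
source) reduces the degree and flags the model.

## Optimization

Each iteration: (1) E-step posterior update, (2) contrast refit, (3)
gradient steps on translation (`epT`), linear part (`epL`) and — from
iteration `diffeo_start` on — every velocity timestep (`epV`). Gradients
are exact reverse-mode adjoints of the discrete objective, assembled from
the multilinear-interpolation primitives (gather/scatter are an exact
transpose pair); they match central finite differences to ≤1e-5 relative
on small instances (tested for v, L, T, and the landmark terms). The raw
velocity gradient is smoothed by `(id − a²Δ)^(−2p)` in the frequency
domain before stepping — the natural-gradient conversion of the covector
— which keeps every iterate in the space of smooth fields; the
regularization term's own natural gradient is then simply `Δt dx^d/σR² ·
v_t`. Divergence (non-finite objective) aborts with a diagnostic naming
the step sizes.

Flow integration is stepwise semi-Lagrangian composition: `nt` Euler
steps (default 3) with multilinear interpolation of the velocity at the
moving positions; the backward map integrates −v in reversed time order.
Forward and inverse displacement grids are both maintained explicitly —
forward carries points, inverse pulls back images — rather than inverting
numerically after the fact. Outside the grid the displacement extends as
a constant (edge value) so marginal cells are still mapped, and such
points are flagged. The integrator and interpolation order are a
numerical choice, not part of the model; tolerances that depend on them
(the ≤0.1 pixel forward∘inverse identity error) are asserted directly in
the tests and hold with two orders of magnitude to spare on the study
fixtures.

For 3D-to-2D alignment the identical machinery runs in three dimensions:
the 2D slice embeds at the x = 0 plane of the (x, y, z) atlas frame
(axis 0 = the out-of-plane, anterior-posterior axis; arrays are indexed
[x, y, z]), the matching sum runs over the slice's pixels, and the affine
and velocity field are 3D. The solved inverse map carries cell
coordinates into atlas space, where each point takes the label of its
nearest voxel (points outside the volume get a sentinel). Section
obliqueness is quantified by the total-least-squares plane of the mapped
points (smallest singular direction of the centered coordinates): RMSE =
root-mean-square orthogonal residual, angle measured between the plane
and the nominal y-z section plane.

## Parameters

| name | meaning | default | unit |
|---|---|---|---|
| dx | raster pixel size / kernel width | 30 | µm |
| sigmaM | matching weight (sd of the matching component) | 1.0 | intensity |
| sigmaR | regularization weight | 5e5 | — |
| sigmaP | landmark weight | 20 | µm |
| sigmaB, sigmaA | background / artifact sd (fixed) | 2, 5 | intensity |
| a | smoothness scale of the regularizer | 500 | µm |
| p | Laplacian power | 2 | — |
| nt | integration timesteps | 3 | — |
| niter, diffeo_start | iterations; first iteration that updates v | 5000, 0 | — |
| epL, epT, epV | step sizes (linear, translation, velocity) | 2e-8, 2e-1, 2e3 | — |

Either `L` and `T` may be given as an initial transform, or `A`, but not
both (validated). With landmarks supplied and no explicit initialization,
`A` starts from the least-squares landmark affine.

Raw-gradient step sizes are scale-dependent: the stable range of `epT`
and `epL` is set by the image intensity scale, the pixel measure `dx^d`,
σM, and (for `epL`) the squared coordinate magnitude, so they must be
retuned whenever those change — retuning per dataset is normal practice
for this family of methods. For the package's desk-scale study fixture
(images normalized to [0, 1], dx = 30 µm, sigmaM = 0.2) the configured
values are `epT = 3e-4`, `epL = 1e-9` (2D) / `1e-8` (3D), `epV = 20`,
chosen by stability analysis (largest stable order of magnitude) followed
by convergence probes selecting the lowest final matching objective;
mixture components sit at muB = 0, σB = 0.05 (empty pixels) and muA = 2,
σA = 0.5 (brighter than any tissue, so dense structures are never
absorbed by the artifact class). These live in `stwarp.fixtures` and are
used by the tests, the examples, and the acceptance script alike.

## Synthetic study conditions

Real benchmark sections are multi-gigabyte downloads, so correctness is
demonstrated on generated tissues with analytically known ground truth
(`stwarp.synth`):

- **Tissue**: mixtures of Gaussian cell clusters plus curved laminar
  bands; the default "toy coronal" fixture has ~3000 cells, 5 cell types,
  20 genes (Poisson counts from type-specific marker profiles), spanning
  ~1.9 mm and rasterized to 64×64 pixels at 30 µm.
- **Warps**: an affine composed with a sum of Gaussian displacement
  bumps. The amplitude bound Σ|amp_i| e^(−1/2)/w_i < 1 certifies a
  positive Jacobian, so the truth is a real diffeomorphism; its inverse
  is computed by damped fixed-point iteration to 1e-8 µm. The default
  warp has 60 µm (two-pixel) bumps plus a (40, −30) µm translation.
- **Degradation**: cells inside a polygon removed (tears / partial
  sections), uniform artifact cells added at a chosen rate.
- **Volumes**: 2D specs stacked and linearly interpolated along the
  out-of-plane axis give a smooth analytic 3D density (24 sections at
  50 µm) with voxel labels from the dominant component; oblique sections
  at a known tilt are sampled analytically, giving exact ground truth for
  the 3D-to-2D plane-recovery experiment.

What these fixtures do *not* emulate: segmentation errors, spatially
varying detection efficiency, cell-type-dependent density artifacts, and
real anatomical texture. Passing the synthetic study shows the estimator
recovers known transformations under its own model class and that the
mixture isolates missing tissue; it does not by itself bound accuracy on
real sections, where kernel scale and step sizes need dataset-level
tuning and landmark initialization may be required for strongly rotated
or partially matched pairs.

## Measured behaviour (recomputed by tests and `scripts/acceptance.py`)

On the fixture above with 500 iterations: self-alignment leaves cells
essentially unmoved (≤1% of image width); a known affine (4° rotation,
3% scale, (80, −50) µm shift) is recovered to <0.01 pixel translation and
<1e-3 per matrix element; the known smooth warp's held-out cell RMSE
drops by ≥70%; with 40% of the target ablated, the matching-posterior
mask (>0.85) identifies the true overlap with precision/recall ≥0.9 and
overlap-region error within 1.5× the full-tissue run; every solved map's
forward∘inverse error stays below 0.1 pixel; and the 3D alignment of an
8°-tilted analytic section recovers the plane angle within 2° (typically
<0.1°) with zero orthogonal residual for the affine-only map. The exact
values for a given seed are what `scripts/acceptance.py` writes.

## Design notes and limitations

- "Iterations" are full parameter-update cycles (E-step, contrast refit,
  one gradient step on each parameter block).
- The optimizer is deterministic given its inputs; all fixture
  randomness is seeded.
- Grid/pseudospot evaluation: half-open 200 µm bins share one origin
  (the target's bounding-box minimum) so two datasets land on identical
  pixels; pseudospot membership uses strict `distance < radius`; CPM
  normalization scales each observation to 1e6 then applies log10(x+1),
  passing all-zero observations through with a flag. Region entropy is
  the standard −Σ p ln p in nats; region expansion takes the union of
  each member's k nearest neighbors (ball tree).
- Landmark files store (x, y) µm; a flag handles legacy (row, col)
  ordered files.
- The mixture models the *target* only, so choose the more complete
  section as the source: a target observation with no source
  correspondence cannot be explained by the deformation, only
  down-weighted.
- Gradient descent on this nonconvex objective can hit local minima;
  landmark initialization is the intended remedy for large rotations or
  small overlaps.
- Not implemented (out of scope): geodesic-shooting/momentum
  parameterizations, symmetric LDDMM variants, multi-resolution
  pyramids, stochastic mini-batching, spatial-autocorrelation gene
  selection, deconvolution/clustering pipelines, atlas ontology
  traversal beyond id → name lookup.
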