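# Methods

## Model

Stack refinement is modelled as heat diffusion of per-slice transforms.
Each slice $i$ carries an unknown transform $f_i$ away from the
maximum-alignment equilibrium; the heat equation drives all $f_i \to 0$.
Discretising by forward-time central-space (FTCS) differences with spacing
$\Delta s$ and Neumann ends, and rewriting the update in terms of the
*known* neighbour transforms $f_{i,j}$ (what a registration of slice $i$
onto slice $j$ returns), gives the two-step sweep implemented in
`tdrecon.diffusion`:

1. **slice update** — interior slices receive
   $\alpha\odot(f_{i,i-1}\oplus f_{i,i+1})$, end slices the doubled
   single-neighbour term $2\alpha\odot f$ (the centred-difference ghost
   slice); all updates are computed simultaneously (Jacobi semantics),
   never in place;
2. **neighbour update** —
   $f_{i,j} \leftarrow u_j \circ f_{i,j} \circ u_i^{-1}$, pure transform
   arithmetic, no image access.

Per-slice updates are accumulated by composition and applied to the images
once, at the very end, so every slice is interpolated exactly once.

Assumptions: anatomy varies slowly relative to $\Delta s$ (so smoothing
removes registration noise before shape); transforms are small enough that
the generalised operators are valid; misalignment is well described by the
chosen transform family.

### Operators per transform family

* **Translation** — $\oplus$ is vector addition, $\odot$ scalar
  multiplication; composition/inversion are exact and commutative.
* **Affine** — log-Euclidean combination
  $\exp(\alpha(\log F_i+\log F_j))$ with the principal matrix logarithm.
  The operator pair is not unique for affine maps; the log-Euclidean choice
  is fixed here and alternatives are untested. A non-real principal
  logarithm (negative real eigenvalue: half-turn rotations, rotation
  combined with anisometric scaling) raises a hard error — no quaternion or
  polar fallback, since the combination is only trusted for small
  transforms anyway. Rigid transforms are diffused in the full affine Lie
  space; the iterates may drift slightly off the rigid manifold.
* **B-spline (ATDR)** — B-splines are not closed under inversion or
  composition, so the control polygon is linearised: inversion negates and
  composition adds coefficient vectors. The whole translation apparatus is
  then reused on the coefficients. Both directions of every pair are
  registered and antisymmetrized,
  $\Delta c'_{i,j} = (\Delta c_{i,j}-\Delta c_{j,i})/2$, which the
  diffusion needs to converge; the sweep algebra then preserves the
  antisymmetry exactly (asserted every sweep). The fixed point is maximum
  alignment of the control polygons, not of the images.

### Injectivity enforcement

Diffusing control points can fold the spline. Before each accumulation the
proposed update is restricted so that every control point's total
displacement satisfies the Choi–Lee sufficient condition for injective 2-D
cubic B-splines, implemented as the per-axis bound
$|\Delta c| < h / K_c$ with $K_c = 2.05$ (configurable). Offending points
have their whole 2-vector update scaled by a single factor (direction
preserved) to the largest admissible step, applied before the neighbour
update. Sufficient ⇒ injective, so the bound is conservative; the restricted
displacement is placed a relative margin $10^{-9}$ inside the bound to keep
the inequality strict in floating point. A weaker sum-based condition is
treated as subsumed: whenever the per-axis bound holds, the field is
accepted without further checks.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| $\alpha$ | 0.45 | – | diffusion step $D\Delta t/\Delta s^2$; stable iff $\le 0.5$; the Nyquist mode's per-sweep gain is $1-4\alpha$, so values in $(0.45, 0.5]$ barely damp slice-alternating noise and trigger a warning |
| $M$ (`sweeps`) | – | sweeps | the only stopping criterion; counts the registration sweep as the first, so $M-1$ transformation-space sweeps run.  $M$ sets the implicit Gaussian scale: $\mathrm{FWHM}_Z = 2\Delta s\sqrt{\alpha M \ln 2}$, $\mathrm{FWHM}_{BW} = \sqrt{\ln 2/(M\alpha)}/\Delta s$ |
| $\Delta s$ | 1.0 | physical | slice spacing; converts sweep counts to physical kernel widths |
| grid spacing $h$ | 16 px (phantoms) | px | B-spline control spacing; also sets the injectivity bound $h/K_c$ |
| $K_c$ | 2.05 | – | Choi–Lee constant for 2-D cubic splines |

Update magnitudes are logged per sweep as diagnostics but never used for
stopping: a magnitude threshold would need its own empirical tuning and has
no counterpart in the Gaussian-filter interpretation.

## Synthetic data

`tdrecon.synthetic` generates the desk-scale study conditions:

* **Sinusoid stacks** — $y_i = \sin(2\pi i/100) + 2.4\,\varepsilon_i$ with
  $\varepsilon_i$ i.i.d. uniform on $[-0.5, 0.5]$ (noise std
  $2.4/\sqrt{12}\approx 0.693$, larger than the unit-amplitude signal);
  the drift variant adds $10^{-2} i - 0.5$. Neighbour registration is
  assumed perfect, $f_{i,j} = y_j - y_i$, isolating the smoothing
  behaviour. Reconstruction error is $\lVert y-\hat y\rVert/N$ — an
  unconventional normalisation, kept verbatim because all quantitative
  comparisons in this package use it. Printed-minimum comparisons are
  always evaluated as means over $\ge 100$ seeds with their standard
  errors, never as a single realisation.
* **Phantom stacks** — a smooth asymmetric two-blob shape whose outline
  varies slowly in z, misaligned by smooth trend + i.i.d. noise in the
  chosen family (translation: 2.5 px trend, ±1.25 px noise; rigid: ±2°
  trend, ±1° angular noise on top of the same translations; B-spline:
  coefficient trend 2 px, noise ±1 px on a shared 16 px grid). The
  misalignment trend spans half a period across the stack — anatomy is
  assumed slow against slice spacing; translation/affine slices are
  evaluated analytically at inversely-mapped coordinates, so the injected
  misalignment is exact to machine precision.

What the phantoms do **not** emulate: staining variability, illumination
artifacts, tissue tears or folds, partial overlap, or the intensity
statistics of real stained sections. Passing tests therefore demonstrate
the correctness of the transform algebra, diffusion dynamics and
registration plumbing — not robustness of image registration on real
tissue, which enters only through the pluggable adapter.

## Numerical choices

* Double precision everywhere; the sweep updates are exact arithmetic with
  no hidden tolerances.
* Matrix log/exp via `scipy.linalg`; an imaginary residue above
  $10^{-8}$ relative is an error, below it is discarded; the homogeneous
  row is re-imposed exactly after each combination.
* B-spline evaluation via `scipy.interpolate.NdBSpline` on uniform knots
  $t_j = \mathrm{origin} + (j-2)h$; grids built by `ControlGrid.for_image`
  cover the image with one control point before the domain and two after.
  Coefficients are stored row-major (x-index outer) with interleaved x/y
  components.
* Correlation registrars subtract the mean and use plain (not whitened)
  cross-correlation: spectral whitening is noise-dominated on smooth
  band-limited images. Matched-filter ties are broken by smaller rotation
  magnitude, then smaller shift norm, with a $10^{-12}$ score tolerance.
  Its accuracy is bounded by the 1° angle grid and integer-pixel
  correlation peaks.
* Resampling pulls intensities through the inverse map
  (`out(x) = in(f^{-1}(x))`), linear for intensities and nearest for
  masks, background fill 0; the B-spline inverse uses the control-polygon
  approximation $f^{-1}(x) \approx x - u(x)$.
* Degenerate inputs fail loudly: stacks shorter than 2 slices, flat images,
  singular affine blocks, mismatched control grids, points outside the
  spline support.

## Design choices

* Direction convention: $f_{i,j}$ is the map produced by registering moving
  slice $i$ onto fixed slice $j$; applying it to slice $i$'s content aligns
  it with slice $j$. All compositions follow this convention.
* Neumann ends are realised by the doubled end-term (equivalent to
  centred-difference ghost slices); no other boundary option exists, and
  the end slices stay free to move.
* Sweeps are strictly parallel; the sequential Gauss-Seidel comparator
  counts each directional pass as one sweep and re-imposes the Neumann ends
  after each pass (the historical scheme under-specifies both; this
  convention reproduces the published optimum locations within sampling
  error).
* The 1-D experiments count pure diffusion iterations (registration assumed
  perfect); the drivers count "M sweeps" as registration sweep plus
  $M-1$ transformation-space sweeps.
* Built-in B-spline *image* registration is deliberately absent: the
  framework is registration-agnostic, so the adapter contract plus a
  JSON/elastix-style import path replaces it.
* Output composition for ATDR accumulates the adjusted (antisymmetrized)
  updates, consistent with the sweep state.

## Problem sizes

The test-suite and acceptance runs use: 100-seed ensembles of the
100-slice sinusoid experiment at 7000 sweeps; phantoms of 10–24 slices at
64×64 px (7×7 control grid); FTCS oracle stacks up to N = 50 and 200
sweeps; stencil-equivalence checks up to N = 30, d = 10; and a 239-slice
dummy stack for registration counting. These sizes keep the full suite
under a minute on one CPU while exercising every code path at double
precision.

## Known limitations

* The affine combination fails loudly for large transforms (non-real
  logarithm) — by construction, not by accident.
* ATDR's coefficient arithmetic is a linearisation: its fixed point aligns
  control polygons, not images, and its inverse/composition are
  approximations (error bounded in tests at 1% of grid spacing for
  coefficients up to 5% of spacing).
* The published minima of the 1-D sinusoid experiment depend strongly on
  the noise realisation; single-seed values can sit far from the ensemble
  mean, which is why all comparisons here are ensemble-based.
* No handling of tissue tears or discontinuities (a smooth-transform
  framework cannot represent them); no anisotropic diffusion; no
  out-of-core streaming for stacks that exceed memory.
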