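# tdrecon

Reconstruction of 3-D volumes from serial 2-D section image stacks by
**transformation diffusion**: instead of repeatedly re-registering slices,
the slice-to-slice transforms themselves are diffused along the stack axis.

## The problem

Serial sectioning (histology, blockface imaging, array tomography) destroys
the rigid alignment between consecutive 2-D slices. Pairwise registration
restores local smoothness, but repeated registration sweeps are expensive,
sequential schemes are biased by their starting slice and accumulate drift,
and unconstrained smoothing converges to *maximum alignment* — the "straight
banana" in which every slice matches its neighbours perfectly and the true
curved shape of the specimen is gone. The practical question is always how
much smoothing to apply, and at what computational price.

## The model

Let $f_i$ be the (unknown) transform of slice $i$ away from maximum
alignment. Treating $f$ as temperature in the 1-D heat equation
$\partial_t f = D\,\nabla^2 f$ and discretising with the explicit FTCS
scheme and Neumann ends gives a per-sweep update that needs only the
*known* neighbour transforms $f_{i,j}$ obtained by registration:

$$
f_i^{m,m+1} = \begin{cases}
\alpha \odot (f_{i,i-1}^m \oplus f_{i,i+1}^m), & 0 < i < N-1\\[2pt]
2\alpha \odot f_{0,1}^m, & i = 0 \quad(\text{and mirrored at } i=N-1)
\end{cases}
$$

with diffusion step $\alpha \le 0.5$ (default 0.45). After each sweep the
neighbour transforms are rewritten *in transformation space*,

$$
f_{i,j}^{m+1} = f_j^{m,m+1} \circ f_{i,j}^m \circ (f_i^{m,m+1})^{-1},
$$

so a reconstruction costs **one** registration sweep ($N-1$ registrations
for translation/affine, $2(N-1)$ for B-splines) no matter how many
smoothing sweeps follow. Running $M$ sweeps is equivalent to filtering the
misalignments with a Gaussian of variance $2\alpha M\,\Delta s^2$, which
makes the sweep count an interpretable bandwidth-selection knob
(`fwhm_z`, `fwhm_bw`).

Concretely:

* **TDR** (translation, rigid, affine): exact — $\oplus,\odot$ are vector
  sums for translations and the log-Euclidean mean
  $\exp(\alpha(\log F_i + \log F_j))$ for affine matrices.
* **ATDR** (tensor-product cubic B-splines): approximate — the diffusion
  runs on the control-point displacements (the control polygon), with each
  update restricted to the Choi–Lee sufficient injectivity bound
  $|\Delta c| < h/2.05$ per axis so no deformation folds over, and the
  result collapses to a single spline per slice.
* **Baseline**: the sequential Gauss–Seidel smoother (back-and-forth
  passes, each slice moved to the midpoint of its neighbours) used for
  comparison, plus a naive multi-level B-spline re-registration baseline.

## Worked example

`python examples/sinusoid_reconstruction.py` reconstructs a 100-slice stack
whose true vertical positions follow a sinusoid, observed with uniform
registration noise of amplitude 2.4:

```
100 slices, noise amplitude 2.4
initial error          : 0.0690
diffusion (TDR)        : min error 0.01844 at sweep 24, plateau 0.0685
Gauss-Seidel           : min error 0.01712 at sweep 11, plateau 0.0707
implicit low-pass bandwidth at the TDR optimum: 0.253 cycles/slice
```

The error ($\lVert y-\hat y\rVert/N$) first drops as high-frequency
registration noise is diffused away, reaches its minimum — the best
achievable reconstruction — and then climbs back to the plateau as the true
sinusoidal shape itself is smoothed into the maximum-alignment (straight)
solution. The sequential baseline reaches its optimum sooner because it
accumulates smoothing within a sweep, which also makes its stopping point
touchier to tune.

The other examples show the image-space pipeline
(`rigid_stack_reconstruction.py`: 23 registrations + transformation-space
sweeps cut a phantom's boundary roughness from 21.5 px to 2.4 px) and
deformable refinement (`bspline_atdr_refinement.py`: ATDR halves the
ground-truth displacement error with every output field verifiably
injective).

A thin CLI wraps the same calls:

```bash
tdr simulate phantom --model translation --n 24 --out work/phantom
tdr reconstruct --transform translation --sweeps 30 \
    --input work/phantom/slices --out work/recon --resample
tdr benchmark --seeds 100 --iterations 7000
```

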