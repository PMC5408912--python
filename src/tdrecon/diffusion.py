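"""Transformation-type-agnostic diffusion engine.

Slice misalignment is modelled as heat diffusion along the stack axis: each
slice holds an (unknown) transform away from the maximum-alignment
equilibrium, and every sweep partly deforms each slice towards its
neighbours.  The discretisation is the explicit forward-time central-space
(FTCS) scheme with Neumann (zero-gradient) ends, which for the end slices
reduces to a doubled single-neighbour term.  Crucially the iteration runs
entirely in transformation space: one registration sweep provides the
neighbour transforms ``f_{i,i-1}, f_{i,i+1}``, and every subsequent sweep
updates them by composition/inversion alone -- no image is registered or
resampled until the accumulated transforms are applied once at the end.

One sweep is a *parallel* (Jacobi-style) update: all slice updates are
computed from the current neighbour transforms simultaneously, then all
neighbour transforms are rewritten.  All arithmetic is double precision and
exact (no hidden tolerances).

The scheme is numerically stable iff ``0 <= alpha <= 0.5``; values close to
0.5 barely damp the highest-frequency (slice-to-slice alternating) noise
mode, whose per-sweep gain is ``1 - 4 alpha``, so 0.45 is the working
default.  After ``M`` sweeps the engine is equivalent to smoothing the
misalignments with a Gaussian of variance ``2 alpha M`` slice spacings
squared; :func:`fwhm_z` and :func:`fwhm_bw` expose the corresponding kernel
width and frequency bandwidth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .transforms import (Affine, BSplineTransform, Translation, Transform,
                         combine_affine, combine_translation, compose, invert)

ALPHA_DEFAULT = 0.45
#: per-sweep gain threshold: high-frequency modes persist when alpha exceeds this
ALPHA_WARN = 0.45


class StackTooShortError(ValueError):
    """Diffusion needs at least two slices."""


class AlphaWarning(UserWarning):
    """alpha in (0.45, 0.5]: stable but high-frequency noise decays slowly."""


@dataclass
class DiffusionConfig:
    """Diffusion parameters.

    alpha
        Diffusion step ``D dt / ds^2``; must lie in (0, 0.5] for stability,
        values above 0.45 trigger :class:`AlphaWarning`.
    sweeps
        Total number of stack sweeps ``M``, counting the registration sweep
        as the first; the engine therefore runs ``sweeps - 1``
        transformation-space sweeps.  ``M`` is the only stopping criterion.
    slice_spacing
        Physical spacing between slice centres (same units as ``fwhm_z``).
    boundary
        Only ``"neumann"`` is supported (ghost-slice mirror ends).
    """

    alpha: float = ALPHA_DEFAULT
    sweeps: int = 1
    slice_spacing: float = 1.0
    boundary: str = "neumann"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 0.5):
            raise ValueError(f"alpha must be in (0, 0.5], got {self.alpha}")
        if self.alpha > ALPHA_WARN:
            warnings.warn(
                f"alpha={self.alpha} > {ALPHA_WARN}: high-frequency alignment "
                "noise is damped very slowly", AlphaWarning, stacklevel=2)
        if self.sweeps < 1:
            raise ValueError("sweeps must be >= 1")
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be positive")
        if self.boundary != "neumann":
            raise ValueError("only Neumann boundaries are supported")


@dataclass
class NeighborTransforms:
    """Per-slice-pair transforms, the state diffused by the engine.

    ``prev[i]`` registers slice ``i`` onto slice ``i-1`` (undefined at 0),
    ``next[i]`` registers slice ``i`` onto slice ``i+1`` (undefined at N-1).
    """

    prev: list
    next: list

    def __post_init__(self) -> None:
        if len(self.prev) != len(self.next):
            raise ValueError("prev/next must have equal length")
        if len(self.prev) < 2:
            raise StackTooShortError("need at least 2 slices")

    def __len__(self) -> int:
        return len(self.prev)


# ---------------------------------------------------------------------------
# Generic (object) operations
# ---------------------------------------------------------------------------


def _combine(a: Transform, b: Transform, alpha: float) -> Transform:
    if isinstance(a, Translation):
        return combine_translation(a, b, alpha)
    if isinstance(a, Affine):
        return combine_affine(a, b, alpha)
    if isinstance(a, BSplineTransform):
        # coefficient arithmetic: the control polygon diffuses like translations
        return BSplineTransform(a.grid, alpha * (a.coeffs + b.coeffs))
    raise TypeError(f"unsupported transform {type(a).__name__}")


def _double(a: Transform, alpha: float) -> Transform:
    """End-slice term ``alpha (f + f)``: 2*alpha*f for distributive operators,
    F^(2 alpha) in the affine Lie space."""
    if isinstance(a, Translation):
        return Translation(2.0 * alpha * a.delta)
    if isinstance(a, Affine):
        return a.power(2.0 * alpha)
    if isinstance(a, BSplineTransform):
        return BSplineTransform(a.grid, 2.0 * alpha * a.coeffs)
    raise TypeError(f"unsupported transform {type(a).__name__}")


def update_slice_transforms(nb: NeighborTransforms, alpha: float) -> list:
    """One slice-update step: interior slices get the alpha-combination of
    their two neighbour transforms, end slices the doubled single-neighbour
    term (Neumann ends)."""
    n = len(nb)
    upd = [None] * n
    upd[0] = _double(nb.next[0], alpha)
    upd[n - 1] = _double(nb.prev[n - 1], alpha)
    for i in range(1, n - 1):
        upd[i] = _combine(nb.prev[i], nb.next[i], alpha)
    return upd


def update_neighbor_transforms(nb: NeighborTransforms, upd: Sequence) -> NeighborTransforms:
    """Rewrite the neighbour transforms purely in transformation space:
    ``f_{i,j} <- u_j o f_{i,j} o u_i^{-1}``.  No image is touched."""
    n = len(nb)
    inv_upd = []
    for i, u in enumerate(upd):
        try:
            inv_upd.append(invert(u))
        except Exception as exc:
            raise type(exc)(f"slice {i}: {exc}") from exc
    prev = [None] * n
    nxt = [None] * n
    for i in range(1, n):
        prev[i] = compose(compose(upd[i - 1], nb.prev[i]), inv_upd[i])
    for i in range(n - 1):
        nxt[i] = compose(compose(upd[i + 1], nb.next[i]), inv_upd[i])
    return NeighborTransforms(prev, nxt)


def accumulate(totals: Sequence, upd: Sequence) -> list:
    """``totals[i] <- u_i o totals[i]``; the composed transform is applied to
    each image only once, after all sweeps, to avoid cumulative resampling
    error."""
    if len(totals) != len(upd):
        raise ValueError("length mismatch between totals and updates")
    for t, u in zip(totals, upd):
        if type(t) is not type(u):
            raise TypeError(
                f"cannot accumulate {type(u).__name__} into {type(t).__name__}")
    return [compose(u, t) for t, u in zip(totals, upd)]


# ---------------------------------------------------------------------------
# Vectorized translation kernel
# ---------------------------------------------------------------------------


def translation_slice_updates(prev: np.ndarray, nxt: np.ndarray,
                              alpha: float) -> np.ndarray:
    """Vectorized slice-update for translation-like parameter arrays.

    ``prev``/``nxt`` have the slice index on axis 0 and arbitrary trailing
    shape (vector components, B-spline coefficients, or a batch of
    independent 1-D problems); ``prev[0]`` and ``nxt[-1]`` are ignored.
    """
    if prev.shape[0] < 2:
        raise StackTooShortError("need at least 2 slices")
    upd = np.empty_like(prev)
    upd[0] = 2.0 * alpha * nxt[0]
    upd[-1] = 2.0 * alpha * prev[-1]
    upd[1:-1] = alpha * (prev[1:-1] + nxt[1:-1])
    return upd


def translation_neighbor_update(prev: np.ndarray, nxt: np.ndarray,
                                upd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    new_prev = prev.copy()
    new_nxt = nxt.copy()
    new_prev[1:] = upd[:-1] + prev[1:] - upd[1:]
    new_nxt[:-1] = upd[1:] + nxt[:-1] - upd[:-1]
    return new_prev, new_nxt


def diffuse_translations(prev: np.ndarray, nxt: np.ndarray, alpha: float,
                         n_sweeps: int,
                         observer: Callable[[int, np.ndarray], None] | None = None,
                         restrict: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
                         ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Run ``n_sweeps`` transformation-space sweeps on parameter arrays.

    ``observer(m, totals)`` is called after each sweep (m = 1..n_sweeps);
    ``restrict(upd, totals)`` may rewrite the proposed update before it is
    accumulated and used to rewrite the neighbour state (injectivity
    enforcement for B-spline coefficients).
    Returns ``(totals, (prev, nxt))``.
    """
    prev = np.array(prev, dtype=float)
    nxt = np.array(nxt, dtype=float)
    totals = np.zeros_like(prev)
    for m in range(1, n_sweeps + 1):
        upd = translation_slice_updates(prev, nxt, alpha)
        if restrict is not None:
            upd = restrict(upd, totals)
        totals += upd
        prev, nxt = translation_neighbor_update(prev, nxt, upd)
        if observer is not None:
            observer(m, totals)
    return totals, (prev, nxt)


# ---------------------------------------------------------------------------
# Analytic utilities: kernel width, bandwidth, stability, stencil algebra
# ---------------------------------------------------------------------------


def fwhm_z(alpha: float, sweeps: int | float, slice_spacing: float = 1.0) -> float:
    """Spatial FWHM of the implicit Gaussian smoothing kernel,
    ``2 ds sqrt(alpha M ln 2)`` (units of ``slice_spacing``)."""
    _check_positive(alpha=alpha, sweeps=sweeps, slice_spacing=slice_spacing)
    return 2.0 * slice_spacing * np.sqrt(alpha * sweeps * np.log(2.0))


def fwhm_bw(alpha: float, sweeps: int | float, slice_spacing: float = 1.0) -> float:
    """Frequency bandwidth of the implicit Gaussian,
    ``(1/ds) sqrt(ln 2 / (M alpha))`` (cycles per unit of ``slice_spacing``)."""
    _check_positive(alpha=alpha, sweeps=sweeps, slice_spacing=slice_spacing)
    return np.sqrt(np.log(2.0) / (sweeps * alpha)) / slice_spacing


def _check_positive(**kw) -> None:
    for name, v in kw.items():
        if not (v > 0):
            raise ValueError(f"{name} must be positive, got {v}")


def stability_amplification(alpha: float, mode_frequency) -> np.ndarray | float:
    """Per-sweep gain ``1 - 4 alpha sin^2(pi nu)`` of a discrete Fourier mode.

    ``mode_frequency`` is in cycles per slice spacing, Nyquist = 0.5, where
    the gain is ``1 - 4 alpha``: zero at alpha = 0.25, -1 (marginal,
    oscillatory -- slices deform past each other) at alpha = 0.5.
    """
    nu = np.asarray(mode_frequency, dtype=float)
    if np.any(nu < 0) or np.any(nu > 0.5):
        raise ValueError("mode_frequency must lie in [0, 0.5] (Nyquist)")
    gain = 1.0 - 4.0 * alpha * np.sin(np.pi * nu) ** 2
    return float(gain) if np.isscalar(mode_frequency) else gain


def max_stable_alpha(tol: float = 1e-12) -> float:
    """Largest alpha whose worst-mode amplification magnitude stays <= 1,
    found by bisection on the Nyquist gain."""
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if abs(1.0 - 4.0 * mid) <= 1.0:   # worst mode: sin^2 = 1
            lo = mid
        else:
            hi = mid
    return round(0.5 * (lo + hi), 12)


def sweep_matrix(n: int, alpha: float) -> np.ndarray:
    """Dense matrix of one FTCS sweep on ``n`` nodes with Neumann (mirror)
    ends; the engine's translation update is algebraically identical to
    multiplying the unknown slice displacements by this matrix."""
    if n < 2:
        raise StackTooShortError("need at least 2 slices")
    a = np.zeros((n, n))
    for i in range(n):
        a[i, i] = 1.0 - 2.0 * alpha
    for i in range(n - 1):
        a[i, i + 1] += alpha
        a[i + 1, i] += alpha
    a[0, 1] += alpha          # ghost phi_{-1} = phi_1
    a[n - 1, n - 2] += alpha  # ghost phi_N = phi_{N-2}
    return a


def radius_kernel(alpha: float, radius: int) -> np.ndarray:
    """Stencil weights of ``radius`` radius-1 sweeps: the d-fold
    self-convolution of ``[alpha, 1-2 alpha, alpha]`` (length 2 d + 1)."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    base = np.array([alpha, 1.0 - 2.0 * alpha, alpha])
    k = base
    for _ in range(radius - 1):
        k = np.convolve(k, base)
    return k


def wide_stencil_matrix(n: int, alpha: float, radius: int) -> np.ndarray:
    """One radius-``d`` sweep with the induced weights of d radius-1 sweeps,
    applied on the Neumann mirror extension (indices reflect about the end
    nodes).  Equals ``sweep_matrix(n, alpha) ** d`` exactly."""
    k = radius_kernel(alpha, radius)
    b = np.zeros((n, n))
    for i in range(n):
        for off in range(-radius, radius + 1):
            j = i + off
            # reflect about nodes 0 and n-1 (ghost mirror), possibly repeatedly
            while j < 0 or j > n - 1:
                if j < 0:
                    j = -j
                if j > n - 1:
                    j = 2 * (n - 1) - j
            b[i, j] += k[off + radius]
    return b
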