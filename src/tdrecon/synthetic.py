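"""Synthetic stacks and metrics for desk-scale experiments.

Two families of test data:

* 1-D sinusoid stacks -- the vertical position of each of ``N`` slices is a
  sinusoid (the "true shape") corrupted by i.i.d. uniform registration
  noise and optionally a linear drift (correlated error).  Registration is
  assumed perfect, ``f_ij = y_j - y_i``, so these experiments exercise the
  diffusion in isolation.
* 2-D phantom image stacks -- a smooth two-blob shape whose outline varies
  slowly along z, misaligned slice-by-slice with known transforms (smooth
  trend + i.i.d. noise).  The trend plays the role of true anatomical shape,
  the noise of registration error; a good reconstruction removes the noise
  before distorting the trend.

The reconstruction error is ``||y - y_hat|| / N``: the Euclidean norm of
the per-slice error vector divided by the number of slices.  That exact
(unconventional) normalisation is kept because all quantitative comparisons
in this package use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .baselines import gauss_seidel_error_curve
from .diffusion import diffuse_translations
from .stack import SliceStack
from .transforms import Affine, BSplineTransform, ControlGrid, Translation

SINUSOID_N = 100
SINUSOID_NOISE_AMP = 2.4
SINUSOID_DRIFT_SLOPE = 1e-2


@dataclass
class Sinusoid1DStack:
    """Noisy sinusoidal slice positions with known ground truth."""

    n_slices: int
    y: np.ndarray
    y_true: np.ndarray
    noise_amp: float
    drift_slope: float
    seed: int


def make_sinusoid_stack(n_slices: int = SINUSOID_N,
                        noise_amp: float = SINUSOID_NOISE_AMP,
                        drift_slope: float = 0.0,
                        seed: int = 0) -> Sinusoid1DStack:
    """``y_i = sin(2 pi i / N) + noise_amp * eps_i (+ drift_slope * i - 0.5)``
    with ``eps_i`` i.i.d. uniform on [-0.5, 0.5]; deterministic given seed.
    The drift offset ``-0.5`` belongs to the drift variant and is applied
    only when ``drift_slope`` is nonzero."""
    if n_slices < 3:
        raise ValueError("need at least 3 slices")
    rng = np.random.default_rng(seed)
    i = np.arange(n_slices)
    y_true = np.sin(2.0 * np.pi * i / n_slices)
    y = y_true + noise_amp * rng.uniform(-0.5, 0.5, size=n_slices)
    if drift_slope != 0.0:
        y = y + drift_slope * i - 0.5
    return Sinusoid1DStack(n_slices, y, y_true, noise_amp, drift_slope, seed)


def make_sinusoid_ensemble(n_seeds: int, base_seed: int = 0,
                           **kwargs) -> tuple[np.ndarray, np.ndarray]:
    """Stack of ``n_seeds`` independent realisations: ``(y (S, N), y_true (N,))``."""
    stacks = [make_sinusoid_stack(seed=base_seed + k, **kwargs)
              for k in range(n_seeds)]
    return np.stack([s.y for s in stacks]), stacks[0].y_true


def reconstruction_error(y_hat: np.ndarray, y_true: np.ndarray) -> np.ndarray:
    """``||y_hat - y_true|| / N`` along the last axis."""
    y_hat = np.asarray(y_hat, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_hat.shape[-1] != y_true.shape[-1]:
        raise ValueError(f"length mismatch: {y_hat.shape[-1]} vs {y_true.shape[-1]}")
    return np.linalg.norm(y_hat - y_true, axis=-1) / y_hat.shape[-1]


def tdr_error_curve(y: np.ndarray, y_true: np.ndarray, iterations: int,
                    alpha: float = 0.45) -> np.ndarray:
    """Error after 0..iterations diffusion sweeps of translation TDR with
    perfect neighbour registration (``f_ij = y_j - y_i``).

    ``y`` may be ``(N,)`` or a batch ``(S, N)``; returns ``(..., iterations + 1)``.
    """
    y = np.asarray(y, dtype=float)
    batched = y.ndim > 1
    ys = np.atleast_2d(y)                      # (S, N)
    n = ys.shape[-1]
    # slice axis first for the kernel; batch rides along as trailing axis
    prev = np.zeros((n, ys.shape[0]))
    nxt = np.zeros((n, ys.shape[0]))
    nxt[:-1] = (ys[:, 1:] - ys[:, :-1]).T
    prev[1:] = (ys[:, :-1] - ys[:, 1:]).T
    errs = np.empty((ys.shape[0], iterations + 1))
    errs[:, 0] = reconstruction_error(ys, y_true)

    def _obs(m: int, totals: np.ndarray) -> None:
        errs[:, m] = reconstruction_error(ys + totals.T, y_true)

    diffuse_translations(prev, nxt, alpha, iterations, observer=_obs)
    return errs if batched else errs[0]


def sinusoid_benchmark(n_seeds: int = 100, iterations: int = 7000,
                       drift: bool = False, alpha: float = 0.45,
                       base_seed: int = 0) -> dict:
    """Minimum-error statistics of TDR and the Gauss-Seidel baseline over an
    ensemble of sinusoid stacks.  Returns per-method mean/SEM of the
    min-over-sweeps error, the median optimum location, the mean error
    curves, and the fraction of seeds where TDR beats Gauss-Seidel."""
    drift_slope = SINUSOID_DRIFT_SLOPE if drift else 0.0
    y, y_true = make_sinusoid_ensemble(n_seeds, base_seed=base_seed,
                                       drift_slope=drift_slope)
    tdr_errs = tdr_error_curve(y, y_true, iterations, alpha=alpha)
    gs_errs = gauss_seidel_error_curve(y, y_true, iterations)
    out = {"n_seeds": n_seeds, "iterations": iterations, "drift": drift}
    for name, errs in (("tdr", tdr_errs), ("gauss_seidel", gs_errs)):
        mins = errs.min(axis=-1)
        out[name] = {
            "min_error_mean": float(mins.mean()),
            "min_error_std": float(mins.std(ddof=1)),
            "min_error_sem": float(mins.std(ddof=1) / np.sqrt(n_seeds)),
            "optimum_sweeps_median": float(np.median(errs.argmin(axis=-1))),
            "mean_curve": errs.mean(axis=0),
            "final_error_mean": float(errs[..., -1].mean()),
        }
    out["tdr_beats_gs_fraction"] = float(
        (tdr_errs.min(axis=-1) < gs_errs.min(axis=-1)).mean())
    return out


# ---------------------------------------------------------------------------
# 2-D phantom stacks
# ---------------------------------------------------------------------------


@dataclass
class PhantomStack:
    """Image stack with known per-slice misalignments.

    ``truth[i]`` is the transform by which slice ``i``'s content is displaced
    (trend + noise); ``trend[i]`` is the smooth component alone -- what an
    ideal reconstruction preserves while removing the noise."""

    stack: SliceStack
    truth: list
    trend: list
    kind: str
    seed: int
    grid: ControlGrid | None = None
    truth_coeffs: np.ndarray | None = None
    trend_coeffs: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.stack)


def _blob(xx: np.ndarray, yy: np.ndarray, frac: float, w: int, h: int) -> np.ndarray:
    """Smooth asymmetric two-blob shape; ``frac`` in [0, 1] drives the slow
    z-variation of the outline."""
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    ax = 0.26 * w * (1.0 + 0.15 * np.sin(2.0 * np.pi * frac + 0.7))
    ay = 0.30 * h * (1.0 + 0.15 * np.cos(2.0 * np.pi * frac))
    main = np.exp(-(((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2))
    px = cx + 0.22 * w * np.cos(0.8 + 0.5 * frac)
    py = cy + 0.18 * h * np.sin(0.3 + 0.5 * frac)
    r = 0.10 * min(w, h)
    satellite = 0.7 * np.exp(-(((xx - px) ** 2 + (yy - py) ** 2) / r ** 2))
    return main + satellite


def make_phantom_stack(n_slices: int = 24, image_size: tuple[int, int] = (64, 64),
                       misalignment: str = "translation", seed: int = 0,
                       trend_amp: float = 2.5, noise_amp: float = 1.25,
                       angle_trend_amp: float = 2.0, angle_noise_amp: float = 1.0,
                       grid_spacing: float = 16.0,
                       coeff_trend_amp: float = 2.0, coeff_noise_amp: float = 1.0,
                       ) -> PhantomStack:
    """Phantom stand-in for a blockface-pre-aligned histology stack.

    The shape outline varies slowly in z; per-slice misalignment is a smooth
    trend plus i.i.d. noise of the requested transform family
    (``"translation"``, ``"affine"`` = small rigid, or ``"bspline"``).
    Translation/affine slices are evaluated analytically at the inversely
    mapped coordinates, so the injected misalignment is exact.
    Deterministic given ``seed``.
    """
    if n_slices < 3:
        raise ValueError("need at least 3 slices")
    h, w = image_size
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    i = np.arange(n_slices)
    # misalignment trend: half a period across the stack -- anatomy is assumed
    # to vary slowly with respect to slice spacing
    phase = np.pi * i / n_slices
    images = np.empty((n_slices, h, w))
    truth: list = []
    trend: list = []
    grid = None
    truth_c = trend_c = None

    if misalignment == "translation":
        tr = trend_amp * np.stack([np.sin(phase), np.cos(phase + 0.4)], axis=1)
        noise = noise_amp * rng.uniform(-1.0, 1.0, size=(n_slices, 2))
        for k in range(n_slices):
            t = tr[k] + noise[k]
            src = pts - t                      # content displaced by +t
            images[k] = _blob(src[:, 0].reshape(h, w), src[:, 1].reshape(h, w),
                              k / n_slices, w, h)
            truth.append(Translation(t))
            trend.append(Translation(tr[k]))
    elif misalignment == "affine":
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
        ang_tr = angle_trend_amp * np.sin(phase + 0.2)
        ang = ang_tr + angle_noise_amp * rng.uniform(-1.0, 1.0, size=n_slices)
        tr = trend_amp * np.stack([np.sin(phase), np.cos(phase + 0.4)], axis=1)
        noise = noise_amp * rng.uniform(-1.0, 1.0, size=(n_slices, 2))
        for k in range(n_slices):
            g = Affine.rigid(ang[k], tr[k] + noise[k], center)
            src = g.invert().apply(pts)
            images[k] = _blob(src[:, 0].reshape(h, w), src[:, 1].reshape(h, w),
                              k / n_slices, w, h)
            truth.append(g)
            trend.append(Affine.rigid(ang_tr[k], tr[k], center))
    elif misalignment == "bspline":
        grid = ControlGrid.for_image(image_size, grid_spacing)
        nx, ny = grid.size
        kk, ll = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        trend_c = np.empty((n_slices, nx, ny, 2))
        for k in range(n_slices):
            trend_c[k, ..., 0] = coeff_trend_amp * np.sin(phase[k]) * np.sin(
                np.pi * kk / max(nx - 1, 1))
            trend_c[k, ..., 1] = coeff_trend_amp * np.cos(phase[k] + 0.4) * np.sin(
                np.pi * ll / max(ny - 1, 1))
        truth_c = trend_c + coeff_noise_amp * rng.uniform(
            -1.0, 1.0, size=trend_c.shape)
        base = _blob(xx, yy, 0.5, w, h)
        for k in range(n_slices):
            t = BSplineTransform(grid, truth_c[k])
            u = t.displace(pts)
            src_x = np.clip(pts[:, 0] - u[:, 0], 0, w - 1).reshape(h, w)
            src_y = np.clip(pts[:, 1] - u[:, 1], 0, h - 1).reshape(h, w)
            from scipy import ndimage

            images[k] = ndimage.map_coordinates(base, [src_y, src_x], order=1)
            truth.append(t)
            trend.append(BSplineTransform(grid, trend_c[k]))
    else:
        raise ValueError(f"unknown misalignment model {misalignment!r}")

    stack = SliceStack(images)
    return PhantomStack(stack, truth, trend, misalignment, seed, grid,
                        truth_c, trend_c)


def phantom_recovery_curve(phantom: PhantomStack, iterations: int,
                           alpha: float = 0.45,
                           sample_points: np.ndarray | None = None) -> np.ndarray:
    """Mean ground-truth displacement error after 0..iterations diffusion
    sweeps, using perfect neighbour registration from the phantom's truth.

    At sweep ``m`` the residual misalignment of slice ``i`` is
    ``u_i^m o g_i`` (accumulated update composed with the injected
    misalignment); the error is its mean distance to the smooth trend
    ``t_i`` over sample points: ``mean_p || (u o g)(p) - t(p) ||``.
    """
    n = len(phantom)
    h, w = phantom.stack.frame_shape
    if sample_points is None:
        gx, gy = np.meshgrid(np.linspace(0.15 * w, 0.85 * w, 5),
                             np.linspace(0.15 * h, 0.85 * h, 5))
        sample_points = np.stack([gx.ravel(), gy.ravel()], axis=1)

    if phantom.kind == "translation":
        t = np.stack([g.delta for g in phantom.truth])
        tr = np.stack([g.delta for g in phantom.trend])
        prev = np.zeros_like(t)
        nxt = np.zeros_like(t)
        nxt[:-1] = t[1:] - t[:-1]
        prev[1:] = t[:-1] - t[1:]
        errs = np.empty(iterations + 1)
        errs[0] = np.linalg.norm(t - tr, axis=1).mean()

        def _obs(m: int, totals: np.ndarray) -> None:
            errs[m] = np.linalg.norm(t + totals - tr, axis=1).mean()

        diffuse_translations(prev, nxt, alpha, iterations, observer=_obs)
        return errs

    if phantom.kind == "affine":
        from .diffusion import DiffusionConfig, NeighborTransforms
        from .tdr import run_tdr
        from .transforms import compose, invert

        nb = NeighborTransforms(
            prev=[None] + [compose(phantom.truth[i - 1], invert(phantom.truth[i]))
                           for i in range(1, n)],
            next=[compose(phantom.truth[i + 1], invert(phantom.truth[i]))
                  for i in range(n - 1)] + [None])
        target = np.stack([tr.apply(sample_points) for tr in phantom.trend])
        errs = np.empty(iterations + 1)
        start = np.stack([g.apply(sample_points) for g in phantom.truth])
        errs[0] = np.linalg.norm(start - target, axis=-1).mean()

        def _obs(m: int, totals: list) -> None:
            cur = np.stack([compose(u, g).apply(sample_points)
                            for u, g in zip(totals, phantom.truth)])
            errs[m] = np.linalg.norm(cur - target, axis=-1).mean()

        run_tdr(nb, DiffusionConfig(alpha=alpha, sweeps=iterations + 1),
                observer=_obs)
        return errs

    if phantom.kind == "bspline":
        from .diffusion import DiffusionConfig
        from .atdr import diffuse_bspline_neighbors

        c = phantom.truth_coeffs
        tr = phantom.trend_coeffs
        grid = phantom.grid
        prev = np.zeros_like(c)
        nxt = np.zeros_like(c)
        nxt[:-1] = c[1:] - c[:-1]
        prev[1:] = c[:-1] - c[1:]

        def _residual_error(total_c: np.ndarray) -> float:
            res = np.empty(n)
            for k in range(n):
                t = BSplineTransform(grid, c[k] + total_c[k] - tr[k])
                res[k] = np.linalg.norm(t.displace(sample_points), axis=-1).mean()
            return float(res.mean())

        errs = np.empty(iterations + 1)
        errs[0] = _residual_error(np.zeros_like(c))

        def _obs(m: int, totals: np.ndarray) -> None:
            errs[m] = _residual_error(totals)

        diffuse_bspline_neighbors(prev, nxt, grid,
                                  DiffusionConfig(alpha=alpha,
                                                  sweeps=iterations + 1),
                                  observer=_obs)
        return errs

    raise ValueError(f"unknown phantom kind {phantom.kind!r}")
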