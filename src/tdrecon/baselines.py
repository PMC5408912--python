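"""Comparison baselines: sequential Gauss-Seidel smoothing and the naive
multi-level B-spline sweep algorithm.

The Gauss-Seidel comparator poses stack smoothing as Laplace's equation
``0 = d^2 phi / dr^2`` along the stack and solves it by sequential
relaxation: sweeping the stack one slice at a time, each slice moves to the
midpoint of its already-updated neighbours.  Because the smoothing is
applied per slice rather than per stack sweep, it accumulates faster than
the parallel diffusion update -- and accumulates correlated errors (drift)
along the sweep direction, which alternating forward/backward passes only
partly cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .diffusion import translation_slice_updates


@dataclass
class GaussSeidelConfig:
    """Sweep count for the sequential baseline; passes alternate
    forward/backward, each directional pass counting as one sweep."""

    sweeps: int
    direction_policy: str = "alternate"

    def __post_init__(self) -> None:
        if self.sweeps < 1:
            raise ValueError("sweeps must be >= 1")
        if self.direction_policy != "alternate":
            raise ValueError("only alternating passes are supported")


def run_gauss_seidel_1d(y: np.ndarray, sweeps: int,
                        callback: Callable[[int, np.ndarray], None] | None = None,
                        ) -> np.ndarray:
    """Sequential back-and-forth Laplace smoothing of 1-D slice positions.

    In-place update ``phi_i <- (phi_{i-1} + phi_{i+1}) / 2`` sweeping forward
    (odd sweeps) or backward (even sweeps); one directional pass is one
    sweep.  Neumann ends ``phi_0 <- phi_1`` and ``phi_{N-1} <- phi_{N-2}``
    are applied at the end of each pass.  ``y`` may carry leading batch axes;
    the slice index is the last axis.
    """
    z = np.array(y, dtype=float)
    n = z.shape[-1]
    if n < 3:
        raise ValueError("need at least 3 slices")
    for m in range(1, sweeps + 1):
        if m % 2 == 1:
            for i in range(1, n - 1):
                z[..., i] = 0.5 * (z[..., i - 1] + z[..., i + 1])
        else:
            for i in range(n - 2, 0, -1):
                z[..., i] = 0.5 * (z[..., i - 1] + z[..., i + 1])
        z[..., 0] = z[..., 1]
        z[..., n - 1] = z[..., n - 2]
        if callback is not None:
            callback(m, z)
    return z


def gauss_seidel_error_curve(y: np.ndarray, y_true: np.ndarray,
                             sweeps: int) -> np.ndarray:
    """Reconstruction error ``||y - y_true|| / N`` after 0..sweeps passes;
    batched over leading axes of ``y``."""
    y = np.asarray(y, dtype=float)
    n = y.shape[-1]
    errs = np.empty(y.shape[:-1] + (sweeps + 1,))
    errs[..., 0] = np.linalg.norm(y - y_true, axis=-1) / n

    def _cb(m: int, z: np.ndarray) -> None:
        errs[..., m] = np.linalg.norm(z - y_true, axis=-1) / n

    run_gauss_seidel_1d(y, sweeps, callback=_cb)
    return errs


def naive_bspline_sweeps(register_state: Callable[[np.ndarray, int, int], np.ndarray],
                         n_slices: int, sweeps: int, alpha: float = 0.45,
                         ) -> tuple[np.ndarray, list[list[np.ndarray]]]:
    """Reference multi-level baseline: every sweep re-registers every
    neighbour pair (``2(N-1)`` registrations per sweep) and appends one new
    B-spline level per slice.

    ``register_state(totals, i, j)`` must return the coefficient field that
    registers the *current* state of slice ``i`` onto slice ``j`` (for a
    mock, the difference of current per-slice states).  Returns the summed
    displacement per slice and the per-slice level lists, whose length grows
    linearly with the sweep count -- the cost the collapsed ATDR
    representation avoids.  Tiny reference implementation for comparisons,
    not optimized.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    totals = None
    levels: list[list[np.ndarray]] = [[] for _ in range(n_slices)]
    for _ in range(sweeps):
        pair_nxt = [register_state(totals, i, i + 1) for i in range(n_slices - 1)]
        pair_prev = [register_state(totals, i + 1, i) for i in range(n_slices - 1)]
        if totals is None:
            shape = np.asarray(pair_nxt[0]).shape
            totals = np.zeros((n_slices, *shape))
        prev = np.zeros_like(totals)
        nxt = np.zeros_like(totals)
        for i in range(n_slices - 1):
            nxt[i] = pair_nxt[i]
            prev[i + 1] = pair_prev[i]
        upd = translation_slice_updates(prev, nxt, alpha)
        totals += upd
        for i in range(n_slices):
            levels[i].append(upd[i].copy())
    return totals, levels
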