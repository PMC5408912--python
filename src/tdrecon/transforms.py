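"""Spatial transform types and the algebra used by transformation diffusion.

Transforms act on continuous, 0-based pixel coordinates ``(x, y)`` with the
origin at the centre of the first pixel.  The package-wide direction
convention is that ``f_ij`` denotes the map produced by registering moving
slice ``i`` onto fixed slice ``j``: applying ``f_ij`` to the *content* of
slice ``i`` aligns it with slice ``j`` (resampling pulls intensities through
the inverse map, see :mod:`tdrecon.stack`).

Three families are provided:

* :class:`Translation` -- exact vector group; combination is the ordinary
  scaled vector sum.
* :class:`Affine` -- 3x3 homogeneous matrices; combination is the
  log-Euclidean mean ``exp(alpha (log F_i + log F_j))``, which requires a
  real principal matrix logarithm.
* :class:`BSplineTransform` -- tensor-product cubic B-spline displacement
  fields on a shared :class:`ControlGrid`; inversion and composition are
  *approximated* by coefficient negation/addition (control-polygon
  linearisation), since B-splines are not closed under either operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import NdBSpline
from scipy.linalg import expm, logm


class TransformError(ValueError):
    """Base class for transform-algebra errors."""


class InvalidTransformError(TransformError):
    """Non-finite or malformed transform parameters."""


class SingularTransformError(TransformError):
    """Affine linear block is not invertible."""


class NonRealLogarithmError(TransformError):
    """The principal matrix logarithm is not real.

    This happens e.g. for a rotation by pi, or a rotation combined with
    anisometric scaling, where the matrix has a negative real eigenvalue.
    The log-Euclidean combination is only valid for transformations that are
    not large; no quaternion or polar fallback is attempted.
    """


class GridMismatchError(TransformError):
    """B-spline coefficient arithmetic requires identical control grids."""


class OutOfDomainError(TransformError):
    """Evaluation point outside the B-spline grid support."""


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class Translation:
    """Pure translation by ``delta`` (pixels or model units).

    ``delta`` may have any dimension; 1-vectors are used by the synthetic
    1-D stack experiments, 2-vectors by image reconstruction.
    """

    delta: np.ndarray

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.delta, dtype=float))
        if not np.all(np.isfinite(d)):
            raise InvalidTransformError(f"non-finite translation {d!r}")
        object.__setattr__(self, "delta", d)

    @classmethod
    def identity(cls, ndim: int = 2) -> "Translation":
        return cls(np.zeros(ndim))

    def compose(self, other: "Translation") -> "Translation":
        """``self o other`` (exact: vector addition, commutative)."""
        return Translation(self.delta + other.delta)

    def invert(self) -> "Translation":
        return Translation(-self.delta)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self.delta

    def as_affine(self) -> "Affine":
        if self.delta.size != 2:
            raise InvalidTransformError("only 2-D translations embed as affine")
        return Affine.translation(self.delta)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Translation) and np.array_equal(self.delta, other.delta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Translation({np.array2string(self.delta, precision=6)})"


def combine_translation(a: Translation, b: Translation, alpha: float) -> Translation:
    """Diffusion combination ``alpha (delta_a + delta_b)``."""
    if not np.isfinite(alpha):
        raise InvalidTransformError("non-finite alpha")
    return Translation(alpha * (a.delta + b.delta))


# ---------------------------------------------------------------------------
# Affine
# ---------------------------------------------------------------------------

_LAST_ROW = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True, eq=False)
class Affine:
    """2-D affine transform as a 3x3 homogeneous matrix ``[[A, d], [0, 1]]``.

    Translation, rigid and similarity transforms are special cases.  The last
    row is enforced to be exactly ``(0, 0, 1)``; the linear block must be
    invertible.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InvalidTransformError(f"affine matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise InvalidTransformError("non-finite affine matrix")
        if not np.allclose(m[2], _LAST_ROW, atol=1e-9):
            raise InvalidTransformError(f"last row must be (0,0,1), got {m[2]!r}")
        m = m.copy()
        m[2] = _LAST_ROW
        if abs(np.linalg.det(m[:2, :2])) < 1e-300:
            raise SingularTransformError("singular linear block")
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls) -> "Affine":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, delta: Sequence[float]) -> "Affine":
        m = np.eye(3)
        m[:2, 2] = np.asarray(delta, dtype=float)
        return cls(m)

    @classmethod
    def rotation(cls, angle_deg: float, center: Sequence[float] | None = None) -> "Affine":
        """Rotation by ``angle_deg`` (counter-clockwise in (x, y) coordinates),
        optionally about ``center``."""
        t = math.radians(angle_deg)
        c, s = math.cos(t), math.sin(t)
        m = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        rot = cls(m)
        if center is None:
            return rot
        ctr = np.asarray(center, dtype=float)
        return cls.translation(ctr).compose(rot).compose(cls.translation(-ctr))

    @classmethod
    def scaling(cls, s, center: Sequence[float] | None = None) -> "Affine":
        sx, sy = (s, s) if np.isscalar(s) else s
        m = np.diag([float(sx), float(sy), 1.0])
        sc = cls(m)
        if center is None:
            return sc
        ctr = np.asarray(center, dtype=float)
        return cls.translation(ctr).compose(sc).compose(cls.translation(-ctr))

    @classmethod
    def rigid(cls, angle_deg: float, delta: Sequence[float],
              center: Sequence[float] | None = None) -> "Affine":
        """Rotation about ``center`` followed by translation ``delta``."""
        return cls.translation(delta).compose(cls.rotation(angle_deg, center))

    # -- accessors ---------------------------------------------------------

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:2, :2]

    @property
    def offset(self) -> np.ndarray:
        return self.matrix[:2, 2]

    # -- group operations --------------------------------------------------

    def compose(self, other: "Affine") -> "Affine":
        """``self o other`` -- apply ``other`` first (matrix product)."""
        return Affine(self.matrix @ other.matrix)

    def invert(self) -> "Affine":
        try:
            inv = np.linalg.inv(self.matrix)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in init
            raise SingularTransformError(str(exc)) from exc
        inv[2] = _LAST_ROW
        return Affine(inv)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.linear.T + self.offset
        return out if np.asarray(points).ndim > 1 else out[0]

    def log(self) -> np.ndarray:
        """Real principal matrix logarithm, or :class:`NonRealLogarithmError`."""
        return _real_logm(self.matrix)

    def power(self, s: float) -> "Affine":
        """Fractional power ``F^s = exp(s log F)`` (log-Euclidean scaling)."""
        return Affine(_fix_last_row(expm(s * self.log())))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Affine) and np.array_equal(self.matrix, other.matrix)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Affine(\n{np.array2string(self.matrix, precision=6)})"


def _real_logm(m: np.ndarray) -> np.ndarray:
    eig = np.linalg.eigvals(m)
    if np.any((eig.real <= 0.0) & (np.abs(eig.imag) <= 1e-12 * np.abs(eig.real).max())):
        raise NonRealLogarithmError(
            "matrix has a non-positive real eigenvalue; the principal logarithm "
            "is not real (e.g. rotation by 180 deg, or rotation combined with "
            "anisometric scaling)")
    lg = logm(m)
    if np.iscomplexobj(lg):
        if np.abs(lg.imag).max() > 1e-8 * max(1.0, np.abs(lg.real).max()):
            raise NonRealLogarithmError("matrix logarithm has a non-negligible "
                                        "imaginary part")
        lg = lg.real
    return lg


def _fix_last_row(m: np.ndarray) -> np.ndarray:
    if not np.allclose(m[2], _LAST_ROW, atol=1e-8):
        raise NonRealLogarithmError(f"combination left homogeneous row {m[2]!r}")
    m = m.copy()
    m[2] = _LAST_ROW
    return m


def combine_affine(a: Affine, b: Affine, alpha: float) -> Affine:
    """Log-Euclidean combination ``exp(alpha (log F_a + log F_b))``."""
    if not np.isfinite(alpha):
        raise InvalidTransformError("non-finite alpha")
    return Affine(_fix_last_row(expm(alpha * (a.log() + b.log()))))


# ---------------------------------------------------------------------------
# Tensor-product cubic B-spline displacement fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ControlGrid:
    """Uniform control-point grid shared by all slices of a reconstruction.

    Control point ``(k, l)`` sits at ``origin + (k hx, l hy)``; ``size`` is the
    number of control points per axis, ``(K+1, L+1)`` with ``k`` along x.  Only
    cubic splines (order 4, degree 3) are supported.  The valid evaluation
    domain, where all four basis functions of a point are defined and the
    basis sums to one, is ``[origin + h, origin + (n - 2) h]`` per axis.
    """

    origin: tuple[float, float]
    spacing: tuple[float, float]
    size: tuple[int, int]
    order: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "size", tuple(int(v) for v in self.size))
        if self.order != 4:
            raise InvalidTransformError("only cubic B-splines (order 4) supported")
        if any(h <= 0 for h in self.spacing):
            raise InvalidTransformError("grid spacing must be positive")
        if any(n < 4 for n in self.size):
            raise InvalidTransformError("need at least 4 control points per axis")

    @classmethod
    def for_image(cls, shape: tuple[int, int], spacing) -> "ControlGrid":
        """Grid covering an image of ``shape`` (rows, cols) with the support
        margin a cubic spline requires (one control before the domain, two
        after)."""
        h, w = shape
        hx, hy = (spacing, spacing) if np.isscalar(spacing) else spacing
        nx = math.ceil(max(w - 1, 1) / hx) + 3
        ny = math.ceil(max(h - 1, 1) / hy) + 3
        return cls(origin=(-hx, -hy), spacing=(hx, hy), size=(nx, ny))

    def knots(self, axis: int) -> np.ndarray:
        n = self.size[axis]
        h = self.spacing[axis]
        o = self.origin[axis]
        return o + (np.arange(n + 4) - 2.0) * h

    @property
    def domain(self) -> tuple[tuple[float, float], tuple[float, float]]:
        lo = tuple(o + h for o, h in zip(self.origin, self.spacing))
        hi = tuple(o + (n - 2) * h
                   for o, h, n in zip(self.origin, self.spacing, self.size))
        return ((lo[0], hi[0]), (lo[1], hi[1]))

    @property
    def n_coeffs(self) -> int:
        return 2 * self.size[0] * self.size[1]

    def control_points(self) -> np.ndarray:
        """(nx, ny, 2) array of control point coordinates."""
        xs = self.origin[0] + np.arange(self.size[0]) * self.spacing[0]
        ys = self.origin[1] + np.arange(self.size[1]) * self.spacing[1]
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.stack([gx, gy], axis=-1)


@dataclass(frozen=True, eq=False)
class BSplineTransform:
    """Free-form deformation: ``f(x) = x + sum_kl dc_kl N_k(x) N_l(y)``.

    ``coeffs`` holds the control-point displacements ``dc_kl`` (pixels) as an
    ``(nx, ny, 2)`` array indexed ``[k, l]`` with ``k`` along x; a flat
    row-major vector (k outer, l inner, components innermost) of length
    ``2 nx ny`` is also accepted.  With all coefficients zero the transform is
    the identity (partition of unity of the basis).
    """

    grid: ControlGrid
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        nx, ny = self.grid.size
        c = np.asarray(self.coeffs, dtype=float)
        if c.ndim == 1:
            if c.size != 2 * nx * ny:
                raise InvalidTransformError(
                    f"flat coefficient vector must have length {2 * nx * ny}, "
                    f"got {c.size}")
            c = c.reshape(nx, ny, 2)
        if c.shape != (nx, ny, 2):
            raise InvalidTransformError(
                f"coefficients must have shape {(nx, ny, 2)}, got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise InvalidTransformError("non-finite B-spline coefficients")
        object.__setattr__(self, "coeffs", c)

    @classmethod
    def identity(cls, grid: ControlGrid) -> "BSplineTransform":
        return cls(grid, np.zeros((*grid.size, 2)))

    @property
    def flat_coeffs(self) -> np.ndarray:
        """Row-major flattened coefficient vector (k outer, l inner)."""
        return self.coeffs.reshape(-1)

    def _spline(self) -> NdBSpline:
        return NdBSpline((self.grid.knots(0), self.grid.knots(1)), self.coeffs, k=3)

    def _check_domain(self, points: np.ndarray) -> None:
        (xlo, xhi), (ylo, yhi) = self.grid.domain
        eps = 1e-9
        if (points[:, 0].min() < xlo - eps or points[:, 0].max() > xhi + eps
                or points[:, 1].min() < ylo - eps or points[:, 1].max() > yhi + eps):
            raise OutOfDomainError(
                f"points outside grid support x:[{xlo},{xhi}] y:[{ylo},{yhi}]")

    def displace(self, points: np.ndarray) -> np.ndarray:
        """Displacement vectors at ``points`` (m, 2) in (x, y)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        self._check_domain(p)
        return self._spline()(p)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p + self.displace(p)
        return out if np.asarray(points).ndim > 1 else out[0]

    def jacobian_determinants(self, points: np.ndarray) -> np.ndarray:
        """det(I + du/dx) at each point; positive values mean no fold-over."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        self._check_domain(p)
        sp = self._spline()
        dux = sp(p, nu=(1, 0))     # d(ux, uy)/dx
        duy = sp(p, nu=(0, 1))     # d(ux, uy)/dy
        j11 = 1.0 + dux[:, 0]
        j12 = duy[:, 0]
        j21 = dux[:, 1]
        j22 = 1.0 + duy[:, 1]
        return j11 * j22 - j12 * j21

    def approx_invert(self) -> "BSplineTransform":
        """Control-polygon approximation of the inverse: negated coefficients."""
        return BSplineTransform(self.grid, -self.coeffs)

    def approx_compose(self, other: "BSplineTransform") -> "BSplineTransform":
        """Control-polygon approximation of ``self o other``: coefficient sum."""
        if self.grid != other.grid:
            raise GridMismatchError("cannot combine B-splines on different grids")
        return BSplineTransform(self.grid, self.coeffs + other.coeffs)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, BSplineTransform) and self.grid == other.grid
                and np.array_equal(self.coeffs, other.coeffs))


def bspline_displace(t: BSplineTransform, points: np.ndarray) -> np.ndarray:
    return t.displace(points)


def bspline_approx_compose(a: BSplineTransform, b: BSplineTransform) -> BSplineTransform:
    return a.approx_compose(b)


def bspline_approx_invert(a: BSplineTransform) -> BSplineTransform:
    return a.approx_invert()


# ---------------------------------------------------------------------------
# Generic dispatch and serialization
# ---------------------------------------------------------------------------

Transform = Translation | Affine | BSplineTransform


def compose(a: Transform, b: Transform) -> Transform:
    """``a o b`` (apply ``b`` first); approximate for B-splines."""
    if isinstance(a, BSplineTransform):
        return a.approx_compose(b)
    if type(a) is not type(b):
        raise TransformError(f"cannot compose {type(a).__name__} with {type(b).__name__}")
    return a.compose(b)


def invert(a: Transform) -> Transform:
    if isinstance(a, BSplineTransform):
        return a.approx_invert()
    return a.invert()


def transform_to_dict(t: Transform) -> dict:
    """JSON-serializable document; bit-exact round trip for all types."""
    if isinstance(t, Translation):
        return {"type": "translation", "parameters": t.delta.tolist()}
    if isinstance(t, Affine):
        return {"type": "affine", "parameters": t.matrix.reshape(-1).tolist()}
    if isinstance(t, BSplineTransform):
        return {"type": "bspline",
                "parameters": t.flat_coeffs.tolist(),
                "grid": {"origin": list(t.grid.origin),
                         "spacing": list(t.grid.spacing),
                         "size": list(t.grid.size),
                         "order": t.grid.order}}
    raise TransformError(f"unknown transform type {type(t).__name__}")


def transform_from_dict(d: dict) -> Transform:
    kind = d["type"]
    if kind == "translation":
        return Translation(np.asarray(d["parameters"], dtype=float))
    if kind == "affine":
        return Affine(np.asarray(d["parameters"], dtype=float).reshape(3, 3))
    if kind == "bspline":
        g = d["grid"]
        grid = ControlGrid(origin=tuple(g["origin"]), spacing=tuple(g["spacing"]),
                           size=tuple(g["size"]), order=g.get("order", 4))
        return BSplineTransform(grid, np.asarray(d["parameters"], dtype=float))
    raise TransformError(f"unknown transform type {kind!r}")
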