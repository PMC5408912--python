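"""Registration adapters producing slice-pair transforms.

The diffusion engine is agnostic of the registration method; it only needs
the per-pair transforms of a declared type.  This module provides:

* a matched-filter rigid registrar (brute-force rotation search, translation
  by normalized cross-correlation peak);
* a phase-correlation translation registrar (fast default for phantoms);
* mock exact registrars that return transform differences of a known ground
  truth without touching images (the perfect-registration regime used by the
  synthetic experiments);
* an import path for transforms computed by an external tool (our JSON
  documents or elastix-style parameter text files).

Adapters declare whether they are *symmetric*: whether the reverse transform
``f_{j,i}`` may be derived as ``invert(f_{i,j})`` instead of a second
registration.  Every adapter counts its calls in ``self.calls``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .stack import SliceStack, apply_transform_to_image
from .transforms import (Affine, BSplineTransform, ControlGrid, Translation,
                         Transform, compose, invert)


class RegistrationError(RuntimeError):
    """Base class for registration failures."""


class FlatImageError(RegistrationError):
    """Zero-variance image: correlation is undefined."""


class RegistrationPairError(RegistrationError):
    """Registration of one slice pair failed; carries the pair index."""

    def __init__(self, moving_index: int, fixed_index: int, cause: Exception):
        self.moving_index = moving_index
        self.fixed_index = fixed_index
        super().__init__(
            f"registration of slice {moving_index} onto {fixed_index} failed: {cause}")


class RegistrationAdapter:
    """Contract: ``register(moving, fixed)`` returns the transform of the
    declared type that aligns the content of ``moving`` with ``fixed``;
    deterministic given inputs and configuration."""

    #: whether f_{j,i} may be obtained as invert(f_{i,j})
    symmetric: bool = False

    def __init__(self) -> None:
        self.calls = 0

    def register_pair(self, stack: SliceStack, i: int, j: int) -> Transform:
        self.calls += 1
        return self._register_pair(stack, i, j)

    def _register_pair(self, stack: SliceStack, i: int, j: int) -> Transform:
        return self.register(np.asarray(stack.images[i]),
                             np.asarray(stack.images[j]))

    def register(self, moving: np.ndarray, fixed: np.ndarray) -> Transform:
        raise NotImplementedError


class MockExactRegistrar(RegistrationAdapter):
    """Perfect registration from known per-slice misalignments.

    Given ground-truth transforms ``g_i`` (each slice's content displaced by
    ``g_i`` from its true position), the exact pair transform is
    ``f_{i,j} = g_j o g_i^{-1}`` -- for translations simply ``y_j - y_i``.
    Never touches image data.
    """

    symmetric = True

    def __init__(self, truth) -> None:
        super().__init__()
        self.truth = [Translation(np.atleast_1d(t)) if not isinstance(
            t, (Translation, Affine, BSplineTransform)) else t for t in truth]

    def _register_pair(self, stack, i: int, j: int) -> Transform:
        return compose(self.truth[j], invert(self.truth[i]))

    def register(self, moving, fixed):  # pragma: no cover
        raise NotImplementedError("mock registrar works on slice indices")


class MockBSplineRegistrar(RegistrationAdapter):
    """Exact-plus-noise coefficient registrar on a shared control grid.

    Ground truth is one coefficient field per slice; pair registration
    returns ``c_j - c_i`` plus optional i.i.d. uniform coefficient noise
    (independent per ordered pair, so the forward and reverse fields are not
    exactly antisymmetric -- as with a real registration tool).
    """

    symmetric = False

    def __init__(self, grid: ControlGrid, coeffs: np.ndarray,
                 noise_amp: float = 0.0, seed: int = 0) -> None:
        super().__init__()
        self.grid = grid
        self.coeffs = np.asarray(coeffs, dtype=float)
        self.noise_amp = float(noise_amp)
        self._rng = np.random.default_rng(seed)

    def _register_pair(self, stack, i: int, j: int) -> BSplineTransform:
        c = self.coeffs[j] - self.coeffs[i]
        if self.noise_amp:
            c = c + self._rng.uniform(-0.5, 0.5, size=c.shape) * self.noise_amp
        return BSplineTransform(self.grid, c)

    def register(self, moving, fixed):  # pragma: no cover
        raise NotImplementedError("mock registrar works on slice indices")


def mock_exact_registrar(truth) -> MockExactRegistrar:
    return MockExactRegistrar(truth)


# ---------------------------------------------------------------------------
# Image-based registrars
# ---------------------------------------------------------------------------


def _check_not_flat(*images) -> None:
    for im in images:
        if np.ptp(im) == 0:
            raise FlatImageError("flat (zero-variance) image: correlation "
                                 "peak is undefined")


class PhaseCorrelationRegistrar(RegistrationAdapter):
    """Translation registration by correlation peak with subpixel
    refinement (upsampled cross-correlation).

    Spectral whitening ("phase" normalization) is disabled by default: it
    weights all frequencies equally and is easily dominated by noise on the
    smooth, band-limited images typical of masked tissue slices.
    """

    symmetric = True

    def __init__(self, upsample_factor: int = 20,
                 normalization: str | None = None) -> None:
        super().__init__()
        self.upsample_factor = upsample_factor
        self.normalization = normalization

    def register(self, moving: np.ndarray, fixed: np.ndarray) -> Translation:
        from skimage.registration import phase_cross_correlation

        _check_not_flat(moving, fixed)
        shift, _, _ = phase_cross_correlation(
            reference_image=fixed, moving_image=moving,
            upsample_factor=self.upsample_factor,
            normalization=self.normalization)
        # skimage returns the (row, col) shift that moves `moving` onto
        # `fixed`; our Translation stores (x, y) = (col, row).
        return Translation(np.array([shift[1], shift[0]]))


class MatchedFilterRigidRegistrar(RegistrationAdapter):
    """Brute-force rigid registration: for every candidate rotation (default
    1-degree steps over [-45, 45] degrees) the optimal translation is the
    normalized cross-correlation peak; the best (angle, shift) pair wins.
    Slow but global -- it cannot get stuck in a local optimum.

    Correlation is computed on mean-subtracted images (optionally within a
    mask); ties at the peak are broken by smallest rotation magnitude, then
    smallest shift norm.
    """

    symmetric = True

    def __init__(self, angle_range: tuple[float, float] = (-45.0, 45.0),
                 angle_step: float = 1.0, mask: np.ndarray | None = None) -> None:
        super().__init__()
        self.angle_range = angle_range
        self.angle_step = angle_step
        self.mask = mask

    def _masked(self, im: np.ndarray) -> np.ndarray:
        if self.mask is not None:
            im = im * self.mask
        return im - im.mean()

    def register(self, moving: np.ndarray, fixed: np.ndarray) -> Affine:
        _check_not_flat(moving, fixed)
        h, w = fixed.shape
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
        f = self._masked(np.asarray(fixed, dtype=float))
        ft_fixed = np.fft.rfft2(f)
        fnorm = np.linalg.norm(f)
        a0, a1 = self.angle_range
        angles = np.arange(a0, a1 + 0.5 * self.angle_step, self.angle_step)
        best = None  # (score, |angle|, |shift|, angle, shift)
        for angle in angles:
            rot_t = Affine.rotation(angle, center)
            rot = apply_transform_to_image(moving, rot_t)
            m = self._masked(rot)
            mnorm = np.linalg.norm(m)
            if mnorm == 0 or fnorm == 0:
                continue
            corr = np.fft.irfft2(ft_fixed * np.conj(np.fft.rfft2(m)), s=f.shape)
            idx = np.unravel_index(np.argmax(corr), corr.shape)
            score = corr[idx] / (fnorm * mnorm)
            dy = idx[0] if idx[0] <= h // 2 else idx[0] - h
            dx = idx[1] if idx[1] <= w // 2 else idx[1] - w
            shift_norm = float(np.hypot(dx, dy))
            key = (-score, abs(angle), shift_norm)
            if best is None or _tie_break(key, best[0]):
                best = (key, angle, (dx, dy))
        if best is None:
            raise RegistrationError("no valid rotation candidate")
        _, angle, (dx, dy) = best
        return Affine.rigid(angle, (float(dx), float(dy)), center)


def _tie_break(key, best_key, tol: float = 1e-12) -> bool:
    """Lexicographic comparison treating near-equal scores as ties."""
    if key[0] < best_key[0] - tol:
        return True
    if key[0] > best_key[0] + tol:
        return False
    return key[1:] < best_key[1:]


# ---------------------------------------------------------------------------
# External transform import
# ---------------------------------------------------------------------------


def load_external_transform(path) -> Transform:
    """Load one transform computed by an external tool.

    Supports this package's JSON documents and minimal elastix-style
    ``TransformParameters`` text files: ``TranslationTransform`` (parameters
    ``tx ty``), ``EulerTransform`` (``theta_rad tx ty`` about
    ``CenterOfRotationPoint``) and ``BSplineTransform`` (all x-coefficients
    then all y-coefficients, x grid index fastest, with ``GridOrigin``,
    ``GridSpacing``, ``GridSize``).  Parameters are mapped literally onto
    this package's types and direction convention; callers importing
    resampling-convention (fixed-to-moving) transforms should invert them.
    """
    p = Path(path)
    text = p.read_text()
    if text.lstrip().startswith(("{", "[")):
        import json

        from .transforms import transform_from_dict

        doc = json.loads(text)
        return transform_from_dict(doc if isinstance(doc, dict) else doc[0])
    fields = dict(re.findall(r"\(\s*(\w+)\s+([^)]*)\)", text))
    kind = fields.get("Transform", "").strip('" ')
    params = np.array([float(v) for v in fields["TransformParameters"].split()])
    if kind == "TranslationTransform":
        return Translation(params)
    if kind in ("EulerTransform", "Euler2DTransform"):
        theta, tx, ty = params
        center = [float(v) for v in
                  fields.get("CenterOfRotationPoint", "0 0").split()]
        return Affine.rigid(np.degrees(theta), (tx, ty), center)
    if kind in ("BSplineTransform", "BSplineTransformWithDiffusion"):
        nx, ny = (int(v) for v in fields["GridSize"].split())
        origin = tuple(float(v) for v in fields["GridOrigin"].split())
        spacing = tuple(float(v) for v in fields["GridSpacing"].split())
        grid = ControlGrid(origin=origin, spacing=spacing, size=(nx, ny))
        half = params.size // 2
        cx = params[:half].reshape(ny, nx).T   # x index fastest in the file
        cy = params[half:].reshape(ny, nx).T
        return BSplineTransform(grid, np.stack([cx, cy], axis=-1))
    raise RegistrationError(f"unsupported external transform {kind!r}")
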