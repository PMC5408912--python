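"""Slice-stack container, image resampling and virtual-slice extraction.

Coordinate convention (used everywhere in the package): continuous, 0-based
pixel coordinates with the origin at the centre of the first pixel; ``x``
runs along columns, ``y`` along rows.  Transforms act on coordinates -- a
transform ``f`` moves image *content* by ``f``, so resampling pulls
intensities through the inverse map: ``out(x) = in(f^{-1}(x))``.  For the
(non-invertible) B-spline fields the control-polygon approximation
``f^{-1}(x) ~ x - u(x)`` is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .transforms import (Affine, BSplineTransform, Transform, TransformError,
                         Translation, transform_from_dict, transform_to_dict)

_INTERP_ORDER = {"nearest": 0, "linear": 1}


@dataclass
class SliceStack:
    """An ordered stack of uniform 2-D grayscale slices.

    ``images`` is ``(N, H, W)`` float64; ``pixel_spacing`` is ``(x, y)`` and
    ``slice_spacing`` the physical distance between slice centres, used for
    display metadata and kernel-width conversions.
    """

    images: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_spacing: float = 1.0
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        im = np.asarray(self.images, dtype=float)
        if im.ndim != 3:
            raise ValueError(f"images must be (N, H, W), got shape {im.shape}")
        if any(s <= 0 for s in self.pixel_spacing) or self.slice_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.ids is not None and len(self.ids) != im.shape[0]:
            raise ValueError("ids length must match slice count")
        self.images = im

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

_SLICE_SUFFIXES = (".tif", ".tiff", ".png")


def read_stack(path, pixel_spacing=(1.0, 1.0), slice_spacing=1.0) -> SliceStack:
    """Read a stack from a directory of TIFF/PNG slices (ordered by filename)
    or a multi-page TIFF.  RGB images are converted to grayscale by channel
    averaging."""
    import imageio.v3 as iio

    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _SLICE_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG slices in {p}")
        frames = [np.asarray(iio.imread(f)) for f in files]
        ids = [f.stem for f in files]
    else:
        import tifffile

        frames = list(tifffile.imread(p))
        ids = [f"{p.stem}_{i:04d}" for i in range(len(frames))]
    frames = [f.mean(axis=-1) if f.ndim == 3 else f for f in frames]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"slices have non-uniform shapes: {sorted(shapes)}")
    return SliceStack(np.stack(frames).astype(float), tuple(pixel_spacing),
                      float(slice_spacing), ids)


def write_stack(stack: SliceStack, directory, fmt: str = "tiff") -> list[Path]:
    """Write one image file per slice (float32 TIFF or 8-bit PNG)."""
    import imageio.v3 as iio
    import tifffile

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, im in enumerate(stack.images):
        name = stack.ids[i] if stack.ids else f"slice_{i:04d}"
        if fmt == "tiff":
            fp = out / f"{name}.tif"
            tifffile.imwrite(fp, im.astype(np.float32))
        elif fmt == "png":
            fp = out / f"{name}.png"
            lo, hi = im.min(), im.max()
            scaled = np.zeros_like(im) if hi == lo else (im - lo) / (hi - lo)
            iio.imwrite(fp, (scaled * 255).astype(np.uint8))
        else:
            raise ValueError(f"unknown format {fmt!r}")
        paths.append(fp)
    return paths


def save_transforms(path, transforms) -> None:
    Path(path).write_text(json.dumps([transform_to_dict(t) for t in transforms],
                                     indent=1))


def load_transforms(path) -> list[Transform]:
    return [transform_from_dict(d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def _inverse_source_coords(t: Transform, shape: tuple[int, int]) -> np.ndarray:
    """(2, H, W) array of (row, col) source coordinates ``f^{-1}(x)``."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    if isinstance(t, Translation):
        if t.delta.size != 2:
            raise TransformError("need a 2-D translation to resample an image")
        sx = xx - t.delta[0]
        sy = yy - t.delta[1]
    elif isinstance(t, Affine):
        inv = t.invert()
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
        src = inv.apply(pts)
        sx = src[:, 0].reshape(shape)
        sy = src[:, 1].reshape(shape)
    elif isinstance(t, BSplineTransform):
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
        u = t.displace(pts)               # approximate inverse: x - u(x)
        sx = (pts[:, 0] - u[:, 0]).reshape(shape)
        sy = (pts[:, 1] - u[:, 1]).reshape(shape)
    else:
        raise TransformError(f"cannot resample through {type(t).__name__}")
    return np.stack([sy, sx])


def apply_transform_to_image(image: np.ndarray, t: Transform,
                             interpolation: str = "linear",
                             background: float = 0.0) -> np.ndarray:
    """Resample ``image`` once through transform ``t`` (content moves by
    ``t``); out-of-field pixels are filled with ``background``."""
    try:
        order = _INTERP_ORDER[interpolation]
    except KeyError:
        raise ValueError(f"interpolation must be one of {list(_INTERP_ORDER)}")
    coords = _inverse_source_coords(t, image.shape)
    return ndimage.map_coordinates(np.asarray(image, dtype=float), coords,
                                   order=order, mode="constant", cval=background)


def resample_stack(stack: SliceStack, totals, interpolation: str = "linear",
                   background: float = 0.0) -> SliceStack:
    """Apply one composed transform per slice -- each slice is resampled
    exactly once, deferring interpolation error to a single step."""
    if len(totals) != len(stack):
        raise ValueError(f"{len(totals)} transforms for {len(stack)} slices")
    out = np.stack([apply_transform_to_image(im, t, interpolation, background)
                    for im, t in zip(stack.images, totals)])
    return SliceStack(out, stack.pixel_spacing, stack.slice_spacing, stack.ids)


# ---------------------------------------------------------------------------
# Virtual slices
# ---------------------------------------------------------------------------


def virtual_slice(stack: SliceStack, plane: str, index: int) -> np.ndarray:
    """Orthogonal resection through the reconstructed volume.

    ``plane="XZ"`` cuts at row ``index`` (output shape ``(N, W)``);
    ``plane="YZ"`` cuts at column ``index`` (output shape ``(N, H)``).
    The z axis is typically anisotropic; ``stack.slice_spacing`` /
    ``stack.pixel_spacing`` give the aspect ratio for display.
    """
    n, h, w = stack.images.shape
    if plane.upper() == "XZ":
        if not 0 <= index < h:
            raise IndexError(f"row index {index} out of range [0, {h})")
        return stack.images[:, index, :]
    if plane.upper() == "YZ":
        if not 0 <= index < w:
            raise IndexError(f"column index {index} out of range [0, {w})")
        return stack.images[:, :, index]
    raise ValueError("plane must be 'XZ' or 'YZ'")
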