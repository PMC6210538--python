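"""Histogram-of-oriented-gradients feature maps and multi-scale pyramids.

The detector scores 5x5-cell part templates against a grid of orientation
histograms ("HOG cells") computed from each video frame.  A feature pyramid
makes detection scale-invariant: level ``k`` holds the HOG grid of the frame
resized by ``2**(-k/interval)``.

Conventions
-----------
* Gradients use central differences in the interior and one-sided
  differences at the borders (the ``numpy.gradient`` stencil).
* Orientations are *unsigned*: angles are folded into ``[0, pi)`` and
  hard-assigned to one of ``bins`` equal sectors, weighted by gradient
  magnitude.
* Cells are non-overlapping ``cell_size_px`` squares anchored at the image
  origin; trailing rows/columns that do not fill a cell are ignored.
* Color frames are converted to luminance with ITU-R BT.601 weights
  (0.299 R + 0.587 G + 0.114 B) before gradients are taken.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.transform import resize

__all__ = [
    "FeatureConfig",
    "HOGLevel",
    "HOGPyramid",
    "compute_hog",
    "normalize_cells",
    "build_pyramid",
    "to_grayscale",
    "ImageSizeError",
]

#: side of a part template, in cells
PATCH_CELLS = 5

_BT601 = np.array([0.299, 0.587, 0.114])


class ImageSizeError(ValueError):
    """Raised when an image is too small for the requested cell grid."""


@dataclass(frozen=True)
class FeatureConfig:
    """HOG settings shared by a model and the frames scored against it."""

    cell_size_px: int = 8
    bins: int = 9
    normalize: str = "block4"  # "block4" | "cell" | "none"
    interval: int = 2
    min_level_px: int = 40
    #: frames are resized by this factor before feature extraction; > 1
    #: refines part localization below the cell quantization (useful when
    #: the subject is small relative to the cell grid)
    upsample: float = 1.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(**d)

    @property
    def patch_px(self) -> int:
        """Side of a part patch in pixels at level 0."""
        return PATCH_CELLS * self.cell_size_px


@dataclass
class HOGLevel:
    """One pyramid level: a rows x cols x bins grid of cell histograms."""

    cells: np.ndarray
    cell_size_px: int
    scale: float
    bins: int

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.cells.shape[0], self.cells.shape[1]

    def cell_topleft_px(self, x: int, y: int) -> tuple[float, float]:
        """Top-left pixel (original-image coordinates) of cell ``(x, y)``."""
        c = self.cell_size_px
        return x * c / self.scale, y * c / self.scale

    def patch_center_px(self, x: int, y: int) -> tuple[float, float]:
        """Center pixel (original-image coordinates) of the 5x5-cell patch
        whose top-left cell is ``(x, y)``."""
        c = self.cell_size_px
        cx = (x + PATCH_CELLS / 2.0) * c - 0.5
        cy = (y + PATCH_CELLS / 2.0) * c - 0.5
        return cx / self.scale, cy / self.scale

    def px_to_cell(self, px: float, py: float) -> tuple[int, int]:
        """Cell index containing original-image pixel ``(px, py)``."""
        c = self.cell_size_px
        return int(np.floor(px * self.scale / c)), int(np.floor(py * self.scale / c))


@dataclass
class HOGPyramid:
    levels: list[HOGLevel]
    interval: int

    def __post_init__(self):
        scales = [lv.scale for lv in self.levels]
        if not scales or scales[0] != 1.0:
            raise ValueError("pyramid must start at scale 1.0")
        if any(b >= a for a, b in zip(scales, scales[1:])):
            raise ValueError("pyramid scales must strictly decrease")

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance conversion (BT.601); pass-through for 2-D input."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return img[..., :3] @ _BT601
    raise ValueError(f"expected 2-D or HxWx3 image, got shape {img.shape}")


def _raw_histograms(img: np.ndarray, cell_size_px: int, bins: int) -> np.ndarray:
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), np.pi)
    b = np.minimum((ang / (np.pi / bins)).astype(np.intp), bins - 1)

    rows = img.shape[0] // cell_size_px
    cols = img.shape[1] // cell_size_px
    h, w = rows * cell_size_px, cols * cell_size_px
    mag, b = mag[:h, :w], b[:h, :w]

    r_idx = np.repeat(np.arange(rows), cell_size_px)[:, None]
    c_idx = np.repeat(np.arange(cols), cell_size_px)[None, :]
    hist = np.zeros((rows, cols, bins))
    np.add.at(
        hist,
        (np.broadcast_to(r_idx, (h, w)), np.broadcast_to(c_idx, (h, w)), b),
        mag,
    )
    return hist


def normalize_cells(hist: np.ndarray, scheme: str = "block4", eps: float = 1e-10) -> np.ndarray:
    """Normalize raw cell histograms into ``[0, 1]``.

    ``"cell"`` divides each cell by its own L2 norm (idempotent); ``"block4"``
    averages the cell normalized by the energies of the four 2x2 blocks that
    contain it (border blocks replicate edge cells); ``"none"`` passes raw
    histograms through.
    """
    if scheme == "none":
        return hist.copy()
    if scheme == "cell":
        norm = np.sqrt((hist ** 2).sum(axis=-1, keepdims=True))
        return np.where(norm > 0, hist / np.where(norm > 0, norm, 1.0), 0.0)
    if scheme == "block4":
        p = np.pad(hist, ((1, 1), (1, 1), (0, 0)), mode="edge")
        e = (p ** 2).sum(-1)
        blk = e[:-1, :-1] + e[:-1, 1:] + e[1:, :-1] + e[1:, 1:]
        inv = 1.0 / np.sqrt(blk + eps)
        f = 0.25 * (inv[:-1, :-1] + inv[:-1, 1:] + inv[1:, :-1] + inv[1:, 1:])
        return hist * f[..., None]
    raise ValueError(f"unknown normalization scheme {scheme!r}")


def compute_hog(
    image: np.ndarray,
    cell_size_px: int = 8,
    bins: int = 9,
    normalize: str = "block4",
    scale: float = 1.0,
) -> HOGLevel:
    """Compute one HOG grid from a grayscale or color image.

    Raises
    ------
    ImageSizeError
        If the image is smaller than a single cell in either dimension.
    """
    if cell_size_px <= 0 or bins <= 0:
        raise ValueError("cell_size_px and bins must be positive")
    img = to_grayscale(image)
    if not np.all(np.isfinite(img)):
        raise ValueError("image intensities must be finite")
    if img.shape[0] < cell_size_px or img.shape[1] < cell_size_px:
        raise ImageSizeError(
            f"image {img.shape} smaller than one {cell_size_px}px cell"
        )
    hist = _raw_histograms(img, cell_size_px, bins)
    return HOGLevel(
        cells=normalize_cells(hist, normalize),
        cell_size_px=cell_size_px,
        scale=scale,
        bins=bins,
    )


def build_pyramid(
    image: np.ndarray,
    cell_size_px: int = 8,
    bins: int = 9,
    interval: int = 2,
    min_level_px: int = 40,
    normalize: str = "block4",
) -> HOGPyramid:
    """Multi-scale HOG pyramid with scales ``2**(-k/interval)``.

    Level 0 is :func:`compute_hog` of the original image; levels stop once a
    resized side would fall below ``min_level_px``.
    """
    if interval <= 0:
        raise ValueError("interval must be a positive integer")
    img = to_grayscale(image)
    if min(img.shape[:2]) < min_level_px:
        raise ImageSizeError(
            f"image {img.shape} smaller than min_level_px={min_level_px}"
        )
    levels = [compute_hog(img, cell_size_px, bins, normalize, scale=1.0)]
    k = 1
    while True:
        s = 2.0 ** (-k / interval)
        shape = (int(round(img.shape[0] * s)), int(round(img.shape[1] * s)))
        if min(shape) < min_level_px:
            break
        small = resize(img, shape, order=1, anti_aliasing=True, preserve_range=True)
        levels.append(compute_hog(small, cell_size_px, bins, normalize, scale=s))
        k += 1
    return HOGPyramid(levels=levels, interval=interval)


def upsample_image(image: np.ndarray, factor: float) -> np.ndarray:
    """Resize a frame by ``factor`` (bilinear); identity for factor 1."""
    img = to_grayscale(image)
    if factor == 1.0:
        return img
    shape = (int(round(img.shape[0] * factor)), int(round(img.shape[1] * factor)))
    return resize(img, shape, order=1, anti_aliasing=factor < 1.0, preserve_range=True)


def pyramid_from_config(image: np.ndarray, cfg: FeatureConfig) -> HOGPyramid:
    """Feature pyramid of a frame under a model's settings (including the
    upsampling factor; pyramid scales stay relative to the resized frame)."""
    return build_pyramid(
        upsample_image(image, cfg.upsample),
        cell_size_px=cfg.cell_size_px,
        bins=cfg.bins,
        interval=cfg.interval,
        min_level_px=cfg.min_level_px,
        normalize=cfg.normalize,
    )
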