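"""Reusable segmentation primitives for the fluorescence-imaging pipelines.

The two imaging readouts in this package (neurite disintegration and NPM1
nucleolar translocation) are composed from a small set of operators that
mirror the building blocks of a CellProfiler-style pipeline: Gaussian
smoothing, two-class Otsu thresholding (global or blocked-adaptive with a
multiplicative correction factor), ridge ("line structure") enhancement,
Sobel edge enhancement, and connected-component labelling with optional
merging and hole filling.

Conventions fixed here and relied on by every downstream module:

* ``smoothing_scale`` is a Gaussian sigma in pixels; scale 0 means no
  smoothing.
* Otsu thresholds are computed on a 256-bin histogram spanning the image's
  own ``[min, max]`` range; candidate thresholds are interior bin edges and
  a pixel belongs to the foreground when its value is >= the threshold.
* Labelling uses 8-connectivity; hole filling uses the complementary
  4-connectivity for the background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "ChannelImage",
    "BinaryMask",
    "LabelMap",
    "ThresholdSpec",
    "DegenerateImageWarning",
    "smooth",
    "otsu_threshold",
    "threshold_mask",
    "enhance_line_structures",
    "sobel_magnitude",
    "label_objects",
]

Channel = Literal["tubulin", "dapi", "npm1", "other"]

OTSU_BINS = 256


class DegenerateImageWarning(UserWarning):
    """Raised (as a warning) when a pipeline meets a blank field of view."""


@dataclass(frozen=True)
class ChannelImage:
    """Single-channel 2-D fluorescence intensity raster.

    Parameters
    ----------
    pixels:
        2-D array of finite, non-negative intensities (arbitrary units).
    channel:
        Which stain the raster holds; informational but carried through
        pipelines so results are traceable.
    scale:
        Microns per pixel, if known. Purely informational.
    """

    pixels: np.ndarray
    channel: Channel = "other"
    scale: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("ChannelImage requires a 2-D raster of at least 2x2 pixels")
        if not np.all(np.isfinite(px)):
            raise ValueError("intensities must be finite")
        if px.min() < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """Boolean raster sharing the geometry of its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            px = px.astype(bool)
        if px.ndim != 2:
            raise ValueError("BinaryMask must be 2-D")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class LabelMap:
    """Integer raster: 0 = background, k > 0 = object k (labels contiguous)."""

    pixels: np.ndarray
    object_count: int = field(default=-1)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("LabelMap must be 2-D")
        px = px.astype(np.int32)
        n = int(px.max(initial=0))
        labels = np.unique(px)
        expected = np.arange(0, n + 1)
        present = np.union1d(labels, [0])
        if not np.array_equal(present, expected):
            raise ValueError("labels must be contiguous 1..object_count")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "object_count", n)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ThresholdSpec:
    """Parameters of one Otsu thresholding step.

    ``correction_factor`` multiplies the computed threshold (values above 1
    shrink the mask), matching the CellProfiler "threshold correction
    factor". ``window`` is the tile side for the adaptive strategy.
    """

    strategy: Literal["global", "adaptive"] = "global"
    smoothing_scale: float = 0.0
    correction_factor: float = 1.0
    window: int = 50
    fill_holes: bool = False
    fill_hole_max: int = 50

    def __post_init__(self) -> None:
        if self.strategy not in ("global", "adaptive"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.smoothing_scale < 0:
            raise ValueError("smoothing_scale must be >= 0")
        if self.correction_factor <= 0:
            raise ValueError("correction_factor must be > 0")
        if self.strategy == "adaptive" and self.window < 8:
            raise ValueError("adaptive window must be >= 8 pixels")


def _as_pixels(image: ChannelImage | np.ndarray) -> np.ndarray:
    if isinstance(image, ChannelImage):
        return image.pixels
    return np.asarray(image, dtype=float)


def smooth(image: ChannelImage, smoothing_scale: float) -> ChannelImage:
    """Gaussian blur with sigma = ``smoothing_scale`` pixels; 0 = identity."""
    if smoothing_scale < 0:
        raise ValueError("smoothing_scale must be >= 0")
    if smoothing_scale == 0:
        return image
    blurred = ndimage.gaussian_filter(image.pixels, sigma=smoothing_scale)
    # reflective boundaries keep total intensity conserved for interior signals
    return ChannelImage(np.clip(blurred, 0, None), image.channel, image.scale)


def _otsu_scalar(values: np.ndarray) -> float:
    """Two-class Otsu threshold over a 256-bin histogram on [min, max].

    Returns the interior bin edge maximizing between-class variance; ties
    break toward the lowest edge. Raises on constant input.
    """
    vmin = float(values.min())
    vmax = float(values.max())
    if vmin == vmax:
        raise ValueError("Otsu threshold undefined for a constant image")
    hist, edges = np.histogram(values.ravel(), bins=OTSU_BINS, range=(vmin, vmax))
    hist = hist.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = np.cumsum(hist)
    m = np.cumsum(hist * centers)
    total_w = w[-1]
    total_m = m[-1]
    # candidate k splits bins [0..k-1] | [k..255], threshold = edges[k]
    w0 = w[:-1]
    w1 = total_w - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (total_m - m[:-1]) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[(w0 == 0) | (w1 == 0)] = -np.inf
    k = int(np.argmax(var_between)) + 1
    return float(edges[k])


def otsu_threshold(image: ChannelImage | np.ndarray) -> float:
    """Global two-class Otsu threshold of an image (see `_otsu_scalar`)."""
    return _otsu_scalar(_as_pixels(image))


def _adaptive_threshold_surface(pixels: np.ndarray, window: int) -> np.ndarray:
    """Per-tile Otsu thresholds bilinearly interpolated between tile centers.

    Tiles whose content is near-constant (standard deviation below 5% of
    the global intensity range) inherit the global threshold, so blank or
    uniformly bright regions do not produce spurious noise-splitting
    thresholds.
    """
    h, wdt = pixels.shape
    global_thr = _otsu_scalar(pixels)
    global_range = float(pixels.max() - pixels.min())
    ny = max(1, h // window)
    nx = max(1, wdt // window)
    y_edges = np.linspace(0, h, ny + 1).astype(int)
    x_edges = np.linspace(0, wdt, nx + 1).astype(int)
    thr = np.empty((ny, nx))
    cy = np.empty(ny)
    cx = np.empty(nx)
    for i in range(ny):
        cy[i] = 0.5 * (y_edges[i] + y_edges[i + 1] - 1)
        for j in range(nx):
            tile = pixels[y_edges[i]:y_edges[i + 1], x_edges[j]:x_edges[j + 1]]
            if tile.std() < 0.05 * global_range:
                thr[i, j] = global_thr
            else:
                thr[i, j] = _otsu_scalar(tile)
    for j in range(nx):
        cx[j] = 0.5 * (x_edges[j] + x_edges[j + 1] - 1)
    yy = np.clip(np.arange(h), cy[0], cy[-1])
    xx = np.clip(np.arange(wdt), cx[0], cx[-1])
    iy = np.clip(np.searchsorted(cy, yy) - 1, 0, max(ny - 2, 0))
    ix = np.clip(np.searchsorted(cx, xx) - 1, 0, max(nx - 2, 0))
    if ny > 1:
        ty = (yy - cy[iy]) / (cy[iy + 1] - cy[iy])
    else:
        ty = np.zeros(h)
        iy = np.zeros(h, dtype=int)
    if nx > 1:
        tx = (xx - cx[ix]) / (cx[ix + 1] - cx[ix])
    else:
        tx = np.zeros(wdt)
        ix = np.zeros(wdt, dtype=int)
    ty = ty[:, None]
    tx = tx[None, :]
    iy = iy[:, None]
    ix = ix[None, :]
    iy1 = np.minimum(iy + 1, ny - 1)
    ix1 = np.minimum(ix + 1, nx - 1)
    surface = (
        thr[iy, ix] * (1 - ty) * (1 - tx)
        + thr[iy1, ix] * ty * (1 - tx)
        + thr[iy, ix1] * (1 - ty) * tx
        + thr[iy1, ix1] * ty * tx
    )
    return surface


def threshold_mask(image: ChannelImage, spec: ThresholdSpec) -> BinaryMask:
    """Smooth, Otsu-threshold (global or adaptive), correct, binarize.

    A constant image yields an empty mask with a `DegenerateImageWarning`
    instead of an exception so pipelines proceed on blank fields of view.
    """
    smoothed = smooth(image, spec.smoothing_scale).pixels
    if smoothed.max() == smoothed.min():
        warnings.warn(
            "constant image: returning an empty mask", DegenerateImageWarning,
            stacklevel=2,
        )
        return BinaryMask(np.zeros(image.shape, dtype=bool))
    if spec.strategy == "global":
        thr = _otsu_scalar(smoothed) * spec.correction_factor
        mask = smoothed >= thr
    else:
        surface = _adaptive_threshold_surface(smoothed, spec.window)
        mask = smoothed >= surface * spec.correction_factor
    if spec.fill_holes:
        mask = _fill_holes(mask, spec.fill_hole_max)
    return BinaryMask(mask)


def enhance_line_structures(image: ChannelImage, feature_size: int) -> ChannelImage:
    """Ridge ("tubeness") response emphasizing curvilinear bright structures.

    Hessian-eigenvalue tubeness at sigma = feature_size / 2: the response is
    the magnitude of the most negative Hessian eigenvalue (scale-normalized
    by sigma^2), clipped at zero, so bright ridges of width up to
    ``feature_size`` score higher than isotropic blobs of equal intensity.
    """
    if feature_size < 2:
        raise ValueError("feature_size must be >= 2")
    sigma = feature_size / 2.0
    # mean subtraction is a no-op mathematically (derivatives kill constants)
    # but avoids the small DC leakage of the sampled derivative kernels
    px = image.pixels - image.pixels.mean()
    hxx = ndimage.gaussian_filter(px, sigma, order=(0, 2))
    hyy = ndimage.gaussian_filter(px, sigma, order=(2, 0))
    hxy = ndimage.gaussian_filter(px, sigma, order=(1, 1))
    trace = hxx + hyy
    root = np.sqrt((hxx - hyy) ** 2 + 4 * hxy ** 2)
    lam_min = 0.5 * (trace - root)  # most negative eigenvalue on bright ridges
    response = np.clip(-lam_min, 0, None) * sigma ** 2
    return ChannelImage(response, image.channel, image.scale)


def sobel_magnitude(image: ChannelImage) -> ChannelImage:
    """Gradient magnitude under the standard (unnormalized) Sobel kernels.

    No normalization is applied: an isolated vertical step of height h gives
    an interior response of 4h on the columns adjacent to the edge.
    """
    px = image.pixels
    gx = ndimage.sobel(px, axis=1, mode="reflect")
    gy = ndimage.sobel(px, axis=0, mode="reflect")
    return ChannelImage(np.hypot(gx, gy), image.channel, image.scale)


def _fill_holes(mask: np.ndarray, max_hole: int) -> np.ndarray:
    """Fill background holes of area <= max_hole enclosed by one object.

    Holes are 4-connected background components not touching the border;
    a hole is filled only when all its 8-neighbouring foreground pixels
    belong to a single object.
    """
    if max_hole <= 0:
        return mask
    labels = measure.label(mask, connectivity=2)
    bg_labels, n_bg = ndimage.label(~mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n_bg == 0:
        return mask
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_bg = np.unique(bg_labels[border & ~mask])
    out = mask.copy()
    for hole_id in range(1, n_bg + 1):
        if hole_id in border_bg:
            continue
        hole = bg_labels == hole_id
        if int(hole.sum()) > max_hole:
            continue
        ring = ndimage.binary_dilation(
            hole, structure=np.ones((3, 3), bool)) & mask
        owners = np.unique(labels[ring])
        owners = owners[owners > 0]
        if owners.size == 1:
            out |= hole
    return out


def label_objects(mask: BinaryMask, merge_all: bool = False,
                  fill_hole_max: int = 0) -> LabelMap:
    """8-connected component labelling with optional merging and hole filling.

    ``merge_all`` collapses all foreground into a single object (the
    CellProfiler SplitOrMergeObjects "merge" behaviour); holes of area up to
    ``fill_hole_max`` enclosed by a single object are filled into it.
    """
    px = mask.pixels
    if merge_all:
        # merge before filling: holes are judged against the single object
        if fill_hole_max > 0:
            px = _fill_holes(px, fill_hole_max)
        return LabelMap(px.astype(np.int32))
    if fill_hole_max > 0:
        px = _fill_holes(px, fill_hole_max)
    return LabelMap(measure.label(px, connectivity=2))
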