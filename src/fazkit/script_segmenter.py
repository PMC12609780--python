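"""Deterministic FAZ segmentation by the morphological script pipeline.

The pipeline reproduces, stage by stage, a semiautomated macro for FAZ
measurement on en-face OCTA angiograms: convert to 8-bit, crop a 512×512
field around the fovea, downscale to a 270×270 working frame, Otsu-binarize
the vessel signal, skeletonize it, dilate eight times and erode four times
to close the perifoveal capillary ring, upscale back to 512×512, and
flood-fill ("wand") the enclosed avascular region from the image center.
The net dilation (8 − 4 iterations at the working scale) closes gaps left
by capillaries whose flow signal drops out near the FAZ border.

All stages are deterministic; identical inputs give bit-identical masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import skeletonize as _skimage_skeletonize
from skimage.segmentation import flood as _flood

from .io import AngiogramImage, BinaryMask

__all__ = [
    "ScriptPipelineConfig",
    "FazRegion",
    "SegmentationError",
    "FazSeedFailure",
    "FazUndefinedError",
    "to_8bit",
    "center_crop",
    "resize_bilinear",
    "otsu_threshold",
    "OtsuResult",
    "skeletonize",
    "dilate",
    "erode",
    "wand_region",
    "WandResult",
    "run_script_pipeline",
]


class SegmentationError(RuntimeError):
    """A segmentation stage failed on this input."""


class FazSeedFailure(SegmentationError):
    """No avascular pixel found near the seed point (vessel-covered center)."""


class FazUndefinedError(SegmentationError):
    """The pipeline cannot define a FAZ on this input (e.g. blank image)."""


@dataclass(frozen=True)
class ScriptPipelineConfig:
    """Stage parameters of the script pipeline.

    Defaults follow the macro verbatim: crop rectangle (127, 127, 512, 512),
    270×270 working size, 8 dilations, 4 erosions, wand seed at (255, 255)
    with tolerance 0.  ``seed_rescue_radius_px`` bounds the nearest-background
    search used when the seed lands on a vessel pixel.  ``wand_connectivity``
    is 4 by default: an 8-connected flood can leak through diagonal
    single-pixel gaps in the dilated vessel wall.  ``wand_on_binary``
    thresholds the upscaled image at 128 before the wand instead of flooding
    the gray image at tolerance 0.
    """

    crop_x: int = 127
    crop_y: int = 127
    crop_w: int = 512
    crop_h: int = 512
    work_size: int = 270
    n_dilate: int = 8
    n_erode: int = 4
    wand_seed: tuple[int, int] = (255, 255)
    wand_tolerance: int = 0
    seed_rescue_radius_px: int = 10
    wand_connectivity: int = 4
    wand_on_binary: bool = False

    def __post_init__(self) -> None:
        if self.crop_w <= 0 or self.crop_h <= 0:
            raise ValueError("crop extents must be positive")
        if self.work_size < 3:
            raise ValueError("work_size must be >= 3")
        if not (self.n_dilate >= self.n_erode >= 0):
            raise ValueError("need n_dilate >= n_erode >= 0")
        if self.wand_connectivity not in (4, 8):
            raise ValueError("wand_connectivity must be 4 or 8")


@dataclass
class FazRegion:
    """A connected FAZ candidate region in 512×512 crop coordinates."""

    mask: BinaryMask
    pixel_count: int
    boundary: np.ndarray  # closed polygon, (N, 2) array of (x, y) vertices
    method: str
    area_mm2: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pixel_count != self.mask.foreground_count:
            raise ValueError("pixel_count does not match mask foreground")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


# ---------------------------------------------------------------------------
# stage 1: bit-depth conversion


def to_8bit(pixels: np.ndarray) -> np.ndarray:
    """Coerce a raster to 8-bit grayscale.

    8-bit input is returned unchanged.  16-bit (or other integer) input is
    linearly min–max scaled over its occupied range onto [0, 255] with
    round-half-up; a constant image maps to 0.  3-channel color input is
    converted to luminance 0.299 R + 0.587 G + 0.114 B and rounded.
    """
    arr = np.asarray(pixels)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(f"unsupported channel count {arr.shape[2]}")
        rgb = arr[..., :3].astype(np.float64)
        lum = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        return np.clip(_round_half_up(lum), 0, 255).astype(np.uint8)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale or 3-channel color image")
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    scaled = (arr - lo) * (255.0 / (hi - lo))
    return np.clip(_round_half_up(scaled), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# stage 2: crop


def center_crop(image: np.ndarray, cfg: ScriptPipelineConfig = ScriptPipelineConfig()) -> np.ndarray:
    """Crop the (crop_x, crop_y, crop_w, crop_h) rectangle from the source."""
    h, w = image.shape[:2]
    need_h, need_w = cfg.crop_y + cfg.crop_h, cfg.crop_x + cfg.crop_w
    if h < need_h or w < need_w:
        raise ValueError(
            f"source {h}x{w} too small for crop: needs at least {need_h}x{need_w} "
            f"(offset ({cfg.crop_x}, {cfg.crop_y}) + extent ({cfg.crop_w}, {cfg.crop_h}))"
        )
    return image[cfg.crop_y : cfg.crop_y + cfg.crop_h, cfg.crop_x : cfg.crop_x + cfg.crop_w]


# ---------------------------------------------------------------------------
# stage 3/8: resize


def _axis_weights(n_in: int, n_out: int, average_on_downscale: bool) -> np.ndarray:
    """Resampling weight matrix (n_out × n_in) for one axis."""
    if n_out == n_in:
        return np.eye(n_in)
    s = n_in / n_out
    w = np.zeros((n_out, n_in))
    if n_out < n_in and average_on_downscale:
        # area (box) averaging: output pixel i integrates source [i·s, (i+1)·s)
        for i in range(n_out):
            lo, hi = i * s, (i + 1) * s
            j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
            for j in range(j0, min(j1, n_in)):
                w[i, j] = (min(j + 1, hi) - max(j, lo)) / s
    else:
        # bilinear: sample at the pixel-center-aligned source coordinate
        src = (np.arange(n_out) + 0.5) * s - 0.5
        src = np.clip(src, 0.0, n_in - 1.0)
        j0 = np.floor(src).astype(int)
        frac = src - j0
        j1 = np.minimum(j0 + 1, n_in - 1)
        for i in range(n_out):
            w[i, j0[i]] += 1.0 - frac[i]
            w[i, j1[i]] += frac[i]
    return w


def resize_bilinear(
    image: np.ndarray, out_w: int, out_h: int, average_on_downscale: bool = True
) -> np.ndarray:
    """Separable resample to (out_h × out_w), 8-bit in, 8-bit out.

    Downscaled axes are box-averaged over the exact source footprint of
    each output pixel (the "average when downsizing" behaviour); upscaled
    axes are bilinearly interpolated with pixel-center alignment.  Results
    are rounded half-up back to 8-bit, so a constant image stays constant.
    """
    if out_w < 1 or out_h < 1:
        raise ValueError("target size must be positive")
    arr = np.asarray(image, dtype=np.float64)
    wr = _axis_weights(arr.shape[0], out_h, average_on_downscale)
    wc = _axis_weights(arr.shape[1], out_w, average_on_downscale)
    out = wr @ arr @ wc.T
    return np.clip(_round_half_up(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# stage 4: Otsu binarization


class OtsuResult(NamedTuple):
    mask: BinaryMask
    threshold: int
    degenerate: bool


def otsu_threshold(image: np.ndarray) -> OtsuResult:
    """Binarize an 8-bit image at the Otsu threshold, vessels ("white") as
    foreground.

    The threshold t* maximizes the between-class variance of the 256-bin
    histogram; pixels with value > t* become foreground (255).  Ties pick
    the lowest threshold.  A constant image has no Otsu threshold: the
    result is an all-background mask flagged ``degenerate``.
    """
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError("otsu_threshold expects an 8-bit image")
    hist = np.bincount(arr.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # count of pixels <= t
    sum0 = np.cumsum(hist * levels)
    w1 = total - w0
    mu0 = np.divide(sum0, w0, out=np.zeros(256), where=w0 > 0)
    mu1 = np.divide(sum0[-1] - sum0, w1, out=np.zeros(256), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2  # scaled between-class variance
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return OtsuResult(BinaryMask(np.zeros(arr.shape, dtype=np.uint8)), 0, True)
    sigma_b[~valid] = -1.0
    t = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    mask = BinaryMask.from_bool(arr > t)
    return OtsuResult(mask, t, False)


# ---------------------------------------------------------------------------
# stage 5: skeletonization


def skeletonize(mask: BinaryMask) -> BinaryMask:
    """Thin the vessel mask to 1-px centerlines (Zhang–Suen iterative
    thinning).  The skeleton is a subset of the input foreground and
    preserves its 8-connected components."""
    thin = _skimage_skeletonize(mask.as_bool(), method="zhang")
    return BinaryMask.from_bool(thin, mask.origin)


# ---------------------------------------------------------------------------
# stage 6/7: morphology

_SE3 = np.ones((3, 3), dtype=bool)  # full 8-neighborhood structuring element


def dilate(mask: BinaryMask, iterations: int) -> BinaryMask:
    """Binary dilation with the 3×3 structuring element, ``iterations``
    times (maximum filter; out-of-bounds neighbors ignored)."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return BinaryMask(mask.pixels.copy(), mask.origin)
    out = ndimage.binary_dilation(mask.as_bool(), structure=_SE3, iterations=iterations)
    return BinaryMask.from_bool(out, mask.origin)


def erode(mask: BinaryMask, iterations: int) -> BinaryMask:
    """Binary erosion with the 3×3 structuring element (minimum filter,
    the dual of :func:`dilate`; out-of-bounds neighbors ignored, so the
    image border does not erode the mask)."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return BinaryMask(mask.pixels.copy(), mask.origin)
    out = ndimage.binary_erosion(
        mask.as_bool(), structure=_SE3, iterations=iterations, border_value=1
    )
    return BinaryMask.from_bool(out, mask.origin)


# ---------------------------------------------------------------------------
# stage 9: wand selection


class WandResult(NamedTuple):
    mask: BinaryMask
    seed: tuple[int, int]
    rescued: bool


def _rescue_seed(image: np.ndarray, seed_xy: tuple[int, int], radius: int) -> tuple[int, int]:
    """Nearest pixel with value < 128 within ``radius`` (Euclidean; ties by
    row-major scan order)."""
    x0, y0 = seed_xy
    h, w = image.shape
    best: tuple[float, int, int] | None = None
    r = int(np.ceil(radius))
    for y in range(max(0, y0 - r), min(h, y0 + r + 1)):
        for x in range(max(0, x0 - r), min(w, x0 + r + 1)):
            if image[y, x] < 128:
                d2 = (x - x0) ** 2 + (y - y0) ** 2
                if d2 <= radius**2:
                    key = (d2, y, x)
                    if best is None or key < best:
                        best = key
    if best is None:
        raise FazSeedFailure(
            f"FAZ seed failure: no background pixel within {radius} px of {seed_xy}"
        )
    return best[2], best[1]


def wand_region(
    image: np.ndarray,
    seed: tuple[int, int],
    tolerance: int = 0,
    rescue_radius: int = 10,
    connectivity: int = 4,
) -> WandResult:
    """Flood-fill the connected region of near-seed-valued pixels.

    ``seed`` is (x, y).  Pixels join the region iff their value differs
    from the seed pixel's value by at most ``tolerance`` and they are
    connected to the seed (4-connectivity by default).  If the seed lands
    on a vessel-valued pixel (>= 128) the nearest darker pixel within
    ``rescue_radius`` is used instead and the result is flagged
    ``rescued``.
    """
    arr = np.asarray(image)
    x, y = seed
    h, w = arr.shape
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"wand seed {seed} outside image {w}x{h}")
    rescued = False
    if arr[y, x] >= 128:
        x, y = _rescue_seed(arr, (x, y), rescue_radius)
        rescued = True
    conn = 1 if connectivity == 4 else 2
    # flood on int16 so the ± tolerance band cannot wrap the uint8 range
    region = _flood(arr.astype(np.int16), (y, x), tolerance=tolerance, connectivity=conn)
    return WandResult(BinaryMask.from_bool(region), (x, y), rescued)


# ---------------------------------------------------------------------------
# full pipeline


def _region_boundary(fg: np.ndarray) -> np.ndarray:
    """Closed boundary polygon of a foreground mask as (N, 2) (x, y) vertices."""
    contours = measure.find_contours(fg.astype(float), 0.5)
    if not contours:
        return np.empty((0, 2))
    longest = max(contours, key=len)
    return longest[:, ::-1]  # (row, col) -> (x, y)


def run_script_pipeline(
    angiogram: AngiogramImage,
    cfg: ScriptPipelineConfig = ScriptPipelineConfig(),
    keep_intermediates: bool = False,
) -> FazRegion:
    """Run the full morphological script pipeline on one angiogram.

    Stage order: to_8bit → center_crop → downscale to the working frame →
    Otsu threshold → skeletonize → dilate ×n → erode ×m → upscale back to
    the crop frame → wand flood-fill at the seed.  Returns the wand region
    as a :class:`FazRegion` (method ``"script"``) with the pixel count
    measured on the crop-sized frame.  When ``keep_intermediates`` is set
    the stage outputs are attached as ``region.intermediates`` (an ordered
    dict of arrays) for debugging.
    """
    stages: dict[str, np.ndarray] = {}

    img8 = to_8bit(angiogram.pixels)
    stages["01_8bit"] = img8
    cropped = center_crop(img8, cfg)
    stages["02_cropped"] = cropped
    small = resize_bilinear(cropped, cfg.work_size, cfg.work_size)
    stages["03_downscaled"] = small

    otsu = otsu_threshold(small)
    if otsu.degenerate:
        raise FazUndefinedError("FAZ undefined: degenerate Otsu threshold (constant image)")
    stages["04_binary"] = otsu.mask.pixels

    skel = skeletonize(otsu.mask)
    stages["05_skeleton"] = skel.pixels
    dil = dilate(skel, cfg.n_dilate)
    stages["06_dilated"] = dil.pixels
    ero = erode(dil, cfg.n_erode)
    stages["07_eroded"] = ero.pixels

    upscaled = resize_bilinear(ero.pixels, cfg.crop_w, cfg.crop_h)
    stages["08_upscaled"] = upscaled
    wand_input = upscaled
    if cfg.wand_on_binary:
        wand_input = np.where(upscaled >= 128, 255, 0).astype(np.uint8)
    wand = wand_region(
        wand_input,
        cfg.wand_seed,
        tolerance=cfg.wand_tolerance,
        rescue_radius=cfg.seed_rescue_radius_px,
        connectivity=cfg.wand_connectivity,
    )
    stages["09_region"] = wand.mask.pixels

    warnings = []
    if wand.rescued:
        warnings.append(f"wand seed {cfg.wand_seed} on vessel; rescued to {wand.seed}")

    region = FazRegion(
        mask=wand.mask,
        pixel_count=wand.mask.foreground_count,
        boundary=_region_boundary(wand.mask.as_bool()),
        method="script",
        warnings=warnings,
    )
    if keep_intermediates:
        region.intermediates = stages  # type: ignore[attr-defined]
    return region
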