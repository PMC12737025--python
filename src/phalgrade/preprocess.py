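"""Image preprocessing for top-view RGB-D and side-view RGB inputs.

Images are numpy arrays: ``(H, W)`` for single-channel (gray/depth),
``(H, W, 3)`` RGB, ``(H, W, 4)`` fused RGB-D; uint8 after normalization.
Coordinates are 0-based with (x = column, y = row) and half-open crop
intervals.

Top-view chain: register the depth image to the RGB image with a fixed
per-rig pixel offset, segment the plant against the white background
(grayscale -> Gaussian blur -> Otsu binarization -> largest component ->
morphological closing), zero the depth image outside the mask and clip
extreme in-mask values by percentile, then stack R,G,B,D into a four-channel
image.  Side-view chain: a fixed-offset crop removing the empty margins that
the constant camera/turntable geometry leaves around the plant.  A linear
brightness model ``B(x, y) = alpha * I(x, y)`` (clipped to the 8-bit range)
drives the lighting-robustness sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, transform

__all__ = [
    "AlignmentOffset",
    "CropSpec",
    "BrightnessSpec",
    "DEFAULT_SIDE_CROP",
    "align_depth",
    "plant_mask",
    "apply_mask",
    "clean_depth",
    "fuse_rgbd",
    "split_rgbd",
    "crop_side_view",
    "resize_for_detector",
    "adjust_brightness",
]


@dataclass(frozen=True)
class AlignmentOffset:
    """Signed pixel shift (dx, dy) registering the depth image to the RGB
    image; positive dx moves content right, positive dy moves it down."""

    dx: int = 0
    dy: int = 0


@dataclass(frozen=True)
class CropSpec:
    """Pixel margins to remove from each border."""

    left: int = 0
    right: int = 0
    top: int = 0
    bottom: int = 0

    def __post_init__(self) -> None:
        if min(self.left, self.right, self.top, self.bottom) < 0:
            raise ValueError(f"crop offsets must be nonnegative: {self}")


@dataclass(frozen=True)
class BrightnessSpec:
    """Linear brightness scaling coefficient; 1.0 is the identity."""

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


#: Side-view margins calibrated for the 4288x2848 capture geometry.
DEFAULT_SIDE_CROP = CropSpec(left=600, right=650, top=300, bottom=0)


def align_depth(depth: np.ndarray, offset: AlignmentOffset, fill: int = 0) -> np.ndarray:
    """Translate the depth image by (dx, dy); exposed borders take `fill`."""
    if depth.ndim != 2:
        raise ValueError(f"depth must be single-channel, got shape {depth.shape}")
    h, w = depth.shape
    if abs(offset.dx) >= w or abs(offset.dy) >= h:
        raise ValueError(
            f"offset {offset} exceeds image size {w}x{h}"
        )
    out = np.full_like(depth, fill)
    dx, dy = offset.dx, offset.dy
    src_x = slice(max(0, -dx), min(w, w - dx))
    src_y = slice(max(0, -dy), min(h, h - dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    out[dst_y, dst_x] = depth[src_y, src_x]
    return out


def plant_mask(rgb: np.ndarray, blur_sigma: float = 1.0,
               close_radius: int = 3) -> np.ndarray:
    """Binary plant mask (1 = plant) from an RGB image on a light background.

    Grayscale, Gaussian blur, Otsu threshold (plant darker than background),
    keep the largest connected component, fill its holes and close it with an
    elliptical (disk) structuring element.  A blank image yields an empty
    mask with a warning rather than an exception.
    """
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {rgb.shape}")
    gray = rgb.astype(float).mean(axis=2)
    blurred = ndimage.gaussian_filter(gray, sigma=blur_sigma)
    if blurred.max() - blurred.min() < 1e-9:
        warnings.warn("blank image: no contour found, returning empty mask")
        return np.zeros(rgb.shape[:2], dtype=bool)
    thresh = filters.threshold_otsu(blurred)
    fg = blurred < thresh  # plant is darker than the white background
    if not fg.any():
        warnings.warn("no foreground after binarization, returning empty mask")
        return fg
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    fg = morphology.closing(fg, morphology.disk(close_radius))
    return fg.astype(bool)


def apply_mask(img: np.ndarray, mask: np.ndarray, fill: int = 255) -> np.ndarray:
    """Replace pixels outside the mask with `fill` (white by default)."""
    out = img.copy()
    out[~mask.astype(bool)] = fill
    return out


def clean_depth(depth: np.ndarray, mask: np.ndarray,
                low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Mask, percentile-clip and rescale a depth image to a uint8 channel.

    Out-of-mask pixels become 0.  In-mask values outside the
    [low_pct, high_pct] percentile band are clipped to it, then the band is
    min-max rescaled to 0-255.  A constant in-mask depth maps to 0 (declared
    convention for a degenerate range); an empty mask returns all zeros with
    a warning.
    """
    if depth.ndim != 2:
        raise ValueError(f"depth must be single-channel, got shape {depth.shape}")
    mask = mask.astype(bool)
    if depth.shape != mask.shape:
        raise ValueError(f"shape mismatch: depth {depth.shape} vs mask {mask.shape}")
    out = np.zeros(depth.shape, dtype=np.uint8)
    if not mask.any():
        warnings.warn("empty mask: clean_depth returns an all-zero image")
        return out
    vals = depth[mask].astype(float)
    lo, hi = np.percentile(vals, [low_pct, high_pct])
    clipped = np.clip(vals, lo, hi)
    if hi - lo < 1e-12:
        return out  # constant depth maps to 0
    scaled = np.round((clipped - lo) / (hi - lo) * 255.0)
    out[mask] = scaled.astype(np.uint8)
    return out


def fuse_rgbd(rgb: np.ndarray, depth_clean: np.ndarray) -> np.ndarray:
    """Stack R,G,B,D into one four-channel image; dimensions preserved."""
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"rgb must be 3-channel, got shape {rgb.shape}")
    if depth_clean.ndim != 2:
        raise ValueError(f"depth must be single-channel, got shape {depth_clean.shape}")
    if rgb.shape[:2] != depth_clean.shape:
        raise ValueError(
            f"dimension mismatch: rgb {rgb.shape[:2]} vs depth {depth_clean.shape}"
        )
    return np.dstack([rgb, depth_clean])


def split_rgbd(rgbd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`fuse_rgbd`."""
    if rgbd.ndim != 3 or rgbd.shape[2] != 4:
        raise ValueError(f"expected a 4-channel image, got shape {rgbd.shape}")
    return rgbd[..., :3], rgbd[..., 3]


def crop_side_view(img: np.ndarray, spec: CropSpec = DEFAULT_SIDE_CROP) -> np.ndarray:
    """Fixed-offset crop, no resampling; errors if the spec leaves nothing."""
    h, w = img.shape[:2]
    new_w = w - spec.left - spec.right
    new_h = h - spec.top - spec.bottom
    if new_w <= 0 or new_h <= 0:
        raise ValueError(
            f"crop spec {spec} does not fit inside a {w}x{h} image"
        )
    return img[spec.top:h - spec.bottom, spec.left:w - spec.right]


def resize_for_detector(img: np.ndarray, size: tuple[int, int] = (640, 640)) -> np.ndarray:
    """Bilinear resize to the detector input resolution (default 640x640);
    channel count and uint8 range preserved."""
    w, h = size
    if img.shape[:2] == (h, w):
        return img.copy()
    out = transform.resize(
        img.astype(float), (h, w), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    if np.issubdtype(img.dtype, np.integer):
        return np.round(out).clip(0, 255).astype(img.dtype)
    return out


def adjust_brightness(img: np.ndarray, spec: BrightnessSpec) -> np.ndarray:
    """Scale every pixel by alpha, clip to [0, 255], round; alpha=1 is the
    identity."""
    if spec.alpha == 1.0:
        return img.copy()
    out = np.round(img.astype(float) * spec.alpha).clip(0, 255)
    return out.astype(np.uint8 if np.issubdtype(img.dtype, np.integer) else img.dtype)
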