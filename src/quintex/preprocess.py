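"""Breast-region preparation: segmentation, pectoral removal, rescaling, ROI.

The descriptor downstream is threshold-relative, so preprocessing aims only
at (a) a clean single-component breast mask without background labels or the
pectoral muscle, and (b) a denoised, bicubically rescaled image.  Contrast is
stretched with a percentile normalisation before thresholding; Otsu's method
plus morphological closing/opening and largest-component selection produce
the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, transform
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

__all__ = [
    "EmptyForegroundError",
    "PreprocessConfig",
    "contrast_stretch",
    "segment_breast",
    "remove_pectoral",
    "denoise_and_rescale",
    "extract_roi_central_square",
]

ALLOWED_SCALES = (1.0, 0.5, 0.25, 0.125, 0.0625)


class EmptyForegroundError(ValueError):
    """Raised when an image contains no foreground to segment."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Rescale factor, median filter size and ROI mode.

    ``scale`` must come from {1, 1/2, 1/4, 1/8, 1/16}; the median filter is
    applied at native resolution before resizing.
    """

    scale: float = 1.0
    median_size: int = 3
    roi_mode: str = "none"  # "none" | "central_square"

    def __post_init__(self) -> None:
        if not any(np.isclose(self.scale, s) for s in ALLOWED_SCALES):
            raise ValueError(f"scale must be one of {ALLOWED_SCALES}")
        if self.median_size % 2 != 1 or self.median_size < 1:
            raise ValueError("median_size must be a positive odd integer")
        if self.roi_mode not in ("none", "central_square"):
            raise ValueError("roi_mode must be 'none' or 'central_square'")


def contrast_stretch(image: np.ndarray, low: float = 1.0, high: float = 99.0) -> np.ndarray:
    """Percentile contrast normalisation to [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = np.percentile(image, [low, high])
    if hi <= lo:
        return np.zeros_like(image)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def segment_breast(image: np.ndarray, disc_radius: int = 5) -> np.ndarray:
    """Segment the breast region as a single connected component.

    Otsu thresholding on a contrast-stretched copy, morphological closing
    then opening with a disc, and largest-component selection (which drops
    label artefacts).  A constant bright image maps to a full-frame mask; an
    all-zero image raises :class:`EmptyForegroundError`.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if image.max() <= 0:
        raise EmptyForegroundError("image has no positive intensities")
    if np.ptp(image) == 0:
        return np.ones(image.shape, dtype=bool)
    enhanced = contrast_stretch(image)
    if np.ptp(enhanced) == 0:
        return np.ones(image.shape, dtype=bool)
    fg = enhanced > threshold_otsu(enhanced)
    if not fg.any():
        raise EmptyForegroundError("thresholding found no foreground")
    selem = morphology.disk(disc_radius)
    fg = morphology.closing(fg, selem)
    fg = morphology.opening(fg, selem)
    if not fg.any():  # morphology erased everything (tiny foreground)
        fg = enhanced > threshold_otsu(enhanced)
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(counts.argmax())
    if counts[keep] == 0:
        raise EmptyForegroundError("no connected foreground component")
    return labels == keep


def remove_pectoral(
    image: np.ndarray,
    mask: np.ndarray,
    view: str = "MLO",
    side: str = "auto",
    poly_degree: int = 2,
    min_contrast: float = 0.05,
) -> np.ndarray:
    """Remove the pectoral-muscle wedge from the top corner of an MLO mask.

    Pixels in the top-corner quadrant are split into two intensity clusters;
    if the bright cluster is well separated and touches the corner, its
    boundary is smoothed with a low-order polynomial per row and everything
    corner-side of that curve is removed.  Returns the mask unchanged (with a
    warning) when no distinct bright corner cluster exists.
    """
    if view.upper() != "MLO":
        raise ValueError("pectoral removal applies to MLO views only")
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    if side == "auto":
        top = slice(0, max(H // 4, 1))
        left_mean = image[top, : W // 2][mask[top, : W // 2]].mean() if mask[top, : W // 2].any() else -np.inf
        right_mean = image[top, W // 2 :][mask[top, W // 2 :]].mean() if mask[top, W // 2 :].any() else -np.inf
        side = "left" if left_mean >= right_mean else "right"
    if side not in ("left", "right"):
        raise ValueError("side must be 'left', 'right' or 'auto'")
    qrows = slice(0, max(H // 2, 1))
    qcols = slice(0, W // 2) if side == "left" else slice(W // 2, W)
    quad = np.zeros_like(mask)
    quad[qrows, qcols] = True
    sel = quad & mask
    if sel.sum() < 10:
        warnings.warn("pectoral removal skipped: top-corner quadrant nearly empty")
        return mask.copy()
    intens = image[sel].reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(intens)
    means = km.cluster_centers_.ravel()
    hi = int(means.argmax())
    span = np.ptp(image[mask]) if mask.any() else 0.0
    if span <= 0 or (means.max() - means.min()) < min_contrast * span:
        warnings.warn("pectoral removal skipped: no distinct bright corner cluster")
        return mask.copy()
    bright = np.zeros_like(mask)
    bright[sel] = km.labels_ == hi
    # keep only the bright component touching the designated top corner
    labels = measure.label(bright, connectivity=2)
    corner_col = 0 if side == "left" else W - 1
    corner_labels = set(labels[0, qcols][labels[0, qcols] > 0])
    corner_labels |= set(labels[qrows, corner_col][labels[qrows, corner_col] > 0])
    if not corner_labels:
        warnings.warn("pectoral removal skipped: bright cluster not in the corner")
        return mask.copy()
    wedge = np.isin(labels, list(corner_labels))
    rows = np.nonzero(wedge.any(axis=1))[0]
    # fit the tissue-side boundary column as a polynomial in the row index
    edges = np.array(
        [wedge[r].nonzero()[0].max() if side == "left" else wedge[r].nonzero()[0].min() for r in rows],
        dtype=np.float64,
    )
    deg = min(poly_degree, max(len(rows) - 1, 0))
    coeffs = np.polyfit(rows, edges, deg)
    fitted = np.polyval(coeffs, rows)
    out = mask.copy()
    cols_grid = np.arange(W)
    for r, e in zip(rows, fitted):
        if side == "left":
            out[r, cols_grid <= e] = False
        else:
            out[r, cols_grid >= e] = False
    if not out.any():
        warnings.warn("pectoral removal skipped: wedge removal emptied the mask")
        return mask.copy()
    return out


def denoise_and_rescale(
    image: np.ndarray, mask: np.ndarray, config: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Median-filter then bicubically rescale; mask follows by nearest-neighbour.

    Output shape is ``round(shape * scale)``; a result smaller than 3 pixels
    on either side is an error.  The mask is resampled with order-0
    interpolation and re-binarised so labels stay crisp.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    filtered = ndimage.median_filter(image, size=config.median_size)
    s = config.scale
    if np.isclose(s, 1.0):
        return filtered, mask.copy()
    out_shape = (int(round(image.shape[0] * s)), int(round(image.shape[1] * s)))
    if min(out_shape) < 3:
        raise ValueError(f"rescaled shape {out_shape} is smaller than 3 pixels")
    resized = transform.resize(
        filtered, out_shape, order=3, anti_aliasing=s < 1, preserve_range=True
    )
    resized = np.clip(resized, 0.0, None)
    mask_small = transform.resize(
        mask.astype(np.float64), out_shape, order=0, anti_aliasing=False, preserve_range=True
    )
    return resized, mask_small > 0.5


def extract_roi_central_square(
    image: np.ndarray,
    mask: np.ndarray,
    coverage: float = 0.95,
    min_side: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """Crop a square ROI centred at the mask centroid.

    Starts from the square inscribed in the mask's bounding box, centred at
    the centroid, and shrinks until at least ``coverage`` of the square lies
    inside the mask.  Raises if no square of ``min_side`` pixels satisfies
    the constraint.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rows, cols = np.nonzero(mask)
    H, W = mask.shape
    cr, cc = rows.mean(), cols.mean()
    side = int(min(rows.max() - rows.min() + 1, cols.max() - cols.min() + 1, H, W))
    while side >= min_side:
        half = side / 2.0
        r0 = int(round(np.clip(cr - half, 0, H - side)))
        c0 = int(round(np.clip(cc - half, 0, W - side)))
        window = mask[r0 : r0 + side, c0 : c0 + side]
        if window.size == side * side and window.mean() >= coverage:
            return (
                image[r0 : r0 + side, c0 : c0 + side].copy(),
                window.copy(),
            )
        side -= max(1, side // 50)
    raise ValueError(f"mask too thin to contain a {min_side}-pixel square ROI")
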