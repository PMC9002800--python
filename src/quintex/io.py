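"""Readers and writers for mammogram-like images and their sidecars.

PGM (MIAS style), PNG and TIFF go through imageio; DICOM (INbreast style)
through pydicom with rescale slope/intercept applied.  Per-image metadata
(view, density label, woman/case ID) travels in a small JSON sidecar next to
the image file.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "write_pgm",
    "write_mask_png",
    "read_sidecar",
    "write_sidecar",
    "load_directory",
]

_DICOM_SUFFIXES = {".dcm", ".dicom"}
_RASTER_SUFFIXES = {".pgm", ".png", ".tif", ".tiff"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2-D grayscale image as float64; intensities are kept as stored.

    DICOM pixel data are mapped through RescaleSlope/RescaleIntercept and
    MONOCHROME1 images are inverted so brighter always means denser tissue.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _DICOM_SUFFIXES:
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        if getattr(ds, "PhotometricInterpretation", "") == "MONOCHROME1":
            arr = arr.max() - arr
    elif suffix in _RASTER_SUFFIXES:
        arr = np.asarray(iio.imread(path)).astype(np.float64)
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"{path.name} is not a 2-D image")
    return np.clip(arr, 0.0, None)


def write_pgm(path: str | Path, image: np.ndarray) -> None:
    """Write an image as 8- or 16-bit PGM (chosen by dynamic range)."""
    image = np.asarray(image)
    if image.min() < 0:
        raise ValueError("PGM images must be non-negative")
    dtype = np.uint8 if image.max() <= 255 else np.uint16
    iio.imwrite(Path(path), np.round(image).astype(dtype))


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def sidecar_path(image_path: str | Path) -> Path:
    return Path(image_path).with_suffix(".json")


def write_sidecar(image_path: str | Path, meta: dict) -> None:
    sidecar_path(image_path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_sidecar(image_path: str | Path) -> dict:
    p = sidecar_path(image_path)
    return json.loads(p.read_text()) if p.exists() else {}


def load_directory(directory: str | Path) -> list[dict]:
    """Load all images (with sidecars) from a directory, sorted by name.

    Returns records with keys ``image``, ``path``, and any sidecar fields
    (``label``, ``woman_id``, ``view``, ...).
    """
    directory = Path(directory)
    records = []
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in _RASTER_SUFFIXES | _DICOM_SUFFIXES:
            continue
        rec = {"path": path, "image": read_image(path)}
        rec.update(read_sidecar(path))
        records.append(rec)
    if not records:
        raise FileNotFoundError(f"no images found in {directory}")
    return records
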