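"""Reading and writing images, masks and box tables.

Intensities are stored internally as floats in [0, 1]; writers rescale to
the container's bit depth (16-bit PNG/TIFF for images, 8-bit PNG for masks).
DICOM reading (MONOCHROME2) is available when pydicom is installed.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["read_image", "read_mask", "write_image", "write_mask", "read_boxes", "write_boxes"]

BOX_COLUMNS = ["image_id", "cx", "cy", "width", "height"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF (8/16-bit) or DICOM image, rescaled to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return _read_dicom(path)
    raw = iio.imread(path)
    if raw.ndim == 3:  # RGB-replicated grayscale
        raw = raw[..., 0]
    arr = raw.astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    return np.clip(arr, 0.0, 1.0)


def _read_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise ImportError("DICOM support requires pydicom") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = arr.min(), arr.max()
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        arr = hi - arr + lo
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask (nonzero = breast)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr != 0


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an intensity image in [0, 1] as 16-bit PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * np.iinfo(np.uint16).max).astype(np.uint16))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG (255 = foreground)."""
    iio.imwrite(Path(path), (np.asarray(mask) != 0).astype(np.uint8) * 255)


def read_boxes(path: str | Path) -> pd.DataFrame:
    """Read a box table CSV with columns image_id,cx,cy,width,height."""
    df = pd.read_csv(path)
    missing = [c for c in BOX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"box CSV missing columns: {missing}")
    return df[BOX_COLUMNS]


def write_boxes(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=BOX_COLUMNS).to_csv(path, index=False)
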