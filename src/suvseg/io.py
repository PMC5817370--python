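"""Reading and writing rasters, masks and contours.

Gray/SUV rasters are accepted as PNG/TIFF (via imageio), NIfTI (via
nibabel) or NPY; masks are written as 8-bit PNG with values {0, 255};
contours as CSV of (row, col) vertices.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InputError


def read_raster(path: str | Path) -> np.ndarray:
    """Read a 2-D raster as float64 from PNG/TIFF/NIfTI/NPY."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    name = path.name.lower()
    try:
        if name.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            data = np.asanyarray(nib.load(str(path)).dataobj)
        elif name.endswith(".npy"):
            data = np.load(path)
        else:
            data = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface as stage-tagged error
        raise InputError(f"cannot read raster {path}: {exc}") from exc
    data = np.squeeze(np.asarray(data, dtype=float))
    if data.ndim != 2:
        raise InputError(f"{path} is not a single 2-D raster (shape {data.shape})")
    return data


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG with foreground 255."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_raster_png16(path: str | Path, raster: np.ndarray, scale: float = 1.0) -> None:
    """Write a nonnegative raster as 16-bit PNG after scaling."""
    data = np.clip(np.asarray(raster, dtype=float) * scale, 0, 65535)
    iio.imwrite(Path(path), data.astype(np.uint16))


def write_contour_csv(path: str | Path, vertices: np.ndarray) -> None:
    np.savetxt(
        Path(path),
        np.asarray(vertices, dtype=float),
        delimiter=",",
        header="row,col",
        comments="",
        fmt="%.4f",
    )


def read_mask(path: str | Path) -> np.ndarray:
    """Read a {0, 255} PNG (or any raster) as a boolean mask."""
    return read_raster(path) > 0
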