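"""TIFF reading/writing for calibrated volumes and label images.

Stacks are stored in the conventional page layout (z, [channel,] y, x); in
memory the package uses (x, y, z) axis order, so both readers transpose.
Calibration is taken from TIFF resolution tags and ImageJ metadata when
present, otherwise the caller must supply it.
"""

from __future__ import annotations

import numpy as np
import tifffile

from .core import Calibration, LabelVolume, Volume

__all__ = ["read_stack", "read_volume", "write_volume", "write_labels", "read_labels"]


def _calibration_from_tif(tif: tifffile.TiffFile) -> Calibration | None:
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        unit_um = 1.0
        ij = tif.imagej_metadata or {}
        if ij.get("unit") in ("micron", "um", "µm", "\\u00b5m"):
            unit_um = 1.0
        if xres is None:
            return None
        num, den = xres.value
        dx = den / num * unit_um  # resolution is pixels per unit
        dz = float(ij.get("spacing", dx))
        return Calibration(dx, dx, dz)
    except Exception:
        return None


def read_stack(
    path, calibration: Calibration | None = None
) -> tuple[list[Volume], Calibration]:
    """Read a single- or multi-channel 3D TIFF into a list of Volumes.

    Accepts page layouts (z, y, x) and (z, c, y, x) / (c, z, y, x) as tagged
    by ImageJ axes metadata; falls back to treating the smallest non-spatial
    axis as channels.
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        axes = tif.series[0].axes if tif.series else ""
        cal = calibration or _calibration_from_tif(tif)
    if cal is None:
        raise ValueError(f"{path}: no calibration in TIFF tags; pass one explicitly")
    if arr.ndim == 3:
        channels = [arr]
    elif arr.ndim == 4:
        if "C" in axes and len(axes) == 4:
            arr = np.moveaxis(arr, axes.index("C"), 0)
        else:  # assume the shortest axis is channels
            arr = np.moveaxis(arr, int(np.argmin(arr.shape)), 0)
        channels = [arr[c] for c in range(arr.shape[0])]
    else:
        raise ValueError(f"unsupported TIFF dimensionality {arr.ndim}")
    vols = [Volume(np.ascontiguousarray(ch.transpose(2, 1, 0)), cal) for ch in channels]
    return vols, cal


def read_volume(path, calibration: Calibration | None = None) -> Volume:
    vols, _ = read_stack(path, calibration)
    if len(vols) != 1:
        raise ValueError(f"{path}: expected a single channel, got {len(vols)}")
    return vols[0]


def _imagej_kwargs(cal: Calibration) -> dict:
    return dict(
        imagej=True,
        resolution=(1.0 / cal.dx, 1.0 / cal.dy),
        metadata={"spacing": cal.dz, "unit": "micron", "axes": "ZYX"},
    )


def write_volume(path, vol: Volume) -> None:
    arr = vol.values.transpose(2, 1, 0)
    if arr.dtype not in (np.uint8, np.uint16, np.float32):
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), np.ascontiguousarray(arr), **_imagej_kwargs(vol.calibration))


def write_labels(path, labels: LabelVolume) -> None:
    """Write a label image as 16-bit TIFF (errors if > 65535 labels)."""
    if labels.values.max(initial=0) > 65535:
        raise ValueError("too many labels for a 16-bit label image")
    arr = labels.values.astype(np.uint16).transpose(2, 1, 0)
    tifffile.imwrite(str(path), np.ascontiguousarray(arr), **_imagej_kwargs(labels.calibration))


def read_labels(path, calibration: Calibration | None = None) -> LabelVolume:
    vol = read_volume(path, calibration)
    return LabelVolume(vol.values.astype(np.int32), vol.calibration)
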