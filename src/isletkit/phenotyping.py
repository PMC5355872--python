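"""Per-cell phenotype assignment from typed supervoxels.

Cytoplasmic marker signal concentrates in a shell around the nucleus: the
probe compartment extends ``inner_radius`` voxels inward and
``outer_radius`` voxels outward from the nucleus boundary (defaults 3 and 2),
intersected with the cell's zone so no neighbouring cell's signal is read.
The cell takes the most abundant marker type within the shell provided that
marker occupies at least a minimum fraction of the shell; otherwise it is
``unlabeled``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LabelVolume
from .supervoxels import CHANNEL_NAMES, TYPE_CODES

__all__ = ["PhenotypeParams", "compute_cell_phenotypes", "CELL_TABLE_COLUMNS"]

CELL_TABLE_COLUMNS = [
    "cell_id",
    "x_um",
    "y_um",
    "z_um",
    "nucleus_voxels",
    "zone_voxels",
    "type",
]


@dataclass
class PhenotypeParams:
    inner_radius: float = 3.0  # XY voxels, inward from the nucleus boundary
    outer_radius: float = 2.0  # XY voxels, outward
    min_marker_fraction: float = 0.05  # of shell voxels

    def __post_init__(self) -> None:
        if self.inner_radius < 0 or self.outer_radius < 0:
            raise ValueError("shell radii must be >= 0")
        if not (0 <= self.min_marker_fraction <= 1):
            raise ValueError("min_marker_fraction must be in [0, 1]")


def _ball(radius: float, aniso: float) -> np.ndarray:
    r = max(radius, 0.0)
    rr = int(np.floor(r))
    rz = int(np.floor(r / aniso))
    x, y, z = np.mgrid[-rr : rr + 1, -rr : rr + 1, -rz : rz + 1]
    return (x * x + y * y + (z * aniso) ** 2) <= r * r + 1e-9


def compute_cell_phenotypes(
    nuclei: LabelVolume,
    zones: LabelVolume,
    typed: LabelVolume,
    params: PhenotypeParams | None = None,
) -> pd.DataFrame:
    """Build the cell table: one row per nucleus with calibrated centroid,
    voxel counts and phenotype in {alpha, beta, delta, unlabeled}."""
    params = params or PhenotypeParams()
    if not (nuclei.shape == zones.shape == typed.shape):
        raise ValueError("label images must be aligned")
    cal = nuclei.calibration
    aniso = cal.anisotropy
    dil = _ball(params.outer_radius, aniso) if params.outer_radius >= 1 else None
    ero = _ball(params.inner_radius, aniso) if params.inner_radius >= 1 else None
    zone_sizes = np.bincount(zones.values.ravel())
    code_to_name = {v: k for k, v in TYPE_CODES.items()}
    rows = []
    objects = ndimage.find_objects(nuclei.values)
    margin = int(np.ceil(params.outer_radius)) + 1
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        box = tuple(
            slice(max(s.start - margin, 0), min(s.stop + margin, dim))
            for s, dim in zip(sl, nuclei.shape)
        )
        nuc = nuclei.values[box] == lab
        outer = ndimage.binary_dilation(nuc, structure=dil) if dil is not None else nuc
        inner_core = ndimage.binary_erosion(nuc, structure=ero) if ero is not None else nuc
        shell = outer & ~inner_core
        shell &= (zones.values[box] == lab) | nuc
        coords = np.argwhere(nuc)
        centroid = coords.mean(axis=0) + [b.start for b in box]
        n_shell = int(shell.sum())
        if n_shell == 0:
            warnings.warn(f"cell {lab}: empty shell, assigned unlabeled")
            ptype = "unlabeled"
        else:
            codes = typed.values[box][shell]
            counts = np.bincount(codes, minlength=4)[1:4]  # alpha, beta, delta
            best = int(np.argmax(counts))  # ties -> channel priority order
            if counts[best] >= params.min_marker_fraction * n_shell and counts[best] > 0:
                ptype = code_to_name[best + 1]
            else:
                ptype = "unlabeled"
        zs = int(zone_sizes[lab]) if lab < len(zone_sizes) else 0
        rows.append(
            {
                "cell_id": lab,
                "x_um": centroid[0] * cal.dx,
                "y_um": centroid[1] * cal.dy,
                "z_um": centroid[2] * cal.dz,
                "nucleus_voxels": int(nuc.sum()),
                "zone_voxels": zs,
                "type": ptype,
            }
        )
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)
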