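"""Kernel intensity surfaces: each stem's contribution is smoothed over a
disc of fixed radius and the contributions are summed on a regular grid.

The default kernel is the uniform disc of radius 5 m: a point contributes
1 / (pi R^2) trees per m^2 to every cell whose centre lies within R of it,
so the surface integrates to n where the discs fit inside the window.  No
boundary renormalisation is applied, so intensity fades towards the window
edge.  An Epanechnikov (parabolic) disc kernel is available as an option.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .stand_model import Window

__all__ = ["IntensityMap", "kernel_intensity", "write_intensity_csv", "write_esri_ascii"]


@dataclass(frozen=True)
class IntensityMap:
    """A gridded intensity surface (trees per m^2).

    ``values[iy, ix]`` is the intensity at the cell centre
    (x_min + (ix + 0.5) cell, y_min + (iy + 0.5) cell): row index increases
    northward.  Writers emit the grid north-up (top row = largest y).
    """

    origin: tuple[float, float]  # window lower-left (x_min, y_min)
    cell: float
    values: np.ndarray

    @property
    def total_mass(self) -> float:
        """Integral of the surface (trees), values x cell area."""
        return float(self.values.sum() * self.cell**2)


def kernel_intensity(
    points,
    window: Window,
    radius: float = 5.0,
    cell: float = 1.0,
    kernel: str = "uniform",
) -> IntensityMap:
    """Disc-kernel intensity surface for a point pattern.

    An empty point set yields an all-zero map.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if cell <= 0 or cell > radius:
        raise ValueError(f"cell must satisfy 0 < cell <= radius, got {cell}")
    if kernel not in ("uniform", "epanechnikov"):
        raise ValueError(f"unknown kernel {kernel!r}")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    nx = int(round(window.width / cell))
    ny = int(round(window.height / cell))
    xs = window.x_min + (np.arange(nx) + 0.5) * cell
    ys = window.y_min + (np.arange(ny) + 0.5) * cell
    values = np.zeros((ny, nx))
    inv_area = 1.0 / (np.pi * radius**2)
    for x, y in pts:
        ix0 = np.searchsorted(xs, x - radius)
        ix1 = np.searchsorted(xs, x + radius, side="right")
        iy0 = np.searchsorted(ys, y - radius)
        iy1 = np.searchsorted(ys, y + radius, side="right")
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        d2 = (xs[ix0:ix1][None, :] - x) ** 2 + (ys[iy0:iy1][:, None] - y) ** 2
        if kernel == "uniform":
            contrib = np.where(d2 <= radius**2, inv_area, 0.0)
        else:
            contrib = np.clip(1.0 - d2 / radius**2, 0.0, None) * (2.0 * inv_area)
        values[iy0:iy1, ix0:ix1] += contrib
    return IntensityMap(origin=(window.x_min, window.y_min), cell=cell, values=values)


def write_intensity_csv(imap: IntensityMap, path: str | Path) -> Path:
    """Write the grid as a north-up CSV matrix plus a JSON sidecar header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, imap.values[::-1], delimiter=",", fmt="%.6g")
    ny, nx = imap.values.shape
    sidecar = path.with_suffix(path.suffix + ".hdr.json")
    sidecar.write_text(
        json.dumps(
            {
                "origin_x": imap.origin[0],
                "origin_y": imap.origin[1],
                "cell": imap.cell,
                "ncols": nx,
                "nrows": ny,
                "units": "trees_per_m2",
                "row_order": "north_up",
            },
            indent=2,
        )
    )
    return path


def write_esri_ascii(imap: IntensityMap, path: str | Path) -> Path:
    """Write the grid in the ESRI ASCII raster dialect for GIS use."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ny, nx = imap.values.shape
    with open(path, "w") as fh:
        fh.write(
            f"ncols {nx}\nnrows {ny}\nxllcorner {imap.origin[0]}\n"
            f"yllcorner {imap.origin[1]}\ncellsize {imap.cell}\nNODATA_value -9999\n"
        )
        np.savetxt(fh, imap.values[::-1], fmt="%.6g")
    return path
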