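"""Voxel grid geometry shared by the simulator and the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TemplateSpace:
    """Isotropic voxel grid with a world (mm) coordinate frame.

    A desk-scale stand-in for a standard 2-mm template: the origin is chosen
    so that world coordinates span negative and positive y, letting ROI and
    peak coordinates read like template-style mm triplets.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float = 2.0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @classmethod
    def default(
        cls, grid_shape: tuple[int, int, int] = (40, 48, 40), voxel_size_mm: float = 2.0
    ) -> "TemplateSpace":
        """Grid with x/z centred on zero and y shifted posterior (60/40 split)."""
        nx, ny, nz = grid_shape
        v = voxel_size_mm
        oy = -round(0.6 * ny * v / v) * v
        origin = (-v * nx / 2.0, float(oy), -v * nz / 2.0)
        return cls(grid_shape=tuple(grid_shape), voxel_size_mm=v, origin_mm=origin)

    @property
    def affine(self) -> np.ndarray:
        """Voxel-index -> world-mm affine (RAS, diagonal)."""
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size_mm
        a[:3, 3] = self.origin_mm
        return a

    def voxel_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx * self.voxel_size_mm + np.asarray(self.origin_mm)

    def world_to_voxel(self, mm) -> np.ndarray:
        mm = np.asarray(mm, dtype=float)
        return np.round((mm - np.asarray(self.origin_mm)) / self.voxel_size_mm).astype(int)

    def contains_voxel(self, idx) -> bool:
        idx = np.asarray(idx)
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.grid_shape)))

    def voxel_center_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of all voxel centers as three broadcastable axes."""
        axes = [
            (np.arange(n) * self.voxel_size_mm + o)
            for n, o in zip(self.grid_shape, self.origin_mm)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)


def raster_argmax(values: np.ndarray, mask: np.ndarray) -> tuple[int, int, int]:
    """Index of the maximum of ``values`` within ``mask``.

    Ties are broken by the smallest linear index in raster order with x
    fastest, then y, then z (i.e. Fortran order for an [x, y, z] array).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    masked = np.where(mask, values, -np.inf)
    flat = masked.flatten(order="F")
    i = int(np.argmax(flat))
    nx, ny, _ = values.shape
    ix = i % nx
    iy = (i // nx) % ny
    iz = i // (nx * ny)
    return ix, iy, iz
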