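"""Probabilistic overlap maps and inter-subject consistency statistics.

Binarised individual activation maps, aligned to the template grid, are
summed voxel-wise so that the value at each non-zero voxel is the number of
subjects with suprathreshold activation there.  Overlap percentages are
reported relative to the number of subjects with any suprathreshold in-ROI
activation at that threshold, and peak separations as Euclidean mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import TemplateSpace, raster_argmax
from .roi_cluster import PeakRecord, ThresholdSpec, split_hc_long_axis


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (matches printed
    whole-number percentages)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class OverlapMap:
    """Per-voxel count of subjects with suprathreshold activation."""

    counts: np.ndarray
    n_subjects_total: int
    n_subjects_active: int
    contrast: str
    threshold: ThresholdSpec
    space: TemplateSpace


@dataclass(frozen=True)
class OverlapPeak:
    coord_mm: tuple[float, float, float]
    count: int
    pct_of_active: int


def build_overlap_map(
    maps: Sequence[np.ndarray],
    n_total: int,
    space: TemplateSpace,
    contrast: str = "scenes>objects",
    threshold: ThresholdSpec | None = None,
    n_active: int | None = None,
) -> OverlapMap:
    """Voxel-wise sum of binarised template-space activation maps."""
    if threshold is None:
        threshold = ThresholdSpec(z_threshold=2.3, fwhm_mm=0.0)
    arrays = [np.asarray(getattr(m, "data", m), dtype=bool) for m in maps]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"maps are on different grids: {sorted(shapes)}")
    if arrays and arrays[0].shape != tuple(space.grid_shape):
        raise ValueError("maps do not match the template grid")
    counts = np.zeros(space.grid_shape, dtype=int)
    for a in arrays:
        counts += a
    if n_active is None:
        n_active = sum(1 for a in arrays if a.any())
    return OverlapMap(
        counts=counts,
        n_subjects_total=n_total,
        n_subjects_active=n_active,
        contrast=contrast,
        threshold=threshold,
        space=space,
    )


def overlap_peak(om: OverlapMap, roi: np.ndarray) -> OverlapPeak:
    """Max-count voxel inside the ROI; ties broken by raster order.

    ``pct_of_active`` is the peak count as a percentage of the subjects with
    any suprathreshold activation, rounded half away from zero.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    if om.n_subjects_active <= 0:
        raise ValueError("no subjects with suprathreshold activation")
    idx = raster_argmax(om.counts.astype(float), roi)
    count = int(om.counts[idx])
    coord = om.space.voxel_to_world(idx)
    pct = _round_half_away(100.0 * count / om.n_subjects_active)
    return OverlapPeak(coord_mm=tuple(float(c) for c in coord), count=count, pct_of_active=pct)


def peak_distance(a_mm, b_mm) -> float:
    """Euclidean distance between two template-mm coordinates, to 0.1 mm."""
    a = np.asarray(a_mm, dtype=float)
    b = np.asarray(b_mm, dtype=float)
    return round(float(np.linalg.norm(a - b)), 1)


def anterior_fraction(peaks: Iterable[PeakRecord], y_split_mm: float) -> int:
    """Integer percentage of HC peak records on the anterior side of the split."""
    peaks = list(peaks)
    if not peaks:
        raise ValueError("no peak records given")
    n_ant = sum(
        1 for p in peaks if split_hc_long_axis(p.coord_mm, y_split_mm) == "anterior"
    )
    return _round_half_away(100.0 * n_ant / len(peaks))


def voxels_within_radius(space: TemplateSpace, center_mm, r_mm: float) -> int:
    """Number of voxel centers within ``r_mm`` (inclusive) of a coordinate.

    On a 2-mm isotropic grid a 5-mm sphere centred on a voxel center holds
    81 voxels.
    """
    if r_mm < 0:
        raise ValueError("radius must be non-negative")
    center = np.asarray(center_mm, dtype=float)
    v = space.voxel_size_mm
    center_vox = (center - np.asarray(space.origin_mm)) / v
    pad = int(np.ceil(r_mm / v)) + 1
    count = 0
    for i in range(int(np.floor(center_vox[0])) - pad, int(np.ceil(center_vox[0])) + pad + 1):
        for j in range(int(np.floor(center_vox[1])) - pad, int(np.ceil(center_vox[1])) + pad + 1):
            for k in range(int(np.floor(center_vox[2])) - pad, int(np.ceil(center_vox[2])) + pad + 1):
                mm = np.array([i, j, k]) * v + np.asarray(space.origin_mm)
                if np.linalg.norm(mm - center) <= r_mm:
                    count += 1
    return count


def consistency_table(
    rows: Iterable[dict],
) -> pd.DataFrame:
    """Assemble per (roi, threshold, fwhm) consistency rows into a table.

    Each row dict provides: roi, z_threshold, fwhm_mm, n_active, peak
    coordinate, count, pct, distance to the group peak, and (for HC) the
    anterior fraction.
    """
    df = pd.DataFrame(list(rows))
    expected = {
        "roi",
        "z_threshold",
        "fwhm_mm",
        "n_active",
        "peak_x_mm",
        "peak_y_mm",
        "peak_z_mm",
        "count",
        "pct_of_active",
        "dist_to_group_peak_mm",
        "anterior_pct",
    }
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"consistency rows missing fields: {sorted(missing)}")
    return df.sort_values(["roi", "z_threshold", "fwhm_mm"]).reset_index(drop=True)
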