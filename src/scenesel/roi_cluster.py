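"""ROI transformation, thresholding, clustering and peak extraction.

This is the individual-level analysis core: template ROI masks are carried
into subject space through the inverse of the subject-to-template affine,
Z maps are binarised at uncorrected voxel-wise thresholds, connected
components are labelled (26-connectivity by default, the FSL convention),
and per-ROI activation flags and peak records are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .first_level_glm import ZMap
from .grid import TemplateSpace, raster_argmax

Z_THRESHOLDS = (2.3, 3.1, 3.9)
SMOOTHING_FWHMS_MM = (0.0, 2.0, 5.0)

#: Conventional anterior/posterior hippocampal boundary (uncal apex) in
#: MNI-style coordinates; the desk-scale template uses its own boundary.
DEFAULT_UNCAL_APEX_Y_MM = -21.0


@dataclass(frozen=True)
class ThresholdSpec:
    z_threshold: float
    fwhm_mm: float = 0.0

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")


@dataclass(frozen=True)
class BinaryActivationMap:
    data: np.ndarray  # bool
    threshold: ThresholdSpec
    contrast: str
    space: str


@dataclass(frozen=True)
class ClusterSet:
    """Connected components of a binary map."""

    labels: np.ndarray  # int labels, 0 = background
    sizes: np.ndarray  # voxel count per cluster, index i -> label i+1
    connectivity: int

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def peak_voxel(self, cluster_label: int, values: np.ndarray) -> tuple[int, int, int]:
        return raster_argmax(values, self.labels == cluster_label)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _voxel_map(affine_mm: np.ndarray, space: TemplateSpace) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-to-voxel affine implied by a world-mm affine on a common grid."""
    vox2mm = space.affine
    m = np.linalg.inv(vox2mm) @ affine_mm @ vox2mm
    return m[:3, :3], m[:3, 3]


def to_subject_space(
    mask: np.ndarray, affine_subject_to_template: np.ndarray, space: TemplateSpace
) -> np.ndarray:
    """Resample a template-space binary mask onto the subject grid.

    Nearest-neighbour resampling through the affine: each subject voxel is
    mapped to template mm via the subject-to-template affine and takes the
    value of the nearest template voxel.  Exact for integer-voxel
    translations.
    """
    affine_subject_to_template = np.asarray(affine_subject_to_template, dtype=float)
    if abs(np.linalg.det(affine_subject_to_template)) < 1e-12:
        raise ValueError("affine_subject_to_template is singular")
    matrix, offset = _voxel_map(affine_subject_to_template, space)
    out = ndimage.affine_transform(
        np.asarray(mask, dtype=float),
        matrix=matrix,
        offset=offset,
        output_shape=np.asarray(mask).shape,
        order=0,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    result = out > 0.5
    if np.asarray(mask, dtype=bool).any() and not result.any():
        raise ValueError("mask resampled to empty; transform moves ROI off the grid")
    return result


def to_template_space(
    map3d: np.ndarray, affine_subject_to_template: np.ndarray, space: TemplateSpace
) -> np.ndarray:
    """Resample a subject-space map onto the template grid (inverse affine)."""
    affine_subject_to_template = np.asarray(affine_subject_to_template, dtype=float)
    if abs(np.linalg.det(affine_subject_to_template)) < 1e-12:
        raise ValueError("affine_subject_to_template is singular")
    matrix, offset = _voxel_map(np.linalg.inv(affine_subject_to_template), space)
    arr = np.asarray(map3d)
    out = ndimage.affine_transform(
        arr.astype(float),
        matrix=matrix,
        offset=offset,
        output_shape=arr.shape,
        order=0,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if arr.dtype == bool:
        return out > 0.5
    return out


def threshold_zmap(zmap: ZMap, spec: ThresholdSpec) -> BinaryActivationMap:
    """Binarise a Z map: voxel included iff Z > threshold (strict, one-sided)."""
    if zmap.fwhm_mm != spec.fwhm_mm:
        raise ValueError(
            f"smoothing mismatch: zmap has FWHM {zmap.fwhm_mm} mm, "
            f"threshold spec says {spec.fwhm_mm} mm"
        )
    return BinaryActivationMap(
        data=zmap.data > spec.z_threshold,
        threshold=spec,
        contrast=zmap.contrast,
        space=zmap.space,
    )


def find_clusters(binary, connectivity: int = 26) -> ClusterSet:
    """Label connected components of a binary activation map."""
    data = binary.data if isinstance(binary, BinaryActivationMap) else np.asarray(binary)
    labels, n = ndimage.label(data.astype(bool), structure=_connectivity_structure(connectivity))
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return ClusterSet(labels=labels, sizes=sizes, connectivity=connectivity)


def roi_has_activation(
    zmap: ZMap, roi: np.ndarray, spec: ThresholdSpec, roi_space: str = "subject"
) -> tuple[bool, int]:
    """Whether any suprathreshold voxel of the Z map falls inside the ROI."""
    if zmap.space != roi_space:
        raise ValueError(f"space mismatch: zmap is {zmap.space!r}, ROI is {roi_space!r}")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    binary = threshold_zmap(zmap, spec)
    count = int(np.count_nonzero(binary.data & roi))
    return count > 0, count


@dataclass(frozen=True)
class PeakRecord:
    subject_id: str
    roi: str
    contrast: str
    z_threshold: float | None
    fwhm_mm: float
    coord_mm: tuple[float, float, float]
    peak_z: float
    hemisphere: str  # "left" | "right" by the sign of x (x >= 0 is right)
    suprathreshold: bool
    long_axis: str | None = None  # "anterior" | "posterior" for HC


def peak_in_roi(
    zmap: ZMap,
    roi: np.ndarray,
    space: TemplateSpace,
    subject_id: str = "",
    roi_name: str = "",
    z_threshold: float | None = None,
) -> PeakRecord:
    """Voxel with maximal Z inside the ROI (ties by raster order, x fastest).

    The record carries a ``suprathreshold`` flag instead of erroring when
    the whole ROI is below threshold, so sub-threshold peaks can still be
    plotted in scatter summaries.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    idx = raster_argmax(zmap.data, roi)
    coord = space.voxel_to_world(idx)
    peak_z = float(zmap.data[idx])
    return PeakRecord(
        subject_id=subject_id,
        roi=roi_name,
        contrast=zmap.contrast,
        z_threshold=z_threshold,
        fwhm_mm=zmap.fwhm_mm,
        coord_mm=tuple(float(c) for c in coord),
        peak_z=peak_z,
        hemisphere="right" if coord[0] >= 0 else "left",
        suprathreshold=(peak_z > z_threshold) if z_threshold is not None else True,
    )


def split_hc_long_axis(
    peak_mm,
    y_split_mm: float = DEFAULT_UNCAL_APEX_Y_MM,
    hc_mask: np.ndarray | None = None,
    space: TemplateSpace | None = None,
) -> str:
    """Classify a hippocampal coordinate as anterior or posterior.

    Anterior iff y >= ``y_split_mm`` (the boundary itself counts as
    anterior).  When a mask and space are supplied, the coordinate is
    checked to lie inside the HC mask.
    """
    peak_mm = np.asarray(peak_mm, dtype=float)
    if hc_mask is not None:
        if space is None:
            raise ValueError("space is required to check the mask")
        idx = space.world_to_voxel(peak_mm)
        if not space.contains_voxel(idx) or not bool(np.asarray(hc_mask, bool)[tuple(idx)]):
            raise ValueError(f"coordinate {peak_mm.tolist()} is outside the HC mask")
    return "anterior" if peak_mm[1] >= y_split_mm else "posterior"
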