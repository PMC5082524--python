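"""Synthetic multi-subject scene-localiser cohort generator.

Emulates the statistical structure the individual-level analyses assume:
per-subject scene-selective activation blobs whose centers are jittered
around consensus template locations inside four bilateral ROIs (PHG, RSC,
TOS, HC), subject-specific response amplitudes, additive low-frequency
drift, and white Gaussian noise on top of a block-design BOLD signal
(TR 3 s, 40 blocks of 16 s, fixation at blocks 1, 14, 27 and 40).

Default effect and noise levels are chosen so that individual-level
detection frequencies across the voxel-wise Z thresholds behave like a
strongly scene-selective cortical cohort: PHG > TOS > RSC > HC in planted
amplitude, with single-voxel temporal SNR of ~50 (noise SD 2% of baseline).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .design_matrix import (
    TR_S,
    BlockSchedule,
    build_block_schedule,
    build_design_matrix,
    double_gamma_hrf,
    make_regressor,
)
from .grid import TemplateSpace

ROI_NAMES = ("PHG", "RSC", "TOS", "HC")

#: Right-hemisphere ellipsoid geometry of each ROI in template mm:
#: (center, semi-axes).  Masks are mirrored across x = 0.  The coordinates
#: are documented, fixed stand-ins sized to the desk-scale template.
ROI_GEOMETRY: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "PHG": ((18.0, -26.0, -12.0), (6.0, 6.0, 5.0)),
    "RSC": ((8.0, -36.0, 6.0), (6.0, 6.0, 6.0)),
    "TOS": ((22.0, -36.0, 16.0), (5.0, 6.0, 7.0)),
    "HC": ((20.0, -8.0, -12.0), (4.0, 11.0, 4.0)),
}

#: y coordinate of the anterior/posterior hippocampal boundary on the
#: desk-scale template (the long axis of the synthetic HC runs through it).
HC_SPLIT_Y_MM = -8.0

#: Consensus (population-level) scene-effect centers, one per ROI; each is a
#: voxel center of the default grids and lies inside its ROI.
CONSENSUS_CENTERS_MM: dict[str, tuple[float, float, float]] = {
    "PHG": (18.0, -26.0, -12.0),
    "RSC": (8.0, -36.0, 6.0),
    "TOS": (22.0, -36.0, 16.0),
    "HC": (20.0, -8.0, -12.0),
}

#: Mean planted scene amplitudes (% of baseline) per ROI, ordered like the
#: detection frequencies of a scene localiser: PHG and TOS strong, RSC and
#: HC weaker.
SCENE_AMPLITUDE_MEAN_PCT: dict[str, float] = {
    "PHG": 3.5,
    "TOS": 3.2,
    "RSC": 2.6,
    "HC": 2.4,
}


class ConfigurationError(ValueError):
    """Raised when a grid cannot hold the requested ROI geometry."""


@dataclass(frozen=True)
class RoiSet:
    """Named, pairwise-disjoint binary ROI masks in template space."""

    masks: dict[str, np.ndarray]
    hc_split_y_mm: float
    space: TemplateSpace

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


def make_template_rois(space: TemplateSpace) -> RoiSet:
    """Rasterise the four bilateral ellipsoid ROIs onto a template grid.

    Raises :class:`ConfigurationError` if the grid is too small to hold all
    four masks disjointly (an ellipsoid clips the grid boundary or two masks
    touch).
    """
    xg, yg, zg = space.voxel_center_grids()
    x_min, x_max = float(xg.min()), float(xg.max())
    y_min, y_max = float(yg.min()), float(yg.max())
    z_min, z_max = float(zg.min()), float(zg.max())

    masks: dict[str, np.ndarray] = {}
    for name, ((cx, cy, cz), (a, b, c)) in ROI_GEOMETRY.items():
        lo = (min(cx - a, -cx - a), cy - b, cz - c)
        hi = (max(cx + a, -cx + a), cy + b, cz + c)
        if not (
            x_min <= lo[0]
            and hi[0] <= x_max
            and y_min <= lo[1]
            and hi[1] <= y_max
            and z_min <= lo[2]
            and hi[2] <= z_max
        ):
            raise ConfigurationError(
                f"grid {space.grid_shape} too small to hold ROI {name} "
                f"(extent {lo}..{hi})"
            )
        right = ((xg - cx) / a) ** 2 + ((yg - cy) / b) ** 2 + ((zg - cz) / c) ** 2 <= 1.0
        left = ((xg + cx) / a) ** 2 + ((yg - cy) / b) ** 2 + ((zg - cz) / c) ** 2 <= 1.0
        mask = right | left
        if not mask.any():
            raise ConfigurationError(f"ROI {name} rasterised to an empty mask")
        masks[name] = mask

    total = np.zeros(space.grid_shape, dtype=int)
    for mask in masks.values():
        total += mask.astype(int)
    if (total > 1).any():
        raise ConfigurationError("ROI masks overlap; grid too small for the geometry")

    hc_y = yg * np.ones_like(masks["HC"], dtype=float)
    if not (
        (masks["HC"] & (hc_y > HC_SPLIT_Y_MM)).any()
        and (masks["HC"] & (hc_y < HC_SPLIT_Y_MM)).any()
    ):
        raise ConfigurationError("HC mask does not straddle the anterior/posterior split")

    return RoiSet(masks=masks, hc_split_y_mm=HC_SPLIT_Y_MM, space=space)


def sample_subject_center(
    consensus_mm,
    jitter_sd_mm: float,
    roi: np.ndarray,
    space: TemplateSpace,
    seed,
) -> np.ndarray:
    """Draw a subject-specific effect center around the consensus location.

    An isotropic Gaussian offset (SD ``jitter_sd_mm`` per axis) is added to
    the consensus coordinate and the result is clamped to the nearest in-ROI
    voxel center.  Deterministic given ``seed`` (an int or a Generator).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    consensus = np.asarray(consensus_mm, dtype=float)
    candidate = consensus + rng.normal(0.0, jitter_sd_mm, size=3)
    coords = np.argwhere(roi)
    centers = coords * space.voxel_size_mm + np.asarray(space.origin_mm)
    d2 = ((centers - candidate) ** 2).sum(axis=1)
    return centers[int(np.argmin(d2))]


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth for one synthetic subject (all coordinates template mm)."""

    subject_id: str
    centers_mm: dict[str, tuple[float, float, float]]
    amplitude_pct: dict[str, float]
    object_amplitude_pct: float
    jitter_sd_mm: float
    noise_sd: float
    drift_amplitude: float
    drift_period_s: float
    drift_phase_rad: float
    baseline: float
    blob_fwhm_mm: float
    affine_subject_to_template: np.ndarray

    def __post_init__(self):
        if any(a < 0 for a in self.amplitude_pct.values()):
            raise ValueError("amplitude_pct must be non-negative")
        if abs(np.linalg.det(self.affine_subject_to_template)) < 1e-12:
            raise ValueError("affine_subject_to_template is singular")

    def to_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "centers_mm": {k: list(map(float, v)) for k, v in self.centers_mm.items()},
            "amplitude_pct": {k: float(v) for k, v in self.amplitude_pct.items()},
            "object_amplitude_pct": float(self.object_amplitude_pct),
            "jitter_sd_mm": float(self.jitter_sd_mm),
            "noise_sd": float(self.noise_sd),
            "drift_amplitude": float(self.drift_amplitude),
            "drift_period_s": float(self.drift_period_s),
            "drift_phase_rad": float(self.drift_phase_rad),
            "baseline": float(self.baseline),
            "blob_fwhm_mm": float(self.blob_fwhm_mm),
            "affine_subject_to_template": np.asarray(
                self.affine_subject_to_template
            ).tolist(),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectTruth":
        d = dict(d)
        d["centers_mm"] = {k: tuple(v) for k, v in d["centers_mm"].items()}
        d["affine_subject_to_template"] = np.asarray(d["affine_subject_to_template"])
        return cls(**d)


@dataclass(frozen=True)
class BoldVolume:
    """4-D BOLD series (*grid, n_volumes) with its grid geometry and the
    subject-to-template affine."""

    data: np.ndarray
    space: TemplateSpace
    affine_subject_to_template: np.ndarray
    subject_id: str = ""
    tr_s: float = TR_S


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate the localiser acquisition (TR 3 s, 214 post-discard
    volumes over 640 s) at the emulated study scale of 51 subjects.
    """

    n_subjects: int = 51
    base_seed: int = 0
    space: TemplateSpace = field(default_factory=TemplateSpace.default)
    scene_amplitude_mean_pct: dict[str, float] = field(
        default_factory=lambda: dict(SCENE_AMPLITUDE_MEAN_PCT)
    )
    scene_amplitude_sd_pct: float = 0.3
    object_amplitude_mean_pct: float = 0.5
    object_amplitude_sd_pct: float = 0.1
    jitter_sd_mm: float = 2.0
    noise_sd: float = 2.0
    drift_amplitude: float = 1.0
    drift_period_s: float = 128.0
    baseline: float = 100.0
    blob_fwhm_mm: float = 4.0
    max_shift_voxels: int = 2
    tr_s: float = TR_S
    n_volumes: int = 214

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name, value in (
            ("scene_amplitude_sd_pct", self.scene_amplitude_sd_pct),
            ("object_amplitude_sd_pct", self.object_amplitude_sd_pct),
            ("jitter_sd_mm", self.jitter_sd_mm),
            ("noise_sd", self.noise_sd),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SubjectRecord:
    bold: BoldVolume
    truth: SubjectTruth
    roi_masks: dict[str, np.ndarray]  # subject-space masks


def _effect_blob(
    center_mm: np.ndarray, space: TemplateSpace, fwhm_mm: float
) -> np.ndarray:
    """Isotropic Gaussian blob (peak 1) truncated at 3 sigma."""
    xg, yg, zg = space.voxel_center_grids()
    d2 = (xg - center_mm[0]) ** 2 + (yg - center_mm[1]) ** 2 + (zg - center_mm[2]) ** 2
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    blob = np.exp(-d2 / (2.0 * sigma**2))
    blob[d2 > (3.0 * sigma) ** 2] = 0.0
    return blob


def generate_subject_bold(
    truth: SubjectTruth,
    schedule: BlockSchedule,
    space: TemplateSpace,
    seed: int,
) -> BoldVolume:
    """Simulate one subject's 4-D BOLD series on the subject grid.

    signal = baseline * (1 + scene_map * r_scenes + object_map * r_objects)
             + drift + noise,
    where each condition regressor is the HRF-convolved boxcar normalised to
    unit peak-to-peak height, so amplitudes are true percent signal change.
    The scene map places a Gaussian blob (FWHM ``truth.blob_fwhm_mm``) at
    the subject's planted center inside each ROI; the object map reuses the
    same blobs at ``object_amplitude_pct``.  Deterministic given ``seed``.
    """
    inv = np.linalg.inv(truth.affine_subject_to_template)
    n_vol = int(np.ceil(schedule.total_duration_s / TR_S))
    hrf = double_gamma_hrf()

    regressors = {}
    for cond in ("scenes", "objects"):
        series, height = make_regressor(schedule, cond, hrf, tr_s=TR_S, n_volumes=n_vol)
        regressors[cond] = series / height if height > 0 else series

    scene_map = np.zeros(space.grid_shape)
    object_map = np.zeros(space.grid_shape)
    for roi_name, center in truth.centers_mm.items():
        center_subj = (inv @ np.append(np.asarray(center, dtype=float), 1.0))[:3]
        blob = _effect_blob(center_subj, space, truth.blob_fwhm_mm)
        scene_map += truth.amplitude_pct[roi_name] / 100.0 * blob
        object_map += truth.object_amplitude_pct / 100.0 * blob

    t = np.arange(n_vol) * TR_S
    drift = truth.drift_amplitude * np.cos(
        2.0 * np.pi * t / truth.drift_period_s + truth.drift_phase_rad
    )

    signal = truth.baseline * (
        1.0
        + scene_map[..., None] * regressors["scenes"][None, None, None, :]
        + object_map[..., None] * regressors["objects"][None, None, None, :]
    )
    signal += drift[None, None, None, :]

    rng = np.random.default_rng(seed)
    if truth.noise_sd > 0:
        signal = signal + rng.normal(0.0, truth.noise_sd, size=signal.shape)

    return BoldVolume(
        data=signal,
        space=space,
        affine_subject_to_template=truth.affine_subject_to_template,
        subject_id=truth.subject_id,
        tr_s=TR_S,
    )


def _subject_seed(base_seed: int, index: int, stream: int) -> int:
    """Stable derived seed below 2**31 for subject ``index`` / ``stream``."""
    ss = np.random.SeedSequence([base_seed, index, stream])
    return int(ss.generate_state(1)[0] % (2**31))


def draw_subject_truth(
    spec: CohortSpec, rois: RoiSet, index: int
) -> SubjectTruth:
    """Draw one subject's ground truth (seeded from base_seed + index)."""
    rng = np.random.default_rng(_subject_seed(spec.base_seed, index, 0))
    amplitudes = {
        roi: float(
            max(0.0, rng.normal(spec.scene_amplitude_mean_pct[roi], spec.scene_amplitude_sd_pct))
        )
        for roi in ROI_NAMES
    }
    object_amp = float(
        max(0.0, rng.normal(spec.object_amplitude_mean_pct, spec.object_amplitude_sd_pct))
    )
    shift_vox = rng.integers(-spec.max_shift_voxels, spec.max_shift_voxels + 1, size=3)
    affine = np.eye(4)
    affine[:3, 3] = shift_vox * spec.space.voxel_size_mm
    centers = {
        roi: tuple(
            sample_subject_center(
                CONSENSUS_CENTERS_MM[roi], spec.jitter_sd_mm, rois[roi], spec.space, rng
            )
        )
        for roi in ROI_NAMES
    }
    return SubjectTruth(
        subject_id=f"sub-{index + 1:02d}",
        centers_mm=centers,
        amplitude_pct=amplitudes,
        object_amplitude_pct=object_amp,
        jitter_sd_mm=spec.jitter_sd_mm,
        noise_sd=spec.noise_sd,
        drift_amplitude=spec.drift_amplitude,
        drift_period_s=spec.drift_period_s,
        drift_phase_rad=float(rng.uniform(0.0, 2.0 * np.pi)),
        baseline=spec.baseline,
        blob_fwhm_mm=spec.blob_fwhm_mm,
        affine_subject_to_template=affine,
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full cohort: BOLD, truth, and subject-space ROI masks.

    Subject ROI masks are the template masks resampled through the inverse
    of each subject's rigid subject-to-template affine (nearest neighbour).
    A pure function of its CohortSpec: regenerating with the same spec
    reproduces bit-identical data.
    """
    from .roi_cluster import to_subject_space

    rois = make_template_rois(spec.space)
    schedule = build_block_schedule()
    records = []
    for i in range(spec.n_subjects):
        truth = draw_subject_truth(spec, rois, i)
        bold = generate_subject_bold(
            truth, schedule, spec.space, seed=_subject_seed(spec.base_seed, i, 1)
        )
        subj_masks = {
            roi: to_subject_space(rois[roi], truth.affine_subject_to_template, spec.space)
            for roi in ROI_NAMES
        }
        records.append(SubjectRecord(bold=bold, truth=truth, roi_masks=subj_masks))
    return records


# ---------------------------------------------------------------------------
# On-disk formats: NIfTI-1 volumes, JSON truth, TSV schedule, text affines
# ---------------------------------------------------------------------------

def save_nifti(data: np.ndarray, space: TemplateSpace, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data), affine=space.affine)
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata())


def save_affine_txt(affine: np.ndarray, path) -> None:
    np.savetxt(str(path), np.asarray(affine), fmt="%.10g")


def load_affine_txt(path) -> np.ndarray:
    a = np.loadtxt(str(path))
    if a.shape != (4, 4):
        raise ValueError(f"expected a 4x4 affine in {path}, got shape {a.shape}")
    return a


def save_truth_json(truths: list[SubjectTruth], path) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in truths], indent=2))


def load_truth_json(path) -> list[SubjectTruth]:
    return [SubjectTruth.from_dict(d) for d in json.loads(Path(path).read_text())]
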