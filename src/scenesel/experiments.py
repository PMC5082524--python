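"""Seeded calibration and recovery studies on synthetic cohorts.

These routines re-run the whole analysis chain (simulate -> first-level GLM
-> threshold -> overlap / group inference) under controlled conditions and
measure its statistical behaviour: null-tail calibration of the Z maps,
family-wise error of the permutation cluster-extent correction, and
recovery of the planted consensus activation voxel.  They are what the
validation suite executes; problem sizes default to a reduced grid
(30x36x30 at 2 mm) so a full study runs in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, stats

from .design_matrix import build_block_schedule, build_design_matrix, highpass
from .first_level_glm import ContrastSpec, contrast_zmap, fit_glm
from .grid import TemplateSpace
from .group_inference import cluster_extent_correct, group_one_sample_z
from .overlap_consistency import build_overlap_map, overlap_peak
from .roi_cluster import ThresholdSpec, threshold_zmap, to_template_space
from .synthetic_cohort import (
    CONSENSUS_CENTERS_MM,
    ROI_NAMES,
    CohortSpec,
    generate_cohort,
    make_template_rois,
)


def _sub_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def _fit_scene_zmaps(records, design, contrast):
    """Unsmoothed scenes>objects Z map for every subject of a cohort."""
    n_vol = design.n_volumes
    zmaps = []
    for rec in records:
        flat = rec.bold.data.reshape(-1, n_vol).T
        filtered = highpass(flat).T.reshape(rec.bold.data.shape)
        fit = fit_glm(filtered, design)
        zmaps.append(contrast_zmap(fit, contrast, space="subject", fwhm_mm=0.0))
    return zmaps


def run_null_calibration(
    seed: int,
    n_subjects: int = 10,
    grid_shape: tuple[int, int, int] = (30, 36, 30),
    z_threshold: float = 3.9,
) -> dict:
    """In-ROI suprathreshold voxel fraction of an amplitude-0 cohort.

    With no planted effects the unsmoothed scenes>objects Z values are null;
    the fraction of in-ROI voxels exceeding ``z_threshold`` across the
    cohort should match the one-sided standard-normal tail within binomial
    error.
    """
    space = TemplateSpace.default(grid_shape)
    spec = CohortSpec(
        n_subjects=n_subjects,
        base_seed=seed,
        space=space,
        scene_amplitude_mean_pct={r: 0.0 for r in ROI_NAMES},
        scene_amplitude_sd_pct=0.0,
        object_amplitude_mean_pct=0.0,
        object_amplitude_sd_pct=0.0,
    )
    records = generate_cohort(spec)
    design = build_design_matrix(build_block_schedule(), records[0].bold.data.shape[-1])
    contrast = ContrastSpec.named("scenes>objects", design.columns)
    count = 0
    n = 0
    for rec, zmap in zip(records, _fit_scene_zmaps(records, design, contrast)):
        roi_union = np.zeros(space.grid_shape, dtype=bool)
        for roi in ROI_NAMES:
            roi_union |= rec.roi_masks[roi]
        in_roi = zmap.data[roi_union]
        count += int((in_roi > z_threshold).sum())
        n += in_roi.size
    p_expected = float(stats.norm.sf(z_threshold))
    se = float(np.sqrt(p_expected * (1 - p_expected) / n))
    return {
        "fraction": count / n,
        "count": count,
        "n_voxels": n,
        "expected_p": p_expected,
        "se": se,
    }


def run_fwe_calibration(
    seed: int,
    n_replicates: int = 200,
    n_subjects: int = 10,
    grid_shape: tuple[int, int, int] = (30, 36, 30),
    n_perm: int = 200,
    alpha: float = 0.05,
    z_form: float = 2.3,
    fwhm_mm: float = 5.0,
    voxel_size_mm: float = 2.0,
) -> dict:
    """Family-wise error rate of the cluster-extent correction under the null.

    Each replicate draws a pure-noise cohort of smooth unit-variance random
    fields (FWHM ``fwhm_mm``, the smoothness of group-level contrast maps)
    and asks whether any cluster survives correction; the rate of replicates
    with a false positive estimates the FWE, nominally ``alpha``.
    """
    rng = np.random.default_rng(seed)
    sigma_vox = fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / voxel_size_mm
    hits = 0
    for rep in range(n_replicates):
        maps = []
        for _ in range(n_subjects):
            field = ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma_vox)
            maps.append(field / field.std())
        gz = group_one_sample_z(maps)
        _, significant, _ = cluster_extent_correct(
            gz, maps, z_form=z_form, alpha=alpha, n_perm=n_perm,
            seed=_sub_seed(seed, rep),
        )
        hits += bool(significant.any())
    return {"fwe_rate": hits / n_replicates, "n_replicates": n_replicates, "alpha": alpha}


def run_recovery(
    seed: int,
    n_replicates: int = 20,
    n_subjects: int = 20,
    grid_shape: tuple[int, int, int] = (30, 36, 30),
    amplitude_pct: float = 3.0,
    z_thresholds: tuple[float, ...] = (2.3, 3.1, 3.9),
) -> dict:
    """Consensus-voxel recovery and threshold monotonicity on planted cohorts.

    Each replicate generates a cohort with zero center jitter and a planted
    scene amplitude, builds the unsmoothed overlap map at Z = 2.3 and checks
    that the overlap peak in every ROI is exactly the planted consensus
    voxel.  Also checks that per-ROI activation counts never increase with
    the Z threshold (nesting of suprathreshold sets).
    """
    space = TemplateSpace.default(grid_shape)
    rois = make_template_rois(space)
    schedule = build_block_schedule()
    recovered = 0
    monotone = 0
    for rep in range(n_replicates):
        spec = CohortSpec(
            n_subjects=n_subjects,
            base_seed=_sub_seed(seed, rep),
            space=space,
            scene_amplitude_mean_pct={r: amplitude_pct for r in ROI_NAMES},
            scene_amplitude_sd_pct=0.0,
            jitter_sd_mm=0.0,
        )
        records = generate_cohort(spec)
        design = build_design_matrix(schedule, records[0].bold.data.shape[-1])
        contrast = ContrastSpec.named("scenes>objects", design.columns)
        zmaps = _fit_scene_zmaps(records, design, contrast)

        template_maps = {}
        for thr in z_thresholds:
            tspec = ThresholdSpec(z_threshold=thr, fwhm_mm=0.0)
            template_maps[thr] = [
                to_template_space(
                    threshold_zmap(z, tspec).data,
                    rec.truth.affine_subject_to_template,
                    space,
                )
                for rec, z in zip(records, zmaps)
            ]

        om = build_overlap_map(
            template_maps[z_thresholds[0]], n_total=n_subjects, space=space,
            threshold=ThresholdSpec(z_thresholds[0], 0.0),
        )
        all_match = True
        for roi in ROI_NAMES:
            n_active = sum(1 for m in template_maps[z_thresholds[0]] if (m & rois[roi]).any())
            if n_active == 0:
                all_match = False
                continue
            peak = overlap_peak(
                dataclasses.replace(om, n_subjects_active=n_active), rois[roi]
            )
            if tuple(peak.coord_mm) != tuple(CONSENSUS_CENTERS_MM[roi]):
                all_match = False
        recovered += all_match

        is_monotone = True
        for roi in ROI_NAMES:
            counts = [
                sum(1 for m in template_maps[thr] if (m & rois[roi]).any())
                for thr in sorted(z_thresholds)
            ]
            if any(b > a for a, b in zip(counts, counts[1:])):
                is_monotone = False
        monotone += is_monotone
    return {
        "recovery_rate": recovered / n_replicates,
        "monotone_rate": monotone / n_replicates,
        "n_replicates": n_replicates,
    }


def glm_oracle_deviation(seed: int, n_instances: int = 100) -> dict:
    """Max deviation of the GLM from hand-rolled normal equations.

    Random small instances (up to 8 time points x 5 voxels): betas and
    contrast t statistics are compared with an explicit (X'X)^-1 X' y
    computation.
    """
    from .design_matrix import DesignMatrix

    rng = np.random.default_rng(seed)
    max_beta = 0.0
    max_t = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(5, 9))
        p = int(rng.integers(2, 5))
        x = rng.standard_normal((n, p))
        x[:, -1] = 1.0
        design = DesignMatrix(
            matrix=x, columns=tuple(f"c{i}" for i in range(p - 1)) + ("constant",),
            tr_s=3.0,
        )
        y = rng.standard_normal((int(rng.integers(1, 6)), n))
        fit = fit_glm(y, design)

        xtx_inv = np.linalg.inv(x.T @ x)
        betas_oracle = (xtx_inv @ x.T @ y.T).T
        resid = y.T - x @ betas_oracle.T
        dof = n - p
        sigma2 = (resid**2).sum(axis=0) / dof
        max_beta = max(max_beta, float(np.abs(fit.betas - betas_oracle).max()))

        w = rng.standard_normal(p)
        w[-1] = 0.0
        if not np.any(w):
            w[0] = 1.0
        denom = np.sqrt(sigma2 * float(w @ xtx_inv @ w))
        t_oracle = np.where(denom > 0, (betas_oracle @ w) / np.where(denom > 0, denom, 1), 0.0)
        eff = fit.betas @ w
        den = np.sqrt(fit.sigma2 * float(w @ fit.xtx_inv @ w))
        t_fit = np.where(den > 0, eff / np.where(den > 0, den, 1), 0.0)
        max_t = max(max_t, float(np.abs(t_fit - t_oracle).max()))
    return {"max_beta_dev": max_beta, "max_t_dev": max_t, "n_instances": n_instances}
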