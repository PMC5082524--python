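"""Group-level inference and cohort summary statistics.

The group map is a voxel-wise one-sample test of subject contrast estimates
against zero, converted to Z scores; family-wise error over clusters is
controlled by sign-flip permutation of the subject maps (cluster-forming
threshold in Z, null distribution of the maximum suprathreshold cluster
extent).  Cohort summaries cover activation-frequency tables, the
scene-vs-object binomial preference matrix, Cochran's Q across regions, and
paired effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .first_level_glm import t_to_z
from .roi_cluster import ClusterSet, find_clusters

#: Z assigned to voxels with zero between-subject variance and non-zero mean.
Z_CAP = 8.2


@dataclass(frozen=True)
class GroupZMap:
    data: np.ndarray
    n_subjects: int
    contrast: str = "scenes>objects"


def _stack(maps) -> np.ndarray:
    arr = np.stack([np.asarray(getattr(m, "data", m), dtype=float) for m in maps])
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    return arr


def group_one_sample_z(contrast_maps, contrast: str = "scenes>objects") -> GroupZMap:
    """Voxel-wise one-sample t of subject values against 0, mapped to Z.

    Voxels with zero between-subject variance get Z = sign(mean) * Z_CAP
    (0 when the mean is also zero) rather than an infinite statistic.
    """
    arr = _stack(contrast_maps)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    zero_var = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, mean / np.where(zero_var, 1.0, se))
    z = t_to_z(t, dof=n - 1)
    z = np.where(zero_var, np.sign(mean) * Z_CAP, z)
    return GroupZMap(data=z, n_subjects=n, contrast=contrast)


def _max_cluster_sizes(
    t_maps: np.ndarray, t_crit: float, connectivity: int
) -> np.ndarray:
    """Maximum suprathreshold cluster extent of each map in a (P, ...) stack."""
    out = np.empty(t_maps.shape[0], dtype=int)
    for i, tmap in enumerate(t_maps):
        cs = find_clusters(tmap > t_crit, connectivity=connectivity)
        out[i] = int(cs.sizes.max()) if cs.n_clusters else 0
    return out


def cluster_extent_correct(
    gz: GroupZMap,
    subject_maps,
    z_form: float = 2.3,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
) -> tuple[ClusterSet, np.ndarray, int]:
    """Permutation (sign-flip) cluster-extent FWE correction.

    Under the one-sample null the subject maps are sign-symmetric, so random
    per-subject sign flips generate the null distribution of the maximum
    suprathreshold cluster size at the cluster-forming threshold ``z_form``.
    Observed clusters are retained iff their extent exceeds the (1 - alpha)
    empirical quantile of that distribution.  The first permutation is the
    identity, so the observed statistic is a member of its own null.

    Returns (observed clusters, significant-cluster mask, extent threshold).
    Cluster formation is done on the t statistic at the t value equivalent
    to ``z_form`` (the t -> Z map is monotone), which avoids converting
    every permuted map.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    arr = _stack(subject_maps)
    n = arr.shape[0]
    dof = n - 1
    t_crit = float(stats.t.ppf(stats.norm.cdf(z_form), dof))

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    signs[0] = 1.0

    flat = arr.reshape(n, -1)
    mean_sq = (flat**2).mean(axis=0)  # invariant under sign flips
    means = (signs @ flat) / n
    var = (mean_sq[None, :] - means**2) * (n / dof)
    se = np.sqrt(var / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, means / np.where(se > 0, se, 1.0), np.where(means > 0, np.inf, 0.0))
    t = t.reshape(n_perm, *arr.shape[1:])

    null_max = _max_cluster_sizes(t, t_crit, connectivity)
    extent_thr = int(np.quantile(null_max, 1.0 - alpha, method="higher"))

    observed = find_clusters(gz.data > z_form, connectivity=connectivity)
    significant = np.zeros(gz.data.shape, dtype=bool)
    for label, size in enumerate(observed.sizes, start=1):
        if size > extent_thr:
            significant |= observed.labels == label
    return observed, significant, extent_thr


def frequency_table(records: pd.DataFrame) -> pd.DataFrame:
    """Proportion of subjects with suprathreshold in-ROI voxels per cell.

    ``records`` must have columns (subject_id, roi, z_threshold, fwhm_mm,
    active); every requested roi x threshold x fwhm cell must be covered by
    every subject.
    """
    required = {"subject_id", "roi", "z_threshold", "fwhm_mm", "active"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    n_subjects = records["subject_id"].nunique()
    cells = records.groupby(["roi", "z_threshold", "fwhm_mm"], as_index=False).agg(
        n_with_cluster=("active", "sum"), n_recorded=("active", "size")
    )
    incomplete = cells[cells["n_recorded"] != n_subjects]
    if len(incomplete):
        bad = incomplete[["roi", "z_threshold", "fwhm_mm"]].to_dict("records")
        raise ValueError(f"incomplete cells (not every subject recorded): {bad}")
    cells["proportion"] = cells["n_with_cluster"] / n_subjects
    return cells.drop(columns="n_recorded")


def binomial_preference(psc: pd.DataFrame) -> pd.DataFrame:
    """Subject x ROI matrix scoring 1 iff scene PSC > object PSC (ties 0).

    ``psc`` must have columns (subject_id, roi, condition, psc) with both
    'scenes' and 'objects' present for every subject x ROI pair.
    """
    required = {"subject_id", "roi", "condition", "psc"}
    missing = required - set(psc.columns)
    if missing:
        raise ValueError(f"psc table missing columns: {sorted(missing)}")
    wide = psc.pivot_table(
        index="subject_id", columns=["roi", "condition"], values="psc", aggfunc="first"
    )
    rois = sorted({c[0] for c in wide.columns})
    out = {}
    for roi in rois:
        for cond in ("scenes", "objects"):
            if (roi, cond) not in wide.columns or wide[(roi, cond)].isna().any():
                raise ValueError(f"missing condition {cond!r} for ROI {roi!r}")
        out[roi] = (wide[(roi, "scenes")] > wide[(roi, "objects")]).astype(int)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class CochranResult:
    q: float
    dof: int
    p_value: float
    column_totals: dict


def cochrans_q(binary: pd.DataFrame | np.ndarray) -> CochranResult:
    """Cochran's Q over a subjects x regions binary matrix.

    Q = k(k-1) * sum_j (G_j - T/k)^2 / (k * sum_i L_i - sum_i L_i^2) with k
    regions, column totals G_j, row totals L_i and grand total T; df = k - 1
    and p from the chi-square upper tail.  When every row is constant the
    denominator vanishes and Q is defined as 0 with p = 1.
    """
    if isinstance(binary, pd.DataFrame):
        cols = list(binary.columns)
        x = binary.to_numpy()
    else:
        x = np.asarray(binary)
        cols = list(range(x.shape[1]))
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 regions")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("entries must be 0 or 1")
    k = x.shape[1]
    g = x.sum(axis=0)
    l = x.sum(axis=1)
    t_total = x.sum()
    denom = k * l.sum() - (l**2).sum()
    dof = k - 1
    if denom == 0:
        return CochranResult(q=0.0, dof=dof, p_value=1.0, column_totals=dict(zip(cols, g)))
    q = float(k * (k - 1) * ((g - t_total / k) ** 2).sum() / denom)
    p = float(stats.chi2.sf(q, dof))
    return CochranResult(q=q, dof=dof, p_value=p, column_totals=dict(zip(cols, map(int, g))))


def paired_effect(psc_a, psc_b) -> tuple[float, float]:
    """Paired t statistic and Cohen's d of the paired differences."""
    a = np.asarray(psc_a, dtype=float)
    b = np.asarray(psc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):  # identical samples: no effect, t defined as 0
            return 0.0, 0.0
        raise ValueError("zero standard deviation of differences")
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    cohen_d = float(d.mean() / sd)
    return t, cohen_d
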