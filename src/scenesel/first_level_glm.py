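"""Single-subject voxel-wise GLM, contrast Z-maps, smoothing and PSC.

Ordinary least squares is fitted independently at every voxel; contrast
t statistics are converted to standard-normal Z scores through a matched
log-tail quantile mapping so that very large |t| still maps to a finite Z.
No autocorrelation prewhitening is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.special import ndtri_exp

from .design_matrix import DesignMatrix

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: The four contrasts of the localiser, as weights over
#: (scenes, objects, scrambled, constant).
CONTRASTS: dict[str, tuple[float, float, float, float]] = {
    "scenes>scrambled": (1.0, 0.0, -1.0, 0.0),
    "scenes>objects": (1.0, -1.0, 0.0, 0.0),
    "objects>scrambled": (0.0, 1.0, -1.0, 0.0),
    "objects>scenes": (-1.0, 1.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    weights: np.ndarray

    @classmethod
    def named(cls, name: str, columns: tuple[str, ...]) -> "ContrastSpec":
        if name not in CONTRASTS:
            raise KeyError(f"unknown contrast {name!r}")
        by_col = dict(zip(("scenes", "objects", "scrambled", "constant"), CONTRASTS[name]))
        return cls(name=name, weights=np.array([by_col.get(c, 0.0) for c in columns]))


@dataclass(frozen=True)
class GlmFit:
    """Per-voxel OLS estimates for one subject.

    ``betas`` has shape (*spatial, n_columns); ``sigma2`` is the residual
    variance SSR/dof with the same spatial shape.
    """

    betas: np.ndarray
    sigma2: np.ndarray
    dof: int
    design: DesignMatrix
    xtx_inv: np.ndarray

    def beta(self, column: str) -> np.ndarray:
        return self.betas[..., self.design.columns.index(column)]


@dataclass(frozen=True)
class ZMap:
    """Voxel-wise Z statistic for one contrast at a recorded smoothing level."""

    data: np.ndarray
    contrast: str
    fwhm_mm: float
    space: str  # "subject" | "template"
    dof: int | None = None


def fit_glm(bold, design: DesignMatrix) -> GlmFit:
    """Voxel-wise ordinary least squares.

    ``bold`` is either an array with time on the last axis or an object with
    a ``data`` attribute shaped (*spatial, n_volumes).  The design must
    already be high-passed to match the data.
    """
    data = np.asarray(getattr(bold, "data", bold), dtype=float)
    x = design.matrix
    n, p = x.shape
    if data.shape[-1] != n:
        raise ValueError(
            f"series length {data.shape[-1]} does not match design rows {n}"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        # name the offending columns via the null space of X
        _, _, vt = np.linalg.svd(x)
        null = np.abs(vt[rank:]).sum(axis=0)
        bad = [c for c, v in zip(design.columns, null) if v > 1e-8]
        raise np.linalg.LinAlgError(f"design is rank deficient; collinear columns: {bad}")

    spatial = data.shape[:-1]
    y = data.reshape(-1, n).T  # (n, V)
    pinv = np.linalg.pinv(x)
    betas = (pinv @ y).T  # (V, p)
    resid = y - x @ betas.T
    dof = n - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    # voxels fitted exactly (constant or noiseless): roundoff-level residual
    # variance is treated as zero so downstream statistics degrade to Z = 0
    msq = (y**2).mean(axis=0)
    sigma2[sigma2 <= msq * (np.finfo(float).eps * n) ** 2] = 0.0
    xtx_inv = np.linalg.inv(x.T @ x)
    return GlmFit(
        betas=betas.reshape(*spatial, p),
        sigma2=sigma2.reshape(spatial),
        dof=dof,
        design=design,
        xtx_inv=xtx_inv,
    )


def t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Map Student-t values to standard-normal quantiles of equal tail mass.

    Computed in log-tail space so |t| up to ~40 maps to a finite Z instead of
    saturating at the float64 CDF resolution.
    """
    t = np.asarray(t, dtype=float)
    log_tail = stats.t.logsf(np.abs(t), dof)
    z = -ndtri_exp(log_tail)
    return np.sign(t) * z


def contrast_zmap(
    fit: GlmFit, contrast: ContrastSpec, space: str = "subject", fwhm_mm: float = 0.0
) -> ZMap:
    """Z map for ``c'beta / sqrt(sigma2 * c'(X'X)^-1 c)``.

    Voxels with zero residual variance (constant or exactly-interpolated
    series) are assigned Z = 0: with no error estimate the statistic is
    undefined and the degenerate case is mapped to the null value.
    """
    w = np.asarray(contrast.weights, dtype=float)
    if w.shape[0] != fit.betas.shape[-1]:
        raise ValueError("contrast length does not match design columns")
    if not np.any(w):
        raise ValueError("contrast weights are all zero")
    effect = fit.betas @ w
    var_scale = float(w @ fit.xtx_inv @ w)
    denom = np.sqrt(fit.sigma2 * var_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, effect / np.where(denom > 0, denom, 1.0), 0.0)
    z = t_to_z(t, fit.dof)
    return ZMap(data=z, contrast=contrast.name, fwhm_mm=fwhm_mm, space=space, dof=fit.dof)


def smooth_volume(vol: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing; ``fwhm_mm = 0`` is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    vol = np.asarray(vol, dtype=float)
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    return ndimage.gaussian_filter(vol, sigma=sigma_vox)


def smooth_bold(data: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Smooth every volume of a 4-D series (*spatial, time) in space only."""
    if fwhm_mm == 0:
        return np.asarray(data, dtype=float).copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    return ndimage.gaussian_filter(
        np.asarray(data, dtype=float), sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0)
    )


@dataclass(frozen=True)
class PscRecord:
    subject_id: str
    roi: str
    condition: str
    psc: float


def percent_signal_change(
    fit: GlmFit,
    condition: str,
    regressor_height: float,
    baseline_mean: float,
    roi: np.ndarray | None = None,
    baseline_condition: str = "scrambled",
) -> float:
    """Percent signal change of a condition relative to the scrambled baseline.

    PSC = 100 * (beta_condition - beta_baseline) * regressor_height /
    baseline_mean, averaged over ROI voxels when a mask is given.
    """
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")
    diff = fit.beta(condition) - fit.beta(baseline_condition)
    psc = 100.0 * diff * regressor_height / baseline_mean
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            raise ValueError("ROI mask is empty")
        psc = psc[roi]
    return float(np.mean(psc))
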