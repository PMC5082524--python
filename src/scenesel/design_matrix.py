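"""Localiser block schedule, HRF-convolved regressors, and high-pass filtering.

The localiser run alternates 16-s blocks of scenes, objects and scrambled
objects, with fixation blocks at fixed positions.  Each condition's boxcar is
convolved with a double-gamma hemodynamic response function (HRF) and sampled
at the volume acquisition times; a Gaussian-weighted running-line high-pass
filter (the FSL convention) removes slow drift from both the data and the
design before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

TR_S = 3.0
BLOCK_DURATION_S = 16.0
N_BLOCKS = 40
FIXATION_POSITIONS = (1, 14, 27, 40)
STIM_DURATION_S = 0.2
ISI_S = 0.8

CONDITIONS = ("scenes", "objects", "scrambled")

#: The three experimental block orders; each is presented four times.
BLOCK_ORDERS: tuple[tuple[str, str, str], ...] = (
    ("objects", "scenes", "scrambled"),
    ("scrambled", "scenes", "objects"),
    ("scenes", "objects", "scrambled"),
)


def trials_per_block(
    block_duration_s: float = BLOCK_DURATION_S,
    stim_duration_s: float = STIM_DURATION_S,
    isi_s: float = ISI_S,
) -> int:
    """Number of trials that fit in one block (stimulus + inter-stimulus gap)."""
    trial_s = stim_duration_s + isi_s
    if trial_s <= 0:
        raise ValueError("trial duration must be positive")
    return int(round(block_duration_s / trial_s))


@dataclass(frozen=True)
class Block:
    position: int  # 1-based position in the run
    condition: str
    onset_s: float
    duration_s: float = BLOCK_DURATION_S


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered list of blocks covering the whole localiser run."""

    blocks: tuple[Block, ...]

    @property
    def total_duration_s(self) -> float:
        last = self.blocks[-1]
        return last.onset_s + last.duration_s

    def condition_blocks(self, condition: str) -> list[Block]:
        return [b for b in self.blocks if b.condition == condition]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [b.onset_s for b in self.blocks],
                "duration_s": [b.duration_s for b in self.blocks],
                "condition": [b.condition for b in self.blocks],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_block_schedule(
    orders: Sequence[Sequence[str]] = BLOCK_ORDERS,
    fixation_positions: Sequence[int] = FIXATION_POSITIONS,
    block_duration_s: float = BLOCK_DURATION_S,
) -> BlockSchedule:
    """Build the 40-block localiser schedule.

    The experimental part cycles through the block orders (each order is a
    triplet of conditions) until every order has been presented four times,
    giving 36 experimental blocks; fixation blocks occupy the stated
    positions (1-based).
    """
    n_triplets = 12
    labels: list[str] = []
    for i in range(n_triplets):
        labels.extend(orders[i % len(orders)])

    blocks: list[Block] = []
    exp_iter = iter(labels)
    n_total = len(labels) + len(fixation_positions)
    for pos in range(1, n_total + 1):
        cond = "fixation" if pos in fixation_positions else next(exp_iter)
        blocks.append(
            Block(
                position=pos,
                condition=cond,
                onset_s=(pos - 1) * block_duration_s,
                duration_s=block_duration_s,
            )
        )
    return BlockSchedule(blocks=tuple(blocks))


# ---------------------------------------------------------------------------
# Hemodynamic response function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hrf:
    """Sampled double-gamma HRF, peak-normalised to 1."""

    dt_s: float
    samples: np.ndarray
    parameters: dict = field(default_factory=dict)


def double_gamma_hrf(
    dt_s: float = 0.1,
    length_s: float = 32.0,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    peak_dispersion_s: float = 3.0,
    undershoot_dispersion_s: float = 3.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> Hrf:
    """Difference of two gamma densities, parameterised by mean lag and SD.

    With mean ``m`` and SD ``s`` the gamma shape is ``(m/s)**2`` and the scale
    ``s**2/m``, so the positive lobe peaks a little before ``peak_delay_s``.
    The curve is normalised so that its global maximum is 1.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if length_s < 32.0:
        raise ValueError("length_s must cover the undershoot (>= 32 s)")

    t = np.arange(0.0, length_s + dt_s / 2, dt_s)

    def gamma_density(mean: float, sd: float) -> np.ndarray:
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return stats.gamma.pdf(t, shape, scale=scale)

    h = gamma_density(peak_delay_s, peak_dispersion_s) - undershoot_ratio * gamma_density(
        undershoot_delay_s, undershoot_dispersion_s
    )
    h = h / h.max()
    h[0] = 0.0
    return Hrf(
        dt_s=dt_s,
        samples=h,
        parameters={
            "peak_delay_s": peak_delay_s,
            "undershoot_delay_s": undershoot_delay_s,
            "peak_dispersion_s": peak_dispersion_s,
            "undershoot_dispersion_s": undershoot_dispersion_s,
            "undershoot_ratio": undershoot_ratio,
        },
    )


# ---------------------------------------------------------------------------
# Regressors and the design matrix
# ---------------------------------------------------------------------------

def make_regressor(
    schedule: BlockSchedule,
    condition: str,
    hrf: Hrf,
    tr_s: float = TR_S,
    n_volumes: int | None = None,
) -> tuple[np.ndarray, float]:
    """HRF-convolved condition boxcar sampled at volume acquisition times.

    Returns the regressor series and its peak-to-peak height (used to scale
    percent-signal-change estimates).  Block onsets need not be TR-aligned:
    the boxcar is built at the HRF micro-time resolution and evaluated at
    ``t = k * tr_s`` exactly.
    """
    known = set(CONDITIONS) | {"fixation"} | {b.condition for b in schedule.blocks}
    if condition not in known:
        raise ValueError(f"unknown condition {condition!r}; expected one of {sorted(known)}")
    if n_volumes is None:
        n_volumes = int(np.ceil(schedule.total_duration_s / tr_s))

    dt = hrf.dt_s
    span_s = max(schedule.total_duration_s, (n_volumes - 1) * tr_s + dt)
    n_fine = int(np.ceil(span_s / dt)) + len(hrf.samples)
    boxcar = np.zeros(n_fine)
    for b in schedule.condition_blocks(condition):
        i0 = int(round(b.onset_s / dt))
        i1 = int(round((b.onset_s + b.duration_s) / dt))
        boxcar[i0:i1] = 1.0

    conv = np.convolve(boxcar, hrf.samples)[:n_fine] * dt
    vol_idx = np.round(np.arange(n_volumes) * tr_s / dt).astype(int)
    series = conv[vol_idx]
    height = float(np.ptp(series)) if series.size else 0.0
    return series, height


@dataclass(frozen=True)
class DesignMatrix:
    """Condition regressors plus a constant column, optionally high-passed."""

    matrix: np.ndarray  # (n_volumes, n_columns)
    columns: tuple[str, ...]
    tr_s: float
    regressor_heights: dict = field(default_factory=dict)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.columns.index(name)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=list(self.columns)).to_csv(
            path, sep="\t", index=False
        )


def build_design_matrix(
    schedule: BlockSchedule,
    n_volumes: int,
    tr_s: float = TR_S,
    hrf: Hrf | None = None,
    highpass_sigma_s: float | None = 50.0,
) -> DesignMatrix:
    """Assemble the three condition regressors plus a constant column.

    When ``highpass_sigma_s`` is given, the condition columns are filtered
    with the same high-pass filter that is applied to the data (the constant
    column is left untouched).
    """
    if hrf is None:
        hrf = double_gamma_hrf()
    cols = []
    heights = {}
    for cond in CONDITIONS:
        series, height = make_regressor(schedule, cond, hrf, tr_s=tr_s, n_volumes=n_volumes)
        heights[cond] = height
        cols.append(series)
    if highpass_sigma_s is not None:
        cols = [highpass(c, sigma_s=highpass_sigma_s, tr_s=tr_s) for c in cols]
    cols.append(np.ones(n_volumes))
    matrix = np.column_stack(cols)
    return DesignMatrix(
        matrix=matrix,
        columns=CONDITIONS + ("constant",),
        tr_s=tr_s,
        regressor_heights=heights,
    )


# ---------------------------------------------------------------------------
# High-pass filter
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _highpass_operator(n: int, sigma_s: float, tr_s: float) -> np.ndarray:
    """Linear operator for Gaussian-weighted running-line detrending.

    At each time point a straight line is fitted by least squares with
    Gaussian weights (SD ``sigma_s``) centred there; the fitted value is
    subtracted and the grand mean added back.  Returns the dense (n, n)
    matrix ``I - H + J/n``.
    """
    t = np.arange(n) * tr_s
    hat = np.empty((n, n))
    for i in range(n):
        w = np.exp(-0.5 * ((t - t[i]) / sigma_s) ** 2)
        d = np.column_stack([np.ones(n), t - t[i]])
        dw = d * w[:, None]
        # fitted value at t_i is the intercept of the local weighted fit
        coef = np.linalg.solve(d.T @ dw, dw.T)
        hat[i] = coef[0]
    return np.eye(n) - hat + np.full((n, n), 1.0 / n)


def highpass(series: np.ndarray, sigma_s: float = 50.0, tr_s: float = TR_S) -> np.ndarray:
    """Gaussian-weighted running-line high-pass filter (mean preserved).

    ``series`` may be 1-D (time,) or 2-D (time, voxels); the filter acts
    along the first axis.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if n < 3:
        raise ValueError("series must have at least 3 time points")
    op = _highpass_operator(n, float(sigma_s), float(tr_s))
    return op @ series
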