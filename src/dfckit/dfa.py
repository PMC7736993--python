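"""Detrended Fluctuation Analysis of dFC increment sequences.

The sequence of instantaneous dFC increments (the frame-to-frame speeds of
a maximally smooth stream, slide step = 1 sample) is treated as the step
lengths of a random walk in FC space.  DFA estimates the walk's
self-similarity exponent: the mean-centred increments are integrated into a
profile, the profile is split into non-overlapping segments of length ``k``,
a least-squares line is removed per segment, and the root-mean-square
residual ``F(k)`` is fit against ``k`` on the log-log plane.  The slope is
the scaling exponent ``alpha``.

Interpretation (attached as a label only): ``alpha < 0.5`` anti-persistent
increments, ``alpha = 0.5`` memoryless (the profile resembles Brownian
motion), ``0.5 < alpha < 1`` persistent, ``alpha >= 1`` non-stationary
(strictly, DFA is undefined).  An exponent is only meaningful when the
log-log relation is actually linear; results with fit R^2 < 0.95 are
flagged non-scaling and must not be read as exponents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .recurrence import compute_dfc_matrix, compute_speeds
from .stream import DFCStream

__all__ = [
    "IncrementSeries",
    "DFAResult",
    "dfc_increments",
    "integrate_profile",
    "dfa_fluctuation",
    "dfa_exponent",
    "default_scales",
]

R2_SCALING_THRESHOLD = 0.95


@dataclass
class IncrementSeries:
    """Instantaneous dFC increments of a smooth stream."""

    values: np.ndarray
    window_size: int
    delta_t: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DFAResult:
    """Fitted DFA scaling: per-scale fluctuations and the log-log OLS fit."""

    scales: np.ndarray
    fluctuations: np.ndarray
    alpha: float
    intercept: float
    fit_r2: float
    scaling: bool
    label: str

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.fluctuations = np.asarray(self.fluctuations, dtype=float)


def _interpretation_label(alpha: float) -> str:
    if alpha >= 1.0:
        return "non-stationary"
    if alpha > 0.5:
        return "persistent"
    if alpha < 0.5:
        return "anti-persistent"
    return "memoryless"


def dfc_increments(stream: DFCStream) -> IncrementSeries:
    """Frame-to-frame speeds of a maximally smooth stream (step = 1).

    Increments are only defined on a stream whose slide step equals the
    minimum sample shift; a coarser stream raises.
    """
    step = stream.config.slide_step
    if step != 1:
        raise ValueError(
            f"increments require a smooth stream with slide_step=1, got "
            f"slide_step={step}"
        )
    sample = compute_speeds(compute_dfc_matrix(stream), frame_offset=1)
    return IncrementSeries(sample.speeds, stream.config.window_size, delta_t=1)


def integrate_profile(inc: IncrementSeries | np.ndarray) -> np.ndarray:
    """Cumulative sum of the mean-centred increments (the walk profile).

    Centring is required: the increments are nonnegative speeds, and the
    uncentred cumulative sum is dominated by its linear mean trend, which
    would distort the exponent.
    """
    values = inc.values if isinstance(inc, IncrementSeries) else np.asarray(inc, float)
    if values.size == 0:
        raise ValueError("empty increment series")
    return np.cumsum(values - values.mean())


def dfa_fluctuation(profile: np.ndarray, k: int) -> float:
    """RMS detrended fluctuation of the profile at segment length ``k``.

    The profile is split into ``M = floor(K/k)`` non-overlapping segments
    (the remainder at the tail is dropped); an order-1 least-squares trend
    is removed per segment; the result is the RMS of the per-segment mean
    squared residuals.
    """
    profile = np.asarray(profile, dtype=float).ravel()
    big_k = profile.size
    if not 4 <= k <= big_k // 4:
        raise ValueError(
            f"scale k={k} outside admissible range [4, {big_k // 4}] "
            f"(need >= 4 segments of >= 4 samples)"
        )
    m = big_k // k
    segs = profile[: m * k].reshape(m, k)
    t = np.arange(k, dtype=float)
    # per-segment linear detrend via least squares on a shared design
    design = np.vstack([t, np.ones_like(t)]).T
    coef, *_ = np.linalg.lstsq(design, segs.T, rcond=None)
    resid = segs.T - design @ coef
    fq2 = np.mean(resid ** 2, axis=0)
    return float(np.sqrt(fq2.mean()))


def default_scales(n_samples: int, n_scales: int = 12, k_min: int = 8
                   ) -> np.ndarray:
    """~``n_scales`` log-spaced integer segment lengths from ``k_min`` to K/4."""
    k_max = n_samples // 4
    if k_max < k_min:
        raise ValueError(
            f"series too short for DFA: K/4 = {k_max} < k_min = {k_min}"
        )
    grid = np.unique(
        np.round(np.geomspace(k_min, k_max, n_scales)).astype(int)
    )
    return grid


def dfa_exponent(inc: IncrementSeries | np.ndarray,
                 scales: np.ndarray | None = None) -> DFAResult:
    """Fit the DFA scaling exponent of an increment series.

    Ordinary least squares of ``log F(k)`` on ``log k`` over the scale
    grid (default: 12 log-spaced scales from 8 to K/4).  Scales with zero
    fluctuation are excluded with a warning; fewer than 3 usable scales is
    an error.  The result carries the fit R^2 and a ``scaling`` flag
    (R^2 >= 0.95); a flagged-False result must not be interpreted as an
    exponent.
    """
    values = inc.values if isinstance(inc, IncrementSeries) else np.asarray(inc, float)
    profile = integrate_profile(values)
    if scales is None:
        scales = default_scales(values.size)
    scales = np.unique(np.asarray(scales, dtype=int))
    flucts = np.array([dfa_fluctuation(profile, int(k)) for k in scales])
    usable = flucts > 1e-12  # zero up to detrending round-off
    if not np.all(usable):
        warnings.warn(
            f"excluding scale(s) {scales[~usable].tolist()} with zero "
            "fluctuation from the log-log fit",
            stacklevel=2,
        )
    scales_u = scales[usable]
    flucts_u = flucts[usable]
    if scales_u.size < 3:
        raise ValueError(
            f"only {scales_u.size} usable scale(s); need at least 3 for a fit"
        )
    lx = np.log(scales_u.astype(float))
    ly = np.log(flucts_u)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    scaling = bool(r2 >= R2_SCALING_THRESHOLD)
    return DFAResult(
        scales=scales_u,
        fluctuations=flucts_u,
        alpha=float(slope),
        intercept=float(intercept),
        fit_r2=r2,
        scaling=scaling,
        label=_interpretation_label(float(slope)),
    )
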