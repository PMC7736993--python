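"""Recurrence structure and reconfiguration speed of dFC streams.

The dFC (recurrence) matrix correlates FC frames observed at different
times: entry ``(a, b)`` is the Pearson correlation between the triangular
parts of frames ``a`` and ``b``.  Blocks of high similarity ("knots") mark
epochs of transient FC stabilisation; stripes of low similarity ("leaps")
mark fast network reconfiguration.

The instantaneous dFC speed compares frames a fixed number of frames
apart: ``V(a) = 1 - dfc[a, a + df]``.  With a non-overlapping stream
(step = W) and ``df = 1`` this is the single-window speed; with a smooth
stream (step = 1) and ``df = W`` it is the window-oversampled estimate in
which each frame is compared with the first non-overlapping one.
Oversampled speeds are not statistically independent samples and are
flagged as such; no decorrelation correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .stream import DFCStream, StreamConfig

__all__ = [
    "DFCMatrix",
    "SpeedSample",
    "SpeedHistogram",
    "compute_dfc_matrix",
    "compute_speeds",
    "typical_speed",
    "pool_speeds",
    "build_speed_histogram",
    "agresti_coull_interval",
]


@dataclass
class DFCMatrix:
    """``F x F`` recurrence matrix of inter-frame FC similarity."""

    values: np.ndarray
    source_config: StreamConfig

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class SpeedSample:
    """Instantaneous dFC speeds with their estimation provenance."""

    speeds: np.ndarray
    window_size: int
    frame_offset: int
    oversampled: bool = False
    pooled_from: list[int] | None = None

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float).ravel()

    def __len__(self) -> int:
        return self.speeds.size


@dataclass
class SpeedHistogram:
    """Normalised speed histogram with binomial confidence intervals."""

    bin_edges: np.ndarray
    bin_probabilities: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    confidence_level: float
    n_observations: int
    n_underflow: int = 0
    n_overflow: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def compute_dfc_matrix(stream: DFCStream) -> DFCMatrix:
    """Correlate every pair of FC frames of a stream.

    Operating on the vector-format columns is equivalent to correlating
    the upper-triangular parts of the frame matrices.
    """
    if stream.n_frames < 2:
        raise ValueError("need at least 2 frames for a recurrence matrix")
    bad = np.nonzero(np.ptp(stream.frames, axis=0) == 0.0)[0]
    if bad.size:
        raise ValueError(
            f"frame(s) {bad.tolist()} are constant across links; "
            "inter-frame correlation is undefined"
        )
    dfc = np.corrcoef(stream.frames, rowvar=False)
    np.fill_diagonal(dfc, 1.0)
    return DFCMatrix(np.clip(dfc, -1.0, 1.0), stream.config)


def compute_speeds(dfc: DFCMatrix, frame_offset: int = 1) -> SpeedSample:
    """Speeds ``V(a) = 1 - dfc[a, a + frame_offset]`` for all valid ``a``.

    Because the recurrence entries lie in [-1, 1], speeds lie in [0, 2].
    """
    f = dfc.n_frames
    if not 1 <= frame_offset < f:
        raise ValueError(
            f"frame_offset must be in [1, {f}), got {frame_offset}"
        )
    a = np.arange(f - frame_offset)
    speeds = 1.0 - dfc.values[a, a + frame_offset]
    oversampled = dfc.source_config.slide_step < dfc.source_config.window_size
    return SpeedSample(
        speeds,
        window_size=dfc.source_config.window_size,
        frame_offset=frame_offset,
        oversampled=oversampled,
    )


def typical_speed(sample: SpeedSample, method: str = "median",
                  bins: int | np.ndarray = 20) -> float:
    """Location of a speed distribution: its median or its histogram mode."""
    if len(sample) == 0:
        raise ValueError("empty speed sample")
    if method == "median":
        return float(np.median(sample.speeds))
    if method == "histogram_mode":
        hist = build_speed_histogram(sample, bins=bins)
        return float(hist.bin_centers[int(np.argmax(hist.bin_probabilities))])
    raise ValueError(f"method must be 'median' or 'histogram_mode', got {method!r}")


def pool_speeds(samples: list[SpeedSample]) -> SpeedSample:
    """Concatenate speed lists across window sizes (window pooling).

    No reweighting is applied; the pooled median is the pooled typical
    speed.  Pooling is a pragmatic smoothing device and should be backed
    by single-window analyses over the pooled range.
    """
    if not samples:
        raise ValueError("no samples to pool")
    speeds = np.concatenate([s.speeds for s in samples])
    windows = [s.window_size for s in samples]
    return SpeedSample(
        speeds,
        window_size=windows[0],
        frame_offset=samples[0].frame_offset,
        oversampled=any(s.oversampled for s in samples),
        pooled_from=windows,
    )


def agresti_coull_interval(x: int, n: int, confidence_level: float = 0.95
                           ) -> tuple[float, float]:
    """Agresti–Coull binomial interval for ``x`` successes of ``n`` trials.

    With ``z`` the standard-normal quantile at ``(1 + level)/2``:
    ``n~ = n + z**2``, ``p~ = (x + z**2/2)/n~``, half-width
    ``z*sqrt(p~(1-p~)/n~)``; the interval is clipped to [0, 1].
    """
    if n < 1:
        raise ValueError("need at least one observation")
    z = stats.norm.ppf(0.5 * (1.0 + confidence_level))
    n_t = n + z * z
    p_t = (x + 0.5 * z * z) / n_t
    hw = z * np.sqrt(p_t * (1.0 - p_t) / n_t)
    return max(0.0, p_t - hw), min(1.0, p_t + hw)


def build_speed_histogram(sample: SpeedSample, bins: int | np.ndarray = 20,
                          confidence_level: float = 0.95) -> SpeedHistogram:
    """Histogram of a speed sample with per-bin Agresti–Coull intervals.

    Default bins: 20 equal-width bins over the full admissible range
    [0, 2].  Observations outside the bin range are counted in flagged
    under/overflow tallies and excluded from bin probabilities, with a
    warning.
    """
    if len(sample) == 0:
        raise ValueError("empty speed sample")
    if np.isscalar(bins):
        edges = np.linspace(0.0, 2.0, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float).ravel()
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing, >= 2 values")
    s = sample.speeds
    under = int(np.sum(s < edges[0]))
    over = int(np.sum(s > edges[-1]))
    if under or over:
        warnings.warn(
            f"{under + over} speed value(s) outside bin range "
            f"[{edges[0]}, {edges[-1]}] counted in overflow tallies",
            stacklevel=2,
        )
    counts, _ = np.histogram(s, bins=edges)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("all observations fall outside the bin range")
    probs = counts / n
    lo = np.empty_like(probs)
    hi = np.empty_like(probs)
    for b, x in enumerate(counts):
        lo[b], hi[b] = agresti_coull_interval(int(x), n, confidence_level)
    return SpeedHistogram(
        bin_edges=edges,
        bin_probabilities=probs,
        ci_low=lo,
        ci_high=hi,
        confidence_level=confidence_level,
        n_observations=n,
        n_underflow=under,
        n_overflow=over,
    )


def plot_speed_histogram(hist: SpeedHistogram, ax=None):
    """Minimal bar plot of a speed histogram with its confidence band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = hist.bin_centers
    width = np.diff(hist.bin_edges)
    ax.bar(centers, hist.bin_probabilities, width=width, alpha=0.6,
           edgecolor="k", label="observed")
    yerr = np.vstack([
        hist.bin_probabilities - hist.ci_low,
        hist.ci_high - hist.bin_probabilities,
    ])
    ax.errorbar(centers, hist.bin_probabilities, yerr=np.clip(yerr, 0, None),
                fmt="none", ecolor="k", capsize=2,
                label=f"{hist.confidence_level:.0%} CI")
    ax.set_xlabel("dFC speed")
    ax.set_ylabel("probability")
    ax.legend()
    return ax
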