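"""Null models for dFC streams.

Two null hypotheses bracket dFC phenomenology:

* **FC stationarity** — fluctuations around a fixed underlying FC.  Probed
  by *phase-randomized* time-series surrogates: each region's series is
  Fourier transformed and one random phase per positive frequency —
  *common to all regions* — rotates the coefficients.  The common rotation
  preserves every auto- and cross-spectrum magnitude, hence each region's
  power spectrum and the static covariance matrix, while destroying any
  systematic non-stationarity.

* **No sequential correlation** — frames are individually genuine but
  temporally exchangeable.  Probed by *time-shuffled* streams: the FC
  frames are randomly permuted, each frame left untouched, preserving every
  link's mean and variance across frames exactly.

Chance bands are percentile envelopes of a feature of interest over an
ensemble of surrogates (default 1000 instances, 5th/95th percentiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .stream import DFCStream
from .timeseries import TimeSeriesMatrix

__all__ = [
    "SurrogateBand",
    "phase_randomize",
    "time_shuffle_stream",
    "surrogate_chance_band",
]


@dataclass
class SurrogateBand:
    """Percentile envelope of a feature over a surrogate ensemble."""

    kind: str
    low: np.ndarray
    high: np.ndarray
    percentiles: tuple[float, float]
    n_instances: int
    seed: int
    values: np.ndarray  # (n_kept, n_features) per-instance feature values
    n_failed: int = 0


def phase_randomize(ts: TimeSeriesMatrix, seed: int | None = None,
                    angles: np.ndarray | None = None,
                    nyquist_sign: float | None = None) -> TimeSeriesMatrix:
    """Phase-randomized surrogate with a common rotation across regions.

    The series are de-meaned, transformed with the real FFT, rotated by one
    uniform random phase per positive frequency (shared by all regions; the
    DC bin is untouched and, for even length, the Nyquist bin is multiplied
    by a common random sign so the inverse transform stays real), inverse
    transformed, and the means are re-added.

    ``angles`` and ``nyquist_sign`` override the random draws (test hooks;
    all-zero angles with sign +1 reproduce the input exactly).
    """
    x = ts.values
    t = x.shape[0]
    rng = np.random.default_rng(seed)
    mean = x.mean(axis=0)
    spec = np.fft.rfft(x - mean, axis=0)
    n_pos = spec.shape[0]
    # bins 1 .. n_pos-1 are rotatable; for even T the last is the Nyquist bin
    has_nyquist = t % 2 == 0
    n_rot = n_pos - 1 - (1 if has_nyquist else 0)
    if angles is None:
        angles = rng.uniform(0.0, 2.0 * np.pi, size=n_rot)
    else:
        angles = np.asarray(angles, dtype=float).ravel()
        if angles.size != n_rot:
            raise ValueError(
                f"expected {n_rot} rotation angles for T={t}, got {angles.size}"
            )
    rot = np.exp(1j * angles)
    spec[1:1 + n_rot] *= rot[:, None]
    if has_nyquist:
        if nyquist_sign is None:
            nyquist_sign = float(rng.choice([-1.0, 1.0]))
        if nyquist_sign not in (-1.0, 1.0):
            raise ValueError("nyquist_sign must be -1 or +1")
        spec[-1] *= nyquist_sign
    out = np.fft.irfft(spec, n=t, axis=0) + mean
    return TimeSeriesMatrix(out, region_labels=ts.region_labels,
                            sample_period=ts.sample_period)


def time_shuffle_stream(stream: DFCStream, seed: int | None = None,
                        permutation: np.ndarray | None = None) -> DFCStream:
    """Randomly permute the FC frames of a stream, each frame unchanged.

    ``permutation`` overrides the random draw (test hook; the identity
    permutation reproduces the stream).
    """
    f = stream.n_frames
    if f < 2:
        raise ValueError("need at least 2 frames to shuffle")
    if permutation is None:
        rng = np.random.default_rng(seed)
        permutation = rng.permutation(f)
    else:
        permutation = np.asarray(permutation, dtype=int).ravel()
        if sorted(permutation.tolist()) != list(range(f)):
            raise ValueError("permutation must rearrange all frame indices")
    return DFCStream(
        stream.frames[:, permutation].copy(),
        stream.config,
        stream.frame_starts.copy(),
        stream.link_index,
        link_ordinals=stream.link_ordinals.copy(),
    )


def surrogate_chance_band(
    feature_fn: Callable[[TimeSeriesMatrix | DFCStream], float | np.ndarray],
    source: TimeSeriesMatrix | DFCStream,
    kind: str = "phase_randomized",
    n_instances: int = 1000,
    seed: int = 0,
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> SurrogateBand:
    """Percentile chance band of a feature over a surrogate ensemble.

    ``kind="phase_randomized"`` expects a :class:`TimeSeriesMatrix` source
    and hands each surrogate series to ``feature_fn``;
    ``kind="time_shuffled"`` expects a :class:`DFCStream` and hands each
    shuffled stream to ``feature_fn``.  Instances on which the feature
    fails are skipped with a warning; more than 10% failures is an error.
    Identical seeds produce identical bands.
    """
    if kind == "phase_randomized":
        if not isinstance(source, TimeSeriesMatrix):
            raise TypeError("phase_randomized surrogates need a TimeSeriesMatrix")
        make = lambda s: phase_randomize(source, seed=s)  # noqa: E731
    elif kind == "time_shuffled":
        if not isinstance(source, DFCStream):
            raise TypeError("time_shuffled surrogates need a DFCStream")
        make = lambda s: time_shuffle_stream(source, seed=s)  # noqa: E731
    else:
        raise ValueError(
            f"kind must be 'phase_randomized' or 'time_shuffled', got {kind!r}"
        )
    if n_instances < 1:
        raise ValueError("need at least one surrogate instance")
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2 ** 31 - 1, size=n_instances)
    rows = []
    n_failed = 0
    for s in sub_seeds:
        try:
            val = np.atleast_1d(np.asarray(feature_fn(make(int(s))), dtype=float))
        except Exception as exc:  # noqa: BLE001 — feature failures are data-dependent
            n_failed += 1
            warnings.warn(f"feature failed on a surrogate instance: {exc}",
                          stacklevel=2)
            continue
        rows.append(val)
    if n_failed > 0.1 * n_instances:
        raise RuntimeError(
            f"feature failed on {n_failed}/{n_instances} surrogate instances"
        )
    values = np.vstack(rows)
    low = np.percentile(values, percentiles[0], axis=0)
    high = np.percentile(values, percentiles[1], axis=0)
    return SurrogateBand(
        kind=kind, low=low, high=high, percentiles=percentiles,
        n_instances=n_instances, seed=seed, values=values, n_failed=n_failed,
    )
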