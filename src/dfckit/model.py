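"""Model/Results facade over the dFC random-walk analyses.

:class:`DFCWalk` is built from a multivariate time-series plus a window
configuration; :meth:`DFCWalk.fit` runs the full analysis battery —
static FC, the non-overlapping speed stream and its recurrence matrix and
speed distribution, the maximally smooth stream feeding DFA and
meta-connectivity, signed-modularity dFC modules, per-module meta-strengths
and modular speeds — and returns a :class:`DFCWalkResults` carrying the
estimates, their provenance, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import ModulePartition, detect_mc_modules
from .dfa import DFAResult, dfa_exponent, dfc_increments
from .metaconn import MCMatrix, MetaStrengths, compute_mc, trimer_strengths
from .recurrence import (DFCMatrix, SpeedHistogram, SpeedSample,
                         build_speed_histogram, compute_dfc_matrix,
                         compute_speeds, typical_speed)
from .stream import DFCStream, StreamConfig, compute_dfc_stream, \
    pick_subgraph_stream
from .timeseries import TimeSeriesMatrix, compute_static_fc

__all__ = ["DFCWalk", "DFCWalkResults"]

_MIN_DFA_INCREMENTS = 64   # below this, K/4 < 16 and a scale grid is meaningless


class DFCWalk:
    """dFC random-walk model of a multivariate time-series.

    Parameters
    ----------
    timeseries
        The ``T x N`` input series.
    window_size
        Sliding-window length ``W`` in samples, used for every windowed
        estimate.
    speed_step
        Slide step of the stream used for speed analysis; default ``W``
        (non-overlapping frames, independent speed samples).
    frame_offset
        Frames between compared pairs in the speed computation; default 1
        for a non-overlapping stream, ``W / speed_step`` (rounded) for an
        oversampled one, so frames are always compared across
        non-overlapping intervals.
    compute_meta, detect_modules
        Toggle meta-connectivity and dFC-module extraction (both need the
        smooth step-1 stream, quadratic in the link count).
    resolution
        Signed-modularity resolution parameter.
    hist_bins
        Bin count of the speed histogram over [0, 2].
    """

    def __init__(self, timeseries: TimeSeriesMatrix, window_size: int, *,
                 speed_step: int | None = None,
                 frame_offset: int | None = None,
                 dfa_scales: np.ndarray | None = None,
                 compute_meta: bool = True,
                 detect_modules: bool = True,
                 resolution: float = 1.0,
                 hist_bins: int = 20) -> None:
        if not isinstance(timeseries, TimeSeriesMatrix):
            timeseries = TimeSeriesMatrix(np.asarray(timeseries))
        self.timeseries = timeseries
        self.window_size = int(window_size)
        self.speed_step = int(speed_step) if speed_step else self.window_size
        if frame_offset is None:
            frame_offset = max(1, round(self.window_size / self.speed_step))
        self.frame_offset = int(frame_offset)
        self.dfa_scales = dfa_scales
        self.compute_meta = compute_meta
        self.detect_modules = detect_modules and compute_meta
        self.resolution = float(resolution)
        self.hist_bins = int(hist_bins)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, window_size: int,
                       **kwargs) -> "DFCWalk":
        return cls(TimeSeriesMatrix.from_dataframe(df), window_size, **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, window_size: int, **kwargs
                 ) -> "DFCWalk":
        return cls(TimeSeriesMatrix.from_csv(path), window_size, **kwargs)

    def fit(self, seed: int = 0) -> "DFCWalkResults":
        """Run the analysis battery; deterministic given ``seed``."""
        ts = self.timeseries
        static_fc = compute_static_fc(ts)

        speed_cfg = StreamConfig(self.window_size, self.speed_step)
        speed_stream = compute_dfc_stream(ts, speed_cfg)
        dfc_matrix = compute_dfc_matrix(speed_stream)
        speeds = compute_speeds(dfc_matrix, self.frame_offset)
        hist = build_speed_histogram(speeds, bins=self.hist_bins)
        typ = typical_speed(speeds, method="median")

        smooth_stream = None
        dfa_result = None
        mc = None
        partition = None
        meta = None
        modular_speeds: dict[int, float] = {}
        need_smooth = self.compute_meta or True  # DFA also wants step 1
        if need_smooth and ts.n_samples - self.window_size + 1 >= 3:
            smooth_stream = compute_dfc_stream(
                ts, StreamConfig(self.window_size, 1))
            inc = dfc_increments(smooth_stream)
            if len(inc) >= _MIN_DFA_INCREMENTS:
                dfa_result = dfa_exponent(inc, self.dfa_scales)
            if self.compute_meta:
                mc = compute_mc(smooth_stream)
                meta = trimer_strengths(mc)
                if self.detect_modules:
                    partition = detect_mc_modules(
                        mc, resolution=self.resolution, seed=seed)
                    modular_speeds = self._modular_speeds(speed_stream,
                                                          partition)
        return DFCWalkResults(
            model=self, seed=seed, static_fc=static_fc,
            speed_stream=speed_stream, dfc_matrix=dfc_matrix, speeds=speeds,
            speed_histogram=hist, typical_speed=typ,
            smooth_stream=smooth_stream, dfa=dfa_result, mc=mc,
            partition=partition, meta_strengths=meta,
            modular_typical_speeds=modular_speeds,
        )

    def _modular_speeds(self, speed_stream: DFCStream,
                        partition: ModulePartition) -> dict[int, float]:
        out: dict[int, float] = {}
        for mod in np.unique(partition.labels):
            links = partition.module_links(int(mod))
            if links.size < 2:
                continue
            sub = pick_subgraph_stream(speed_stream, links)
            try:
                sub_speeds = compute_speeds(
                    compute_dfc_matrix(sub), self.frame_offset)
            except ValueError:
                continue  # degenerate restricted stream
            out[int(mod)] = typical_speed(sub_speeds, method="median")
        return out


@dataclass
class DFCWalkResults:
    """Fitted dFC random-walk descriptors of one session."""

    model: DFCWalk
    seed: int
    static_fc: np.ndarray
    speed_stream: DFCStream
    dfc_matrix: DFCMatrix
    speeds: SpeedSample
    speed_histogram: SpeedHistogram
    typical_speed: float
    smooth_stream: DFCStream | None
    dfa: DFAResult | None
    mc: MCMatrix | None
    partition: ModulePartition | None
    meta_strengths: MetaStrengths | None
    modular_typical_speeds: dict[int, float] = field(default_factory=dict)

    @property
    def meta_hub(self) -> int | None:
        """Region with the largest trimer meta-strength, if MC was computed."""
        if self.meta_strengths is None:
            return None
        return int(np.argmax(self.meta_strengths.values))

    def summary(self) -> str:
        """Plain-text summary table of the fitted descriptors."""
        m = self.model
        ts = m.timeseries
        lines = [
            "dFC random-walk analysis".center(58),
            "=" * 58,
            f"{'regions (N)':<30}{ts.n_regions:>28}",
            f"{'samples (T)':<30}{ts.n_samples:>28}",
            f"{'window size W':<30}{m.window_size:>28}",
            f"{'speed-stream step':<30}{m.speed_step:>28}",
            f"{'speed frames F':<30}{self.speed_stream.n_frames:>28}",
            f"{'frame offset':<30}{m.frame_offset:>28}",
            "-" * 58,
            f"{'typical dFC speed (median)':<30}{self.typical_speed:>28.4f}",
            f"{'speed sample size':<30}{len(self.speeds):>28}",
        ]
        if self.dfa is not None:
            flag = "" if self.dfa.scaling else " [non-scaling]"
            lines += [
                f"{'DFA exponent alpha':<30}{self.dfa.alpha:>28.4f}",
                f"{'DFA fit R^2':<30}{self.dfa.fit_r2:>28.4f}",
                f"{'DFA regime':<30}{self.dfa.label + flag:>28}",
            ]
        if self.partition is not None:
            lines += [
                "-" * 58,
                f"{'dFC modules':<30}{self.partition.n_modules:>28}",
                f"{'signed modularity':<30}{self.partition.quality:>28.4f}",
            ]
            if self.meta_hub is not None:
                hub = self.meta_hub
                name = (ts.region_labels[hub] if ts.region_labels
                        else str(hub))
                strength = self.meta_strengths.values[hub]
                lines.append(
                    f"{'top meta-hub (region)':<30}"
                    f"{name + f' ({strength:.2f})':>28}"
                )
            for mod, v in sorted(self.modular_typical_speeds.items()):
                lines.append(f"{f'module {mod} typical speed':<30}{v:>28.4f}")
        lines += ["=" * 58, f"dfckit {__version__}  seed={self.seed}"]
        return "\n".join(lines)
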