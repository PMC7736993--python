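"""Sliding-window dFC streams: temporal networks of windowed FC frames.

A dFC stream is the sequence of FC matrices estimated over sliding windows
of ``W`` samples advanced by ``slide_step`` samples: frame ``k`` covers the
half-open sample range ``[k*step, k*step + W)``.  Trailing windows that
would be trimmed by the end of the series are dropped, so the frame count
is exactly ``F = floor((T - W) / step) + 1``.

Streams are stored in compact vector format: an ``L x F`` matrix whose rows
are the FC time-courses ``FC_ij(t_k)`` of individual links and whose columns
are FC frames.  This is half the footprint of the dense ``N x N x F`` tensor
and is the layout every downstream analysis (recurrence, speeds, DFA,
meta-connectivity) consumes directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .linkindex import LinkIndex
from .timeseries import TimeSeriesMatrix, vector_to_matrix

__all__ = [
    "StreamConfig",
    "DFCStream",
    "compute_dfc_stream",
    "pick_subgraph_stream",
    "write_stream",
    "read_stream",
]

LINK_ORDER_VERSION = "rowmajor-upper-v1"


@dataclass(frozen=True)
class StreamConfig:
    """Window size ``W`` and slide step (both in samples)."""

    window_size: int
    slide_step: int | None = None

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError(f"window_size must be >= 2, got {self.window_size}")
        step = self.window_size if self.slide_step is None else self.slide_step
        if step < 1:
            raise ValueError(f"slide_step must be >= 1, got {step}")
        object.__setattr__(self, "slide_step", step)

    def n_frames(self, n_samples: int) -> int:
        """F = floor((T - W) / step) + 1; trailing trimmed windows dropped."""
        if self.window_size > n_samples:
            raise ValueError(
                f"window_size {self.window_size} exceeds series length {n_samples}"
            )
        return (n_samples - self.window_size) // self.slide_step + 1


@dataclass
class DFCStream:
    """``L x F`` vector-format stream of windowed FC frames.

    ``link_ordinals`` maps each row to an undirected link ordinal of
    ``link_index`` — the identity ``arange(L)`` for a full stream, a subset
    after :func:`pick_subgraph_stream`.
    """

    frames: np.ndarray
    config: StreamConfig
    frame_starts: np.ndarray
    link_index: LinkIndex
    link_ordinals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError("frames must be a 2-D (L x F) array")
        self.frame_starts = np.asarray(self.frame_starts, dtype=int)
        if self.frame_starts.size != self.frames.shape[1]:
            raise ValueError("frame_starts length must equal frame count")
        if self.link_ordinals is None:
            if self.frames.shape[0] != self.link_index.n_links:
                raise ValueError(
                    f"{self.frames.shape[0]} rows but link index has "
                    f"{self.link_index.n_links} links"
                )
            self.link_ordinals = np.arange(self.link_index.n_links)
        else:
            self.link_ordinals = np.asarray(self.link_ordinals, dtype=int)
            if self.link_ordinals.size != self.frames.shape[0]:
                raise ValueError("link_ordinals length must equal row count")

    @property
    def n_links(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    @property
    def is_full(self) -> bool:
        """True when rows cover every link of the index in canonical order."""
        return (
            self.n_links == self.link_index.n_links
            and np.array_equal(self.link_ordinals, np.arange(self.n_links))
        )

    def frame_matrix(self, k: int) -> np.ndarray:
        """Frame ``k`` as a symmetric ``N x N`` matrix (full streams only)."""
        if not self.is_full:
            raise ValueError(
                "matrix view is only defined for full (unrestricted) streams"
            )
        return vector_to_matrix(self.frames[:, k], self.link_index.n_regions)

    def to_tensor(self) -> np.ndarray:
        """Dense ``N x N x F`` tensor view (full streams only)."""
        return np.stack(
            [self.frame_matrix(k) for k in range(self.n_frames)], axis=-1
        )


def compute_dfc_stream(ts: TimeSeriesMatrix, cfg: StreamConfig) -> DFCStream:
    """Estimate the dFC stream of ``ts`` under window/step config ``cfg``.

    Each frame is the Pearson-correlation FC of the sample slice
    ``[k*step, k*step + W)``.  A region that is constant within any window
    raises, naming the (region, frame): NaN frames would silently poison
    every downstream correlation.
    """
    t, n = ts.values.shape
    f = cfg.n_frames(t)  # raises if W > T
    w, step = cfg.window_size, cfg.slide_step
    iu, ju = np.triu_indices(n, k=1)
    frames = np.empty((iu.size, f))
    starts = np.arange(f) * step
    x = ts.values
    for k in range(f):
        sl = x[starts[k]:starts[k] + w]
        bad = np.nonzero(np.ptp(sl, axis=0) == 0.0)[0]
        if bad.size:
            raise ValueError(
                f"region(s) {bad.tolist()} constant within frame {k} "
                f"(samples [{starts[k]}, {starts[k] + w}))"
            )
        c = np.corrcoef(sl, rowvar=False)
        frames[:, k] = np.clip(c[iu, ju], -1.0, 1.0)
    return DFCStream(frames, cfg, starts, LinkIndex(n))


def pick_subgraph_stream(stream: DFCStream, links: np.ndarray) -> DFCStream:
    """Restrict a stream to a list of link ordinals (rows).

    The restriction need not be a dFC module — any list of links of
    interest (an anatomical subdivision, a classic network) works, and the
    restricted stream feeds every downstream analysis unchanged.
    """
    links = np.asarray(links, dtype=int).ravel()
    if links.size == 0:
        raise ValueError("link restriction is empty")
    ordinals = stream.link_ordinals
    pos = {int(o): r for r, o in enumerate(ordinals)}
    rows = []
    for m in links:
        if int(m) not in pos:
            raise IndexError(
                f"link ordinal {int(m)} not present in this stream "
                f"(valid: subset of [0, {stream.link_index.n_links}))"
            )
        rows.append(pos[int(m)])
    return DFCStream(
        stream.frames[rows].copy(),
        stream.config,
        stream.frame_starts.copy(),
        stream.link_index,
        link_ordinals=links.copy(),
    )


def write_stream(stream: DFCStream, path: str | Path, sep: str = ",") -> None:
    """Write the L x F frame matrix as delimited text plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, stream.frames, delimiter=sep)
    sidecar = {
        "n_regions": stream.link_index.n_regions,
        "window_size": stream.config.window_size,
        "slide_step": stream.config.slide_step,
        "frame_starts": stream.frame_starts.tolist(),
        "link_ordinals": stream.link_ordinals.tolist(),
        "link_order": LINK_ORDER_VERSION,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_stream(path: str | Path, sep: str = ",") -> DFCStream:
    """Read a stream written by :func:`write_stream`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if meta.get("link_order") != LINK_ORDER_VERSION:
        raise ValueError(
            f"unsupported link ordering {meta.get('link_order')!r}; "
            f"expected {LINK_ORDER_VERSION!r}"
        )
    frames = np.loadtxt(path, delimiter=sep, ndmin=2)
    return DFCStream(
        frames,
        StreamConfig(meta["window_size"], meta["slide_step"]),
        np.asarray(meta["frame_starts"], dtype=int),
        LinkIndex(meta["n_regions"]),
        link_ordinals=np.asarray(meta["link_ordinals"], dtype=int),
    )
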