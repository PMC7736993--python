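"""Meta-connectivity: the covariance structure of FC link fluctuations.

Where FC describes inter-node covariance, meta-connectivity (MC) describes
inter-link covariance: entry ``MC_ij,kl`` is the Pearson correlation
between the time-courses ``FC_ij(t)`` and ``FC_kl(t)`` of two links across
the frames of a dFC stream.  MC captures higher-order (3- and 4-region)
coordination: a *trimer* couples two links sharing a root region, a
*tetramer* two non-incident links.  Regions rooting many strong trimers
(large trimer meta-strength ``MC(i)``) are *meta-hubs* — localized
controllers of distributed sets of covarying links.

Storage follows the compact convention: the canonical object is the
``L x L`` matrix over unordered links.  The redundant ``M x M`` view over
ordered region pairs (``M = N(N-1)``), in which every unique value occupies
its eight degenerate positions, is materialised only on demand and behind a
memory cap, since it grows with the fourth power of the region count.

Edge-centric FC (eFC) is the windowless analogue: the correlation matrix of
the instantaneous z-score product series ``P_ij(t) = z_i(t) * z_j(t)``.
MC and eFC entries are strongly correlated, but MC profits from
sliding-window smoothing of link fluctuations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .linkindex import LinkIndex
from .stream import DFCStream, StreamConfig
from .timeseries import TimeSeriesMatrix

__all__ = [
    "MCMatrix",
    "MetaStrengths",
    "compute_mc",
    "expand_mc",
    "trimer_strengths",
    "compute_efc",
    "DEFAULT_EXPAND_CAP_BYTES",
]

DEFAULT_EXPAND_CAP_BYTES = 4 * 1024 ** 3  # refuse larger expanded views


@dataclass
class MCMatrix:
    """Compact ``L x L`` meta-connectivity over unordered links."""

    compact: np.ndarray
    n_regions: int
    source_config: StreamConfig
    link_ordinals: np.ndarray | None = None  # set when built from a restricted stream

    def __post_init__(self) -> None:
        self.compact = np.asarray(self.compact, dtype=float)
        if self.compact.ndim != 2 or self.compact.shape[0] != self.compact.shape[1]:
            raise ValueError("compact MC must be square")

    @property
    def n_links(self) -> int:
        return self.compact.shape[0]

    @property
    def link_index(self) -> LinkIndex:
        return LinkIndex(self.n_regions)


@dataclass
class MetaStrengths:
    """Per-region trimer meta-strengths ``MC(i)``."""

    values: np.ndarray
    restricted_to: str | None = None


def compute_mc(stream: DFCStream) -> MCMatrix:
    """Correlate all pairs of link time-courses of a dFC stream.

    All entries are retained unthresholded.  A link whose FC time-course is
    constant across frames is uninformative: its MC row and column are set
    to 0 (diagonal 1) and a warning lists the affected links.
    """
    if stream.n_frames < 3:
        raise ValueError(
            f"need at least 3 frames to estimate inter-link correlations, "
            f"got {stream.n_frames}"
        )
    rows = stream.frames
    const = np.nonzero(np.ptp(rows, axis=1) == 0.0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mc = np.corrcoef(rows)
    if const.size:
        links = stream.link_ordinals[const]
        warnings.warn(
            f"link(s) {links.tolist()} have constant FC time-courses; their "
            "MC rows are set to 0",
            stacklevel=2,
        )
        mc[const, :] = 0.0
        mc[:, const] = 0.0
    np.fill_diagonal(mc, 1.0)
    mc = np.clip(mc, -1.0, 1.0)
    ordinals = None if stream.is_full else stream.link_ordinals.copy()
    return MCMatrix(mc, stream.link_index.n_regions, stream.config,
                    link_ordinals=ordinals)


def expand_mc(mc: MCMatrix, max_bytes: int = DEFAULT_EXPAND_CAP_BYTES
              ) -> np.ndarray:
    """Materialise the redundant ``M x M`` view over ordered region pairs.

    Each unique inter-link value lands in its eight degenerate positions
    (four on the diagonal blocks where both ordered pairs cover the same
    unordered link).  Refuses, pointing back to compact-mode operations,
    when the dense view would exceed ``max_bytes``.
    """
    if mc.link_ordinals is not None:
        raise ValueError(
            "expanded view is only defined for a full-link MC matrix"
        )
    idx = mc.link_index
    m = idx.n_directed
    need = m * m * 8
    if need > max_bytes:
        raise MemoryError(
            f"expanded MC would need {m}x{m} doubles ({need / 1e9:.1f} GB) "
            f"> cap {max_bytes / 1e9:.1f} GB; use compact-mode operations "
            "or raise max_bytes"
        )
    u = idx.directed_to_undirected()
    return mc.compact[np.ix_(u, u)]


def trimer_strengths(mc: MCMatrix, restrict_links: np.ndarray | None = None,
                     label: str | None = None) -> MetaStrengths:
    """Trimer meta-strength ``MC(i)`` of every region.

    ``MC(i)`` sums the meta-connectivity between all unordered pairs of
    *distinct* links incident on region ``i`` (each pair counted once; the
    self meta-link excluded).  On an all-ones compact MC this gives
    ``(N-1)(N-2)/2``.  When ``restrict_links`` is given (e.g. the links of
    one dFC module), both links of each pair must belong to the
    restriction, yielding module-restricted meta-strengths.
    """
    if mc.link_ordinals is not None:
        raise ValueError("meta-strengths require a full-link MC matrix")
    idx = mc.link_index
    n = idx.n_regions
    allowed: set[int] | None = None
    if restrict_links is not None:
        restrict_links = np.asarray(restrict_links, dtype=int).ravel()
        if restrict_links.size and (
            restrict_links.min() < 0 or restrict_links.max() >= idx.n_links
        ):
            raise IndexError("restriction contains out-of-range link ordinals")
        allowed = set(restrict_links.tolist())
        if not allowed:
            warnings.warn("empty link restriction: all meta-strengths are 0",
                          stacklevel=2)
    out = np.zeros(n)
    for i in range(n):
        inc = idx.incident_links(i)
        if allowed is not None:
            inc = np.array([m for m in inc if int(m) in allowed], dtype=int)
        if inc.size < 2:
            continue
        sub = mc.compact[np.ix_(inc, inc)]
        out[i] = 0.5 * (sub.sum() - np.trace(sub))
    return MetaStrengths(out, restricted_to=label)


def compute_efc(ts: TimeSeriesMatrix) -> np.ndarray:
    """Edge-centric FC: correlation matrix of z-score product series.

    Each region is z-scored over the full session (sample std, ddof=1);
    ``P_ij(t) = z_i(t) * z_j(t)`` for ``i < j`` in canonical link order;
    the result is the ``L x L`` Pearson correlation matrix of the ``L``
    product series.
    """
    x = ts.values
    bad = np.nonzero(np.ptp(x, axis=0) == 0.0)[0]
    if bad.size:
        raise ValueError(
            f"region(s) {bad.tolist()} are constant; z-scoring is undefined"
        )
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    i, j = np.triu_indices(ts.n_regions, k=1)
    products = z[:, i] * z[:, j]  # T x L
    efc = np.corrcoef(products, rowvar=False)
    np.fill_diagonal(efc, 1.0)
    return np.clip(efc, -1.0, 1.0)
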