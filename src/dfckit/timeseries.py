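"""Multivariate time-series container, static FC, and vector/matrix formats.

The universal input is a ``T x N`` real matrix: rows are time samples,
columns are regions (brain parcels, channels, or any real-valued signals).
Static functional connectivity (FC) is the full-session Pearson correlation
matrix between region pairs; *all* entries are retained, with no
significance masking or thresholding, because FC entries are treated as
features, not as tested hypotheses.

Symmetric FC matrices carry ``L = N(N-1)/2`` independent entries, so a
compact vector format under the canonical :class:`~dfckit.linkindex.LinkIndex`
ordering is used for all heavy computation; conversions are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .linkindex import LinkIndex

__all__ = [
    "TimeSeriesMatrix",
    "compute_static_fc",
    "matrix_to_vector",
    "vector_to_matrix",
    "n_regions_of_length",
]

_SYMMETRY_TOL = 1e-10


@dataclass
class TimeSeriesMatrix:
    """``T x N`` matrix of real-valued regional activity.

    Parameters
    ----------
    values
        Array of shape ``(T, N)`` with ``T >= 2`` samples and ``N >= 2``
        regions; all entries must be finite.
    region_labels
        Optional region names (length ``N``).
    sample_period
        Seconds per sample (e.g. the fMRI TR). Metadata only; no operation
        converts between samples and seconds implicitly.
    """

    values: np.ndarray
    region_labels: list[str] | None = None
    sample_period: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D array, got ndim={self.values.ndim}")
        t, n = self.values.shape
        if t < 2 or n < 2:
            raise ValueError(f"need T >= 2 and N >= 2, got T={t}, N={n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time-series contain non-finite entries")
        if self.region_labels is not None and len(self.region_labels) != n:
            raise ValueError(
                f"{len(self.region_labels)} labels for {n} regions"
            )
        if self.sample_period is not None and self.sample_period <= 0:
            raise ValueError("sample_period must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def link_index(self) -> LinkIndex:
        return LinkIndex(self.n_regions)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_period: float | None = None
                       ) -> "TimeSeriesMatrix":
        """Build from a DataFrame with one column per region."""
        labels = [str(c) for c in df.columns]
        return cls(df.to_numpy(dtype=float), region_labels=labels,
                   sample_period=sample_period)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None,
                 header: bool | None = None,
                 sample_period: float | None = None) -> "TimeSeriesMatrix":
        """Read a delimited text matrix (rows = time, columns = regions).

        ``header=None`` sniffs the first row: if any cell is non-numeric it
        is taken as a row of region labels.
        """
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        first = pd.read_csv(path, sep=sep, header=None, nrows=1)
        if header is None:
            header = any(
                not _is_number(v) for v in first.iloc[0].tolist()
            )
        df = pd.read_csv(path, sep=sep, header=0 if header else None)
        bad = df.columns[df.dtypes == object]
        if len(bad):
            raise ValueError(
                f"non-numeric cells in column(s) {list(bad)} of {path}"
            )
        labels = [str(c) for c in df.columns] if header else None
        return cls(df.to_numpy(dtype=float), region_labels=labels,
                   sample_period=sample_period)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        cols = self.region_labels
        df = pd.DataFrame(self.values, columns=cols)
        df.to_csv(path, sep=sep, index=False, header=cols is not None)


def _is_number(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def _check_nonconstant(values: np.ndarray, context: str = "") -> None:
    bad = np.nonzero(np.ptp(values, axis=0) == 0.0)[0]
    if bad.size:
        where = f" {context}" if context else ""
        raise ValueError(
            f"region(s) {bad.tolist()} are constant{where}; "
            "Pearson correlation is undefined for zero-variance signals"
        )


def compute_static_fc(ts: TimeSeriesMatrix, format: str = "matrix") -> np.ndarray:
    """Full-session (static) FC: Pearson correlation between all region pairs.

    Every entry is retained unthresholded.  ``format="matrix"`` returns the
    symmetric ``N x N`` matrix with unit diagonal; ``format="vector"`` the
    compact length-``L`` upper-triangle vector in canonical link order.
    """
    if format not in ("matrix", "vector"):
        raise ValueError(f"format must be 'matrix' or 'vector', got {format!r}")
    _check_nonconstant(ts.values)
    fc = np.corrcoef(ts.values, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    fc = np.clip(fc, -1.0, 1.0)
    if format == "vector":
        return matrix_to_vector(fc)
    return fc


def n_regions_of_length(length: int) -> int:
    """Recover N from a vector length L = N(N-1)/2, or raise."""
    n = int((1 + np.sqrt(1 + 8 * length)) / 2)
    if n * (n - 1) // 2 != length:
        raise ValueError(
            f"length {length} is not of the form N(N-1)/2 for any integer N"
        )
    return n


def matrix_to_vector(fc: np.ndarray) -> np.ndarray:
    """Compact a symmetric FC matrix into its canonical length-L vector."""
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {fc.shape}")
    if not np.allclose(fc, fc.T, atol=_SYMMETRY_TOL, rtol=0.0):
        raise ValueError(
            f"matrix is asymmetric beyond tolerance {_SYMMETRY_TOL}"
        )
    i, j = np.triu_indices(fc.shape[0], k=1)
    return fc[i, j].copy()


def vector_to_matrix(vec: np.ndarray, n_regions: int | None = None) -> np.ndarray:
    """Expand a canonical length-L link vector into the symmetric N x N matrix.

    The diagonal is set to exactly 1 (self-correlation).
    """
    vec = np.asarray(vec, dtype=float).ravel()
    n = n_regions_of_length(vec.size) if n_regions is None else n_regions
    if n * (n - 1) // 2 != vec.size:
        raise ValueError(
            f"vector length {vec.size} inconsistent with N={n}"
        )
    out = np.eye(n)
    i, j = np.triu_indices(n, k=1)
    out[i, j] = vec
    out[j, i] = vec
    return out
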