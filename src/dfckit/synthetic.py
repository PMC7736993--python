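"""Seedable synthetic generators with the structure the analyses assume.

Four generator families make the whole toolbox testable without any
external recording, each emitting its planted parameters alongside the
data so downstream tests are parameter-recovery tests:

* stationary multivariate Gaussian series with a prescribed covariance —
  the FC-stationarity null;
* covariance-switching series, whose piecewise-stationary regimes produce
  the "knot"/"leap" block structure of the recurrence matrix;
* series with planted covarying link groups (ground-truth dFC modules),
  built from a slowly modulated time-varying covariance;
* exact fractional Gaussian noise, the calibration series for the DFA
  exponent (alpha tracks the Hurst exponent H).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .linkindex import LinkIndex
from .timeseries import TimeSeriesMatrix

__all__ = [
    "gen_stationary_gaussian",
    "gen_switching_covariance",
    "gen_planted_mc_modules",
    "gen_fgn_increments",
    "PlantedModules",
    "paired_covariance",
]

_EIG_TOL = 1e-10


def _psd_factor(cov: np.ndarray, what: str = "covariance") -> np.ndarray:
    """Factor A with A @ A.T = cov, flooring tiny negative eigenvalues."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"{what} must be square")
    if not np.allclose(cov, cov.T, atol=1e-12, rtol=0.0):
        raise ValueError(f"{what} must be symmetric")
    vals, vecs = np.linalg.eigh(cov)
    floor = -_EIG_TOL * max(1.0, float(vals.max(initial=1.0)))
    if vals.min() < floor:
        raise ValueError(
            f"{what} is not positive semi-definite "
            f"(min eigenvalue {vals.min():.3e})"
        )
    if vals.min() < 0:
        warnings.warn(
            f"{what}: eigenvalue floor applied "
            f"(min eigenvalue {vals.min():.3e} clipped to 0)",
            stacklevel=3,
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def gen_stationary_gaussian(n_regions: int, n_samples: int,
                            covariance: np.ndarray | None = None,
                            seed: int = 0) -> TimeSeriesMatrix:
    """i.i.d.-in-time draws from a zero-mean Gaussian with given covariance."""
    cov = np.eye(n_regions) if covariance is None else np.asarray(covariance)
    if cov.shape != (n_regions, n_regions):
        raise ValueError(
            f"covariance shape {cov.shape} inconsistent with N={n_regions}"
        )
    a = _psd_factor(cov)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, n_regions))
    return TimeSeriesMatrix(z @ a.T)


def paired_covariance(n_regions: int, r: float, offset: int = 0) -> np.ndarray:
    """Covariance coupling disjoint region pairs ``(offset+2m, offset+2m+1)``.

    A convenience for switching fixtures: two calls with offsets 0 and 1
    give regimes with orthogonal coupling structure.
    """
    cov = np.eye(n_regions)
    i = offset
    while i + 1 < n_regions:
        cov[i, i + 1] = cov[i + 1, i] = r
        i += 2
    return cov


def gen_switching_covariance(covariances: list[np.ndarray], dwell: int,
                             n_samples: int, seed: int = 0
                             ) -> tuple[TimeSeriesMatrix, np.ndarray]:
    """Piecewise-stationary Gaussian series cycling through regimes.

    Regimes alternate cyclically, each lasting ``dwell`` samples.  Returns
    the series and the ground-truth regime label of every sample.  With a
    single regime this reduces to :func:`gen_stationary_gaussian`.
    """
    if not covariances:
        raise ValueError("need at least one regime covariance")
    if dwell < 2:
        raise ValueError(f"dwell must be >= 2 samples, got {dwell}")
    factors = [_psd_factor(c, f"regime {r} covariance")
               for r, c in enumerate(covariances)]
    n = factors[0].shape[0]
    if any(f.shape[0] != n for f in factors):
        raise ValueError("all regime covariances must share one region count")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, n))
    labels = (np.arange(n_samples) // dwell) % len(covariances)
    out = np.empty_like(z)
    for r, a in enumerate(factors):
        mask = labels == r
        out[mask] = z[mask] @ a.T
    return TimeSeriesMatrix(out), labels


@dataclass
class PlantedModules:
    """A planted-module fixture and its ground truth."""

    timeseries: TimeSeriesMatrix
    link_labels: np.ndarray     # module id per link ordinal; -1 = background
    modulations: np.ndarray     # (T, n_modules) modulation signals a_m(t)
    templates: list[np.ndarray]  # symmetric N x N link-group templates B_m


def _default_module_pairs(n_regions: int) -> list[list[tuple[int, int]]]:
    """Two clique link groups on disjoint halves of the regions."""
    if n_regions < 6:
        raise ValueError("default module layout needs at least 6 regions")
    half = n_regions // 2
    groups = [range(half), range(half, n_regions)]
    return [
        [(i, j) for a, i in enumerate(g) for j in list(g)[a + 1:]]
        for g in groups
    ]


def gen_planted_mc_modules(
    n_regions: int = 10,
    n_samples: int = 4000,
    module_pairs: list[list[tuple[int, int]]] | None = None,
    amplitude: float = 0.25,
    baseline: float = 0.3,
    smoothing_span: int = 100,
    seed: int = 0,
) -> PlantedModules:
    """Series with planted groups of covarying links (ground-truth dFC modules).

    The time-varying covariance is
    ``Sigma(t) = I + sum_m (baseline + a_m(t)) * B_m``, where each template
    ``B_m`` places unit weight on one disjoint group of links (default: two
    cliques over disjoint halves of the regions) and each modulation
    ``a_m(t)`` is an independent, seeded, moving-average-smoothed Gaussian
    signal scaled to standard deviation ``amplitude``.  The combined
    coefficient ``baseline + a_m(t)`` is clipped to the widest interval for
    which every eigenvalue of ``Sigma(t)`` stays at least 0.05, so the
    covariance remains positive definite by construction (no flooring
    needed at the shipped defaults).  Should a numerically non-PD
    ``Sigma(t)`` still arise, an eigenvalue floor is applied and the
    fixture is rejected if the repair moves any entry by more than 10% of
    its magnitude.
    """
    if module_pairs is None:
        module_pairs = _default_module_pairs(n_regions)
    idx = LinkIndex(n_regions)
    link_labels = np.full(idx.n_links, -1, dtype=int)
    templates: list[np.ndarray] = []
    seen: set[int] = set()
    for mod, pairs in enumerate(module_pairs):
        b = np.zeros((n_regions, n_regions))
        for (i, j) in pairs:
            m = idx.ordinal_of(i, j)
            if m in seen:
                raise ValueError(
                    f"link ({i},{j}) appears in more than one module group"
                )
            seen.add(m)
            link_labels[m] = mod
            b[i, j] = b[j, i] = 1.0
        templates.append(b)
    rng = np.random.default_rng(seed)
    n_mod = len(templates)
    # smoothed, unit-std modulation signals
    pad = smoothing_span
    white = rng.standard_normal((n_samples + 2 * pad, n_mod))
    kernel = np.ones(smoothing_span) / smoothing_span
    smooth = np.vstack([
        np.convolve(white[:, m], kernel, mode="same") for m in range(n_mod)
    ]).T[pad:pad + n_samples]
    smooth /= smooth.std(axis=0)
    mods = amplitude * smooth
    # clip the combined coefficient c = baseline + a_m so every eigenvalue
    # of I + c*B_m stays >= 0.05 (disjoint region groups keep the blocks
    # independent, so per-template bounds suffice for the default layout)
    for m, b in enumerate(templates):
        lam = np.linalg.eigvalsh(b)
        c_hi = 0.95 / (-lam[0]) if lam[0] < 0 else np.inf
        c_lo = -0.95 / lam[-1] if lam[-1] > 0 else -np.inf
        c = np.clip(baseline + mods[:, m], c_lo, c_hi)
        mods[:, m] = c - baseline
    sigma = np.broadcast_to(np.eye(n_regions),
                            (n_samples, n_regions, n_regions)).copy()
    for m, b in enumerate(templates):
        sigma += (baseline + mods[:, m])[:, None, None] * b
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        repaired = _floor_stack(sigma)
        delta = np.abs(repaired - sigma)
        scale = np.maximum(np.abs(sigma), 1e-12)
        if np.any(delta > 0.1 * scale):
            raise ValueError(
                "PSD repair changed a covariance entry by more than 10%; "
                "fixture invalid — lower the modulation amplitude"
            ) from None
        chol = np.linalg.cholesky(repaired)
    z = rng.standard_normal((n_samples, n_regions))
    values = np.einsum("tij,tj->ti", chol, z)
    return PlantedModules(TimeSeriesMatrix(values), link_labels, mods, templates)


def _floor_stack(sigma: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(sigma)
    vals = np.clip(vals, eps, None)
    return np.einsum("tij,tj,tkj->tik", vecs, vals, vecs)


def gen_fgn_increments(hurst: float, n_samples: int, seed: int = 0
                       ) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant spectral synthesis.

    Embeds the fGn autocovariance
    ``gamma(k) = (|k+1|^(2H) - 2|k|^(2H) + |k-1|^(2H)) / 2`` in a circulant
    matrix of order ``2K`` whose eigenvalues are obtained by FFT; a
    Hermitian Gaussian spectrum drawn under those eigenvalues transforms
    back to an exact unit-variance fGn sample.  Negative circulant
    eigenvalues (possible for small K at extreme H) abort with a
    suggestion to enlarge K.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"Hurst exponent must be in (0, 1), got {hurst}")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    k = np.arange(n_samples + 1, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst)
                   - 2 * np.abs(k) ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    # first row of the order-2K circulant embedding
    c = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8:
        raise ValueError(
            f"circulant embedding has negative eigenvalue {lam.min():.3e}; "
            "spectral synthesis infeasible — try a larger n_samples"
        )
    lam = np.clip(lam, 0.0, None)
    m = c.size  # 2K
    rng = np.random.default_rng(seed)
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[m // 2] = np.sqrt(lam[m // 2] / m) * rng.standard_normal()
    a = rng.standard_normal(m // 2 - 1)
    b = rng.standard_normal(m // 2 - 1)
    w[1:m // 2] = np.sqrt(lam[1:m // 2] / (2 * m)) * (a + 1j * b)
    w[m // 2 + 1:] = np.conj(w[m // 2 - 1:0:-1])
    x = np.fft.fft(w)
    return x[:n_samples].real
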