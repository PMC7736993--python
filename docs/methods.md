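# Methods

## The model

`dfckit` treats the temporal evolution of functional connectivity (FC) as a
random walk in the space of possible FC networks.  Given a real-valued
multivariate series `TS_i(t)` (`T` samples, `N` regions), the pipeline is:

1. **Static FC** — the full-session Pearson correlation matrix
   `FC_ij = Corr[TS_i, TS_j]`.  All entries are retained without
   thresholding or significance masking: FC entries are features for
   downstream description, not tested hypotheses.
2. **dFC stream** — windowed FC frames `FC_ij(t_k)` over half-open sample
   slices `[k·Δτ, k·Δτ + W)`; trailing trimmed windows are dropped, so the
   frame count is exactly `F = floor((T − W)/Δτ) + 1`.  Streams are stored
   in vector format (`L × F`, `L = N(N−1)/2`) under a fixed row-major
   upper-triangular link ordering; the dense `N × N × F` tensor is a view.
3. **Recurrence (dFC) matrix** — `dFC(t_a, t_b) = Corr` between the
   triangular parts of frames `a` and `b`.  Blocks of persistent
   similarity ("knots") and stripes of dissimilarity ("leaps") visualise
   the walk's intermittent stabilisation.
4. **dFC speed** — `V(a) = 1 − dFC(a, a + Δf)`; with `Δτ = W, Δf = 1` the
   non-overlapping single-window speed, with `Δτ = 1, Δf = W` the
   window-oversampled estimate.  Speeds lie in [0, 2].  The *typical
   speed* is the sample median by default (binning-free, robust at small
   samples); the mode of a 20-bin histogram over [0, 2] is available as an
   option.  Histogram bins carry Agresti–Coull binomial confidence
   intervals.  Window pooling concatenates speed lists across nearby
   window sizes without reweighting; it is a pragmatic smoothing device
   and should be cross-checked against single-window analyses.
5. **DFA** — the frame-to-frame increments of a maximally smooth stream
   (`Δτ = 1`) are mean-centred, integrated, split into `floor(K/k)`
   non-overlapping segments per scale `k`, linearly detrended per segment,
   and the RMS fluctuation `F(k)` is fit against `k` by OLS on the log-log
   plane.  The slope `α` distinguishes anti-persistent (< 0.5), memoryless
   (0.5), persistent (0.5–1) and non-stationary (≥ 1) walks.
6. **Meta-connectivity (MC)** — the `L × L` correlation matrix between
   link time-courses of a smooth stream; trimer meta-strengths
   `MC(i) = Σ MC_{ik,il}` localise *meta-hubs*; signed community detection
   on MC yields *dFC modules*, and any analysis (speeds, DFA,
   meta-strengths) can be restricted to a module's links.  Edge-centric FC
   (the correlation of instantaneous z-score products) is provided as the
   windowless analogue.
7. **Surrogates** — phase-randomized series (common random rotation per
   frequency across regions; preserves all spectra and the static
   covariance; null of FC stationarity) and time-shuffled streams
   (permuted frames; preserves every frame and per-link moments; null of
   no sequential correlation), with percentile chance bands over seeded
   ensembles.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `window_size` (W) | samples | user-set | FC estimation scale; short W gives noisy frames but more of them |
| `slide_step` (Δτ) | samples | W (speeds) / 1 (DFA, MC) | non-overlapping frames give independent speeds; step 1 gives the smooth stream DFA/MC need |
| `frame_offset` (Δf) | frames | `W/Δτ` rounded | compared frames never overlap in time |
| DFA scale grid | samples | 12 log-spaced ints, 8 → K/4 | log spacing equalises leverage in the log-log fit; K/4 keeps ≥ 4 segments |
| histogram bins | — | 20 over [0, 2] | deterministic, covers the admissible speed range |
| signed-modularity resolution | — | 1.0 | the common default of the configuration-null quality |
| surrogate ensemble size | — | 1000 | percentile bands at 5/95% stable to ~1% |

## Numerical choices

- Pearson correlations use the sample (n−1) normalisation throughout
  (irrelevant to correlation values, fixed for the z-scoring in eFC).
- Window slices are half-open, 0-based, in sample units.
- A region constant within a window, or a constant FC frame, raises an
  error naming the offender rather than emitting NaN — NaN frames would
  silently poison every downstream correlation.  Constancy is detected
  exactly (`max − min == 0`), not via a variance threshold.
- A link whose FC time-course is constant across frames gets a zeroed MC
  row/column and a warning: it is uninformative, not a failure.
- DFA mean-centres the increments before integration (standard
  Peng-style practice): the increments are nonnegative speeds, and the
  uncentred profile is dominated by its linear mean trend.
- DFA segments drop the tail remainder; no reverse-direction pass.
  Detrending is order-1 only.  Scales with fluctuation below 1e−12
  (exactly detrendable profiles up to round-off) are excluded with a
  warning; fewer than 3 usable scales is an error.
- A DFA fit with R² < 0.95 is flagged *non-scaling* and must not be
  interpreted as an exponent — a linear log-log relation is a
  precondition, not a given.  (A full Bayesian model comparison of
  scaling laws is out of scope; the R² flag is a deliberate, simple
  stand-in.)
- Phase randomization de-means before the FFT and re-adds means after;
  for even T the Nyquist bin is multiplied by a common random sign, which
  keeps the inverse transform real while remaining a valid common
  rotation.  One angle is drawn per positive frequency bin, shared by all
  regions — this is what preserves the cross-spectra and hence the static
  covariance exactly.
- The redundant `M × M` MC view (`M = N(N−1)`) is a fancy-indexed copy of
  the compact matrix, refused above a configurable memory cap (default
  4 GB): its footprint grows with the fourth power of N.
- Trimer sums run over unordered pairs of distinct links incident on the
  root, each pair counted once, diagonal excluded; on an all-ones MC this
  gives `(N−1)(N−2)/2`.  (The redundant-view equivalent is the ordered
  sum divided by two.)
- Oversampled speeds are flagged non-independent in metadata; no
  effective-sample-size correction is applied, and none is applied for
  the autocorrelation that overlapping windows induce in MC link
  time-courses.

## Signed community detection

MC weights are signed, so dFC modules are extracted by optimising a signed
modularity: the Leiden algorithm on a two-layer multiplex (positive
weights in one layer, absolute negative weights in the other entering
with layer weight −1), RB-configuration quality, resolution 1, seeded and
deterministic.  The quality reported with a partition is the Gómez-style
signed modularity `Q = v⁺/(v⁺+v⁻)·Q⁺ − v⁻/(v⁺+v⁻)·Q⁻`, computed
independently of the optimiser.  An MC with no off-diagonal weight yields
a flagged, uninformative singleton partition.

## What the synthetic generators emulate — and what they do not

- `gen_stationary_gaussian`: i.i.d.-in-time Gaussian draws with a
  prescribed covariance — the exact null of FC stationarity.
- `gen_switching_covariance`: piecewise-stationary regimes with fixed
  dwell times — produces the knot/leap block structure of the recurrence
  matrix with ground-truth regime labels.
- `gen_planted_mc_modules`: a time-varying covariance
  `Σ(t) = I + Σ_m (baseline + a_m(t))·B_m` with clique link-group
  templates over disjoint region halves, static baseline coupling 0.3,
  and independent moving-average-smoothed modulations (span 100 samples,
  std 0.25, clipped so every eigenvalue of Σ(t) stays ≥ 0.05 — positive
  definite by construction at the shipped defaults, no flooring).  The
  defaults were chosen once so that, at T = 4000, W = 20, Δτ = 1, the
  planted within-group MC contrast exceeds 0.2, signed-partition recovery
  is essentially exact, and MC matrices from independent seeds correlate
  above 0.8 (the group-averageability property).  Note that with a
  nonzero static baseline, finite-window FC estimates of links sharing a
  region co-fluctuate slightly even without any planted modulation
  (sampling covariance), so the "no planted structure" control is the
  `amplitude = 0, baseline = 0` case.
- `gen_fgn_increments`: exact fractional Gaussian noise by Davies–Harte
  circulant spectral synthesis, validated against the closed-form lag-1
  autocovariance `2^{2H−1} − 1` and by DFA exponent recovery.

None of the generators model haemodynamics, scanner drift, motion
artefacts, or heavy-tailed physiological noise.  Passing tests therefore
demonstrate algorithmic correctness and statistical calibration under the
stated Gaussian conditions, not robustness to real fMRI confounds; on
real data the usual preprocessing decisions (filtering, global
regression) remain the user's responsibility and are deliberately outside
this package.

## Problem sizes used in the shipped checks

The test-suite and the reproduction script use desk-scale problems chosen
as the smallest sizes at which the statistical contracts are comfortably
away from their thresholds: DFA calibration at K = 4096 with 20
replicates; planted-module recovery at N = 10, T = 4000; regime contrast
at T = 2000, dwell 200, W = 50; phase-randomized chance bands with 100–200
instances (the library default remains 1000).

## Known limitations

- dFC speeds and DFA exponents depend on W by construction; the package
  reports per-window results and leaves window pooling of exponents to
  the user.
- Similarity is Pearson correlation only; alternative frame-similarity
  metrics (e.g. Jaccard on binarised networks) are not implemented.
- Surrogate machinery covers stream/speed features; no surrogate test for
  MC matrices is provided.
- `expand_mc` exists for graph-theoretic interoperability; every shipped
  analysis operates on the compact form.
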