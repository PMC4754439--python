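# Methods

`hrvchaos` quantifies the complexity of instantaneous heart-rate (BPM) time
series with two independent nonlinear estimators and compares recording
states (rest vs. meditation) subject by subject.  This note documents the
models, the parameter choices, the synthetic ground-truth generators, and the
numerical decisions.

## The signal model and its assumptions

Instantaneous heart rate is sampled once per detected beat, so it is unevenly
spaced in time.  Both estimators here deliberately treat the recording as an
ordered sample sequence `x(1..N)` and ignore the time stamps (carried as
metadata only).  This is the convention of the analyses the package
implements; users needing evenly-resampled HRV measures should resample
upstream.  No stationarity is assumed — both methods are designed for
non-stationary signals.

## MF-DFA (multifractal detrended fluctuation analysis)

Pipeline: profile `Y(i) = Σ_{k≤i}(x(k) − x̄)` → split into `N_s = ⌊N/s⌋`
non-overlapping forward bins of length `s` → per-bin mean squared residual
`F²(s,v)` around an order-`m` least-squares polynomial → q-th order
fluctuation function

    F_q(s) = { (1/N_s) Σ_v [F²(s,v)]^{q/2} }^{1/q},

with the logarithmic-average limit `F_0(s) = exp{ (1/2N_s) Σ_v ln F²(s,v) }`
for `|q| < 1e-6` → generalized Hurst exponent `h(q)` as the OLS slope of
`log₂F_q(s)` vs `log₂s` → `τ(q) = q·h(q) − 1` → Legendre transform
`α = h + q·h′`, `f(α) = q(α − h) + 1` → **spectrum width Δα = max α − min α**,
the headline multifractality measure (≈0 for monofractals).

Defaults and why:

- **q grid**: 100 equidistant values on [−5, 5], endpoints inclusive.  |q|>5
  moments are dominated by a handful of extreme bins at these lengths.  The
  even count means q=0 is not on the default grid; the q→0 branch is
  implemented and tested regardless.
- **scale grid**: 16 integer scales log-spaced on [16, 256], deduplicated
  after rounding.  s < 16 leaves too few points per bin for a stable linear
  fit; s > N/4 leaves too few bins per scale.
- **detrending order m = 1** (linear).  Configurable; order-2 detrending
  costs degrees of freedom in 16-point bins.
- **binning**: forward-only, discarding the tail remainder, matching the
  definition above.  The bidirectional variant (bins counted from both ends,
  2·N_s bins) is available behind `bidirectional_bins=True`, default off.
- **h′(q)**: central finite differences on the q grid, one-sided at the
  endpoints.
- **width over the finite q grid**, not extrapolated to q→±∞: the width is a
  property of the spectrum actually computed.
- **degenerate bins**: a zero detrending residual with q < 0 raises an error
  naming the scale and a remediation (reduce m, drop the scale) rather than
  silently producing infinities.
- **reliability floor**: below N ≈ 1024 there are too few bins at the larger
  scales; `run_mfdfa` warns, and the comparison pipeline suppresses MF-DFA
  entirely (the width columns are reported absent) unless told otherwise.

## Visibility graph and the PSVG exponent

Each sample is a node; samples m < n are linked iff the chord between
`(m, X_m)` and `(n, X_n)` passes **strictly** above every intermediate
sample.  Collinear intermediates therefore block visibility — ties break
toward fewer edges.  Construction is an O(n²) sweep maintaining, per anchor,
the running maximum of slopes to intermediate samples (a sample is visible
iff its slope strictly exceeds that maximum); an O(n³) literal evaluation of
the criterion is kept in the test suite as an independent oracle.  The
criterion depends only on value differences, so the graph is invariant under
adding any constant; the conventional shift-to-positive preprocessing is
applied anyway and tested to be a no-op on the graph.

For fractal series the degree distribution follows `P(k) ∝ k^{−λ_p}`.  The
PSVG exponent λ_p is the OLS gradient of `log₂P(k)` vs `log₂(1/k)` —
positive for decaying distributions — reported with standard error and R².
λ_p decreases linearly with the Hurst exponent (λ ≈ 3 − 2H for fBm), and the
estimator stays usable down to a few hundred samples, which is what makes it
the method of choice for short recordings.

**Fit range.** By default the fit uses all observed degrees, and the range
actually used is recorded in `PsvgFit.fit_range`.  The exponent is sensitive
to this window: the asymptotic power law governs the distribution's tail,
and the small-k head (saturated by the always-present chain edges) biases a
full-range fit downward.  Validation against the λ = 3 − 2H law therefore
uses a tail fit (`k_min = 5`); analyses of BPM data use the full range
unless the caller restricts it.

## Comparison pipeline

Per subject: λ_p and Δα in both states; percent increase
`100·(med − pre)/pre` per quantity; shuffled-surrogate widths as a baseline
(single seeded permutation per state by default, `n_shuffles` averages more).
Per cohort: per-group min/max percent increases, state means of λ_p, and
Pearson correlations between the two methods' values over subjects with
MF-DFA present — pooled over both states, meditation-only, pre-only.
Correlations operate on the same summary values the table reports.  Percent
values are conventionally printed at 1 decimal place; full precision is kept
internally.  The package ships the published per-subject summary values of
the PhysioNet meditation cohort (`hrvchaos.reference`) so that all cohort
arithmetic is recomputable without downloading recordings.

## Synthetic generators (ground truth)

- **fGn / fBm** — circulant embedding of the exact autocovariance
  `γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})`: the output is Gaussian
  with exactly this covariance (not a spectral approximation), which is what
  makes 3-standard-error oracle tests meaningful.  A non-positive embedding
  (numerically impossible for H ∈ (0,1) at these sizes, but checked) raises
  with instructions to increase n.
- **Binomial cascade** — deterministic length-2^L series
  `x_k = a^{b} (1−a)^{L−b}` with `b` the bit count of `k−1`; closed-form
  `h(q) = 1/q − ln(a^q + (1−a)^q)/(q ln 2)` (`cascade_hurst`).  **Numerical
  caveat**: the cascade's multifractality lives on dyadic cells, so
  validation against the closed form uses dyadic scales {16, 32, 64, 128,
  256}.  Non-dyadic scales make bins straddle cell boundaries and bias the
  positive-q moments low (measured ≈ −0.12 at q = 5, L = 13); this is a
  property of the oracle series, not of data analysis, so the default scale
  grid is unchanged.
- **BPM-like** — baseline + slow sinusoid + `noise_scale`·fGn, a visual
  stand-in for heart-rate recordings (defaults span ≈55–105 BPM), *not* a
  physiological model: no respiratory sinus arrhythmia, no 1/f spectral
  shoulder, no beat-to-beat quantisation.  Tests passing on it demonstrate
  estimator correctness, not physiological validity.
- **Shuffle surrogate** — seeded uniform permutation; preserves the value
  multiset exactly, destroys all temporal correlation.

## What shuffling does and does not show

Shuffling removes *correlation-driven* multifractality but preserves the
*distribution-driven* part.  For a genuinely multifractal series (the
cascade) the surrogate width drops well below the original in essentially
every permutation.  For monofractal fGn the width is finite-size noise on
both sides of the shuffle, and no systematic width drop exists; the shuffle
signature there is the collapse of h(2) from H to ≈0.5.  The test suite
asserts each effect where it actually holds.

## Problem sizes used in the test and acceptance runs

Synthetic validation uses n = 2^13 for MF-DFA oracles (10 seeds per
condition), n = 4096 for visibility-graph λ–H recovery, L = 13 cascades, and
10 permutations for surrogate checks — sizes at which the estimator
tolerances quoted in the tests (±0.1 on h(2), ±0.3 on λ_p, ±0.05 on cascade
h(q)) hold with margin while keeping the whole suite under a minute of
compute.

## Known limitations

- Unevenly sampled BPM series are analysed in beat order; results are not
  directly comparable to time-resampled HRV analyses.
- λ_p depends on the degree fit window; comparisons are meaningful only at a
  fixed window choice (recorded in every `PsvgFit`).
- MF-DFA widths for N < 1024 are unstable; the pipeline refuses them by
  default rather than reporting noise.
- The reader accepts single-column and two-column text only; native
  PhysioNet WFDB binary formats must be converted (e.g. with `rdsamp`)
  upstream.
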