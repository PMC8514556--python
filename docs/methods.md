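# Methods

## Scoring model

Both scoring methods operate on delay-coordinate reconstructions. A scalar
channel `x` of length `L` is standardized (z-scored, toggleable) and unfolded
into `n = L − (D−1)τ` delay vectors `[x(t), x(t+τ), …, x(t+(D−1)τ)]`. The
embedding dimension `D` and delay `τ` are shared across all pairs of a run so
that scores stay commensurable; when not supplied, `τ` is the first local
minimum of the lagged mutual information (3-point smoothed histogram
estimator; fallback: first zero-crossing of the autocorrelation) and `D` the
smallest dimension whose Kennel false-nearest-neighbor fraction drops below
0.05 (capped with a warning — the criterion never stabilizes for stochastic
signals). Defaults for the simulated systems: logistic maps (2, 1), Van der
Pol oscillators (3, 3), AR processes (3, 1).

### Convergent cross sorting

For every unordered time-point pair `(i, j)` with `|i − j|` greater than a
Theiler-style exclusion window (default `D·τ`; prevents trivially close
temporal neighbors from monopolizing the low ranks), the Euclidean distances
in both reconstructions are ranked (ascending, average ranks on ties). The
signed rank error is `ERR = R_X − R_Y` for every pair. Direction convention:
`score(x→y)` quantifies the influence of x on y and conditions the error
sequence on `R_Y` — the ranks in the manifold of the *driven* variable,
which is the reconstruction that contains the driver.

Each squared error is normalized against its expectation under uncorrelated
ranks. Two nulls are provided:

- **conditional (default)**: `E[(R_X − r)² | R_Y = r] = (n²−1)/12 + ((n+1)/2 − r)²`.
  Conditioning on the rank makes the expectation rank-dependent; with this
  null, uncorrelated ranks give `NERR² = (null − ERR²)/null ≈ 0` at *every*
  conditioning rank, so independent series score 0. This is required for the
  score to be calibrated: with the marginal null below, the expectation at
  extreme conditioning ranks is roughly twice the marginal value and
  independent series would score −1 rather than 0.
- **marginal**: `E[(R_X − R_Y)²] = (n²−1)/6`, the unconditional expectation
  (verified exactly by enumeration for n ≤ 6 in the test suite).

The cumulative average of `NERR²` over the `k` lowest conditioning ranks is
evaluated on a rank grid normalized to (0, 1], truncated at
`max_rank_frac = 0.25` (considering only the best-covered quarter of the
manifold; smaller fractions are noisier on short series, larger ones dilute
the local correspondence), and fit by least squares with `a·exp(−b·r) + c`,
`b ≥ 0` — the minimal exponential family with a free asymptote. The score is
the intercept `a + c`, clipped to [−1, 1] so both methods share a scale. A
numerically constant curve short-circuits to its value; a non-convergent fit
falls back to the intercept of a linear fit on the lowest decile and is
flagged `fit_ok = False`. Beyond 2×10⁶ pairs, pairs are uniformly subsampled
with a seeded generator (an approximation never reached at the lengths used
here).

Significance uses circular-shift surrogates of one series with the plus-one
estimator `p = (1 + #{surrogate ≥ observed})/(1 + n_surrogates)`. The
minimum shift is `max(exclusion + 1, L/10)`: for deterministic signals a
copy shifted by only a few steps is still genuinely coupled to the original
(rank correspondence decays at the trajectory-divergence rate), so very
small shifts are not null.

### Cross-mapping baseline

The baseline scores a direction by cross-mapping: `score(x→y)` embeds the
driven variable `y`, finds the `D+1` nearest neighbors of each delay vector
(excluding neighbors within the same exclusion window), forms the estimate
`x̂_t = Σ w_i x_{t_i}` with `w_i ∝ exp(−d_i/d_1)` (weight collapsing onto
exact matches when `d_1 = 0`), and reports the Pearson correlation of
estimates with truth, clipped to [−1, 1]. Zero-variance estimates score 0
with a warning. All preprocessing matches the rank-sorting scorer so
comparisons differ only in the correspondence statistic.

## Simulated systems

- **Logistic maps** (deterministic, discrete, chaotic):
  `x_i(t+1) = x_i(t)[r_i − r_i x_i(t) − Σ_j K_{j→i} x_j(t)]`, `r_i ~ U(3.6, 3.9)`
  per trial, initial conditions `U(0.2, 0.8)`, burn-in 500 steps. Coupling or
  noise can push the state out of (0, 1); it is clipped back each step (at
  moderate K the per-trajectory escape probability approaches 1, so
  resampling is not viable).
- **Van der Pol oscillators** (deterministic, continuous, ~periodic):
  `x¨_i = μ_i(1−x_i²)x˙_i − x_i + Σ_j K_{j→i}(x_j − x_i)` (diffusive
  coupling; direct forcing available), `μ_i ~ U(0.8, 2.5)`, fixed-step RK4 at
  `dt = 0.05`, sampled every 10 steps, burn-in 50 nominal periods. Dynamical
  noise enters the velocity each step scaled by `√dt`, making its magnitude
  step-size independent.
- **AR processes** (linear, stochastic):
  `x_i(t) = Σ_p a_{i,p} x_i(t−p) + Σ_j K_{j→i} x_j(t−1) + ε·ξ`, default AR(1)
  with `a_i ~ U(0.3, 0.9)`; the innovations are the dynamical stochasticity
  (sd ε, defaulting to 1 since a noiseless AR process decays to zero). The
  joint companion matrix must have spectral radius < 1.

Measurement noise is zero-mean Gaussian added to the finished series with
RMS = RMS(signal)/10^(SNR_dB/20); SNR = ∞ leaves the series untouched and
0 dB means equal RMS ("magnitude" is interpreted as RMS throughout).
Dynamical and measurement noise are orthogonal controls: ε = 0 with infinite
SNR reproduces the deterministic trajectory bit-for-bit under the same seed.

Detection trials use the three-variable topologies free of transitive causal
paths (common driver, common sink, bidirectional pair with an isolated
third), both edges sharing one coupling strength; transitive layouts are
refused because they make pairwise ground truth ambiguous. Bidirectional
two-variable networks vary `K_{x→y}` and `K_{y→x}` independently.

## Evaluation harness

Detection pools the six directed scores of every trial into one ROC
(coupled vs non-coupled directed pairs) and computes the AUC by the
Mann–Whitney rank formulation (tested equal to trapezoidal integration);
95% CIs come from a stratified percentile bootstrap (1000 resamples).
Relative strength is the Spearman correlation between
`score(x→y) − score(y→x)` and `K_{x→y} − K_{y→x}` over a bidirectional
grid. Unidirectional sweeps hold `K_{x→y} = 0`, compare the two directions'
score distributions per `K_{y→x}` with Welch t-tests, and control the sweep
with Benjamini–Hochberg.

**Study conditions.** The benchmark conditions are: detection coupling
K = 0.075 per trial, default length L = 200 (L = 50 for the short-series
point), dynamical-noise sweep ε ∈ {0, 0.005, 0.01, 0.02} for the maps. The
weak-coupling regime is where detection is genuinely hard on short series
and the methods separate; the sweep tops out near 8% of the signal RMS,
where detection has degraded substantially but remains above chance. The
acceptance experiments use 200 trials per condition; statistical suite
checks that need many replicates run at 12–200 replicates each so the whole
suite completes on a single CPU in minutes.

## Network-state analysis

Three-channel recordings are cut into epochs; each window (3 per epoch by
default, tiling it) is summarized by the 6-vector of directed CCS scores.
Vectors are standardized, whitened by full-dimensional PCA, and quantized by
seeded k-means (k = 5 default, 10 restarts); the first two principal
components serve display only — clustering runs in the full whitened space —
and centroids are back-transformed to raw score units (the round trip is
tested to numerical tolerance). Each epoch becomes a state sequence,
canonicalized to its lexicographically smallest cyclic rotation because the
phase of an epoch cut from a longer event is uninformative. Frequency tables
carry the binomial standard error of the percentage. The extremeness of the
n-th most frequent pattern is −log₁₀ of the probability that the *n-th
largest* count under a uniform-over-canonical-classes null reaches the
observed count, estimated by seeded Monte Carlo over multinomial draws
(2000 by default); a plain per-class binomial tail is available behind a
flag but overstates extremeness because the most frequent pattern is
selected after the fact. The number of canonical classes is the necklace
count `(1/w)Σ_{d|w} φ(d)k^{w/d}` (45 for 5 states, length 3).

The synthetic stand-in for multichannel field-potential recordings is a
triad of coupled maps/oscillators with scripted regime switches; it
reproduces switching directed coupling but none of the spectral content,
nonstationarity, or volume conduction of real recordings, so passing tests
demonstrate correct recovery of scripted coupling structure, not performance
on real neural data.

## Known limitations

- The baseline cross-mapping implementation is noise-robust at moderate
  lengths: dynamical noise originating in a driver propagates through the
  coupling and is itself cross-predictable, so the baseline's detection
  accuracy under map dynamical noise matches or exceeds the rank-sorting
  method in this package's conditions. Orderings reported elsewhere may
  depend on simulation settings that are not part of this package's declared
  defaults.
- Scores saturate near 1 for strongly coupled noise-free maps, compressing
  resolution at high K (small noise restores it).
- No lagged cross-map variants, non-uniform embeddings, or multivariate
  embeddings; one (D, τ) per run is shared across channels by design.
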