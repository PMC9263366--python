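# Methods

This note documents the models and estimators implemented in `nlts`, the
conventions and numerical choices behind them, what the built-in synthetic
benchmarks do and do not establish, and the known limitations.

## Conventions shared by all estimators

**Embedding.**  A scalar series is embedded by delays,
`states[k, j] = x[k + j·τ]`, so a state's row index refers to its *last*
coordinate and a prediction at horizon Δt reads the sample Δt steps after
that coordinate.  Indexing is 0-based.

**Distances.**  The maximum norm is the default everywhere (Euclidean is
selectable); distances are reported in data units.  Under the maximum norm
the diameter of a state set equals its widest per-coordinate range, which
makes attractor diameters and recurrence-segment diameters O(n) exact.

**Theiler exclusion.**  Neighbor statistics exclude pairs with temporal
separation ≤ w.  The package default for w is 0; the analyses that need it
(correlation sums, Lyapunov curves on flows) take it explicitly.  Twice the
autocorrelation time (first zero crossing of the ACF, or N/10 if none
within N/2 lags) is the conventional choice; the space–time separation plot
suggests w as the first Δt where the median inter-state distance plateaus
(slope over a 5-sample window below 1% of the attractor diameter per
sample — an explicit rule standing in for the usual visual judgement).

**Exactness.**  Neighbor search, correlation sums, recurrence-time
extraction and RQA line counts are exact (no approximate indexing); each is
verified in the tests against an independent hand-written O(n²) loop.

## Embedding-parameter selection

*Deterministic route.*  The delay τ is the first minimum of the auto-mutual
information; because binned AMI curves of noise-free periodic signals carry
single-lag dips from the discretization, a lag only counts as the first
minimum if no smaller value occurs within the following 5 lags.  If the FNN
criterion fails at the AMI delay, the autocorrelation time is tried as a
fallback delay.  The dimension is chosen by the Kennel false-nearest-
neighbor criterion: the nearest neighbor of each state (maximum norm) is
false if adding the next delay coordinate increases the pair distance by
more than Rtol (default 10) times its d-dimensional value, or beyond
Atol (default 2) × SD of the series.  "Drops to zero" is operationalized as
a fraction below 1% (configurable).  Neighbor pairs closer than 1e-10·SD
are treated as exact recurrences, not false neighbors — otherwise floating-
point noise between identical states of a periodic signal produces
arbitrary distance ratios.

*Stochastic route.*  The Ragwitz criterion scores every (d, τ) cell with
the RMS error of a local-constant predictor (mean of the one-step futures
of the k nearest neighbors, default k = 10) and returns the argmin, ties
broken toward smaller d then smaller τ.  Default grid: d = 2–9,
τ spanning 10–100% of the autocorrelation time.

## Correlation dimension

C(ε) is computed over 30 log-spaced ε between 1% and 100% of the attractor
diameter (chunked exact pair counting, float32 distances).  D₂ is the
least-squares slope of log C vs log ε; when no fit range is given, the
longest contiguous interval whose point-to-point slopes stay within 15% of
their window mean is used (at least 3 points with C > 0).  A plateau value
across embedding dimensions 3–9 is reported as the median of the per-
dimension slopes; its stability across dimensions (spread below ~10%) is
the determinism check.

## Largest Lyapunov exponent

δ(Δt) follows Kantz (log of the *mean* distance between the reference's
future and all ε-neighbors' futures, averaged over references) or
Rosenstein (single nearest neighbor).  The exponent is the slope of δ(Δt),
per sample, and additionally per second when the sampling rate is known.
The library default fit range is iterations 1–10, appropriate for maps
(the fully chaotic logistic map recovers λ = ln 2 within a few percent
fitting iterations 0–4 at ε = 1% of the diameter).

For flows the divergence curve has an initial *alignment transient*: the
random offset between neighbors takes about one orbital period to rotate
into the most expanding direction, and during that phase the apparent slope
is roughly double the true exponent.  The Lorenz benchmark (40 Hz sampling,
orbital period ≈ 24 samples) is therefore analyzed with a small
neighborhood (0.5% of the attractor diameter, so the curve has room before
saturating at the attractor scale) and a fit over Δt = 24–120 samples, past
the transient and before saturation.  This yields λ ≈ 0.85–0.94 s⁻¹ across
seeds against the reference 0.906 s⁻¹; both algorithms agree within 10%.

## Unstable periodic orbits (period one, map data)

The series is read as successor pairs (x_n, x_{n+1}).  Each point's local
slope s_n comes from a least-squares line through its k = 10 nearest pairs;
the point maps to the tangent-diagonal intersection
x* = (x_{n+1} − s̃_n x_n)/(1 − s̃_n) with a randomized slope
s̃_n = s_n + u_n (x_{n+1} − x_n)/SD(x), u_n ~ U[−κ, κ], κ = 0.1·SD(x),
drawn fresh per repetition.  The perturbation is proportional to the local
displacement, so it vanishes exactly at fixed points: over many repetitions
fixed points accumulate density on the phase-space diagonal while unrelated
points disperse.  The histogram uses 400 bins over the data range
(resolution ~0.002 in map units for the logistic map — coarse histograms
visibly bias the mode), is normalized to integrate to 1, and its mode is
the fixed-point estimate.  Significance is assessed by comparing the
observed peak density with the peak-density distribution over surrogate
series (default amplitude-adjusted), as a Z score.  For the logistic map at
a = 3.92 (100 iterates, 500 repetitions) the mode lands at 0.745–0.755
against the analytic fixed point 1 − 1/a = 0.7449.

## Recurrence analysis

A state recurs when the trajectory re-enters its ε-neighborhood.  The
recurrence time T of one recurrence is the run of consecutive
non-recurrent samples between leaving and re-entering — identical to the
number of adjacent vertical zeros between recurrence blocks in the
recurrence matrix, which is the tested equivalence.  Extraction streams
over reference columns in chunks and never materializes the n×n matrix;
for SREPS the chunk distances are computed once and reused across the
entire ε grid, making the grid scan O(n²) total in distances.

- **Rate mode.**  Instead of a fixed ε, each point receives the distance to
  its ⌈rate·(admissible partners)⌉-th neighbor, so the realized fill rate
  matches the target (default 5%).
- **RPDE** is the entropy of P(T) normalized by log(number of admissible
  T values), in [0, 1].
- **Generalized autocorrelation** is the diagonal-wise mean of the matrix.
- **Recurrence amplitude.**  Each recurrence's trajectory segment (between
  its bounding recurrent states, inclusive) has a maximum phase-space
  diameter; a(T) averages these per period and is reported as
  half-diameter, so a sinusoid of amplitude a reads a(T) ≈ a at its period
  (raw diameters are exposed alongside).  The weighted spectrum a(T)·P(T)
  suppresses rare large excursions.
- **SREPS** evaluates P(T, ε) over ε = 1–100% of the SD of the analyzed
  series (step 1).  Reading a spectrum: at small ε recurrences are sparse
  and quasi-uniform (noise regime), at large ε the mass shifts to small T,
  and the band's crossing with the noise regime is the best period
  estimate.  `dominant_period` operationalizes the crossing as the first ε
  column with a meaningful recurrence count (≥ 50 and ≥ 1% of the
  best-filled column) and a peak ≥ 5× the uniform level; within that column
  the fundamental is the smallest-T local peak reaching 30% of the column
  maximum, so combs of multi-cycle returns resolve to their base period.
- **TRAS** computes P(T, window) in windows (default one tenth of the data,
  50% overlap) at fixed ε (% of the whole-series SD).  Because recurrence
  ignores waveform shape, sawtooth and square oscillations produce the same
  single fundamental band as a sinusoid — no harmonics, unlike a
  short-time Fourier transform.

## Information-theoretic estimators

All values are in bits.  Binned estimators use equal-width bins with the
Freedman–Diaconis rule (width 2·IQR·n^{−1/3}) as the automatic choice and a
+log₂(bin width) correction when a differential entropy is wanted.  The
nearest-neighbor estimators are Kozachenko–Leonenko for differential
entropy and Kraskov–Stögbauer–Grassberger algorithm 1 (maximum norm,
strictly-inside marginal counts) for mutual information; exact duplicate
points are broken by a deterministic 1e-10-scale jitter.  Active
information storage is the mutual information between the delay-embedded
past state and the next sample.  Every estimator returns local (per-sample)
values whose mean equals the global estimate by construction — the identity
is asserted in tests at 1e-10 relative.  Against Gaussian closed forms
(n = 10⁴): binned entropy errs by ~7·10⁻³ bits, KL by ~2·10⁻², KSG mutual
information at ρ = 0.9 by ~5·10⁻⁴.  Known estimator drifts — binned MI
rising with bin count, KSG falling for very large mass — are trend-checked,
not corrected.

## Surrogates and statistics

Shuffle surrogates permute values (multiset conserved exactly); block
shuffle permutes blocks of one autocorrelation time by default; phase
randomization rotates the phases of the positive-frequency Fourier bins
(DC and Nyquist untouched), conserving the amplitude spectrum exactly; the
amplitude-adjusted variant iterates rank-remapping onto the original values
against spectrum replacement until the relative spectral discrepancy
changes by < 10⁻⁴ (max 100 iterations), ending on the rank step so the
value distribution is conserved exactly.  The surrogate Z test uses
Z = (observed − mean)/SD over the ensemble, two-sided normal p, and
rejects at |Z| > 1.96 for α = 5%.  Permutation p-values always carry the
+1 correction.  The cluster test thresholds a pointwise Welch t at the
97.5th percentile of its own permutation distribution and scores contiguous
suprathreshold runs by summed t against the permutation null of the maximum
|cluster mass|.

## Synthetic benchmarks: what they show and what they do not

The generators reproduce the canonical validation conditions: the Lorenz
system (a = 10, b = 28, c = 8/3; fixed-step RK4 at 10 substeps per output
sample — step-halving changes the trajectory by < 10⁻⁶ over 10 s; 10 s of
transient discarded; random initial condition uniform in [−10, 10]³),
the logistic map, correlated Gaussian pairs built from a Cholesky factor
(exact degenerate case at full covariance), and compound
sine/sawtooth/square oscillations with noise scaled to a fraction of the
clean signal's SD.  All generators are bit-reproducible under a fixed seed.

Benchmark sizes are chosen to keep the full validation under ~2 minutes on
one CPU: 250 s of Lorenz at 40 Hz for embedding/D₂/λ, the first 100 s for
the SREPS grid scan (the period estimate is unchanged by the longer
series), 100 logistic iterates with 500 transform repetitions for the UPO,
n = 10⁴ for the Gaussian suite and DFA (with DFA scales capped at n/10,
where enough windows exist per scale for a stable fit).

These are clean, stationary, low-dimensional systems.  Passing them shows
the estimators are correctly implemented and calibrated at realistic sample
sizes; it does not show that the same settings are adequate for real
recordings, which add measurement noise, nonstationarity, high-dimensional
background activity and filtering artifacts.  For real data the
preprocessing chain (window → detrend → zero-phase Butterworth →
z-score; normalization deliberately last so that ε in % SD refers to the
analyzed signal) and the surrogate tests are the guardrails.

One benchmark is knowingly not reproducible and kept honest: the
time-reversal test on the Lorenz X component.  The Lorenz equations are
invariant under (X, Y) → (−X, −Y) and the attractor samples both wings
symmetrically, so ⟨(x_t − x_{t−Δt})³⟩ has expectation zero; across seeds
the observed Q is an order of magnitude smaller than the surrogate spread
and |Z| stays far below 1.96.  The test statistic, surrogates and Z are
implemented exactly as specified and the computed Z is reported as-is; on
signals with genuine temporal asymmetry (sawtooths, the Lorenz Z
component) the test rejects decisively.

## Limitations

- Lyapunov estimation returns only the largest exponent; fit-range choice
  on flows matters and the automatic plateau helper is a heuristic.
- UPO detection covers period-one orbits of 1-D map data only.
- Rate-mode recurrence matrices are asymmetric by construction (per-point
  radii); RQA measures are computed on them as-is.
- The binned AIS for long histories multiplies bin counts per coordinate;
  histories beyond d ≈ 3 need few bins to stay populated.
- Cross-recurrence requires equal embedding dimensions; bivariate RQA
  summary statistics beyond the univariate set are not provided.
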