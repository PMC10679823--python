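# Methods

`phasebehav` implements an analysis chain for trial-epoched multi-area LFP
recordings that asks whether interareal rhythmic synchronization predicts
single-trial behavioral reaction times (RTs), together with a synthetic
session generator that makes every stage of the chain verifiable against
known ground truth.  This note documents the models, the estimators, the
generator, the numerical choices, and the limits of what the tests show.

## The analysis chain

**Preprocessing.**  Unipolar electrode signals are re-referenced by local
bipolar derivation: neighboring electrodes on the same lane of the grid are
subtracted (higher within-lane index minus lower — the sign convention is
arbitrary but fixed; magnitudes of PPC and GC are unaffected, phase relations
flip deterministically).  Any signal common to all electrodes, in particular
the shared recording reference, cancels exactly because the derivation is
linear.  Line noise at 50/100/150 Hz is removed per trial by projecting the
full trial onto the cosine/sine pair at each line frequency (exact for an
integer number of cycles, which the default 1400 ms trials guarantee).
Trials are kept only if (i) their variance is at most five times the mean
trial variance on every site, (ii) the target changed before the distractor,
(iii) the change came at least 800 ms after cue onset, and (iv) the trial was
correct.  The variance baseline is computed once per site over all trials
(single pass; no iterative re-screening).  By default a single bad site
rejects the trial (`variance_scope="any-site"`); the per-site alternative is
available because the underlying convention is ambiguous.  After rejection,
each trial is linearly detrended and each site z-scored using mean/SD over
all retained data of that site.

**Spectral estimation.**  Analysis windows are the last 200 ms before the
target change (power, PPC, GPR) or the last 400 ms (GC).  Every window is
multiplied by a periodic Hann taper of its own length, zero-padded to 1 s,
and Fourier transformed, which puts all spectra on an exact 1 Hz grid;
analyses use 1–95 Hz.  Aperiodic (1/f) removal for power-spectrum display is
a fixed-mode (knee-free) log-log linear fit with iterative exclusion of bins
more than 2.5 residual SDs above the fit (oscillatory peaks), subtracted in
log10-power units; the residual "flattened" spectrum may be negative.
Sliding band power uses 50 windows of 200 ms stepped by exactly 4 ms, the
first covering [-400, -200] ms (the 50th therefore ends at -4 ms; an exact
4 ms step is kept so that lags convert exactly).

**PPC and selection.**  Phase locking per site pair is the pairwise phase
consistency, the unbiased average cosine of all pairwise differences of
per-trial relative phases, computed via the algebraic identity
PPC = (|Σ_t e^{iθ_t}|² − N)/(N(N−1)).  Site pairs whose PPC above 100 Hz
(101–200 Hz grid from the same epochs) exceeds mean+5SD of the pooled >100 Hz
values of their area pair are excluded as artifact-contaminated.  Note that
the null PPC distribution has an exponential right tail, so this rule
excludes a nonzero percentage of clean pairs by construction.  Among the
remaining pairs, those whose 1–95 Hz PPC exceeds, at any frequency, mean+3SD
of all values pooled over inter-areal site pairs and frequencies
(condition-pooled trials) are selected.

**Clusters and alignment.**  Per area pair, PPC is averaged over its
selected site pairs (over its non-artifact pairs when none were selected, so
every area pair enters the pooled statistics).  Area pairs exceeding
mean+3SD of all pooled area-pair values at any frequency are retained, and
connected components of the retained pairs define the clusters, labeled by
the band of their strongest peak (search ranges: beta 10–30 Hz, gamma
40–95 Hz).  Each cluster's peak frequency is the argmax of its average PPC
within the band (ties break to the lower frequency), and downstream spectra
are re-indexed to peak-relative frequency over ±15 Hz (beta) or ±20 Hz
(gamma).

**GPR.**  Per site pair and trial, the phase relation is the angle of
coeff_a·conj(coeff_b) at the aligned frequency; the series is rotated so its
circular mean is zero, and the goodness of phase relation is the cosine of
the rotated deviation: +1 at the typical phase relation, −1 opposite.  At
the area-pair, cluster, and population levels the rotated deviations are
first averaged over member site pairs per trial (arithmetic mean of the
wrapped angles — the deviations concentrate near zero where this coincides
with the circular mean, which is available by flag) and the cosine of the
average is the pooled GPR.  The population level averages both clusters at
their own aligned frequencies over the common ±15 Hz peak-relative axis.
Pooling suppresses estimation noise without the inflation that trial binning
would cause, which is why the GPR-RT correlation strengthens monotonically
with the pooling level when a shared trial-wise deviation exists.
Correlations with RT are Pearson (Spearman available), computed within
condition, with the rotation also performed within condition.

**Granger causality.**  Per site pair, the trial-averaged cross-spectral
density on the full 0–500 Hz grid is factorized by Wilson's iterative
minimum-phase spectral matrix factorization (S = ψψ*, H = ψψ(0)⁻¹,
Σ = ψ(0)ψ(0)*), and the Geweke frequency-domain measure gives both directed
influences; with correlated innovations the transfer function is transformed
(H̃_ab = H_ab + (Σ_ab/Σ_aa)H_aa) before the ratio, the standard form that
reduces to the naive one for diagonal Σ.  GC is computed bivariately per
site pair, not conditionally.  Inter-cluster site pairs get their own
mean+3SD PPC selection pooled over inter-cluster values only; the top pairs
by beta-peak PPC (default 3) enter the GC stage, ordered so that direction
index 0 is top-down along the configured hierarchy.

**Jackknife GC-RT correlation.**  GC is not defined per trial, so its
single-trial correlation with RT uses leave-one-out replications: GC is
recomputed on every subsample (an affine update of the averaged CSD followed
by a batched factorization) and correlated with the leave-one-out mean RT.
For any statistic that is a per-trial scalar averaged over trials this is
exactly the ordinary Pearson correlation, which the tests verify to 1e-10.

**Lagged power-power correlation.**  Cluster-averaged beta-band
(14–16 Hz) power time courses are log-transformed (variance stabilization;
raw option retained) and correlated across pooled (trial, window) points for
every window lag; the peak lag estimates the lead of one cluster over the
other.  Trial-shuffled surrogates with max-based correction across lags give
significance thresholds.

**Inference.**  Family-wise error across frequencies (or lags) is
controlled by the max-statistic approach: each of n_rand randomizations
(default 1000) contributes the minimum and maximum of the recomputed
statistic; the 2.5th percentile of the min distribution and the 97.5th of
the max distribution (nearest-rank percentiles) bound a two-sided 5% test.
Relabeling schemes: RT shuffling for GPR-RT/GC-RT spectra, condition
permutation for IN−OUT contrasts, trial shuffling for power surrogates.
Condition contrasts report the z score of the observed difference against
the permutation null and, optionally, the exact empirical
permutation p-value (1+exceedances)/(n_rand+1), which is valid by
construction; the empirical form is used when calibration matters.
Per-frequency condition contrasts across site pairs use Wilcoxon rank-sum
tests with Bonferroni correction over frequencies.  Multi-subject results
are averaged within subject over its units first and then across subjects
with equal weight.

## The synthetic session generator

The generator produces the statistical structure the chain is designed to
detect; it makes no biophysical claims.  Default configuration: 9 areas
(4 occipital, 5 fronto-central; the order encodes the hierarchy), 4
electrodes per area on one lane, 300 trials per attention condition, 1 kHz,
1400 ms trials with the cue at 100 ms and the change uniform in 900–1300 ms.

Per channel and trial the unipolar signal sums:

- a cluster oscillation — occipital gamma (70 Hz) or fronto-central beta
  (16 Hz, shifted +1 Hz in attend-IN) — with a per-trial uniform common
  phase, a fixed channel offset (area-specific base plus a π/2 step per
  electrode along the lane, so bipolar differences retain the oscillation),
  per-channel von Mises jitter (κ = 8 attend-IN, 4 attend-OUT), and a shared
  per-trial deviation s_t ~ von Mises(0, κ = 4) entering with a per-area
  weight graded from 1 to 0 along each cluster's hierarchy — so every
  inter-areal pair carries part of the deviation, nearby areas less,
  distant areas more;
- a fronto-central beta source with a slow multiplicative log-normal
  envelope (log-SD 0.4, 30 ms Gaussian smoothing) scaled by a per-trial
  coupling gain g_t (log-normal, log-SD 0.5);
- three occipital beta components: a coherent copy of the fronto-central
  source delayed by the power lag (default 32 ms), scaled by g_t, with
  transmission phase jitter (κ = 4); a phase-incoherent component with the
  same delayed envelope but random carrier phase, independent of g_t; and an
  intrinsic per-channel beta rhythm.  The coherent copy produces the
  top-down GC whose trial-wise strength tracks g_t (the intrinsic rhythm
  keeps the coherence unsaturated so GC stays gain-sensitive); the
  incoherent component carries most of the lagged power correlation without
  inflating inter-cluster phase coupling;
- 1/f^1.5 background noise (spectrally shaped white noise, unit SD), line
  noise at 50/100/150 Hz with per-channel gains and per-trial phases, and a
  pink-noise common-reference signal added identically to all electrodes.

RTs in attend-IN follow
RT = 300 + 90·(1 − cos s_t) − 40·(g_t − 1) + N(0, 30²) ms: the typical
phase relation (s_t = 0) and strong top-down coupling give short RTs.
Attend-OUT trials draw RTs from the identical marginal model but with
independent surrogate latents, and use cluster-wise independent deviations,
so all phase-RT, gain-RT, and cross-cluster links are severed without any
marginal difference.  A configurable fraction of trials is generated as
artifact (whole-trial ×3 scaling, i.e. ≥9× variance), distractor-first,
early-change (<800 ms after cue), or error trials, exercising every
rejection rule.

Amplitudes and concentrations were chosen once so that the pipeline's own
order statistics behave as in real data: within-cluster PPC is high and
heterogeneous, inter-cluster beta PPC is an order of magnitude weaker (the
mean+3SD rules are order statistics of the pooled PPC distribution, so
cluster recovery requires supra-threshold values to be a minority), the
>100 Hz artifact scan excludes only a small percentage of pairs, and
high-gain trials are not systematically removed by the variance rule.

`oracle_statistics` computes the expected site-pair GPR-RT correlation by
Monte Carlo directly from the generative equations — no signal processing:
the site-pair deviation is the pair-weighted shared deviation plus the
half-sum of the four electrode jitters (the bipolar site phase responds to
each electrode jitter with weight 1/2 at the π/2 offset spacing), averaged
over the occipital cluster's pair-weight distribution.  The recovery test
asks the measured spectrum to sit within twice the session-level sampling SE
(Fisher approximation, conservative because pair averaging can only shrink
the estimator's variance) plus the oracle's own Monte-Carlo SE.

### What the generator does not emulate

Constant-amplitude sinusoids stand in for burst-like rhythms; there is no
spike activity, no eye-position or microsaccade structure, no
session-to-session nonstationarity, no volume conduction beyond the shared
reference, and a single synthetic subject (the equal-weight subject
combination is tested on constructed inputs instead).  Passing tests show
that the estimators and the inference are correct and that implanted effects
of realistic size survive the full chain — not that effects of this size
exist in any particular recording.

## Numerical choices

- Wilson factorization: upper-triangular Cholesky initialization from the
  lag-0 autocovariance, plus-operator with halved and triangularized zero
  lag, diagonal loading 1e-8·mean trace/k when the smallest eigenvalue falls
  below it, relative max-norm update as the convergence measure (default
  tol 1e-12, max 1000 iterations).  On smooth spectra (analytic VAR, white
  noise) convergence is quadratic and the reconstruction reaches 1e-12; on
  rough empirical CSDs from single tapered epochs the iteration stalls
  around 1e-5, which is inherent to such estimates, so the empirical paths
  run a fixed budget (default 100 iterations) in non-strict mode and carry
  the reconstruction error in the result.
- GC clipping: the log argument is clipped when the noise term exceeds the
  spectrum (warning); numerically negative GC beyond −1e-10 warns, all
  negatives clip to 0.
- Degenerate inputs raise: zero-variance sites (named), zero-amplitude
  Fourier coefficients (trial named), all-identical PPC pools, empty trial
  selections, fewer than 2 trials/members.  Constant GPR or constant RT
  yield NaN ("missing") rather than an error where a correlation is simply
  undefined.
- Quintile binning drops the n mod 5 slowest trials after sorting; median
  and 2nd-vs-4th-bin contrasts use the same machinery via parameters.
- Percentiles are nearest-rank everywhere in the randomization machinery.

## Test problem sizes

The acceptance-style tests fix their own sizes: the GPR-RT recovery uses 20
replicates of the full default session (300+300 trials) with 500
randomizations; pooling monotonicity uses 100 direct shared-signal
replicates (400 trials, 2 clusters × 6 area pairs × 6 site pairs); the GC-RT
recovery uses 20 replicates of a reduced 2+2-area session (150
trials/condition, 3 inter-cluster pairs, 30 Wilson iterations); lag recovery
uses 20 replicates per implanted lag (16/32/48 ms) of 2+2-area sessions with
300 trials/condition; inference validity uses 200 null simulations × 500
randomizations plus 200 permutation-p runs.  These sizes are the package's
own trade-off between statistical resolution and a test suite that runs in
minutes; all seeds are fixed.

## Known limitations

Bivariate (not conditional) GC cannot distinguish direct from relayed
influences.  The jackknife correlation is exact only for linear statistics;
for GC it is a first-order approximation whose sign and band structure, not
magnitude, are the tested claims.  The aperiodic fit is a fixed-mode
power-law without knee and is used only for spectrum flattening, not for
peak parameterization.  Cluster recovery depends on the pooled-threshold
order statistics and can fail for generative regimes where most pairs are
coupled; the generator documents this regime dependence rather than hiding
it.
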