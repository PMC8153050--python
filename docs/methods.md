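# Methods

This document describes the generative model behind the synthetic cohorts,
the analysis conventions, the numerical choices, and the known limitations.
Everything here is implemented in `src/urgewave/` and exercised by the test
suite; no empirical claim below is made without a corresponding computation.

## 1. Generative model (`urgewave.synthetic`)

### 1.1 Cohort layout

A default cohort (`CohortConfig()`) contains **26 subjects**, each recorded
in three **330 s blocks** at **250 Hz**: free viewing (`NoSupp`), verbal
suppression instruction (`Supp`), and suppression for reward (`SuppRwd`).
Each session carries three latent sources — `left_prefrontal`, `acc`
(anterior cingulate) and `eog` — mixed into 8 channels by a random
full-rank mixing matrix, plus (in the suppression conditions) a continuous
urgeometer trace. All randomness flows from one master
`numpy.random.SeedSequence` through named substreams, so a (config, seed)
pair reproduces every sample exactly.

### 1.2 Blink trains

Per-subject blink rates are drawn from **Gamma distributions** matched to the
target condition means and SDs (17.8 ± 8.9, 10.7 ± 6.2, 8.4 ± 4.4 blinks/min
for NoSupp / Supp / SuppRwd). A Gamma is used instead of a truncated normal
because truncation at zero would bias the realized means upward by a rate-
dependent amount; the Gamma matches both moments exactly while staying
positive.

Given a rate, blink times form a **renewal process with an absolute
refractory period** (0.5 s): inter-event gaps are `refractory + Exp(μ)` with
`μ = 60/rate − refractory`, so the realized event rate equals the nominal
rate exactly (naive thinning of a Poisson train would undershoot by
10–15 % at NoSupp rates). The first event is drawn from the equilibrium
forward-recurrence distribution of this renewal process, which removes the
edge bias a "start at zero" construction would introduce: the expected count
in a block is exactly `duration × rate / 60`. This is verified empirically
in the test suite (800-replicate mean within 4 SE of the nominal count).

Each blink contributes a stereotyped **biphasic raised-cosine waveform**
(300 ms, positive lobe peaking at 30 % of the waveform, amplitude 8× the
background SD) to the EOG source; the annotated blink latency is the
positive peak, matching what a peak-picking detector can recover.

### 1.3 Urge kernel and urgeometer

The urge time course is a piecewise-linear kernel with analytic landmarks:

* flat zero before the **onset** at −5.0 s,
* a shallow rise to 0.3 of the peak at the **elbow**, −1.8 s,
* a steep rise to the **peak** (amplitude 1) at −0.4 s,
* a linear decay through zero at the **return**, +2.0 s, with a small
  (depth 0.05) raised-cosine undershoot, giving a total duration of 7.0 s.

High-urge trials carry the kernel scaled by a mean-1 gamma gain (SD 0.2) and
shifted by Gaussian jitter (SD 0.1 s); Low-urge trials are noise only. Both
receive low-pass (10 Hz) Gaussian noise (SD 0.1). The probability of a High
trial is 0.5. The session urgeometer trace is the superposition of
per-blink kernels plus that noise, so closely spaced blinks overlap exactly
as they would in a real recording.

### 1.4 EEG sources and planted spectral effects

Each source is unit-variance **1/f noise** (spectrum shaped in the rFFT
domain, flat below 1 Hz). Oscillatory effects are planted by exact dB
rescaling of a band-passed component: with band signal `b` extracted by a
6th-order zero-phase Butterworth filter, the modified source is
`x − b + 10^(g(t)/20)·b`, where the envelope `g(t)` (in dB) is the sum of
per-blink windows with **0.5 s raised-cosine ramps**. This construction
changes in-band power by exactly the planted dB amount while leaving
out-of-band power untouched, so the generator's "effect size" and the
ERSP's dB units live on the same scale.

Default effects:

* **theta (4–8 Hz), +3 dB** on `left_prefrontal` over [−1.5, +0.5] s around
  each blink, in `Supp` and `SuppRwd` only — the suppression main effect;
* **delta (1–4 Hz), −3 dB** on `acc` over [−1.0, +1.0] s for High-urge
  blinks in both suppression conditions *and* Low-urge blinks in `SuppRwd` —
  the urge main effect, with the reward condition equalising the two urge
  classes (which also creates an urge × reward interaction).

### 1.5 Dipole cloud

Equivalent-dipole coordinates are sampled as **12 isotropic Gaussian
clusters** (SD 8 mm) around fixed, well-separated (≥ 40 mm) template
centroids, 76 dipoles per cluster, each tagged with a subject id such that
every subject contributes to every cluster.

## 2. Analysis pipeline

### 2.1 Blink detection and behavioural statistics (`preprocess`)

Blinks are detected on the EOG source as local maxima above
`median + 5 × (1.4826 × MAD)` with a 0.5 s minimum peak separation. The
robust scale estimate is insensitive to the sparse high-amplitude blinks
themselves; the factor 5 puts the threshold far above the Gaussian-
background upcrossing regime while staying well below the 8-SD blink peaks.
Counts are normalised to blinks/min and compared with all-pairs paired
t-tests, Bonferroni-corrected (p × 3, capped at 1). Subjects enter the
EEG analyses only with **> 20 NoSupp blinks and > 10 blinks in each
suppression condition** (strict inequalities).

Degenerate inputs are handled explicitly: identical rate columns give
t = 0, p = 1; a constant non-zero difference (zero variance, non-zero mean)
raises `DegenerateInputError` rather than returning an infinite t.

### 2.2 Epoching

Epochs span **[−4.03, +1.0] s** around each blink peak plus a **1.5 s pad**
on each side. The sample at relative time 0 equals the recording sample at
the event latency exactly; events whose padded epoch crosses a recording
edge are excluded and counted. The pad exists solely to absorb wavelet edge
artifacts (below); it is never analysed.

### 2.3 ERSP (`ersp`)

Complex **Morlet wavelets** with cycles growing linearly from 3 at 1 Hz to
16 at 55 Hz; each wavelet's support is `cycles/f` seconds and its energy is
normalised to 1. Convolution is FFT-based. The epoch pad must cover at
least half the longest wavelet (1.5 s at 1 Hz/3 cycles) beyond the output
window, otherwise `EdgeContaminationError` is raised — no silently
contaminated pixels. Power is averaged across trials per unit (subject),
then expressed as `10·log10(P / P̄_baseline)` with the per-frequency baseline
mean taken over **[−4, −3] s**. The output grid is **100 linear frequencies
(1–55 Hz) × 252 latencies (−4.03 … +1.0 s)**, nearest-sample resampled from
the native 250 Hz grid. Because the dB map is a ratio, it is invariant to
any global rescaling of the raw signal (tested).

### 2.4 Cluster-mass permutation statistics (`cluster_stats`)

Pixelwise statistics:

* `paired_t_map` — paired t, df = n−1, two-sided p; zero-variance pixels
  get t = 0, p = 1;
* `rm_anova_map` — one-way repeated-measures ANOVA F (no sphericity
  correction), df = (k−1, (k−1)(n−1)); at k = 2 this satisfies F = t²
  exactly (tested);
* `interaction_map` — one-sample t² on the per-unit 2×2 interaction
  contrast `X₁₁ − X₁₂ − X₂₁ + X₂₂`, reported as F with df (1, n−1).

Pixels with p below the contrast's threshold are grouped into connected
clusters (4-connectivity by default) and each cluster's **mass** is the sum
of |statistic| over its pixels. The null distribution of the **maximum
cluster mass** is built by re-labelling within units: random sign flips of
per-unit differences (paired and interaction designs; `n_perm="exhaustive"`
enumerates all 2ⁿ flips and is verified against brute force), or independent
within-unit permutations of the k condition labels (repeated-measures
design). A cluster is significant when its mass exceeds the chosen
percentile of that null — this controls the familywise error **weakly**
(under the global null; calibration at α = 0.05 verified within the
binomial 95 % interval over 200 null simulations). Reported corrected
p-values use the add-one estimator `(1 + #{null ≥ mass}) / (1 + n_perm)`.

Contrast conventions (defaults in `pipeline.CONTRASTS`): suppression main
effect — rm-ANOVA, pixel p < 0.001, 99.9th percentile; urge main effect —
paired t, pixel p < 0.005, 99.5th percentile; urge × reward — interaction
F, pixel p < 0.001, 99.9th percentile. The sign-flip permutations exploit
the invariance of Σd² under sign flips, so each permutation only recomputes
the flipped sum — the full 500-permutation null over 25 200 pixels takes a
few seconds.

### 2.5 Urge classification and landmarks (`urge`)

Each suppression-failure trial is correlated (Pearson) with its subject's
mean urge epoch; the per-subject **median split** of these correlations
labels trials High (strictly above the median) or Low. Ties and degenerate
all-equal cases go Low, and a zero-variance trial gets r = 0 by convention.

Landmarks are read off the grand-mean Urge High curve after a **0.2 s
moving-average smoothing** (edge-coverage-normalised, so flat curves stay
flat at the edges):

* **peak** — argmax (earliest sample on ties);
* **rise onset** — earliest time after which the curve stays above
  `baseline mean + 2 × baseline SD` for ≥ 0.25 s, with the baseline taken
  from the earliest 0.5 s of the grid;
* **elbow** — the two-line least-squares changepoint of the [onset, peak]
  segment: the interior grid point minimising the summed SSE of independent
  line fits to the two sub-segments. The exhaustive grid scan is the
  reference; a ternary-search variant (`method="bisection"`) gives the same
  answer on unimodal SSE profiles and is verified against the reference on
  random curves. Prefix-sum accumulators make the exhaustive scan O(n);
* **return / duration** — first sustained (≥ 0.25 s) drop back to the
  baseline band after the peak; if the curve never returns inside the
  epoch, the duration is right-censored at the epoch edge and flagged.

All landmark latencies are translation-equivariant (shifting the time grid
shifts them identically; tested).

### 2.6 IC clustering (`ic_clustering`)

Dipole coordinates are partitioned with best-of-50-restarts k-means for
each candidate k (2…20 by default) and scored with silhouette (argmax),
Davies–Bouldin (argmin) and Calinski–Harabasz (argmax). An index whose
score curve is monotone over the scanned range is reported as having **no
optimum** rather than an endpoint argmax. Exact score ties break toward the
solution with the higher mean number of unique subjects per cluster.

## 3. Numerical choices

* All filters are zero-phase (`sosfiltfilt`) Butterworth cascades in
  second-order sections; band edges are validated against Nyquist.
* 1/f noise is synthesised in the rFFT domain and renormalised to unit
  variance; the spectrum is flat below 1 Hz to keep the variance finite.
* Blink latencies snap to the sample grid before waveform insertion so the
  planted latency and the epoch t = 0 sample coincide exactly.
* Wavelet transforms run on `next_fast_len` FFT sizes in frequency chunks
  of 16 to bound memory (≈ n_epochs × 16 × n_fft complex doubles).
* Permutation nulls, t/F maps and the two-line SSE profile are fully
  vectorised; the only Python-level loops are over permutations and units.
* Percentile thresholds on the permutation null use the `"higher"` order
  statistic (conservative for discrete nulls).
* `np.quantile`/`scipy.stats` tails are used everywhere rather than
  hand-rolled distribution code.

## 4. Known limitations

* **Ramp-crossing bias of cluster onsets.** A planted effect whose dB
  envelope ramps up over 0.5 s reaches pixel-level significance partway up
  the ramp, not at the ramp foot. At the strict suppression threshold
  (pixel p < 0.001) the recovered earliest theta latency is typically
  −1.36 … −1.30 s for an envelope whose ramp starts at −1.5 s; the more
  lenient urge contrast (p < 0.005) recovers its −1.0 s onset almost
  unbiased (0.94–1.06 s lead time). This is a property of thresholded
  detection of gradual onsets, not an implementation error, and is left
  uncorrected.
* **Return-time censoring under blink overlap.** In the suppression
  conditions the mean inter-blink interval (≈ 6 s) is shorter than the urge
  kernel support (7.5 s), so session-epoched mean urge curves often stay
  slightly elevated after the return and the duration is right-censored at
  the +2.5 s epoch edge. The landmark benchmark therefore uses isolated
  simulated trials; the pipeline flags censoring explicitly.
* **No sphericity correction.** The repeated-measures F uses uncorrected
  degrees of freedom; pixel p-values are only used for cluster forming, and
  the final inference comes from the permutation null, which does not
  assume sphericity.
* **Weak FWER only.** The cluster-mass test controls the familywise error
  under the global null; localisation claims about *which* pixels belong to
  a cluster carry no pixel-level guarantee.
* **Single-trial baselining is off by default.** The classic trial-averaged
  baseline is used; `ERSPConfig(single_trial_baseline=True)` exists but
  amplifies low-frequency variance on short baselines.
* **Dipole model is idealised.** Isotropic Gaussian clusters with equal
  sizes and guaranteed subject coverage; no depth bias, no localisation
  error model, and the mixing matrix plays no role in the dipole analysis.
* **Urge classification is within-subject only.** The median split forces
  ≈ 50 % High trials per subject regardless of the true High fraction; with
  the default p(High) = 0.5 this is consistent, but a different true
  fraction would bias class assignment toward the median.
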