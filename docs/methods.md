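# Methods

## Scope and model

`backmap` implements the analysis chain for TMS mapping of back-muscle
representations in M1 and a generative model of such experiments. The analysis
assumes: a rectangular scalp grid of stimulation sites with known cm
coordinates (default 5 columns × 8 rows, 1 cm spacing; x = 0–4 cm lateral of
the midline, y = −2…+5 cm relative to the vertex, positive anterior); a fixed
number of stimuli per site (default 5); EMG sampled at 2000 Hz with at least
500 ms of pre-stimulus signal; and MEP amplitude quantified as RMS EMG.

The simulator's latent model is deliberately minimal: one isotropic 2-D
Gaussian amplitude surface per muscle per subject,
`A(x, y) = peak · exp(−((x−μx)² + (y−μy)²) / 2σ²)`, with the centre (the true
CoG) drawn per subject from a group-level normal distribution truncated to the
grid. This is not a biophysical cortical model — it is the simplest surface
whose amplitude-weighted centroid, area and volume are analytically known, so
every downstream estimator can be checked for parameter recovery.

## Sweep generation

Each sweep is tonic background EMG (zero-mean Gaussian with configurable RMS,
default 10 µV, emulating a sustained 10% MVC contraction; an optional mains
component can be toggled on) plus an MEP burst at latency 20 ± 2 ms. The burst
is a damped 60 Hz sinusoid (decay τ = 8 ms, duration 20 ms) scaled to a target
RMS drawn lognormally with mean equal to the surface amplitude at the site and
a configurable coefficient of variation (default 0.2). Choices and rationale:

- **Waveform shape.** Real MEPs are polyphasic; since all downstream metrics
  are RMS-based, shape only matters to the detector. 60 Hz keeps each
  rectified lobe longer than the detector's 5 ms sustain requirement, and the
  sharp onset makes detected latencies match ground truth.
- **Lognormal amplitude noise.** Per-stimulus MEP amplitudes are positive and
  right-skewed; the lognormal is a standard choice and is parameterised by CV
  so the noiseless limit (CV = 0) is exact. No claim is made that real
  paraspinal MEP variability is lognormal.
- **Muscle coupling.** The DM centre anchors each subject; other muscles sit
  at `DM + (1 − coupling)·(fixed offset + jitter)`. `overlap_coupling = 1`
  collapses all muscles onto one centre (full overlap); 0 gives independent
  centres. DM's between-subject dispersion therefore equals the generating
  `cog_dispersion` exactly, which keeps parameter-recovery clean.
- **Truncation.** True CoGs are redrawn within grid bounds (truncated normal),
  as required for the surface to be mappable. For dispersions up to ~0.9 cm
  about a mid-grid centre this shrinks realized dispersion by ≲ 10%; larger
  dispersions are increasingly truncated — recovered ratios then understate
  the generating contrast, which is a property of mapping a bounded grid, not
  an estimator bug.

Determinism: the cohort seed spawns per-group streams; each subject gets a
stored seed; each site's sweeps derive from a hash of (subject seed, muscle,
site), so any subset of the data can be regenerated bit-identically in any
order.

## Sweep processing

- **Background RMS**: over [−500, −5) ms pre-stimulus. A sweep without 500 ms
  of pre-stimulus signal is an error naming the shortfall.
- **Detection** (automated stand-in for visual onset/offset marking): the
  rectified signal is smoothed with a 2 ms moving average (stabilises crossing
  times at 2 kHz); threshold = background mean + k·SD of the same smoothed
  signal (k = 3); onset = first crossing sustained ≥ 5 ms inside the 10–40 ms
  latency band (paraspinal MEP latencies; configurable, as real bands vary
  with muscle and stimulation intensity); offset = start of the first ≥ 5 ms
  sub-threshold run after onset, else the end of the sweep. The threshold is
  floored at 10⁻⁹ of the signal peak so an exactly-silent background still
  separates signal from the smoothing filter's floating-point residue. No
  crossing means "no MEP" — a value, not an error. Manual per-sweep windows
  override the detector.
- **Correction and averaging**: amplitude = max(MEP RMS − background RMS, 0).
  The clamp exists because negative differences are physically meaningless and
  would corrupt volume sums. Site amplitude is the mean over sweeps with a
  detected MEP; a site with none contributes 0 (not missing), keeping the map
  a full grid.
- **Channel QC**: `no-mep` when no site responds; `poor-quality` when median
  background RMS exceeds a ceiling (default 30 µV, i.e. the contraction or
  electrode is unacceptable) or more than half the sweeps are clipped;
  `usable` otherwise. Non-usable channels are dropped, so per-muscle group n
  shrinks exactly as it does in real cohorts with rejected channels.

Note one small bias: with background b and true burst RMS A, the measured
window RMS is ≈ √(A² + b²), so corrected amplitudes underestimate weak sites
relative to strong ones. The map is normalised, so this slightly sharpens maps
but leaves the CoG of a symmetric footprint unbiased; the parameter-recovery
study bounds the end-to-end effect.

## Map metrics

Maps are normalised to the hot spot; sites with z strictly below the threshold
fraction (default 0.25) are removed. A site at exactly 25% is **kept** (the
keep-rule is ≥); both fraction and convention are configurable. Volume, area
and CoG are all computed on the thresholded map, which keeps the three metrics
mutually consistent (volume = 0 ⇔ area = 0 ⇔ CoG undefined). Overlap is the
Jaccard index of active masks, 0 by convention when both are empty. CoG
variation uses the arithmetic group-mean CoG; per-subject deviations are
|Δx|, |Δy| and the Euclidean distance. The group mean of per-subject CoG
vectors is not the vector of the group-mean CoG; report whichever the analysis
needs (both are available).

## Statistics

- Variance gate: Levene's test, median-centred, at α = 0.05 (the robust
  default). Homogeneous → classic ANOVA + Duncan; heterogeneous → Welch +
  Games–Howell. The gate can be forced either way.
- η² is always classic SSB/(SSB+SSW), including next to a Welch F — the
  convention used in published Welch rows.
- From-summary forms: classic F needs only (mean, SD, n) per group
  (SSB = Σnᵢ(mᵢ−m̄)², SSW = Σ(nᵢ−1)sᵢ²); Welch's F and its Satterthwaite df
  likewise. These are algebraically identical to the raw-data routines, a
  property the test suite enforces to 10⁻¹⁰ relative error.
- Duncan's multiple range test is natively a decision procedure; the reported
  per-pair p is the smallest protection-adjusted α at which the pair
  separates, `1 − (1 − P_r(q))^(1/(r−1))` for a pair spanning r ordered means,
  with the multiple-range monotonicity constraint (a pair inside a
  non-separated span cannot separate). Unequal n uses the pair's harmonic
  mean.
- Games–Howell: per-pair studentized-range statistic with Welch–Satterthwaite
  df.
- Shapiro–Wilk is reported as a diagnostic only; it does not switch the
  analysis to non-parametric tests.
- Spearman uses mid-ranks for ties; a constant vector yields an undefined
  (NaN) rho rather than an arbitrary number.
- No multiplicity adjustment anywhere, by design (exploratory analyses).

## Validation studies and problem sizes

`backmap.validation` fixes the study designs used by the test suite and
`scripts/acceptance.py`:

- Published-table recomputation from transcribed (mean, SD, n) rows. Because
  printed summaries are rounded to two decimals, recomputed F and η² can
  differ from printed values by up to ~1%.
- Oracle identities: 200 random datasets (2–5 groups, n 3–15) for the
  summary-vs-raw ANOVA identity; 500 random 5×8 tables against a
  straight-loop reference for map metrics.
- Parameter recovery: two groups (CoG dispersion 0.3 vs 0.9 cm, both centred
  at (2.0, 1.5) cm so truncation stays symmetric), 50 subjects/group,
  20 seeds, amplitude CV 0.2, 10 µV background, 5 stimuli/site, DM channel.
  Recovered group-mean CoG error is ~0.03 cm; per-axis dispersion is recovered
  within ~12% (dominated by the truncation shrink at 0.9 cm); the estimated
  3× variation contrast comes out ≈ 2.8.
- Calibration: classic-ANOVA type-I error under a 4-group normal null
  (2000 reps) and worst pairwise Games–Howell rejection rate under a
  heteroscedastic null with SDs 1/2/4/8 and n 12/10/8/6 (1000 reps).
- Pain-link recovery: a monotone link between true CoG deviation and pain is
  injected; the sign of Spearman's rho between the *estimated* deviation and
  pain must be recovered.

These sizes keep the full suite and the acceptance script each within a few
minutes on one CPU while leaving Monte-Carlo error well inside the asserted
bands.

## What passing tests do and do not show

The simulator emulates the statistical structure the analysis assumes —
Gaussian-like amplitude surfaces, group-specific CoG scatter, multiplicative
per-stimulus amplitude noise, stationary tonic background. It does not emulate
coil-positioning error, neuronavigation drift, electrode movement, fatigue or
non-stationary contraction level, polyphasic/variable MEP morphology, or
cross-site correlation of excitability fluctuations. Passing recovery tests
therefore show the estimators are correct and well-calibrated under the stated
model, not that real recordings meet that model. Subject-level published
results (specific group differences, specific pain correlations) are not
reproducible without the original raw recordings and are covered only
qualitatively (orderings, signs) by simulation.

## Known limitations

- The detector is a threshold-crossing surrogate for expert visual marking;
  on real, noisy, polyphasic MEPs its windows will differ from a rater's.
  Manual annotation files are first-class inputs for that reason.
- Welch's η² convention (classic SSB/(SSB+SSW)) slightly overstates explained
  variance under strong heteroscedasticity; it is used for comparability with
  published tables.
- Duncan's test has weak family-wise error control by construction; it is
  provided for fidelity to the analysis it reproduces, not as a
  recommendation.
- `scipy.stats.studentized_range` is numerically slow for large designs; the
  Games–Howell calibration study is the dominant cost in the acceptance run.
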