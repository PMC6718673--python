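# Methods notes

## Scope and data model

The package analyzes stimulus-evoked calcium responses of cultured neurons
recorded as per-ROI fluorescence time series, in a design where each affected
subject (ST) is paired with an unaffected monozygotic co-twin (HT) and each
subject is recorded under two treatment conditions (`pre`/`post`, e.g. before
and after an antipsychotic). It also quantifies how strongly an
illness-related differential-expression signature overlaps a sex-specific
gene set. Neither arm fits expression models or segments images: inputs are
already-extracted ROI traces and already-fitted DEG tables.

## Trace processing

**Background subtraction.** The background signal is the pointwise mean of
the cell-free background ROIs (three by default in the simulator) and is
subtracted from every cell trace. Background traces are kept on the corrected
recording so the subtraction is auditable.

**Denoising.** Stationary (maximal-overlap) discrete wavelet transform, Haar
filters, level 3, in the normalized (variance-preserving) convention of
PyWavelets. Detail coefficients are soft-thresholded with the
Donoho–Johnstone universal threshold λⱼ = σ̂ⱼ √(2 ln N); the approximation
band is untouched. By default σ̂ⱼ = median(|dⱼ|)/0.6745 is estimated per
level ("level-dependent rescaling"); a single-level mode that reuses the
finest level's σ̂ at all levels is available, since denoising toolboxes offer
both and the choice is not recoverable from a published figure. Series are
reflection-padded at the end to the next multiple of 2³ and trimmed after
reconstruction; reflection avoids wrap-around artifacts near stimulus onsets
at the recording boundaries. A `threshold_scale` of 0 disables shrinkage and
must reproduce the input exactly (perfect-reconstruction check). Denoising
exists precisely so the min/max extrema below are usable; the quantification
deliberately uses extrema, not window averages.

One property worth knowing: on a *noiseless* multi-transient trace the
per-level medians are dominated by the exponential tails of earlier
transients, so the universal threshold is small but nonzero and peaks are
shaved by a few tenths of a percent. Tests of the exact dF\* closed form
therefore use single-transient recordings, where more than half of each
level's coefficients are exactly zero and the threshold vanishes.

**Response statistic.** dF\* = (f − f₀)/f₀ with f = max over the half-open
post-window (onset, onset + 20 s] and f₀ = min over the closed pre-window
[onset − 50 s, onset]. Endpoint conventions are a package choice (the verbal
definitions "following" and "before" do not fix them); including the onset
sample in the pre-window biases f₀ downward, i.e. conservatively. f₀ ≤ 0
raises a degenerate-baseline error — it signals failed background
subtraction rather than a measurable response. Both windows must lie inside
the recording, which constrains stimulus schedules (the simulator validates
this up front).

**Neuron classification.** A cell is a neuron iff
dF\*(KCl)/dF\*(ionomycin) ≥ `min_ratio` (default 0.1). The KCl criterion is
standard for excitable cells; the numeric cutoff is a package default, chosen
so that zero-amplitude non-responders at realistic noise levels fall well
below it, and is configurable.

**Calibration.** Every response is divided by the cell's ionomycin dF\*
(receptor-independent, per-cell maximal response), then agonist responses are
divided by the ionomycin-calibrated KCl response. With both numerator and
denominator ionomycin-calibrated, the ionomycin term cancels algebraically,
so final ratios equal raw(agent)/raw(KCl); the two-stage form is kept because
both intermediate scales are reported and audited. Cells without a positive
ionomycin transient cannot be calibrated and are dropped by the pipeline (in
practice only pathological traces). Final KCl-calibrated values are reported
for neurons only.

## Two-level twin-contrast model

Level one pools all cells of one subject in one stimulus × treatment stratum.
Outliers are removed first: x is dropped when |x − median| > k · 1.4826 · MAD
with k = 3; when MAD = 0 (at least half the values identical) the rule is
degenerate and everything is kept. Outlier removal is applied within the
subject × treatment × stimulus group — the finest grouping at which the
summary statistics are computed, and the only granularity at which the filter
is well defined. The subject summary is the mean and the variance *of the
mean* (unbiased sample variance / n); the pair contrast is y = mean(ST) −
mean(HT), v = v_ST + v_HT. At least two cells per subject are required;
subjects or pairs that fail are dropped with a logged warning. A zero v
(all cells identical) would give an infinite weight; it is floored at 10⁻¹²
with a warning instead.

Level two is the inverse-variance-weighted random-effects pool with the
DerSimonian–Laird moment estimator of the between-pair variance τ²,
truncated at zero. p-values are two-sided normal; with k ≈ 5 pairs the
normal reference is known to be mildly anticonservative, which is why the
type-I error acceptance band is [0.03, 0.09] rather than a point at 0.05.
Each treatment condition is tested separately (cells are never pooled across
pre/post at level one), matching how per-condition contrasts are reported in
this design.

## Synthetic data

**Traces.** Cell traces are baseline + background + one transient per
stimulus + white Gaussian noise; background ROIs are background + noise. The
transient is a difference of exponentials (rise 1 s, decay 8 s by default),
normalized so its sampled peak equals the configured amplitude exactly —
which gives the noiseless closed form dF\* = amplitude/baseline. Non-neuronal
cells (a 1 − `neuron_fraction` share, default 20%) respond only to ionomycin.
The default schedule applies GABA, glutamate + glycine (Mg-free), KCl and
finally ionomycin for 2 s each on a 400 s recording at 2 Hz; the sampling
rate is a generic imaging choice, not a measured one, and is configurable.
Amplitude defaults (ionomycin 2.0, KCl 1.0, agonists 0.5–0.6 a.u. on a 1.0
baseline) put calibrated agonist responses near 0.5, a plausible scale for
receptor responses relative to depolarization. An `outlier_fraction` of cells
gets agonist amplitudes multiplied by `outlier_scale`, giving the MAD filter
concrete aberrant responders to remove. What the simulator does **not**
emulate: indicator photophysics, bleaching, drift or motion — so passing
tests show the statistics behave correctly for stimulus-locked transients on
stationary baselines, not that the pipeline is robust to every microscopy
artifact.

**Cohorts.** Each pair draws one effect δᵢ ~ N(δ, τ²) (defaults δ = 0.3,
between-pair SD 0.1); the affected twin's expected calibrated target-agonist
response is baseline_response + δᵢ in the treatments where the effect applies
(default: `pre` only, emulating a treatment that abolishes the difference),
and cell responses scatter around the subject mean with SD 0.15. The default
cohort (5 pairs × 50 cells) mirrors the scale of a five-pair discordant-twin
study with tens of analyzable neurons per coverslip. The trace-level
generator embeds the drawn responses as transient amplitudes (amplitude =
response × KCl amplitude, so the calibrated ratio recovers the draw; negative
draws clamp to zero amplitude — with the default response scale that happens
with probability < 10⁻³ per cell). The response-level generator emits the
calibrated values directly and is used for Monte-Carlo studies (2000-cohort
type-I error, 500-cohort bias), where re-denoising a million traces would add
runtime but no information; the trace path is exercised end to end at
single-cohort scale. Ground truth (pair effects, expected responses, neuron
labels, contaminated cells) is stored in metadata.

**DEG tables.** Construction is exact, not sampled: the sex-specific set has
round(frac × n_genes) members, exactly `n_illness_degs` genes pass the filter
(p_adj < 0.05 strict, |log2FC| ≥ 1 inclusive), and round(frac_overlap ×
n_degs) of them are sex-specific. Passing genes get |log2FC| = 1 + |N(1,1)|
and p_adj uniform below 0.05; failing genes get small fold changes or
non-significant p-values, never both passing. Defaults mirror a
transcriptome-scale comparison: 19,462 genes, 2327 sex-specific (~12%), a
41-gene illness list with 25 overlapping (61.0%).

## Overlap statistics

The primary 2×2 table is the standard disjoint partition
[[overlap, list-only], [reference-only, neither]] over the universe; Fisher's
exact test is two-sided by default (one-sided "greater" available) and the
Pearson χ² uses no continuity correction (Yates optional). Because published
overlap p-values do not always state whether the reference margin excludes
the tested list, an alternative construction comparing the list proportion to
the raw reference/universe margin is also reported (`fisher_p_marginal`);
for a 7-of-19 list against a 2327/19,462 baseline the two give 4.7 × 10⁻³
and 4.8 × 10⁻³. For a 25-of-41 list the χ² p-value is below 2.2 × 10⁻¹⁶,
the conventional reporting floor, so only the floor — not the exact value —
is meaningful there. The universe is always supplied by the caller, never
inferred from the inputs.

## Numerical and design choices

- Thresholds, windows, and the MAD rule use the exact constants stated above;
  all are configurable dataclass fields with validation at construction.
- All randomness flows through explicit seeds (`numpy.random.default_rng` /
  `SeedSequence` spawning); equal (config, seed) gives bitwise-equal outputs,
  including byte-identical response TSVs on re-runs.
- Recording CSVs round-trip floats exactly (shortest-repr writing,
  `float_precision="round_trip"` reading).
- The acceptance script's bias check uses a 3-standard-error Monte-Carlo band
  (99.7% coverage) around the true δ; a 1-SE band would fail a third of the
  time for an unbiased estimator.
- Monte-Carlo problem sizes (2000 null cohorts, 500 effect cohorts, 1000
  random meta-analysis instances) were chosen so binomial/MC uncertainty is
  well inside the asserted bands while the whole suite stays interactive.

## Known limitations

- The normal-theory p-values of the pooled contrast are approximate for very
  few pairs; no small-sample (e.g. Hartung–Knapp) correction is implemented.
- The MAD filter assumes a roughly symmetric bulk; heavily skewed response
  distributions would be better served by a transformed scale.
- The denoiser's universal threshold assumes approximately white noise;
  strongly autocorrelated noise inflates σ̂ at coarse levels.
- No multiple-testing correction across stimuli/treatments is applied; each
  contrast is reported on its own, and correction is the caller's decision.
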