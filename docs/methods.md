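# Methods

## The measurement model

One *trial* is a maximal isometric contraction recorded as a force trace
(newtons) and usually a surface-EMG trace (volts), both uniformly sampled
(nominally 1961 Hz). A *study* is n subjects × 2 sessions (typically a
week apart) × up to 3 trials. Four scalars are extracted per trial —
MVC, RFD200ms, time to 90% MVC, peak EMG RMS — aggregated per session
(mean-of-3 or best-of-3), and the resulting n × 2 matrix per outcome is
the unit of reliability analysis.

## Signal conditioning and outcome extraction

* **Force filter.** 4th-order Butterworth low-pass, 15 Hz cutoff, applied
  forward–backward (`sosfiltfilt`). Zero-phase filtering preserves event
  timing; the two passes square the magnitude response, so a 50 Hz
  component is attenuated to ~6.7·10⁻⁵ of its amplitude.
* **Onset detection.** Baseline mean m and SD s over the first 500 ms
  (must be pre-contraction); onset is the first sample > m + 3s that stays
  above threshold for 25 ms. The hold is a debounce that stands in for the
  visual confirmation a human rater performs; window, k and hold are all
  configurable (`OnsetSpec`). Detection runs on the filtered trace. Onset
  on a noiseless step is exact; on the default synthetic trial it lands
  within ~10 ms of the generator's onset (the zero-phase filter smears the
  corner symmetrically, so the crossing can move a few ms *earlier*).
* **MVC** = max(force) − m, computed on the filtered trace by default
  (`mvc_raw=True` reads the peak off the raw trace instead, for
  workflows that take peak amplitude from the acquisition software). A
  peak occurring before onset triggers an artefact warning.
* **RFD200ms** = (F(onset + 200 ms) − m)/0.2, nearest-sample evaluation
  (at 1961 Hz the timing quantisation is ~0.5 ms, negligible against
  between-session error). The force is baseline-corrected; dividing an
  uncorrected force would fold the resting offset into a rate. A switch
  (`rfd_baseline_correct=False`) restores the uncorrected reading.
* **t90** = first time ≥ onset at which baseline-corrected force reaches
  0.9 × MVC, minus onset. If the trace maximum precedes the detected
  onset (artefact-dominated recording) the criterion can be unreachable;
  the trial then errors out and the extraction layer drops and logs it.
* **EMG.** 4th-order Butterworth band-pass 10–500 Hz zero-phase (the band
  edge is below Nyquist at any rate > 1 kHz, which is enforced); centred
  moving-RMS envelope, default window 50 ms (the search region ±1 s
  around the force peak is standard; the RMS window length is a free
  choice and is configurable); peak of the envelope within ±1 s of the
  force peak, clipped to the recording.

## Reliability statistics

Two-way random-effects ANOVA with one observation per cell gives MS_rows
(subjects), MS_cols (sessions) and MS_error; the sums of squares satisfy
SS_total = SS_rows + SS_cols + SS_error exactly. The single-measure
absolute-agreement ICC is

    ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)),

which charges a systematic session shift to the denominator (adding a
constant to one session strictly lowers it), unlike the consistency form.
The 95% CI is the McGraw–Wong (1996) F-based interval for ICC(A,1), with
Satterthwaite degrees of freedom for the mixed denominator mean square;
the implementation is cross-checked in the tests against pingouin's
ICC(A,1) point estimate (1e-6) and against an independent numerical
inversion of the defining F test (1e-6). Degenerate inputs: an all-equal
matrix raises ("no variance"); a matrix whose denominator vanishes with
nonzero numerator (perfectly anti-correlated sessions) returns the
clipped limit ±1; estimates and bounds are clipped to [−1, 1].

**SEM.** The measurement literature uses several SEM definitions. Default
here is √MS_error — the within-subject error SD of the same
absolute-agreement ANOVA; the pooled-SD·√(1−ICC) alternative is available
(`sem_formula="sd1micc"`). SEM% = 100·SEM / grand mean of all cells.

**Normality / log transform.** Each session column is screened with
Shapiro–Wilk (delegated to `scipy.stats.shapiro`); p < 0.05 in either
column triggers a natural-log transform of all cells. ICC/CI/SEM/SEM% are
then reported on the log scale with a flag set, while session means/SDs
stay on the raw scale for readability. Two caveats follow from reporting
SEM% on the analysis scale: it is no longer scale-free in the usual sense,
and it can even be negative when the mean log is negative (outcomes with
magnitude < 1). Running with `log_transform=False` reproduces the
raw-scale metrics for comparison.

**Classification.** Point estimate and CI lower bound are banded as
excellent (≥ 0.90), good (0.75–0.89), moderate (0.50–0.74), poor (< 0.50);
reporting the lower bound's band guards against over-reading small-sample
point estimates.

## The synthetic-data generator

* **Trace shape.** Force is zero to onset, then
  `peak · tanh((t − onset)/(2τ))` — the upper half of a logistic. Force is
  exactly zero at onset and the slope is maximal there (peak/2τ), matching
  an instructed "pull as fast and hard as possible" effort, and the
  outcome measures have closed forms: RFD200 = peak·tanh(0.1/τ)/0.2,
  t90 = 2τ·atanh(0.9). Gaussian sensor noise (default SD 0.5 N) is added
  throughout. Defaults: peak 142 N, τ = 0.35 s (t90 ≈ 1.03 s), onset
  1.5 s, contraction 4.5 s, rate 1961 Hz. A single-timescale sigmoid
  cannot simultaneously reproduce the fast early rise (RFD200 of several
  hundred N/s) *and* the slow creep to 90% (t90 well above 1 s) seen in
  impaired contractions; the defaults favour a realistic t90.
* **EMG.** Amplitude-modulated Gaussian noise band-limited to 10–500 Hz,
  instantaneous SD = 0.01 V + 0.0013 V/N × force(t), giving ~0.2 V RMS at
  peak force. The carrier is renormalised to unit sample SD, so the
  envelope ground truth is the SD profile itself.
* **Study model.** Target peak of subject i, session j, trial t is
  μ + b_i + s_ij + w_ijt with independent zero-mean normals of SD
  σ_between, σ_session, σ_trial; s is a *subject-by-session interaction*
  (drawn per subject-session), not a common session shift — absolute
  agreement penalises either, and the interaction keeps replicate studies
  exchangeable. Targets are floored at 1 N (log transforms must remain
  possible); >1% floored draws triggers a model-misspecification warning.
  True mean-of-m ICC: σ_b²/(σ_b² + σ_s² + σ_w²/m). Best-of-m has no clean
  closed form (max of correlated normals); `true_icc` returns the
  mean-of-m value as an approximation and `simulate_outcome_matrix` gives
  a simulation-based truth. Defaults (μ = 142, σ_b = 64.7, σ_s = 6,
  σ_w = 14) put the aggregated error SD at ~10 N, i.e. true ICC ≈ 0.977 —
  the regime of a reliable MVC protocol.
* **What it does not emulate.** Only the peak amplitude varies between
  subjects and trials; rise time τ is common. Time-based outcomes (t90 is
  exactly peak-invariant) therefore have near-zero between-subject
  variance at the trace level and show poor ICC by construction —
  reliability-layer validation for such outcomes uses the scalar
  variance-component simulator, where any true ICC can be dialled in.
  No fatigue, co-contraction, tremor, amplifier drift/saturation, or
  non-Gaussian EMG statistics; passing tests demonstrate algorithmic
  correctness under the stated model, not robustness to every artefact of
  real recordings (the onset debounce and artefact warnings are the hooks
  for those).

## Numerical and design choices

* Nearest-sample (no interpolation) event timing everywhere; first
  occurrence wins on ties (max, threshold crossings) — deterministic.
* SS_error is clamped at 0 to absorb float cancellation in near-perfect
  matrices; filters reject traces shorter than 3 warm-up lengths.
* Aggregation over fewer than 3 available trials is allowed and logged
  (a session's remaining valid trials are used); subjects missing a whole
  session, or missing EMG, are dropped listwise for the affected outcome
  only, and logged.
* Simulation sizes used by the validation suite were chosen to estimate
  each quantity comfortably within its tolerance: n = 2000 subjects for
  the variance-component ICC reproductions (sampling SE < 0.015), 500
  replicates for bias at n = 13, 1000 for CI coverage, n = 5000 for the
  variance-convergence check at 5%.

## Known limitations

* The ICC(2,1) point estimator carries the classic O(1/n) negative bias:
  at n = 13 the mean estimate sits ~0.03 below a true ICC of 0.5
  (shrinking to ~0.01 at 0.95). This is a property of the estimator, not
  of the implementation — the CI coverage stays at ~95–96% — but it means
  small-sample point ICCs read slightly pessimistic in the mid-range.
* Log-scale SEM% (see above) is hard to interpret and not comparable
  across transformed and untransformed outcomes.
* The CI procedure assumes normality on the analysis scale; the transform
  step helps but is itself a data-dependent decision, and its alpha is a
  tunable.
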