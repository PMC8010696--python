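# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `meridianvision`. It is written for users who need to
judge what the package's simulations and tests do — and do not — establish
about real psychophysical and EEG data.

## Generative observer model

Real CSF experiments sample sensitivity point-wise and never commit to a
functional form, so the synthetic observer needs one only as generative
truth. We use the truncated log-parabola, the standard parametric CSF in the
psychophysics literature:

    log10 S(f) = log10 G − 4·log10(2) · ( log10(f / f_peak) / B )²,

floored on the low-frequency side at `t·G` (the low-frequency plateau seen
in empirical CSFs). Parameters and defaults for the canonical observer:

| parameter | meaning | default | rationale |
|---|---|---|---|
| `peak_gain` G | sensitivity at the peak (1/contrast) | 45 | puts AULCSF near 1.55 log-units², typical of corrected adult eyes |
| `peak_sf` | peak frequency, cyc/deg | 3 | mid-range adult peak |
| `log_bandwidth` B | width in log₁₀-frequency units (S halves at ±B/2) | 1.0 | acuity lands near 40 cyc/deg |
| `low_freq_truncation` t | plateau fraction of G | 0.3 | keeps 0.5 cyc/deg sensitivity realistic |

The **weak meridian** is the strong-meridian curve attenuated by a vertical
log₁₀ shift *d* (drawn per eye, clipped at 0 so weak ≤ strong holds
everywhere). A pure gain shift was chosen because every downstream summary
(AULCSF, acuity, SF threshold) then has a closed-form generative value,
making parameter recovery checkable.

**2IFC responses.** P(correct) = γ + (1 − γ − λ)·W(c), with guess rate
γ = 0.5 (two intervals), lapse rate λ = 0.02, and Weibull
W(c) = 1 − exp(−(c·S(f))^β) with slope β = 3 — conventional values for
contrast detection. The task specifies only the paradigm and the staircase's
convergence level; β and λ are free generative choices and the staircase's
convergence level is insensitive to them.

**Sweep-VEP truth.** Each 1 s epoch at swept frequency f_k carries a 12 Hz
sinusoid of amplitude

    A(f_k) = A₀ · max(0, (f_thr − f_k) / (f_thr − f_ref)),

a linear descent from A₀ (default 4 µV, matching typical occipital
second-harmonic amplitudes) at the first swept value f_ref = 2 cyc/deg to
zero at the eye's generative threshold f_thr. Linearity is deliberate: the
analysis estimates the threshold by linear regression to zero amplitude, so
a linear truth makes recovery well-posed and any estimation error
attributable to the analysis chain, not to model mismatch. The response is
present only on Oz/O1/O2 and uses a per-eye response phase plus one
Gaussian phase-jitter draw per trial (SD 0.2 rad).

**Noise.** Background EEG is 1/f^α Gaussian (α = 1, the canonical EEG
spectral slope) plus white noise, independent per channel, with RMS 10 µV
and 5 µV respectively — a realistic occipital amplitude that leaves the
12 Hz response clearly above the noise floor at low swept frequencies and
near criterion at high ones. The generator emits already-digitized,
unfiltered signals; hardware anti-aliasing and the acquisition band-pass
are not simulated because the 1–30 Hz analysis band contains all signal
content of interest. No artifacts (blinks, muscle) are simulated.

**Cohorts.** Two groups mirror the study design: astigmats (AST, 20 eyes,
mean CSF disparity 0.15 log-units, mean sVEP-threshold disparity
2.6 cyc/deg) and meridional amblyopes (MA, 19 eyes, lower peak gain, CSF
disparity 0.26, sVEP disparity 2.3). Disparities are drawn per eye
(SD 0.05 log-units / 0.8 cyc/deg) and clipped at zero; the modest spreads
keep generative disparities clearly one-signed, which is what the
sign-recovery checks require.

## Staircase

Three-down one-up with multiplicative steps: contrast × 0.9 after every
third consecutive correct response (the streak counter resets after a
step — standard k-down bookkeeping), × 1/0.9 after every error. The up-step
is the reciprocal, i.e. log-symmetric, which preserves the canonical
(1/2)^(1/3) ≈ 79.37 % convergence level; a literal +10 % step is available
via `step_up_factor=1.1`. Contrast is clipped to [10⁻⁴, 1].

*Start contrast* defaults to 0.1. With 10 % steps, a start of 0.5 would
need ~90 trials to descend to a typical 2 % threshold, leaving a 100-trial
block without enough reversals to score; from 0.1 the descent takes ~40
trials and blocks yield ~9–12 reversals.

*Threshold estimate*: reversals are the extremum trials where the direction
of contrast change flips (plateaus at the clip bounds do not flip
direction). The first four reversals are discarded when that leaves an even
count, otherwise the first three — guaranteeing an even number — and the
estimate is the geometric mean of the retained reversal contrasts
(averaging in log contrast matches the multiplicative step geometry).
Fewer than six reversals flags the cell non-converged; non-converged cells
are omitted from CSF summaries and flagged.

Measured behavior (reproduced by the test suite): late-run accuracy
79.3 ± 1.5 % over the last 100 of 200 trials; ~13 reversals per 80-trial
block across the 7-frequency session grid; median threshold-recovery error
below 0.05 log₁₀ units against the generative 79.37 %-correct contrast.

## CSF summaries

Points are (log₁₀ f, log₁₀ S). Between points the curve is linear in
log-log coordinates; beyond the outermost points it is extended
log-linearly from the outer two, with the high-side slope clamped ≤ 0.

* **AULCSF** integrates log₁₀ S, floored at 0, over log₁₀ f ∈
  [log₁₀ 1.5, log₁₀ 18]. The integral is computed exactly on each linear
  piece (zero crossings are inserted as knots before flooring), so it is
  non-negative, and scaling all sensitivities by 10^k shifts the unfloored
  area by exactly k·log₁₀(18/1.5).
* **CSF acuity** is the log₁₀ frequency where the descending
  high-frequency limb crosses log₁₀ S = 0, scanned from the highest
  frequency downward; it is reported in log₁₀ cyc/deg.
* **SF threshold at contrast c** (default 0.80) is the analogous crossing
  of log₁₀(1/c), reported in linear cyc/deg.

When every measured sensitivity exceeds the crossing level, the crossing is
obtained by extrapolating the last segment and flagged. Extrapolated
crossings are *approximate*: a curved (log-parabola-like) limb sampled at
12 and 16 cyc/deg extrapolates linearly with a shallow slope, so crossings
far beyond 16 cyc/deg are overestimated. Crossings bracketed by the grid
are recovered to better than 0.05 log₁₀ units. This is an intrinsic limit
of point-wise CSF sampling, not of the implementation.

## Sweep-VEP analysis

* **Filtering**: zero-phase 4th-order Butterworth band-pass, 1–30 Hz,
  applied to the whole 10 s trial. A 12 Hz probe passes within 1 %; the
  zero-phase edge transient attenuates the first epoch's amplitude by a few
  percent, which slightly biases the window's peak selection but not the
  regression threshold.
* **Epoching**: ten contiguous 1 s epochs, epoch k ↔ swept frequency k.
  One-second epochs give 1 Hz spectral resolution, so 11/12/13 Hz are
  exactly resolvable and mutually orthogonal (integer cycles per epoch).
* **RLS harmonic estimation**: the filter recursively fits
  y(t) ≈ Σ aⱼcos(2πfⱼt) + bⱼsin(2πfⱼt) over the targets {11, 12, 13} Hz
  with exponential forgetting λ and reads out aⱼ − i·bⱼ at the epoch end
  (numba-compiled recursion, inverse-covariance initialization 10⁸).
  The default is λ = 1 (no forgetting), which makes the epoch-end readout
  the exact ordinary-least-squares projection — and, for integer-cycle
  epochs, the DFT bin; the test suite verifies this equivalence to 10⁻⁶.
  λ < 1 is supported down to 0.9, but note that the effective memory
  1/(1−λ) samples must remain ≳ 1 s of data for the 1 Hz-spaced targets to
  stay resolvable; at 2048 Hz, λ = 0.995 (memory ≈ 0.1 s) ill-conditions
  the joint 11/12/13 Hz design, which is why no-forgetting is the default.
* **Averaging**: complex coefficients are averaged across Oz/O1/O2, then
  vector-averaged across the 10 repeats. The vector standard error pools
  the real and imaginary sample variances: SE = √((s²_Re + s²_Im)/n).
  The analysis uses the modulus of the vector mean (coherent averaging),
  never the mean of moduli, so random-phase noise cancels as 1/√n.
* **SNR gate**: noise amplitude is the mean modulus of the vector-averaged
  11 and 13 Hz coefficients; SNR = signal/noise with an infinity sentinel
  at exactly zero noise. Epochs must exceed 3:1.
* **Threshold regression**: the scoring window runs from the
  highest-amplitude epoch passing the gate through the last subsequent
  passing epoch (the descending limb of the sweep response function); an
  OLS line of amplitude vs swept frequency over the window is extrapolated
  to zero amplitude. Windows with fewer than three epochs or a
  non-negative slope are flagged invalid with a reason token rather than
  producing a number. Group statistics exclude sVEP thresholds pairwise:
  an eye contributes only when both meridians' fits are valid.

Since the vector-mean modulus is non-negatively biased at low SNR (Rice
bias), amplitudes near the noise floor are slightly inflated and sweep-VEP
thresholds tend to overestimate — a known property of the method.

Measured behavior: on a 20-eye cohort at default noise, the median absolute
threshold-recovery error is below 1 cyc/deg and the strong-minus-weak
disparity sign is recovered in ≥ 90 % of eyes; with noise disabled the
recovery is exact to 10⁻⁶ cyc/deg.

## Statistics

Per-eye disparity = strong − weak, eyes treated as independent sampling
units (both eyes retained; a one-random-eye-per-subject mode exists for
sensitivity analyses). Paired contrasts are one-sample t on disparities
(df = n − 1); group contrasts are pooled-variance two-sample t
(df = n₁ + n₂ − 2); correlations are Pearson with two-sided p; Bonferroni
adjustment is min(1, p·m) applied within each group's metric family.
Degenerate inputs (zero variance, < 3 eyes) raise or, inside the report
builder, produce descriptive rows with NaN inferential columns. Under a
null cohort the paired contrast's type-I rate is 5 % ± 2 % (2000
replicates). Mixed-model (LMM) estimation is intentionally out of scope;
the per-eye disparity tables are exported so external tools can fit LMMs.

## Reproducibility and problem sizes

A single run seed fans out to per-eye/per-stage generators through
`SeedSequence([seed, stage, eye, …])`, so identical configs reproduce every
artifact bit-identically (checksummed in the run manifest) and any stage
can be re-run in isolation. Simulation sizes used by the shipped checks:
1000 × 200-trial staircases for the convergence level, 1000 × 80-trial
staircases for the reversal count, 500 staircases for estimator recovery,
a 20-eye cohort with 10 sweep repeats per meridian for sVEP recovery, and
2000 replicates for the type-I rate; the demo pipeline scales the cohort
and repeat counts down (the `demo_config` helper) while keeping all
distributions identical.

## Known limitations

* The generative CSF shape, Weibull slope, and linear amplitude-vs-frequency
  law are stand-ins; real eyes need not follow them, so passing recovery
  tests validates the *analysis chain*, not any claim about human data.
* Extrapolated CSF crossings (acuity/SF threshold beyond the measured grid)
  are biased, as described above; they are flagged, not corrected.
* The EEG generator omits artifacts, non-stationarity, electrode
  covariance, and alpha-band structure; SNR-gating behavior on real data
  will be harsher than in simulation.
* EEG serialization is a plain-text matrix + JSON sidecar; no EDF export.
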