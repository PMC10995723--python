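# Methods

## Signal model and estimation

A recording of an excitation test is modelled as three phases: quiet
baseline, a broadband forced transient during and just after the impact,
and a free vibration governed by one linear mode with viscous damping. Over
a window of the free phase the acceleration is

    a(t) = A1 e^(−t/τ) cos(ωt) + A2 e^(−t/τ) sin(ωt) + A3 + A4 t + A5 t²,

with angular frequency ω (rad/s), time constant τ (s; the envelope falls to
e⁻¹ ≈ 36.8% of its starting value at elapsed time τ), damped-component
coefficients A1, A2 (m/s²) and a quadratic trend A3–A5 absorbing sensor
drift. Only one mode is fitted; multi-modal responses are outside the
model and show up as elevated misfit.

The model is linear in A1–A5 for fixed (ω, τ), so fitting uses variable
projection: at every objective evaluation A1–A5 are solved exactly by least
squares over the design {e^(−t/τ)cos ωt, e^(−t/τ)sin ωt, 1, t, t²}, and a
Nelder–Mead simplex minimizes the RMS misfit ε over (log ω, log τ) — the
log parameterization enforces positivity without constraints. Nine starts
on a {0.5, 1, 2}² multiplicative grid around automated initial estimates
guard against local minima; ties are broken toward smaller τ, then smaller
ω. Convergence tolerances are 1e−10 on ε and 1e−8 on the log parameters,
with at most 2000 iterations per start. The fit is a deterministic function
of the window and options.

Initial estimates replace visual inspection: ω₀ from the dominant discrete
Fourier peak of the quadratically detrended window (falling back to π times
the zero-crossing rate), τ₀ from the slope of a line through the log of the
envelope peaks (falling back to the window duration when the envelope does
not decay).

### Misfit normalization

ε is the plain root-mean-square error of the printed formula, computed
after dividing the window by its standard deviation. This makes ε
scale-free: a pure-noise window fits at ε ≈ 1 regardless of gain, a clean
decaying sinusoid at signal-to-noise 10 fits at ε ≈ 0.1, and the
conventional acceptance threshold ε < 0.5 separates the two robustly.
Normalizing by peak |a| instead would compress pure-noise misfits to ≈ 0.3
(the RMS-to-peak ratio of Gaussian noise) and defeat the threshold, so the
standard-deviation convention is used throughout and ε is reported on that
scale; the A1–A5 written to output tables are rescaled to physical units.

## Window selection

Fitting windows must start after the forced transient rings down and end
when the signal sinks into the noise floor. The noise floor is the RMS of a
linearly detrended quiet span (≥ 10 ms, by default the pre-event segment).
The envelope operator is the magnitude of the analytic (Hilbert) signal
smoothed by a centered moving average of about one vibration period; the
nominal period is bootstrapped from the dominant spectral peak of the
ringing region after the |a| maximum (the span still clearing 5× the noise
floor), so trailing noise cannot widen the smoother.

The onset is chosen by three tiers, each covering a regime the previous one
cannot:

1. **Prominent dip.** A broadband burst shows several comparable envelope
   spikes with deep dips between them, while measurement noise cannot
   produce a ≥ 20% dip in the smoothed envelope; the last envelope minimum
   that is followed by a dominant rise (dip < 0.8 × the following maximum,
   with ≥ 10% prominence, and a post-dip peak carrying ≥ 10% of the overall
   envelope) marks the forced/free boundary, and the window starts at the
   post-dip peak.
2. **Rising hump top.** When the smoother merges the forced and free phases
   into one hump but the envelope still rises ≥ 10% after the |a| maximum,
   the free vibration dominates the hump and the window starts at its top.
3. **Crown shedding.** Otherwise the window starts where the envelope has
   shed half of its forced crown — for an impact-excited trace this sits at
   the forced/free boundary — refined to the first nearby envelope peak
   from which k (default 2) consecutive peaks are non-increasing.

The window ends at the first sample where the smoothed envelope drops below
`threshold_factor` (default 3) times the noise-floor RMS, walked back to
the last sample where the raw envelope itself still cleared the threshold
(the moving average lags a decaying edge by up to half its width, and that
lag would otherwise append pure noise and bias τ low). With a zero noise
floor the window is capped at the last nonzero sample. Detected windows can
be overridden per recording by a manual CSV of (recording_id, start_s,
end_s), mirroring how such windows are traditionally chosen by eye.

A window is fittable if it spans at least `min_cycles` (default 1) cycles
of a frequency hint, has at least two zero crossings, and holds at least 32
samples (the model has 7 parameters; windows near that size overfit
perfectly and mean nothing).

## Fit acceptance

A fit is accepted iff

1. ε < 0.5;
2. τ is smaller than the window duration (a τ outside the window is not
   observed, only extrapolated);
3. ω and τ are positive;
4. the window holds ≥ 1 full cycle of the *fitted* curve, and the curve
   completes ≥ 1 cycle within its own decay time (f·τ ≥ 1). The second
   clause is the quantitative reading of "a clear decaying sinusoid": a
   fit that dies before finishing one cycle is a transient spike, not a
   vibration mode. Without it, spike-chasing fits (hundreds of Hz with
   sub-millisecond τ) can pass criteria 1–3 on marginal windows and
   dominate group means;
5. frequency and τ lie within 3 sample SD of their group × excitation-type
   cell mean, computed in a single pass over the fits surviving 1–4. Cells
   with fewer than two survivors skip this filter and are flagged.

Every rejection records all violated criteria.

## Waveform metrics

Peak amplitude is max |a| over the whole event (forced + free) after
subtracting the pre-event mean, so DC offsets cannot inflate it. Total
vibration duration is the span over which the smoothed envelope exceeds
3× the noise-floor RMS; for a noise-free exponential envelope A₀e^(−t/τ)
and threshold θ this equals τ·ln(A₀/θ), which the implementation matches
within one smoothing period. Spatial attenuation compares per-clutch mean
peak amplitudes of pendulum impacts at 1 and 2 cm (absolute difference and
2 cm / 1 cm ratio; a ratio above 1 marks clutches where vibration is larger
farther from the impact).

## Group statistics

Group summaries are n / mean / SD (n−1) / range. Welch's unequal-variance
t-test is computed in closed form from summaries, so it applies equally to
raw measurements and to published summary tables; p-values are two-sided
and uncorrected. Reproductions of published t statistics from rounded
summaries agree to ~1e−3, not machine precision. Mixed-model analyses with
clutch as a random effect are deliberately out of scope; the pipeline
exports tidy per-recording tables for external model fitting.

## Synthetic recordings and cohorts

Each synthetic excitation test is quiet baseline + broadband transient
(white Gaussian burst with exponential envelope, time constant one third of
the transient duration — it exists only to exercise window detection) +
free vibration following the model exactly + quiet tail, with additive
white Gaussian noise throughout. The signal-to-noise convention is
SNR = RMS(noise-free free segment) / noise SD; amplitudes default to
A1 = A2 = 1 m/s² since absolute calibration is arbitrary. Generation is a
pure function of (spec, seed).

Cohorts draw one (frequency, τ) pair per clutch from truncated-normal group
distributions (reject non-positive, 100 retries) and a free-segment
duration per recording from the per-excitation window-length distributions
reported for the two study species, floored at one full vibration cycle —
the sampling rule of the original workflow, which only admitted windows
containing at least one cycle. Per-recording random streams are derived by
hashing (root seed, group, clutch, excitation, replicate), so cohorts are
reproducible and order-independent.

The two-species preset emulates the published study design: 16 stiff-clutch
(105.15 ± 36.7 Hz, τ 0.02 ± 0.02 s) and 17 soft-clutch (25.65 ± 26.06 Hz,
τ 0.10 ± 0.06 s) clutches, 4 excitation types × 5 replicates, SNR 10.
Limitations worth knowing:

- The published ± SDs are spreads across fitted excitation tests, but the
  preset (by design) places them entirely between clutches. For the
  soft-clutch group the SD exceeds the mean, so positive truncation shifts
  the realized group mean from 25.65 to ≈ 33 Hz and the expected
  between-group frequency ratio from ≈ 4.1 to ≈ 3.2, with a realization SD
  of ≈ 0.6 across 17-clutch cohorts. Group-contrast ratios from a single
  synthetic cohort therefore scatter widely even though estimation itself
  is unbiased (group mean frequency tracks the realized truth to < 1%).
- The τ-vs-window acceptance filter removes τ overestimates asymmetrically
  (an overestimate is more likely to exceed the window), which biases the
  accepted-fit mean τ of the fast-damping group low by ~10–15%; this is a
  property of the filter itself, not of the estimator.
- The generator's free segment stops abruptly at its nominal duration
  rather than decaying below the noise floor, so measured total durations
  are bounded by the segment length; at SNR 10 the absolute published
  durations (0.15 / 0.44 s) are not reproducible — they imply far higher
  recording SNR — but the ≈ 3× between-species duration contrast is.
- No multi-modal response, no frequency-dependent sensor response, no
  propagation physics: the generator realizes the single-mode assumption
  only, so passing recovery tests validate the estimation pipeline, not the
  biomechanics of real clutches.

## Problem sizes and numerical choices

Monte-Carlo studies run at a 4 kHz sample rate (Nyquist-safe for the
< 300 Hz modes of interest) rather than the 44.1 kHz of field recordings,
which the generator keeps as its default; this keeps the 660-recording
recovery study at about a minute on one CPU with no change in behavior at
the frequencies involved. Degenerate inputs are explicit errors: stereo or
non-finite recordings, rank-deficient designs (duplicated times), windows
with fewer than two zero crossings, empty groups, and both-zero-SD Welch
inputs. Byte-identical outputs for identical config + seed are part of the
pipeline contract.
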