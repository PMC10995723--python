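# clutchvibe

Time-domain modal analysis of egg-clutch vibration recordings.

Arboreal treefrog embryos (e.g. *Agalychnis callidryas* and *A. spurrelli*)
hatch prematurely when their egg clutch vibrates in a snake attack, so the
mechanical properties of the clutch — how it rings and how fast the ringing
dies — shape what information reaches the embryos. `clutchvibe` estimates
those properties from accelerometer recordings of standardized excitation
tests (pendulum impacts at 1 or 2 cm from the sensor, large/small water
drops): it locates the free-vibration segment of each trace, fits a damped
sinusoid to it, filters implausible fits, measures waveform-level amplitude
and duration, and compares groups. A synthetic-recording generator with
known ground truth backs every step with parameter-recovery validation.

## Model

The free vibration is assumed to be dominated by a single linear mode with
viscous damping, riding on a slow quadratic drift:

```
a(t) = A1 e^(−t/τ) cos(ωt) + A2 e^(−t/τ) sin(ωt) + A3 + A4 t + A5 t²
```

where `ω` (rad/s) is the angular frequency of the mode (`f = ω/2π`,
period `T = 2π/ω`), `τ` (s) is the time constant — the time for the
envelope to decay to e⁻¹ ≈ 36.8% of its starting value — and `A1…A5` are
amplitude/phase and trend coefficients in acceleration units.

Fitting is separable least squares: for any candidate `(ω, τ)` the
coefficients `A1–A5` are the exact linear least-squares solution, and a
Nelder–Mead simplex searches `(log ω, log τ)` to minimize the RMS misfit

```
ε = sqrt( (1/N) Σ |aₙ − ãₙ|² )
```

computed on the window scaled by its standard deviation, so that ε ≈ 0 is a
perfect fit, ε ≈ 1 is no better than a constant, and the conventional
acceptance threshold ε < 0.5 is gain-independent. Accepted fits must also
have `τ` shorter than the fitted window, positive parameters, at least one
full cycle of the fitted curve in the window and in its decay time, and
frequency/τ within 3 SD of their group × excitation cell.

## Worked example

Simulate a small two-species cohort, run the full pipeline, and look at the
recovery of the generating parameters:

```python
from clutchvibe import PipelineConfig, run_pipeline
from clutchvibe.synthetic_signals import species_cohort_spec

cohort = species_cohort_spec(seed=1, sample_rate_hz=4000.0, snr=10.0)
result = run_pipeline(PipelineConfig(out_dir="demo_out", cohort=cohort, seed=1))
print(result["counts"])
print(result["recovery"].per_parameter)
```

prints

```
{'recordings': 660, 'windows': 660, 'fits': 609, 'accepted': 273}
      parameter      bias  median_rel_error      rmse
0  frequency_hz  0.381224          0.000954  2.527938
1         tau_s  0.000220          0.022731  0.012976
```

i.e. of 660 simulated excitation tests (16 + 17 clutches × 4 excitation
types × 5 replicates), 609 windows produced fits and 273 survived the
acceptance filters; on those, the median frequency error is about 0.1% and
the median time-constant error about 2.3%. `demo_out/` holds tidy CSVs for
every stage (windows, fits with rejection reasons, waveform metrics,
attenuation per clutch, group statistics with Welch tests, and a run
manifest with stage counts).

The same pipeline runs from the shell:

```
clutchvibe run --config config.yaml
clutchvibe simulate --cohort config.yaml --out sim_out --seed 1
```

with exit code 2 for an invalid config and 3 when no fit survives the
filters.

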