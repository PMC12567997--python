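# ringppg

Design tooling for rotation-robust smart-ring PPG sensors.

A PPG ring rotates on the finger during wear. Because the light path from
the LED through the finger to the photodiode (PD) depends on where both
sit relative to the internal anatomy, rotation can silently destroy signal
quality. This package provides the computational side of designing a
layout that is robust to rotation:

- **Monte Carlo photon transport** through a layered cylindrical finger
  model (epidermis / dermis / microcirculation core with embedded vessels
  and bone), scoring each LED–PD layout by the fraction of detected light
  that traversed the capillary-rich microcirculation — the tissue believed
  to generate the pulsatile PPG component.
- **Layout sweep and ranking**: every (LED angle, PD angle) pair on a 30°
  grid (12 × 12 combinations = 12 LED–PD angles Δ at 12 rotational
  positions each); averaging the traversal fraction over the positions
  sharing one Δ scores that layout's rotation robustness.
- **Signal-quality indices** on 6-s PPG segments — pulse amplitude AC,
  DC, perfusion index PI = AC/DC, SNR, spectral skewness/kurtosis
  S_PSD/K_PSD, and the periodicity dispersions STD_periods/STD_peaks from
  the normalized autocorrelation — combined into the figure of merit

      FoM = (PI · AC · S_PSD · K_PSD) / (STD_periods · STD_peaks)

  on per-session min–max-normalized indices.
- **Heart rate** from PPG: 0.5–8 Hz band-pass, adaptive-threshold systolic
  peak detection, HR = 60 / mean inter-beat interval, plus MAE scoring
  against a reference.
- **Synthetic PPG generator** with ground truth (beat times, HR, AC/DC,
  controllable noise and motion artifacts), so the whole signal path is
  testable without recorded data.
- **Front-end calculators** for the ring hardware: LED duty cycle, ON-time
  budget, TIA settling and compensation, effective bandwidth, module
  current budget and battery life.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Score one layout against rotation at 940 nm with the packaged default
finger model (desk-scale photon budget):

```python
from ringppg import build_default_finger, TransportConfig
from ringppg.sweep import sweep, aggregate_by_angle, rank_angles

model = build_default_finger((940,))
table = sweep(model, 940, TransportConfig(n_photons=10_000, seed=1), grid_step=30)
for agg in aggregate_by_angle(table)[:3]:
    print(f"delta {agg.delta:5.0f}: mean {agg.mean_fraction:.3f} "
          f"sd {agg.dispersion:.3f} n {agg.n_valid}")
```

prints

```
delta     0: mean 0.022 sd 0.002 n 12
delta    30: mean 0.584 sd 0.062 n 12
delta    60: mean 0.969 sd 0.053 n 12
```

i.e. with LED and PD co-located (Δ = 0°) only ~2% of the detected light
ever entered the microcirculation (it shortcuts through the superficial
layers), while at Δ = 60° nearly all of it did — the reason separated
layouts read the pulsatile tissue. Ranking the bundled large-photon-count
reference table picks Δ = 60° as the optimum at all three wavelengths
(550, 628, 940 nm).

The signal path and hardware budget from the command line:

```bash
ringppg synth --hr 72 --duration 60 --seed 1 --out ppg.csv --truth truth.json
ringppg hr --in ppg.csv --out hr.csv
ringppg sqi --in ppg.csv --out sqi.json
ringppg budget --config budget.yaml --out budget.json
```

With the six-module current budget (201 + 157 + 179 + 21 + 1.5 + 35 μA)
and a 22 mAh battery, `budget` prints

```
total 594.5 uA, lifetime 37.0 h, duty cycle 0.70%
```

— a 0.59 mA average system current and more than 30 h of continuous
acquisition, with the LED ON window of 70 μs (30 ADC + 20 TIA + 10 LED/PD
setup + 10 margin) at a 100 Hz firing rate giving each LED a 0.7% duty
cycle.

On a clean 60-s synthetic recording at 72 bpm, `ringppg hr` recovers the
true rate to well within 1 bpm (the 11 windowed estimates in `hr.csv` span
71.7–72.6 bpm; the record's beat-interval jitter is real, 2% HRV).

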