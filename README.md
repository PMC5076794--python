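# bsmap — Bloch–Siegert B1+ mapping for multi-peak MR spectroscopy

Quantitative X-nuclear spectroscopy (³¹P-MRS of the human heart at 7 T being
the motivating case) is usually performed with surface coils whose transmit
field B1+ varies severalfold across the tissue of interest.  Without a
per-subject B1+ map, partial-saturation corrections — and hence metabolite
concentrations — cannot be computed.  Magnitude-based flip-angle methods
(multi-TR, dual-TR, AFI) need long scans and known metabolite T1 values,
which change in disease.  Bloch–Siegert mapping instead encodes B1+ in the
*phase* of each spectral peak and is therefore fast and T1-insensitive.

`bsmap` implements the full simulation-to-map pipeline for this method:

* **Sensitizing pulse design** (`bsmap.pulses`, `bsmap.blochsim`): Fermi
  envelopes `1/(1+exp((|t|−T₀)/a))`, a hard-pulse Bloch integrator, the
  stop-band deviation metric `ΔM_xy = (1/1000)·Σ_{ω=1500}^{2500} |M_xy(ω)|²`,
  and the grid search that selects the shortest pulse keeping `ΔM_xy` below
  threshold for all γB1 in 100–1000 Hz.
* **Phase-based estimators** (`bsmap.estimators`): an off-resonance pulse at
  offset ω_RF from a peak adds the phase

      φ_BS = π (γB1⁺_peak)² B̃ / ω_RF ,   B̃ = ∫|envelope(t)|² dt ,

  inverted by four acquisition strategies — dual-acquisition ± (A), on/off
  single-peak (B′), on/off multi-peak with inverse-variance pooling (B″),
  and single-acquisition pairwise differences (C) — with first-order error
  propagation, wrap-safe complex-division phase differences, manual
  unwrapping, CRLB-based voxel masking, and NIfTI map export.
* **Monte Carlo framework** (`bsmap.montecarlo`): per-peak phase noise at
  the Cramér–Rao bound of a damped complex-exponential fit (Fisher-matrix
  CRLB_φ/√N), bias (ε_B) and coefficient-of-variation surfaces per strategy.
* **Synthetic spectra and fitting** (`bsmap.spectra`): multi-peak 7 T ³¹P
  FIDs (PCr 0 Hz, γ/α/β-ATP at −300/−900/−1950 Hz, ATP multiplets with
  J = 16.3 Hz), AMARES-style time-domain prior-knowledge fitting with CRLBs,
  and the reference flip-angle methods (multi-TR/dual-TR saturation fits,
  multi-flip-angle sine fit).
* **Phantom and CSI simulation** (`bsmap.phantom`): Biot–Savart loop-coil
  fields, 3D CSI acquisition of box phantoms (ideal-voxel or
  acquisition-weighted PSF mode), and the intravoxel isochromat analysis of
  phase dispersion across large CSI voxels.

## Worked example

```python
import math
import bsmap

pulse = bsmap.optimized_fermi_pulse()          # TP=3.5 ms, T0=0.875 ms, a=0.224 ms
btilde = bsmap.normalized_squared_integral(pulse)
model = bsmap.BSPhaseModel(b_tilde=btilde, omega_rf=2000.0)

print(f"B-tilde = {btilde*1e3:.4f} ms")
for dphi in (55.6, 86.9):
    est = bsmap.estimate_A(math.radians(dphi), model)
    print(f"delta-phi = {dphi:5.1f} deg  ->  gamma-B1+ = {est.gamma_b1:6.1f} Hz")
print(f"dynamic range (pi)  = {bsmap.dynamic_range(model, math.pi):6.1f} Hz")
print(f"dynamic range (2pi) = {bsmap.dynamic_range(model, 2*math.pi):6.1f} Hz")
```

prints

```
B-tilde = 1.3197 ms
delta-phi =  55.6 deg  ->  gamma-B1+ =  483.8 Hz
delta-phi =  86.9 deg  ->  gamma-B1+ =  604.8 Hz
dynamic range (pi)  =  870.5 Hz
dynamic range (2pi) = 1231.1 Hz
```

i.e. a 55.6° phase difference between the +2 kHz and −2 kHz acquisitions of
a quadriceps voxel corresponds to γB1+ = 484 Hz, and the principal-value
phase difference maps fields up to 871 Hz (1231 Hz after one manual unwrap).

The command line exposes the same pipelines (`bsmap --help`):

```bash
bsmap demo --outdir demo/        # synthetic phantom -> B1+ map -> report
bsmap fermi-design --out pulse.csv
bsmap bloch-profile --pulse pulse.csv --b1 500 --offsets -5000:5000:50 --out profile.csv
bsmap mc-compare --snr 31 --out strategies.csv
```

`bsmap demo` simulates a uniform phantom seen by a 10-cm loop, reconstructs
the Method A map from the ±2 kHz arms, and reports the worked-example
inversions together with the maximum map-vs-truth error (≈1e-13 % for the
noiseless ideal-voxel scene).

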