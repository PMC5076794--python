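# Methods

## The Bloch–Siegert phase model

During an off-resonance RF pulse the Larmor frequency of a spin shifts
transiently; over the pulse duration a transverse spin accumulates the extra
phase

    φ_BS = 2π ∫ (γB1⁺(t))² / (2 ω_RF) dt = π (γB1⁺_peak)² B̃ / ω_RF ,

where ω_RF is the frequency offset from the pulse to the resonance (Hz) and
B̃ = ∫|f(t)|²dt is the squared integral of the unit-peak envelope.  The
expression is the leading term of the effective-field expansion
√(ω² + γB1²) ≈ |ω| + γB1²/2|ω| and holds in the linear regime
|ω_RF| ≫ γB1; `bs_phase` warns below |ω_RF| < 3·γB1.  All of B1 is quoted
as a nutation frequency γB1 in Hz (γ(³¹P) = 17.235 MHz/T is carried for
conversions to tesla).

Sign conventions: a positive resonance offset precesses in the positive
sense, FIDs are synthesized as `e^{+i2πft}`, and φ_BS carries the sign of
ω_RF (peak minus pulse).  Under this convention the acquisition with the
pulse *below* the peak gains positive phase; scanner reconstruction
pipelines that conjugate the FID report the opposite labeling, which is why
the map reconstruction defines its phase difference so that the published
worked examples come out positive.  Only phase differences enter any
estimator, so the choice is internally consistent and externally documented.

## Estimators and uncertainty

Four acquisition strategies invert φ_BS:

| id | scans | data | γB1² expression |
|----|-------|------|-----------------|
| A  | 2 (±ω) | 1 peak | Δφ·ω / (2π B̃) |
| B′ | 2 (on/off) | 1 peak | (φ_on−φ_off)·ω / (π B̃) |
| B″ | 2 (on/off) | n peaks | inverse-variance pool of per-peak γB1², weights ω_i⁻² |
| C  | 1 | n peaks | pool over pairs (φ_j−φ_i)/(πB̃(ω_j⁻¹−ω_i⁻¹)), weights (ω_j⁻¹−ω_i⁻¹)² |

The multi-peak combinations are maximum-likelihood pools under equal phase
variances; both reduce exactly to their single-peak/single-pair forms.  A
negative combined γB1² (low field or uncorrected wrap) yields an *invalid*
estimate, never a complex number.  Method C additionally assumes zeroth- and
first-order spectral phase have been corrected by the caller; no correction
algorithm is provided.

Uncertainty propagates to first order, Δq = √Σ(∂q/∂φ_i · Δφ_i)², evaluated
by central differences of the exact estimator expression (step 1e-7 rad);
Method A also has a closed form used as a cross-check.  First-order
propagation is exact only up to O((Δφ/φ_BS)²): Monte Carlo SDs exceed it by
that ratio when the accumulated phase is small (e.g. +3% for the on/off
strategy at ω = 3000 Hz, γB1 = 200 Hz).  Tests therefore assert
standard-error-level agreement in the linear regime and percent-level
agreement elsewhere.

Two noise-accounting conventions matter when comparing strategies:

* The on/off comparison treats the pulse-off reference phase as noise-free
  (a fully characterized baseline).  Under that accounting B′ is exactly √2
  less precise than A; with an equally noisy reference the factor is 2.
  The package exposes both (`MCConfig.reference_noise`), defaulting to the
  noisy-reference (conservative) model, and uses the noiseless-reference
  accounting for the published √2 relation.
* Method C with the pulse midway between two peaks measures the same phase
  difference as Method A in half the scans; granting its single acquisition
  the full scan time (phase SD / √2 via `n_scans=2`) yields the √2
  precision advantage.

The per-phase noise floor is the Cramér–Rao bound of the phase of a damped
complex-exponential model (parameters per peak: amplitude, frequency,
Lorentzian FWHM, phase) under white complex Gaussian noise, computed from
the analytic Fisher matrix and divided by √N for N-scan averages.
`noise_sd` is the per-quadrature SD per time point throughout.

## Sensitizing-pulse design

The Fermi envelope f(t) = 1/(1+exp((|t|−T₀)/a)) is sampled on a centered
grid (default dt = 1 µs for synthesis; 5 µs inside the grid search, which
changes the stop-band metric by <1%).  The integrator applies one rotation
per sample *interval* using midpoint envelope values, so the simulated
duration is exactly TP; a resolution guard rejects >36° rotation per step.

The design metric sums residual transverse excitation from equilibrium over
a 1500–2500 Hz stop-band, `ΔM_xy = (1/1000)·Σ|M_xy(ω)|²`, literally at 1 Hz
spacing (1001 points); coarser grids are rescaled by 1001/count.  The grid
search scans TP = 1–10 ms (step 0.5), T₀ = 0.1–0.5·TP (step 0.05·TP),
a = 0.01–0.3·TP (step 0.001·TP) and γB1 = 100–1000 Hz (step 100),
aggregates across γB1 as the worst case (mean available), and returns the
shortest TP whose minimal aggregated metric is below threshold (default
0.01; the threshold's published scale is ambiguous between fraction and
percent, so it is configuration).  Argmin ties resolve to the first cell in
row-major order.

On this package's metric the TP = 3.5 ms slice selects T₀ = 0.875 ms and
a = 0.2065 ms.  The a-direction of the surface is very shallow: the
0.224 ms cell quoted for the original design sits within ~10% of the
minimum metric, and the 0.2065 ms argmin is stable against dt (5→2 µs),
offset sampling (101→1001 points), integration rule and aggregation choice.
Both pulses satisfy the design threshold with an order of magnitude to
spare.

## Direct excitation

`direct_excitation_error` simulates a noiseless acquisition per strategy
arm: an ideal excitation of flip α (default 30°, the Ernst angle of the
TR = 0.5 s cardiac protocol) leaves a longitudinal residue cos α that the
sensitizing pulse can tip into the transverse plane; the perturbed peak
phases (read against a pulse-off reference) are fed to the estimator.  The
bias depends strongly on α — the interference term scales roughly with
cot α — and on the spin-vs-RF phase at the pulse start, both of which are
explicit parameters.  For the 1950 Hz two-peak split (ω = ∓975 Hz) at
γB1 = 277 Hz the error is ≈1% at α = 90°, ≈11% at α = 30° (≈20% in the
phase/B1² domain), and ≈18% at α = 20°; at the ±2 kHz offsets of the
dual-acquisition protocol it stays below 0.3%.

## Synthetic spectra and fitting

FIDs are sums of Lorentzian lines, `a·e^{iφ}·exp((2πif − π·lw)t)`, with
`lw` the FWHM in Hz; the default acquisition is 2048 points at 6 kHz.
Multiplets (ATP doublets 1:1, triplet 1:2:1, J = 16.3 Hz — literature
conventions, configurable) share one amplitude scale, frequency, width and
phase, which is exactly the equality-constraint structure the AMARES-style
time-domain least-squares fit imposes; per-peak `fixed` flags freeze
individual parameters.  CRLBs come from the Fisher matrix at the solution
with the noise SD estimated from the residual unless supplied.  Spectral
amplitude SNR is defined as tallest-peak height over spectral noise SD
(σ_t·√N for white time-domain noise), and `noise_sd_for_snr` calibrates the
stated 18/31/44 study conditions.  The published strategy-comparison table
cannot be reproduced cell-for-cell because its phase-noise inputs derive
from an unpublished study-mean lineshape; at a phase SD of 0.0451 rad the
Method A condition reproduces the published ±28 Hz precision, and our MC
bias is small and *negative* (the sqrt estimator is concave), whereas the
published biases are positive — treated as an inconsistency of the source
table, not a target.

The reference methods fit the steady-state saturation model
S = M₀ sinθ (1−E)/(1−E cosθ), E = e^{−TR/T1}: jointly over (θ, M₀) for the
eight-TR protocol (multi-start in θ to avoid the supplementary-angle
ambiguity), by bracketed root finding of the two-TR signal ratio, and by a
two-parameter A·sin(360°·c·V·TP) fit of the fully-relaxed voltage sweep
(multi-start in c because the sine fit has local minima between signal
nulls; sweeps confined below 30° flip trigger an ill-conditioning warning).
Magnitude data are used as-is; the Rician noise floor is ignored, which is
justified at validation SNRs but would bias very low-SNR fits.

## Coil field, CSI simulation and intravoxel dispersion

The loop coil is integrated by Biot–Savart over ≥90 straight segments
(360 default; on-axis agreement with the closed form R²/(R²+z²)^{3/2} to
1e-6).  The field *magnitude* serves as γB1⁺, assuming the coil axis is
perpendicular to B0 as for a chest surface coil, and the receive weight
B1⁻ is proportional to it by reciprocity.  Calibration pins γB1 at a named
reference point, matching how field values are quoted in practice.

`simulate_csi` computes, per voxel, per spectral line, the complex
amplitude Σ_r sin(flip(r))·sat(r)·B1⁻(r)·e^{iφ_BS(r)} over isochromats in
the signal compartments.  The default one-isochromat-per-voxel "ideal
voxel" mode matches how measured maps quote a single value per voxel and
makes the noiseless ±2 kHz round trip exact inside the dynamic range;
`subdivision>1` adds intravoxel B1-spread physics, and `mode="psf"`
convolves the voxel grid with the point spread of the (Hanning-shaped,
k₀-average-scaled) acquisition weighting.  Map reconstruction extracts peak
phases by matched-filter projection onto the known lineshape (exact for
noiseless single-resonance voxels; the AMARES fit is available when noise
or overlap matters), forms the wrap-safe phase difference, and applies the
Method A inversion with CRLB/negative-difference masking.

The intravoxel analysis places a grid of isochromats (default 64³, scaled
from much denser production analyses; 48³ vs 64³ agree within 1%) across
one voxel, gives each the dual-acquisition phase difference 2φ_BS(local
γB1) and a receive weight ∝ local field, and reports the SNR drop
1 − |Σw e^{iΔφ}|/Σw plus the deviation of the phase-model-inverted summed-signal
phase from the weighted-mean field.  For the cardiac-protocol voxel
(30×25×15 mm) 10 cm on-axis from a 10-cm loop this box-voxel reading gives
a 34% drop at a 1000 Hz voxel center (2.4% at 500 Hz) and <1% weighted-mean
deviation.  A published figure of ~50% at 1000 Hz is reproducible only with
a wider effective voxel (the acquisition-weighted spatial response roughly
doubles the voxel extent and raises the drop to ~75%) or lateral voxel
placement (~4.5 cm off-axis gives 46%); the literal box-voxel contract is
the default and the sensitivity is reported rather than hidden.

## Synthetic data: what it does and does not emulate

The generators cover multi-peak Lorentzian ³¹P spectra with white complex
Gaussian noise at calibrated SNR, Bloch–Siegert phase offsets, partial
saturation, surface-coil falloff and CSI voxelization.  They do not model
B0 inhomogeneity or eddy-current phase, non-Lorentzian lineshapes, chemical
exchange during the pulse, motion, or coil loading differences between
subjects.  Passing tests therefore demonstrate correctness of the
estimators and simulators under the stated physics, not robustness to every
in vivo confound; the T1-insensitivity of the method itself is what removes
the largest such confound by construction.

## Numerical choices

* Bloch integration: Rodrigues rotations about the per-interval effective
  field; exact for piecewise-constant envelopes; norm conserved to 1e-9.
* Grid search runtime: the full TP = 3.5 ms slice (9×291 shapes × 10 fields
  × 101 offsets) runs in ~1 minute via chunked vectorized propagation.
* Monte Carlo: `numpy.random.default_rng` (PCG64), fully seeded; invalid
  draws excluded from moments and reported.  Test suites use 2×10⁵ draws
  (SD standard error ≈0.16%); the config default is 10⁶.
* Fits: `scipy.optimize.least_squares` (LM for small problems, TRF with
  bounds otherwise), `brentq` for the two-TR ratio.
* Degenerate inputs raise `ParameterError` naming the violated invariant;
  estimator-level invalidity (negative γB1²) is a flagged result instead.
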