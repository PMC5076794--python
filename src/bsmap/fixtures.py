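"""Self-contained synthetic inputs for tests, demos and worked examples.

Everything here is generated programmatically from a seed; no scanner data
is required anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import phantom, pulses, spectra
from .estimators import BSPhaseModel
from .pulses import PulseShape


@dataclass
class FixtureBundle:
    """Worked-example inputs used across the test suite and the demo."""

    pulse: PulseShape
    b_tilde: float
    model_2khz: BSPhaseModel
    phase_pairs_deg: tuple          # published worked-example phase diffs
    point_source_csi: dict          # small 4x4x4 point-source scene, +/- arms
    uniform_csi: dict               # uniform-box scene, +/- arms
    method_c_peaks: tuple           # pulse-to-peak offsets of the 1950 Hz split
    seed: int


def make_fixtures(seed: int = 0, small: bool = True) -> FixtureBundle:
    """Build the fixture bundle; identical seeds give identical bundles.

    ``small=True`` keeps the CSI grids tiny (4x4x4 and 8x4x4) so the full
    suite stays fast; the acceptance pipeline builds the full 16x8x8 grid
    itself.
    """
    pulse = pulses.optimized_fermi_pulse()
    btilde = pulses.normalized_squared_integral(pulse)
    model = BSPhaseModel(b_tilde=btilde, omega_rf=2000.0)

    coil = phantom.LoopCoil(reference_point=(0.0, 0.0, 0.10),
                            reference_gamma_b1=600.0)

    ps_protocol = phantom.CSIProtocol(
        matrix=(4, 4, 4), fov=(0.080, 0.080, 0.080), tr=10.0,
        excitation_tp=200e-6, n_points=512, grid_center=(0.0, 0.0, 0.10))
    ps_scene = phantom.point_source_scene(center=(0.0, 0.0, 0.10))
    point_source = {
        arm: phantom.simulate_csi(ps_scene, ps_protocol, coil,
                                  pulse=pulse, pulse_offset=off)
        for arm, off in (("plus", +2000.0), ("minus", -2000.0))
    }

    uni_matrix = (8, 4, 4) if small else (8, 8, 16)
    uni_protocol = phantom.CSIProtocol(
        matrix=uni_matrix, fov=(0.320, 0.320, 0.150), tr=0.5,
        excitation_tp=300e-6, n_points=512, grid_center=(0.0, 0.0, 0.105))
    uni_scene = phantom.uniform_box_scene(size=(0.27, 0.27, 0.12),
                                          center=(0.0, 0.0, 0.105))
    uniform = {
        arm: phantom.simulate_csi(uni_scene, uni_protocol, coil,
                                  pulse=pulse, pulse_offset=off)
        for arm, off in (("plus", +2000.0), ("minus", -2000.0))
    }

    return FixtureBundle(
        pulse=pulse,
        b_tilde=btilde,
        model_2khz=model,
        phase_pairs_deg=(55.6, 86.9),
        point_source_csi=point_source,
        uniform_csi=uniform,
        method_c_peaks=(-975.0, +975.0),
        seed=seed,
    )


def snr_calibrated_fid(snr: float, seed: int,
                       model: spectra.SpectrumModel | None = None) -> spectra.FID:
    """A 2048-point, 6 kHz 31P FID at a target spectral amplitude SNR."""
    model = model or spectra.cardiac_31p_model()
    sd = spectra.noise_sd_for_snr(model, snr)
    return spectra.synthesize_fid(model, noise_sd=sd, seed=seed)
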