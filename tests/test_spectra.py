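"""FID synthesis, prior-knowledge fitting, saturation reference methods."""

import math

import numpy as np
import pytest

from bsmap import montecarlo as mc
from bsmap import spectra as sp
from bsmap.pulses import ParameterError
from bsmap.spectra import (
    Peak,
    SaturationModel,
    SpectrumModel,
    cardiac_31p_model,
    ernst_angle_deg,
    fit_amares,
    fit_dual_tr,
    fit_multi_fa,
    fit_multi_tr,
    noise_sd_for_snr,
    saturation_signal,
    single_peak_model,
    synthesize_fid,
)


class TestSynthesizeFid:
    def test_noiseless_peak_lands_on_its_offset_bin(self):
        model = single_peak_model(offset=-900.0, damping=25.0)
        fid = synthesize_fid(model, n_points=2048, bandwidth=6000.0)
        freqs, spec = fid.spectrum()
        assert freqs[np.argmax(np.abs(spec))] == pytest.approx(-900.0, abs=3.0)

    def test_seed_controls_noise_only(self):
        model = cardiac_31p_model()
        a = synthesize_fid(model, noise_sd=0.01, seed=1)
        b = synthesize_fid(model, noise_sd=0.01, seed=2)
        clean = synthesize_fid(model)
        assert not np.allclose(a.samples, b.samples)
        # noiseless parts identical: the difference is pure noise
        assert np.std((a.samples - clean.samples).real) == pytest.approx(
            0.01, rel=0.1)
        assert np.array_equal(
            synthesize_fid(model, noise_sd=0.01, seed=1).samples, a.samples)

    def test_aliasing_warns(self):
        with pytest.warns(UserWarning, match="alias"):
            synthesize_fid(single_peak_model(offset=4000.0), bandwidth=6000.0)

    def test_snr_calibration_over_seeds(self):
        """Requested spectral amplitude SNR is realized within 5%
        (empirical check over 100 noise draws at each condition)."""
        model = cardiac_31p_model()
        height = sp.spectrum_peak_height(model)
        for snr in (18.0, 31.0, 44.0):
            sd = noise_sd_for_snr(model, snr)
            realized = []
            for seed in range(100):
                fid = synthesize_fid(model, noise_sd=sd, seed=seed)
                _, spec = fid.spectrum()
                # noise region far from all peaks (positive frequencies)
                sel = fid.spectrum()[0] > 1200.0
                realized.append(height / np.std(spec[sel].real))
            assert np.mean(realized) == pytest.approx(snr, rel=0.05)

    def test_multiplet_ratios_default_binomial(self):
        triplet = Peak("beta-ATP", -1950.0, n_lines=3, j_hz=16.3)
        deltas, ratios = triplet.line_pattern()
        assert np.allclose(deltas, [-16.3, 0.0, 16.3])
        assert np.allclose(ratios, [0.25, 0.5, 0.25])


class TestFitAmares:
    def test_noiseless_fit_recovers_exactly(self):
        model = cardiac_31p_model()
        fid = synthesize_fid(model)
        fit = fit_amares(fid, model)
        # residual below 1e-8 of the signal energy
        assert fit.residual_norm < 1e-8 * np.linalg.norm(fid.samples)

    def test_perturbed_prior_converges_to_truth(self):
        truth = single_peak_model(offset=-300.0, amplitude=2.0, damping=35.0,
                                  phase=0.4)
        fid = synthesize_fid(truth)
        prior = single_peak_model(offset=-280.0, amplitude=1.0, damping=25.0,
                                  phase=0.0)
        fit = fit_amares(fid, prior)
        p = fit.model.peaks[0]
        assert p.offset == pytest.approx(-300.0, abs=1e-4)
        assert p.amplitude == pytest.approx(2.0, rel=1e-6)
        assert p.phase == pytest.approx(0.4, abs=1e-6)

    def test_peak_order_invariance(self):
        model = cardiac_31p_model()
        fid = synthesize_fid(model, noise_sd=0.005, seed=4)
        fit_fwd = fit_amares(fid, model)
        swapped = SpectrumModel(peaks=tuple(reversed(model.peaks)))
        fit_rev = fit_amares(fid, swapped)
        by_name_fwd = {p.name: p.phase for p in fit_fwd.model.peaks}
        by_name_rev = {p.name: p.phase for p in fit_rev.model.peaks}
        for name in by_name_fwd:
            assert by_name_fwd[name] == pytest.approx(by_name_rev[name],
                                                      abs=1e-6)

    def test_fixed_parameters_stay_fixed(self):
        truth = single_peak_model(offset=-300.0, damping=35.0)
        fid = synthesize_fid(truth)
        prior = SpectrumModel(peaks=(Peak("Pi", -295.0, damping=30.0,
                                          fixed=("damping",)),))
        fit = fit_amares(fid, prior)
        assert fit.model.peaks[0].damping == 30.0
        assert fit.crlb["Pi"]["damping"] == 0.0

    def test_phase_scatter_attains_crlb(self, btilde):
        """Over 100 noisy realizations at SNR 18 the fitted PCr phase SD is
        within 20% of the Fisher-matrix bound."""
        model = cardiac_31p_model()
        n_points, bw = 512, 6000.0
        sd = noise_sd_for_snr(model, 18.0, n_points=n_points, bandwidth=bw)
        bound = mc.crlb_phase(model, sd, 1 / bw, n_points)[0]
        phases = []
        for seed in range(100):
            fid = synthesize_fid(model, n_points=n_points, bandwidth=bw,
                                 noise_sd=sd, seed=seed)
            fit = fit_amares(fid, model, noise_sd=sd)
            phases.append(fit.model.peaks[0].phase)
        scatter = np.std(phases, ddof=1)
        assert scatter == pytest.approx(bound, rel=0.20)
        # and the estimates are unbiased within MC error
        assert np.mean(phases) == pytest.approx(
            0.0, abs=3 * scatter / math.sqrt(len(phases)))


class TestSaturation:
    def test_fully_relaxed_limit(self):
        s = saturation_signal(SaturationModel(theta_deg=37.0, tr=100.0, t1=1.0,
                                              m0=2.0))
        assert s == pytest.approx(2.0 * math.sin(math.radians(37.0)), rel=1e-9)

    def test_90deg_tr_equals_t1(self):
        s = saturation_signal(SaturationModel(theta_deg=90.0, tr=3.0, t1=3.0))
        assert s == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_ernst_angle_maximizes_signal(self):
        tr, t1 = 0.5, 3.09
        thetas = np.linspace(1.0, 120.0, 2000)
        signals = [saturation_signal(SaturationModel(th, tr, t1))
                   for th in thetas]
        assert thetas[int(np.argmax(signals))] == pytest.approx(
            ernst_angle_deg(tr, t1), abs=0.1)

    def test_monotone_in_tr_below_90deg(self):
        sigs = [saturation_signal(SaturationModel(60.0, tr, 2.0))
                for tr in (0.3, 1.0, 3.0, 10.0)]
        assert np.all(np.diff(sigs) > 0)


class TestMultiTR:
    TRS = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)  # phantom protocol
    T1 = 8.57

    def _signals(self, theta, m0=1.7):
        return [saturation_signal(SaturationModel(theta, tr, self.T1, m0))
                for tr in self.TRS]

    @pytest.mark.parametrize("theta", [12.0, 52.3, 120.0])
    def test_noiseless_round_trip(self, theta):
        res = fit_multi_tr(self._signals(theta), self.TRS, self.T1,
                           tp_exc=300e-6)
        assert res["theta_deg"] == pytest.approx(theta, rel=1e-6)
        assert res["gamma_b1_hz"] == pytest.approx(theta / (360 * 300e-6),
                                                   rel=1e-6)

    def test_scale_invariance(self):
        a = fit_multi_tr(self._signals(40.0, m0=1.0), self.TRS, self.T1)
        b = fit_multi_tr(np.array(self._signals(40.0, m0=1.0)) * 7.5,
                         self.TRS, self.T1)
        assert b["theta_deg"] == pytest.approx(a["theta_deg"], rel=1e-9)
        assert b["m0"] == pytest.approx(7.5 * a["m0"], rel=1e-6)

    def test_small_noise_small_bias(self):
        """1% signal noise over the 8-TR protocol biases theta < 1%
        (100 noise draws)."""
        rng = np.random.default_rng(42)
        clean = np.array(self._signals(52.3))
        thetas = []
        for _ in range(100):
            noisy = clean * (1 + 0.01 * rng.standard_normal(len(clean)))
            thetas.append(fit_multi_tr(noisy, self.TRS, self.T1)["theta_deg"])
        assert abs(np.mean(thetas) - 52.3) / 52.3 < 0.01

    def test_degenerate_trs_rejected(self):
        with pytest.raises(ParameterError):
            fit_multi_tr([1.0, 1.0], [2.0, 2.0], self.T1)

    def test_agrees_with_dual_tr_on_two_points(self):
        sigs = self._signals(33.0)
        dual = fit_dual_tr(sigs[0], sigs[5], self.TRS[0], self.TRS[5], self.T1)
        multi = fit_multi_tr([sigs[0], sigs[5]], [self.TRS[0], self.TRS[5]],
                             self.T1)["theta_deg"]
        assert dual == pytest.approx(multi, rel=1e-5)


class TestDualTR:
    def test_round_trip(self):
        t1 = 1.8  # alpha-ATP literature value used in vivo
        s1 = saturation_signal(SaturationModel(30.0, 2.2, t1))
        s2 = saturation_signal(SaturationModel(30.0, 0.37, t1))
        assert fit_dual_tr(s1, s2, 2.2, 0.37, t1) == pytest.approx(30.0,
                                                                   rel=1e-6)

    def test_equal_trs_rejected(self):
        with pytest.raises(ParameterError):
            fit_dual_tr(1.0, 1.0, 0.5, 0.5, 1.8)

    def test_unattainable_ratio_raises(self):
        with pytest.raises(ValueError, match="attainable"):
            fit_dual_tr(100.0, 1.0, 2.2, 0.37, 1.8)

    def test_small_angle_limit_matches_expansion(self):
        # as theta -> 0 the ratio tends to (1-E1)(1-E2 c)/... evaluated at
        # c ~ 1; generate at 2 degrees and recover
        t1 = 1.8
        s1 = saturation_signal(SaturationModel(2.0, 2.2, t1))
        s2 = saturation_signal(SaturationModel(2.0, 0.37, t1))
        assert fit_dual_tr(s1, s2, 2.2, 0.37, t1) == pytest.approx(2.0,
                                                                   rel=1e-4)


class TestMultiFA:
    def test_noiseless_round_trip_through_nulls(self):
        """The 10-200 V sweep passes the signal null (flip > 180 deg), which
        pins the B1-per-volt scale unambiguously."""
        volts = np.linspace(10.0, 200.0, 20)
        c_true, tp = 1.8, 4e-3  # ~520 deg max flip
        amps = 2.5 * np.sin(2 * np.pi * c_true * volts * tp) * np.exp(1j * 0.9)
        res = fit_multi_fa(amps, volts, tp)
        assert res["b1_per_volt_hz"] == pytest.approx(c_true, rel=1e-6)
        assert res["max_amplitude"] == pytest.approx(2.5, rel=1e-6)

    def test_global_receiver_phase_is_irrelevant(self):
        volts = np.linspace(10.0, 200.0, 20)
        base = 1.0 * np.sin(2 * np.pi * 1.5 * volts * 4e-3)
        c0 = fit_multi_fa(base, volts, 4e-3)["b1_per_volt_hz"]
        c1 = fit_multi_fa(base * np.exp(1j * 2.1), volts, 4e-3)["b1_per_volt_hz"]
        assert c1 == pytest.approx(c0, rel=1e-9)

    def test_linear_region_warns(self):
        volts = np.linspace(1.0, 5.0, 10)
        amps = np.sin(2 * np.pi * 1.0 * volts * 4e-3)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            fit_multi_fa(amps, volts, 4e-3)
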