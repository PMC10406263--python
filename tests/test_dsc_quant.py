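import numpy as np
import pytest

from dscsim import (
    Agent,
    DeconvolutionConfig,
    PerfusionEstimate,
    RelaxationTimecourse,
    SignalTimecourse,
    delta_s,
    exclude_voxels,
    kappa,
    rcbf_mtt,
    rcbv,
    signal_to_relaxation,
    snr,
    svd_deconvolve,
    temporal_gaussian_filter,
    truncate_to_bolus_window,
)
from dscsim.dsc_quant import convolution_matrix, residue_mtt_diagnostic


def _signal(samples, tr=1.5, te=0.03, baseline=None):
    return SignalTimecourse(np.asarray(samples, float), TR=tr, TE=te,
                            baseline_window=baseline)


class TestSignalToRelaxation:
    def test_flat_series_is_zero(self):
        dr2 = signal_to_relaxation(_signal(np.full(30, 0.7)))
        np.testing.assert_allclose(dr2.samples, 0.0)

    def test_analytic_inverse(self):
        s = np.full(30, 0.5)
        s[15:] = 0.5 * np.exp(-0.3)
        dr2 = signal_to_relaxation(_signal(s, baseline=np.arange(10)))
        assert dr2.samples[20] == pytest.approx(10.0, rel=1e-12)

    def test_global_scaling_invariance(self):
        rng = np.random.default_rng(0)
        s = 0.6 + 0.05 * rng.random(40)
        a = signal_to_relaxation(_signal(s))
        b = signal_to_relaxation(_signal(3.7 * s))
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-12)

    def test_non_positive_signal_rejected(self):
        s = np.full(20, 0.5)
        s[7] = -0.1
        with pytest.raises(ValueError, match="index 7"):
            signal_to_relaxation(_signal(s))


class TestDeltaSAndSnr:
    def test_delta_s_percentage(self):
        s = np.full(25, 100.0)
        s[12] = 60.0
        assert delta_s(_signal(s, baseline=np.arange(10))) == pytest.approx(40.0)
        assert delta_s(_signal(np.full(25, 5.0))) == 0.0

    def test_noiseless_snr_flagged_infinite(self):
        with pytest.warns(UserWarning, match="noiseless"):
            assert snr(_signal(np.full(25, 1.0))) == np.inf

    def test_snr_is_delta_s_over_noise(self):
        rng = np.random.default_rng(1)
        s = np.full(40, 100.0) + rng.normal(0, 2.0, 40)
        s[20] = 60.0
        tc = _signal(s, baseline=np.arange(10))
        base = s[:10]
        eps = 100 * base.std(ddof=1) / base.mean()
        assert snr(tc) == pytest.approx(delta_s(tc) / eps, rel=1e-9)

    def test_baseline_sd_recovers_known_sigma(self):
        rng = np.random.default_rng(42)
        sigma = 0.02
        s0 = 0.5
        s = s0 + rng.normal(0, sigma * s0, 200)
        tc = _signal(s, baseline=np.arange(20))
        eps = delta_s(tc) / snr(tc)  # percent
        assert eps == pytest.approx(100 * sigma, rel=0.30)


class TestTemporalFilter:
    def test_constant_series_unchanged(self):
        tc = _signal(np.full(30, 0.8))
        np.testing.assert_allclose(temporal_gaussian_filter(tc).samples, 0.8)

    def test_impulse_spreads_to_unit_sum(self):
        x = np.zeros(31)
        x[15] = 1.0
        out = temporal_gaussian_filter(_signal(x)).samples
        assert np.count_nonzero(out) == 5
        assert out.sum() == pytest.approx(1.0)

    def test_reduces_white_noise_variance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.5, 0.05, 200)
        out = temporal_gaussian_filter(_signal(x)).samples
        assert out.var() < x.var()


class TestBolusWindow:
    def _course(self, onset, width, n=60, amp=10.0):
        x = np.zeros(n)
        x[onset:onset + width] = amp
        return RelaxationTimecourse(x, TR=1.5)

    def test_window_bookkeeping(self):
        aif = self._course(10, 10)
        vof = self._course(14, 37)
        tis = self._course(11, 20, amp=0.5)
        t, a, v = truncate_to_bolus_window(tis, aif, vof)
        assert a.samples.size == 50 - 10 + 1

    def test_window_contains_aif_peak(self):
        aif = self._course(10, 8)
        vof = self._course(13, 12)
        tis = self._course(11, 9)
        _, a, _ = truncate_to_bolus_window(tis, aif, vof)
        assert a.samples.max() == 10.0

    def test_flat_series_rejected(self):
        flat = RelaxationTimecourse(np.zeros(30), TR=1.5)
        with pytest.raises(ValueError, match="no detectable bolus"):
            truncate_to_bolus_window(flat, flat, flat)


class TestRcbv:
    def test_proportional_curves(self):
        ref = RelaxationTimecourse(np.sin(np.linspace(0, np.pi, 30)) * 10, TR=1.5)
        tis = RelaxationTimecourse(0.04 * ref.samples, TR=1.5)
        est = rcbv(tis, ref, Agent.DOHB)
        assert est.rCBV == pytest.approx(4 * (1 / 0.69), rel=1e-9)

    def test_kappa_values(self):
        assert kappa(Agent.GD, 0.4) == pytest.approx(0.6 / 0.724, rel=1e-12)
        assert kappa(Agent.GD, 0.4) == pytest.approx(0.8287, abs=5e-4)
        # red-cell-borne contrast: hematocrit cancels
        assert kappa(Agent.DOHB, 0.4) == kappa(Agent.DOHB, 0.3)
        assert kappa(Agent.DOHB) == pytest.approx(1 / 0.69, rel=1e-12)

    def test_negative_area_flagged(self):
        ref = RelaxationTimecourse(np.ones(20), TR=1.5)
        tis = RelaxationTimecourse(-np.ones(20), TR=1.5)
        est = rcbv(tis, ref, Agent.GD)
        assert est.excluded and est.reason == "negative_rcbv"


class TestSvdDeconvolution:
    def _aif(self, n=40, tr=1.5):
        # well-conditioned bolus-like curve: appreciable first sample and tail
        t = (np.arange(n) + 1) * tr
        x = (t / 2.5) ** 3 * np.exp(3 * (1 - t / 2.5))
        return RelaxationTimecourse(10 * x + 0.05, TR=tr)

    def test_forward_inverse_identity_full_rank(self):
        aif = self._aif()
        rng = np.random.default_rng(7)
        b_true = np.exp(-np.arange(40) / 5.0) * 0.01
        A = convolution_matrix(aif.samples, aif.TR)
        tis = RelaxationTimecourse(A @ b_true, TR=aif.TR)
        b = svd_deconvolve(tis, aif, DeconvolutionConfig(0.0))
        np.testing.assert_allclose(b, b_true, atol=1e-10)

    def test_self_deconvolution_is_impulse(self):
        aif = self._aif()
        b = svd_deconvolve(aif, aif, DeconvolutionConfig(0.0))
        assert np.argmax(b) == 0
        assert b[0] == pytest.approx(1 / aif.TR, rel=1e-6)

    def test_threshold_never_raises_peak(self):
        aif = self._aif()
        A = convolution_matrix(aif.samples, aif.TR)
        b_true = 0.013 * np.exp(-np.arange(40) * 1.5 / 2.95)
        tis = RelaxationTimecourse(A @ b_true, TR=aif.TR)
        peaks = [
            svd_deconvolve(tis, aif, DeconvolutionConfig(thr)).max()
            for thr in (0.0, 0.05, 0.1, 0.2, 0.3)
        ]
        assert np.all(np.diff(peaks) <= 1e-12)

    def test_zero_aif_rejected(self):
        flat = RelaxationTimecourse(np.zeros(20), TR=1.5)
        with pytest.raises(ValueError, match="singular"):
            svd_deconvolve(flat, flat, DeconvolutionConfig(0.2))

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            DeconvolutionConfig(1.0)


class TestRcbfMtt:
    def test_central_volume_consistency(self):
        # rCBV/rCBF*60 equals area-over-max when both come from the same series
        aif = np.sin(np.linspace(0.1, np.pi, 30)) * 20
        A = convolution_matrix(aif, 1.5)
        b_true = 0.0135 * np.exp(-np.arange(30) * 1.5 / 2.95)
        tis = A @ b_true
        est = rcbv(RelaxationTimecourse(tis, 1.5), RelaxationTimecourse(aif, 1.5),
                   Agent.GD)
        b = svd_deconvolve(RelaxationTimecourse(tis, 1.5),
                           RelaxationTimecourse(aif, 1.5), DeconvolutionConfig(0.0))
        rcbf_val, mtt = rcbf_mtt(b, est.rCBV, Agent.GD)
        # area ratio of tissue to AIF equals trapezoid integral of b
        assert mtt == pytest.approx(
            np.trapezoid(tis, dx=1.5) / np.trapezoid(aif, dx=1.5) / b.max(),
            rel=1e-6,
        )
        assert residue_mtt_diagnostic(b, 1.5) == pytest.approx(
            np.trapezoid(b, dx=1.5) / b.max(), rel=1e-12
        )

    def test_non_positive_peak_flagged(self):
        rcbf_val, mtt = rcbf_mtt(np.array([-1.0, -2.0]), 4.0, Agent.GD)
        assert np.isnan(rcbf_val) and np.isnan(mtt)


class TestExclusion:
    def test_negative_rcbv_excluded_with_reason(self):
        ests = [PerfusionEstimate(4.0), PerfusionEstimate(-1.0),
                PerfusionEstimate(2.0)]
        kept, report = exclude_voxels(ests)
        assert len(kept) == 2
        assert report["negative_rcbv"] == 1
        assert ests[1].excluded and ests[1].reason == "negative_rcbv"

    def test_all_positive_nothing_excluded(self):
        kept, report = exclude_voxels([PerfusionEstimate(1.0)])
        assert len(kept) == 1 and report["n_excluded"] == 0
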