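import numpy as np
import pytest

from dscsim import (
    Compartment,
    GammaVariateSpec,
    HypoxicBolusSpec,
    PhysicsConstants,
    TimeGrid,
    TransportSpec,
    VesselClass,
    VoxelLabel,
    VoxelModel,
    arterial_voxel,
    csf_voxel,
    ees_relaxation,
    frequency_shift,
    gamma_variate_bolus,
    hypoxic_bolus,
    ivs_relaxation,
    signal_to_relaxation,
    simulate_signal_timecourse,
    tissue_voxel,
    venous_voxel,
    voxel_signal,
)
from dscsim.contrast_inputs import Agent
from dscsim.forward_signal import CompartmentKind
from dscsim.tracer_transport import BiexponentialResidue, MonoexponentialResidue

TISSUE = TransportSpec(BiexponentialResidue(), delay=1.0)
VENOUS = TransportSpec(MonoexponentialResidue(4.0), delay=2.0)


class TestFrequencyShift:
    def test_fully_oxygenated_no_agent_is_zero(self):
        assert frequency_shift(Y0=1.0) == 0.0

    def test_venous_baseline_magnitude(self, gamma_b0):
        # 0.264e-6 * 0.4 * 0.4 * gamma * B0 ~ 33.9 rad/s
        expected = 0.264e-6 * 0.4 * 0.4 * gamma_b0
        assert frequency_shift(Y0=0.6) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(33.9, abs=0.1)

    def test_one_millimolar_gd(self, gamma_b0):
        expected = 0.026e-6 * gamma_b0
        assert frequency_shift(Y0=1.0, gd=1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(20.9, abs=0.1)

    def test_gd_equivalent_dy_consistency(self, constants):
        # Gd term equals the dOHb formula with dY' = -0.246*[Gd]
        via_gd = frequency_shift(Y0=0.98, gd=1.3, k=constants)
        via_dy = frequency_shift(
            Y0=0.98, dY=-constants.gd_equivalent_dy * 1.3, k=constants
        )
        assert via_gd == pytest.approx(via_dy, rel=1e-12)

    def test_hyperoxic_overshoot_clipped(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert frequency_shift(Y0=1.0, dY=0.05) == 0.0


class TestRelaxationRates:
    def test_ees_single_capillary(self):
        voxel = VoxelModel(
            (Compartment(CompartmentKind.CAPILLARY, 1.0, 0.775,
                         VesselClass.CAPILLARY_5UM),),
            VoxelLabel.GM,
        )
        assert ees_relaxation(voxel, [19.08]) == pytest.approx(0.0387 * 19.08)

    def test_ees_zero_shifts_and_volume_linearity(self):
        v1 = tissue_voxel(2.0)
        v2 = tissue_voxel(4.0)
        shifts = [10.0] * 5
        assert ees_relaxation(v1, [0.0] * 5) == 0.0
        assert ees_relaxation(v2, shifts) == pytest.approx(
            2 * ees_relaxation(v1, shifts)
        )

    def test_ees_mismatched_lists_rejected(self):
        with pytest.raises(ValueError):
            ees_relaxation(tissue_voxel(4.0), [1.0, 2.0])

    @pytest.mark.parametrize(
        "y0,dy,expected",
        [(1.0, 0.0, 0.0), (0.6, 0.0, 181 * 0.16), (0.98, -0.23, 181 * 0.0625)],
    )
    def test_ivs_quadratic(self, y0, dy, expected):
        assert ivs_relaxation(y0, dy) == pytest.approx(expected, rel=1e-12)


class TestVoxelSignal:
    def test_pure_blood_artery_baseline(self):
        voxel = arterial_voxel(100.0, y0=1.0)
        assert voxel_signal(voxel) == pytest.approx(np.exp(-0.03 * 13.8), rel=1e-12)

    def test_pure_tissue_baseline(self):
        assert voxel_signal(csf_voxel()) == pytest.approx(
            np.exp(-0.03 * 20.99), rel=1e-12
        )

    def test_baseline_artery_above_vein(self):
        # baseline oxygen saturation orders the baseline signals
        assert voxel_signal(arterial_voxel(100.0)) > voxel_signal(venous_voxel(100.0))

    def test_contrast_never_raises_signal(self):
        for voxel in (arterial_voxel(100.0), venous_voxel(50.0), tissue_voxel(4.0)):
            s0 = voxel_signal(voxel, Agent.DOHB, 0.0)
            levels = np.linspace(0, -0.25, 10)
            s = voxel_signal(voxel, Agent.DOHB, levels)
            assert np.all(s <= s0 + 1e-15)
            assert np.all(np.diff(s) <= 1e-15)  # monotone in |dY|
        s_gd = voxel_signal(tissue_voxel(4.0), Agent.GD, np.linspace(0, 3, 7))
        assert np.all(np.diff(s_gd) <= 1e-15)


class TestSimulatedTimecourses:
    def test_flat_for_zero_bolus(self, fine_grid):
        bolus = gamma_variate_bolus(GammaVariateSpec(a=0.0, onset=10), fine_grid)
        tc = simulate_signal_timecourse(bolus, tissue_voxel(4.0), TISSUE,
                                        venous_spec=VENOUS)
        np.testing.assert_allclose(tc.samples, tc.samples[0])

    def test_full_blood_voxel_round_trip_identity(self, fine_grid):
        # for CBV=100% the log-ratio conversion must return exactly the
        # intravascular relaxation difference
        bolus = hypoxic_bolus(HypoxicBolusSpec(onset=10), fine_grid)
        voxel = arterial_voxel(100.0, y0=0.98)
        tc = simulate_signal_timecourse(bolus, voxel, TISSUE, venous_spec=VENOUS)
        dr2 = signal_to_relaxation(tc)
        idx = np.round(tc.times / fine_grid.dt).astype(int)
        analytic = ivs_relaxation(0.98, bolus.values[idx]) - ivs_relaxation(0.98, 0.0)
        np.testing.assert_allclose(dr2.samples, analytic, atol=1e-9)

    def test_tissue_peak_linear_in_cbv(self, fine_grid):
        # GM/WM regime: peak relaxation change is linear in total CBV
        bolus = hypoxic_bolus(HypoxicBolusSpec(onset=10), fine_grid)
        cbvs = np.arange(1.0, 5.01, 0.5)
        peaks = []
        for cbv in cbvs:
            tc = simulate_signal_timecourse(bolus, tissue_voxel(cbv), TISSUE,
                                            venous_spec=VENOUS)
            peaks.append(signal_to_relaxation(tc).samples.max())
        r = np.corrcoef(cbvs, peaks)[0, 1]
        assert r**2 > 0.99

    def test_csf_partial_volume_has_small_slow_response(self, fine_grid):
        bolus = gamma_variate_bolus(GammaVariateSpec(onset=10), fine_grid)
        csf = csf_voxel(partial_venous_cbv=1.0)
        slow = TransportSpec(MonoexponentialResidue(12.0), delay=3.0)
        tc = simulate_signal_timecourse(bolus, csf, TISSUE, venous_spec=VENOUS,
                                        csf_spec=slow)
        gm = simulate_signal_timecourse(bolus, tissue_voxel(4.0), TISSUE,
                                        venous_spec=VENOUS)
        assert 0 < signal_to_relaxation(tc).samples.max() < \
            signal_to_relaxation(gm).samples.max()


class TestVoxelModelInvariants:
    def test_total_cbv_capped(self):
        with pytest.raises(ValueError):
            VoxelModel(
                (Compartment(CompartmentKind.ARTERY, 101.0, 1.0,
                             VesselClass.LARGE_VESSEL_200UM_90DEG),),
                VoxelLabel.ARTERIAL,
            )

    def test_tissue_split_is_1_2_2(self):
        voxel = tissue_voxel(4.0)
        by_kind = {c.kind.value: c.pCBV for c in voxel.compartments}
        assert by_kind["artery"] + by_kind["arteriole"] == pytest.approx(0.8)
        assert by_kind["capillary"] == pytest.approx(1.6)
        assert by_kind["vein"] + by_kind["venule"] == pytest.approx(1.6)
        assert voxel.total_CBV == pytest.approx(4.0)

    def test_table_coefficients(self):
        assert VesselClass.CAPILLARY_5UM.ees_coeff == 0.0387
        assert VesselClass.SMALL_VESSEL_16_200UM.ees_coeff == 0.0433
        assert VesselClass.LARGE_VESSEL_200UM_90DEG.ees_coeff == 0.0798
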