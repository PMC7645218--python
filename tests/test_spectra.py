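"""Forward lineshape simulation: Pake horn positions, symmetry, linearity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidphase import (
    AcquisitionParams,
    PakeComponent,
    PhaseModel,
    ValidationError,
    build_chain_model,
    fid_to_spectrum,
    gen_profile,
    horn_separation,
    order_to_splitting,
    powder_kernel,
    simulate_fid,
    simulate_spectrum,
    splitting_to_order,
)
from lipidphase.profiles import ChainDescriptor
from lipidphase.synth import ProfileSpec


class TestFid:
    def test_initial_amplitude_is_total_weight(self, acq_small, single_component):
        fid = simulate_fid(single_component(0.2), acq_small)
        assert fid.amplitudes[0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_order_gives_pure_exponential_decay(self, acq_small):
        phase = PhaseModel("iso-like", (PakeComponent(0.0, 100.0, 1.0),))
        fid = simulate_fid(phase, acq_small)
        expected = np.exp(-np.pi * 100.0 * acq_small.times)
        np.testing.assert_allclose(fid.amplitudes, expected, rtol=0, atol=1e-12)

    def test_mixture_fractions_must_sum_to_one(self, acq_small, single_component):
        phases = [single_component(0.1), single_component(0.3)]
        with pytest.raises(ValidationError):
            simulate_fid(phases, acq_small, fractions=[0.6, 0.5])
        with pytest.raises(ValidationError):
            simulate_fid(phases, acq_small, fractions=[-0.2, 1.2])

    def test_linearity_of_mixtures(self, acq_small, single_component):
        pa, pb = single_component(0.15, 80.0), single_component(0.35, 120.0)
        mix = simulate_spectrum([pa, pb], acq_small, fractions=[0.3, 0.7])
        sa = simulate_spectrum(pa, acq_small)
        sb = simulate_spectrum(pb, acq_small)
        combined = 0.3 * sa.intensities + 0.7 * sb.intensities
        assert np.max(np.abs(mix.intensities - combined)) < 1e-8


class TestSpectrum:
    def test_horn_separation_at_s02(self, acq_default, single_component):
        spec = fid_to_spectrum(simulate_fid(single_component(0.2), acq_default))
        bin_khz = acq_default.frequency_resolution_khz
        assert abs(horn_separation(spec) - 25.05) <= bin_khz

    def test_even_symmetry(self, acq_small, single_component):
        spec = fid_to_spectrum(simulate_fid(single_component(0.25, 50.0), acq_small))
        assert spec.symmetry_defect() < 1e-6

    def test_zero_order_peaks_at_zero_frequency(self, acq_small):
        phase = PhaseModel("iso", (), isotropic_weight=1.0, isotropic_lb=100.0)
        spec = fid_to_spectrum(simulate_fid(phase, acq_small))
        assert spec.frequencies[np.argmax(spec.intensities)] == pytest.approx(0.0)

    def test_zero_fill_does_not_move_horns(self, single_component):
        p1 = AcquisitionParams(zero_fill_factor=1)
        p4 = AcquisitionParams(zero_fill_factor=4)
        s1 = fid_to_spectrum(simulate_fid(single_component(0.2), p1))
        s4 = fid_to_spectrum(simulate_fid(single_component(0.2), p4))
        original_bin = 1.0 / (p1.n_points * p1.dwell_time) / 1e3
        assert abs(horn_separation(s1) - horn_separation(s4)) <= original_bin

    def test_positive_integral(self, acq_small, single_component):
        spec = fid_to_spectrum(simulate_fid(single_component(0.2, 100.0), acq_small))
        assert spec.integral() > 0

    def test_line_broadening_lowers_and_widens_peaks(self):
        params = AcquisitionParams(n_points=1024, zero_fill_factor=8)

        def peak_and_fwhm(lb):
            phase = PhaseModel("t", (PakeComponent(0.1, lb, 1.0),))
            spec = fid_to_spectrum(simulate_fid(phase, params))
            peak = spec.intensities.max()
            above = spec.intensities >= peak / 2
            width = spec.frequencies[above].max() - spec.frequencies[above].min()
            return peak, width

        peaks, widths = zip(*(peak_and_fwhm(lb) for lb in (100.0, 500.0, 2000.0)))
        assert peaks[0] > peaks[1] > peaks[2]
        assert widths[0] < widths[1] < widths[2]


class TestQuadrature:
    """The theta-grid trapezoid sum, Gauss-Legendre, and the Fresnel
    closed form must agree on the powder kernel and on whole FIDs."""

    def test_kernel_methods_agree(self):
        phi = np.linspace(0.0, 900.0, 181)
        trap = powder_kernel(phi, method="trapezoid")
        gauss = powder_kernel(phi, method="gauss")
        fres = powder_kernel(phi, method="fresnel")
        assert np.max(np.abs(trap - gauss)) < 1e-8
        assert np.max(np.abs(trap - fres)) < 1e-8

    def test_fid_methods_agree(self, single_component):
        params = AcquisitionParams(n_points=512)
        phase = PhaseModel(
            "t",
            (
                PakeComponent(0.45, 100.0, 2.0),
                PakeComponent(0.2, 80.0, 2.0),
                PakeComponent(0.05, 60.0, 3.0),
            ),
        )
        ft = simulate_fid(phase, params, method="trapezoid").amplitudes
        fg = simulate_fid(phase, params, method="gauss").amplitudes
        fi = simulate_fid(phase, params, method="interp").amplitudes
        assert np.max(np.abs(ft - fg)) < 1e-8
        assert np.max(np.abs(ft - fi)) < 1e-8

    def test_kernel_at_zero(self):
        assert powder_kernel(np.array([0.0]))[0] == pytest.approx(1.0, abs=1e-12)


class TestSplittingConversion:
    def test_reference_values(self):
        assert order_to_splitting(0.2, 167.0) == pytest.approx(25.05)
        assert order_to_splitting(0.5, 167.0) == pytest.approx(62.625)
        assert splitting_to_order(0.0, 167.0) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(order=st.floats(0.0, 1.0), chi=st.floats(50.0, 300.0))
    def test_round_trip(self, order, chi):
        assert splitting_to_order(
            order_to_splitting(order, chi), chi
        ) == pytest.approx(order, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            order_to_splitting(-0.1)
        with pytest.raises(ValidationError):
            splitting_to_order(-5.0)


class TestChainModel:
    def test_palmitoyl_deuteron_bookkeeping(self):
        profile = gen_profile(
            ProfileSpec(plateau=0.2, knee=8, decay=3, methyl=0.015), "palmitoyl-d31"
        )
        model = build_chain_model(profile, "palmitoyl-d31", lb=100.0)
        assert len(model.components) == 15
        weights = np.array([c.weight for c in model.components])
        assert weights.sum() == pytest.approx(1.0)
        # CD2 : CD3 = 2 : 3 out of 31 deuterons
        assert weights[0] == pytest.approx(2 / 31)
        assert weights[-1] == pytest.approx(3 / 31)

    def test_three_site_chain(self):
        chain = ChainDescriptor("sterol-like", 4, methyl=False)
        profile = gen_profile(ProfileSpec(plateau=0.3, knee=4, decay=3), chain)
        model = build_chain_model(profile, chain)
        assert len(model.components) == 3
        assert all(c.weight == pytest.approx(1 / 3) for c in model.components)

    def test_missing_carbons_rejected(self):
        from lipidphase import OrderProfile

        short = OrderProfile("palmitoyl-d31", [2, 3, 4], [0.2, 0.2, 0.2])
        with pytest.raises(ValidationError, match=r"missing carbons"):
            build_chain_model(short, "palmitoyl-d31")


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"chi": -1.0},
            {"dwell_time": 0.0},
            {"n_points": 1},
            {"n_points": 1000},  # not a power of two
            {"zero_fill_factor": 0},
            {"theta_increment": 0.0},
            {"theta_increment": 2.0},
        ],
    )
    def test_bad_acquisition_params(self, kwargs):
        with pytest.raises(ValidationError):
            AcquisitionParams(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"order": -0.1},
            {"order": 1.5},
            {"line_broadening": -1.0},
            {"weight": 0.0},
        ],
    )
    def test_bad_components(self, kwargs):
        defaults = {"order": 0.2, "line_broadening": 0.0, "weight": 1.0}
        defaults.update(kwargs)
        with pytest.raises(ValidationError):
            PakeComponent(**defaults)

    def test_empty_phase_rejected(self):
        with pytest.raises(ValidationError):
            PhaseModel("empty", (), isotropic_weight=0.0)
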