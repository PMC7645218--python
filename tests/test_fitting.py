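"""Two-phase lineshape decomposition: recovery, labels, reporting."""

import numpy as np
import pytest
from dataclasses import replace

from lipidphase import (
    FitConfig,
    OrderProfile,
    Spectrum,
    ValidationError,
    extract_profile,
    fit_temperature_series,
    fit_two_phase,
    format_fractions,
    gen_two_phase_spectrum,
    phase_fractions_report,
)
from lipidphase.profiles import ChainDescriptor
from lipidphase.synth import PRESETS, ProfileSpec, SpectrumScenario


def serotonin_scenario(**kwargs):
    """Fast two-phase scenario on the two-site chain (distinct plateaus)."""
    defaults = dict(
        fraction_I=0.6,
        fraction_II=0.4,
        profile_I=ProfileSpec(plateau=0.10, knee=2.0, decay=2.5),
        profile_II=ProfileSpec(plateau=0.30, knee=2.0, decay=2.5),
        lb_I=80.0,
        lb_II=120.0,
        chain="serotonin-d4",
    )
    defaults.update(kwargs)
    return SpectrumScenario(**defaults)


SEROTONIN_CONFIG = FitConfig(chain="serotonin-d4", n_phases=2)


class TestExtractProfile:
    def test_sort_and_assign_convention(self):
        chain = ChainDescriptor("toy", 6, methyl=False)  # carbons 2..6
        profile = extract_profile([12.0, 30.0, 25.0, 5.0], chain, chi=167.0)
        np.testing.assert_array_equal(profile.carbons, [2, 3, 4, 5])
        expected = np.array([30.0, 25.0, 12.0, 5.0]) / (0.75 * 167.0)
        np.testing.assert_allclose(profile.orders, expected)

    def test_ceiling_splitting_maps_to_half(self):
        profile = extract_profile([62.625], "palmitoyl-d31")
        assert profile.orders[0] == pytest.approx(0.5)
        assert profile.carbons[0] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            extract_profile([], "palmitoyl-d31")

    def test_too_many_splittings_rejected(self):
        with pytest.raises(ValidationError, match="only"):
            extract_profile(np.ones(16), "palmitoyl-d31")


class TestTwoPhaseFit:
    def test_degenerate_single_phase_recovery(self):
        """A two-phase fit of single-phase data puts ~all weight on one
        phase and leaves a residual at numerical-noise level."""
        spectrum, _ = gen_two_phase_spectrum(PRESETS["popc_no5ht"])
        fit = fit_two_phase(spectrum, FitConfig())
        assert max(fit.fraction_I, fit.fraction_II) >= 0.999
        assert fit.residual_rms < 1e-6 * spectrum.intensities.max()

    def test_noiseless_serotonin_mixture_recovery(self):
        spectrum, truth = gen_two_phase_spectrum(serotonin_scenario())
        fit = fit_two_phase(spectrum, SEROTONIN_CONFIG)
        assert fit.fraction_I == pytest.approx(0.6, abs=0.01)
        np.testing.assert_allclose(
            fit.profile_I.orders, truth.profile_I.orders, atol=0.005
        )
        np.testing.assert_allclose(
            fit.profile_II.orders, truth.profile_II.orders, atol=0.005
        )

    def test_label_stability_under_generator_swap(self):
        """Swapping which generator slot holds the ordered phase must not
        change which fitted phase is labelled II."""
        a, _ = gen_two_phase_spectrum(serotonin_scenario())
        b, _ = gen_two_phase_spectrum(
            serotonin_scenario(
                fraction_I=0.4,
                fraction_II=0.6,
                profile_I=ProfileSpec(plateau=0.30, knee=2.0, decay=2.5),
                profile_II=ProfileSpec(plateau=0.10, knee=2.0, decay=2.5),
                lb_I=120.0,
                lb_II=80.0,
            )
        )
        fit_a = fit_two_phase(a, SEROTONIN_CONFIG)
        fit_b = fit_two_phase(b, SEROTONIN_CONFIG)
        assert fit_a.fraction_II == pytest.approx(fit_b.fraction_II, abs=0.01)
        assert fit_a.profile_II.orders[0] == pytest.approx(
            fit_b.profile_II.orders[0], abs=0.005
        )
        assert fit_a.profile_II.orders[0] > fit_a.profile_I.orders[0]

    def test_best_start_not_worse_than_any_start(self):
        spectrum, _ = gen_two_phase_spectrum(serotonin_scenario())
        fit = fit_two_phase(spectrum, SEROTONIN_CONFIG)
        assert fit.cost <= min(fit.start_costs) + 1e-12

    def test_fraction_bias_vanishes_with_snr(self):
        """Common noise realizations scaled by 1/SNR: the fraction error
        must shrink as the spectra get cleaner."""
        bias = {}
        for snr in (20.0, 200.0):
            errs = []
            for seed in (101, 102, 103):
                spectrum, _ = gen_two_phase_spectrum(
                    serotonin_scenario(snr=snr, seed=seed)
                )
                fit = fit_two_phase(spectrum, SEROTONIN_CONFIG)
                errs.append(fit.fraction_I - 0.6)
            bias[snr] = abs(np.mean(errs))
        assert bias[200.0] < bias[20.0]

    def test_grid_mismatch_rejected(self):
        spectrum, _ = gen_two_phase_spectrum(serotonin_scenario())
        broken = Spectrum(
            spectrum.frequencies[:-10], spectrum.intensities[:-10], spectrum.params
        )
        with pytest.raises(ValidationError, match="grid"):
            fit_two_phase(broken, SEROTONIN_CONFIG)


class TestTemperatureSeries:
    @staticmethod
    def _series_spectra(plateaus, seeds=None):
        spectra = []
        for i, plat in enumerate(plateaus):
            sc = SpectrumScenario(
                fraction_I=1.0,
                fraction_II=0.0,
                profile_I=ProfileSpec(plateau=plat, knee=2.0, decay=2.5),
                lb_I=80.0,
                chain="serotonin-d4",
            )
            spectra.append(gen_two_phase_spectrum(sc)[0])
        return spectra

    def test_plateau_tracks_temperature(self):
        spectra = self._series_spectra([0.45, 0.40, 0.35])
        config = FitConfig(chain="serotonin-d4", n_phases=1)
        table, fits = fit_temperature_series(spectra, [20.0, 30.0, 40.0], config)
        assert (table["error"] == "").all()
        plateaus = table["plateau_I"].to_numpy()
        assert np.all(np.diff(plateaus) < 0)
        np.testing.assert_allclose(plateaus, [0.45, 0.40, 0.35], atol=0.01)

    def test_single_element_series_matches_plain_fit(self):
        spectra = self._series_spectra([0.30])
        config = FitConfig(chain="serotonin-d4", n_phases=1)
        table, fits = fit_temperature_series(spectra, [30.0], config)
        plain = fit_two_phase(spectra[0], config)
        assert fits[0].fraction_I == pytest.approx(plain.fraction_I, abs=1e-9)
        assert table.loc[0, "plateau_I"] == pytest.approx(
            plain.profile_I.orders[0], abs=1e-9
        )

    def test_corrupt_spectrum_flagged_and_series_continues(self):
        spectra = self._series_spectra([0.45, 0.35])
        bad = Spectrum(
            spectra[0].frequencies,
            np.zeros_like(spectra[0].intensities),
            spectra[0].params,
        )
        config = FitConfig(chain="serotonin-d4", n_phases=1)
        table, fits = fit_temperature_series(
            [spectra[0], bad, spectra[1]], [20.0, 30.0, 40.0], config
        )
        assert (table["error"] != "").sum() == 1
        assert table.loc[1, "error"] != ""
        assert fits[1] is None
        assert np.isfinite(table.loc[0, "plateau_I"])
        assert np.isfinite(table.loc[2, "plateau_I"])

    def test_non_increasing_temperatures_rejected(self):
        spectra = self._series_spectra([0.4, 0.35])
        with pytest.raises(ValidationError):
            fit_temperature_series(spectra, [30.0, 30.0], FitConfig())


class TestReporting:
    def test_simple_rounding(self):
        assert format_fractions([0.604, 0.396, 0.0]) == "60 / 40 / 0"

    def test_three_component_percentages(self):
        assert format_fractions([0.28, 0.65, 0.07]) == "28 / 65 / 7"

    def test_largest_remainder_sums_to_100(self):
        pct = [int(p) for p in format_fractions([1 / 3, 1 / 3, 1 / 3]).split(" / ")]
        assert sum(pct) == 100

    def test_report_table(self):
        profile = OrderProfile("serotonin-d4", [2, 3], [0.1, 0.08])
        profile_hi = OrderProfile("serotonin-d4", [2, 3], [0.3, 0.2])
        from lipidphase import TwoPhaseFit

        fit = TwoPhaseFit(
            fraction_I=0.604, fraction_II=0.396, fraction_iso=0.0,
            profile_I=profile, profile_II=profile_hi,
            lb_I=80.0, lb_II=120.0, lb_iso=0.0,
            residual_rms=0.0, n_evaluations=1, seed=0,
        )
        table = phase_fractions_report(fit)
        assert list(table["percent"]) == [60, 40, 0]
        assert table.attrs["formatted"] == "60 / 40 / 0"
        assert table["percent"].sum() == 100
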