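"""Spectral processing: baselines, integrals, conversion, trace assembly."""

import numpy as np
import pandas as pd
import pytest

from autokinetics import (
    ConcentrationTrace,
    NoiseModel,
    ProcessingRecipe,
    Region,
    Spectrum,
    absorbance_at,
    baseline_correct,
    conversion_from_integrals,
    integrate_region,
    render_series,
    simulate_network,
    trace_from_spectra,
)
from autokinetics import studies


def uv_spectrum(x, y, t=0.0):
    return Spectrum(x=np.asarray(x, float), y=np.asarray(y, float), modality="uvvis", timestamp=t)


class TestBaselineCorrect:
    def test_flat_spectrum_goes_to_zero(self):
        x = np.linspace(400, 600, 201)
        seg = baseline_correct(uv_spectrum(x, np.full_like(x, 3.7)), Region(450, 550, "r"))
        assert np.allclose(seg.y, 0.0, atol=1e-12)

    def test_linear_ramp_goes_to_zero(self):
        x = np.linspace(400, 600, 201)
        seg = baseline_correct(uv_spectrum(x, 0.01 * x - 2.0), Region(450, 550, "r"))
        assert np.allclose(seg.y, 0.0, atol=1e-12)

    def test_lorentzian_on_ramp_recovers_pure_lorentzian(self):
        # region edges 2000 half-widths from the center: tail < 1e-6 of peak
        x = np.linspace(-4.0, 4.0, 8001)
        gamma = 1e-3
        lorentz = gamma**2 / ((x - 0.0) ** 2 + gamma**2)
        ramp = 0.3 * x + 1.0
        seg = baseline_correct(uv_spectrum(x, lorentz + ramp), Region(-2.0, 2.0, "r"))
        interior = slice(1, -1)
        pure = gamma**2 / (seg.x**2 + gamma**2)
        assert np.max(np.abs(seg.y[interior] - pure[interior])) < 1e-6

    def test_region_outside_range_rejected(self):
        x = np.linspace(400, 600, 50)
        with pytest.raises(ValueError, match="outside"):
            baseline_correct(uv_spectrum(x, x * 0), Region(300, 500, "r"))


class TestIntegrateRegion:
    def test_unit_rectangle_area_equals_width(self):
        x = np.linspace(0, 10, 1001)
        y = np.where((x >= 2) & (x <= 6), 1.0, 0.0)
        res = integrate_region(uv_spectrum(x, y), Region(2.0, 6.0, "rect"))
        assert res.value == pytest.approx(4.0, abs=1e-9)

    def test_lorentzian_captures_analytic_fraction_within_20_widths(self):
        gamma, height = 0.01, 5.0
        x = np.linspace(-1, 1, 40001)
        y = height * gamma**2 / (x**2 + gamma**2)
        res = integrate_region(uv_spectrum(x, y), Region(-20 * gamma, 20 * gamma, "L"))
        total = np.pi * gamma * height
        assert res.value >= 0.96 * total
        assert res.value <= total

    def test_orientation_independent_positive_area(self, single_peak_signature):
        # descending-ppm NMR axis still yields a positive peak area
        x = np.linspace(2.0, 3.0, 2001)
        y = np.exp(-0.5 * ((x - 2.5) / 0.01) ** 2)
        nmr = Spectrum(x=x[::-1], y=y[::-1], modality="nmr", timestamp=0.0)
        res = integrate_region(nmr, Region(2.4, 2.6, "peak"))
        assert res.value > 0

    def test_additive_over_region_splits(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 501)
        y = rng.normal(size=x.size)
        whole = integrate_region(uv_spectrum(x, y), Region(0.1, 0.9, "w")).value
        left = integrate_region(uv_spectrum(x, y), Region(0.1, 0.5, "l")).value
        right = integrate_region(uv_spectrum(x, y), Region(0.5, 0.9, "r")).value
        assert left + right == pytest.approx(whole, abs=1e-9)

    def test_region_with_too_few_points_rejected(self):
        x = np.linspace(0, 10, 11)
        with pytest.raises(ValueError, match="fewer than 2|>= 3"):
            integrate_region(uv_spectrum(x, x * 0), Region(4.2, 4.4, "empty"))


class TestConversionFromIntegrals:
    def test_half_conversion(self):
        assert conversion_from_integrals(1.0, [1.0, 1.0]) == 0.5

    def test_zero_product(self):
        assert conversion_from_integrals(0.0, [0.0, 2.0]) == 0.0

    def test_small_negative_areas_clipped(self):
        assert conversion_from_integrals(-0.001, [1.0, -0.002]) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="no tosyl signal"):
            conversion_from_integrals(0.0, [0.0, 0.0])

    @pytest.mark.parametrize("scale", [0.1, 1.0, 173.0])
    def test_invariant_to_uniform_rescaling(self, scale):
        base = conversion_from_integrals(0.7, [0.7, 1.9])
        assert conversion_from_integrals(0.7 * scale, [0.7 * scale, 1.9 * scale]) == pytest.approx(base)

    def test_round_trip_at_30_percent_conversion(self):
        # render a tosylation snapshot at exactly 30% conversion, re-integrate
        tscl0 = studies.TOSYL_TSCL0_MM
        trace = ConcentrationTrace(
            times=np.array([0.0]),
            concentrations={
                "TsCl": np.array([0.7 * tscl0]),
                "ArNH2": np.array([50.0]),
                "TsNHAr": np.array([0.3 * tscl0]),
            },
        )
        spectra = render_series(trace, studies.tosylation_signature(), studies.tosylation_grid())
        recipe = studies.tosylation_recipe()
        assert recipe.conversion_of(spectra[0]) == pytest.approx(0.30, abs=0.01)


class TestAbsorbanceAt:
    def test_exact_grid_point(self):
        x = np.array([400.0, 450.0, 500.0])
        assert absorbance_at(uv_spectrum(x, [0.1, 0.5, 0.2]), 450.0) == 0.5

    def test_midpoint_is_arithmetic_mean(self):
        x = np.array([400.0, 450.0])
        assert absorbance_at(uv_spectrum(x, [0.2, 0.6]), 425.0) == pytest.approx(0.4)

    def test_band_center_matches_model_peak(self):
        sig = studies.iedda_signature()
        trace = ConcentrationTrace(
            times=np.array([0.0]),
            concentrations={"Tz": np.array([1.5]), "EVE": np.array([100.0]), "Pz": np.array([0.0])},
        )
        spec = render_series(trace, sig, studies.iedda_grid())[0]
        expected = 1.5 * studies.IEDDA_BAND.response
        assert absorbance_at(spec, studies.IEDDA_BAND.center) == pytest.approx(expected, rel=1e-6)

    def test_out_of_range_rejected(self):
        x = np.array([400.0, 500.0])
        with pytest.raises(ValueError, match="outside"):
            absorbance_at(uv_spectrum(x, [0.0, 0.0]), 600.0)


class TestTraceFromSpectra:
    def _tosylation_spectra(self, sigma=0.01, seed=5):
        net = studies.tosylation_network(k=studies.TOSYL_K_REF, amine_order=0.7)
        times = np.arange(15) * 1.0
        trace = simulate_network(net, {"TsCl": 5.0, "ArNH2": 100.0, "TsNHAr": 0.0}, times)
        spectra = render_series(
            trace,
            studies.tosylation_signature(),
            studies.tosylation_grid(),
            NoiseModel(relative_sigma=sigma, seed=seed),
        )
        return trace, spectra

    def test_round_trip_conversion_within_two_percent(self):
        trace, spectra = self._tosylation_spectra()
        df = trace_from_spectra(spectra, studies.tosylation_recipe())
        true_conv = 1.0 - trace["TsCl"] / 5.0
        assert np.max(np.abs(df["conversion"].to_numpy() - true_conv)) < 0.02

    def test_monotone_within_noise(self):
        _, spectra = self._tosylation_spectra()
        conv = trace_from_spectra(spectra, studies.tosylation_recipe())["conversion"].to_numpy()
        assert np.all(np.diff(conv) > -0.02)

    def test_empty_list_gives_empty_series(self):
        out = trace_from_spectra([], studies.tosylation_recipe())
        assert isinstance(out, pd.DataFrame) and out.empty

    def test_shuffled_timestamps_rejected(self):
        _, spectra = self._tosylation_spectra()
        with pytest.raises(ValueError, match="increasing"):
            trace_from_spectra([spectra[3], spectra[1]], studies.tosylation_recipe())

    def test_mixed_modalities_rejected(self):
        _, spectra = self._tosylation_spectra()
        uv = uv_spectrum(np.array([400.0, 500.0]), [0.0, 0.0], t=99.0)
        with pytest.raises(ValueError, match="mixed"):
            trace_from_spectra([spectra[0], uv], studies.tosylation_recipe())

    def test_calibrated_absorbance_yields_concentration_trace(self):
        net = studies.iedda_network()
        times = np.arange(5) * 2.0
        trace = simulate_network(net, {"Tz": 1.5, "EVE": 100.0, "Pz": 0.0}, times)
        spectra = render_series(trace, studies.iedda_signature(), studies.iedda_grid())
        out = trace_from_spectra(spectra, studies.iedda_recipe())
        assert isinstance(out, ConcentrationTrace)
        assert np.allclose(out["Tz"], trace["Tz"], atol=1e-6)
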