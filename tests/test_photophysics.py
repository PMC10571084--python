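"""Spectrum evaluation, channel composition, and ratio inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionsense.equilibria import SpeciationResult, fraction_bound
from ionsense.photophysics import (
    Channel,
    ChannelSet,
    SpeciesSpectrum,
    compose_channel_intensities,
    evaluate_spectrum,
    ratio_isotherm,
    ratio_to_free_metal,
)


def mixture_state(s_total, frac_bound):
    """A hand-built speciation state: free/bound sensor mixture."""
    return SpeciationResult(
        free={"sensor": s_total * (1 - frac_bound)},
        complexes={"sensor_Mg": s_total * frac_bound},
        residuals={"sensor": 0.0},
        converged=True,
        iterations=0,
    )


class TestEvaluateSpectrum:
    def test_zero_brightness_is_dark(self):
        spec = SpeciesSpectrum("x", [(500, 20, 1.0)], brightness=0.0)
        assert np.all(evaluate_spectrum(spec, np.arange(400, 700)) == 0)

    def test_peak_value_at_band_center(self):
        spec = SpeciesSpectrum("x", [(530, 30, 2.0)], brightness=0.5)
        assert evaluate_spectrum(spec, np.array([530.0]))[0] == pytest.approx(1.0)

    def test_band_additivity(self):
        b1, b2 = (500, 20, 1.0), (530, 25, 0.7)
        grid = np.linspace(400, 700, 301)
        both = evaluate_spectrum(SpeciesSpectrum("x", [b1, b2]), grid)
        s1 = evaluate_spectrum(SpeciesSpectrum("x", [b1]), grid)
        s2 = evaluate_spectrum(SpeciesSpectrum("x", [b2]), grid)
        np.testing.assert_allclose(both, s1 + s2, rtol=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            evaluate_spectrum(SpeciesSpectrum("x", [(500, 20, 1)]), np.array([]))

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            SpeciesSpectrum("x", [(500, 0.0, 1.0)])


class TestComposeChannels:
    def test_all_free_gives_r_min(self, spectra, channels, limiting_ratios):
        m = compose_channel_intensities(
            mixture_state(10e-6, 0.0), spectra, channels, "F530", "F500"
        )
        assert m.ratio == pytest.approx(limiting_ratios["r_min"], rel=1e-12)

    def test_all_bound_gives_r_max(self, spectra, channels, limiting_ratios):
        m = compose_channel_intensities(
            mixture_state(10e-6, 1.0), spectra, channels, "F530", "F500"
        )
        assert m.ratio == pytest.approx(limiting_ratios["r_max"], rel=1e-12)

    def test_mixture_ratio_strictly_between_limits(
        self, spectra, channels, limiting_ratios
    ):
        m = compose_channel_intensities(
            mixture_state(10e-6, 0.5), spectra, channels, "F530", "F500"
        )
        assert limiting_ratios["r_min"] < m.ratio < limiting_ratios["r_max"]

    def test_missing_spectrum_warns_and_contributes_nothing(self, spectra, channels):
        state = SpeciationResult(
            free={"sensor": 1e-6, "mystery": 1e-6},
            complexes={}, residuals={}, converged=True, iterations=0,
        )
        with pytest.warns(UserWarning, match="mystery"):
            m = compose_channel_intensities(state, spectra, channels, "F530", "F500")
        ref = compose_channel_intensities(
            mixture_state(1e-6, 0.0), spectra, channels, "F530", "F500"
        )
        assert m.intensities == pytest.approx(ref.intensities)

    def test_zero_denominator_flagged_not_raised(self, channels):
        dark = {"sensor": SpeciesSpectrum("sensor", [], brightness=0.0)}
        m = compose_channel_intensities(
            mixture_state(1e-6, 0.0), dark, channels, "F530", "F500"
        )
        assert not m.ratio_defined
        assert np.isnan(m.ratio)

    def test_ratiometric_invariance_to_sensor_total(
        self, spectra, channels
    ):
        """The ratio cancels sensor concentration over >= 3 decades."""
        f = fraction_bound(0.14e-3, 0.5e-3)
        ratios = [
            compose_channel_intensities(
                mixture_state(s, f), spectra, channels, "F530", "F500"
            ).ratio
            for s in np.logspace(-7, -4, 7)  # 0.1 to 100 uM
        ]
        assert np.ptp(ratios) / ratios[0] < 1e-3


class TestRatioIsotherm:
    def test_zero_metal_point_sits_at_r_min(self, spectra, channels, limiting_ratios):
        out = ratio_isotherm(
            0.14e-3, 10e-6, [0.0, 1e-6], spectra, channels, "F530", "F500"
        )
        assert out[0].ratio == pytest.approx(limiting_ratios["r_min"], rel=1e-9)

    def test_saturating_metal_approaches_r_max(self, spectra, channels, limiting_ratios):
        out = ratio_isotherm(
            0.14e-3, 10e-6, [0.0, 50e-3], spectra, channels, "F530", "F500"
        )
        assert out[-1].ratio == pytest.approx(limiting_ratios["r_max"], rel=0.01)

    def test_monotone_in_metal(self, spectra, channels):
        grid = np.logspace(-6, -1, 10)
        out = ratio_isotherm(0.14e-3, 10e-6, grid, spectra, channels, "F530", "F500")
        ratios = [m.ratio for m in out]
        assert np.all(np.diff(ratios) > 0)

    def test_half_saturation_ratio_at_kd(self, spectra, channels, limiting_ratios):
        """With s_total << kd, the ratio at [M]=Kd is the beta-weighted
        midpoint (R_max + beta R_min) / (1 + beta)."""
        kd = 0.14e-3
        out = ratio_isotherm(
            kd, 1e-9, [0.0, kd], spectra, channels, "F530", "F500"
        )
        r_mid = (limiting_ratios["r_max"] + limiting_ratios["beta"] * limiting_ratios["r_min"]) / (
            1 + limiting_ratios["beta"]
        )
        assert out[-1].ratio == pytest.approx(r_mid, rel=1e-4)


class TestRatioInversion:
    def test_near_r_min_maps_to_near_zero(self, limiting_ratios):
        lr = limiting_ratios
        m = ratio_to_free_metal(
            lr["r_min"] * 1.000001, lr["r_min"], lr["r_max"], 0.14e-3, lr["beta"]
        )
        assert 0 < m < 1e-8

    def test_out_of_range_names_saturated_direction(self, limiting_ratios):
        lr = limiting_ratios
        with pytest.raises(ValueError, match="saturated"):
            ratio_to_free_metal(lr["r_max"] + 1, lr["r_min"], lr["r_max"], 1e-3, 1.0)
        with pytest.raises(ValueError, match="metal-free"):
            ratio_to_free_metal(lr["r_min"] - 1, lr["r_min"], lr["r_max"], 1e-3, 1.0)

    @pytest.mark.parametrize("m_over_kd", np.logspace(-2, 2, 9))
    def test_round_trip_isotherm_then_invert(
        self, m_over_kd, spectra, channels, limiting_ratios
    ):
        """Forward-compose a ratio at free metal M, invert, recover M to 0.1%."""
        kd = 0.14e-3
        m_true = kd * m_over_kd
        out = ratio_isotherm(
            kd, 1e-10, [0.0, m_true], spectra, channels, "F530", "F500"
        )  # s_total << kd so free metal ~= total
        lr = limiting_ratios
        m_rec = ratio_to_free_metal(
            out[-1].ratio, lr["r_min"], lr["r_max"], kd, lr["beta"]
        )
        assert m_rec == pytest.approx(m_true, rel=1e-3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(ratio_frac=st.floats(1e-6, 1 - 1e-6))
    def test_inversion_strictly_increasing(self, ratio_frac, limiting_ratios):
        lr = limiting_ratios
        r = lr["r_min"] + ratio_frac * (lr["r_max"] - lr["r_min"])
        m = ratio_to_free_metal(r, lr["r_min"], lr["r_max"], 1e-3, lr["beta"])
        r2 = min(r * 1.001, lr["r_max"] * (1 - 1e-9))
        if r2 > r:
            m2 = ratio_to_free_metal(r2, lr["r_min"], lr["r_max"], 1e-3, lr["beta"])
            assert m2 > m


class TestChannelSet:
    def test_requires_two_channels(self):
        with pytest.raises(ValueError):
            ChannelSet(390.0, [Channel("only", 500, 1)])

    def test_parse_compact_spec(self):
        cs = ChannelSet.parse("BP450:450/50,BP530:530/30", excitation=405)
        assert cs["BP450"].bandwidth == 50
        assert cs["BP530"].center == 530
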