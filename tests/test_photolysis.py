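"""Direct-photolysis kinetics: screening, speciation, rate summation, schedules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import flat_quantum_spectrum
from parcf.exceptions import ConfigurationError
from parcf.photolysis import (
    LN10,
    Compound,
    KdModel,
    WaterBody,
    annual_average_k,
    apparent_k,
    half_life,
    k_direct,
    kd_from_doc,
    phenolate_fraction,
    rate_result,
    screening_factor,
    seasonal_rate_distributions,
    two_depth_schedule,
)
from parcf.spectra import WAVELENGTHS_NM, Spectrum


class TestScreeningFactor:
    def test_optically_thin_limit(self):
        assert screening_factor(1e-9) == pytest.approx(1.0, abs=1e-8)

    def test_unit_optical_depth_closed_form(self):
        assert screening_factor(1.0) == pytest.approx((1 - 0.1) / np.log(10), abs=1e-12)

    def test_strictly_decreasing(self):
        assert screening_factor(2.0) < screening_factor(1.0) < screening_factor(0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(x=st.floats(1e-12, 50.0))
    def test_bounded_in_unit_interval(self, x):
        s = screening_factor(x)
        assert 0.0 < s <= 1.0

    def test_series_branch_continuous_at_cutoff(self):
        # S(x) ~ 1 - x ln10 / 2 near 0, so the two evaluations differ by
        # ~2.3e-9 from the argument change alone; the branch switch itself
        # must add nothing beyond that
        below, above = screening_factor(0.999e-6), screening_factor(1.001e-6)
        drift = 0.002e-6 * np.log(10) / 2
        assert abs(below - above) < drift + 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            screening_factor(-0.1)
        with pytest.raises(ConfigurationError):
            screening_factor(1.0, z=0.0)


class TestKdModel:
    def test_zero_doc_no_baseline_is_transparent(self):
        kd = kd_from_doc(0.0, KdModel(a=0.5, b=1.2))
        assert not kd.any()
        assert screening_factor(kd[0], z=100.0) == pytest.approx(1.0)

    def test_linear_closed_form(self):
        kd = kd_from_doc(2.0, KdModel(a=0.5, b=1.0))
        assert np.allclose(kd, 1.0)

    def test_doubling_doc_doubles_kd_at_unit_exponent(self):
        model = KdModel(a=0.3, b=1.0)
        assert np.allclose(kd_from_doc(4.0, model), 2 * kd_from_doc(2.0, model))

    def test_missing_coefficients_guide_the_user(self):
        with pytest.raises(ConfigurationError, match="Kd"):
            kd_from_doc(2.0, None)


def _monochromatic_spectrum(wavelength, intensity):
    irr = np.where(WAVELENGTHS_NM == wavelength, intensity, 0.0)
    return Spectrum(irr, units="quantum")


def _uniform_compound(eps=1000.0, phi=0.1, pka=None):
    return Compound(
        epsilon=np.full(WAVELENGTHS_NM.shape, eps), quantum_yield=phi, pka=pka
    )


class TestKDirect:
    def test_zero_spectrum_gives_zero(self):
        spec = Spectrum(np.zeros(WAVELENGTHS_NM.shape), units="quantum")
        assert k_direct(spec, _uniform_compound(), None) == 0.0

    def test_monochromatic_unit_analysis_oracle(self):
        # single 1 nm bin; hand unit analysis: the mmol -> mol factor (1e-3)
        # cancels the litre -> cm^3 factor (1e3) in the molar absorptivity,
        # so k = ln10 * I0 * eps * phi * dl exactly
        spec = _monochromatic_spectrum(400.0, 1e-6)
        compound = Compound(
            epsilon=np.where(WAVELENGTHS_NM == 400.0, 1000.0, 0.0),
            quantum_yield=0.1,
        )
        expected = LN10 * 1e-6 * 1000.0 * 0.1 * 1.0
        assert k_direct(spec, compound, None) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_spectrum(self):
        spec = flat_quantum_spectrum(2e-6)
        compound = _uniform_compound()
        k1 = k_direct(spec, compound, None)
        k2 = k_direct(spec.scale(0.76), compound, None)
        assert k2 == pytest.approx(0.76 * k1, rel=1e-15)

    def test_five_wavelength_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        wavelengths = [310.0, 380.0, 450.0, 520.0, 690.0]
        irr = np.zeros(WAVELENGTHS_NM.shape)
        eps = np.zeros(WAVELENGTHS_NM.shape)
        for w in wavelengths:
            irr[WAVELENGTHS_NM == w] = rng.uniform(1e-7, 1e-5)
            eps[WAVELENGTHS_NM == w] = rng.uniform(10, 5000)
        phi = 0.31
        kd = np.full(WAVELENGTHS_NM.shape, 0.002)
        water = WaterBody(ph=7.0, kd_table=kd, depth_schedule={6: 500.0})
        z = 500.0
        # independent summation oracle
        expected = 0.0
        for w in wavelengths:
            i = np.flatnonzero(WAVELENGTHS_NM == w)[0]
            s = (1 - 10 ** (-kd[i] * z)) / (np.log(10) * kd[i] * z)
            expected += np.log(10) * irr[i] * eps[i] * phi * s
        k = k_direct(Spectrum(irr, units="quantum"), Compound(eps, phi), water, z)
        assert k == pytest.approx(expected, rel=1e-12)

    def test_optically_thin_depth_average_matches_surface(self):
        spec = flat_quantum_spectrum(1e-6)
        compound = _uniform_compound()
        water = WaterBody(ph=7.0, kd_table=np.full(WAVELENGTHS_NM.shape, 1e-6),
                          depth_schedule={6: 100.0})
        k_surface = k_direct(spec, compound, None)
        k_depth = k_direct(spec, compound, water, 100.0)  # Kd*z = 1e-4
        assert k_depth == pytest.approx(k_surface, rel=1e-3)

    def test_monotone_decreasing_in_depth_and_attenuation(self):
        spec = flat_quantum_spectrum(1e-6)
        compound = _uniform_compound()
        water = WaterBody(ph=7.0, kd_table=np.full(WAVELENGTHS_NM.shape, 0.005),
                          depth_schedule={})
        k_shallow = k_direct(spec, compound, water, 200.0)
        k_deep = k_direct(spec, compound, water, 1000.0)
        assert k_deep < k_shallow
        water2 = WaterBody(ph=7.0, kd_table=np.full(WAVELENGTHS_NM.shape, 0.05),
                           depth_schedule={})
        assert k_direct(spec, compound, water2, 200.0) < k_shallow

    def test_natural_log_kd_convention(self):
        spec = flat_quantum_spectrum(1e-6)
        compound = _uniform_compound()
        kd_dec = np.full(WAVELENGTHS_NM.shape, 0.01)
        decadic = WaterBody(ph=7.0, kd_table=kd_dec, depth_schedule={})
        natural = WaterBody(ph=7.0, kd_table=kd_dec * LN10, depth_schedule={},
                            kd_convention="natural")
        assert k_direct(spec, compound, natural, 300.0) == pytest.approx(
            k_direct(spec, compound, decadic, 300.0), rel=1e-12
        )


class TestSpeciation:
    def test_half_dissociated_at_pka(self):
        assert phenolate_fraction(8.05, 8.05) == pytest.approx(0.5)

    def test_lake_conditions_closed_form(self):
        # pH 8.6 water, pKa 8.05 phenol: alpha = 1/(1 + 10^-0.55)
        assert phenolate_fraction(8.6, 8.05) == pytest.approx(0.7802, abs=1e-4)

    def test_fully_dissociated_limit(self):
        assert phenolate_fraction(11.05, 8.05) == pytest.approx(0.999, abs=5e-4)

    def test_apparent_k_scales_by_fraction(self):
        assert apparent_k(1e-6, 8.05, 8.05) == pytest.approx(5e-7)
        assert apparent_k(1e-6, 9.0, 8.05) <= 1e-6

    def test_apparent_k_monotone_in_ph(self):
        ks = [apparent_k(1e-6, ph, 8.05) for ph in (6.0, 7.0, 8.0, 9.0, 10.0)]
        assert all(a < b for a, b in zip(ks, ks[1:]))


class TestHalfLife:
    def test_lake_case_study_value(self):
        # k = 5.48e-7 s^-1 corresponds to a 14.6 day half-life
        assert half_life(5.48e-7) == pytest.approx(14.6, abs=0.05)

    def test_one_second_half_life(self):
        assert half_life(np.log(2)) == pytest.approx(1 / 86400, rel=1e-12)

    def test_doubling_k_halves_half_life(self):
        assert half_life(2e-7) == pytest.approx(half_life(1e-7) / 2, rel=1e-12)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ConfigurationError):
            half_life(0.0)


class TestAnnualAverage:
    def _water(self, schedule):
        return WaterBody(ph=8.6, kd_table=np.full(WAVELENGTHS_NM.shape, 0.001),
                         depth_schedule=schedule)

    def test_constant_inputs_give_constant_annual_k(self):
        spectra = {m: flat_quantum_spectrum(1e-6) for m in range(1, 13)}
        compound = _uniform_compound(pka=8.05)
        water = self._water({m: 500.0 for m in range(1, 13)})
        k_annual = annual_average_k(spectra, compound, water)
        k_june = apparent_k(
            k_direct(spectra[6], compound, water, 500.0), water.ph, compound.pka
        )
        assert k_annual == pytest.approx(k_june, rel=1e-12)

    def test_deeper_mixing_slows_photolysis(self):
        spectra = {m: flat_quantum_spectrum(1e-6) for m in range(1, 13)}
        compound = _uniform_compound(pka=8.05)
        shallow = self._water({m: 500.0 for m in range(1, 13)})
        deep = self._water({m: 1780.0 for m in range(1, 13)})
        assert annual_average_k(spectra, compound, deep) < annual_average_k(
            spectra, compound, shallow
        )

    def test_two_depth_schedule_matches_hand_weighted_mean(self):
        spectra = {m: flat_quantum_spectrum(1e-6) for m in range(1, 13)}
        compound = _uniform_compound(pka=8.05)
        schedule = two_depth_schedule(1780.0, 500.0)  # mixed Dec-Mar
        water = self._water(schedule)
        k_annual = annual_average_k(spectra, compound, water, year=2020)
        # arithmetic oracle: day-count-weighted mean of the two k levels
        k_mixed = apparent_k(
            k_direct(spectra[1], compound, water, 1780.0), water.ph, compound.pka
        )
        k_strat = apparent_k(
            k_direct(spectra[6], compound, water, 500.0), water.ph, compound.pka
        )
        days_mixed = 31 + 29 + 31 + 31  # Dec, Jan, Feb, Mar of a leap year
        expected = (days_mixed * k_mixed + (366 - days_mixed) * k_strat) / 366
        assert k_annual == pytest.approx(expected, rel=1e-12)

    def test_missing_month_rejected(self):
        spectra = {m: flat_quantum_spectrum(1e-6) for m in range(1, 12)}
        with pytest.raises(ConfigurationError):
            annual_average_k(spectra, _uniform_compound(pka=8.05),
                             self._water({m: 500.0 for m in range(1, 13)}))


class TestSeasonalDistributions:
    def _daily_inputs(self, cf_value=1.0, rng=None):
        days = pd.date_range("2020-01-01", "2020-12-31", freq="D")
        spectra, cfs = {}, {}
        for i, day in enumerate(days):
            level = 1e-6 * (1 + 0.5 * np.sin(2 * np.pi * day.dayofyear / 366))
            spectra[day] = flat_quantum_spectrum(level)
            if rng is None:
                cfs[day] = cf_value
            else:
                cfs[day] = rng.uniform(0.4, 1.0)
        return spectra, cfs

    def test_unit_cf_gives_identical_distributions(self):
        spectra, cfs = self._daily_inputs(1.0)
        water = WaterBody(ph=8.6, depth_schedule={})
        stats = seasonal_rate_distributions(spectra, cfs,
                                            _uniform_compound(pka=8.05), water)
        wide = stats.pivot(index="season", columns="scenario", values="median")
        assert np.allclose(wide["clear_sky"], wide["cf_corrected"])

    def test_half_cf_halves_median(self):
        spectra, cfs = self._daily_inputs(0.5)
        water = WaterBody(ph=8.6, depth_schedule={})
        stats = seasonal_rate_distributions(spectra, cfs,
                                            _uniform_compound(pka=8.05), water)
        wide = stats.pivot(index="season", columns="scenario", values="median")
        assert np.allclose(wide["cf_corrected"], 0.5 * wide["clear_sky"])

    def test_variable_cf_widens_relative_spread(self):
        spectra, cfs = self._daily_inputs(rng=np.random.default_rng(12))
        water = WaterBody(ph=8.6, depth_schedule={})
        stats = seasonal_rate_distributions(spectra, cfs,
                                            _uniform_compound(pka=8.05), water)
        for season, sub in stats.groupby("season"):
            sub = sub.set_index("scenario")
            rel_spread = {
                s: (sub.loc[s, "q3"] - sub.loc[s, "q1"]) / sub.loc[s, "median"]
                for s in ("clear_sky", "cf_corrected")
            }
            assert rel_spread["cf_corrected"] > rel_spread["clear_sky"]

    def test_whiskers_respect_tukey_fences(self):
        spectra, cfs = self._daily_inputs(rng=np.random.default_rng(13))
        water = WaterBody(ph=8.6, depth_schedule={})
        stats = seasonal_rate_distributions(spectra, cfs,
                                            _uniform_compound(pka=8.05), water)
        for _, row in stats.iterrows():
            iqr = row["q3"] - row["q1"]
            assert row["whisker_low"] >= row["q1"] - 1.5 * iqr - 1e-18
            assert row["whisker_high"] <= row["q3"] + 1.5 * iqr + 1e-18
            assert row["whisker_low"] <= row["q1"] <= row["median"] <= row["q3"] <= row["whisker_high"]


def test_rate_result_bundles_consistent_quantities():
    spec = flat_quantum_spectrum(1e-6)
    compound = _uniform_compound(pka=8.05)
    water = WaterBody(ph=8.6, kd_table=np.full(WAVELENGTHS_NM.shape, 0.001),
                      depth_schedule={6: 500.0})
    res = rate_result(spec, compound, water, 500.0)
    assert res.k_app == pytest.approx(res.k_dir * phenolate_fraction(8.6, 8.05))
    assert res.half_life_days == pytest.approx(half_life(res.k_app))
    assert res.contributions["dk"].sum() == pytest.approx(res.k_dir, rel=1e-12)
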