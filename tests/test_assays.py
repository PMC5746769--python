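"""Generators (binding, swelling, scanning) and assay analytics
(endpoint/rate signals, 4PL calibration, LOD, regeneration, band extraction)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from wlrs import (
    BindingParams,
    InvalidInputError,
    ScanLayout,
    build_calibration,
    endpoint_signal,
    extract_band_signals,
    four_parameter_logistic,
    initial_rate,
    regeneration_stats,
    sensorgram_to_spectra,
    simulate_binding,
    simulate_scan,
    simulate_swelling,
)

from .oracles import langmuir_thickness


class TestSimulateBinding:
    times = np.linspace(0.0, 600.0, 301)

    def test_zero_concentration_flat(self):
        p = BindingParams(k_on=1e5, k_off=1e-3, analyte_conc=0.0, d_max=5.0)
        sg = simulate_binding(p, self.times)
        assert np.all(sg.thickness == 0.0)

    def test_matches_closed_form(self):
        p = BindingParams(k_on=1e5, k_off=1e-3, analyte_conc=2e-8, d_max=5.0)
        sg = simulate_binding(p, self.times)
        ref = langmuir_thickness(p.k_on, p.k_off, p.analyte_conc, p.d_max, self.times)
        assert np.allclose(sg.thickness, ref, atol=1e-12)

    @given(
        k_on=st.floats(1e3, 1e7),
        k_off=st.floats(1e-5, 1e-1),
        conc=st.floats(1e-12, 1e-5),
        d_max=st.floats(0.5, 20.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_equilibrium_identity(self, k_on, k_off, conc, d_max):
        """Plateau/d_max = C/(C + K_D) to 1e-9 for all parameter draws."""
        p = BindingParams(k_on=k_on, k_off=k_off, analyte_conc=conc, d_max=d_max)
        k_obs = k_on * conc + k_off
        t_inf = np.array([0.0, 50.0 / k_obs])
        sg = simulate_binding(p, t_inf)
        expected = conc / (conc + k_off / k_on)
        assert sg.thickness[-1] / d_max == pytest.approx(expected, abs=1e-9)

    def test_initial_slope_matches_analytic_derivative(self):
        p = BindingParams(k_on=1e5, k_off=1e-3, analyte_conc=1e-8, d_max=5.0)
        dt = 1e-4
        sg = simulate_binding(p, np.array([0.0, dt]))
        fd = (sg.thickness[1] - sg.thickness[0]) / dt
        assert fd == pytest.approx(p.d_max * p.k_on * p.analyte_conc, rel=1e-3)

    def test_dissociation_decays_with_k_off(self):
        p = BindingParams(k_on=1e5, k_off=1e-2, analyte_conc=1e-7, d_max=5.0)
        t = np.linspace(0.0, 1200.0, 601)
        sg = simulate_binding(p, t, dissociation_start=600.0)
        d600 = sg.thickness[t == 600.0][0]
        after = t > 600.0
        expected = d600 * np.exp(-p.k_off * (t[after] - 600.0))
        assert np.allclose(sg.thickness[after], expected, atol=1e-12)


class TestSimulateSwelling:
    def test_zero_swelling_constant(self):
        sg = simulate_swelling(0.0, tau=10.0, baseline=55.0, times=np.linspace(0, 100, 11))
        assert np.all(sg.thickness == 55.0)

    def test_63_percent_at_tau(self):
        sg = simulate_swelling(0.10, tau=30.0, baseline=55.0, times=np.array([0.0, 30.0]))
        step = 55.0 * 0.10
        completed = (sg.thickness[1] - 55.0) / step
        assert completed == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_sorption_desorption_returns_to_baseline(self):
        t = np.linspace(0.0, 600.0, 1201)
        sg = simulate_swelling(0.10, tau=30.0, baseline=55.0, times=t, desorption_start=300.0)
        final = sg.thickness[-1]
        # 5 tau after desorption start: within 0.1% of baseline
        assert abs(final - 55.0) / 55.0 < 1e-3


class TestSensorgramToSpectra:
    def test_noiseless_constant_sensorgram_identical_spectra(self, chip_with_adlayer, grid):
        from wlrs import Sensorgram

        sg = Sensorgram(times=np.arange(3.0), thickness=np.full(3, 2.0))
        series = sensorgram_to_spectra(sg, chip_with_adlayer, grid, 0.0, seed=0)
        assert np.array_equal(series[0][1].values, series[2][1].values)

    def test_seed_determinism(self, chip_with_adlayer, grid):
        from wlrs import Sensorgram

        sg = Sensorgram(times=np.arange(4.0), thickness=np.linspace(0, 3, 4))
        a = sensorgram_to_spectra(sg, chip_with_adlayer, grid, 0.01, seed=42)
        b = sensorgram_to_spectra(sg, chip_with_adlayer, grid, 0.01, seed=42)
        for (ta, sa), (tb, sb) in zip(a, b):
            assert ta == tb and np.array_equal(sa.values, sb.values)

    def test_unknown_adlayer_rejected(self, sio2_1000, grid):
        from wlrs import Sensorgram

        sg = Sensorgram(times=np.arange(2.0), thickness=np.zeros(2))
        with pytest.raises(InvalidInputError):
            sensorgram_to_spectra(sg, sio2_1000, grid, 0.0, seed=0)


class TestSignals:
    params = BindingParams(k_on=1e5, k_off=1e-3, analyte_conc=1e-8, d_max=5.0)

    def test_endpoint_of_flat_run_is_zero(self):
        p = BindingParams(k_on=1e5, k_off=1e-3, analyte_conc=0.0, d_max=5.0)
        sg = simulate_binding(p, np.linspace(0, 600, 61))
        assert endpoint_signal(sg, 600.0) == 0.0

    def test_endpoint_matches_closed_form_midcourse(self):
        sg = simulate_binding(self.params, np.linspace(0, 600, 601))
        expected = langmuir_thickness(1e5, 1e-3, 1e-8, 5.0, np.array([300.0]))[0]
        assert endpoint_signal(sg, 300.0) == pytest.approx(expected, abs=1e-9)

    def test_endpoint_reaches_plateau(self):
        p = BindingParams(k_on=1e6, k_off=1e-3, analyte_conc=1e-6, d_max=5.0)
        sg = simulate_binding(p, np.linspace(0, 60, 301))
        assert endpoint_signal(sg, 60.0) == pytest.approx(p.equilibrium_thickness, rel=1e-6)

    def test_initial_rate_constant_run_is_zero(self):
        p = BindingParams(k_on=1e5, k_off=1e-3, analyte_conc=0.0, d_max=5.0)
        sg = simulate_binding(p, np.linspace(0, 600, 61))
        assert initial_rate(sg, 60.0) == 0.0

    def test_initial_rate_approaches_analytic_slope(self):
        sg = simulate_binding(self.params, np.linspace(0, 600, 60001))
        slope = initial_rate(sg, 0.05)  # window → 0 limit
        assert slope == pytest.approx(self.params.d_max * 1e5 * 1e-8, rel=1e-3)

    def test_rate_linear_in_concentration_below_kd(self):
        """At C ≪ K_D the initial rate is proportional to C (r² > 0.999)."""
        kd = 1e-8  # k_off/k_on
        concs = np.logspace(-12, -10, 6)  # well below K_D
        rates = []
        for c in concs:
            p = BindingParams(k_on=1e5, k_off=1e-3, analyte_conc=c, d_max=5.0)
            sg = simulate_binding(p, np.linspace(0, 60, 601))
            rates.append(initial_rate(sg, 60.0))
        r = np.corrcoef(concs, rates)[0, 1]
        assert r**2 > 0.999

    def test_endpoint_and_rate_rank_concentrations_identically(self):
        concs = np.logspace(-10, -7, 7)
        ends, rates = [], []
        for c in concs:
            p = BindingParams(k_on=1e5, k_off=1e-3, analyte_conc=c, d_max=5.0)
            sg = simulate_binding(p, np.linspace(0, 600, 601))
            ends.append(endpoint_signal(sg, 600.0))
            rates.append(initial_rate(sg, 60.0))
        rho, _ = spearmanr(ends, rates)
        assert rho == 1.0


class TestCalibration:
    @staticmethod
    def _table(direction, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        a, b, c, d = (0.05, 1.2, 1.0, 3.0) if direction == "up" else (3.0, 1.2, 1.0, 0.05)
        concs = np.concatenate([[0.0] * 4, np.logspace(-2, 2, 9)])
        y = four_parameter_logistic(concs, a, b, c, d)
        if noise_sd:
            y = y + noise_sd * rng.standard_normal(y.shape)
        return concs, y, (a, b, c, d)

    def test_4pl_self_inversion(self):
        concs, y, truth = self._table("up", noise_sd=1e-4, seed=1)
        curve = build_calibration(concs, y, format="direct")
        for got, want in zip(curve.model_params, truth):
            assert got == pytest.approx(want, rel=1e-2)
        assert curve.monotone

    def test_competitive_direction_enforced(self):
        concs, y, _ = self._table("down", noise_sd=1e-4, seed=2)
        curve = build_calibration(concs, y, format="competitive")
        assert curve.monotone
        xs = np.logspace(-2, 2, 50)
        pred = curve.predict(xs)
        assert np.all(np.diff(pred) < 0)

    def test_wrong_direction_flagged(self):
        concs, y, _ = self._table("up", noise_sd=1e-4, seed=3)
        curve = build_calibration(concs, y, format="competitive")
        assert not curve.monotone

    def test_degenerate_blank_flagged(self):
        concs, y, _ = self._table("up")  # exactly on the curve: blank SD = 0
        curve = build_calibration(concs, y, format="direct")
        assert curve.degenerate_blank
        assert curve.lod == 0.0

    def test_lod_tracks_blank_noise(self):
        """LOD within 2-fold of the analytic blank+3SD crossing, across seeds."""
        a, b, c, d = 0.05, 1.2, 1.0, 3.0
        sd = 0.01
        # analytic: dose where 4PL rises 3*sd above a
        y_crit = a + 3 * sd
        analytic = c * ((a - d) / (y_crit - d) - 1) ** (1 / b)
        for seed in (1, 2, 3, 4, 5):
            concs, y, _ = self._table("up", noise_sd=sd, seed=seed)
            curve = build_calibration(concs, y, format="direct")
            assert analytic / 2 < curve.lod < analytic * 2

    def test_requires_blank_and_enough_levels(self):
        with pytest.raises(InvalidInputError):
            build_calibration(np.array([1.0, 2, 3, 4, 5]), np.ones(5))  # no blank
        with pytest.raises(InvalidInputError):
            build_calibration(np.array([0.0, 1, 2]), np.ones(3))


class TestRegeneration:
    def test_identical_cycles_zero_cv(self):
        stats = regeneration_stats(np.full(20, 2.5))
        assert stats.cv_percent == 0.0
        assert stats.within_tolerance

    def test_two_cycle_cv(self):
        stats = regeneration_stats(np.array([100.0, 110.0]))
        assert stats.cv_percent == pytest.approx(100 * np.std([100, 110], ddof=1) / 105, abs=1e-9)
        assert stats.cv_percent == pytest.approx(6.7343, abs=1e-3)

    def test_twenty_cycles_within_five_percent(self):
        rng = np.random.default_rng(0)
        cycles = 100.0 * (1 + 0.04 * (2 * rng.random(20) - 1))  # ±4% of cycle 1 scale
        cycles[0] = 100.0
        stats = regeneration_stats(cycles)
        assert stats.max_abs_deviation_percent <= 5.0
        assert stats.within_tolerance

    def test_excursion_detected(self):
        stats = regeneration_stats(np.array([100.0, 100.0, 112.0]))
        assert not stats.within_tolerance
        assert stats.max_abs_deviation_percent == pytest.approx(12.0)


class TestScan:
    layout = ScanLayout(
        band_width=0.5, band_pitch=1.0, n_bands=7, probe_spot_fwhm=0.4, step=0.25
    )

    def test_zero_width_spot_exact_tophat(self):
        layout = ScanLayout(band_width=0.5, band_pitch=1.0, n_bands=3, probe_spot_fwhm=0.0, step=0.25)
        pos, sig = simulate_scan(layout, noise_sd=0.0)
        for x, s in zip(pos, sig):
            inside = any(
                layout.band_edges(i)[0] <= x < layout.band_edges(i)[1] for i in range(3)
            )
            assert s == (1.0 if inside else 0.0)

    def test_huge_spot_merges_bands(self):
        layout = ScanLayout(
            band_width=0.5, band_pitch=1.0, n_bands=7, probe_spot_fwhm=10.0, step=0.1
        )
        pos, sig = simulate_scan(layout, noise_sd=0.0)
        mid = (pos > 0.5) & (pos < layout.span - 0.5)
        contrast = (sig[mid].max() - sig[mid].min()) / (sig[mid].max() + sig[mid].min())
        assert contrast < 0.10
        bands = extract_band_signals(pos, sig, layout)
        assert bands.overlap_flag

    def test_seven_band_discrimination_with_noise(self):
        """7 bands, 0.5/1.0 mm, step 0.25 mm, 0.4 mm spot, 1% noise: CV < 5%."""
        cvs = []
        for seed in range(10):
            pos, sig = simulate_scan(self.layout, noise_sd=0.01, seed=seed)
            bands = extract_band_signals(pos, sig, self.layout)
            assert not bands.overlap_flag
            cvs.append(bands.cv_percent)
        assert max(cvs) < 5.0

    def test_double_response_band_recovered(self):
        layout = ScanLayout(
            band_width=0.5,
            band_pitch=1.0,
            n_bands=5,
            probe_spot_fwhm=0.2,
            step=0.05,
            band_responses=(1.0, 1.0, 2.0, 1.0, 1.0),
        )
        pos, sig = simulate_scan(layout, noise_sd=0.0)
        bands = extract_band_signals(pos, sig, layout)
        assert bands.band_means[2] / np.mean(np.delete(bands.band_means, 2)) == pytest.approx(
            2.0, rel=0.02
        )

    def test_uniform_profile_zero_cv(self):
        layout = ScanLayout(band_width=1.0, band_pitch=1.0, n_bands=4, probe_spot_fwhm=0.0, step=0.1)
        pos, sig = simulate_scan(layout, noise_sd=0.0)
        bands = extract_band_signals(pos, sig, layout)
        assert bands.cv_percent == pytest.approx(0.0, abs=1e-12)

    def test_invalid_layout_rejected(self):
        with pytest.raises(InvalidInputError):
            ScanLayout(band_width=2.0, band_pitch=1.0)
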