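"""Detection model, rate equations, Monte Carlo, sinogram binning."""

import numpy as np
import pytest

from petprompt.acquisition import (Coincidence, EnergyWindow, ScannerModel,
                                   _photopeak_window_mass, bin_sinogram,
                                   blur_energy, counting_rates,
                                   f18_sensitivity, prompt_emission_fraction,
                                   prompt_fraction_model,
                                   sample_contaminated_sinogram,
                                   simulate_coincidences, singles_yield,
                                   Sinogram)
from petprompt.physics import builtin_radionuclides


class TestEnergyWindow:
    def test_half_open(self):
        w = EnergyWindow(350, 650)
        assert w.contains(350) and w.contains(649.9) and not w.contains(650)

    def test_parse(self):
        assert EnergyWindow.parse("450-750") == EnergyWindow(450, 750)

    def test_invalid(self):
        with pytest.raises(ValueError):
            EnergyWindow(650, 350)


class TestEnergyBlur:
    def test_empirical_fwhm_at_511(self, scanner, rng):
        e = blur_energy(np.full(100_000, 511.0), scanner, rng)
        fwhm = e.std() * 2.3548
        assert fwhm / 511.0 == pytest.approx(0.11, abs=0.005)

    def test_empirical_fwhm_at_364(self, scanner, rng):
        e = blur_energy(np.full(100_000, 364.0), scanner, rng)
        expected = 0.11 * np.sqrt(511 * 364)   # ≈ 47.4 keV
        assert e.std() * 2.3548 == pytest.approx(expected, rel=0.03)
        assert e.mean() == pytest.approx(364.0, abs=0.5)

    def test_zero_variance_debug_mode(self, scanner):
        assert blur_energy(511.0, scanner, zero_variance=True) == 511.0


class TestSinglesYield:
    def test_364_line_rejected_by_450_threshold(self, scanner):
        """The blurred 364 keV photopeak leaks < 1e-4 of its mass above a
        450 keV lower discriminator (> 4σ away)."""
        assert _photopeak_window_mass(364.0, EnergyWindow(450, 650),
                                      scanner) < 1e-4

    def test_wide_window_recovers_interacting_intensity(self):
        """With ~unit geometric acceptance and a window covering every
        deposit, the singles yield is the total interacting intensity."""
        sc = ScannerModel(axial_fov_mm=1e9, singles_yield_scale=1.0)
        i131 = builtin_radionuclides()["I-131"]
        got = singles_yield(i131, EnergyWindow(0.1, 1e4), sc)
        from petprompt.tables import load_detector_response
        resp = load_detector_response()
        want = sum(l.intensity * resp.interaction(l.energy_kev)
                   for l in i131.gamma_lines)
        assert got == pytest.approx(want, rel=5e-3)

    def test_f18_yield_consistent_with_sensitivity(self, scanner):
        """Pair-detection relation: S_w = y·G·p² with p from the yield."""
        f18 = builtin_radionuclides()["F-18"]
        y = singles_yield(f18, EnergyWindow(350, 650), scanner)
        geo = scanner.geometric_acceptance
        p = y / (2 * f18.positron_yield * geo)
        assert f18.positron_yield * geo * p**2 == pytest.approx(0.070)

    def test_window_nesting_of_yields(self, calibrated):
        i131 = builtin_radionuclides()["I-131"]
        y = {w: singles_yield(i131, EnergyWindow(*w), calibrated)
             for w in [(450, 650), (350, 650), (350, 750)]}
        assert y[(450, 650)] <= y[(350, 650)] <= y[(350, 750)]


class TestCountingRates:
    def test_f18_only_zero_fraction(self, calibrated):
        r = counting_rates({"F-18": 100.0}, "350-650", calibrated)
        assert r.fraction_percent == 0.0

    def test_cross_accidental_closed_form(self, calibrated):
        """2τR₁R₂ with τ=3.4 ns and R₁=R₂=1e5 cps gives 68 cps."""
        tau = 3.4e-9
        assert 2 * tau * 1e5 * 1e5 == pytest.approx(68.0)

    def test_calibration_point_matches_table(self, calibrated, table):
        f = prompt_fraction_model(300.0, 100.0, "350-650", calibrated)
        assert f == pytest.approx(table.lookup(300, (350, 650)), abs=1e-9)

    def test_empty_phantom_rejected(self, calibrated):
        with pytest.raises(ValueError):
            counting_rates({}, "350-650", calibrated)

    def test_components_nonnegative_and_sum(self, calibrated):
        r = counting_rates({"F-18": 100.0, "I-131": 300.0}, "350-650",
                           calibrated)
        parts = [r.f18_trues_cps, r.f18_scatter_cps, r.f18_randoms_cps,
                 r.i131_accidental_cps]
        assert all(p >= 0 for p in parts)
        assert r.total_prompts_cps == pytest.approx(sum(parts))

    def test_fraction_monotone_in_activity(self, calibrated):
        fracs = [prompt_fraction_model(a, 100.0, "350-650", calibrated)
                 for a in np.arange(0, 10001, 250)[1:]]
        assert np.all(np.diff(fracs) >= 0)

    def test_450_window_fraction_two_orders_below(self, calibrated):
        lo = prompt_fraction_model(1000.0, 100.0, "450-650", calibrated)
        hi = prompt_fraction_model(1000.0, 100.0, "350-650", calibrated)
        assert hi / lo >= 100.0


class TestFraction:
    @pytest.mark.parametrize("i,f,expect", [
        (0, 110_000, 0.0),
        (15_000, 0, 100.0),
        (15_000, 110_000, 12.0),
    ])
    def test_arithmetic(self, i, f, expect):
        events = ([Coincidence(0, 0, "i131-contaminated", 400, 400)] * i
                  + [Coincidence(0, 0, "true", 511, 511)] * f)
        assert prompt_emission_fraction(events) == pytest.approx(expect)

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError):
            prompt_emission_fraction([])


class TestMonteCarlo:
    def test_contaminated_rate_matches_analytic(self, calibrated):
        """I-131 only: MC accidental counts within 3σ of τR² on ten seeds."""
        acts = {"I-131": 30.0}
        expected = counting_rates(acts, "350-650",
                                  calibrated).i131_accidental_cps * 0.05
        for seed in range(10):
            ev = simulate_coincidences(acts, "350-650", calibrated, 0.05, seed)
            n = sum(e.kind == "i131-contaminated" for e in ev)
            assert abs(n - expected) <= 3 * np.sqrt(expected), f"seed {seed}"

    def test_f18_point_source_all_true_and_central(self, calibrated):
        """No scatter medium: essentially all coincidences are trues (a
        handful of inter-decay randoms is physical) and every true LOR
        passes within one radial bin of the centre."""
        ev = simulate_coincidences({"F-18": 10.0}, "350-650", calibrated,
                                   0.02, 5)
        kinds = [e.kind for e in ev]
        assert ev and set(kinds) <= {"true", "random"}
        assert kinds.count("true") / len(ev) > 0.99
        assert max(abs(e.s_mm) for e in ev
                   if e.kind == "true") < calibrated.radial_bin_mm

    def test_f18_trues_rate_matches_sensitivity(self, calibrated):
        rep = counting_rates({"F-18": 10.0}, "350-650", calibrated)
        expected = rep.f18_prompts_cps * 0.05
        counts = [sum(e.kind == "true" for e in
                      simulate_coincidences({"F-18": 10.0}, "350-650",
                                            calibrated, 0.05, s))
                  for s in range(5)]
        assert abs(np.mean(counts) - expected) <= 3 * np.sqrt(expected / 5)

    def test_window_nesting_same_event_stream(self, calibrated):
        """Sub-window coincidence counts are nested for one event stream."""
        ev = simulate_coincidences({"I-131": 30.0, "F-18": 5.0}, "350-750",
                                   calibrated, 0.05, 9)
        def in_win(e, lo, hi):
            return (lo <= e.e1_kev < hi) and (lo <= e.e2_kev < hi)
        n_450_650 = sum(in_win(e, 450, 650) for e in ev)
        n_350_650 = sum(in_win(e, 350, 650) for e in ev)
        n_350_750 = sum(in_win(e, 350, 750) for e in ev)
        assert n_450_650 <= n_350_650 <= n_350_750 == len(ev)

    def test_seed_determinism(self, calibrated):
        a = simulate_coincidences({"I-131": 20.0}, "350-650", calibrated,
                                  0.02, 77)
        b = simulate_coincidences({"I-131": 20.0}, "350-650", calibrated,
                                  0.02, 77)
        assert a == b

    def test_event_cap_guard(self, calibrated):
        with pytest.raises(RuntimeError, match="scale down"):
            simulate_coincidences({"I-131": 10_000.0}, "350-650", calibrated,
                                  1e4, 0)


class TestBinSinogram:
    def test_single_event(self, scanner):
        sino = bin_sinogram([Coincidence(0.0, 90.0, "true", 511, 511)],
                            scanner)
        assert sino.total == 1
        iphi = int(round(90.0 / (180.0 / scanner.n_angles)))
        assert sino.counts[iphi, (scanner.n_radial_bins - 1) // 2
                           + 1] >= 0  # shape sane
        assert sino.counts.max() == 1

    def test_count_conservation_with_overflow(self, scanner):
        events = [Coincidence(0.0, 10.0, "true", 511, 511),
                  Coincidence(1e4, 10.0, "true", 511, 511)]  # out of FOV
        sino = bin_sinogram(events, scanner)
        assert sino.total + sino.meta["overflow"] == len(events)
        assert sino.meta["overflow"] == 1

    def test_centered_point_profile_flat_in_angle(self, calibrated):
        ev = simulate_coincidences({"F-18": 20.0}, "350-650", calibrated,
                                   0.03, 21)
        sino = bin_sinogram(ev, calibrated)
        per_angle = sino.counts.sum(axis=1)
        lam = per_angle.mean()
        assert np.all(np.abs(per_angle - lam) < 6 * np.sqrt(lam) + 3)


class TestContaminatedSampling:
    def test_zero_fraction_identity(self, rng):
        trues = Sinogram(np.ones((8, 8)))
        out = sample_contaminated_sinogram(trues, 0.0, rng)
        assert np.array_equal(out.counts, trues.counts)

    def test_expected_background_total(self, rng):
        trues = Sinogram(np.full((100, 100), 100.0))  # sum 1e6
        out = sample_contaminated_sinogram(trues, 12.0, rng)
        bg = out.total - trues.total
        expect = 0.12 / 0.88 * 1e6
        assert abs(bg - expect) < 4 * np.sqrt(expect)

    def test_fraction_50_doubles_in_expectation(self, rng):
        trues = Sinogram(np.full((50, 50), 200.0))
        out = sample_contaminated_sinogram(trues, 50.0, rng)
        assert out.total == pytest.approx(2 * trues.total, rel=0.02)

    def test_invalid_fraction(self, rng):
        with pytest.raises(ValueError):
            sample_contaminated_sinogram(Sinogram(np.ones((4, 4))), 100.0, rng)
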