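"""The synthetic-data generators against their own closed forms."""

import math

import numpy as np
import pytest
from scipy import stats

import opcycle as oc
from opcycle.synthetic import flip_ideal_decay, frap_ideal_recovery


def _binomial_3se(p, n):
    return 3 * math.sqrt(p * (1 - p) / n)


class TestSimulateCohort:
    def test_full_growth_fraction_all_cycling(self, control_spec):
        cells = oc.simulate_cohort(control_spec, 1000, seed=7)
        assert len(cells) == 1000
        assert all(c.cycling for c in cells)

    def test_quiescent_fraction_matches_g(self, control_phases):
        spec = oc.PopulationSpec.single(control_phases, growth_fraction=0.57)
        cells = oc.simulate_cohort(spec, 10_000, seed=11)
        frac = sum(c.cycling for c in cells) / len(cells)
        assert frac == pytest.approx(0.57, abs=0.015)
        assert all(c.cycle_position is None for c in cells if not c.cycling)

    def test_determinism(self, control_spec):
        a = oc.simulate_cohort(control_spec, 500, seed=3)
        b = oc.simulate_cohort(control_spec, 500, seed=3)
        assert a == b

    def test_cycle_positions_uniform(self, control_spec):
        n = 10_000
        cells = oc.simulate_cohort(control_spec, n, seed=5)
        pos = [c.cycle_position / 76.6 for c in cells]
        d = stats.kstest(pos, "uniform").statistic
        assert d < 3 * math.sqrt(math.log(2) / n)

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            oc.PopulationSpec(())


class TestCumulativeEdu:
    def test_matches_analytic_index_pointwise(self, control_phases):
        """Simulated L.I. within 3 binomial SE of the closed form."""
        n = 10_000
        for g in (1.0, 0.6):
            spec = oc.PopulationSpec.single(control_phases, g)
            cohort = oc.simulate_cohort(spec, n, seed=13)
            for t in (0.5, 6, 12, 24, 50):
                pt = oc.run_cumulative_edu(cohort, spec, [t])[0]
                li_exp = oc.expected_li(control_phases, g, t)
                tol = max(_binomial_3se(li_exp, n), 1e-9)
                assert pt.li == pytest.approx(li_exp, abs=tol)

    def test_plateau_reaches_growth_fraction(self, control_phases):
        spec = oc.PopulationSpec.single(control_phases, 1.0)
        cohort = oc.simulate_cohort(spec, 2000, seed=17)
        pt = oc.run_cumulative_edu(cohort, spec, [76.6 - 13.5 + 0.1])[0]
        assert pt.li == 1.0

    def test_population_constant_across_durations(self, control_spec):
        cohort = oc.simulate_cohort(control_spec, 3000, seed=19)
        pts = oc.run_cumulative_edu(cohort, control_spec, [3, 12, 24, 48, 96])
        assert {p.n_total for p in pts} == {3000}
        lis = [p.li for p in pts]
        assert all(b >= a for a, b in zip(lis, lis[1:]))

    def test_mixture_matches_weighted_analytic_mean(self):
        """80/20 mixture of slow and fast cyclers at t = 12 h."""
        slow = oc.PhaseDurations(t_g1=205.1 - 16.7, t_s=16.7, t_g2=0, t_m=0)
        fast = oc.PhaseDurations(t_g1=77 - 13.5, t_s=13.5, t_g2=0, t_m=0)
        spec = oc.PopulationSpec.two_way(0.8, slow, fast)
        n = 20_000
        cohort = oc.simulate_cohort(spec, n, seed=23)
        pt = oc.run_cumulative_edu(cohort, spec, [12])[0]
        li_exp = spec.expected_li(12)
        assert li_exp == pytest.approx(
            0.8 * oc.expected_li(slow, 1, 12) + 0.2 * oc.expected_li(fast, 1, 12)
        )
        assert pt.li == pytest.approx(li_exp, abs=_binomial_3se(li_exp, n))

    def test_mixture_slope_additivity(self):
        """Fitted pre-plateau slope equals sum of w_i g_i / t_c_i to 1e-9."""
        slow = oc.PhaseDurations(t_g1=180, t_s=18, t_g2=2, t_m=0)
        fast = oc.PhaseDurations(t_g1=60, t_s=12, t_g2=2, t_m=2)
        spec = oc.PopulationSpec.two_way(0.7, slow, fast, g_first=0.9, g_second=1.0)
        times = [2, 6, 10, 14, 18]  # well before the fast plateau at 64 h
        pts = [
            oc.LabelingCurvePoint(t, 1.0, spec.expected_li(t)) for t in times
        ]
        fit = oc.fit_labeling_curve(pts, g=max(spec.expected_li(1e6), 1e-9))
        assert fit.m == pytest.approx(spec.analytic_slope, rel=1e-9)


class TestPulseChase:
    def test_fraction_matches_labeled_mitoses_formula(self):
        """f_ph3 = (t_chase - t_g2)/t_s when t_chase <= t_g2 + t_m."""
        phases = oc.PhaseDurations(t_g1=59.8, t_s=13.5, t_g2=2, t_m=3)
        spec = oc.PopulationSpec.single(phases)
        cohort = oc.simulate_cohort(spec, 10_000, seed=29)
        obs = oc.run_pulse_chase(cohort, spec, t_chase=4)
        f_exp = (4 - 2) / 13.5
        assert obs.f_ph3 == pytest.approx(f_exp, abs=3 * math.sqrt(f_exp / obs.n_edu))

    def test_no_mitoses_before_g2_cleared(self):
        phases = oc.PhaseDurations(t_g1=59, t_s=13.5, t_g2=3, t_m=1)
        spec = oc.PopulationSpec.single(phases)
        cohort = oc.simulate_cohort(spec, 5000, seed=31)
        obs = oc.run_pulse_chase(cohort, spec, t_chase=2)
        assert obs.f_ph3 == 0.0

    def test_fraction_capped_by_m_duration(self):
        """With a short M, labeled cells pass through mitosis and divide:
        f_ph3 ~ min(t_m, t_chase - t_g2)/t_s."""
        phases = oc.PhaseDurations(t_g1=60, t_s=13.5, t_g2=2, t_m=1)
        spec = oc.PopulationSpec.single(phases)
        cohort = oc.simulate_cohort(spec, 10_000, seed=37)
        obs = oc.run_pulse_chase(cohort, spec, t_chase=4)
        f_exp = 1 / 13.5
        assert obs.f_ph3 == pytest.approx(f_exp, abs=3 * math.sqrt(f_exp / obs.n_edu))

    def test_g2_estimator_exact_within_mitotic_window(self):
        """Bias below one simulated hour when t_chase <= t_g2 + t_m."""
        phases = oc.PhaseDurations(t_g1=58.3, t_s=13.5, t_g2=2.0, t_m=3.0)
        spec = oc.PopulationSpec.single(phases)
        cohort = oc.simulate_cohort(spec, 10_000, seed=41)
        obs = oc.run_pulse_chase(cohort, spec, t_chase=4)
        est = oc.estimate_g2(obs.t_chase, obs.f_ph3, phases.t_s)
        assert abs(est.t_g2 - 2.0) < 1.0

    def test_g2_estimator_overestimates_beyond_window(self):
        """Once labeled cells have divided out of M, the estimate inflates."""
        phases = oc.PhaseDurations(t_g1=59.7, t_s=13.5, t_g2=1.8, t_m=0.5)
        spec = oc.PopulationSpec.single(phases)
        cohort = oc.simulate_cohort(spec, 10_000, seed=43)
        obs = oc.run_pulse_chase(cohort, spec, t_chase=6)  # > t_g2 + t_m
        est = oc.estimate_g2(obs.t_chase, obs.f_ph3, phases.t_s)
        assert est.t_g2 >= 1.8


class TestFrapGenerators:
    def test_zero_noise_matches_closed_form(self):
        params = oc.FrapSimParams(mobile_fraction=0.67, rate_k=0.1)
        trace = oc.generate_frap_trace(params, seed=1)
        t_post = trace.t_post
        expected_roi = params.background_level + frap_ideal_recovery(params, t_post)
        np.testing.assert_allclose(trace.roi[trace.bleach_index :], expected_roi, atol=1e-12)
        np.testing.assert_allclose(trace.roi[: trace.bleach_index],
                                   params.background_level + 1.0, atol=1e-12)

    def test_immobile_pool_gives_flat_postbleach(self):
        params = oc.FrapSimParams(mobile_fraction=0.0, rate_k=0.1, bleach_depth=0.3)
        trace = oc.generate_frap_trace(params, seed=2)
        post = trace.roi[trace.bleach_index :] - params.background_level
        np.testing.assert_allclose(post, 0.3, atol=1e-12)

    def test_full_recovery_returns_to_prebleach(self):
        params = oc.FrapSimParams(
            mobile_fraction=1.0, rate_k=0.5, n_postbleach=200, frame_interval=0.5
        )
        trace = oc.generate_frap_trace(params, seed=3)
        assert trace.roi[-1] - params.background_level == pytest.approx(1.0, abs=1e-6)

    def test_planted_half_recovery_time(self):
        params = oc.FrapSimParams(mobile_fraction=0.67, rate_k=0.1)
        norm = oc.normalize_frap(oc.generate_frap_trace(params, seed=4))
        t_post = np.arange(params.n_postbleach) * params.frame_interval
        # At t = ln2/k the normalized recovery is half the plateau.
        idx = np.argmin(np.abs(t_post - math.log(2) / 0.1))
        post = norm[params.n_prebleach :]
        assert post[idx] == pytest.approx(0.67 / 2, abs=0.01)

    def test_flip_closed_form(self):
        params = oc.FrapSimParams(mobile_fraction=0.67, rate_k=0.05)
        t_half = math.log(2) / 0.05
        assert flip_ideal_decay(params, np.array([t_half]))[0] == pytest.approx(
            0.33 + 0.335, abs=1e-12
        )

    def test_flip_extremes(self):
        flat = oc.generate_flip_trace(oc.FrapSimParams(mobile_fraction=0.0), seed=5)
        post = flat.roi[flat.bleach_index :]
        assert np.ptp(post) < 1e-12
        full = oc.generate_flip_trace(
            oc.FrapSimParams(mobile_fraction=1.0, rate_k=0.5, n_postbleach=200), seed=6
        )
        assert full.roi[-1] - 0.05 == pytest.approx(0.0, abs=1e-6)

    def test_determinism_with_noise(self):
        params = oc.FrapSimParams(mobile_fraction=0.5, noise_sd=0.02)
        a = oc.generate_frap_trace(params, seed=9)
        b = oc.generate_frap_trace(params, seed=9)
        np.testing.assert_array_equal(a.roi, b.roi)


class TestPeakUniverse:
    def test_planted_frequencies_recovered(self):
        params = oc.PeakUniverseParams(n_foreground=5000, n_background=5000)
        fg, bg = oc.generate_peak_universe(params, seed=8)
        for motif, p_fg in params.motif_probs_foreground.items():
            assert fg[motif].mean() == pytest.approx(p_fg, abs=_binomial_3se(p_fg, 5000))
        for motif, p_bg in params.motif_probs_background.items():
            assert bg[motif].mean() == pytest.approx(p_bg, abs=_binomial_3se(max(p_bg, 1e-3), 5000))

    def test_zero_probability_motif_absent(self):
        params = oc.PeakUniverseParams(
            n_foreground=500,
            n_background=500,
            motif_probs_foreground={"X": 0.0},
            motif_probs_background={"X": 0.0},
        )
        fg, bg = oc.generate_peak_universe(params, seed=10)
        assert fg["X"].sum() == 0 and bg["X"].sum() == 0

    def test_same_seed_identical(self):
        params = oc.PeakUniverseParams(n_foreground=200, n_background=200)
        a_fg, a_bg = oc.generate_peak_universe(params, seed=12)
        b_fg, b_bg = oc.generate_peak_universe(params, seed=12)
        assert a_fg.equals(b_fg) and a_bg.equals(b_bg)

    def test_intervals_are_valid_bed(self):
        params = oc.PeakUniverseParams(n_foreground=100, n_background=100)
        fg, _ = oc.generate_peak_universe(params, seed=14)
        assert (fg["end"] - fg["start"] == params.interval_length).all()
        assert (fg["start"] >= 0).all()


class TestChildSeed:
    def test_deterministic_and_bounded(self):
        assert oc.child_seed(1, "a") == oc.child_seed(1, "a")
        assert oc.child_seed(1, "a") != oc.child_seed(1, "b")
        assert 0 <= oc.child_seed(2**30, "anything") < 2**31 - 1
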