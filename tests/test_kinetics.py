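"""Two-state switching model: closed form, fitting, units, equilibrium."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from episwitch.kinetics import (
    DEFAULT_GENERATION_TIME_HR,
    PER_GENERATION,
    PER_HOUR,
    POOLED,
    PER_REPLICATE_AVERAGED,
    RelaxationTimeCourse,
    TwoStateRates,
    UnidentifiableError,
    equilibrium_check,
    fit_rates,
    to_per_generation,
    to_per_hour,
    x_on_predicted,
)
from episwitch.simulate import RelaxationSimConfig, simulate_relaxation


def rk_oracle(k_on, k_off, t, x0):
    """Independent Runge-Kutta integration of dx/dt = k_on - (k_on+k_off) x."""
    sol = solve_ivp(
        lambda _, x: k_on - (k_on + k_off) * x,
        (0.0, t),
        [x0],
        rtol=1e-10,
        atol=1e-12,
    )
    return float(sol.y[0, -1])


def make_noiseless_courses(k_on, k_off, initial_state, times=None, genotype="g"):
    rates = TwoStateRates(k_on, k_off, PER_HOUR)
    times = np.arange(0.0, 49.0, 4.0) if times is None else np.asarray(times)
    n = 100_000  # large count so rounding error is < 1e-5 in x_on
    pts = tuple(
        (t, n, int(round(n * float(x_on_predicted(rates, t, initial_state))))) for t in times
    )
    return [RelaxationTimeCourse(genotype, "r1", initial_state, pts)]


class TestClosedForm:
    def test_initial_conditions(self):
        r = TwoStateRates(0.2, 0.4)
        assert x_on_predicted(r, 0.0, "sorted_silenced") == 0.0
        assert x_on_predicted(r, 0.0, "sorted_expressed") == 1.0

    def test_equilibrium_from_either_start(self):
        r = TwoStateRates(0.1, 0.3)
        assert x_on_predicted(r, 1e4, "sorted_silenced") == pytest.approx(0.25, abs=1e-12)
        assert x_on_predicted(r, 1e4, "sorted_expressed") == pytest.approx(0.25, abs=1e-12)

    def test_matches_runge_kutta(self):
        got = x_on_predicted(TwoStateRates(0.05, 0.15), 5.0, "sorted_silenced")
        assert got == pytest.approx(rk_oracle(0.05, 0.15, 5.0, 0.0), abs=1e-8)

    @pytest.mark.parametrize("k_on", [0.001, 0.05, 0.4])
    @pytest.mark.parametrize("k_off", [0.01, 0.2, 1.0])
    @pytest.mark.parametrize("x0, state", [(0.0, "sorted_silenced"), (1.0, "sorted_expressed")])
    def test_rate_grid_against_rk(self, k_on, k_off, x0, state):
        for t in (0.5, 3.0, 12.0):
            got = x_on_predicted(TwoStateRates(k_on, k_off), t, state)
            assert got == pytest.approx(rk_oracle(k_on, k_off, t, x0), abs=1e-6)

    def test_satisfies_ode_by_finite_difference(self):
        r = TwoStateRates(0.07, 0.21)
        s, eq = r.k_on + r.k_off, r.k_on / (r.k_on + r.k_off)
        for t in (0.5, 2.0, 8.0, 20.0):
            h = 1e-6
            x = x_on_predicted(r, t, "sorted_silenced")
            dxdt = (x_on_predicted(r, t + h, "sorted_silenced") - x_on_predicted(r, t - h, "sorted_silenced")) / (2 * h)
            assert dxdt / s + x == pytest.approx(eq, abs=1e-6)

    def test_branch_gap_decays_exponentially(self):
        r = TwoStateRates(0.1, 0.4)
        s = r.k_on + r.k_off
        for t in (1.0, 5.0, 10.0):
            gap = x_on_predicted(r, t, "sorted_expressed") - x_on_predicted(r, t, "sorted_silenced")
            assert gap == pytest.approx(np.exp(-s * t), abs=1e-12)

    def test_zero_rates_silenced_start_is_degenerate_not_error(self):
        r = TwoStateRates(0.0, 0.0)
        assert x_on_predicted(r, 10.0, "sorted_silenced") == 0.0
        assert x_on_predicted(r, 10.0, "sorted_expressed") == 1.0

    def test_rejects_per_generation_rates(self):
        r = TwoStateRates(0.003, 0.11, PER_GENERATION)
        with pytest.raises(ValueError, match="per-hour"):
            x_on_predicted(r, 1.0, "sorted_silenced")


class TestUnitConversion:
    def test_round_trip(self):
        r = TwoStateRates(0.00153, 0.056, PER_HOUR, generation_time_hr=1.96)
        per_gen = to_per_generation(r)
        assert per_gen.k_on == pytest.approx(0.003, rel=2e-3)
        assert per_gen.unit == PER_GENERATION
        back = to_per_hour(per_gen)
        assert back.k_on == pytest.approx(r.k_on, rel=1e-12)
        assert back.k_off == pytest.approx(r.k_off, rel=1e-12)

    def test_zero_rates_and_identity_generation_time(self):
        assert to_per_generation(TwoStateRates(0.0, 0.0, PER_HOUR, 5.0)).k_on == 0.0
        r = TwoStateRates(0.2, 0.3, PER_HOUR, generation_time_hr=1.0)
        pg = to_per_generation(r)
        assert (pg.k_on, pg.k_off) == (0.2, 0.3)

    def test_noop_with_warning_when_already_converted(self):
        pg = TwoStateRates(0.1, 0.2, PER_GENERATION)
        with pytest.warns(UserWarning, match="already"):
            assert to_per_generation(pg) == pg


class TestFitRates:
    def test_noiseless_recovery_to_numerical_precision(self):
        courses = make_noiseless_courses(0.02, 0.3, "sorted_silenced")
        fit = fit_rates(courses)
        assert fit.rates.k_on == pytest.approx(0.02, rel=1e-4)
        assert fit.rates.k_off == pytest.approx(0.3, rel=1e-4)
        assert fit.fit_method == POOLED
        assert fit.n_points == len(courses[0].points)

    def test_noiseless_recovery_expressed_start(self):
        courses = make_noiseless_courses(0.05, 0.1, "sorted_expressed")
        fit = fit_rates(courses)
        assert fit.rates.k_on == pytest.approx(0.05, rel=1e-4)
        assert fit.rates.k_off == pytest.approx(0.1, rel=1e-4)

    def test_single_time_point_unidentifiable(self):
        tc = RelaxationTimeCourse("g", "r1", "sorted_silenced", ((0.0, 500, 0),))
        with pytest.raises(UnidentifiableError):
            fit_rates([tc])

    def test_constant_x_on_flagged_unidentifiable(self):
        pts = tuple((float(t), 100, 50) for t in range(6))
        with pytest.raises(UnidentifiableError, match="unidentifiable"):
            fit_rates([RelaxationTimeCourse("g", "r1", "sorted_silenced", pts)])

    def test_pooled_and_averaged_agree_on_synthetic_data(self):
        rates = TwoStateRates(0.014, 0.78, PER_GENERATION)
        cfg = RelaxationSimConfig(rates=rates, initial_state="sorted_expressed", seed=11)
        courses = simulate_relaxation(cfg)
        pooled = fit_rates(courses, method=POOLED)
        averaged = fit_rates(courses, method=PER_REPLICATE_AVERAGED)
        assert averaged.fit_method == PER_REPLICATE_AVERAGED
        assert averaged.sd_k_off is not None
        # both estimates of the dominant rate agree within their mutual spread
        tol = max(3 * averaged.sd_k_off, 0.2 * pooled.rates.k_off)
        assert abs(pooled.rates.k_off - averaged.rates.k_off) < tol

    def test_ci_k_on_narrower_from_sorted_silenced(self):
        # slow-relaxation regime (wild-type rates): watching a silenced
        # population lose silencing pins down k_on directly
        rates = TwoStateRates(0.003, 0.11, PER_GENERATION)
        widths = {}
        for state in ("sorted_silenced", "sorted_expressed"):
            w = []
            for seed in range(10):
                cfg = RelaxationSimConfig(rates=rates, initial_state=state, seed=300 + seed)
                fit = fit_rates(simulate_relaxation(cfg))
                w.append(fit.ci_k_on[1] - fit.ci_k_on[0])
            widths[state] = np.median(w)
        assert widths["sorted_silenced"] < widths["sorted_expressed"]

    def test_ci_bounds_ordered_and_nonnegative(self):
        rates = TwoStateRates(0.033, 0.5, PER_GENERATION)
        cfg = RelaxationSimConfig(rates=rates, seed=5)
        fit = fit_rates(simulate_relaxation(cfg))
        for lo, hi in (fit.ci_k_on, fit.ci_k_off):
            assert 0 <= lo <= hi


class TestEquilibriumCheck:
    def test_double_mutant_ratio(self):
        chk = equilibrium_check(TwoStateRates(0.033, 0.5, PER_GENERATION), 90, 10)
        assert chk.kon_over_koff == pytest.approx(0.066, abs=5e-4)

    def test_wild_type_e_over_s(self):
        chk = equilibrium_check(TwoStateRates(0.003, 0.11, PER_GENERATION), 99, 1)
        assert round(chk.e_over_s, 2) == 0.01

    def test_symmetric_case(self):
        chk = equilibrium_check(TwoStateRates(0.2, 0.2, PER_GENERATION), 50, 50)
        assert chk.e_over_s == pytest.approx(1.0)
        assert chk.kon_over_koff == pytest.approx(1.0)
        assert chk.discrepancy == pytest.approx(1.0)

    def test_percentages_must_sum_to_100(self):
        with pytest.raises(ValueError, match="sum to 100"):
            equilibrium_check(TwoStateRates(0.1, 0.2, PER_GENERATION), 80, 10)

    def test_all_expressed_is_unidentifiable(self):
        with pytest.raises(UnidentifiableError):
            equilibrium_check(TwoStateRates(0.1, 0.2, PER_GENERATION), 0, 100)


def test_timecourse_invariants():
    with pytest.raises(ValueError, match="strictly increasing"):
        RelaxationTimeCourse("g", "r", "sorted_silenced", ((0.0, 10, 1), (0.0, 10, 2)))
    with pytest.raises(ValueError, match="n_gfp_pos"):
        RelaxationTimeCourse("g", "r", "sorted_silenced", ((0.0, 10, 11),))
    with pytest.raises(ValueError, match="initial_state"):
        RelaxationTimeCourse("g", "r", "mixed", ((0.0, 10, 1),))
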