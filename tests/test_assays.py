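"""CRASH/FLAME flow quantification, pedigree rates, Yates comparisons."""

import numpy as np
import pandas as pd
import pytest

from episwitch.assays import (
    ESTABLISHMENT,
    LOSS,
    FlowPopulation,
    GateSeparationWarning,
    PedigreeCounts,
    compare_rates_yates,
    crash_apparent_loss_rate,
    crash_rate_summary,
    flame_equilibrium_fractions,
    gfp_gate_from_controls,
    pedigree_rate,
)
from episwitch.kinetics import PER_GENERATION, TwoStateRates
from episwitch.simulate import LineageSimConfig, simulate_crash_population, simulate_state_lineages


def boolean_population(n_rfp_only, n_both, n_gfp_only, n_neg=0):
    rows = (
        [(True, False)] * n_rfp_only
        + [(True, True)] * n_both
        + [(False, True)] * n_gfp_only
        + [(False, False)] * n_neg
    )
    return FlowPopulation(events=pd.DataFrame(rows, columns=["rfp_pos", "gfp_pos"]))


def yates_hand_formula(a, b, c, d):
    """Independent oracle: N(|ad-bc| - N/2)^2 / (row and column products)."""
    n = a + b + c + d
    num = n * (abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return max(0.0, num / den) if abs(a * d - b * c) >= n / 2 else 0.0


class TestCrashRate:
    def test_direct_ratio_excludes_old_loss_cells(self):
        res = crash_apparent_loss_rate(boolean_population(990, 10, 500))
        assert res.rate == pytest.approx(0.01)
        assert res.n_gfp_only == 500

    def test_all_silenced_gives_zero(self):
        assert crash_apparent_loss_rate(boolean_population(1000, 0, 0)).rate == 0.0

    def test_invariant_to_rfp_negative_events(self):
        r1 = crash_apparent_loss_rate(boolean_population(500, 5, 0)).rate
        r2 = crash_apparent_loss_rate(boolean_population(500, 5, 10_000)).rate
        assert r1 == r2

    def test_zero_denominator_is_explicit_error(self):
        with pytest.raises(ZeroDivisionError):
            crash_apparent_loss_rate(boolean_population(0, 0, 100))

    def test_simulated_wild_type_matches_closed_form(self):
        # wild type loses silencing in ~0.1% of divisions; RFP persists 2 gens,
        # so the expected apparent rate is 1 - (1 - 0.001)^2
        cfg = LineageSimConfig(loss_rate=0.001, rfp_persistence_gens=2,
                               n_founders=16, n_generations=13, seed=3)
        pop = simulate_crash_population(cfg)
        assert len(pop) >= 100_000
        res = crash_apparent_loss_rate(pop)
        expected = 1 - (1 - 0.001) ** 2
        se = np.sqrt(expected * (1 - expected) / (res.n_rfp_gfp + res.n_rfp_only))
        assert abs(res.rate - expected) < 3 * se

    def test_replicate_summary_mean_sd(self):
        pops = [boolean_population(990, 10, 0), boolean_population(980, 20, 0)]
        mean, sd, rates = crash_rate_summary(pops)
        assert mean == pytest.approx(np.mean(rates))
        assert sd == pytest.approx(np.std(rates, ddof=1))


class TestFlameFractions:
    def test_all_expressed_control(self):
        res = flame_equilibrium_fractions(boolean_population(0, 0, 1000))
        assert (res.pct_silenced, res.pct_expressed) == (0.0, 100.0)

    def test_half_half_mixture_within_counting_error(self):
        rng = np.random.default_rng(0)
        gfp = rng.random(20_000) < 0.5
        pop = FlowPopulation(events=pd.DataFrame({"rfp_pos": ~gfp, "gfp_pos": gfp}))
        res = flame_equilibrium_fractions(pop)
        se_pct = 100 * np.sqrt(0.25 / 20_000)
        assert abs(res.pct_expressed - 50) < 3 * se_pct
        assert res.pct_silenced + res.pct_expressed == pytest.approx(100.0)

    def test_stationary_population_recovers_generator_equilibrium(self):
        # fractions converge to the rates' stationary distribution
        rates = TwoStateRates(0.003, 0.11, PER_GENERATION)
        pop = simulate_state_lineages(rates, n_cells=50_000, n_generations=10, seed=4)
        res = flame_equilibrium_fractions(pop)
        eq = 100 * rates.equilibrium_expressed
        se = np.sqrt(eq * (100 - eq) / 50_000)
        assert res.pct_expressed == pytest.approx(eq, abs=4 * se)

    def test_wild_type_equilibrium_population_reads_99_to_1(self):
        # population drawn at the wild-type equilibrium: ~99% silenced, ~1% expressed
        rng = np.random.default_rng(21)
        gfp = rng.random(50_000) < 0.01
        pop = FlowPopulation(events=pd.DataFrame({"rfp_pos": ~gfp, "gfp_pos": gfp}))
        res = flame_equilibrium_fractions(pop)
        assert res.pct_silenced == pytest.approx(99, abs=0.2)
        assert res.pct_expressed == pytest.approx(1, abs=0.2)

    def test_raw_intensity_gating_and_gap_warning(self):
        rng = np.random.default_rng(1)
        silenced = 10 ** rng.normal(1.0, 0.1, 500)
        expressed = 10 ** rng.normal(3.0, 0.1, 500)
        thr, lo, hi = gfp_gate_from_controls(silenced, expressed)
        assert silenced.max() < thr < expressed.min()
        events = pd.DataFrame({"rfp": np.ones(1000), "gfp": np.concatenate([silenced, expressed])})
        pop = FlowPopulation(events=events, rfp_threshold=0.5, gfp_threshold=thr)
        res = flame_equilibrium_fractions(pop, gate_band=(lo, hi))
        assert res.pct_expressed == pytest.approx(50.0)
        assert res.gap_fraction == 0.0
        # smear everything into the gap -> poor-separation warning
        bad = FlowPopulation(
            events=pd.DataFrame({"rfp": np.ones(100), "gfp": np.full(100, thr * 1.001)}),
            rfp_threshold=0.5, gfp_threshold=thr,
        )
        with pytest.warns(GateSeparationWarning):
            res = flame_equilibrium_fractions(bad, gate_band=(lo, hi))
        assert res.poor_separation


class TestPedigreeRate:
    def test_wilson_interval_small_counts(self):
        rate, (lo, hi) = pedigree_rate(PedigreeCounts("wt", LOSS, 1000, 3))
        assert rate == pytest.approx(0.003)
        assert lo == pytest.approx(0.0010208, rel=1e-3)
        assert hi == pytest.approx(0.0087830, rel=1e-3)

    def test_zero_events_lower_bound_zero(self):
        rate, (lo, _) = pedigree_rate(PedigreeCounts("wt", LOSS, 100, 0))
        assert rate == 0.0
        assert lo == 0.0

    def test_all_events_upper_bound_one(self):
        rate, (_, hi) = pedigree_rate(PedigreeCounts("wt", LOSS, 50, 50))
        assert rate == 1.0
        assert hi == 1.0

    def test_wilson_coverage_at_rate_001(self):
        # 1000 simulated pedigrees of 1000 divisions at true rate 0.01
        rng = np.random.default_rng(20)
        true = 0.01
        hits = 0
        for _ in range(1000):
            k = rng.binomial(1000, true)
            _, (lo, hi) = pedigree_rate(PedigreeCounts("sim", LOSS, 1000, int(k)))
            hits += lo <= true <= hi
        assert 930 <= hits <= 970

    def test_invariants(self):
        with pytest.raises(ValueError):
            PedigreeCounts("g", LOSS, 10, 11)
        with pytest.raises(ValueError):
            PedigreeCounts("g", "sideways", 10, 1)


class TestYatesChiSquare:
    def test_matches_hand_formula(self):
        a = PedigreeCounts("a", LOSS, 100, 5)
        b = PedigreeCounts("b", LOSS, 100, 15)
        chi2, p = compare_rates_yates(a, b)
        assert chi2 == pytest.approx(4.5)
        assert chi2 == pytest.approx(yates_hand_formula(5, 95, 15, 85))
        assert p < 0.05

    def test_identical_groups(self):
        a = PedigreeCounts("a", LOSS, 100, 5)
        chi2, p = compare_rates_yates(a, a)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_correction_clipped_at_zero_for_tiny_effect(self):
        # |ad - bc| = 1 < N/2 = 10.5 -> statistic clipped to 0
        a = PedigreeCounts("a", LOSS, 11, 1)
        b = PedigreeCounts("b", LOSS, 10, 1)
        chi2, _ = compare_rates_yates(a, b)
        assert chi2 == 0.0
        assert yates_hand_formula(1, 10, 1, 9) == 0.0

    def test_symmetric_in_group_order(self):
        a = PedigreeCounts("a", LOSS, 900, 4)
        b = PedigreeCounts("b", LOSS, 950, 17)
        ab, ba = compare_rates_yates(a, b), compare_rates_yates(b, a)
        assert ab[0] == pytest.approx(ba[0], rel=1e-12)
        assert ab[1] == pytest.approx(ba[1], rel=1e-12)

    def test_p_value_monotone_in_effect_size(self):
        base = PedigreeCounts("a", LOSS, 1000, 10)
        pvals = [
            compare_rates_yates(base, PedigreeCounts("b", LOSS, 1000, k))[1]
            for k in (20, 40, 80)
        ]
        assert pvals[0] > pvals[1] > pvals[2]

    def test_empty_margin_advises_exact_test(self):
        a = PedigreeCounts("a", LOSS, 10, 0)
        b = PedigreeCounts("b", LOSS, 10, 0)
        with pytest.raises(ValueError, match="exact"):
            compare_rates_yates(a, b)


def test_population_dialect_detection_and_validation():
    with pytest.raises(ValueError, match="columns"):
        FlowPopulation(events=pd.DataFrame({"x": [1]}))
    with pytest.raises(ValueError, match=">= 0"):
        FlowPopulation(events=pd.DataFrame({"rfp": [-1.0], "gfp": [1.0]}))
    raw = FlowPopulation(events=pd.DataFrame({"rfp": [1.0], "gfp": [2.0]}))
    with pytest.raises(ValueError, match="threshold"):
        raw.classified()
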