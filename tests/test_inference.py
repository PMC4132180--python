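"""Rate estimators, MLE behavior, hypothesis tests, and the dynamics scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from germcoal.coalescent import simulate_coefficients
from germcoal.germline import RateVector, ValidationError, resolve_partition
from germcoal.inference import (
    classical_rate,
    first_division_ratio,
    fit_mle,
    hypothesis,
    lr_test,
    male_female_ratio,
    overall_rate,
    scan_dynamics,
)
from germcoal.patterns import (
    EMPTY,
    MutationPattern,
    PatternTally,
    enumerate_patterns,
    pattern_log_prob,
)


class TestOverallRate:
    def test_published_interval_rates(self, part6, rates97):
        # width-weighted sums of the published six-interval estimates
        assert round(overall_rate(rates97), 4) == 0.0821
        u98 = RateVector.of(
            [x * 1e-3 for x in (28.660, 0.272, 0.006, 0.018, 0.089, 1.443)], part6
        )
        assert round(overall_rate(u98), 4) == 0.0380

    def test_zero_rates(self, part6):
        assert overall_rate(RateVector.of([0.0] * 6, part6)) == 0.0


class TestClassicalRate:
    @pytest.mark.parametrize(
        "mutants, lines, expected",
        [(2673, 271794, 0.0098), (30781, 271794, 0.1133), (10766, 271794, 0.0396)],
    )
    def test_published_counts(self, mutants, lines, expected):
        assert round(classical_rate(mutants, lines), 4) == expected

    def test_edge_cases(self):
        assert classical_rate(0, 100) == 0.0
        with pytest.raises(ValidationError):
            classical_rate(1, 0)
        with pytest.raises(ValidationError):
            classical_rate(5, 4)


class TestFirstDivisionRatio:
    def test_equal_rates(self):
        # the printed formula sums 31 interval-divisions but divides by 32
        assert first_division_ratio([1, 1, 1, 1, 1, 1]) == pytest.approx(32 / 31)

    def test_published_row_direct_arithmetic(self, rates97):
        assert round(first_division_ratio(rates97), 1) == 448.6

    def test_zero_numerator(self):
        assert first_division_ratio([0, 1, 1, 1, 1]) == 0.0
        assert first_division_ratio([1, 0, 0, 0, 0]) == math.inf


class TestMaleFemaleRatio:
    def test_published_examples(self):
        assert round(male_female_ratio(100, 400, 30), 1) == 3.9
        assert round(male_female_ratio(500, 400, 30), 1) == 1.7

    def test_large_ratio_asymptote(self):
        assert male_female_ratio(1e9, 400, 30) == pytest.approx(1.0, abs=1e-6)


class TestHypotheses:
    def test_five_interval_degrees_of_freedom(self):
        expected = {"H1": 4, "H2": 2, "H3": 1, "H4": 1, "H4b": 1, "H5": 1,
                    "H6": 1, "H7": 1}
        for name, df in expected.items():
            assert hypothesis(name, 5).df == df

    def test_six_interval_H1(self):
        assert hypothesis("H1", 6).df == 5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(I=st.integers(4, 8), name=st.sampled_from(
        ["H1", "H2", "H3", "H4", "H4b", "H5", "H6", "H7", "H8"]))
    def test_df_is_free_parameter_difference(self, I, name):
        spec = hypothesis(name, I)
        classes = spec.classes
        covered = sorted(i for c in classes for i in c)
        assert covered == list(range(1, I + 1))
        assert spec.df == I - len(classes)

    def test_expand_assigns_shared_values(self):
        spec = hypothesis("H1", 4)
        assert np.allclose(spec.expand(np.array([0.3])), [0.3] * 4)


@pytest.fixture(scope="module")
def sampled_mini_fit(mini_dyn):
    """Tally sampled from the model itself at known rates (f=5, D=6)."""
    part = resolve_partition((2, 4), 6)
    cs = simulate_coefficients(5, mini_dyn, M=1500, seed=2)
    u_true = RateVector.of([0.05, 0.005, 0.02], part)
    pats = enumerate_patterns(5)
    probs = np.array([math.exp(pattern_log_prob(k, 5, u_true, cs)) for k in pats])
    rng = np.random.default_rng(3)
    draws = rng.multinomial(5000, probs / probs.sum())
    tally = PatternTally()
    for k, n in zip(pats, draws):
        if n:
            tally.add(5, k, int(n))
    return part, cs, u_true, tally


class TestFitMle:
    def test_all_nonmutant_families_give_zero_rates(self, mini_dyn):
        part = resolve_partition((2, 4), 6)
        cs = simulate_coefficients(4, mini_dyn, M=50, seed=1)
        tally = PatternTally()
        tally.add(4, EMPTY, 30)
        est = fit_mle(tally, part, {4: cs})
        assert est.u.u == (0.0, 0.0, 0.0)
        assert est.loglik == pytest.approx(0.0)

    def test_parameter_recovery_on_sampled_tally(self, sampled_mini_fit):
        part, cs, u_true, tally = sampled_mini_fit
        est = fit_mle(tally, part, {5: cs}, n_starts=4)
        assert est.converged
        assert est.u.u[0] / u_true.u[0] == pytest.approx(1.0, abs=0.25)
        assert overall_rate(est.u) / overall_rate(u_true) == pytest.approx(1.0, abs=0.15)

    def test_flat_truth_makes_H1_unrestrictive(self, mini_dyn):
        part = resolve_partition((2, 4), 6)
        cs = simulate_coefficients(4, mini_dyn, M=1000, seed=5)
        u_flat = RateVector.of([0.03] * 3, part)
        pats = enumerate_patterns(4)
        probs = np.array([math.exp(pattern_log_prob(k, 4, u_flat, cs)) for k in pats])
        rng = np.random.default_rng(8)
        draws = rng.multinomial(2000, probs / probs.sum())
        tally = PatternTally()
        for k, n in zip(pats, draws):
            if n:
                tally.add(4, k, int(n))
        stat, df, p = lr_test(tally, "H1", part, {4: cs}, n_starts=3)
        assert df == 2
        assert stat < 8.0  # no real constraint violated
        assert p > 0.01


class TestTypeIError:
    def test_H1_rejection_rate_near_nominal(self, mini_dyn):
        """Flat-rate truth: the H1 LRT should reject at ~the nominal level."""
        part = resolve_partition((2, 4), 6)
        cs = simulate_coefficients(4, mini_dyn, M=800, seed=6)
        u_flat = RateVector.of([0.03] * 3, part)
        pats = enumerate_patterns(4)
        probs = np.array([math.exp(pattern_log_prob(k, 4, u_flat, cs)) for k in pats])
        probs = probs / probs.sum()
        rng = np.random.default_rng(7)
        n_reps, rejections = 120, 0
        for _ in range(n_reps):
            draws = rng.multinomial(400, probs)
            tally = PatternTally()
            for k, n in zip(pats, draws):
                if n:
                    tally.add(4, k, int(n))
            _, _, p = lr_test(tally, "H1", part, {4: cs}, n_starts=2, seed=1)
            rejections += p < 0.05
        rate = rejections / n_reps
        se = math.sqrt(0.05 * 0.95 / n_reps)
        assert rate < 0.05 + 3 * se + 1e-9


class TestScanDynamics:
    def test_feasibility_mask_follows_bottleneck_rule(self, mini_dyn):
        tally = PatternTally()
        tally.add(5, EMPTY, 10)
        tally.add(5, MutationPattern.of(1), 2)
        result = scan_dynamics(
            tally,
            n5_groups=[(1, 2), (1,)],
            n8_groups=[(13, 14, 15), (9, 10, 11)],
            partition_spec=(1, 2, 14, -5),
            M=60,
            n_starts=1,
            seed=0,
        )
        t = result.table

        def cell(n5g, n8g):
            sel = (t.n5_group == n5g) & (t.n8_group == n8g)
            return t.loc[sel].iloc[0]

        assert cell((1, 2), (13, 14, 15)).members == 3  # only n5=2 feasible
        assert not cell((1,), (13, 14, 15)).feasible
        assert not cell((1,), (9, 10, 11)).feasible
        assert np.all(result.table.loc[result.table.feasible, "delta"] >= 0)
        assert (result.table.delta == 0).sum() >= 1

    def test_adding_nonmutant_families_keeps_delta_ranks(self):
        from germcoal.simulate import SynthConfig, generate_experiment
        from germcoal.screen import LethalityWindow, LineRecord, CrossRecord, screen_experiment
        from germcoal.germline import build_dynamics

        cfg = SynthConfig(
            n_families=150, lines_per_family=10, seed=21,
            dynamics=build_dynamics(38, 6, 8, 128),
        )
        exp = generate_experiment(cfg)
        lines = [
            LineRecord(r.family, r.line, int(r.zz), int(r.total))
            for r in exp.lines.itertuples()
        ]
        crosses = [
            CrossRecord(r.family, r.line_a, r.line_b, int(r.zz), int(r.total))
            for r in exp.crosses.itertuples()
        ]
        tally, _, _ = screen_experiment(lines, crosses, LethalityWindow(0.97, 1.0))
        grid = dict(
            n5_groups=[(1,), (6,), (32,)],
            n8_groups=[(8,)],
            partition_spec=(1, 2, 3, 14, -5),
            M=400,
            n_starts=2,
            seed=5,
        )
        base = scan_dynamics(tally, **grid)
        padded = tally.scaled(1)
        padded.families[10] += 60  # 60 extra non-mutant families
        shifted = scan_dynamics(padded, **grid)
        order_a = base.table.sort_values("delta").n5_group.tolist()
        order_b = shifted.table.sort_values("delta").n5_group.tolist()
        assert order_a == order_b
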