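"""QC, complementation statistics, and mutation delineation."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from germcoal.germline import ValidationError
from germcoal.patterns import MutationPattern
from germcoal.screen import (
    CrossRecord,
    LethalityWindow,
    LineRecord,
    ScreenConfig,
    allelism_lr,
    delineate_mutations,
    exclude_high_mutant_families,
    extract_pattern,
    family_qc,
    line_stats,
    tally_patterns,
)


class TestLineStats:
    @pytest.mark.parametrize(
        "zz, total, frac", [(29, 112, 0.259), (3, 90, 0.033), (0, 70, 0.0)]
    )
    def test_published_rows(self, zz, total, frac):
        got_frac, got_d = line_stats(LineRecord("140", "x", zz, total))
        assert round(got_frac, 3) == frac
        assert got_d == pytest.approx(1 - zz / total)

    def test_empty_line_rejected(self):
        with pytest.raises(ValidationError):
            line_stats(LineRecord("f", "x", 0, 0))


class TestAllelismLr:
    def test_equal_proportions_give_zero(self):
        assert allelism_lr(1, 10, 1, 10, 2, 20) == pytest.approx(0.0)

    def test_all_zero_counts(self):
        assert allelism_lr(0, 50, 0, 60, 0, 70) == 0.0

    def test_matches_independent_deviance(self):
        # Eq-style statistic equals the G-test on the pooled-vs-cross table
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n1, n2, n3 = rng.integers(20, 200, size=3)
            z1 = rng.binomial(n1, 0.1)
            z2 = rng.binomial(n2, 0.1)
            z3 = rng.binomial(n3, rng.uniform(0.01, 0.4))
            if z1 + z2 + z3 == 0 or (z1 + z2 == n1 + n2 and z3 == n3):
                continue
            table = np.array(
                [[z1 + z2, n1 + n2 - z1 - z2], [z3, n3 - z3]], dtype=float
            )
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            g = chi2_contingency(table, correction=False, lambda_="log-likelihood")
            lr = allelism_lr(z1, n1, z2, n2, z3, n3)
            assert lr == pytest.approx(g.statistic, abs=1e-9)

    def test_null_rejection_rate_matches_nominal(self):
        rng = np.random.default_rng(1)
        from scipy.stats import chi2

        level = 0.02  # an alpha/m-scale per-test level
        crit = chi2.isf(level, 1)
        n = 20000
        rej = 0
        for _ in range(n):
            z1 = rng.binomial(118, 0.175)
            z2 = rng.binomial(118, 0.175)
            z3 = rng.binomial(100, 0.175)
            rej += allelism_lr(z1, 118, z2, 118, z3, 100) > crit
        se = np.sqrt(level * (1 - level) / n)
        assert abs(rej / n - level) < 3 * se

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            allelism_lr(1, 10, 1, 0, 1, 10)


class TestFamilyQC:
    def test_family140_records_17_lines(self, family140):
        lines, crosses = family140
        qc = family_qc(lines, crosses)
        assert qc.ok
        assert len(qc.recorded) == 17
        reasons = dict(qc.dropped)
        assert reasons["31"] == "balancer offspring in F3"
        assert "fewer than 40" in reasons["32"]
        # line 2 is a high-lethality line never crossed: undeterminable
        assert reasons["2"] == "untested line above lethality threshold"
        assert qc.size == 16

    def test_single_line_family_rejected(self):
        qc = family_qc([LineRecord("f", "1", 2, 100)], [])
        assert not qc.ok and qc.rejected == "too few lines"

    def test_lone_candidate_is_kept_untested(self):
        # one high-lethality line, no other candidate: no cross was
        # possible, so its identity is unambiguous and it stays
        lines = [
            LineRecord("f", "1", 0, 100),
            LineRecord("f", "2", 20, 100),
            LineRecord("f", "3", 18, 100),
        ]
        qc = family_qc(lines, [])
        assert qc.ok and qc.size == 3

    def test_untested_candidate_removed_when_others_tested(self):
        lines = [
            LineRecord("f", "1", 0, 100),
            LineRecord("f", "2", 1, 100),  # untested, d = 0.99
            LineRecord("f", "3", 0, 100),
            LineRecord("f", "4", 18, 100),
        ]
        crosses = [CrossRecord("f", "1", "3", 1, 100)]
        qc = family_qc(lines, crosses)
        assert [r for r, _ in qc.dropped] == ["2"]
        assert qc.size == 3


class TestDelineation:
    def test_family140_two_mutations(self, family140):
        lines, crosses = family140
        qc = family_qc(lines, crosses)
        res = delineate_mutations(qc, crosses)
        assert res.n_groups == 2
        by_size = sorted(res.groups, key=lambda g: g.size)
        assert by_size[0].members == ("3",)
        assert by_size[0].lethality == 1.0
        assert by_size[1].size == 14
        # pooled z/z of the big group is low but not in the top window
        assert 0.97 < by_size[1].lethality < 0.99

    def test_family140_pattern_extraction(self, family140):
        lines, crosses = family140
        qc = family_qc(lines, crosses)
        res = delineate_mutations(qc, crosses)
        top = extract_pattern(res, LethalityWindow(0.99, 1.0), qc.size)
        assert top == MutationPattern.of(1)
        mid = extract_pattern(res, LethalityWindow(0.98, 0.99, closed_top=False), qc.size)
        assert mid == MutationPattern.of(14)

    def test_all_nonsignificant_crosses_merge(self):
        lines = [LineRecord("f", str(i), 0, 100) for i in range(4)]
        crosses = [
            CrossRecord("f", "0", "1", 0, 100),
            CrossRecord("f", "1", "2", 0, 100),
            CrossRecord("f", "2", "3", 0, 100),
        ]
        qc = family_qc(lines, crosses)
        res = delineate_mutations(qc, crosses)
        assert res.n_groups == 1 and res.groups[0].size == 4

    def test_two_planted_mutations_recovered(self):
        """d=1.0 and d=0.98 mutations, complementing crosses at baseline."""
        rng = np.random.default_rng(11)
        successes = 0
        reps = 200
        for _ in range(reps):
            group_a = [LineRecord("f", f"a{i}", 0, 118) for i in range(3)]
            group_b = [
                LineRecord("f", f"b{i}", int(rng.binomial(118, 0.02)), 118)
                for i in range(3)
            ]
            lines = group_a + group_b
            crosses = []
            for ga, gb, q in (
                (group_a, group_a, 0.0),
                (group_b, group_b, 0.02),
                (group_a, group_b, 0.175),
            ):
                for x in ga:
                    for y in gb:
                        if x.line < y.line:
                            crosses.append(
                                CrossRecord(
                                    "f", x.line, y.line,
                                    int(rng.binomial(100, q)), 100,
                                )
                            )
            qc = family_qc(lines, crosses)
            res = delineate_mutations(qc, crosses, ScreenConfig(alpha=0.10))
            successes += res.n_groups == 2
        assert successes >= 0.95 * reps

    def test_relabeling_invariance(self, family140):
        lines, crosses = family140
        mapping = {ln.line: f"L{idx}" for idx, ln in enumerate(lines)}
        relabeled_lines = [
            LineRecord(ln.family, mapping[ln.line], ln.zz, ln.total,
                       ln.balancer_offspring_seen)
            for ln in lines
        ]
        relabeled_crosses = [
            CrossRecord(c.family, mapping[c.line_a], mapping[c.line_b], c.zz, c.total)
            for c in crosses
        ]
        base = delineate_mutations(family_qc(lines, crosses), crosses)
        reled = delineate_mutations(
            family_qc(relabeled_lines, relabeled_crosses), relabeled_crosses
        )
        base_sizes = sorted(g.size for g in base.groups)
        reled_sizes = sorted(g.size for g in reled.groups)
        assert base_sizes == reled_sizes

    def test_raising_alpha_never_merges_groups(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            k = int(rng.integers(3, 6))
            lines = [
                LineRecord("f", str(i), int(rng.binomial(100, rng.uniform(0, 0.05))), 100)
                for i in range(k)
            ]
            crosses = []
            for i in range(k):
                for j in range(i + 1, k):
                    if rng.random() < 0.7:
                        crosses.append(
                            CrossRecord(
                                "f", str(i), str(j),
                                int(rng.binomial(100, rng.uniform(0, 0.25))), 100,
                            )
                        )
            qc = family_qc(lines, crosses)
            if not qc.ok:
                continue
            n_low = delineate_mutations(qc, crosses, ScreenConfig(alpha=0.1)).n_groups
            n_high = delineate_mutations(qc, crosses, ScreenConfig(alpha=0.5)).n_groups
            assert n_high >= n_low


class TestTallyAndExclusion:
    def test_size20_published_collection(self):
        fams = [(20, MutationPattern.of(1))] * 11
        fams += [(20, MutationPattern.of(2)), (20, MutationPattern.of(3)),
                 (20, MutationPattern.of(17))]
        fams += [(20, MutationPattern.of(1, 1))] * 2
        fams += [(20, MutationPattern(()))] * 95
        tally, stats = tally_patterns(fams)
        assert tally.families[20] == 111
        assert tally.n_empty(20) == 95
        assert sum(tally.patterns_for(20).values()) == 16
        assert stats.m_t == 11 + 1 + 1 + 1 + 2 * 2

    def test_mutation_count_distribution_totals(self):
        # published >=99% distribution: 1052/81/2 families with 1/2/3 mutations
        fams = []
        fams += [(30, MutationPattern.of(1))] * 1052
        fams += [(30, MutationPattern.of(1, 1))] * 81
        fams += [(30, MutationPattern.of(1, 1, 1))] * 2
        tally, stats = tally_patterns(fams)
        assert stats.m_t == 1052 + 2 * 81 + 3 * 2 == 1220

    def test_empty_input(self):
        tally, stats = tally_patterns([])
        assert stats.m_t == stats.n_m == stats.lines == 0
        assert stats.mu_tilde == 0.0

    def test_exclusion_threshold(self):
        fams = [
            (20, MutationPattern.of(17, 1)),  # 18/20 mutants
            (20, MutationPattern.of(10)),
            (30, MutationPattern.of(27)),
        ]
        kept, n_excluded = exclude_high_mutant_families(fams, 0.90)
        assert n_excluded == 2
        assert kept == [(20, MutationPattern.of(10))]
        kept_all, none_excluded = exclude_high_mutant_families(fams, 1.0)
        assert none_excluded == 0

    def test_exclusion_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        fams = []
        for _ in range(50):
            f = int(rng.integers(2, 30))
            k = int(rng.integers(0, f + 1))
            fams.append((f, MutationPattern((1,) * k)))
        last = -1
        for thr in (1.0, 0.9, 0.8, 0.5, 0.2):
            _, n = exclude_high_mutant_families(fams, thr)
            assert n >= last
            last = n

    def test_oversized_pattern_is_integrity_error(self):
        with pytest.raises(ValidationError):
            tally_patterns([(2, MutationPattern.of(2, 1))])
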