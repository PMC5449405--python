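import numpy as np
import pytest
from hypothesis import given, strategies as st

from foldspec.enrichment import (
    ContingencyTable,
    SpecificityResult,
    assign_best_interval,
    bonferroni,
    fisher_one_sided,
    select_terms,
    step1_enrichment,
    step2_specificity,
)
from foldspec.intervals import Interval, interval_gene_list, rank_and_partition
from foldspec.records import GeneRecord, GeneSetAnnotation
from helpers import fisher_oracle


class TestFisherOneSided:
    def test_single_most_extreme_table(self):
        # only one of C(4,2) draws puts both focal genes inside
        assert fisher_one_sided(ContingencyTable(2, 0, 0, 2)) == pytest.approx(1 / 6)

    def test_degenerate_margin_gives_one(self):
        assert fisher_one_sided(ContingencyTable(5, 0, 0, 0)) == pytest.approx(1.0)

    def test_zero_observed_gives_one(self):
        assert fisher_one_sided(ContingencyTable(0, 7, 3, 11)) == pytest.approx(1.0)

    def test_reference_worked_table_matches_oracle(self):
        t = ContingencyTable(96, 12, 167, 514)
        assert fisher_one_sided(t) == pytest.approx(fisher_oracle(96, 12, 167, 514), abs=1e-12)

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    def test_agrees_with_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_one_sided(ContingencyTable(a, b, c, d)) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )

    def test_monotone_in_overlap_at_fixed_margins(self):
        # shifting one focal gene into the interval can only shrink the tail
        ps = [fisher_one_sided(ContingencyTable(a, 10 - a, 20 - a, 70 - 10 + a))
              for a in range(0, 11)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestBonferroni:
    def test_identity_cap_and_product(self):
        assert bonferroni(0.001, 1) == 0.001
        assert bonferroni(0.01, 200) == 1.0
        assert bonferroni(1e-6, 420) == pytest.approx(4.2e-4)

    def test_multiplier_below_one_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


def _uniform_partition(n, q=6, direction="up"):
    recs = [GeneRecord(f"U{i:04d}", direction, 1.5 + 0.01 * i) for i in range(n)]
    return rank_and_partition(recs, q)


class TestStep1:
    def test_maximally_enriched_term_flagged(self):
        part = _uniform_partition(36, q=6)
        ann = GeneSetAnnotation()
        # term = exactly the weakest quantile, absent elsewhere in a 400-gene universe
        for g in interval_gene_list(part, Interval(1, 1)):
            ann.add("T:FOCAL", g)
        for i in range(30):
            ann.add("T:OTHER", f"BG{i:03d}")
        background = {f"BG{i:03d}" for i in range(400)} | part.genes()
        results = step1_enrichment(part, ann, background, alpha1=0.001)
        focal = [r for r in results if r.term_id == "T:FOCAL" and r.interval == Interval(1, 1)]
        assert focal[0].significant
        assert focal[0].counts.a == 6 and focal[0].counts.b == 0

    def test_proportional_term_not_significant(self):
        # term spread proportionally to the background: no enrichment signal
        part = _uniform_partition(20, q=4)
        ann = GeneSetAnnotation()
        for g in part.ordered_genes[::2]:  # every other gene, all quantiles alike
            ann.add("T:FLAT", g)
        ann.add("T:PAD", part.ordered_genes[0]); ann.add("T:PAD", part.ordered_genes[5])
        background = part.genes() | {f"BG{i}" for i in range(20)}
        results = step1_enrichment(part, ann, background)
        flat = [r for r in results if r.term_id == "T:FLAT"]
        assert flat and not any(r.significant for r in flat)

    def test_adjusted_never_below_raw_and_multiplier_consistent(self):
        part = _uniform_partition(30, q=6)
        ann = GeneSetAnnotation()
        for i, g in enumerate(part.ordered_genes):
            ann.add(f"T{i % 3}", g)
        results = step1_enrichment(part, ann, part.genes())
        assert results
        for r in results:
            assert r.adj_p >= r.raw_p
            assert r.adj_p == pytest.approx(min(1.0, r.raw_p * 3 * 21))

    def test_empty_background_rejected(self):
        part = _uniform_partition(12)
        with pytest.raises(ValueError):
            step1_enrichment(part, GeneSetAnnotation(), set())

    def test_missing_degs_added_to_background(self):
        part = _uniform_partition(12)
        ann = GeneSetAnnotation()
        ann.add("T0", part.ordered_genes[0]); ann.add("T0", part.ordered_genes[1])
        results = step1_enrichment(part, ann, {"ONLYBG01"})
        assert all(r.counts.universe == 13 for r in results)


class TestStep2:
    def test_reference_worked_example_counts_and_fractions(self, table1_partition):
        """108 term genes among 789 UGs, 96 inside the 263-gene weakest interval."""
        part = table1_partition
        inside = interval_gene_list(part, Interval(1, 2))
        outside = [g for g in part.ordered_genes if g not in set(inside)]
        ann = GeneSetAnnotation()
        # spread the 96 members evenly over the interval so (1,2) is the signal
        members = [inside[round(i * len(inside) / 96)] for i in range(96)]
        for g in members + outside[:12]:
            ann.add("GO:translation", g)
        results = step2_specificity(["GO:translation"], part, ann)
        (res,) = results
        assert res.fold_change_specific
        assert res.best_interval == Interval(1, 2)
        t = res.best_counts
        assert (t.a, t.b, t.c, t.d) == (96, 12, 167, 514)
        assert 100 * t.a / t.focal_total == pytest.approx(88.9, abs=0.05)
        assert 100 * t.interval_total / t.universe == pytest.approx(33.3, abs=0.05)
        raw = [r for iv, r, _ in res.per_interval if iv == Interval(1, 2)][0]
        assert raw == pytest.approx(fisher_oracle(96, 12, 167, 514), abs=1e-12)

    def test_full_interval_would_be_uninformative(self, table1_partition):
        # with every gene inside, the one-sided p is identically 1 — the
        # reason the full interval is excluded from the 20 tested
        n = table1_partition.n
        assert fisher_one_sided(ContingencyTable(108, 0, n - 108, 0)) == pytest.approx(1.0)
        ann = GeneSetAnnotation()
        for g in table1_partition.ordered_genes[:108]:
            ann.add("T", g)
        (res,) = step2_specificity(["T"], table1_partition, ann)
        assert len(res.per_interval) == 20
        assert all(iv != Interval(1, 6) for iv, _, _ in res.per_interval)

    def test_uniformly_spread_term_not_specific(self):
        part = _uniform_partition(120, q=6)
        ann = GeneSetAnnotation()
        for g in part.ordered_genes[::2]:
            ann.add("T:FLAT", g)
        (res,) = step2_specificity(["T:FLAT"], part, ann)
        assert not res.fold_change_specific
        assert res.best_interval is None

    def test_term_without_deg_genes_skipped(self):
        part = _uniform_partition(12)
        ann = GeneSetAnnotation()
        ann.add("T:ELSEWHERE", "NOT_A_DEG")
        assert step2_specificity(["T:ELSEWHERE"], part, ann) == []


class TestAssignBestInterval:
    def _mk(self, pvals):
        per = [(iv, p, p) for iv, p in pvals.items()]
        return SpecificityResult("T", "up", per, None, True)

    def test_strict_minimum(self):
        res = self._mk({Interval(1, 1): 1e-8, Interval(1, 2): 1e-5})
        assert assign_best_interval(res) == Interval(1, 1)

    def test_tie_prefers_shortest_then_weakest(self):
        res = self._mk({Interval(1, 2): 1e-6, Interval(1, 1): 1e-6, Interval(2, 2): 1e-6})
        assert assign_best_interval(res) == Interval(1, 1)

    def test_no_tested_intervals_rejected(self):
        with pytest.raises(ValueError):
            assign_best_interval(SpecificityResult("T", "up", [], None, False))


class TestTwoStepIntegration:
    def test_planted_term_recovered_end_to_end(self):
        from foldspec.pipeline import planted_term_trial

        outcome = planted_term_trial(seed=7, q=6, pi=0.9)
        assert outcome.recovered
        assert outcome.n_false_positives == 0

    def test_significance_invariant_under_input_permutation(self):
        rng = np.random.default_rng(3)
        recs = [GeneRecord(f"U{i:03d}", "up", float(fc))
                for i, fc in enumerate(rng.uniform(1.5, 50, size=60))]
        ann = GeneSetAnnotation()
        for g in recs[:12]:
            ann.add("T:A", g.gene_id)
        for g in recs[30:40]:
            ann.add("T:B", g.gene_id)
        bg = {r.gene_id for r in recs} | {f"BG{i}" for i in range(100)}

        def run(order):
            part = rank_and_partition(order, 6)
            res = step1_enrichment(part, ann, bg)
            return {(r.term_id, r.interval): (r.raw_p, r.significant) for r in res}

        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert run(recs) == run(shuffled)
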