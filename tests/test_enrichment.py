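"""Set assembly, contingency construction and conditional odds-ratio inference."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from devchar import (
    ContingencyTable,
    DataError,
    GeneSet,
    assemble_union_set,
    build_contingency,
    contingency_from_counts,
    cornfield_ci,
    enrich,
    enrich_table,
    exact_ci,
    fisher_two_sided,
    odds_ratio_cmle,
    odds_ratio_sample,
    read_gmt,
    write_gmt,
)
from devchar.enrichment import _conditional_pmf

SHARED_VITD_GENES = {"CAMP", "CD274", "CYP19A1", "CYP24A1", "DHCR7",
                     "LGMN", "MED13", "NFKBIA", "TNFSF4", "VDR"}


def enumeration_fisher_p(t):
    """Two-sided Fisher p by direct enumeration over the support (oracle)."""
    m1, m2, n1 = t.a + t.b, t.c + t.d, t.a + t.c
    xs = np.arange(max(0, n1 - m2), min(m1, n1) + 1)
    logp = (gammaln(m1 + 1) - gammaln(xs + 1) - gammaln(m1 - xs + 1)
            + gammaln(m2 + 1) - gammaln(n1 - xs + 1) - gammaln(m2 - n1 + xs + 1))
    logp -= np.log(np.exp(logp - logp.max()).sum()) + logp.max()
    p = np.exp(logp)
    obs = p[xs == t.a][0]
    return min(1.0, p[p <= obs * (1 + 1e-7)].sum())


class TestAssembleUnion:
    def test_shared_genes_between_approaches(self):
        supervised = GeneSet("go_entrez", SHARED_VITD_GENES | {"CYP27B1", "TRIM24"})
        unsupervised = GeneSet("stimulation", SHARED_VITD_GENES | {"LAMP3", "TXNIP"})
        res = assemble_union_set([supervised], [unsupervised])
        assert res.intersection == SHARED_VITD_GENES
        assert len(res.gene_set) == 14
        assert res.gene_set.provenance["VDR"] == {"supervised", "unsupervised"}
        assert res.gene_set.provenance["LAMP3"] == {"unsupervised"}

    def test_disjoint_lists_union_is_sum(self):
        a = GeneSet("a", {"g1", "g2"})
        b = GeneSet("b", {"g3", "g4", "g5"})
        res = assemble_union_set([a], [b])
        assert len(res.gene_set) == 5
        assert res.intersection == set()

    def test_random_overlaps_match_set_algebra(self, rng):
        universe = [f"g{i}" for i in range(200)]
        sup = [GeneSet(f"s{k}", set(rng.choice(universe, 30, replace=False)))
               for k in range(3)]
        unsup = [GeneSet(f"u{k}", set(rng.choice(universe, 40, replace=False)))
                 for k in range(2)]
        res = assemble_union_set(sup, unsup)
        expected_sup = set().union(*(g.genes for g in sup))
        expected_unsup = set().union(*(g.genes for g in unsup))
        assert res.gene_set.genes == expected_sup | expected_unsup
        assert res.intersection == expected_sup & expected_unsup

    def test_gmt_round_trip(self, tmp_path):
        sets = [GeneSet("setA", {"g1", "g2"}), GeneSet("setB", {"g3"})]
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert {s.name: s.genes for s in back} == {s.name: s.genes for s in sets}


class TestContingency:
    def test_minimal_table(self):
        t = build_contingency(GeneSet("a", {"g1"}), GeneSet("b", {"g1"}), {"g1", "g2"})
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_sibling_pair_counts_reconstruct(self):
        t = contingency_from_counts(overlap=12, size_a=38, size_b=2697,
                                    universe_size=20188)
        assert (t.a, t.b, t.c, t.d) == (12, 26, 2685, 17465)
        assert t.total == 20188

    def test_random_sets_match_direct_counting(self, rng):
        universe = {f"g{i}" for i in range(500)}
        a = set(rng.choice(sorted(universe), 60, replace=False))
        b = set(rng.choice(sorted(universe), 120, replace=False))
        t = build_contingency(GeneSet("a", a), GeneSet("b", b), universe)
        assert t.a == len(a & b)
        assert t.b == len(a - b)
        assert t.c == len(b - a)
        assert t.d == len(universe - a - b)

    def test_members_outside_universe_dropped(self):
        t = build_contingency(GeneSet("a", {"g1", "zz"}), GeneSet("b", {"g1"}),
                              {"g1", "g2"})
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_empty_universe_rejected(self):
        with pytest.raises(DataError):
            build_contingency(GeneSet("a", {"g1"}), GeneSet("b", {"g1"}), set())


class TestFisher:
    def test_balanced_table_is_maximally_unextreme(self):
        assert fisher_two_sided(ContingencyTable(1, 1, 1, 1)) == 1.0

    def test_transpose_invariance(self, rng):
        for _ in range(20):
            cells = rng.integers(0, 30, size=4)
            t = ContingencyTable(*map(int, cells))
            assert fisher_two_sided(t) == pytest.approx(
                fisher_two_sided(t.transpose()), rel=1e-12)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            cells = [int(v) for v in rng.integers(0, 50, size=4)]
            t = ContingencyTable(*cells)
            expected = stats.fisher_exact([[t.a, t.b], [t.c, t.d]])[1]
            assert fisher_two_sided(t) == pytest.approx(expected, abs=1e-11)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            cells = [int(v) for v in rng.integers(0, 40, size=4)]
            t = ContingencyTable(*cells)
            assert fisher_two_sided(t) == pytest.approx(enumeration_fisher_p(t), abs=1e-12)


class TestOddsRatios:
    def test_sibling_pair_or_rounds_to_printed_value(self):
        t = ContingencyTable(12, 26, 2685, 17465)
        assert round(odds_ratio_sample(t), 2) == 3.00

    def test_treatment_or_rounds_to_printed_value(self):
        t = ContingencyTable(11, 27, 3357, 21565)
        assert round(odds_ratio_sample(t), 2) == 2.62

    def test_proportional_table_gives_unity(self):
        assert odds_ratio_sample(ContingencyTable(10, 20, 30, 60)) == pytest.approx(1.0)

    def test_zero_cell_flags(self):
        assert odds_ratio_sample(ContingencyTable(3, 0, 5, 7)) == np.inf
        assert np.isnan(odds_ratio_sample(ContingencyTable(0, 0, 5, 7)))

    def test_cmle_matches_scipy_conditional(self, rng):
        for _ in range(25):
            cells = [int(v) for v in rng.integers(1, 40, size=4)]
            t = ContingencyTable(*cells)
            expected = stats.contingency.odds_ratio(
                [[t.a, t.b], [t.c, t.d]], kind="conditional").statistic
            assert odds_ratio_cmle(t) == pytest.approx(expected, rel=1e-6)

    def test_cmle_boundary_cases(self):
        assert odds_ratio_cmle(ContingencyTable(0, 5, 3, 7)) == 0.0
        assert odds_ratio_cmle(ContingencyTable(5, 0, 3, 7)) == np.inf


class TestConfidenceIntervals:
    def test_exact_ci_matches_scipy(self, rng):
        for _ in range(15):
            cells = [int(v) for v in rng.integers(1, 30, size=4)]
            t = ContingencyTable(*cells)
            ref = stats.contingency.odds_ratio(
                [[t.a, t.b], [t.c, t.d]], kind="conditional").confidence_interval(0.95)
            low, high = exact_ci(t)
            assert low == pytest.approx(ref.low, rel=1e-6)
            assert high == pytest.approx(ref.high, rel=1e-6)

    def test_exact_ci_tail_probabilities_by_direct_summation(self, rng):
        for cells in [(4, 6, 3, 9), (2, 10, 7, 5), (12, 26, 30, 40), (1, 3, 5, 2)]:
            t = ContingencyTable(*cells)
            low, high = exact_ci(t)
            x, w = _conditional_pmf(t, np.log(low))
            assert w[x >= t.a].sum() == pytest.approx(0.025, abs=1e-6)
            x, w = _conditional_pmf(t, np.log(high))
            assert w[x <= t.a].sum() == pytest.approx(0.025, abs=1e-6)

    def test_bounds_bracket_cmle(self, rng):
        for _ in range(20):
            cells = [int(v) for v in rng.integers(1, 25, size=4)]
            t = ContingencyTable(*cells)
            cmle = odds_ratio_cmle(t)
            for method in (exact_ci, cornfield_ci):
                low, high = method(t)
                assert low <= cmle <= high

    def test_intervals_nest_with_level(self):
        t = ContingencyTable(12, 26, 2685, 17465)
        lo99, hi99 = exact_ci(t, level=0.99)
        lo95, hi95 = exact_ci(t, level=0.95)
        lo80, hi80 = exact_ci(t, level=0.80)
        assert lo99 < lo95 < lo80 < hi80 < hi95 < hi99

    def test_cornfield_reproduces_printed_intervals(self):
        low, high = cornfield_ci(ContingencyTable(12, 26, 2685, 17465))
        assert (round(low, 2), round(high, 2)) == (1.43, 6.21)
        low, high = cornfield_ci(ContingencyTable(11, 27, 3357, 21565))
        assert (round(low, 2), round(high, 2)) == (1.22, 5.50)

    def test_boundary_table_flags(self):
        low, high = exact_ci(ContingencyTable(0, 5, 3, 7))
        assert low == 0.0 and np.isfinite(high)
        low, high = exact_ci(ContingencyTable(5, 0, 0, 7))
        assert high == np.inf

    def test_coverage_on_simulated_tables(self, rng):
        """Exact conditional intervals are conservative: coverage >= nominal."""
        psi, m1, m2, n1 = 2.5, 15, 25, 12
        template = ContingencyTable(min(m1, n1), m1 - min(m1, n1),
                                    n1 - min(m1, n1), m2 - n1 + min(m1, n1))
        x_sup, w = _conditional_pmf(template, np.log(psi))
        hits = 0
        n_rep = 300
        draws = rng.choice(x_sup, size=n_rep, p=w)
        for a in draws:
            a = int(a)
            t = ContingencyTable(a, m1 - a, n1 - a, m2 - (n1 - a))
            low, high = exact_ci(t)
            hits += low <= psi <= high
        se = np.sqrt(0.95 * 0.05 / n_rep)
        assert hits / n_rep >= 0.95 - 3 * se


class TestEnrich:
    def test_sibling_pair_analysis_reproduces_headline(self):
        universe = [f"g{i}" for i in range(20188)]
        set_b = GeneSet("de", set(universe[:2697]))
        set_a = GeneSet("vdlung", set(universe[:12]) | set(universe[2697:2723]))
        res = enrich(set_a, set_b, universe)
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (12, 26, 2685, 17465)
        assert round(res.or_sample, 2) == 3.00
        assert (round(res.ci95[0], 2), round(res.ci95[1], 2)) == (1.43, 6.21)

    def test_label_order_invariance(self, rng):
        universe = {f"g{i}" for i in range(300)}
        a = GeneSet("a", set(rng.choice(sorted(universe), 40, replace=False)))
        b = GeneSet("b", set(rng.choice(sorted(universe), 90, replace=False)))
        r1 = enrich(a, b, universe)
        r2 = enrich(b, a, universe)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided, rel=1e-12)
        assert r1.or_sample == pytest.approx(r2.or_sample, rel=1e-12)

    def test_identical_sets_maximal_association(self):
        universe = {f"g{i}" for i in range(50)}
        a = GeneSet("a", set(sorted(universe)[:10]))
        res = enrich(a, a, universe)
        assert res.or_sample == np.inf
        assert res.p_two_sided < 1e-9

    def test_null_type_one_error_at_most_nominal(self, rng):
        universe = sorted(f"g{i}" for i in range(400))
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = set(rng.choice(universe, 25, replace=False))
            b = set(rng.choice(universe, 60, replace=False))
            t = build_contingency(GeneSet("a", a), GeneSet("b", b), universe)
            rejections += fisher_two_sided(t) < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rejections / n_rep <= 0.05 + 3 * se

    def test_json_record_is_serializable(self):
        res = enrich_table(ContingencyTable(12, 26, 2685, 17465))
        record = res.to_dict()
        assert record["cells"] == {"a": 12, "b": 26, "c": 2685, "d": 17465}
        import json
        json.loads(res.to_json())
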