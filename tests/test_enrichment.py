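import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nasfinder.enrichment import (
    ReferenceGeneSet,
    annotate_subnetworks,
    consolidate,
    dice_similarity,
    filter_functional_groups,
    functional_group_score,
    hypergeom_pvalue,
    read_gmt,
)
from nasfinder.pathfinder import SubNetwork
from nasfinder.regulators import DEGModule


def brute_force_upper_tail(k, t, r, N):
    """Enumerate the hypergeometric upper tail with binomial coefficients."""
    total = math.comb(N, t)
    return sum(math.comb(r, i) * math.comb(N - r, t - i)
               for i in range(k, min(t, r) + 1)) / total


class TestReadGmt:
    def test_dedup(self, write_tsv):
        (ref,) = read_gmt(write_tsv(["P1\tdesc\tg1\tg2\tg2"]))
        assert ref.name == "P1" and ref.genes == {"g1", "g2"}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("")
        assert read_gmt(path) == []

    def test_two_field_line_errors(self, write_tsv):
        with pytest.raises(Exception, match="line 1"):
            read_gmt(write_tsv(["P1\tdesc"]))

    def test_source_db_tag(self, write_tsv):
        (ref,) = read_gmt(write_tsv(["P1\td\tg1"]), source_db="KEGG")
        assert ref.source_db == "KEGG"


class TestDice:
    def test_identity(self):
        assert dice_similarity({"a", "b"}, {"a", "b"}) == 1.0

    def test_worked_example(self):
        assert dice_similarity({"g1", "g2", "g3"}, {"g2", "g3", "g4", "g5"}) == pytest.approx(4 / 7)

    def test_disjoint(self):
        assert dice_similarity({"a"}, {"b"}) == 0.0

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            dice_similarity(set(), set())

    @given(
        st.sets(st.integers(0, 20)),
        st.sets(st.integers(0, 20), min_size=1),
    )
    @settings(deadline=None, derandomize=True)
    def test_symmetric_bounded_one_iff_equal(self, T, R):
        d = dice_similarity(T, R)
        assert d == dice_similarity(R, T)
        assert 0.0 <= d <= 1.0
        assert (d == 1.0) == (T == R)

    @given(st.sets(st.integers(0, 20), min_size=1), st.sets(st.integers(0, 20), min_size=1))
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_shared_genes(self, T, R):
        d0 = dice_similarity(T, R)
        in_r = next(iter(R - T), None)
        if in_r is not None:
            assert dice_similarity(T | {in_r}, R) >= d0
        outside = next(x for x in range(100) if x not in R and x not in T)
        assert dice_similarity(T | {outside}, R) <= d0


class TestHypergeom:
    def test_k_zero_is_one(self):
        assert hypergeom_pvalue(0, 3, 4, 10) == 1.0

    def test_worked_example(self):
        # N=10, t=3, r=4, k=2: (C(4,2)C(6,1) + C(4,3)C(6,0)) / C(10,3)
        assert hypergeom_pvalue(2, 3, 4, 10) == pytest.approx(1 / 3)

    def test_certain_event(self):
        assert hypergeom_pvalue(5, 5, 5, 5) == pytest.approx(1.0)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(5, 3, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_pvalue(1, 3, 4, 2)

    def test_matches_brute_force_enumeration(self):
        for N in (5, 9, 15):
            for t in range(N + 1):
                for r in range(N + 1):
                    for k in range(min(t, r) + 1):
                        assert hypergeom_pvalue(k, t, r, N) == pytest.approx(
                            brute_force_upper_tail(k, t, r, N), abs=1e-12
                        )


def _subnet(regulator, covered, module_id="m1"):
    return SubNetwork(
        regulator=regulator, module_id=module_id,
        nodes=set(covered) | {regulator}, covered_genes=set(covered),
    )


def _module(genes, fc=1.0):
    return DEGModule(module_id="m1", comparison="c",
                     genes={g: (fc, 0.01) for g in genes})


NORM = {g: 0.8 for g in "abcdefgh"}


class TestAnnotate:
    def test_single_candidate(self):
        refs = [ReferenceGeneSet("P1", frozenset("abz"))]
        results = annotate_subnetworks(
            [_subnet("r1", {"a", "b"})], _module("ab"), refs, NORM, universe=20
        )
        assert results[0].reference.name == "P1"
        assert results[0].p_value == pytest.approx(hypergeom_pvalue(2, 2, 3, 20))
        assert results[0].selected

    def test_equal_p_tie_goes_to_higher_dice(self):
        # with t = N every upper-tail p is exactly 1, so only Dice separates:
        # T = {a,b,c,d}; dice(BIGGER)=2*2/6, dice(SINGLE)=2*1/5
        refs = [
            ReferenceGeneSet("SINGLE", frozenset("a")),
            ReferenceGeneSet("BIGGER", frozenset("ab")),
        ]
        (res,) = annotate_subnetworks(
            [_subnet("r1", {"a", "b", "c", "d"})], _module("abcd"), refs, NORM,
            universe=4,
        )
        assert res.p_value == 1.0
        assert res.reference.name == "BIGGER"

    def test_equal_p_and_dice_tie_goes_to_name_order(self):
        refs = [
            ReferenceGeneSet("ZZZ", frozenset("cd")),
            ReferenceGeneSet("AAA", frozenset("ab")),
        ]
        (res,) = annotate_subnetworks(
            [_subnet("r1", {"a", "b", "c", "d"})], _module("abcd"), refs, NORM,
            universe=4,
        )
        assert res.reference.name == "AAA"

    def test_equal_dice_tie_selected_by_nas(self):
        # two sub-networks for one regulator, same dice, different NAS via MNF
        refs = [ReferenceGeneSet("P", frozenset("ab"))]
        s1 = _subnet("r1", {"a"})
        s2 = _subnet("r1", {"b"})
        norm = {"a": 0.9, "b": 0.2}
        results = annotate_subnetworks([s1, s2], _module("ab"), refs, norm, universe=10)
        sel = [r for r in results if r.selected]
        assert len(sel) == 1
        assert sel[0].subnetwork.covered_genes == {"a"}  # NAS 0.45 beats 0.1

    def test_cdr_scope_module_uses_full_deg_list(self):
        # module gene "b" lies outside the sub-network; with cdr_scope
        # "module" it still counts toward the overlap
        refs = [ReferenceGeneSet("P", frozenset("ab"))]
        sub = _subnet("r1", {"a"})
        norm = {"a": 1.0, "b": 1.0}
        (by_target,) = annotate_subnetworks([sub], _module("ab"), refs, norm, universe=10)
        (by_module,) = annotate_subnetworks(
            [sub], _module("ab"), refs, norm, universe=10, cdr_scope="module"
        )
        assert by_target.nas_record.cdr == 1
        assert by_module.nas_record.cdr == 2
        assert by_module.nas > by_target.nas

    def test_all_empty_targets_error(self):
        refs = [ReferenceGeneSet("P", frozenset("ab"))]
        empty = SubNetwork(regulator="r", module_id="m1")
        with pytest.raises(ValueError, match="no mappable gene"):
            annotate_subnetworks([empty], _module("ab"), refs, NORM)

    def test_one_selected_per_regulator(self):
        refs = [ReferenceGeneSet("P", frozenset("abcd"))]
        subs = [_subnet("r1", {"a"}), _subnet("r1", {"a", "b"}), _subnet("r2", {"c"})]
        results = annotate_subnetworks(subs, _module("abcd"), refs, NORM, universe=10)
        per_reg = {}
        for r in results:
            per_reg.setdefault(r.subnetwork.regulator, 0)
            per_reg[r.subnetwork.regulator] += r.selected
        assert per_reg == {"r1": 1, "r2": 1}


class TestFunctionalGroupScore:
    def test_david_equivalence(self):
        assert functional_group_score([0.05, 0.05, 0.05]) == pytest.approx(1.301, abs=1e-3)

    def test_p_one_scores_zero(self):
        assert functional_group_score([1.0]) == 0.0

    def test_geometric_mean_arithmetic(self):
        assert functional_group_score([0.1, 0.001]) == pytest.approx(2.0)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            functional_group_score([0.0, 0.1])
        with pytest.raises(ValueError):
            functional_group_score([])

    def test_filter_keeps_significant_term_genes(self):
        groups = {
            "kept": [(0.01, {"g1", "g2"}), (0.2, {"g3"})],
            "weak": [(0.9, {"g4"}), (0.8, {"g5"})],
        }
        out = filter_functional_groups(groups)
        assert out == {"kept": {"g1", "g2"}}  # g3's term p >= 0.05


class TestConsolidate:
    def _result(self, name, regulator, nas, p):
        from nasfinder.enrichment import EnrichmentResult
        ref = ReferenceGeneSet(name, frozenset("ab"))
        return EnrichmentResult(
            subnetwork=_subnet(regulator, {"a"}), target_set=frozenset("a"),
            reference=ref, dice=0.5, p_value=p, nas=nas, selected=True,
        )

    def test_same_name_merged(self):
        results = [
            self._result("CARDIACEGF", "EGFR", 0.3, 0.01),
            self._result("CARDIACEGF", "IL12RB2", 0.2, 0.005),
            self._result("CARDIACEGF", "PPARA", 0.1, 0.02),
        ]
        (c,) = consolidate(results)
        assert set(c.regulators) == {"EGFR", "IL12RB2", "PPARA"}
        assert c.nas == 0.3 and c.p_value == 0.005

    def test_distinct_names_pass_through(self):
        results = [self._result("A", "r1", 0.1, 0.1), self._result("B", "r2", 0.2, 0.2)]
        assert len(consolidate(results)) == 2

    def test_empty_and_unselected(self):
        assert consolidate([]) == []
        r = self._result("A", "r1", 0.1, 0.1)
        r.selected = False
        assert consolidate([r]) == []
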