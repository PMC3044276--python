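"""Per-read SEED/KO/taxon assignment semantics and oracle equivalence."""

import numpy as np

from blastbin import (
    NO_HITS,
    NOT_ASSIGNED,
    AssignmentParams,
    FunctionMap,
    Hierarchy,
    KoMap,
    TaxonMap,
    assign_ko,
    assign_seed,
    assign_taxon,
)

from _oracles import brute_best_mapped, brute_taxon, random_tree

P = AssignmentParams(min_score=35, top_percent=10, min_support=1)


class TestAssignSeed:
    def test_best_mapped_hit_wins(self, hits_factory):
        fm = FunctionMap({"accA": "RoleX", "accB": "RoleY"})
        a = assign_seed(hits_factory("r1", [("accA", 60), ("accB", 50)]), fm, P)
        assert a.target == "RoleX"
        assert a.hit.subject_id == "accA"

    def test_unmapped_top_hit_falls_through(self, hits_factory):
        # top hit has no mapping; the best *mapped* hit provides the role
        fm = FunctionMap({"accB": "RoleY"})
        rh = hits_factory("r1", [("accA", 60), ("accB", 58)])
        assert assign_seed(rh, fm, P).target == "RoleY"

    def test_strict_mode_bins_unmapped_top_hit(self, hits_factory):
        fm = FunctionMap({"accB": "RoleY"})
        rh = hits_factory("r1", [("accA", 60), ("accB", 58)])
        assert assign_seed(rh, fm, P, strict=True).target == NOT_ASSIGNED

    def test_zero_hits_is_nohits(self, hits_factory):
        a = assign_seed(hits_factory("r1", []), FunctionMap({}), P)
        assert a.target == NO_HITS and a.hit is None

    def test_no_mapped_hits_is_notassigned(self, hits_factory):
        a = assign_seed(hits_factory("r1", [("x", 60)]), FunctionMap({"y": "R"}), P)
        assert a.target == NOT_ASSIGNED

    def test_raising_min_score_never_creates_assignment(self, hits_factory):
        fm = FunctionMap({"accA": "RoleX"})
        rh = hits_factory("r1", [("accA", 40)])
        low = assign_seed(rh, fm, AssignmentParams(min_score=35))
        high = assign_seed(rh, fm, AssignmentParams(min_score=50))
        assert low.target == "RoleX" and high.target == NOT_ASSIGNED


class TestAssignKo:
    def test_best_hit_with_known_ko_wins(self, hits_factory):
        km = KoMap({"accB": "K00001"})
        rh = hits_factory("r1", [("accA", 80), ("accB", 75)])
        assert assign_ko(rh, km, P).target == "K00001"

    def test_all_unmapped_is_notassigned(self, hits_factory):
        rh = hits_factory("r1", [("accA", 80)])
        assert assign_ko(rh, KoMap({}), P).target == NOT_ASSIGNED

    def test_score_tie_resolves_to_smaller_accession(self, hits_factory):
        km = KoMap({"accB": "K00002", "accA": "K00001"})
        forward = assign_ko(hits_factory("r1", [("accB", 70), ("accA", 70)]), km, P)
        backward = assign_ko(hits_factory("r1", [("accA", 70), ("accB", 70)]), km, P)
        assert forward.target == backward.target == "K00001"


class TestAssignTaxon:
    def test_sibling_hits_place_on_parent(self, hits_factory, taxonomy):
        tm = TaxonMap({"a1": "B", "a2": "C"})
        rh = hits_factory("r1", [("a1", 60), ("a2", 58)])
        assert assign_taxon(rh, tm, taxonomy, P).target == "A"

    def test_single_hit_places_on_its_taxon(self, hits_factory, taxonomy):
        tm = TaxonMap({"a1": "B"})
        assert assign_taxon(hits_factory("r1", [("a1", 60)]), tm, taxonomy, P).target == "B"

    def test_filter_runs_before_lca(self, hits_factory, taxonomy):
        tm = TaxonMap({"a1": "B", "a2": "C"})
        rh = hits_factory("r1", [("a1", 100), ("a2", 85)])  # 85 outside 10% window
        assert assign_taxon(rh, tm, taxonomy, P).target == "B"

    def test_dangling_taxon_ignored(self, hits_factory, taxonomy):
        tm = TaxonMap({"a1": "GhostTaxon", "a2": "C"})
        rh = hits_factory("r1", [("a1", 60), ("a2", 59)])
        assert assign_taxon(rh, tm, taxonomy, P).target == "C"

    def test_result_is_ancestor_of_every_hit_taxon(self, hits_factory, taxonomy):
        tm = TaxonMap({"a1": "B", "a2": "E"})
        a = assign_taxon(hits_factory("r1", [("a1", 60), ("a2", 60)]), tm, taxonomy, P)
        for taxon in ("B", "E"):
            assert a.target in taxonomy.ancestors(taxon)


class TestPermutationInvariance:
    def test_assignment_independent_of_hit_order(self, hits_factory, rng):
        fm = FunctionMap({f"a{i}": f"Role{i % 3}" for i in range(6)})
        pairs = [(f"a{i}", float(40 + i)) for i in range(6)]
        baseline = assign_seed(hits_factory("r", pairs), fm, P).target
        for _ in range(5):
            perm = [pairs[i] for i in rng.permutation(len(pairs))]
            assert assign_seed(hits_factory("r", perm), fm, P).target == baseline


class TestOracleEquivalence:
    """Exhaustive-scan oracles on random inputs (smaller version of the
    acceptance sweep, run per-operation here for quick localization)."""

    def test_seed_and_ko_match_brute_force(self, hits_factory, rng):
        for _ in range(50):
            accs = [f"a{i}" for i in range(int(rng.integers(1, 12)))]
            mapping = {a: f"R{rng.integers(0, 4)}" for a in accs if rng.random() < 0.7}
            pairs = [
                (accs[int(rng.integers(len(accs)))], float(np.round(rng.uniform(20, 120), 1)))
                for _ in range(int(rng.integers(0, 20)))
            ]
            rh = hits_factory("r", pairs)
            expect = brute_best_mapped(pairs, mapping, 35, 10)
            assert assign_seed(rh, FunctionMap(mapping), P).target == expect
            assert assign_ko(rh, KoMap(mapping), P).target == expect

    def test_taxon_matches_brute_force(self, hits_factory, rng):
        for _ in range(50):
            parent = random_tree(rng, int(rng.integers(2, 50)))
            h = Hierarchy(parent)
            nodes = sorted(h.nodes)
            accs = [f"a{i}" for i in range(8)]
            mapping = {
                a: nodes[int(rng.integers(len(nodes)))] for a in accs if rng.random() < 0.8
            }
            pairs = [
                (accs[int(rng.integers(len(accs)))], float(np.round(rng.uniform(20, 120), 1)))
                for _ in range(int(rng.integers(0, 20)))
            ]
            rh = hits_factory("r", pairs)
            expect = brute_taxon(pairs, mapping, parent, 35, 10)
            assert assign_taxon(rh, TaxonMap(mapping), h, P).target == expect
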