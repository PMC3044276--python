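"""Count profiles: multi-labeled placement, recurrence, joins, normalization."""

import pytest

from blastbin import (
    Assignment,
    DegenerateInputError,
    build_profile,
    join_profiles,
    normalize,
)
from blastbin.profiles import role_table, read_profile_tsv, table_from_columns


def seed_assignments(pairs):
    return [Assignment(f"r{i}", "seed-role", role) for i, role in enumerate(pairs)]


class TestBuildProfile:
    def test_single_leaf_role(self, seed_tree):
        prof = build_profile(seed_assignments(["RoleA"]), seed_tree)
        assert prof.assigned == {"L1": 1}
        summ = prof.summarized()
        assert summ["S1"] == 1 and summ["root"] == 1

    def test_multilabeled_role_placed_on_every_leaf(self, seed_tree):
        prof = build_profile(seed_assignments(["RoleB"]), seed_tree)
        assert prof.assigned == {"L2": 1, "L3": 1}  # tree view counts twice
        assert prof.unique_assigned == 1  # unique-read audit counts once

    def test_empty_assignments_all_zero(self, seed_tree):
        prof = build_profile([], seed_tree)
        assert prof.assigned == {} and prof.total_reads == 0

    def test_unknown_role_routes_to_notassigned(self, seed_tree):
        prof = build_profile(seed_assignments(["GhostRole"]), seed_tree)
        assert prof.bins["NotAssigned"] == 1 and prof.unique_assigned == 0

    def test_bins_counted(self, seed_tree):
        assignments = [
            Assignment("r1", "seed-role", "NoHits"),
            Assignment("r2", "seed-role", "NotAssigned"),
            Assignment("r3", "seed-role", "RoleA"),
        ]
        prof = build_profile(assignments, seed_tree)
        assert prof.bins == {"NoHits": 1, "NotAssigned": 1}
        assert prof.total_reads == 3

    def test_unique_role_totals_equal_assigned_reads(self, seed_tree):
        roles = ["RoleA", "RoleB", "RoleB", "RoleC", "RoleB"]
        prof = build_profile(seed_assignments(roles), seed_tree)
        assert sum(prof.unique_by_target.values()) == prof.unique_assigned == 5

    def test_summarized_recurrence_everywhere(self, seed_tree):
        prof = build_profile(seed_assignments(["RoleA", "RoleB", "RoleC"] * 4), seed_tree)
        summ = prof.summarized()
        for node in seed_tree.nodes:
            assert summ.get(node, 0) == prof.assigned.get(node, 0) + sum(
                summ.get(c, 0) for c in seed_tree.children(node)
            )

    def test_additive_over_disjoint_read_sets(self, seed_tree):
        a = build_profile(seed_assignments(["RoleA", "RoleB"]), seed_tree)
        b_assignments = [Assignment(f"q{i}", "seed-role", r) for i, r in enumerate(["RoleC", "RoleB"])]
        b = build_profile(b_assignments, seed_tree)
        both = build_profile(
            seed_assignments(["RoleA", "RoleB"]) + b_assignments, seed_tree
        )
        merged = a + b
        assert merged.assigned == both.assigned
        assert merged.unique_assigned == both.unique_assigned

    def test_profile_tsv_round_trip(self, taxonomy, tmp_path):
        assignments = [Assignment(f"r{i}", "taxon", n) for i, n in enumerate(["B", "B", "A", "E"])]
        assignments.append(Assignment("r9", "taxon", "NoHits"))
        prof = build_profile(assignments, taxonomy, "sX")
        p = tmp_path / "sX.profile.tsv"
        prof.write_tsv(p)
        back = read_profile_tsv(p, taxonomy)
        assert back.sample_id == "sX"
        assert back.assigned == prof.assigned
        assert back.bins == prof.bins


class TestJoinAndNormalize:
    def test_identical_profiles_give_equal_columns(self, seed_tree):
        a = build_profile(seed_assignments(["RoleA", "RoleC"]), seed_tree, "s1")
        b = build_profile(seed_assignments(["RoleA", "RoleC"]), seed_tree, "s2")
        table = join_profiles([a, b], mode="assigned")
        assert (table.data["s1"] == table.data["s2"]).all()

    def test_join_preserves_each_column(self, seed_tree):
        profs = [
            build_profile(seed_assignments(roles), seed_tree, f"s{i}")
            for i, roles in enumerate([["RoleA"], ["RoleB", "RoleC"], ["RoleC"] * 3])
        ]
        table = join_profiles(profs, mode="assigned")
        for p in profs:
            for node, c in p.assigned.items():
                assert table.data.loc[node, p.sample_id] == c
        # column sums (without bins) match tree-view totals
        no_bins = table.drop_bins()
        for p in profs:
            assert no_bins.data[p.sample_id].sum() == sum(p.assigned.values())

    def test_role_table_uses_unique_counts(self, seed_tree):
        prof = build_profile(seed_assignments(["RoleB", "RoleB"]), seed_tree, "s1")
        other = build_profile(seed_assignments(["RoleA"]), seed_tree, "s2")
        table = role_table([prof, other])
        assert table.data.loc["RoleB", "s1"] == 2  # not 4 despite two leaves

    def test_relative_normalization_sums_to_one(self):
        table = table_from_columns({"s1": {"a": 2, "b": 2}, "s2": {"a": 1, "b": 3}})
        rel = normalize(table, "relative")
        assert rel.data["s1"].tolist() == [0.5, 0.5]
        assert rel.data.sum(axis=0).tolist() == pytest.approx([1.0, 1.0])

    def test_none_mode_is_identity(self):
        table = table_from_columns({"s1": {"a": 2}, "s2": {"a": 1}})
        assert normalize(table, "none") is table

    def test_zero_total_column_names_the_sample(self):
        table = table_from_columns({"good": {"a": 2}, "empty": {}})
        with pytest.raises(DegenerateInputError, match="empty"):
            normalize(table, "relative")
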