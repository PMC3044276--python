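"""Ecological indices, UniFrac, and distance-matrix export formats."""

import numpy as np
import pytest

from blastbin import (
    ECOLOGICAL_INDICES,
    Hierarchy,
    ecological_distance,
    export_network,
    read_phylip,
    unifrac,
)
from blastbin.profiles import table_from_columns

from _oracles import brute_unifrac, random_tree


def table(cols):
    return table_from_columns(cols)


class TestEcologicalIndices:
    @pytest.mark.parametrize("index", ECOLOGICAL_INDICES)
    def test_identical_columns_give_zero(self, index):
        t = table({"s1": {"a": 3, "b": 1}, "s2": {"a": 3, "b": 1}})
        dm = ecological_distance(t, index)
        assert dm[("s1", "s2")] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("index", ["bray-curtis", "kulczynski"])
    def test_disjoint_support_gives_one(self, index):
        t = table({"s1": {"a": 5, "b": 2}, "s2": {"c": 1, "d": 9}})
        assert ecological_distance(t, index)[("s1", "s2")] == pytest.approx(1.0)

    def test_bray_curtis_hand_example(self):
        t = table({"x": {"i": 1, "j": 2, "k": 3}, "y": {"i": 3, "j": 2, "k": 1}})
        assert ecological_distance(t, "bray-curtis")[("x", "y")] == pytest.approx(1 / 3)

    def test_hellinger_hand_example(self):
        # relative columns (1/4, 3/4) vs (3/4, 1/4)
        t = table({"x": {"i": 1, "j": 3}, "y": {"i": 3, "j": 1}})
        expect = np.sqrt(2 * (np.sqrt(0.25) - np.sqrt(0.75)) ** 2)
        assert ecological_distance(t, "hellinger")[("x", "y")] == pytest.approx(expect)

    def test_euclidean_on_relative_abundances(self):
        t = table({"x": {"i": 1, "j": 1}, "y": {"i": 1, "j": 3}})
        expect = np.sqrt((0.5 - 0.25) ** 2 + (0.5 - 0.75) ** 2)
        assert ecological_distance(t, "euclidean")[("x", "y")] == pytest.approx(expect)

    def test_chi_square_drops_zero_mass_rows(self):
        base = table({"x": {"i": 1, "j": 2}, "y": {"i": 2, "j": 1}})
        padded = table({"x": {"i": 1, "j": 2, "z": 0}, "y": {"i": 2, "j": 1, "z": 0}})
        assert ecological_distance(base, "chi-square")[("x", "y")] == pytest.approx(
            ecological_distance(padded, "chi-square")[("x", "y")]
        )

    def test_goodall_ranks_similar_pairs_below_dissimilar(self, rng):
        cols = {
            "a1": {f"r{i}": 10 + i for i in range(6)},
            "a2": {f"r{i}": 11 + i for i in range(6)},
            "b1": {f"r{i}": 60 - 9 * i for i in range(6)},
        }
        dm = ecological_distance(table(cols), "goodall")
        assert dm[("a1", "a2")] < dm[("a1", "b1")]

    @pytest.mark.parametrize("index", ECOLOGICAL_INDICES)
    def test_symmetry_zero_diagonal_and_bounds(self, index, rng):
        for _ in range(5):
            cols = {
                f"s{i}": {f"r{j}": float(rng.integers(0, 30)) for j in range(8)}
                for i in range(4)
            }
            for col in cols.values():  # avoid all-zero samples
                col["r0"] += 1.0
            dm = ecological_distance(table(cols), index)
            assert np.allclose(dm.values, dm.values.T)
            assert np.allclose(np.diag(dm.values), 0.0)
            assert (dm.values >= -1e-12).all()
            if index in ("bray-curtis", "kulczynski", "goodall"):
                assert (dm.values <= 1 + 1e-12).all()

    def test_unknown_index_rejected(self):
        with pytest.raises(ValueError, match="unknown index"):
            ecological_distance(table({"a": {"r": 1}, "b": {"r": 2}}), "jaccard")

    def test_single_sample_rejected(self):
        from blastbin import DegenerateInputError

        with pytest.raises(DegenerateInputError):
            ecological_distance(table({"a": {"r": 1}}), "bray-curtis")


class TestUniFrac:
    def two_leaf_star(self):
        return Hierarchy({"root": "root", "x": "root", "y": "root"})

    @pytest.mark.parametrize("variant", ["unweighted", "weighted-normalized"])
    def test_distinct_leaves_give_one(self, variant):
        h = self.two_leaf_star()
        t = table_from_columns({"s1": {"x": 5}, "s2": {"y": 3}}, h)
        assert unifrac(t, h, variant)[("s1", "s2")] == pytest.approx(1.0)

    @pytest.mark.parametrize("variant", ["unweighted", "weighted-normalized"])
    def test_identical_samples_give_zero(self, variant, taxonomy):
        t = table_from_columns({"s1": {"B": 2, "E": 1}, "s2": {"B": 2, "E": 1}}, taxonomy)
        assert unifrac(t, taxonomy, variant)[("s1", "s2")] == pytest.approx(0.0)

    def test_zero_mass_sample_rejected(self, taxonomy):
        from blastbin import DegenerateInputError

        t = table_from_columns({"s1": {"B": 2}, "s2": {}}, taxonomy)
        with pytest.raises(DegenerateInputError):
            unifrac(t, taxonomy, "unweighted")

    @pytest.mark.parametrize("variant", ["unweighted", "weighted-normalized"])
    def test_matches_brute_force_on_random_trees(self, variant, rng):
        for _ in range(20):
            parent = random_tree(rng, 10)
            h = Hierarchy(parent)
            nodes = sorted(h.nodes)
            cols = {
                s: {n: float(rng.integers(0, 5)) for n in nodes} for s in ("s1", "s2")
            }
            for col in cols.values():
                col[nodes[int(rng.integers(len(nodes)))]] += 1.0
            dm = unifrac(table_from_columns(cols, h), h, variant)
            expect = brute_unifrac(parent, h.root, cols["s1"], cols["s2"], variant)
            assert dm[("s1", "s2")] == pytest.approx(expect)

    def test_agrees_with_skbio_on_tip_counts(self, rng):
        """Independent cross-check against scikit-bio's UniFrac on a star-free
        tree with counts only at tips and unit branch lengths."""
        from skbio import TreeNode
        from skbio.diversity import beta_diversity

        newick = "((a:1,b:1)i1:1,(c:1,(d:1,e:1)i2:1)i3:1)root;"
        h = Hierarchy(
            {"root": "root", "i1": "root", "i3": "root", "a": "i1", "b": "i1",
             "c": "i3", "i2": "i3", "d": "i2", "e": "i2"}
        )
        tree = TreeNode.read([newick])
        for _ in range(5):
            counts = rng.integers(0, 8, size=(2, 5))
            counts[:, 0] += 1
            tips = ["a", "b", "c", "d", "e"]
            cols = {
                "s1": dict(zip(tips, map(float, counts[0]))),
                "s2": dict(zip(tips, map(float, counts[1]))),
            }
            t = table_from_columns(cols, h)
            ours_u = unifrac(t, h, "unweighted")[("s1", "s2")]
            ours_w = unifrac(t, h, "weighted-normalized")[("s1", "s2")]
            ref_u = beta_diversity(
                "unweighted_unifrac", counts, ids=["s1", "s2"], taxa=tips, tree=tree
            )[0, 1]
            ref_w = beta_diversity(
                "weighted_unifrac", counts, ids=["s1", "s2"], taxa=tips, tree=tree,
                normalized=True,
            )[0, 1]
            assert ours_u == pytest.approx(ref_u)
            assert ours_w == pytest.approx(ref_w)


class TestExport:
    @pytest.fixture
    def dm(self):
        from blastbin import DistanceMatrix

        vals = np.array([[0.0, 0.25], [0.25, 0.0]])
        return DistanceMatrix(["s1", "s2"], vals, "bray-curtis")

    def test_phylip_header_and_round_trip(self, dm, tmp_path):
        p = tmp_path / "m.phylip"
        export_network(dm, p, "phylip-matrix")
        assert p.read_text().splitlines()[0] == "2"
        back = read_phylip(p)
        assert back.sample_ids == dm.sample_ids
        assert np.allclose(back.values, dm.values)

    def test_nexus_block_present(self, dm, tmp_path):
        p = tmp_path / "m.nex"
        export_network(dm, p, "nexus-distances")
        text = p.read_text()
        assert text.startswith("#NEXUS")
        assert "BEGIN Distances;" in text and "ntax=2" in text

    def test_edge_tsv_has_n_choose_2_edges(self, tmp_path, rng):
        from blastbin import DistanceMatrix

        vals = rng.uniform(0, 1, size=(8, 8))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(8)], vals, "x")
        p = tmp_path / "edges.tsv"
        export_network(dm, p, "edge-tsv")
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 28
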