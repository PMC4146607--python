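import numpy as np
import pytest

from preyscale.errors import ParameterError, ValidationError
from preyscale.treekit import (
    Phylogeny,
    TreeEnsemble,
    find_polytomies,
    prune,
    read_ensemble,
    read_newick,
    resolve_polytomies,
)

from conftest import star_tree


class TestPhylogeny:
    def test_geometry(self, toy_tree):
        assert toy_tree.n_tips == 3
        assert toy_tree.height == pytest.approx(2.0)
        assert toy_tree.is_binary()
        assert toy_tree.is_ultrametric()

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValidationError):
            Phylogeny.from_newick("((A:1,A:1):1,B:2);")

    def test_non_ultrametric_detected(self):
        t = Phylogeny.from_newick("((A:1,B:5):1,C:2);")
        assert not t.is_ultrametric()

    def test_zero_length_terminals_reported(self):
        t = Phylogeny.from_newick("((A:0,B:0):2,C:2);")
        assert set(t.zero_length_terminals()) == {"A", "B"}

    def test_newick_roundtrip(self, toy_tree):
        again = Phylogeny.from_newick(toy_tree.to_newick())
        assert again.to_newick() == toy_tree.to_newick()
        assert again.root_distances() == toy_tree.root_distances()


class TestPrune:
    def test_edge_summing_example(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        p = prune(t, {"A", "C"})
        assert set(p.tip_labels) == {"A", "C"}
        # A's path 1+1 is preserved by suppressing the degree-2 node
        assert p.root_distances() == {"A": pytest.approx(2.0), "C": pytest.approx(2.0)}

    def test_identity_prune(self, toy_tree):
        p = prune(toy_tree, set(toy_tree.tip_labels))
        assert set(p.tip_labels) == set(toy_tree.tip_labels)
        assert p.root_distances() == toy_tree.root_distances()

    def test_depths_preserved_on_larger_tree(self):
        nwk = "(((A:1,B:1):1,(C:0.5,D:0.5):1.5):1,(E:2.5,F:2.5):0.5);"
        t = Phylogeny.from_newick(nwk)
        keep = {"A", "D", "F"}
        p = prune(t, keep)
        before = t.root_distances()
        after = p.root_distances()
        for sp in keep:
            assert after[sp] == pytest.approx(before[sp])

    def test_missing_species_listed(self, toy_tree):
        with pytest.raises(ValidationError) as exc:
            prune(toy_tree, {"A_a", "Zz_zz"})
        assert "Zz_zz" in exc.value.problems

    def test_underscore_space_matching(self):
        t = Phylogeny.from_newick("((Aa_bb:1,Cc_dd:1):1,Ee_ff:2);")
        p = prune(t, {"Aa bb", "Ee ff"})
        assert set(p.tip_labels) == {"Aa_bb", "Ee_ff"}


class TestFindPolytomies:
    def test_binary_tree_empty(self, toy_tree):
        assert find_polytomies(toy_tree) == []

    def test_star_tree_degree_five(self):
        t = star_tree(list("ABCDE"))
        found = find_polytomies(t)
        assert len(found) == 1
        assert found[0][1] == 5

    def test_two_trichotomies(self):
        t = Phylogeny.from_newick("((A:1,B:1,C:1):1,(D:1,E:1,F:1):1);")
        degrees = sorted(d for _, d in find_polytomies(t))
        assert degrees == [3, 3]


class TestResolvePolytomies:
    def test_bad_n_trees(self, trichotomy):
        with pytest.raises(ParameterError):
            resolve_polytomies(trichotomy, 0, seed=1)

    def test_non_ultrametric_rejected(self):
        t = Phylogeny.from_newick("(A:1,B:5,C:2);")
        with pytest.raises(ValidationError, match="ultrametric"):
            resolve_polytomies(t, 1, seed=1)

    def test_binary_input_returns_copies(self, toy_tree):
        ens = resolve_polytomies(toy_tree, 10, seed=3)
        assert len(ens) == 10
        assert all(t.to_newick() == toy_tree.to_newick() for t in ens)

    def test_trichotomy_topologies_uniform(self, trichotomy):
        # DERIVED oracle: 3 labeled topologies for 3 tips; uniform means
        # each appears with frequency 1/3 +- 3*SE over 3000 draws.
        n = 3000
        ens = resolve_polytomies(trichotomy, n, seed=11)
        counts = {"A_a": 0, "B_b": 0, "C_c": 0}  # keyed by the outgroup tip
        for t in ens:
            root_kids = t.dendropy_tree.seed_node.child_nodes()
            leaves = [k for k in root_kids if k.is_leaf()]
            assert len(leaves) == 1
            counts[leaves[0].taxon.label] += 1
        p = 1.0 / 3.0
        se = np.sqrt(p * (1 - p) / n)
        for c in counts.values():
            assert abs(c / n - p) <= 3 * se

    def test_new_node_count(self):
        k = 6
        t = star_tree([f"T{i}" for i in range(k)], depth=2.0)
        resolved = resolve_polytomies(t, 1, seed=5)[0]
        n_internal = sum(1 for _ in resolved.dendropy_tree.preorder_internal_node_iter())
        assert resolved.is_binary()
        assert n_internal == k - 1  # gained k-2 on top of the single root

    def test_preserves_tips_ages_and_ultrametricity(self):
        nwk = "((A:1,B:1,C:1,D:1):1.5,(E:2,F:2,G:2):0.5);"
        t = Phylogeny.from_newick(nwk)
        ens = resolve_polytomies(t, 20, seed=9)
        root_age = t.height
        inner_ages = {
            round(t.node_age(nd), 9)
            for nd in t.dendropy_tree.preorder_internal_node_iter()
        }
        for r in ens:
            assert set(r.tip_labels) == set(t.tip_labels)
            assert r.is_binary()
            assert r.is_ultrametric()
            assert r.height == pytest.approx(root_age)
            new_ages = {
                round(r.node_age(nd), 9)
                for nd in r.dendropy_tree.preorder_internal_node_iter()
            }
            # ages of pre-existing nodes survive resolution
            assert inner_ages <= new_ages

    def test_new_ages_within_polytomy_bounds(self):
        t = Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1):0;")
        for seed in range(5):
            r = resolve_polytomies(t, 1, seed=seed)[0]
            for nd in r.dendropy_tree.preorder_node_iter():
                if nd.parent_node is not None:
                    assert (nd.edge.length or 0.0) >= 0.0
            for nd in r.dendropy_tree.preorder_internal_node_iter():
                assert 0.0 <= r.node_age(nd) <= 1.0 + 1e-9

    def test_seeded_determinism_bit_identical(self, trichotomy):
        a = resolve_polytomies(trichotomy, 25, seed=42)
        b = resolve_polytomies(trichotomy, 25, seed=42)
        assert [t.to_newick() for t in a] == [t.to_newick() for t in b]
        c = resolve_polytomies(trichotomy, 25, seed=43)
        assert [t.to_newick() for t in a] != [t.to_newick() for t in c]


class TestEnsembleIO:
    def test_write_read_roundtrip(self, tmp_path, trichotomy):
        ens = resolve_polytomies(trichotomy, 4, seed=2)
        path = tmp_path / "ens.nwk"
        ens.write(path)
        back = read_ensemble(path)
        assert len(back) == 4
        assert back.seeds == ens.seeds
        assert [t.to_newick() for t in back] == [t.to_newick() for t in ens]

    def test_validate_mixed_tipsets(self, toy_tree):
        other = Phylogeny.from_newick("((X:1,Y:1):1,Z:2);")
        ens = TreeEnsemble(trees=[toy_tree, other])
        with pytest.raises(ValidationError):
            ens.validate()

    def test_read_newick_single(self, tmp_path, toy_tree):
        path = tmp_path / "t.nwk"
        toy_tree.write_newick(path)
        assert read_newick(path).to_newick() == toy_tree.to_newick()
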