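"""Trees: NJ, midpoint rooting, bootstrap, PNJ, comparison statistics."""

import io

import dendropy
import numpy as np
import pytest

from structphy.distances import DistanceMatrix, distance_matrix
from structphy.errors import (UndefinedStatisticError, UsageError,
                              ValidationError)
from structphy.msa import Alignment
from structphy.seqstruct_io import write_newick
from structphy.trees import (Node, ProfileAssignment, Tree, average_support,
                             bipartitions, bootstrap_support, leaf_distances,
                             midpoint_root, neighbor_joining, profile_nj,
                             profiles_from_tree, robinson_foulds)

from conftest import edge_length_map, random_unrooted_tree


def additive_matrix(tree):
    dists = leaf_distances(tree)
    labels = sorted(tree.leaf_labels())
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dists[(a, labels[j])]
    return DistanceMatrix(labels=labels, d=d)


class TestNeighborJoining:
    def test_two_taxa_split_symmetrically(self):
        t = neighbor_joining(DistanceMatrix(labels=["A", "B"],
                                            d=np.array([[0, 1.0], [1.0, 0]])))
        assert all(leaf.length == 0.5 for leaf in t.leaves())

    def test_three_taxa_three_point_formula(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        t = neighbor_joining(DistanceMatrix(labels=["A", "B", "C"], d=d))
        lengths = {l.label: l.length for l in t.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_quartet_recovers_split_and_internal_edge(self):
        # tree ((A:1,B:1):1,(C:1,D:1):1)
        d = np.array([[0, 2, 3, 3], [2, 0, 3, 3],
                      [3, 3, 0, 2], [3, 3, 2, 0]], float)
        t = neighbor_joining(DistanceMatrix(labels=list("ABCD"), d=d))
        assert bipartitions(t) == {frozenset({"C", "D"})}
        internal = [n for n in t.postorder()
                    if not n.is_leaf and n is not t.root]
        assert internal[0].length == pytest.approx(1.0)

    def test_additive_matrices_recover_tree_exactly(self, rng):
        for n in (5, 8, 13):
            labels = [f"t{i:02d}" for i in range(n)]
            truth = random_unrooted_tree(labels, rng)
            out = neighbor_joining(additive_matrix(truth))
            assert robinson_foulds(out, truth) == 0
            want, got = edge_length_map(truth), edge_length_map(out)
            for key, length in want.items():
                assert got[key] == pytest.approx(length, abs=1e-9)

    def test_agrees_with_dendropy_on_noisy_matrix(self, rng):
        """Independent NJ cross-check on non-additive distances."""
        n = 8
        labels = [f"t{i}" for i in range(n)]
        truth = random_unrooted_tree(labels, rng)
        d = additive_matrix(truth).d
        noise = rng.uniform(0, 0.05, size=d.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        dm = DistanceMatrix(labels=labels, d=d + noise)
        ours = neighbor_joining(dm)
        csv = "x," + ",".join(labels) + "\n" + "\n".join(
            lab + "," + ",".join(f"{x:.10f}" for x in row)
            for lab, row in zip(labels, dm.d))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=",")
        theirs = dendropy.Tree.get(data=pdm.nj_tree().as_string(schema="newick"),
                                   schema="newick")
        tns = theirs.taxon_namespace
        mine = dendropy.Tree.get(data=write_newick(ours), schema="newick",
                                 taxon_namespace=tns)
        rf = dendropy.calculate.treecompare.symmetric_difference(
            mine, theirs)
        assert rf == 0

    def test_non_finite_entries_rejected(self):
        d = np.array([[0, np.inf], [np.inf, 0]])
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(labels=["a", "b"], d=d))


class TestMidpointRoot:
    def test_chain_rooted_exactly_between(self):
        inner = Node(length=2.0, children=[Node("B", 2.0)])
        t = Tree(Node(children=[Node("A", 0.0), inner]), rooted=False)
        # path A -0- x -2- y -2- B: diameter 4, midpoint 2 from each leaf
        rooted = midpoint_root(t)
        dists = leaf_distances(rooted)
        assert dists[("A", "B")] == pytest.approx(4.0)
        depths = {}
        def walk(node, depth):
            if node.is_leaf:
                depths[node.label] = depth
            for c in node.children:
                walk(c, depth + c.length)
        walk(rooted.root, 0.0)
        assert depths["A"] == pytest.approx(2.0)
        assert depths["B"] == pytest.approx(2.0)

    def test_caterpillar_root_on_diameter_path(self, rng):
        # caterpillar with long pendant edges at both ends
        labels = ["a", "b", "c", "d", "e"]
        t = random_unrooted_tree(labels, rng)
        for leaf in t.leaves():
            if leaf.label in ("a", "e"):
                leaf.length = 10.0
        rooted = midpoint_root(t)
        left = {l.label for l in Tree(rooted.root.children[0]).leaves()}
        assert ("a" in left) != ("e" in left)  # diameter endpoints split

    def test_rerooting_preserves_leaf_path_lengths(self, rng):
        for n in (4, 9, 16):
            t = random_unrooted_tree([f"t{i}" for i in range(n)], rng)
            before = leaf_distances(t)
            after = leaf_distances(midpoint_root(t))
            for key, val in before.items():
                assert after[key] == pytest.approx(val, abs=1e-9)

    def test_all_zero_lengths_warns_and_roots_deterministically(self):
        t = random_unrooted_tree([f"t{i}" for i in range(5)],
                                 np.random.default_rng(0))
        for node in t.postorder():
            if node.length is not None:
                node.length = 0.0
        with pytest.warns(UserWarning):
            rooted = midpoint_root(t)
        assert sorted(rooted.leaf_labels()) == sorted(t.leaf_labels())


class TestBootstrap:
    @staticmethod
    def builder(aln):
        return neighbor_joining(distance_matrix(aln, saturation="cap"))

    def test_congruent_columns_give_full_support(self):
        rows = {"a": "AAAAGGGG", "b": "AAAAGGGG",
                "c": "CCCCGGGG", "d": "CCCCUUUU"}
        aln = Alignment(ids=list(rows), rows=list(rows.values()),
                        alphabet="nuc")
        t = bootstrap_support(aln, self.builder, n_reps=50, seed=1)
        sups = [n.support for n in t.postorder() if n.support is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_seed_reproducibility(self, rng):
        rows = ["".join("ACGU"[i] for i in rng.integers(0, 4, size=50))
                for _ in range(6)]
        aln = Alignment(ids=[f"s{i}" for i in range(6)], rows=rows,
                        alphabet="nuc")
        t1 = bootstrap_support(aln, self.builder, n_reps=30, seed=9)
        t2 = bootstrap_support(aln, self.builder, n_reps=30, seed=9)
        assert write_newick(t1) == write_newick(t2)
        t3 = bootstrap_support(aln, self.builder, n_reps=30, seed=10)
        for a, b in zip(t1.postorder(), t3.postorder()):
            if a.support is not None:
                assert abs(a.support - (b.support or 0)) <= 40  # sampling error

    def test_supports_in_range_and_internal_only(self, rng):
        rows = ["".join("ACGU"[i] for i in rng.integers(0, 4, size=50))
                for _ in range(7)]
        aln = Alignment(ids=[f"s{i}" for i in range(7)], rows=rows,
                        alphabet="nuc")
        t = bootstrap_support(aln, self.builder, n_reps=20, seed=3)
        for node in t.postorder():
            if node.is_leaf:
                assert node.support is None
            elif node.support is not None:
                assert 0 <= node.support <= 100

    def test_zero_replicates_rejected(self, rng):
        aln = Alignment(ids=["a", "b"], rows=["AC", "AC"], alphabet="nuc")
        with pytest.raises(UsageError):
            bootstrap_support(aln, self.builder, n_reps=0, seed=0)


class TestProfileNJ:
    def _random_alignment(self, rng, n=10, L=120):
        rows = ["".join("ACGU"[i] for i in rng.integers(0, 4, size=L))]
        for _ in range(n - 1):
            prev = rows[int(rng.integers(len(rows)))]
            mutated = list(prev)
            for pos in rng.choice(L, size=8, replace=False):
                mutated[pos] = "ACGU"[int(rng.integers(4))]
            rows.append("".join(mutated))
        return Alignment(ids=[f"s{i:02d}" for i in range(n)], rows=rows,
                         alphabet="nuc")

    def test_singletons_and_unreachable_threshold_reproduce_nj(self, rng):
        aln = self._random_alignment(rng)
        nj = neighbor_joining(distance_matrix(aln, saturation="cap"))
        assignment = ProfileAssignment(profiles={i: [i] for i in aln.ids})
        pnj, _ = profile_nj(aln, assignment, iterations=2, bs_threshold=101,
                            n_reps=5, seed=0, saturation="cap")
        assert bipartitions(pnj) == bipartitions(nj)

    def test_zero_iterations_equals_nj_on_initial_profiles(self, rng):
        aln = self._random_alignment(rng)
        assignment = ProfileAssignment(profiles={i: [i] for i in aln.ids})
        pnj, audit = profile_nj(aln, assignment, iterations=0, n_reps=5,
                                seed=0, saturation="cap")
        nj = neighbor_joining(distance_matrix(aln, saturation="cap"))
        assert len(audit) == 1
        assert bipartitions(pnj) == bipartitions(nj)

    def test_three_separated_clades_recovered_with_high_support(self):
        from structphy import simulate
        from structphy.encoding import encode

        cfg = simulate.default_config(n_taxa=12, n_sites=400, seed=21,
                                      scale=0.4)
        tree = simulate.simulate_tree(cfg)
        records, aln, _ = simulate.simulate_alignment(tree, cfg)
        nj = neighbor_joining(distance_matrix(aln, saturation="cap"))
        assignment = profiles_from_tree(midpoint_root(nj), min_size=2,
                                        max_size=4)
        if len(assignment.profiles) < 4:
            pytest.skip("profile layout too small on this draw")
        pnj, audit = profile_nj(aln, assignment, iterations=2,
                                bs_threshold=75, n_reps=50, seed=5,
                                saturation="cap")
        # profiles stay mutually exclusive groups in the expanded tree
        for name, members in audit[0].profiles.items():
            if len(members) < 2:
                continue
        assert average_support(pnj) > 50

    def test_threshold_validation(self, rng):
        aln = self._random_alignment(rng, n=4)
        assignment = ProfileAssignment(profiles={i: [i] for i in aln.ids})
        with pytest.raises(UsageError):
            profile_nj(aln, assignment, bs_threshold=150)

    def test_overlapping_profiles_rejected(self):
        with pytest.raises(ValidationError):
            ProfileAssignment(profiles={"a": ["x", "y"], "b": ["y"]})


class TestTreeStatistics:
    def test_average_support_examples(self):
        inner1 = Node(length=1.0, support=100.0,
                      children=[Node("A", 1), Node("B", 1)])
        inner2 = Node(length=1.0, support=80.0,
                      children=[inner1, Node("C", 1)])
        inner3 = Node(length=1.0, support=60.0,
                      children=[inner2, Node("D", 1)])
        t = Tree(Node(children=[inner3, Node("E", 1), Node("F", 1)]),
                 rooted=False)
        assert average_support(t) == pytest.approx(80.0)

    def test_single_supported_edge(self):
        inner = Node(length=1.0, support=77.0,
                     children=[Node("A", 1), Node("B", 1)])
        t = Tree(Node(children=[inner, Node("C", 1), Node("D", 1)]),
                 rooted=False)
        assert average_support(t) == 77.0

    def test_no_supports_undefined(self, rng):
        t = random_unrooted_tree(["a", "b", "c", "d"], rng)
        with pytest.raises(UndefinedStatisticError):
            average_support(t)

    def test_average_support_invariant_under_rerooting(self, rng):
        t = random_unrooted_tree([f"t{i}" for i in range(8)], rng)
        for node in t.postorder():
            if not node.is_leaf and node is not t.root:
                node.support = float(rng.integers(50, 101))
        before = average_support(t)
        after = average_support(midpoint_root(t))
        assert after == pytest.approx(before)

    def test_rf_identical_zero(self, rng):
        t = random_unrooted_tree([f"t{i}" for i in range(10)], rng)
        assert robinson_foulds(t, t.copy()) == 0

    def test_rf_quartet_topologies(self):
        def quartet(pair):
            inner = Node(length=1.0, children=[Node(pair[0], 1.0),
                                               Node(pair[1], 1.0)])
            others = [l for l in "ABCD" if l not in pair]
            return Tree(Node(children=[inner] + [Node(o, 1.0) for o in others]),
                        rooted=False)
        assert robinson_foulds(quartet("AB"), quartet("AC")) == 2

    def test_rf_upper_bound_and_dendropy_agreement(self, rng):
        for n in (5, 8, 12):
            labels = [f"t{i}" for i in range(n)]
            t1 = random_unrooted_tree(labels, rng)
            t2 = random_unrooted_tree(labels, rng)
            rf = robinson_foulds(t1, t2)
            assert 0 <= rf <= 2 * (n - 3)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert rf == dendropy.calculate.treecompare.symmetric_difference(d1, d2)

    def test_rf_requires_same_leaf_set(self, rng):
        t1 = random_unrooted_tree(["a", "b", "c", "d"], rng)
        t2 = random_unrooted_tree(["a", "b", "c", "e"], rng)
        with pytest.raises(UsageError):
            robinson_foulds(t1, t2)


class TestProfilesFromTree:
    def _balanced8(self):
        def cherry(a, b):
            return Node(length=1.0, children=[Node(a, 1.0), Node(b, 1.0)])
        left = Node(length=1.0, children=[cherry("a", "b"), cherry("c", "d")])
        right = Node(length=1.0, children=[cherry("e", "f"), cherry("g", "h")])
        return Tree(Node(children=[left, right]), rooted=True)

    def test_balanced_eight_leaves_depth_one(self):
        a = profiles_from_tree(self._balanced8(), min_size=2, depth=1)
        assert len(a.profiles) == 2
        assert sorted(map(len, a.profiles.values())) == [4, 4]
        assert a.unassigned == []

    def test_min_size_too_large_leaves_all_unassigned(self):
        a = profiles_from_tree(self._balanced8(), min_size=5, depth=1)
        assert a.profiles == {}
        assert len(a.unassigned) == 8

    def test_profiles_always_monophyletic(self, rng):
        for n in (8, 14):
            t = midpoint_root(random_unrooted_tree([f"t{i}" for i in range(n)],
                                                   rng))
            a = profiles_from_tree(t, min_size=2, max_size=4)
            clades = {frozenset(Tree(node).leaf_labels())
                      for node in t.postorder()}
            for members in a.profiles.values():
                assert frozenset(members) in clades
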