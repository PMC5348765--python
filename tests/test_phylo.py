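"""Distances, neighbor joining, bootstrap, monophyly, aRNH clustering."""

import math

import numpy as np
import pytest

from retromine import simulate
from retromine.phylo import (
    DistanceMatrix,
    bootstrap_support,
    center_star_msa,
    cluster_individual_arnh,
    is_monophyletic,
    nj_tree,
    protein_distance,
)


def random_additive_matrix(rng, n):
    """Leaf-to-leaf path distances of a random binary tree with branch
    lengths in [0.1, 1.0] (additive by construction)."""
    D = {}
    nodes = [(i, {i: 0.0}) for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (_, da), (_, db) = nodes[i], nodes[j]
        la, lb = rng.uniform(0.1, 1.0, 2)
        for x in da:
            for y in db:
                D[(x, y)] = D[(y, x)] = da[x] + la + db[y] + lb
        merged = {k: v + la for k, v in da.items()}
        merged.update({k: v + lb for k, v in db.items()})
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((-1, merged))
    labels = [f"t{i:02d}" for i in range(n)]
    M = np.zeros((n, n))
    for (x, y), d in D.items():
        M[x, y] = d
    return DistanceMatrix(labels, M)


def tree_path_distances(tree):
    """Pairwise leaf distances along the tree (independent of NJ)."""
    import collections

    adj = collections.defaultdict(list)
    names = {}

    def build(node):
        if node.is_leaf:
            names[id(node)] = node.name
        for child, length in node.children:
            adj[id(node)].append((id(child), length))
            adj[id(child)].append((id(node), length))
            build(child)

    build(tree.root)
    out = {}
    for src, name in names.items():
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, l in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + l
                    stack.append(v)
        for dst, other in names.items():
            if dst != src:
                out[(name, other)] = dist[dst]
    return out


class TestProteinDistance:
    def test_identical_sequences(self):
        assert protein_distance("ACDEF", "ACDEF") == 0.0

    def test_closed_form_at_ten_percent(self):
        a = "A" * 10
        b = "C" + "A" * 9
        assert protein_distance(a, b) == pytest.approx(-math.log(0.9))

    def test_matches_independent_recomputation(self, rng):
        from retromine.profiles import AMINO_ACIDS

        for _ in range(20):
            n = int(rng.integers(20, 80))
            a = "".join(rng.choice(list(AMINO_ACIDS) + ["-"], size=n))
            b = "".join(rng.choice(list(AMINO_ACIDS) + ["-"], size=n))
            pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not pairs:
                continue
            p = sum(x != y for x, y in pairs) / len(pairs)
            expected = 10.0 if p >= 1 - math.exp(-10.0) else -math.log(1 - p)
            assert protein_distance(a, b) == pytest.approx(expected)

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            protein_distance("A---", "-CC-")

    def test_symmetry(self, rng):
        a, b = "ACDEFGHIKL", "ACDWFGHIKV"
        assert protein_distance(a, b) == protein_distance(b, a)


class TestNeighborJoining:
    def test_exact_recovery_on_additive_matrices(self, rng):
        """NJ is consistent on additive distances: the reconstructed tree
        reproduces every pairwise path distance (hence the topology)."""
        for _ in range(20):
            n = int(rng.integers(6, 13))
            dm = random_additive_matrix(rng, n)
            tree = nj_tree(dm)
            paths = tree_path_distances(tree)
            for i, la in enumerate(dm.labels):
                for j, lb in enumerate(dm.labels):
                    if i < j:
                        assert paths[(la, lb)] == pytest.approx(
                            dm.values[i, j], abs=1e-8
                        )

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]]))
        tree = nj_tree(dm)
        lengths = {child.name: length for child, length in tree.root.children}
        assert lengths["a"] == pytest.approx(1.0)  # (3+4-5)/2
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_label_permutation_invariance(self, rng):
        dm = random_additive_matrix(rng, 8)
        tree = nj_tree(dm)
        perm = rng.permutation(len(dm.labels))
        shuffled = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        assert set(nj_tree(shuffled).bipartitions()) == set(tree.bipartitions())

    def test_agrees_with_scikit_bio(self, rng):
        """Independent implementation check on a noisy (non-additive)
        distance matrix: same unrooted topology."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        dm = random_additive_matrix(rng, 9)
        noisy = dm.values + rng.uniform(0, 0.01, dm.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        mine = nj_tree(DistanceMatrix(dm.labels, noisy))
        sk_tree = skbio_nj(skbio.DistanceMatrix(noisy, ids=dm.labels))
        leaves = frozenset(dm.labels)
        ref = min(leaves)
        sk_bips = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(leaves) - 2:
                sk_bips.add(side if ref not in side else leaves - side)
        assert set(mine.bipartitions()) <= sk_bips | {frozenset()}
        assert set(mine.bipartitions()) == {b for b in sk_bips if b}


class TestBootstrap:
    def _two_clades(self, rng):
        base = simulate.default_domain_templates()["RT_LTR"].protein
        other = simulate._variant(rng, base, 0.35)
        rows = {f"a{i}": simulate._variant(rng, base, 0.05) for i in range(5)}
        rows.update({f"b{i}": simulate._variant(rng, other, 0.05) for i in range(5)})
        labels = sorted(rows)
        return labels, [rows[l] for l in labels]

    def test_separated_clades_strongly_supported(self, rng):
        labels, rows = self._two_clades(rng)
        tree = bootstrap_support(labels, rows, n_reps=100, seed=4)
        bips = tree.bipartitions()
        clade = frozenset(l for l in labels if l.startswith("a"))
        canon = clade if min(labels) not in clade else frozenset(labels) - clade
        assert canon in bips
        assert bips[canon].support >= 90

    def test_zero_replicates_leave_supports_absent(self, rng):
        labels, rows = self._two_clades(rng)
        tree = bootstrap_support(labels, rows, n_reps=0, seed=4)
        assert all(node.support is None for node, _ in tree.edges())

    def test_same_seed_reproduces_supports(self, rng):
        labels, rows = self._two_clades(rng)
        t1 = bootstrap_support(labels, rows, n_reps=50, seed=9)
        t2 = bootstrap_support(labels, rows, n_reps=50, seed=9)
        assert t1.newick() == t2.newick()


class TestMonophyly:
    @pytest.fixture()
    def tree(self, rng):
        return nj_tree(random_additive_matrix(rng, 8))

    def test_singleton_and_full_set_are_trivially_monophyletic(self, tree):
        leaves = sorted(tree.leaves())
        assert is_monophyletic(tree, [leaves[0]])
        assert is_monophyletic(tree, leaves)

    def test_split_subset_is_not_monophyletic(self, rng):
        base = simulate.default_domain_templates()["aRNH"].protein
        far = simulate._variant(rng, base, 0.40)
        rows = {
            "a1": simulate._variant(rng, base, 0.03),
            "a2": simulate._variant(rng, base, 0.03),
            "b1": simulate._variant(rng, far, 0.03),
            "b2": simulate._variant(rng, far, 0.03),
        }
        labels = sorted(rows)
        tree = nj_tree(DistanceMatrix.from_alignment(labels, [rows[l] for l in labels]))
        assert is_monophyletic(tree, ["a1", "a2"])
        assert not is_monophyletic(tree, ["a1", "b1"])

    def test_unknown_label_rejected(self, tree):
        with pytest.raises(ValueError, match="unknown"):
            is_monophyletic(tree, ["not-a-leaf"])


class TestCenterStar:
    def test_rows_equal_length_and_preserve_residues(self, rng):
        dom = simulate.default_domain_templates()
        seqs = {
            "a": dom["aRNH"].protein,
            "b": dom["aRNH_Archon"].protein,
            "c": dom["aRNH_L1"].protein[:120],  # shorter on purpose
        }
        labels, rows = center_star_msa(seqs)
        assert len({len(r) for r in rows}) == 1
        for lab, row in zip(labels, rows):
            assert row.replace("-", "") == seqs[lab]


class TestClusterIndividuals:
    def test_remnants_join_source_group_and_unrelated_founds_novel(self, rng):
        dom = simulate.default_domain_templates()
        refs = simulate.arnh_domain_references()
        individuals = {}
        for i in range(3):
            individuals[f"arch{i}"] = simulate._variant(
                rng, dom["aRNH_Archon"].protein, 0.08
            )
            individuals[f"l1_{i}"] = simulate._variant(
                rng, dom["aRNH_L1"].protein, 0.08
            )
            individuals[f"cell{i}"] = simulate._variant(
                rng, dom["aRNH_cellular"].protein, 0.05
            )
        calls = cluster_individual_arnh(individuals, refs, seed=6)
        assert all(calls[f"arch{i}"] == "Archon" for i in range(3))
        assert all(calls[f"l1_{i}"] == "L1" for i in range(3))
        novel = {calls[f"cell{i}"] for i in range(3)}
        assert len(novel) == 1
        assert novel.pop().startswith("novel-")

    def test_single_sequence_gets_deterministic_label(self, rng):
        dom = simulate.default_domain_templates()
        refs = simulate.arnh_domain_references()
        one = {"only": simulate._variant(rng, dom["aRNH_Utopia"].protein, 0.05)}
        first = cluster_individual_arnh(one, refs, seed=2)
        second = cluster_individual_arnh(one, refs, seed=2)
        assert first == second
        assert first["only"] == "Utopia"
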