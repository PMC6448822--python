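"""Distances, neighbor joining, bootstrap and dotplot."""

import math

import numpy as np
import pytest

from regevol import phylo, synthetic
from regevol.phylo import (
    DistanceMatrix,
    bootstrap_support,
    dotplot,
    jc_correct,
    nj_tree,
    p_distance,
)


def random_quartet(rng):
    """Additive 4-taxon matrix from tree ((a,b),(c,d)) with random lengths."""
    la, lb, lc, ld = rng.uniform(0.05, 0.5, 4)
    m = rng.uniform(0.1, 0.6)  # internal edge, well separated
    labels = ["a", "b", "c", "d"]
    d = np.zeros((4, 4))
    dist = {
        ("a", "b"): la + lb,
        ("c", "d"): lc + ld,
        ("a", "c"): la + m + lc,
        ("a", "d"): la + m + ld,
        ("b", "c"): lb + m + lc,
        ("b", "d"): lb + m + ld,
    }
    for (x, y), v in dist.items():
        i, j = labels.index(x), labels.index(y)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(labels, d), {"a", "b"}


def random_additive(rng, n):
    """Additive matrix from a random binary tree built by sequential attachment."""
    # leaf i sits at the end of a chain of random edges; track pairwise paths
    # via a simple recursive tree of nested tuples: (left, right, llen, rlen)
    nodes = [(f"t{i}",) for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append((left, right, float(rng.uniform(0.05, 0.4)),
                      float(rng.uniform(0.05, 0.4))))
    root = nodes[0]

    depths = {}

    def collect(node, acc):
        if len(node) == 1:
            depths[node[0]] = acc
            return
        left, right, ll, rl = node
        collect(left, acc + [("L", ll)])
        collect(right, acc + [("R", rl)])

    collect(root, [])
    labels = sorted(depths)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            pa, pb = depths[a], depths[b]
            # shared prefix length
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] == pb[k]:
                k += 1
            total = sum(w for _, w in pa[k:]) + sum(w for _, w in pb[k:])
            d[i, j] = d[j, i] = total
    return DistanceMatrix(labels, d)


class TestPDistance:
    def test_identical_rows_are_zero(self):
        dm = p_distance([("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT")])
        assert np.allclose(dm.d, 0)

    def test_one_difference_in_four(self):
        dm = p_distance([("a", "ACGT"), ("b", "ACGA"), ("c", "ACGT")])
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_ignores_gap_columns(self):
        dm = p_distance([("a", "AC-T"), ("b", "ACGA"), ("c", "ACGT")])
        # a vs b: comparable sites A,C,T vs A,C,A -> 1/3
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_sites_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance([("a", "--AA"), ("b", "GG--"), ("c", "GGAA")])

    def test_agrees_with_per_site_counting_oracle(self):
        rng = np.random.default_rng(19)
        alphabet = "ACGT-"
        for _ in range(30):
            n = int(rng.integers(3, 7))
            length = int(rng.integers(10, 60))
            rows = ["".join(alphabet[i] for i in rng.choice(5, length, p=[0.23] * 4 + [0.08]))
                    for _ in range(n)]
            msa = [(f"t{i}", r) for i, r in enumerate(rows)]
            try:
                dm = p_distance(msa)
            except ValueError:
                continue  # a pair with no comparable sites
            for i in range(n):
                for j in range(i + 1, n):
                    comp = diff = 0
                    for x, y in zip(rows[i], rows[j]):
                        if x != "-" and y != "-":
                            comp += 1
                            diff += x != y
                    assert dm.d[i, j] == pytest.approx(diff / comp)


class TestJukesCantor:
    def test_zero_maps_to_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_known_value(self):
        assert jc_correct(0.3) == pytest.approx(0.3831, abs=5e-5)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            jc_correct(0.75)

    def test_correction_never_below_p(self):
        for p in np.linspace(0.0, 0.74, 100):
            assert jc_correct(p) >= p


class TestNJTree:
    def test_three_taxa_exact_branch_lengths(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_quartets_match_four_point_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            dm, true_split = random_quartet(rng)
            # oracle: the split minimizing the sum of within-pair distances
            labels = dm.labels
            sums = {}
            for pair in [("a", "b"), ("a", "c"), ("a", "d")]:
                rest = tuple(x for x in labels if x not in pair)
                i, j = labels.index(pair[0]), labels.index(pair[1])
                k, l = labels.index(rest[0]), labels.index(rest[1])
                sums[frozenset(pair)] = dm.d[i, j] + dm.d[k, l]
            oracle_split = min(sums, key=sums.get)
            assert set(oracle_split) == true_split
            tree = nj_tree(dm)
            bps = tree.bipartitions()
            assert len(bps) == 1
            got = next(iter(bps))
            assert got == frozenset(true_split) or got == frozenset(labels) - set(true_split)

    def test_additive_matrices_reconstructed_exactly(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            dm = random_additive(rng, n)
            tree = nj_tree(dm)
            for i, a in enumerate(dm.labels):
                for j in range(i + 1, n):
                    assert tree.path_distance(a, dm.labels[j]) == pytest.approx(
                        dm.d[i, j], abs=1e-9
                    )

    def test_label_permutation_keeps_topology(self):
        rng = np.random.default_rng(31)
        dm = random_additive(rng, 7)
        tree = nj_tree(dm)
        perm = list(rng.permutation(len(dm.labels)))
        dm2 = DistanceMatrix([dm.labels[i] for i in perm], dm.d[np.ix_(perm, perm)])
        tree2 = nj_tree(dm2)
        assert tree.bipartitions() == tree2.bipartitions()

    def test_matches_scikit_bio_topology(self):
        import skbio

        rng = np.random.default_rng(37)
        for _ in range(5):
            dm = random_additive(rng, 6)
            mine = nj_tree(dm).bipartitions()
            sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.labels))
            all_leaves = frozenset(dm.labels)
            ref = sorted(all_leaves)[0]
            theirs = set()
            for node in sk_tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = all_leaves - side
                if 2 <= len(side) <= len(all_leaves) - 2:
                    theirs.add(side)
            assert mine == theirs

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], d)

    def test_negative_branch_lengths_clamped(self):
        # triangle-inequality violation forces a negative terminal estimate
        d = np.array([[0.0, 0.1, 0.1], [0.1, 0.0, 0.4], [0.1, 0.4, 0.0]])
        with pytest.warns(UserWarning, match="clamped"):
            tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        for node, _ in phylo._walk_with_parent(tree.root):
            assert node.length >= 0


EIGHT_TAXON_TREE = (
    "(((a:0.05,b:0.05):0.1,(c:0.05,d:0.05):0.1):0.1,"
    "((e:0.05,f:0.05):0.1,(g:0.05,h:0.05):0.1):0.1);"
)


class TestBootstrap:
    def test_true_bipartitions_strongly_supported(self):
        msa = synthetic.simulate_alignment(EIGHT_TAXON_TREE, 2000, seed=41)
        tree = bootstrap_support(msa, replicates=50, seed=42)
        supports = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert supports and min(supports) >= 90

    def test_single_replicate_supports_are_zero_or_hundred(self):
        msa = synthetic.simulate_alignment(EIGHT_TAXON_TREE, 500, seed=43)
        tree = bootstrap_support(msa, replicates=1, seed=44)
        for n in tree.internal_nodes():
            assert n.support in (0.0, 100.0)

    def test_same_seed_reproduces_supports(self):
        msa = synthetic.simulate_alignment(EIGHT_TAXON_TREE, 500, seed=45)
        t1 = bootstrap_support(msa, replicates=20, seed=7)
        t2 = bootstrap_support(msa, replicates=20, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_taxon_order_invariant_supports(self):
        msa = synthetic.simulate_alignment(EIGHT_TAXON_TREE, 500, seed=46)
        shuffled = list(reversed(msa))
        t1 = bootstrap_support(msa, replicates=20, seed=9)
        t2 = bootstrap_support(shuffled, replicates=20, seed=9)

        def support_map(tree):
            out = {}
            all_leaves = frozenset(tree.leaf_names())
            ref = sorted(all_leaves)[0]
            for n in tree.internal_nodes():
                side = frozenset(leaf.name for leaf in n.leaves())
                if ref in side:
                    side = all_leaves - side
                out[side] = n.support
            return out

        assert support_map(t1).keys() == support_map(t2).keys()

    def test_newick_parses_with_dendropy(self):
        import dendropy

        msa = synthetic.simulate_alignment(EIGHT_TAXON_TREE, 500, seed=47)
        tree = bootstrap_support(msa, replicates=5, seed=3)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set("abcdefgh")


class TestDotplot:
    def test_self_comparison_has_main_diagonal(self):
        seq = "ACGTACGGTTCAACGGA"
        result = dotplot(seq, seq, w=5)
        diag = [(i, i) for i in range(len(seq) - 4)]
        assert set(diag) <= set(result.matches)
        assert result.alignable_fraction == 1.0

    def test_unrelated_sequences_nearly_unalignable(self):
        rng = np.random.default_rng(51)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        assert dotplot(a, b, w=10).alignable_fraction < 0.05

    def test_agrees_with_all_pairs_oracle(self):
        rng = np.random.default_rng(53)
        for _ in range(20):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            w = int(rng.integers(3, 8))
            expected = {
                (i, j)
                for i in range(len(a) - w + 1)
                for j in range(len(b) - w + 1)
                if a[i : i + w] == b[j : j + w]
            }
            assert set(dotplot(a, b, w=w).matches) == expected

    def test_too_short_sequences_rejected(self):
        with pytest.raises(ValueError, match="at least w"):
            dotplot("ACG", "ACGTACGT", w=5)
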