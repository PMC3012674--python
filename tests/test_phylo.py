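"""Distances, neighbor joining and bootstrap support."""

import math

import numpy as np
import pytest

from bacpanel import phylo
from bacpanel import synthetic_data as sim


def _aln(**seqs):
    return phylo.Alignment(names=list(seqs), seqs=dict(seqs))


class TestDistances:
    def test_identical_sequences_zero_under_every_model(self):
        aln = _aln(a="ACGTACGTAC", b="ACGTACGTAC")
        for model in ("p", "jc", "tn93_pooled"):
            assert phylo.compute_distances(aln, model).get("a", "b") == 0.0

    def test_p_and_jc_closed_form(self):
        aln = _aln(a="AAAA", b="AAAT")
        assert phylo.compute_distances(aln, "p").get("a", "b") == 0.25
        assert phylo.compute_distances(aln, "jc").get("a", "b") == pytest.approx(
            0.30410, abs=1e-5
        )

    def test_jc_saturation_names_pair(self):
        aln = _aln(a="AAAA", b="CCCC")
        with pytest.raises(phylo.DistanceUndefinedError, match="a.*b"):
            phylo.compute_distances(aln, "jc")

    def test_no_shared_sites_rejected(self):
        aln = _aln(a="AC--", b="--AC")
        with pytest.raises(phylo.DistanceUndefinedError, match="shared"):
            phylo.compute_distances(aln, "p")

    def test_gapped_columns_dropped_per_pair(self):
        aln = _aln(a="ACGT-A", b="ACGTCA", c="ACNTCA")
        d = phylo.compute_distances(aln, "p")
        assert d.get("a", "b") == 0.0  # gap column excluded
        assert d.get("a", "c") == 0.0  # N column excluded

    def test_jc_monotone_in_p(self):
        ps = np.linspace(0.0, 0.74, 200)
        jc = [-0.75 * math.log(1 - 4 * p / 3) for p in ps]
        assert all(b > a for a, b in zip(jc, jc[1:]))

    def test_tn93_approaches_jc_on_equal_rate_data(self):
        # two 10 kb sequences diverged ~0.1 under Jukes-Cantor
        cfg = sim.AlignmentSimConfig(
            n_taxa=3, n_sites=10_000, branch_min=0.05, branch_max=0.05
        )
        aln, _ = sim.gen_alignment(cfg, seed=9)
        pair = (aln.names[0], aln.names[1])
        jc = phylo.compute_distances(aln, "jc").get(*pair)
        tn = phylo.compute_distances(aln, "tn93_pooled").get(*pair)
        assert tn == pytest.approx(jc, rel=0.02)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = phylo.DistanceMatrix(
            names=["A", "B", "C"],
            matrix=np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float),
        )
        tree = phylo.neighbor_joining(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_additive_four_taxon_recovery(self):
        # unrooted tree: A:1, B:2 joined; C:3, D:1 joined; internal edge 1
        a = phylo.Node(name="A", length=1)
        b = phylo.Node(name="B", length=2)
        c = phylo.Node(name="C", length=3)
        d = phylo.Node(name="D", length=1)
        u = phylo.Node(children=[a, b], length=1)
        root = phylo.Node(children=[u, c, d])
        dm = phylo.tree_distance_matrix(root)
        assert dm.get("A", "B") == 3 and dm.get("B", "C") == 6
        tree = phylo.neighbor_joining(dm)
        assert phylo.tree_bipartitions(tree) == phylo.tree_bipartitions(root)
        # exact branch lengths recovered from the additive matrix
        leaf_len = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert leaf_len == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 1})

    def test_degenerate_equal_distances_resolve_deterministically(self):
        n = 4
        m = np.ones((n, n)) - np.eye(n)
        dm = phylo.DistanceMatrix(names=list("ABCD"), matrix=m)
        t1 = phylo.neighbor_joining(dm)
        t2 = phylo.neighbor_joining(dm)
        assert t1.to_newick() == t2.to_newick()

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            phylo.neighbor_joining(phylo.DistanceMatrix(list("ABC"), m))

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_random_additive_topologies(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        tree = sim.gen_random_tree(n, rng)
        dm = phylo.tree_distance_matrix(tree)
        recovered = phylo.neighbor_joining(dm)
        assert phylo.tree_bipartitions(recovered) == phylo.tree_bipartitions(tree)

    def test_agrees_with_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(42)
        tree = sim.gen_random_tree(8, rng)
        dm = phylo.tree_distance_matrix(tree)
        ours = phylo.neighbor_joining(dm)

        sk_dm = skbio.DistanceMatrix(dm.matrix, ids=dm.names)
        sk_tree = skbio.tree.nj(sk_dm)
        ref = min(dm.names)
        all_taxa = frozenset(dm.names)
        sk_bips = set()
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(all_taxa) - 2:
                sk_bips.add(side if ref not in side else all_taxa - side)
        assert phylo.tree_bipartitions(ours) == sk_bips

    def test_newick_parses_in_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(5)
        tree = sim.gen_random_tree(6, rng)
        dm = phylo.tree_distance_matrix(tree)
        nwk = phylo.neighbor_joining(dm).to_newick()
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.taxon.label for t in parsed.leaf_node_iter()} == set(dm.names)


class TestBootstrap:
    def _congruent_aln(self):
        # 200 sites: 80% constant, 20% splitting {a,b} from {c,d}
        const = "A" * 160
        split_ab = "C" * 40
        split_cd = "G" * 40
        return _aln(
            a=const + split_ab, b=const + split_ab,
            c=const + split_cd, d=const + split_cd,
        )

    def test_fully_congruent_split_reaches_100(self):
        tree = phylo.bootstrap_support(
            self._congruent_aln(), model="p", replicates=200, seed=1
        )
        supports = [
            n.support for n in _internal_nodes(tree) if n.support is not None
        ]
        assert supports == [100.0]

    def test_same_seed_reproduces_support(self):
        aln, _ = sim.gen_alignment(
            sim.AlignmentSimConfig(n_taxa=6, n_sites=500), seed=3
        )
        t1 = phylo.bootstrap_support(aln, replicates=50, seed=9)
        t2 = phylo.bootstrap_support(aln, replicates=50, seed=9)
        assert t1.to_newick(with_support=True) == t2.to_newick(with_support=True)

    def test_support_invariant_to_taxon_order(self):
        aln, _ = sim.gen_alignment(
            sim.AlignmentSimConfig(n_taxa=5, n_sites=800), seed=4
        )
        reordered = phylo.Alignment(
            names=list(reversed(aln.names)), seqs=dict(aln.seqs)
        )
        s1 = _support_by_bipartition(phylo.bootstrap_support(aln, seed=2,
                                                             replicates=100))
        s2 = _support_by_bipartition(phylo.bootstrap_support(reordered, seed=2,
                                                             replicates=100))
        assert set(s1) == set(s2)
        for bp in s1:
            assert s1[bp] == pytest.approx(s2[bp], abs=12)  # MC error only

    def test_short_alignment_rejected(self):
        aln = _aln(a="ACG", b="ACG", c="ACG", d="ACG")
        with pytest.raises(ValueError, match="4 columns"):
            phylo.bootstrap_support(aln)

    def test_random_columns_give_middling_support(self):
        rng = np.random.default_rng(8)
        sites = 400
        seqs = {
            n: "".join("ACGT"[i] for i in rng.integers(0, 4, sites))
            for n in "abcd"
        }
        tree = phylo.bootstrap_support(_aln(**seqs), model="p",
                                       replicates=300, seed=5)
        (support,) = [
            n.support for n in _internal_nodes(tree) if n.support is not None
        ]
        assert 5 < support < 95


def _internal_nodes(tree):
    out = []

    def walk(node):
        for c in node.children:
            if not c.is_leaf:
                out.append(c)
                walk(c)

    walk(tree)
    return out


def _support_by_bipartition(tree):
    all_taxa = tree.leaf_names()
    ref = min(all_taxa)
    out = {}
    for node in _internal_nodes(tree):
        side = node.leaf_names()
        if 2 <= len(side) <= len(all_taxa) - 2 and node.support is not None:
            bp = side if ref not in side else all_taxa - side
            out[bp] = node.support
    return out
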