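"""Tree inference: masks, JC distances, NJ, bootstrap, rooting, verdict."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invorigin.alignment import LabeledAlignment
from invorigin.genealogy import (
    DistanceMatrix,
    GenealogyError,
    SaturationError,
    bootstrap_support,
    concordance_verdict,
    jc_distance_matrix,
    nj_tree,
    partial_deletion_mask,
    root_with_outgroup,
)
from invorigin.popgen import jc_correct

from conftest import random_alignment


def random_additive_matrix(rng, n_taxa):
    """Distances from a random binary tree with positive branch lengths.

    Independent oracle for NJ: builds the tree by sequential attachment and
    returns leaf-to-leaf path-length distances plus the tree's bipartitions.
    """
    # node ids; edges as dict child -> (parent, length)
    parent = {}
    next_internal = [n_taxa]

    def new_internal():
        next_internal[0] += 1
        return next_internal[0] - 1

    # start from a 3-star
    root = new_internal()
    edges = {i: (root, float(rng.uniform(0.05, 1.0))) for i in (0, 1, 2)}
    children = {root: [0, 1, 2]}
    for leaf in range(3, n_taxa):
        # split a random existing edge
        child = int(rng.choice(list(edges)))
        par, ln = edges[child]
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8))
        edges[child] = (mid, ln * split)
        edges[mid] = (par, ln * (1 - split))
        children[par] = [mid if c == child else c for c in children[par]]
        children[mid] = [child, leaf]
        edges[leaf] = (mid, float(rng.uniform(0.05, 1.0)))

    def path_to_root(v):
        out = {}
        total = 0.0
        while v in edges:
            out[v] = total
            par, ln = edges[v]
            total += ln
            v = par
        out[v] = total
        return out

    d = np.zeros((n_taxa, n_taxa))
    paths = [path_to_root(i) for i in range(n_taxa)]
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            common = min(
                paths[i][v] + paths[j][v] for v in paths[i] if v in paths[j]
            )
            d[i, j] = d[j, i] = common

    def leafset(v):
        if v < n_taxa:
            return frozenset([v])
        out = frozenset()
        for c in children[v]:
            out |= leafset(c)
        return out

    all_leaves = frozenset(range(n_taxa))
    bips = set()
    for v in children:
        ls = leafset(v)
        if 1 < len(ls) < n_taxa - 1:
            bips.add(ls if 0 not in ls else all_leaves - ls)
    return d, bips


def tree_bipartitions(gt):
    labels = gt.labels
    index = {l: i for i, l in enumerate(labels)}
    out = set()
    for side in gt.clade_leaf_sets():
        out.add(frozenset(index[l] for l in side))
    return out


class TestPartialDeletion:
    def test_gap_free_keeps_all(self, rng):
        aln = random_alignment(rng, n=10, length=50)
        assert partial_deletion_mask(aln).all()

    def test_one_gap_in_ten_drops_at_95(self, rng):
        aln = random_alignment(rng, n=10, length=20)
        aln.matrix[0, 5] = b"-"
        mask = partial_deletion_mask(aln, coverage=0.95)
        assert not mask[5] and mask.sum() == 19

    def test_low_coverage_keeps_all(self, rng):
        aln = random_alignment(rng, n=10, length=20, p_gap=0.2)
        assert partial_deletion_mask(aln, coverage=1e-9).all()

    def test_coverage_out_of_range(self, rng):
        aln = random_alignment(rng, n=4, length=10)
        with pytest.raises(GenealogyError):
            partial_deletion_mask(aln, coverage=0.0)
        with pytest.raises(GenealogyError):
            partial_deletion_mask(aln, coverage=1.5)


class TestJcDistanceMatrix:
    def test_identical_sequences_zero(self):
        aln = LabeledAlignment.from_sequences(["a", "b", "c"], ["ACGTACGT"] * 3)
        dm = jc_distance_matrix(aln)
        assert np.allclose(dm.values, 0)

    def test_matches_hand_count(self):
        # 9 differences over 100 sites between a and b
        a = "A" * 100
        b = "A" * 91 + "G" * 9
        aln = LabeledAlignment.from_sequences(["a", "b", "c"], [a, b, a])
        dm = jc_distance_matrix(aln)
        assert dm.values[0, 1] == pytest.approx(jc_correct(0.09))
        assert dm.values[0, 2] == 0.0

    def test_pairwise_complete_within_mask(self):
        a = "AAAA-AAA"
        b = "AAAATCAA"
        c = "AAAATAAA"
        aln = LabeledAlignment.from_sequences(["a", "b", "c"], [a, b, c])
        dm = jc_distance_matrix(aln)  # no mask: pairwise deletion
        assert dm.values[0, 1] == pytest.approx(jc_correct(1 / 7))
        assert dm.values[1, 2] == pytest.approx(jc_correct(1 / 8))

    def test_saturated_pair_named(self):
        a = "A" * 10
        b = "C" * 10
        aln = LabeledAlignment.from_sequences(["seqA", "seqB", "c"], [a, b, a])
        with pytest.raises(SaturationError, match="seqB"):
            jc_distance_matrix(aln)

    def test_symmetry_zero_diagonal(self, rng):
        aln = random_alignment(rng, n=8, length=200, p_mut=0.1)
        dm = jc_distance_matrix(aln)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        gt = nj_tree(DistanceMatrix(("a", "b", "c"), d))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in gt.tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_too_few_taxa(self):
        d = np.array([[0, 1], [1, 0]], dtype=float)
        with pytest.raises(GenealogyError):
            nj_tree(DistanceMatrix(("a", "b"), d))

    @given(seed=st.integers(0, 10_000), n_taxa=st.integers(4, 12))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_recovers_additive_matrices_exactly(self, seed, n_taxa):
        rng = np.random.default_rng(seed)
        d, true_bips = random_additive_matrix(rng, n_taxa)
        labels = tuple(f"t{i:02d}" for i in range(n_taxa))
        gt = nj_tree(DistanceMatrix(labels, d))
        assert tree_bipartitions(gt) == true_bips
        # branch lengths: leaf-to-leaf path distances reproduce the input
        pdm = gt.tree.phylogenetic_distance_matrix()
        tns = gt.tree.taxon_namespace
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                got = pdm.distance(
                    tns.get_taxon(labels[i]), tns.get_taxon(labels[j])
                )
                assert got == pytest.approx(d[i, j], abs=1e-9)

    def test_matches_scikit_bio_topology(self, rng):
        """Independent-implementation cross-check on a random matrix."""
        skbio = pytest.importorskip("skbio")
        n = 8
        aln = random_alignment(rng, n=n, length=300, p_mut=0.1)
        dm = jc_distance_matrix(aln)
        ours = nj_tree(dm)
        sk_dm = skbio.DistanceMatrix(dm.values, ids=list(dm.labels))
        sk_tree = skbio.tree.nj(sk_dm)
        index = {l: i for i, l in enumerate(dm.labels)}
        all_ids = frozenset(range(n))
        sk_bips = set()
        for node in sk_tree.non_tips(include_self=False):
            ls = frozenset(index[t.name] for t in node.tips())
            if 1 < len(ls) < n - 1:
                sk_bips.add(ls if 0 not in ls else all_ids - ls)
        assert tree_bipartitions(ours) == sk_bips

    def test_deterministic_under_ties(self):
        # four equidistant taxa: every pair ties on the Q criterion
        d = np.ones((4, 4)) - np.eye(4)
        labels = ("d", "c", "b", "a")
        g1 = nj_tree(DistanceMatrix(labels, d))
        g2 = nj_tree(DistanceMatrix(labels, d))
        assert g1.newick() == g2.newick()


class TestBootstrap:
    def _two_group_alignment(self, rng):
        n = 8
        bases = np.frombuffer(b"ACGT", dtype="S1")
        anc = rng.integers(0, 4, size=400)
        other = anc.copy()  # second group core: divergent at 30% of sites
        moved = rng.random(400) < 0.3
        other[moved] = (other[moved] + 2) % 4
        rows = []
        for i in range(n):
            core = anc.copy() if i < 4 else other.copy()
            hits = rng.random(400) < 0.02
            core[hits] = (core[hits] + rng.integers(1, 4, size=hits.sum())) % 4
            rows.append(bases[core])
        return LabeledAlignment(
            ids=[f"g{i//4}_{i%4}" for i in range(n)],
            matrix=np.vstack(rows),
            regions=["P"] * 4 + ["Q"] * 4,
            arrangements=["x"] * n,
        )

    def test_strong_split_support_near_100(self, rng):
        aln = self._two_group_alignment(rng)
        gt = bootstrap_support(aln, n=200, seed=5)
        split = frozenset(f"g1_{i}" for i in range(4))
        assert gt.supports[split] >= 99.0

    def test_same_seed_same_supports(self, rng):
        aln = self._two_group_alignment(rng)
        a = bootstrap_support(aln, n=50, seed=9).supports
        b = bootstrap_support(aln, n=50, seed=9).supports
        assert a == b

    def test_single_replicate_supports_binary(self, rng):
        aln = self._two_group_alignment(rng)
        gt = bootstrap_support(aln, n=1, seed=2)
        assert set(gt.supports.values()) <= {0.0, 100.0}

    def test_invalid_replicate_count(self, rng):
        aln = self._two_group_alignment(rng)
        with pytest.raises(GenealogyError):
            bootstrap_support(aln, n=0, seed=1)


def build_tree(newick, labels):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return_labels = tuple(labels)
    from invorigin.genealogy import GenealogyTree

    return GenealogyTree(tree=tree, labels=return_labels)


class TestRootingAndVerdict:
    def test_root_moves_outgroup_basal(self, rng):
        aln = random_alignment(rng, n=6, length=300, p_mut=0.1)
        gt = nj_tree(jc_distance_matrix(aln))
        rooted = root_with_outgroup(gt, "s3")
        kids = rooted.tree.seed_node.child_nodes()
        basal = {
            l.taxon.label for k in kids for l in k.leaf_iter() if k.is_leaf()
        }
        assert "s3" in basal

    def test_rerooting_preserves_bipartitions(self, rng):
        aln = random_alignment(rng, n=7, length=300, p_mut=0.1)
        gt = nj_tree(jc_distance_matrix(aln))
        rooted = root_with_outgroup(gt, "s0")
        assert gt.clade_leaf_sets() == rooted.clade_leaf_sets()

    def test_missing_outgroup_error(self, rng):
        aln = random_alignment(rng, n=5, length=100, p_mut=0.1)
        gt = nj_tree(jc_distance_matrix(aln))
        with pytest.raises(GenealogyError):
            root_with_outgroup(gt, "nope")

    def _regions(self):
        return {
            "ak1": "AK", "ak2": "AK", "ah1": "AH2",
            "ab1": "AB", "ab2": "AB",
            "ag1": "AG", "ag2": "AG", "gal1": "GAL",
            "og": "outgroup",
        }

    def test_discordant_pattern(self):
        nwk = "((((ak1:1,ak2:1):1,ah1:1):1,(ab1:1,ab2:1):1):1,((ag1:1,ag2:1):1,gal1:1):1,og:5);"
        gt = build_tree(nwk, self._regions())
        assert concordance_verdict(gt, self._regions()) == "discordant"

    def test_concordant_pattern(self):
        nwk = "((((ak1:1,ak2:1):1,ah1:1):1,(ag1:1,ag2:1):1,gal1:1):1,(ab1:1,ab2:1):1,og:5);"
        gt = build_tree(nwk, self._regions())
        assert concordance_verdict(gt, self._regions()) == "concordant"

    def test_interleaved_focal_unresolved(self):
        nwk = "(((ak1:1,ab1:1):1,(ak2:1,ah1:1):1,ab2:1):1,(ag1:1,(ag2:1,gal1:1):1):1,og:5);"
        gt = build_tree(nwk, self._regions())
        assert concordance_verdict(gt, self._regions()) == "unresolved"

    def test_gal_sister_is_skipped_not_judged(self):
        # focal clade's immediate sister is GAL; first informative split is AG
        nwk = "(((((ak1:1,ak2:1):1,ah1:1):1,gal1:1):1,(ag1:1,ag2:1):1):1,(ab1:1,ab2:1):1,og:5);"
        gt = build_tree(nwk, self._regions())
        assert concordance_verdict(gt, self._regions()) == "concordant"

    def test_missing_region_error(self):
        regions = {k: v for k, v in self._regions().items() if v != "AG"}
        nwk = "(((ak1:1,ak2:1):1,ah1:1):1,(ab1:1,ab2:1):1,og:5);"
        gt = build_tree(nwk, regions)
        with pytest.raises(GenealogyError):
            concordance_verdict(gt, regions)
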