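"""Distance-based genealogy inference and topology interrogation.

The inference chain mirrors the standard distance workflow for
breakpoint-flank alignments: a partial-deletion column filter (95% site
coverage), Jukes-Cantor pairwise distances, Saitou-Nei neighbor joining with
the usual Q criterion, nonparametric bootstrap over alignment columns, and
outgroup rooting.  The agglomeration, distance computation and bootstrap
counting are implemented here; :mod:`dendropy` serves as the tree container
(rerooting, MRCA queries, newick serialization).

The endpoint is :func:`concordance_verdict`: does the inferred genealogy
place the AK/AH2 sequences (youngest arrangements) with AB (the ancestral
arrangement, discordant with the cytological phylogeny) or with AG (their
cytological parent, concordant)?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import LabeledAlignment
from .popgen import jc_correct

_TIE_TOL = 1e-9


class GenealogyError(ValueError):
    pass


class SaturationError(GenealogyError):
    """A sequence pair exceeds the Jukes-Cantor saturation limit."""


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise GenealogyError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise GenealogyError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise GenealogyError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise GenealogyError("distances must be non-negative")


@dataclass
class GenealogyTree:
    """A tree plus per-internal-edge bootstrap supports (percent).

    ``supports`` maps a canonical bipartition key — the frozenset of leaf
    labels on the side not containing the reference (first) taxon — to a
    support percentage in [0, 100].
    """

    tree: dendropy.Tree
    labels: tuple[str, ...]
    supports: dict[frozenset, float] = field(default_factory=dict)

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        t = self.tree.clone(depth=1)
        if self.supports:
            for node in t.preorder_node_iter():
                if node.is_leaf() or node.parent_node is None:
                    continue
                key = self._bipartition_key(
                    frozenset(l.taxon.label for l in node.leaf_iter())
                )
                if key in self.supports:
                    node.label = f"{self.supports[key]:.0f}"
        return t.as_string(schema="newick", suppress_rooting=True).strip()

    def _bipartition_key(self, side: frozenset) -> frozenset:
        ref = self.labels[0]
        return frozenset(self.labels) - side if ref in side else side

    def clade_leaf_sets(self) -> set[frozenset]:
        """Canonical bipartition keys of all internal edges."""
        out: set[frozenset] = set()
        all_labels = frozenset(self.labels)
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(side) < len(all_labels) - 1:
                out.add(self._bipartition_key(side))
        return out

    def mrca(self, labels) -> dendropy.Node:
        return self.tree.mrca(taxon_labels=list(labels))

    def is_monophyletic(self, labels) -> bool:
        node = self.mrca(labels)
        below = {l.taxon.label for l in node.leaf_iter()}
        return below == set(labels)


# ---------------------------------------------------------------------------
# column filters and distances

def partial_deletion_mask(aln: LabeledAlignment, coverage: float = 0.95) -> np.ndarray:
    """Keep columns whose fraction of unambiguous bases is >= ``coverage``."""
    if not (0.0 < coverage <= 1.0):
        raise GenealogyError("coverage must lie in (0, 1]")
    valid = aln.valid_mask()
    return valid.mean(axis=0) >= coverage


def jc_distance_matrix(
    aln: LabeledAlignment, mask: np.ndarray | None = None
) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances over masked columns.

    Comparison is pairwise-complete within the mask: a column contributes to
    a pair only if both sequences are unambiguous there.  A saturated pair
    (raw difference proportion >= 0.75) raises, naming the pair.
    """
    if aln.n_sequences < 3:
        raise GenealogyError("need at least three sequences for a tree")
    matrix = aln.matrix if mask is None else aln.matrix[:, np.asarray(mask)]
    valid = np.isin(matrix, np.frombuffer(b"ACGT", dtype="S1"))
    n = aln.n_sequences
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        both = valid[i + 1 :] & valid[i]
        diffs = ((matrix[i + 1 :] != matrix[i]) & both).sum(axis=1)
        sites = both.sum(axis=1)
        if np.any(sites == 0):
            j = int(i + 1 + np.flatnonzero(sites == 0)[0])
            raise GenealogyError(
                f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
        p = diffs / sites
        if np.any(p >= 0.75):
            j = int(i + 1 + np.flatnonzero(p >= 0.75)[0])
            raise SaturationError(
                f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}) is saturated "
                f"(p = {p.max():.3f} >= 0.75)"
            )
        d[i, i + 1 :] = jc_correct(p)
    d += d.T
    return DistanceMatrix(labels=tuple(aln.ids), values=d)


# ---------------------------------------------------------------------------
# neighbor joining

def _nj_agglomerate(
    d: np.ndarray, labels: tuple[str, ...]
) -> tuple[list[tuple[int, int, int, float, float]], dict[int, int]]:
    """Saitou-Nei agglomeration on a working copy of ``d``.

    Returns the merge list ``(child_i, child_j, parent, bl_i, bl_j)`` over
    node ids (leaves ``0..n-1``, internal nodes numbered upward) and the
    final three-way (or two-way) join encoded as extra merges onto the last
    parent id.  Q-criterion ties are broken by the lexicographically
    smallest pair of cluster keys, a cluster's key being the smallest leaf
    label it contains.  Negative branch lengths are clamped to zero with a
    warning.

    Also returns ``masks``: node id -> leaf bitmask (python int), used for
    bipartition bookkeeping.
    """
    n = len(labels)
    total = 2 * n - 2
    D = np.zeros((total, total), dtype=float)
    D[:n, :n] = d
    active = list(range(n))
    keys: dict[int, str] = {i: labels[i] for i in range(n)}
    masks: dict[int, int] = {i: 1 << i for i in range(n)}
    merges: list[tuple[int, int, int, float, float]] = []
    next_id = n

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0", stacklevel=3)
            return 0.0
        return x

    while len(active) > 3:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = len(idx)
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + _TIE_TOL * max(1.0, abs(qmin)))
        best = min(
            (tuple(sorted((keys[idx[a]], keys[idx[b]]))), a, b)
            for a, b in cand
            if a < b
        )
        a, b = best[1], best[2]
        i, j = int(idx[a]), int(idx[b])
        dij = D[i, j]
        vi_raw = 0.5 * dij + (R[a] - R[b]) / (2 * (r - 2))
        vi, vj = clamp(vi_raw), clamp(dij - vi_raw)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - dij)
        merges.append((i, j, u, vi, vj))
        keys[u] = min(keys[i], keys[j])
        masks[u] = masks[i] | masks[j]
        active = [k for k in active if k not in (i, j)] + [u]

    # final star join of the 3 (or fewer) remaining clusters
    root = next_id
    if len(active) == 3:
        i, j, k = active
        vi = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
        vj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
        vk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
        merges.append((i, j, root, vi, vj))
        merges.append((k, -1, root, vk, 0.0))
    elif len(active) == 2:
        i, j = active
        merges.append((i, j, root, D[i, j] / 2, D[i, j] / 2))
    masks[root] = sum(masks[k] for k in active)
    return merges, masks


def nj_tree(dm: DistanceMatrix) -> GenealogyTree:
    """Neighbor-joining tree (unrooted; root node is the final trifurcation)."""
    n = len(dm.labels)
    if n < 3:
        raise GenealogyError("neighbor joining needs at least three taxa")
    merges, _ = _nj_agglomerate(dm.values, dm.labels)
    tns = dendropy.TaxonNamespace(list(dm.labels))
    nodes: dict[int, dendropy.Node] = {
        i: dendropy.Node(taxon=tns.get_taxon(dm.labels[i])) for i in range(n)
    }
    for i, j, parent, vi, vj in merges:
        if parent not in nodes:
            nodes[parent] = dendropy.Node()
        node = nodes[parent]
        nodes[i].edge.length = vi
        node.add_child(nodes[i])
        if j >= 0:
            nodes[j].edge.length = vj
            node.add_child(nodes[j])
    root_id = merges[-1][2]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[root_id])
    tree.is_rooted = False
    return GenealogyTree(tree=tree, labels=tuple(dm.labels))


def _bipartitions_from_merges(
    merges, masks: dict[int, int], n: int
) -> set[int]:
    """Canonical internal-edge bitmasks (side not containing leaf 0)."""
    full = (1 << n) - 1
    out: set[int] = set()
    for node_id, mask in masks.items():
        if node_id < n or mask == full:
            continue
        size = mask.bit_count()
        if size < 2 or size > n - 2:
            continue
        out.add(full ^ mask if mask & 1 else mask)
    return out


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(
    aln: LabeledAlignment,
    mask: np.ndarray | None = None,
    n: int = 1000,
    seed: int | None = None,
) -> GenealogyTree:
    """Full-data NJ tree with column-bootstrap supports on internal edges.

    The deletion mask is fixed once from the full data; each replicate
    resamples the masked columns with replacement, rebuilds the NJ tree, and
    the support of each full-tree internal bipartition is the percentage of
    replicates recovering it.
    """
    if n < 1:
        raise GenealogyError("bootstrap replicate count must be >= 1")
    if mask is None:
        mask = np.ones(aln.n_sites, dtype=bool)
    cols = np.flatnonzero(np.asarray(mask))
    m = len(cols)
    if m == 0:
        raise GenealogyError("mask retains no columns")

    full_dm = jc_distance_matrix(aln, mask)
    full = nj_tree(full_dm)
    labels = full_dm.labels
    nt = len(labels)

    # per-pair per-column difference / validity indicators (float32 for BLAS)
    matrix = aln.matrix[:, cols]
    valid = np.isin(matrix, np.frombuffer(b"ACGT", dtype="S1"))
    pairs = [(i, j) for i in range(nt) for j in range(i + 1, nt)]
    diff_cols = np.empty((len(pairs), m), dtype=np.float32)
    valid_cols = np.empty((len(pairs), m), dtype=np.float32)
    for k, (i, j) in enumerate(pairs):
        both = valid[i] & valid[j]
        diff_cols[k] = ((matrix[i] != matrix[j]) & both).astype(np.float32)
        valid_cols[k] = both.astype(np.float32)

    rng = np.random.default_rng(seed)
    # column weights for all replicates at once
    W = rng.multinomial(m, np.full(m, 1.0 / m), size=n).T.astype(np.float32)
    diffs_all = diff_cols @ W   # (n_pairs, n)
    sites_all = valid_cols @ W

    counts: dict[int, int] = {}
    iu = np.triu_indices(nt, k=1)
    for rep in range(n):
        sites = sites_all[:, rep]
        if np.any(sites == 0):
            continue  # replicate dropped: some pair has no comparable site
        p = diffs_all[:, rep] / sites
        p = np.minimum(p, 0.7499)  # guard: resampling can push a pair to saturation
        dvec = jc_correct(p)
        d = np.zeros((nt, nt))
        d[iu] = dvec
        d += d.T
        merges, masks = _nj_agglomerate(d, labels)
        for bp in _bipartitions_from_merges(merges, masks, nt):
            counts[bp] = counts.get(bp, 0) + 1

    full_merges, full_masks = _nj_agglomerate(full_dm.values, labels)
    supports: dict[frozenset, float] = {}
    for bp in _bipartitions_from_merges(full_merges, full_masks, nt):
        side = frozenset(labels[i] for i in range(nt) if bp >> i & 1)
        supports[side] = 100.0 * counts.get(bp, 0) / n
    full.supports = supports
    return full


# ---------------------------------------------------------------------------
# rooting and the verdict

def root_with_outgroup(gt: GenealogyTree, label: str) -> GenealogyTree:
    """Root the tree on the outgroup's pendant edge (split at its midpoint)."""
    tree = gt.tree.clone(depth=1)
    leaf = None
    for node in tree.leaf_node_iter():
        if node.taxon.label == label:
            leaf = node
            break
    if leaf is None:
        raise GenealogyError(f"outgroup label {label!r} not found in tree")
    half = (leaf.edge.length or 0.0) / 2.0
    tree.reroot_at_edge(leaf.edge, length1=half, length2=half)
    tree.is_rooted = True
    return GenealogyTree(tree=tree, labels=gt.labels, supports=dict(gt.supports))


def concordance_verdict(
    gt: GenealogyTree, regions: dict[str, str]
) -> str:
    """Classify the genealogy against the cytological phylogeny.

    ``regions`` maps leaf label -> breakpoint-region name.  The focal group
    is AK u AH2.  Their smallest containing clade must hold no other AB/AG
    leaves (GAL and outgroup leaves are ignored), otherwise ``unresolved``.
    Walking rootward from that clade, the first split whose far side carries
    AB or AG leaves decides: only AB -> ``discordant`` (the finding the
    heterokaryotype models explain), only AG -> ``concordant``, both ->
    ``unresolved``.

    The tree must be rooted (root with the outgroup first).
    """
    leaf_labels = set(gt.leaf_labels())
    missing = leaf_labels - set(regions)
    if missing:
        raise GenealogyError(f"no region label for leaves: {sorted(missing)[:3]} ...")
    by_region: dict[str, set[str]] = {}
    for leaf, region in regions.items():
        if leaf in leaf_labels:
            by_region.setdefault(region, set()).add(leaf)
    for required in ("AB", "AG", "AK", "AH2"):
        if not by_region.get(required):
            raise GenealogyError(f"region {required} has no leaves in the tree")

    focal = by_region["AK"] | by_region["AH2"]
    informative = {"AB", "AG"}

    node = gt.mrca(focal)
    clade = {l.taxon.label for l in node.leaf_iter()}
    stray = {l for l in clade - focal if regions[l] in informative}
    if stray:
        return "unresolved"

    current = clade
    while node.parent_node is not None:
        parent = node.parent_node
        parent_leaves = {l.taxon.label for l in parent.leaf_iter()}
        far = {regions[l] for l in parent_leaves - current} & informative
        if far == {"AB"}:
            return "discordant"
        if far == {"AG"}:
            return "concordant"
        if far == {"AB", "AG"}:
            return "unresolved"
        node, current = parent, parent_leaves
    return "unresolved"
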