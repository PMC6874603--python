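"""Distances, distance trees, midpoint rooting, haplotype genealogies.

Pairwise distances between diploid individuals take both phased alleles
into account: at each shared locus all four allele-pair comparisons are
made, each Jukes-Cantor corrected, and averaged; locus values are combined
by a cleaned-length-weighted mean (a pooled-site mode is available).  The
tree is built by neighbor joining followed by unweighted least-squares
re-estimation of branch lengths on the fixed topology, which reproduces
additive matrices exactly, and is displayed midpoint-rooted.  Per-locus
haplotype genealogies collapse identical alleles into frequency-weighted
nodes connected by a minimum-spanning network over Hamming distances.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import networkx as nx
import numpy as np

from .seqdata import AlignedLocus

logger = logging.getLogger("pelletpop")


class SaturationError(ValueError):
    """Mismatch proportion >= 3/4: Jukes-Cantor distance undefined."""


def jc69_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor corrected distance between two equal-length sequences.

    d = -(3/4) ln(1 - 4p/3) with p the observed mismatch proportion;
    p >= 0.75 raises :class:`SaturationError`.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    p = sum(1 for x, y in zip(seq_a, seq_b) if x != y) / len(seq_a)
    return jc69_from_p(p)


def jc69_from_p(p: float) -> float:
    """Jukes-Cantor correction of a mismatch proportion."""
    if p < 0 or p >= 0.75:
        raise SaturationError(f"mismatch proportion {p} outside [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def diploid_distance(ind_a: str, ind_b: str, loci: list[AlignedLocus],
                     mode: str = "length_weighted") -> float:
    """Distance between two diploid individuals over their shared loci.

    Per locus the mean of the four allele-pair Jukes-Cantor distances is
    taken; loci are combined by a cleaned-length-weighted mean (default) or
    by pooling mismatch and site counts across loci before the correction
    (``mode="pooled"``).
    """
    if mode not in ("length_weighted", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    per_locus = []   # (locus length, mean JC distance)
    pooled_mismatches = np.zeros(4)
    pooled_sites = 0
    found = False
    for locus in loci:
        pa = locus.alleles.get(ind_a)
        pb = locus.alleles.get(ind_b)
        if pa is None or pb is None:
            continue
        found = True
        if mode == "pooled":
            for idx, (x, y) in enumerate((a, b) for a in pa for b in pb):
                pooled_mismatches[idx] += sum(1 for u, v in zip(x, y) if u != v)
            pooled_sites += locus.length
        else:
            d4 = [jc69_distance(a, b) for a in pa for b in pb]
            per_locus.append((locus.length, float(np.mean(d4))))
    if not found:
        raise ValueError(f"individuals {ind_a!r} and {ind_b!r} share no loci")
    if mode == "pooled":
        return float(np.mean([jc69_from_p(m / pooled_sites) for m in pooled_mismatches]))
    lengths = np.array([ln for ln, _ in per_locus], dtype=float)
    vals = np.array([v for _, v in per_locus])
    return float((lengths * vals).sum() / lengths.sum())


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix in substitutions per site."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.isfinite(self.d).all():
            raise ValueError("non-finite distances")
        if np.abs(self.d - self.d.T).max() > 1e-12:
            raise ValueError("matrix not symmetric")
        if np.abs(np.diag(self.d)).max() > 0:
            raise ValueError("nonzero diagonal")
        if (self.d < 0).any():
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.d[ia, ib])


def distance_matrix_diploid(individuals: list[str], loci: list[AlignedLocus],
                            mode: str = "length_weighted") -> DistanceMatrix:
    """All-pairs diploid distance matrix; fails loudly on missing pairs."""
    labels = sorted(individuals)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = diploid_distance(labels[i], labels[j], loci, mode=mode)
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# neighbor joining + least-squares branch lengths

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-matrix.

    Ties in Q are resolved deterministically by the lexicographic order of
    the clusters' smallest member labels.  The returned tree is unrooted
    (trifurcating seed node) with NJ branch lengths.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    # active clusters: (min leaf label, node); D indexed in parallel
    keys = list(dm.labels)
    active = list(nodes)
    D = dm.d.copy()
    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        best = None
        for i, j in combinations(range(m), 2):
            q = (m - 2) * D[i, j] - r[i] - r[j]
            cand = (q, *sorted((keys[i], keys[j])))
            if best is None or cand < best[0]:
                best = (cand, i, j)
        _, i, j = best
        vi = D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i, j] - vi
        parent = dendropy.Node()
        ci, cj = active[i], active[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = max(vi, 0.0)
        cj.edge.length = max(vj, 0.0)
        newrow = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([np.hstack([D[np.ix_(keep, keep)],
                                  newrow[keep][:, None]]),
                       np.hstack([newrow[keep], [0.0]])])
        active = [active[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [min(keys[i], keys[j])]
    root = dendropy.Node()
    if len(active) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lens = [(d01 + d02 - d12) / 2, (d01 + d12 - d02) / 2, (d02 + d12 - d01) / 2]
    else:  # exactly 2 (only when the while loop never ran with n=3 handled above)
        lens = [D[0, 1] / 2, D[0, 1] / 2]
    for nd, ln in zip(active, lens):
        root.add_child(nd)
        nd.edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def least_squares_branch_lengths(tree: dendropy.Tree, dm: DistanceMatrix) -> dendropy.Tree:
    """Re-estimate branch lengths by unweighted least squares on the topology.

    Solves ``min ||A x - d||`` where each row of A marks the edges on one
    leaf-pair path; negative estimates are clamped to 0.  For an additive
    matrix this recovers the generating lengths exactly (up to how a
    root-adjacent edge pair shares its sum).
    """
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
    eidx = {id(e): i for i, e in enumerate(edges)}
    # ancestor chains for path computation
    def chain(node):
        out = []
        while node.parent_node is not None:
            out.append(node)
            node = node.parent_node
        return out
    labels = dm.labels
    rows, targets = [], []
    for a, b in combinations(labels, 2):
        ca, cb = chain(leaves[a]), chain(leaves[b])
        sa, sb = set(id(x) for x in ca), set(id(x) for x in cb)
        row = np.zeros(len(edges))
        for nd in ca:
            if id(nd) not in sb:
                row[eidx[id(nd.edge)]] = 1
        for nd in cb:
            if id(nd) not in sa:
                row[eidx[id(nd.edge)]] = 1
        rows.append(row)
        targets.append(dm.get(a, b))
    A = np.array(rows)
    x, *_ = np.linalg.lstsq(A, np.array(targets), rcond=None)
    for e, ln in zip(edges, x):
        e.length = max(float(ln), 0.0)
    return tree


def build_distance_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """NJ topology with least-squares-refitted branch lengths."""
    tree = neighbor_joining(dm)
    return least_squares_branch_lengths(tree, dm)


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic leaf-to-leaf distances of a tree, as a DistanceMatrix."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels=labels, d=d)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    Ties between equally long paths are broken by lexicographic order of the
    sorted leaf-label pair.  A tree whose branch lengths are all zero is
    rooted at the first internal node with a warning.
    """
    tree = tree.clone(depth=1)
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs >= 2 leaves")
    best = None
    for la, lb in combinations(leaves, 2):
        dist = pdm.patristic_distance(la.taxon, lb.taxon)
        key = (-dist, la.taxon.label, lb.taxon.label)
        if best is None or key < best[0]:
            best = (key, la, lb, dist)
    _, leaf_a, leaf_b, dmax = best
    if dmax == 0:
        logger.warning("all path lengths zero; rooting at first internal node")
        internal = next(nd for nd in tree.preorder_node_iter() if not nd.is_leaf())
        tree.reroot_at_node(internal, update_bipartitions=True,
                            suppress_unifurcations=True)
        return tree
    # walk the a->b path; find the edge containing the midpoint
    def chain(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out
    ca, cb = chain(leaf_a), chain(leaf_b)
    ids_b = {id(x) for x in cb}
    mrca = next(nd for nd in ca if id(nd) in ids_b)
    up = ca[:ca.index(mrca)]                      # edges from a up to mrca
    down = cb[:cb.index(mrca)][::-1]              # then down to b
    half = dmax / 2.0
    acc = 0.0
    for nd, toward_a in [(x, True) for x in up] + [(x, False) for x in down]:
        ln = nd.edge.length or 0.0
        if acc + ln >= half - 1e-15:
            offset = half - acc                   # from the a-proximal end
            if toward_a:
                # edge traversed child->parent; a-proximal end is the child (head)
                l_head, l_tail = offset, ln - offset
            else:
                # traversed parent->child; a-proximal end is the parent (tail)
                l_head, l_tail = ln - offset, offset
            tree.reroot_at_edge(nd.edge, length1=max(l_tail, 0.0),
                                length2=max(l_head, 0.0),
                                update_bipartitions=True,
                                suppress_unifurcations=True)
            tree.is_rooted = True
            return tree
        acc += ln
    raise AssertionError("midpoint not located on path")  # pragma: no cover


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# haplotype genealogies

@dataclass
class HaplotypeNode:
    hap_id: str
    sequence: str
    frequency: int
    group_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class HaplotypeGenealogy:
    """Frequency-weighted haplotype graph for one locus.

    Nodes are distinct alleles (frequency = number of allele copies, with
    per-group composition); edges carry the number of differing sites and
    form a minimum-spanning network.
    """

    locus_name: str
    nodes: list[HaplotypeNode]
    edges: list[tuple[str, str, int]]

    @property
    def total_alleles(self) -> int:
        return sum(n.frequency for n in self.nodes)

    def is_connected(self) -> bool:
        if len(self.nodes) <= 1:
            return True
        g = nx.Graph()
        g.add_nodes_from(n.hap_id for n in self.nodes)
        g.add_edges_from((a, b) for a, b, _ in self.edges)
        return nx.is_connected(g)


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def collapse_to_genealogy(locus: AlignedLocus, groups: dict[str, str],
                          subset=None) -> HaplotypeGenealogy:
    """Collapse a locus's alleles into a haplotype genealogy.

    Identical sequences merge into one node; nodes are connected by a
    minimum spanning tree over Hamming distances with ties resolved by
    (weight, node-index order).
    """
    inds = locus.individuals if subset is None else sorted(set(subset) & set(locus.alleles))
    seq_order: dict[str, int] = {}
    freq: Counter = Counter()
    comp: dict[str, Counter] = {}
    for ind in inds:
        grp = groups.get(ind, "ungrouped")
        for seq in locus.alleles[ind]:
            if seq not in seq_order:
                seq_order[seq] = len(seq_order)
                comp[seq] = Counter()
            freq[seq] += 1
            comp[seq][grp] += 1
    nodes = [
        HaplotypeNode(hap_id=f"H{i + 1}", sequence=seq, frequency=freq[seq],
                      group_counts=dict(comp[seq]))
        for seq, i in sorted(seq_order.items(), key=lambda kv: kv[1])
    ]
    if len(nodes) <= 1:
        return HaplotypeGenealogy(locus_name=locus.locus_name, nodes=nodes, edges=[])
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    # insertion in (i, j) order => kruskal's stable sort breaks weight ties
    # by node-index order
    for i, j in combinations(range(len(nodes)), 2):
        g.add_edge(i, j, weight=hamming(nodes[i].sequence, nodes[j].sequence))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    edges = sorted(
        (nodes[min(i, j)].hap_id, nodes[max(i, j)].hap_id, int(data["weight"]))
        for i, j, data in mst.edges(data=True)
    )
    return HaplotypeGenealogy(locus_name=locus.locus_name, nodes=nodes, edges=edges)
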