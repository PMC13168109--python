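"""Core-genome distance phylogeny, marker trees and congruence statistics.

The concatenated-alignment ML step of typical phage pangenome studies is
deliberately replaced here by a distance design: per core cluster, pairwise
protein distances (1 - local-alignment identity), averaged over clusters into
a genome distance matrix, followed by classical neighbor joining, midpoint
rooting, and cluster-resampling (gene-jackknife-style) support.  Congruence
between trees is summarized by the unrooted Robinson-Foulds distance and the
fraction of shared internal bipartitions.

Trees are :class:`dendropy.Tree` objects; Newick is the on-disk format with
support values carried as internal node labels.
"""

from __future__ import annotations

import itertools
import warnings

import dendropy
import numpy as np
import pandas as pd

from .protclust import ProteinCluster, pairwise_protein_identity
from .genome_io import ProteinRecord, write_matrix_tsv, read_matrix_tsv

__all__ = [
    "DistanceMatrix",
    "nj_tree",
    "midpoint_root",
    "core_distance_matrix",
    "cluster_distance_stack",
    "resample_support",
    "marker_tree",
    "bipartitions",
    "rf_distance",
    "shared_bipartitions",
    "read_newick",
    "write_newick",
]


class DistanceMatrix:
    """Labeled symmetric non-negative matrix with zero diagonal."""

    def __init__(self, labels: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise ValueError("shape does not match labels")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-9):
            raise ValueError("diagonal must be zero")
        if values.min() < -1e-9:
            raise ValueError("negative distances")
        self.labels = list(labels)
        self.values = values

    def to_tsv(self, path) -> None:
        write_matrix_tsv(
            pd.DataFrame(self.values, index=self.labels, columns=self.labels), path
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = read_matrix_tsv(path)
        return cls(list(df.index), df.to_numpy())


# ---------------------------------------------------------------------------
# Distances from protein clusters


def _pick_member(cluster: ProteinCluster, by_key: dict, genome: str) -> ProteinRecord:
    """One member per genome: longest, then lexicographically smallest gene id."""
    cands = [by_key[(g, gid)] for g, gid in cluster.members if g == genome]
    if not cands:
        raise ValueError(
            f"cluster {cluster.cluster_id} has no member in genome {genome!r} "
            "(not a core cluster)"
        )
    return min(cands, key=lambda p: (-len(p.aa_sequence), p.gene_id))


def _cluster_distances(cluster: ProteinCluster, by_key: dict,
                       genomes: list[str]) -> np.ndarray:
    n = len(genomes)
    picked = [_pick_member(cluster, by_key, g) for g in genomes]
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ident, _, _ = pairwise_protein_identity(
            picked[i].aa_sequence, picked[j].aa_sequence
        )
        d[i, j] = d[j, i] = 1.0 - ident
    return d


def cluster_distance_stack(clusters: list[ProteinCluster],
                           proteins: list[ProteinRecord],
                           genomes: list[str]) -> np.ndarray:
    """Per-cluster pairwise distance matrices, stacked (m, n, n)."""
    by_key = {p.key: p for p in proteins}
    return np.stack(
        [_cluster_distances(cl, by_key, genomes) for cl in clusters]
    )


def core_distance_matrix(clusters: list[ProteinCluster],
                         proteins: list[ProteinRecord],
                         genomes: list[str] | None = None) -> DistanceMatrix:
    """Mean over core clusters of per-cluster protein distance (in [0, 1])."""
    if not clusters:
        raise ValueError("no core clusters")
    if genomes is None:
        genomes = sorted(set.union(*(cl.genomes() for cl in clusters)))
    stack = cluster_distance_stack(clusters, proteins, genomes)
    return DistanceMatrix(genomes, stack.mean(axis=0))


# ---------------------------------------------------------------------------
# Neighbor joining


def _min_leaf(node: dendropy.Node) -> str:
    return min(lf.taxon.label for lf in node.leaf_iter())


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Classical neighbor joining; exact on additive matrices.

    Deterministic: ties in the Q criterion are broken by the smallest
    (label, label) pair, comparing each candidate node by its smallest
    descendant leaf.  Negative branch lengths are clamped to zero with the
    deficit transferred to the sister edge.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    tns = dendropy.TaxonNamespace(d.labels)
    nodes: list[dendropy.Node] = []
    for label in d.labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
    keys = list(d.labels)  # sort key per active node (smallest leaf below)
    D = d.values.copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> int:
        # clamp-and-transfer for negative limb lengths
        if li < 0:
            lj = max(0.0, lj + li)
            li = 0.0
        if lj < 0:
            li = max(0.0, li + lj)
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        return len(nodes) - 1

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cands = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((keys[active[a]], keys[active[b]]))), a, b)
            for a, b in cands if a < b
        )
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        new = join(i, j, li, lj)
        # distances from the new node to the remaining actives
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[i, k] + D[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new]

    # final trifurcation
    i, j, k = active
    root = dendropy.Node()
    for x, y, z in ((i, j, k), (j, i, k), (k, i, j)):
        lx = max(0.0, 0.5 * (D[x, y] + D[x, z] - D[y, z]))
        root.add_child(nodes[x])
        nodes[x].edge.length = lx
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Midpoint rooting


def _leaf_path(u: dendropy.Node, v: dendropy.Node) -> list[tuple[dendropy.Node, float, str]]:
    """Edges along the path u -> v as (child_node, length, 'up'|'down')."""
    anc_u = [u]
    node = u
    while node.parent_node is not None:
        node = node.parent_node
        anc_u.append(node)
    anc_v = [v]
    node = v
    while node.parent_node is not None:
        node = node.parent_node
        anc_v.append(node)
    set_u = {id(x): i for i, x in enumerate(anc_u)}
    mrca_vi = next(i for i, x in enumerate(anc_v) if id(x) in set_u)
    mrca_ui = set_u[id(anc_v[mrca_vi])]
    path = [
        (anc_u[i], anc_u[i].edge.length or 0.0, "up") for i in range(mrca_ui)
    ]
    path += [
        (anc_v[i], anc_v[i].edge.length or 0.0, "down")
        for i in range(mrca_vi - 1, -1, -1)
    ]
    return path


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties are broken by the lexicographically smallest endpoint label pair.
    If every branch length is zero, the tree is rooted at the first edge in
    preorder (deterministic) with a warning.
    """
    tree = tree.clone(depth=1)
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    if len(leaves) < 2:
        raise ValueError("need >= 2 leaves")
    best = None
    for lu, lv in itertools.combinations(leaves, 2):
        dist = pdm.patristic_distance(lu.taxon, lv.taxon)
        key = (-dist, lu.taxon.label, lv.taxon.label)
        if best is None or key < best[0]:
            best = (key, lu, lv, dist)
    _, u, v, total = best
    if total <= 0:
        warnings.warn("all branch lengths zero; rooting at an arbitrary edge")
        target_child, from_child = u, 0.0
    else:
        half = total / 2.0
        cum = 0.0
        target_child = None
        for child, length, direction in _leaf_path(u, v):
            if cum + length >= half - 1e-12:
                off = half - cum  # from the entering end of this edge
                from_child = off if direction == "up" else max(0.0, length - off)
                target_child = child
                break
            cum += length
        if target_child is None:  # numeric fallthrough: last edge
            child, length, direction = _leaf_path(u, v)[-1]
            target_child, from_child = child, 0.0
    parent = target_child.parent_node
    length = target_child.edge.length or 0.0
    from_child = min(max(from_child, 0.0), length)
    new = dendropy.Node()
    parent.remove_child(target_child)
    parent.add_child(new)
    new.edge.length = length - from_child
    new.add_child(target_child)
    target_child.edge.length = from_child
    tree.reroot_at_node(new, update_bipartitions=False)
    tree.suppress_unifurcations()
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Bipartitions, Robinson-Foulds, support


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions of the unrooted topology.

    Each is canonicalized as the side NOT containing the lexicographically
    smallest leaf label, so rooted and unrooted versions of the same topology
    yield identical sets.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaf_labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(leaf_labels - below) if anchor in below else below
        if 2 <= len(side) <= len(leaf_labels) - 2:
            out.add(side)
    return out


def _check_leafsets(t1: dendropy.Tree, t2: dendropy.Tree) -> None:
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance (symmetric bipartition difference)."""
    _check_leafsets(t1, t2)
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def shared_bipartitions(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Fraction of internal bipartitions shared between the two topologies."""
    _check_leafsets(t1, t2)
    b1, b2 = bipartitions(t1), bipartitions(t2)
    denom = max(len(b1), len(b2))
    if denom == 0:
        return 1.0
    return len(b1 & b2) / denom


def resample_support(clusters: list[ProteinCluster],
                     proteins: list[ProteinRecord],
                     n_reps: int = 200,
                     seed: int = 0,
                     genomes: list[str] | None = None) -> dendropy.Tree:
    """Cluster-resampling support on the midpoint-rooted core tree.

    Core clusters are resampled with replacement ``n_reps`` times; each
    replicate's mean distance matrix is rebuilt into an NJ tree, and support
    for an internal bipartition is the percentage of replicates containing
    it.  Supports are written as internal node labels.  Reproducible for a
    fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(clusters) < 1:
        raise ValueError("need at least one core cluster")
    if genomes is None:
        genomes = sorted(set.union(*(cl.genomes() for cl in clusters)))
    stack = cluster_distance_stack(clusters, proteins, genomes)
    base = midpoint_root(nj_tree(DistanceMatrix(genomes, stack.mean(axis=0))))
    rng = np.random.default_rng(seed)
    m = stack.shape[0]
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, m, size=m)
        rep_tree = nj_tree(DistanceMatrix(genomes, stack[idx].mean(axis=0)))
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    leaf_labels = {lf.taxon.label for lf in base.leaf_node_iter()}
    anchor = min(leaf_labels)
    for node in base.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(leaf_labels - below) if anchor in below else below
        if 2 <= len(side) <= len(leaf_labels) - 2:
            node.label = f"{100.0 * counts.get(side, 0) / n_reps:.0f}"
    return base


def marker_tree(cluster: ProteinCluster,
                proteins: list[ProteinRecord],
                genomes: list[str] | None = None) -> dendropy.Tree:
    """Midpoint-rooted NJ tree from a single universal protein cluster."""
    if genomes is None:
        genomes = sorted(cluster.genomes())
    missing = set(genomes) - cluster.genomes()
    if missing:
        raise ValueError(
            f"cluster {cluster.cluster_id} not universal: missing {sorted(missing)}"
        )
    by_key = {p.key: p for p in proteins}
    d = DistanceMatrix(genomes, _cluster_distances(cluster, by_key, genomes))
    return midpoint_root(nj_tree(d))


# ---------------------------------------------------------------------------
# Newick IO


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path), schema="newick",
        suppress_rooting=False, unquoted_underscores=True,
    )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True,
    )
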