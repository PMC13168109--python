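"""Neighbor joining, midpoint rooting, resampling support and congruence."""

import itertools

import dendropy
import numpy as np
import pytest

from phagepan.genome_io import ProteinRecord
from phagepan.phylo import (
    DistanceMatrix,
    bipartitions,
    core_distance_matrix,
    marker_tree,
    midpoint_root,
    nj_tree,
    read_newick,
    resample_support,
    rf_distance,
    shared_bipartitions,
    write_newick,
)
from phagepan.synth import CommunityConfig, generate_community


def random_additive_tree(n, rng):
    """Random binary tree with positive lengths; returns (tree, labels, D)."""
    labels = [f"t{i:02d}" for i in range(n)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(l)) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(rng.uniform(0.05, 1.0))
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(rng.uniform(0.05, 1.0))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for x in nodes:
        root.add_child(x)
        x.edge.length = float(rng.uniform(0.05, 1.0))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(tns.get_taxon(labels[i]), tns.get_taxon(labels[j]))
        D[i, j] = D[j, i] = d
    return tree, labels, D


def leaf_path_lengths(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for a, b in itertools.combinations(taxa, 2):
        out[(a.label, b.label)] = pdm.patristic_distance(a, b)
    return out


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = nj_tree(d)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.5)
        assert lengths["b"] == pytest.approx(1.5)
        assert lengths["c"] == pytest.approx(2.5)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_additive_quartet_recovered_exactly(self):
        rng = np.random.default_rng(21)
        src, labels, D = random_additive_tree(4, rng)
        est = nj_tree(DistanceMatrix(labels, D))
        assert rf_distance(src, est) == 0
        got = leaf_path_lengths(est)
        want = leaf_path_lengths(src)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_random_additive_trees_recovered(self, n):
        """NJ recovers topology and path lengths of additive matrices."""
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            src, labels, D = random_additive_tree(n, rng)
            est = nj_tree(DistanceMatrix(labels, D))
            assert rf_distance(src, est) == 0
            got = leaf_path_lengths(est)
            want = leaf_path_lengths(src)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-8)

    def test_topology_agrees_with_skbio(self):
        """Independent cross-check against scikit-bio's NJ implementation."""
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix as SkDM

        rng = np.random.default_rng(7)
        src, labels, D = random_additive_tree(9, rng)
        ours = nj_tree(DistanceMatrix(labels, D))
        theirs = skbio_tree.nj(SkDM(D, ids=labels))
        ours_bips = bipartitions(ours)
        theirs_d = dendropy.Tree.get(
            data=str(theirs).replace("root", ""), schema="newick"
        )
        assert bipartitions(theirs_d) == ours_bips


class TestMidpoint:
    def test_two_leaf_split_evenly(self):
        tree = read_newick_str("(a:1.0,b:3.0);")
        rooted = midpoint_root(tree)
        lengths = {lf.taxon.label: lf.edge.length for lf in rooted.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(2.0)
        assert lengths["b"] == pytest.approx(2.0)

    def test_balanced_quartet_root_on_central_edge(self):
        tree = read_newick_str("((a:1,b:1):1,(c:1,d:1):1);")
        rooted = midpoint_root(tree)
        sides = sorted(
            frozenset(l.taxon.label for l in ch.leaf_iter())
            for ch in rooted.seed_node.child_nodes()
        )
        assert set(map(frozenset, sides)) == {frozenset("ab"), frozenset("cd")}

    def test_long_terminal_edge_attracts_root(self):
        """Caterpillar with one long leaf edge: exhaustive longest-path oracle."""
        tree = read_newick_str("(((a:0.1,b:0.1):0.1,c:0.1):0.1,(d:0.1,e:5.0):0.1);")
        # oracle: longest path is e..a/b/c; midpoint falls inside e's edge
        rooted = midpoint_root(tree)
        root_children = rooted.seed_node.child_nodes()
        leafsets = [frozenset(l.taxon.label for l in ch.leaf_iter()) for ch in root_children]
        assert frozenset("e") in leafsets

    def test_all_zero_lengths_warns(self):
        tree = read_newick_str("((a:0,b:0):0,(c:0,d:0):0);")
        with pytest.warns(UserWarning, match="zero"):
            midpoint_root(tree)


class TestRF:
    def test_identity(self):
        t = read_newick_str("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        assert rf_distance(t, t) == 0
        assert shared_bipartitions(t, t) == 1.0

    def test_distinct_quartets(self):
        t1 = read_newick_str("((a:1,b:1):1,c:1,d:1);")
        t2 = read_newick_str("((a:1,c:1):1,b:1,d:1);")
        assert rf_distance(t1, t2) == 2
        assert shared_bipartitions(t1, t2) == 0.0

    def test_leaf_mismatch_lists_difference(self):
        t1 = read_newick_str("((a:1,b:1):1,c:1,d:1);")
        t2 = read_newick_str("((a:1,b:1):1,c:1,e:1);")
        with pytest.raises(ValueError, match="d.*e"):
            rf_distance(t1, t2)

    def test_metric_properties_five_leaves(self):
        """Identity, symmetry, triangle over random 5-leaf trees, and
        agreement with dendropy's RF as an independent cross-check."""
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(17)
        trees = [random_additive_tree(5, rng)[0] for _ in range(6)]
        tns = dendropy.TaxonNamespace([f"t{i:02d}" for i in range(5)])
        canon = [
            dendropy.Tree.get(data=t.as_string(schema="newick"),
                              schema="newick", taxon_namespace=tns)
            for t in trees
        ]
        for t in canon:
            t.encode_bipartitions()
        n = len(trees)
        d = np.zeros((n, n), int)
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = rf_distance(trees[i], trees[j])
            assert d[i, j] == treecompare.symmetric_difference(canon[i], canon[j])
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, k] <= d[i, j] + d[j, k]
        assert (np.diag(d) == 0).all()


def read_newick_str(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestCoreDistances:
    def _identical_everywhere(self):
        prots = [
            ProteinRecord(g, "x", "MKLVWYAERT" * 5) for g in ("g1", "g2", "g3")
        ]
        from phagepan.protclust import ProteinCluster
        cl = ProteinCluster("c1", ("g1", "x"), [p.key for p in prots])
        return [cl], prots

    def test_identical_proteins_zero_matrix(self):
        clusters, prots = self._identical_everywhere()
        d = core_distance_matrix(clusters, prots)
        assert np.allclose(d.values, 0.0)

    def test_mean_over_clusters(self):
        """Two clusters with pairwise identities 0.9 and 0.8 -> distance 0.15."""
        from unittest import mock
        from phagepan.protclust import ProteinCluster
        prots = [ProteinRecord(g, gene, "M" * 50)
                 for g in ("g1", "g2") for gene in ("a", "b")]
        cls = [
            ProteinCluster("c1", ("g1", "a"), [("g1", "a"), ("g2", "a")]),
            ProteinCluster("c2", ("g1", "b"), [("g1", "b"), ("g2", "b")]),
        ]
        idents = iter([0.9, 0.8])
        with mock.patch(
            "phagepan.phylo.pairwise_protein_identity",
            side_effect=lambda p, q: (next(idents), 1.0, 1.0),
        ):
            d = core_distance_matrix(cls, prots, ["g1", "g2"])
        assert d.values[0, 1] == pytest.approx(0.15)

    def test_missing_genome_rejected(self):
        clusters, prots = self._identical_everywhere()
        with pytest.raises(ValueError, match="not a core cluster"):
            core_distance_matrix(clusters, prots, ["g1", "g2", "g3", "g4"])

    def test_clade_separation(self, small_community, small_clusters):
        genomes, proteins, _, truth = small_community
        ids = sorted(g.genome_id for g in genomes)
        core = [c for c in small_clusters if c.genomes() == set(ids)]
        d = core_distance_matrix(core, proteins, ids)
        clade = truth.clades
        within = [d.values[i, j] for i, j in itertools.combinations(range(len(ids)), 2)
                  if clade[ids[i]] == clade[ids[j]]]
        between = [d.values[i, j] for i, j in itertools.combinations(range(len(ids)), 2)
                   if clade[ids[i]] != clade[ids[j]]]
        assert np.mean(within) < np.mean(between)


class TestSupportAndMarkers:
    def test_single_cluster_all_supports_100(self, small_community, small_clusters):
        genomes, proteins, _, _ = small_community
        ids = sorted(g.genome_id for g in genomes)
        core = [c for c in small_clusters if c.genomes() == set(ids)]
        t = resample_support(core[:1], proteins, n_reps=20, seed=3, genomes=ids)
        labels = [n.label for n in t.preorder_node_iter()
                  if not n.is_leaf() and n.parent_node is not None and n.label]
        assert labels and all(l == "100" for l in labels)

    def test_seed_reproducibility_and_stability(self, small_community, small_clusters):
        genomes, proteins, _, truth = small_community
        ids = sorted(g.genome_id for g in genomes)
        core = [c for c in small_clusters if c.genomes() == set(ids)]
        t1 = resample_support(core, proteins, n_reps=50, seed=5, genomes=ids)
        t2 = resample_support(core, proteins, n_reps=50, seed=5, genomes=ids)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        t3 = resample_support(core, proteins, n_reps=50, seed=6, genomes=ids)
        assert rf_distance(t1, t3) == 0  # same topology, supports may differ

    def test_marker_requires_universal_cluster(self, small_community, small_clusters):
        genomes, proteins, _, _ = small_community
        ids = sorted(g.genome_id for g in genomes)
        partial = next(c for c in small_clusters if c.genomes() != set(ids))
        with pytest.raises(ValueError, match="not universal"):
            marker_tree(partial, proteins, genomes=ids)

    def test_concordant_marker_rf_zero_minimal_community(self):
        """With 2 clades x 2 genomes the clade split is the only internal
        edge, so a concordant marker reproduces the core tree exactly."""
        cfg = CommunityConfig(
            n_clades=2, genomes_per_clade=(2, 2), n_core_families=8,
            n_signature_families=(0, 0), n_accessory_families=0,
            gene_length_aa=(80, 120), seed=23,
        )
        genomes, proteins, _, _ = generate_community(cfg)
        from phagepan.protclust import ClusterParams, greedy_cluster
        clusters = greedy_cluster(proteins, ClusterParams(0.70, 0.50))
        ids = sorted(g.genome_id for g in genomes)
        core = [c for c in clusters if c.genomes() == set(ids)]
        assert len(core) == 8
        core_t = midpoint_root(nj_tree(core_distance_matrix(core, proteins, ids)))
        good = marker_tree(core[0], proteins, genomes=ids)
        assert rf_distance(core_t, good) == 0

    def test_discordant_marker_conflicts_with_core_tree(self):
        """A simulated transfer pulls the recipient toward the donor clade:
        its marker distances favor the donor clade, its core distances its
        own clade, and the two topologies conflict."""
        from phagepan.phylo import _cluster_distances

        cfg = CommunityConfig(
            n_clades=2, genomes_per_clade=(3, 3), n_core_families=8,
            n_signature_families=(0, 0), n_accessory_families=0,
            gene_length_aa=(80, 120), within_clade_sub_rate=0.02,
            between_clade_sub_rate=0.10, discordant_families=1,
            discordant_genomes=1, seed=29,
        )
        genomes, proteins, _, truth = generate_community(cfg)
        from phagepan.protclust import ClusterParams, greedy_cluster
        clusters = greedy_cluster(proteins, ClusterParams(0.50, 0.50))
        ids = sorted(g.genome_id for g in genomes)
        core = [c for c in clusters if c.genomes() == set(ids)]
        concordant = [c for c in core
                      if all(gene != "core001" for _, gene in c.members)]
        core_d = core_distance_matrix(concordant, proteins, ids)
        core_t = midpoint_root(nj_tree(core_d))
        clade_bip = {frozenset(m) for m in truth.clade_partition()}
        assert bipartitions(core_t) & clade_bip

        recipient = "SynPhi01"
        own = [g for g in ids if truth.clades[g] == truth.clades[recipient]
               and g != recipient]
        donor = [g for g in ids if truth.clades[g] != truth.clades[recipient]]
        discordant = next(c for c in core
                          if any(gene == "core001" for _, gene in c.members))
        by_key = {p.key: p for p in proteins}
        md = _cluster_distances(discordant, by_key, ids)
        col = {g: i for i, g in enumerate(ids)}
        r = col[recipient]
        marker_own = np.mean([md[r, col[g]] for g in own])
        marker_donor = np.mean([md[r, col[g]] for g in donor])
        core_own = np.mean([core_d.values[r, col[g]] for g in own])
        core_donor = np.mean([core_d.values[r, col[g]] for g in donor])
        assert marker_donor < marker_own      # transferred allele
        assert core_own < core_donor          # rest of the genome
        bad = marker_tree(discordant, proteins, genomes=ids)
        assert rf_distance(core_t, bad) > 0


class TestNewickIO:
    def test_round_trip(self, tmp_path):
        t = read_newick_str("((a:1,b:2)75:0.5,(c:1,d:1)90:0.5);")
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        back = read_newick(p)
        assert rf_distance(t, back) == 0
        assert {n.label for n in back.preorder_node_iter() if not n.is_leaf()} >= {"75", "90"}
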