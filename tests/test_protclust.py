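"""Protein identity kernel and greedy centroid clustering."""

import itertools

import numpy as np
import pytest

from phagepan.genome_io import ProteinRecord
from phagepan.protclust import (
    ClusterParams,
    cluster_counts_matrix,
    greedy_cluster,
    pairwise_protein_identity,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(n, rng):
    return "".join(rng.choice(list(AA), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(4242)


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        p = random_protein(100, rng)
        assert pairwise_protein_identity(p, p) == (1.0, 1.0, 1.0)

    def test_containment_coverage(self, rng):
        p = random_protein(100, rng)
        q = p[:40]
        ident, cov_p, cov_q = pairwise_protein_identity(p, q)
        assert ident == pytest.approx(1.0)
        assert cov_p == pytest.approx(0.40)
        assert cov_q == pytest.approx(1.0)

    def test_scattered_substitutions_identity(self, rng):
        """20 substitutions in 100 residues give identity 0.80 when the
        full-length ungapped alignment is optimal (constructed so by using
        maximally dissimilar replacement residues)."""
        p = random_protein(100, rng)
        # substitute every 5th position with a residue of negative BLOSUM score
        swap = {"A": "W", "C": "D", "D": "W", "E": "W", "F": "D", "G": "W",
                "H": "C", "I": "D", "K": "W", "L": "D", "M": "D", "N": "W",
                "P": "W", "Q": "C", "R": "D", "S": "W", "T": "W", "V": "D",
                "W": "P", "Y": "P"}
        q = "".join(swap[c] if i % 5 == 0 else c for i, c in enumerate(p))
        ident, cov_p, cov_q = pairwise_protein_identity(p, q)
        assert cov_p > 0.95 and cov_q > 0.95
        assert ident == pytest.approx(0.80, abs=0.02)

    def test_symmetry_of_identity(self, rng):
        p, q = random_protein(80, rng), random_protein(80, rng)
        i1, _, _ = pairwise_protein_identity(p, q)
        i2, _, _ = pairwise_protein_identity(q, p)
        assert i1 == pytest.approx(i2, abs=1e-9)


def _prot(gid, gene, seq):
    return ProteinRecord(gid, gene, seq)


class TestGreedyCluster:
    def test_three_identical_copies_one_cluster(self, rng):
        s = random_protein(120, rng)
        prots = [_prot(f"g{i}", "a", s) for i in range(3)]
        clusters = greedy_cluster(prots, ClusterParams(0.70, 0.50))
        assert len(clusters) == 1
        assert clusters[0].size == 3
        assert clusters[0].representative in [p.key for p in prots]

    def test_unrelated_proteins_singletons(self, rng):
        prots = [
            _prot("g1", "a", random_protein(150, rng)),
            _prot("g2", "b", random_protein(150, rng)),
        ]
        clusters = greedy_cluster(prots, ClusterParams(0.70, 0.50))
        assert [c.size for c in clusters] == [1, 1]

    def test_identity_and_coverage_thresholds(self, rng):
        """A/B cluster at 80% identity; a 40% fragment fails coverage."""
        a = random_protein(100, rng)
        swap = {"A": "W", "C": "D", "D": "W", "E": "W", "F": "D", "G": "W",
                "H": "C", "I": "D", "K": "W", "L": "D", "M": "D", "N": "W",
                "P": "W", "Q": "C", "R": "D", "S": "W", "T": "W", "V": "D",
                "W": "P", "Y": "P"}
        b = "".join(swap[c] if i % 5 == 0 else c for i, c in enumerate(a))
        c = a[:40]
        prots = [_prot("g1", "A", a), _prot("g2", "B", b), _prot("g3", "C", c)]
        clusters = greedy_cluster(prots, ClusterParams(0.70, 0.50, "both"))
        sizes = sorted(c.size for c in clusters)
        assert sizes == [1, 2]
        big = next(cl for cl in clusters if cl.size == 2)
        assert {g for g, _ in big.members} == {"g1", "g2"}

    def test_duplicate_key_rejected(self, rng):
        s = random_protein(50, rng)
        with pytest.raises(ValueError, match="duplicate"):
            greedy_cluster([_prot("g", "x", s), _prot("g", "x", s)])

    def test_permutation_invariance(self, rng):
        prots = [
            _prot(f"g{i}", f"p{j}", random_protein(int(rng.integers(60, 200)), rng))
            for i in range(3) for j in range(5)
        ]
        ref = greedy_cluster(prots, ClusterParams(0.5, 0.5))
        perm = list(prots)
        np.random.default_rng(1).shuffle(perm)
        out = greedy_cluster(perm, ClusterParams(0.5, 0.5))
        assert [set(c.members) for c in ref] == [set(c.members) for c in out]

    def test_total_membership_conserved(self, small_community, small_clusters):
        _, proteins, _, _ = small_community
        n_members = sum(c.size for c in small_clusters)
        assert n_members == len([p for p in proteins if not p.has_internal_stop])

    def test_clusters_refine_threshold_graph_components(self, rng):
        """Greedy clusters are subsets of connected components of the
        all-pairs >= threshold graph (brute-force oracle, <= 30 proteins)."""
        params = ClusterParams(0.5, 0.5)
        base = [random_protein(90, rng) for _ in range(6)]
        prots = []
        k = 0
        for b in base:
            for _ in range(int(rng.integers(2, 5))):
                seq = list(b)
                for pos in rng.choice(len(seq), size=int(rng.integers(0, 12)), replace=False):
                    seq[pos] = str(rng.choice(list(AA)))
                prots.append(_prot(f"g{k}", "p", "".join(seq)))
                k += 1
        prots = prots[:30]
        clusters = greedy_cluster(prots, params)

        # oracle: brute-force all-pairs threshold graph, BFS components
        idx = {p.key: i for i, p in enumerate(prots)}
        n = len(prots)
        adj = np.zeros((n, n), dtype=bool)
        for i, j in itertools.combinations(range(n), 2):
            ident, cp, cq = pairwise_protein_identity(
                prots[i].aa_sequence, prots[j].aa_sequence
            )
            ok = ident >= params.min_identity and min(cp, cq) >= params.min_coverage
            adj[i, j] = adj[j, i] = ok
        comp = -np.ones(n, dtype=int)
        c = 0
        for s in range(n):
            if comp[s] >= 0:
                continue
            stack = [s]
            comp[s] = c
            while stack:
                u = stack.pop()
                for v in np.flatnonzero(adj[u]):
                    if comp[v] < 0:
                        comp[v] = c
                        stack.append(v)
            c += 1
        for cl in clusters:
            comps = {comp[idx[m]] for m in cl.members}
            assert len(comps) == 1

    def test_raising_identity_never_merges(self, rng):
        prots = [
            _prot(f"g{i}", "p", random_protein(100, rng)) for i in range(8)
        ]
        n_low = len(greedy_cluster(prots, ClusterParams(0.4, 0.5)))
        n_high = len(greedy_cluster(prots, ClusterParams(0.8, 0.5)))
        assert n_high >= n_low


class TestCountsMatrix:
    def test_counts_and_column_sums(self, small_community, small_clusters):
        genomes, proteins, _, _ = small_community
        ids = [g.genome_id for g in genomes]
        m = cluster_counts_matrix(small_clusters, ids)
        per_genome = {gid: 0 for gid in ids}
        for p in proteins:
            if not p.has_internal_stop:
                per_genome[p.genome_id] += 1
        assert m.sum(axis=0).to_dict() == per_genome

    def test_unknown_genome_rejected(self, small_clusters):
        with pytest.raises(ValueError, match="unknown genome"):
            cluster_counts_matrix(small_clusters, ["nope"])

    def test_paralog_counted_twice(self, rng):
        s = random_protein(100, rng)
        prots = [_prot("g1", "a", s), _prot("g1", "b", s), _prot("g2", "a", s)]
        clusters = greedy_cluster(prots, ClusterParams(0.7, 0.5))
        m = cluster_counts_matrix(clusters, ["g1", "g2"])
        assert m.iloc[0].tolist() == [2, 1]
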