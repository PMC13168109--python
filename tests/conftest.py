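"""Shared fixtures: small synthetic communities and a full default run."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from phagepan import pangenome, protclust
from phagepan.pipeline import RunConfig, run_full
from phagepan.synth import CommunityConfig, generate_community

SMALL_CONFIG = CommunityConfig(
    n_clades=2,
    genomes_per_clade=(3, 3),
    n_core_families=12,
    n_signature_families=(2, 2),
    n_accessory_families=2,
    accessory_rate=0.25,
    gene_length_aa=(80, 140),
    seed=11,
)


@pytest.fixture(scope="session")
def small_community():
    """A fast 6-genome, 12-core-family community for unit tests."""
    return generate_community(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_clusters(small_community):
    _, proteins, _, _ = small_community
    return protclust.greedy_cluster(proteins, protclust.ClusterParams(0.70, 0.50))


@pytest.fixture(scope="session")
def small_pa(small_community, small_clusters):
    genomes, _, _, _ = small_community
    return pangenome.make_pa_matrix(small_clusters, [g.genome_id for g in genomes])


@pytest.fixture(scope="session")
def default_community(tmp_path_factory):
    """The default two-clade community (9+6 genomes, 63 core families)."""
    out = tmp_path_factory.mktemp("community")
    return generate_community(CommunityConfig(seed=20177), out_dir=out), out


@pytest.fixture(scope="session")
def default_run(default_community, tmp_path_factory):
    """Full pipeline run on the default community."""
    (genomes, proteins, metadata, truth), comm_dir = default_community
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        genomes=str(comm_dir / "genomes.fasta"),
        proteins=str(comm_dir / "proteins.faa"),
        metadata=str(comm_dir / "metadata.tsv"),
        out_dir=str(out),
        reps=200,
        seed=20177,
    )
    report = run_full(
        cfg, genomes=genomes, proteins=proteins, metadata=metadata
    )
    return report, truth, out


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_components(labels, values, threshold):
    """Exhaustive BFS connected components of the >= threshold graph."""
    n = len(labels)
    seen = set()
    comps = []
    for s in range(n):
        if s in seen:
            continue
        comp = {s}
        frontier = [s]
        while frontier:
            u = frontier.pop()
            for v in range(n):
                if v not in comp and values[u][v] >= threshold:
                    comp.add(v)
                    frontier.append(v)
        seen |= comp
        comps.append(frozenset(labels[i] for i in comp))
    return set(comps)
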