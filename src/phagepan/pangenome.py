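"""Presence/absence matrix, core/accessory partition and signature genes.

The presence/absence (PA) matrix is a boolean cluster x genome table derived
from protein clusters.  Core clusters are those present in (by default) every
genome; upset-style summaries count *exclusive* intersections (each cluster
contributes to exactly one genome-subset signature); a clade-signature
cluster is present in every member of one group and absent from every member
of a contrast group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protclust import ProteinCluster

__all__ = [
    "PAMatrix",
    "PangenomeSummary",
    "make_pa_matrix",
    "core_clusters",
    "upset_intersections",
    "signature_clusters",
    "rank_core_table",
]


class PAMatrix:
    """Boolean cluster x genome matrix; every cluster has >= 1 member."""

    def __init__(self, df: pd.DataFrame):
        df = df.astype(bool)
        if df.empty:
            raise ValueError("empty PA matrix")
        absent = df.index[~df.any(axis=1)].tolist()
        if absent:
            raise ValueError(f"clusters with no members: {absent}")
        self.df = df

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_genomes(self) -> int:
        return self.df.shape[1]

    def prevalence(self) -> pd.Series:
        """Number of genomes carrying each cluster."""
        return self.df.sum(axis=1)

    def subset_genomes(self, genomes: list[str]) -> "PAMatrix":
        sub = self.df[genomes]
        return PAMatrix(sub[sub.any(axis=1)])

    def to_tsv(self, path) -> None:
        self.df.astype(int).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "PAMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0).astype(bool))


@dataclass
class PangenomeSummary:
    n_core: int
    n_accessory: int
    intersections: list[tuple[tuple[str, ...], int]]
    per_genome_unique: dict[str, int] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.n_core + self.n_accessory


def make_pa_matrix(clusters: list[ProteinCluster], genomes: list[str]) -> PAMatrix:
    """Booleanized cluster presence per genome.

    Rows ordered by descending prevalence then cluster id; paralogs collapse
    to a single True.  A member genome absent from ``genomes`` is an error.
    """
    if not clusters:
        raise ValueError("no clusters")
    known = set(genomes)
    data = {}
    for cl in clusters:
        present = cl.genomes()
        missing = present - known
        if missing:
            raise ValueError(
                f"cluster {cl.cluster_id} has members in genomes not in the "
                f"genome list: {sorted(missing)}"
            )
        data[cl.cluster_id] = [g in present for g in genomes]
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(genomes))
    order = sorted(df.index, key=lambda cid: (-int(df.loc[cid].sum()), cid))
    return PAMatrix(df.loc[order])


def core_clusters(pa: PAMatrix, min_prevalence: float = 1.0) -> set[str]:
    """Clusters present in >= ceil(min_prevalence * n_genomes) genomes."""
    need = math.ceil(min_prevalence * pa.n_genomes)
    prev = pa.prevalence()
    return set(prev.index[prev >= need])


def upset_intersections(pa: PAMatrix) -> PangenomeSummary:
    """Exclusive intersection counts (standard UpSet semantics).

    Each cluster contributes to exactly one signature: the exact set of
    genomes that contain it.  Intersections are sorted by count descending
    (ties by signature); their counts sum to the total cluster count.
    """
    sigs: dict[tuple[str, ...], int] = {}
    genomes = pa.genome_ids
    arr = pa.df.to_numpy()
    for row in arr:
        sig = tuple(g for g, present in zip(genomes, row) if present)
        sigs[sig] = sigs.get(sig, 0) + 1
    intersections = sorted(sigs.items(), key=lambda kv: (-kv[1], kv[0]))
    all_sig = tuple(genomes)
    n_core = sigs.get(all_sig, 0)
    per_genome_unique = {
        g: sigs.get((g,), 0) for g in genomes
    }
    return PangenomeSummary(
        n_core=n_core,
        n_accessory=len(pa.cluster_ids) - n_core,
        intersections=intersections,
        per_genome_unique=per_genome_unique,
    )


def signature_clusters(pa: PAMatrix, group_a: set[str], group_b: set[str]) -> set[str]:
    """Clusters present in EVERY genome of group_a and NO genome of group_b."""
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("groups must be nonempty")
    if group_a & group_b:
        raise ValueError(f"groups overlap: {sorted(group_a & group_b)}")
    unknown = (group_a | group_b) - set(pa.genome_ids)
    if unknown:
        raise ValueError(f"unknown genomes: {sorted(unknown)}")
    in_all_a = pa.df[list(group_a)].all(axis=1)
    in_no_b = ~pa.df[list(group_b)].any(axis=1)
    return set(pa.df.index[in_all_a & in_no_b])


def rank_core_table(pa: PAMatrix, grouping: dict[str, str]) -> dict:
    """Per-taxon unique-core counts plus the set-wide core.

    For each taxon: clusters present in all of its members and absent from
    all non-members.  With a single taxon the unique core equals the global
    core.  Taxa with zero members are an error; grouping must cover every
    genome in the matrix.
    """
    genomes = set(pa.genome_ids)
    missing = genomes - set(grouping)
    if missing:
        raise ValueError(f"grouping does not cover genomes: {sorted(missing)}")
    taxa: dict[str, set[str]] = {}
    for g in pa.genome_ids:
        taxa.setdefault(grouping[g], set()).add(g)
    for t, members in taxa.items():
        if not members:
            raise ValueError(f"taxon {t!r} has zero members")
    result: dict[str, dict] = {"per_taxon": {}, "global_core": sorted(core_clusters(pa))}
    for t, members in sorted(taxa.items()):
        others = genomes - members
        if others:
            uniq = signature_clusters(pa, members, others)
        else:
            uniq = core_clusters(pa)
        result["per_taxon"][t] = {
            "n_members": len(members),
            "unique_core": sorted(uniq),
            "n_unique_core": len(uniq),
        }
    return result
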