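"""Shared-cluster similarity and threshold-based rank delineation.

Genome relatedness from gene content: the Jaccard similarity of two genomes
is the percentage of protein clusters shared out of their union.  Taxonomic
ranks (species, genus) are delineated by single-linkage clustering of an
intergenomic similarity matrix at fixed thresholds (defaults: 95% for
species, 70% for genus, the ICTV convention for tailed phages); because the
species threshold is the higher one, species components nest inside genus
components.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genome_io import SimilarityMatrix
from .pangenome import PAMatrix

__all__ = [
    "GroupingScheme",
    "jaccard_matrix",
    "shared_pc_percent",
    "group_stats",
    "delineate_ranks",
]

RANKS = ("species", "genus", "subfamily", "clade")


@dataclass
class GroupingScheme:
    """A total assignment of genomes to taxon labels at one rank."""

    rank: str
    assignment: dict[str, str]

    def __post_init__(self):
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if any(not v for v in self.assignment.values()):
            raise ValueError("empty taxon label")

    def taxa(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, t in self.assignment.items():
            out.setdefault(t, set()).add(g)
        return out

    def partition(self) -> set[frozenset[str]]:
        return {frozenset(m) for m in self.taxa().values()}

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"genome_id": list(self.assignment), "taxon": list(self.assignment.values())}
        ).to_csv(path, sep="\t", index=False)


def jaccard_matrix(pa: PAMatrix) -> SimilarityMatrix:
    """Pairwise percent Jaccard similarity of cluster content.

    entry(i, j) = 100 * |clusters in both| / |clusters in either|.
    A genome with zero clusters is an error (undefined union ratio).
    """
    m = pa.df.to_numpy(dtype=bool)
    sizes = m.sum(axis=0)
    empty = [g for g, s in zip(pa.genome_ids, sizes) if s == 0]
    if empty:
        raise ValueError(f"genomes with zero clusters: {empty}")
    inter = (m.T.astype(np.int64)) @ m.astype(np.int64)
    union = sizes[:, None] + sizes[None, :] - inter
    vals = 100.0 * inter / union
    np.fill_diagonal(vals, 100.0)
    df = pd.DataFrame(vals, index=pa.genome_ids, columns=pa.genome_ids)
    return SimilarityMatrix(df)


def shared_pc_percent(pa: PAMatrix, i: str, j: str, mode: str = "jaccard") -> float:
    """Percent shared protein clusters between two genomes.

    ``jaccard``: shared / union; ``of_smaller``: shared / min(|i|, |j|).
    """
    if i == j:
        raise ValueError("i and j must differ")
    if mode not in ("jaccard", "of_smaller"):
        raise ValueError(f"unknown mode {mode!r}")
    ci = pa.df[i].to_numpy(dtype=bool)
    cj = pa.df[j].to_numpy(dtype=bool)
    shared = int((ci & cj).sum())
    if mode == "jaccard":
        union = int((ci | cj).sum())
        if union == 0:
            raise ValueError(f"genomes {i!r} and {j!r} have no clusters")
        return 100.0 * shared / union
    smaller = min(int(ci.sum()), int(cj.sum()))
    if smaller == 0:
        raise ValueError(f"genome with zero clusters in pair ({i!r}, {j!r})")
    return 100.0 * shared / smaller


def group_stats(sim: SimilarityMatrix, grouping: GroupingScheme) -> pd.DataFrame:
    """Intra- and inter-taxon similarity distributions (five-number summary).

    One row per unordered taxon pair (taxon vs itself = intra); columns:
    taxon_a, taxon_b, kind, n_pairs, min, q1, median, q3, max.  Singleton
    taxa yield an intra row with n_pairs 0.  No genome pair is counted twice.
    """
    missing = set(sim.labels) - set(grouping.assignment)
    if missing:
        raise ValueError(f"grouping does not cover genomes: {sorted(missing)}")
    taxa = {t: sorted(m) for t, m in grouping.taxa().items() if m & set(sim.labels)}
    rows = []
    names = sorted(taxa)
    for a_idx, ta in enumerate(names):
        for tb in names[a_idx:]:
            if ta == tb:
                vals = [
                    sim[g1, g2]
                    for g1, g2 in itertools.combinations(taxa[ta], 2)
                ]
                kind = "intra"
            else:
                vals = [sim[g1, g2] for g1 in taxa[ta] for g2 in taxa[tb]]
                kind = "inter"
            row = {
                "taxon_a": ta,
                "taxon_b": tb,
                "kind": kind,
                "n_pairs": len(vals),
            }
            if vals:
                q = np.percentile(vals, [0, 25, 50, 75, 100])
                row.update(min=q[0], q1=q[1], median=q[2], q3=q[3], max=q[4])
            else:
                row.update(min=np.nan, q1=np.nan, median=np.nan, q3=np.nan, max=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def _components(sim: SimilarityMatrix, threshold: float) -> list[int]:
    adj = sim.values() >= threshold
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return list(labels)


def delineate_ranks(sim: SimilarityMatrix, species_thr: float = 95.0,
                    genus_thr: float = 70.0) -> dict[str, GroupingScheme]:
    """Species/genus assignment by single-linkage threshold components.

    Components of the graph with edges sim >= threshold; since
    species_thr >= genus_thr, every species component nests inside exactly
    one genus component.  Component labels are numbered by the smallest
    genome id they contain, so output is invariant to genome order.
    """
    if species_thr < genus_thr:
        raise ValueError("species threshold must be >= genus threshold")
    out: dict[str, GroupingScheme] = {}
    for rank, thr in (("species", species_thr), ("genus", genus_thr)):
        labels = _components(sim, thr)
        members: dict[int, list[str]] = {}
        for g, lab in zip(sim.labels, labels):
            members.setdefault(lab, []).append(g)
        ordered = sorted(members.values(), key=lambda ms: min(ms))
        assignment = {
            g: f"{rank}_{i + 1}" for i, ms in enumerate(ordered) for g in ms
        }
        out[rank] = GroupingScheme(rank, assignment)
    return out
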