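"""Greedy centroid protein clustering at identity/coverage thresholds.

All-vs-representative comparison with exact Smith-Waterman local alignments
(BLOSUM62, gap open 11 / extend 1).  Identity counts gap columns in the
denominator; coverage is the aligned footprint on a sequence divided by its
length.  Proteins are processed longest-first (ties by genome then gene id)
and joined to the first existing cluster whose representative meets both the
identity and the coverage criterion, CD-HIT style; otherwise they found a new
cluster.  The result is deterministic and independent of input order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import ProteinRecord

__all__ = [
    "ClusterParams",
    "ProteinCluster",
    "pairwise_protein_identity",
    "greedy_cluster",
    "cluster_counts_matrix",
]


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds for cluster membership.

    coverage_mode:
        ``both``    - alignment must cover >= min_coverage of both sequences
        ``shorter`` - of the shorter sequence only
        ``target``  - of the candidate (non-representative) sequence
    """

    min_identity: float = 0.70
    min_coverage: float = 0.50
    coverage_mode: str = "both"

    def __post_init__(self):
        if not (0 < self.min_identity <= 1 and 0 < self.min_coverage <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.coverage_mode not in ("both", "shorter", "target"):
            raise ValueError(f"unknown coverage_mode {self.coverage_mode!r}")


@dataclass
class ProteinCluster:
    """A protein family: representative, members, optional function label."""

    cluster_id: str
    representative: tuple[str, str]
    members: list[tuple[str, str]] = field(default_factory=list)
    label: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()
_BLOSUM_ALPHABET = set(str(_ALIGNER.substitution_matrix.alphabet))


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    if set(seq) <= _BLOSUM_ALPHABET:
        return seq
    return "".join(c if c in _BLOSUM_ALPHABET else "X" for c in seq)


def pairwise_protein_identity(p: str, q: str) -> tuple[float, float, float]:
    """Local-alignment identity and per-sequence coverage for two proteins.

    Returns ``(identity, coverage_p, coverage_q)`` where identity is
    matches / alignment columns (gap columns included) of the optimal local
    alignment and coverage_x is the aligned footprint on x over len(x).
    Returns all zeros when no alignment with positive score exists.
    """
    if not p or not q:
        raise ValueError("protein sequences must be nonempty")
    p, q = _sanitize(p), _sanitize(q)
    if p == q:
        return 1.0, 1.0, 1.0
    alignments = _ALIGNER.align(p, q)
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0, 0.0, 0.0
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    if columns == 0:
        return 0.0, 0.0, 0.0
    identity = counts.identities / columns
    (t_blocks, q_blocks) = aln.aligned
    span_p = int(t_blocks[-1][1] - t_blocks[0][0])
    span_q = int(q_blocks[-1][1] - q_blocks[0][0])
    return identity, span_p / len(p), span_q / len(q)


def _coverage_ok(cov_rep: float, cov_cand: float, len_rep: int, len_cand: int,
                 params: ClusterParams) -> bool:
    if params.coverage_mode == "both":
        return cov_rep >= params.min_coverage and cov_cand >= params.min_coverage
    if params.coverage_mode == "shorter":
        cov_short = cov_cand if len_cand <= len_rep else cov_rep
        return cov_short >= params.min_coverage
    return cov_cand >= params.min_coverage  # target


def greedy_cluster(proteins: list[ProteinRecord],
                   params: ClusterParams | None = None) -> list[ProteinCluster]:
    """Cluster proteins into families by greedy centroid assignment.

    Records flagged with an internal stop are excluded.  Output clusters are
    sorted by descending member count, then cluster id; ids reflect founding
    order.  Duplicate (genome_id, gene_id) pairs are an error.
    """
    if params is None:
        params = ClusterParams()
    usable = [p for p in proteins if not p.has_internal_stop]
    if not usable:
        raise ValueError("no clusterable proteins")
    keys = [p.key for p in usable]
    if len(set(keys)) != len(keys):
        dup = next(k for k, c in Counter(keys).items() if c > 1)
        raise ValueError(f"duplicate protein identifier {dup[0]}|{dup[1]}")

    order = sorted(
        usable, key=lambda p: (-len(p.aa_sequence), p.genome_id, p.gene_id)
    )
    clusters: list[ProteinCluster] = []
    reps: list[ProteinRecord] = []
    member_labels: list[list[str | None]] = []
    by_seq: dict[str, int] = {}  # representative sequence -> cluster index

    for prot in order:
        assigned = None
        exact = by_seq.get(prot.aa_sequence)
        if exact is not None:
            # identical to a representative: identity 1.0, coverage 1.0 on
            # both sides, so it necessarily belongs to that cluster (any
            # earlier-founded qualifying cluster would have absorbed the
            # representative itself)
            assigned = exact
        else:
            lp = len(prot.aa_sequence)
            for ci, rep in enumerate(reps):
                lr = len(rep.aa_sequence)
                # necessary condition: identity <= len_short / (cov * len_long)
                len_short, len_long = min(lp, lr), max(lp, lr)
                if params.coverage_mode == "both" and (
                    len_short < params.min_identity * params.min_coverage * len_long
                ):
                    continue
                ident, cov_rep, cov_cand = pairwise_protein_identity(
                    rep.aa_sequence, prot.aa_sequence
                )
                if ident >= params.min_identity and _coverage_ok(
                    cov_rep, cov_cand, lr, lp, params
                ):
                    assigned = ci
                    break
        if assigned is None:
            ci = len(clusters)
            clusters.append(
                ProteinCluster(f"PC{ci + 1:05d}", prot.key, [prot.key])
            )
            reps.append(prot)
            member_labels.append([prot.label])
            by_seq.setdefault(prot.aa_sequence, ci)
        else:
            clusters[assigned].members.append(prot.key)
            member_labels[assigned].append(prot.label)

    for cl, labels in zip(clusters, member_labels):
        cl.label = _majority_label(labels, rep_label=labels[0])
    clusters.sort(key=lambda c: (-c.size, c.cluster_id))
    return clusters


def _majority_label(labels: list[str | None], rep_label: str | None) -> str | None:
    informative = [
        l for l in labels if l and "hypothetical" not in l.lower()
    ]
    if not informative:
        return rep_label
    counts = Counter(informative)
    best = counts.most_common()
    if len(best) > 1 and best[0][1] == best[1][1]:
        return rep_label if rep_label else best[0][0]
    return best[0][0]


def cluster_counts_matrix(clusters: list[ProteinCluster],
                          genomes: list[str]) -> pd.DataFrame:
    """Cluster x genome member-count matrix (column sums = proteins/genome)."""
    known = set(genomes)
    m = np.zeros((len(clusters), len(genomes)), dtype=int)
    col = {g: i for i, g in enumerate(genomes)}
    for ri, cl in enumerate(clusters):
        for g, _ in cl.members:
            if g not in known:
                raise ValueError(
                    f"cluster {cl.cluster_id} references unknown genome {g!r}"
                )
            m[ri, col[g]] += 1
    return pd.DataFrame(m, index=[c.cluster_id for c in clusters], columns=genomes)


def write_clusters_tsv(clusters: list[ProteinCluster], path) -> None:
    """Membership table: cluster_id, genome_id, gene_id, is_representative, label."""
    rows = []
    for cl in clusters:
        for g, gene in cl.members:
            rows.append(
                {
                    "cluster_id": cl.cluster_id,
                    "genome_id": g,
                    "gene_id": gene,
                    "is_representative": int((g, gene) == cl.representative),
                    "label": cl.label or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
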