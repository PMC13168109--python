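"""End-to-end orchestration: similarity -> clustering -> pangenome -> ranks -> trees.

``run_full`` executes the whole comparative analysis on a genome FASTA plus a
protein complement (protein FASTA with ``genomeID|geneID`` headers, or
GenBank files), writes every artifact (TSV matrices, cluster tables, Newick
trees, JSON report) into an output directory, and returns the report.  Every
threshold used is echoed verbatim into the report's provenance block, and a
rerun with the same inputs, config and seed reproduces the artifacts.
"""

from __future__ import annotations

import dataclasses
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import intergenomic, pangenome, phylo, protclust, taxa
from .genome_io import (
    GenomeRecord,
    MetadataTable,
    ProteinRecord,
    read_fasta,
    read_genbank_cds,
    read_protein_fasta,
    write_json,
)
from .protclust import write_clusters_tsv

__all__ = ["RunConfig", "run_full", "clade_metadata_concordance"]


@dataclass
class RunConfig:
    """Configuration of a full run; every field lands in the report."""

    genomes: str
    proteins: str
    metadata: str | None = None
    out_dir: str = "phagepan_out"
    cluster_id: float = 0.70
    cluster_cov: float = 0.50
    coverage_mode: str = "both"
    species_thr: float = 95.0
    genus_thr: float = 70.0
    reps: int = 200
    seed: int = 0
    marker_labels: tuple[str, ...] = ("terminase large subunit", "portal protein")

    def provenance(self) -> dict:
        return dataclasses.asdict(self)


def _log(stage: str, t0: float) -> None:
    print(f"[phagepan] {stage} done in {time.time() - t0:.1f}s", file=sys.stderr)


def _load_proteins(path: str) -> list[ProteinRecord]:
    p = Path(path)
    if p.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank"):
        return read_genbank_cds(p)
    return read_protein_fasta(p)


def clade_metadata_concordance(grouping: taxa.GroupingScheme,
                               metadata: MetadataTable,
                               fld: str = "year",
                               year_split: tuple[int, int] = (2013, 2020)) -> dict:
    """Cross-tabulate clades against a metadata field; report purity.

    Years are binned as <= year_split[0] vs >= year_split[1] by default;
    other fields are used as-is.  Genomes with a missing value are excluded
    with a warning count.  Purity is the fraction of genomes falling in their
    clade's majority bin.
    """
    rows = []
    n_missing = 0
    for g, clade in grouping.assignment.items():
        if g not in metadata or fld not in metadata.df.columns:
            n_missing += 1
            continue
        val = metadata.df.loc[g, fld]
        if pd.isna(val):
            n_missing += 1
            continue
        if fld == "year":
            y = int(val)
            if y <= year_split[0]:
                val = f"<={year_split[0]}"
            elif y >= year_split[1]:
                val = f">={year_split[1]}"
            else:
                val = f"{year_split[0] + 1}-{year_split[1] - 1}"
        rows.append({"clade": clade, "bin": str(val)})
    if n_missing:
        print(f"[phagepan] concordance: {n_missing} genomes lacked {fld!r}",
              file=sys.stderr)
    if not rows:
        raise ValueError(f"no usable values for field {fld!r}")
    df = pd.DataFrame(rows)
    table = pd.crosstab(df["clade"], df["bin"])
    purity = float(table.max(axis=1).sum() / table.to_numpy().sum())
    return {
        "field": fld,
        "contingency": {c: table.loc[c].to_dict() for c in table.index},
        "purity": purity,
        "n_excluded_missing": n_missing,
    }


def _clades_from_tree(tree) -> taxa.GroupingScheme:
    """Clade partition = the two subtrees under the midpoint root."""
    root = tree.seed_node
    assignment: dict[str, str] = {}
    children = root.child_nodes()
    sides = sorted(
        ({lf.taxon.label for lf in ch.leaf_iter()} for ch in children),
        key=lambda s: min(s),
    )
    for i, side in enumerate(sides):
        for g in side:
            assignment[g] = f"clade_{i + 1}"
    return taxa.GroupingScheme("clade", assignment)


def run_full(config: RunConfig,
             genomes: list[GenomeRecord] | None = None,
             proteins: list[ProteinRecord] | None = None,
             metadata: MetadataTable | None = None) -> dict:
    """Run the full comparative pipeline and write all artifacts.

    In-memory records may be passed directly (the file paths in ``config``
    are then only provenance).  Stages: intergenomic similarity, protein
    clustering, pangenome/PA matrix, Jaccard + rank demarcation, core-genome
    NJ tree with resampling support, marker-tree congruence, metadata
    concordance.  Any stage error aborts with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": config.provenance(), "artifacts": {}}

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            _log(name, t0)
            return result
        return wrap

    if genomes is None:
        genomes = stage("read_genomes")(lambda: read_fasta(config.genomes))
    if len(genomes) < 3:
        raise ValueError("need at least 3 genomes")
    if proteins is None:
        proteins = stage("read_proteins")(lambda: _load_proteins(config.proteins))
    if metadata is None and config.metadata:
        metadata = MetadataTable.from_tsv(config.metadata)
    genome_ids = [g.genome_id for g in genomes]

    # 1. intergenomic similarity
    sim = stage("intergenomic_similarity")(
        lambda: intergenomic.similarity_matrix(genomes)
    )
    sim.to_tsv(out / "intergenomic_similarity.tsv")
    report["artifacts"]["intergenomic_similarity"] = "intergenomic_similarity.tsv"
    report["min_intergenomic_similarity"] = float(sim.values().min())

    # 2. protein clustering
    params = protclust.ClusterParams(
        config.cluster_id, config.cluster_cov, config.coverage_mode
    )
    clusters = stage("protein_clustering")(
        lambda: protclust.greedy_cluster(proteins, params)
    )
    write_clusters_tsv(clusters, out / "protein_clusters.tsv")
    report["artifacts"]["protein_clusters"] = "protein_clusters.tsv"
    report["n_clusters"] = len(clusters)

    # 3. pangenome
    pa = pangenome.make_pa_matrix(clusters, genome_ids)
    pa.to_tsv(out / "pa_matrix.tsv")
    report["artifacts"]["pa_matrix"] = "pa_matrix.tsv"
    core_ids = sorted(pangenome.core_clusters(pa))
    summary = pangenome.upset_intersections(pa)
    report["n_core_clusters"] = len(core_ids)
    report["n_accessory_clusters"] = summary.n_accessory
    report["core_cluster_ids"] = core_ids

    # 4. Jaccard + rank demarcation
    jac = taxa.jaccard_matrix(pa)
    jac.to_tsv(out / "jaccard_similarity.tsv")
    report["artifacts"]["jaccard_similarity"] = "jaccard_similarity.tsv"
    ranks = taxa.delineate_ranks(sim, config.species_thr, config.genus_thr)
    for rank, scheme in ranks.items():
        scheme.to_tsv(out / f"rank_{rank}.tsv")
        report[f"n_{rank}"] = len(scheme.partition())
        report[f"{rank}_assignment"] = dict(scheme.assignment)

    # 5. core-genome tree with resampling support
    by_id = {c.cluster_id: c for c in clusters}
    core = [by_id[c] for c in core_ids]
    tree = stage("core_tree")(
        lambda: phylo.resample_support(
            core, proteins, n_reps=config.reps, seed=config.seed,
            genomes=sorted(genome_ids),
        )
    )
    phylo.write_newick(tree, out / "core_tree.nwk")
    report["artifacts"]["core_tree"] = "core_tree.nwk"

    clade_scheme = _clades_from_tree(tree)
    clade_scheme.to_tsv(out / "rank_clade.tsv")
    report["clade_assignment"] = dict(clade_scheme.assignment)
    clade_sets = {t: sorted(m) for t, m in clade_scheme.taxa().items()}
    report["clades"] = clade_sets

    # clade bipartition supports
    supports = {}
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.parent_node is not None and node.label:
            below = sorted(lf.taxon.label for lf in node.leaf_iter())
            supports["|".join(below)] = float(node.label)
    report["bipartition_support"] = supports

    # 6. clade signature clusters (both directions)
    if len(clade_sets) == 2:
        (na, ma), (nb, mb) = sorted(clade_sets.items())
        report["signature_clusters"] = {
            na: sorted(pangenome.signature_clusters(pa, set(ma), set(mb))),
            nb: sorted(pangenome.signature_clusters(pa, set(mb), set(ma))),
        }

    # 7. marker trees and congruence
    universal = {c.cluster_id for c in core}
    markers = {}
    for want in config.marker_labels:
        hit = next(
            (c for c in core if c.label and want.lower() in c.label.lower()), None
        )
        if hit is not None:
            markers[want] = hit
    if not markers and core:
        markers = {core[0].label or core[0].cluster_id: core[0]}
    congruence = {}
    for name, cl in markers.items():
        mtree = phylo.marker_tree(cl, proteins, genomes=sorted(genome_ids))
        fname = f"marker_{name.replace(' ', '_')}.nwk"
        phylo.write_newick(mtree, out / fname)
        report["artifacts"][f"marker_tree:{name}"] = fname
        congruence[name] = {
            "cluster_id": cl.cluster_id,
            "rf_distance": phylo.rf_distance(tree, mtree),
            "shared_bipartition_fraction": phylo.shared_bipartitions(tree, mtree),
        }
    report["marker_congruence"] = congruence

    # 8. metadata concordance
    if metadata is not None:
        try:
            report["clade_metadata_concordance"] = clade_metadata_concordance(
                clade_scheme, metadata, "year"
            )
        except ValueError:
            pass

    write_json(report, out / "report.json")
    report["artifacts"]["report"] = "report.json"
    return report
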