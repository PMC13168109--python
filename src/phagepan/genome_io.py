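"""Core record types and on-disk formats.

Reads and writes every artifact the pipeline touches: nucleotide and protein
FASTA, GenBank flat files (CDS extraction and translation, table 11), labeled
numeric matrices as TSV, and metadata tables.

Conventions
-----------
* Coordinates are 1-based inclusive throughout (GenBank convention).
* Translation uses NCBI table 11 (bacterial/plastid); an annotated alternative
  start codon (GTG/TTG) is rendered as M.
* Genomes may contain N; alignment code treats N as mismatching everything.
* Protein FASTA headers use the ``genomeID|geneID`` dialect so that the genome
  of origin is an unambiguous join key for presence/absence analysis.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeRecord",
    "ProteinRecord",
    "MetadataTable",
    "SimilarityMatrix",
    "read_fasta",
    "write_fasta",
    "read_protein_fasta",
    "write_protein_fasta",
    "read_genbank_cds",
    "translate_cds",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

_DNA_ALPHABET = frozenset("ACGTN")
_START_CODONS = ("ATG", "GTG", "TTG")


@dataclass
class GenomeRecord:
    """One phage genome: identifier, nucleotide sequence and metadata."""

    genome_id: str
    sequence: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be nonempty")
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id!r}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence, start=1) if c in bad
            )
            raise ValueError(
                f"genome {self.genome_id!r}: illegal character "
                f"{self.sequence[pos - 1]!r} at position {pos}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    """One predicted protein and its (optional) coordinates on the genome.

    ``start``/``end`` are 1-based inclusive on the forward strand of the
    parent genome; they are ``None`` when the protein came from a bare FASTA
    file with no positional information.  ``has_internal_stop`` flags records
    whose conceptual translation contained an internal stop; such records are
    excluded from clustering.
    """

    genome_id: str
    gene_id: str
    aa_sequence: str
    start: int | None = None
    end: int | None = None
    strand: str = "+"
    label: str | None = None
    has_internal_stop: bool = False

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValueError(
                f"protein {self.genome_id}|{self.gene_id}: empty sequence"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start is not None and self.end is not None and self.end < self.start:
            raise ValueError(
                f"protein {self.genome_id}|{self.gene_id}: end < start"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.genome_id, self.gene_id)


class MetadataTable:
    """Per-genome metadata (year, tissue, cultivar, optional clade label)."""

    COLUMNS = ("year", "tissue", "cultivar", "clade")

    def __init__(self, df: pd.DataFrame):
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate genome_id in metadata: {dups}")
        self.df = df

    @classmethod
    def from_records(cls, rows: Mapping[str, Mapping]) -> "MetadataTable":
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "genome_id"
        return cls(df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetadataTable":
        df = pd.read_csv(path, sep="\t", index_col="genome_id")
        if "year" in df.columns:
            bad = df["year"].dropna().astype(int)
            if ((bad < 1000) | (bad > 9999)).any():
                raise ValueError("year must be a 4-digit integer")
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t")

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.df.index

    def year(self, genome_id: str) -> int:
        return int(self.df.loc[genome_id, "year"])


class SimilarityMatrix:
    """Symmetric genome x genome matrix of percent similarity in [0, 100]."""

    def __init__(self, df: pd.DataFrame):
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        v = df.to_numpy(dtype=float)
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 100.0, atol=1e-8):
            raise ValueError("diagonal must be 100")
        if v.min() < -1e-9 or v.max() > 100 + 1e-9:
            raise ValueError("entries must lie in [0, 100]")
        self.df = df.astype(float)

    @property
    def labels(self) -> list[str]:
        return list(self.df.index)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.df.loc[i, j])

    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def to_distance(self) -> pd.DataFrame:
        """Distance = 100 - similarity."""
        return 100.0 - self.df

    def to_tsv(self, path: str | Path) -> None:
        write_matrix_tsv(self.df, path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        return cls(read_matrix_tsv(path))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read nucleotide FASTA into :class:`GenomeRecord` objects.

    Header token up to the first whitespace becomes the genome id; sequences
    are uppercased; characters outside ``{A,C,G,T,N}`` are rejected with the
    offending record and position named.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = rec.id
        if gid in seen:
            raise ValueError(f"duplicate identifier {gid!r} in {path}")
        seen.add(gid)
        records.append(GenomeRecord(gid, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.genome_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA with ``genomeID|geneID`` headers.

    The description after the id, if any, is carried as the annotation label.
    """
    out: list[ProteinRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(
                f"protein header {rec.id!r} lacks 'genomeID|geneID' form"
            )
        gid, gene = rec.id.split("|", 1)
        if (gid, gene) in seen:
            raise ValueError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add((gid, gene))
        desc = rec.description.partition(" ")[2].strip() or None
        out.append(
            ProteinRecord(gid, gene, str(rec.seq).upper(), label=desc)
        )
    if not out:
        raise ValueError(f"no records in {path}")
    return out


def write_protein_fasta(proteins: Iterable[ProteinRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            label = f" {p.label}" if p.label else ""
            fh.write(f">{p.genome_id}|{p.gene_id}{label}\n")
            for i in range(0, len(p.aa_sequence), width):
                fh.write(p.aa_sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank / translation


def translate_cds(nt: str, table: int = 11) -> str:
    """Translate an in-frame CDS with the given NCBI table.

    A trailing stop is dropped; an annotated alternative start (GTG/TTG) is
    rendered as M.  Internal stops are left as ``*`` for the caller to flag.
    """
    nt = nt.upper()
    aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if aa and nt[:3] in _START_CODONS:
        aa = "M" + aa[1:]
    return aa


def read_genbank_cds(path: str | Path) -> list[ProteinRecord]:
    """Extract one :class:`ProteinRecord` per CDS feature of a GenBank file.

    A ``/translation`` qualifier is used verbatim when present; otherwise the
    CDS is translated with table 11 (join/complement locations supported).
    Records whose conceptual translation contains an internal stop are flagged
    (``has_internal_stop``) with a warning and later excluded from clustering.
    """
    out: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        gid = rec.id if rec.id and rec.id != "<unknown id>" else rec.name
        n = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n += 1
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
            if start < 1 or end > len(rec.seq):
                raise ValueError(
                    f"{gid}: CDS coordinates {start}..{end} outside sequence "
                    f"of length {len(rec.seq)}"
                )
            strand = "-" if feat.location.strand == -1 else "+"
            gene = (
                feat.qualifiers.get("locus_tag", [None])[0]
                or feat.qualifiers.get("protein_id", [None])[0]
                or f"CDS_{n:04d}"
            )
            label = feat.qualifiers.get("product", [None])[0]
            if "translation" in feat.qualifiers:
                aa = feat.qualifiers["translation"][0]
            else:
                aa = translate_cds(str(feat.extract(rec.seq)))
            flagged = "*" in aa
            if flagged:
                warnings.warn(
                    f"{gid}|{gene}: internal stop in conceptual translation; "
                    "record flagged and excluded from clustering"
                )
            out.append(
                ProteinRecord(
                    gid, gene, aa, start=start, end=end, strand=strand,
                    label=label, has_internal_stop=flagged,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Labeled matrix TSV (fixed 4-decimal serialization, strict round-trip)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled numeric matrix; values at fixed 4-decimal precision."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([""] + [str(c) for c in df.columns])
        for label, row in zip(df.index, df.to_numpy()):
            w.writerow([str(label)] + [f"{v:.4f}" for v in row])


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a labeled numeric matrix written by :func:`write_matrix_tsv`."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0][1:]
    ncol = len(header)
    labels: list[str] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) - 1 != ncol:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row) - 1} cells, expected {ncol})"
            )
        labels.append(row[0])
        vals = []
        for col, cell in zip(header, row[1:]):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {row[0]!r}, "
                    f"column {col!r}: {cell!r}"
                ) from None
        data.append(vals)
    return pd.DataFrame(data, index=labels, columns=header)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
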