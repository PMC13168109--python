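"""Synthetic phage-community generator with known truth.

Emulates a set of ~45 kb tailed-phage genomes structured into clades: a root
ancestor carries a conserved set of core gene families; each clade ancestor
derives from it by substitution, carries additional clade-exclusive
(signature) families, and each genome derives from its clade ancestor with
further substitutions plus sporadic accessory families.  Genomes are
assembled as ordered genes separated by (likewise inherited) intergenic
spacers, and the emitted protein complement is exactly the table-11
translation of the emitted CDS regions.

Divergence semantics: the configured ``within_clade_sub_rate`` and
``between_clade_sub_rate`` are target *pairwise* per-site substitution
divergences — each genome mutates at within/2 from its clade ancestor and
each clade ancestor at (between - within)/2 from the root, so realized
pairwise Hamming divergence over shared sequence matches the configured
value up to binomial noise (and the tiny correction for coincident hits).
The substitution model is substitution-only (no indels), keeping the
divergence arithmetic exact for oracles; mutations that would create an
internal stop codon are redrawn to a different base at the same site,
preserving per-site divergence.

Total intergenomic divergence additionally includes the clade-exclusive and
accessory gene content, which is unaligned sequence.  The default
configuration plants two temporally distinct clades (9 "late" genomes,
years 2021-2022, with 3 signature families; 6 "early" genomes, years
1987-2013, with 4) and 63 universal core families, with substitution rates
(0.5% within, 2.5% between) and short signature/accessory genes sized so
that the realized intergenomic similarity is >99% within clades and ~96%
between them — i.e. all genomes remain one species at the 95% demarcation
while every clade-exclusive family splits out at the 70% protein identity
threshold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (
    GenomeRecord,
    MetadataTable,
    ProteinRecord,
    translate_cds,
    write_fasta,
    write_protein_fasta,
)
from .intergenomic import revcomp

__all__ = ["CommunityConfig", "CommunityTruth", "generate_community", "mutate_sequence"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]
_FUNCTIONS = [
    "terminase large subunit",
    "portal protein",
    "major capsid protein",
    "tail sheath protein",
    "tail tube protein",
    "baseplate wedge subunit",
    "tail fiber protein",
    "DNA polymerase",
    "DNA helicase",
    "DNA primase",
    "endolysin",
    "holin",
    "tail length tape measure protein",
    "head-tail adaptor",
    "virion structural protein",
]


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of the planted community (defaults: the study conditions)."""

    n_clades: int = 2
    genomes_per_clade: tuple[int, ...] = (9, 6)
    n_core_families: int = 63
    n_signature_families: tuple[int, ...] = (3, 4)
    n_accessory_families: int = 3
    accessory_rate: float = 0.10
    gene_length_aa: tuple[int, int] = (160, 260)
    signature_length_aa: tuple[int, int] = (45, 65)
    accessory_length_aa: tuple[int, int] = (35, 55)
    intergenic_bp: tuple[int, int] = (2, 60)
    within_clade_sub_rate: float = 0.005
    between_clade_sub_rate: float = 0.02
    paralog_rate: float = 0.0
    discordant_families: int = 0
    discordant_genomes: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_clades < 1 or len(self.genomes_per_clade) != self.n_clades:
            raise ValueError("genomes_per_clade must list one count per clade")
        if len(self.n_signature_families) != self.n_clades:
            raise ValueError("n_signature_families must list one count per clade")
        if min(self.genomes_per_clade) < 1 or self.n_core_families < 1:
            raise ValueError("counts must be positive")
        if min(self.n_signature_families) < 0 or self.n_accessory_families < 0:
            raise ValueError("family counts must be non-negative")
        for r in (self.within_clade_sub_rate, self.between_clade_sub_rate,
                  self.accessory_rate, self.paralog_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        if self.between_clade_sub_rate < self.within_clade_sub_rate:
            raise ValueError("between-clade rate must be >= within-clade rate")
        for rng_name in ("gene_length_aa", "signature_length_aa", "accessory_length_aa"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid {rng_name} range")
        if not (0 < self.intergenic_bp[0] <= self.intergenic_bp[1]):
            raise ValueError("invalid intergenic_bp range")
        if self.discordant_families > self.n_core_families:
            raise ValueError("discordant families exceed core families")
        # a genome cannot carry more gene content than a phage-sized capsid;
        # refuse configs whose expected length strays wildly from plausibility
        mean_gene = 3 * (sum(self.gene_length_aa) / 2 + 1)
        n_genes = self.n_core_families + max(self.n_signature_families)
        if mean_gene * n_genes > 500_000:
            raise ValueError("configured gene content exceeds genome capacity")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CommunityConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for k in ("genomes_per_clade", "n_signature_families", "gene_length_aa",
                  "signature_length_aa", "accessory_length_aa", "intergenic_bp"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


@dataclass
class CommunityTruth:
    """Ground truth emitted alongside the community."""

    clades: dict[str, str]
    families: dict[str, dict]
    expected_divergence: dict[str, float]
    config: dict = field(default_factory=dict)

    def clade_partition(self) -> set[frozenset[str]]:
        out: dict[str, set[str]] = {}
        for g, c in self.clades.items():
            out.setdefault(c, set()).add(g)
        return {frozenset(v) for v in out.values()}

    def signature_families(self, clade: str) -> set[str]:
        return {
            f for f, info in self.families.items()
            if info["type"] == "signature" and info["clade"] == clade
        }

    def core_families(self) -> set[str]:
        return {f for f, info in self.families.items() if info["type"] == "core"}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CommunityTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


# ---------------------------------------------------------------------------
# Mutation primitives


def mutate_sequence(s: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. per-site substitution to a uniformly chosen different base.

    Length-preserving; positions holding N are left untouched.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero((rng.random(len(arr)) < rate) & (arr != ord("N")))
    if hits.size:
        idx = np.searchsorted(_BASES, arr[hits])
        offsets = rng.integers(1, 4, size=hits.size)
        arr[hits] = _BASES[(idx + offsets) % 4]
    return arr.tobytes().decode("ascii")


def _mutate_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Mutate a CDS without creating internal stops or destroying the stop.

    A substitution that would create an internal stop codon (or turn the
    terminal stop into a sense codon) is redrawn to a different base at the
    same site; in the rare case where no alternative works it is reverted.
    """
    mutated = list(mutate_sequence(cds, rate, rng))
    n_codons = len(cds) // 3
    for ci in range(1, n_codons):
        off = 3 * ci
        codon = "".join(mutated[off : off + 3])
        original = cds[off : off + 3]
        if codon == original:
            continue
        changed = [k for k in range(3) if codon[k] != original[k]]
        is_last = ci == n_codons - 1
        bad = (codon in _STOPS) if not is_last else (codon not in _STOPS)
        if not bad:
            continue
        fixed = False
        for k in changed:
            for alt in "ACGT":
                if alt in (original[k], codon[k]):
                    continue
                trial = codon[:k] + alt + codon[k + 1 :]
                ok = (trial not in _STOPS) if not is_last else (trial in _STOPS)
                if ok and trial != original:
                    mutated[off + k] = alt
                    codon = trial
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            mutated[off : off + 3] = list(original)
    return "".join(mutated)


def _compose_divergence(branches: list[float]) -> float:
    """Expected pairwise difference along a path of substitution branches.

    Uniform 4-base substitution: two difference probabilities compose as
    p o q = p + q - (4/3) p q.
    """
    d = 0.0
    for p in branches:
        d = d + p - (4.0 / 3.0) * d * p
    return d


def _random_cds(aa_len: int, rng: np.random.Generator) -> str:
    body = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=aa_len - 1)
    )
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Community generation


def _clade_names_and_years(config: CommunityConfig, rng: np.random.Generator):
    if config.n_clades == 2 and config.genomes_per_clade == (9, 6):
        names = ["clade_2021_2022", "clade_1987_2013"]
        years = [
            [2021, 2021, 2022, 2022, 2022, 2022, 2022, 2022, 2022],
            [1987, 1987, 2012, 2012, 2013, 2013],
        ]
    else:
        names = [f"clade_{i + 1}" for i in range(config.n_clades)]
        base = 1987
        years = [
            [base + 10 * i + int(rng.integers(0, 3)) for _ in range(n)]
            for i, n in enumerate(config.genomes_per_clade)
        ]
    return names, years


def generate_community(config: CommunityConfig, out_dir: str | Path | None = None):
    """Generate a community; returns (genomes, proteins, metadata, truth).

    When ``out_dir`` is given, also writes ``genomes.fasta``, ``proteins.faa``,
    ``metadata.tsv``, ``truth.json`` and ``config.json`` there.  Identical
    seeds give byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    half_within = config.within_clade_sub_rate / 2.0
    half_between = (config.between_clade_sub_rate - config.within_clade_sub_rate) / 2.0

    clade_names, clade_years = _clade_names_and_years(config, rng)

    # --- family roots -----------------------------------------------------
    length_ranges = {
        "core": config.gene_length_aa,
        "signature": config.signature_length_aa,
        "accessory": config.accessory_length_aa,
    }
    families: dict[str, dict] = {}
    fam_root: dict[str, str] = {}
    fam_order: list[str] = []

    def add_family(fid: str, ftype: str, label: str, clade: str | None = None):
        lo, hi = length_ranges[ftype]
        aa_len = int(rng.integers(lo, hi + 1))
        fam_root[fid] = _random_cds(aa_len, rng)
        families[fid] = {"type": ftype, "label": label, "clade": clade,
                         "genomes": [], "genes": {}}
        fam_order.append(fid)

    n_hyp = 0
    for i in range(config.n_core_families):
        if i < len(_FUNCTIONS):
            label = _FUNCTIONS[i]
        elif rng.random() < 0.35:
            n_hyp += 1
            label = "hypothetical protein"
        else:
            label = f"putative protein family {i + 1}"
        add_family(f"core{i + 1:03d}", "core", label)
    for ci, nsig in enumerate(config.n_signature_families):
        for j in range(nsig):
            label = "homing endonuclease" if j % 2 == 0 else "hypothetical protein"
            add_family(f"sig_{clade_names[ci]}_{j + 1}", "signature", label,
                       clade=clade_names[ci])
    for j in range(config.n_accessory_families):
        add_family(f"acc{j + 1:02d}", "accessory", "hypothetical protein")

    # --- clade-level variants --------------------------------------------
    fam_clade_variant: dict[tuple[str, str], str] = {}
    spacer_root: dict[str, str] = {}
    spacer_clade_variant: dict[tuple[str, str], str] = {}
    s_lo, s_hi = config.intergenic_bp
    for fid in fam_order:
        spacer_root[fid] = _random_dna(int(rng.integers(s_lo, s_hi + 1)), rng)
    for cname in clade_names:
        for fid in fam_order:
            fam_clade_variant[(cname, fid)] = _mutate_cds(
                fam_root[fid], half_between, rng
            )
            spacer_clade_variant[(cname, fid)] = mutate_sequence(
                spacer_root[fid], half_between, rng
            )

    # simulated transfer: the first `discordant_families` core families of the
    # first `discordant_genomes` genomes of clade 0 inherit clade 1's variant
    discordant_fams = [f"core{i + 1:03d}" for i in range(config.discordant_families)]
    fam_index = {fid: i for i, fid in enumerate(fam_order)}

    # --- per-genome content and assembly ----------------------------------
    genomes: list[GenomeRecord] = []
    proteins: list[ProteinRecord] = []
    meta_rows: dict[str, dict] = {}
    clades: dict[str, str] = {}
    gnum = 0
    tissues = ("Leaf", "Stem")
    cultivars = ("O'Henry", "Norman", "Contender", "Winblo", "Carored")
    genome_clade_idx: dict[str, int] = {}

    for ci, (cname, n_genomes) in enumerate(zip(clade_names, config.genomes_per_clade)):
        for gi in range(n_genomes):
            gnum += 1
            gid = f"SynPhi{gnum:02d}"
            clades[gid] = cname
            genome_clade_idx[gid] = ci
            meta_rows[gid] = {
                "year": clade_years[ci][gi],
                "tissue": tissues[int(rng.integers(0, len(tissues)))],
                "cultivar": cultivars[int(rng.integers(0, len(cultivars)))],
                "clade": cname,
            }
            content: list[str] = []
            for fid in fam_order:
                info = families[fid]
                if info["type"] == "core":
                    content.append(fid)
                elif info["type"] == "signature":
                    if info["clade"] == cname:
                        content.append(fid)
                elif rng.random() < config.accessory_rate:
                    content.append(fid)

            parts: list[str] = []
            pos = 0
            for idx, fid in enumerate(content):
                source_clade = cname
                if (
                    fid in discordant_fams
                    and ci == 0
                    and gi < config.discordant_genomes
                    and config.n_clades > 1
                ):
                    source_clade = clade_names[1]
                spacer = mutate_sequence(
                    spacer_clade_variant[(cname, fid)], half_within, rng
                )
                cds = _mutate_cds(
                    fam_clade_variant[(source_clade, fid)], half_within, rng
                )
                n_copies = 2 if rng.random() < config.paralog_rate else 1
                parts.append(spacer)
                pos += len(spacer)
                for copy in range(n_copies):
                    strand = "-" if fam_index[fid] % 6 == 5 else "+"
                    start = pos + 1
                    end = pos + len(cds)
                    parts.append(cds if strand == "+" else revcomp(cds))
                    pos = end
                    gene_id = fid if copy == 0 else f"{fid}_p2"
                    aa = translate_cds(cds)
                    proteins.append(
                        ProteinRecord(
                            gid, gene_id, aa, start=start, end=end,
                            strand=strand, label=families[fid]["label"],
                        )
                    )
                    families[fid]["genes"].setdefault(gid, []).append(gene_id)
                if gid not in families[fid]["genomes"]:
                    families[fid]["genomes"].append(gid)
            genomes.append(GenomeRecord(gid, "".join(parts), dict(meta_rows[gid])))

    # drop accessory families that ended up with no member
    for fid in list(families):
        if not families[fid]["genomes"]:
            del families[fid]

    # --- expected pairwise divergence --------------------------------------
    expected: dict[str, float] = {}
    ids = [g.genome_id for g in genomes]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            if genome_clade_idx[a] == genome_clade_idx[b]:
                branches = [half_within, half_within]
            else:
                branches = [half_within, half_between, half_between, half_within]
            expected[f"{a}|{b}"] = _compose_divergence(branches)

    metadata = MetadataTable.from_records(meta_rows)
    truth = CommunityTruth(
        clades=clades,
        families=families,
        expected_divergence=expected,
        config=dataclasses.asdict(config),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genomes, out / "genomes.fasta")
        write_protein_fasta(proteins, out / "proteins.faa")
        metadata.to_tsv(out / "metadata.tsv")
        truth.to_json(out / "truth.json")
        config.to_json(out / "config.json")
    return genomes, proteins, metadata, truth
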