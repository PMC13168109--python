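#!/usr/bin/env python
"""Fetch the deposited Xap-phage genomes from NCBI (network required).

Downloads the 15 GenBank accessions into ``data/deposited/`` as
``xap_genomes.fasta`` (nucleotide) and ``xap_genomes.gbff`` (GenBank flat
file with CDS features), which is what the deposited-data acceptance tests
read.  The 45-genome comparative set additionally needs
``family45_proteins.faa`` ("genomeID|geneID" headers) and
``family45_grouping.tsv`` (columns: genome_id, genus, subfamily) assembled
from the ICTV Virus Metadata Resource; those accessions are not scripted
here.

Usage:  python scripts/fetch_deposited.py [--out data/deposited]
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSIONS = [
    "PP391659", "PP391660", "PP391661", "PP391662", "PP391663", "PP391664",
    "PX630731", "PX630732", "PX630733", "PX630734", "PX630735", "PX630736",
    "PX630737", "PX630738", "PX630739",
]

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def efetch(ids: list[str], rettype: str) -> str:
    params = urllib.parse.urlencode(
        {"db": "nuccore", "id": ",".join(ids), "rettype": rettype, "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=120) as resp:
        return resp.read().decode()


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("data/deposited"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fasta_chunks, gb_chunks = [], []
    for i in range(0, len(ACCESSIONS), 5):
        batch = ACCESSIONS[i : i + 5]
        fasta_chunks.append(efetch(batch, "fasta"))
        time.sleep(0.5)  # NCBI rate limit
        gb_chunks.append(efetch(batch, "gbwithparts"))
        time.sleep(0.5)

    fasta = "".join(fasta_chunks)
    # strip version suffixes so ids match the bare accessions
    fasta = "\n".join(
        f">{line[1:].split()[0].split('.')[0]}" if line.startswith(">") else line
        for line in fasta.splitlines()
    )
    (args.out / "xap_genomes.fasta").write_text(fasta + "\n")
    (args.out / "xap_genomes.gbff").write_text("".join(gb_chunks))
    print(f"wrote {len(ACCESSIONS)} genomes to {args.out}")


if __name__ == "__main__":
    main()
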