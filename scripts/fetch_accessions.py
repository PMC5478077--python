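#!/usr/bin/env python
"""Fetch the eleven study mitogenomes from GenBank (network required).

Downloads each accession's GenBank record via NCBI efetch, writes the
sequence as FASTA and the annotation as the package's simplified feature
table under ``data/accessions/``.  The repository deliberately ships no
sequence data; run this once before executing the published-number
acceptance tests:

    python scripts/fetch_accessions.py
"""

from __future__ import annotations

import io
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

from Bio import SeqIO

ACCESSIONS = [
    "KM504390.1", "DQ355300.1", "JQ821835.1", "JQ821836.1", "HM125579.1",
    "JQ821838.1", "HM125578.1", "JF293094.1", "JQ821840.1", "HQ149047.1",
    "DQ355299.1",
]

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

# normalize the various CDS gene spellings to the package's symbols
_GENE_ALIASES = {
    "COI": "COX1", "COII": "COX2", "COIII": "COX3", "CO1": "COX1",
    "CO2": "COX2", "CO3": "COX3", "COXI": "COX1", "COXII": "COX2",
    "COXIII": "COX3", "CYTB": "CYTB", "COB": "CYTB", "ATPASE6": "ATP6",
    "ATPASE8": "ATP8", "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3",
    "NAD4": "ND4", "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
}


def _fetch(acc: str) -> str:
    params = urllib.parse.urlencode({
        "db": "nuccore", "id": acc, "rettype": "gbwithparts",
        "retmode": "text"})
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=60) as resp:
        return resp.read().decode()


def _gene_name(feature, counters: dict) -> str:
    quals = feature.qualifiers
    name = (quals.get("gene") or quals.get("product") or ["?"])[0]
    upper = name.upper().replace(" ", "").replace("-", "")
    if feature.type == "CDS":
        return _GENE_ALIASES.get(upper, upper)
    if feature.type == "tRNA":
        counters["trna"] = counters.get("trna", 0) + 1
        return f"trn{counters['trna']}_{name.replace(' ', '_')}"
    if feature.type == "rRNA":
        return "rrn12" if "12" in name else "rrn16"
    return name.replace(" ", "_")


def convert(gb_text: str) -> tuple[str, str]:
    """GenBank flat file -> (FASTA text, simplified feature-table text)."""
    rec = SeqIO.read(io.StringIO(gb_text), "genbank")
    seq = str(rec.seq).upper()
    lines = ["#ftype\tname\tspan\tstrand\tcodon_start\ttransl_table"]
    counters: dict = {}
    seen: set = set()
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature"):
            continue
        ftype = feat.type
        if ftype in ("D-loop", "misc_feature"):
            text = str(feat.qualifiers.get("note", [""])[0]).lower()
            if ftype == "misc_feature" and "control" not in text \
                    and "d-loop" not in text:
                continue
            ftype = "control_region"
            name = "CR"
        else:
            name = _gene_name(feat, counters)
        if name in seen:
            continue
        seen.add(name)
        start = int(feat.location.start) + 1     # back to 1-based inclusive
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        codon_start = int(feat.qualifiers.get("codon_start", ["1"])[0])
        table = int(feat.qualifiers.get("transl_table", ["2"])[0])
        lines.append(f"{ftype}\t{name}\t{start}..{end}\t{strand}"
                     f"\t{codon_start}\t{table}")
    fasta = [f">{rec.id}"]
    for i in range(0, len(seq), 70):
        fasta.append(seq[i:i + 70])
    return "\n".join(fasta) + "\n", "\n".join(lines) + "\n"


def main() -> int:
    outdir = Path(__file__).resolve().parent.parent / "data" / "accessions"
    outdir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        fasta_path = outdir / f"{acc}.fa"
        if fasta_path.exists():
            print(f"{acc}: already present, skipping")
            continue
        print(f"fetching {acc} ...")
        fasta, table = convert(_fetch(acc))
        fasta_path.write_text(fasta)
        (outdir / f"{acc}.ft.tsv").write_text(table)
        time.sleep(0.4)   # NCBI rate courtesy
    print(f"done; genomes in {outdir}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
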