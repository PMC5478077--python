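"""Sequence, annotation and read I/O plus the core genome data model.

File formats handled here:

* FASTA (one genome per file, written uppercase at 70 columns),
* FASTQ with Phred+33 qualities,
* a simplified tab-separated feature table
  (``ftype<TAB>name<TAB>span<TAB>strand[<TAB>codon_start[<TAB>transl_table]]``
  with 1-based inclusive spans like ``1..1100``; origin-spanning features on
  circular genomes use a span whose end is numerically smaller than its
  start and are stored unrolled past the sequence length),
* Newick (delegated to :mod:`mitochron.phylo`).

Internally all coordinates are 0-based half-open; conversion to and from
the 1-based inclusive convention of the feature table happens only at the
I/O boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

from .phylo import PhyloTree, parse_newick, write_newick

__all__ = [
    "Feature", "GenomeRecord", "QualityRead",
    "parse_genome", "parse_feature_table", "parse_fasta", "write_fasta",
    "write_feature_table", "parse_fastq", "write_fastq",
    "write_newick", "parse_newick",
]

FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "control_region", "other_noncoding"}
_STRICT_ALPHABET = set("ACGTN")
_IUPAC_ALPHABET = set("ACGTNRYSWKMBDHV")


@dataclass
class Feature:
    """One annotated region of a mitogenome.

    Coordinates are 0-based half-open on the genome; for origin-spanning
    features on a circular genome ``end`` may exceed the sequence length
    (the feature is stored unrolled) — use :meth:`segments` for in-range
    spans.  ``codon_start`` is the 0-2 phase offset of the first complete
    codon; ``transl_table`` the NCBI genetic-code id (2 = vertebrate
    mitochondrial).
    """

    name: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    codon_start: int = 0
    transl_table: int = 2

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.start >= self.end:
            raise ValueError(f"{self.name}: empty span {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: bad strand {self.strand!r}")
        if not 0 <= self.codon_start <= 2:
            raise ValueError(f"{self.name}: codon_start {self.codon_start}")
        if self.ftype == "CDS" and (self.end - self.start - self.codon_start) < 3:
            raise ValueError(f"{self.name}: CDS shorter than one codon")

    def __len__(self) -> int:
        return self.end - self.start

    def segments(self, genome_length: int) -> list[tuple[int, int]]:
        """In-range [start, end) spans; two segments if the feature wraps."""
        if self.end <= genome_length:
            return [(self.start, self.end)]
        return [(self.start, genome_length), (0, self.end - genome_length)]

    def contains(self, pos: int, genome_length: int) -> bool:
        return any(a <= pos < b for a, b in self.segments(genome_length))

    def extract(self, sequence: str) -> str:
        """Feature sequence in reading orientation (reverse-complemented on -)."""
        raw = "".join(sequence[a:b] for a, b in self.segments(len(sequence)))
        if self.strand == "-":
            raw = str(Seq(raw).reverse_complement())
        return raw


@dataclass
class GenomeRecord:
    """An annotated (usually circular) mitochondrial genome."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        self.sequence = self.sequence.upper()
        if not self.label:
            self.label = self.id

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.id}: no feature named {name!r}")

    def cds_features(self) -> list[Feature]:
        return [f for f in self.features if f.ftype == "CDS"]

    def feature_at(self, pos: int) -> Optional[Feature]:
        """First feature (in start order) covering a genome position."""
        for f in self.features:
            if f.contains(pos, len(self.sequence)):
                return f
        return None

    def rotated(self, offset: int) -> "GenomeRecord":
        """Genome rotated so old position `offset` becomes position 0."""
        n = len(self.sequence)
        if not self.circular and offset % n != 0:
            raise ValueError(f"{self.id}: cannot rotate a linear genome")
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            start = (f.start - offset) % n
            feats.append(replace(f, start=start, end=start + len(f)))
        feats.sort(key=lambda f: f.start)
        return GenomeRecord(self.id, seq, self.circular, feats, self.label)


@dataclass
class QualityRead:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"{self.id}: {len(self.bases)} bases but {len(self.quals)} quality scores")
        if self.quals and not all(0 <= q <= 93 for q in self.quals):
            raise ValueError(f"{self.id}: Phred score outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)


# ---------------------------------------------------------------------------
# Sequence validation


def _validate_alphabet(seq: str, rec_id: str, allow_ambiguity: bool) -> None:
    allowed = _IUPAC_ALPHABET if allow_ambiguity else _STRICT_ALPHABET
    bad = set(seq) - allowed
    if bad:
        raise ValueError(
            f"{rec_id}: disallowed characters {sorted(bad)}"
            + ("" if allow_ambiguity else " (pass allow_ambiguity=True for IUPAC codes)"))


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(text: str, allow_ambiguity: bool = False) -> list[tuple[str, str]]:
    """All (id, sequence) pairs from FASTA text, uppercased and validated."""
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        _validate_alphabet(seq, rec.id, allow_ambiguity)
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], width: int = 70) -> str:
    out = []
    for rec_id, seq in records:
        out.append(f">{rec_id}")
        seq = seq.upper()
        for i in range(0, len(seq), width):
            out.append(seq[i:i + width])
    return "\n".join(out) + "\n"


def write_genome_fasta(g: GenomeRecord, width: int = 70) -> str:
    return write_fasta([(g.id, g.sequence)], width=width)


# ---------------------------------------------------------------------------
# Feature table


def _span_to_internal(span: str, genome_length: int, circular: bool,
                      name: str) -> tuple[int, int]:
    """1-based inclusive 'a..b' → 0-based half-open; wrap → unrolled."""
    try:
        a_text, b_text = span.split("..")
        a, b = int(a_text), int(b_text)
    except ValueError as exc:
        raise ValueError(f"{name}: bad span {span!r}") from exc
    if a < 1 or b < 1:
        raise ValueError(f"{name}: coordinates are 1-based, got {span}")
    if b >= a:
        start, end = a - 1, b
    else:
        # origin-spanning feature, e.g. 16001..120 on a 16.5 kb circle
        if not circular:
            raise ValueError(f"{name}: span {span} wraps on a linear genome")
        start, end = a - 1, b + genome_length
    if end > genome_length and not circular:
        raise ValueError(f"{name}: span {span} exceeds linear genome length "
                         f"{genome_length}")
    if end > 2 * genome_length or start >= genome_length:
        raise ValueError(f"{name}: span {span} outside genome of length "
                         f"{genome_length}")
    return start, end


def _span_to_external(f: Feature, genome_length: int) -> str:
    if f.end <= genome_length:
        return f"{f.start + 1}..{f.end}"
    return f"{f.start + 1}..{f.end - genome_length}"


def parse_feature_table(text: str, genome_length: int,
                        circular: bool = True) -> list[Feature]:
    """Parse the simplified tab-separated feature table (see module docs)."""
    features: list[Feature] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"feature table line {lineno}: expected at least "
                             f"4 tab-separated fields, got {len(parts)}")
        ftype, name, span, strand = parts[:4]
        codon_start = int(parts[4]) - 1 if len(parts) > 4 and parts[4] else 0
        transl_table = int(parts[5]) if len(parts) > 5 and parts[5] else 2
        if name in seen:
            raise ValueError(f"duplicate gene name {name!r}")
        seen.add(name)
        start, end = _span_to_internal(span, genome_length, circular, name)
        features.append(Feature(name=name, ftype=ftype, start=start, end=end,
                                strand=strand, codon_start=codon_start,
                                transl_table=transl_table))
    features.sort(key=lambda f: f.start)
    return features


def write_feature_table(g: GenomeRecord) -> str:
    lines = ["#ftype\tname\tspan\tstrand\tcodon_start\ttransl_table"]
    for f in sorted(g.features, key=lambda f: f.start):
        lines.append("\t".join([
            f.ftype, f.name, _span_to_external(f, len(g.sequence)), f.strand,
            str(f.codon_start + 1), str(f.transl_table)]))
    return "\n".join(lines) + "\n"


def parse_genome(fasta_text: str, feature_table_text: str = "",
                 circular: bool = True, label: str = "",
                 allow_ambiguity: bool = False,
                 fill_unannotated: bool = False) -> GenomeRecord:
    """Build a :class:`GenomeRecord` from FASTA + feature-table text.

    The FASTA must contain exactly one record.  With ``fill_unannotated``
    every unannotated span is given an ``other_noncoding`` feature so that
    region breakdowns partition the genome.
    """
    records = parse_fasta(fasta_text, allow_ambiguity=allow_ambiguity)
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    rec_id, seq = records[0]
    features = parse_feature_table(feature_table_text, len(seq), circular)
    genome = GenomeRecord(id=rec_id, sequence=seq, circular=circular,
                          features=features, label=label or rec_id)
    if fill_unannotated:
        genome.features = _fill_unannotated(genome)
    return genome


def _fill_unannotated(g: GenomeRecord) -> list[Feature]:
    n = len(g.sequence)
    covered = [False] * n
    for f in g.features:
        for a, b in f.segments(n):
            for i in range(a, b):
                covered[i] = True
    feats = list(g.features)
    i, k = 0, 0
    while i < n:
        if not covered[i]:
            j = i
            while j < n and not covered[j]:
                j += 1
            k += 1
            feats.append(Feature(name=f"nc{k}", ftype="other_noncoding",
                                 start=i, end=j, strand="+"))
            i = j
        else:
            i += 1
    feats.sort(key=lambda f: f.start)
    return feats


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)


def parse_fastq(text: str) -> list[QualityRead]:
    """Parse Phred+33 FASTQ text into :class:`QualityRead` records."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator
    reads = []
    try:
        for title, bases, qual in FastqGeneralIterator(io.StringIO(text)):
            rec_id = title.split()[0]
            if len(bases) != len(qual):
                raise ValueError(f"{rec_id}: sequence length {len(bases)} != "
                                 f"quality length {len(qual)}")
            reads.append(QualityRead(id=rec_id, bases=bases.upper(),
                                     quals=[ord(c) - 33 for c in qual]))
    except ValueError as exc:
        # surface the offending record id for truncated/mismatched input
        last = reads[-1].id if reads else "<first record>"
        raise ValueError(f"FASTQ parse error after {last}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[QualityRead]) -> str:
    out = []
    for read in reads:
        out.append(f"@{read.id}")
        out.append(read.bases)
        out.append("+")
        out.append("".join(chr(q + 33) for q in read.quals))
    return "\n".join(out) + "\n" if out else ""
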