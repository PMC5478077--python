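"""Whole-mitogenome comparison: alignment, variant classification, summaries.

Two near-identical mitogenomes are compared by (1) rotating the query so
both circular sequences start at homologous positions, (2) computing a
deterministic global affine-gap alignment, and (3) classifying every
aligned difference as a transition, transversion, or indel event (one
event per maximal gap run, regardless of length).  Substitutions are
assigned to the annotated region (control region, CDS, tRNA, rRNA, other
noncoding) of the reference coordinate.

Multi-genome alignments use center-star merging of pairwise alignments
("once a gap, always a gap"), which is exact for the gap-sparse,
near-identical genomes this package targets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

from .seq_io import Feature, GenomeRecord

__all__ = [
    "PairwiseAlignment", "Variant", "VariantTable", "CompositionSummary",
    "DivergenceSummary", "MultipleAlignment", "align_pair",
    "rotate_to_reference", "classify_variants", "region_breakdown",
    "base_composition", "divergence_summary", "msa_center_star",
]

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_BASES = set("ACGT")

REGION_CLASSES = ("control_region", "CDS", "tRNA", "rRNA", "other_noncoding")


# ---------------------------------------------------------------------------
# Data types


@dataclass
class PairwiseAlignment:
    """A gapped global alignment of two genomes with coordinate maps."""

    ref_id: str
    qry_id: str
    ref_aln: str
    qry_aln: str
    column_to_ref: list[Optional[int]] = field(default_factory=list)
    column_to_qry: list[Optional[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.qry_aln):
            raise ValueError("gapped rows differ in length")
        if not self.column_to_ref:
            self.column_to_ref = _coordinate_map(self.ref_aln)
            self.column_to_qry = _coordinate_map(self.qry_aln)

    def __len__(self) -> int:
        return len(self.ref_aln)


def _coordinate_map(gapped: str) -> list[Optional[int]]:
    out: list[Optional[int]] = []
    i = 0
    for c in gapped:
        if c == "-":
            out.append(None)
        else:
            out.append(i)
            i += 1
    return out


@dataclass
class Variant:
    """One classified difference between reference and query."""

    ref_pos: int                    # 0-based reference coordinate
    ref_base: str                   # base, run of bases, or '-' for insertions
    alt_base: str
    vclass: str                     # transition | transversion | insertion | deletion
    region: Optional[tuple[str, str]] = None   # (feature name, ftype)
    codon_effect: Optional[dict] = None        # set by selection_scan

    @property
    def is_substitution(self) -> bool:
        return self.vclass in ("transition", "transversion")

    @property
    def direction(self) -> str:
        return f"{self.ref_base}->{self.alt_base}"


@dataclass
class VariantTable:
    """All classified differences of one genome pair, with count summaries."""

    ref_id: str
    qry_id: str
    variants: list[Variant]
    n_excluded_ambiguous: int = 0

    @property
    def substitutions(self) -> list[Variant]:
        return [v for v in self.variants if v.is_substitution]

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    @property
    def n_transitions(self) -> int:
        return sum(1 for v in self.variants if v.vclass == "transition")

    @property
    def n_transversions(self) -> int:
        return sum(1 for v in self.variants if v.vclass == "transversion")

    @property
    def n_indel_events(self) -> int:
        return sum(1 for v in self.variants if v.vclass in ("insertion", "deletion"))

    @property
    def n_variable_positions(self) -> int:
        """Substitution count plus indel events (each event counted once)."""
        return self.n_substitutions + self.n_indel_events

    @property
    def per_direction(self) -> Counter:
        return Counter(v.direction for v in self.substitutions)

    def to_tsv(self) -> str:
        lines = ["#ref_pos\tref\talt\tclass\tregion\tftype"]
        for v in self.variants:
            name, ftype = v.region if v.region else ("", "other_noncoding")
            lines.append(f"{v.ref_pos + 1}\t{v.ref_base}\t{v.alt_base}\t"
                         f"{v.vclass}\t{name}\t{ftype}")
        return "\n".join(lines) + "\n"


@dataclass
class CompositionSummary:
    genome_id: str
    pct_T: float
    pct_C: float
    pct_A: float
    pct_G: float
    total: int

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float, float]:
        return tuple(round(x, ndigits)
                     for x in (self.pct_T, self.pct_C, self.pct_A, self.pct_G))


@dataclass
class DivergenceSummary:
    pair: tuple[str, str]
    n_divergent: int        # mismatched aligned base columns
    pct_divergent: float    # percent of compared (both-base) columns
    n_gaps: int             # gap events (maximal runs)
    n_compared: int         # both-base columns entering the percent


@dataclass
class MultipleAlignment:
    """Rows of equal-length gapped sequences keyed by genome id."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("MSA rows differ in length")

    def __len__(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rec_id: str) -> str:
        return self.rows[self.ids.index(rec_id)]

    def complete_deletion_columns(self) -> list[int]:
        """Columns free of gaps and ambiguous bases in every row."""
        keep = []
        for j in range(len(self)):
            if all(r[j] in _BASES for r in self.rows):
                keep.append(j)
        return keep

    def complete_deletion(self) -> "MultipleAlignment":
        cols = self.complete_deletion_columns()
        rows = ["".join(r[j] for j in cols) for r in self.rows]
        return MultipleAlignment(list(self.ids), rows)

    def to_fasta(self) -> str:
        out = []
        for rec_id, row in zip(self.ids, self.rows):
            out.append(f">{rec_id}")
            for i in range(0, len(row), 70):
                out.append(row[i:i + 70])
        return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Alignment


def _make_aligner(match: float, mismatch: float, gap_open: float,
                  gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_pair(ref: GenomeRecord, qry: GenomeRecord, match: float = 1.0,
               mismatch: float = -2.0, gap_open: float = -5.0,
               gap_extend: float = -2.0) -> PairwiseAlignment:
    """Optimal global affine-gap alignment with deterministic traceback.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``.  Among co-optimal
    alignments the aligner's canonical first traceback is returned, so
    repeated runs give identical output.
    """
    if not ref.sequence or not qry.sequence:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    result = aligner.align(ref.sequence, qry.sequence)
    best = result[0]
    ref_aln, qry_aln = str(best[0]), str(best[1])
    return PairwiseAlignment(ref_id=ref.id, qry_id=qry.id,
                             ref_aln=ref_aln, qry_aln=qry_aln)


def alignment_score(aln: PairwiseAlignment, match: float = 1.0,
                    mismatch: float = -2.0, gap_open: float = -5.0,
                    gap_extend: float = -2.0) -> float:
    """Recompute the affine-gap score of an existing alignment."""
    score = 0.0
    prev_gap = None  # which side was gapped in the previous column
    for a, b in zip(aln.ref_aln, aln.qry_aln):
        if a == "-" or b == "-":
            side = "ref" if a == "-" else "qry"
            score += gap_extend if prev_gap == side else gap_open
            prev_gap = side
        else:
            score += match if a == b else mismatch
            prev_gap = None
    return score


def rotate_to_reference(ref: GenomeRecord, qry: GenomeRecord,
                        seed_length: int = 24, n_anchors: int = 32
                        ) -> GenomeRecord:
    """Rotate a circular query so it starts at the reference's start.

    Exact ``seed_length``-mers sampled along the reference are located in
    the doubled query; the modal implied rotation offset wins.  Robust to
    the percent-scale divergence typical of conspecific mitogenomes, since
    only a minority of anchors can span a mutation.
    """
    if not (ref.circular and qry.circular):
        raise ValueError("rotation requires circular genomes")
    n_ref, n_qry = len(ref.sequence), len(qry.sequence)
    if seed_length > n_qry:
        raise ValueError("seed longer than query")
    doubled = qry.sequence + qry.sequence[:seed_length]
    step = max(1, n_ref // n_anchors)
    votes: Counter = Counter()
    for p in range(0, n_ref - seed_length + 1, step):
        seed = ref.sequence[p:p + seed_length]
        idx = doubled.find(seed)
        while idx != -1 and idx < n_qry:
            votes[(idx - p) % n_qry] += 1
            idx = doubled.find(seed, idx + 1)
    if not votes:
        raise ValueError(
            f"no exact {seed_length}-mer anchor shared between {ref.id} and "
            f"{qry.id}; increase divergence tolerance or align in linear mode")
    offset = votes.most_common(1)[0][0]
    return qry.rotated(offset)


# ---------------------------------------------------------------------------
# Variant classification


def _substitution_class(a: str, b: str) -> str:
    return "transition" if frozenset((a, b)) in _TRANSITIONS else "transversion"


def classify_variants(aln: PairwiseAlignment,
                      ref_features: Optional[Sequence[Feature]] = None,
                      ref_length: Optional[int] = None) -> VariantTable:
    """Classify every aligned difference into a :class:`VariantTable`.

    Mismatching base columns become directed substitutions (reference to
    query orientation); each maximal run of gap columns on one side becomes
    a single insertion or deletion event.  Columns with N or another
    ambiguity code on either side are excluded from substitution counts and
    tallied in ``n_excluded_ambiguous``.
    """
    if ref_length is None:
        ref_length = sum(1 for c in aln.ref_aln if c != "-")
    features = list(ref_features) if ref_features else []

    def region_of(pos: int) -> Optional[tuple[str, str]]:
        for f in features:
            if f.contains(pos, ref_length):
                return (f.name, f.ftype)
        return None

    variants: list[Variant] = []
    excluded = 0
    n_cols = len(aln)
    j = 0
    last_ref_pos = -1
    while j < n_cols:
        a, b = aln.ref_aln[j], aln.qry_aln[j]
        if a != "-" and b != "-":
            ref_pos = aln.column_to_ref[j]
            last_ref_pos = ref_pos
            if a != b:
                if a in _BASES and b in _BASES:
                    variants.append(Variant(
                        ref_pos=ref_pos, ref_base=a, alt_base=b,
                        vclass=_substitution_class(a, b),
                        region=region_of(ref_pos)))
                else:
                    excluded += 1
            j += 1
            continue
        # maximal gap run on one side
        side = "ref" if a == "-" else "qry"
        start = j
        while j < n_cols and ((aln.ref_aln[j] == "-") if side == "ref"
                              else (aln.qry_aln[j] == "-")):
            j += 1
        ref_run = aln.ref_aln[start:j]
        qry_run = aln.qry_aln[start:j]
        if side == "ref":
            pos = last_ref_pos + 1      # insertion anchored after last ref base
            variants.append(Variant(ref_pos=pos, ref_base="-", alt_base=qry_run,
                                    vclass="insertion",
                                    region=region_of(min(pos, ref_length - 1))))
        else:
            pos = aln.column_to_ref[start]
            last_ref_pos = aln.column_to_ref[j - 1]
            variants.append(Variant(ref_pos=pos, ref_base=ref_run, alt_base="-",
                                    vclass="deletion", region=region_of(pos)))
    return VariantTable(ref_id=aln.ref_id, qry_id=aln.qry_id,
                        variants=variants, n_excluded_ambiguous=excluded)


def region_breakdown(vt: VariantTable, features: Sequence[Feature],
                     ref_length: Optional[int] = None
                     ) -> dict[str, tuple[int, float]]:
    """Partition substitutions among region classes with percents.

    Percents use the substitution count as denominator (indel events are
    excluded), so the values sum to 100 up to rounding.  A substitution
    covered by no feature counts as ``other_noncoding``.
    """
    if ref_length is None:
        ref_length = max((f.end for f in features), default=0)
    subs = vt.substitutions
    counts = Counter()
    for v in subs:
        ftype = None
        for f in features:
            if f.contains(v.ref_pos, ref_length):
                ftype = f.ftype
                break
        counts[ftype or "other_noncoding"] += 1
    denom = len(subs)
    out = {}
    for region in REGION_CLASSES:
        c = counts.get(region, 0)
        out[region] = (c, 100.0 * c / denom if denom else 0.0)
    return out


def base_composition(g: GenomeRecord) -> CompositionSummary:
    """Percentages of T, C, A, G over unambiguous positions."""
    counts = Counter(g.sequence)
    acgt = sum(counts[b] for b in "ACGT")
    if acgt == 0:
        raise ValueError(f"{g.id}: no unambiguous bases")
    pct = {b: 100.0 * counts[b] / acgt for b in "TCAG"}
    return CompositionSummary(genome_id=g.id, pct_T=pct["T"], pct_C=pct["C"],
                              pct_A=pct["A"], pct_G=pct["G"],
                              total=len(g.sequence))


def divergence_summary(aln: PairwiseAlignment) -> DivergenceSummary:
    """Divergent-base count, percent of compared columns, and gap events."""
    n_div = 0
    n_cmp = 0
    n_gap_events = 0
    in_gap = False
    for a, b in zip(aln.ref_aln, aln.qry_aln):
        if a == "-" or b == "-":
            if not in_gap:
                n_gap_events += 1
            in_gap = True
            continue
        in_gap = False
        if a in _BASES and b in _BASES:
            n_cmp += 1
            if a != b:
                n_div += 1
    pct = 100.0 * n_div / n_cmp if n_cmp else 0.0
    return DivergenceSummary(pair=(aln.ref_id, aln.qry_id), n_divergent=n_div,
                             pct_divergent=pct, n_gaps=n_gap_events,
                             n_compared=n_cmp)


# ---------------------------------------------------------------------------
# Center-star multiple alignment


def msa_center_star(genomes: Sequence[GenomeRecord], center: str,
                    divergence_cap: float = 0.30, rotate: bool = True,
                    **align_kwargs) -> MultipleAlignment:
    """Merge pairwise alignments to a center genome into one MSA.

    Every genome is aligned to the center; gap patterns are merged with
    the "once a gap, always a gap" rule.  Removing gaps from any output row
    reproduces the input sequence.  Pairs more divergent than
    ``divergence_cap`` only trigger a warning (center-star quality degrades
    with divergence).
    """
    if len(genomes) < 3:
        raise ValueError("need at least 3 genomes")
    by_id = {g.id: g for g in genomes}
    if center not in by_id:
        raise ValueError(f"center {center!r} not among genomes")
    center_g = by_id[center]
    others = [g for g in genomes if g.id != center]

    master = center_g.sequence          # center row with accumulated gaps
    rows: list[str] = []                # non-center rows, padded to master
    ids: list[str] = [center]

    import warnings
    for g in others:
        qry = g
        if rotate and g.circular and center_g.circular:
            qry = rotate_to_reference(center_g, g)
        aln = align_pair(center_g, qry, **align_kwargs)
        div = divergence_summary(aln)
        if div.n_compared and div.pct_divergent / 100.0 > divergence_cap:
            warnings.warn(f"{g.id} is {div.pct_divergent:.1f}% divergent from "
                          f"center {center}; center-star MSA may be poor")
        master, rows, new_row = _merge_into_master(master, rows, aln)
        rows.append(new_row)
        ids.append(g.id)
    return MultipleAlignment(ids=ids, rows=[master] + rows)


def _merge_into_master(master: str, rows: list[str], aln: PairwiseAlignment
                       ) -> tuple[str, list[str], str]:
    """Merge one center-vs-query alignment into the running master MSA."""
    c_aln, q_aln = aln.ref_aln, aln.qry_aln
    out_master: list[str] = []
    out_rows: list[list[str]] = [[] for _ in rows]
    out_q: list[str] = []
    i = j = 0
    while i < len(master) or j < len(c_aln):
        m_gap = i < len(master) and master[i] == "-"
        c_gap = j < len(c_aln) and c_aln[j] == "-"
        if i < len(master) and j < len(c_aln) and (m_gap == c_gap):
            # both advance: matching center base, or simultaneous gap columns
            out_master.append(master[i])
            for r, row in zip(out_rows, rows):
                r.append(row[i])
            out_q.append(q_aln[j])
            i += 1
            j += 1
        elif m_gap or j >= len(c_aln):
            # master-only gap column: query gets a gap here
            out_master.append(master[i])
            for r, row in zip(out_rows, rows):
                r.append(row[i])
            out_q.append("-")
            i += 1
        else:
            # new gap column introduced by this query
            out_master.append("-")
            for r in out_rows:
                r.append("-")
            out_q.append(q_aln[j])
            j += 1
    return ("".join(out_master), ["".join(r) for r in out_rows], "".join(out_q))
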