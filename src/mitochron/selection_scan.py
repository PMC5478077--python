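"""Codon-level substitution effects and count-ratio dN/dS per gene.

For each of the 13 mitochondrial protein-coding genes, substitutions
between a reference and a query genome are mapped into codons, translated
under the vertebrate mitochondrial genetic code (NCBI table 2), and
classified as synonymous or nonsynonymous.  The per-gene dN/dS is the raw
ratio of nonsynonymous to synonymous substitution *counts* — not a
site-normalized (Nei–Gojobori style) estimate — with the convention that
the ratio is undefined (rendered "—") unless both counts are positive.
A site-normalized Nei–Gojobori variant is available behind a flag.

Ratios below 1 are called purifying, exactly 1 (integer count equality)
neutral, above 1 positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_compare import PairwiseAlignment, Variant, VariantTable
from .seq_io import Feature, GenomeRecord

__all__ = ["SelectionResult", "translate_cds", "classify_cds_substitution",
           "gene_selection_table", "codon_translations"]


def _codon_table(table_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


def codon_translations(table_id: int = 2) -> dict[str, str]:
    """codon -> amino acid (or '*' for stops) for a genetic code table."""
    table = _codon_table(table_id)
    out = dict(table.forward_table)
    for stop in table.stop_codons:
        out[stop] = "*"
    return out


@dataclass
class SelectionResult:
    """Per-gene synonymous/nonsynonymous counts and selection category."""

    gene: str
    n_synonymous: int
    n_nonsynonymous: int
    aa_changes: list[str] = field(default_factory=list)
    dnds: Optional[float] = None
    category: str = "undefined"

    @classmethod
    def from_counts(cls, gene: str, n_syn: int, n_nonsyn: int,
                    aa_changes: Sequence[str] = ()) -> "SelectionResult":
        dnds: Optional[float] = None
        category = "undefined"
        if n_syn > 0 and n_nonsyn > 0:
            dnds = n_nonsyn / n_syn
            if n_nonsyn == n_syn:
                category = "neutral"
            elif n_nonsyn < n_syn:
                category = "purifying"
            else:
                category = "positive"
        return cls(gene=gene, n_synonymous=n_syn, n_nonsynonymous=n_nonsyn,
                   aa_changes=list(aa_changes), dnds=dnds, category=category)

    def dnds_text(self) -> str:
        return "—" if self.dnds is None else f"{self.dnds:.6g}"


# ---------------------------------------------------------------------------
# Translation


def translate_cds(g: GenomeRecord, f: Feature) -> str:
    """Translate a CDS feature honoring strand, phase and genetic code.

    A trailing incomplete codon (completed by polyadenylation in vivo, as
    for several mitochondrial genes) is dropped; a trailing stop codon is
    removed from the returned protein.  An internal stop raises, naming the
    gene and codon position.
    """
    if f.ftype != "CDS":
        raise ValueError(f"{f.name}: not a CDS feature")
    nt = f.extract(g.sequence)[f.codon_start:]
    nt = nt[:len(nt) - len(nt) % 3]
    aa = str(Seq(nt).translate(table=f.transl_table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        pos = aa.index("*")
        raise ValueError(f"{f.name}: internal stop codon at codon {pos + 1}")
    return aa


# ---------------------------------------------------------------------------
# Codon mapping


def _cds_offset(f: Feature, ref_pos: int, genome_length: int) -> Optional[int]:
    """Offset of a genome position within the feature's unwrapped span."""
    if f.start <= ref_pos < f.end:
        return ref_pos - f.start
    if f.end > genome_length and ref_pos < f.end - genome_length:
        return ref_pos + genome_length - f.start
    return None


def _codon_index_and_phase(f: Feature, offset: int) -> Optional[tuple[int, int]]:
    """(codon index, within-codon position) in reading orientation."""
    length = f.end - f.start
    if f.strand == "+":
        k = offset - f.codon_start
    else:
        k = (length - 1 - offset) - f.codon_start
    if k < 0:
        return None
    if k >= (length - f.codon_start) - (length - f.codon_start) % 3:
        return None     # trailing partial codon
    return k // 3, k % 3


def _codon_at(g: GenomeRecord, f: Feature, codon_index: int) -> str:
    coding = f.extract(g.sequence)[f.codon_start:]
    return coding[3 * codon_index: 3 * codon_index + 3]


def classify_cds_substitution(v: Variant, g_ref: GenomeRecord,
                              g_qry: GenomeRecord, f: Feature,
                              qry_pos: Optional[int] = None,
                              aln: Optional[PairwiseAlignment] = None) -> Optional[dict]:
    """Codon effect of one substitution inside a CDS.

    The full reference codon is compared against the full query codon, so a
    codon hit by several substitutions is evaluated once as a whole (each
    hit receives the same whole-codon classification).  Codons containing
    N or a gap are left unclassified (returns None).

    The query codon is read from the query genome; when query coordinates
    differ from reference coordinates (indels elsewhere), pass either the
    aligned query position ``qry_pos`` or the alignment itself.
    """
    if not v.is_substitution:
        raise ValueError("codon classification applies to substitutions only")
    n = len(g_ref.sequence)
    offset = _cds_offset(f, v.ref_pos, n)
    if offset is None:
        raise ValueError(f"{f.name}: position {v.ref_pos} outside feature")
    idx_phase = _codon_index_and_phase(f, offset)
    if idx_phase is None:
        return None
    codon_idx, phase = idx_phase
    ref_codon = _codon_at(g_ref, f, codon_idx)

    if qry_pos is None and aln is not None:
        col = aln.column_to_ref.index(v.ref_pos)
        qry_pos = aln.column_to_qry[col]
    qry_codon = _query_codon(v, g_ref, g_qry, f, codon_idx, phase, qry_pos)
    if qry_codon is None or len(ref_codon) != 3 or len(qry_codon) != 3:
        return None
    if set(ref_codon + qry_codon) - set("ACGT"):
        return None
    trans = codon_translations(f.transl_table)
    aa_ref, aa_qry = trans[ref_codon], trans[qry_codon]
    effect = "synonymous" if aa_ref == aa_qry else "nonsynonymous"
    return {"effect": effect, "ref_codon": ref_codon, "qry_codon": qry_codon,
            "aa_ref": aa_ref, "aa_qry": aa_qry, "codon_index": codon_idx,
            "aa_change": None if effect == "synonymous" else f"{aa_ref}->{aa_qry}"}


def _query_codon(v: Variant, g_ref: GenomeRecord, g_qry: GenomeRecord,
                 f: Feature, codon_idx: int, phase: int,
                 qry_pos: Optional[int]) -> Optional[str]:
    """Query codon homologous to a reference codon.

    When the two genomes are colinear over the codon (the common case for
    these gap-sparse comparisons) the codon is read at the shifted query
    coordinates; otherwise the reference codon with the variant base
    patched in is used (correct unless a second unseen difference falls in
    the same codon and the genomes are not colinear there).
    """
    if qry_pos is None:
        qry_pos = v.ref_pos if len(g_ref.sequence) == len(g_qry.sequence) else None
    if qry_pos is not None:
        shift = qry_pos - v.ref_pos
        n = len(g_ref.sequence)
        # reference coordinates of the codon's three bases (genome order)
        if f.strand == "+":
            base0 = f.start + f.codon_start + 3 * codon_idx
            ref_positions = [base0, base0 + 1, base0 + 2]
        else:
            base_hi = f.end - 1 - f.codon_start - 3 * codon_idx
            ref_positions = [base_hi, base_hi - 1, base_hi - 2]
        out = []
        for rp in ref_positions:
            qp = (rp % n) + shift
            if not 0 <= qp < len(g_qry.sequence):
                return None
            base = g_qry.sequence[qp]
            if f.strand == "-":
                base = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(base, "N")
            out.append(base)
        return "".join(out)
    # fallback: patch the single variant base into the reference codon
    ref_codon = _codon_at(g_ref, f, codon_idx)
    alt = v.alt_base
    if f.strand == "-":
        alt = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(alt, "N")
    return ref_codon[:phase] + alt + ref_codon[phase + 1:]


# ---------------------------------------------------------------------------
# Per-gene table


def gene_selection_table(vt: VariantTable, g_ref: GenomeRecord,
                         g_qry: GenomeRecord,
                         aln: Optional[PairwiseAlignment] = None,
                         site_normalized: bool = False) -> list[SelectionResult]:
    """One :class:`SelectionResult` per CDS of the reference annotation.

    Each substitution falling in a CDS is classified codon-wise; counts are
    attributed per substitution (a doubly-hit codon contributes each of its
    hits with the whole-codon classification).  With ``site_normalized``
    the ratio reported is (N_obs/N_sites)/(S_obs/S_sites) using
    Nei–Gojobori style synonymous/nonsynonymous site counts of the
    reference gene; the default is the raw count ratio.
    """
    cds = g_ref.cds_features()
    if not cds:
        raise ValueError(f"{g_ref.id}: no CDS features annotated")
    col_of_ref = None
    if aln is not None:
        col_of_ref = {p: c for c, p in enumerate(aln.column_to_ref) if p is not None}
    results = []
    n = len(g_ref.sequence)
    for f in cds:
        n_syn = n_nonsyn = 0
        aa_changes: list[str] = []
        for v in vt.substitutions:
            if _cds_offset(f, v.ref_pos, n) is None:
                continue
            qry_pos = None
            if col_of_ref is not None:
                qry_pos = aln.column_to_qry[col_of_ref[v.ref_pos]]
            eff = classify_cds_substitution(v, g_ref, g_qry, f, qry_pos=qry_pos)
            v.codon_effect = eff
            if eff is None:
                continue
            if eff["effect"] == "synonymous":
                n_syn += 1
            else:
                n_nonsyn += 1
                aa_changes.append(eff["aa_change"])
        res = SelectionResult.from_counts(f.name, n_syn, n_nonsyn, aa_changes)
        if site_normalized and res.dnds is not None:
            s_sites, n_sites = _ng_site_counts(g_ref, f)
            if s_sites > 0 and n_sites > 0:
                res.dnds = (n_nonsyn / n_sites) / (n_syn / s_sites)
        results.append(res)
    return results


def _ng_site_counts(g: GenomeRecord, f: Feature) -> tuple[float, float]:
    """Nei–Gojobori synonymous/nonsynonymous site counts of a gene."""
    trans = codon_translations(f.transl_table)
    coding = f.extract(g.sequence)[f.codon_start:]
    coding = coding[:len(coding) - len(coding) % 3]
    s_sites = n_sites = 0.0
    for i in range(0, len(coding), 3):
        codon = coding[i:i + 3]
        if set(codon) - set("ACGT") or trans.get(codon) == "*":
            continue
        for pos in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if trans[mut] != "*" and trans[mut] == trans[codon]:
                    syn += 1
            s_sites += syn / 3.0
            n_sites += 1.0 - syn / 3.0
    return s_sites, n_sites


def selection_table_tsv(results: Sequence[SelectionResult]) -> str:
    lines = ["Gene\tSynonymous\tNonsynonymous\tReplacements\tdN/dS\tCategory"]
    for r in results:
        repl = "/".join(r.aa_changes) if r.aa_changes else "—"
        dnds = "—" if r.dnds is None else f"{r.dnds:.6f}".rstrip("0").rstrip(".")
        lines.append(f"{r.gene}\t{r.n_synonymous}\t{r.n_nonsynonymous}\t"
                     f"{repl}\t{dnds}\t{r.category}")
    return "\n".join(lines) + "\n"
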