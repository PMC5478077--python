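"""Synthetic mitogenome evolution: trees, annotated genomes, reads.

The generator emulates the structure of a small colobine mitogenome study:
eleven ~16.5 kb circular genomes (seven closely related ingroup taxa plus
four outgroups joined by a deeper stem), evolved under a TN93 substitution
process with strong transition bias, region-structured rates (control
region fastest, tRNA slowest), codon-aware evolution inside the 13
protein-coding genes targeting per-gene dN/dS count ratios under the
vertebrate mitochondrial code, optional noncoding-only deletions, and
sequencing reads with a two-component quality distribution.

Every random choice flows from the single ``seed`` in
:class:`SimulationConfig`; identical configurations give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genome_compare import MultipleAlignment, PairwiseAlignment
from .phylo import Node, PhyloTree
from .seq_io import Feature, GenomeRecord, QualityRead
from .selection_scan import codon_translations
from .tree_infer import TN93Model

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_timetree",
           "evolve_genome", "simulate_reads", "simulate_dataset",
           "default_feature_layout", "pairwise_from_msa"]

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

# protein-coding gene lengths (nt, multiples of 3), after typical primate
# mitogenome proportions; ND6 sits on the light strand
_CDS_LENGTHS = [("ND1", 957), ("ND2", 1044), ("COX1", 1542), ("COX2", 684),
                ("ATP8", 207), ("ATP6", 681), ("COX3", 783), ("ND3", 345),
                ("ND4L", 297), ("ND4", 1377), ("ND5", 1812), ("ND6", 528),
                ("CYTB", 1140)]
_TRNA_NAMES = ["trnF", "trnV", "trnL1", "trnI", "trnQ", "trnM", "trnW",
               "trnA", "trnN", "trnC", "trnY", "trnS1", "trnD", "trnK",
               "trnG", "trnR", "trnH", "trnS2", "trnL2", "trnE", "trnT",
               "trnP"]


@dataclass
class SimulationConfig:
    """All knobs of the forward simulator (defaults emulate the study system)."""

    n_taxa: int = 11
    n_outgroups: int = 4
    birth_rate: float = 1.0
    root_age: float = 1.0            # ingroup crown age, relative time units
    root_split_age: float = 2.7      # ingroup/outgroup split, same units
    outgroup_crown_age: float = 1.6
    rate_model: str = "strict"       # "strict" | "lognormal"
    rate_sigma: float = 0.4          # sdlog of lineage rates (lognormal model)
    mean_rate: float = 0.02          # substitutions/site per time unit
    min_internal_time: float = 0.04  # Yule draws conditioned on resolvable edges
    freqs: tuple = (0.321, 0.259, 0.116, 0.304)   # piA, piC, piG, piT
    kappa1: float = 8.0              # purine transition/transversion ratio
    kappa2: float = 8.0              # pyrimidine transition/transversion ratio
    genome_length: int = 16500
    region_rates: dict = field(default_factory=lambda: {
        "control_region": 4.0, "rRNA": 1.0, "CDS": 0.8, "tRNA": 0.3,
        "other_noncoding": 1.0})
    dnds: float = 0.3                # target per-gene nonsyn/syn count ratio
    per_gene_dnds: dict = field(default_factory=dict)
    indel_rate: float = 0.0          # deletions / noncoding site / subst unit
    read_length: int = 100
    coverage: float = 10.0
    q_low_prob: float = 0.08         # P(Q <= 7) per base
    q_low: int = 5
    q_high: int = 38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3 or not 0 <= self.n_outgroups < self.n_taxa:
            raise ValueError("need >=3 taxa and outgroups a proper subset")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if any(m <= 0 for m in self.region_rates.values()):
            raise ValueError("region rate multipliers must be positive")
        if not self.root_age < self.root_split_age:
            raise ValueError("root_split_age must exceed the ingroup crown age")
        if not self.outgroup_crown_age < self.root_split_age:
            raise ValueError("outgroup crown must be younger than the root split")

    def model(self) -> TN93Model:
        return TN93Model(self.freqs, self.kappa1, self.kappa2)

    def gene_dnds(self, gene: str) -> float:
        return self.per_gene_dnds.get(gene, self.dnds)


@dataclass
class SimulatedDataset:
    """Ground truth plus observable data from one simulator run."""

    config: SimulationConfig
    time_tree: PhyloTree        # ultrametric; node.age = true age
    subst_tree: PhyloTree       # branch lengths in substitutions/site
    genomes: dict               # id -> GenomeRecord (own coordinates)
    msa: MultipleAlignment      # true alignment (root coordinates)
    root_features: list         # annotation of the root genome
    outgroups: list

    @property
    def ingroup(self) -> list:
        return [g for g in self.genomes if g not in set(self.outgroups)]


# ---------------------------------------------------------------------------
# Trees


def _pure_birth(n_tips: int, birth_rate: float, rng: np.random.Generator,
                prefix: str) -> tuple[Node, float]:
    """Yule tree from a crown of two lineages; returns (root, crown depth)."""
    if n_tips < 2:
        node = Node(label=f"{prefix}1")
        node.age = 0.0
        return node, 0.0
    root = Node()
    tips = [root.add_child(Node()), root.add_child(Node())]
    birth_times = {id(root): 0.0}
    t = 0.0
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        victim = tips.pop(rng.integers(len(tips)))
        birth_times[id(victim)] = t
        tips.append(victim.add_child(Node()))
        tips.append(victim.add_child(Node()))
    t += rng.exponential(1.0 / (birth_rate * len(tips)))
    depth = t
    for i, tip in enumerate(tips, 1):
        tip.label = f"{prefix}{i}"
    # assign ages (time before present) and branch durations
    for node in root.postorder():
        node.age = 0.0 if node.is_leaf() else depth - birth_times[id(node)]
    for node in root.postorder():
        if node.parent is not None:
            node.length = node.parent.age - node.age
    return root, depth


def _rescale_ages(root: Node, target_depth: float) -> None:
    if root.age and root.age > 0:
        f = target_depth / root.age
        for node in root.postorder():
            node.age *= f
            if node.length is not None:
                node.length *= f


def _conditioned_yule(n_tips: int, crown_age: float, cfg: SimulationConfig,
                      rng: np.random.Generator, prefix: str) -> Node:
    """A rescaled Yule clade conditioned on resolvable internal branches.

    Draws are rejected until every internal (non-pendant) branch lasts at
    least ``min_internal_time`` after rescaling, so the emitted phylogeny
    carries enough substitutions per internal edge to be recoverable —
    mirroring the fully resolved trees of the study system rather than
    near-polytomies.
    """
    for _ in range(1000):
        root, _ = _pure_birth(n_tips, cfg.birth_rate, rng, prefix)
        _rescale_ages(root, crown_age)
        ok = all((node.length or 0.0) >= cfg.min_internal_time
                 for node in root.postorder()
                 if node.parent is not None and not node.is_leaf())
        if ok or n_tips < 3:
            return root
    raise ValueError("could not draw a tree satisfying min_internal_time; "
                     "lower it or the tip count")


def simulate_timetree(cfg: SimulationConfig,
                      rng: Optional[np.random.Generator] = None
                      ) -> tuple[PhyloTree, PhyloTree]:
    """True timetree and the matching substitutions/site branch-length tree.

    The ingroup is a pure-birth (Yule) tree rescaled to ``root_age``; the
    outgroups form their own pure-birth clade grafted via a stem so the
    ingroup/outgroup split sits at ``root_split_age``.  Under the
    lognormal rate model every branch draws an independent lineage rate
    with median 1; branch lengths of the substitution tree are duration ×
    ``mean_rate`` × lineage rate.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_in = cfg.n_taxa - cfg.n_outgroups
    in_root = _conditioned_yule(n_in, cfg.root_age if n_in > 1 else 0.0,
                                cfg, rng, "IN")
    if cfg.n_outgroups == 0:
        time_root = in_root
    else:
        out_root = _conditioned_yule(
            cfg.n_outgroups,
            cfg.outgroup_crown_age if cfg.n_outgroups > 1 else 0.0,
            cfg, rng, "OUT")
        time_root = Node()
        time_root.age = cfg.root_split_age
        time_root.add_child(in_root)
        time_root.add_child(out_root)
        in_root.length = cfg.root_split_age - (in_root.age or 0.0)
        out_root.length = cfg.root_split_age - (out_root.age or 0.0)
    time_tree = PhyloTree(time_root, rooted=True)

    subst_root = time_root.copy()
    for node in subst_root.postorder():
        if node.length is None:
            continue
        rate = 1.0
        if cfg.rate_model == "lognormal":
            rate = float(rng.lognormal(0.0, cfg.rate_sigma))
        elif cfg.rate_model != "strict":
            raise ValueError(f"unknown rate model {cfg.rate_model!r}")
        node.rate = rate
        node.length = node.length * cfg.mean_rate * rate
    return time_tree, PhyloTree(subst_root, rooted=True)


# ---------------------------------------------------------------------------
# Feature layout


def default_feature_layout(genome_length: int = 16500) -> list[Feature]:
    """A mitogenome-like annotation tiling the genome without overlap.

    Order: control region, two rRNAs, then protein-coding genes with tRNAs
    interspersed; short unannotated spacers absorb the remaining length.
    """
    blocks: list[tuple[str, str, int, str]] = [("control_region", "CR", 1050, "+"),
                                               ("tRNA", _TRNA_NAMES[0], 70, "+"),
                                               ("rRNA", "rrn12", 950, "+"),
                                               ("tRNA", _TRNA_NAMES[1], 70, "+"),
                                               ("rRNA", "rrn16", 1560, "+")]
    trna_iter = iter(_TRNA_NAMES[2:])
    for gene, length in _CDS_LENGTHS:
        try:
            blocks.append(("tRNA", next(trna_iter), 70, "+"))
        except StopIteration:
            pass
        strand = "-" if gene == "ND6" else "+"
        blocks.append(("CDS", gene, length, strand))
    for name in trna_iter:
        blocks.append(("tRNA", name, 70, "+"))
    occupied = sum(b[2] for b in blocks)
    spare = genome_length - occupied
    if spare < 0:
        raise ValueError(f"genome_length {genome_length} too short for the "
                         f"standard layout ({occupied} nt)")
    # distribute the spare length as inter-block spacers, remainder at the end
    gap_each, extra = divmod(spare, len(blocks))
    features = []
    pos = 0
    for i, (ftype, name, length, strand) in enumerate(blocks):
        features.append(Feature(name=name, ftype=ftype, start=pos,
                                end=pos + length, strand=strand))
        pos += length + gap_each + (1 if i < extra else 0)
    return features


# ---------------------------------------------------------------------------
# Genome evolution


def _draw_root(features: Sequence[Feature], genome_length: int,
               model: TN93Model, rng: np.random.Generator) -> np.ndarray:
    """Root genome from the stationary distribution, stop-free inside CDS."""
    seq = rng.choice(4, size=genome_length, p=model.freqs)
    trans = codon_translations(2)
    stops = {c for c, aa in trans.items() if aa == "*"}
    for f in features:
        if f.ftype != "CDS":
            continue
        length = (f.end - f.start) // 3 * 3
        codons = ["ATG"]
        while len(codons) * 3 < length:
            codon = "".join(_BASES[b] for b in rng.choice(4, 3, p=model.freqs))
            if codon in stops:
                continue
            codons.append(codon)
        coding = "".join(codons)[:length]
        if f.strand == "-":
            coding = coding.translate(_COMP)[::-1]
        idx = np.arange(f.start, f.start + length) % genome_length
        seq[idx] = [_BASES.index(b) for b in coding]
    return seq


def _mutation_rates(seq: np.ndarray, model: TN93Model) -> np.ndarray:
    """Per-site relative total mutation rate -Q[b,b] for current bases."""
    return -np.diag(model.q)[seq]


def evolve_genome(tree: PhyloTree, cfg: SimulationConfig,
                  rng: Optional[np.random.Generator] = None
                  ) -> SimulatedDataset:
    """Evolve an annotated root genome down a substitutions/site tree.

    Noncoding and RNA sites evolve site-independently under TN93 with their
    region's rate multiplier.  CDS sites evolve by proposal/rejection:
    substitutions are proposed at the gene's multiplier like any site, then
    evaluated codon-wise — proposals creating an internal stop are always
    rejected, synonymous proposals accepted, and nonsynonymous proposals
    thinned so the expected realized nonsyn/syn count ratio matches the
    gene's target dN/dS.  Optional indels are simulated as short deletions
    confined to noncoding regions, so no reading frame ever breaks.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    model = cfg.model()
    n = cfg.genome_length
    features = default_feature_layout(n)
    mult = np.empty(n)
    mult.fill(cfg.region_rates.get("other_noncoding", 1.0))
    cds_sites: dict[str, np.ndarray] = {}
    noncoding_mask = np.ones(n, dtype=bool)
    for f in features:
        idx = np.concatenate([np.arange(a, b) for a, b in f.segments(n)])
        mult[idx] = cfg.region_rates.get(f.ftype, 1.0)
        if f.ftype == "CDS":
            length = (f.end - f.start) // 3 * 3
            cds_sites[f.name] = np.arange(f.start, f.start + length) % n
            noncoding_mask[idx] = False
        elif f.ftype in ("tRNA", "rRNA"):
            noncoding_mask[idx] = False
    cds_mask = np.zeros(n, dtype=bool)
    for idx in cds_sites.values():
        cds_mask[idx] = True

    root_seq = _draw_root(features, n, model, rng)
    nonsyn_accept = {gene: _nonsyn_acceptance(root_seq, cds_sites[gene],
                                              features, gene, model,
                                              cfg.gene_dnds(gene))
                     for gene in cds_sites}

    trans = codon_translations(2)
    stops = {c for c, aa in trans.items() if aa == "*"}

    sequences: dict[str, np.ndarray] = {}
    deleted: dict[str, np.ndarray] = {}

    def evolve_branch(seq: np.ndarray, dele: np.ndarray, blen: float
                      ) -> tuple[np.ndarray, np.ndarray]:
        seq = seq.copy()
        dele = dele.copy()
        if blen <= 0:
            return seq, dele
        # non-CDS sites: direct TN93 sampling at region-scaled branch length
        for m in np.unique(mult[~cds_mask]):
            sites = np.where(~cds_mask & (mult == m) & ~dele)[0]
            if sites.size == 0:
                continue
            p = model.p_matrix(blen * m)
            cdf = np.cumsum(p, axis=1)
            u = rng.random(sites.size)
            rows = cdf[seq[sites]]
            seq[sites] = (u[:, None] > rows).sum(axis=1)
        # CDS: site-wise proposals, codon-wise accept/reject; proposal
        # intensity compensates the rejected fraction so the realized rate
        # matches the region multiplier
        for gene, sites in cds_sites.items():
            accept, comp = nonsyn_accept[gene]
            _evolve_cds(seq, sites, blen * mult[sites[0]] * comp, model,
                        trans, stops, accept,
                        "-" if _gene_strand(features, gene) == "-" else "+",
                        rng)
        # deletions in noncoding DNA only
        if cfg.indel_rate > 0:
            live_nc = np.where(noncoding_mask & ~dele)[0]
            n_events = rng.poisson(cfg.indel_rate * live_nc.size * blen)
            for _ in range(n_events):
                if live_nc.size == 0:
                    break
                start = int(rng.choice(live_nc))
                length = int(rng.integers(1, 6))
                for p in range(start, min(start + length, n)):
                    if noncoding_mask[p]:
                        dele[p] = True
                live_nc = np.where(noncoding_mask & ~dele)[0]
        return seq, dele

    states = {id(tree.root): (root_seq, np.zeros(n, dtype=bool))}
    for node in tree.preorder():
        if node.parent is not None:
            pseq, pdel = states[id(node.parent)]
            states[id(node)] = evolve_branch(pseq, pdel, node.length or 0.0)
        if node.is_leaf():
            sequences[node.label], deleted[node.label] = states[id(node)]

    ids = [leaf.label for leaf in tree.leaves()]
    rows = []
    genomes = {}
    for tid in ids:
        seq, dele = sequences[tid], deleted[tid]
        chars = np.array(list(_BASES))[seq]
        row = chars.copy()
        row[dele] = "-"
        rows.append("".join(row))
        kept = ~dele
        genome_seq = "".join(chars[kept])
        offsets = np.concatenate([[0], np.cumsum(kept)])
        feats = []
        for f in features:
            start = int(offsets[f.start])
            end = int(offsets[min(f.end, n)])
            if f.end > n:
                end += int(offsets[f.end - n])
            if end > start:
                feats.append(replace(f, start=start, end=end))
        genomes[tid] = GenomeRecord(id=tid, sequence=genome_seq, circular=True,
                                    features=feats, label=tid)
    msa = MultipleAlignment(ids=ids, rows=rows)
    outgroups = [t for t in ids if t.startswith("OUT")]
    return SimulatedDataset(config=cfg, time_tree=tree, subst_tree=tree,
                            genomes=genomes, msa=msa, root_features=features,
                            outgroups=outgroups)


def _gene_strand(features: Sequence[Feature], gene: str) -> str:
    for f in features:
        if f.name == gene:
            return f.strand
    return "+"


def _nonsyn_acceptance(root_seq: np.ndarray, sites: np.ndarray,
                       features: Sequence[Feature], gene: str,
                       model: TN93Model, target: float) -> tuple[float, float]:
    """Thinning probability and rate compensation for one gene.

    The raw nonsyn/syn proposal-rate ratio R is computed by enumerating all
    nine single-base neighbors of every root codon weighted by the TN93
    rates; accepting nonsynonymous proposals with probability target/R (and
    synonymous always) makes the expected realized count ratio ≈ target.
    The second return value is the factor by which the proposal intensity
    must be inflated so the *realized* per-site rate still equals the
    gene's region multiplier despite the rejected proposals (including
    always-rejected stop-codon mutations).
    """
    trans = codon_translations(2)
    strand = _gene_strand(features, gene)
    coding = "".join(_BASES[b] for b in root_seq[sites])
    if strand == "-":
        coding = coding.translate(_COMP)[::-1]
    rate_n = rate_s = rate_stop = 0.0
    for i in range(0, len(coding) - 2, 3):
        codon = coding[i:i + 3]
        aa = trans.get(codon)
        if aa is None or aa == "*":
            continue
        for pos in range(3):
            old = codon[pos]
            for new in _BASES:
                if new == old:
                    continue
                rate = model.q[_BASES.index(old), _BASES.index(new)]
                mut = codon[:pos] + new + codon[pos + 1:]
                if trans[mut] == "*":
                    rate_stop += rate
                elif trans[mut] == aa:
                    rate_s += rate
                else:
                    rate_n += rate
    if rate_s <= 0 or rate_n <= 0:
        return 1.0, 1.0
    accept = min(1.0, target * rate_s / rate_n)
    accepted = rate_s + accept * rate_n
    total = rate_s + rate_n + rate_stop
    comp = min(total / accepted, 3.0) if accepted > 0 else 1.0
    return accept, comp


def _evolve_cds(seq: np.ndarray, sites: np.ndarray, blen: float,
                model: TN93Model, trans: dict, stops: set,
                accept_nonsyn: float, strand: str,
                rng: np.random.Generator) -> None:
    """Propose site substitutions, filter codon-wise, apply in place."""
    if blen <= 0:
        return
    p = model.p_matrix(blen)
    cdf = np.cumsum(p, axis=1)
    u = rng.random(sites.size)
    proposed = (u[:, None] > cdf[seq[sites]]).sum(axis=1)
    changed = np.where(proposed != seq[sites])[0]
    if changed.size == 0:
        return
    # coding-orientation index of each gene position
    length = sites.size
    for k in changed:
        site = sites[k]
        old = seq[site]
        new = proposed[k]
        if strand == "+":
            cpos = k
            codon_start = k - k % 3
            codon_sites = sites[codon_start:codon_start + 3]
            codon = "".join(_BASES[b] for b in seq[codon_sites])
            phase = cpos % 3
            new_base = _BASES[new]
        else:
            cpos = length - 1 - k
            codon_idx = cpos // 3
            lo = length - 3 * (codon_idx + 1)
            codon_sites = sites[lo:lo + 3]
            raw = "".join(_BASES[b] for b in seq[codon_sites])
            codon = raw.translate(_COMP)[::-1]
            phase = cpos % 3
            new_base = _BASES[new].translate(_COMP)
        mutated = codon[:phase] + new_base + codon[phase + 1:]
        if mutated in stops or trans.get(codon) == "*":
            continue
        if trans[mutated] == trans[codon]:
            seq[site] = new
        elif rng.random() < accept_nonsyn:
            seq[site] = new


# ---------------------------------------------------------------------------
# Reads


def simulate_reads(g: GenomeRecord, cfg: SimulationConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> list[QualityRead]:
    """Uniform-start reads with a two-component quality distribution.

    The expected read count is coverage × genome length / read length; each
    base's quality is ``q_low`` with probability ``q_low_prob`` (at most 7,
    i.e. a filter-relevant base) and ``q_high`` otherwise.  Reads wrap
    around the origin on circular genomes.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = len(g.sequence)
    if cfg.read_length > n and not g.circular:
        raise ValueError("read length exceeds linear genome length")
    if cfg.coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= cfg.q_low_prob <= 1 or cfg.q_low > 7 or cfg.q_high <= 7:
        raise ValueError("quality distribution must straddle the Q7 boundary")
    n_reads = int(round(cfg.coverage * n / cfg.read_length))
    doubled = g.sequence + g.sequence
    reads = []
    hi = n if g.circular else n - cfg.read_length + 1
    starts = rng.integers(0, hi, size=n_reads)
    low = rng.random((n_reads, cfg.read_length)) < cfg.q_low_prob
    for i in range(n_reads):
        bases = doubled[starts[i]:starts[i] + cfg.read_length]
        quals = np.where(low[i], cfg.q_low, cfg.q_high).tolist()
        reads.append(QualityRead(id=f"read{i + 1}", bases=bases, quals=quals))
    return reads


# ---------------------------------------------------------------------------
# Convenience


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Timetree + genomes + alignment from one seed, ready for the pipeline."""
    rng = np.random.default_rng(cfg.seed)
    time_tree, subst_tree = simulate_timetree(cfg, rng)
    data = evolve_genome(subst_tree, cfg, rng)
    return replace(data, time_tree=time_tree, subst_tree=subst_tree)


def pairwise_from_msa(msa: MultipleAlignment, ref_id: str,
                      qry_id: str) -> PairwiseAlignment:
    """Extract a two-row alignment (dropping shared gap columns)."""
    a, b = msa.row(ref_id), msa.row(qry_id)
    cols = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
    return PairwiseAlignment(ref_id=ref_id, qry_id=qry_id,
                             ref_aln="".join(x for x, _ in cols),
                             qry_aln="".join(y for _, y in cols))
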