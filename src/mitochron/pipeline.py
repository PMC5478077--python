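"""End-to-end orchestration: QC → compare → selection → tree → dating → report.

A single run configuration (YAML mapping, or the equivalent dict) drives
the whole analysis and every output is regenerated from inputs + config
alone.  Inputs are either a set of genome FASTA / feature-table files or a
``simulate:`` section handed to :mod:`mitochron.synthetic_data`.

Outputs written to the run directory:

* ``variants.tsv``      classified differences reference vs. each query
* ``selection.tsv``     per-gene synonymous/nonsynonymous counts and dN/dS
* ``region_breakdown.tsv``  substitutions per region class with percents
* ``composition.tsv``   per-genome base composition
* ``divergence.tsv``    pairwise divergent-base and gap-event counts
* ``msa.fasta``         the center-star multiple alignment
* ``tree.nwk``          NJ tree with bootstrap supports
* ``ml_tree.nwk``       ML tree (when enabled)
* ``timetree.nwk`` / ``node_ages.tsv``  calibrated ages
* ``run.log``           seeds, parameters, stage timings
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .genome_compare import (align_pair, base_composition, classify_variants,
                             divergence_summary, msa_center_star,
                             region_breakdown, rotate_to_reference)
from .distances import build_distance_matrix
from .read_qc import filter_reads
from .reltime import (CalibrationPoint, calibrate_timetree, reltime_relative,
                      root_with_outgroup)
from .selection_scan import gene_selection_table, selection_table_tsv
from .seq_io import parse_fastq, parse_genome, write_fastq, write_newick
from .synthetic_data import SimulationConfig, simulate_dataset
from .tree_infer import bootstrap_support, optimize_ml_tree

__all__ = ["run_pipeline"]


def _load_genomes(config: dict) -> tuple[dict, list[str], Optional[object]]:
    if "simulate" in config:
        sim_cfg = SimulationConfig(**config["simulate"])
        data = simulate_dataset(sim_cfg)
        return data.genomes, data.outgroups, data
    genomes = {}
    for entry in config["genomes"]:
        fasta = Path(entry["fasta"]).read_text()
        table = Path(entry["features"]).read_text() if "features" in entry else ""
        g = parse_genome(fasta, table, circular=entry.get("circular", True),
                         label=entry.get("label", ""))
        genomes[g.id] = g
    return genomes, list(config.get("outgroups", [])), None


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run the full comparative analysis; returns a summary dict.

    Raises before any computation if the reference genome lacks a CDS
    annotation (the selection stage would be meaningless without it).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"mitochron {__version__}"]
    t0 = time.time()
    summary: dict = {}

    def stage(name: str) -> None:
        log.append(f"[{time.time() - t0:8.2f}s] {name}")

    seed = int(config.get("seed", 0))
    log.append(f"seed: {seed}")
    log.append("config: " + json.dumps(config, default=str, sort_keys=True))

    genomes, outgroups, sim = _load_genomes(config)
    ref_id = config.get("reference") or (sim and sim.ingroup[0]) or next(iter(genomes))
    ref = genomes[ref_id]
    if not ref.cds_features():
        raise ValueError(f"reference {ref_id} has no CDS annotation; aborting "
                         "before any computation")
    stage(f"loaded {len(genomes)} genomes, reference {ref_id}")

    # --- optional read QC -------------------------------------------------
    if "reads" in config:
        reads = parse_fastq(Path(config["reads"]).read_text())
        kept, stats = filter_reads(
            reads, base_threshold=int(config.get("qc_qmax", 7)),
            max_low_fraction=float(config.get("qc_max_low_frac", 0.10)))
        (out / "kept_reads.fastq").write_text(write_fastq(kept))
        (out / "qc_stats.tsv").write_text(stats.to_tsv())
        summary["qc"] = asdict(stats)
        stage(f"read QC: kept {stats.kept}/{stats.total}")

    # --- pairwise comparison vs reference --------------------------------
    queries = [g for gid, g in genomes.items() if gid != ref_id]
    compare_ids = config.get("compare", [q.id for q in queries])
    var_lines = []
    div_lines = ["#ref\tqry\tdivergent_bases\tpct_divergent\tgap_events"]
    first_vt = first_aln = first_qry = None
    for qid in compare_ids:
        qry = genomes[qid]
        if qry.circular and ref.circular:
            qry = rotate_to_reference(ref, qry)
        aln = align_pair(ref, qry)
        vt = classify_variants(aln, ref.features, len(ref.sequence))
        div = divergence_summary(aln)
        div_lines.append(f"{ref.id}\t{qid}\t{div.n_divergent}\t"
                         f"{div.pct_divergent:.2f}\t{div.n_gaps}")
        var_lines.append(f"## {ref.id} vs {qid}: "
                         f"{vt.n_variable_positions} variable positions "
                         f"({vt.n_transitions} ts, {vt.n_transversions} tv, "
                         f"{vt.n_indel_events} indel events)")
        var_lines.append(vt.to_tsv().rstrip())
        if first_vt is None:
            first_vt, first_aln, first_qry = vt, aln, genomes[qid]
    (out / "variants.tsv").write_text("\n".join(var_lines) + "\n")
    (out / "divergence.tsv").write_text("\n".join(div_lines) + "\n")
    stage(f"compared {len(compare_ids)} genome pairs")

    # --- region breakdown and selection table (first comparison pair) ----
    if first_vt is not None:
        bd = region_breakdown(first_vt, ref.features, len(ref.sequence))
        lines = ["#region\tsubstitutions\tpercent"]
        for region, (count, pct) in bd.items():
            lines.append(f"{region}\t{count}\t{pct:.2f}")
        (out / "region_breakdown.tsv").write_text("\n".join(lines) + "\n")
        sel = gene_selection_table(first_vt, ref, first_qry, aln=first_aln)
        (out / "selection.tsv").write_text(selection_table_tsv(sel))
        summary["n_variable_positions"] = first_vt.n_variable_positions
        summary["n_transitions"] = first_vt.n_transitions
        summary["n_transversions"] = first_vt.n_transversions
        summary["n_indel_events"] = first_vt.n_indel_events
        summary["region_breakdown"] = {k: v for k, v in bd.items()}
        summary["selection"] = [(r.gene, r.n_synonymous, r.n_nonsynonymous,
                                 r.dnds, r.category) for r in sel]
        stage("selection scan done")

    # --- composition ------------------------------------------------------
    comp_lines = ["#genome\tT\tC\tA\tG\ttotal"]
    for g in genomes.values():
        c = base_composition(g)
        t, cc, a, gg = c.rounded(1)
        comp_lines.append(f"{g.id}\t{t}\t{cc}\t{a}\t{gg}\t{c.total}")
    (out / "composition.tsv").write_text("\n".join(comp_lines) + "\n")

    # --- multiple alignment and trees ------------------------------------
    if sim is not None and config.get("use_true_alignment", True):
        msa = sim.msa
    else:
        msa = msa_center_star(list(genomes.values()), center=ref_id)
    (out / "msa.fasta").write_text(msa.to_fasta())
    summary["msa_columns"] = len(msa)
    summary["complete_deletion_columns"] = len(msa.complete_deletion_columns())
    stage(f"MSA: {len(msa)} columns "
          f"({summary['complete_deletion_columns']} after complete deletion)")

    n_boot = int(config.get("bootstrap", 1000))
    nj = bootstrap_support(msa, model=config.get("distance_model", "TN93-MCL"),
                           policy=config.get("deletion_policy", "complete"),
                           n_replicates=n_boot, seed=seed)
    (out / "tree.nwk").write_text(write_newick(nj, decorations="support"))
    summary["nj_sum_branch_lengths"] = nj.total_branch_length()
    stage(f"NJ tree with {n_boot} bootstrap replicates")

    dating_tree = nj
    if config.get("ml", True):
        ml, fit = optimize_ml_tree(msa, model_name=config.get("ml_model", "TN93"))
        (out / "ml_tree.nwk").write_text(write_newick(ml))
        summary["ml_loglik"] = fit.loglik
        summary["ml_bic"] = fit.bic
        summary["nj_ml_same_topology"] = nj.same_topology(ml)
        dating_tree = ml
        stage(f"ML tree lnL={fit.loglik:.4f}")

    # --- dating -----------------------------------------------------------
    if outgroups and "calibration" in config:
        cal_cfg = config["calibration"]
        cal = CalibrationPoint(taxon_a=cal_cfg["taxon_a"],
                               taxon_b=cal_cfg["taxon_b"],
                               age=float(cal_cfg["age"]),
                               interval=(float(cal_cfg.get("min", 0.0)),
                                         float(cal_cfg.get("max", 0.0))))
        rooted = root_with_outgroup(dating_tree, outgroups)
        tt = calibrate_timetree(reltime_relative(rooted, outgroups), cal)
        (out / "timetree.nwk").write_text(write_newick(tt.tree, decorations="age"))
        (out / "node_ages.tsv").write_text(tt.to_tsv())
        summary["node_ages"] = {row["clade"]: round(row["age_ma"], 2)
                                for row in tt.ages_table()}
        stage("calibrated timetree")

    (out / "run.log").write_text("\n".join(log) + "\n")
    return summary
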