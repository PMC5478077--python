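"""Alignment, rotation, variant classification and divergence summaries."""

import numpy as np
import pytest

from mitochron.genome_compare import (MultipleAlignment, PairwiseAlignment,
                                      align_pair, alignment_score,
                                      base_composition, classify_variants,
                                      divergence_summary, msa_center_star,
                                      region_breakdown, rotate_to_reference)
from mitochron.seq_io import Feature, GenomeRecord
from mitochron.synthetic_data import SimulationConfig, simulate_dataset, \
    pairwise_from_msa


def _g(seq, gid="g", circular=False, features=()):
    return GenomeRecord(id=gid, sequence=seq, circular=circular,
                        features=list(features))


def _gotoh_score(a, b, match=1.0, mismatch=-2.0, gap_open=-5.0,
                 gap_extend=-2.0):
    """Independent quadratic-space affine-gap DP (global), score only."""
    neg = -1e18
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (deletion from a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


class TestAlignPair:
    def test_identity(self):
        aln = align_pair(_g("ACGT"), _g("ACGT", "h"))
        assert len(aln) == 4 and "-" not in aln.ref_aln + aln.qry_aln

    def test_forced_deletion(self):
        aln = align_pair(_g("ACGT"), _g("AGT", "h"))
        assert aln.qry_aln.count("-") == 1 and aln.ref_aln.count("-") == 0

    def test_gapless_ungapped_rows_reproduce_inputs(self):
        aln = align_pair(_g("ACGTTTGA"), _g("ACGTTGA", "h"))
        assert aln.ref_aln.replace("-", "") == "ACGTTTGA"
        assert aln.qry_aln.replace("-", "") == "ACGTTGA"

    @pytest.mark.parametrize("seed", range(5))
    def test_score_matches_dp_oracle(self, seed):
        """Optimal score equals an independent Gotoh DP on 2%-divergent pairs."""
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        a = "".join(rng.choice(bases, 400))
        b = list(a)
        for i in rng.choice(400, 8, replace=False):
            b[i] = rng.choice(bases)
        # plant one indel
        del b[200:202]
        b = "".join(b)
        aln = align_pair(_g(a), _g(b, "h"))
        assert alignment_score(aln) == pytest.approx(_gotoh_score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            GenomeRecord(id="e", sequence="")


class TestRotation:
    def test_constructed_rotation_recovered(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        ref = _g(seq, "ref", circular=True)
        qry = _g(seq[100:] + seq[:100], "qry", circular=True)
        rotated = rotate_to_reference(ref, qry)
        assert rotated.sequence == seq

    def test_identity_rotation(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        ref = _g(seq, "ref", circular=True)
        assert rotate_to_reference(ref, _g(seq, "q", circular=True)).sequence \
            == seq

    def test_rotation_with_mutations(self):
        """Offset recovered exactly despite 1% mutations, 100/100 trials."""
        rng = np.random.default_rng(2)
        bases = list("ACGT")
        hits = 0
        for _ in range(100):
            seq = "".join(rng.choice(bases, 3000))
            offset = int(rng.integers(1, 3000))
            mutated = list(seq[offset:] + seq[:offset])
            for i in rng.choice(3000, 30, replace=False):
                mutated[i] = rng.choice(bases)
            qry = _g("".join(mutated), "q", circular=True)
            rotated = rotate_to_reference(_g(seq, "r", circular=True), qry)
            back = qry.sequence[(3000 - offset) % 3000:] + \
                qry.sequence[:(3000 - offset) % 3000]
            hits += rotated.sequence == back
        assert hits >= 99

    def test_rotation_rotates_annotation(self):
        seq = "ACGTACGTACGTACGTACGT"
        f = Feature(name="t", ftype="tRNA", start=4, end=8)
        g = _g(seq, circular=True, features=[f]).rotated(4)
        assert g.feature("t").start == 0
        assert g.sequence == seq[4:] + seq[:4]

    def test_unrelated_sequences_error(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), 500))
        b = "".join(rng.choice(list("ACGT"), 500))
        with pytest.raises(ValueError, match="anchor"):
            rotate_to_reference(_g(a, circular=True), _g(b, "q", circular=True))


class TestClassifyVariants:
    def _aln(self, ref, qry):
        return PairwiseAlignment(ref_id="r", qry_id="q", ref_aln=ref,
                                 qry_aln=qry)

    def test_transition_and_direction(self):
        vt = classify_variants(self._aln("CAT", "TAT"))
        v = vt.variants[0]
        assert v.vclass == "transition" and v.direction == "C->T"

    def test_transversion(self):
        vt = classify_variants(self._aln("CAT", "AAT"))
        assert vt.variants[0].vclass == "transversion"

    def test_gap_run_is_one_event(self):
        vt = classify_variants(self._aln("ACGGGTA", "AC---TA"))
        assert vt.n_indel_events == 1 and vt.n_substitutions == 0
        assert vt.variants[0].vclass == "deletion"
        assert vt.variants[0].ref_base == "GGG"

    def test_insertion_vs_deletion_sides(self):
        vt = classify_variants(self._aln("AC--TA", "ACGGTA"))
        assert vt.variants[0].vclass == "insertion"

    def test_n_columns_excluded_and_logged(self):
        vt = classify_variants(self._aln("ANT", "AGT"))
        assert vt.n_substitutions == 0 and vt.n_excluded_ambiguous == 1

    def test_counts_identity(self):
        """transitions + transversions + indel events = variable positions."""
        vt = classify_variants(self._aln("CATG--GGAT", "TAAGCC-GAT"))
        assert vt.n_transitions + vt.n_transversions == vt.n_substitutions
        assert vt.n_variable_positions == \
            vt.n_substitutions + vt.n_indel_events

    def test_swap_preserves_class_reverses_direction(self):
        ref, qry = "CATGCGATCG", "TATACGATCA"
        fwd = classify_variants(self._aln(ref, qry))
        rev = classify_variants(self._aln(qry, ref))
        assert [v.vclass for v in fwd.variants] == \
            [v.vclass for v in rev.variants]
        assert [v.direction for v in rev.variants] == \
            ["->".join(reversed(v.direction.split("->")))
             for v in fwd.variants]

    def test_simulator_truth_agrees(self, sim_default):
        """Direct column comparison of the true MSA matches the classifier."""
        ids = list(sim_default.genomes)
        aln = pairwise_from_msa(sim_default.msa, ids[0], ids[1])
        vt = classify_variants(aln)
        manual = sum(1 for a, b in zip(aln.ref_aln, aln.qry_aln)
                     if a != b and "-" not in (a, b))
        assert vt.n_substitutions == manual


class TestRegionBreakdown:
    def test_single_cds_gets_everything(self):
        f = Feature(name="ND1", ftype="CDS", start=0, end=9)
        aln = PairwiseAlignment(ref_id="r", qry_id="q",
                                ref_aln="ATGAAATGA", qry_aln="ATGAAGTGA")
        vt = classify_variants(aln, [f], 9)
        bd = region_breakdown(vt, [f], 9)
        assert bd["CDS"] == (1, 100.0)

    def test_percent_denominator_excludes_indels(self):
        f = Feature(name="CR", ftype="control_region", start=0, end=20)
        aln = PairwiseAlignment(ref_id="r", qry_id="q",
                                ref_aln="ATGAAATGACCGG--ATACGG",
                                qry_aln="ATGAAGTGACCGGTTATACGG")
        vt = classify_variants(aln, [f], 19)
        bd = region_breakdown(vt, [f], 19)
        assert bd["control_region"][0] == 1
        assert sum(pct for _, pct in bd.values()) == pytest.approx(100.0)

    def test_brute_force_interval_membership(self, sim_default):
        """Region assignment equals naive per-feature interval check."""
        data = sim_default
        ids = list(data.genomes)
        aln = pairwise_from_msa(data.msa, ids[0], ids[-1])
        feats = data.root_features
        n = data.config.genome_length
        vt = classify_variants(aln, feats, n)
        assert vt.n_substitutions >= 100
        for v in vt.substitutions[:1000]:
            naive = None
            for f in feats:
                if any(a <= v.ref_pos < b for a, b in f.segments(n)):
                    naive = (f.name, f.ftype)
                    break
            assert v.region == naive


class TestSummaries:
    def test_composition_trivial(self):
        c = base_composition(_g("ACGT"))
        assert c.rounded() == (25.0, 25.0, 25.0, 25.0) and c.total == 4

    def test_composition_forced(self):
        c = base_composition(_g("A" * 40 + "C" * 10 + "G" * 10 + "T" * 40))
        assert c.rounded() == (40.0, 10.0, 40.0, 10.0)

    def test_divergence_construction(self):
        ref = "ACGT" * 10
        qry = list(ref)
        for i in range(10):
            qry[4 * i] = "C" if ref[4 * i] != "C" else "G"
        aln = PairwiseAlignment(
            ref_id="r", qry_id="q",
            ref_aln=ref + "GG" + "ACGT", qry_aln="".join(qry) + "--" + "ACGT")
        d = divergence_summary(aln)
        assert (d.n_divergent, d.n_gaps) == (10, 1)

    def test_divergence_identity(self):
        aln = PairwiseAlignment(ref_id="r", qry_id="q", ref_aln="ACGT",
                                qry_aln="ACGT")
        d = divergence_summary(aln)
        assert d.n_divergent == 0 and d.n_gaps == 0


class TestCenterStar:
    def test_identical_sequences_gap_free(self):
        gs = [_g("ACGTACGTAC", f"g{i}") for i in range(3)]
        msa = msa_center_star(gs, center="g0", rotate=False)
        assert all("-" not in r for r in msa.rows) and len(msa) == 10

    def test_planted_single_indel_one_gap_column(self):
        base = "ACGTTGCAACGGTTACAGT"
        gs = [_g(base, "g0"), _g(base, "g1"),
              _g(base[:8] + base[9:], "g2")]
        msa = msa_center_star(gs, center="g0", rotate=False)
        gap_cols = [j for j in range(len(msa))
                    if any(r[j] == "-" for r in msa.rows)]
        assert len(gap_cols) == 1
        assert msa.row("g2").replace("-", "") == base[:8] + base[9:]

    def test_rows_reproduce_sources(self, sim_small):
        genomes = list(sim_small.genomes.values())
        msa = msa_center_star(genomes, center=genomes[0].id, rotate=False)
        for g in genomes:
            assert msa.row(g.id).replace("-", "") == g.sequence

    def test_complete_deletion_drops_gap_and_n_columns(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["AC-GN", "ACTGA"])
        assert msa.complete_deletion_columns() == [0, 1, 3]
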