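# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package, in the order of the pipeline stages.

## Read filtering

A base is *low-quality* iff its Phred score Q ≤ `base_threshold`
(default 7, boundary inclusive); a read is discarded iff its low-quality
fraction strictly exceeds `max_low_fraction` (default 0.10), so a 100 bp
read with exactly 10 low-quality bases is kept. N bases are not treated as
low-quality — only the quality string decides. Reads are filtered
individually; if inputs are paired, mates of discarded reads survive
(an alternative pair-dropping policy would discard both, which we do not
implement). Zero-length reads are discarded and counted separately.

## Alignment and variant classification

Circular genomes are first rotated: exact 24-mers sampled along the
reference are located in the doubled query and the modal implied offset
wins. With percent-scale divergence, a minority of anchors can overlap a
mutation, so the vote is near-unanimous in practice; no anchor at all
raises an error suggesting linear mode.

Pairwise alignment is deterministic global affine-gap alignment
(match +1, mismatch −2, gap open −5, extend −2; a length-L gap costs
−5 −2(L−1)), computed with Biopython's `PairwiseAligner` and verified in
the tests against an independent Gotoh dynamic program. Among co-optimal
alignments the aligner's canonical first traceback is used, making runs
repeatable.

Classification walks alignment columns: a mismatching base column is a
directed substitution (reference→query), transition iff {A,G} or {C,T};
each *maximal run* of gap columns on one side is a single insertion or
deletion event regardless of length. Columns containing N or another
ambiguity code are excluded from substitution counts and tallied.
Region percentages use the substitution count as denominator (indel
events excluded), so they sum to 100%. A substitution covered by no
feature counts as `other_noncoding`; overlapping features resolve to the
first by start coordinate.

Multi-genome alignment is center-star: every genome is aligned to the
chosen center and gap patterns are merged under "once a gap, always a
gap". For the gap-sparse, near-identical genomes this package targets the
heuristic is essentially exact; pairs more than 30% divergent from the
center trigger a warning. *Complete deletion* drops every column holding
a gap or ambiguous base in any row; *pairwise deletion* drops sites per
pair.

## Selection summaries

Codon effects are evaluated on whole codons under the vertebrate
mitochondrial code (NCBI table 2; ATA→M, AGA/AGG are stops): a
substitution is synonymous iff the full reference codon and full query
codon translate identically, so a codon hit by several substitutions is
evaluated once as a unit and each hit inherits the whole-codon
classification. Codons containing N or a gap are left unclassified but
still reported in the raw counts reconciliation. Strand and `codon_start`
phase follow the annotation (ND6 is typically light-strand); trailing
partial codons (completed by polyadenylation in vivo) are dropped.

The headline dN/dS is deliberately the raw count ratio
n_nonsyn / n_syn — the statistic printed by the study this package
mirrors — and is *undefined* (rendered "—") unless both counts are
positive. Category calls use integer count comparison (equality → neutral),
never floating-point equality. The Nei–Gojobori site-normalized variant
(dividing each count by the gene's synonymous/nonsynonymous site totals)
is available via `site_normalized=True`; because nonsynonymous sites
outnumber synonymous ones roughly 2.5:1, it is systematically smaller
than the count ratio and the two must not be compared across studies.

## Distances

`SitePairCounts` records the transition proportions split by purine
(P1: A↔G) and pyrimidine (P2: C↔T) classes, the transversion proportion
Q, and base frequencies. Closed forms:

* K2P: d = −½·ln[(1−2P−Q)·√(1−2Q)], P = P1+P2;
* TN93: the three-logarithm Tamura–Nei form with empirical frequencies;
  degenerate frequency configurations (a missing purine or pyrimidine)
  fall back to K2P, the model's own limit.

Saturated pairs (non-positive log arguments) are flagged as infinite and
the matrix builder raises, listing them. The `TN93-MCL` variant pools
base frequencies over all rows of the alignment (restricted to the
retained columns) so every pair shares one frequency vector — the
practical core of composite-likelihood distance estimation; per-pair
difference proportions remain pair-specific. No attempt is made to
replicate any particular program's simultaneous optimization, and no
gamma rate heterogeneity is applied; see Limitations.

## Tree inference

Neighbor-joining follows Saitou–Nei: Q-matrix minimization with ties
broken by the smallest index pair (bit-reproducible), two-point branch
length formulas, and standard matrix reduction. Negative branch lengths
are clamped to zero with the deficit shifted to the sibling; the raw
values drive the reduction so additive matrices are reconstructed
exactly. BioNJ adds the variance-weighted reduction with λ clamped to
[0, 1].

Likelihoods use Felsenstein pruning over unique site patterns with
per-pattern rescaling; gaps and ambiguity codes contribute flat partials
(missing data). The TN93 rate matrix is eigendecomposed once via the
π-symmetrization, so P(t) costs one 4×4 congruence per branch. Because
the models are reversible, the likelihood is root-placement invariant
(verified to <1e−8 in the tests).

ML search: branch lengths are optimized one at a time by bounded Brent
(tolerance 1e−8, bounds [1e−9, 10]) in full-tree sweeps until the
improvement falls below 1e−6 (at most 50 sweeps); NNI moves are accepted
when they improve lnL by more than 1e−6; both NJ and BioNJ starting trees
are pursued and the better local optimum kept. Rate parameters
(κ1, κ2) are estimated by alternating Nelder–Mead steps with branch
sweeps, initialized from empirical pair counts; frequencies are empirical.
BIC = −2·lnL + k·ln(n_sites) with k counting branches plus free model
parameters (0 / 1 / 5 for JC69 / K2P / TN93), evaluated on one fixed NJ
topology for model ranking.

Bootstrap supports resample alignment columns; computationally each
replicate draws multinomial weights over the compressed site patterns,
which is distributionally identical and orders of magnitude faster.
Replicate r uses seed `seed + r`, so runs are reproducible and
individually parallelizable. Supports are the percentage of replicates
containing each bipartition of the point-estimate tree.

## Relative-rate dating

The rooted tree comes from placing the root on the edge separating the
outgroups from the ingroup. Because the split of that edge is not
identifiable from a reversible model, the dating step re-balances it to
the *clock-consistent point* where both sides have equal mean tip depth;
dating is therefore invariant to how the rooting step cut the edge, and
exact under a clock.

Rates and heights: post-order, each node's mean tip depth
m(v) = mean over children of (b_c + m(c)) (lineage-averaged, not
tip-count-weighted). Pre-order from the ingroup crown, the children of a
node with parent-lineage rate r get rates r·d_i/mean(d) where
d_i = b_i + m(c_i), and heights h(c_i) = h(v)·m(c_i)/d_i. Normalizing by
the sister *mean* (rather than, say, the geometric mean) is what makes
the recursion self-consistent: both children imply the same node height,
tip heights are exactly zero, and ages are parent-monotone. On a
clock-like tree every rate is 1 and heights equal node depths exactly.
The ingroup stem evolves at reference rate 1; outgroup-internal nodes
receive no rates or ages. Zero-length sister pairs get equal rates with
a warning.

Calibration multiplies all relative heights by cal.age / h(MRCA); ages
are therefore homogeneous of degree 1 in the calibration age. The
calibration is treated as a fixed point; its interval only scales the
CI endpoints. Sampling CIs come from site bootstrap (≥100 replicates):
resampled columns → branch lengths re-optimized on the fixed rooted
topology → dating and calibration per replicate → 2.5/97.5 percentiles,
widened if needed to contain the point estimate and compounded with the
calibration interval. The two root-adjacent branch lengths are summed
through the re-balancing step, so their likelihood non-identifiability
adds noise only to the root age.

## Synthetic data generator

The generator emulates the study system: eleven ~16.5 kb circular
genomes — seven closely related ingroup taxa (pairwise divergence
≤ ~4%, within the realistic 0.1–5% band for conspecific/congeneric
mitogenomes) and four outgroups joined by a deeper stem.

* **Trees.** Yule (pure-birth) ingroup and outgroup clades, rescaled to
  crown ages 1.0 and 1.6 (relative units) and joined at a root split of
  2.7 — proportions chosen so that calibrating the root at 6.57 Ma puts
  the ingroup crown near 2.4 Ma, matching the depth structure of the
  study clade. Draws are conditioned on every internal branch lasting at
  least `min_internal_time` (0.04 units), mirroring the fully resolved
  published trees rather than near-polytomies. Under the lognormal rate
  model each branch draws an independent rate with median 1
  (σ = 0.4 by default).
* **Substitutions.** TN93 with the composition of the study genomes
  (π_A 0.321, π_C 0.259, π_G 0.116, π_T 0.304) and strong transition
  bias (κ1 = κ2 = 8). The genome-wide rate is 0.02 substitutions/site
  per time unit. Region multipliers: control region 4×, rRNA 1×,
  CDS 0.8×, tRNA 0.3× — the fast-control-region / slow-tRNA ordering
  seen in primate mitogenomes. Within CDS, proposals are evaluated
  codon-wise: stop-creating changes are always rejected and
  nonsynonymous changes are thinned so the realized nonsyn/syn count
  ratio targets the configured per-gene dN/dS (default 0.3); the
  proposal intensity is inflated by the computed rejection fraction so
  the realized CDS rate still equals its region multiplier.
* **Indels.** Optional deletions (1–5 bp) confined to unannotated
  noncoding DNA and the control region, so no reading frame ever breaks;
  insertions are not simulated.
* **Reads.** Fixed-length reads from uniform circular start positions;
  qualities are two-component (Q = 5 with probability `q_low_prob`
  = 0.08, else Q = 38), so the read filter's kept fraction has an exact
  binomial prediction.

All randomness flows from the single config seed; identical configs give
identical outputs.

What the generator does *not* emulate: instrument-specific error
profiles, heteroplasmy, structural rearrangements, insertions,
context-dependent mutation, and CpG effects. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
stated generative model, not robustness to every feature of real data.

## Problem sizes used by the tests and the acceptance script

Full-genome analyses run at the native 16.5 kb / 11-taxon scale.
Replicated experiments are sized for tight, stable statistics at modest
cost: the topology/root-age recovery experiment uses 100 seeds in the
test suite and 30 in the acceptance script; NJ bootstraps use 200
replicates (supports converge well before that — the study-scale 10,000
is supported but unnecessary for verification); dating CIs use 100
bootstrap replicates on 6-taxon alignments.

The recovery experiment is run under a configuration matching the
estimators' assumptions — homogeneous region rates and neutral coding —
because its purpose is to verify the inference machinery. Under the full
region-structured, selection-thinned defaults the same pipeline shows a
systematic ~4–8% compression of the deepest ages; see Limitations.

## Limitations

* **Among-site rate variation.** The distance corrections and likelihood
  models are site-homogeneous (no gamma), while both real mitogenomes
  and the full synthetic defaults are strongly heterogeneous (control
  region ~4× tRNA; fast third codon positions under purifying
  selection). This compresses deep distances relative to shallow ones
  and biases the deepest relative ages downward by several percent at
  the divergences simulated here. Calibrating at a deep node (as the
  mirrored study does) largely cancels the effect for nodes of similar
  depth.
* **dN/dS as a count ratio** ignores site counts and multiple hits; it
  is a descriptive statistic, not an evolutionary rate ratio, and
  becomes inflated on deep pairs where doubly-hit codons are common.
* **Center-star MSA** is exact only in the gap-sparse near-identical
  regime; highly divergent outgroups can accumulate suboptimal gap
  placements (hence the divergence-cap warning).
* **Bootstrap CIs for ages** condition on the point-estimate topology
  and ignore topological uncertainty; the root-adjacent branch
  indeterminacy adds noise to the root age only.
* **NNI-only search** can in principle stop at a local optimum;
  both NJ and BioNJ starts mitigate but do not eliminate this.
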