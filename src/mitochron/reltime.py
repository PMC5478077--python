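"""Relative-rate divergence dating with a single calibration point.

Given a rooted tree with branch lengths in substitutions/site, every
ingroup lineage receives a relative rate and every ingroup node a relative
height, without assuming a global molecular clock.  In post-order each
node's mean tip depth m(v) (the lineage-averaged substitution path from v
to its descendant tips) is computed; in pre-order the two child lineages
of each node are assigned rates proportional to their depths d_i = b_i +
m(child_i), normalized by their mean, so that both children imply the same
node height and all tips land at height exactly zero.  A clock-like tree
therefore yields all rates 1 and heights equal to node depths.

The outgroup is used only to root the tree and to define the stem of the
ingroup, which evolves at relative rate 1; outgroup-internal nodes get no
rates or ages.  A single calibration (here the fixed 6.57 Ma split used
for the colobine dataset) converts relative heights to absolute ages by a
linear scale factor; confidence intervals come from site bootstrap with
branch lengths re-optimized on the fixed topology.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome_compare import MultipleAlignment
from .phylo import Node, PhyloTree

__all__ = ["CalibrationPoint", "TimeTree", "root_with_outgroup",
           "reltime_relative", "calibrate_timetree", "timetree_ci"]


@dataclass
class CalibrationPoint:
    """A node (MRCA of two taxa) with a fixed age and uncertainty interval."""

    taxon_a: str
    taxon_b: str
    age: float              # Ma
    interval: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("calibration age must be positive")
        lo, hi = self.interval
        if lo == hi == 0.0:
            self.interval = (self.age, self.age)
        else:
            if not (min(lo, hi) <= self.age <= max(lo, hi)):
                raise ValueError("calibration age outside its interval")
            self.interval = (min(lo, hi), max(lo, hi))


@dataclass
class TimeTree:
    """A rooted tree whose nodes carry relative rates/heights and ages (Ma)."""

    tree: PhyloTree
    outgroups: frozenset
    calibration: Optional[CalibrationPoint] = None

    def ingroup_nodes(self) -> list[Node]:
        return [n for n in self.tree.postorder() if n.rel_height is not None]

    def node_age(self, labels: Sequence[str]) -> Optional[float]:
        """Absolute age (Ma) of the MRCA of a set of leaf labels."""
        return self.tree.mrca(labels).age

    def ages_table(self) -> list[dict]:
        rows = []
        for node in self.tree.postorder():
            if node.is_leaf() or node.rel_height is None:
                continue
            rows.append({
                "clade": "|".join(sorted(node.leaf_labels())),
                "rel_height": node.rel_height,
                "age_ma": node.age,
                "ci_low": node.ci[0] if node.ci else None,
                "ci_high": node.ci[1] if node.ci else None,
            })
        return rows

    def to_tsv(self) -> str:
        lines = ["#clade\trel_height\tage_ma\tci_low\tci_high"]
        for row in self.ages_table():
            def fmt(x):
                return "" if x is None else f"{x:.6g}"
            lines.append("\t".join([row["clade"], fmt(row["rel_height"]),
                                    fmt(row["age_ma"]), fmt(row["ci_low"]),
                                    fmt(row["ci_high"])]))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Rooting


def root_with_outgroup(tree: PhyloTree, outgroups: Sequence[str],
                       fraction: float = 0.5) -> PhyloTree:
    """Root on the edge separating the outgroups from the ingroup.

    The outgroups must form one side of a split of the (unrooted) tree; the
    edge carrying that split is divided at ``fraction`` (ingroup side gets
    ``fraction`` of its length).  The result has the ingroup monophyletic.
    """
    out = frozenset(outgroups)
    all_taxa = tree.root.leaf_labels()
    if not out or not out < all_taxa:
        raise ValueError("outgroups must be a proper nonempty subset of the taxa")
    work = tree.copy()
    target = None
    for node in work.postorder():
        if node.parent is None:
            continue
        side = node.leaf_labels()
        if side == out or all_taxa - side == out:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroups {sorted(out)} do not form a split of the tree; "
            "they are not separable from the ingroup")
    frac = fraction if target.leaf_labels() == out else 1.0 - fraction
    rooted = work.reroot_on_edge(target, fraction=frac)
    return rooted


# ---------------------------------------------------------------------------
# Relative rates and heights


def _mean_tip_depth(node: Node, memo: dict) -> float:
    """Lineage-averaged substitution path length from a node to its tips."""
    if node.is_leaf():
        memo[id(node)] = 0.0
        return 0.0
    vals = [(c.length or 0.0) + _mean_tip_depth(c, memo) for c in node.children]
    m = sum(vals) / len(vals)
    memo[id(node)] = m
    return m


def reltime_relative(tree: PhyloTree, outgroups: Sequence[str]) -> TimeTree:
    """Assign relative lineage rates and node heights (see module docstring).

    The ingroup stem lineage is the reference at rate 1; the root's
    relative height is stem length plus the crown's mean tip depth, so the
    root (the ingroup/outgroup split) is datable.  Ties of zero-length
    sister lineages receive equal rates with a warning.
    """
    if not tree.rooted:
        tree = root_with_outgroup(tree, outgroups)
    work = tree.copy()
    out = frozenset(outgroups)
    root = work.root
    ingroup_children = [c for c in root.children if not (c.leaf_labels() & out)]
    if len(ingroup_children) != 1 or \
            any((c.leaf_labels() - out) for c in root.children
                if c not in ingroup_children):
        raise ValueError("tree is not rooted between outgroups and ingroup")
    crown = ingroup_children[0]
    others = [c for c in root.children if c is not crown]

    # Re-balance the root position on the ingroup/outgroup edge: the split
    # of that edge by the rooting step is arbitrary, so place the root where
    # both sides have equal mean tip depth (the clock-consistent point).
    # Dating then does not depend on how the unrooted edge was split.
    if len(others) == 1:
        other = others[0]
        memo_out: dict = {}
        m_out = _mean_tip_depth(other, memo_out)
        memo_in: dict = {}
        m_in = _mean_tip_depth(crown, memo_in)
        edge = (crown.length or 0.0) + (other.length or 0.0)
        b_in = min(max((edge + m_out - m_in) / 2.0, 0.0), edge)
        crown.length = b_in
        other.length = edge - b_in

    memo: dict = {}
    _mean_tip_depth(crown, memo)
    stem = crown.length or 0.0
    if stem + memo[id(crown)] <= 0:
        raise ValueError("ingroup has zero total depth; nothing to date")

    # root height in substitution units of the rate-1 stem lineage
    root.rel_height = stem + memo[id(crown)]
    root.rate = None
    crown.rate = 1.0
    crown.rel_height = memo[id(crown)]

    def descend(v: Node, v_rate: float) -> None:
        if v.is_leaf():
            v.rel_height = 0.0
            return
        depths = [(c.length or 0.0) + memo[id(c)] for c in v.children]
        mean_d = sum(depths) / len(depths)
        if mean_d <= 0.0:
            warnings.warn("zero-length sister lineages; rates set equal")
            for c in v.children:
                c.rate = v_rate
                c.rel_height = v.rel_height
                descend(c, v_rate)
            return
        for c, d in zip(v.children, depths):
            if d <= 0.0:
                c.rate = v_rate
                c.rel_height = v.rel_height
                descend(c, c.rate)
            else:
                c.rate = v_rate * d / mean_d
                c.rel_height = v.rel_height * memo[id(c)] / d
                descend(c, c.rate)

    descend(crown, 1.0)
    return TimeTree(tree=work, outgroups=out)


def calibrate_timetree(tt: TimeTree, cal: CalibrationPoint) -> TimeTree:
    """Convert relative heights to absolute ages via one calibration node.

    Every dated node's age is its relative height times
    ``cal.age / rel_height(MRCA(taxon_a, taxon_b))``; ages therefore scale
    linearly in the calibration age.  Pre-existing sampling CIs (from
    :func:`timetree_ci`) are compounded with the calibration interval;
    otherwise the CI reflects the calibration interval alone.
    """
    node = tt.tree.mrca([cal.taxon_a, cal.taxon_b])
    if node.rel_height is None:
        raise ValueError("calibration node lies in the undated outgroup part")
    if node.rel_height <= 0:
        raise ValueError("calibration node has zero relative height")
    factor = cal.age / node.rel_height
    lo_f = cal.interval[0] / cal.age
    hi_f = cal.interval[1] / cal.age
    for n in tt.tree.postorder():
        if n.rel_height is None:
            continue
        n.age = n.rel_height * factor
        if n.ci is not None:
            n.ci = (n.ci[0] * lo_f, n.ci[1] * hi_f)
        else:
            n.ci = (n.age * lo_f, n.age * hi_f)
    tt.calibration = cal
    return tt


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals


def timetree_ci(msa: MultipleAlignment, tree: PhyloTree,
                cal: CalibrationPoint, outgroups: Sequence[str],
                n_boot: int = 200, seed: int = 0,
                model_name: str = "TN93",
                max_failure_rate: float = 0.05) -> TimeTree:
    """Site-bootstrap 95% CIs for node ages on a fixed topology.

    Each replicate resamples alignment columns, re-optimizes branch lengths
    on the fixed rooted topology, reruns the relative-rate dating and the
    calibration, and records every dated node's age; the 2.5/97.5
    percentiles become the CI, compounded with the calibration interval.
    """
    from .tree_infer import (TN93Model, _compress_patterns, _fit_model_params,
                             _pruning_loglik, optimize_branch_lengths)
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rooted = tree if tree.rooted else root_with_outgroup(tree, outgroups)
    _, model, _ = _fit_model_params(rooted, msa, model_name, rounds=1)
    base_tree, _ = optimize_branch_lengths(rooted, msa, model)
    base_tt = calibrate_timetree(reltime_relative(base_tree, outgroups), cal)

    enc_patterns, counts, taxa = _compress_patterns(msa)
    n_cols = int(counts.sum())
    probs = counts / n_cols

    ages: dict[frozenset, list[float]] = {}
    failures = 0
    for rep in range(n_boot):
        rng = np.random.default_rng(seed + rep)
        w = rng.multinomial(n_cols, probs).astype(float)
        keep = w > 0
        try:
            rep_msa = _expand_patterns(enc_patterns[:, keep], w[keep], taxa)
            rep_tree, _ = optimize_branch_lengths(rooted, rep_msa, model)
            rep_tt = calibrate_timetree(reltime_relative(rep_tree, outgroups), cal)
        except (ValueError, ZeroDivisionError):
            failures += 1
            continue
        for node in rep_tt.tree.postorder():
            if node.is_leaf() or node.age is None:
                continue
            ages.setdefault(node.leaf_labels(), []).append(node.age)
    if failures > max_failure_rate * n_boot:
        raise ValueError(f"{failures}/{n_boot} bootstrap replicates failed")

    lo_f = cal.interval[0] / cal.age
    hi_f = cal.interval[1] / cal.age
    for node in base_tt.tree.postorder():
        if node.is_leaf() or node.age is None:
            continue
        sample = ages.get(node.leaf_labels())
        if not sample:
            continue
        lo, hi = np.percentile(sample, [2.5, 97.5])
        lo, hi = min(lo, node.age), max(hi, node.age)   # CI contains the point
        node.ci = (lo * lo_f, hi * hi_f)
    return base_tt


def _expand_patterns(patterns: np.ndarray, weights: np.ndarray,
                     taxa: list[str]) -> MultipleAlignment:
    """Materialize a resampled alignment from weighted site patterns."""
    reps = weights.astype(int)
    cols = np.repeat(patterns, reps, axis=1)
    alphabet = np.array(list("ACGT-"))
    rows = ["".join(alphabet[row]) for row in cols]
    return MultipleAlignment(ids=list(taxa), rows=rows)
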