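"""Distance and likelihood tree inference.

Neighbor-joining (Saitou & Nei) and its variance-weighted BioNJ variant
build trees from a :class:`~mitochron.distances.DistanceMatrix`;
likelihoods are computed by Felsenstein pruning under nested reversible
nucleotide models (JC69 ⊂ K2P ⊂ TN93) with site-pattern compression and
per-pattern rescaling.  Maximum-likelihood search optimizes each branch by
bounded scalar optimization in full-tree sweeps and explores topology by
nearest-neighbor interchanges; candidate substitution models are ranked by
BIC = −2·lnL + k·ln(n_sites).

Tie-breaking in NJ (smallest index pair) and the derivation of bootstrap
replicate seeds (root seed + replicate index) are fixed so that runs are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .distances import DistanceMatrix, build_distance_matrix, encode_alignment
from .genome_compare import MultipleAlignment
from .phylo import Node, PhyloTree

__all__ = ["TN93Model", "ModelFit", "nj_tree", "bionj_tree",
           "tree_log_likelihood", "optimize_branch_lengths",
           "optimize_ml_tree", "bootstrap_support", "select_model_bic",
           "estimate_tn93_params"]

_MIN_BLEN = 1e-9
_MAX_BLEN = 10.0


# ---------------------------------------------------------------------------
# Substitution model


class TN93Model:
    """Reversible TN93 rate matrix with closed eigendecomposition.

    ``kappa1``/``kappa2`` are the purine (A<->G) and pyrimidine (C<->T)
    transition/transversion rate ratios; base order is A, C, G, T.  The
    matrix is scaled to one expected substitution per site per unit branch
    length.  JC69 is the special case of equal frequencies and both kappas
    1; K2P equal frequencies and kappa1 = kappa2.
    """

    def __init__(self, freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                 kappa1: float = 1.0, kappa2: float = 1.0,
                 name: str = "TN93") -> None:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs <= 0):
            raise ValueError("frequencies must be 4 positive numbers")
        self.freqs = freqs / freqs.sum()
        if kappa1 <= 0 or kappa2 <= 0:
            raise ValueError("rate ratios must be positive")
        self.kappa1, self.kappa2 = float(kappa1), float(kappa2)
        self.name = name
        self._decompose()

    def _decompose(self) -> None:
        pi = self.freqs
        rel = np.ones((4, 4))
        rel[0, 2] = rel[2, 0] = self.kappa1    # A<->G
        rel[1, 3] = rel[3, 1] = self.kappa2    # C<->T
        q = rel * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        q /= scale
        self.q = q
        sqrt_pi = np.sqrt(pi)
        sym = q * sqrt_pi[:, None] / sqrt_pi[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        self._lam = lam
        self._left = u.T * sqrt_pi[None, :]
        self._right = (u.T / sqrt_pi[None, :]).T

    def p_matrix(self, t: float) -> np.ndarray:
        """Transition probability matrix P(t) = exp(Qt)."""
        if t < 0:
            raise ValueError("negative branch length")
        p = (self._right * np.exp(self._lam * t)[None, :]) @ self._left
        return np.clip(p, 0.0, 1.0)

    @classmethod
    def jc(cls) -> "TN93Model":
        return cls(name="JC69")

    @classmethod
    def k2p(cls, kappa: float) -> "TN93Model":
        return cls(kappa1=kappa, kappa2=kappa, name="K2P")

    @property
    def n_free_params(self) -> int:
        if self.name == "JC69":
            return 0
        if self.name == "K2P":
            return 1
        return 5    # two rate ratios + three free frequencies


@dataclass
class ModelFit:
    model: str
    loglik: float
    n_params: int
    bic: float
    fitted: Optional[TN93Model] = None
    tree: Optional[PhyloTree] = None


# ---------------------------------------------------------------------------
# Neighbor-joining / BioNJ


def _nj_engine(dm: DistanceMatrix, bionj: bool) -> PhyloTree:
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries")
    d = dm.d.copy()
    v = dm.d.copy()     # variance terms (BioNJ)
    nodes: list[Node] = [Node(label=t) for t in dm.taxa]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qij = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or qij < best[0] - 1e-12:
                    best = (qij, i, j)
        _, i, j = best
        bi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = d[i, j] - bi
        parent = Node()
        ni, nj = nodes[i], nodes[j]
        # clamped lengths go on the tree; raw values drive the reduction
        ni.length, nj.length = _clamp_pair(bi, bj)
        parent.add_child(ni)
        parent.add_child(nj)
        if bionj:
            denom = 2.0 * (m - 2) * v[i, j] if v[i, j] > 0 else 0.0
            if denom > 0:
                sum_diff = sum(v[j, k] - v[i, k] for k in active
                               if k not in (i, j))
                lam = 0.5 + sum_diff / denom
                lam = min(1.0, max(0.0, lam))
            else:
                lam = 0.5
        else:
            lam = 0.5
        for k in active:
            if k in (i, j):
                continue
            dik, djk = d[i, k], d[j, k]
            new_d = lam * (dik - bi) + (1.0 - lam) * (djk - bj)
            d[i, k] = d[k, i] = new_d
            v[i, k] = v[k, i] = (lam * v[i, k] + (1.0 - lam) * v[j, k]
                                 - lam * (1.0 - lam) * v[i, j])
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    root = Node()
    bi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    bj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    bk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, b in zip((i, j, k), (bi, bj, bk)):
        nodes[idx].length = max(b, 0.0)
        root.add_child(nodes[idx])
    return PhyloTree(root, rooted=False)


def _clamp_pair(bi: float, bj: float) -> tuple[float, float]:
    """Clamp a negative branch to zero, shifting the deficit to its sibling."""
    if bi < 0.0:
        bj += bi
        bi = 0.0
    if bj < 0.0:
        bi += bj
        bj = 0.0
    return max(bi, 0.0), max(bj, 0.0)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor-joining; ties broken by smallest index pair."""
    return _nj_engine(dm, bionj=False)


def bionj_tree(dm: DistanceMatrix) -> PhyloTree:
    """BioNJ (Gascuel 1997): variance-weighted distance reduction."""
    return _nj_engine(dm, bionj=True)


# ---------------------------------------------------------------------------
# Likelihood


def _compress_patterns(msa: MultipleAlignment
                       ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Unique site patterns (rows × patterns), their counts, and taxon order."""
    enc = encode_alignment(msa.rows)
    patterns, counts = np.unique(enc, axis=1, return_counts=True)
    return patterns, counts.astype(float), list(msa.ids)


_LEAF_PARTIALS = np.vstack([np.eye(4), np.ones(4)])   # code 4 = missing


def _pruning_loglik(tree: PhyloTree, model: TN93Model, patterns: np.ndarray,
                    weights: np.ndarray, taxa: list[str]) -> float:
    row_of = {t: i for i, t in enumerate(taxa)}
    n_pat = patterns.shape[1]
    log_scale = np.zeros(n_pat)
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            if node.label not in row_of:
                raise ValueError(f"leaf {node.label!r} missing from alignment")
            codes = patterns[row_of[node.label]]
            partial[id(node)] = _LEAF_PARTIALS[codes]
            continue
        acc = np.ones((n_pat, 4))
        for child in node.children:
            t = child.length if child.length is not None else 0.0
            p = model.p_matrix(max(t, 0.0))
            acc *= partial.pop(id(child)) @ p.T
        mx = acc.max(axis=1)
        mx[mx == 0.0] = 1.0
        acc /= mx[:, None]
        log_scale += np.log(mx)
        partial[id(node)] = acc
    root_partial = partial[id(tree.root)]
    site_lik = root_partial @ model.freqs
    if np.any(site_lik <= 0.0):
        return -math.inf
    return float(((np.log(site_lik) + log_scale) * weights).sum())


def tree_log_likelihood(tree: PhyloTree, msa: MultipleAlignment,
                        model: TN93Model) -> float:
    """Log-likelihood of an alignment on a tree under a reversible model.

    Sites are compressed to unique patterns; gaps/ambiguities contribute a
    flat partial (missing data).  Because the model is reversible the value
    is independent of root placement.
    """
    patterns, weights, taxa = _compress_patterns(msa)
    if set(tree.root.leaf_labels()) != set(taxa):
        raise ValueError("tree leaves and alignment rows disagree")
    return _pruning_loglik(tree, model, patterns, weights, taxa)


def optimize_branch_lengths(tree: PhyloTree, msa: MultipleAlignment,
                            model: TN93Model, tol: float = 1e-8,
                            max_sweeps: int = 50) -> tuple[PhyloTree, float]:
    """Optimize every branch by bounded Brent sweeps until convergence."""
    patterns, weights, taxa = _compress_patterns(msa)
    tree = tree.copy()
    edges = [n for n in tree.postorder() if n.parent is not None]
    for n in edges:
        if n.length is None or n.length < _MIN_BLEN:
            n.length = _MIN_BLEN
    current = _pruning_loglik(tree, model, patterns, weights, taxa)
    for _ in range(max_sweeps):
        previous = current
        for node in edges:
            def neg(t: float, node=node) -> float:
                node.length = t
                return -_pruning_loglik(tree, model, patterns, weights, taxa)
            res = minimize_scalar(neg, bounds=(_MIN_BLEN, _MAX_BLEN),
                                  method="bounded",
                                  options={"xatol": tol})
            node.length = float(res.x)
        current = _pruning_loglik(tree, model, patterns, weights, taxa)
        if current - previous < 1e-6:
            break
    return tree, current


def estimate_tn93_params(msa: MultipleAlignment) -> tuple[np.ndarray, float, float]:
    """Empirical TN93 starting values (frequencies, kappa1, kappa2)."""
    enc = encode_alignment(msa.rows)
    counts = np.array([(enc == k).sum() for k in range(4)], dtype=float)
    if counts.sum() == 0:
        raise ValueError("alignment has no unambiguous bases")
    pi = counts / counts.sum()
    pi_r, pi_y = pi[0] + pi[2], pi[1] + pi[3]
    n_rows = enc.shape[0]
    p1 = p2 = q = total = 0
    for i in range(n_rows):
        for j in range(i + 1, n_rows):
            a, b = enc[i], enc[j]
            ok = (a < 4) & (b < 4)
            ai, bi = a[ok], b[ok]
            diff = ai != bi
            ts = diff & (np.abs(ai - bi) == 2)
            p1 += (ts & (ai % 2 == 0)).sum()
            p2 += (ts & (ai % 2 == 1)).sum()
            q += (diff & ~ts).sum()
            total += ok.sum()
    if total == 0 or q == 0:
        return pi, 2.0, 2.0
    tv_rate = q / total / (2.0 * pi_r * pi_y)
    k1 = max((p1 / total) / (2.0 * pi[0] * pi[2]) / tv_rate, 0.05) \
        if pi[0] * pi[2] > 0 else 1.0
    k2 = max((p2 / total) / (2.0 * pi[1] * pi[3]) / tv_rate, 0.05) \
        if pi[1] * pi[3] > 0 else 1.0
    return pi, float(k1), float(k2)


def _fit_model_params(tree: PhyloTree, msa: MultipleAlignment,
                      model_name: str, rounds: int = 2
                      ) -> tuple[PhyloTree, TN93Model, float]:
    """Alternate branch-length sweeps with rate-parameter optimization."""
    pi, k1, k2 = estimate_tn93_params(msa)
    if model_name == "JC69":
        model = TN93Model.jc()
    elif model_name == "K2P":
        model = TN93Model.k2p((k1 + k2) / 2.0)
    else:
        model = TN93Model(pi, k1, k2)
    tree, lnl = optimize_branch_lengths(tree, msa, model)
    if model_name == "JC69":
        return tree, model, lnl
    patterns, weights, taxa = _compress_patterns(msa)
    for _ in range(rounds):
        if model_name == "K2P":
            def neg(x: np.ndarray) -> float:
                m = TN93Model.k2p(math.exp(x[0]))
                return -_pruning_loglik(tree, m, patterns, weights, taxa)
            res = minimize(neg, [math.log(model.kappa1)], method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6})
            model = TN93Model.k2p(math.exp(res.x[0]))
        else:
            def neg(x: np.ndarray) -> float:
                m = TN93Model(model.freqs, math.exp(x[0]), math.exp(x[1]))
                return -_pruning_loglik(tree, m, patterns, weights, taxa)
            res = minimize(neg, [math.log(model.kappa1), math.log(model.kappa2)],
                           method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6})
            model = TN93Model(model.freqs, math.exp(res.x[0]),
                              math.exp(res.x[1]), name=model.name)
        tree, lnl = optimize_branch_lengths(tree, msa, model)
    return tree, model, lnl


# ---------------------------------------------------------------------------
# NNI search


def _nni_neighborhoods(tree: PhyloTree) -> list[PhyloTree]:
    """All trees one nearest-neighbor interchange away.

    For each internal edge (u, v) every (sibling-of-v, child-of-v) swap is
    generated; with a trifurcating root this covers both flanking subtrees.
    """
    out = []
    n_internal = sum(1 for n in tree.postorder()
                     if n.parent is not None and not n.is_leaf())
    for edge_idx in range(n_internal):
        probe = [n for n in tree.postorder()
                 if n.parent is not None and not n.is_leaf()]
        v0 = probe[edge_idx]
        n_sib = len(v0.parent.children) - 1
        n_child = len(v0.children)
        for si in range(n_sib):
            for xi in range(n_child):
                t = tree.copy()
                nodes = [n for n in t.postorder()
                         if n.parent is not None and not n.is_leaf()]
                v = nodes[edge_idx]
                u = v.parent
                s = [c for c in u.children if c is not v][si]
                x = v.children[xi]
                u.children[u.children.index(s)] = x
                v.children[v.children.index(x)] = s
                s.parent, x.parent = v, u
                out.append(t)
    return out


def optimize_ml_tree(msa: MultipleAlignment, model_name: str = "TN93",
                     starts: Sequence[str] = ("nj", "bionj"),
                     max_rounds: int = 20) -> tuple[PhyloTree, ModelFit]:
    """ML tree by NNI hill-climbing from NJ and BioNJ starting trees.

    Branch lengths are optimized by per-branch scalar sweeps; an NNI move
    is accepted when it improves lnL by more than 1e-6.  Both starting
    trees are pursued and the better local optimum returned.
    """
    if len(msa.ids) < 4:
        raise ValueError("ML search needs at least 4 taxa")
    dm = build_distance_matrix(msa, model="TN93-MCL", policy="complete")
    start_trees = []
    for s in starts:
        start_trees.append(nj_tree(dm) if s == "nj" else bionj_tree(dm))
    best: Optional[tuple[PhyloTree, TN93Model, float]] = None
    for start in start_trees:
        tree, model, lnl = _fit_model_params(start, msa, model_name)
        for _ in range(max_rounds):
            improved = False
            for cand in _nni_neighborhoods(tree):
                cand_opt, cand_lnl = optimize_branch_lengths(cand, msa, model)
                if cand_lnl > lnl + 1e-6:
                    tree, lnl = cand_opt, cand_lnl
                    improved = True
                    break
            if not improved:
                break
        tree, model, lnl = _fit_model_params(tree, msa, model_name, rounds=1)
        if best is None or lnl > best[2]:
            best = (tree, model, lnl)
    tree, model, lnl = best
    n_sites = len(msa)
    n_branches = sum(1 for n in tree.postorder() if n.parent is not None)
    k = n_branches + model.n_free_params
    fit = ModelFit(model=model.name, loglik=lnl, n_params=k,
                   bic=-2.0 * lnl + k * math.log(n_sites), fitted=model,
                   tree=tree)
    return tree, fit


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(msa: MultipleAlignment, model: str = "TN93-MCL",
                      policy: str = "complete", n_replicates: int = 1000,
                      seed: int = 0, method: str = "nj") -> PhyloTree:
    """NJ/BioNJ tree with bootstrap clade supports (percent of replicates).

    Columns are resampled with replacement; computationally the alignment
    is compressed to unique patterns and each replicate draws multinomial
    pattern weights, which is distributionally identical to resampling
    columns.  Replicate r uses seed ``seed + r``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    enc = encode_alignment(msa.rows)
    patterns, counts = np.unique(enc, axis=1, return_counts=True)
    n_cols = int(counts.sum())
    probs = counts / n_cols
    builder = nj_tree if method == "nj" else bionj_tree

    dm = build_distance_matrix(msa, model=model, policy=policy)
    main_tree = builder(dm)
    target_splits = {}
    for node in main_tree.postorder():
        if node.parent is not None and not node.is_leaf():
            target_splits[id(node)] = node

    all_taxa = main_tree.root.leaf_labels()
    anchor = min(all_taxa)
    split_counts: dict[frozenset, int] = {}
    failures = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        w = rng.multinomial(n_cols, probs).astype(float)
        keep = w > 0
        try:
            rep_dm = build_distance_matrix(
                msa, model=model, policy=policy,
                pattern_weights=(patterns[:, keep], w[keep]))
            rep_tree = builder(rep_dm)
        except ValueError:
            failures += 1
            continue
        for split in rep_tree.bipartitions():
            split_counts[split] = split_counts.get(split, 0) + 1
    effective = n_replicates - failures
    if effective == 0:
        raise ValueError("all bootstrap replicates failed")
    for node in main_tree.postorder():
        if node.parent is None or node.is_leaf():
            continue
        side = node.leaf_labels()
        if anchor in side:
            side = all_taxa - side
        if 2 <= len(side) <= len(all_taxa) - 2:
            node.support = 100.0 * split_counts.get(frozenset(side), 0) / effective
    return main_tree


# ---------------------------------------------------------------------------
# Model selection


def select_model_bic(msa: MultipleAlignment,
                     candidates: Sequence[str] = ("JC69", "K2P", "TN93")
                     ) -> tuple[list[ModelFit], ModelFit]:
    """Fit candidate models on one fixed NJ topology; rank by BIC."""
    dm = build_distance_matrix(msa, model="TN93-MCL", policy="complete")
    topo = nj_tree(dm)
    n_sites = len(msa)
    n_branches = sum(1 for n in topo.postorder() if n.parent is not None)
    fits = []
    for name in candidates:
        tree, model, lnl = _fit_model_params(topo, msa, name)
        k = n_branches + model.n_free_params
        fits.append(ModelFit(model=name, loglik=lnl, n_params=k,
                             bic=-2.0 * lnl + k * math.log(n_sites),
                             fitted=model, tree=tree))
    best = min(fits, key=lambda f: f.bic)
    return fits, best
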