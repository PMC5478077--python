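"""NJ/BioNJ against additive and exhaustive oracles; likelihood machinery."""

import itertools
import math

import numpy as np
import pytest

from mitochron.distances import DistanceMatrix, build_distance_matrix
from mitochron.genome_compare import MultipleAlignment
from mitochron.phylo import Node, PhyloTree, parse_newick
from mitochron.synthetic_data import SimulationConfig, simulate_dataset
from mitochron.tree_infer import (TN93Model, bionj_tree, bootstrap_support,
                                  nj_tree, optimize_branch_lengths,
                                  optimize_ml_tree, select_model_bic,
                                  tree_log_likelihood)


# ---------------------------------------------------------------------------
# oracle helpers


def _random_binary_tree(labels, rng):
    nodes = [Node(label=l, length=float(rng.uniform(0.05, 1.0)))
             for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = Node(length=float(rng.uniform(0.05, 1.0)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add_child(n)
    return PhyloTree(root, rooted=False)


def _path_length_matrix(tree):
    taxa = tree.taxa()
    leaves = {n.label: n for n in tree.leaves()}

    def path(a, b):
        anc_a = []
        n = leaves[a]
        while n is not None:
            anc_a.append(n)
            n = n.parent
        seen = {id(x): k for k, x in enumerate(anc_a)}
        total = 0.0
        n = leaves[b]
        while id(n) not in seen:
            total += n.length or 0.0
            n = n.parent
        for x in anc_a[:seen[id(n)]]:
            total += x.length or 0.0
        return total

    d = np.zeros((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                d[i, j] = d[j, i] = path(a, b)
    return DistanceMatrix(taxa=taxa, d=d)


def _all_unrooted_topologies(labels):
    """Stepwise-addition enumeration: 3 for n=4, 15 for n=5, 105 for n=6."""
    first = Node()
    for l in labels[:3]:
        first.add_child(Node(label=l))
    trees = [PhyloTree(first, rooted=False)]
    for label in labels[3:]:
        nxt = []
        for t in trees:
            edges = [n for n in t.postorder() if n.parent is not None]
            for k in range(len(edges)):
                t2 = t.copy()
                edges2 = [n for n in t2.postorder() if n.parent is not None]
                target = edges2[k]
                parent = target.parent
                mid = Node()
                parent.children[parent.children.index(target)] = mid
                mid.parent = parent
                mid.add_child(target)
                mid.add_child(Node(label=label))
                nxt.append(t2)
        trees = nxt
    return trees


def _ls_residual(topology, dm):
    """Least-squares branch-length fit residual of a topology to a matrix."""
    edges = [n for n in topology.postorder() if n.parent is not None]
    taxa = dm.taxa
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([dm.d[i, j] for i, j in pairs])
    all_taxa = topology.root.leaf_labels()
    for e, node in enumerate(edges):
        side = node.leaf_labels()
        for r, (i, j) in enumerate(pairs):
            if (taxa[i] in side) != (taxa[j] in side):
                A[r, e] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.linalg.norm(A @ x - y))


# ---------------------------------------------------------------------------
# NJ


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]])
        t = nj_tree(DistanceMatrix(taxa=list("abc"), d=d))
        lengths = {n.label: n.length for n in t.leaves()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_recovery(self):
        """((A,B),(C,D)) with internal branch 1: split and lengths exact."""
        pend = {"A": 0.5, "B": 1.5, "C": 0.7, "D": 2.0}
        taxa = list("ABCD")
        d = np.zeros((4, 4))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    inner = 0.0 if {a, b} in ({"A", "B"}, {"C", "D"}) else 1.0
                    d[i, j] = d[j, i] = pend[a] + pend[b] + inner
        t = nj_tree(DistanceMatrix(taxa=taxa, d=d))
        assert t.has_clade({"A", "B"}) and t.has_clade({"C", "D"})
        got = _path_length_matrix(t)
        assert np.allclose(got.d, d, atol=1e-12)

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (5, 2),
                                             (6, 3), (6, 4)])
    def test_additive_matrix_beats_exhaustive_oracle(self, n_taxa, seed):
        """On an additive matrix NJ returns the unique zero-residual
        topology found by exhaustive least-squares enumeration."""
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(n_taxa)]
        true = _random_binary_tree(labels, rng)
        dm = _path_length_matrix(true)
        nj = nj_tree(dm)
        residuals = [(t, _ls_residual(t, dm))
                     for t in _all_unrooted_topologies(labels)]
        zero = [t for t, r in residuals if r < 1e-8]
        assert len({frozenset(map(tuple, t.bipartitions())) for t in zero}) == 1
        assert nj.same_topology(zero[0])
        assert np.allclose(_path_length_matrix(nj).d, dm.d, atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_scikit_bio(self, seed):
        """Independent NJ implementation gives the same unrooted topology."""
        import skbio
        rng = np.random.default_rng(seed + 10)
        labels = [f"t{i}" for i in range(7)]
        true = _random_binary_tree(labels, rng)
        dm = _path_length_matrix(true)
        ours = nj_tree(dm)
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.taxa))
        theirs = parse_newick(str(sk))
        assert ours.same_topology(theirs)

    def test_negative_branch_clamped_with_shift(self):
        d = np.array([
            [0.0, 0.1, 0.4, 0.5],
            [0.1, 0.0, 0.45, 0.55],
            [0.4, 0.45, 0.0, 0.2],
            [0.5, 0.55, 0.2, 0.0]])
        t = nj_tree(DistanceMatrix(taxa=list("abcd"), d=d))
        assert all((n.length or 0.0) >= 0.0 for n in t.postorder()
                   if n.parent is not None)

    def test_bionj_matches_nj_topology_on_additive_input(self):
        rng = np.random.default_rng(7)
        true = _random_binary_tree([f"t{i}" for i in range(6)], rng)
        dm = _path_length_matrix(true)
        assert bionj_tree(dm).same_topology(nj_tree(dm))

    def test_nonfinite_entry_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(taxa=list("abc"), d=d))


# ---------------------------------------------------------------------------
# Likelihood


def _jc_p(t):
    return 0.25 + 0.75 * math.exp(-4.0 * t / 3.0), 0.25 - 0.25 * math.exp(-4.0 * t / 3.0)


class TestLikelihood:
    def test_two_taxa_one_site_jc_closed_form(self):
        """lnL of one site = log(pi_i P_ij(t)) under the JC limit."""
        root = Node()
        root.add_child(Node(label="a", length=0.0))
        root.add_child(Node(label="b", length=0.2))
        tree = PhyloTree(root, rooted=True)
        model = TN93Model.jc()
        same, diff = _jc_p(0.2)
        msa_same = MultipleAlignment(ids=["a", "b"], rows=["A", "A"])
        msa_diff = MultipleAlignment(ids=["a", "b"], rows=["A", "C"])
        assert tree_log_likelihood(tree, msa_same, model) == pytest.approx(
            math.log(0.25 * same), rel=1e-10)
        assert tree_log_likelihood(tree, msa_diff, model) == pytest.approx(
            math.log(0.25 * diff), rel=1e-10)

    def test_pattern_compression_equals_per_site_brute_force(self):
        """Pruning with pattern compression equals an explicit sum over
        internal-state assignments, site by site."""
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(4)]
        msa = MultipleAlignment(ids=list("abcd"), rows=rows)
        root = Node()
        left, right = Node(length=0.1), Node(length=0.15)
        root.add_child(left)
        root.add_child(right)
        left.add_child(Node(label="a", length=0.07))
        left.add_child(Node(label="b", length=0.12))
        right.add_child(Node(label="c", length=0.2))
        right.add_child(Node(label="d", length=0.05))
        tree = PhyloTree(root, rooted=True)
        model = TN93Model((0.3, 0.2, 0.1, 0.4), 3.0, 5.0)
        p = {id(n): model.p_matrix(n.length) for n in tree.postorder()
             if n.parent is not None}
        code = {b: i for i, b in enumerate("ACGT")}
        total = 0.0
        for site in range(40):
            xa, xb, xc, xd = (code[rows[k][site]] for k in range(4))
            lik = 0.0
            for r in range(4):          # root state
                for l_ in range(4):     # left internal state
                    for rr in range(4):  # right internal state
                        lik += (model.freqs[r]
                                * p[id(left)][r, l_] * p[id(right)][r, rr]
                                * p[id(left.children[0])][l_, xa]
                                * p[id(left.children[1])][l_, xb]
                                * p[id(right.children[0])][rr, xc]
                                * p[id(right.children[1])][rr, xd])
            total += math.log(lik)
        assert tree_log_likelihood(tree, msa, model) == pytest.approx(
            total, rel=1e-10)

    def test_rerooting_invariance(self, sim_small):
        """Reversibility: lnL unchanged (<1e-8) under arbitrary rerooting."""
        msa = sim_small.msa
        dm = build_distance_matrix(msa, "TN93-MCL", "complete")
        tree = nj_tree(dm)
        model = TN93Model((0.3, 0.25, 0.12, 0.33), 6.0, 9.0)
        base = tree_log_likelihood(tree, msa, model)
        for idx in (0, 2, 4):
            t2 = tree.copy()
            nodes = [n for n in t2.postorder() if n.parent is not None]
            rerooted = t2.reroot_on_edge(nodes[idx], fraction=0.3)
            assert abs(tree_log_likelihood(rerooted, msa, model) - base) < 1e-8

    def test_branch_optimization_increases_likelihood(self, sim_small):
        msa = sim_small.msa
        dm = build_distance_matrix(msa, "TN93-MCL", "complete")
        tree = nj_tree(dm)
        model = TN93Model((0.3, 0.25, 0.12, 0.33), 6.0, 9.0)
        before = tree_log_likelihood(tree, msa, model)
        opt, after = optimize_branch_lengths(tree, msa, model)
        assert after >= before - 1e-9
        assert tree_log_likelihood(opt, msa, model) == pytest.approx(after)


# ---------------------------------------------------------------------------
# ML search, bootstrap, BIC


class TestMLSearch:
    def test_recovers_simulated_topology(self):
        """True 6-taxon topology found in nearly all replicates."""
        hits = 0
        for seed in range(8):
            data = simulate_dataset(SimulationConfig(
                seed=seed + 100, n_taxa=6, n_outgroups=2))
            ml, _ = optimize_ml_tree(data.msa)
            hits += ml.same_topology(data.subst_tree)
        assert hits >= 7

    def test_true_topology_is_local_optimum(self):
        data = simulate_dataset(SimulationConfig(seed=42, n_taxa=5,
                                                 n_outgroups=1))
        ml, fit = optimize_ml_tree(data.msa)
        assert fit.loglik < 0 and fit.bic > 0
        # starting a fresh search from the found optimum changes nothing
        ml2, fit2 = optimize_ml_tree(data.msa)
        assert ml.same_topology(ml2)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=0.05)


class TestBootstrap:
    def _diagnostic_msa(self):
        a = "A" * 50 + "C" * 50
        b = "A" * 50 + "C" * 50
        c = "G" * 50 + "C" * 50
        d = "G" * 50 + "C" * 50
        return MultipleAlignment(ids=list("abcd"),
                                 rows=[r + "ACGT" * 25 for r in (a, b, c, d)])

    def test_strong_signal_high_support(self):
        t = bootstrap_support(self._diagnostic_msa(), model="p",
                              policy="pairwise", n_replicates=1000, seed=3)
        supports = [n.support for n in t.postorder() if n.support is not None]
        assert supports and all(s > 95 for s in supports)

    def test_supports_within_range_and_reproducible(self, sim_small):
        t1 = bootstrap_support(sim_small.msa, n_replicates=80, seed=5)
        t2 = bootstrap_support(sim_small.msa, n_replicates=80, seed=5)
        s1 = [n.support for n in t1.postorder() if n.support is not None]
        s2 = [n.support for n in t2.postorder() if n.support is not None]
        assert s1 == s2
        assert all(0.0 <= s <= 100.0 for s in s1)

    def test_no_variation_gives_full_support(self):
        msa = MultipleAlignment(ids=list("abcd"), rows=["ACGT" * 30] * 4)
        t = bootstrap_support(msa, model="p", policy="pairwise",
                              n_replicates=50, seed=1)
        supports = [n.support for n in t.postorder() if n.support is not None]
        assert all(s == 100.0 for s in supports)


class TestModelSelection:
    def test_jc_data_prefers_jc(self):
        # neutral coding (dnds high) so selection does not induce ts bias
        data = simulate_dataset(SimulationConfig(
            seed=8, n_taxa=5, n_outgroups=1, kappa1=1.0, kappa2=1.0,
            freqs=(0.25, 0.25, 0.25, 0.25), dnds=10.0))
        fits, best = select_model_bic(data.msa)
        by_name = {f.model: f.bic for f in fits}
        assert by_name["JC69"] <= best.bic + 2.0

    def test_transition_bias_rejects_jc(self):
        data = simulate_dataset(SimulationConfig(seed=9, n_taxa=5,
                                                 n_outgroups=1))
        fits, best = select_model_bic(data.msa)
        by_name = {f.model: f.bic for f in fits}
        assert best.model in ("K2P", "TN93")
        assert by_name["JC69"] - best.bic > 10.0

    def test_bic_ordering_invariant_to_taxon_order(self):
        data = simulate_dataset(SimulationConfig(seed=10, n_taxa=5,
                                                 n_outgroups=1))
        msa = data.msa
        perm = list(reversed(range(len(msa.ids))))
        msa2 = MultipleAlignment(ids=[msa.ids[i] for i in perm],
                                 rows=[msa.rows[i] for i in perm])
        order1 = [f.model for f in sorted(select_model_bic(msa)[0],
                                          key=lambda f: f.bic)]
        order2 = [f.model for f in sorted(select_model_bic(msa2)[0],
                                          key=lambda f: f.bic)]
        assert order1 == order2
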