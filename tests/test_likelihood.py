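"""Pruning likelihood, branch-length optimization, model fitting and NNI search."""

import numpy as np
import pytest

import nrevphylo as nv
from nrevphylo.alignment import NucAlignment
from nrevphylo.errors import DomainError, LabellingError
from nrevphylo.likelihood import FitOptions, PhyloLikelihood, fit_model, nni_search
from nrevphylo.models import transition_matrix
from nrevphylo.trees import Node, RootedTree

from _oracles import brute_force_loglik


class TestLogLikelihood:
    def test_two_taxa_zero_lengths_single_site(self):
        tree = RootedTree.from_newick("(A:0,B:0);")
        aln = NucAlignment(names=["A", "B"], sequences=["A", "A"])
        q = nv.ladder_matrix(0.0)
        ll = nv.log_likelihood(aln, tree, q, nv.BaseFrequencies.uniform())
        assert ll == pytest.approx(np.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("ntaxa", [3, 4])
    def test_matches_exhaustive_enumeration(self, ntaxa, rng):
        """Pruning equals brute-force summation over internal states for
        random (Q, branch lengths, gamma) configurations."""
        for trial in range(10):
            lens = rng.uniform(0.02, 1.5, size=2 * ntaxa - 2)
            if ntaxa == 3:
                nwk = "((A:{}:,B:{}):{},C:{});".replace(":{}:", ":{}")
                nwk = "((A:%g,B:%g):%g,C:%g);" % tuple(lens[:4])
            else:
                nwk = "((A:%g,B:%g):%g,(C:%g,D:%g):%g);" % tuple(lens[:6])
            tree = RootedTree.from_newick(nwk)
            q = nv.normalize_q(nv.build_nrev12_q(rng.uniform(0.05, 3.0, 12)))
            pi = nv.stationary_distribution(q)
            gamma = nv.discretize_gamma(rng.uniform(0.3, 2.0), int(rng.integers(1, 4)))
            aln = nv.simulate_alignment(tree, q, 5, gamma=gamma, seed=trial)
            ll = nv.log_likelihood(aln, tree, q, pi, gamma)
            bf = brute_force_loglik(aln, tree, q, pi, gamma)
            assert ll == pytest.approx(bf, abs=1e-10)

    def test_ambiguity_codes_as_partial_observations(self, quartet_tree):
        q = nv.ladder_matrix(2.0)
        pi = nv.stationary_distribution(q)
        aln = NucAlignment(names=list("ABCD"), sequences=["AR", "C-", "GN", "TY"])
        ll = nv.log_likelihood(aln, quartet_tree, q, pi)
        bf = brute_force_loglik(aln, quartet_tree, q, pi)
        assert ll == pytest.approx(bf, abs=1e-10)

    def test_gamma_ncat1_equals_no_gamma(self, quartet_tree):
        q = nv.ladder_matrix(4.0)
        pi = nv.stationary_distribution(q)
        aln = nv.simulate_alignment(quartet_tree, q, 100, seed=5)
        a = nv.log_likelihood(aln, quartet_tree, q, pi, nv.discretize_gamma(0.6, 1))
        b = nv.log_likelihood(aln, quartet_tree, q, pi)
        assert a == b

    def test_invariant_to_taxon_order(self, quartet_tree):
        q = nv.ladder_matrix(2.0)
        pi = nv.stationary_distribution(q)
        aln = nv.simulate_alignment(quartet_tree, q, 200, seed=9)
        perm = [2, 0, 3, 1]
        aln2 = NucAlignment(names=[aln.names[i] for i in perm],
                            sequences=[aln.sequences[i] for i in perm])
        assert nv.log_likelihood(aln, quartet_tree, q, pi) == pytest.approx(
            nv.log_likelihood(aln2, quartet_tree, q, pi), abs=1e-9)

    def test_unmatched_tip_label(self, quartet_tree):
        aln = NucAlignment(names=["A", "B", "C", "X"], sequences=["A"] * 4)
        with pytest.raises(LabellingError):
            nv.log_likelihood(aln, quartet_tree, nv.ladder_matrix(0.0),
                              nv.BaseFrequencies.uniform())

    def test_site_logliks_nonpositive(self, quartet_tree):
        q = nv.ladder_matrix(0.0)
        pi = nv.stationary_distribution(q)
        aln = nv.simulate_alignment(quartet_tree, q, 50, seed=1)
        eng = PhyloLikelihood(aln, quartet_tree)
        eng.set_model(q, pi, nv.GammaRates.none())
        assert np.all(eng.site_logliks() <= 1e-12)


class TestPulleyPrinciple:
    def _reroot_along_root_edge(self, tree, delta):
        """Move the root along the edge between its two children."""
        t = tree.copy()
        a, b = t.root.children
        total = a.length + b.length
        a.length = delta
        b.length = total - delta
        return t

    def test_reversible_model_root_invariant(self, rng):
        tree = RootedTree.from_newick("((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.3);")
        pi = nv.BaseFrequencies(rng.dirichlet(np.ones(4)))
        q = nv.normalize_q(nv.build_gtr_q(rng.uniform(0.2, 2.0, 6), pi), pi)
        aln = nv.simulate_alignment(tree, q, 300, seed=2)
        lls = [nv.log_likelihood(aln, self._reroot_along_root_edge(tree, d), q, pi)
               for d in (0.05, 0.25, 0.45)]
        assert max(lls) - min(lls) < 1e-8

    def test_nonreversible_model_root_position_matters(self):
        tree = RootedTree.from_newick("((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.3);")
        q = nv.ladder_matrix(8.0, normalized=True)
        pi = nv.stationary_distribution(q)
        aln = nv.simulate_alignment(tree, q, 300, seed=2)
        lls = [nv.log_likelihood(aln, self._reroot_along_root_edge(tree, d), q, pi)
               for d in (0.05, 0.45)]
        assert abs(lls[0] - lls[1]) > 1e-4


class TestBranchOptimization:
    def test_monotone_from_truth(self, quartet_tree):
        q = nv.ladder_matrix(2.0)
        pi = nv.stationary_distribution(q)
        aln = nv.simulate_alignment(quartet_tree, q, 2000, seed=3)
        before = nv.log_likelihood(aln, quartet_tree, q, pi)
        t2 = nv.optimize_branch_lengths(aln, quartet_tree, q, pi)
        after = nv.log_likelihood(aln, t2, q, pi)
        assert after >= before - 1e-9
        assert after - before < 10.0  # truth is near-optimal at 2000 sites

    def test_recovers_inflated_branch(self):
        tree = nv.synthetic_true_tree(8, seed=11).scale_branches(1.5)
        q = nv.ladder_matrix(0.0)
        pi = nv.stationary_distribution(q)
        aln = nv.simulate_alignment(tree, q, 5000, seed=4)
        broken = tree.copy()
        victim = [n for n in broken.preorder()
                  if n.parent is not None and n.length > 0.05][0]
        truth = victim.length
        victim.length = truth * 10
        fixed = nv.optimize_branch_lengths(aln, broken, q, pi, sweeps=6)
        recovered = [n for n, m in zip(fixed.preorder(), broken.preorder())
                     if m is victim][0].length
        assert recovered == pytest.approx(truth, rel=0.2)

    def test_zero_start_on_divergent_data(self, quartet_tree):
        q = nv.ladder_matrix(0.0)
        pi = nv.stationary_distribution(q)
        aln = nv.simulate_alignment(quartet_tree, q, 1000, seed=6)
        flat = quartet_tree.copy()
        for n in flat.preorder():
            if n.parent is not None:
                n.length = 0.0
        out = nv.optimize_branch_lengths(aln, flat, q, pi, sweeps=6)
        assert all(n.length > 0 for n in out.preorder() if n.parent is not None)


@pytest.fixture(scope="module")
def sim12():
    tree = nv.synthetic_true_tree(12, seed=21).scale_branches(2.0)
    q = nv.ladder_matrix(2.0, normalized=True)
    aln = nv.simulate_alignment(tree, q, 2000, seed=22)
    return aln, tree


class TestFitModel:
    def test_model_nesting_on_likelihood(self, sim12):
        aln, tree = sim12
        opts = FitOptions(gamma_ncat=1)
        fits = {f: fit_model(aln, tree, f, opts) for f in ("GTR", "NREV6", "NREV12")}
        assert fits["NREV12"].logL >= fits["NREV6"].logL - 1e-4
        assert fits["NREV12"].logL >= fits["GTR"].logL - 1e-4

    def test_aicc_consistent_with_formula(self, sim12):
        aln, tree = sim12
        fit = fit_model(aln, tree, "NREV6", FitOptions(gamma_ncat=1))
        assert fit.aicc == pytest.approx(nv.aicc(fit.logL, fit.k, fit.n), abs=1e-9)
        # 5 class rates + 22 branches for a 12-taxon bifurcating rooted tree
        assert fit.k == 5 + len(fit.tree.branches())

    def test_identical_sequences_zero_branches(self):
        tree = RootedTree.from_newick("((A:0.2,B:0.3):0.1,(C:0.1,D:0.2):0.2);")
        aln = NucAlignment(names=list("ABCD"), sequences=["ACGTACGTAC" * 6] * 4)
        fit = fit_model(aln, tree, "GTR", FitOptions(gamma_ncat=1))
        assert all(n.length <= 1e-6 for n in fit.tree.preorder() if n.parent is not None)

    def test_nrev12f_estimates_root_freqs(self, sim12):
        aln, tree = sim12
        opts = FitOptions(gamma_ncat=1)
        f12 = fit_model(aln, tree, "NREV12", opts)
        f12f = fit_model(aln, tree, "NREV12F",
                         FitOptions(gamma_ncat=1,
                                    init_rates=np.concatenate(
                                        [[f12.rates12[0]], f12.rates12[2:]])))
        assert f12f.root_freq_source == "free"
        assert f12f.logL >= f12.logL - 1e-4
        assert f12f.k == f12.k + 3

    def test_unknown_family_rejected(self, sim12):
        aln, tree = sim12
        with pytest.raises(DomainError):
            fit_model(aln, tree, "HKY")


class TestNNISearch:
    def test_true_topology_is_local_optimum(self):
        tree = nv.synthetic_true_tree(6, seed=31).scale_branches(3.0)
        q = nv.ladder_matrix(0.0, normalized=True)
        aln = nv.simulate_alignment(tree, q, 3000, seed=32)
        out, fit = nni_search(aln, "GTR", tree, seed=0, opts=FitOptions(gamma_ncat=1))
        same = nv.rf_distance(out, tree) == 0
        assert same

    def test_deterministic_given_seed(self):
        tree = nv.synthetic_true_tree(6, seed=41)
        q = nv.ladder_matrix(4.0)
        aln = nv.simulate_alignment(tree.scale_branches(4.0), q, 500, seed=42)
        start = nv.nj_start_tree(aln)
        t1, f1 = nni_search(aln, "NREV12", start, seed=7, opts=FitOptions(gamma_ncat=1))
        t2, f2 = nni_search(aln, "NREV12", start, seed=7, opts=FitOptions(gamma_ncat=1))
        assert t1.to_newick() == t2.to_newick()
        assert f1.logL == f2.logL

    def test_matches_exhaustive_five_taxon_search(self):
        """NNI hill climbing finds the ML topology among all 15 unrooted
        5-taxon trees on clean data."""
        true = RootedTree.from_newick(
            "(((A:0.4,B:0.45):0.25,C:0.6):0.2,(D:0.5,E:0.4):0.2);")
        q = nv.ladder_matrix(0.0)
        aln = nv.simulate_alignment(true, q, 2000, seed=50)
        opts = FitOptions(gamma_ncat=1)
        start = nv.nj_start_tree(aln)
        found, fit = nni_search(aln, "GTR", start, seed=0, opts=opts)
        best = -np.inf
        for topo in _all_five_taxon_topologies():
            f = fit_model(aln, topo, "GTR", opts)
            best = max(best, f.logL)
        assert fit.logL == pytest.approx(best, abs=0.05)


def _all_five_taxon_topologies():
    """All 15 unrooted labelled topologies on {A..E}, arbitrarily rooted."""
    base = RootedTree.from_newick("((A:0.1,B:0.1):0.1,C:0.1);")
    trees = []
    for t3 in [base]:
        for edge_i in range(len(t3.branches())):
            t4 = _attach(t3, edge_i, "D")
            for edge_j in range(len(t4.branches())):
                trees.append(_attach(t4, edge_j, "E"))
    # deduplicate by split sets
    from nrevphylo.trees import unrooted_splits
    seen = {}
    for t in trees:
        key = frozenset(k for k in unrooted_splits(t) if len(k) > 1)
        seen.setdefault(key, t)
    assert len(seen) == 15
    return list(seen.values())


def _attach(tree, edge_index, label):
    t = tree.copy()
    victim = t.branches()[edge_index]
    parent = victim.parent
    mid = Node(length=max(victim.length / 2, 0.05))
    victim.length = max(victim.length / 2, 0.05)
    parent.children[parent.children.index(victim)] = mid
    mid.parent = parent
    mid.add(victim)
    mid.add(Node(name=label, length=0.1))
    return RootedTree(t.root)
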