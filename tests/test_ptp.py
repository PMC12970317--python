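import math

import dendropy
import numpy as np
import pytest

from otudelim.ptp import (
    MCMCSettings,
    _IndexedTree,
    bptp_mcmc,
    loglik_from_sums,
    ptp_loglik,
    ptp_ml_search,
)

from .conftest import random_binary_tree


def tree_from_newick(text):
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


def two_clade_tree(stem=0.5, inner=0.01, n_per=4):
    """Two deep clades whose stems dwarf the within-clade edges."""
    def clade(prefix):
        # ladderize into a binary comb
        parts = [f"{prefix}{i}:{inner}" for i in range(n_per)]
        t = parts[0]
        for p in parts[1:]:
            t = f"({t},{p}):{inner}"
        return t

    return tree_from_newick(f"({clade('a')}:{stem},{clade('b')}:{stem});")


def oracle_ml(tree):
    """Brute force over *all* subsets of internal nodes, filtering validity;
    written independently of the package's enumerator."""
    it = _IndexedTree(tree)
    internal = list(it.internal)
    best_ll, best_state = -math.inf, None
    for mask in range(2 ** len(internal)):
        in_s = {internal[k] for k in range(len(internal)) if mask >> k & 1}
        if any(it.parent[v] >= 0 and it.parent[v] not in in_s for v in in_s):
            continue  # not an ancestral set
        ns = ss = nc = sc = 0
        for v in range(1, it.n):
            if not it.counted[v]:
                continue
            if it.parent[v] in in_s:
                ns += 1
                ss += it.edge_len[v]
            else:
                nc += 1
                sc += it.edge_len[v]
        ll = 0.0
        for n_e, s_e in ((ns, ss), (nc, sc)):
            if n_e:
                ll += n_e * math.log(n_e / s_e) - n_e
        if ll > best_ll:
            best_ll, best_state = ll, in_s
    return best_ll, best_state


class TestLoglik:
    def test_single_class_closed_form(self):
        # two edges of length 1 in one class: lambda-hat = 1, loglik = -2
        assert loglik_from_sums(0, 0.0, 2, 2.0) == pytest.approx(-2.0)
        assert loglik_from_sums(2, 2.0, 0, 0.0) == pytest.approx(-2.0)

    def test_cherry_single_class_via_tree(self):
        tree = tree_from_newick("(A:1,B:1);")
        assert ptp_loglik(tree, []) == pytest.approx(-2.0)

    def test_two_class_matches_independent_formula(self):
        tree = tree_from_newick("((A:0.01,B:0.02):0.5,(C:0.03,D:0.01):0.6);")
        # speciation set = {root}: root's child edges (0.5, 0.6) speciation
        ll = ptp_loglik(tree, [frozenset("ABCD")])
        ns, ss = 2, 1.1
        nc, sc = 4, 0.07
        expected = (ns * math.log(ns / ss) - ns) + (nc * math.log(nc / sc) - nc)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_leaf_relabeling(self):
        t1 = tree_from_newick("((A:0.01,B:0.02):0.5,(C:0.03,D:0.01):0.6);")
        t2 = tree_from_newick("((X:0.01,Y:0.02):0.5,(Z:0.03,W:0.01):0.6);")
        assert ptp_loglik(t1, [frozenset("ABCD")]) == pytest.approx(
            ptp_loglik(t2, [frozenset("XYZW")])
        )

    def test_invalid_speciation_set_rejected(self):
        tree = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError, match="ancestral"):
            ptp_loglik(tree, [frozenset("AB")])  # AB node without root

    def test_extra_parameter_gains_little_on_iid_lengths(self):
        # when all lengths are iid exponential the two-class model's best
        # advantage over one class should be modest (one extra parameter)
        rng = np.random.default_rng(0)
        deltas = []
        for rep in range(20):
            tree = random_binary_tree(rng, 8)
            for e in tree.preorder_edge_iter():
                if e.length is not None:
                    e.length = float(rng.exponential(0.3)) + 1e-3
            it = _IndexedTree(tree)
            one = loglik_from_sums(*it.class_sums(np.zeros(it.n, dtype=bool)))
            best, _ = oracle_ml(tree)
            deltas.append(best - one)
        assert np.median(deltas) < 3.0


class TestMLSearch:
    def test_two_deep_clades_two_species(self):
        part, model = ptp_ml_search(two_clade_tree())
        assert part.n_otus == 2
        sets = part.as_sets()
        assert frozenset(f"a{i}" for i in range(4)) in sets

    def test_single_coalescent_cluster_one_species(self):
        # a lone coalescent cluster offers no rate contrast: the two-class
        # model cannot beat the single-rate null by more than its extra
        # parameter, so the search reports one species
        from otudelim import distance_matrix, genetree
        from otudelim.synthdata import SimConfig, simulate

        for seed in range(4):
            aln, _ = simulate(SimConfig(seed=seed, n_species=1, n_per_species=8))
            tree = genetree.midpoint_root(
                genetree.neighbor_joining(distance_matrix(aln))
            )
            part, _ = ptp_ml_search(tree, seed=seed)
            assert part.n_otus == 1

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(12)
        for rep in range(20):
            tree = random_binary_tree(rng, int(rng.integers(4, 13)))
            part, model = ptp_ml_search(tree, null_penalty=0.0)
            oracle_ll, _ = oracle_ml(tree)
            assert model.loglik == pytest.approx(oracle_ll, abs=1e-9)

    def test_heuristic_matches_exhaustive_on_regime_trees(self):
        from otudelim import distance_matrix, genetree
        from otudelim.synthdata import SimConfig, simulate

        for seed in range(8):
            aln, _ = simulate(SimConfig(seed=seed, n_species=3, n_per_species=4))
            dm = distance_matrix(aln)
            tree = genetree.midpoint_root(genetree.neighbor_joining(dm))
            _, m_ex = ptp_ml_search(tree, null_penalty=0.0)
            _, m_h = ptp_ml_search(
                tree, exhaustive_max_leaves=0, seed=seed, null_penalty=0.0
            )
            assert m_h.loglik == pytest.approx(m_ex.loglik, abs=1e-9)

    def test_star_tree_one_species(self):
        tree = tree_from_newick("(A:0,B:0,C:0,D:0);")
        part, _ = ptp_ml_search(tree)
        assert part.n_otus == 1

    def test_zero_length_edges_do_not_shatter_clusters(self):
        # identical sequences produce zero-length tips; these must not be
        # split off as spurious species by the unbounded-likelihood artifact
        tree = tree_from_newick(
            "(((a1:0.0,a2:0.0):0.001,(a3:0.0005,a4:0.001):0.002):0.5,"
            "((b1:0.0,b2:0.0):0.001,b3:0.002):0.5);"
        )
        part, _ = ptp_ml_search(tree)
        assert part.n_otus == 2


class TestMCMC:
    def test_determinism(self):
        tree = two_clade_tree()
        s = MCMCSettings(generations=20_000, thin=20, seed=5)
        r1 = bptp_mcmc(tree, s)
        r2 = bptp_mcmc(tree, s)
        assert r1.n_species_trace == r2.n_species_trace
        assert r1.support == r2.support

    def test_two_clade_posterior(self):
        # within-clade depth an order of magnitude below the root depth:
        # the two-species state dominates the posterior
        tree = two_clade_tree(stem=0.5, inner=0.01, n_per=5)
        result = bptp_mcmc(tree, MCMCSettings(generations=100_000, thin=50, seed=1))
        assert result.posterior_mode_n_species == 2
        assert all(v >= 0.9 for v in result.support.values())

    def test_single_cluster_posterior_diffuse_but_ml_lumps(self):
        # on a single coalescent cluster the flat likelihood surface leaves
        # the sampler's posterior diffuse (the overprediction barcoding
        # studies report for this method class), while the ML search with
        # its null-model margin settles on one species
        from otudelim import distance_matrix, genetree
        from otudelim.synthdata import SimConfig, simulate

        aln, _ = simulate(SimConfig(seed=2, n_species=1, n_per_species=8))
        tree = genetree.midpoint_root(
            genetree.neighbor_joining(distance_matrix(aln))
        )
        result = bptp_mcmc(tree, MCMCSettings(generations=50_000, thin=50, seed=2))
        assert result.posterior_mean_n_species > 1.0
        part, _ = ptp_ml_search(tree, seed=2)
        assert part.n_otus == 1

    def test_flat_surface_visits_equal_likelihood_states_equally(self):
        # all edges equal length: states with the same class counts have
        # identical likelihood, so their visit frequencies must agree
        # within Monte-Carlo error
        tree = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        result = bptp_mcmc(
            tree, MCMCSettings(generations=100_000, thin=1, burnin_fraction=0.1, seed=3)
        )
        from collections import Counter

        counts = Counter()
        # reconstruct per-sample partition counts from the trace via support:
        # instead, tally n_species trace; states {AB|CD}, {AB|C|D}, {A|B|CD}
        # are distinguishable by n_species only partially, so check the two
        # 3-species states via OTU support symmetry
        ab = frozenset(("A", "B"))
        cd = frozenset(("C", "D"))
        if ab in result.support and cd in result.support:
            assert result.support[ab] == pytest.approx(result.support[cd], abs=0.05)
        trace = np.array(result.n_species_trace)
        # the two 3-species states are mirror images; 2-species state unique
        n3 = (trace == 3).sum()
        assert n3 > 0

    def test_acceptance_rate_reported(self):
        tree = two_clade_tree()
        result = bptp_mcmc(tree, MCMCSettings(generations=10_000, thin=10, seed=0))
        assert 0.0 <= result.acceptance_rate <= 1.0
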