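"""Tree I/O, pruning, consensus, and the BM / Mk trait models."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize

from beaknest import phylo, synth
from beaknest.phylo import BMParams, MkParams, TreeError

from conftest import star_tree


class TestNewickIO:
    def test_read_small_tree(self):
        t = phylo.read_newick("((A:1,B:1):1,C:2);")
        assert sorted(phylo.tip_labels(t)) == ["A", "B", "C"]
        C = phylo.vcv_matrix(t)
        assert C.loc["A", "A"] == pytest.approx(2.0)  # root-to-tip depth
        assert C.loc["A", "B"] == pytest.approx(1.0)
        assert C.loc["A", "C"] == pytest.approx(0.0)

    def test_round_trip_preserves_structure(self, yule_tree_200):
        s = phylo.write_newick(yule_tree_200)
        back = phylo.read_newick(s)
        assert sorted(phylo.tip_labels(back)) == sorted(phylo.tip_labels(yule_tree_200))
        D0 = phylo.patristic_distance_matrix(yule_tree_200)
        D1 = phylo.patristic_distance_matrix(back).loc[D0.index, D0.columns]
        np.testing.assert_allclose(D0.to_numpy(), D1.to_numpy(), atol=1e-9)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeError):
            phylo.read_newick("((A:1,B:1):1,A:2);")

    def test_malformed_newick_rejected(self):
        with pytest.raises(TreeError):
            phylo.read_newick("((A:1,B:1:1,C:2);")


class TestPrune:
    def test_prune_cherry(self):
        t = phylo.read_newick("((A:1,B:1):1,C:2);")
        p = phylo.prune_to_taxa(t, {"A", "B"})
        assert sorted(phylo.tip_labels(p)) == ["A", "B"]
        assert phylo.patristic_distance_matrix(p).loc["A", "B"] == pytest.approx(2.0)

    def test_prune_to_all_tips_is_identity(self, yule_tree_200):
        p = phylo.prune_to_taxa(yule_tree_200, set(phylo.tip_labels(yule_tree_200)))
        D0 = phylo.patristic_distance_matrix(yule_tree_200)
        D1 = phylo.patristic_distance_matrix(p).loc[D0.index, D0.columns]
        np.testing.assert_allclose(D0.to_numpy(), D1.to_numpy(), atol=1e-9)

    def test_missing_taxa_listed(self):
        t = phylo.read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(TreeError, match="X"):
            phylo.prune_to_taxa(t, {"A", "X"})

    def test_pairwise_distances_preserved_against_dendropy(self):
        # independent oracle: dendropy's own patristic distances on the
        # unpruned tree, restricted to the retained taxa
        tree = synth.simulate_tree(50, seed=3)
        labels = sorted(phylo.tip_labels(tree))[:20]
        pdm = tree.phylogenetic_distance_matrix()
        tx = tree.taxon_namespace
        expected = {
            (a, b): pdm.patristic_distance(tx.get_taxon(a), tx.get_taxon(b))
            for a, b in itertools.combinations(labels, 2)
        }
        pruned = phylo.prune_to_taxa(tree, labels)
        D = phylo.patristic_distance_matrix(pruned)
        for (a, b), d in expected.items():
            assert D.loc[a, b] == pytest.approx(d, abs=1e-9)

    def test_prune_preserves_covariance_of_retained_tips(self):
        # marginalizing BM over dropped tips = restricting C: the pruned
        # tree must induce the same covariance submatrix
        tree = synth.simulate_tree(40, seed=9)
        keep = sorted(phylo.tip_labels(tree))[:15]
        C_full = phylo.vcv_matrix(tree).loc[keep, keep]
        C_pruned = phylo.vcv_matrix(phylo.prune_to_taxa(tree, keep)).loc[keep, keep]
        np.testing.assert_allclose(C_full.to_numpy(), C_pruned.to_numpy(), atol=1e-9)


def _oracle_clade_frequencies(trees):
    """Clade frequencies via dendropy's own leaf iteration (independent of
    the implementation's postorder union bookkeeping)."""
    freq = {}
    for t in trees:
        for node in t.preorder_node_iter():
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(clade) > 1:
                freq[clade] = freq.get(clade, 0) + 1
    return freq


class TestConsensus:
    def test_identical_trees_returned_unchanged(self):
        trees = [phylo.read_newick("((A:1,B:1):1,C:2);") for _ in range(10)]
        cons = phylo.consensus_tree(trees)
        assert phylo.patristic_distance_matrix(cons).loc["A", "B"] == pytest.approx(2.0)
        assert phylo.patristic_distance_matrix(cons).loc["A", "C"] == pytest.approx(4.0)

    def test_majority_topology_selected_with_median_lengths(self):
        t1 = phylo.read_newick("((A:1,B:1):1,C:2);")
        t2 = phylo.read_newick("((A:2,B:2):2,C:4);")
        t3 = phylo.read_newick("((A:1,C:1):1,B:2);")
        cons = phylo.consensus_tree([t1, t2, t3])
        # AB clade appears twice, AC once -> AB topology wins
        D = phylo.patristic_distance_matrix(cons)
        # medians: A over {1,2,1}=1, B over {1,2,2}=2
        assert D.loc["A", "B"] == pytest.approx(1.0 + 2.0)

    def test_mcc_matches_exhaustive_scoring_on_5_tip_sample(self):
        rng = np.random.default_rng(17)
        trees = [synth.simulate_tree(5, seed=int(s)) for s in rng.integers(0, 30, size=12)]
        freq = _oracle_clade_frequencies(trees)
        n = len(trees)
        scores = []
        for t in trees:
            clades = [
                frozenset(lf.taxon.label for lf in node.leaf_iter())
                for node in t.preorder_node_iter()
            ]
            scores.append(
                sum(math.log(freq[c] / n) for c in clades if len(c) > 1)
            )
        best = int(np.argmax(scores))
        cons = phylo.consensus_tree(trees)
        expected_clades = set(_oracle_clade_frequencies([trees[best]]))
        got_clades = set(_oracle_clade_frequencies([cons]))
        assert got_clades == expected_clades

    def test_mcc_is_member_of_sample(self, small_dataset):
        trees = small_dataset.trees
        cons = phylo.consensus_tree(trees)
        member_clades = [set(_oracle_clade_frequencies([t])) for t in trees]
        assert set(_oracle_clade_frequencies([cons])) in member_clades

    def test_mismatched_tip_sets_rejected(self):
        t1 = phylo.read_newick("((A:1,B:1):1,C:2);")
        t2 = phylo.read_newick("((A:1,B:1):1,D:2);")
        with pytest.raises(TreeError, match="symmetric"):
            phylo.consensus_tree([t1, t2])


class TestBrownianMotion:
    def test_constant_trait_gives_zero_rate(self):
        t = phylo.read_newick("((A:1,B:1):1,C:2);")
        fit = phylo.fit_bm(t, {"A": 5.0, "B": 5.0, "C": 5.0})
        assert fit.sigma2 == 0.0
        assert fit.z0 == 5.0

    def test_star_tree_closed_form(self):
        # C = I on a unit star: GLS mean = sample mean, sigma2 = mean squared
        # deviation
        labels = list("ABCDEFGH")
        t = star_tree(labels)
        rng = np.random.default_rng(4)
        x = dict(zip(labels, rng.normal(size=len(labels))))
        fit = phylo.fit_bm(t, x)
        v = np.array(list(x.values()))
        assert fit.z0 == pytest.approx(v.mean(), abs=1e-10)
        assert fit.sigma2 == pytest.approx(((v - v.mean()) ** 2).mean(), abs=1e-10)

    def test_matches_direct_numerical_mvn_maximization(self):
        tree = synth.simulate_tree(10, seed=5)
        x = phylo.simulate_bm(tree, BMParams(2.0, 1.0), seed=2)["rep0"]
        fit = phylo.fit_bm(tree, x)
        order = list(x.index)
        C = phylo.vcv_matrix(tree).loc[order, order].to_numpy()
        Cinv = np.linalg.inv(C)
        _, logdetC = np.linalg.slogdet(C)
        vals = x.to_numpy()
        n = len(vals)

        def nll(p):
            s2, z0 = math.exp(p[0]), p[1]
            r = vals - z0
            return 0.5 * (n * math.log(2 * math.pi * s2) + logdetC + r @ Cinv @ r / s2)

        res = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        assert fit.sigma2 == pytest.approx(math.exp(res.x[0]), abs=1e-6)
        assert fit.z0 == pytest.approx(res.x[1], abs=1e-6)
        assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-6)

    def test_simulation_moments(self):
        # single tip at depth d: Var = sigma2 * d; sisters sharing stem s:
        # Cov = sigma2 * s
        t = phylo.read_newick("((A:0.5,B:0.5):1.5,C:2);")
        sims = phylo.simulate_bm(t, BMParams(sigma2=3.0, z0=-1.0), n_reps=10000, seed=8)
        a, b = sims.loc["A"].to_numpy(), sims.loc["B"].to_numpy()
        var_a = a.var()
        mc_se_var = 3.0 * 2.0 * math.sqrt(2 / (len(a) - 1))
        assert abs(var_a - 3.0 * 2.0) < 3 * mc_se_var
        cov_ab = np.cov(a, b)[0, 1]
        assert abs(cov_ab - 3.0 * 1.5) < 3 * mc_se_var
        assert sims.mean(axis=1).loc["C"] == pytest.approx(-1.0, abs=0.1)

    def test_zero_rate_simulation_is_constant(self):
        t = phylo.read_newick("((A:1,B:1):1,C:2);")
        sims = phylo.simulate_bm(t, BMParams(0.0, 7.0), n_reps=3, seed=0)
        assert (sims.to_numpy() == 7.0).all()


class TestMk:
    def test_zero_rate_keeps_root_state(self):
        t = phylo.read_newick("((A:1,B:1):1,C:2);")
        sims = phylo.simulate_mk(t, MkParams(k=3, q=0.0, levels=("x", "y", "z")),
                                 n_reps=20, seed=1)
        assert (sims.nunique(axis=0) == 1).all()

    def test_two_state_transition_probability(self):
        # tips joined by total path t: P(differ) = (1 - exp(-2 q t)) / 2
        t = phylo.read_newick("(A:0.5,B:0.5);")
        q = 0.7
        sims = phylo.simulate_mk(t, MkParams(k=2, q=q, levels=(0, 1)), n_reps=40000, seed=6)
        p_diff = float((sims.loc["A"] != sims.loc["B"]).mean())
        expected = (1 - math.exp(-2 * q * 1.0)) / 2
        se = math.sqrt(expected * (1 - expected) / 40000)
        assert abs(p_diff - expected) < 4 * se

    def test_fitted_rate_is_ml(self):
        tree = synth.simulate_tree(40, seed=13)
        states = phylo.simulate_mk(tree, MkParams(k=2, q=0.3, levels=("a", "b")),
                                   seed=4)["rep0"]
        fit = phylo.fit_mk(tree, states, levels=("a", "b"))
        ll_hat = phylo.mk_log_likelihood(tree, states, 2, fit.q, ("a", "b"))
        for q_alt in (fit.q / 2, fit.q * 2):
            assert ll_hat >= phylo.mk_log_likelihood(tree, states, 2, q_alt, ("a", "b"))

    def test_single_observed_state_warns_and_returns_zero(self):
        t = phylo.read_newick("((A:1,B:1):1,C:2);")
        with pytest.warns(UserWarning, match="single observed state"):
            fit = phylo.fit_mk(t, {"A": "x", "B": "x", "C": "x"}, levels=("x", "y"))
        assert fit.q == 0.0


def test_bm_parameter_recovery_smoke(yule_tree_200):
    """simulate_bm -> fit_bm recovers the rate on a single 200-tip draw."""
    x = phylo.simulate_bm(yule_tree_200, BMParams(1.5, 0.0), seed=99)["rep0"]
    fit = phylo.fit_bm(yule_tree_200, x)
    assert 0.5 * 1.5 < fit.sigma2 < 2.0 * 1.5
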