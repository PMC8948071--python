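"""Likelihood engine: closed-form oracles, invariances, search behavior."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from barcode_associate.mltree import (
    LikelihoodResult,
    PatternLikelihood,
    SubstitutionModel,
    compare_models,
    information_criteria,
    ml_bootstrap,
    ml_tree,
    model_parameters_fit,
    nni_search,
    optimize_branch_lengths,
    site_log_likelihood,
)
from barcode_associate.records import Dataset
from barcode_associate.synthgen import SimulationConfig, simulate_dataset
from barcode_associate.tree import PhyloTree

from conftest import make_record

DEC = np.array(list("ACGT"))


def two_leaf_dataset(seq_a, seq_b):
    return Dataset([make_record("s1", seq_a), make_record("s2", seq_b, stage="larva")])


def two_leaf_tree(t):
    tree = PhyloTree()
    a, b = tree.add_node("s1"), tree.add_node("s2")
    tree.add_edge(a, b, t)
    return tree


def simulate_pair(model, t, L, seed):
    rng = np.random.default_rng(seed)
    a = rng.choice(4, size=L, p=model.base_freqs)
    P = model.transition_matrix(t)
    cum = P.cumsum(axis=1)
    b = (rng.random(L)[:, None] > cum[a]).sum(axis=1)
    return "".join(DEC[a]), "".join(DEC[b])


class TestSubstitutionModel:
    def test_rate_matrix_is_scaled_and_reversible(self):
        m = SubstitutionModel.tim2(np.array([0.35, 0.15, 0.1, 0.4]), 1.3, 5.0, 7.0)
        Q = m.q_matrix()
        pi = m.base_freqs
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0)
        np.testing.assert_allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)

    def test_transition_matrix_matches_expm(self):
        m = SubstitutionModel.hky(np.array([0.3, 0.2, 0.2, 0.3]), kappa=3.0)
        for t in (0.01, 0.2, 1.5):
            np.testing.assert_allclose(
                m.transition_matrix(t), expm(m.q_matrix() * t), atol=1e-10
            )

    def test_constraint_violations_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionModel("TIM2", np.full(4, 0.25), np.array([1, 2, 3, 4, 5, 6.0]))
        with pytest.raises(ValueError):
            SubstitutionModel("JC", np.array([0.3, 0.2, 0.2, 0.3]), np.ones(6))

    def test_category_rates_have_mean_one(self):
        for alpha in (0.1, 0.5, 2.0, 50.0):
            rates = SubstitutionModel.jc(gamma_alpha=alpha).category_rates()
            assert len(rates) == 4
            assert rates.mean() == pytest.approx(1.0, abs=1e-10)
            assert np.all(np.diff(rates) > 0)

    def test_free_parameter_counts(self):
        n = 10  # 17 branches on an unrooted binary tree
        assert SubstitutionModel.jc().n_free_parameters(n) == 17
        assert SubstitutionModel.k2p(2.0).n_free_parameters(n) == 18
        assert SubstitutionModel.hky(np.full(4, 0.25), 2.0).n_free_parameters(n) == 21
        assert SubstitutionModel.tim2(np.full(4, 0.25), gamma_alpha=0.5).n_free_parameters(n) == 24


class TestPruningOracles:
    def test_identical_pair_zero_length_is_base_freq_sum(self):
        seq = "ACGT" * 50
        ds = two_leaf_dataset(seq, seq)
        lr = site_log_likelihood(two_leaf_tree(0.0), ds, SubstitutionModel.jc())
        assert lr.log_likelihood == pytest.approx(200 * math.log(0.25), abs=1e-10)

    @pytest.mark.parametrize("model_name", ["jc", "k2p"])
    def test_two_leaf_matches_closed_form(self, model_name):
        model = (
            SubstitutionModel.jc()
            if model_name == "jc"
            else SubstitutionModel.k2p(kappa=4.0)
        )
        t = 0.25
        sa, sb = simulate_pair(model, t, 400, seed=8)
        ds = two_leaf_dataset(sa, sb)
        lr = site_log_likelihood(two_leaf_tree(t), ds, model)
        # independent oracle: P(t) by scipy expm, per-site pair probabilities
        P = expm(model.q_matrix() * t)
        enc = {c: i for i, c in enumerate("ACGT")}
        expect = sum(
            math.log(0.25 * P[enc[x], enc[y]]) for x, y in zip(sa, sb)
        )
        assert lr.log_likelihood == pytest.approx(expect, abs=1e-8)

    def test_gamma_degenerates_at_large_alpha(self):
        # barcode-scale divergence on a full-length fragment
        model = SubstitutionModel.k2p(kappa=4.0)
        sa, sb = simulate_pair(model, 0.1, 658, seed=2)
        ds = two_leaf_dataset(sa, sb)
        hom = site_log_likelihood(two_leaf_tree(0.1), ds, model).log_likelihood
        g4 = site_log_likelihood(
            two_leaf_tree(0.1), ds, SubstitutionModel.k2p(4.0, gamma_alpha=1e6)
        ).log_likelihood
        assert g4 == pytest.approx(hom, abs=1e-6)

    def test_relabeling_invariance(self):
        cfg = SimulationConfig(n_species=5, specimens_per_species=(2, 2),
                               fraction_unknown=0.0, seed=3)
        ds, _ = simulate_dataset(cfg)
        from barcode_associate.distmat import build_matrix
        from barcode_associate.njtree import nj

        tree = nj(build_matrix(ds, "k2p"))
        model = SubstitutionModel.hky(np.array([0.3, 0.2, 0.2, 0.3]), 4.0, 0.7)
        lnl = site_log_likelihood(tree, ds, model).log_likelihood
        # permute record order; tree and data identities are unchanged
        perm = Dataset(list(reversed(ds.records)))
        lnl_perm = site_log_likelihood(tree, perm, model).log_likelihood
        assert lnl_perm == pytest.approx(lnl, abs=1e-8)

    def test_missing_data_leaf_is_uninformative(self):
        seq = "ACGT" * 30
        ds = two_leaf_dataset(seq, "N" * 120)
        lr = site_log_likelihood(two_leaf_tree(0.4), ds, SubstitutionModel.jc())
        assert lr.log_likelihood == pytest.approx(120 * math.log(0.25), abs=1e-10)


class TestOptimization:
    def test_two_leaf_optimum_is_analytic_jc_distance(self):
        model = SubstitutionModel.jc()
        sa, sb = simulate_pair(model, 0.3, 600, seed=4)
        p = np.mean([x != y for x, y in zip(sa, sb)])
        analytic = -0.75 * math.log(1 - 4 * p / 3)
        lr = optimize_branch_lengths(two_leaf_tree(0.1), two_leaf_dataset(sa, sb), model)
        (_, _, fitted) = lr.tree.edges()[0]
        assert fitted == pytest.approx(analytic, abs=1e-4)

    def test_lnl_never_decreases(self):
        cfg = SimulationConfig(n_species=4, specimens_per_species=(2, 2),
                               fraction_unknown=0.0, seed=6)
        ds, _ = simulate_dataset(cfg)
        from barcode_associate.distmat import build_matrix
        from barcode_associate.njtree import nj

        start = nj(build_matrix(ds, "k2p"))
        model = SubstitutionModel.k2p(4.0)
        before = site_log_likelihood(start, ds, model).log_likelihood
        lr = optimize_branch_lengths(start, ds, model)
        assert lr.log_likelihood >= before - 1e-9
        again = optimize_branch_lengths(lr.tree, ds, model)
        assert again.log_likelihood >= lr.log_likelihood - 1e-6


class TestNNISearch:
    def _quartet_data(self, seed=0):
        # strongly informative quartet: ab | cd
        t = PhyloTree()
        a, b, c, d = (t.add_node(x) for x in ("A", "B", "C", "D"))
        u, v = t.add_node(), t.add_node()
        t.add_edge(u, a, 0.05)
        t.add_edge(u, b, 0.05)
        t.add_edge(u, v, 0.15)
        t.add_edge(v, c, 0.05)
        t.add_edge(v, d, 0.05)
        model = SubstitutionModel.k2p(4.0)
        rng = np.random.default_rng(seed)
        L = 800
        root = rng.choice(4, size=L)
        seqs = {}

        def walk(node, parent, state):
            for nb, ln in t.adj[node].items():
                if nb == parent:
                    continue
                P = model.transition_matrix(ln)
                cum = P.cumsum(axis=1)
                child_state = (rng.random(L)[:, None] > cum[state]).sum(axis=1)
                if t.is_leaf(nb):
                    seqs[t.leaf_name[nb]] = "".join(DEC[child_state])
                else:
                    walk(nb, node, child_state)

        walk(u, None, root)
        ds = Dataset([make_record(k, v, species=k) for k, v in sorted(seqs.items())])
        return ds, model

    def _wrong_start(self):
        t = PhyloTree()
        a, c, b, d = (t.add_node(x) for x in ("A", "C", "B", "D"))
        u, v = t.add_node(), t.add_node()
        t.add_edge(u, a, 0.05)
        t.add_edge(u, c, 0.05)
        t.add_edge(u, v, 0.05)
        t.add_edge(v, b, 0.05)
        t.add_edge(v, d, 0.05)
        return t

    def test_recovers_true_quartet_from_wrong_start(self):
        ds, model = self._quartet_data(seed=1)
        res = nni_search(self._wrong_start(), ds, model)
        assert res.tree.has_split({"A", "B"})

    def test_true_start_is_stable(self):
        ds, model = self._quartet_data(seed=2)
        from barcode_associate.distmat import build_matrix
        from barcode_associate.njtree import nj

        start = nj(build_matrix(ds, "k2p"))
        assert start.has_split({"A", "B"})
        res = nni_search(start, ds, model)
        assert res.tree.has_split({"A", "B"})

    def test_search_never_decreases_lnl(self):
        ds, model = self._quartet_data(seed=3)
        start = self._wrong_start()
        before = optimize_branch_lengths(start, ds, model).log_likelihood
        res = nni_search(start, ds, model)
        assert res.log_likelihood >= before - 1e-9


class TestModelFit:
    def test_jc_fit_is_fully_constrained(self):
        cfg = SimulationConfig(n_species=4, specimens_per_species=(2, 2),
                               fraction_unknown=0.0, seed=9)
        ds, _ = simulate_dataset(cfg)
        from barcode_associate.distmat import build_matrix
        from barcode_associate.njtree import nj

        tree = nj(build_matrix(ds, "k2p"))
        m = model_parameters_fit(tree, ds, "JC", gamma=False)
        assert np.allclose(m.exchangeabilities, 1.0)
        assert np.allclose(m.base_freqs, 0.25)

    def test_tim2_recovers_rate_ordering(self):
        # simulate with r_AG >> r_CT; the fit must preserve the ordering
        true = SubstitutionModel.tim2(
            np.array([0.3, 0.2, 0.2, 0.3]), r_ac=1.0, r_ag=10.0, r_ct=1.5
        )
        rng = np.random.default_rng(12)
        L = 1500
        root = rng.choice(4, size=L, p=true.base_freqs)
        recs = []
        for i in range(6):
            P = true.transition_matrix(0.12)
            cum = P.cumsum(axis=1)
            state = (rng.random(L)[:, None] > cum[root]).sum(axis=1)
            recs.append(make_record(f"s{i}", "".join(DEC[state]), species=f"S{i}"))
        ds = Dataset(recs)
        from barcode_associate.distmat import build_matrix
        from barcode_associate.njtree import nj

        tree = nj(build_matrix(ds, "k2p"))
        fitted = model_parameters_fit(tree, ds, "TIM2", gamma=False, max_sweeps=2)
        r = dict(zip(("AC", "AG", "AT", "CG", "CT", "GT"), fitted.exchangeabilities))
        assert r["AG"] > r["CT"] > 0
        assert r["AC"] == pytest.approx(r["AT"])
        assert r["CG"] == pytest.approx(r["GT"])

    def test_alpha_ordering_recovered(self):
        def sim(alpha, seed):
            cfg = SimulationConfig(
                n_species=5, specimens_per_species=(2, 2), fraction_unknown=0.0,
                gamma_alpha=alpha, alignment_length=900, seed=seed,
            )
            ds, _ = simulate_dataset(cfg)
            from barcode_associate.distmat import build_matrix
            from barcode_associate.njtree import nj

            tree = nj(build_matrix(ds, "k2p"))
            return model_parameters_fit(tree, ds, "K2P", gamma=True, max_sweeps=2).gamma_alpha

        assert sim(0.3, seed=21) < sim(8.0, seed=21)


class TestInformationCriteria:
    def test_arithmetic(self):
        lr = LikelihoodResult(-100.0, PhyloTree(), SubstitutionModel.jc(), 5)
        ic = information_criteria(lr, 100)
        assert ic["AIC"] == pytest.approx(210.0)
        assert ic["AICc"] == pytest.approx(210.0 + 60.0 / 94.0)
        assert ic["BIC"] == pytest.approx(5 * math.log(100) + 200.0)

    def test_small_sample_aicc_not_applicable(self):
        lr = LikelihoodResult(-100.0, PhyloTree(), SubstitutionModel.jc(), 5)
        assert math.isnan(information_criteria(lr, 6)["AICc"])

    def test_nested_models_never_fit_worse_when_richer(self):
        cfg = SimulationConfig(n_species=4, specimens_per_species=(2, 2),
                               fraction_unknown=0.0, seed=14)
        ds, _ = simulate_dataset(cfg)
        from barcode_associate.distmat import build_matrix
        from barcode_associate.njtree import nj

        tree = nj(build_matrix(ds, "k2p"))
        scores = compare_models(ds, tree, ("JC", "K2P", "HKY"), gamma=False)
        assert scores["K2P"]["lnL"] >= scores["JC"]["lnL"] - 1e-6
        assert scores["HKY"]["lnL"] >= scores["K2P"]["lnL"] - 1e-3


class TestMLBootstrap:
    def test_reproducible_and_bounded(self):
        cfg = SimulationConfig(n_species=4, specimens_per_species=(2, 2),
                               fraction_unknown=0.0, seed=15)
        ds, _ = simulate_dataset(cfg)
        model = SubstitutionModel.k2p(4.0)
        r1 = ml_bootstrap(ds, model, replicates=5, seed=3, do_nni=False)
        r2 = ml_bootstrap(ds, model, replicates=5, seed=3, do_nni=False)
        assert r1.tree.support == r2.tree.support
        assert all(0 <= v <= 100 for v in r1.tree.support.values())

    def test_single_replicate_all_or_nothing(self):
        cfg = SimulationConfig(n_species=4, specimens_per_species=(2, 2),
                               fraction_unknown=0.0, seed=16)
        ds, _ = simulate_dataset(cfg)
        r = ml_bootstrap(ds, SubstitutionModel.k2p(4.0), replicates=1, seed=1, do_nni=False)
        assert set(r.tree.support.values()) <= {0.0, 100.0}
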