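import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import irisphylo as ip
from irisphylo.mk import MkFit, candidate_models, gamma_category_rates, mk_model


def _enumeration_loglik(tree, char, Q, prior=None):
    """Brute-force likelihood: sum over all joint internal-state assignments."""
    arr = tree.arrays
    k = Q.shape[0]
    prior = prior if prior is not None else np.full(k, 1.0 / k)
    internal = [i for i in range(arr.n) if arr.child_count[i] > 0]
    tipstate = {arr.index[lbl]: s for lbl, s in char.items()}
    P = [expm(Q * arr.blen[i]) for i in range(arr.n)]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(tipstate)
        p = prior[st[arr.root]]
        for i in range(arr.n - 1):
            p *= P[i][st[arr.parent[i]], st[i]]
        total += p
    return np.log(total)


def _enumeration_marginals(tree, char, Q, prior=None):
    arr = tree.arrays
    k = Q.shape[0]
    prior = prior if prior is not None else np.full(k, 1.0 / k)
    internal = [i for i in range(arr.n) if arr.child_count[i] > 0]
    tipstate = {arr.index[lbl]: s for lbl, s in char.items()}
    P = [expm(Q * arr.blen[i]) for i in range(arr.n)]
    marg = {i: np.zeros(k) for i in internal}
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(tipstate)
        p = prior[st[arr.root]]
        for i in range(arr.n - 1):
            p *= P[i][st[arr.parent[i]], st[i]]
        for i in internal:
            marg[i][st[i]] += p
    return {arr.names[i]: v / v.sum() for i, v in marg.items()}


class TestTransitionMatrix:
    def test_identity_at_zero(self):
        Q = mk_model("ER", 3).generator([0.7])
        assert np.allclose(ip.transition_matrix(Q, 0.0), np.eye(3))

    def test_two_state_er_closed_form(self):
        Q = mk_model("ER", 2).generator([0.5])
        P = ip.transition_matrix(Q, 1.0)
        stay = 0.5 + 0.5 * np.exp(-2 * 0.5 * 1.0)
        assert abs(P[0, 0] - stay) < 1e-10
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_long_time_stationarity(self):
        Q = mk_model("ER", 4).generator([0.3])
        P = ip.transition_matrix(Q, 1e4)
        assert np.allclose(P, 0.25, atol=1e-6)

    def test_invalid_generator(self):
        with pytest.raises(ValueError):
            ip.transition_matrix(np.array([[1.0, 1.0], [1.0, 1.0]]), 1.0)


class TestLoglik:
    def test_frozen_uniform_data(self, balanced4):
        m = mk_model("ER", 2)
        ll = ip.mk_loglik(balanced4, {"A": 0, "B": 0, "C": 0, "D": 0}, m, [1e-12])
        assert abs(ll - np.log(0.5)) < 1e-6

    def test_zero_rate_discordant_is_neg_inf(self, balanced4):
        m = mk_model("ER", 2)
        ll = ip.mk_loglik(balanced4, {"A": 0, "B": 1, "C": 0, "D": 0}, m, [0.0])
        assert ll == -np.inf

    def test_matches_enumeration_ard(self):
        tree = ip.gen_tree(5, seed=3)
        char = dict(zip(tree.tip_labels, [0, 1, 1, 0, 1]))
        m = mk_model("ARD", 2)
        rates = np.array([0.3, 0.8])
        ll = ip.mk_loglik(tree, char, m, rates)
        oracle = _enumeration_loglik(tree, char, m.generator(rates))
        assert abs(ll - oracle) < 1e-10

    def test_missing_tip_is_uninformative(self, balanced4):
        m = mk_model("ER", 2)
        ll = ip.mk_loglik(balanced4, {"A": 0, "B": 0, "C": 0, "D": None}, m, [0.4])
        # marginalizing D = summing likelihoods over D in {0, 1}
        l0 = ip.mk_loglik(balanced4, {"A": 0, "B": 0, "C": 0, "D": 0}, m, [0.4])
        l1 = ip.mk_loglik(balanced4, {"A": 0, "B": 0, "C": 0, "D": 1}, m, [0.4])
        assert abs(np.exp(ll) - (np.exp(l0) + np.exp(l1))) < 1e-12

    def test_tip_order_invariance(self):
        tree = ip.gen_tree(8, seed=5)
        char = dict(zip(tree.tip_labels, [0, 1, 0, 1, 1, 0, 0, 1]))
        m = mk_model("ER", 2)
        ll1 = ip.mk_loglik(tree, char, m, [0.6])
        ll2 = ip.mk_loglik(tree, dict(reversed(list(char.items()))), m, [0.6])
        assert abs(ll1 - ll2) < 1e-12

    def test_gamma_category_rates_mean_one(self):
        for alpha in (0.3, 1.0, 5.0):
            r = gamma_category_rates(alpha, 4)
            assert abs(r.mean() - 1.0) < 1e-8
            assert np.all(np.diff(r) > 0)


class TestCandidateModels:
    def test_fourteen_models(self):
        models = candidate_models()
        assert len(models) == 14
        by_name = {m.name: m for m in models}
        assert by_name["Mk-ER"].n_params == 1
        assert by_name["Mk-ARD"].n_params == 2

    def test_hrm_forbids_double_transitions(self):
        # symmetric HRMs: a transition changing both the observed state and
        # the hidden class simultaneously must have rate zero
        for m in candidate_models():
            if not m.name.startswith(("HRM2", "HRM3")):
                continue
            Q = m.generator(np.linspace(0.2, 1.0, m.n_rate_params))
            for i in range(m.n_expanded):
                for j in range(m.n_expanded):
                    if i == j:
                        continue
                    if m.obs_of[i] != m.obs_of[j] and _class_of(m, i) != _class_of(m, j):
                        assert Q[i, j] == 0.0, m.name

    def test_one_sided_hrm_class_switch_keeps_observed_state(self):
        # hidden-when-present: the class switch P1<->P2 never changes the
        # observed state, and the single-class absent state connects to both
        for name in ("HRM-hidden-present-ER", "HRM-hidden-absent-ER"):
            m = {mm.name: mm for mm in candidate_models()}[name]
            Q = m.generator(np.linspace(0.2, 1.0, m.n_rate_params))
            assert m.obs_of[1] == m.obs_of[2]
            assert Q[1, 2] > 0 and Q[2, 1] > 0
            assert Q[0, 1] > 0 and Q[0, 2] > 0

    def test_irreversible_structures(self):
        by_name = {m.name: m for m in candidate_models()}
        Qg = by_name["Mk-gain-only"].generator([0.5])
        assert Qg[1, 0] == 0.0 and Qg[0, 1] == 0.5
        Ql = by_name["Mk-loss-only"].generator([0.5])
        assert Ql[0, 1] == 0.0 and Ql[1, 0] == 0.5


def _class_of(model, i):
    """Hidden class index of expanded state i (states grouped by obs_of pattern)."""
    seen = {}
    for j, o in enumerate(model.obs_of):
        seen.setdefault(o, []).append(j)
    return seen[model.obs_of[i]].index(i)


class TestFitMk:
    def test_er_ard_nesting(self):
        tree = ip.gen_tree(60, seed=2)
        Q = mk_model("ER", 2).generator([0.6])
        tips, _ = ip.sim_mk(tree, Q, 0, seed=1)
        fer = ip.fit_mk(tree, tips, mk_model("ER", 2), restarts=3, seed=0)
        fard = ip.fit_mk(tree, tips, mk_model("ARD", 2), restarts=3, seed=0)
        assert fer.loglik <= fard.loglik + 1e-6

    def test_er_recovery_modest(self):
        tree = ip.gen_tree(200, seed=7)
        Q = mk_model("ER", 2).generator([0.5])
        qs = []
        for rep in range(10):
            tips, _ = ip.sim_mk(tree, Q, 0, seed=100 + rep)
            fit = ip.fit_mk(tree, tips, mk_model("ER", 2), restarts=2, seed=rep)
            qs.append(fit.rates[0])
        assert 0.3 < np.median(qs) < 0.8

    def test_boundary_flagged_for_impossible_irreversible(self):
        # state 1 only deep in the tree: gain-only cannot lose it again, so
        # the fit is pushed to a rate boundary
        tree = ip.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        char = {"A": 1, "B": 0, "C": 0, "D": 0}
        m = mk_model("ER", 2)
        by_name = {mm.name: mm for mm in candidate_models()}
        fit = ip.fit_mk(tree, {"A": 0, "B": 0, "C": 0, "D": 0}, m, restarts=2, seed=0)
        assert fit.boundary or not fit.converged  # invariant data: degenerate

    def test_seed_reproducibility(self):
        tree = ip.gen_tree(40, seed=3)
        tips, _ = ip.sim_mk(tree, mk_model("ER", 2).generator([0.5]), 0, seed=4)
        f1 = ip.fit_mk(tree, tips, mk_model("ARD", 2), restarts=4, seed=11)
        f2 = ip.fit_mk(tree, tips, mk_model("ARD", 2), restarts=4, seed=11)
        assert np.allclose(f1.rates, f2.rates)
        assert f1.loglik == f2.loglik


class TestSelectModel:
    def _fit(self, aic, k):
        m = mk_model("ER", 2)
        return MkFit(
            model=m, rates=np.array([0.1] * 1), loglik=(2 * k - aic) / 2.0, aic=aic,
            converged=True, boundary=False, restarts_used=1, states=(0, 1),
        )

    def test_akaike_weights_closed_form(self):
        best, w = ip.select_model([self._fit(10.0, 1), self._fit(12.0, 1)])
        assert abs(w[0] - 0.731) < 1e-3
        assert abs(w[1] - 0.269) < 1e-3
        assert abs(w.sum() - 1.0) < 1e-12

    def test_tie_prefers_fewer_params(self):
        m1 = mk_model("ER", 2)
        m2 = mk_model("ARD", 2)
        f1 = MkFit(m1, np.array([0.1]), -5.0, 2 * 1 + 10.0, True, False, 1, (0, 1))
        f2 = MkFit(m2, np.array([0.1, 0.1]), -4.0, 2 * 2 + 8.0, True, False, 1, (0, 1))
        best, _ = ip.select_model([f2, f1])
        assert best.model.n_params == 1

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError):
            ip.select_model([self._fit(10.0, 1)])

    def test_aic_consistency_on_fits(self):
        tree = ip.gen_tree(30, seed=9)
        tips, _ = ip.sim_mk(tree, mk_model("ER", 2).generator([0.5]), 0, seed=2)
        fit = ip.fit_mk(tree, tips, mk_model("ARD", 2), restarts=2, seed=0)
        assert abs(fit.aic - (2 * 2 - 2 * fit.loglik)) < 1e-9


class TestMarginalASR:
    def test_symmetric_tips_give_even_root(self, balanced4):
        char = {"A": 1, "B": 1, "C": 0, "D": 0}
        m = mk_model("ER", 2)
        fit = MkFit(m, np.array([0.5]), 0.0, 0.0, True, False, 1, (0, 1))
        rec = ip.marginal_asr(balanced4, char, fit)
        root = balanced4.arrays.names[balanced4.arrays.root]
        assert np.allclose(rec.node_probs[root], [0.5, 0.5], atol=1e-12)

    def test_matches_enumeration_small_trees(self):
        rng = np.random.default_rng(0)
        for rep in range(10):
            tree = ip.gen_tree(rng.integers(4, 7), seed=200 + rep)
            states = rng.integers(0, 2, tree.n_tips)
            if len(set(states)) < 2:
                states[0] = 1 - states[0]
            char = dict(zip(tree.tip_labels, states.tolist()))
            m = mk_model("ARD", 2)
            rates = rng.uniform(0.1, 2.0, 2)
            fit = MkFit(m, rates, 0.0, 0.0, True, False, 1, (0, 1))
            rec = ip.marginal_asr(tree, char, fit)
            oracle = _enumeration_marginals(tree, char, m.generator(rates))
            for node, probs in oracle.items():
                assert np.abs(rec.node_probs[node] - probs).max() < 1e-8

    def test_low_rate_all_present_limit(self):
        tree = ip.gen_tree(10, seed=4)
        char = {t: 1 for t in tree.tip_labels}
        m = mk_model("ER", 2)
        fit = MkFit(m, np.array([1e-6]), 0.0, 0.0, True, False, 1, (0, 1))
        rec = ip.marginal_asr(tree, char, fit)
        for node, probs in rec.node_probs.items():
            assert probs[1] > 0.999
        assert all(rec.presence_calls().values())

    def test_hidden_classes_marginalized(self):
        tree = ip.gen_tree(12, seed=8)
        tips, _ = ip.sim_mk(tree, mk_model("ER", 2).generator([0.5]), 0, seed=3)
        hrm = [m for m in candidate_models() if m.name == "HRM2-ER"][0]
        fit = ip.fit_mk(tree, tips, hrm, restarts=2, seed=0)
        rec = ip.marginal_asr(tree, tips, fit)
        for probs in rec.node_probs.values():
            assert len(probs) == 2
            assert abs(probs.sum() - 1.0) < 1e-9


def test_polymorphic_state_space_has_31_combinations():
    combos = ip.polymorphic_state_space()
    assert len(combos) == 31
    assert frozenset(["brown"]) in combos
    assert frozenset(["brown", "green", "yellow", "gray", "blue"]) in combos
    assert len(set(combos)) == 31
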