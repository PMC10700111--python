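import itertools
import math

import numpy as np
import pytest

from orthotrim.phylo_hmm import (
    BinaryCTMC,
    EmissionParams,
    HMMSpec,
    MissingEmission,
    PhyloEmission,
    StickinessParams,
    TableEmission,
    TipJump,
    column_emission,
    forward_backward,
    missing_emission,
    prune_likelihood,
    read_params,
    simulate,
    train_discriminative,
    write_params,
)
from orthotrim.trees import ArrayTree


# ----------------------------------------------------------------------
# oracles
# ----------------------------------------------------------------------
def enumerate_path_likelihood(start, trans, emission_probs):
    """Brute-force total likelihood over all state paths."""
    t_len, n_states = emission_probs.shape
    total = 0.0
    for path in itertools.product(range(n_states), repeat=t_len):
        p = start[path[0]] * emission_probs[0, path[0]]
        for t in range(1, t_len):
            p *= trans[path[t - 1], path[t]] * emission_probs[t, path[t]]
        total += p
    return total


def enumerate_pruning(tree: ArrayTree, ctmc, jump, column):
    """Sum over all internal-node state assignments."""
    internal = [i for i, kids in enumerate(tree.children) if kids]
    tip_pos = {int(t): j for j, t in enumerate(tree.tip_index)}
    obs = [column[label] for label in tree.tip_labels]
    parent = {}
    for i, kids in enumerate(tree.children):
        for c in kids:
            parent[c] = i
    pi = ctmc.stationary
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internal)):
        states = dict(zip(internal, assign))
        p = pi[states[tree.n_nodes - 1]]
        for i in range(tree.n_nodes):
            if i == tree.n_nodes - 1:
                continue
            trans = ctmc.transition(float(tree.edge_length[i]))
            if tree.children[i]:
                p *= trans[states[parent[i]], states[i]]
            else:
                s = obs[tip_pos[i]]
                row = trans[states[parent[i]]]
                tip_lik = 0.0
                for x in (0, 1):
                    emit = (1 - jump.epsilon) * (s == x) + jump.epsilon * (
                        jump.q if s == 1 else 1 - jump.q
                    )
                    tip_lik += row[x] * emit
                p *= tip_lik
        total += p
    return total


def betabinom_logpmf_oracle(c, n, a, b):
    """Explicit log-gamma identity for the beta-binomial pmf."""
    lg = math.lgamma
    return (
        lg(n + 1)
        - lg(c + 1)
        - lg(n - c + 1)
        + lg(c + a)
        + lg(n - c + b)
        - lg(n + a + b)
        - (lg(a) + lg(b) - lg(a + b))
    )


# ----------------------------------------------------------------------
# CTMC
# ----------------------------------------------------------------------
class TestBinaryCTMC:
    def test_rows_stochastic(self, rng):
        for _ in range(20):
            ctmc = BinaryCTMC(float(rng.random() * 5), float(rng.random() * 5))
            for t in (0.0, 0.1, 1.0, 10.0):
                p = ctmc.transition(t)
                assert p.sum(axis=1) == pytest.approx([1.0, 1.0])
                assert (p >= 0).all()

    def test_stationary_fixed_point(self):
        ctmc = BinaryCTMC(1.3, 0.7)
        pi = ctmc.stationary
        assert pi @ ctmc.transition(3.0) == pytest.approx(pi)

    def test_zero_rates_identity(self):
        assert BinaryCTMC(0, 0).transition(5.0) == pytest.approx(np.eye(2))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            BinaryCTMC(-1, 1)


# ----------------------------------------------------------------------
# pruning
# ----------------------------------------------------------------------
class TestPruneLikelihood:
    def test_one_tip_stationary(self):
        tree = ArrayTree.from_newick("(A:0);")
        ctmc = BinaryCTMC(0.3, 0.7)  # stationary (0.7 gap, 0.3 non-gap)
        assert prune_likelihood(tree, ctmc, TipJump(0, 0.5), {"A": 1}) == pytest.approx(0.3)

    def test_epsilon_one_ignores_tree(self, balanced_tree):
        jump = TipJump(1.0, 0.4)
        ctmc = BinaryCTMC(2.0, 0.5)
        col = {"A": 1, "B": 0, "C": 1, "D": 1}
        expected = 0.4 * 0.6 * 0.4 * 0.4
        assert prune_likelihood(balanced_tree, ctmc, jump, col) == pytest.approx(expected)

    def test_matches_enumeration_oracle(self, rng):
        for newick in ["((A:0.3,B:0.5):0.2,C:0.7);", "((A:0.3,B:0.5):0.2,(C:0.1,D:0.4):0.6);",
                       "(((A:0.2,B:0.2):0.2,C:0.4):0.1,(D:0.3,E:0.3):0.2);"]:
            tree = ArrayTree.from_newick(newick)
            for _ in range(10):
                ctmc = BinaryCTMC(float(rng.random() * 3), float(rng.random() * 3))
                jump = TipJump(float(rng.random()), float(rng.random()))
                col = {label: int(rng.integers(0, 2)) for label in tree.tip_labels}
                got = prune_likelihood(tree, ctmc, jump, col)
                want = enumerate_pruning(tree, ctmc, jump, col)
                assert got == pytest.approx(want, rel=1e-12, abs=1e-15)

    def test_normalization_over_columns(self, rng):
        for _ in range(20):
            tree = ArrayTree.from_newick("((A:0.3,B:0.5):0.2,(C:0.1,D:0.4):0.6);")
            ctmc = BinaryCTMC(float(rng.random() * 4), float(rng.random() * 4))
            jump = TipJump(float(rng.random()), float(rng.random()))
            total = sum(
                prune_likelihood(tree, ctmc, jump, dict(zip(tree.tip_labels, bits)))
                for bits in itertools.product([0, 1], repeat=4)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            ArrayTree.from_newick("(A:-1,B:1);")


# ----------------------------------------------------------------------
# column emission
# ----------------------------------------------------------------------
class TestColumnEmission:
    def _params(self, a=1.0, b=1.0):
        return EmissionParams(BinaryCTMC(1.0, 1.0), TipJump(0.1, 0.5), StickinessParams(a, b))

    def test_uniform_stickiness(self, balanced_tree):
        params = self._params(1.0, 1.0)
        col = {"A": 1, "B": 0, "C": 1, "D": 0}
        prev = {"A": 1, "B": 1, "C": 0, "D": 0}
        base = column_emission(params, balanced_tree, col, None)
        with_prev = column_emission(params, balanced_tree, col, prev)
        assert with_prev - base == pytest.approx(math.log(1 / 5))

    def test_constant_count_full(self, balanced_tree):
        params = self._params(3.0, 2.0)
        col = {"A": 1, "B": 0, "C": 1, "D": 0}
        got = column_emission(params, balanced_tree, col, col)
        base = column_emission(params, balanced_tree, col, None)
        assert got - base == pytest.approx(betabinom_logpmf_oracle(4, 4, 3.0, 2.0))

    def test_betabinom_matches_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 8))
            a, b = float(rng.random() * 5 + 0.1), float(rng.random() * 5 + 0.1)
            c = int(rng.integers(0, n + 1))
            from scipy.stats import betabinom as sp_bb

            assert sp_bb.logpmf(c, n, a, b) == pytest.approx(
                betabinom_logpmf_oracle(c, n, a, b), rel=1e-12
            )

    def test_betabinom_normalizes(self):
        from scipy.stats import betabinom as sp_bb

        n, a, b = 6, 2.5, 0.7
        assert sum(sp_bb.pmf(c, n, a, b) for c in range(n + 1)) == pytest.approx(1.0)


# ----------------------------------------------------------------------
# missing emission
# ----------------------------------------------------------------------
class TestMissingEmission:
    def test_single_tip_normalizes(self):
        tree = ArrayTree.from_newick("(A:0.5);")
        ctmc = BinaryCTMC(1.0, 2.0)
        jump = TipJump(0.3, 0.4)
        p1 = missing_emission(tree, ctmc, jump, {"A": 1}, "A")
        p0 = missing_emission(tree, ctmc, jump, {"A": 0}, "A")
        assert p0 + p1 == pytest.approx(1.0)

    def test_concordant_limit(self):
        # 3-tip star with tiny branch lengths, no jump: the posterior of
        # agreeing with the other tips approaches 1
        tree = ArrayTree.from_newick("(A:0.001,B:0.001,C:0.001);")
        ctmc = BinaryCTMC(1.0, 1.0)
        jump = TipJump(0.0, 0.5)
        post = missing_emission(tree, ctmc, jump, {"A": 1, "B": 1, "C": 1}, "A")
        assert post > 0.99

    def test_sums_to_one_general(self, balanced_tree, rng):
        ctmc = BinaryCTMC(1.2, 0.4)
        jump = TipJump(0.2, 0.6)
        for _ in range(10):
            col = {label: int(rng.integers(0, 2)) for label in balanced_tree.tip_labels}
            flipped = dict(col)
            flipped["C"] = 1 - flipped["C"]
            total = missing_emission(balanced_tree, ctmc, jump, col, "C") + missing_emission(
                balanced_tree, ctmc, jump, flipped, "C"
            )
            assert total == pytest.approx(1.0)


# ----------------------------------------------------------------------
# engine
# ----------------------------------------------------------------------
class TestForwardBackward:
    def test_one_state(self):
        table = np.array([[0.25, 0.75]])
        spec = HMMSpec(["s"], np.array([1.0]), np.array([[1.0]]), TableEmission(table))
        obs = [0, 1, 1, 0]
        res = forward_backward(spec, obs)
        assert res.posteriors == pytest.approx(np.ones((4, 1)))
        expected = sum(math.log(table[0, o]) for o in obs)
        assert res.log_likelihood == pytest.approx(expected)

    def test_matches_enumeration(self, rng):
        for _ in range(50):
            n_states = int(rng.integers(2, 5))
            t_len = int(rng.integers(1, 9))
            start = rng.dirichlet(np.ones(n_states))
            trans = rng.dirichlet(np.ones(n_states), size=n_states)
            table = rng.dirichlet(np.ones(3), size=n_states)
            obs = rng.integers(0, 3, t_len)
            spec = HMMSpec(
                [f"s{i}" for i in range(n_states)], start, trans, TableEmission(table)
            )
            res = forward_backward(spec, obs)
            want = enumerate_path_likelihood(start, trans, table[:, obs].T)
            assert res.log_likelihood == pytest.approx(math.log(want), rel=1e-10)
            assert res.posteriors.sum(axis=1) == pytest.approx(np.ones(t_len), abs=1e-9)

    def test_deterministic_emissions_recover_path(self, rng):
        table = np.eye(3) * 0.999 + 0.0005
        table /= table.sum(axis=1, keepdims=True)
        trans = np.full((3, 3), 1 / 3)
        spec = HMMSpec(["a", "b", "c"], np.full(3, 1 / 3), trans, TableEmission(table))
        path = rng.integers(0, 3, 30)
        res = forward_backward(spec, path)
        assert np.array_equal(res.posteriors.argmax(axis=1), path)

    def test_all_zero_emission_errors(self):
        table = np.array([[1.0, 0.0], [1.0, 0.0]])
        spec = HMMSpec(["a", "b"], np.array([0.5, 0.5]), np.full((2, 2), 0.5), TableEmission(table))
        with pytest.raises(ValueError, match="position 2"):
            forward_backward(spec, [0, 0, 1, 0])

    def test_empty_observation(self):
        table = np.array([[0.5, 0.5]])
        spec = HMMSpec(["s"], np.array([1.0]), np.array([[1.0]]), TableEmission(table))
        res = forward_backward(spec, [])
        assert res.log_likelihood == 0.0


# ----------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------
def _toy_spec(tree, n_states=2):
    params = [
        EmissionParams(BinaryCTMC(3.0, 0.3), TipJump(0.05, 0.9), StickinessParams(5, 1)),
        EmissionParams(BinaryCTMC(0.4, 3.6), TipJump(0.05, 0.1), StickinessParams(5, 1)),
    ][:n_states]
    start = np.full(n_states, 1 / n_states)
    trans = np.full((n_states, n_states), 0.1 / (n_states - 1)) if n_states > 1 else np.ones((1, 1))
    if n_states > 1:
        np.fill_diagonal(trans, 0.9)
    return HMMSpec([f"s{i}" for i in range(n_states)], start, trans, PhyloEmission(tree, params))


class TestSimulate:
    def test_length_zero(self, balanced_tree):
        path, cols = simulate(_toy_spec(balanced_tree), balanced_tree, 0, seed=5)
        assert path.size == 0 and cols.shape == (4, 0)

    def test_seed_reproducible(self, balanced_tree):
        spec = _toy_spec(balanced_tree)
        a = simulate(spec, balanced_tree, 50, seed=7)
        b = simulate(spec, balanced_tree, 50, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_tip_frequency_approaches_stationary(self, balanced_tree):
        params = [EmissionParams(BinaryCTMC(3.0, 1.0), TipJump(0.0, 0.5), StickinessParams(1, 1))]
        spec = HMMSpec(["s"], np.array([1.0]), np.array([[1.0]]), PhyloEmission(balanced_tree, params))
        _, cols = simulate(spec, balanced_tree, 10_000, seed=11)
        freq = cols.mean()
        pi_non_gap = 0.75
        sigma = math.sqrt(pi_non_gap * (1 - pi_non_gap) / 10_000)
        # tips are correlated within a column: allow 3 sigma on the
        # effective per-column sample plus correlation slack
        assert abs(freq - pi_non_gap) < 3 * sigma * 4


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------
class TestTraining:
    def test_truth_labels_do_not_increase_loss(self, balanced_tree):
        spec = _toy_spec(balanced_tree)
        path, cols = simulate(spec, balanced_tree, 150, seed=3)
        result = train_discriminative(spec, [(cols, path)], maxiter=3)
        assert result.history[-1] <= result.history[0] + 1e-12

    def test_separable_two_state_accuracy(self, balanced_tree):
        truth = _toy_spec(balanced_tree)
        path, cols = simulate(truth, balanced_tree, 400, seed=13)
        # perturb the starting point
        perturbed_params = [
            EmissionParams(BinaryCTMC(2.0, 0.8), TipJump(0.2, 0.6), StickinessParams(2, 2)),
            EmissionParams(BinaryCTMC(0.8, 2.0), TipJump(0.2, 0.4), StickinessParams(2, 2)),
        ]
        spec0 = HMMSpec(
            list(truth.states),
            np.array([0.5, 0.5]),
            np.array([[0.8, 0.2], [0.2, 0.8]]),
            PhyloEmission(balanced_tree, perturbed_params),
        )
        result = train_discriminative(spec0, [(cols, path)], maxiter=15)
        hold_path, hold_cols = simulate(truth, balanced_tree, 2000, seed=14)
        decoded = forward_backward(result.spec, hold_cols).posteriors.argmax(axis=1)
        accuracy = (decoded == hold_path).mean()
        assert accuracy >= 0.95

    def test_history_monotone(self, balanced_tree):
        truth = _toy_spec(balanced_tree)
        path, cols = simulate(truth, balanced_tree, 200, seed=21)
        spec0 = _toy_spec(balanced_tree)
        # nudge away from truth so there is something to improve
        spec0 = HMMSpec(
            list(truth.states),
            np.array([0.5, 0.5]),
            np.array([[0.6, 0.4], [0.4, 0.6]]),
            truth.emission,
        )
        result = train_discriminative(spec0, [(cols, path)], maxiter=10)
        assert all(b < a for a, b in zip(result.history, result.history[1:]))

    def test_empty_labels_rejected(self, balanced_tree):
        spec = _toy_spec(balanced_tree)
        with pytest.raises(ValueError):
            train_discriminative(spec, [(np.zeros((4, 0), dtype=int), np.array([], dtype=int))])


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------
def test_params_round_trip(tmp_path, balanced_tree):
    spec = _toy_spec(balanced_tree)
    path = tmp_path / "params.tsv"
    write_params(path, spec)
    states, start, trans, params = read_params(path)
    assert states == spec.states
    assert start == pytest.approx(spec.start)
    assert trans == pytest.approx(spec.trans)
    for got, want in zip(params, spec.emission.params):
        assert got == want
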