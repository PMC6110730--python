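"""Equal-rates binary Markov model: parsing, likelihood, marginals, rate fitting."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from physprr import (
    ancestral_marginals,
    er_loglik,
    fit_er_rate,
    read_newick,
    simulate_er_states,
    transition_probability,
)


def enumeration_likelihood(tree, states, q):
    """Sum of path-probability products over all internal-state assignments."""
    internals = [n.index for n in tree.nodes if not n.is_leaf]
    total = 0.0
    marg = {i: [0.0, 0.0] for i in internals}
    for assign in itertools.product([0, 1], repeat=len(internals)):
        st_map = dict(zip(internals, assign))
        for n in tree.nodes:
            if n.is_leaf:
                st_map[n.index] = states[n.label]
        p = 0.5
        for n in tree.nodes:
            if n.parent is not None:
                pm = transition_probability(q, n.edge_length)
                p *= pm[st_map[n.parent], st_map[n.index]]
        total += p
        for i in internals:
            marg[i][st_map[i]] += p
    probs = {f"node_{i}": marg[i][1] / (marg[i][0] + marg[i][1]) for i in internals}
    return total, probs


def random_tree_newick(rng, n_tips):
    """Random binary topology with random branch lengths."""
    parts = [f"t{i}:{rng.uniform(0.05, 2.0):.4f}" for i in range(n_tips)]
    while len(parts) > 2:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        merged = f"({parts[i]},{parts[j]}):{rng.uniform(0.05, 2.0):.4f}"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    return f"({parts[0]},{parts[1]});"


def balanced_newick(depth):
    def rec(d, prefix):
        if d == 0:
            return prefix + ":1"
        return f"({rec(d - 1, prefix + '0')},{rec(d - 1, prefix + '1')}):1"

    return rec(depth, "t") + ";"


class TestNewick:
    def test_two_tips(self):
        tree = read_newick("(A:1,B:1);")
        assert sorted(tree.tip_labels) == ["A", "B"]
        assert all(n.edge_length == 1.0 for n in tree.nodes if n.parent is not None)

    def test_nested_with_internal_branch(self):
        tree = read_newick("((A:1,B:1):0.5,C:1.5);")
        assert tree.n_tips == 3
        internal = [n for n in tree.nodes if not n.is_leaf and n.parent is not None]
        assert len(internal) == 1
        assert internal[0].edge_length == 0.5

    @pytest.mark.parametrize(
        "bad", ["(A:1,", "", "(A:1,A:1);", "(A:1,B:-1);", "(A:1,B);"]
    )
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            read_newick(bad)

    def test_polytomy_allowed(self):
        tree = read_newick("(A:1,B:1,C:1);")
        assert tree.n_tips == 3


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        assert np.allclose(transition_probability(0.7, 0.0), np.eye(2))

    def test_long_time_reaches_stationary(self):
        p = transition_probability(1.0, 50.0)
        assert np.allclose(p, 0.25 + np.full((2, 2), 0.25), atol=1e-12)

    def test_closed_form_value(self):
        p = transition_probability(1.0, 1.0)
        assert p[0, 0] == pytest.approx((1 + math.exp(-2)) / 2, abs=1e-5)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(-0.1, 1.0)


class TestLikelihood:
    def test_frozen_chain_same_states(self):
        tree = read_newick("(A:1,B:1);")
        assert math.exp(er_loglik(tree, {"A": 0, "B": 0}, 0.0)) == pytest.approx(0.5)

    def test_frozen_chain_conflicting_states(self):
        tree = read_newick("(A:1,B:1);")
        assert er_loglik(tree, {"A": 0, "B": 1}, 0.0) == -math.inf

    def test_two_tip_closed_form(self):
        tree = read_newick("(A:1,B:1);")
        p00 = (1 + math.exp(-0.2)) / 2
        expected = 0.5 * (p00**2 + (1 - p00) ** 2)
        assert math.exp(er_loglik(tree, {"A": 0, "B": 0}, 0.1)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_missing_state_rejected(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            er_loglik(tree, {"A": 0}, 0.1)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n_tips=st.integers(3, 5),
        q=st.floats(0.01, 3.0),
    )
    def test_pruning_equals_enumeration(self, seed, n_tips, q):
        rng = np.random.default_rng(seed)
        tree = read_newick(random_tree_newick(rng, n_tips))
        states = {lab: int(rng.integers(2)) for lab in tree.tip_labels}
        expected, _ = enumeration_likelihood(tree, states, q)
        assert er_loglik(tree, states, q) == pytest.approx(math.log(expected), abs=1e-10)

    def test_label_swap_symmetry(self):
        tree = read_newick("((A:0.3,B:1.2):0.5,(C:0.7,D:0.2):0.9);")
        states = {"A": 0, "B": 1, "C": 1, "D": 1}
        swapped = {k: 1 - v for k, v in states.items()}
        assert er_loglik(tree, states, 0.6) == pytest.approx(
            er_loglik(tree, swapped, 0.6), abs=1e-12
        )


class TestMarginals:
    def test_symmetric_two_tip_root(self):
        tree = read_newick("(A:1,B:1);")
        recon = ancestral_marginals(tree, {"A": 0, "B": 1}, 0.4)
        (prob,) = recon.prob_present.values()
        assert prob == pytest.approx(0.5, abs=1e-12)

    def test_uniform_tips_dominate_everywhere(self):
        tree = read_newick("((A:0.3,B:1.2):0.5,(C:0.7,D:0.2):0.9);")
        recon = ancestral_marginals(tree, {t: 1 for t in "ABCD"}, 0.5)
        assert all(p > 0.5 for p in recon.prob_present.values())

    def test_large_rate_approaches_stationary(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        recon = ancestral_marginals(tree, {"A": 0, "B": 0, "C": 1, "D": 1}, 500.0)
        for p in recon.prob_present.values():
            assert p == pytest.approx(0.5, abs=1e-3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_tips=st.integers(3, 5), q=st.floats(0.01, 3.0))
    def test_marginals_equal_enumeration(self, seed, n_tips, q):
        rng = np.random.default_rng(seed)
        tree = read_newick(random_tree_newick(rng, n_tips))
        states = {lab: int(rng.integers(2)) for lab in tree.tip_labels}
        _, expected = enumeration_likelihood(tree, states, q)
        recon = ancestral_marginals(tree, states, q)
        for node, prob in recon.prob_present.items():
            assert prob == pytest.approx(expected[node], abs=1e-10)


class TestRateFitting:
    def test_uniform_tips_hit_lower_bound(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        recon = fit_er_rate(tree, {t: 0 for t in "ABCD"})
        assert recon.at_bound
        assert recon.rate == pytest.approx(1e-8)

    def test_agrees_with_dense_grid_search(self):
        tree = read_newick(balanced_newick(4))
        states = simulate_er_states(tree, 0.4, seed=2)
        if len(set(states.values())) < 2:
            pytest.skip("degenerate simulation draw")
        recon = fit_er_rate(tree, states)
        grid = np.logspace(math.log10(1e-8), math.log10(100.0 / tree.height), 1000)
        lls = [er_loglik(tree, states, g) for g in grid]
        best = grid[int(np.argmax(lls))]
        step = grid[1] / grid[0]
        assert best / step <= recon.rate <= best * step

    def test_simulated_rate_recovered_within_factor_two(self):
        tree = read_newick(balanced_newick(6))
        estimates = [fit_er_rate(tree, simulate_er_states(tree, 0.5, seed=s)).rate for s in range(20)]
        assert 0.25 <= np.median(estimates) <= 1.0
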