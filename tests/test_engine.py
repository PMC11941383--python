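"""Outranking engine: preference functions, flows, preorders, decomposition."""

import math

import numpy as np
import pytest

from fpromethee import (
    FLOW_TOLERANCE,
    InsufficientAlternativesError,
    PreferenceFunctionSpec,
    aggregated_preference,
    complete_ranking,
    compute_flows,
    estimate_gaussian_spread,
    negative_flow,
    net_flow,
    partial_order,
    positive_flow,
    preference_value,
    signed_difference,
    unicriterion_net_flows,
)
from fpromethee.engine import (
    INCOMPARABLE,
    INDIFFERENT,
    PREFERRED,
    UnresolvedParameterError,
)

from conftest import oracle_flows, random_problem

USUAL = PreferenceFunctionSpec(kind="usual")


# --- signed differences and preference functions ---------------------------


@pytest.mark.parametrize("a,b,direction,expected", [
    (5, 3, "maximize", 2),
    (5, 3, "minimize", -2),
    (3, 5, "minimize", 2),
    (4, 4, "maximize", 0),
    (4, 4, "minimize", 0),
])
def test_signed_difference(a, b, direction, expected):
    assert signed_difference(a, b, direction) == expected


class TestPreferenceValue:
    @pytest.mark.parametrize("kind,kwargs", [
        ("usual", {}),
        ("u_shape", {"q": 0.5}),
        ("v_shape", {"p": 2.0}),
        ("level", {"q": 0.5, "p": 2.0}),
        ("linear", {"q": 0.5, "p": 2.0}),
        ("gaussian", {"s": 1.0}),
    ])
    @pytest.mark.parametrize("d", [-0.4, 0.0, -10.0])
    def test_no_preference_for_worse_or_equal(self, kind, kwargs, d):
        assert preference_value(d, PreferenceFunctionSpec(kind=kind, **kwargs)) == 0.0

    def test_gaussian_at_one_spread(self):
        spec = PreferenceFunctionSpec(kind="gaussian", s=2.5)
        assert preference_value(2.5, spec) == pytest.approx(1 - math.exp(-0.5), abs=1e-12)

    def test_usual_jumps_to_one(self):
        assert preference_value(0.3, USUAL) == 1.0

    def test_v_shape_ramps_and_saturates(self):
        spec = PreferenceFunctionSpec(kind="v_shape", p=2.0)
        assert preference_value(1.0, spec) == pytest.approx(0.5)
        assert preference_value(5.0, spec) == 1.0

    def test_linear_with_zero_indifference_equals_v_shape(self):
        lin = PreferenceFunctionSpec(kind="linear", q=0.0, p=2.0)
        v = PreferenceFunctionSpec(kind="v_shape", p=2.0)
        for d in np.linspace(-1, 4, 23):
            assert preference_value(d, lin) == pytest.approx(preference_value(d, v))

    def test_level_thresholds(self):
        spec = PreferenceFunctionSpec(kind="level", q=1.0, p=3.0)
        assert preference_value(0.5, spec) == 0.0
        assert preference_value(2.0, spec) == 0.5
        assert preference_value(4.0, spec) == 1.0

    def test_u_shape_threshold(self):
        spec = PreferenceFunctionSpec(kind="u_shape", q=1.0)
        assert preference_value(0.9, spec) == 0.0
        assert preference_value(1.1, spec) == 1.0

    def test_unresolved_auto_spread_raises(self):
        with pytest.raises(UnresolvedParameterError):
            preference_value(1.0, PreferenceFunctionSpec(kind="gaussian", s="auto"))

    def test_values_always_within_unit_interval(self):
        rng = np.random.default_rng(3)
        specs = [USUAL,
                 PreferenceFunctionSpec(kind="u_shape", q=0.3),
                 PreferenceFunctionSpec(kind="v_shape", p=1.7),
                 PreferenceFunctionSpec(kind="level", q=0.2, p=1.0),
                 PreferenceFunctionSpec(kind="linear", q=0.1, p=2.2),
                 PreferenceFunctionSpec(kind="gaussian", s=0.8)]
        d = rng.normal(scale=3, size=1000)
        for spec in specs:
            out = preference_value(d, spec)
            assert np.all((out >= 0) & (out <= 1))


class TestGaussianSpread:
    @pytest.mark.parametrize("column,expected", [
        ((1, 2, 3), 1.0),
        ((5, 5, 5, 5), 0.0),
        ((0, 10), 10 / math.sqrt(2)),
    ])
    def test_sample_std(self, column, expected):
        assert estimate_gaussian_spread(column) == pytest.approx(expected, abs=1e-9)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientAlternativesError):
            estimate_gaussian_spread([1.0])


# --- aggregated preference and flows ----------------------------------------


class TestAggregatedPreference:
    def test_two_alternative_hand_example(self):
        grid = np.array([[1.0, 0.0], [0.0, 1.0]])
        pi = aggregated_preference(grid, [0.7, 0.3], [USUAL, USUAL],
                                   ["maximize", "maximize"])
        assert pi[0, 1] == pytest.approx(0.7)
        assert pi[1, 0] == pytest.approx(0.3)
        assert pi[0, 0] == pi[1, 1] == 0.0

    def test_identical_rows_give_zero(self):
        grid = np.array([[2.0, 3.0]] * 4)
        pi = aggregated_preference(grid, [0.5, 0.5], [USUAL, USUAL],
                                   ["maximize", "minimize"])
        assert np.all(pi == 0.0)

    def test_single_criterion_usual(self):
        grid = np.array([[2.0], [1.0]])
        pi = aggregated_preference(grid, [1.0], [USUAL], ["maximize"])
        assert pi[0, 1] == 1.0 and pi[1, 0] == 0.0

    def test_dimension_mismatch_rejected(self):
        grid = np.zeros((3, 2))
        with pytest.raises(ValueError):
            aggregated_preference(grid, [1.0], [USUAL, USUAL],
                                  ["maximize", "maximize"])

    def test_bounded_in_unit_interval_with_normalized_weights(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            grid, w, specs, dirs = random_problem(rng)
            pi = aggregated_preference(grid, w, specs, dirs)
            assert np.all((pi >= 0) & (pi <= 1 + 1e-12))
            assert np.all(np.diag(pi) == 0)


class TestFlows:
    def setup_method(self):
        grid = np.array([[1.0, 0.0], [0.0, 1.0]])
        self.pi = aggregated_preference(grid, [0.7, 0.3], [USUAL, USUAL],
                                        ["maximize", "maximize"])

    def test_two_alternative_flows(self):
        assert positive_flow(self.pi) == pytest.approx([0.7, 0.3])
        assert negative_flow(self.pi) == pytest.approx([0.3, 0.7])
        assert net_flow(positive_flow(self.pi), negative_flow(self.pi)) \
            == pytest.approx([0.4, -0.4])

    def test_zero_matrix_gives_zero_flows(self):
        pi = np.zeros((3, 3))
        assert np.all(positive_flow(pi) == 0)
        assert np.all(negative_flow(pi) == 0)

    def test_negative_flow_is_positive_flow_of_transpose(self):
        rng = np.random.default_rng(5)
        pi = rng.uniform(size=(6, 6))
        np.fill_diagonal(pi, 0)
        assert negative_flow(pi) == pytest.approx(positive_flow(pi.T), abs=1e-15)

    def test_single_alternative_rejected(self):
        with pytest.raises(InsufficientAlternativesError):
            positive_flow(np.zeros((1, 1)))

    def test_net_flow_length_mismatch(self):
        with pytest.raises(ValueError):
            net_flow([0.1, 0.2], [0.1])

    def test_published_flow_pair_arithmetic(self):
        # the top-ranked platform's printed flow pair
        assert net_flow([0.0348], [0.0002])[0] == pytest.approx(0.0346, abs=1e-12)


# --- partial preorder --------------------------------------------------------


class TestPartialOrder:
    def test_identical_alternatives_indifferent(self):
        po = partial_order([0.5, 0.5], [0.2, 0.2])
        assert po.relation(0, 1) == INDIFFERENT
        assert po.relation(1, 0) == INDIFFERENT

    def test_dominance_yields_preference(self):
        # a beats b on every criterion -> stronger and less outranked
        grid = np.array([[2.0, 3.0], [1.0, 1.0], [0.0, 2.0]])
        table = compute_flows(grid, [0.5, 0.5], [USUAL, USUAL],
                              ["maximize", "maximize"])
        po = partial_order(table.phi_plus, table.phi_minus)
        assert po.relation(0, 1) == PREFERRED
        assert po.relation(1, 0) == "outranked"

    def test_incomparability_found_by_search(self):
        # brute-force search over small random problems until the two flows
        # disagree in direction for some pair
        rng = np.random.default_rng(17)
        found = False
        for _ in range(200):
            grid, w, specs, dirs = random_problem(rng, n_max=5, k_max=4)
            if grid.shape[0] < 3:
                continue
            table = compute_flows(grid, w, specs, dirs)
            po = partial_order(table.phi_plus, table.phi_minus)
            n = grid.shape[0]
            for i in range(n):
                for j in range(n):
                    if i != j and po.relation(i, j) == INCOMPARABLE:
                        # verify the defining condition directly
                        dp = table.phi_plus[i] - table.phi_plus[j]
                        dm = table.phi_minus[i] - table.phi_minus[j]
                        assert dp * dm > 0
                        assert po.relation(j, i) == INCOMPARABLE  # symmetric
                        found = True
            if found:
                break
        assert found, "no incomparable pair found in 200 random problems"

    def test_edge_list_uses_alternative_ids(self):
        po = partial_order([0.5, 0.5], [0.2, 0.2])
        edges = po.edges(["x", "y"])
        assert ("x", INDIFFERENT, "y") in edges


# --- ranking and unicriterion decomposition ---------------------------------


class TestCompleteRanking:
    def test_descending_net_flows(self):
        assert complete_ranking([0.4, -0.4]) == [1, 2]
        assert complete_ranking([-0.1, 0.7, 0.3]) == [3, 1, 2]

    def test_all_tied_share_rank_one(self):
        ranks = complete_ranking([0.2, 0.2, 0.2, 0.2])
        assert ranks == [1, 1, 1, 1]

    def test_competition_ranking_with_partial_tie(self):
        assert complete_ranking([0.5, 0.3, 0.3, 0.1]) == [1, 2, 2, 4]

    def test_tie_flagged_on_flow_table(self):
        grid = np.array([[1.0], [1.0], [0.0]])
        table = compute_flows(grid, [1.0], [USUAL], ["maximize"])
        assert table.has_ties
        assert table.ranks[0] == table.ranks[1] == 1

    def test_tied_alternatives_keep_input_order(self):
        grid = np.array([[1.0], [1.0], [0.0]])
        table = compute_flows(grid, [1.0], [USUAL], ["maximize"],
                              alternative_ids=["first", "second", "last"])
        assert table.ranking() == [(1, "first"), (1, "second"), (3, "last")]


class TestUnicriterionFlows:
    def test_single_criterion_equals_net_flow(self):
        grid = np.array([[3.0], [1.0], [2.0]])
        table = compute_flows(grid, [1.0], [USUAL], ["maximize"])
        uni = unicriterion_net_flows(grid, [USUAL], ["maximize"])
        assert uni[:, 0] == pytest.approx(table.phi_net, abs=1e-12)

    def test_identical_rows_give_zero_grid(self):
        grid = np.array([[1.0, 2.0]] * 3)
        uni = unicriterion_net_flows(grid, [USUAL, USUAL], ["maximize", "minimize"])
        assert np.all(uni == 0)

    def test_weighted_recombination_matches_net_flow(self):
        rng = np.random.default_rng(23)
        grid = rng.normal(size=(5, 3))
        w = np.array([0.2, 0.5, 0.3])
        specs = [PreferenceFunctionSpec(kind="gaussian", s="auto")] * 3
        dirs = ["maximize", "minimize", "maximize"]
        table = compute_flows(grid, w, specs, dirs)
        uni = unicriterion_net_flows(grid, specs, dirs)
        assert uni @ w == pytest.approx(table.phi_net, abs=1e-9)


# --- global properties -------------------------------------------------------


class TestEngineProperties:
    def test_conservation_over_random_problems(self):
        rng = np.random.default_rng(100)
        for _ in range(100):
            grid, w, specs, dirs = random_problem(rng)
            table = compute_flows(grid, w, specs, dirs)
            assert abs(table.phi_net.sum()) < 1e-9
            assert table.phi_plus.sum() == pytest.approx(table.phi_minus.sum(), abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(200)
        for _ in range(100):
            grid, w, specs, dirs = random_problem(rng)
            table = compute_flows(grid, w, specs, dirs)
            plus, minus, net, pi = oracle_flows(grid.tolist(), w.tolist(), dirs)
            assert table.phi_plus == pytest.approx(plus, abs=1e-12)
            assert table.phi_minus == pytest.approx(minus, abs=1e-12)
            assert table.phi_net == pytest.approx(net, abs=1e-12)

    def test_dominance_preservation(self):
        rng = np.random.default_rng(300)
        for _ in range(30):
            grid, w, specs, dirs = random_problem(rng, n_max=6, k_max=5)
            # make row 0 strictly best everywhere
            for j, d in enumerate(dirs):
                col = grid[:, j]
                margin = max(np.ptp(col), 1.0) * 0.1
                grid[0, j] = (col.max() + margin) if d == "maximize" \
                    else (col.min() - margin)
            table = compute_flows(grid, w, specs, dirs)
            assert table.ranks[0] == 1
            assert np.all(table.phi_net[0] > table.phi_net[1:])

    def test_translation_invariance(self):
        rng = np.random.default_rng(400)
        grid, w, specs, dirs = random_problem(rng, n_max=6, k_max=4)
        base = compute_flows(grid, w, specs, dirs)
        shifted = grid.copy()
        shifted[:, 0] += 123.456
        after = compute_flows(shifted, w, specs, dirs)
        assert after.phi_net == pytest.approx(base.phi_net, abs=1e-9)
        assert after.ranks == base.ranks

    def test_scale_invariance_with_auto_spread(self):
        rng = np.random.default_rng(500)
        grid, w, specs, dirs = random_problem(rng, n_max=6, k_max=4)
        base = compute_flows(grid, w, specs, dirs)
        scaled = grid.copy()
        scaled[:, 0] *= 37.0  # spread rescales with the data
        after = compute_flows(scaled, w, specs, dirs)
        assert after.phi_net == pytest.approx(base.phi_net, abs=1e-9)
        assert after.ranks == base.ranks

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(600)
        grid, w, specs, dirs = random_problem(rng, n_max=7, k_max=4)
        perm = rng.permutation(grid.shape[0])
        base = compute_flows(grid, w, specs, dirs)
        after = compute_flows(grid[perm], w, specs, dirs)
        assert after.phi_net == pytest.approx(base.phi_net[perm], abs=1e-12)

    def test_constant_column_contributes_nothing(self):
        grid = np.array([[1.0, 5.0], [1.0, 3.0], [1.0, 4.0]])
        specs = [PreferenceFunctionSpec(kind="gaussian", s="auto")] * 2
        full = compute_flows(grid, [0.5, 0.5], specs, ["maximize", "maximize"])
        only = compute_flows(grid[:, 1:], [0.5], specs[1:], ["maximize"])
        # the constant column adds zero preference everywhere
        assert full.phi_net == pytest.approx(only.phi_net, abs=1e-12)
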