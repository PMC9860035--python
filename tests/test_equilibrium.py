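"""Analytic conditions versus brute-force equilibrium checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopnet import (
    GameParams,
    InfeasibleRoleError,
    InstitutionalNetwork,
    Strategy,
    all_contributors,
    all_free_riders,
    brute_force_socially_efficient_nash,
    compute_allocation,
    compute_payoffs,
    degree_constraints,
    efficiency_condition,
    is_nash,
    max_out_degree,
    min_in_degree,
)
from coopnet.netgen import OptimalNetworkSpec, build_cycle, sample_optimal

C, F = Strategy.CONTRIBUTOR, Strategy.FREE_RIDER


def circulant(n: int, k: int) -> InstitutionalNetwork:
    """Every node monitors its next k neighbours: k_in = k_out = k everywhere."""
    return InstitutionalNetwork(
        n, [(i, (i + d) % n) for i in range(n) for d in range(1, k + 1)]
    )


class TestEfficiencyCondition:
    def test_no_monitoring_reduces_to_b_gt_one(self):
        params = GameParams(N=6, b=2, m=1, p=1, c_t=1, c_p=0.5)
        assert efficiency_condition(params, K=0)
        assert not efficiency_condition(params.replace(b=1.0), K=0)

    def test_boundary_is_strict(self):
        # b exactly at N c_t / (N c_t - K/m) does not satisfy the condition
        params = GameParams(N=6, b=4 / 3, m=4, p=1, c_t=1, c_p=0.5)
        K = 6  # pool = 6 - 1.5 = 4.5, boundary b = 6/4.5 = 4/3
        assert not efficiency_condition(params, K)
        assert efficiency_condition(params.replace(b=4 / 3 + 1e-6), K)

    def test_monitoring_overhead_exceeding_pool_is_never_efficient(self):
        params = GameParams(N=6, b=100, m=1, p=1, c_t=1, c_p=0.5)
        assert not efficiency_condition(params, K=30)  # pool = 6 - 30 = -24
        # cross-check: universal contribution is a net loss on such a network
        net = circulant(6, 5)
        res = compute_payoffs(
            net, all_contributors(6), params.replace(m=10.0, b=1.0)
        )  # affordable variant with b at its floor
        assert res.group_payoff < 0

    def test_sign_of_group_payoff_tracks_condition(self):
        # Pi_N under universal contribution flips sign exactly at the Eq-1 boundary
        net = build_cycle(6)
        K = net.n_links
        base = GameParams(N=6, b=2, m=4, p=5, c_t=1, c_p=0.2)
        boundary = 6 / (6 - K / base.m)
        for b in np.concatenate([np.linspace(1.0, 2.0, 21), [boundary]]):
            params = base.replace(b=float(b))
            pi = compute_payoffs(net, all_contributors(6), params).group_payoff
            assert efficiency_condition(params, K) == (pi > 1e-9)


class TestDegreeFormulas:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(N=6, c_t=1, c_p=1, p=1, b=2), 1),
            (dict(N=6, c_t=1, c_p=0.2, p=0.6, b=2), 5),
        ],
    )
    def test_min_in_degree_arithmetic(self, kwargs, expected):
        params = GameParams(m=1, **kwargs)
        assert min_in_degree(params) == expected

    @pytest.mark.parametrize(
        "m,c_t,c_p,expected",
        [(4, 1, 0.25, 3), (4, 1, 1, 0), (50, 1, 0.8, 10)],
    )
    def test_max_out_degree_arithmetic(self, m, c_t, c_p, expected):
        params = GameParams(N=6, b=2, m=m, p=1, c_t=c_t, c_p=c_p)
        assert max_out_degree(params) == expected

    def test_ceiling_applies_to_exact_value(self):
        # argument is exactly 2: the ceiling must not bump it to 3
        params = GameParams(N=6, b=1, m=1, p=2.3, c_t=1, c_p=0.2)
        assert params.c_p * (params.p + params.b / 5) == pytest.approx(0.5)
        assert min_in_degree(params) == 2

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_min_in_matches_deviation_oracle(self, seed):
        # smallest uniform in-degree at which contributing is weakly better
        rng = np.random.default_rng(seed)
        n = 6
        params = GameParams(
            N=n, b=float(rng.uniform(1, 3)), m=50.0,
            p=float(rng.uniform(0.3, 2.0)), c_t=1.0,
            c_p=float(rng.uniform(0.15, 0.6)),
        )
        target = min_in_degree(params)
        stable = [
            k for k in range(1, n) if is_nash(circulant(n, k), all_contributors(n), params)
        ]
        if target <= n - 1:
            assert min(stable) == target
        else:
            assert stable == []

    def test_max_out_matches_affordability_oracle(self):
        params = GameParams(N=8, b=2, m=4, p=1, c_t=1, c_p=0.25)
        cap = max_out_degree(params)  # floor(4 * 0.75) = 3
        for k_out in range(1, 8):
            net = InstitutionalNetwork(8, [(0, j) for j in range(1, k_out + 1)])
            if k_out <= cap:
                compute_allocation(0, net, all_contributors(8), params)
            else:
                with pytest.raises(InfeasibleRoleError):
                    compute_allocation(0, net, all_contributors(8), params)

    def test_degree_constraints_composition(self):
        params = GameParams(N=6, b=2, m=50, p=0.6, c_t=1, c_p=0.2)
        dc = degree_constraints(params)
        assert dc.min_in == 5 and dc.max_out == 40
        assert dc.feasible == efficiency_condition(params, 30)

    def test_infeasible_when_cap_below_requirement(self):
        params = GameParams(N=6, b=2, m=1, p=0.6, c_t=1, c_p=0.2)
        dc = degree_constraints(params)
        assert dc.max_out < dc.min_in and not dc.feasible

    def test_cycle_only_regime(self):
        # both bounds pinned at 1: feasible, and the cycle satisfies them
        params = GameParams(N=6, b=4, m=1.5, p=5, c_t=1, c_p=0.3)
        dc = degree_constraints(params)
        assert (dc.min_in, dc.max_out) == (1, 1) and dc.feasible
        assert is_nash(build_cycle(6), all_contributors(6), params)

    @given(
        p1=st.floats(0.2, 4.0), p2=st.floats(0.2, 4.0),
        cp1=st.floats(0.05, 1.0), cp2=st.floats(0.05, 1.0),
        m1=st.floats(0.5, 20.0), m2=st.floats(0.5, 20.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_degree_bound_monotonicity(self, p1, p2, cp1, cp2, m1, m2):
        base = dict(N=6, b=2.0, c_t=1.0)
        lo_p, hi_p = sorted([p1, p2])
        a = GameParams(m=1.0, p=lo_p, c_p=0.3, **base)
        b = GameParams(m=1.0, p=hi_p, c_p=0.3, **base)
        assert min_in_degree(a) >= min_in_degree(b)  # non-increasing in p
        lo_c, hi_c = sorted([cp1, cp2])
        a = GameParams(m=1.0, p=1.0, c_p=lo_c, **base)
        b = GameParams(m=1.0, p=1.0, c_p=hi_c, **base)
        assert min_in_degree(a) >= min_in_degree(b)  # non-increasing in c_p
        lo_m, hi_m = sorted([m1, m2])
        a = GameParams(m=lo_m, p=1.0, c_p=0.3, **base)
        b = GameParams(m=hi_m, p=1.0, c_p=0.3, **base)
        assert max_out_degree(a) <= max_out_degree(b)  # non-decreasing in m


class TestNash:
    def test_universal_contribution_on_feasible_sample(self):
        params = GameParams(N=6, b=2, m=10, p=5, c_t=1, c_p=0.2)
        dc = degree_constraints(params)
        assert dc.feasible
        net = sample_optimal(
            OptimalNetworkSpec(6, dc.min_in, min(dc.max_out, 5)), 1, seed=0
        )[0]
        assert is_nash(net, all_contributors(6), params)

    def test_undermonitored_node_defects(self):
        # node with k_in below the analytic minimum gains by free-riding
        params = GameParams(N=6, b=2, m=10, p=0.6, c_t=1, c_p=0.2)
        assert min_in_degree(params) == 5
        assert not is_nash(circulant(6, 4), all_contributors(6), params)

    def test_universal_free_riding_always_nash(self, fig3_network, fig3_params):
        assert is_nash(fig3_network, all_free_riders(3), fig3_params)
        params = GameParams(N=6, b=2, m=10, p=5, c_t=1, c_p=0.2)
        assert is_nash(circulant(6, 2), all_free_riders(6), params)


class TestBruteForce:
    def test_feasible_network_yields_universal_contribution(self):
        params = GameParams(N=5, b=2, m=10, p=5, c_t=1, c_p=0.2)
        assert degree_constraints(params).feasible
        net = build_cycle(5)
        best = brute_force_socially_efficient_nash(net, params)
        assert best == all_contributors(5)
        res = compute_payoffs(net, best, params)
        closed = params.b * (5 - net.n_links / params.m) - 5
        assert res.group_payoff == pytest.approx(closed)

    def test_inefficient_parameters_yield_universal_free_riding(self):
        # Eq-1 fails: contributing cannot repay the monitoring overhead
        params = GameParams(N=5, b=1.05, m=1.1, p=5, c_t=1, c_p=0.2)
        assert not efficiency_condition(params, 5)
        best = brute_force_socially_efficient_nash(build_cycle(5), params)
        assert best == all_free_riders(5)
        assert compute_payoffs(build_cycle(5), best, params).group_payoff == 0

    def test_unmonitored_node_forces_universal_free_riding(
        self, fig3_network, fig3_params
    ):
        # node 0 has no monitor, so universal contribution is never Nash
        best = brute_force_socially_efficient_nash(fig3_network, fig3_params)
        assert best == all_free_riders(3)

    def test_size_guard(self):
        params = GameParams(N=13, b=2, m=10, p=5, c_t=1, c_p=0.2)
        with pytest.raises(ValueError, match="N <= 12"):
            brute_force_socially_efficient_nash(build_cycle(13), params)

    def test_mixed_nash_on_constraint_violating_network(self):
        # a monitored dyad plus unmonitored bystanders supports a non-uniform
        # socially efficient Nash: uniformity is a property of networks that
        # satisfy the degree constraints, not of arbitrary topologies
        params = GameParams(N=4, b=3, m=10, p=2, c_t=1, c_p=0.5)
        net = InstitutionalNetwork(4, [(0, 1), (1, 0)])
        best = brute_force_socially_efficient_nash(net, params)
        assert best == (C, C, F, F)
        assert compute_payoffs(net, best, params).group_payoff > 0
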