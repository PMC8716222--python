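import math

import numpy as np
import pytest

from trimlogit.core import FitCounter, RegGrid, build_grids, compute_lambda_max, subset_standardization
from trimlogit.search import (
    ARCstepConfig,
    acceptance_probability,
    ar_cstep_run,
    count_stratified_subsets,
    cstep_fixed,
    cstep_grid,
    default_temperature_divisor,
    draw_initial_subset,
    exhaustive_oracle,
    multi_start_search,
)
from trimlogit.trimming import make_plan


class TestAcceptanceProbability:
    def test_k0_always_one(self):
        assert acceptance_probability(-50.0, -1.0, 0, 2.5) == 1.0

    def test_equal_logliks_one(self):
        assert acceptance_probability(-3.0, -3.0, 7, 2.5) == 1.0

    def test_printed_arithmetic(self):
        # D = 0.1 * 100 * (1 - 0.75) = 2.5; k = 9; delta = -1
        D = default_temperature_divisor(100, 0.75)
        assert D == pytest.approx(2.5)
        p = acceptance_probability(-11.0, -10.0, 9, D)
        assert p == pytest.approx(math.exp(-math.log(10) / 2.5), abs=1e-12)
        assert p == pytest.approx(0.398107, abs=1e-6)

    def test_strictly_decreasing_in_k(self):
        ps = [acceptance_probability(-11.0, -10.0, k, 2.5) for k in range(1, 20)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_bounds(self):
        for k in range(10):
            p = acceptance_probability(-40.0, -10.0, k, 2.5)
            assert 0.0 < p <= 1.0

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            acceptance_probability(-1.0, -1.0, 1, 0.0)
        with pytest.raises(ValueError):
            acceptance_probability(-1.0, -1.0, -1, 2.5)


@pytest.fixture(scope="module")
def tiny_setup(tiny12):
    data = tiny12.data
    plan = make_plan(data.n1, data.n0, 0.75)
    lam_max = compute_lambda_max(data)
    std = subset_standardization(data.X, np.arange(data.n))
    return data, plan, 0.1 * lam_max, std


class TestCstepFixed:
    def test_monotone_Q(self, tiny_setup):
        data, plan, lam, std = tiny_setup
        rng = np.random.default_rng(0)
        H0 = draw_initial_subset(data.y, rng)
        state, trace = cstep_fixed(data, H0, lam, 0.5, plan, standardization=std)
        qs = [r["Q"] for r in trace.records]
        assert all(a >= b - 1e-9 for a, b in zip(qs, qs[1:]))
        assert trace.converged

    def test_fixed_point_from_oracle_optimum(self, tiny_setup):
        data, plan, lam, std = tiny_setup
        oracle = exhaustive_oracle(data, plan, lam, 0.5, standardization=std)
        state, trace = cstep_fixed(data, np.asarray(oracle.H), lam, 0.5, plan,
                                   standardization=std)
        assert state.Q == pytest.approx(oracle.Q, abs=1e-8)
        assert len(trace.records) <= 2

    def test_small_start_expands_to_h(self, tiny_setup):
        data, plan, lam, std = tiny_setup
        state, _ = cstep_fixed(data, [0, 1, 2, 10, 11], lam, 0.5, plan,
                               standardization=std)
        assert len(state.H) == plan.h

    def test_fit_count_recorded(self, tiny_setup):
        data, plan, lam, std = tiny_setup
        counter = FitCounter()
        _, trace = cstep_fixed(data, list(range(plan.h)), lam, 0.5, plan,
                               standardization=std, counter=counter)
        assert trace.fit_count == counter.count
        assert trace.fit_count >= len(trace.records)


class TestCstepGrid:
    def test_singleton_grid_reduces_to_cstep_fixed(self, tiny_setup):
        data, plan, lam, std = tiny_setup
        lam_max = compute_lambda_max(data)
        grid = RegGrid(lambda_max=lam, lambda_fractions=np.array([1.0]),
                       alphas=np.array([0.5]))
        H0 = list(range(plan.h))
        best, trace = cstep_grid(data, [H0], grid, plan)
        ref, _ = cstep_fixed(data, H0, lam, 0.5, plan)
        assert best.Q == pytest.approx(ref.Q, abs=1e-10)
        assert trace.meta["cstep_runs"] == 1

    def test_returns_min_over_combinations(self, tiny_setup):
        data, plan, lam, std = tiny_setup
        lam_max = compute_lambda_max(data)
        grid = RegGrid(lambda_max=lam_max,
                       lambda_fractions=np.array([0.1, 0.5, 1.0]),
                       alphas=np.array([0.5, 1.0]))
        H0 = list(range(plan.h))
        best, trace = cstep_grid(data, [H0], grid, plan)
        per_combo = []
        for alpha in grid.alphas:
            for lam_v in grid.lambdas:
                st, _ = cstep_fixed(data, H0, float(lam_v), float(alpha), plan)
                per_combo.append(st.Q)
        assert best.Q <= min(per_combo) + 1e-10
        assert trace.meta["cstep_runs"] == 6


class TestExhaustiveOracle:
    def test_enumeration_count(self, tiny_setup):
        data, plan, lam, std = tiny_setup
        counter = FitCounter()
        exhaustive_oracle(data, plan, lam, 0.5, standardization=std,
                          counter=counter)
        assert counter.count == count_stratified_subsets(plan)

    def test_beats_any_cstep_run(self, tiny_setup):
        data, plan, lam, std = tiny_setup
        oracle = exhaustive_oracle(data, plan, lam, 0.5, standardization=std)
        rng = np.random.default_rng(1)
        for _ in range(5):
            st, _ = cstep_fixed(data, draw_initial_subset(data.y, rng), lam,
                                0.5, plan, standardization=std)
            assert oracle.Q <= st.Q + 1e-10

    def test_deterministic(self, tiny_setup):
        data, plan, lam, std = tiny_setup
        a = exhaustive_oracle(data, plan, lam, 0.5, standardization=std)
        b = exhaustive_oracle(data, plan, lam, 0.5, standardization=std)
        assert a.H == b.H and a.Q == b.Q

    def test_guard(self, small_contaminated):
        data = small_contaminated.data
        plan = make_plan(data.n1, data.n0, 0.75)
        with pytest.raises(ValueError, match="guard"):
            exhaustive_oracle(data, plan, 0.1, 0.5, guard=1000)


class TestARCstep:
    def test_q_opt_non_increasing(self, small_contaminated):
        data = small_contaminated.data
        plan = make_plan(data.n1, data.n0, 0.75)
        lam_max = compute_lambda_max(data)
        grid = build_grids(lam_max, "iteration")
        cfg = ARCstepConfig(seed=0)
        rng = np.random.default_rng(0)
        H0 = draw_initial_subset(data.y, rng)
        state, trace = ar_cstep_run(data, H0, plan, grid, cfg, rng)
        qopts = trace.q_opt_sequence
        finite = [q for q in qopts if np.isfinite(q)]
        assert all(a >= b - 1e-9 for a, b in zip(finite, finite[1:]))
        assert state.Q == pytest.approx(min(finite), abs=1e-9)

    def test_requires_rng(self, small_contaminated):
        data = small_contaminated.data
        plan = make_plan(data.n1, data.n0, 0.75)
        grid = build_grids(compute_lambda_max(data), "iteration")
        with pytest.raises(ValueError):
            ar_cstep_run(data, list(range(plan.h)), plan, grid,
                         ARCstepConfig(), None)

    def test_stall_stops_run(self, tiny_setup):
        data, plan, lam, std = tiny_setup
        grid = build_grids(compute_lambda_max(data), "iteration")
        cfg = ARCstepConfig(seed=0, stall_limit_r=3)
        rng = np.random.default_rng(0)
        # fixed lam: a self-candidate ends the run as converged
        state, trace = ar_cstep_run(data, list(range(plan.h)), plan, grid, cfg,
                                    rng, lam_alpha=(lam, 0.5),
                                    standardization=std)
        assert trace.converged or trace.stalled or trace.hit_max_iter

    def test_worse_candidate_needs_bernoulli(self, small_contaminated):
        """Whenever Q_cand <= Q_cur the candidate is accepted outright."""
        data = small_contaminated.data
        plan = make_plan(data.n1, data.n0, 0.75)
        grid = build_grids(compute_lambda_max(data), "iteration")
        cfg = ARCstepConfig(seed=1)
        rng = np.random.default_rng(1)
        _, trace = ar_cstep_run(data, draw_initial_subset(data.y, rng), plan,
                                grid, cfg, rng)
        for rec in trace.records:
            if rec.get("self_candidate"):
                continue
            if rec["Q_candidate"] <= rec["Q_current"] + 1e-12 and rec["accepted"]:
                assert rec["p"] == 1.0


class TestMultiStart:
    def test_initial_subsets_three_per_class(self, small_contaminated):
        data = small_contaminated.data
        rng = np.random.default_rng(2)
        for _ in range(50):
            H0 = draw_initial_subset(data.y, rng)
            assert len(H0) == 6
            assert int(np.sum(data.y[H0] == 1)) == 3

    def test_single_start_reduces_to_one_run(self, small_contaminated):
        data = small_contaminated.data
        plan = make_plan(data.n1, data.n0, 0.75)
        grid = build_grids(compute_lambda_max(data), "iteration")
        cfg = ARCstepConfig(n_starts=1, keep=1, seed=3)
        best, trace = multi_start_search(data, plan, grid, cfg,
                                         np.random.default_rng(3))
        assert len(best.H) == plan.h
        assert trace.meta["retained_Q"][0] >= best.Q - 1e-9

    def test_returned_beats_retained(self, small_contaminated):
        data = small_contaminated.data
        plan = make_plan(data.n1, data.n0, 0.75)
        grid = build_grids(compute_lambda_max(data), "iteration")
        cfg = ARCstepConfig(n_starts=20, keep=4, seed=4)
        best, trace = multi_start_search(data, plan, grid, cfg,
                                         np.random.default_rng(4))
        assert best.Q <= min(trace.meta["retained_Q"]) + 1e-9

    def test_too_few_per_class(self):
        from trimlogit.core import LabeledMatrix

        rng = np.random.default_rng(0)
        data = LabeledMatrix.from_arrays(rng.standard_normal((8, 3)),
                                         [1, 1, 0, 0, 0, 0, 0, 0])
        plan = make_plan(3, 5, 0.75)  # plan itself is fine
        grid = build_grids(1.0, "iteration")
        with pytest.raises(ValueError, match="too few"):
            multi_start_search(data, plan, grid, ARCstepConfig(),
                               np.random.default_rng(0))

    def test_deterministic_given_seed(self, small_contaminated):
        data = small_contaminated.data
        plan = make_plan(data.n1, data.n0, 0.75)
        grid = build_grids(compute_lambda_max(data), "iteration")
        cfg = ARCstepConfig(n_starts=10, keep=2, seed=9)
        a, _ = multi_start_search(data, plan, grid, cfg, np.random.default_rng(9))
        b, _ = multi_start_search(data, plan, grid, cfg, np.random.default_rng(9))
        assert a.H == b.H
        assert a.Q == pytest.approx(b.Q, abs=0)
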