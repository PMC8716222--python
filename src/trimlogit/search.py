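"""Subset-search algorithms for the trimmed penalized likelihood.

Four searchers over size-h observation subsets:

* ``cstep_fixed``   — classic concentration steps at fixed (lam, alpha);
  monotone in Q and guaranteed to converge.
* ``cstep_grid``    — cstep_fixed run to convergence for every grid
  combination (the slow baseline).
* ``ar_cstep_run``  — concentration steps with a Metropolis-type
  accept/reject of the candidate subset, tracking the best state seen, for
  the realistic setting where (lam, alpha) are re-selected by CV every
  iteration and monotonicity is lost.
* ``exhaustive_oracle`` — brute force over all stratified subsets (tests).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    DegenerateSubsetError,
    FitCounter,
    LabeledMatrix,
    PenalizedModel,
    RegGrid,
    Standardization,
    cv_select,
    fit_penalized_logistic,
    subset_standardization,
)
from .trimming import (
    SubsetState,
    TrimmingPlan,
    criterion,
    select_candidate_subset,
    select_smallest,
)


@dataclass(frozen=True)
class ARCstepConfig:
    """Knobs of the acceptance-rejection concentration-step search."""

    n_starts: int = 500
    warm_steps: int = 2
    keep: int = 10
    stall_limit_r: int = 3
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    folds: int = 5
    cv_rule: str = "min"
    #: fixed lambda fraction used during the warm phase, where CV on
    #: 6-observation subsets is meaningless; one shared value keeps the
    #: criterion comparable across starts
    warm_lambda_fraction: float = 0.5

    def __post_init__(self):
        if self.keep > self.n_starts:
            raise ValueError("keep must not exceed n_starts")
        if self.stall_limit_r < 1:
            raise ValueError("stall_limit_r must be >= 1")


@dataclass
class SearchTrace:
    """Per-iteration log plus a penalized-fit counter (hardware-free cost)."""

    records: list = field(default_factory=list)
    fit_count: int = 0
    stalled: bool = False
    converged: bool = False
    hit_max_iter: bool = False
    meta: dict = field(default_factory=dict)

    def log(self, **rec):
        self.records.append(rec)

    def merge(self, other: "SearchTrace"):
        self.fit_count += other.fit_count

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(r, default=float) for r in self.records)

    @property
    def q_opt_sequence(self) -> list:
        return [r["Q_opt"] for r in self.records if "Q_opt" in r]


def acceptance_probability(loglik_cand: float, loglik_cur: float, k: int, D: float) -> float:
    """Probability of accepting a worsening candidate at iteration k.

    p = exp(tau_k * (loglik_cand - loglik_cur)) with tau_k = log(k+1)/D,
    clipped to (0, 1].  At k = 0, tau = 0 so p = 1 regardless.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if k < 0:
        raise ValueError("k must be >= 0")
    tau = math.log(k + 1) / D
    p = math.exp(tau * (loglik_cand - loglik_cur))
    return min(p, 1.0)


def default_temperature_divisor(n: int, eta: float) -> float:
    """D = 0.1 * n * (1 - eta)."""
    return 0.1 * n * (1.0 - eta)


def _fit(data, H, lam, alpha, standardization, counter, strict=True):
    return fit_penalized_logistic(
        data, H, lam, alpha, standardization=standardization, counter=counter,
        strict=strict,
    )


def cstep_fixed(
    data: LabeledMatrix,
    H0,
    lam: float,
    alpha: float,
    plan: TrimmingPlan,
    tol: float = 1e-6,
    max_iter: int = 30,
    stratified: bool = True,
    standardization: Standardization | None = None,
    counter: FitCounter | None = None,
) -> tuple[SubsetState, SearchTrace]:
    """Concentration steps at fixed (lam, alpha) until Q stabilizes.

    The initial subset may be smaller than h; the first move expands it to h
    by deviance ranking.  Column standardization is frozen for the whole run
    (from the first size-h subset unless given), so Q is a single objective
    and the chain Q(H_k; b_k) >= Q(H_{k+1}; b_k) >= Q(H_{k+1}; b_{k+1})
    holds at every iteration.
    """
    trace = SearchTrace()
    counter = counter if counter is not None else FitCounter()
    c0 = counter.count

    def _select(dev):
        if stratified:
            return select_candidate_subset(dev, data.y, plan)
        return select_smallest(dev, plan.h)

    H = np.asarray(sorted(H0), dtype=np.int64)
    retried = False
    while True:
        try:
            if H.size < plan.h:
                # expansion fit only seeds a ranking; best-effort is fine
                pre = _fit(data, H, lam, alpha, None, counter, strict=False)
                H = _select(pre.deviances_full)
            if standardization is None:
                standardization = subset_standardization(data.X, H)
            break
        except DegenerateSubsetError:
            if retried:
                raise
            retried = True
            H = _select(np.zeros(data.n))
    Q_prev = None
    model = None
    converged = False
    for k in range(max_iter):
        # warm start from the previous iterate (same frozen coordinates):
        # coordinate descent only improves on it, so the second Eq-style
        # inequality of the chain holds by construction
        init = (model.intercept, model.beta) if model is not None else None
        try:
            model = fit_penalized_logistic(
                data, H, lam, alpha, standardization=standardization,
                counter=counter, init=init)
        except DegenerateSubsetError:
            if retried:
                raise
            retried = True
            H = _select(np.zeros(data.n))
            model = _fit(data, H, lam, alpha, standardization, counter)
        Q = criterion(H, model)
        H_next = _select(model.deviances_full)
        Q_cross = criterion(H_next, model)  # Q(H_{k+1}; beta_k)
        trace.log(k=k, Q=Q, Q_cross=Q_cross, H_size=int(H.size))
        if Q_prev is not None and abs(Q - Q_prev) < tol:
            converged = True
            break
        Q_prev = Q
        if np.array_equal(H_next, H):
            converged = True
            break
        H = H_next
    trace.converged = converged
    trace.hit_max_iter = not converged
    trace.fit_count = counter.count - c0
    state = SubsetState.from_model(H, model)
    return state, trace


def cstep_grid(
    data: LabeledMatrix,
    starts: Sequence,
    grid: RegGrid,
    plan: TrimmingPlan,
    tol: float = 1e-6,
    max_iter: int = 30,
    stratified: bool = True,
    counter: FitCounter | None = None,
) -> tuple[SubsetState, SearchTrace]:
    """Run cstep_fixed to convergence for every (lam, alpha) grid combination
    and every start; return the converged state with the smallest Q."""
    counter = counter if counter is not None else FitCounter()
    c0 = counter.count
    trace = SearchTrace()
    best = None
    runs = 0
    for H0 in starts:
        for alpha in grid.alphas:
            for lam in grid.lambdas:
                state, _ = cstep_fixed(
                    data, H0, float(lam), float(alpha), plan,
                    tol=tol, max_iter=max_iter, stratified=stratified,
                    counter=counter,
                )
                runs += 1
                if best is None or state.Q < best.Q:
                    best = state
    trace.fit_count = counter.count - c0
    trace.meta["cstep_runs"] = runs
    return best, trace


def ar_cstep_run(
    data: LabeledMatrix,
    H0,
    plan: TrimmingPlan,
    grid: RegGrid,
    cfg: ARCstepConfig,
    rng: np.random.Generator,
    lam_alpha: tuple[float, float] | None = None,
    standardization: Standardization | None = None,
    counter: FitCounter | None = None,
    max_iter: int | None = None,
    initial_model: PenalizedModel | None = None,
) -> tuple[SubsetState, SearchTrace]:
    """Acceptance-rejection concentration-step search from one start.

    Per iteration k: build the stratified candidate from the current model's
    full-data deviances; select (lam, alpha) for the candidate (by stratified
    CV over `grid` unless `lam_alpha` pins them); fit; accept the candidate
    outright when its criterion does not worsen, otherwise accept with the
    Metropolis probability exp(tau_k * (loglik_cand - loglik_cur)).  The best
    size-h state seen (H_opt) is returned, not the last one.

    A self-candidate (H_cand == H_k) counts as a non-replacement; the run
    stops after `stall_limit_r` consecutive non-replacements or at max_iter.
    Under CV-selected parameters a later fold reshuffle can still perturb the
    ranking, so a self-candidate ends the run immediately only when
    (lam, alpha) are pinned and the iteration is exactly reproducible.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    counter = counter if counter is not None else FitCounter()
    c0 = counter.count
    max_iter = cfg.max_iter if max_iter is None else max_iter
    D = default_temperature_divisor(plan.n, plan.eta)
    trace = SearchTrace()

    def _select_params(H):
        if lam_alpha is not None:
            return lam_alpha
        seed = int(rng.integers(2**31 - 1))
        return cv_select(
            data, H, grid, folds=cfg.folds, seed=seed, counter=counter, rule=cfg.cv_rule
        )

    H_cur = np.asarray(sorted(H0), dtype=np.int64)
    if initial_model is not None:
        model_cur = initial_model
    else:
        if H_cur.size >= plan.h:
            lam0, alpha0 = _select_params(H_cur)
        elif lam_alpha is not None:
            lam0, alpha0 = lam_alpha
        else:
            lam0, alpha0 = (cfg.warm_lambda_fraction * grid.lambda_max,
                            float(grid.alphas[0]))
        model_cur = _fit(data, H_cur, lam0, alpha0, standardization, counter,
                         strict=H_cur.size >= plan.h)
    Q_cur = criterion(H_cur, model_cur)

    H_opt, model_opt, Q_opt = None, None, np.inf
    if H_cur.size == plan.h:
        H_opt, model_opt, Q_opt = H_cur, model_cur, Q_cur

    stall = 0
    for k in range(max_iter):
        H_cand = select_candidate_subset(model_cur.deviances_full, data.y, plan)
        if np.array_equal(H_cand, H_cur):
            # no fresh fit: the current parameters would reproduce H_cand
            stall += 1
            trace.log(k=k, Q_current=Q_cur, Q_candidate=Q_cur, accepted=False,
                      Q_opt=Q_opt, self_candidate=True)
            if lam_alpha is not None or stall >= cfg.stall_limit_r:
                trace.converged = lam_alpha is not None
                trace.stalled = lam_alpha is None
                break
            # refresh the fit with new CV folds to perturb the ranking
            lam_k, alpha_k = _select_params(H_cur)
            model_cur = _fit(data, H_cur, lam_k, alpha_k, standardization, counter)
            Q_cur = criterion(H_cur, model_cur)
            if Q_cur < Q_opt:
                H_opt, model_opt, Q_opt = H_cur, model_cur, Q_cur
            continue
        lam_k, alpha_k = _select_params(H_cand)
        model_cand = _fit(data, H_cand, lam_k, alpha_k, standardization, counter)
        Q_cand = criterion(H_cand, model_cand)
        comparable = H_cur.size == plan.h
        if not comparable or Q_cand <= Q_cur:
            accepted = True
            p = 1.0
        else:
            p = acceptance_probability(
                model_cand.loglik_subset, model_cur.loglik_subset, k, D
            )
            accepted = bool(rng.random() < p)
        small_change = comparable and accepted and abs(Q_cand - Q_cur) < cfg.tol
        if accepted:
            H_cur, model_cur, Q_cur = H_cand, model_cand, Q_cand
            stall = 0
        else:
            stall += 1
        if Q_cur < Q_opt and H_cur.size == plan.h:
            H_opt, model_opt, Q_opt = H_cur, model_cur, Q_cur
        trace.log(k=k, Q_current=Q_cur, Q_candidate=Q_cand, accepted=accepted,
                  p=p, lam=lam_k, alpha=alpha_k, Q_opt=Q_opt)
        if small_change:
            trace.converged = True
            break
        if stall >= cfg.stall_limit_r:
            trace.stalled = True
            break
    else:
        trace.hit_max_iter = True
    if H_opt is None:
        raise RuntimeError("no size-h state visited; increase max_iter")
    trace.fit_count = counter.count - c0
    state = SubsetState.from_model(H_opt, model_opt)
    return state, trace


def draw_initial_subset(
    y: np.ndarray, rng: np.random.Generator, per_class: int = 3
) -> np.ndarray:
    """Elemental start: `per_class` samples from each class, no replacement."""
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    if idx1.size < per_class or idx0.size < per_class:
        raise ValueError("too few samples per class")
    pick1 = rng.choice(idx1, size=per_class, replace=False)
    pick0 = rng.choice(idx0, size=per_class, replace=False)
    return np.sort(np.concatenate([pick1, pick0]))


def multi_start_search(
    data: LabeledMatrix,
    plan: TrimmingPlan,
    grid: RegGrid,
    cfg: ARCstepConfig,
    rng: np.random.Generator,
    counter: FitCounter | None = None,
) -> tuple[SubsetState, SearchTrace]:
    """Full search: many elemental starts, a short warm phase, then the best
    few runs carried to convergence.

    Warm phase: `n_starts` initial subsets of six observations (three per
    class) each advanced `warm_steps` accept/reject iterations at a fixed
    heavy-shrinkage lambda (`warm_lambda_fraction * lambda_max`, shared so Q
    is comparable across starts).  The `keep` best states then run to
    convergence with per-iteration CV selection of (lam, alpha).
    """
    if data.n1 < 3 or data.n0 < 3:
        raise ValueError("too few samples per class (need >= 3 in each)")
    counter = counter if counter is not None else FitCounter()
    c0 = counter.count
    trace = SearchTrace()
    lam_warm = cfg.warm_lambda_fraction * grid.lambda_max
    alpha_warm = 0.5
    trace.meta["warm_lambda"] = lam_warm
    trace.meta["warm_alpha"] = alpha_warm

    warm_states = []
    for _ in range(cfg.n_starts):
        H0 = draw_initial_subset(data.y, rng)
        state, _t = ar_cstep_run(
            data, H0, plan, grid, cfg, rng,
            lam_alpha=(lam_warm, alpha_warm),
            counter=counter, max_iter=cfg.warm_steps,
        )
        warm_states.append(state)
    warm_states.sort(key=lambda s: s.Q)
    retained = warm_states[: cfg.keep]
    trace.meta["warm_best_Q"] = retained[0].Q

    best = None
    for state in retained:
        final, t = ar_cstep_run(
            data, np.asarray(state.H), plan, grid, cfg, rng, counter=counter,
            initial_model=state.model,
        )
        if best is None or final.Q < best.Q:
            best = final
    trace.fit_count = counter.count - c0
    trace.meta["retained_Q"] = [s.Q for s in retained]
    return best, trace


def exhaustive_oracle(
    data: LabeledMatrix,
    plan: TrimmingPlan,
    lam: float,
    alpha: float,
    standardization: Standardization | None = None,
    counter: FitCounter | None = None,
    guard: int = 100_000,
) -> SubsetState:
    """Global minimum of Q over every (h1, h0)-stratified subset (testing only)."""
    from itertools import combinations

    idx1 = np.flatnonzero(data.y == 1)
    idx0 = np.flatnonzero(data.y == 0)
    n_comb = math.comb(idx1.size, plan.h1) * math.comb(idx0.size, plan.h0)
    if n_comb > guard:
        raise ValueError(f"{n_comb} stratified subsets exceeds guard {guard}")
    best = None
    for c1 in combinations(idx1.tolist(), plan.h1):
        for c0 in combinations(idx0.tolist(), plan.h0):
            H = np.sort(np.array(c1 + c0, dtype=np.int64))
            model = _fit(data, H, lam, alpha, standardization, counter)
            Q = criterion(H, model)
            if best is None or Q < best.Q:
                best = SubsetState.from_model(H, model)
    return best


def count_stratified_subsets(plan: TrimmingPlan) -> int:
    """C(n1, h1) * C(n0, h0) — the oracle's enumeration size."""
    return math.comb(plan.n1, plan.h1) * math.comb(plan.n0, plan.h0)
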