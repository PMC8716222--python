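"""Trimming-plan arithmetic, the trimmed criterion Q, and candidate subsets."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import PenalizedModel, elastic_net_penalty

# guard against 15.0 evaluating as 14.999999... before floor()
_FLOOR_EPS = 1e-9


def _floor(x: float) -> int:
    return int(math.floor(x + _FLOOR_EPS))


@dataclass(frozen=True)
class TrimmingPlan:
    """Subset sizes for retained fraction eta (1 - eta is trimmed).

    h = floor(n*eta); the class-1 quota is h1 = floor((n1+1)*eta), capped at
    min(h, n1) so the plan stays feasible as eta -> 1; h0 = h - h1.
    """

    eta: float
    n: int
    n1: int
    n0: int
    h: int
    h1: int
    h0: int

    def __post_init__(self):
        if not (0.5 < self.eta <= 1.0):
            raise ValueError("eta must lie in (0.5, 1]")
        if self.h != self.h1 + self.h0:
            raise ValueError("h must equal h1 + h0")
        if not (0 < self.h1 <= self.n1):
            raise ValueError("h1 out of range")
        if not (0 < self.h0 <= self.n0):
            raise ValueError("h0 out of range")
        if self.h > self.n:
            raise ValueError("h exceeds n")


def make_plan(n1: int, n0: int, eta: float) -> TrimmingPlan:
    """Build a TrimmingPlan from class counts and retained fraction eta."""
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 samples per class")
    if not (0.5 < eta <= 1.0):
        raise ValueError("eta must lie in (0.5, 1]")
    n = n1 + n0
    h = _floor(n * eta)
    # clamp the printed quota into the feasible band: at least one row per
    # class must be retained and neither class can exceed its count
    h1 = min(_floor((n1 + 1) * eta), n1, h - 1)
    h1 = max(h1, h - n0, 1)
    h0 = h - h1
    return TrimmingPlan(eta=eta, n=n, n1=n1, n0=n0, h=h, h1=h1, h0=h0)


def criterion(H, model: PenalizedModel, h: int | None = None) -> float:
    """Q(H; beta) = sum_{i in H} d_i + h * lam * P_alpha(beta)."""
    H = np.asarray(sorted(H), dtype=np.int64)
    if h is not None and H.size != h:
        raise ValueError(f"subset has size {H.size}, expected {h}")
    dev = float(np.sum(model.deviances_full[H]))
    return dev + H.size * model.lam * elastic_net_penalty(model.beta, model.alpha)


@dataclass(frozen=True)
class SubsetState:
    """A size-h subset with its fitted model and criterion value."""

    H: tuple[int, ...]
    model: PenalizedModel
    Q: float
    lam: float
    alpha: float

    @classmethod
    def from_model(cls, H, model: PenalizedModel) -> "SubsetState":
        H = tuple(sorted(int(i) for i in H))
        return cls(H=H, model=model, Q=criterion(H, model), lam=model.lam, alpha=model.alpha)

    def recompute_Q(self) -> float:
        return criterion(self.H, self.model)


def select_candidate_subset(
    deviances: np.ndarray, y: np.ndarray, plan: TrimmingPlan
) -> np.ndarray:
    """Stratified candidate: h1 smallest-deviance class-1 rows, h0 class-0 rows.

    Ties break toward the lower sample index.  Returns sorted indices.
    """
    deviances = np.asarray(deviances, dtype=float)
    y = np.asarray(y)
    if deviances.shape != y.shape:
        raise ValueError("deviances and y must have equal length")
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    if plan.h1 > idx1.size or plan.h0 > idx0.size:
        raise ValueError("plan infeasible for these labels")
    pick1 = idx1[np.argsort(deviances[idx1], kind="stable")[: plan.h1]]
    pick0 = idx0[np.argsort(deviances[idx0], kind="stable")[: plan.h0]]
    return np.sort(np.concatenate([pick1, pick0]))


def select_smallest(deviances: np.ndarray, h: int) -> np.ndarray:
    """Unstratified candidate: the h smallest-deviance rows (classic C-step)."""
    deviances = np.asarray(deviances, dtype=float)
    if h > deviances.size:
        raise ValueError("h exceeds n")
    return np.sort(np.argsort(deviances, kind="stable")[:h])
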