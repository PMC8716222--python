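"""Penalized logistic regression on observation subsets.

Inner-model layer: labeled data container, subset-based standardization,
the elastic-net logistic solver wrapper, per-observation deviances,
regularization grids, and cross-validated grid selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._cd import cd_enet_logistic, cd_enet_logistic_path

logger = logging.getLogger(__name__)

#: probabilities are clipped to [PROB_CLIP, 1 - PROB_CLIP] before taking logs
PROB_CLIP = 1e-10

#: coordinate-descent tolerance / pass budget
SOLVER_TOL = 1e-7
SOLVER_MAX_PASS = 100_000


class DegenerateLabelsError(ValueError):
    """Labels carry no usable signal (single class / zero score)."""


class DegenerateSubsetError(ValueError):
    """A fitting subset contains only one class."""


class ConvergenceError(RuntimeError):
    """The inner solver failed to converge within its pass budget."""


@dataclass(frozen=True)
class LabeledMatrix:
    """An n x p numeric feature matrix with binary 0/1 labels."""

    X: np.ndarray
    y: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        object.__setattr__(self, "X", X)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = X.shape
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains missing or non-finite values")
        if y.shape != (n,):
            raise ValueError(f"y has length {y.shape}, expected ({n},)")
        vals = set(np.unique(y).tolist())
        if not vals <= {0, 1}:
            raise ValueError(f"labels must be 0/1, found values {sorted(vals)}")
        if len(vals) < 2:
            raise DegenerateLabelsError("both classes must be present")
        object.__setattr__(self, "y", y.astype(np.int64))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n1(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n0(self) -> int:
        return int(np.sum(self.y == 0))

    @classmethod
    def from_arrays(cls, X, y) -> "LabeledMatrix":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        return cls(
            X=X,
            y=np.asarray(y),
            sample_ids=tuple(f"s{i:05d}" for i in range(n)),
            feature_ids=tuple(f"f{j:05d}" for j in range(p)),
        )


@dataclass(frozen=True)
class Standardization:
    """Column location/scale estimated from a row subset (sd guard: 0 -> 1)."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if means.shape != sds.shape or means.ndim != 1:
            raise ValueError("means and sds must be 1-d with equal length")
        if np.any(sds <= 0):
            raise ValueError("every sd must be strictly positive")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) / self.sds


@dataclass(frozen=True)
class PenalizedModel:
    """A fitted elastic-net logistic model tied to its fitting subset.

    ``beta`` lives on the standardized scale; ``beta_original`` and
    ``intercept_original`` reproduce the same predictions from raw features.
    ``deviances_full`` holds the per-observation deviance of every sample in
    the data the model was fitted against (not just the subset).
    """

    intercept: float
    beta: np.ndarray
    lam: float
    alpha: float
    standardization: Standardization
    deviances_full: np.ndarray
    loglik_subset: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        if np.any(self.deviances_full < 0):
            raise ValueError("deviances must be nonnegative")

    @property
    def beta_original(self) -> np.ndarray:
        return self.beta / self.standardization.sds

    @property
    def intercept_original(self) -> float:
        return self.intercept - float(
            np.dot(self.beta, self.standardization.means / self.standardization.sds)
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probabilities of class 1 for raw-scale features X."""
        eta = self.intercept_original + X @ self.beta_original
        return 1.0 / (1.0 + np.exp(-eta))

    def penalty_value(self) -> float:
        """P_alpha(beta) on the standardized scale."""
        return elastic_net_penalty(self.beta, self.alpha)

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.beta != 0.0))


@dataclass(frozen=True)
class RegGrid:
    """Multiplicative lambda grid anchored at lambda_max, plus alpha values."""

    lambda_max: float
    lambda_fractions: np.ndarray
    alphas: np.ndarray

    def __post_init__(self):
        lf = np.asarray(self.lambda_fractions, dtype=float)
        al = np.asarray(self.alphas, dtype=float)
        if self.lambda_max <= 0:
            raise ValueError("lambda_max must be positive")
        if lf.size == 0 or np.any(np.diff(lf) <= 0):
            raise ValueError("lambda_fractions must be strictly increasing")
        if not (0 < lf[0] and abs(lf[-1] - 1.0) < 1e-12):
            raise ValueError("lambda_fractions must lie in (0, 1] and end at 1")
        if al.size == 0 or np.any((al <= 0) | (al > 1)):
            raise ValueError("alphas must lie in (0, 1]")
        object.__setattr__(self, "lambda_fractions", lf)
        object.__setattr__(self, "alphas", al)

    @property
    def lambdas(self) -> np.ndarray:
        return self.lambda_fractions * self.lambda_max

    @property
    def size(self) -> int:
        return self.lambda_fractions.size * self.alphas.size


def elastic_net_penalty(beta: np.ndarray, alpha: float) -> float:
    """P_alpha(beta) = alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2."""
    beta = np.asarray(beta, dtype=float)
    return float(alpha * np.sum(np.abs(beta)) + 0.5 * (1 - alpha) * np.sum(beta**2))


def compute_lambda_max(X, y=None, standardize: bool = True) -> float:
    """Smallest penalty that anchors the grid: max_j |X_j' y| / n.

    Accepts a LabeledMatrix or an (X, y) pair.  By default columns are
    standardized (full-data mean/sd) first, matching how the solver sees
    them.  Raises DegenerateLabelsError when the score is not strictly
    positive (e.g. y identically zero).
    """
    if isinstance(X, LabeledMatrix):
        X, y = X.X, X.y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if standardize:
        std = subset_standardization(X, np.arange(n))
        X = std.transform(X)
    lam_max = float(np.max(np.abs(X.T @ y)) / n)
    if lam_max <= 0:
        raise DegenerateLabelsError("degenerate labels: max_j |X_j'y|/n is zero")
    return lam_max


def subset_standardization(X: np.ndarray, subset) -> Standardization:
    """Column means/sds from the given rows (population sd; sd 0 -> 1)."""
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    sub = X[subset]
    means = sub.mean(axis=0)
    sds = sub.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    return Standardization(means=means, sds=sds)


def standardize_by_subset(data: LabeledMatrix, subset) -> tuple[np.ndarray, Standardization]:
    """Standardize ALL rows using column statistics from `subset` rows only."""
    std = subset_standardization(data.X, subset)
    return std.transform(data.X), std


def per_observation_deviance(
    intercept: float, beta: np.ndarray, Xs: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """d_i = -[y_i log pi_i + (1-y_i) log(1-pi_i)], probabilities clipped."""
    eta = intercept + Xs @ beta
    pi = 1.0 / (1.0 + np.exp(-eta))
    pi = np.clip(pi, PROB_CLIP, 1.0 - PROB_CLIP)
    return -(y * np.log(pi) + (1 - y) * np.log1p(-pi))


def model_deviances(model: PenalizedModel, data: LabeledMatrix) -> np.ndarray:
    """Per-observation deviances of `model` on arbitrary data (raw scale)."""
    Xs = model.standardization.transform(data.X)
    return per_observation_deviance(model.intercept, model.beta, Xs, data.y)


class FitCounter:
    """Counts single-(lambda, alpha) penalized fits — a hardware-free cost proxy."""

    def __init__(self):
        self.count = 0

    def add(self, k: int = 1):
        self.count += k


def fit_penalized_logistic(
    data: LabeledMatrix,
    subset,
    lam: float,
    alpha: float,
    standardization: Standardization | None = None,
    counter: FitCounter | None = None,
    strict: bool = True,
    init: tuple[float, np.ndarray] | None = None,
) -> PenalizedModel:
    """Fit EN-penalized logistic regression on `subset` rows.

    Minimizes sum_{i in H} d_i + h*lam*P_alpha(beta) with an unpenalized
    intercept.  Rows are standardized with statistics from the subset itself
    unless an explicit `standardization` is supplied; deviances are then
    recomputed for all n samples on that scale.

    With ``strict=False`` a fit that exhausts its pass budget (possible on
    tiny near-separable subsets at weak penalty) is returned best-effort
    instead of raising — appropriate when the fit only seeds a deviance
    ranking.
    """
    subset = np.asarray(sorted(subset), dtype=np.int64)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    ysub = data.y[subset]
    if ysub.min() == ysub.max():
        raise DegenerateSubsetError("degenerate subset: only one class present")
    if standardization is None:
        standardization = subset_standardization(data.X, subset)
    Xs_full = standardization.transform(data.X)
    Xs = np.ascontiguousarray(Xs_full[subset])
    yf = ysub.astype(np.float64)
    b0_init, beta_init = (0.0, np.zeros(data.p)) if init is None else (
        float(init[0]), np.asarray(init[1], dtype=float))
    b0, beta, n_pass, converged = cd_enet_logistic(
        Xs, yf, lam, alpha, b0_init, beta_init, SOLVER_TOL, SOLVER_MAX_PASS
    )
    if not converged:
        if strict:
            raise ConvergenceError(
                f"inner solver did not converge within {n_pass} passes"
            )
        logger.debug("best-effort fit kept after %d passes (no convergence)", n_pass)
    if counter is not None:
        counter.add()
    dev = per_observation_deviance(b0, beta, Xs_full, data.y)
    return PenalizedModel(
        intercept=float(b0),
        beta=beta,
        lam=float(lam),
        alpha=float(alpha),
        standardization=standardization,
        deviances_full=dev,
        loglik_subset=-float(np.sum(dev[subset])),
    )


def build_grids(lambda_max: float, phase: str) -> RegGrid:
    """Lambda/alpha grids for the two phases.

    ``iteration``: 20 lambda fractions in steps of 0.05, alpha fixed at 0.5.
    ``refit``:     100 lambda fractions in steps of 0.01, alphas 0.1 .. 1.0.
    """
    if lambda_max <= 0:
        raise ValueError("lambda_max must be positive")
    if phase == "iteration":
        fractions = np.linspace(0.05, 1.0, 20)
        alphas = np.array([0.5])
    elif phase == "refit":
        fractions = np.linspace(0.01, 1.0, 100)
        alphas = np.linspace(0.1, 1.0, 10)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return RegGrid(lambda_max=lambda_max, lambda_fractions=fractions, alphas=alphas)


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator):
    """Deterministic stratified fold assignment (round-robin after shuffle)."""
    assign = np.empty(y.shape[0], dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def cv_select(
    data: LabeledMatrix,
    subset,
    grid: RegGrid,
    folds: int = 5,
    seed: int = 0,
    counter: FitCounter | None = None,
    rule: str = "min",
) -> tuple[float, float]:
    """Pick (lam, alpha) minimizing mean held-out deviance over stratified folds.

    Ties (and the ``1se`` rule) resolve toward larger lambda then smaller
    alpha, i.e. toward the more parsimonious model.  Deterministic given seed.
    """
    subset = np.asarray(sorted(subset), dtype=np.int64)
    ysub = data.y[subset]
    n1 = int(np.sum(ysub == 1))
    n0 = int(np.sum(ysub == 0))
    if min(n1, n0) < 2:
        raise DegenerateSubsetError("cv_select needs >= 2 rows per class")
    max_folds = min(n1, n0)
    if max_folds < folds:
        logger.warning("reducing CV folds from %d to %d (small subset)", folds, max_folds)
        folds = max(2, max_folds)
    rng = np.random.default_rng(seed)
    assign = _stratified_folds(ysub, folds, rng)
    lambdas_desc = grid.lambdas[::-1].copy()  # descending for warm starts
    L = lambdas_desc.size
    A = grid.alphas.size
    # cv_dev[a, l] indexed on the descending lambda order
    cv_dev = np.zeros((A, L))
    cv_se_acc = np.zeros((A, L))
    fold_means = np.zeros((A, L, folds))
    for f in range(folds):
        train = subset[assign != f]
        test = subset[assign == f]
        std = subset_standardization(data.X, train)
        Xs = std.transform(data.X)
        Xtr = np.ascontiguousarray(Xs[train])
        ytr = data.y[train].astype(np.float64)
        Xte = Xs[test]
        yte = data.y[test]
        for a in range(A):
            b0s, betas, _, _ = cd_enet_logistic_path(
                Xtr, ytr, lambdas_desc, grid.alphas[a], SOLVER_TOL, SOLVER_MAX_PASS
            )
            if counter is not None:
                counter.add(L)
            for l in range(L):
                d = per_observation_deviance(b0s[l], betas[l], Xte, yte)
                fold_means[a, l, f] = float(np.mean(d))
    cv_dev = fold_means.mean(axis=2)
    best = None
    # scan from largest lambda / smallest alpha so ties keep the sparser model
    for a in range(A):
        for l in range(L):
            val = cv_dev[a, l]
            if best is None or val < best[0] - 1e-12:
                best = (val, l, a)
    if rule == "1se":
        _, l_star, a_star = best
        se = float(fold_means[a_star, l_star].std(ddof=1) / np.sqrt(folds))
        thresh = best[0] + se
        for l in range(L):
            if cv_dev[a_star, l] <= thresh:
                best = (cv_dev[a_star, l], l, a_star)
                break
    elif rule != "min":
        raise ValueError(f"unknown CV rule {rule!r}")
    _, l_star, a_star = best
    return float(lambdas_desc[l_star]), float(grid.alphas[a_star])
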