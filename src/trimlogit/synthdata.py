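"""Seeded generator of sparse logistic datasets with label-flip contamination.

The design is a documented stand-in: features are multivariate normal with
AR(1) correlation, a sparse coefficient vector with alternating-sign effects
drives the clean labels, and a stated fraction of labels is then flipped,
stratified by class.  All parameters are explicit so recovery experiments
are self-describing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .core import LabeledMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    n: int = 200
    p: int = 400
    q: int = 10
    effect: float = 2.0
    rho: float = 0.2
    epsilon: float = 0.1
    balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.q > self.p:
            raise ValueError("q must not exceed p")
        if not (0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must lie in [0, 0.5)")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if not (0 < self.balance < 1):
            raise ValueError("balance must lie in (0, 1)")

    @property
    def n_flips(self) -> int:
        return int(np.floor(self.epsilon * self.n))


#: the contamination levels and matrix scale used in the headline experiments
PAPER_SCALE_PRESET = dict(n=500, p=1000, q=10, effect=2.0, rho=0.2, balance=0.5)


@dataclass(frozen=True)
class SyntheticDataset:
    data: LabeledMatrix
    true_support: tuple[int, ...]
    flipped: tuple[int, ...]
    clean_y: np.ndarray
    spec: SyntheticSpec

    def __post_init__(self):
        diff = np.flatnonzero(self.data.y != self.clean_y)
        if set(diff.tolist()) != set(self.flipped):
            raise ValueError("y must differ from clean_y exactly on flipped")


def _ar1_normal(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """N(0, Sigma) rows with Sigma_jk = rho^|j-k|, via the AR(1) recursion."""
    X = np.empty((n, p))
    X[:, 0] = rng.standard_normal(n)
    if p > 1:
        innov = rng.standard_normal((n, p - 1)) * np.sqrt(1.0 - rho**2)
        for j in range(1, p):
            X[:, j] = rho * X[:, j - 1] + innov[:, j - 1]
    return X


def support_indices(spec: SyntheticSpec) -> np.ndarray:
    """True features spread evenly so AR(1) neighbours do not cancel."""
    return np.unique((np.arange(spec.q) * spec.p // spec.q).astype(np.int64))


def true_beta(spec: SyntheticSpec) -> np.ndarray:
    beta = np.zeros(spec.p)
    idx = support_indices(spec)
    signs = np.where(np.arange(idx.size) % 2 == 0, 1.0, -1.0)
    beta[idx] = signs * spec.effect
    return beta


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset; bit-reproducible given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    X = _ar1_normal(rng, spec.n, spec.p, spec.rho)
    beta = true_beta(spec)
    lp = X @ beta

    def mean_prob(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(lp + b0))))) - spec.balance

    b0 = brentq(mean_prob, -50.0, 50.0)
    pi = 1.0 / (1.0 + np.exp(-(lp + b0)))
    clean_y = (rng.random(spec.n) < pi).astype(np.int64)
    # both classes must survive: re-draw boundary cases deterministically
    if clean_y.min() == clean_y.max():
        clean_y[int(np.argmin(pi)) if clean_y[0] == 1 else int(np.argmax(pi))] ^= 1

    n_flips = spec.n_flips
    idx1 = np.flatnonzero(clean_y == 1)
    idx0 = np.flatnonzero(clean_y == 0)
    k1 = min(int(round(n_flips * idx1.size / spec.n)), idx1.size)
    k0 = min(n_flips - k1, idx0.size)
    k1 = n_flips - k0  # rebalance if the class-0 side was capped
    flip1 = rng.choice(idx1, size=k1, replace=False) if k1 else np.empty(0, np.int64)
    flip0 = rng.choice(idx0, size=k0, replace=False) if k0 else np.empty(0, np.int64)
    flipped = np.sort(np.concatenate([flip1, flip0]).astype(np.int64))
    y = clean_y.copy()
    y[flipped] = 1 - y[flipped]

    data = LabeledMatrix(
        X=X,
        y=y,
        sample_ids=tuple(f"s{i:05d}" for i in range(spec.n)),
        feature_ids=tuple(f"g{j:05d}" for j in range(spec.p)),
    )
    return SyntheticDataset(
        data=data,
        true_support=tuple(int(j) for j in support_indices(spec)),
        flipped=tuple(int(i) for i in flipped),
        clean_y=clean_y,
        spec=spec,
    )


def write_fixture(ds: SyntheticDataset, path_prefix) -> tuple[Path, Path]:
    """Write <prefix>.csv (sample_id, label, features) and <prefix>.truth.json."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".truth.json")
    data = ds.data
    with open(csv_path, "w") as fh:
        fh.write("sample_id,label," + ",".join(data.feature_ids) + "\n")
        for i in range(data.n):
            row = ",".join(repr(float(v)) for v in data.X[i])
            fh.write(f"{data.sample_ids[i]},{int(data.y[i])},{row}\n")
    truth = {
        "true_support": list(ds.true_support),
        "flipped": list(ds.flipped),
        "clean_y": ds.clean_y.tolist(),
        "spec": asdict(ds.spec),
    }
    with open(json_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    return csv_path, json_path
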