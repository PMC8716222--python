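"""Reweighting step: refit on the optimal subset, flag outliers by Pearson
residual, refit on the cleaned sample set."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    FitCounter,
    LabeledMatrix,
    PenalizedModel,
    RegGrid,
    build_grids,
    compute_lambda_max,
    cv_select,
    fit_penalized_logistic,
)
from .search import ARCstepConfig, SearchTrace, multi_start_search
from .trimming import make_plan

#: default Pearson-residual cutoff.  |r| > 1 for a binary outcome means the
#: fitted probability sits on the wrong side of 1/2, i.e. the label
#: contradicts the model's prediction; with CV-shrunk sparse fits the
#: classical 2.5-sigma convention flags essentially nothing because fitted
#: probabilities are rarely extreme enough.
DEFAULT_CUTOFF = 1.0


@dataclass(frozen=True)
class OutlierReport:
    pearson_residuals: np.ndarray
    cutoff_c: float
    flags: np.ndarray
    flagged_ids: tuple[str, ...]

    def __post_init__(self):
        if self.cutoff_c <= 0:
            raise ValueError("cutoff_c must be positive")
        expected = np.abs(self.pearson_residuals) > self.cutoff_c
        if not np.array_equal(expected, self.flags):
            raise ValueError("flags inconsistent with residuals and cutoff")

    @property
    def flagged_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flags)

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.flags)


@dataclass(frozen=True)
class RobustFit:
    """Raw and reweighted solutions with the outlier report in between."""

    raw_model: PenalizedModel
    H_opt: tuple[int, ...]
    rwt_model: PenalizedModel
    H_rwt: tuple[int, ...]
    report: OutlierReport
    trace: SearchTrace

    @property
    def selected_features(self) -> np.ndarray:
        """Indices of features with nonzero reweighted coefficients."""
        return np.flatnonzero(self.rwt_model.beta != 0.0)


def refit_on_subset(
    data: LabeledMatrix,
    H,
    grid: RegGrid,
    folds: int = 5,
    seed: int = 0,
    counter: FitCounter | None = None,
    cv_rule: str = "min",
) -> PenalizedModel:
    """CV over the fine grid on H, then a final fit at the winning (lam, alpha)."""
    lam, alpha = cv_select(data, H, grid, folds=folds, seed=seed, counter=counter,
                           rule=cv_rule)
    return fit_penalized_logistic(data, H, lam, alpha, counter=counter)


def pearson_residuals(model: PenalizedModel, data: LabeledMatrix) -> np.ndarray:
    """r_i = (y_i - pi_i) / sqrt(pi_i * (1 - pi_i)), probabilities clipped."""
    from .core import PROB_CLIP

    pi = model.predict_proba(data.X)
    pi = np.clip(pi, PROB_CLIP, 1.0 - PROB_CLIP)
    return (data.y - pi) / np.sqrt(pi * (1.0 - pi))


def detect_outliers(
    residuals: np.ndarray, cutoff_c: float, sample_ids=None
) -> OutlierReport:
    residuals = np.asarray(residuals, dtype=float)
    if cutoff_c <= 0:
        raise ValueError("cutoff_c must be positive")
    flags = np.abs(residuals) > cutoff_c
    if sample_ids is None:
        sample_ids = [str(i) for i in range(residuals.size)]
    flagged_ids = tuple(sample_ids[i] for i in np.flatnonzero(flags))
    return OutlierReport(
        pearson_residuals=residuals, cutoff_c=float(cutoff_c),
        flags=flags, flagged_ids=flagged_ids,
    )


def run_mtl_en(
    data: LabeledMatrix,
    eta: float = 0.75,
    cfg: ARCstepConfig | None = None,
    cutoff_c: float = DEFAULT_CUTOFF,
    counter: FitCounter | None = None,
) -> RobustFit:
    """Full pipeline: subset search, raw refit, outlier flagging, clean refit."""
    cfg = cfg or ARCstepConfig()
    counter = counter if counter is not None else FitCounter()
    rng = np.random.default_rng(cfg.seed)
    plan = make_plan(data.n1, data.n0, eta)
    lam_max = compute_lambda_max(data.X, data.y)
    iter_grid = build_grids(lam_max, "iteration")
    refit_grid = build_grids(lam_max, "refit")

    best, trace = multi_start_search(data, plan, iter_grid, cfg, rng, counter=counter)
    H_opt = best.H

    seed_raw = int(rng.integers(2**31 - 1))
    raw_model = refit_on_subset(
        data, H_opt, refit_grid, folds=cfg.folds,
        seed=seed_raw, counter=counter, cv_rule=cfg.cv_rule,
    )
    resid = pearson_residuals(raw_model, data)
    report = detect_outliers(resid, cutoff_c, data.sample_ids)
    H_rwt = tuple(int(i) for i in report.kept_indices)
    seed_rwt = int(rng.integers(2**31 - 1))
    rwt_model = refit_on_subset(
        data, H_rwt, refit_grid, folds=cfg.folds,
        seed=seed_rwt, counter=counter, cv_rule=cfg.cv_rule,
    )
    trace.meta["refit_seed_raw"] = seed_raw
    trace.meta["refit_seed_rwt"] = seed_rwt
    trace.meta["H_rwt_size"] = len(H_rwt)
    trace.fit_count = counter.count
    return RobustFit(
        raw_model=raw_model, H_opt=tuple(int(i) for i in H_opt),
        rwt_model=rwt_model, H_rwt=H_rwt, report=report, trace=trace,
    )


def outlier_table(fit: RobustFit, data: LabeledMatrix) -> "pandas.DataFrame":
    """Per-sample report: id, label, fitted probability, residual, flag."""
    import pandas as pd

    pi = fit.raw_model.predict_proba(data.X)
    return pd.DataFrame(
        {
            "sample_id": list(data.sample_ids),
            "label": data.y,
            "fitted_prob": pi,
            "pearson_residual": fit.report.pearson_residuals,
            "outlier": fit.report.flags,
        }
    )
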