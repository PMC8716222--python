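"""Accuracy metrics for outlier detection and variable selection.

Outlier side: Sn (share of truly mislabeled samples flagged) and FPR (share
of correctly labeled samples flagged).  Selection side: PSR (share of true
features selected), FDR (share of selected features that are false), and
their geometric-mean summary GM = sqrt(PSR * (1 - FDR)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class MetricSet:
    Sn: float | None
    FPR: float
    PSR: float
    FDR: float
    GM: float
    model_size: float

    def __post_init__(self):
        for name in ("FPR", "PSR", "FDR", "GM"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.Sn is not None and not (0.0 <= self.Sn <= 1.0):
            raise ValueError("Sn outside [0, 1]")


def outlier_metrics(true_flipped, flagged, n: int) -> tuple[float | None, float]:
    """(Sn, FPR); Sn is None when there are no true outliers."""
    true_flipped = set(int(i) for i in true_flipped)
    flagged = set(int(i) for i in flagged)
    if not true_flipped <= set(range(n)) or not flagged <= set(range(n)):
        raise ValueError("indices must lie in [0, n)")
    sn = len(flagged & true_flipped) / len(true_flipped) if true_flipped else None
    n_clean = n - len(true_flipped)
    fpr = len(flagged - true_flipped) / n_clean if n_clean else 0.0
    return sn, fpr


def selection_metrics(true_support, selected) -> tuple[float, float, float, int]:
    """(PSR, FDR, GM, model_size); empty selection gives PSR=FDR=GM=0."""
    true_support = set(int(i) for i in true_support)
    selected = set(int(i) for i in selected)
    if not true_support:
        raise ValueError("true_support must be non-empty")
    psr = len(selected & true_support) / len(true_support)
    fdr = len(selected - true_support) / len(selected) if selected else 0.0
    gm = math.sqrt(psr * (1.0 - fdr))
    return psr, fdr, gm, len(selected)


def evaluate(true_flipped, flagged, n, true_support, selected) -> MetricSet:
    sn, fpr = outlier_metrics(true_flipped, flagged, n)
    psr, fdr, gm, size = selection_metrics(true_support, selected)
    return MetricSet(Sn=sn, FPR=fpr, PSR=psr, FDR=fdr, GM=gm, model_size=size)


def replicate_summary(per_replicate: list[MetricSet]) -> MetricSet:
    """Fieldwise means; GM is averaged per replicate, never recomputed from
    the mean PSR/FDR (the two differ whenever replicates vary)."""
    if not per_replicate:
        raise ValueError("need at least one replicate")
    k = len(per_replicate)
    sn_vals = [m.Sn for m in per_replicate if m.Sn is not None]
    return MetricSet(
        Sn=sum(sn_vals) / len(sn_vals) if sn_vals else None,
        FPR=sum(m.FPR for m in per_replicate) / k,
        PSR=sum(m.PSR for m in per_replicate) / k,
        FDR=sum(m.FDR for m in per_replicate) / k,
        GM=sum(m.GM for m in per_replicate) / k,
        model_size=sum(m.model_size for m in per_replicate) / k,
    )


def metrics_table(rows: dict[str, MetricSet]) -> str:
    """TSV with one row per labeled MetricSet."""
    header = "name\tmodel_size\tSn\tFPR\tPSR\tFDR\tGM"
    lines = [header]
    for name, m in rows.items():
        sn = "" if m.Sn is None else f"{m.Sn:.4f}"
        lines.append(
            f"{name}\t{m.model_size:.2f}\t{sn}\t{m.FPR:.4f}"
            f"\t{m.PSR:.4f}\t{m.FDR:.4f}\t{m.GM:.4f}"
        )
    return "\n".join(lines) + "\n"
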