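"""Cross-image concentration-dependence analysis.

In simple binary phase separation, once droplets have nucleated both phase
concentrations are pinned: C_dil stays at the saturation concentration C_sat
and C_den at the dense-phase binodal, with only the volume fraction growing
with total concentration. In a multicomponent system the tie-lines shift, so
C_dil and C_den themselves climb with C_tot. This module correlates per-image
phase metrics against C_tot and classifies the series accordingly.

The verdict combines statistical significance of the Pearson correlation with
an effect-size guard: the fitted relative change of a metric across the
observed C_tot range must exceed ``rel_change_threshold`` before the metric
counts as "increasing". Without the guard, a truly constant metric measured
with iid noise yields a sample r with sd ≈ 1/sqrt(n−1) (≈ 0.16 at n = 40), so
a pure |r| rule misclassifies a substantial fraction of binary series. Setting
``rel_change_threshold=0`` recovers the significance-only rule.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import InsufficientVarianceError
from .metrics import PhaseMetrics

__all__ = ["BehaviourVerdict", "series_table", "correlate_metrics", "binned_profile"]

log = logging.getLogger(__name__)

VERDICT_METRICS = ("volume_fraction", "mean_condensate_volume", "c_den", "c_dil")


def series_table(metrics: Sequence[PhaseMetrics], image_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """One row of phase metrics per image, indexed by image id."""
    ids = list(image_ids) if image_ids is not None else [f"img{i:03d}" for i in range(len(metrics))]
    if len(ids) != len(metrics):
        raise ValueError("image_ids and metrics length mismatch")
    return pd.DataFrame([m.as_dict() for m in metrics], index=pd.Index(ids, name="image_id"))


@dataclass
class BehaviourVerdict:
    r_per_metric: dict[str, float]
    p_per_metric: dict[str, float]
    rel_change_per_metric: dict[str, float]
    verdict: str  # binary-like | multicomponent-like | indeterminate
    criteria_trace: str
    n_images: int = 0

    def as_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "n_images": self.n_images,
            "r": self.r_per_metric,
            "p": self.p_per_metric,
            "rel_change": self.rel_change_per_metric,
            "criteria_trace": self.criteria_trace,
        }


def _metric_vs_ctot(table: pd.DataFrame, metric: str) -> tuple[float, float, float]:
    """(r, p, fitted relative change across the c_tot range) for one metric,
    NaN rows excluded pairwise."""
    sub = table[["c_tot", metric]].dropna()
    if len(sub) < 3:
        raise InsufficientVarianceError(
            f"need >= 3 valid (c_tot, {metric}) pairs, got {len(sub)}"
        )
    x = sub["c_tot"].to_numpy(dtype=float)
    y = sub[metric].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise InsufficientVarianceError("c_tot has zero variance across images")
    if np.ptp(y) == 0:
        return 0.0, 1.0, 0.0
    r, p = stats.pearsonr(x, y)
    # effect size from a robust (Theil-Sen) slope: a couple of badly segmented
    # images must not manufacture an apparent concentration dependence
    slope = stats.theilslopes(y, x).slope
    scale = np.median(y)
    rel = abs(slope) * np.ptp(x) / abs(scale) if scale != 0 else math.inf
    return float(r), float(p), float(rel)


def correlate_metrics(
    table: pd.DataFrame,
    p_threshold: float = 0.05,
    r_flat: float = 0.2,
    rel_change_threshold: float = 0.10,
) -> BehaviourVerdict:
    """Pearson r/p of each phase metric against C_tot plus the regime verdict.

    multicomponent-like: C_dil and C_den both increase significantly with
    C_tot (r > 0, p < ``p_threshold``) by more than ``rel_change_threshold``
    relative across the observed range. binary-like: C_dil and C_den are flat
    (relative change below threshold, or |r| < ``r_flat`` and not significant)
    while the volume fraction increases significantly. Anything else is
    indeterminate.
    """
    r: dict[str, float] = {}
    p: dict[str, float] = {}
    rel: dict[str, float] = {}
    for m in VERDICT_METRICS:
        r[m], p[m], rel[m] = _metric_vs_ctot(table, m)

    def increasing(m: str) -> bool:
        return r[m] > 0 and p[m] < p_threshold and rel[m] >= rel_change_threshold

    def flat(m: str) -> bool:
        return rel[m] < rel_change_threshold or (abs(r[m]) < r_flat and p[m] >= p_threshold)

    trace = [
        f"{m}: r={r[m]:+.3f}, p={p[m]:.3g}, rel_change={rel[m]:.3f}" for m in VERDICT_METRICS
    ]
    if increasing("c_dil") and increasing("c_den"):
        verdict = "multicomponent-like"
        trace.append("C_dil and C_den both increase significantly with C_tot -> multicomponent-like")
    elif flat("c_dil") and flat("c_den") and increasing("volume_fraction"):
        verdict = "binary-like"
        trace.append(
            "C_dil and C_den flat while volume fraction grows with C_tot -> binary-like"
        )
    else:
        verdict = "indeterminate"
        trace.append("mixed signals -> indeterminate")
    return BehaviourVerdict(
        r_per_metric=r,
        p_per_metric=p,
        rel_change_per_metric=rel,
        verdict=verdict,
        criteria_trace="\n".join(trace),
        n_images=len(table),
    )


def binned_profile(table: pd.DataFrame, metric: str, n_bins: int = 4) -> pd.DataFrame:
    """Mean ± SEM of ``metric`` in equal-width C_tot bins.

    SEM = SD/√n; a single-point bin reports SEM 0 with ``sem_singleton=True``
    so profiles stay plottable. Empty bins are absent from the output.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    sub = table[["c_tot", metric]].dropna()
    x = sub["c_tot"].to_numpy(dtype=float)
    y = sub[metric].to_numpy(dtype=float)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    if len(np.unique(idx)) == 1:
        log.warning("all %d points fall in a single c_tot bin", len(x))
    rows = []
    for b in range(n_bins):
        yy = y[idx == b]
        if yy.size == 0:
            continue
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "mean": float(yy.mean()),
                "sem": float(yy.std(ddof=1) / math.sqrt(yy.size)) if yy.size > 1 else 0.0,
                "n": int(yy.size),
                "sem_singleton": yy.size == 1,
            }
        )
    return pd.DataFrame(rows)
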