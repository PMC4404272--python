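"""DVH metrics and model-evaluation statistics.

Vx / Dx extraction by linear interpolation of the cumulative DVH,
ROC analysis with the Youden cutoff and Hanley-McNeil AUC confidence
interval, the DeLong Z-test for two correlated ROC curves, the
NTCP-vs-fractional-volume Spearman correlation curve, and risk
stratification of a cohort at an NTCP cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .dvh_io import Cohort, CumulativeDVH
from .lkb import LKBParams, lkb_ntcp

__all__ = [
    "RocResult",
    "AucComparison",
    "StratificationResult",
    "v_at_dose",
    "d_at_volume",
    "roc_analysis",
    "auc_hanley_mcneil_ci",
    "compare_auc_paired",
    "dx_correlation_curve",
    "stratify_by_cutoff",
]


@dataclass(frozen=True)
class RocResult:
    curve: np.ndarray  # (k, 2): (1 - specificity, sensitivity)
    thresholds: np.ndarray
    auc: float
    auc_ci_95: tuple[float, float]
    youden_cutoff: float
    youden_j: float


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    z: float
    p_value: float


@dataclass(frozen=True)
class StratificationResult:
    cutoff: float
    n_above: int
    events_above: int
    n_below: int
    events_below: int
    incidence_above: float | None  # None when the group is empty
    incidence_below: float | None


def v_at_dose(dvh: CumulativeDVH, dose: float) -> float:
    """Fraction of organ volume receiving at least ``dose`` Gy (linear
    interpolation; 1.0 below the first bin, 0.0 above the last)."""
    if dose < 0:
        raise ValueError("dose must be >= 0 Gy")
    d, v = dvh.dose_bins, dvh.volume_fractions
    if dose <= d[0]:
        return 1.0
    if dose > d[-1]:
        return 0.0
    return float(np.interp(dose, d, v))


def d_at_volume(dvh: CumulativeDVH, x: float) -> float:
    """D_x: minimum dose received by the hottest fraction ``x`` of the organ.

    Inverse linear interpolation of the cumulative curve — the smallest
    dose d with V(d) <= x. Equals the maximum bin dose when x is at or
    below the final volume fraction, and the first bin dose at x = 1.
    """
    if not 0 < x <= 1:
        raise ValueError("volume fraction x must be in (0, 1]")
    d, v = dvh.dose_bins, dvh.volume_fractions
    if x <= v[-1]:
        return float(d[-1])
    if x >= v[0]:
        return float(d[0])
    # v is non-increasing: interpolate on the reversed (increasing) curve
    return float(np.interp(x, v[::-1], d[::-1]))


def auc_hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int, confidence: float = 0.95):
    """Hanley-McNeil standard-error confidence interval for an AUC."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (
        n_pos * n_neg
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 + confidence / 2)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc_analysis(scores, outcomes) -> RocResult:
    """ROC curve, Mann-Whitney AUC (ties 0.5), Hanley-McNeil 95% CI and
    Youden cutoff (ties broken toward the lowest cutoff).

    The cutoff uses the >= rule: a patient is called positive when their
    score is at or above the cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and outcomes must be 1-D of equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    auc = float(roc_auc_score(y, scores))
    j = tpr - fpr
    jmax = j.max()
    # roc_curve thresholds are decreasing; last index with max J = lowest cutoff
    best = np.flatnonzero(np.isclose(j, jmax))[-1]
    cutoff = float(thr[best])
    if np.isinf(cutoff):  # sklearn's sentinel above the highest score
        cutoff = float(scores.max())
    return RocResult(
        curve=np.column_stack([fpr, tpr]),
        thresholds=thr,
        auc=auc,
        auc_ci_95=auc_hanley_mcneil_ci(auc, n_pos, n_neg),
        youden_cutoff=cutoff,
        youden_j=float(jmax),
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, y: np.ndarray):
    """Placement values for one score vector (DeLong's V10 / V01)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n            # per-positive placements
    v01 = 1.0 - (all_r[m:] - neg_r) / m      # per-negative placements
    return float(auc), v10, v01


def compare_auc_paired(scores_a, scores_b, outcomes) -> AucComparison:
    """DeLong Z-test for two correlated ROC curves on the same patients.

    z = (AUC_a - AUC_b) / SE(AUC_a - AUC_b) with the covariance estimated
    from placement values; two-sided normal p-value. Identical score
    vectors give z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b, outcomes must have equal shapes")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both outcome classes must be present")
    auc_a, v10_a, v01_a = _delong_placements(a, y)
    auc_b, v10_b, v01_b = _delong_placements(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var_diff <= 0 or np.isclose(diff, 0.0, atol=1e-15):
        z = 0.0 if np.isclose(diff, 0.0, atol=1e-15) else np.sign(diff) * np.inf
    else:
        z = diff / float(np.sqrt(var_diff))
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return AucComparison(auc_a=auc_a, auc_b=auc_b, z=float(z), p_value=p)


def dx_correlation_curve(cohort: Cohort, params: LKBParams, x_grid=None):
    """Spearman correlation of LKB NTCP with outcome when the dose input
    is D_x, for each fractional volume x on the grid.

    For each x the per-patient minimum dose to the hottest x fraction is
    computed, fed through the probit response in place of the gEUD, and
    the resulting NTCP vector is rank-correlated with the late-GI
    outcome. Default grid: 5% to 100% in 5% steps.
    """
    if x_grid is None:
        x_grid = np.arange(0.05, 1.0001, 0.05)
    x_grid = np.asarray(x_grid, dtype=float)
    y = cohort.outcomes
    out = []
    for x in x_grid:
        dx = np.array([d_at_volume(p.dvh, float(x)) for p in cohort])
        ntcp = np.asarray(lkb_ntcp(dx, params))
        if np.all(ntcp == ntcp[0]):
            rs = np.nan
        else:
            rs = float(stats.spearmanr(ntcp, y).statistic)
        out.append((float(x), rs))
    return out


def stratify_by_cutoff(ntcp_values, outcomes, cutoff: float) -> StratificationResult:
    """Partition patients at NTCP >= cutoff and report the late-toxicity
    incidence in each group (None for an empty group)."""
    p = np.asarray(ntcp_values, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if p.shape != y.shape:
        raise ValueError("ntcp_values and outcomes must have equal length")
    above = p >= cutoff
    n_above = int(above.sum())
    n_below = int((~above).sum())
    ev_above = int(y[above].sum())
    ev_below = int(y[~above].sum())
    return StratificationResult(
        cutoff=float(cutoff),
        n_above=n_above,
        events_above=ev_above,
        n_below=n_below,
        events_below=ev_below,
        incidence_above=(ev_above / n_above) if n_above else None,
        incidence_below=(ev_below / n_below) if n_below else None,
    )
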