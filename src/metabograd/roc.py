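"""Single-marker ROC evaluation: curves, Youden cut-offs, DeLong inference.

The trapezoidal AUC equals the Mann-Whitney U statistic divided by n1*n2,
so the ROC view and the rank-test view of a marker agree exactly; that
identity is exploited for the AUC p-value.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import mann_whitney


@dataclasses.dataclass
class ROCRecord:
    metabolite: str
    comparison: str
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    flipped: bool
    cutoff: float
    sensitivity: float
    specificity: float


def roc_curve(cases, controls, orient: bool = True):
    """ROC points for a continuous marker.

    Returns ``(fpr, tpr, thresholds, flipped)`` with one point per distinct
    threshold plus the (0,0) and (1,1) endpoints.  When ``orient`` is true
    and the raw AUC is below 0.5 the marker sign is flipped so higher values
    indicate cases, and the flip is reported.
    """
    x = np.asarray(cases, dtype=float)
    y = np.asarray(controls, dtype=float)
    flipped = False
    if orient:
        _, _, auc = mann_whitney(x, y)
        if auc < 0.5:
            x, y = -x, -y
            flipped = True
    scores = np.concatenate([x, y])
    labels = np.concatenate([np.ones_like(x), np.zeros_like(y)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    distinct = np.r_[np.diff(scores) != 0, True]
    tps = np.cumsum(labels)[distinct]
    fps = np.cumsum(1 - labels)[distinct]
    tpr = np.r_[0.0, tps / len(x)]
    fpr = np.r_[0.0, fps / len(y)]
    thresholds = np.r_[np.inf, scores[distinct]]
    return fpr, tpr, thresholds, flipped


def trapezoidal_auc(fpr, tpr) -> float:
    return float(np.trapezoid(tpr, fpr))


def best_cutoff(fpr, tpr, thresholds) -> tuple[float, float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher sensitivity.  A sample is called a case
    when its (oriented) marker value is >= the returned threshold.
    """
    j = tpr - fpr
    best = np.lexsort((tpr, j))[-1]  # max J, then max sensitivity
    return float(thresholds[best]), float(tpr[best]), float(1 - fpr[best])


def _delong_variance(x: np.ndarray, y: np.ndarray) -> float:
    """DeLong placement-based variance of the empirical AUC."""
    # V10_i: fraction of controls below case i (half weight for ties)
    v10 = np.array([np.mean((y < xi) + 0.5 * (y == xi)) for xi in x])
    v01 = np.array([np.mean((x > yj) + 0.5 * (x == yj)) for yj in y])
    n1, n2 = len(x), len(y)
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n2 > 1 else 0.0
    return s10 / n1 + s01 / n2


def auc_inference(cases, controls, level: float = 0.95):
    """AUC with a DeLong 95% CI and a p-value against AUC = 0.5.

    The p-value is the tie-corrected normal-approximation two-sided
    Mann-Whitney p on the same data, since U/(n1*n2) is the AUC.
    """
    x = np.asarray(cases, dtype=float)
    y = np.asarray(controls, dtype=float)
    _, p, auc = mann_whitney(x, y)
    var = _delong_variance(x, y)
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half)), p


def evaluate_markers(
    matrix,
    metadata,
    metabolites,
    case_group: str = "CTEPH",
    control_groups=("HC", "DC"),
) -> pd.DataFrame:
    """ROCRecord table for each marker against each comparator group."""
    md = metadata.data
    cases_idx = md.index[md["group"] == case_group]
    rows = []
    for ctrl in control_groups:
        ctrl_idx = md.index[md["group"] == ctrl]
        for met in metabolites:
            x = matrix.data.loc[cases_idx, met].dropna().to_numpy()
            y = matrix.data.loc[ctrl_idx, met].dropna().to_numpy()
            fpr, tpr, thr, flipped = roc_curve(x, y)
            auc, (lo, hi), p = auc_inference(-x if flipped else x,
                                             -y if flipped else y)
            cut, sens, spec = best_cutoff(fpr, tpr, thr)
            rows.append(dataclasses.asdict(ROCRecord(
                metabolite=met, comparison=f"{case_group}_vs_{ctrl}",
                auc=auc, ci_low=lo, ci_high=hi, p_value=p, flipped=flipped,
                cutoff=cut, sensitivity=sens, specificity=spec,
            )))
    if not rows:
        cols = [f.name for f in dataclasses.fields(ROCRecord)]
        return pd.DataFrame(columns=cols).set_index(["metabolite", "comparison"])
    return pd.DataFrame(rows).set_index(["metabolite", "comparison"])
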