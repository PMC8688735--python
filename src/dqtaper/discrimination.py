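"""Weighted ROC analysis of average DQ with optimal cut-off selection.

Two discrimination questions are asked of the interval records: does a
higher average dose quotient predict treatment response (versus
relapse), and does it predict a stable SPARCC score (bone-marrow edema
not increased)?  In both the positive class is the favourable state and
higher scores vote positive, so a reported cut-off reads as a minimum
maintenance dose.  The "GEE" versus "GEE+IPTW" variants are the same
records with unit versus stabilized IPTW weights.

Sensitivity at threshold c is the weighted fraction of positives with
score >= c; specificity the weighted fraction of negatives with
score < c.  The AUC is the trapezoidal area over (1 - specificity,
sensitivity), which equals the weighted pairwise concordance
(Mann-Whitney statistic with ties counted 1/2).  The optimal cut-off
maximizes Youden's J = sensitivity + specificity - 1, ties broken
toward the higher threshold (so less drug exposure is never
misclassified as adequate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateLabelsError, DqTaperError

__all__ = ["RocResult", "roc_curve", "auc", "optimal_cutoff", "roc_analysis"]


@dataclass
class RocResult:
    """A weighted ROC curve and, once selected, its optimal operating point.

    ``thresholds`` are the sorted-descending unique scores with +/-inf
    sentinels; ``sensitivity``/``specificity`` align with them.
    """

    label_name: str
    weighted: bool
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float = float("nan")
    optimal_cutoff: float = float("nan")
    sens_at_cutoff: float = float("nan")
    spec_at_cutoff: float = float("nan")


def roc_curve(
    scores,
    labels,
    weights=None,
    label_name: str = "",
) -> RocResult:
    """Weighted ROC curve; thresholds at observed score values.

    ``labels`` are truthy for the positive class; ``weights`` default to
    unit (the weighted computation with unit weights is bit-identical
    to the unweighted one — there is a single code path).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if weights is None:
        w = np.ones_like(s)
        weighted = False
    else:
        w = np.asarray(weights, dtype=float)
        weighted = True
    if s.shape != y.shape or s.shape != w.shape:
        raise DqTaperError("scores, labels and weights must align")
    w_pos = float(w[y].sum())
    w_neg = float(w[~y].sum())
    if w_pos <= 0 or w_neg <= 0:
        raise DegenerateLabelsError(
            "both classes must be present with positive total weight"
        )
    # Sort descending by score; cumulative positive/negative weight at
    # each distinct threshold c gives the weight with score >= c.
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    pos_w = np.where(y[order], w[order], 0.0).cumsum()
    neg_w = np.where(~y[order], w[order], 0.0).cumsum()
    # Last index of each run of tied scores.
    last = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), s_sorted.size - 1]
    uniq = s_sorted[last]
    sens_obs = pos_w[last] / w_pos
    spec_obs = 1.0 - neg_w[last] / w_neg
    thresholds = np.concatenate(([np.inf], uniq, [-np.inf]))
    sensitivity = np.concatenate(([0.0], sens_obs, [1.0]))
    specificity = np.concatenate(([1.0], spec_obs, [0.0]))
    return RocResult(
        label_name=label_name,
        weighted=weighted,
        thresholds=thresholds,
        sensitivity=sensitivity,
        specificity=specificity,
    )


def auc(roc: RocResult) -> float:
    """Trapezoidal area under the curve over (1 - specificity, sensitivity).

    Equals the weighted concordance (Mann-Whitney) statistic with tied
    scores counted one half.
    """
    fpr = 1.0 - roc.specificity
    return float(np.trapezoid(roc.sensitivity, fpr))


def optimal_cutoff(roc: RocResult, method: str = "youden") -> RocResult:
    """Select the operating threshold and record it on the result.

    ``youden`` maximizes sensitivity + specificity - 1; ties are broken
    toward the higher threshold.  ``closest-topleft`` minimizes the
    Euclidean distance to the (0, 1) corner, same tie-break.
    """
    if method == "youden":
        objective = roc.sensitivity + roc.specificity - 1.0
    elif method == "closest-topleft":
        objective = -(
            (1.0 - roc.sensitivity) ** 2 + (1.0 - roc.specificity) ** 2
        )
    else:
        raise DqTaperError(f"unknown cut-off method {method!r}")
    finite = np.isfinite(roc.thresholds)
    idx = np.flatnonzero(finite)
    if idx.size == 0:
        raise DegenerateLabelsError("no finite thresholds on the curve")
    best_val = objective[idx].max()
    # Thresholds are stored descending, so the first maximizer among the
    # finite thresholds is the highest qualifying score; the tolerance
    # keeps exact ties from being broken by floating-point noise.
    best = idx[np.flatnonzero(objective[idx] >= best_val - 1e-12)[0]]
    roc.auc = auc(roc)
    roc.optimal_cutoff = float(roc.thresholds[best])
    roc.sens_at_cutoff = float(roc.sensitivity[best])
    roc.spec_at_cutoff = float(roc.specificity[best])
    return roc


def roc_analysis(
    scores,
    labels,
    weights=None,
    label_name: str = "",
    method: str = "youden",
) -> RocResult:
    """Curve, AUC and optimal cut-off in one call."""
    roc = roc_curve(scores, labels, weights=weights, label_name=label_name)
    return optimal_cutoff(roc, method=method)
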