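"""Classification metrics, bootstrap CIs, and paired ROC comparison tests.

The metric suite is the one standard in clinical model reporting:
accuracy, sensitivity, specificity, PPV, NPV (on the dichotomized
malnourished-vs-normal problem) and micro-averaged multiclass AUC, each
with a 95% bootstrap percentile CI.  Paired model comparison uses the
DeLong test on correlated AUCs (structural components), categorical Net
Reclassification Improvement (NRI) and Integrated Discrimination
Improvement (IDI).

Micro-AUC pools the one-vs-rest (label, score) pairs of all classes into a
single ROC curve; ties are handled with midranks throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ComparisonResult",
    "EvaluationError",
    "binary_metrics",
    "confusion_from_predictions",
    "micro_auc",
    "bootstrap_ci",
    "delong_test",
    "nri",
    "idi",
    "evaluate_predictions",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    """Point metrics with optional (lo, hi) 95% CIs; NaN marks undefined."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float = math.nan
    ci: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
        }
        if self.ci:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


@dataclass(frozen=True)
class ComparisonResult:
    delta_auc: float
    delong_p: float
    nri: float
    nri_p: float
    idi: float
    idi_p: float

    def as_dict(self) -> dict:
        return {
            "delta_auc": self.delta_auc,
            "delong_p": self.delong_p,
            "nri": self.nri,
            "nri_p": self.nri_p,
            "idi": self.idi,
            "idi_p": self.idi_p,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def binary_metrics(counts: ConfusionCounts) -> MetricSet:
    """Standard definitions; zero-denominator ratios come back as NaN."""
    if counts.n < 1:
        raise EvaluationError("empty confusion table")
    return MetricSet(
        accuracy=_ratio(counts.tp + counts.tn, counts.n),
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
    )


def confusion_from_predictions(y_true_bin, y_pred_bin) -> ConfusionCounts:
    t = np.asarray(y_true_bin).astype(int)
    p = np.asarray(y_pred_bin).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def _auc_mannwhitney(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the midrank Mann-Whitney statistic."""
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def micro_auc(probabilities: np.ndarray, labels, n_classes: int = 3) -> float:
    """Micro-averaged multiclass AUC.

    One-vs-rest (label, score) pairs for every class are pooled into a
    single binary problem and a single ROC area is computed (midrank ties).
    """
    P = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if P.ndim != 2 or P.shape[0] != y.size:
        raise EvaluationError("probabilities must be (n, n_classes)")
    if np.unique(y).size < 2:
        raise EvaluationError("micro-AUC undefined with a single class")
    onehot = np.zeros_like(P)
    onehot[np.arange(y.size), y] = 1.0
    return float(_auc_mannwhitney(onehot.ravel().astype(int), P.ravel()))


def bootstrap_ci(
    statistic,
    sample,
    B: int = 1000,
    seed: int | None = 0,
    level: float = 0.95,
    max_redraws: int = 10 * 1000,
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``statistic(sample[idx])``.

    ``sample`` is indexed along axis 0 (tuple of arrays allowed for paired
    resampling).  Resamples on which the statistic is undefined (raises or
    returns NaN) are redrawn; the redraw count is capped.
    """
    arrays = sample if isinstance(sample, tuple) else (sample,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = arrays[0].shape[0]
    if n < 2:
        raise EvaluationError("bootstrap needs n >= 2")
    if B < 100:
        raise EvaluationError("B must be at least 100")
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    redraws = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        try:
            v = statistic(*(a[idx] for a in arrays))
        except (EvaluationError, ZeroDivisionError):
            v = math.nan
        if math.isnan(v):
            redraws += 1
            if redraws > max_redraws:
                raise EvaluationError("statistic undefined on too many resamples")
            continue
        vals[b] = v
        b += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# DeLong test for two correlated AUCs

def _structural_components(labels: np.ndarray, scores: np.ndarray):
    """Midrank placement values V10 (events) and V01 (nonevents)."""
    pos = labels == 1
    x, ycomp = scores[pos], scores[~pos]
    m, n = x.size, ycomp.size
    ranks_all = stats.rankdata(np.concatenate([x, ycomp]))
    rx = stats.rankdata(x)
    ry = stats.rankdata(ycomp)
    v10 = (ranks_all[:m] - rx) / n          # P(X > Y) per event, midranks
    v01 = 1.0 - (ranks_all[m:] - ry) / m    # per nonevent
    auc = v10.mean()
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong test for the difference of two paired AUCs.

    Returns (AUC_a - AUC_b, two-sided normal p).  Degenerate variance
    (e.g. identical or all-tied scores) yields p = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if not (sa.shape == sb.shape == y.shape):
        raise EvaluationError("paired scores and labels must share shape")
    if np.unique(y).size < 2:
        raise EvaluationError("both classes must be present")
    auc_a, v10a, v01a = _structural_components(y, sa)
    auc_b, v10b, v01b = _structural_components(y, sb)
    m, n = v10a.size, v01a.size
    delta = float(auc_a - auc_b)
    if m < 2 or n < 2:
        return delta, 1.0
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return delta, 1.0
    z = delta / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return delta, float(p)


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUC (used for unpaired algebra checks)."""
    y = np.asarray(labels).astype(int)
    _, v10, v01 = _structural_components(y, np.asarray(scores, dtype=float))
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


# ---------------------------------------------------------------------------
# NRI / IDI

def _risk_categories(p: np.ndarray, thresholds) -> np.ndarray:
    return np.digitize(p, np.asarray(thresholds, dtype=float), right=False)


def nri(
    probs_old,
    probs_new,
    labels,
    thresholds=(1 / 3, 2 / 3),
) -> tuple[float, float]:
    """Categorical Net Reclassification Improvement with asymptotic z-test.

    ``probs_*`` are positive-class risks; ``thresholds`` define the risk
    categories.  NRI = (P(up|event) - P(down|event)) +
    (P(down|nonevent) - P(up|nonevent)).
    """
    po = np.asarray(probs_old, dtype=float)
    pn = np.asarray(probs_new, dtype=float)
    y = np.asarray(labels).astype(int)
    if not (po.shape == pn.shape == y.shape):
        raise EvaluationError("paired probabilities and labels must share shape")
    ev, ne = y == 1, y == 0
    n_ev, n_ne = int(ev.sum()), int(ne.sum())
    if n_ev == 0 or n_ne == 0:
        raise EvaluationError("NRI needs both events and nonevents")
    co = _risk_categories(po, thresholds)
    cn = _risk_categories(pn, thresholds)
    up, down = cn > co, cn < co
    p_up_e = up[ev].mean()
    p_dn_e = down[ev].mean()
    p_up_n = up[ne].mean()
    p_dn_n = down[ne].mean()
    value = (p_up_e - p_dn_e) + (p_dn_n - p_up_n)
    se = math.sqrt((p_up_e + p_dn_e) / n_ev + (p_up_n + p_dn_n) / n_ne)
    if se == 0:
        return float(value), 1.0
    z = value / se
    return float(value), float(2.0 * stats.norm.sf(abs(z)))


def idi(probs_old, probs_new, labels) -> tuple[float, float]:
    """Integrated Discrimination Improvement: discrimination-slope change.

    IDI = (mean p_new | event - mean p_new | nonevent)
        - (mean p_old | event - mean p_old | nonevent),
    with a paired z-test on the per-subject risk differences.
    """
    po = np.asarray(probs_old, dtype=float)
    pn = np.asarray(probs_new, dtype=float)
    y = np.asarray(labels).astype(int)
    if not (po.shape == pn.shape == y.shape):
        raise EvaluationError("paired probabilities and labels must share shape")
    ev, ne = y == 1, y == 0
    n_ev, n_ne = int(ev.sum()), int(ne.sum())
    if n_ev == 0 or n_ne == 0:
        raise EvaluationError("IDI needs both events and nonevents")
    d = pn - po
    value = d[ev].mean() - d[ne].mean()
    se_ev = d[ev].std(ddof=1) / math.sqrt(n_ev) if n_ev > 1 else 0.0
    se_ne = d[ne].std(ddof=1) / math.sqrt(n_ne) if n_ne > 1 else 0.0
    se = math.sqrt(se_ev**2 + se_ne**2)
    if se == 0:
        return float(value), 1.0 if value == 0 else 0.0
    z = value / se
    return float(value), float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# high-level report

def evaluate_predictions(
    probabilities: np.ndarray,
    labels,
    B: int = 1000,
    seed: int = 0,
) -> MetricSet:
    """Full MetricSet (dichotomized binary metrics + micro-AUC) with CIs.

    The three-class problem is collapsed to malnourished-or-worse vs normal
    for accuracy/sensitivity/specificity/PPV/NPV; the AUC stays
    micro-averaged over the three classes.  CIs are percentile bootstrap.
    """
    P = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    y_bin = (y >= 1).astype(int)
    pred_bin = (P.argmax(axis=1) >= 1).astype(int)
    ms = binary_metrics(confusion_from_predictions(y_bin, pred_bin))
    ms.auc = micro_auc(P, y)
    if B <= 0:  # point estimates only
        return ms

    def stat_factory(name):
        def acc(t, p):
            return binary_metrics(confusion_from_predictions(t, p)).as_dict()[name]
        return acc

    ci = {}
    point = ms.as_dict()
    for i, name in enumerate(["accuracy", "sensitivity", "specificity", "ppv", "npv"]):
        if math.isnan(point[name]):
            ci[name] = (math.nan, math.nan)
            continue
        try:
            ci[name] = bootstrap_ci(
                stat_factory(name), (y_bin, pred_bin), B=B, seed=seed + i
            )
        except EvaluationError:
            ci[name] = (math.nan, math.nan)
    try:
        ci["auc"] = bootstrap_ci(
            lambda pp, yy: micro_auc(pp, yy), (P, y), B=B, seed=seed + 5
        )
    except EvaluationError:
        ci["auc"] = (math.nan, math.nan)
    ms.ci = ci
    return ms


def compare_models(
    probs_a: np.ndarray,
    probs_b: np.ndarray,
    labels,
    nri_thresholds=(1 / 3, 2 / 3),
) -> ComparisonResult:
    """DeLong + NRI + IDI for paired three-class models (a = new, b = old).

    The positive-class risk used for DeLong/NRI/IDI is the dichotomized
    probability P(malnourished or severe).
    """
    Pa = np.asarray(probs_a, dtype=float)
    Pb = np.asarray(probs_b, dtype=float)
    y = np.asarray(labels).astype(int)
    risk_a = Pa[:, 1:].sum(axis=1)
    risk_b = Pb[:, 1:].sum(axis=1)
    y_bin = (y >= 1).astype(int)
    d_auc, d_p = delong_test(risk_a, risk_b, y_bin)
    nri_v, nri_p = nri(risk_b, risk_a, y_bin, thresholds=nri_thresholds)
    idi_v, idi_p = idi(risk_b, risk_a, y_bin)
    return ComparisonResult(
        delta_auc=d_auc, delong_p=d_p, nri=nri_v, nri_p=nri_p, idi=idi_v, idi_p=idi_p
    )
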