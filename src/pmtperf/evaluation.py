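"""Performance and group-comparison statistics.

Confusion matrices with one-vs-rest sensitivity/specificity and overall
accuracy; ROC curves with the Mann-Whitney (pair-counting) AUC and a
Hanley-McNeil 95% confidence interval; Mann-Whitney U tests (midranks,
tie-corrected normal approximation with continuity correction, exact
enumeration for small samples) with Benjamini-Hochberg false-discovery-rate
control; and an integer-consistency reconstructor that recovers every 2x2
confusion matrix compatible with a printed (sensitivity, specificity, n)
triple - useful for auditing published performance figures.

Percentages are rounded half-up for display (1 decimal for sensitivity and
specificity, 2 for accuracy); full precision is kept internally.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm, rankdata

EXACT_ENUMERATION_MAX_N = 12


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (0.5 rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# confusion matrices


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    classes: Tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if c.shape != (k, k):
            raise ValueError("counts must be K x K for K classes")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(labels_true, labels_pred, classes: Sequence[str]) -> ConfusionMatrix:
    """Exact cross-tabulation in the given class order."""
    yt = list(labels_true)
    yp = list(labels_pred)
    if len(yt) != len(yp):
        raise ValueError("label vectors must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(yt, yp):
        if t not in index or p not in index:
            raise ValueError(f"label outside class set: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


@dataclass(frozen=True)
class ClasswisePerformance:
    """One-vs-rest sensitivity/specificity per class plus overall accuracy.

    Values are percentages at full precision; ``rounded()`` applies the
    display convention (half-up, 1 decimal for class rates, 2 for accuracy).
    """

    classes: Tuple[str, ...]
    sensitivity_pct: Dict[str, float]
    specificity_pct: Dict[str, float]
    accuracy_pct: float
    undefined: Tuple[str, ...] = ()

    def rounded(self, rate_decimals: int = 1, accuracy_decimals: int = 2) -> "ClasswisePerformance":
        return replace(
            self,
            sensitivity_pct={c: round_half_up(v, rate_decimals) for c, v in self.sensitivity_pct.items()},
            specificity_pct={c: round_half_up(v, rate_decimals) for c, v in self.specificity_pct.items()},
            accuracy_pct=round_half_up(self.accuracy_pct, accuracy_decimals),
        )

    def as_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "sensitivity_pct": dict(self.sensitivity_pct),
            "specificity_pct": dict(self.specificity_pct),
            "accuracy_pct": self.accuracy_pct,
        }


def classwise_performance(cm: ConfusionMatrix) -> ClasswisePerformance:
    """Per-class one-vs-rest rates and overall accuracy from a confusion matrix."""
    c = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    sens: Dict[str, float] = {}
    spec: Dict[str, float] = {}
    undefined: List[str] = []
    for i, name in enumerate(cm.classes):
        row = int(c[i].sum())
        col = int(c[:, i].sum())
        if row == 0:
            undefined.append(name)
            sens[name] = float("nan")
        else:
            sens[name] = 100.0 * c[i, i] / row
        negatives = total - row
        if negatives == 0:
            spec[name] = float("nan")
        else:
            fp = col - int(c[i, i])
            spec[name] = 100.0 * (negatives - fp) / negatives
    accuracy = 100.0 * float(np.trace(c)) / total
    return ClasswisePerformance(
        classes=cm.classes,
        sensitivity_pct=sens,
        specificity_pct=spec,
        accuracy_pct=accuracy,
        undefined=tuple(undefined),
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci95: Tuple[float, float]
    direction: str  # "greater" if higher scores indicate the positive class

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.auc <= hi + 1e-12):
            raise ValueError("CI must contain the AUC")


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), via midranks."""
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int) -> Tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(0.975)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc_auc(
    scores,
    labels,
    positive,
    ci_method: str = "hanley-mcneil",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC curve and AUC for a single score against a binary label.

    The AUC is computed with the Mann-Whitney identity (ties count 1/2) and
    reported for the direction giving AUC >= 0.5, recorded in ``direction``.
    The default 95% CI is Hanley-McNeil; ``ci_method="bootstrap"`` resamples
    subjects instead.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if v == positive else 0 for v in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    pos, neg = s[y == 1], s[y == 0]
    auc = _auc_mann_whitney(pos, neg)
    direction = "greater"
    if auc < 0.5:
        auc = 1.0 - auc
        direction = "less"
        s = -s
        pos, neg = -pos, -neg

    # operating points over distinct thresholds, descending
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(s))[::-1]])
    tpr = np.array([(pos >= t).mean() if np.isfinite(t) else 0.0 for t in thresholds])
    fpr = np.array([(neg >= t).mean() if np.isfinite(t) else 0.0 for t in thresholds])

    if ci_method == "hanley-mcneil":
        ci = _hanley_mcneil_ci(auc, n_pos, n_neg)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        stats = []
        for _ in range(n_boot):
            bp = rng.choice(pos, size=n_pos, replace=True)
            bn = rng.choice(neg, size=n_neg, replace=True)
            stats.append(_auc_mann_whitney(bp, bn))
        lo, hi = np.percentile(stats, [2.5, 97.5])
        ci = (min(float(lo), auc), max(float(hi), auc))
    else:
        raise ValueError(f"unknown ci_method '{ci_method}'")
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc, ci95=ci, direction=direction)


# ---------------------------------------------------------------------------
# Mann-Whitney U and FDR


@dataclass(frozen=True)
class GroupTestResult:
    u: float
    p: float
    q: Optional[float] = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.q is not None and self.q < self.p - 1e-12:
            raise ValueError("q must be >= p")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Permutation-exact two-sided p: P(|U - mu| >= |u_obs - mu|) over all
    assignments of the pooled values to groups (handles ties via midranks)."""
    pooled = np.concatenate([a, b])
    n, n1 = pooled.size, a.size
    mu = n1 * (pooled.size - n1) / 2.0
    dev = abs(u_obs - mu) - 1e-12
    hits = 0
    count = 0
    idx = np.arange(n)
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        count += 1
        if abs(u - mu) >= dev:
            hits += 1
    return hits / count


def mann_whitney_u(sample_a, sample_b, method: str = "auto") -> GroupTestResult:
    """Two-sided Mann-Whitney U test.

    U is the rank-sum statistic for ``sample_a`` (midranks on ties).
    ``method``: "exact" enumerates all group assignments (default whenever
    n1 + n2 <= 12), "normal" uses the tie-corrected normal approximation
    with continuity correction, "auto" picks between them by sample size.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    u = _u_statistic(a, b)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(u=u, p=1.0, method="degenerate")
    if method == "auto":
        method = "exact" if a.size + b.size <= EXACT_ENUMERATION_MAX_N else "normal"
    if method == "exact":
        return GroupTestResult(u=u, p=_exact_two_sided_p(a, b, u), method="exact")
    if method != "normal":
        raise ValueError(f"unknown method '{method}'")
    n1, n2, n = a.size, b.size, pooled.size
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return GroupTestResult(u=u, p=1.0, method="normal")
    z = (abs(u - mu) - 0.5) / np.sqrt(var)  # continuity correction
    p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return GroupTestResult(u=u, p=p, method="normal")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min_{j: p_(j)>=p_(i)} m p_(j)/j."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# integer-consistency reconstruction of printed 2x2 performance


@dataclass(frozen=True)
class ReconstructedMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
                "n_positive": self.n_positive, "accuracy_pct": self.accuracy_pct}


def reconstruct_confusion(
    sens_pct: float, spec_pct: float, n_total: int, decimals: int = 1
) -> List[ReconstructedMatrix]:
    """Every integer 2x2 matrix over ``n_total`` subjects whose sensitivity
    and specificity, rounded half-up to ``decimals``, equal the inputs.

    Enumerates positive-class sizes 1..n_total-1 exhaustively. An empty list
    means the printed pair is inconsistent with any integer matrix at that
    sample size - a useful audit of published tables.
    """
    if n_total < 2:
        raise ValueError("need at least 2 subjects")
    out: List[ReconstructedMatrix] = []
    for p_size in range(1, n_total):
        n_size = n_total - p_size
        tps = [tp for tp in range(p_size + 1)
               if round_half_up(100.0 * tp / p_size, decimals) == sens_pct]
        if not tps:
            continue
        tns = [tn for tn in range(n_size + 1)
               if round_half_up(100.0 * tn / n_size, decimals) == spec_pct]
        for tp in tps:
            for tn in tns:
                out.append(ReconstructedMatrix(tp=tp, fn=p_size - tp, tn=tn, fp=n_size - tn))
    return out
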