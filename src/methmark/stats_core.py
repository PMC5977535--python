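"""Statistical primitives shared by every pipeline stage.

Standard tests are delegated to scipy / scikit-learn / lifelines; the two
pieces authored here are the Benjamini-Hochberg step-up (so the FDR family
and ordering semantics are explicit) and information gain with MDL-based
entropy discretization (the classic WEKA preprocessing for ranking
continuous attributes against a class label).

Degenerate inputs (zero-variance differences, constant vectors, all-censored
groups) are never silently NaN: results carry a ``degenerate`` flag so
callers can exclude them from downstream FDR families.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    degenerate: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# basic tests
# ---------------------------------------------------------------------------


def paired_t_test(x, y) -> TestResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), d = x - y.

    Identical vectors (all differences zero) are degenerate and reported as
    t = 0, p = 1; a non-zero constant difference is degenerate with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0):
            return TestResult(0.0, 1.0, degenerate=True, note="zero differences")
        t = math.inf if d[0] > 0 else -math.inf
        return TestResult(t, 0.0, degenerate=True, note="constant nonzero differences")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(float(t), float(p))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j >= i} (m * p(j) / j) over the sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-d")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    Two-sided p is the sum of hypergeometric probabilities of all tables
    with the observed margins that are no more probable than the observed
    one (the R convention).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("counts must be integers")
    t = np.round(t).astype(np.int64)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(float(odds), float(p))


def pearson_r(x, y) -> TestResult:
    """Pearson correlation on pairwise-complete observations.

    ``statistic`` is r; the p-value uses the usual t transformation.
    Fewer than 3 complete pairs or a constant vector yields a degenerate
    result (r = nan, p = nan) meant to be excluded downstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[ok], y[ok]
    if len(xs) < 3:
        return TestResult(math.nan, math.nan, degenerate=True, note="<3 complete pairs")
    if xs.std() == 0.0 or ys.std() == 0.0:
        return TestResult(math.nan, math.nan, degenerate=True, note="constant vector")
    r, p = sps.pearsonr(xs, ys)
    return TestResult(float(r), float(p))


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate evaluated at the event times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival_probs, dtype=float)
        if len(s) and (s[0] > 1 + 1e-12 or np.any(np.diff(s) > 1e-12)):
            raise ValueError("survival probabilities must start <= 1 and be non-increasing")


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator with right censoring (events: 1=death, 0=censored)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    # number at risk just before each event time
    n_at_risk = np.array([(times >= t).sum() for t in event_times])
    return SurvivalCurve(event_times, surv, n_at_risk)


def logrank_test(times, events, group) -> TestResult:
    """Log-rank test across >= 2 groups (chi-square, k-1 df).

    Degenerate when fewer than two non-empty groups or no events at all.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) < 2:
        raise ValueError("logrank needs >= 2 non-empty groups")
    if events.sum() == 0:
        return TestResult(0.0, 1.0, degenerate=True, note="no events")
    from lifelines.statistics import logrank_test as _lr
    from lifelines.statistics import multivariate_logrank_test as _mlr

    if len(levels) == 2:
        m0, m1 = group == levels[0], group == levels[1]
        res = _lr(times[m0], times[m1], event_observed_A=events[m0], event_observed_B=events[m1])
    else:
        res = _mlr(times, group, events)
    return TestResult(float(res.test_statistic), float(res.p_value))


def logrank_statistic(times, events, mask) -> float:
    """O-E log-rank chi-square for a binary split, direct formulation.

    Small self-contained implementation used as the engine for permutation
    nulls in tests; independent of lifelines.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    mask = np.asarray(mask, dtype=bool)
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & mask).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & mask).sum()
        if n <= 1:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        o_minus_e += d1 - e1
        var += v
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


# ---------------------------------------------------------------------------
# information gain with MDL discretization
# ---------------------------------------------------------------------------


def _entropy(labels: np.ndarray) -> float:
    n = len(labels)
    if n == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / n
    return float(-(p * np.log2(p)).sum())


def _best_cut(x: np.ndarray, y: np.ndarray):
    """Best binary entropy cut on sorted data; returns (index, cut value,
    gain) or None.  Candidate cuts are midpoints between adjacent distinct
    values (restricting to class-boundary points is an optimization that
    never changes the optimum)."""
    n = len(x)
    base = _entropy(y)
    best = None
    # candidate boundaries where value changes
    change = np.nonzero(np.diff(x) > 0)[0]
    for i in change:
        left, right = y[: i + 1], y[i + 1 :]
        cond = (len(left) * _entropy(left) + len(right) * _entropy(right)) / n
        gain = base - cond
        if best is None or gain > best[2]:
            best = (i, (x[i] + x[i + 1]) / 2.0, gain)
    return best


def _mdl_accept(y, left, right, gain) -> bool:
    """Fayyad-Irani MDL stopping criterion for a candidate binary split."""
    n = len(y)
    k = len(np.unique(y))
    k1 = len(np.unique(left))
    k2 = len(np.unique(right))
    delta = math.log2(3**k - 2) - (
        k * _entropy(y) - k1 * _entropy(left) - k2 * _entropy(right)
    )
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def mdl_discretize(values, labels) -> list[float]:
    """Cut points from recursive entropy minimization with the MDL stop rule.

    Returns a sorted list of thresholds; an uninformative feature yields no
    cuts (a single bin, hence zero information gain).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(x, kind="mergesort")
    x, y = x[order], y[order]

    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        xs, ys = x[lo:hi], y[lo:hi]
        if len(xs) < 2 or len(np.unique(ys)) < 2:
            return
        best = _best_cut(xs, ys)
        if best is None:
            return
        i, cut, gain = best
        if not _mdl_accept(ys, ys[: i + 1], ys[i + 1 :], gain):
            return
        cuts.append(cut)
        recurse(lo, lo + i + 1)
        recurse(lo + i + 1, hi)

    recurse(0, len(x))
    return sorted(cuts)


def info_gain(feature, labels, method: str = "mdl", n_bins: int = 10) -> float:
    """Information gain (bits) of a continuous feature about binary labels.

    IG = H(labels) - sum_bins p(bin) H(labels | bin), computed base 2 after
    discretizing the feature.  ``method`` is "mdl" (Fayyad-Irani entropy
    discretization, the default) or "uniform" (fixed-width ``n_bins`` bins).
    Missing feature values are dropped with their labels.  Single-class
    labels yield 0 with a warning.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels)
    ok = ~np.isnan(x)
    x, y = x[ok], y[ok]
    if len(np.unique(y)) < 2:
        logger.warning("info_gain: single-class labels, IG = 0")
        return 0.0
    if len(np.unique(y)) > 2:
        raise ValueError("labels must be binary")
    if method == "mdl":
        cuts = mdl_discretize(x, y)
        bins = np.digitize(x, cuts) if cuts else np.zeros(len(x), dtype=int)
    elif method == "uniform":
        lo, hi = x.min(), x.max()
        if hi == lo:
            bins = np.zeros(len(x), dtype=int)
        else:
            edges = np.linspace(lo, hi, n_bins + 1)[1:-1]
            bins = np.digitize(x, edges)
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    h = _entropy(y)
    cond = 0.0
    for b in np.unique(bins):
        sel = bins == b
        cond += sel.mean() * _entropy(y[sel])
    return max(0.0, h - cond)


# ---------------------------------------------------------------------------
# classification accuracy
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; exactly P(score_pos > score_neg) + 0.5 P(tie)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))
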