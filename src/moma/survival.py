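"""Multidimensional scores, Kaplan-Meier estimation, and log-rank tests.

A gene's score in a patient counts its concurrent alterations (0–4): mRNA
overexpression, majority targeting-miRNA downregulation, copy-number
increase, and hypomethylation.  Patient groups ordered by score are compared
with the standard two-group log-rank test or, for three or more groups, the
one-degree-of-freedom log-rank test for trend

    χ² = [Σ_g w_g (O_g − E_g)]² / (wᵀ V w),

where O, E and the covariance matrix V accumulate the usual hypergeometric
contributions over distinct event times and w are the group scores.  Small
groups (five or fewer patients by default) merge into their nearest larger
neighbour before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "SurvTestResult",
    "build_scores",
    "merge_small_groups",
    "km_estimate",
    "logrank_test",
    "logrank_trend_test",
    "stratify_by_score",
    "stratify_by_overexpression_count",
    "stratify_by_median",
    "plot_km",
]


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


def build_scores(
    overexpressed: pd.DataFrame,
    majority_down: pd.DataFrame,
    cn_increase: pd.DataFrame,
    hypomethylated: pd.DataFrame,
) -> pd.DataFrame:
    """Sum the four boolean gene × patient call matrices into 0–4 scores.

    Returns a patient × gene integer DataFrame.  All four inputs must cover
    identical genes and patients.
    """
    ref = overexpressed
    for other, name in [
        (majority_down, "majority_down"),
        (cn_increase, "cn_increase"),
        (hypomethylated, "hypomethylated"),
    ]:
        if not ref.index.equals(other.index) or not ref.columns.equals(other.columns):
            raise ValueError(f"call matrix {name} misaligned with overexpression")
    total = (
        overexpressed.astype(int)
        + majority_down.astype(int)
        + cn_increase.astype(int)
        + hypomethylated.astype(int)
    )
    return total.T  # patient × gene


# ---------------------------------------------------------------------------
# group merging
# ---------------------------------------------------------------------------


def merge_small_groups(
    sizes: dict[int, int], min_size: int = 5
) -> dict[int, str]:
    """Merge score groups of ``min_size`` or fewer into larger neighbours.

    Iteratively, the smallest undersized group (ties broken toward the lower
    score) merges into whichever adjacent group is larger, ties toward the
    lower score, until every group exceeds ``min_size`` or only one remains.
    Returns a map from each original score to its merged group label; merged
    labels are score ranges such as ``"3-4"``.
    """
    groups: list[tuple[list[int], int]] = [
        ([s], sizes[s]) for s in sorted(sizes)
    ]
    groups = [g for g in groups if g[1] > 0]
    while len(groups) > 1:
        under = [i for i, (_, n) in enumerate(groups) if n <= min_size]
        if not under:
            break
        i = min(under, key=lambda k: (groups[k][1], groups[k][0][0]))
        left = groups[i - 1] if i > 0 else None
        right = groups[i + 1] if i + 1 < len(groups) else None
        if left is None:
            j = i + 1
        elif right is None:
            j = i - 1
        else:
            j = i - 1 if left[1] >= right[1] else i + 1
        scores = sorted(groups[i][0] + groups[j][0])
        merged = (scores, groups[i][1] + groups[j][1])
        lo, hi = min(i, j), max(i, j)
        groups = groups[:lo] + [merged] + groups[hi + 1 :]
    out: dict[int, str] = {}
    for scores, _ in groups:
        label = str(scores[0]) if len(scores) == 1 else f"{scores[0]}-{scores[-1]}"
        for s in scores:
            out[s] = label
    for s in sizes:  # empty groups map to themselves, unreferenced
        out.setdefault(s, str(s))
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``event_times``/``at_risk``/``survival`` describe the step function at
    the distinct event times; ``censor_times`` are the censoring marks.
    Survival starts at 1 and is right-continuous and non-increasing.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def at(self, t: float) -> float:
        """Survival probability S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Subjects censored exactly at an event time are counted in the risk set
    at that time (the standard convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event indicator not in {0,1}")
    ev_times = np.unique(t[e == 1])
    at_risk = np.empty(ev_times.size)
    n_events = np.empty(ev_times.size)
    surv = np.empty(ev_times.size)
    s = 1.0
    for i, et in enumerate(ev_times):
        n = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n
        at_risk[i], n_events[i], surv[i] = n, d, s
    return KMCurve(
        event_times=ev_times,
        at_risk=at_risk,
        n_events=n_events,
        survival=surv,
        censor_times=np.sort(t[e == 0]),
    )


# ---------------------------------------------------------------------------
# log-rank machinery
# ---------------------------------------------------------------------------


@dataclass
class SurvTestResult:
    """Outcome of a log-rank or log-rank-trend test."""

    test: str
    statistic: float
    df: int
    p: float
    group_labels: list
    group_sizes: list[int]
    group_scores: list[float] | None = None

    def __str__(self) -> str:
        groups = ", ".join(
            f"{l} (n={n})" for l, n in zip(self.group_labels, self.group_sizes)
        )
        return (
            f"{self.test}: chi2 = {self.statistic:.4g}, df = {self.df}, "
            f"p = {self.p:.4g} [{groups}]"
        )


def _logrank_moments(times, events, labels):
    """Observed/expected event counts and hypergeometric covariance.

    Returns (group order, O, E, V) summed over distinct event times.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    lab = np.asarray(labels)
    order = list(pd.unique(pd.Series(lab).sort_values()))
    k = len(order)
    gidx = np.array([order.index(l) for l in lab])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        n = int(at_risk.sum())
        d = int(((t == et) & (e == 1)).sum())
        ng = np.bincount(gidx[at_risk], minlength=k).astype(float)
        og = np.bincount(gidx[(t == et) & (e == 1)], minlength=k).astype(float)
        O += og
        E += d * ng / n
        if n > 1:
            c = d * (n - d) / (n - 1)
            V += c * (np.diag(ng) * n - np.outer(ng, ng)) / n**2
    return order, O, E, V


def logrank_test(times, events, groups) -> SurvTestResult:
    """Two-group log-rank test (1 df chi-square)."""
    order, O, E, V = _logrank_moments(times, events, groups)
    if len(order) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(order)}")
    if np.asarray(events, dtype=int).sum() < 1:
        raise ValueError("no events")
    sizes = [int((np.asarray(groups) == g).sum()) for g in order]
    v = V[0, 0]
    if v <= 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = float((O[0] - E[0]) ** 2 / v)
        p = float(stats.chi2.sf(chi2, 1))
    return SurvTestResult("logrank", chi2, 1, p, order, sizes)


def logrank_trend_test(times, events, groups, group_scores=None) -> SurvTestResult:
    """Log-rank test for trend across ordered groups (1 df).

    ``group_scores`` maps each group label to its numeric weight; by default
    the label itself (which must then be numeric) is used.  With two groups
    the statistic reduces algebraically to the plain log-rank test.
    """
    order, O, E, V = _logrank_moments(times, events, groups)
    if len(order) < 2:
        raise ValueError("trend test needs >= 2 groups with distinct scores")
    if np.asarray(events, dtype=int).sum() < 1:
        raise ValueError("no events")
    if group_scores is None:
        w = np.array([float(g) for g in order])
    else:
        w = np.array([float(group_scores[g]) for g in order])
    sizes = [int((np.asarray(groups) == g).sum()) for g in order]
    u = float(w @ (O - E))
    var = float(w @ V @ w)
    if var <= 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = u**2 / var
        p = float(stats.chi2.sf(chi2, 1))
    return SurvTestResult(
        "logrank_trend", chi2, 1, p, order, sizes, group_scores=list(w)
    )


# ---------------------------------------------------------------------------
# stratifications
# ---------------------------------------------------------------------------


def _auto_test(times, events, labels, scores_by_label) -> SurvTestResult:
    """Log-rank for two groups, trend test for three or more."""
    uniq = pd.unique(pd.Series(labels).sort_values())
    if len(uniq) == 2:
        res = logrank_test(times, events, labels)
        res.group_scores = [scores_by_label[l] for l in res.group_labels]
        return res
    return logrank_trend_test(times, events, labels, group_scores=scores_by_label)


def stratify_by_score(
    score: pd.Series, clinical: pd.DataFrame, min_size: int = 5
) -> tuple[SurvTestResult | None, pd.Series]:
    """Group patients by an integer score, merge small groups, and test.

    ``clinical`` must be indexed by patient with ``os_days``/``event``
    columns.  Returns the test result (None when a single merged group
    remains) and the per-patient merged group label.  Trend weights are the
    mean raw score of each merged group's patients.
    """
    score = score.reindex(clinical.index)
    if score.isna().any():
        missing = list(score.index[score.isna()])
        raise ValueError(f"patients without a score: {missing}")
    sizes = score.value_counts().to_dict()
    relabel = merge_small_groups({int(k): int(v) for k, v in sizes.items()}, min_size)
    labels = score.map(lambda s: relabel[int(s)])
    uniq = sorted(labels.unique(), key=lambda l: float(str(l).split("-")[0]))
    if len(uniq) < 2:
        return None, labels
    weights = {l: float(score[labels == l].mean()) for l in uniq}
    res = _auto_test(
        clinical["os_days"].to_numpy(), clinical["event"].to_numpy(), labels, weights
    )
    return res, labels


def stratify_by_overexpression_count(
    over_calls: pd.DataFrame, clinical: pd.DataFrame, min_size: int = 5
) -> tuple[SurvTestResult | None, pd.Series]:
    """Stratify by the number of panel genes over-expressed per patient."""
    counts = over_calls.sum(axis=0).astype(int)
    return stratify_by_score(counts, clinical, min_size=min_size)


def stratify_by_median(
    feature: pd.Series, clinical: pd.DataFrame
) -> tuple[SurvTestResult | None, pd.Series]:
    """Two-group split at the feature median (ties at the median go below).

    Returns (result, labels); result is None for a constant feature, where
    no test applies.
    """
    feature = feature.reindex(clinical.index)
    if feature.isna().any():
        raise ValueError("feature not defined for all patients")
    med = float(feature.median())
    labels = pd.Series(
        np.where(feature > med, "above_median", "at_or_below_median"),
        index=feature.index,
    )
    if labels.nunique() < 2:
        return None, labels
    res = logrank_test(
        clinical["os_days"].to_numpy(), clinical["event"].to_numpy(), labels
    )
    return res, labels


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------


def plot_km(
    curves: dict[str, KMCurve],
    ax=None,
    max_days: float = 2000.0,
    five_year_line: bool = True,
):
    """Step-plot Kaplan-Meier curves, truncated at ``max_days`` for display.

    The five-year mark (1826 days) is drawn as a dotted vertical line.  Only
    the plot is truncated; statistics always use full follow-up.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, c in curves.items():
        x = np.concatenate([[0.0], c.event_times])
        y = np.concatenate([[1.0], c.survival])
        ax.step(x, y, where="post", label=str(label))
    if five_year_line:
        ax.axvline(5 * 365.25, linestyle=":", color="grey")
    ax.set_xlim(0, max_days)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("Overall survival (days)")
    ax.set_ylabel("Survival probability")
    ax.legend()
    return ax
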