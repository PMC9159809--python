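"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a statistic from first principles (enumeration or
the defining product/sum), deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def quartile_linear(xs, q: float) -> float:
    """Quantile by linear interpolation between order statistics (type 7)."""
    s = sorted(float(x) for x in xs)
    h = (len(s) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def fences_oracle(xs, multiplier: float = 1.5) -> tuple[float, float]:
    q1 = quartile_linear(xs, 0.25)
    q3 = quartile_linear(xs, 0.75)
    iqr = q3 - q1
    return q1 - multiplier * iqr, q3 + multiplier * iqr


def bh_oracle(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the defining step-up minimum."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def km_oracle(times, events):
    """Product-limit estimate as explicit products over distinct event times.

    Returns (event_times, survival).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    ev = np.unique(t[e == 1])
    surv = []
    for et in ev:
        s = 1.0
        for u in ev[ev <= et]:
            n = (t >= u).sum()
            d = ((t == u) & (e == 1)).sum()
            s *= 1 - d / n
        surv.append(s)
    return ev, np.asarray(surv)


def signed_ranks(diffs) -> np.ndarray:
    """Average ranks of |d| for the non-zero differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    a = np.abs(d)
    order = np.argsort(a)
    ranks = np.empty(d.size)
    i = 0
    sorted_a = a[order]
    while i < d.size:
        j = i
        while j + 1 < d.size and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return np.where(d > 0, ranks, -ranks)


def wilcoxon_exact_oracle(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments.

    The null distribution of W+ is symmetric about n(n+1)/4, so the
    two-sided p is P(|W+ − μ| ≥ |w+ − μ|).
    """
    r = signed_ranks(diffs)
    n = r.size
    if n == 0:
        return 1.0
    mags = np.abs(r)
    w_obs = r[r > 0].sum()
    mu = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = float(np.dot(signs, mags))
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2**n


def logrank_oracle(times, events, is_group1) -> float:
    """Two-group log-rank chi-square by direct per-time accumulation."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(is_group1, bool)
    O = E = V = 0.0
    for et in np.unique(t[e == 1]):
        at = t >= et
        n = at.sum()
        n1 = (at & g).sum()
        d = ((t == et) & (e == 1)).sum()
        d1 = ((t == et) & (e == 1) & g).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n - d) / (n - 1) * n1 * (n - n1) / n**2
    return (O - E) ** 2 / V if V > 0 else 0.0
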