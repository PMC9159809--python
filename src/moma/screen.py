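"""miRNA screens: expression filter, paired differential test, target
anti-correlation, and the majority-downregulation gene flag.

The differential screen runs a two-sided Wilcoxon signed-rank test on
tumour − normal differences within matched pairs, with the exact null
distribution for small usable n and the continuity-corrected normal
approximation otherwise, followed by Benjamini-Hochberg correction across
all tested miRNAs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

__all__ = [
    "filter_expressed",
    "paired_differential",
    "spearman_screen",
    "majority_down",
]

#: largest number of non-zero paired differences for which the exact
#: signed-rank null distribution is enumerated
EXACT_WILCOXON_MAX_N = 25


def filter_expressed(
    em: ExpressionMatrix,
    min_rpm: float = 1.0,
    frac_at_min: float = 0.10,
    frac_positive: float = 0.50,
    per_role: bool = True,
) -> list[str]:
    """Return miRNAs passing the expression-level filter.

    A miRNA passes within a tissue role if it reaches >= ``min_rpm`` RPM in
    at least ``frac_at_min`` of that role's samples *and* is > 0 RPM in at
    least ``frac_positive`` of them.  With ``per_role=True`` (default) the
    filter is applied separately within each role and a miRNA is kept if it
    passes in at least one role.
    """
    if em.values.empty:
        raise ValueError("empty expression matrix")
    groups = (
        [em.tumour_samples, em.normal_samples] if per_role else [em.sample_ids]
    )
    kept = pd.Series(False, index=em.values.index)
    for samples in groups:
        if not samples:
            continue
        sub = em.values[samples]
        ok = ((sub >= min_rpm).mean(axis=1) >= frac_at_min) & (
            (sub > 0).mean(axis=1) >= frac_positive
        )
        kept |= ok
    return list(kept.index[kept])


def _signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p; zero differences dropped first."""
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 1.0
    method = "exact" if nz.size <= EXACT_WILCOXON_MAX_N else "approx"
    res = stats.wilcoxon(
        nz,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    return float(min(res.pvalue, 1.0))


def paired_differential(
    em: ExpressionMatrix,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Paired tumour-vs-normal differential screen over every miRNA.

    Returns one row per miRNA with columns ``median_tumour``,
    ``median_normal``, ``raw_p``, ``bh_q``, ``direction`` and
    ``significant``.  Significance requires BH q below ``q_threshold`` and a
    positive median in at least one group; direction follows the ordering of
    the two medians.
    """
    if not em.pairing:
        raise ValueError("expression matrix carries no tumour↔normal pairing")
    t_ids = list(em.pairing)
    n_ids = [em.pairing[t] for t in t_ids]
    if len(t_ids) < 2:
        raise ValueError("need >= 2 pairs for the signed-rank test")
    tum = em.values[t_ids].to_numpy(dtype=float)
    norm = em.values[n_ids].to_numpy(dtype=float)
    med_t = np.median(em.values[em.tumour_samples], axis=1)
    med_n = np.median(em.values[em.normal_samples], axis=1)
    raw_p = np.array([_signed_rank_p(d) for d in tum - norm])
    _, bh_q, _, _ = multipletests(raw_p, method="fdr_bh")
    direction = np.where(med_t < med_n, "down", np.where(med_t > med_n, "up", "none"))
    significant = (bh_q < q_threshold) & (np.maximum(med_t, med_n) > 0)
    return pd.DataFrame(
        {
            "median_tumour": med_t,
            "median_normal": med_n,
            "raw_p": raw_p,
            "bh_q": bh_q,
            "direction": direction,
            "significant": significant,
        },
        index=em.values.index.rename("mirna"),
    )


def spearman_screen(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    target_map: dict[str, frozenset[str]],
    downregulated_ids,
    rho_threshold: float = -0.2,
    p_threshold: float = 0.05,
    tumour_only: bool = True,
) -> pd.DataFrame:
    """Screen (miRNA, target gene) pairs for negative expression correlation.

    Spearman ρ (average ranks on ties, p from the t approximation) is
    computed across the samples shared by both matrices — tumours only by
    default.  A pair passes iff ρ < ``rho_threshold`` and p < ``p_threshold``.
    Constant input vectors leave ρ undefined (NaN) and never pass.
    """
    if tumour_only:
        shared = [s for s in mirna.tumour_samples if s in set(mrna.tumour_samples)]
    else:
        shared = [s for s in mirna.sample_ids if s in set(mrna.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples for correlation")
    down = set(downregulated_ids)
    rows = []
    for m in sorted(target_map):
        if m not in down or m not in mirna.values.index:
            continue
        x = mirna.values.loc[m, shared].to_numpy(dtype=float)
        for g in sorted(target_map[m]):
            if g not in mrna.values.index:
                continue
            y = mrna.values.loc[g, shared].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rho, p = float("nan"), float("nan")
            else:
                with np.errstate(invalid="ignore"):
                    rho, p = stats.spearmanr(x, y)
            passes = bool(
                np.isfinite(rho) and rho < rho_threshold and p < p_threshold
            )
            rows.append((m, g, rho, p, passes))
    return pd.DataFrame(rows, columns=["mirna", "gene", "rho", "p", "passes"])


def majority_down(
    target_map: dict[str, frozenset[str]],
    down_calls: pd.DataFrame,
    annotated_ids,
    genes,
) -> pd.DataFrame:
    """Per gene and tumour sample: are at least half of the annotated
    targeting miRNAs down-called?

    ``down_calls`` is the miRNA × tumour-sample boolean matrix from the
    z-score rule.  Only annotated miRNAs enter the count ("at least half"
    means 2·count ≥ T for a targeting set of size T); genes with no
    annotated targeting miRNA are always False.
    """
    annotated = set(annotated_ids)
    samples = down_calls.columns
    out = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=samples)
    for g in genes:
        targeting = sorted(
            m for m in target_map if g in target_map[m] and m in annotated
        )
        if not targeting:
            continue
        missing = [m for m in targeting if m not in down_calls.index]
        if missing:
            raise KeyError(
                f"down-calls missing annotated targeting miRNAs {missing} for {g!r}"
            )
        counts = down_calls.loc[targeting].sum(axis=0)
        out.loc[g] = 2 * counts >= len(targeting)
    return out
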