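"""Per-sample alteration calls for a gene panel.

Four boolean call types feed the multidimensional score:

* **mRNA overexpression** — a tumour sample's log2(FPKM+1) exceeds the upper
  Tukey fence (Q3 + 1.5·IQR) of the non-malignant samples for that gene.
* **Copy-number increase** — a discrete gene-level call of 1 (gain) or
  2 (amplification).
* **Hypomethylation** — two stages: probes are screened at the cohort level
  (mean Δβ < −0.1 and BH-corrected t-test p < 0.05), then a tumour sample is
  called if its mean β over the gene's screened probes falls below the lower
  Tukey fence of the non-malignant per-sample means.
* **miRNA downregulation** — per miRNA and tumour sample, a z-score against
  the non-malignant reference below −1.645 (the lower 5% normal tail).

All threshold comparisons are strict, so boundary ties never produce calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, MethylationData, CopyNumberCalls

__all__ = [
    "FencePair",
    "HypomethProbeSet",
    "tukey_fences",
    "log2_expression",
    "call_expression_outliers",
    "call_probe_hypomethylation",
    "call_sample_hypomethylation",
    "call_cn_increase",
    "call_mirna_downregulation",
]


@dataclass(frozen=True)
class FencePair:
    """Tukey fences: [Q1 − m·IQR, Q3 + m·IQR] with quartiles by linear
    interpolation between order statistics."""

    lower: float
    upper: float
    q1: float
    q3: float
    iqr: float
    multiplier: float = 1.5


def tukey_fences(values, multiplier: float = 1.5) -> FencePair:
    """Compute the Tukey (IQR) outlier fences of a sample.

    Quartiles use linear interpolation between order statistics, the default
    convention of mainstream numeric stacks.

    Raises
    ------
    ValueError
        If fewer than two finite values are supplied.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 2:
        raise ValueError(f"need >= 2 values for fences, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite value in fence input")
    q1, q3 = np.percentile(arr, [25.0, 75.0])
    iqr = q3 - q1
    return FencePair(
        lower=q1 - multiplier * iqr,
        upper=q3 + multiplier * iqr,
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        multiplier=multiplier,
    )


def log2_expression(em: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(abundance + pseudocount) for every cell of the matrix."""
    return np.log2(em.values + pseudocount)


def call_expression_outliers(
    gene: str,
    em: ExpressionMatrix,
    direction: str = "over",
    multiplier: float = 1.5,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Flag tumour samples whose expression lies beyond the non-malignant fence.

    Expression is log2(FPKM + pseudocount); the fence is computed from
    non-malignant samples only.  ``direction="over"`` flags values strictly
    above the upper fence, ``"under"`` strictly below the lower fence.

    Returns a boolean Series indexed by tumour sample.
    """
    if gene not in em.values.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    if direction not in ("over", "under"):
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    normals = em.normal_samples
    if len(normals) < 2:
        raise ValueError("need >= 2 non-malignant samples for the fence")
    logvals = np.log2(em.values.loc[gene] + pseudocount)
    fence = tukey_fences(logvals[normals], multiplier=multiplier)
    tumour_vals = logvals[em.tumour_samples]
    if direction == "over":
        return tumour_vals > fence.upper
    return tumour_vals < fence.lower


@dataclass
class HypomethProbeSet:
    """Cohort-level probe screen results.

    ``table`` has one row per tested probe with columns ``gene``,
    ``delta_beta``, ``p``, ``q`` and ``kept``; a probe is kept iff its mean
    Δβ (tumour − non-malignant) is below the effect threshold and its
    BH-corrected p-value below the FDR threshold.
    """

    table: pd.DataFrame

    def kept_probes(self, gene: str) -> list[str]:
        t = self.table
        return list(t.index[(t["gene"] == gene) & t["kept"]])


def _welch_or_paired_p(
    tum: np.ndarray, norm: np.ndarray, paired_index: tuple | None
) -> np.ndarray:
    if paired_index is not None:
        ti, ni = paired_index
        diffs = tum[:, ti] - norm[:, ni]
        res = stats.ttest_rel(tum[:, ti], norm[:, ni], axis=1)
        p = np.asarray(res.pvalue, dtype=float)
        allzero = np.all(diffs == 0, axis=1)
        p[allzero] = 1.0
        return p
    with warnings.catch_warnings():
        # degenerate zero-variance probes are overwritten explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(tum, norm, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate probes: zero variance in both groups
    var0 = (tum.var(axis=1) == 0) & (norm.var(axis=1) == 0)
    same = tum.mean(axis=1) == norm.mean(axis=1)
    p[var0 & same] = 1.0
    p[var0 & ~same] = 0.0
    return p


def call_probe_hypomethylation(
    md: MethylationData,
    delta_threshold: float = -0.1,
    q_threshold: float = 0.05,
    paired: bool = False,
    pairing: dict[str, str] | None = None,
) -> HypomethProbeSet:
    """Screen every probe for cohort-level hypomethylation.

    Per probe, Δβ = mean(β, tumour) − mean(β, non-malignant) and a two-sided
    t-test (Welch by default) compares the two groups; BH correction runs
    jointly across all probes of all genes.
    """
    tum_s = md.tumour_samples
    norm_s = md.normal_samples
    if len(tum_s) < 2 or len(norm_s) < 2:
        raise ValueError("need >= 2 samples per role for the probe screen")
    tum = md.beta[tum_s].to_numpy(dtype=float)
    norm = md.beta[norm_s].to_numpy(dtype=float)
    delta = tum.mean(axis=1) - norm.mean(axis=1)
    paired_index = None
    if paired:
        if not pairing:
            raise ValueError("paired test requested but no pairing given")
        ti = [tum_s.index(t) for t in pairing if t in tum_s]
        ni = [norm_s.index(pairing[t]) for t in pairing if t in tum_s]
        paired_index = (np.asarray(ti), np.asarray(ni))
    p = _welch_or_paired_p(tum, norm, paired_index)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    kept = (delta < delta_threshold) & (q < q_threshold)
    table = pd.DataFrame(
        {
            "gene": md.probe_gene.values,
            "delta_beta": delta,
            "p": p,
            "q": q,
            "kept": kept,
        },
        index=md.beta.index,
    )
    return HypomethProbeSet(table=table)


def call_sample_hypomethylation(
    gene: str,
    probe_set: HypomethProbeSet,
    md: MethylationData,
    multiplier: float = 1.5,
) -> pd.Series:
    """Flag tumour samples hypomethylated at a gene.

    The sample statistic is its mean β over the gene's screened (kept)
    probes; the fence comes from the non-malignant per-sample means.  Genes
    with no kept probes can never earn the hypomethylation point, so every
    tumour sample is False.
    """
    tumours = md.tumour_samples
    kept = probe_set.kept_probes(gene)
    if not kept:
        return pd.Series(False, index=pd.Index(tumours))
    means = md.beta.loc[kept].mean(axis=0)
    fence = tukey_fences(means[md.normal_samples], multiplier=multiplier)
    return means[tumours] < fence.lower


def call_cn_increase(cn: CopyNumberCalls) -> pd.DataFrame:
    """Gene × sample booleans: True for gain (1) or amplification (2)."""
    return cn.calls >= 1


def call_mirna_downregulation(
    em: ExpressionMatrix,
    z_threshold: float = -1.645,
    scale: str = "rpm",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Flag per-sample miRNA downregulation by z-score against normals.

    z = (x − mean_ref) / sd_ref with the reference mean and sample standard
    deviation (n−1 denominator) taken over the non-malignant samples.  By
    default z is computed on raw RPM; ``scale="log2"`` uses
    log2(RPM + pseudocount) instead.  miRNAs whose reference sd is zero are
    never called.

    Returns a miRNA × tumour-sample boolean DataFrame.
    """
    normals = em.normal_samples
    if len(normals) < 2:
        raise ValueError("need >= 2 non-malignant samples for the z reference")
    if scale == "rpm":
        vals = em.values
    elif scale == "log2":
        vals = np.log2(em.values + pseudocount)
    else:
        raise ValueError(f"unknown z-score scale {scale!r}")
    ref = vals[normals]
    mean_ref = ref.mean(axis=1)
    sd_ref = ref.std(axis=1, ddof=1)
    tum = vals[em.tumour_samples]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = tum.sub(mean_ref, axis=0).div(sd_ref, axis=0)
    out = z < z_threshold
    out[sd_ref == 0] = False
    return out
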