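"""Synthetic multi-omics cohort generator.

Emulates a tumour/adjacent-normal cohort over a small gene panel with
planted, parameterised alterations so every downstream stage of the
pipeline is testable without external data:

* mRNA log2(FPKM+1) is Gaussian per gene; planted overexpression adds a
  fixed log2 shift before back-transforming.
* β values are Beta-distributed per probe; planted hypomethylation shifts
  all of a gene's probes by a negative Δβ, clipped to [0, 1].
* Copy-number calls are 0 except in planted samples, which draw gain (1) or
  amplification (2).
* miRNA RPM is log-normal; planted downregulation subtracts a multiple of
  the reference standard deviation on the raw scale (floored at 0).
* Survival is exponential with hazard
  ``baseline_hazard · exp(hazard_log_hr_per_point · total_alteration_count)``
  and independent uniform right-censoring, so greater alteration burden
  shortens survival log-linearly.

Each data modality draws from its own child stream of the master seed, so
regenerating one modality never perturbs the others, and a fixed seed
reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as omio
from .io import (
    ExpressionMatrix,
    MethylationData,
    CopyNumberCalls,
    ClinicalTable,
    TUMOUR,
    NON_MALIGNANT,
)

__all__ = ["SimConfig", "Cohort", "generate_cohort", "write_cohort"]

DEFAULT_PANEL = ("VHL", "CUL2", "RBX1", "ELOB", "ELOC")

_REGIONS = ("5'UTR", "gene_body", "promoter", "other")


def _as_gene_map(value, genes) -> dict[str, float]:
    if isinstance(value, dict):
        return {g: float(value[g]) for g in genes}
    return {g: float(value) for g in genes}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Cohort sizes default to the TCGA-LIHC-like 377 tumours / 59 adjacent
    non-malignant samples with 49 matched pairs.  Planting fractions may be
    a single float (shared by all genes) or a per-gene mapping.
    """

    seed: int = 0
    n_tumour: int = 377
    n_normal: int = 59
    n_pairs: int = 49
    gene_panel: tuple[str, ...] = DEFAULT_PANEL
    n_probes_per_gene: int = 8
    n_background_mirnas: int = 20
    n_targeting_mirnas: int = 20
    n_novel_mirnas: int = 5
    frac_overexpressed: float | dict = 0.40
    frac_cn_gain: float | dict = 0.35
    frac_hypomethylated: float | dict = 0.50
    frac_mirna_down: float | dict = 0.30
    expr_shift_log2: float = 3.0
    delta_beta_effect: float = -0.3
    mirna_down_shift_sd: float = 3.0
    hazard_log_hr_per_point: float = 0.3
    baseline_hazard: float = 1.0 / 4000.0
    censor_max_days: float = 3650.0

    def __post_init__(self) -> None:
        if self.n_tumour < 1 or self.n_normal < 2:
            raise ValueError("need >= 1 tumour and >= 2 non-malignant samples")
        if not self.gene_panel:
            raise ValueError("empty gene panel")
        if self.n_pairs > min(self.n_tumour, self.n_normal):
            raise ValueError("n_pairs exceeds available samples")
        if self.baseline_hazard <= 0 or self.censor_max_days <= 0:
            raise ValueError("baseline_hazard and censor_max_days must be > 0")
        self.gene_panel = tuple(self.gene_panel)
        for name in (
            "frac_overexpressed",
            "frac_cn_gain",
            "frac_hypomethylated",
            "frac_mirna_down",
        ):
            m = _as_gene_map(getattr(self, name), self.gene_panel)
            if any(not 0 <= f <= 1 for f in m.values()):
                raise ValueError(f"{name} fractions must lie in [0, 1]")
            setattr(self, name, m)


@dataclass
class Cohort:
    """A complete synthetic cohort plus its planted truth.

    ``truth`` is long-format with one row per (tumour sample, gene):
    planted flags for each alteration type and the per-gene true score;
    ``truth_total`` is the per-patient sum of gene scores that drives the
    survival hazard.
    """

    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    methylation: MethylationData
    cn: CopyNumberCalls
    target_map: dict[str, frozenset[str]]
    annotated_mirnas: frozenset[str]
    clinical: ClinicalTable
    truth: pd.DataFrame
    truth_total: pd.Series
    config: SimConfig

    def truth_flags(self, kind: str) -> pd.DataFrame:
        """Planted flags as a gene × tumour-sample boolean matrix."""
        col = {
            "overexpressed": "planted_overexpr",
            "cn_increase": "planted_cn",
            "hypomethylated": "planted_hypometh",
            "mirna_down": "planted_mirna_down",
        }[kind]
        wide = self.truth.pivot(index="gene", columns="sample", values=col)
        genes = list(self.config.gene_panel)
        samples = self.mrna.tumour_samples
        return wide.reindex(index=genes, columns=samples).astype(bool)

    def truth_scores(self) -> pd.DataFrame:
        """Per-patient per-gene true scores (patient × gene)."""
        wide = self.truth.pivot(index="sample", columns="gene", values="true_score")
        return wide.reindex(
            index=self.mrna.tumour_samples, columns=list(self.config.gene_panel)
        ).astype(int)


def _plant(rng: np.random.Generator, frac: dict, genes, n: int) -> np.ndarray:
    return np.vstack([rng.random(n) < frac[g] for g in genes])


def generate_cohort(cfg: SimConfig) -> Cohort:
    """Draw a full cohort; identical config + seed gives identical output."""
    genes = list(cfg.gene_panel)
    n_t, n_n = cfg.n_tumour, cfg.n_normal
    tum_ids = [f"T{i + 1:04d}" for i in range(n_t)]
    norm_ids = [f"N{i + 1:04d}" for i in range(n_n)]
    samples = tum_ids + norm_ids
    roles = pd.Series(
        [TUMOUR] * n_t + [NON_MALIGNANT] * n_n, index=samples, name="role"
    )
    pairing = dict(zip(tum_ids[: cfg.n_pairs], norm_ids[: cfg.n_pairs]))

    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_plant, rng_mrna, rng_meth, rng_cn, rng_mirna, rng_surv = (
        np.random.default_rng(s) for s in streams
    )

    # planted flags, independent across alteration types and genes
    planted_over = _plant(rng_plant, cfg.frac_overexpressed, genes, n_t)
    planted_cn = _plant(rng_plant, cfg.frac_cn_gain, genes, n_t)
    planted_hm = _plant(rng_plant, cfg.frac_hypomethylated, genes, n_t)
    planted_md = _plant(rng_plant, cfg.frac_mirna_down, genes, n_t)

    # --- mRNA: Gaussian on the log2(FPKM+1) scale ---
    mu = rng_mrna.uniform(4.0, 9.0, size=len(genes))
    sd = rng_mrna.uniform(0.4, 0.8, size=len(genes))
    y = rng_mrna.normal(
        mu[:, None], sd[:, None], size=(len(genes), len(samples))
    )
    y[:, :n_t] += cfg.expr_shift_log2 * planted_over
    mrna_vals = np.clip(np.exp2(y) - 1.0, 0.0, None)
    mrna = ExpressionMatrix(
        values=pd.DataFrame(mrna_vals, index=genes, columns=samples),
        sample_role=roles.copy(),
        pairing=dict(pairing),
    )

    # --- methylation: Beta per probe, planted shift on all gene probes ---
    probes, probe_gene, probe_region = [], [], []
    beta_rows = []
    pidx = 0
    for gi, g in enumerate(genes):
        pm = rng_meth.uniform(0.45, 0.85, size=cfg.n_probes_per_gene)
        kappa = 60.0
        for j in range(cfg.n_probes_per_gene):
            pidx += 1
            probes.append(f"cg{pidx:08d}")
            probe_gene.append(g)
            probe_region.append(_REGIONS[int(rng_meth.integers(len(_REGIONS)))])
            b = rng_meth.beta(pm[j] * kappa, (1 - pm[j]) * kappa, size=len(samples))
            b[:n_t] = b[:n_t] + cfg.delta_beta_effect * planted_hm[gi]
            beta_rows.append(np.clip(b, 0.0, 1.0))
    methylation = MethylationData(
        beta=pd.DataFrame(np.vstack(beta_rows), index=probes, columns=samples),
        probe_gene=pd.Series(probe_gene, index=probes, name="gene"),
        probe_region=pd.Series(probe_region, index=probes, name="region"),
        sample_role=roles.copy(),
    )

    # --- copy number: tumour samples only ---
    amp = rng_cn.random(size=(len(genes), n_t)) < 0.25  # amplification vs gain
    cn_calls = np.where(planted_cn, np.where(amp, 2, 1), 0)
    cn = CopyNumberCalls(
        calls=pd.DataFrame(cn_calls, index=genes, columns=tum_ids)
    )

    # --- miRNA: log-normal RPM; targeting miRNAs shifted in planted samples
    targeting = [f"hsa-miR-t{i + 1:03d}" for i in range(cfg.n_targeting_mirnas)]
    background = [f"hsa-miR-b{i + 1:03d}" for i in range(cfg.n_background_mirnas)]
    novel = [f"nov-miR-{i + 1}" for i in range(cfg.n_novel_mirnas)]
    all_mirnas = targeting + background + novel
    annotated = frozenset(targeting + background)
    target_map: dict[str, set[str]] = {}
    for i, m in enumerate(targeting):
        target_map.setdefault(m, set()).add(genes[i % len(genes)])
    for i, m in enumerate(novel):  # novel miRNAs may target but never score
        target_map.setdefault(m, set()).add(genes[i % len(genes)])

    mmu = rng_mirna.uniform(3.0, 9.0, size=len(all_mirnas))
    msd = rng_mirna.uniform(0.4, 0.8, size=len(all_mirnas))
    ylog = rng_mirna.normal(
        mmu[:, None], msd[:, None], size=(len(all_mirnas), len(samples))
    )
    rpm = np.clip(np.exp2(ylog) - 1.0, 0.0, None)
    # distributional moments of the log-normal reference
    ln_mu, ln_sd = mmu * np.log(2.0), msd * np.log(2.0)
    ref_sd = np.sqrt(
        (np.exp(ln_sd**2) - 1.0) * np.exp(2 * ln_mu + ln_sd**2)
    )
    gene_of = {m: next(iter(target_map[m])) for m in targeting}
    for mi, m in enumerate(targeting):
        gi = genes.index(gene_of[m])
        shift = cfg.mirna_down_shift_sd * ref_sd[mi]
        rpm[mi, :n_t] = np.where(
            planted_md[gi], np.clip(rpm[mi, :n_t] - shift, 0.0, None), rpm[mi, :n_t]
        )
    mirna = ExpressionMatrix(
        values=pd.DataFrame(rpm, index=all_mirnas, columns=samples),
        sample_role=roles.copy(),
        pairing=dict(pairing),
    )

    # --- truth and survival ---
    score = (
        planted_over.astype(int)
        + planted_cn.astype(int)
        + planted_hm.astype(int)
        + planted_md.astype(int)
    )
    truth = pd.DataFrame(
        {
            "sample": np.repeat(tum_ids, len(genes)),
            "gene": np.tile(genes, n_t),
            "planted_overexpr": planted_over.T.ravel().astype(int),
            "planted_cn": planted_cn.T.ravel().astype(int),
            "planted_hypometh": planted_hm.T.ravel().astype(int),
            "planted_mirna_down": planted_md.T.ravel().astype(int),
            "true_score": score.T.ravel(),
        }
    )
    total = pd.Series(score.sum(axis=0), index=tum_ids, name="true_score_total")
    hazard = cfg.baseline_hazard * np.exp(
        cfg.hazard_log_hr_per_point * total.to_numpy()
    )
    t_event = rng_surv.exponential(1.0 / hazard)
    t_cens = rng_surv.uniform(0.0, cfg.censor_max_days, size=n_t)
    os_days = np.round(np.minimum(t_event, t_cens), 2)
    event = (t_event <= t_cens).astype(int)
    clinical = ClinicalTable(
        table=pd.DataFrame({"os_days": os_days, "event": event}, index=tum_ids)
    )

    return Cohort(
        mrna=mrna,
        mirna=mirna,
        methylation=methylation,
        cn=cn,
        target_map={m: frozenset(gs) for m, gs in target_map.items()},
        annotated_mirnas=annotated,
        clinical=clinical,
        truth=truth,
        truth_total=total,
        config=cfg,
    )


#: file names written by write_cohort, consumed by the pipeline reader
COHORT_FILES = {
    "mrna": "mrna_fpkm.tsv",
    "mirna": "mirna_rpm.tsv",
    "beta": "methylation_beta.tsv",
    "annotation": "probe_annotation.tsv",
    "cn": "cn_calls.tsv",
    "clinical": "clinical.tsv",
    "roles": "sample_roles.tsv",
    "pairing": "pairing.tsv",
    "target_map": "target_map.tsv",
    "annotated": "annotated_mirnas.tsv",
    "truth": "truth.tsv",
}


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as the TSV file set consumed by the pipeline."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    f = {k: out / v for k, v in COHORT_FILES.items()}
    omio.write_expression(cohort.mrna, f["mrna"], f["roles"], f["pairing"])
    omio.write_expression(cohort.mirna, f["mirna"])
    omio.write_methylation(cohort.methylation, f["beta"], f["annotation"])
    omio.write_cn(cohort.cn, f["cn"])
    omio.write_clinical(cohort.clinical, f["clinical"])
    omio.write_target_map(cohort.target_map, f["target_map"])
    omio.write_id_set(cohort.annotated_mirnas, f["annotated"])
    cohort.truth.to_csv(f["truth"], sep="\t", index=False)
    return f


def read_cohort(in_dir: str | Path):
    """Load a written cohort directory back into the in-memory model."""
    d = Path(in_dir)
    f = {k: d / v for k, v in COHORT_FILES.items()}
    for key in ("mrna", "mirna", "beta", "cn", "clinical", "roles", "target_map"):
        if not f[key].exists():
            raise FileNotFoundError(f"missing input file {f[key]}")
    mrna = omio.read_expression(
        f["mrna"], f["roles"], f["pairing"] if f["pairing"].exists() else None
    )
    mirna = omio.read_expression(
        f["mirna"], f["roles"], f["pairing"] if f["pairing"].exists() else None
    )
    meth = omio.read_methylation(f["beta"], f["annotation"], f["roles"])
    cn = omio.read_cn(f["cn"])
    clinical = omio.read_clinical(f["clinical"])
    tm = omio.read_target_map(f["target_map"])
    annotated = (
        omio.read_id_set(f["annotated"])
        if f["annotated"].exists()
        else frozenset(mirna.feature_ids)
    )
    return mrna, mirna, meth, cn, tm, annotated, clinical
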