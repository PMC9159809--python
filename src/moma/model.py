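"""Model/Results interface over the whole analysis.

``MultiOmicsModel`` bundles the cohort tables (expression, methylation,
copy number, targets, clinical) with a :class:`~moma.io.Config`;
``fit()`` runs alteration calling, the miRNA screens, score construction
and the survival tests, and returns a ``MultiOmicsResults`` object carrying
every intermediate call matrix, the screen tables, the per-patient score
table and the per-gene survival test results, with ``summary()`` for a
human-readable report and ``plot_km`` for the stratified curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calls as _calls
from . import screen as _screen
from . import survival as _surv
from .io import (
    Config,
    ExpressionMatrix,
    MethylationData,
    CopyNumberCalls,
    ClinicalTable,
)

__all__ = ["MultiOmicsModel", "MultiOmicsResults"]


class MultiOmicsModel:
    """Multi-omics alteration scoring model for a gene panel.

    Parameters
    ----------
    mrna, mirna : ExpressionMatrix
        Bulk mRNA (FPKM) and miRNA (RPM) abundances with sample roles; the
        miRNA matrix should carry the tumour↔normal pairing used by the
        differential screen.
    methylation : MethylationData
    cn : CopyNumberCalls
    target_map : dict
        miRNA id → set of panel genes it is predicted to target.
    annotated_mirnas : set
        Ids of annotated (non-novel) miRNAs; only these can contribute the
        miRNA point of the score.
    clinical : ClinicalTable
    config : Config, optional
        Analysis thresholds; defaults are the published values.
    gene_panel : sequence, optional
        Genes to analyse; defaults to the genes shared by the mRNA,
        copy-number and methylation tables.
    """

    def __init__(
        self,
        mrna: ExpressionMatrix,
        mirna: ExpressionMatrix,
        methylation: MethylationData,
        cn: CopyNumberCalls,
        target_map: dict[str, frozenset[str]],
        annotated_mirnas,
        clinical: ClinicalTable,
        config: Config | None = None,
        gene_panel=None,
    ):
        self.mrna = mrna
        self.mirna = mirna
        self.methylation = methylation
        self.cn = cn
        self.target_map = target_map
        self.annotated_mirnas = frozenset(annotated_mirnas)
        self.clinical = clinical
        self.config = config or Config()
        if gene_panel is None:
            meth_genes = set(methylation.probe_gene)
            gene_panel = [
                g
                for g in mrna.feature_ids
                if g in set(cn.gene_ids) and g in meth_genes
            ]
        if not gene_panel:
            raise ValueError("empty gene panel")
        self.gene_panel = list(gene_panel)
        self.patients = [
            s for s in mrna.tumour_samples if s in set(clinical.sample_ids)
        ]
        if not self.patients:
            raise ValueError("no tumour samples with clinical follow-up")

    @classmethod
    def from_directory(cls, in_dir: str | Path, config: Config | None = None):
        """Build a model from a directory of pipeline TSV files."""
        from .simulate import read_cohort

        mrna, mirna, meth, cn, tm, annotated, clinical = read_cohort(in_dir)
        return cls(mrna, mirna, meth, cn, tm, annotated, clinical, config=config)

    @classmethod
    def from_cohort(cls, cohort, config: Config | None = None):
        return cls(
            cohort.mrna,
            cohort.mirna,
            cohort.methylation,
            cohort.cn,
            cohort.target_map,
            cohort.annotated_mirnas,
            cohort.clinical,
            config=config,
            gene_panel=list(cohort.config.gene_panel),
        )

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "MultiOmicsResults":
        cfg = self.config
        genes, patients = self.gene_panel, self.patients

        def _gene_matrix(fn):
            return pd.DataFrame(
                {g: fn(g) for g in genes}
            ).T.reindex(index=genes, columns=patients).fillna(False).astype(bool)

        over = _gene_matrix(
            lambda g: _calls.call_expression_outliers(
                g,
                self.mrna,
                "over",
                multiplier=cfg.fence_multiplier,
                pseudocount=cfg.log2_pseudocount,
            )
        )
        under = _gene_matrix(
            lambda g: _calls.call_expression_outliers(
                g,
                self.mrna,
                "under",
                multiplier=cfg.fence_multiplier,
                pseudocount=cfg.log2_pseudocount,
            )
        )
        probe_set = _calls.call_probe_hypomethylation(
            self.methylation,
            delta_threshold=cfg.delta_beta_threshold,
            q_threshold=cfg.methylation_q_threshold,
            paired=cfg.paired_methylation_test,
            pairing=self.mrna.pairing,
        )
        hypo = _gene_matrix(
            lambda g: _calls.call_sample_hypomethylation(
                g, probe_set, self.methylation, multiplier=cfg.fence_multiplier
            )
        )
        cn_up = (
            _calls.call_cn_increase(self.cn)
            .reindex(index=genes, columns=patients)
            .fillna(False)
            .astype(bool)
        )
        down_calls = _calls.call_mirna_downregulation(
            self.mirna,
            z_threshold=cfg.mirna_z_threshold,
            scale=cfg.mirna_z_scale,
            pseudocount=cfg.log2_pseudocount,
        )
        maj_down = _screen.majority_down(
            self.target_map, down_calls, self.annotated_mirnas, genes
        )[patients]

        expressed = _screen.filter_expressed(
            self.mirna,
            min_rpm=cfg.expr_min_rpm,
            frac_at_min=cfg.expr_frac_at_min,
            frac_positive=cfg.expr_frac_positive,
        )
        diff = (
            _screen.paired_differential(self.mirna, q_threshold=cfg.diff_q_threshold)
            .loc[lambda d: d.index.isin(expressed)]
            if self.mirna.pairing
            else None
        )
        if diff is not None:
            down_ids = list(
                diff.index[diff["significant"] & (diff["direction"] == "down")]
            )
            corr = _screen.spearman_screen(
                self.mirna,
                self.mrna,
                self.target_map,
                down_ids,
                rho_threshold=cfg.spearman_rho_threshold,
                p_threshold=cfg.spearman_p_threshold,
                tumour_only=cfg.spearman_tumour_only,
            )
        else:
            down_ids, corr = [], None

        scores = _surv.build_scores(over, maj_down, cn_up, hypo)
        clin = self.clinical.table.loc[patients]
        gene_tests, gene_groups = {}, {}
        for g in genes:
            res, labels = _surv.stratify_by_score(
                scores[g], clin, min_size=cfg.min_group_size
            )
            gene_tests[g], gene_groups[g] = res, labels
        oe_test, oe_groups = _surv.stratify_by_overexpression_count(
            over, clin, min_size=cfg.min_group_size
        )

        return MultiOmicsResults(
            model=self,
            overexpressed=over,
            underexpressed=under,
            hypomethylated=hypo,
            cn_increase=cn_up,
            mirna_down_calls=down_calls,
            mirna_majority_down=maj_down,
            hypometh_probes=probe_set.table,
            expressed_mirnas=expressed,
            diff_mirna=diff,
            downregulated_ids=down_ids,
            corr=corr,
            scores=scores,
            gene_tests=gene_tests,
            gene_groups=gene_groups,
            overexpression_count_test=oe_test,
            overexpression_count_groups=oe_groups,
        )


@dataclass
class MultiOmicsResults:
    """Fitted alteration calls, screen tables, scores and survival tests."""

    model: MultiOmicsModel
    overexpressed: pd.DataFrame
    underexpressed: pd.DataFrame
    hypomethylated: pd.DataFrame
    cn_increase: pd.DataFrame
    mirna_down_calls: pd.DataFrame
    mirna_majority_down: pd.DataFrame
    hypometh_probes: pd.DataFrame
    expressed_mirnas: list[str]
    diff_mirna: pd.DataFrame | None
    downregulated_ids: list[str]
    corr: pd.DataFrame | None
    scores: pd.DataFrame
    gene_tests: dict
    gene_groups: dict
    overexpression_count_test: object
    overexpression_count_groups: pd.Series

    @property
    def alteration_prevalence(self) -> pd.DataFrame:
        """Fraction of patients carrying each alteration, per gene."""
        return pd.DataFrame(
            {
                "overexpressed": self.overexpressed.mean(axis=1),
                "mirna_majority_down": self.mirna_majority_down.mean(axis=1),
                "cn_increase": self.cn_increase.mean(axis=1),
                "hypomethylated": self.hypomethylated.mean(axis=1),
            }
        )

    def calls_long(self) -> pd.DataFrame:
        """All gene-level calls in long format (sample, gene, call_type, flag)."""
        frames = []
        for name, mat in [
            ("overexpressed", self.overexpressed),
            ("underexpressed", self.underexpressed),
            ("cn_increase", self.cn_increase),
            ("hypomethylated", self.hypomethylated),
            ("mirna_majority_down", self.mirna_majority_down),
        ]:
            long = (
                mat.rename_axis(index="gene", columns="sample")
                .stack()
                .rename("flag")
                .reset_index()
            )
            long["call_type"] = name
            frames.append(long[["sample", "gene", "call_type", "flag"]])
        out = pd.concat(frames, ignore_index=True)
        out["flag"] = out["flag"].astype(int)
        return out

    def km_curves(self, labels: pd.Series) -> dict[str, _surv.KMCurve]:
        """Kaplan-Meier curve per group label."""
        clin = self.model.clinical.table.loc[labels.index]
        out = {}
        for lab in sorted(labels.unique(), key=str):
            sel = labels == lab
            out[str(lab)] = _surv.km_estimate(
                clin.loc[sel, "os_days"], clin.loc[sel, "event"]
            )
        return out

    def plot_km(self, gene: str | None = None, ax=None):
        """Plot score-stratified survival for a gene (or the panel-wide
        overexpression-count stratification when ``gene`` is None)."""
        labels = (
            self.gene_groups[gene] if gene else self.overexpression_count_groups
        )
        return _surv.plot_km(
            self.km_curves(labels),
            ax=ax,
            max_days=self.model.config.plot_max_days,
        )

    def summary(self) -> str:
        lines = ["Multi-omics alteration score — fit summary", "=" * 44]
        lines.append(
            f"Patients: {len(self.model.patients)}   "
            f"Genes: {', '.join(self.model.gene_panel)}"
        )
        lines.append("")
        lines.append("Alteration prevalence (fraction of patients):")
        lines.append(
            self.alteration_prevalence.to_string(float_format=lambda v: f"{v:.3f}")
        )
        kept = int(self.hypometh_probes["kept"].sum())
        lines.append("")
        lines.append(
            f"Hypomethylated probes: {kept}/{len(self.hypometh_probes)} kept "
            f"(mean dBeta < {self.model.config.delta_beta_threshold}, "
            f"BH q < {self.model.config.methylation_q_threshold})"
        )
        if self.diff_mirna is not None:
            n_down = len(self.downregulated_ids)
            lines.append(
                f"Expressed miRNAs: {len(self.expressed_mirnas)}; "
                f"significantly downregulated: {n_down}"
            )
        if self.corr is not None and len(self.corr):
            lines.append(
                f"Anti-correlated (miRNA, gene) pairs: "
                f"{int(self.corr['passes'].sum())}/{len(self.corr)}"
            )
        lines.append("")
        lines.append("Score distribution (patients per score, by gene):")
        dist = pd.DataFrame(
            {
                g: self.scores[g].value_counts().reindex(range(5), fill_value=0)
                for g in self.model.gene_panel
            }
        )
        dist.index.name = "score"
        lines.append(dist.to_string())
        lines.append("")
        lines.append("Survival stratified by per-gene score:")
        for g, res in self.gene_tests.items():
            lines.append(f"  {g}: {res if res is not None else 'single group - n/a'}")
        lines.append(
            f"Stratified by overexpressed-gene count: "
            f"{self.overexpression_count_test if self.overexpression_count_test is not None else 'single group - n/a'}"
        )
        return "\n".join(lines)
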