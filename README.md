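# moma — multi-omics alteration scoring and survival analysis

`moma` quantifies how often, and through which mechanisms, the genes of a
small panel are deregulated in a tumour cohort with adjacent non-malignant
reference tissue, and tests whether accumulated alterations predict
overall survival. It was built around the five-gene Cullin-2 RING E3
ubiquitin ligase panel (*VHL*, *CUL2*, *RBX1*, *ELOB*, *ELOC*) in
hepatocellular carcinoma, but works for any gene panel with the same
input types.

For each patient *i* and gene *g* the package computes four boolean
alteration calls and their sum, the **multidimensional score**
S(i, g) ∈ {0…4}:

- **mRNA overexpression**: log2(FPKM+1) above the upper Tukey fence
  (Q3 + 1.5·IQR) of the non-malignant samples;
- **copy-number increase**: gene-level discrete call ≥ 1 (gain or
  amplification);
- **hypomethylation**: mean β over the gene's cohort-level hypomethylated
  probes (mean Δβ < −0.1, Welch t-test BH q < 0.05) below the lower Tukey
  fence of the non-malignant per-sample means;
- **miRNA downregulation**: at least half of the annotated miRNAs
  predicted to target the gene have z < −1.645 against the non-malignant
  reference (the lower 5% normal tail).

Patients grouped by score are compared with Kaplan-Meier curves and the
log-rank test (two groups) or the 1-df log-rank test for trend
(three or more ordered groups), χ² = [Σ w_g (O_g − E_g)]² / (wᵀVw), with
hypergeometric moments accumulated over event times; groups of ≤ 5
patients merge into their nearest larger neighbour first. Supporting
screens identify expressed miRNAs, tumour-vs-normal differential miRNAs
(paired Wilcoxon signed-rank, exact for small n, + BH), and miRNA–target
anti-correlations (Spearman ρ < −0.2, p < 0.05).

A synthetic-cohort simulator with planted, parameterised alterations and
an exponential survival model whose hazard increases with alteration
burden makes the whole pipeline testable end to end without external
data. See `docs/methods.md` for the full model description and design
choices.

## Worked example

```python
from moma import SimConfig, generate_cohort, MultiOmicsModel

cohort = generate_cohort(SimConfig(seed=42, n_tumour=120, n_normal=40, n_pairs=30))
res = MultiOmicsModel.from_cohort(cohort).fit()
print(res.summary())
```

prints (abridged):

```
Multi-omics alteration score — fit summary
============================================
Patients: 120   Genes: VHL, CUL2, RBX1, ELOB, ELOC

Alteration prevalence (fraction of patients):
      overexpressed  mirna_majority_down  cn_increase  hypomethylated
VHL           0.383                0.242        0.283           0.508
CUL2          0.267                0.292        0.308           0.550
...
Survival stratified by per-gene score:
  VHL: logrank_trend: chi2 = 7.399, df = 1, p = 0.006527 [0 (n=17), 1 (n=49), 2 (n=43), 3-4 (n=11)]
  ...
Stratified by overexpressed-gene count: logrank_trend: chi2 = 5.72, df = 1, p = 0.01677 [0 (n=6), 1 (n=40), 2 (n=40), 3 (n=27), 4-5 (n=7)]
```

The prevalence block gives the fraction of patients carrying each
alteration per gene (here reflecting the simulator's planting fractions).
Each survival line is a log-rank trend test across the merged score
groups: for *VHL*, patients with more concurrent alterations have
significantly worse overall survival (χ²₁ = 7.4, p ≈ 0.0065); the group
"3-4" is the merger of the score-3 and score-4 groups, the latter having
≤ 5 patients. `res.plot_km("VHL")` draws the corresponding Kaplan-Meier
curves, truncated at 2000 days with the five-year mark dotted.

The same pipeline runs from the shell, each stage exchanging only TSV
files:

```bash
moma simulate --out cohort/ --seed-override 42
moma call    --in cohort/ --out results/
moma screen  --in cohort/ --out results/
moma score   --in cohort/ --out results/
moma survive --in cohort/ --out results/ --plots
# or everything at once, with a checksummed manifest:
moma run-all --out run/ --seed-override 42
```

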