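# Methods

## Overview

`moma` implements a multi-omics procedure for quantifying how often, and
through which mechanisms, the genes of a small panel are deregulated in a
tumour cohort with adjacent non-malignant reference tissue, and for testing
whether the accumulated alterations are associated with overall survival.
The motivating application is the five-gene Cullin-2 RING E3 ubiquitin
ligase panel (*VHL*, *CUL2*, *RBX1*, *ELOB*, *ELOC*) in hepatocellular
carcinoma, but nothing in the implementation is specific to those genes.

Four per-sample, per-gene boolean alteration calls are combined into an
integer score from 0 to 4:

1. **mRNA overexpression.** Expression is log2(FPKM + 1). A tumour sample
   is called overexpressed for a gene when its value exceeds the upper
   Tukey fence (Q3 + 1.5·IQR) of the non-malignant samples for that gene.
   Underexpression calls mirror this with the lower fence.
2. **Copy-number increase.** Gene-level discrete calls in {−2…2}
   (GISTIC-style categories) are inputs; gain (1) and amplification (2)
   both count.
3. **Hypomethylation.** Probes are first screened at the cohort level:
   mean Δβ = mean(β, tumour) − mean(β, normal) must be below −0.1 and a
   two-sided Welch t-test must survive Benjamini-Hochberg correction at
   q < 0.05, with the BH family being all probes of all panel genes
   jointly. A tumour sample is then called hypomethylated for a gene when
   its mean β over the gene's screened probes falls below the lower Tukey
   fence of the non-malignant per-sample means. A gene with no screened
   probe can never earn this point.
4. **miRNA-mediated downregulation.** Per miRNA, a tumour sample is
   down-called when its z-score against the non-malignant reference
   (sample mean and n−1 standard deviation) is below −1.645, the lower 5%
   tail of a standard normal. A gene earns the point when at least half of
   the *annotated* miRNAs predicted to target it are down-called
   (2·count ≥ T, i.e. the integer ceiling for odd targeting-set sizes T);
   unannotated (novel) miRNAs never contribute.

Every threshold comparison is strict, so a value exactly on a fence or at
−1.645 is never called. All thresholds live in `moma.io.Config` and default
to the values above.

Two companion miRNA screens are included. The expression filter keeps a
miRNA if, within at least one tissue role, it reaches ≥ 1 RPM in ≥ 10% of
samples and > 0 RPM in ≥ 50% of samples (the union over roles gives the
broadest view of the transcriptome). The paired differential screen runs a
two-sided Wilcoxon signed-rank test on tumour − normal differences within
matched pairs — exact null distribution when at most 25 non-zero
differences remain after dropping zeros, continuity-corrected normal
approximation otherwise — followed by BH correction; a miRNA is
significantly differential when q < 0.05 and its median RPM is positive in
at least one group. Downregulated significant miRNAs feed a Spearman
screen against their predicted target genes over tumour samples, with a
pair passing at ρ < −0.2 and p < 0.05 (t-approximation). The p threshold is
configurable; 10⁻⁴ is a natural stricter preset when many pairs are
screened.

## Survival analysis

Patients are grouped by their per-gene score (or by the number of
overexpressed panel genes, or above/below the median of a feature, with
median ties going to the lower group). Groups of five or fewer patients
merge iteratively into their adjacent group, choosing the larger
neighbour and breaking ties toward the lower score, until every group
exceeds the minimum or one remains; merged groups take range labels such
as "3-4".

Two groups are compared with the standard log-rank test; three or more
ordered groups with the one-degree-of-freedom log-rank test for trend,

    χ² = [Σ_g w_g (O_g − E_g)]² / (wᵀ V w),

where O, E and the covariance matrix V accumulate hypergeometric
contributions over distinct event times (V includes the (N−d)/(N−1)
tie correction; a time with one subject at risk contributes no variance)
and the weights w_g are the mean raw score of each merged group's
patients (group ranks after merging are an alternative the configuration
exposes). With two groups the trend statistic reduces algebraically to the
plain log-rank statistic; the test suite verifies the equality to 1e−9.
p-values use the asymptotic χ²₁ upper tail; zero total variance yields
p = 1. Kaplan-Meier curves use the product-limit estimator with subjects
censored at an event time kept in the risk set at that time. Plots
truncate the x-axis at 2000 days and mark the five-year point with a
dotted line; the tests always use full follow-up — truncation is display
only.

## Synthetic cohort generator

The generator (`moma.simulate`) emulates a TCGA-style cohort: by default
377 tumours, 59 adjacent non-malignant samples and 49 matched pairs, a
five-gene panel with 8 methylation probes per gene, and 45 miRNAs (20
annotated targeting, 20 annotated background, 5 novel). Alterations are
planted independently per sample, gene and alteration type:

| parameter | default | meaning |
|---|---|---|
| `frac_overexpressed` | 0.40 | per-gene fraction of tumours with planted overexpression |
| `frac_cn_gain` | 0.35 | planted copy-number gain/amplification fraction |
| `frac_hypomethylated` | 0.50 | planted hypomethylation fraction |
| `frac_mirna_down` | 0.30 | planted miRNA-downregulation fraction |
| `expr_shift_log2` | 3.0 | log2-FPKM shift added to planted overexpression |
| `delta_beta_effect` | −0.3 | β shift of all of a gene's probes in planted samples |
| `mirna_down_shift_sd` | 3.0 | downward shift in reference SDs (raw RPM scale) |
| `hazard_log_hr_per_point` | 0.3 | log hazard ratio per point of total alteration count |
| `baseline_hazard` | 1/4000 per day | hazard of an unaltered patient |
| `censor_max_days` | 3650 | uniform right-censoring horizon |

Mechanics: non-malignant log2(FPKM+1) is Gaussian per gene (mean uniform
in [4, 9], SD in [0.4, 0.8]); β values are Beta-distributed per probe
(mean uniform in [0.45, 0.85], concentration 60) with planted shifts
clipped to [0, 1]; copy-number calls are 0 except in planted samples
(gain with probability 0.75, amplification 0.25); miRNA RPM is log-normal
with planted samples shifted down by a multiple of the distributional
standard deviation and floored at zero. The planting fractions were chosen
once as round values in the range of the alteration prevalences reported
for liver tumours; the hypomethylation fraction must exceed one third for
the cohort-level probe screen to engage at the default Δβ effect (group
mean Δβ = fraction × effect must pass the −0.1 gate), and 0.50 reflects the
strong probe-level losses seen in that setting. Survival times are
exponential with hazard `baseline_hazard · exp(log_hr · total score)`
where the total is the patient's alteration count summed over genes, so
hazard increases log-linearly with alteration burden; censoring is
independent and uniform. Each data modality draws from its own child
stream of the master seed, so adding or regenerating one modality never
perturbs another, and a fixed seed reproduces every file byte-for-byte.

What the generator does **not** emulate: batch effects, tumour purity,
probe cross-reactivity, correlation between alteration types within a
sample (alterations are planted independently, so the miRNA–mRNA
anti-correlation screen finds essentially no passing pairs on default
synthetic cohorts), missing values (the loaders reject them), and
non-proportional hazards. Passing tests therefore demonstrate correctness
of the calling rules and test statistics under a clean generative model,
not robustness to those real-data artefacts.

## Numerical and design choices

- **Quantiles** use linear interpolation between order statistics (the
  "type 7" convention of mainstream numeric stacks); the fence multiplier
  is configurable, the quantile type is not.
- **Pseudocount**: log2 transforms use +1, required for zero FPKM/RPM.
- **Welch t-test**, unpaired, for the probe screen: robust to the very
  unequal group sizes (hundreds of tumours vs dozens of normals); a paired
  variant over the matched pairs is available via configuration. Probes
  with zero variance in both groups get p = 1 when means agree and p = 0
  otherwise.
- **miRNA z-scores** are computed on raw RPM by default (log2 scale is a
  configuration switch); a zero reference SD disables calls for that miRNA.
- **Wilcoxon**: pairs with zero difference are dropped before ranking
  (the convention under which the exact test is defined); all differences
  zero gives p = 1.
- **Spearman** uses average ranks on ties and the t-approximation for p;
  constant vectors yield an undefined (NaN) ρ and never pass. Correlations
  run over tumour samples only by default, since downregulation is
  tumour-relative.
- **Missing data** are rejected at load with an error naming the offending
  cell — failing loudly beats silent imputation.
- **Small-group merging** processes the smallest undersized group first
  (ties toward the lower score); the spec of "five or fewer" is inclusive
  (≤ 5).
- All on-disk tables are TSV (UTF-8, header row, dot decimal separator);
  floats are written with 17 significant digits and parsed with
  round-trip precision so write→read is exact and reruns are
  byte-identical.

## Validation problem sizes

The statistical acceptance checks run at sizes chosen to make the
sampling error of the checks themselves small: oracle comparisons use 100
random instances per statistic; trend/log-rank equivalence uses 50 random
two-group datasets; type-I error uses 200 simulated cohorts of 300
tumours with the hazard effect set to zero (rejection rate compared
against the binomial 95% interval around 0.05); power and planted-flag
recovery use 100 and 10 cohorts of 300 tumours with large planted effects
(`expr_shift_log2 = 4`, `delta_beta_effect = −0.3`,
`mirna_down_shift_sd = 4`, log HR 0.5 per point), where each calling
modality recovers planted flags with sensitivity and specificity above
0.9 and the trend test's power exceeds 0.8.

## Known limitations

- The alteration calls are marginal per gene; no joint modelling across
  genes or alteration types.
- The trend test's asymptotic χ² p-value is optimistic for very small
  groups; the merging rule mitigates but does not remove this.
- Target maps and miRNA annotation status are inputs; no target
  prediction is performed.
- No Cox regression or covariate adjustment; the survival analysis is
  deliberately limited to KM curves and (trend) log-rank tests.
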