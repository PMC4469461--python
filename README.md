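# ivmr

Two-sample Mendelian randomization (MR) from GWAS summary statistics,
built for epidemiologists asking whether a modifiable risk factor
(blood pressure, lipids, glycemic traits, adiposity, smoking,
education) is *causally* related to a disease outcome such as Alzheimer
disease.  Genetic variants robustly associated with the exposure serve
as instrumental variables: because alleles are randomized at meiosis,
the genetically predicted exposure–outcome association is immune to the
confounding and reverse causation that afflict observational estimates.

## What it computes

For harmonized per-SNP effects (β̂_Xj, σ_Xj) on the exposure and
(β̂_Yj, σ_Yj) on outcome log-odds, the per-SNP Wald ratio is
θ̂_j = β̂_Yj / β̂_Xj with SE σ_Yj/|β̂_Xj|, and the fixed-effect
inverse-variance weighted (IVW) causal estimate is

    θ̂ = Σ w_j β̂_Xj β̂_Yj / Σ w_j β̂_Xj²,   se(θ̂) = (Σ w_j β̂_Xj²)^(-1/2),
    w_j = σ_Yj⁻²,

reported as an odds ratio per analysis unit of exposure (per SD for
continuous traits) and rescalable to any natural-unit difference.
Around the estimator sit the working parts of a complete analysis:

* **`ivmr.summary_data`** — tab-separated association-table I/O with
  row-level validation, allele/strand harmonization (including
  frequency-resolution of palindromic SNPs), instrument-set assembly,
  and greedy LD pruning (r² threshold);
* **`ivmr.mr_core`** — Wald ratios, IVW, unit rescaling, Cochran's Q
  heterogeneity test, Table-style report serialization;
* **`ivmr.sensitivity`** — Bonferroni pleiotropy screen (α / N over the
  unique SNPs of *all* sets), leave-one-out analysis, standardized-
  residual scatter outliers, QQ-plot statistics and plots;
* **`ivmr.score_analysis`** — unweighted allele scores from dosage
  matrices and covariate-adjusted linear/logistic associations
  (statsmodels), stratified fits, quartile summaries;
* **`ivmr.synthetic_data`** — cohort generator with known causal
  structure (confounding, pleiotropy, case-control sampling) plus
  replicated two-sample simulation studies;
* **`ivmr.pipeline` / `ivmr` CLI** — configuration-driven orchestration
  with byte-reproducible reports and a run log.

See `docs/methods.md` for the model, its assumptions, every default,
and known limitations.

## Worked example

Rescaling a published per-SD systolic blood pressure (SBP) estimate to
a 10-mm Hg difference (1 SD = 15.4 mm Hg):

```python
import math
from ivmr import MrEstimate, rescale_estimate
from ivmr.mr_core import Z95

beta = math.log(0.75)
se = (math.log(0.91) - math.log(0.62)) / (2 * Z95)   # from the 95% CI
per_sd = MrEstimate(beta=beta, se=se, n_snps=24, unit_label="1 SD (15.4 mm Hg)")
print(per_sd)
print(rescale_estimate(per_sd, 10 / 15.4, "10 mm Hg"))
```

```
OR 0.75 (0.62-0.91) per 1 SD (15.4 mm Hg), p = 0.0033, 24 SNP(s)
OR 0.83 (0.73-0.94) per 10 mm Hg, p = 0.0033, 24 SNP(s)
```

A genetically predicted SD higher SBP is associated with 25% lower
outcome odds; per 10 mm Hg the same estimate reads OR 0.83 — smaller
per-unit, identically significant, because rescaling multiplies the
log-OR and its SE together.

End-to-end on synthetic data with a known causal effect (θ = −0.3,
i.e. true OR e^−0.3 ≈ 0.74 per exposure unit):

```bash
$ ivmr simulate --preset causal --out demo --seed 3
$ ivmr mr --exposure demo/exposure_gwas.tsv --outcome demo/outcome_gwas.tsv \
          --trait-name "synthetic exposure"
synthetic exposure: OR 0.73 (0.63-0.84) per 1 unit, p = 1.5e-05, 30 SNP(s)

$ ivmr score --dosages demo/dosages.tsv --phenotypes demo/phenotypes.tsv \
             --exposure demo/exposure_gwas.tsv --outcome-col exposure --family linear
score (30 SNPs) vs exposure: 0.1061 outcome units per allele (SE 0.0020, p = 0, n = 20000)
```

The IVW estimate recovers the generating OR, and the unweighted allele
score associates with the exposure at ~0.106 units per raising allele
(the mean per-SNP effect in this scenario is 0.1).

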