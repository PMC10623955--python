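# bileaxis

Analysis pipeline for the gut microbiome–bile acid–FGF19 axis in
case–control cohorts, built around atrial fibrillation (AF) as the case
condition. The package links three layers of evidence:

1. **Metagenomic enzyme profiling.** Genes from a non-redundant catalogue
   that align to the 13 bile-acid (BA) biotransformation enzymes — BSH,
   7α-/7β-HSDH and the ten *bai*-operon genes — are filtered with the
   MEGAN-style rule (keep hits with e-value ≤ 10 × the best hit), reduced
   to a best-hit enzyme per gene, and summed into an enzyme × sample
   relative-abundance profile. Per-gene taxonomy hits pass the same filter
   and a lowest-common-ancestor step, so enzyme genes can be attributed to
   genera and *potential producer genera* called per synthesis pathway
   (UDCA via the HSDH pair; LCA/DCA via the *bai* operon). Group
   differences use the two-sided Wilcoxon rank-sum test.
2. **Faecal BA metabolomics.** A targeted 24-analyte panel (nmol/g) is
   summarised into primary/secondary composition, tested BA-by-BA,
   projected by PCA, and modelled with OPLS-DA. Variable importance in
   projection (VIP, with mean VIP² = 1 by construction) selects candidate
   marker BAs at VIP > 1, and each candidate is evaluated as a biomarker
   with an ROC curve: AUC = U/(n₁n₀) (Mann–Whitney with ties ½), DeLong
   95% CI, and the Youden cutpoint maximising J = sens + spec − 1.
3. **Clinical association.** Baseline tables (t / Mann–Whitney /
   chi-square / Fisher as appropriate), the Pearson correlation of
   circulating FGF19 (pg/mL) with left atrial diameter (LAD, mm), and a
   univariate logistic screen (p < 0.10, diabetes forced in) feeding a
   multivariable logistic model whose FGF19 odds ratio is reported per
   pg/mL with Wald intervals.

Because patient-level data of this kind are rarely shareable, the package
ships a first-class **synthetic-cohort generator** that emulates all five
inputs with planted, machine-readable ground truth (log-normal abundances
closed to a compositional sum, multiplicative group effects, decoy
taxonomy hits provably outside the 10× window, a controlled negative
FGF19–LAD correlation). Every pipeline stage is verified by recovering
what was planted.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/04_ba_metabolomics.py` prints:

```
secondary-BA proportion: AF median 0.323 vs control 0.645 (Wilcoxon p = 9.37e-08)
differential BAs at p<0.05: 12 up, 3 down in AF (planted: 12 up, 4 down)

OPLS-DA: R2Y = 0.967, Q2 = 0.931, mean VIP^2 = 1.000000
VIP > 1 selects 14 BAs, top five:
  3-DHCA       VIP=1.39  p=8.3e-08
  ...
UDCA as an AF marker: AUC = 0.915 (95% CI 0.834-0.996)
Youden cutpoint 48.4 nmol/g: sensitivity 0.96, specificity 0.78
```

The secondary-BA proportion collapses in AF because the planted
enrichment of primary BAs (CA, CDCA and conjugates) outweighs the mixed
secondary-BA shifts; UDCA, planted four-fold higher in AF, separates the
groups with a high AUC and the cutpoint is the concentration that best
splits them. The full pipeline is one call:

```python
from bileaxis import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(outdir="bileaxis_out", seed=1))
```

or, from the shell, `bileaxis run --outdir bileaxis_out --seed 1` (the
`simulate`, `profile`, `producers`, `metabolome` and `clinical`
subcommands run single stages on files).

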