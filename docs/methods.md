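# Methods

## Scope and data model

The pipeline analyses a two-group cross-sectional design (cases = atrial
fibrillation, coded 1; controls coded 0) across three data layers that
are measured on separate cohorts: a metagenomic gene catalogue with
per-sample relative abundances, a targeted faecal bile-acid (BA) panel in
nmol/g, and a clinical covariate table with circulating FGF19 in pg/mL.
The three layers never need to share samples; each stage is self-contained
and communicates only through plain-text tables.

## Enzyme profiling

Alignment hits of catalogue genes against the 13 BA-enzyme references
(BSH, 7α-HSDH, 7β-HSDH, BaiB, BaiF, BaiA, BaiH, BaiI, BaiN, BaiCD, BaiE,
BaiA2, BaiG) are filtered per gene by the 10× rule: keep hits with
e-value ≤ 10 × the gene's best e-value, inclusive, so the top hit always
survives and the filter is idempotent. E-values of exactly 0 are clamped
to 1e-308 before multiplication; otherwise the threshold would be 0 and
would discard everything but exact-zero hits. Each gene is then assigned
the enzyme of its single best hit (lowest e-value, ties broken by higher
bitscore, then lexicographic enzyme name for determinism). Best-hit
assignment — rather than spreading a gene over all retained hits — is a
design choice; the hit tables rarely leave it ambiguous because reference
enzymes are well separated. Enzyme abundance is the sum of member-gene
relative abundances per sample, so the profile never exceeds the sample's
total abundance of 1.

Taxonomy hits pass the same 10× filter; a gene's assignment is the
deepest rank prefix (superkingdom → species) shared by every retained
lineage, the classic lowest-common-ancestor rule. Lineages must satisfy
the prefix property (no rank named below a missing rank); violations are
an input error, not silently repaired. Genes resolving above genus are
kept in enzyme profiles but excluded from all genus-level analyses.

Group differences use the two-sided Wilcoxon rank-sum test: exact when
both groups have ≤ 12 observations and the pooled data is tie-free,
otherwise the normal approximation with tie and continuity corrections.
The switch point keeps exact enumeration cheap while matching the
approximation well before it takes over. Fold changes are
log2(median_AF/median_control) with a pseudo-count of half the feature's
smallest nonzero value. Raw p-values are primary; a Benjamini–Hochberg
column is available but off by default.

## Producer genera

A genus is a potential producer of a pathway when it harbours ≥ 1 gene
for any enzyme of that pathway. The default map follows the chemistry:
UDCA synthesis = {7α-HSDH, 7β-HSDH} (CDCA ↔ UDCA epimerisation), and LCA
and DCA synthesis both = the ten *bai* genes (7-dehydroxylation of
CDCA/UDCA and of CA). BSH deconjugates upstream of all three routes and
belongs to no pathway set by default. Both the map and the
"bai-complete" threshold (≥ 5 distinct *bai* genes, reflecting the five-
to-six-gene operons seen in real producers) are configurable. The
enzyme–genus network correlates producer-genus abundance with enzyme
abundance (Spearman by default, Pearson optional), keeps signed edges
with p < 0.05, and skips constant vectors with a logged warning.

## BA panel analysis

The 24-analyte panel is classified into host-synthesised primary BAs
(CA, CDCA and their glycine/taurine conjugates) and microbially derived
secondary BAs (DCA, LCA, UDCA, HCA families and their keto/dehydro
derivatives and conjugates); the map is configurable since panel
definitions vary between laboratories. The secondary proportion is
Σ secondary / Σ all per sample; zero-total samples have no defined
proportion and are flagged out of the group test.

Multivariate models use log10(x + ε) with ε = half the variable's
smallest nonzero value, then centring and unit-variance scaling; constant
variables are dropped with a warning. PCA is by full SVD on the scaled
matrix. OPLS-DA is a NIPALS fit with orthogonal-signal correction: for
each orthogonal component the y-predictive direction is removed from the
loading to give an orthogonal weight, and its component is deflated from
X before the single predictive component is extracted. y is the 0/1
class label, centred. VIP is computed on the predictive component —
VIP_j = √K · |w_j| with ‖w‖ = 1 — so mean VIP² = 1 exactly and VIP > 1
flags above-average contributors. Q2 comes from 7-fold venetian-blind
(interleaved) cross-validation with the scaling refit inside every
training fold; one orthogonal component is the default, as is standard
when a single predictive component is extracted.

ROC analysis computes AUC as the normalised Mann–Whitney U with tied
pairs worth ½, the DeLong placement-variance 95% CI, and the Youden
cutpoint over midpoints between adjacent observed values (smallest
cutpoint among ties), reported on the original marker scale. Markers
whose AUC would fall below 0.5 are auto-flipped and the orientation
recorded.

## Clinical modelling

Baseline comparisons gate the continuous-variable test on Shapiro–Wilk at
0.05 in both groups (t test with pooled variance when normal-looking,
Mann–Whitney otherwise) and the categorical test on expected cell counts
(chi-square with Yates continuity, Fisher exact when any expected cell
< 5). A summary-statistics t test is provided for published
mean ± SD rows. The FGF19–LAD association is a complete-case Pearson
correlation. The modelling workflow fits one single-predictor logistic
model per covariate, keeps those with p < 0.100 plus any forced-in set
(diabetes by default, a known confounder of FGF19), and fits the
multivariable logistic model by Newton/IRLS maximum likelihood
(tolerance 1e-8) with Wald standard errors, OR = exp(β) and 95% CI
exp(β ± 1.96·SE). FGF19 enters untransformed, so its OR is per pg/mL.
Perfect separation is flagged, never silently returned. Complete-case
analysis throughout; no imputation.

## Synthetic cohort generator

The generator produces every input with planted truth and is the
package's verification instrument, not a model of any particular cohort.

*Metagenome.* Gene relative abundances are log-normal (per-gene size
effect N(0,1), within-gene log-SD 1.0) renormalised to sum to 1 per
sample — heavy-tailed and compositional like real catalogues. Enzyme
genes are laid out over genera in disjoint roles so producer counts are
exact functions of the configuration: 4 genera carry 5–6 distinct *bai*
genes, 6 carry both HSDHs, and each enzyme gets dedicated single-enzyme
scatter genera; the remaining genes take random genera and no enzyme.
Planted log2 effects (default: −2 for BaiH/BaiCD, −1.5 for
7α-HSDH/BaiN, −1 for 7β-HSDH/BaiA/BaiA2, all depleted in cases)
multiply case samples before renormalisation and are sized to give each
enzyme comfortably ≥ 80% Wilcoxon power at 50/50 samples. Hit tables put
the true enzyme on top with off-target hits either beyond the 10× window
or inside it with worse e-values; taxonomy decoys are strictly beyond
10× (a configurable confounder rate can plant within-window disagreeing
lineages for LCA stress tests). E-values are log-uniform; exact zeros
are never generated.

*BA panel.* Concentrations are log-normal around faeces-like baseline
medians dominated by free secondary BAs (DCA 450, LCA 280 nmol/g, …)
with a common coefficient of variation (default 0.8 → log-SD ≈ 0.70).
The default effect map plants 12 BAs up (+2 log2: UDCA, bUDCA, HCA,
7-KetoLCA, 3-DHCA, 6-KetoLCA, CDCA, TCA, CA, GUDCA, TCDCA, TUDCA) and 4
down (−1.5 log2: dehydroLCA, 12-KetoLCA, LCA, GDCA) in cases; the
primary-BA enrichment then drives the secondary proportion down in cases
even though several secondary BAs rise, mirroring the biology the
pipeline is meant to resolve. Effects give ≥ 80% per-BA Wilcoxon power
at 23/23.

*Clinical.* FGF19 is log-normal (median 232.8 pg/mL in controls, log-SD
0.70 derived by averaging the spreads implied by typical printed group
quartiles, natural-log case shift −0.51); LAD is normal (37 ± 4 mm,
+4 mm in cases) with a controlled correlation to FGF19: the latent
Gaussian correlation is inflated by √(e^σ²−1)/σ so that the *raw*
FGF19–LAD Pearson correlation matches the configured target (−0.3
within groups; group shifts push the pooled value further negative).
LVEF is normal (64 ± 5, −4 in cases), DM Bernoulli (0.20/0.15), age,
BMI normal, sex Bernoulli ½.

Determinism: one master seed; each table draws from its own
deterministically derived child stream, so regenerating any table does
not perturb the others and identical configurations are byte-identical
on disk.

What the generator does *not* emulate: read-level noise, gene-catalogue
construction artefacts, correlated BA families beyond the common class
structure, covariate confounding between layers, measurement floors/LLOQ
censoring, or batch effects. Passing tests therefore demonstrate that
the statistical machinery recovers known effects under the assumed
generative model — not that any particular clinical finding would
replicate.

## Problem sizes and numerical choices

The test suite uses catalogues of 120–300 genes over 40 genera with the
full 50/50, 23/23 and 36/24 cohort sizes; Monte-Carlo checks use 200
seeds for recovery properties, 1000–2000 replicates for oracle and
calibration properties, and 100 permutations for the OPLS-DA label
permutation null. Tie-breaks are everywhere deterministic (documented
above); iterative fits converge at 1e-8; Wald z uses 1.95996. Known
limitations: DeLong intervals are degenerate under perfect separation
(width 0); the univariate screen refits rather than profiling likelihood;
the OPLS-DA implementation extracts exactly one predictive component, the
usual choice for a two-class model.
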