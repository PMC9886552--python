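# Methods

This note documents the models implemented in `mmaomics`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real cohorts.

## Severity phenomics

The clinical severity score (CSS) is the sum of five binary indicators;
missing indicators contribute 0 and are surfaced through a completeness
count rather than imputed, so a partially documented patient can still be
scored but the score's support is visible. Early onset, when derived from a
continuous age-at-onset, is binarized at ≤ 28 days (the neonatal window);
the threshold is a configurable constant (`EARLY_ONSET_DAYS`).

The correlation matrix uses Spearman rank correlation for *every* variable
pair, including binary–binary (where it equals a rank phi coefficient).
One coherent estimator keeps a mixed-type matrix interpretable; cells are
computed on pairwise-complete observations (no imputation) and left missing
below 3 complete pairs or for constant variables.

The association screen natural-log transforms a continuous variable only
when it is strictly positive; otherwise it falls back to log(x+1) with a
warning. Both sides are z-standardized before ordinary least squares, so the
reported effect size is the standardized slope (equal in magnitude to the
Pearson correlation of the transformed variables) and is invariant to
affine rescaling of the inputs. Benjamini–Hochberg runs across the screened
set; the default significance threshold is adjusted p < 0.05.

## Kinship mixed model

Model: y = μ1 + xβ + u + ε with u ~ N(0, σ_g²K), ε ~ N(0, σ_e²I), where K =
MᵀM/p over the p genes of the doubly standardized expression matrix M. The
double standardization alternates column and row z-scoring (population
variance) until every margin mean is below 1e−6 and every margin variance
within 1e−5 of 1, with a 100-iteration cap; the tolerances are artifact
choices — the procedure typically converges in well under 50 alternations
on log-scale expression data. Constant rows/columns are rejected as
degenerate rather than silently perturbed.

The response is rank-inverse-normal transformed, Φ⁻¹((r−0.5)/n) with
average ranks for ties, so the Gaussian likelihood assumption holds by
construction.

Fitting profiles the variance ratio δ = σ_e²/σ_g² on the eigenbasis of K:
one eigendecomposition serves the entire scan, after which each per-gene fit
is a one-dimensional optimization of the *restricted* log-likelihood in
log δ over [−10, 10] (41-point grid, then bounded Brent refinement around
the best grid point). REML is the default because per-gene variance
components would otherwise be biased by the two estimated fixed effects;
maximum likelihood is available behind a flag. The Wald statistic for β uses
a t reference with n − p degrees of freedom, which makes the K = I case
collapse *exactly* onto ordinary least squares — the primary internal
consistency check (agreement to |Δp| < 1e−6). Genes are standardized before
use as fixed effects so β is a comparable effect size across genes.
p-values are invariant to positive rescaling of K because δ absorbs the
scale (verified to ~1e−5, limited by the finite optimizer grid).

Calibration, measured by the test suite and the acceptance script on
expression-derived kinships (n = 100, 2,000 null fits): type-I error at
α = 0.05 stays within a few thousandths of nominal, and the genomic
inflation of a 500-gene null scan stays near 1 (single-scan estimates
scatter roughly ±0.2 because all genes share one response draw).

BLUP prediction uses û = σ_g²KV⁻¹(y − Xβ̂) computed on the same eigenbasis;
with σ_g² = 0 it reduces to the fixed-effect regression prediction, and
with K = I and intercept only it shrinks deviations from the mean by
σ_g²/(σ_g²+σ_e²) — both limits are tested in closed form.

## Cross-omics correlation

Per-gene transcript–protein Spearman correlations are computed within each
genotype group (deficient versus everyone else); pairs are retained only
when present in both layers with ≥ 4 samples per group. Two-sided p-values
use the t approximation, replaced by full permutation enumeration at
n ≤ 9 without ties (the null distribution of ρ is cached per n). The
diagonal distance d = (ρ_def − ρ_ctrl)/√2 is the signed displacement from
the equal-correlation diagonal. The difference test is Fisher's z with
variance 1/(n−3) per group — chosen as the standard closed form; a
permutation comparison in the test suite confirms factor-two agreement near
the null, which is where a method choice could change conclusions.
Sample-level summaries use the shared-pair set only.

## Isotope tracing

Fractions: peak areas are divided by the sample's matching-polarity internal
standard, missing isotopologue rows are imputed as zero area, and each
(sample, metabolite) vector is normalized to sum 1. No natural-abundance
isotope correction is applied by default (the analysis consumes
pre-integrated peak tables; a correction hook can be layered on the raw
areas before fraction computation).

The forward simulator is a discrete-turn propagation, not a flux-balance
model. Per turn: the glutamine-derived oxoglutarate pool holds fraction e
at M+5; the oxidative branch (weight 1−r) removes one carbon — a labeled
carbon with probability i/n for the M+i species, positionally agnostic — to
form the 4-carbon backbone shared by succinate/fumarate/malate, mixes it
with unlabeled anaplerotic inflow a, and condenses with unlabeled
acetyl-CoA into citrate at an unchanged mass shift; the reductive branch
(weight r) carboxylates oxoglutarate with unlabeled CO₂ directly to citrate
(M+5 → M+5). From the second turn on, recycled citrate re-enters as
oxoglutarate (losing one carbon) blended 50/50 with fresh glutamine-derived
material; the blend weight is a fixed model constant, chosen because the
claims the simulator supports are pattern-level (M+4 versus M+5 citrate,
M+0 dilution by anaplerotic inflow, monotonicity of the M+5/M+4 ratio in
r), all of which are insensitive to it and are property-tested across the
parameter grid. Default turns = 3; the single-turn mode yields the
hand-checkable identities (r=0,a=0,e=1 → all-M+4 backbone and citrate;
r=1 → all-M+5 citrate).

Reductive-fraction recovery minimizes the squared error between observed
and simulated citrate vectors over r ∈ [0,1] (101-point grid plus bounded
refinement); a flat objective (range < 1e−8, e.g. at zero enrichment) flags
the fit as non-identifiable instead of returning an arbitrary boundary
value. Recovery is exact to 1e−3 noiseless and unbiased to ±0.05 under
fraction noise of sd 0.02.

Pool comparisons use the two-sided Wilcoxon rank-sum with exact enumeration
for groups of ≤ 10 without ties, normal approximation otherwise.
Metabolite-set enrichment is the upper-tail hypergeometric with BH
adjustment across pathways.

## IP–MS

Identification thresholds are strict inequalities: protein probability
> 0.99 and ≥ 2 peptides with probability > 0.95. "Pulled down by a bait"
means detected in ≥ 1 replicate of that bait (exposed as `min_replicates`);
exclusion by negative controls is absolute — one control replicate removes
a prey. The ANOVA runs on log₂ intensities per protein across bait
triplicates with no multiplicity adjustment (the specificity filter, not
the ANOVA, carries the burden of excluding background). Degenerate
constant-across-all-groups proteins receive F = 0, p = 1 by convention and
are logged.

## Variant triage

Filters compose as frequency AND read-support AND (coding OR clinical OR
splice). CNV records bypass read support (they derive from depth profiles,
not individual reads) but not the frequency rule. Compound heterozygosity
assumes trans phase for ≥ 2 distinct passing hets in one gene — without
trio data this is the only available call, and it is a documented
limitation; both alleles must pass the filters (a VUS partner that fails
every prioritization rule does not support a call). The allele census
counts homozygous calls twice. The expression-outlier screen is a
deliberately simple robust-z rule, z = (x − median)/(1.4826·MAD) < −3 per
gene, standing in for model-based aberrant-expression detection; it flags
strong under-expression (e.g. nonsense-mediated decay) but has no
count-noise model and no autoencoder-style confounder control.

## Synthetic cohort generator

The generator's defaults encode the study conditions the analyses assume:
230 samples (150 MMUT-deficient, 60 other-MMA, 20 unaffected), 4,318
transcript–protein pairs, a standard-normal latent severity axis shifted by
+1 SD for the deficient group and +0.5 SD for other-MMA, log-normal
expression with genotype effects applied on the log₂ scale (MMUT −1/−1
rna/protein log₂FC, OGDH protein −0.8, GLUD1 protein +0.8, ALDH2 +0.5/+0.5,
PDK4 transcript +0.8), and a default transcript–protein coupling of 0.15 —
chosen so the per-gene Pearson coupling c maps through the Gaussian
rank-correlation relation ρ_S = (6/π)·arcsin(c/2) to the modest gene-level
concordance typical of proteogenomics, while a shared per-gene base
abundance (sd 0.8 against a protein-specific offset of sd 1.2) produces the
higher sample-level concordance. Phenotypes follow
loading·severity + noise, exponentiated for concentrations/activities;
binary traits use a logistic link. PI+ loads negatively on severity (−1.2),
the CSS components positively. Tracing conditions: control r = 0.05,
a = 0.5 versus deficient r = 0.3, a = 0.15 at e = 0.95 — the deficient
condition relies more on glutamine anaplerosis (less unlabeled inflow, less
M+0) and more on the reductive route (higher citrate M+5/M+4). Variant
consequence classes are drawn with frequencies proportional to a large
MMUT-cohort allele census (missense:truncating:splicing:in-frame:CNV =
165:105:21:2:3), and every decoy allele violates at least one filter by
construction. Noise parameters throughout are artifact choices exposed in
the config; the assays they imitate publish no noise model.

One seed drives everything through named `SeedSequence` substreams
(severity, phenotypes, omics, variants, tracing, ipms), so layers are
independently regenerable and full bundles are byte-reproducible.

What passing tests show — and don't: parameter recovery on this generator
establishes that each estimator inverts its own generative model at
realistic sizes and noise levels, and that the pipeline's plumbing,
thresholds and set logic are exact. It does not establish robustness to the
pathologies of real data the generator omits: batch effects, heavy-tailed
and missing-not-at-random proteomics intensities, linkage between variants,
population stratification beyond expression-derived kinship, isotope
natural abundance, or phenotype ascertainment bias.

## Problem sizes

Default analysis scale is the full synthetic cohort (230 × 4,318; the
mixed-model scan takes seconds thanks to the single eigendecomposition).
The end-to-end pipeline demo and its determinism test run at 40 samples ×
800 genes; calibration simulations use n = 100 with 2,000 null fits and
effect-recovery at n = 200 with 200 replicates — sizes at which the
Monte-Carlo error of the checked quantities is several times smaller than
the acceptance bands.
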