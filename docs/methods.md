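# Methods

## The oxidative balance score

Seven a-priori exposures enter the score: three prooxidants (total iron
intake, smoking status, alcohol consumption) and four antioxidants (vitamin
C, retinol, carotene, physical activity in MET/day).  Continuous exposures
are cut at the analysis cohort's own empirical tertiles and scored 0–2;
prooxidants are scored opposite to antioxidants so that a higher score always
means antioxidant predominance:

| component | scoring |
| --- | --- |
| iron | 2 = 1st tertile, 1 = 2nd, 0 = 3rd |
| vitamin C, retinol, carotene, activity | 0 = 1st tertile, 1 = 2nd, 2 = 3rd |
| smoking | 2 = never, 1 = former, 0 = current |
| alcohol | 0 = heavy (≥50 g/day), 2 = otherwise |

The alcohol component is a binary clinical cut rather than a tertile; the
cut-off (50 g/day) and its direction are configurable.  The right-skewed
nutrient intakes may be natural-log transformed
(`log_transform_components`); because tertile membership is rank-based the
transform cannot change any component score — an identity the test suite
asserts — so it matters only for analyses using the continuous exposures.
Alcohol is never transformed (its threshold is absolute g/day) and physical
activity is approximately symmetric already.

Three weighting schemes combine the component scores:

- **equal**: the unweighted sum, range 0–14;
- **beta-coefficient**: one multivariable logistic model of MetS on all seven
  component scores plus age, sex, area and BMI is fitted; the weight of
  component *j* is −β̂<sub>j</sub>, so protective components receive positive
  weight, and the score is the weighted sum of component scores.  A single
  joint model is used (not seven marginal ones) because the components are
  mutually adjusted exposures of one construct;
- **PCA**: the component scores are standardized, the correlation matrix is
  eigendecomposed, components with eigenvalue > 1 are retained, and the
  first retained PC's loadings weight the standardized scores.  The
  eigenvalue-greater-than-one rule replaces visual scree inspection, which is
  not reproducible; only the leading PC forms the score so that every scheme
  yields one scalar.  Loadings are sign-oriented so the mean loading of the
  four antioxidant components is positive.

Weights are applied to the 0/1/2 component scores, not the raw intakes: the
scores are the representation shared by all three schemes, which keeps the
schemes comparable.  Each continuous score is cut at its empirical 25/50/75
percentiles into quartiles Q1–Q4 with Q1 (prooxidant predominance) the
reference.

Quantiles everywhere are type-7 (linear interpolation) with lower-inclusive
bins ((−∞, q₁], (q₁, q₂], …).  This is documented deliberately: quartile
membership feeds every downstream model, and any re-implementation must
reproduce the same tie-handling.  Adjacent quartile cutpoints may coincide on
heavily tied scores (leaving a bin empty, as integer-valued equal-weight
scores sometimes do); a distribution whose 25th and 75th percentiles coincide
is rejected as degenerate.

## Metabolic-syndrome phenotype

MetS is ≥3 of five components (NCEP-ATP III, Korean waist cut-offs):
waist ≥90 cm (men) / ≥85 cm (women); triglycerides ≥150 mg/dL; HDL
<40 / <50 mg/dL; systolic ≥130 or diastolic ≥85 mmHg **or** antihypertensive
medication; fasting glucose ≥100 mg/dL **or** antidiabetic medication.  All
thresholds are inclusive on the adverse side exactly as printed and are
overridable via `MetSCriteria`.  Lipid-lowering medication does not modify
the TG/HDL components (no published rule prescribes it).  Participants
missing any required trait are excluded complete-case, with the count
logged.  Diabetes is FPG ≥126 mg/dL, 2-hour OGTT glucose ≥200 mg/dL,
HbA1c ≥6.5 %, or insulin / oral antidiabetic medication; a missing lab is
non-informative for its criterion, and a participant with every criterion
missing raises an error rather than silently classifying.

## Association models

Quartile logistic models use indicator coding with Q1 reference, adjusted
for age (continuous), sex, area (single indicators) and BMI (continuous);
odds ratios carry Wald 95 % intervals and p-values (standard asymptotics; the
choice of Wald over profile likelihood is conventional in epidemiologic
reporting).  The trend test enters the quartile as a single ordinal 1–4
score; its Wald p is invariant to affine recoding.  AUC is the rank
(Mann–Whitney) statistic of the full fitted model's predicted probabilities —
covariates plus quartiles — so AUCs across weighting schemes are directly
comparable and, because the covariates dominate, tend to be nearly
identical.  Inflammation markers are modelled by OLS on the same design; CRP
is log-transformed (right-skewed), WBC stays on its raw scale.

## The interaction scan

Per SNP the model is

    logit P(MetS) = β0 + β_age Age + β_sex Sex + β_area Area
                    + β_obs OBS + β_bmi BMI + β_g G + β_gxobs G·OBS

with G the additive minor-allele dosage (alleles are re-oriented per SNP so G
counts the minor allele; an allele swap flips the signs of β_g and β_gxobs
but leaves the p-value untouched) and OBS the continuous beta-coefficient
weighted score, standardized to unit variance by default so that β_gxobs is
log-odds per allele per SD of OBS (raw-scale mode available).  H₀:
β_gxobs = 0 is tested with a 1-df Wald test; a likelihood-ratio mode is
available and agrees with Wald to within a few percent at moderate
significance.  Monomorphic SNPs are skipped with a log entry; missing
genotypes are dropped per SNP (complete-case, matching marginal scans);
separation or non-convergence yields a flagged row with an absent p-value
rather than a crash.  SNP-level multiplicity uses Benjamini–Hochberg step-up
q-values.

## Pathway enrichment

The enrichment stage reconstructs a significance-proportion-corrected GSEA
for scan output:

1. SNPs map to genes within gene ± 100 kb, **inclusive** at exactly 100,000
   bp (configurable flank); a SNP may map to several genes.  BED input is
   0-based half-open on disk and converted once at the I/O boundary.
2. Gene statistic = max −log₁₀ p over the gene's mapped SNPs.  Genes without
   any tested SNP are dropped from the ranking (they are not "selected").
   Ranking ties break lexicographically by gene id — determinism is worth
   more here than any statistical nicety.
3. Gene sets with <20 or >200 genes are excluded.  By default the filter
   counts *selected* genes, since unmapped genes cannot contribute to the
   running sum; filtering on annotated size is available via config.
4. ES is the signed maximum deviation of a weighted KS running sum:
   increments |stat|^w (w = 1 by default) normalized by the in-set total,
   decrements 1/(N − N_set).  If every in-set statistic is zero the
   increments fall back to uniform.
5. A gene is *significant* when at least one of its SNPs lies in the top 5 %
   (configurable) of all SNP p-values;
   k = (significant fraction within the set) / (significant fraction among
   all selected genes), and ES* = k·ES.  When no gene at all is significant,
   k is undefined and the pathway's p is 1.
6. SNP-label permutation: the p-values are reassigned to SNP positions B
   times (B ≥ 100 enforced, 1,000 by default) and gene statistics, ES, k and
   ES* recomputed.  Nominal p = (1 + #{ES*_perm ≥ ES*_obs})/(B + 1), so the
   smallest attainable p is 1/(B+1).  The pathway FDR follows the GSEA
   recipe on per-pathway-normalized positive ES* (pooled permuted fraction
   above the observed value over the observed fraction, clipped to [0, 1]).
   A BH FDR over the nominal pathway p-values is reported alongside
   (`fdr_bh`), since "FDR" at the pathway level is ambiguous between the two
   conventions; both columns are emitted and the permutation FDR is primary.
   Permutation-based quantities are deterministic given the config seed.

The pathway FDR is deliberately distinct from the SNP-level BH q-values of
the scan.

## The synthetic-study generator

The generator emulates a middle-aged population cohort (ages uniform 40–75,
two geographic areas, BMI ~ N(24.5, 3)) with log-normal nutrient intakes,
sex-dependent smoking, zero-inflated log-normal alcohol, and truncated-normal
physical activity; genotypes are independent binomial(2, MAF) draws with MAF
uniform on (0.05, 0.5] — Hardy–Weinberg, no linkage disequilibrium by
default, since the scan treats SNPs marginally.  Genes are non-overlapping
intervals (5–30 kb, spaced 250 kb so that ±100 kb windows of neighbours do
not overlap); configured fractions of SNPs fall inside genes (60 %), within
the 100 kb flank (25 %), and beyond it (15 %).  Pathways are gene sets
sampled uniformly; causal pathways receive their planted SNPs inside member
genes, round-robin, so several genes host effects.

Effects are planted on the **true antioxidant index**: the standardized
equal-weight OBS of the generated exposures.  Using the simplest scheme keeps
the ground truth independent of any weights fitted downstream.  Two outcome
paths exist:

- **Liability-threshold outcomes** (`generate_outcomes`): each of the five
  MetS components has a latent liability — covariate effects + OBS main
  effect + centered causal-SNP main and interaction terms + N(0, noise_sd) —
  thresholded at the empirical quantile matching its configured prevalence
  (defaults 0.34/0.31/0.56/0.21/0.19).  Continuous measurements are placed
  on the adverse side of each clinical cut-off exactly when the liability
  is, so phenotype classification round-trips the intended states exactly;
  a fraction of adverse blood-pressure/glucose cases instead carry a
  medication flag with a controlled (sub-threshold) measurement, exercising
  the medication override.  CRP is log-linear and WBC linear in the index
  (default slopes −0.10 and −0.35 per SD).
- **Direct logistic outcomes** (`generate_case_control`): MetS drawn from
  the exact per-SNP interaction model.  Calibration, coefficient-recovery
  and power studies use this path, because thresholding five liabilities
  and requiring three adverse components attenuates coefficients — only the
  direct outcome carries the planted log-odds at face value.

Planted dosage terms enter **centered** (g − ḡ): this is a pure
reparameterization absorbed by the OBS main term, so each SNP's interaction
coefficient remains exactly `interaction_beta` while the aggregate of many
planted SNPs does not inflate the marginal OBS effect.

Default study conditions: n = 2,000 participants, 900 SNPs, 240 genes, 50
pathways of 25–40 genes, one causal pathway with 10 planted SNPs at
interaction β = 0.5, OBS main effect −0.3, SNP main effects 0.1.  The SNP
density is chosen so that ~96 % of genes carry at least one tested SNP and
pathways reliably survive the 20-gene selected-size filter.  Every random
stream derives from `config.seed` plus a fixed per-stage offset, making runs
bit-reproducible end to end.

### What the synthetic studies do and do not show

The generator reproduces the *statistical structure* the pipeline assumes —
skewed exposures, correlated binary components with realistic prevalences,
HWE genotypes, effects concentrated in pathways — but not linkage
disequilibrium, population structure, assay error, FFQ measurement error, or
genuine biological pathway topology.  Passing tests therefore demonstrate
correctness and calibration of the *methods* (type-I error near nominal,
planted coefficients recovered with nominal coverage, planted pathways
ranked first with high probability, null pathway FDR conservative), not that
any particular real-cohort estimate would be reproduced.  Real-cohort odds
ratios, AUCs and specific enriched pathways depend on controlled-access data
and are out of scope.  Relatedly, the PCA scheme's leading component in
synthetic data reflects whatever correlation dominates the generated scores
(often the sex-linked smoking/alcohol axis), so its association with MetS is
weaker and more variable than the other schemes — a property of the data,
not a defect of the estimator.

## Numerical conventions and edge cases

- Logistic and OLS fits use maximum likelihood / least squares via
  statsmodels with Wald inference; non-convergence and separation raise (for
  cohort-level models) or flag the row (per-SNP scans).
- Tertile/quartile cutting rejects degenerate distributions explicitly
  (constant input; coincident outer quartile cutpoints).
- Zeros under the log transform are handled by a configurable `log(x +
  offset)`; the default offset is 0 and zeros raise, forcing an explicit
  choice.
- p-values entering BH must lie in (0, 1]; q-values are monotone by
  construction and never below their p-values.
- All writers emit TSV with `.` for missing and a `# key=value` parameter
  echo; every writer's output is accepted by its reader (round-trip
  identity, tested per format).  PLINK bed/bim/fam is read-only.

## Problem sizes used in validation

The shipped validation studies use n = 1,000–2,000 participants, up to 2,000
SNPs, and B = 200 permutations with 5–25 replicates per property — sizes at
which every claimed calibration property is measurable with comfortable
Monte-Carlo margins while a full run of the suite stays fast on a single
CPU.
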