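# Methods

## Data model

The pipeline operates on a samples × aptamers matrix of strictly
positive relative fluorescence units (RFU), a sample table (group ∈
{centenarian, offspring, control}, sex, age at blood draw, collection
year, survival follow-up years and vital status) and an aptamer table
(SomaScan-style id, UniProt accession, gene symbol). All analysis is on
natural-log RFU. The log base is irrelevant for fold changes (they are
exponentials of log-mean differences, so the base cancels) but is fixed
to ln throughout for consistency of effect sizes. Gene symbols may map
to several aptamers; signatures are counted at both aptamer and
unique-protein granularity, and protein-level deduplication happens
only in reporting and set-membership tests, never in per-aptamer
statistics.

## Sample QC

Each sample's mean Pearson correlation to all other samples (log-RFU)
is scored with a robust z (median/MAD with the 1.4826 consistency
factor); samples below −5 robust SD are removed and the criterion is
re-evaluated once. The procedure aborts if it would remove more than
10% of samples — wholesale removal indicates a data problem rather
than a few outlying arrays. The cutoff z = 5 is deliberately extreme:
clean simulated cohorts keep all samples in ≥ 95% of runs, while
samples whose aptamer values are randomly permuted (destroying the
shared abundance profile) are always caught.

## Differential analysis

Per aptamer, a nested-OLS F test compares the full model
(intercept + sex + collection year + two group indicators) with the
reduced model without the group indicators; p comes from F(2, n−5).
Collection year enters as a linear term (a categorical option exists in
the design but linear is the default: storage-time effects on aptamer
signal are approximately monotone). All aptamers are tested jointly and
adjusted with Benjamini–Hochberg; the signature is {q < 0.01}.
Constant (zero-variance) aptamers return F = 0, p = 1 rather than
erroring, so expressionless reagents flow through the pipeline.

Direction calls use the covariate-adjusted group means: an aptamer is
up (down) in centenarians only when the centenarian adjusted mean is
above (below) *both* younger groups; discordant aptamers are flagged
"mixed" and excluded from the up/down sets. Fold changes are reported
as ratios of geometric means in the control-vs-centenarian and
offspring-vs-centenarian orientations (FC > 1 ⇔ lower in
centenarians).

The offspring-vs-control contrast is the analogous adjusted two-group
t test. Its nominal p < 0.05 list feeds the delayed-aging pattern
analysis: among aptamers shared with the centenarian signature, each is
placed in a sign quadrant of (aging direction, offspring−control
direction); the off-diagonal quadrants — proteins that rise with age
but sit lower in offspring, or fall with age but sit higher — are the
delayed-aging candidates.

## Survival signatures

Follow-up is dichotomized, not modeled as time-to-event, matching the
design this pipeline implements. Centenarians: short = died with
survival < 2 years; long = survival ≥ 2 years (boundary closed on
long). Offspring/controls: short = died within ≤ 10 years (death at
exactly 10.0 → short); long = survival > 10 years; alive with
follow-up not yet past the cutoff → unlabeled and excluded. Per
aptamer, OLS of log-RFU on the long/short indicator adjusted for sex
and age at draw (plus participant type in the pooled younger groups).
Because no aptamer is expected to survive genome-wide correction at
these sample sizes, selection is at nominal p < 0.005 and the
observed/expected ratio n_selected/(m·α) quantifies the excess over
chance. The reported fold change long-vs-short is exp(adjusted
coefficient), so its sign is consistent with the effect by
construction (the raw geometric-mean ratio can disagree in sign with
the adjusted effect for weak associations).

## Cross-study concordance and meta-analysis

External studies enter as per-protein summary tables (effect sign,
p-value, sample size). On the platform intersection, BH is recomputed
for both studies within the intersection — tiers must be defined on
the compared universe, not each study's original one — and each result
is tiered: significant (q < 1% FDR), not significant (p > 0.2),
ambiguous (between). The tier cross-table, sign-concordance Fisher
test, and three derived sets (replicated = jointly significant with
equal signs; extreme-old-age = internally significant, externally flat;
immune-senescence = externally significant, internally flat) follow.
Jointly significant but sign-discordant aptamers are reported
separately, never silently merged.

The meta-analysis combines aptamers with p < 0.2 in both studies.
Each study contributes a signed z = sign(effect)·Φ⁻¹(1 − p/2) (p
clipped at 1e−300); the combination is Stouffer with weights √n and BH
within the restricted set. Weighted Stouffer is the method of choice
here because it needs only the quantities external studies actually
exchange (sign, p, n); inverse-variance fixed effects would require
standard errors that are not available.

## Enrichment and pathway projection

Over-representation is a two-sided Fisher exact test (minimum-
likelihood summation convention, hypergeometric point probabilities
with a 1+1e−7 tie tolerance) of target-set × gene-set membership over
an explicit universe — the full annotated platform protein set, not
only the tested aptamers — with BH across the collection. Set
membership is at gene-symbol level, so multiple aptamers per protein
count once.

Pathway projection scores each sample on each gene set as the mean of
the member aptamers' z-standardized log-RFU profiles; sets with fewer
than 5 platform members are dropped. Mean-of-z is simple,
deterministic, linear in the data and invariant to per-aptamer affine
rescaling; a rank-based single-sample statistic would be more robust to
single outlying aptamers but loses direct interpretability of the
group-difference direction. Pathway scores then run through exactly the
same adjusted group/survival tests as single proteins, with BH across
pathways at 5% FDR.

## Co-expression networks

Within each layer (centenarians; offspring + controls pooled), on the
most-variable aptamer subset (default 1 500, a standard economy that
drops near-constant reagents):

1. Pearson correlation of log-RFU (zero-variance aptamers get r = 0
   with a warning).
2. Unsigned soft-threshold adjacency a = |r|^β, β ∈ 1..12 chosen as the
   smallest power whose scale-free topology fit R² ≥ 0.8 (else argmax).
   Unsigned, because modules are expected to mix up- and down-regulated
   proteins.
3. Topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) +
   1 − a_ij).
4. Average-linkage hierarchical clustering of 1 − TOM with an
   **adaptive flat cut**: candidate heights are the midpoints of
   consecutive merge heights; the chosen cut maximizes the number of
   *coherent* clusters — size between min_module_size (default 20) and
   half the universe, and mean within-cluster |r| at least twice the
   matrix-wide background mean |r|. Ties break toward the lowest cut
   (conservative cores), and a refinement pass then assigns each
   unassigned aptamer to its most similar module when that mean
   similarity also clears the coherence bar. A fixed-height cut was
   rejected during development: merge heights compress toward 1 − TOM ≈
   1 and their quantiles are dominated by background merges, so no
   single fraction recovers planted blocks across seeds. The coherence
   filter is what makes a pure-noise matrix return every aptamer
   unassigned (the "null module") instead of chained pseudo-modules.
   The procedure has no random element.
5. Module eigengene: first principal component of the per-aptamer
   z-standardized member submatrix, unit variance, sign-oriented to
   correlate positively with the module mean profile. Module group
   difference: mean over members of (mean z in focal group − mean z in
   the rest), antisymmetric under swapping orientation.
6. Two-layer graph: within-layer edges where |cor(eigengenes)| > 0.8,
   cross-layer edges where membership Jaccard > 0.10; null modules are
   excluded.

Covariates are not regressed out before correlation by default (a
config flag enables residualizing sex and collection year).

## The simulator

`simulate_cohort` emulates the cohort the analysis assumes: group sizes
77/82/65 with female fractions 0.66/0.66/0.55 (exact to the nearest
sample) and ages N(105.7, 3.6²)/N(71.2, 9.3²)/N(70.6, 7.8²); a
4 785-aptamer platform with ~14% of gene symbols shared by two
aptamers; log-RFU built additively from a N(7, 1) baseline, the
centenarian log fold change, per-aptamer sex and collection-year
shifts, coherent module latent factors (shared-sign loadings), a
survival-class shift, and N(0, residual_sd_log²) noise. Planted fold
changes are drawn from shifted-exponential distributions truncated to
the configured ranges — up: (1.02, 3.33) with median ≈ 1.26, down:
(0.56, 0.97) with median ≈ 0.88, fractions 733/4785 and 695/4785 —
reproducing the skewed spectra such studies report. Survival classes
are latent per sample (short with probability 42/73 in centenarians and
22/70 in the younger groups); observed follow-up is drawn from
class-conditional uniforms straddling the 2-/10-year cutoffs, with a
small fraction of younger samples censored before the cutoff
(unlabeled). Sex and collection-year effects are planted additively so
the adjusted models are correctly specified — the pipeline's covariate
adjustment is tested under exactly the conditions it assumes.

Defaults that are calibration choices rather than reported values:
residual_sd_log = 0.25 (per-aptamer measurement variance is not
published for such data; 0.25 on the natural-log scale gives
coefficients of variation ~25%, typical of serum aptamer panels),
sex_effect_sd = 0.05, batch_effect_sd = 0.02 per year,
module_latent_sd = 0.2, survival_effect_log = 0.3.

One generative subtlety: because the short-survival prevalence differs
between centenarians and the younger groups, a planted survival effect
induces a real (≈ 0.075 log-unit) group difference. Survival-planted
aptamers are therefore *not* true nulls for the three-group contrast,
and recovery experiments that measure the empirical FDR of the
differential signature plant no survival effects.

What the simulator does not emulate: assay normalization artifacts
(hybridization controls, dilution bins), heavy-tailed or heteroskedastic
noise, age-dependent effect sizes within groups, sample relatedness
(offspring are simulated as independent), and missingness. Passing the
recovery tests therefore demonstrates correctness of the statistical
machinery under a well-specified model, not robustness to every failure
mode of real serum data.

`simulate_external_study` draws, per aptamer, a signed z centered on
attenuation·log(FC)·√n/noise_sd; attenuation = 0 yields an exact null
study. `make_fixture_gene_sets` builds GMT collections enriched for
planted-up/-down genes and module members plus random decoys, with a
contamination dial.

## Numerical choices

* BH is the standard step-up (statsmodels); input order preserved.
* Fisher two-sided uses the minimum-likelihood convention (scipy),
  which is what makes a modal observed table return p = 1 exactly.
* Hypergeometric upper tails are summed in log space (logsumexp of
  log-pmfs) to survive extreme tails.
* The batch linear-model tests compute residual sums of squares via QR
  of the shared design, one matrix product for all aptamers; the
  single-response entry points agree with statsmodels OLS to 1e−10.
* p = 0 is clipped to 1e−300 before normal inversion in the
  meta-analysis.
* Degenerate inputs (constant response, empty modules, single-level
  indicators, non-symmetric adjacency) either return the defined
  neutral result (F = 0/p = 1) or raise with the offending records
  named.

## Problem sizes

The test suite and acceptance script run the calibration experiments at
2 000 aptamers × 224 samples (20 seeds), recovery experiments at
1 000–2 000 aptamers (5 seeds), and network experiments at 200–250
aptamers (5 seeds); the pipeline's network stage restricts to the
1 500 most-variable aptamers by default. These sizes give stable
Monte-Carlo estimates (binomial 99% intervals for calibration, ±0.02
on sensitivity) while keeping a full run in minutes on one CPU.

## Known limitations

* "ANOVA type analysis" is implemented as plain OLS F tests; a
  moderated/empirical-Bayes variance estimator (limma-style) would gain
  power at these sample sizes but changes the null distribution; the
  choice is documented, not configurable.
* Survival is dichotomized; no Kaplan–Meier or Cox modeling.
* External studies are summary-level only; their raw data are never
  re-analyzed.
* Module detection's coherence factor (2× background mean |r|) is a
  structural prior, not a fitted quantity; very weakly coherent real
  modules below that bar will land in the null module.
* The exact module counts reported by any particular study depend on
  unpublished method settings and the restricted data; only the
  qualitative structure (coherent modules, a large null module,
  cross-group conservation) is reproducible and tested here.
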