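# Methods

`rarefam` reimplements, as a tested pipeline, the analysis chain used in
family-based rare-variant studies of complex autoimmune disease: an exome
variant filtering cascade over multicase pedigrees, segregation analysis of
the surviving candidates, and gene-based rare-variant case-control
association in an independent cohort, with population-stratification and
multiple-testing corrections. Individual-level data from such studies is
typically confidential, so the package carries first-class synthetic
generators that state a known ground truth for every stage.

## 1. Variant filtering cascade

Input is a multi-sample VCF of exome SNV calls with annotation fields
(consequence, control-population MAFs, chimpanzee allele, predictor scores).
Stages run in a fixed order, and a report records, for every removed record,
the first rule it failed:

1. **Quality** — carriers must have ≥ 6 supporting reads (inclusive; "a
   minimum of six reads" is read as ≥ 6); positions inside repeat-masked
   intervals are excluded; SNVs whose alternative allele equals the
   chimpanzee (ancestral) allele are excluded. An *unknown* chimpanzee
   allele passes: dropping un-annotatable sites would silently discard
   variants for a reason unrelated to their quality. Indels are excluded by
   record type.
2. **Consequence** — only stop-gain, stop-loss, essential (canonical 2-bp)
   splice-site and missense classes are kept; synonyms from common
   annotation vocabularies are normalized first, unknown terms warn-and-drop
   (configurable to error).
3. **Family sharing** — a variant survives iff *every* sequenced affected
   member of at least one family carries it. Carriage means genotype ≥ 1;
   requiring identical genotypes would be a stricter reading, and carriage
   is flagged here as the implemented interpretation.
4. **Frequency** — three OR-combined inclusion branches against the internal
   control genomes: (a) control MAF ≤ 0.5 %; (b) absent from controls; (c)
   some case is homozygous for the alternative allele while controls carry
   it only heterozygously at MAF ≤ 5 % (the "case-only-homozygous" route).
   A missing control MAF is treated as never-observed (branch b).

Linkage-region annotation (±20 Mb around supplied peaks, Z-scores carried
through as input, never computed) is pure annotation and runs last; the
retained set is invariant to stage order, which a property test verifies.

The packaged 19-variant candidate table ships as a versioned TSV
(`rarefam/data/table1_variants.tsv`). The synthetic filtering fixture plants
those 19 records — positions and population frequencies as published,
alleles and genotypes synthetic — among decoys that each violate exactly one
rule. Eight of the 19 published internal-control MAFs lie between 0.5 % and
1 %, which cannot pass branch (a); the fixture plants one case-homozygous
carrier with het-only controls for those records so that they enter through
branch (c). This is a property of the synthetic genotypes only (none are
published) and is the package's resolution of an internal inconsistency in
its source material between the stated 0.5 % cut and the printed
frequencies.

## 2. Segregation analysis

Genotyping QC first drops samples with call rate < 80 %, then variants with
call rate < 90 % among retained samples (both boundaries inclusive). For a
variant and a family, the carrier count is the number of *affected* members
with genotype ≥ 1; affected members with missing calls are removed from the
denominator rather than counted as non-carriers, which would bias carrier
fractions downward. "Affected" is configurable per analysis — the default
is SLE-only, widened to any autoimmune diagnosis (SLE, RA, MS, partial-SLE)
for families where co-segregation with related autoimmunity is the
question.

Cross-family ranking sorts by total carriers over all families, with ties
broken by overall carrier fraction (total carriers / total genotyped
affected across the summarized families) and then by genomic position —
fully deterministic. Variants with MAF strictly above 5 % in the regional
(Nordic) control panel are flagged as population polymorphisms. Predicted
deleteriousness combines a consensus flag (≥ 3 prediction algorithms calling
deleterious) with score bands [0, 0.5) possibly neutral / [0.5, 0.7]
possibly deleterious / (0.7, 1] deleterious; the predictors themselves are
inputs, never re-implemented.

## 3. Gene-based rare-variant association

For each candidate gene in a case-control cohort of dosage data: the gene
region is extended by 500 kb on both sides; markers passing post-imputation
QC (SNP rate ≥ 99 %, sample rate ≥ 95 %, info ≥ 0.7, concordance ≥ 95 %, no
frequency restriction) are restricted to *rare* variation, MAF < 1 %
(strict) computed over called alleles in the pooled sample and folded to the
minor allele; monomorphic markers carry no information and are dropped; the
survivors are greedily LD-pruned in position order so every retained pair
has r² < 0.1 (earliest position wins ties; verified against a brute-force
pairwise oracle on every run of the test suite).

Two tests are then run per gene, both adjusted for the 10 leading principal
components of the standardized genome-wide dosage matrix (deterministic SVD;
each component's sign fixed by its largest-magnitude loading):

* **Enrichment (burden) test** — logistic regression of case status on the
  per-individual sum of rare minor alleles (missing dosages contribute 0).
  The reported statistic is the burden coefficient's 1-df Wald chi-square;
  Wald is chosen because the downstream genomic-control step divides a
  chi-square statistic. Constant scores and separated fits are flagged and
  reported as p = 1.
* **SKAT** — with null model fit `y ~ 1 + PCs` and means μ̂, score vector
  S = (GW)'(y − μ̂) for weight matrix W (flat by default; Beta(a, b)-density
  MAF weights available), statistic Q = Σ w_j² S_j², and null distribution
  Σ λ_k χ²₁ with λ_k the eigenvalues of the weighted, null-projected
  genotype covariance.

### Numerical choice: evaluating the chi-square mixture

The mixture tail probability is computed by **exact characteristic-function
inversion** (Imhof's integral, evaluated by a vectorized midpoint rule whose
step is set by the aliasing period and whose truncation point follows the
envelope decay; absolute accuracy ≈ 1e-6, ~0.1–0.5 ms per call). A
four-moment match to a scaled noncentral chi-square is retained
(`liu_sf`) and used as a fallback deep in the tail. The moment match alone
was measured to be biased at the distribution *median* for the skewed
eigenvalue spectra rare markers produce (p ≈ 0.474–0.490 at the true
median); because the genomic-control factor is a median statistic, that bias
masquerades as λ ≈ 1.12–1.15 of spurious "inflation" under a homogeneous
null. Exact inversion removes it.

### Stratification correction

λ_GC is the median of the per-gene statistics (p-values converted to 1-df
chi-square quantiles) divided by the χ²₁ median (0.4549; the exact value is
used rather than the rounded 0.456). Statistics are divided by λ:
enrichment chi-squares are re-referred to χ²₁, SKAT Q values are rescaled by
1/λ and re-evaluated against the *unscaled* eigenvalue mixture — the
simplest reading of "statistic divided by λ", flagged as an interpretation.
λ is meaningful only across a reasonably large set of tested genes; the
runner accepts externally estimated λ overrides for short gene lists.

### Multiple-testing correction

The empirical correction pools the LD-pruned rare markers of all tested
genes into one table; for each gene, N draws of equally many markers are
taken without replacement, the same test with the same covariates and the
same λ correction is run, and
`Pmult = (1 + #{p_perm ≤ p_obs}) / (N + 1)` — the add-one estimator, so
Pmult ∈ [1/(N+1), 1] and a zero p-value is never reported. Draws are
independent across repetitions; one root seed drives the whole schedule, so
results are bit-reproducible. N defaults to 10,000 (tests use hundreds, a
budget-driven scale-down stated where used). GC correction precedes the
permutation, and permuted statistics are corrected identically (order not
fixed by the source material; this is the implemented choice).

## 4. Synthetic data: what is emulated and what is not

* **Pedigrees** — multi-generation families built from a founder couple,
  married-in spouses, and a configurable number of children per couple.
  Genotypes gene-drop: founders draw alleles at the configured frequencies;
  each parent transmits each copy with probability ½. Disease is logistic
  and additive in the member's total minor-allele count (baseline risk 5 %,
  odds ratio 2 per allele by default), deliberately matching the burden
  test's own model. *Planted mode* fixes the affected set and
  rejection-resamples gene drops (bounded retries) until the target
  affected-carrier count is met exactly — published tables give counts, not
  genotypes. The two packaged families have 8 affected (6 SLE + 1 RA + 1 MS;
  any autoimmune diagnosis counts) and 7 affected (SLE), matching the
  denominators of the published carrier columns.
* **Cohorts** — case-control samples at reduced scale (the emulated study
  used ~4.2k cases / ~4.3k controls; tests use 1–3k total samples). Rare
  gene markers draw ancestral MAFs log-uniform on [5 × 10⁻⁴, 0.01]
  (n ≈ 20 markers per gene, matching the published per-gene marker counts of
  19–58); a common-marker background panel (MAF 0.05–0.5) stands in for the
  genome-wide genotyping used for PCA. Stratification follows the
  Balding–Nichols model: subpopulation frequencies are Beta-distributed
  around the ancestral value with variance F·p(1−p). LD comes from
  block-haplotype copying — markers in a block share a latent uniform with
  probability 0.9 — which guarantees valid genotypes and within-block
  r² ≈ 0.8 against ≈ 0 across blocks, exactly what the pruning stage needs.
  Disease is logistic with intercept −1.0, per-subpopulation intercept
  shifts (default ±0.75 when stratified; prevalence differences are what
  make stratification confound) and an optional per-allele burden effect in
  one causal gene; sampling is retrospective until the case/control quotas
  are met.
* **Not emulated** — coalescent realism, recombination maps, sequencing
  reads, genotyping error, imputation uncertainty (info/concordance metadata
  are carried and thresholded but simulated as clean), linkage-score
  computation. A green test therefore establishes that the *statistical
  machinery* behaves as specified on data with the stated structure — not
  that the pipeline is robust to artifacts these generators do not produce.

## 5. Known limitations and degenerate-input behaviour

* Rare-variant test statistics are *discrete* at desk scale: when a gene's
  few carriers split evenly between cases and controls the burden
  coefficient is exactly 0 and p = 1, producing a small conservative atom at
  the top of the null p-value distribution (~4 % at 3,000 samples). Size at
  conventional α is unaffected (verified), but two-sided
  goodness-of-uniformity checks will eventually flag the atom.
* The asymptotic mixture null of SKAT differs from the exact permutation
  null by O(1/n) moments (mean inflated by n/(n−1), variance deflated by the
  Bernoulli residual kurtosis). At n = 60 this gap (~0.01–0.05 on the
  p-scale) dominates Monte-Carlo error; small-sample moment adjustments are
  out of scope here, and the package should not be trusted for kernel tests
  on dozens of samples.
* λ_GC estimated from a few hundred genes carries sampling noise of ±0.1 or
  more, amplified by p-value atoms near the median; the runner therefore
  accepts externally estimated λ for short gene lists.
* Pmult can fall below the observed P when the pooled null markers are so
  sparse that permuted tests are conservative; ranking by (Pmult, P) is the
  deterministic tie-break used for gene prioritization.
* Planted pedigree mode can fail (with a clear error) when a target count
  has vanishing probability under the family structure; the bounded retry
  count (50,000) makes all published counts reachable with comfortable
  margin.
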