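# Methods

## Strain distances

The unit of comparison is the dominant-strain consensus sequence of one
species in one sample, over the alphabet {A, C, G, T, N, -}. Pairwise
distances use the Jukes-Cantor (JC69) single-parameter substitution model:
with *p* the mismatch proportion over jointly resolved sites,
d = −(3/4)·ln(1 − (4/3)·p) substitutions per site. Sites where either
sequence carries a gap or an ambiguous base are removed pairwise; a pair
with zero jointly resolved sites carries no information and is omitted
(logged), rather than reported as zero. JC69 saturates at p = 3/4; saturated
pairs carry a literal `inf` sentinel, are excluded from species medians, and
can never satisfy a finite matching threshold — this keeps the matched set
monotone in θ.

Species differ widely in intrinsic strain diversity, so raw distances are
not comparable across species. Each species' distances are therefore
divided by the median of **all** of that species' finite pairwise distances
(donor-batch samples included if present — an `exclude` flag is not needed
because batch samples are off by default in the generator and excluded from
the intra/inter density split regardless). After normalisation the median
finite distance of every species is exactly 1, and the transform is
invariant to rescaling a species' raw distances. A species whose median is
zero (all compared strains identical) is flagged; its zero raw distances
map to normalised 0 so identical strains remain matchable, avoiding 0/0.

## Matching and subtraction

A donor sample matches a recipient post-treatment sample for a species when
the normalised distance is ≤ θ. The threshold is inclusive; a strictness
flag switches to `<` for sensitivity analyses. Two filters remove matches
that cannot be attributed to engraftment:

* **Baseline subtraction** — the *same donor sample* also matches the
  recipient's own baseline sample for that species at θ, so the
  donor-matching strain was present before treatment. The alternative
  reading (baseline-to-post strain persistence) is deliberately not the
  default: the filter asks whether the donor-matching strain was already in
  the recipient, not whether the recipient's baseline strain survived.
  Recipients with no baseline sample at all cannot be evaluated and are
  excluded from every downstream count (logged), not treated as negatives.
* **Placebo subtraction** — the (donor, species) strain, pooled over the
  donor's samples, also survives baseline subtraction in some placebo
  recipient; since placebo recipients received no donor material, such
  matches are ambient background. The filter operates at
  (donor subject, species) granularity and is idempotent.

Everywhere, the distinctness unit is the species: several donor samples
matching the same species in one recipient count once. Surviving matches
are classified **novel** if the species has zero relative abundance in the
recipient's baseline taxonomic profile and **replacement** otherwise;
species missing from the abundance table stay unclassified (logged).

## Pairing prediction, sweep, recall, efficiency

A recipient's predicted donor pool is every donor with at least one
surviving distinct-species match. Predictions are scored against the
reference pairings over the full universe of (donor, evaluable recipient)
pairs — evaluable meaning the recipient has both baseline and
post-treatment samples. Precision, recall and F1 use the 0/0 → 0
convention, so an empty prediction scores zero rather than being skipped.

The threshold sweep re-runs the complete pipeline (candidate calling,
baseline subtraction — whose flags are θ-dependent — optional placebo
subtraction, prediction, scoring) at every grid point, by default
0.001–3.000 in steps of 0.001. The implementation precomputes, once, every
(species, donor sample, recipient post sample) distance together with the
same donor sample's distance to the recipient's baseline, after which each
θ costs two vector comparisons; property tests assert the fast path equals
the explicit step-by-step pipeline. The optimum maximises F1 with ties
broken toward the smallest (most stringent) θ. Whether the placebo
background set is recomputed at each θ or frozen at a fixed θ is
selectable (`per_theta`, the default, or `fixed`). Pairing evaluation and
efficiency default to baseline subtraction only; placebo subtraction is a
flag.

Donor recall is tp/(tp+fn) over each donor's true recipients (donors with
none are excluded, logged). Engraftment efficiency per true pairing is
100 × (distinct species with a surviving match in the recipient) /
(distinct species with a profiled strain in ≥ 1 of the donor's samples);
donors with zero profiled strains are excluded (logged). Novel-strain
fractions of two cohorts are compared with the two-sample equal-proportions
chi-square test with Yates continuity correction (the two-sample
`prop.test` equivalent), two-sided.

## Community metrics

* **Shannon index** in nats, on species renormalised to sum 1; the
  unclassified ("UNKNOWN") fraction is excluded by default — the index
  describes the observed community — with a flag to include it as a
  pseudo-taxon.
* **Bray–Curtis** on relative abundances and **Jaccard** on
  presence/absence (> 0). On flat {0, c} profiles Bray–Curtis reduces to
  the Sørensen form symdiff/(|A|+|B|), which lower-bounds Jaccard and
  equals it exactly for identical or disjoint supports.
* ***Prevotella*/*Bacteroides* ratio** from genus-level sums; genus
  membership defaults to the name prefix before the first underscore, with
  explicit taxa lists overriding. 0/denominator → 0; positive/0 → `inf`
  sentinel; 0/0 → NaN (logged). Model-fitting stages treat non-finite
  ratios as missing (complete-case per model).
* **COG renormalisation**: each (gene, category) pair counts once, genes
  with several categories count once per category, unannotated genes fall
  into NA; counts are divided by the number of distinct genes and the
  vector renormalised to sum exactly 1 (multi-annotation makes the raw
  weights exceed 1). Zero-gene samples are omitted (logged).
* **PCoA**: Gower double-centring and eigendecomposition (via scikit-bio);
  negative eigenvalues are reported, never corrected; requesting more axes
  than positive eigenvalues truncates with a warning.
* **PERMANOVA**: one-term distance-based linear model. With hat matrix H
  from the predictor's design matrix (dummy-coded labels or a single
  centred covariate plus intercept) and G the Gower-centred inner-product
  matrix, pseudo-F = (tr(HG)/(m−1)) / (tr((I−H)G)/(n−m)) and
  R² = tr(HG)/tr(G). The permutation p-value is
  (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations) with observations
  permuted whole (no residualisation — single-term models only), seeded.
  An exhaustive mode enumerates all n! permutations for small n and is used
  as the test oracle. A 1e−12 slack on the F comparison absorbs floating
  round-off in tied permutations.

## Determinants of efficiency

The covariate table holds one row per true pairing: efficiency (percent,
untransformed), mean donor Shannon diversity, recipient baseline Shannon
diversity, mean donor-recipient Bray–Curtis and Jaccard species
dissimilarity, mean donor-recipient functional (COG) Bray–Curtis
dissimilarity, mean donor and recipient P/B ratios, and donor batch size.
Donor-level values average over the donor's samples; dissimilarities are
averaged over per-sample comparisons against the recipient baseline, never
computed on mean profiles.

Mixed models use donor and recipient identity as crossed random intercepts,
implemented as variance components over a trivial grouping in statsmodels'
MixedLM. The full model adds donor×recipient interactions for α-diversity
and P/B ratio to the reduced (no-interaction) model; the likelihood-ratio
test always compares maximum-likelihood fits (the fixed-effect structures
differ, so REML likelihoods are not comparable), with χ² degrees of freedom
equal to the difference in fixed-effect counts and p = 1 for zero
difference. Reported estimates come from REML fits by default. Confidence
intervals are Wald (the fitter does not profile) and tagged as such.
Zero-variance covariates are dropped from both models with a warning
(e.g. batch size in fixed-pool designs). The per-category difference model
regresses efficiency on mean donor-minus-recipient differences per COG
category; because differences over a full profile sum to zero, one category
(NA when present) serves as the reference to keep the design full rank.
The optimiser falls back across lbfgs → bfgs → cg → powell until a
converged fit with finite standard errors is found; a variance component
estimated at ~0 flags the fit singular but retains it.

Group comparisons: Kruskal-Wallis with Dunn's z-test on tie-corrected mean
ranks (Holm adjustment by default — the adjustment method is a flag and is
echoed in the result), one-way ANOVA with Tukey's HSD (family correction
inherent), and the exact/asymptotic Wilcoxon rank-sum test. Pearson
correlation is reported with its least-squares line and R² = r².

## Synthetic cohort generator

The generator emulates the observable structure of a multi-donor FMT trial
at the point where strain profiling has already happened; it does not
simulate reads, marker databases, assembly, or real taxonomy.

Per species, a root sequence is drawn uniformly over {A,C,G,T} and each
lineage derives from it by independent per-site substitution at rate
`d_inter` (default 0.02/site); every subject carrying the species holds one
lineage, and each sample's consensus adds fresh per-site noise at
`d_intra` (default 5e−4/site). With these defaults intra-lineage pairs land
near 0.02–0.03 after median normalisation and inter-lineage pairs near 1 —
the bimodal structure the matching threshold exploits. With probability
`p_shared_lineage` (default 0.05) a carrier reuses another carrier's
lineage, producing the ambient strain sharing that motivates placebo
subtraction; the default is calibrated so that a plausible fraction of
placebo recipients show donor-matching strains.

Cohort shape defaults: 9 donors with 2–3 donation samples each, 12 FMT and
6 placebo recipients with baseline and post samples, fixed pools of 4
donors per recipient, 36 species at 25% per-subject prevalence — giving a
mean of ~8 profiled strains per sample (range ~1–17). Carriage is truncated
below at one species per subject (a stool sample is never sterile).
Per-donor engraftment probabilities default to an even spread over 0–0.15,
including a zero-efficiency donor; engraftment assigns each (recipient,
species) at most one winning donor among the pool members whose engraftment
draws succeeded. Detection of a strain in a sample is Bernoulli with
probability logistic in log10 read depth (≈0.78 at 1M reads, ≈0.95 at 8M;
read depths log-uniform over 1–8M), or a constant/callable override.
Abundances are symmetric-Dirichlet over the subject's carried species,
scaled by a per-sample unknown fraction (uniform 0.02–0.2); the first
species carry *Prevotella* and *Bacteroides* genus labels so ratio
covariates are computable. COG annotations draw each sample's gene
categories (Poisson mean 200 genes) from a subject-level Dirichlet profile
over 23 categories, with 10% unannotated (NA) and 8% doubly annotated
genes. One global seed fans out to independent child streams (design,
lineages, assignment, engraftment, detection, abundances, annotations), so
generation is reproducible and sub-components are independently stable.

What passing tests on this generator do **not** show: robustness to
profiler error (chimeric consensus, within-sample strain mixtures), real
phylogenetic covariance between species, compositional coupling between
abundance and detection, or batch effects — the generator's detection
dropout is independent across samples and its abundances are exchangeable
given carriage.

Two regimes recur in the tests. The *paper-emulating default* keeps
background lineage sharing and the 0–15% efficiency spread; under it the
sweep-selected F1 lands around 0.6–0.8, because shared lineages put a hard
ceiling on precision — consistent with what threshold optimisation can
achieve on real trial data. The *clean recovery regime*
(`p_shared_lineage=0`, uniform donor efficiency 0.35, detection 0.9) is the
regime in which the true pools are information-theoretically recoverable;
there the pipeline attains F1 ≥ 0.9 in ≥ 18/20 seeds, precision 1 at any
gap threshold, and exact recovery of the truth event set under full
detection. The 0.35 efficiency default for this regime comes from a power
calculation: with ~9 carried species per donor and 90% per-sample
detection, per-pair recall is 1−(1−e·0.89)^k, which at e = 0.15 gives ~0.73
recall (F1 ~0.84) — too low for pool recovery regardless of implementation
— and at e = 0.35 gives ~0.95.

## Problem sizes and runtime choices

Test and acceptance runs use cohorts of ~60 samples × 36 species × 1 kb
markers (≈3–5k pairwise distances), full 3000-point sweeps, 999-permutation
PERMANOVAs (200 null replicates for calibration), and mixed-model
simulations of 60–150 pairings (20 recovery seeds, 200 null LRT
replicates). The full suite runs in about a minute on one CPU; the
acceptance script in a few seconds.

## Known limitations

* Only the JC69 model is implemented; no K80/GTR, no tree inference, and
  dominant strains only (no within-sample strain mixtures).
* PERMANOVA is single-term with raw-observation permutation; no
  multi-term, stratified or residualised designs.
* Mixed-model CIs are Wald, slightly anticonservative at few donor levels;
  the LRT relies on the asymptotic χ² distribution.
* Engraftment persistence across later timepoints and donor-batch sample
  matching are out of scope; batch samples are only ever excluded from the
  density split.
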