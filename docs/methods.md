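# Methods

## Data model

Scores live on the percent scale [0, 100], one value per (chromosome,
position) CCGG site per subject, interpreted as proportional to the
probability the site is methylated in the sampled cell population.
Site identity ignores strand (CCGG is its own reverse complement).
Coordinates are 1-based inclusive internally; BED output is 0-based
half-open. Missing sites are handled solely by intersecting to the
sites present in every subject — no imputation — and an empty
intersection is a hard error because nothing downstream is defined
without a common site set.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the sequencing process:

- **Baseline landscape.** Per-site baseline methylation is drawn from
  Beta(α=0.5, β=0.5) × 100, mimicking the bimodal mostly-on/mostly-off
  methylation landscape of real genomes. α, β are configurable.
- **Planted signal.** `n_differential` sites get their CP-group mean
  shifted by ±`effect_size` (default 20 points). The sign is
  hyper-methylated in CP with probability 3779/6588 ≈ 0.574, the
  hyper:hypo imbalance observed in the real-data analysis this
  emulates. Baselines of planted sites are rejection-sampled from the
  same Beta conditioned on the full shift fitting inside [0, 100]:
  with a bimodal baseline roughly 30% of planted sites would otherwise
  saturate at the scale boundary and carry a fraction of the nominal
  effect, which would silently change the study conditions every test
  assumes (a nominal 20-point effect would deliver ~15 on average).
  Shifts that still cannot fit (effect > 100) clip and emit a warning
  record.
- **Noise.** Per-subject scores are group mean + Gaussian noise
  (sd default 3 points), clipped to [0, 100]. The within-group
  variance of real score data is uncharacterized; sd 3 is a free
  parameter chosen once so that group differences have standard error
  ≈ 1 point at n = 16+16, a regime where a 10-point filter is
  meaningful. An optional binomial read-depth mode
  (score = 100·Bin(depth, p)/depth) adds count-quantization realism.
- **Cohort shape.** Defaults mirror the target study: 16 CP + 16
  control adolescents; a blinded cohort of 6 CP + 5 control young
  children whose planted effects are multiplied by
  `effect_attenuation` ∈ [0, 1] to model age-related signal decay
  (1 = undiminished, 0 = null). Blinded subjects carry UNKNOWN labels;
  the hidden assignment is stored separately for scoring.
- **Toy genome.** 4 chromosomes × 10 Mbp with uniform random site
  placement and non-overlapping toy genes (5–50 kb, random strand,
  5'UTR/exon/intron/CpG-island features, 2 kb promoters, six
  KEGG-style top-level categories), so 1-Mbp binning and gene/domain
  ΔML aggregation are exercised.

What the generator does **not** model: read-level HpaII digestion,
sequencing error, blood cell-type composition, age trends within a
cohort, or spatial correlation between neighboring CpGs. Passing tests
therefore demonstrate the pipeline's statistical machinery under its
own assumptions, not performance on real patient data.

## Differential testing

Each site is tested by a Gaussian LRT of group means vs a common mean.
The analysis this reimplements repurposed count-model machinery
(an edgeR/limma hybrid with tagwise dispersion) for linear methylation
scores on the grounds that the scores are normally distributed; since
the exact hybridization is unpublished, this package implements the
fully specifiable equivalent: a moderated Gaussian test with
limma-style empirical-Bayes variance shrinkage,

    s²_mod = (d0·s0² + d·s²) / (d0 + d),    d = n − 2,

with (d0, s0²) fitted by moment matching on log variances (trigamma
inversion by Newton iteration; a log-variance spread at or below the
pure sampling level yields d0 = ∞, i.e. complete pooling).

**p-values.** The moderated statistic (RSS0 − RSS1)/s²_mod has an
*exact* F(1, d0 + d) null when the variance hierarchy holds; p-values
use that finite-sample distribution by default. The χ²(1) asymptotic
on the deviance n·log(RSS0'/RSS1') is available
(`p_method="asymptotic"`) but is visibly anticonservative at n = 32
(the deviance's null mean is ~14% above 1), enough to fail a KS
uniformity check at 10,000 sites; the exact-F default is what keeps
the null calibrated, and the test suite verifies both the uniformity
and the FDR-level type-I control on null cohorts.

Other conventions: fold changes are log2(mean_CP/mean_control) with
means floored at 0.5% so volcano values stay finite; "at least 10%"
filtering is inclusive and means absolute percentage points; top-k
ranking orders by ascending p, then |difference| descending, then
(chrom, pos), making the top-200 pool reproducible; heatmap orders
come from average-linkage Euclidean hierarchical clustering of rows
and columns.

## Methylation load

ΔML over a span is Σ site deltas / site count, with delta =
control mean − CP mean (positive = control more methylated). The
hotspot rule marks a 1-Mbp bin equivalent when |ΔML| is less than
twice the genome-wide average ΔML; "average" is read as the mean of
|ΔML| over non-empty bins, because the signed mean sits near zero and
would classify almost nothing as equivalent. A bin with ΔML exactly 0
is always equivalent (covers the degenerate all-zero genome). Empty
bins carry ΔML 0 and an explicit flag. Gene spans add 2 kb upstream
of the strand-aware start, clipped to the chromosome; site-in-span
tests are inclusive on both ends; sites in overlapping genes count in
each; per-interval normalization uses the sites present in that
interval.

## NMDS

Subjects are embedded from pairwise distances on informative-site
profiles. The default metric is Euclidean on percent scores
(methylation scores are interval-scaled); Bray–Curtis is offered for
parity with ecology-style ordination tooling. Minimization is
Kruskal's rank-based stress-1 via isotonic-regression SMACOF
(scikit-learn's `smacof(metric=False, normalized_stress=True)`); the
first restart starts from classical (Torgerson) MDS for
reproducibility, remaining restarts are random, and the best final
stress wins. Convergence is |Δstress| < tol (default 1e-6) within
max_iter (default 500); non-convergence is reported, not raised.
Group ellipses are Gaussian: center = group mean, shape = group
covariance, drawn at Mahalanobis radius √χ²₂(level), level 0.90 by
default; rank-deficient covariances are flagged degenerate.

## Ensemble classifier

- **LDA regularization.** With 16 training subjects and up to 40
  sites the pooled covariance is singular. The discriminant uses
  convex shrinkage toward the diagonal, (1−λ)Σ + λ·diag(Σ), λ default
  0.5 (λ = 1 is diagonal LDA) plus a 1e-8-scale diagonal floor — the
  smallest departure from textbook LDA that is well-posed at p > n.
- **Score normalization.** Only the center point (5) of the
  normalized score is externally specified; the unit spread (class
  means at 4 and 6) is this package's declared convention so that the
  vote rule (> 5 vs < 5) is scale-free. A degenerate fit (zero
  between-class separation) scores every subject exactly 5.
- **Gates.** Pooled confusion counts across the 20 replicates (not
  the mean of per-replicate rates — robust when a replicate's
  validation class is tiny); strict inequalities (> 0.98, > 0.90).
- **Adaptive reweighting.** Every `reweight_interval` evaluations
  (default 10,000), pool sites appearing in good models more often
  than the pool median get their sampling weight multiplied by 2 and
  weights are renormalized. The intent (concentrate sampling on
  recurring sites) is externally specified; the rule and boost factor
  are this package's parameterization.
- **Voting.** Replay of the stored training-phase fits is the default
  (a refit-from-stored-splits mode exists). Scores exactly at 5
  abstain — the vote rule covers only < 5 and > 5. A tied vote
  classifies as control with a flag, conservative toward the
  no-disease class. Vote totals are always 20 × number of good
  models, abstentions included in the total.
- **Theoretical ROC.** Random subject subsets of the labelled cohort
  (size 11, matching the blinded cohort) are vote-classified with the
  stored fits; pooled (fraction, label) pairs over all bootstraps give
  the envelope curve.

## Pipeline and reproducibility

A single master seed spawns per-stage seeds through
`numpy.random.SeedSequence`, so stages are independently rerunnable
and the whole run is bit-identical for a fixed config (the test suite
checks output checksums). Every analysis constant — 10-point filter,
top 200, 15–40 panel sizes, 8+8 splits, 20 replicates, 98%/90% gates,
10,000-evaluation reweight interval, 1-Mbp bins, 2-kb promoters —
lives in the config, never in stage logic, and the manifest records
each artifact with its parameters and seed.

## Problem sizes

Defaults are desk scale, chosen as this package's own working point:
20,000 synthetic sites (the real assay interrogates ~1.5 M common
sites), a 20,000-evaluation search budget with an optional early stop
once a target number of good models is found (the original search ran
6.8 M evaluations on a 36-core server). At the default effect size the
panel search saturates almost immediately — nearly every top-200 panel
is a good model — so tests that probe the *adaptive* behaviour of the
search use a moderate-effect scenario (9-point effect, noise sd 6)
where single sites cannot separate the groups and the search must
concentrate on jointly predictive subsets.

## Known limitations

- The commercial FASTQ→score model is not reconstructed; scores are
  taken as given, and the moderated Gaussian LRT is a declared
  stand-in for the unpublished edgeR/limma hybrid, not a
  reconstruction of it.
- No covariate adjustment (age, sex, cell composition); the target
  analysis fit none.
- Functional-category aggregation requires a user-supplied gene →
  category map; there is no live KEGG/GO lookup.
- Real-data headline counts (1.47 M common sites, 61 k informative,
  6.6 k significant, 252 good models) depend on undeposited patient
  data; on synthetic cohorts the corresponding quantities are
  recomputed against known truth instead.
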