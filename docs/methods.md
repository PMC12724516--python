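# Methods

This note documents the statistical model behind `poolscreen`, the choices
made where the design was genuinely open, what the synthetic data emulate,
and the known limitations.

## Screen model and per-guide test

A pooled knockout viability screen measures, per sgRNA, sequencing counts in
control and exposed arms after an exposure spanning several population
doublings. Disruption of a gene that modulates toxicity changes the fitness
of cells carrying its guides, multiplying their expected abundance by
`2^effect`, where `effect` is the total log2 abundance change over the whole
exposure (not per doubling; the pipeline only observes endpoint counts, so
doublings are carried as metadata).

**Normalization.** Median-of-ratios size factors (the estimator used
throughout count-based sequencing models): for sample *s*,
`factor_s = median_g counts[g,s] / geomean_over_samples(counts[g,·])` over
guides with strictly positive counts in every sample, rescaled to geometric
mean 1. A `total_count` fallback exists for sparse toy data where no guide
is positive everywhere. Normalizing an already-normalized matrix returns
unit factors (idempotence, tested).

**Log2 fold change.** `log2((m_e + c)/(m_c + c))` on normalized condition
means with pseudocount `c = 1.0` by default. The pseudocount avoids infinite
values at zero counts; `c = 0` is allowed only when all means are positive.
Gene-level log2FC is the median of the gene's guide values (robust to one
bad guide; mean available by configuration).

**Mean–variance trend and tail p-values.** The per-guide test is a normal
approximation: `z = (m_e − m_c)/sqrt(v(m_c)(1/n_c + 1/n_e))`, with
`p_low = Φ(z)` (depletion) and `p_high = 1 − Φ(z)` (enrichment). The
variance function is fitted on the control replicates as the count-model
form `v(μ) = aμ + φμ²` by generalized least squares on per-guide sample
variances, with working weights `1/v²` refined over two passes, and floored
at the Poisson line `v ≥ μ`. Two estimator notes:

- With three replicates each sample variance has only two degrees of
  freedom; log-scale regressions of such variances are badly biased and
  noisy, while the two-coefficient GLS fit pools all guides and recovers
  the trend to a few percent (tested against planted Poisson and
  negative-binomial truth).
- The linear coefficient *a* absorbs real departures from unit Poisson
  scaling: depth-normalized counts from a shallow replicate have variance
  `μ/depth`, so *a* is the average inverse relative depth of the control
  arm, not exactly 1.

On null screens the resulting p-values are uniform to a Kolmogorov–Smirnov
distance of ~0.03 at 10,000 guides (tested). This test is a deliberately
closed-form stand-in for a full negative-binomial likelihood: rank
aggregation consumes only the guide ranking, which this test reproduces,
and its calibration is verified directly.

## Gene scoring: modified robust rank aggregation (α-RRA)

Guides are ranked ascending by the chosen tail p-value; ties get average
ranks; rank fractions are `r = rank/N`. For a gene with sorted rank
fractions `r₍₁₎…r₍k₎`, only ranks below `α = 0.25` are considered
informative; the score is `ρ = min_j BetaCDF(r₍ⱼ₎; j, k−j+1)` over those,
and `ρ = 1` when no rank clears α. Under a uniform null, `r₍ⱼ₎` is the j-th
order statistic of k uniforms, so each Beta CDF value is the probability of
seeing a j-th-best rank this extreme — ρ rewards genes with at least one
strongly concordant subset of guides and ignores guides in the
uninformative tail.

Significance uses an empirical null: `n_perm = 10,000` draws of k rank
fractions sampled without replacement from the screen's own rank list, with
one shared null per guide count k (O(n_perm) rather than O(G·n_perm);
standard practice since the null depends on ranks only through k). The
add-one estimator bounds p at `1/(n_perm+1)`. The Monte Carlo null matches
exhaustive enumeration on small screens (tested on all C(6,2) pairs), and
under a global-null simulation the fraction of genes with `p < 0.01` is
0.01 within a 3σ binomial band (tested).

Candidates are called on raw permutation p (`p < 0.01`, strict) together
with a gene log2FC magnitude above 0.6 in the matching direction; the sign
constraint makes sensitive/resistant labels mutually exclusive. BH-adjusted
FDRs are reported per direction but not used for calling. α is not
prescribed by the underlying screen design and 0.25 is the conventional
default; it is recorded in run metadata.

## Random-set disease enrichment

For a query (candidate) gene set of size n, each disease's observed
annotated proportion is compared with `n_random = 1,000` sets of n genes
drawn uniformly without replacement from the universe:
`z = (observed − null_mean)/null_sd`, `null_sd` being the population
(divide-by-n) standard deviation of the null proportions — the draws *are*
the empirical null, and ddof changes the result by <0.05% at n = 1000.
P-values are one-sided per direction (over: upper normal tail; under:
lower); the two directions are separate analyses, as over- and
under-representation are reported separately. Diseases whose observed
proportion does not exceed 0.001 are reported but excluded from ranking;
significant diseases (p < 0.05) are ranked by p with |z| breaking ties and
the top 15 per direction reported, along with the null draws for
histogramming.

Design choices that were genuinely open:

- **Universe.** Default `library_intersect`: annotated genes that were
  actually screened, so random sets are drawn from genes that could have
  been candidates. `annotation_universe` (all annotated genes) is offered
  for annotation-faithful replication, and an explicit universe can be
  supplied. The choice shifts null means when the annotation source covers
  many unscreened genes.
- **Sidedness.** One-sided per direction. A two-sided option exists in the
  configuration.
- **Degenerate nulls.** `null_sd = 0` with observed equal to the null mean
  (e.g. a disease annotating every gene) gives z = 0, p = 0.5; with
  observed ≠ null mean the z is flagged undefined and the disease is
  reported but unranked.

The resampled null converges on the hypergeometric closed form
(mean K/N, sd `sqrt(n(K/N)(1−K/N)(N−n)/(N−1))/n`; asserted within standard
errors at 1,000 draws), random queries produce ~5% significant one-sided
tests at the 0.05 threshold, and a 5× planted annotation-rate enrichment
(universe 5,000, query 150, base rate 2%) is detected in ≥90% of
replicates (all tested). Normal-tail p-values on a discrete proportion are
approximate when the expected annotated count in the query is small
(base rate × query size of only a few genes); the calibration test covers
the regime the defaults produce.

## Synthetic data

`simulate_screen_counts` emulates the screen design end to end: 2,000 genes
by default (study scale 18,819), two guides per gene, three replicates per
arm, 400× coverage, ~10 doublings of exposure. Guide baseline abundances
are log-normal (σ = 0.5, natural log), sample depth factors are U(0.7, 1.3)
so column sums genuinely differ and normalization is exercised, and counts
are negative binomial with dispersion 0.05 (`var = μ + 0.05μ²`,
sequencing-replicate scale). One percent of genes are planted sensitive and
one percent resistant at a total effect of ∓3 log2 units — large enough to
survive 400× counting noise, matching the strong exemplar hits a viability
screen is powered for. Guide-level heterogeneity (σ = 0.25 in log2)
perturbs the planted gene effect per guide, modeling variable knockout
efficiency; it applies only to genes whose disruption has an effect, since
a guide targeting a neutral gene has no phenotype to transmit however well
it cuts. Neutral genes therefore see pure counting noise.

`simulate_gene_disease_annotations` draws independent Bernoulli
(gene, disease) links at a 2% base rate over 200 diseases, with planted
diseases whose rate is multiplied inside a target gene set.

What the simulations do **not** model: sequencing error and FASTQ quality
profiles, multiplicity of infection and multiple integrations, copy-number
artifacts, guide off-target activity, correlated gene effects (pathway
structure), and real CTD annotation topology (hub diseases, correlated
annotations). Passing recovery tests therefore demonstrate correctness of
the scoring machinery under the stated generative model, not performance on
any particular real screen.

## Numerical and reproducibility choices

- All RNG flows through `numpy.random.Generator`; a single global seed
  derives per-stage seeds by SHA-256 hashing of the stage name, so one seed
  reproduces a whole run, and rerunning a pipeline with identical inputs
  and seed is byte-identical (tested).
- Sampling k of N ranks without replacement uses rejection on within-row
  collisions when 4k ≤ N (vectorized, exact) and per-row `choice`
  otherwise.
- Ties in ranks use average ranks; ties in report ordering break by |z| or
  |log2FC| descending with a stable sort.
- p-values are clamped to (1e-300, 1]; permutation p is bounded below by
  `1/(n_perm+1)` by construction.
- The 4PL dose-response fit is bounded least squares
  (`lower ∈ [−0.5, 1]`, `upper ∈ [0, 2]`, `hill ∈ [0.05, 20]`, ec50 within
  two decades of the dosed range); ICx follows in closed form
  `ec50·(x/(100−x))^(1/hill)`. Flat series (response span < 0.05) are
  flagged `no_inhibition` and return NaN ICx instead of an unstable fit.

## Problem sizes

Default analyses run at 2,000 genes × 2 guides, `n_perm = 10,000`,
`n_random = 1,000`; calibration checks use 200 random-query trials and
20-replicate detection experiments. These sizes give Monte-Carlo error well
inside every asserted band while keeping the full test suite and the
acceptance script in the tens of seconds on one CPU; the machinery is
vectorized and runs unchanged at the 18,819-gene study scale.

## Limitations

- The per-guide test is a normal approximation; at very low coverage
  (counts ≪ 30) its calibration degrades and a dedicated count likelihood
  would be preferable.
- Only unpaired two-arm designs are supported (no paired samples, no
  multi-condition contrasts, no copy-number correction).
- Guide counting is exact 20-mer matching (optionally scanning all
  offsets); no mismatch tolerance, adapter trimming or demultiplexing.
- Enrichment p-values are not multiplicity-adjusted by design (the
  reporting convention thresholds raw p at 0.05 and takes the top 15); an
  FDR column can be derived from the output table if needed.
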