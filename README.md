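# poolscreen

Analysis of pooled genome-wide CRISPR knockout viability screens under
chemical exposure. Given sgRNA counts for control and exposed replicate
samples, `poolscreen` normalizes across samples, ranks guides, aggregates
them to gene-level significance with the modified robust rank aggregation
(α-RRA) statistic against a permutation null, calls *sensitive* and
*resistant* candidate genes, and tests candidate gene sets for disease
over/under-representation against equally sized random gene sets drawn from
the screened universe. A synthetic-screen generator with known planted truth
makes every stage verifiable without any external data.

It is written for toxicologists and functional genomicists running
loss-of-function screens (e.g. a HepG2/C3A knockout pool exposed to a
xenobiotic at a sublethal concentration for ~10 population doublings at
~400× library coverage) who want a transparent, fully reproducible scoring
path from counts to candidate genes and disease associations.

## The statistics

**Per-guide ranking.** Counts are depth-normalized with median-of-ratios
size factors. Each guide gets a log2 fold change
`log2((mean_exposed + c) / (mean_control + c))` (pseudocount `c = 1` by
default) and two tail p-values from a normal approximation
`z = (μ̂_e − μ̂_c) / sqrt(v(μ̂_c)(1/n_c + 1/n_e))`, where `v(μ)` is a
mean–variance trend `v = aμ + φμ²` fitted to the control replicates and
floored at the Poisson line.

**Gene-level α-RRA.** Guides are ranked by tail p-value; with normalized
ranks `r₍₁₎ ≤ … ≤ r₍k₎` for a gene's k guides, the gene score is

    ρ = min over j with r₍ⱼ₎ < α of  BetaCDF(r₍ⱼ₎; j, k−j+1),   α = 0.25

i.e. the best order-statistic tail probability among the guide ranks that
fall in the informative top fraction α. Significance comes from an
empirical null of ρ built by sampling k ranks at random (10,000 draws,
shared across genes of equal k), with the add-one estimator
`p = (1 + #{ρ_null ≤ ρ}) / (n_perm + 1)`. Candidates are called with
`p < 0.01` and `log2FC < −0.6` (sensitive) or `> 0.6` (resistant).

**Random-set disease enrichment.** For a candidate set of n genes, each
disease's observed annotated proportion is compared with 1,000 random
n-gene sets from the universe: `z = (observed − null mean) / null sd` with a
one-sided normal p per direction, a 0.001 floor on the observed proportion,
significance at 0.05, and top-15 reporting per direction.

A small four-parameter log-logistic dose-response utility
(`DoseResponseModel`) estimates ICx concentrations (e.g. the IC25 used to
set screen exposure) in closed form from the fitted curve.

## Worked example

```python
from poolscreen import PooledScreenModel
from poolscreen.simulate import ScreenSimParams, simulate_screen_counts, evaluate_hit_recovery

sim = simulate_screen_counts(ScreenSimParams(seed=170))   # 2,000 genes, 2 guides/gene
res = PooledScreenModel(sim.counts, sim.design, library=sim.library).fit(
    n_perm=10_000, seed=170
)
print(res.summary())
```

```
Pooled CRISPR screen alpha-RRA results
======================================================
guides                       4000
genes                        2000
normalization          median_ratio
alpha                       0.250
permutations                10000
seed                          170
candidate thresholds   p < 0.01, |log2FC| > 0.6
sensitive genes                21
resistant genes                21

top genes by p-value:
     gene  n_guides  gene_log2fc     p_low  p_high     label
GENE01752         2       -3.413 9.999e-05       1 sensitive
GENE01483         2       -3.279 9.999e-05       1 sensitive
...
```

The simulation planted 20 sensitive and 20 resistant genes at |log2
effect| = 3; the fit calls 21 of each, and scoring against the planted
truth gives precision 0.952 and recall 1.0 in both directions:

```python
evaluate_hit_recovery(res.labels(), sim.truth)
```

The top genes sit at the permutation floor `p = 1/10001 ≈ 1e-4` with
realized log2FCs near the planted −3. Disease enrichment runs the same way
from a candidate list:

```python
from poolscreen import RandomSetEnrichment
enr = RandomSetEnrichment(query_genes, annotations, library_genes=sim.library.genes).fit(seed=170)
print(enr.summary())          # z, p per disease; top-15 per direction
```

There is also a CLI: `poolscreen simulate | count | analyze | enrich | icx
| all` (see `poolscreen --help`), driven by one YAML config and a single
global seed from which each stage's seed is derived.

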