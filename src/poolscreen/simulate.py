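"""Synthetic pooled-screen and annotation generators with known ground truth.

The screen simulator emulates a genome-wide knockout viability screen read
out by sequencing: two guides per gene, three replicates per arm, ~400x
coverage, negative-binomial counts, and multiplicative fitness effects of
gene disruption accumulated over the exposure (expressed as the total log2
change in expected exposed abundance).  The annotation simulator plants
disease terms whose annotation rate is multiplied inside a target gene set.
Recovery and calibration evaluators score the pipeline against the planted
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneDiseaseTable, GuideLibrary, SampleSheet
from .enrichment import EnrichmentConfig, resampling_z_test

_BASES = np.array(list("ACGT"))


def cells_for_coverage(n_guides: int, coverage: float) -> int:
    """Cells (or reads) needed to keep every guide represented ``coverage``-fold.

    A 40,000-guide library held at 400x needs 16,000,000 cells per sample.
    """
    if n_guides <= 0 or coverage <= 0:
        raise ValueError("n_guides and coverage must be positive")
    return int(round(n_guides * coverage))


@dataclass(frozen=True)
class ScreenSimParams:
    """Study-condition knobs of the screen simulator.

    n_genes: genes in the library (2,000 by default for desk-scale work;
        the emulated study screened 18,819).
    guides_per_gene: guides per gene (2, a minimal library).
    n_rep: replicates per arm (3 control + 3 exposed).
    coverage: expected reads (and cells) per guide, ~400x.
    doublings: population doublings over the exposure (metadata; effects are
        parameterized as totals over the screen, not per doubling).
    dispersion: negative-binomial overdispersion (var = mu + dispersion*mu^2).
    frac_sensitive / frac_resistant: fraction of genes planted with effects.
    effect_log2_per_screen: |total log2 abundance change| of planted genes.
    guide_noise_sd: per-guide log2 effect heterogeneity around the gene effect.
    baseline_sigma: natural-log SD of guide baseline abundances.
    depth_range: per-sample depth factors drawn U(lo, hi), so column sums
        differ by design and normalization is actually exercised.
    """

    n_genes: int = 2000
    guides_per_gene: int = 2
    n_rep: int = 3
    coverage: float = 400.0
    doublings: float = 10.0
    dispersion: float = 0.05
    frac_sensitive: float = 0.01
    frac_resistant: float = 0.01
    effect_log2_per_screen: float = 3.0
    guide_noise_sd: float = 0.25
    baseline_sigma: float = 0.5
    depth_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 170

    def __post_init__(self) -> None:
        if self.frac_sensitive + self.frac_resistant >= 1:
            raise ValueError("planted fractions must sum to < 1")
        for name in ("n_genes", "guides_per_gene", "n_rep", "coverage", "doublings"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimTruth:
    """Planted ground truth of a simulated screen and/or annotation table."""

    gene_effects: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    sensitive_genes: list[str] = field(default_factory=list)
    resistant_genes: list[str] = field(default_factory=list)
    planted_diseases: dict[str, dict] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "gene_effects": {g: float(e) for g, e in self.gene_effects.items() if e != 0},
            "sensitive_genes": self.sensitive_genes,
            "resistant_genes": self.resistant_genes,
            "planted_diseases": self.planted_diseases,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


class SimulatedScreen(NamedTuple):
    library: GuideLibrary
    design: SampleSheet
    counts: CountMatrix
    truth: SimTruth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with mean mu and var mu + dispersion*mu^2 (Poisson when dispersion=0)."""
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def _random_sequences(rng: np.random.Generator, n: int) -> list[str]:
    seqs: set[str] = set()
    while len(seqs) < n:
        block = rng.integers(0, 4, size=(n - len(seqs), 20))
        seqs.update("".join(_BASES[row]) for row in block)
    return sorted(seqs)[:n]  # sorted for order determinism across set hashing


def simulate_screen_counts(params: ScreenSimParams) -> SimulatedScreen:
    """Generate (library, design, counts, truth) for one simulated screen.

    Guide baseline abundances are log-normal (sigma on the natural-log
    scale); expected control count = coverage x relative abundance x sample
    depth factor; expected exposed count multiplies in 2^effect, where the
    guide effect is the planted gene effect plus Gaussian guide noise.
    Counts are negative binomial per replicate.  Deterministic given seed.
    """
    rng = np.random.default_rng(params.seed)
    G, gpg = params.n_genes, params.guides_per_gene
    n_guides = G * gpg

    genes = np.repeat([f"GENE{i:05d}" for i in range(G)], gpg)
    guide_ids = [f"GENE{i:05d}_sg{j + 1}" for i in range(G) for j in range(gpg)]
    sequences = _random_sequences(rng, n_guides)
    library = GuideLibrary(
        pd.DataFrame(
            {"gene": genes, "sequence": sequences},
            index=pd.Index(guide_ids, name="guide_id"),
        )
    )

    gene_names = [f"GENE{i:05d}" for i in range(G)]
    n_sens = int(round(params.frac_sensitive * G))
    n_res = int(round(params.frac_resistant * G))
    planted = rng.choice(G, size=n_sens + n_res, replace=False)
    effects = np.zeros(G)
    effects[planted[:n_sens]] = -params.effect_log2_per_screen
    effects[planted[n_sens:]] = +params.effect_log2_per_screen
    gene_effects = pd.Series(effects, index=gene_names, name="effect_log2")

    baseline = rng.lognormal(mean=0.0, sigma=params.baseline_sigma, size=n_guides)
    rel_abund = baseline / baseline.mean()
    # guide heterogeneity models variable knockout efficiency: it perturbs the
    # planted gene effect and is absent for neutral genes, whose guides have
    # no phenotype to transmit however well they cut
    guide_effect = np.repeat(effects, gpg)
    has_effect = guide_effect != 0
    guide_effect[has_effect] += rng.normal(
        0.0, params.guide_noise_sd, int(has_effect.sum())
    )

    sample_ids, conditions, replicates = [], [], []
    for cond in ("control", "exposed"):
        for r in range(1, params.n_rep + 1):
            sample_ids.append(f"{cond}_{r}")
            conditions.append(cond)
            replicates.append(r)
    design = SampleSheet(
        pd.DataFrame(
            {"condition": conditions, "replicate": replicates},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    depth = rng.uniform(*params.depth_range, size=len(sample_ids))
    mu_control = params.coverage * rel_abund
    mu_exposed = mu_control * np.exp2(guide_effect)
    cols = {}
    for s, cond, d in zip(sample_ids, conditions, depth):
        mu = (mu_control if cond == "control" else mu_exposed) * d
        cols[s] = _nb_draw(rng, mu, params.dispersion)
    counts = CountMatrix(
        pd.DataFrame(cols, index=library.table.index, dtype=np.int64),
        library.gene_of_guide.copy(),
    )

    truth = SimTruth(
        gene_effects=gene_effects,
        sensitive_genes=sorted(gene_effects.index[gene_effects < 0]),
        resistant_genes=sorted(gene_effects.index[gene_effects > 0]),
        params=asdict(params),
    )
    return SimulatedScreen(library, design, counts, truth)


@dataclass(frozen=True)
class AnnotationSimParams:
    """Gene-disease annotation simulator settings.

    Each (gene, disease) pair is annotated independently with probability
    base_rate, multiplied by the planted rate multiplier for genes inside a
    planted disease's target set.
    """

    n_diseases: int = 200
    base_rate: float = 0.02
    planted: tuple = ()  # (disease_id, tuple(target genes), multiplier)
    seed: int = 170

    def __post_init__(self) -> None:
        for d, _genes, mult in self.planted:
            if self.base_rate * mult > 1:
                raise ValueError(f"planted rate {self.base_rate * mult} > 1 for {d}")


def simulate_gene_disease_annotations(
    genes, params: AnnotationSimParams
) -> tuple[GeneDiseaseTable, SimTruth]:
    """Independent Bernoulli annotations with planted enriched diseases."""
    rng = np.random.default_rng(params.seed)
    universe = pd.Index([str(g).upper() for g in genes])
    disease_ids = [f"MESH:D{i:05d}" for i in range(params.n_diseases)]
    planted_map = {d: (set(t), m) for d, t, m in params.planted}
    for d, (targets, _m) in planted_map.items():
        if not targets <= set(universe):
            raise ValueError(f"planted target genes for {d} not all in the universe")

    rows = []
    for d in disease_ids:
        prob = np.full(len(universe), params.base_rate)
        if d in planted_map:
            targets, mult = planted_map[d]
            prob[universe.isin(sorted(targets))] *= mult
        hit = rng.random(len(universe)) < prob
        for g in universe[hit]:
            rows.append((g, d, f"Disease {d.split(':')[-1]}", "simulated"))
    table = GeneDiseaseTable(
        pd.DataFrame(rows, columns=["gene", "disease_id", "disease_name", "category"])
    )
    truth = SimTruth(
        planted_diseases={
            d: {"targets": sorted(t), "multiplier": m} for d, (t, m) in planted_map.items()
        },
        params=asdict(params) | {"planted": [[d, sorted(t), m] for d, (t, m) in planted_map.items()]},
    )
    return table, truth


def evaluate_hit_recovery(labels: pd.Series, truth: SimTruth) -> dict:
    """Precision / recall / F1 per direction against the planted gene sets.

    ``labels`` maps gene -> {sensitive, resistant, none}.  Genes with no
    planted effect and no call are true negatives.  Undefined precision
    (no calls) is reported as 0.0 with a flag.
    """
    out = {}
    for direction, true_set in (
        ("sensitive", set(truth.sensitive_genes)),
        ("resistant", set(truth.resistant_genes)),
    ):
        called = set(labels.index[labels == direction])
        tp = len(called & true_set)
        precision_defined = len(called) > 0
        precision = tp / len(called) if precision_defined else 0.0
        recall = tp / len(true_set) if true_set else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        out[direction] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "n_called": len(called),
            "n_true": len(true_set),
            "precision_defined": precision_defined,
        }
    return out


def evaluate_enrichment_calibration(
    annot: GeneDiseaseTable,
    universe,
    config: EnrichmentConfig,
    n_trials: int = 200,
    query_size: int = 150,
    seed: int = 170,
    exclude_diseases=(),
) -> float:
    """Empirical type-I error of the random-set test on random queries.

    Draws ``n_trials`` random candidate sets from the universe and runs the
    resampling z test on each.  Every (disease, query) pair contributes two
    one-sided tests (over- and under-representation are separate analyses);
    the return value is the fraction of those tests with p < sig_threshold.
    Planted diseases can be excluded from the tally.
    """
    if n_trials < 100:
        raise ValueError("n_trials must be >= 100")
    rng = np.random.default_rng(seed)
    universe = pd.Index([str(g).upper() for g in universe])
    excl = set(exclude_diseases)
    n_sig = n_tests = 0
    for t in range(n_trials):
        query = rng.choice(universe, size=query_size, replace=False)
        cfg = EnrichmentConfig(
            n_random=config.n_random,
            min_proportion=config.min_proportion,
            sig_threshold=config.sig_threshold,
            seed=int(rng.integers(0, 2**31 - 1)),
            universe_policy="annotation_universe",
            two_sided=config.two_sided,
        )
        res = resampling_z_test(query, annot, cfg, universe=universe)
        res = res[res["z_defined"] & ~res["disease_id"].isin(excl)]
        # at most one of the two one-sided tests can fall below a threshold
        # < 0.5, so the pair's reported min-tail p counts the significant ones
        n_sig += int((res["p"] < config.sig_threshold).sum())
        n_tests += 2 * len(res)
    return n_sig / n_tests if n_tests else float("nan")
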