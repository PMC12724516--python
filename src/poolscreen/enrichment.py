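"""Gene-disease over/under-representation by random-set resampling.

For each disease term, the proportion of a candidate (query) gene set
annotated to it is compared with the proportions seen in ``n_random`` gene
sets of the same size drawn uniformly without replacement from the universe.
The summary is an empirical z-score,

    z = (observed - null_mean) / null_sd,

with null_mean and null_sd the mean and population standard deviation of the
random-set proportions, and a one-sided normal-tail p-value per direction
(over-representation: upper tail; under: lower).  Diseases whose observed
proportion does not exceed a floor (default 0.001) are reported but excluded
from ranking, and the top 15 per direction are reported by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneDiseaseTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentConfig:
    """Parameters of the random-set test.

    n_random: number of random gene sets (>= 100; 1000 matches common use).
    min_proportion: ranking floor on the query's observed proportion.
    sig_threshold: p-value cutoff for reporting.
    seed: RNG seed; the whole null is deterministic given it.
    universe_policy: 'library_intersect' draws random sets only from
        annotated genes that were screened (the genes that could have been
        candidates); 'annotation_universe' uses every annotated gene.
    two_sided: report 2 * min(tails) instead of the one-sided p.
    """

    n_random: int = 1000
    min_proportion: float = 0.001
    sig_threshold: float = 0.05
    seed: int = 170
    universe_policy: str = "library_intersect"
    two_sided: bool = False

    def __post_init__(self) -> None:
        if self.n_random < 100:
            raise ValueError("n_random must be >= 100")
        if not (0 <= self.min_proportion < 1):
            raise ValueError("min_proportion must be in [0, 1)")
        if not (0 < self.sig_threshold < 1):
            raise ValueError("sig_threshold must be in (0, 1)")
        if self.universe_policy not in ("library_intersect", "annotation_universe"):
            raise ValueError(f"unknown universe_policy {self.universe_policy!r}")


def build_universe(
    annot: GeneDiseaseTable,
    library_genes=None,
    policy: str = "library_intersect",
) -> pd.Index:
    """Gene universe random sets are drawn from."""
    universe = annot.genes
    if policy == "library_intersect" and library_genes is not None:
        universe = universe.intersection(pd.Index([g.upper() for g in library_genes]))
    return pd.Index(sorted(universe))


def _retained_query(query, universe: pd.Index) -> list[str]:
    q = {str(g).upper() for g in query}
    if not q:
        raise ValueError("query gene set is empty")
    retained = sorted(q & set(universe))
    dropped = len(q) - len(retained)
    if dropped:
        logger.info("dropped %d query genes outside the universe", dropped)
    if not retained:
        raise ValueError("no query genes remain after intersecting with the universe")
    return retained


def observed_proportions(query, annot: GeneDiseaseTable, universe=None) -> pd.Series:
    """Per-disease fraction of the (retained) query annotated to the disease."""
    if universe is None:
        universe = annot.genes
    retained = _retained_query(query, pd.Index(universe))
    memb = annot.membership(retained)
    return memb.sum(axis=1) / len(retained)


def resampling_z_test(
    query,
    annot: GeneDiseaseTable,
    config: EnrichmentConfig = EnrichmentConfig(),
    library_genes=None,
    return_null_draws: bool = False,
    universe=None,
):
    """Run the random-set z test for every disease.

    Returns a DataFrame (disease_id, disease_name, category, observed,
    null_mean, null_sd, z, p, direction, passed_floor, z_defined), and the
    (n_random x n_disease) null proportion matrix when requested.  An
    explicit ``universe`` (which may include unannotated genes) overrides
    the configured universe policy.

    Degenerate null_sd = 0: z = 0 and p = 0.5 when observed equals the null
    mean; otherwise z is undefined and the disease is reported but unranked.
    """
    if universe is None:
        universe = build_universe(annot, library_genes, config.universe_policy)
    else:
        universe = pd.Index(sorted({str(g).upper() for g in universe}))
    retained = _retained_query(query, universe)
    n = len(retained)
    if n > len(universe):
        raise ValueError("query larger than the universe")

    memb = annot.membership(universe)          # disease x universe-gene, bool
    memb_f = memb.to_numpy(dtype=np.float32)
    observed = memb[retained].to_numpy(dtype=np.float32).sum(axis=1) / n

    rng = np.random.default_rng(config.seed)
    n_univ = len(universe)
    draws = np.zeros((config.n_random, n_univ), dtype=np.float32)
    rows = np.repeat(np.arange(config.n_random), n)
    cols = np.concatenate(
        [rng.choice(n_univ, size=n, replace=False) for _ in range(config.n_random)]
    )
    draws[rows, cols] = 1.0
    null = draws @ memb_f.T / n                # n_random x n_disease

    null_mean = null.mean(axis=0).astype(float)
    null_sd = null.std(axis=0, ddof=0).astype(float)
    obs = observed.astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - null_mean) / null_sd
    z_defined = np.isfinite(z)
    degenerate_ok = (null_sd == 0) & np.isclose(obs, null_mean)
    z = np.where(degenerate_ok, 0.0, z)
    z_defined = z_defined | degenerate_ok

    p = np.where(z > 0, stats.norm.sf(z), stats.norm.cdf(z))
    if config.two_sided:
        p = np.minimum(2 * p, 1.0)
    p = np.where(z == 0, 0.5 if not config.two_sided else 1.0, p)
    p = np.where(z_defined, p, np.nan)
    z = np.where(z_defined, z, np.nan)

    names = annot.disease_names().reindex(memb.index)
    out = pd.DataFrame(
        {
            "disease_id": memb.index,
            "disease_name": names["disease_name"].to_numpy(),
            "category": names["category"].to_numpy(),
            "n_query": n,
            "observed": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p": p,
            "direction": np.where(z > 0, "over", "under"),
            "passed_floor": obs > config.min_proportion,
            "z_defined": z_defined,
        }
    ).reset_index(drop=True)
    if return_null_draws:
        return out, pd.DataFrame(null, columns=memb.index)
    return out


def rank_and_report(
    results: pd.DataFrame,
    top_n: int = 15,
    sig_threshold: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Top significant diseases per direction.

    Keeps diseases with a defined z, passed_floor and p < sig_threshold,
    sorted by p ascending with |z| descending breaking ties; at most top_n
    per direction.  Empty tables are a valid outcome.
    """
    ok = results[results["z_defined"] & results["passed_floor"]
                 & (results["p"] < sig_threshold)]
    report = {}
    for direction in ("over", "under"):
        sub = ok[ok["direction"] == direction].copy()
        sub = (
            sub.assign(_a=-sub["z"].abs())
            .sort_values(["p", "_a"], kind="mergesort")
            .drop(columns="_a")
            .head(top_n)
            .reset_index(drop=True)
        )
        report[direction] = sub
    return report
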