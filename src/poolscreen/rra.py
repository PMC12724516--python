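"""Gene-level scoring by modified robust rank aggregation (alpha-RRA).

Guides are ranked by their tail p-value in a chosen direction; each gene's
score rho is the smallest Beta order-statistic CDF over its guide ranks that
fall below the fraction alpha, so a gene scores well when a subset of its
guides ranks near the top even if other guides are noise.  Significance comes
from an empirical null built by repeatedly assigning k guide ranks at random,
shared across all genes with the same guide count k.  Candidate genes are
then called with a raw permutation p-value and a gene-level log2FC threshold:
sensitive when p_low < 0.01 and log2FC < -0.6, resistant when p_high < 0.01
and log2FC > 0.6 (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class RRAConfig:
    """Knobs of the rank-aggregation step.

    alpha: fraction of the ranked guide list considered informative (0, 1].
    n_perm: random guide-to-gene assignments per guide-count k (>= 100).
    seed: RNG seed; every null draw is deterministic given it.
    p_threshold / lfc_threshold: candidate-calling cutoffs, strict.
    gene_lfc: summary of guide log2FCs per gene ('median' or 'mean').
    """

    alpha: float = 0.25
    n_perm: int = 10_000
    seed: int = 170
    p_threshold: float = 0.01
    lfc_threshold: float = 0.6
    gene_lfc: str = "median"

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.gene_lfc not in ("median", "mean"):
            raise ValueError("gene_lfc must be 'median' or 'mean'")


def normalized_ranks(pvalues: pd.Series) -> pd.Series:
    """Rank fractions r in (0, 1]: ascending p, average ranks on ties, r = rank/N."""
    if len(pvalues) == 0:
        raise ValueError("no guides to rank")
    r = stats.rankdata(pvalues.to_numpy(), method="average") / len(pvalues)
    return pd.Series(r, index=pvalues.index, name="rank_fraction")


def rho_score(ranks: np.ndarray, alpha: float) -> float:
    """alpha-RRA rho for one gene's sorted rank fractions.

    Only ranks below alpha contribute; rho = min_j BetaCDF(r_(j); j, k-j+1)
    over those, and 1.0 when no rank clears alpha.
    """
    r = np.asarray(ranks, dtype=float)
    if np.any(np.diff(r) < 0):
        raise ValueError("ranks must be sorted ascending")
    return float(_rho_matrix(r[None, :], alpha)[0])


def _rho_matrix(sorted_ranks: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized rho over rows of an (m, k) sorted rank-fraction matrix."""
    k = sorted_ranks.shape[1]
    j = np.arange(1, k + 1, dtype=float)
    cdf = special.betainc(j, k - j + 1.0, sorted_ranks)
    cdf = np.where(sorted_ranks < alpha, cdf, np.inf)
    rho = cdf.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def _sample_rank_rows(
    rng: np.random.Generator, all_ranks: np.ndarray, k: int, n_perm: int
) -> np.ndarray:
    """n_perm rows of k ranks sampled without replacement from all_ranks."""
    n = len(all_ranks)
    if k > n:
        raise ValueError(f"gene has {k} guides but only {n} ranks exist")
    if k == n or 4 * k > n:
        idx = np.stack([rng.choice(n, size=k, replace=False) for _ in range(n_perm)])
    else:
        # rejection sampling on within-row collisions; fast for k << n
        idx = rng.integers(0, n, size=(n_perm, k))
        while True:
            srt = np.sort(idx, axis=1)
            bad = (np.diff(srt, axis=1) == 0).any(axis=1)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), k))
    return all_ranks[idx]


def permutation_null(
    all_ranks: np.ndarray,
    guides_per_gene: int,
    alpha: float,
    n_perm: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sorted empirical null of rho for genes with k guides.

    Each draw samples k ranks without replacement from the full rank list and
    scores them; the null is shared by every gene of that guide count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = _sample_rank_rows(rng, np.asarray(all_ranks, dtype=float), guides_per_gene, n_perm)
    rows.sort(axis=1)
    return np.sort(_rho_matrix(rows, alpha))


def _empirical_p(null_sorted: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Add-one permutation p: (1 + #{null <= obs}) / (n_perm + 1)."""
    n = len(null_sorted)
    return (1.0 + np.searchsorted(null_sorted, observed, side="right")) / (n + 1.0)


def gene_scores(stats_df: pd.DataFrame, config: RRAConfig) -> pd.DataFrame:
    """Score every gene in both directions.

    ``stats_df`` is the per-guide table (gene, log2fc, p_low, p_high).  For
    each direction, guides are ranked by that tail p-value, rho is computed
    per gene, and the permutation p-value comes from the shared null for the
    gene's guide count.  Gene log2FC is the median (or mean) of its guides'
    log2FCs; BH-adjusted FDRs are reported alongside raw p-values.
    """
    if stats_df["gene"].isna().any():
        raise ValueError("every guide must be assigned to a gene")
    genes = stats_df.groupby("gene", sort=True)
    agg = genes["log2fc"].median() if config.gene_lfc == "median" else genes["log2fc"].mean()
    out = pd.DataFrame({"gene": agg.index, "n_guides": genes.size().to_numpy(),
                        "gene_log2fc": agg.to_numpy()}).set_index("gene")

    ss = np.random.SeedSequence(config.seed)
    ks = sorted(int(k) for k in out["n_guides"].unique())
    seeds = ss.spawn(2 * len(ks))
    child = {(d, k): seeds[i * len(ks) + j]
             for i, d in enumerate(("low", "high")) for j, k in enumerate(ks)}
    positions = genes.indices  # gene -> integer row positions in stats_df

    for direction, pcol in (("low", "p_low"), ("high", "p_high")):
        all_ranks = normalized_ranks(stats_df[pcol]).to_numpy()
        rho_obs = pd.Series(
            {
                g: _rho_matrix(np.sort(all_ranks[pos])[None, :], config.alpha)[0]
                for g, pos in positions.items()
            }
        ).reindex(out.index)
        pvals = pd.Series(index=out.index, dtype=float)
        for k in ks:
            null = permutation_null(
                all_ranks, int(k), config.alpha, config.n_perm,
                np.random.default_rng(child[(direction, int(k))]),
            )
            sel = out.index[out["n_guides"] == k]
            pvals[sel] = _empirical_p(null, rho_obs[sel].to_numpy())
        out[f"rho_{direction}"] = rho_obs
        out[f"p_{direction}"] = pvals
        out[f"fdr_{direction}"] = multipletests(pvals.to_numpy(), method="fdr_bh")[1]

    return out.reset_index()


def call_candidates(
    scores: pd.DataFrame,
    p_threshold: float = 0.01,
    lfc_threshold: float = 0.6,
) -> tuple[pd.DataFrame, dict]:
    """Label genes sensitive / resistant / none with strict thresholds.

    sensitive: p_low < p_threshold and gene_log2fc < -lfc_threshold;
    resistant: p_high < p_threshold and gene_log2fc > lfc_threshold.
    The log2FC sign constraint makes the labels mutually exclusive.
    """
    out = scores.copy()
    sens = (out["p_low"] < p_threshold) & (out["gene_log2fc"] < -lfc_threshold)
    resi = (out["p_high"] < p_threshold) & (out["gene_log2fc"] > lfc_threshold)
    out["label"] = np.select([sens, resi], ["sensitive", "resistant"], default="none")
    summary = {
        "n_sensitive": int(sens.sum()),
        "n_resistant": int(resi.sum()),
        "n_total": int(len(out)),
    }
    return out, summary


def sort_gene_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Order by min(p_low, p_high) ascending, then |gene_log2fc| descending."""
    key_p = scores[["p_low", "p_high"]].min(axis=1)
    return (
        scores.assign(_p=key_p, _a=-scores["gene_log2fc"].abs())
        .sort_values(["_p", "_a"], kind="mergesort")
        .drop(columns=["_p", "_a"])
        .reset_index(drop=True)
    )
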