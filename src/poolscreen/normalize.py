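"""Count normalization and per-sgRNA statistics.

Size factors equalize sequencing depth across samples (median-of-ratios by
default, as in DESeq-style count models); per-guide log2 fold changes compare
mean normalized exposed to control abundance with a pseudocount; and a
normal-approximation test over a fitted mean-variance trend supplies the two
tail p-values (depletion / enrichment) that rank aggregation consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleSheet

logger = logging.getLogger(__name__)

_P_EPS = 1e-300  # p-values clamped to (eps, 1]


@dataclass(frozen=True)
class NormalizedMatrix:
    """Depth-normalized counts: ``normalized = raw / size_factor`` columnwise."""

    normalized: pd.DataFrame   # guide x sample, non-negative real
    size_factors: pd.Series    # per sample, positive
    method: str


def compute_size_factors(counts: pd.DataFrame, method: str = "median_ratio") -> pd.Series:
    """Per-sample size factors, rescaled so their geometric mean is 1.

    ``median_ratio``: for each sample, the median over guides (with positive
    geometric mean across samples) of count / geometric-mean.  ``total_count``:
    proportional to column sums.
    """
    arr = counts.to_numpy(dtype=float)
    zero_samples = counts.columns[(arr > 0).sum(axis=0) == 0]
    if len(zero_samples):
        raise ValueError(f"sample {zero_samples[0]!r} has all-zero counts")
    if method == "median_ratio":
        pos = (arr > 0).all(axis=1)
        if not pos.any():
            raise ValueError(
                "median_ratio requires at least one guide with nonzero counts "
                "in every sample; use method='total_count' for sparse data"
            )
        loggeo = np.log(arr[pos]).mean(axis=1)
        factors = np.exp(np.median(np.log(arr[pos]) - loggeo[:, None], axis=0))
    elif method == "total_count":
        factors = arr.sum(axis=0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, method: str = "median_ratio") -> NormalizedMatrix:
    sf = compute_size_factors(counts, method)
    return NormalizedMatrix(counts / sf, sf, method)


def _condition_means(norm: pd.DataFrame, design: SampleSheet) -> tuple[pd.Series, pd.Series]:
    ctrl = design.samples_of("control")
    expo = design.samples_of("exposed")
    missing = [s for s in ctrl + expo if s not in norm.columns]
    if missing:
        raise ValueError(f"design samples absent from count matrix: {missing}")
    return norm[ctrl].mean(axis=1), norm[expo].mean(axis=1)


def sgrna_log2fc(
    norm: pd.DataFrame, design: SampleSheet, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-guide log2((mean_exposed + c) / (mean_control + c)).

    A pseudocount c = 0 is allowed only when every mean is positive.
    """
    mc, me = _condition_means(norm, design)
    if pseudocount == 0 and ((mc <= 0) | (me <= 0)).any():
        raise ValueError("pseudocount 0 requires all condition means > 0")
    lfc = np.log2(me + pseudocount) - np.log2(mc + pseudocount)
    return pd.DataFrame(
        {"mean_control": mc, "mean_exposed": me, "log2fc": lfc}
    )


def fit_mean_variance_trend(norm: pd.DataFrame, design: SampleSheet):
    """Fit v(mu), the per-replicate variance of normalized counts at mean mu.

    Per-guide sample variances from the control replicates are regressed on
    the count-model form v = a*mu + phi*mu^2 by generalized least squares,
    with working weights 1/v^2 refined over two reweighting passes.  With few
    replicates each s^2 is extremely noisy, but the two coefficients pool
    information across every guide, so the fitted trend is accurate to a few
    percent where guides are dense; the linear coefficient absorbs
    depth-driven departures from unit Poisson scaling.  The returned trend is
    floored at the Poisson line, v(mu) >= mu, so the model is never
    sub-Poisson; with fewer than two control replicates it falls back to
    Poisson with a logged warning.
    """
    ctrl = design.samples_of("control")
    if len(ctrl) < 2:
        logger.warning("fewer than 2 control replicates: using Poisson variance trend")
        return lambda mu: np.maximum(np.asarray(mu, dtype=float), 1e-8)

    sub = norm[ctrl]
    m = sub.mean(axis=1).to_numpy()
    v = sub.var(axis=1, ddof=1).to_numpy()
    ok = m > 0
    if ok.sum() < 10:
        logger.warning("too few informative guides for a variance trend; using Poisson")
        return lambda mu: np.maximum(np.asarray(mu, dtype=float), 1e-8)

    mm, vv = m[ok], v[ok]
    X = np.column_stack([mm, mm**2])
    a, phi = 1.0, 0.0
    for _ in range(3):
        w = 1.0 / (a * mm + phi * mm**2) ** 2  # ~1/Var(s^2)
        wx = X * w[:, None]
        coef = np.linalg.solve(X.T @ wx, wx.T @ vv)
        a = float(np.clip(coef[0], 0.1, None))
        phi = float(max(coef[1], 0.0))

    def trend(mu):
        mu = np.clip(np.asarray(mu, dtype=float), 1e-8, None)
        return np.maximum(a * mu + phi * mu**2, mu)

    trend.poisson_scale = a
    trend.dispersion = phi
    return trend


def sgrna_tail_pvalues(
    norm: pd.DataFrame,
    design: SampleSheet,
    gene_of_guide: pd.Series,
    trend=None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-guide statistics: means, log2fc, and depletion/enrichment p-values.

    The score is z = (mean_exposed - mean_control) / sqrt(v(mean_control) *
    (1/n_ctrl + 1/n_exp)); p_low = Phi(z) is small for depleted guides and
    p_high = 1 - Phi(z) for enriched ones.  Both are clamped to (eps, 1] and
    satisfy p_low + p_high = 1.
    """
    if trend is None:
        trend = fit_mean_variance_trend(norm, design)
    base = sgrna_log2fc(norm, design, pseudocount)
    n_c = len(design.samples_of("control"))
    n_e = len(design.samples_of("exposed"))
    se = np.sqrt(trend(base["mean_control"].to_numpy()) * (1.0 / n_c + 1.0 / n_e))
    z = (base["mean_exposed"] - base["mean_control"]).to_numpy() / se
    p_low = np.clip(stats.norm.cdf(z), _P_EPS, 1.0)
    p_high = np.clip(stats.norm.sf(z), _P_EPS, 1.0)
    out = base.copy()
    out.insert(0, "gene", gene_of_guide.reindex(out.index))
    out["score"] = z
    out["p_low"] = p_low
    out["p_high"] = p_high
    return out
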