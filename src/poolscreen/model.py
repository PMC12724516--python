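"""Model/Results facades over the screen analysis and enrichment stages.

``PooledScreenModel`` holds a count matrix plus its design and, on ``fit``,
runs normalization, the per-guide test, alpha-RRA aggregation and candidate
calling, returning a ``ScreenResults`` with the per-gene table, diagnostics
and a text ``summary()``.  ``RandomSetEnrichment`` does the same for the
random-set gene-disease test.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as pio
from .enrichment import EnrichmentConfig, rank_and_report, resampling_z_test
from .io import CountMatrix, GeneDiseaseTable, GuideLibrary, SampleSheet
from .normalize import (
    fit_mean_variance_trend,
    normalize_counts,
    sgrna_tail_pvalues,
)
from .rra import RRAConfig, call_candidates, gene_scores, sort_gene_table


class PooledScreenModel:
    """Pooled knockout screen: counts + design, ready to fit.

    Parameters
    ----------
    counts : CountMatrix
        Raw integer guide x sample counts with gene assignments.
    design : SampleSheet
        Maps samples to control/exposed arms and replicates.
    library : GuideLibrary, optional
        When given, count rows are validated against it and genes present in
        the library but absent from the counts are reported as skipped.
    normalization : 'median_ratio' (default) or 'total_count'.
    pseudocount : added to condition means inside the log2 fold change.
    """

    def __init__(
        self,
        counts: CountMatrix,
        design: SampleSheet,
        library: GuideLibrary | None = None,
        normalization: str = "median_ratio",
        pseudocount: float = 1.0,
    ):
        missing = [s for s in design.sample_ids if s not in counts.samples]
        if missing:
            raise ValueError(f"design samples missing from counts: {missing}")
        if library is not None:
            counts.check_library(library)
        self.counts = counts
        self.design = design
        self.library = library
        self.normalization = normalization
        self.pseudocount = pseudocount

    @classmethod
    def from_files(
        cls, count_table, sample_sheet, library=None, **kwargs
    ) -> "PooledScreenModel":
        lib = pio.read_guide_library(library) if library is not None else None
        return cls(
            pio.read_count_table(count_table, lib),
            pio.read_sample_sheet(sample_sheet),
            library=lib,
            **kwargs,
        )

    def fit(self, config: RRAConfig | None = None, **config_kwargs) -> "ScreenResults":
        """Normalize, test guides, aggregate to genes and call candidates."""
        if config is None:
            config = RRAConfig(**config_kwargs)
        elif config_kwargs:
            raise ValueError("pass either a config or keyword overrides, not both")

        norm = normalize_counts(self.counts.counts, self.normalization)
        trend = fit_mean_variance_trend(norm.normalized, self.design)
        stats = sgrna_tail_pvalues(
            norm.normalized,
            self.design,
            self.counts.gene_of_guide,
            trend=trend,
            pseudocount=self.pseudocount,
        )
        scores = gene_scores(stats, config)
        scores, summary = call_candidates(
            scores, config.p_threshold, config.lfc_threshold
        )
        scores = sort_gene_table(scores)

        skipped: list[str] = []
        if self.library is not None:
            counted = set(self.counts.gene_of_guide)
            skipped = sorted(g for g in self.library.genes if g not in counted)
        return ScreenResults(self, config, norm, stats, scores, summary, skipped)


class ScreenResults:
    """Fitted screen: per-guide statistics, per-gene alpha-RRA scores, calls."""

    def __init__(self, model, config, norm, sgrna_stats, gene_table, call_summary,
                 skipped_genes):
        self.model = model
        self.config = config
        self.size_factors = norm.size_factors
        self.normalized = norm.normalized
        self.sgrna_stats = sgrna_stats
        self.gene_table = gene_table
        self.call_summary = call_summary
        self.skipped_genes = skipped_genes

    @property
    def candidates(self) -> pd.DataFrame:
        return self.gene_table[self.gene_table["label"] != "none"].reset_index(drop=True)

    def labels(self) -> pd.Series:
        return self.gene_table.set_index("gene")["label"]

    def summary(self) -> str:
        s = self.call_summary
        top = self.gene_table.head(10)
        lines = [
            "Pooled CRISPR screen alpha-RRA results",
            "=" * 54,
            f"guides                 {len(self.sgrna_stats):>10d}",
            f"genes                  {s['n_total']:>10d}",
            f"normalization          {self.model.normalization:>10s}",
            f"alpha                  {self.config.alpha:>10.3f}",
            f"permutations           {self.config.n_perm:>10d}",
            f"seed                   {self.config.seed:>10d}",
            f"candidate thresholds   p < {self.config.p_threshold:g}, "
            f"|log2FC| > {self.config.lfc_threshold:g}",
            f"sensitive genes        {s['n_sensitive']:>10d}",
            f"resistant genes        {s['n_resistant']:>10d}",
            "",
            "top genes by p-value:",
            top[["gene", "n_guides", "gene_log2fc", "p_low", "p_high", "label"]]
            .to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        if self.skipped_genes:
            lines.append(f"\nskipped genes (no counted guides): {len(self.skipped_genes)}")
        return "\n".join(lines)

    def to_directory(self, outdir) -> None:
        """Write gene_summary.tsv, candidates.tsv and sgrna_summary.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        params = {
            "alpha": self.config.alpha,
            "n_perm": self.config.n_perm,
            "seed": self.config.seed,
            "normalization": self.model.normalization,
            "pseudocount": self.model.pseudocount,
        }
        pio.write_result_table(
            self.sgrna_stats.reset_index(names="guide_id"),
            outdir / "sgrna_summary.tsv", "sgrna_summary", params,
        )
        pio.write_result_table(
            self.gene_table, outdir / "gene_summary.tsv", "gene_summary", params
        )
        pio.write_result_table(
            self.candidates, outdir / "candidates.tsv", "candidates", params
        )
        if self.skipped_genes:
            pio.write_result_table(
                pd.DataFrame({"gene": self.skipped_genes}),
                outdir / "skipped_genes.tsv", "skipped_genes",
            )


class RandomSetEnrichment:
    """Random-set gene-disease over/under-representation model.

    Parameters
    ----------
    query : candidate gene symbols (e.g. the sensitive or resistant set).
    annotations : GeneDiseaseTable of curated gene-disease links.
    library_genes : screened genes; with the default universe policy the
        random sets are drawn from annotated genes that were screened.
    """

    def __init__(self, query, annotations: GeneDiseaseTable, library_genes=None):
        self.query = sorted({str(g).upper() for g in query})
        self.annotations = annotations
        self.library_genes = library_genes

    @classmethod
    def from_files(cls, query_path, annotation_path, dialect="ctd_export",
                   library=None):
        query = [
            line.strip()
            for line in open(query_path)
            if line.strip() and not line.startswith("#")
        ]
        annot = pio.read_gene_disease_table(annotation_path, dialect)
        lib = pio.read_guide_library(library).genes if library else None
        return cls(query, annot, lib)

    def fit(self, config: EnrichmentConfig | None = None, **config_kwargs):
        if config is None:
            config = EnrichmentConfig(**config_kwargs)
        elif config_kwargs:
            raise ValueError("pass either a config or keyword overrides, not both")
        table, null_draws = resampling_z_test(
            self.query, self.annotations, config, self.library_genes,
            return_null_draws=True,
        )
        return EnrichmentResults(self, config, table, null_draws)


class EnrichmentResults:
    """Per-disease observed proportion, empirical null, z, p and direction."""

    def __init__(self, model, config, table, null_draws):
        self.model = model
        self.config = config
        self.table = table
        self.null_draws = null_draws  # n_random x disease proportions

    def top(self, direction: str = "over", n: int = 15) -> pd.DataFrame:
        return rank_and_report(self.table, n, self.config.sig_threshold)[direction]

    def summary(self) -> str:
        sig = self.table[self.table["z_defined"] & self.table["passed_floor"]
                         & (self.table["p"] < self.config.sig_threshold)]
        lines = [
            "Random-set gene-disease enrichment",
            "=" * 50,
            f"query genes retained   {int(self.table['n_query'].iloc[0]) if len(self.table) else 0:>8d}",
            f"diseases tested        {len(self.table):>8d}",
            f"random sets            {self.config.n_random:>8d}",
            f"seed                   {self.config.seed:>8d}",
            f"significant (p < {self.config.sig_threshold:g})"
            f"   over: {int((sig['direction'] == 'over').sum())}"
            f"   under: {int((sig['direction'] == 'under').sum())}",
            "",
            "top over-represented diseases:",
        ]
        top = self.top("over")
        if len(top):
            lines.append(
                top[["disease_id", "disease_name", "observed", "null_mean", "z", "p"]]
                .to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        else:
            lines.append("(none)")
        return "\n".join(lines)

    def to_directory(self, outdir, histogram_diseases=()) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        params = {"n_random": self.config.n_random, "seed": self.config.seed,
                  "universe_policy": self.config.universe_policy}
        report = rank_and_report(self.table, sig_threshold=self.config.sig_threshold)
        for direction in ("over", "under"):
            pio.write_result_table(
                report[direction],
                outdir / f"disease_enrichment_{direction}.tsv",
                f"disease_enrichment_{direction}", params,
            )
        pio.write_result_table(
            self.table, outdir / "disease_enrichment_all.tsv",
            "disease_enrichment_all", params,
        )
        for d in histogram_diseases:
            if d not in self.null_draws.columns:
                raise KeyError(f"disease {d!r} not in results")
            safe = d.replace(":", "_").replace("/", "_")
            pio.write_result_table(
                pd.DataFrame({"null_proportion": self.null_draws[d]}),
                outdir / f"null_draws_{safe}.tsv", "null_draws",
                {"disease": d,
                 "observed": float(self.table.set_index("disease_id").loc[d, "observed"])},
            )
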