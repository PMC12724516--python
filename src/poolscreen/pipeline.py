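"""Configuration-driven orchestration of the full screen analysis.

One YAML config (or an in-memory :class:`RunConfig`) drives count reading or
FASTQ counting, normalization, the per-guide test, alpha-RRA scoring,
candidate calling and, optionally, disease enrichment.  A single global seed
deterministically derives a per-stage seed from the stage name, so one seed
reproduces every random draw; every threshold, seed and input checksum is
echoed into ``run_metadata.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as pio
from .enrichment import EnrichmentConfig
from .model import PooledScreenModel, RandomSetEnrichment
from .rra import RRAConfig
from .simulate import (
    AnnotationSimParams,
    ScreenSimParams,
    simulate_gene_disease_annotations,
    simulate_screen_counts,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised before any compute when the run configuration is invalid."""


@dataclass
class RunConfig:
    """Everything a run needs; unknown keys are rejected on load."""

    count_table: str | None = None
    sample_sheet: str | None = None
    guide_library: str | None = None
    fastq: dict = field(default_factory=dict)   # sample_id -> fastq path
    annotation_table: str | None = None
    annotation_dialect: str = "ctd_export"
    out_dir: str = "poolscreen_out"
    seed: int = 170
    normalization: str = "median_ratio"
    pseudocount: float = 1.0
    alpha: float = 0.25
    n_perm: int = 10_000
    p_threshold: float = 0.01
    lfc_threshold: float = 0.6
    gene_lfc: str = "median"
    run_enrichment: bool = False
    n_random: int = 1000
    min_proportion: float = 0.001
    sig_threshold: float = 0.05
    universe_policy: str = "library_intersect"
    fastq_offset: int | str = 0
    simulate: dict | None = None   # ScreenSimParams overrides for `simulate`

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.count_table is None and not self.fastq:
            raise ConfigError("config needs a count_table or fastq inputs")
        if self.fastq and self.guide_library is None:
            raise ConfigError("FASTQ counting requires a guide_library")
        if self.sample_sheet is None:
            raise ConfigError("config needs a sample_sheet")
        if self.run_enrichment and self.annotation_table is None:
            raise ConfigError("enrichment requested without an annotation_table")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived by hashing the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute count -> normalize -> test -> RRA -> call (-> enrichment).

    Returns the run metadata dict (also written to ``run_metadata.json``).
    Any stage failure raises with a stage-tagged message.
    """
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    current = stage("load")
    try:
        library = None
        if config.guide_library:
            library = pio.read_guide_library(config.guide_library)
            inputs[config.guide_library] = _sha256(config.guide_library)
        design = pio.read_sample_sheet(config.sample_sheet)
        inputs[config.sample_sheet] = _sha256(config.sample_sheet)

        if config.fastq:
            current = stage("count")
            cols, reports = [], {}
            for sample_id, path in config.fastq.items():
                cm, rep = pio.count_guides_from_fastq(
                    path, library, offset=config.fastq_offset, sample_id=sample_id
                )
                cols.append(cm.counts)
                reports[sample_id] = asdict(rep) | {
                    "mapping_rate": rep.mapping_rate,
                    "unmapped_reads": rep.unmapped_reads,
                }
                inputs[str(path)] = _sha256(path)
            counts = pio.CountMatrix(
                cols[0].join(cols[1:]) if len(cols) > 1 else cols[0],
                library.gene_of_guide.copy(),
            )
            pio.write_count_table(counts, outdir / "counts.tsv")
            with open(outdir / "counting_report.json", "w") as fh:
                json.dump(reports, fh, indent=1, sort_keys=True)
        else:
            counts = pio.read_count_table(config.count_table, library)
            inputs[config.count_table] = _sha256(config.count_table)

        current = stage("analyze")
        model = PooledScreenModel(
            counts, design, library=library,
            normalization=config.normalization, pseudocount=config.pseudocount,
        )
        rra_cfg = RRAConfig(
            alpha=config.alpha, n_perm=config.n_perm,
            seed=stage_seed(config.seed, "rra"),
            p_threshold=config.p_threshold, lfc_threshold=config.lfc_threshold,
            gene_lfc=config.gene_lfc,
        )
        results = model.fit(rra_cfg)
        results.to_directory(outdir)
        print(
            f"candidates: {results.call_summary['n_sensitive']} sensitive, "
            f"{results.call_summary['n_resistant']} resistant of "
            f"{results.call_summary['n_total']} genes"
        )

        enrich_meta = {}
        if config.run_enrichment:
            current = stage("enrich")
            annot = pio.read_gene_disease_table(
                config.annotation_table, config.annotation_dialect
            )
            inputs[config.annotation_table] = _sha256(config.annotation_table)
            for direction in ("sensitive", "resistant"):
                genes = results.gene_table.loc[
                    results.gene_table["label"] == direction, "gene"
                ]
                if len(genes) == 0:
                    logger.warning("no %s candidates; skipping enrichment", direction)
                    continue
                enr = RandomSetEnrichment(
                    genes, annot,
                    library_genes=library.genes if library else None,
                ).fit(EnrichmentConfig(
                    n_random=config.n_random,
                    min_proportion=config.min_proportion,
                    sig_threshold=config.sig_threshold,
                    seed=stage_seed(config.seed, f"enrich:{direction}"),
                    universe_policy=(
                        config.universe_policy if library else "annotation_universe"
                    ),
                ))
                enr.to_directory(outdir / f"enrichment_{direction}")
                enrich_meta[direction] = {
                    "n_significant": int(
                        (enr.table["p"] < config.sig_threshold).sum()
                    )
                }

        current = stage("metadata")
        metadata = {
            "tool": "poolscreen",
            "version": __version__,
            "config": asdict(config),
            "stage_seeds": {
                "rra": stage_seed(config.seed, "rra"),
                "enrich:sensitive": stage_seed(config.seed, "enrich:sensitive"),
                "enrich:resistant": stage_seed(config.seed, "enrich:resistant"),
            },
            "input_checksums": inputs,
            "size_factors": {k: float(v) for k, v in results.size_factors.items()},
            "candidate_summary": results.call_summary,
            "enrichment": enrich_meta,
        }
        with open(outdir / "run_metadata.json", "w") as fh:
            json.dump(metadata, fh, indent=1, sort_keys=True)
        return metadata
    except ConfigError:
        raise
    except Exception as exc:  # tag the failing stage for the operator
        raise RuntimeError(f"[stage {current}] {exc}") from exc


def run_simulation(config: RunConfig) -> dict:
    """``simulate`` stage: emit library, sample sheet, counts and truth.json."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    overrides = dict(config.simulate or {})
    ann_overrides = overrides.pop("annotations", None)
    params = ScreenSimParams(
        **({"seed": stage_seed(config.seed, "simulate")} | overrides)
    )
    sim = simulate_screen_counts(params)
    pio.write_guide_library(sim.library, outdir / "library.tsv")
    pio.write_sample_sheet(sim.design, outdir / "sample_sheet.csv")
    pio.write_count_table(sim.counts, outdir / "counts.tsv")
    truth = sim.truth
    if ann_overrides is not None:
        ann_params = AnnotationSimParams(
            **({"seed": stage_seed(config.seed, "simulate:annotations")}
               | ann_overrides)
        )
        annot, ann_truth = simulate_gene_disease_annotations(
            sim.library.genes, ann_params
        )
        pio.write_gene_disease_table(annot, outdir / "gene_disease.tsv")
        truth.planted_diseases = ann_truth.planted_diseases
    truth.to_json(outdir / "truth.json")
    return {"out_dir": str(outdir), "n_guides": sim.library.n_guides,
            "n_genes": sim.library.n_genes}
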