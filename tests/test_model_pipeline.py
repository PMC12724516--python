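"""Model facades, end-to-end pipeline runs, config validation and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from poolscreen import PooledScreenModel, RandomSetEnrichment
from poolscreen import io as pio
from poolscreen.cli import main as cli_main
from poolscreen.enrichment import EnrichmentConfig
from poolscreen.pipeline import ConfigError, RunConfig, run_pipeline, stage_seed
from poolscreen.simulate import (
    AnnotationSimParams,
    ScreenSimParams,
    simulate_gene_disease_annotations,
    simulate_screen_counts,
)


@pytest.fixture(scope="module")
def small_sim():
    return simulate_screen_counts(ScreenSimParams(n_genes=120, seed=21))


class TestScreenModel:
    def test_fit_produces_complete_gene_table(self, small_sim):
        res = PooledScreenModel(
            small_sim.counts, small_sim.design, library=small_sim.library
        ).fit(n_perm=500, seed=1)
        gt = res.gene_table
        assert len(gt) == 120
        for col in ("rho_low", "rho_high", "p_low", "p_high",
                    "fdr_low", "fdr_high", "gene_log2fc", "label"):
            assert col in gt.columns
        assert gt["p_low"].between(1 / 501, 1).all()
        assert ((gt["rho_low"] > 0) & (gt["rho_low"] <= 1)).all()

    def test_summary_reports_thresholds_and_counts(self, small_sim):
        res = PooledScreenModel(small_sim.counts, small_sim.design).fit(
            n_perm=500, seed=1
        )
        text = res.summary()
        assert "alpha" in text and "0.250" in text
        assert "sensitive genes" in text

    def test_config_and_kwargs_mutually_exclusive(self, small_sim):
        from poolscreen.rra import RRAConfig

        model = PooledScreenModel(small_sim.counts, small_sim.design)
        with pytest.raises(ValueError):
            model.fit(RRAConfig(), n_perm=500)

    def test_missing_design_sample_rejected(self, small_sim):
        bad = pio.SampleSheet(
            pd.DataFrame(
                {"condition": ["control", "exposed"], "replicate": [1, 1]},
                index=pd.Index(["nope", "exposed_1"], name="sample_id"),
            )
        )
        with pytest.raises(ValueError, match="nope"):
            PooledScreenModel(small_sim.counts, bad)

    def test_to_directory_writes_sorted_tables(self, small_sim, tmp_path):
        res = PooledScreenModel(small_sim.counts, small_sim.design).fit(
            n_perm=500, seed=1
        )
        res.to_directory(tmp_path)
        gene = pd.read_csv(tmp_path / "gene_summary.tsv", sep="\t", comment="#")
        assert len(gene) == 120
        key = gene[["p_low", "p_high"]].min(axis=1)
        assert key.is_monotonic_increasing
        cand = pd.read_csv(tmp_path / "candidates.tsv", sep="\t", comment="#")
        assert (cand["label"] != "none").all()


class TestEnrichmentModel:
    def test_fit_and_top(self):
        universe = [f"G{i:04d}" for i in range(800)]
        annot, _ = simulate_gene_disease_annotations(
            universe, AnnotationSimParams(n_diseases=30, base_rate=0.05, seed=2)
        )
        res = RandomSetEnrichment(universe[:60], annot, library_genes=universe).fit(
            n_random=200, seed=3
        )
        assert len(res.table) == 30
        assert res.null_draws.shape == (200, 30)
        assert "Random-set" in res.summary()

    def test_histogram_export(self, tmp_path):
        universe = [f"G{i:04d}" for i in range(300)]
        annot, _ = simulate_gene_disease_annotations(
            universe, AnnotationSimParams(n_diseases=5, base_rate=0.2, seed=2)
        )
        res = RandomSetEnrichment(universe[:40], annot).fit(n_random=150, seed=3)
        d = res.table["disease_id"].iloc[0]
        res.to_directory(tmp_path, histogram_diseases=[d])
        hist = pd.read_csv(
            tmp_path / f"null_draws_{d.replace(':', '_')}.tsv", sep="\t", comment="#"
        )
        assert len(hist) == 150


def _write_screen(tmp_path, sim):
    pio.write_guide_library(sim.library, tmp_path / "library.tsv")
    pio.write_count_table(sim.counts, tmp_path / "counts.tsv")
    pio.write_sample_sheet(sim.design, tmp_path / "sheet.csv")


class TestPipeline:
    def test_end_to_end_with_enrichment(self, small_sim, tmp_path, capsys):
        _write_screen(tmp_path, small_sim)
        annot, _ = simulate_gene_disease_annotations(
            small_sim.library.genes,
            AnnotationSimParams(n_diseases=15, base_rate=0.1, seed=5),
        )
        pio.write_gene_disease_table(annot, tmp_path / "gd.tsv")
        cfg = RunConfig(
            count_table=str(tmp_path / "counts.tsv"),
            sample_sheet=str(tmp_path / "sheet.csv"),
            guide_library=str(tmp_path / "library.tsv"),
            annotation_table=str(tmp_path / "gd.tsv"),
            run_enrichment=True,
            out_dir=str(tmp_path / "out"),
            n_perm=500,
            n_random=150,
            seed=99,
        )
        meta = run_pipeline(cfg)
        out = tmp_path / "out"
        for f in ("gene_summary.tsv", "candidates.tsv", "sgrna_summary.tsv",
                  "run_metadata.json"):
            assert (out / f).exists()
        assert "candidate_summary" in meta
        assert capsys.readouterr().out.startswith("candidates:")

    def test_rerun_byte_identical(self, small_sim, tmp_path):
        _write_screen(tmp_path, small_sim)
        tables = []
        for run in ("a", "b"):
            cfg = RunConfig(
                count_table=str(tmp_path / "counts.tsv"),
                sample_sheet=str(tmp_path / "sheet.csv"),
                out_dir=str(tmp_path / run),
                n_perm=500,
                seed=42,
            )
            run_pipeline(cfg)
            tables.append((tmp_path / run / "gene_summary.tsv").read_bytes())
        assert tables[0] == tables[1]

    def test_enrichment_without_annotations_fails_before_compute(self, tmp_path):
        cfg = RunConfig(
            count_table="does_not_matter.tsv",
            sample_sheet="also.csv",
            run_enrichment=True,
        )
        with pytest.raises(ConfigError, match="annotation"):
            run_pipeline(cfg)

    def test_unknown_config_keys_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump({"count_table": "x.tsv", "typo_key": 1}))
        with pytest.raises(ConfigError, match="typo_key"):
            RunConfig.from_yaml(p)

    def test_stage_seeds_distinct_deterministic_and_small(self):
        assert stage_seed(1, "rra") == stage_seed(1, "rra")
        assert stage_seed(1, "rra") != stage_seed(1, "enrich:sensitive")
        assert stage_seed(1, "rra") != stage_seed(2, "rra")
        assert 0 <= stage_seed(2**20, "simulate") < 2**31


class TestCLI:
    def test_simulate_then_analyze(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        r = runner.invoke(cli_main, [
            "simulate", "--seed", "11", "--out-dir", str(sim_dir),
            "--n-genes", "80",
        ])
        assert r.exit_code == 0, r.output
        assert (sim_dir / "truth.json").exists()

        out_dir = tmp_path / "out"
        r = runner.invoke(cli_main, [
            "analyze",
            "--counts", str(sim_dir / "counts.tsv"),
            "--sample-sheet", str(sim_dir / "sample_sheet.csv"),
            "--library", str(sim_dir / "library.tsv"),
            "--n-perm", "500", "--seed", "11", "--out-dir", str(out_dir),
        ])
        assert r.exit_code == 0, r.output
        assert (out_dir / "gene_summary.tsv").exists()
        meta = json.loads((out_dir / "run_metadata.json").read_text())
        assert meta["config"]["n_perm"] == 500

    def test_count_subcommand(self, tmp_path, tiny_library):
        pio.write_guide_library(tiny_library, tmp_path / "lib.tsv")
        g1 = tiny_library.table.loc["g1", "sequence"]
        fq = tmp_path / "s1.fastq"
        fq.write_text(f"@r0\n{g1}\n+\n{'I' * 20}\n" * 4)
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "count", "--library", str(tmp_path / "lib.tsv"),
            "--fastq", f"s1={fq}", "--out-dir", str(tmp_path / "out"),
        ])
        assert r.exit_code == 0, r.output
        counts = pio.read_count_table(tmp_path / "out" / "counts.tsv")
        assert counts.counts.loc["g1", "s1"] == 4

    def test_icx_subcommand(self):
        runner = CliRunner()
        doses = "0,10,30,100,300,1000"
        resp = ",".join(
            str(1 / (1 + d / 100)) for d in [0, 10, 30, 100, 300, 1000]
        )
        r = runner.invoke(cli_main, ["icx", "--doses", doses,
                                     "--responses", resp, "-x", "25"])
        assert r.exit_code == 0, r.output
        assert "IC25" in r.output
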