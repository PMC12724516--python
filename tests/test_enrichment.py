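"""Random-set gene-disease enrichment: proportions, z-test, ranking."""

import numpy as np
import pandas as pd
import pytest

from poolscreen.enrichment import (
    EnrichmentConfig,
    build_universe,
    observed_proportions,
    rank_and_report,
    resampling_z_test,
)
from poolscreen.simulate import (
    AnnotationSimParams,
    simulate_gene_disease_annotations,
)

from conftest import make_annotation


class TestObservedProportions:
    def test_three_of_four_query_genes(self, hypergeom_universe):
        genes, annot, query = hypergeom_universe
        props = observed_proportions(query, annot, universe=genes)
        assert props["D1"] == pytest.approx(0.75)

    def test_disease_with_no_query_gene_is_zero(self, hypergeom_universe):
        genes, annot, _ = hypergeom_universe
        annot2 = make_annotation(
            list(annot.table.itertuples(index=False)) + [("G9", "D2", "D2", "")]
        )
        props = observed_proportions(["G5", "G6"], annot2, universe=genes)
        assert props["D1"] == 0.0 and props["D2"] == 0.0

    def test_whole_universe_query_gives_annotation_rates(self, hypergeom_universe):
        genes, annot, _ = hypergeom_universe
        props = observed_proportions(genes, annot, universe=genes)
        assert props["D1"] == pytest.approx(5 / 10)

    def test_empty_retained_query_errors(self, hypergeom_universe):
        genes, annot, _ = hypergeom_universe
        with pytest.raises(ValueError):
            observed_proportions(["NOT_A_GENE"], annot, universe=genes)


class TestResamplingZTest:
    def test_hypergeometric_oracle(self, hypergeom_universe):
        """N=10, K=5, n=4, k=3: null mean 0.5, sd 0.2041, z 1.2247 (closed form)."""
        genes, annot, query = hypergeom_universe
        cfg = EnrichmentConfig(n_random=1000, seed=5)
        res = resampling_z_test(query, annot, cfg, universe=genes).iloc[0]
        N, K, n = 10, 5, 4
        sd_exact = np.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1)) / n
        se_mean = sd_exact / np.sqrt(cfg.n_random)
        se_sd = sd_exact / np.sqrt(2 * (cfg.n_random - 1))
        assert res["observed"] == pytest.approx(0.75)
        assert res["null_mean"] == pytest.approx(0.5, abs=3 * se_mean)
        assert res["null_sd"] == pytest.approx(sd_exact, abs=3 * se_sd)
        z_exact = (0.75 - 0.5) / sd_exact
        assert z_exact == pytest.approx(1.2247, abs=1e-4)
        # z inherits both errors; 3 combined standard errors
        se_z = np.sqrt((se_mean / sd_exact) ** 2 + (z_exact * se_sd / sd_exact) ** 2)
        assert res["z"] == pytest.approx(z_exact, abs=3 * se_z)
        assert res["direction"] == "over"

    def test_same_seed_byte_identical(self, hypergeom_universe):
        genes, annot, query = hypergeom_universe
        cfg = EnrichmentConfig(n_random=200, seed=9)
        a = resampling_z_test(query, annot, cfg, universe=genes)
        b = resampling_z_test(query, annot, cfg, universe=genes)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_disease_annotating_whole_universe_degenerate(self):
        genes = [f"G{i}" for i in range(8)]
        annot = make_annotation([(g, "DALL", "All", "") for g in genes])
        res = resampling_z_test(
            genes[:3], annot, EnrichmentConfig(n_random=200, seed=1), universe=genes
        ).iloc[0]
        assert res["observed"] == 1.0 and res["null_sd"] == 0.0
        assert res["z"] == 0.0 and res["p"] == 0.5
        assert res["z_defined"]

    def test_undefined_z_when_sd_zero_and_observed_differs(self):
        """A disease no random set ever hits yields an unranked undefined z."""
        genes = [f"G{i:05d}" for i in range(5000)]
        annot = make_annotation(
            [("G00000", "DRARE", "Rare", "")]
            + [(g, "DCOM", "Common", "") for g in genes]
        )
        # query holds the single annotated gene; with n=2 from N=5000 the
        # chance a random pair hits it is ~4e-4 per draw
        for seed in range(20):
            res = resampling_z_test(
                ["G00000", "G00001"], annot,
                EnrichmentConfig(n_random=100, seed=seed), universe=genes,
            ).set_index("disease_id")
            if res.loc["DRARE", "null_sd"] == 0.0:
                assert not res.loc["DRARE", "z_defined"]
                assert np.isnan(res.loc["DRARE", "z"])
                report = rank_and_report(res.reset_index())
                assert "DRARE" not in report["over"]["disease_id"].tolist()
                break
        else:
            pytest.fail("degenerate null never produced")

    def test_floor_excludes_from_ranking_but_not_report(self, hypergeom_universe):
        genes, annot, query = hypergeom_universe
        cfg = EnrichmentConfig(n_random=200, seed=3, min_proportion=0.9)
        res = resampling_z_test(query, annot, cfg, universe=genes)
        assert not res["passed_floor"].iloc[0]
        report = rank_and_report(res, sig_threshold=1.0 - 1e-12)
        assert len(report["over"]) == 0 and len(report["under"]) == 0

    def test_query_equal_to_universe_degenerates_cleanly(self, hypergeom_universe):
        """Genes outside the universe are dropped; a whole-universe query has a
        zero-variance null equal to the observed annotation rates."""
        genes, annot, _ = hypergeom_universe
        res = resampling_z_test(
            genes + ["NOT_SCREENED"], annot,
            EnrichmentConfig(n_random=100, seed=0), universe=genes,
        ).iloc[0]
        assert res["observed"] == pytest.approx(0.5)
        assert res["null_sd"] == 0.0 and res["z"] == 0.0 and res["z_defined"]


class TestUniversePolicy:
    def test_library_intersect_restricts(self, hypergeom_universe):
        genes, annot, _ = hypergeom_universe
        uni = build_universe(annot, library_genes=genes[:4], policy="library_intersect")
        assert list(uni) == sorted(genes[:4])  # annotated AND screened
        uni_all = build_universe(annot, library_genes=genes[:4],
                                 policy="annotation_universe")
        assert list(uni_all) == sorted(annot.genes)

    def test_unannotated_genes_shrink_proportions_only_via_query(
        self, hypergeom_universe
    ):
        genes, annot, query = hypergeom_universe
        small = observed_proportions(query, annot, universe=genes[:5])
        # query genes outside the smaller universe are dropped before the ratio
        assert small["D1"] == pytest.approx(1.0)
        large = observed_proportions(query, annot, universe=genes)
        assert large["D1"] == pytest.approx(0.75)


class TestRankAndReport:
    @staticmethod
    def _many_significant(n_diseases=25, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "disease_id": [f"D{i}" for i in range(n_diseases)],
                "disease_name": [f"d{i}" for i in range(n_diseases)],
                "category": "",
                "observed": 0.5,
                "null_mean": 0.1,
                "null_sd": 0.05,
                "z": rng.uniform(2.5, 8.0, n_diseases),
                "p": rng.uniform(1e-6, 0.01, n_diseases),
                "direction": "over",
                "passed_floor": True,
                "z_defined": True,
            }
        )

    def test_top_15_of_20_significant(self):
        res = self._many_significant(20)
        report = rank_and_report(res, top_n=15)
        assert len(report["over"]) == 15
        assert report["over"]["p"].is_monotonic_increasing

    def test_zero_significant_is_empty_success(self):
        res = self._many_significant(5)
        res["p"] = 0.9
        report = rank_and_report(res)
        assert len(report["over"]) == 0

    def test_p_ties_broken_by_abs_z_descending(self):
        res = self._many_significant(4)
        res["p"] = 0.001
        res["z"] = [3.0, 5.0, 4.0, 2.6]
        report = rank_and_report(res)
        assert report["over"]["z"].tolist() == [5.0, 4.0, 3.0, 2.6]


def test_power_planted_enrichment_detected():
    """A disease 5x enriched in the query is significant in >=90% of replicates."""
    universe = [f"GENE{i:05d}" for i in range(5000)]
    rng = np.random.default_rng(5)
    detected = 0
    n_rep = 20
    for rep in range(n_rep):
        query = sorted(rng.choice(universe, 150, replace=False))
        annot, _ = simulate_gene_disease_annotations(
            universe,
            AnnotationSimParams(
                n_diseases=10,
                planted=(("MESH:D00000", tuple(query), 5.0),),
                seed=100 + rep,
            ),
        )
        res = resampling_z_test(
            query, annot, EnrichmentConfig(seed=200 + rep), universe=universe
        ).set_index("disease_id").loc["MESH:D00000"]
        detected += int(res["p"] < 0.05 and res["z"] > 0 and res["passed_floor"])
    assert detected >= 0.9 * n_rep


def test_config_validation():
    with pytest.raises(ValueError):
        EnrichmentConfig(n_random=10)
    with pytest.raises(ValueError):
        EnrichmentConfig(min_proportion=1.0)
    with pytest.raises(ValueError):
        EnrichmentConfig(universe_policy="everything")
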