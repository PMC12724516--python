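import numpy as np
import pandas as pd
import pytest

from poolscreen.io import CountMatrix, GeneDiseaseTable, GuideLibrary, SampleSheet


@pytest.fixture
def tiny_library() -> GuideLibrary:
    return GuideLibrary(
        pd.DataFrame(
            {
                "gene": ["GENEA", "GENEA", "GENEB", "GENEB"],
                "sequence": [
                    "ACGTACGTACGTACGTACGT",
                    "TTTTACGTACGTACGTAAAA",
                    "GGGGACGTACGTACGTCCCC",
                    "AAAACCCCGGGGTTTTACGG",
                ],
            },
            index=pd.Index(["g1", "g2", "g3", "g4"], name="guide_id"),
        )
    )


@pytest.fixture
def six_sample_design() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "condition": ["control"] * 3 + ["exposed"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
            },
            index=pd.Index(
                ["control_1", "control_2", "control_3",
                 "exposed_1", "exposed_2", "exposed_3"],
                name="sample_id",
            ),
        )
    )


@pytest.fixture
def toy_counts(tiny_library, six_sample_design) -> CountMatrix:
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(50, 500, size=(4, 6)),
        index=tiny_library.table.index,
        columns=six_sample_design.sample_ids,
        dtype=np.int64,
    )
    return CountMatrix(counts, tiny_library.gene_of_guide.copy())


def make_annotation(rows) -> GeneDiseaseTable:
    return GeneDiseaseTable(
        pd.DataFrame(rows, columns=["gene", "disease_id", "disease_name", "category"])
    )


@pytest.fixture
def hypergeom_universe():
    """Ten-gene universe with one disease annotating half of it."""
    genes = [f"G{i}" for i in range(10)]
    annot = make_annotation([(g, "D1", "Disease one", "") for g in genes[:5]])
    query = genes[:3] + [genes[9]]  # 3 of 4 annotated
    return genes, annot, query
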