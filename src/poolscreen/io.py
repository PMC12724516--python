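"""Readers and writers for every external artifact the pipeline touches.

Guide libraries, FASTQ reads, count tables, sample sheets, gene-disease
annotation tables (CTD export dialect), and result tables.  All tables are
tab-separated UTF-8 with a mandatory header; lines starting with ``#`` are
comments.  Gene symbols are stored upper-case throughout so that library and
annotation sources that differ only in case agree.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__

logger = logging.getLogger(__name__)

GUIDE_LEN = 20
_SEQ_RE = re.compile(r"^[ACGT]{20}$")

#: Column-name aliases accepted for guide libraries (case-insensitive).
_GUIDE_ALIASES = {"guide_id", "guide", "sgrna", "sgrna_id"}
_GENE_ALIASES = {"gene", "gene_symbol", "genesymbol", "symbol"}
_SEQ_ALIASES = {"sequence", "seq", "guide_sequence"}


class TableFormatError(ValueError):
    """Raised when an input table violates its format contract."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideLibrary:
    """sgRNA -> gene map, optionally with 20-nt guide sequences.

    ``table`` is indexed by unique ``guide_id`` and has a ``gene`` column
    (upper-case symbols) and, when available, a ``sequence`` column of
    20-mers over ACGT.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise TableFormatError(f"duplicate guide_id {dup!r} in guide library")
        if "gene" not in self.table.columns:
            raise TableFormatError("guide library requires a 'gene' column")
        if "sequence" in self.table.columns:
            seqs = self.table["sequence"].dropna()
            bad = seqs[~seqs.str.match(_SEQ_RE)]
            if len(bad):
                raise TableFormatError(
                    f"guide {bad.index[0]!r}: sequence {bad.iloc[0]!r} is not a "
                    f"20-nt ACGT string"
                )
            if seqs.duplicated().any():
                d = seqs[seqs.duplicated()].iloc[0]
                raise TableFormatError(f"guide sequence {d!r} assigned to multiple guides")

    @property
    def n_guides(self) -> int:
        return len(self.table)

    @property
    def n_genes(self) -> int:
        return self.table["gene"].nunique()

    @property
    def genes(self) -> pd.Index:
        return pd.Index(sorted(self.table["gene"].unique()))

    @property
    def gene_of_guide(self) -> pd.Series:
        return self.table["gene"]

    def sequence_index(self) -> dict[str, str]:
        """Map 20-mer sequence -> guide_id (requires sequences present)."""
        if "sequence" not in self.table.columns or self.table["sequence"].isna().any():
            raise TableFormatError("guide library has no complete sequence column")
        return {s: g for g, s in self.table["sequence"].items()}


@dataclass(frozen=True)
class SampleSheet:
    """Sample -> (condition, replicate) design of the screen."""

    table: pd.DataFrame  # index sample_id; columns condition, replicate

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise TableFormatError("duplicate sample_id in sample sheet")
        bad = set(self.table["condition"]) - {"control", "exposed"}
        if bad:
            raise TableFormatError(
                f"condition must be 'control' or 'exposed', got {sorted(bad)}"
            )
        for cond in ("control", "exposed"):
            if not (self.table["condition"] == cond).any():
                raise TableFormatError(f"sample sheet has no {cond} sample")
        if (self.table["replicate"].astype(int) <= 0).any():
            raise TableFormatError("replicate numbers must be positive integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_of(self, condition: str) -> list[str]:
        return list(self.table.index[self.table["condition"] == condition])


@dataclass(frozen=True)
class CountMatrix:
    """Raw integer sgRNA x sample counts with the guide -> gene assignment."""

    counts: pd.DataFrame      # index guide_id, columns sample ids, int
    gene_of_guide: pd.Series  # index guide_id, values gene symbols

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise TableFormatError(f"duplicated guide row {dup!r} in count matrix")
        arr = self.counts.to_numpy()
        if not np.isfinite(arr).all():
            raise TableFormatError("counts must be finite")
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere((arr < 0) | (arr != np.round(arr)))[0]
            raise TableFormatError(
                f"count at guide {self.counts.index[g]!r}, sample "
                f"{self.counts.columns[s]!r} is {arr[g, s]!r}: counts must be "
                f"non-negative integers"
            )
        if not self.gene_of_guide.index.equals(self.counts.index):
            raise TableFormatError("gene_of_guide index must match count rows")

    @property
    def guide_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def check_library(self, library: GuideLibrary) -> None:
        missing = self.counts.index.difference(library.table.index)
        if len(missing):
            raise TableFormatError(
                f"{len(missing)} count-table guides absent from the library "
                f"(first: {missing[0]!r})"
            )


@dataclass(frozen=True)
class GeneDiseaseTable:
    """De-duplicated (gene, disease) association pairs with a derivable universe."""

    table: pd.DataFrame  # columns gene, disease_id, disease_name, category

    @property
    def genes(self) -> pd.Index:
        return pd.Index(sorted(self.table["gene"].unique()))

    @property
    def diseases(self) -> pd.Index:
        return pd.Index(sorted(self.table["disease_id"].unique()))

    def disease_names(self) -> pd.Series:
        """First-seen name/category per disease_id."""
        return self.table.drop_duplicates("disease_id").set_index("disease_id")[
            ["disease_name", "category"]
        ]

    def membership(self, universe: Sequence[str]) -> pd.DataFrame:
        """Boolean disease x gene matrix over ``universe`` (genes as columns)."""
        universe = pd.Index(universe)
        sub = self.table[self.table["gene"].isin(universe)]
        mat = pd.DataFrame(
            False, index=self.diseases, columns=universe, dtype=bool
        )
        if len(sub):
            mat.values[
                mat.index.get_indexer(sub["disease_id"]),
                mat.columns.get_indexer(sub["gene"]),
            ] = True
        return mat


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", dtype=str, skip_blank_lines=True)


def _resolve_column(columns: Iterable[str], aliases: set[str], what: str) -> str:
    for c in columns:
        if c.strip().lower() in aliases:
            return c
    raise TableFormatError(
        f"no {what} column found; expected one of {sorted(aliases)}, got {list(columns)}"
    )


def read_guide_library(path, fmt: str | None = None) -> GuideLibrary:
    """Read a guide library table (csv or tsv; inferred from the extension).

    Requires a header with at least a guide-id and a gene column; a sequence
    column is optional.  Reports the parsed guide and gene counts.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".txt"} else "csv"
    df = _read_table(path, "\t" if fmt == "tsv" else ",")
    gcol = _resolve_column(df.columns, _GUIDE_ALIASES, "guide id")
    genecol = _resolve_column(df.columns, _GENE_ALIASES, "gene")
    out = pd.DataFrame({"guide_id": df[gcol].astype(str).str.strip()})
    out["gene"] = df[genecol].astype(str).str.strip().str.upper()
    for c in df.columns:
        if c.strip().lower() in _SEQ_ALIASES:
            out["sequence"] = df[c].astype(str).str.strip().str.upper()
            break
    lib = GuideLibrary(out.set_index("guide_id"))
    logger.info("guide library %s: %d guides, %d genes", path.name, lib.n_guides, lib.n_genes)
    return lib


def write_guide_library(library: GuideLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line("guide_library"))
        library.table.reset_index().to_csv(fh, sep="\t", index=False)


def read_sample_sheet(path) -> SampleSheet:
    """Read a ``sample_id,condition,replicate`` CSV sample sheet."""
    df = _read_table(path, ",")
    need = {"sample_id", "condition", "replicate"}
    if not need <= {c.strip().lower() for c in df.columns}:
        raise TableFormatError(f"sample sheet must have columns {sorted(need)}")
    df.columns = [c.strip().lower() for c in df.columns]
    df["replicate"] = df["replicate"].astype(int)
    df["condition"] = df["condition"].str.strip().str.lower()
    return SampleSheet(df.set_index("sample_id")[["condition", "replicate"]])


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.reset_index().to_csv(path, index=False)


def read_count_table(path, library: GuideLibrary | None = None) -> CountMatrix:
    """Read a MAGeCK-count-layout TSV: ``sgRNA  gene  <sample1> ...``."""
    df = _read_table(path, "\t")
    if df.shape[1] < 3:
        raise TableFormatError(
            "count table needs at least guide, gene and one sample column"
        )
    gcol, genecol = df.columns[0], df.columns[1]
    samples = list(df.columns[2:])
    counts = pd.DataFrame(
        index=pd.Index(df[gcol].astype(str), name="guide_id"), dtype=int
    )
    for s in samples:
        vals = pd.to_numeric(df[s], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise TableFormatError(
                f"count at guide {df[gcol].iloc[i]!r}, sample {s!r} is "
                f"{df[s].iloc[i]!r}: counts must be non-negative integers"
            )
        counts[s] = vals.astype(np.int64).to_numpy()
    gene = pd.Series(
        df[genecol].astype(str).str.strip().str.upper().to_numpy(), index=counts.index,
        name="gene",
    )
    cm = CountMatrix(counts, gene)
    if library is not None:
        cm.check_library(library)
    return cm


def write_count_table(cm: CountMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line("count_table"))
        out = cm.counts.copy()
        out.insert(0, "gene", cm.gene_of_guide)
        out.index.name = "sgRNA"
        out.reset_index().to_csv(fh, sep="\t", index=False)


def read_gene_disease_table(path, dialect: str = "ctd_export") -> GeneDiseaseTable:
    """Read gene-disease associations.

    ``ctd_export``: tab-separated with at least GeneSymbol, DiseaseName and
    DiseaseID columns (extra columns such as DirectEvidence are ignored).
    ``two_column``: header ``gene<TAB>disease_id``.
    (gene, disease_id) pairs are de-duplicated; gene case is normalized upper.
    """
    df = _read_table(path, "\t")
    lower = {c.strip().lower(): c for c in df.columns}
    if dialect == "ctd_export":
        need = ["genesymbol", "diseasename", "diseaseid"]
        if not all(k in lower for k in need):
            raise TableFormatError(
                "CTD export requires columns GeneSymbol, DiseaseName, DiseaseID; "
                f"got {list(df.columns)}"
            )
        out = pd.DataFrame(
            {
                "gene": df[lower["genesymbol"]].astype(str).str.strip().str.upper(),
                "disease_id": df[lower["diseaseid"]].astype(str).str.strip(),
                "disease_name": df[lower["diseasename"]].astype(str).str.strip(),
            }
        )
        out["category"] = (
            df[lower["diseasecategories"]].astype(str)
            if "diseasecategories" in lower
            else ""
        )
    elif dialect == "two_column":
        if not ({"gene", "disease_id"} <= set(lower)):
            raise TableFormatError(
                "two_column dialect requires header 'gene<TAB>disease_id'; "
                f"got {list(df.columns)}"
            )
        out = pd.DataFrame(
            {
                "gene": df[lower["gene"]].astype(str).str.strip().str.upper(),
                "disease_id": df[lower["disease_id"]].astype(str).str.strip(),
            }
        )
        out["disease_name"] = out["disease_id"]
        out["category"] = ""
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out = out.drop_duplicates(["gene", "disease_id"]).reset_index(drop=True)
    return GeneDiseaseTable(out)


def write_gene_disease_table(annot: GeneDiseaseTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line("gene_disease_table"))
        annot.table.rename(
            columns={
                "gene": "GeneSymbol",
                "disease_name": "DiseaseName",
                "disease_id": "DiseaseID",
                "category": "DiseaseCategories",
            }
        ).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ guide counting
# ---------------------------------------------------------------------------

@dataclass
class CountingReport:
    total_reads: int = 0
    mapped_reads: int = 0
    ambiguous_reads: int = 0

    @property
    def unmapped_reads(self) -> int:
        return self.total_reads - self.mapped_reads - self.ambiguous_reads

    @property
    def mapping_rate(self) -> float:
        return self.mapped_reads / self.total_reads if self.total_reads else 0.0


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_guides_from_fastq(
    reads,
    library: GuideLibrary,
    offset: int | str = 0,
    sample_id: str = "sample",
) -> tuple[CountMatrix, CountingReport]:
    """Count exact 20-mer guide matches in FASTQ reads.

    ``reads`` is a path (plain or ``.gz``), an open handle, or a list of
    either.  With an integer ``offset`` the 20-mer at that position is looked
    up; with ``offset="scan"`` every read position is searched and the first
    exact hit is used.  A read matching 20-mers of two different guides is
    counted as ambiguous and excluded so no read is ever double-counted.
    Each read contributes at most one count; column counts + ambiguous +
    unmapped always sum to the total read number.
    """
    seq_to_guide = library.sequence_index()
    counts = {g: 0 for g in library.table.index}
    report = CountingReport()
    scan = offset == "scan"
    if not scan:
        offset = int(offset)

    sources = reads if isinstance(reads, (list, tuple)) else [reads]
    for src in sources:
        handle = _open_maybe_gzip(src) if isinstance(src, (str, Path)) else src
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                report.total_reads += 1
                seq = str(rec.seq).upper()
                if scan:
                    hits = {
                        seq_to_guide[seq[i : i + GUIDE_LEN]]
                        for i in range(len(seq) - GUIDE_LEN + 1)
                        if seq[i : i + GUIDE_LEN] in seq_to_guide
                    }
                    if len(hits) == 1:
                        counts[hits.pop()] += 1
                        report.mapped_reads += 1
                    elif len(hits) > 1:
                        report.ambiguous_reads += 1
                else:
                    kmer = seq[offset : offset + GUIDE_LEN]
                    guide = seq_to_guide.get(kmer)
                    if guide is not None:
                        counts[guide] += 1
                        report.mapped_reads += 1
        finally:
            if isinstance(src, (str, Path)):
                handle.close()

    if report.total_reads == 0:
        logger.warning("no reads in FASTQ input; emitting zero-count column")
    col = pd.DataFrame({sample_id: pd.Series(counts, dtype=np.int64)})
    col = col.loc[library.table.index]
    return CountMatrix(col, library.gene_of_guide.copy()), report


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def _provenance_line(kind: str, params: dict | None = None) -> str:
    extra = "".join(f" {k}={v}" for k, v in (params or {}).items())
    return f"# poolscreen v{__version__} {kind}{extra}\n"


def write_result_table(df: pd.DataFrame, path, kind: str, params: dict | None = None,
                       index: bool = False) -> None:
    """Write a result table as TSV with a ``#`` provenance header line."""
    with open(path, "w") as fh:
        fh.write(_provenance_line(kind, params))
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")
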