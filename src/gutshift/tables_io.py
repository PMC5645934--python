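"""Tabular data model, validation, and TSV readers/writers.

All pipeline inputs and outputs are plain UTF-8 tab-separated tables with a
'.' decimal point: feature x sample matrices (first column = feature id,
header row = sample ids), a per-sample metadata table, a gene annotation
table, and a BLAST-outfmt-6-like homology hit table with an explicit
coverage column.

Relative abundances are stored in percent (0-100) throughout, matching how
microbiome surveys report them; fractions are an internal detail of the
statistical routines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GutshiftError",
    "CountTable",
    "GeneAnnotation",
    "AbundanceMatrix",
    "SampleMetadata",
    "HitTable",
    "GROUP_ENCODING",
    "read_count_table",
    "write_count_table",
    "read_annotation",
    "write_annotation",
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "write_metadata",
    "read_hit_table",
    "write_hit_table",
]


class GutshiftError(ValueError):
    """Raised for malformed or inconsistent input tables."""


#: Clinical factor levels implied by the cohort label: the alcohol-dependence
#: cohort without advanced liver disease (ADS) is dependent but not cirrhotic,
#: the alcoholic-liver-cirrhosis cohort (ALC) is both, controls are neither.
GROUP_ENCODING = {
    "ADS": {"dependence": "yes", "cirrhosis": "no"},
    "ALC": {"dependence": "yes", "cirrhosis": "yes"},
    "Control": {"dependence": "no", "cirrhosis": "no"},
}

ABUNDANCE_LEVELS = ("gene", "species", "genus", "ko", "vf_gene")


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise GutshiftError(f"duplicate {what} id(s): {', '.join(map(str, dups[:5]))}")


@dataclass
class CountTable:
    """Gene x sample matrix of mapped-read counts.

    ``counts`` is a DataFrame indexed by gene id with sample-id columns;
    entries are non-negative integers (reads mapped to each catalogue gene).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                bad = np.argwhere(np.not_equal(np.mod(values, 1), 0))[0]
                raise GutshiftError(
                    "non-integer count at gene "
                    f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise GutshiftError(
                "negative count at gene "
                f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.counts.columns.tolist()


@dataclass
class GeneAnnotation:
    """Per-gene annotations: length (bp), optional KO / species / genus labels.

    ``table`` is indexed by gene id with columns ``length_bp`` (int >= 1) and
    optional ``ko``, ``species``, ``genus`` (empty string = unannotated).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene")
        if "length_bp" not in self.table.columns:
            raise GutshiftError("annotation table must have a 'length_bp' column")
        lengths = self.table["length_bp"].to_numpy()
        if (lengths < 1).any():
            gene = self.table.index[np.argmax(lengths < 1)]
            raise GutshiftError(f"gene {gene!r} has length_bp < 1")
        for col in ("ko", "species", "genus"):
            if col not in self.table.columns:
                self.table[col] = ""
            self.table[col] = self.table[col].fillna("").astype(str)

    def require_genes(self, gene_ids) -> None:
        """Every gene with counts must have an annotation row (lengths are
        needed for normalization); a missing row is fatal, not a silent drop."""
        missing = pd.Index(gene_ids).difference(self.table.index)
        if len(missing):
            raise GutshiftError(
                f"{len(missing)} gene(s) in counts lack annotation, "
                f"e.g. {missing[0]!r}"
            )

    def lengths(self, gene_ids) -> np.ndarray:
        return self.table.loc[gene_ids, "length_bp"].to_numpy(dtype=float)

    def labels(self, gene_ids, level: str) -> pd.Series:
        col = {"ko": "ko", "species": "species", "genus": "genus"}[level]
        return self.table.loc[gene_ids, col]


@dataclass
class AbundanceMatrix:
    """Feature x sample relative abundances in percent of total.

    Columns sum to 100 for a complete matrix and to less after subsetting
    (sums above 100 + 1e-6 are rejected).
    """

    values: pd.DataFrame
    level: str = "species"

    def __post_init__(self) -> None:
        if self.level not in ABUNDANCE_LEVELS:
            raise GutshiftError(
                f"unknown abundance level {self.level!r}; expected one of {ABUNDANCE_LEVELS}"
            )
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any() or (arr > 100 + 1e-6).any():
            raise GutshiftError("abundance entries must lie in [0, 100]")
        colsum = arr.sum(axis=0)
        if (colsum > 100 + 1e-6).any():
            sample = self.values.columns[np.argmax(colsum > 100 + 1e-6)]
            raise GutshiftError(f"column sum exceeds 100% for sample {sample!r}")

    @property
    def feature_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values[list(sample_ids)], level=self.level)


@dataclass
class SampleMetadata:
    """Per-sample clinical factors.

    ``table`` is indexed by sample id with columns ``group`` (ADS/ALC/Control),
    ``dependence`` and ``cirrhosis`` (yes/no), ``gender`` (F/M) and an
    optional numeric ``age``.  When only ``group`` is given the two binary
    factors are derived from it (ADS -> yes/no, ALC -> yes/yes,
    Control -> no/no).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        if "group" not in self.table.columns:
            raise GutshiftError("metadata must have a 'group' column")
        unknown = set(self.table["group"]) - set(GROUP_ENCODING)
        if unknown:
            raise GutshiftError(
                f"unknown group label(s): {', '.join(sorted(map(str, unknown)))}"
            )
        for factor in ("dependence", "cirrhosis"):
            if factor not in self.table.columns:
                self.table[factor] = [
                    GROUP_ENCODING[g][factor] for g in self.table["group"]
                ]
            bad = set(self.table[factor]) - {"yes", "no"}
            if bad:
                raise GutshiftError(f"{factor} must be yes/no, got {sorted(bad)}")
        if "gender" in self.table.columns:
            bad = set(self.table["gender"]) - {"F", "M"}
            if bad:
                raise GutshiftError(f"gender must be F/M, got {sorted(bad)}")

    @property
    def sample_ids(self) -> list:
        return self.table.index.tolist()

    def group_samples(self, group: str) -> list:
        """Sample ids with the given group label, or with the given yes value
        of a binary factor when ``group`` is 'dependence' or 'cirrhosis'."""
        if group in GROUP_ENCODING:
            return self.table.index[self.table["group"] == group].tolist()
        if group in ("dependence", "cirrhosis"):
            return self.table.index[self.table[group] == "yes"].tolist()
        raise GutshiftError(f"unknown group or factor {group!r}")

    def factor_values(self, factor: str) -> pd.Series:
        """Factor as a label Series aligned to sample order."""
        if factor not in self.table.columns:
            raise GutshiftError(f"metadata has no factor {factor!r}")
        return self.table[factor]

    def binary_design(self, factors=("dependence", "cirrhosis", "gender")) -> pd.DataFrame:
        """0/1 design columns: yes=1/no=0, gender M=1/F=0."""
        cols = {}
        for f in factors:
            s = self.factor_values(f)
            if f == "gender":
                cols[f] = (s == "M").astype(float)
            else:
                cols[f] = (s == "yes").astype(float)
        return pd.DataFrame(cols, index=self.table.index)


HIT_COLUMNS = ["catalogue_gene_id", "vf_gene_id", "evalue", "percent_identity", "coverage_fraction"]


@dataclass
class HitTable:
    """Homology hits of catalogue genes against virulence-factor reference
    genes, in BLAST tabular style with an explicit coverage column."""

    hits: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=HIT_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in HIT_COLUMNS if c not in self.hits.columns]
        if missing:
            raise GutshiftError(f"hit table missing column(s): {', '.join(missing)}")
        self.hits = self.hits[HIT_COLUMNS].reset_index(drop=True)
        if len(self.hits):
            if (self.hits["evalue"] < 0).any():
                raise GutshiftError("negative e-value in hit table")
            pid = self.hits["percent_identity"]
            if ((pid < 0) | (pid > 100)).any():
                raise GutshiftError("percent_identity must lie in [0, 100]")
            cov = self.hits["coverage_fraction"]
            if ((cov < 0) | (cov > 1)).any():
                raise GutshiftError("coverage_fraction must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.hits)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_matrix(path, value_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.empty and df.shape[1] == 0:
        raise GutshiftError(f"{value_name} table at {path} has no sample columns")
    return df


def read_count_table(path) -> CountTable:
    """Read a gene x sample TSV of integer read counts."""
    df = _read_matrix(path, "count")
    try:
        return CountTable(df)
    except GutshiftError as err:
        raise GutshiftError(f"{path}: {err}") from None


def write_count_table(table: CountTable, path) -> None:
    table.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, keep_default_na=False)
    df.index = df.index.astype(str)
    df["length_bp"] = pd.to_numeric(df["length_bp"]).astype(np.int64)
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.table.rename_axis("gene_id").to_csv(path, sep="\t")


def read_abundance(path, level: str = "species") -> AbundanceMatrix:
    return AbundanceMatrix(_read_matrix(path, "abundance").astype(float), level=level)


def write_abundance(abund: AbundanceMatrix, path) -> None:
    abund.values.rename_axis(abund.level).to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    """Read per-sample metadata; binary factors are derived from the group
    label when only ``group`` is present."""
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    df.index = df.index.astype(str)
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_hit_table(path) -> HitTable:
    df = pd.read_csv(path, sep="\t", dtype={"catalogue_gene_id": str, "vf_gene_id": str})
    return HitTable(df)


def write_hit_table(hits: HitTable, path) -> None:
    hits.hits.to_csv(path, sep="\t", index=False)
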