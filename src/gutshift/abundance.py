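"""Relative-abundance normalization, aggregation, and prevalence filtering.

The gene-level relative abundance of gene *g* in sample *s* is its read
count divided by gene length, renormalized over all catalogue genes:

    a_gs = 100 * (c_gs / L_g) / sum_g' (c_g's / L_g')

so each sample column sums to 100%.  Taxon and KO abundances are plain sums
of member-gene (or member-species) abundances — no renormalization, so a
full partition preserves column sums exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import AbundanceMatrix, CountTable, GeneAnnotation, GutshiftError

__all__ = [
    "PrevalenceFilterSpec",
    "GENUS_FILTER",
    "SPECIES_FILTER",
    "gene_relative_abundance",
    "aggregate",
    "prevalence_filter",
    "subset_ko",
]


@dataclass(frozen=True)
class PrevalenceFilterSpec:
    """Keep a feature iff its abundance exceeds ``threshold_percent``
    (strictly) in at least one sample."""

    threshold_percent: float
    scope: str = "generic"

    def __post_init__(self) -> None:
        if self.threshold_percent <= 0:
            raise GutshiftError("prevalence threshold must be positive")
        if self.scope not in ("genus", "species", "generic"):
            raise GutshiftError(f"unknown filter scope {self.scope!r}")


#: The comparative-analysis inclusion thresholds: genera kept above 1% and
#: species above 0.1% in at least one sample.
GENUS_FILTER = PrevalenceFilterSpec(1.0, "genus")
SPECIES_FILTER = PrevalenceFilterSpec(0.1, "species")


def gene_relative_abundance(counts: CountTable, ann: GeneAnnotation) -> AbundanceMatrix:
    """Length-normalized gene relative abundances in percent.

    Raises on a sample with no mapped reads (no normalizable signal) and on
    genes missing from the annotation (their lengths are required).
    """
    ann.require_genes(counts.gene_ids)
    lengths = ann.lengths(counts.gene_ids)
    weighted = counts.counts.to_numpy(dtype=float) / lengths[:, None]
    totals = weighted.sum(axis=0)
    if (totals <= 0).any():
        sample = counts.counts.columns[int(np.argmax(totals <= 0))]
        raise GutshiftError(f"sample {sample!r} has no mapped reads")
    values = 100.0 * weighted / totals
    df = pd.DataFrame(values, index=counts.counts.index, columns=counts.counts.columns)
    return AbundanceMatrix(df, level="gene")


def aggregate(abund: AbundanceMatrix, labels, level: str) -> AbundanceMatrix:
    """Sum feature abundances by group label (gene->KO, gene->taxon,
    species->genus).

    ``labels`` maps feature id to group label; unlabeled features (missing
    or empty label) are dropped from the output but were already counted in
    the normalization totals, so column sums may fall below 100.
    """
    labels = pd.Series(labels)
    labels = labels.reindex(abund.values.index).fillna("")
    keep = labels != ""
    if not keep.any():
        warnings.warn("aggregation label set is empty; returning empty matrix")
        empty = pd.DataFrame(
            np.empty((0, abund.values.shape[1])), columns=abund.values.columns
        )
        return AbundanceMatrix(empty, level=level)
    grouped = abund.values.loc[keep].groupby(labels[keep], sort=True).sum()
    grouped.index = grouped.index.astype(str)
    # Summing floats can overshoot a full column by rounding error; clip it.
    return AbundanceMatrix(grouped.clip(upper=100.0), level=level)


def prevalence_filter(abund: AbundanceMatrix, spec: PrevalenceFilterSpec) -> AbundanceMatrix:
    """Drop features never exceeding the threshold; row order preserved."""
    keep = (abund.values.to_numpy() > spec.threshold_percent).any(axis=1)
    return AbundanceMatrix(abund.values.loc[keep], level=abund.level)


def subset_ko(abund: AbundanceMatrix, ko_list) -> AbundanceMatrix:
    """Row subset in ``ko_list`` order (e.g. the alcohol-metabolism KO set).

    KO groups absent from the matrix are kept as all-zero rows with a
    warning so fixed-size gene-group panels keep their shape.
    """
    ko_list = list(ko_list)
    if len(set(ko_list)) != len(ko_list):
        raise GutshiftError("ko_list contains duplicates")
    missing = [k for k in ko_list if k not in abund.values.index]
    if missing:
        warnings.warn(
            f"{len(missing)} KO group(s) absent from matrix kept as zero rows: "
            + ", ".join(missing[:5])
        )
    out = abund.values.reindex(ko_list, fill_value=0.0)
    return AbundanceMatrix(out, level=abund.level)
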