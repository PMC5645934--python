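"""Virulence-factor gene quantification from homology hits, and functional
differential comparisons.

Catalogue genes are linked to virulence-factor (VF) reference genes by
precomputed homology hits (BLAST tabular style).  Hits must pass the
similarity criterion — e value < 1e-5, percent identity > 80% over > 80%
of the reference gene length (all strict) — and each surviving VF gene's
relative abundance is the per-sample sum of its similar catalogue genes'
abundances.  A catalogue gene similar to several VF genes contributes its
full abundance to each of them (abundances are summed, not split).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import PrevalenceFilterSpec
from .differential import differential_features
from .tables_io import AbundanceMatrix, GutshiftError, HitTable, SampleMetadata

__all__ = ["VfAbundance", "filter_hits", "vf_aggregate", "functional_differential"]


@dataclass
class VfAbundance:
    """VF-gene x sample abundances plus the contributing catalogue genes."""

    abundance: AbundanceMatrix
    contributors: dict = field(default_factory=dict)


def filter_hits(
    hits: HitTable,
    e_max: float = 1e-5,
    min_identity: float = 80.0,
    min_coverage: float = 0.8,
) -> HitTable:
    """Apply the similarity criterion; all three thresholds are strict."""
    df = hits.hits
    keep = (
        (df["evalue"] < e_max)
        & (df["percent_identity"] > min_identity)
        & (df["coverage_fraction"] > min_coverage)
    )
    return HitTable(df.loc[keep].reset_index(drop=True))


def vf_aggregate(hits: HitTable, gene_abund: AbundanceMatrix) -> VfAbundance:
    """Sum catalogue-gene abundances per VF reference gene.

    Hits referring to catalogue genes missing from the abundance matrix are
    skipped with a warning; VF genes without any surviving hit do not appear.
    """
    df = hits.hits.drop_duplicates(["catalogue_gene_id", "vf_gene_id"])
    known = df["catalogue_gene_id"].isin(gene_abund.values.index)
    if (~known).any():
        warnings.warn(
            f"{int((~known).sum())} hit(s) refer to catalogue genes absent from the "
            "gene abundance matrix; skipped"
        )
        df = df.loc[known]
    if df.empty:
        warnings.warn("no hits survive; VF abundance matrix is empty")
        empty = pd.DataFrame(
            np.empty((0, gene_abund.values.shape[1])), columns=gene_abund.values.columns
        )
        return VfAbundance(AbundanceMatrix(empty, level="vf_gene"), {})
    contributors = {
        vf: sorted(sub["catalogue_gene_id"]) for vf, sub in df.groupby("vf_gene_id")
    }
    rows = {
        vf: gene_abund.values.loc[genes].sum(axis=0).clip(upper=100.0)
        for vf, genes in contributors.items()
    }
    values = pd.DataFrame(rows).T.sort_index()
    values.index.name = "vf_gene"
    return VfAbundance(AbundanceMatrix(values, level="vf_gene"), contributors)


def functional_differential(
    abund: AbundanceMatrix,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
    q_threshold: float = 0.05,
    filter_spec: PrevalenceFilterSpec | None = None,
) -> pd.DataFrame:
    """Two-group Mann-Whitney differential comparison of KO-group or VF-gene
    abundances at the functional significance threshold (q < 0.05 by
    default); no prevalence filter is applied unless one is passed.
    Adds an ``increased``/``decreased`` call (relative to ``group_a``)."""
    out = differential_features(
        abund, meta, group_a, group_b, q_threshold=q_threshold, filter_spec=filter_spec
    )
    out["call"] = np.where(out["direction"] > 0, "increased", "decreased")
    return out
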