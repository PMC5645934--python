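"""Rank-based enrichment test for oral (buccal) species in the gut.

Elevated gut abundance of mouth-resident taxa (Streptococcus salivarius,
Veillonella spp., ...) is a hallmark of liver cirrhosis.  Because their
absolute abundances are small and zero-inflated, enrichment is assessed on
within-sample abundance ranks: with N the number of species detected in at
least one sample, each sample's detected species get ranks 1 (most
abundant) .. N (least abundant) and species undetected in that sample get
the sentinel N + 1.  Each candidate species' rank vectors are then compared
between cohorts with a one-tailed Mann-Whitney test; the sentinels enter as
ties and no multiple-testing adjustment is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .differential import mann_whitney
from .tables_io import AbundanceMatrix, GutshiftError, SampleMetadata

__all__ = ["RankMatrix", "rank_transform", "oral_rank_test", "enrichment_table"]


class RankMatrix:
    """Species x sample integer ranks with sentinel N + 1 for non-detection."""

    def __init__(self, ranks: pd.DataFrame, n_species: int):
        arr = ranks.to_numpy()
        if len(ranks) and ((arr < 1) | (arr > n_species + 1)).any():
            raise GutshiftError("ranks must lie in {1..N+1}")
        self.ranks = ranks
        self.n_species = n_species

    @property
    def sentinel(self) -> int:
        return self.n_species + 1


def rank_transform(abund: AbundanceMatrix) -> RankMatrix:
    """Within-sample abundance ranks.

    Species never detected (abundance 0 in every sample) are excluded from N
    first.  Within a sample, detected species are ranked by decreasing
    abundance; tied abundances share their average rank rounded half-up
    (species order within a tie is immaterial once ranks are shared, and
    rows are kept in deterministic lexicographic order).
    """
    values = abund.values
    detected_anywhere = (values.to_numpy() > 0).any(axis=1)
    values = values.loc[detected_anywhere].sort_index()
    n = len(values)
    out = np.full(values.shape, n + 1, dtype=np.int64)
    arr = values.to_numpy(dtype=float)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        det = col > 0
        if det.any():
            r = scipy.stats.rankdata(-col[det], method="average")
            out[det, j] = np.floor(r + 0.5).astype(np.int64)  # half-up
    return RankMatrix(pd.DataFrame(out, index=values.index, columns=values.columns), n)


def oral_rank_test(
    ranks: RankMatrix,
    meta: SampleMetadata,
    species: list,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """One-tailed Mann-Whitney on each candidate species' rank vectors.

    The alternative is "more abundant (numerically smaller rank) in
    ``group_a``"; to test for cirrhosis-linked enrichment pass the
    cirrhotic cohort as ``group_a``.  Species undetected across both groups
    get p = 1 with a flag; species missing from the rank matrix entirely
    are dropped with a warning.
    """
    samples_a = meta.group_samples(group_a)
    samples_b = meta.group_samples(group_b)
    if not samples_a or not samples_b:
        raise GutshiftError("both groups must be non-empty")
    missing = [s for s in species if s not in ranks.ranks.index]
    if missing:
        warnings.warn(
            f"{len(missing)} candidate species absent from the rank matrix: "
            + ", ".join(map(str, missing[:5]))
        )
    rows = []
    for sp in species:
        if sp in missing:
            continue
        r_a = ranks.ranks.loc[sp, samples_a].to_numpy()
        r_b = ranks.ranks.loc[sp, samples_b].to_numpy()
        undetected = bool((r_a == ranks.sentinel).all() and (r_b == ranks.sentinel).all())
        if undetected:
            p = 1.0
        else:
            _, p = mann_whitney(r_a, r_b, alternative="less")
        rows.append(
            {
                "species": sp,
                "p": p,
                f"median_rank_{group_a}": float(np.median(r_a)),
                f"median_rank_{group_b}": float(np.median(r_b)),
                "undetected": undetected,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "p",
            f"median_rank_{group_a}",
            f"median_rank_{group_b}",
            "undetected",
        ],
    ).set_index("species")


def enrichment_table(
    abund: AbundanceMatrix, species: list, min_percent: float = 1.0
) -> pd.DataFrame:
    """Ordered (sample, species, abundance%) occurrences of the candidate
    species above ``min_percent`` (strict), sorted by decreasing abundance —
    the layout of a buccal-species enrichment table."""
    present = [s for s in species if s in abund.values.index]
    rows = []
    for sp in present:
        vals = abund.values.loc[sp]
        for sample, v in vals.items():
            if v > min_percent:
                rows.append({"sample": sample, "species": sp, "abundance_percent": float(v)})
    out = pd.DataFrame(rows, columns=["sample", "species", "abundance_percent"])
    return out.sort_values(
        ["abundance_percent", "sample", "species"], ascending=[False, True, True]
    ).reset_index(drop=True)
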