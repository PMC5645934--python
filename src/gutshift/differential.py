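"""Two-group differential abundance with false-discovery-rate control, and
pathway-level calling.

Features are compared between cohorts with the Mann-Whitney rank test (the
appropriate choice for heavy-tailed, zero-inflated relative abundances) and
p values are adjusted with the Benjamini-Hochberg step-up procedure across
the features retained by the prevalence filter.  A KEGG pathway is called
shifted when at least half of its KO terms are individually differential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .abundance import PrevalenceFilterSpec, prevalence_filter
from .tables_io import AbundanceMatrix, GutshiftError, SampleMetadata

__all__ = [
    "mann_whitney",
    "bh_adjust",
    "differential_features",
    "pathway_calls",
]

#: Largest pooled size at which the exact null distribution is enumerated
#: (when the data are tie-free); beyond it the normal approximation with
#: tie correction is used.
EXACT_LIMIT = 12


def mann_whitney(group_a, group_b, alternative: str = "two_sided") -> tuple[float, float]:
    """Mann-Whitney U test -> (U_A, p).

    Exact p when n_A + n_B <= 12: by enumeration of the rank-sum null for
    tie-free data, and by exhaustive permutation (average ranks) when ties
    are present.  Beyond that, normal approximation with tie correction.
    ``alternative='greater'`` tests for stochastically larger values in
    group A.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise GutshiftError("Mann-Whitney requires non-empty groups")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}.get(alternative)
    if alt is None:
        raise GutshiftError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    if len(pooled) <= EXACT_LIMIT:
        if len(np.unique(pooled)) == len(pooled):
            res = scipy.stats.mannwhitneyu(a, b, alternative=alt, method="exact")
            return float(res.statistic), float(min(res.pvalue, 1.0))
        return _mann_whitney_permutation(a, b, alt)
    res = scipy.stats.mannwhitneyu(a, b, alternative=alt, method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _mann_whitney_permutation(a: np.ndarray, b: np.ndarray, alt: str) -> tuple[float, float]:
    """Exhaustive-permutation p for small tied samples: U (with average
    ranks) over every split of the pooled data into groups of the observed
    sizes; two-sided p is twice the smaller tail, capped at 1."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    n, n_a = len(pooled), len(a)
    offset = n_a * (n_a + 1) / 2.0
    u_obs = ranks[:n_a].sum() - offset
    us = np.array([
        sum(ranks[i] for i in idx) - offset for idx in combinations(range(n), n_a)
    ])
    p_greater = float((us >= u_obs - 1e-12).mean())
    p_less = float((us <= u_obs + 1e-12).mean())
    if alt == "greater":
        p = p_greater
    elif alt == "less":
        p = p_less
    else:
        p = 2.0 * min(p_greater, p_less)
    return float(u_obs), float(min(p, 1.0))


def _mann_whitney_matrix(x_a: np.ndarray, x_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided test over rows (features); asymptotic with tie
    correction, matching :func:`mann_whitney` at these sample sizes."""
    res = scipy.stats.mannwhitneyu(x_a, x_b, alternative="two-sided", method="asymptotic", axis=1)
    return np.asarray(res.statistic, float), np.minimum(np.asarray(res.pvalue, float), 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q), input order kept."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise GutshiftError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_features(
    abund: AbundanceMatrix,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
    q_threshold: float = 0.01,
    filter_spec: PrevalenceFilterSpec | None = None,
) -> pd.DataFrame:
    """Feature-wise Mann-Whitney comparison of two cohorts with BH control.

    The prevalence filter (when given) is applied before testing and BH runs
    across the retained features only.  Returns one row per retained
    feature: U statistic, raw p, q, direction (+1 = enriched in ``group_a``,
    by median then mean), per-group medians and means, and a ``significant``
    flag at ``q < q_threshold``.
    """
    if filter_spec is not None:
        abund = prevalence_filter(abund, filter_spec)
    samples_a = meta.group_samples(group_a)
    samples_b = meta.group_samples(group_b)
    if not samples_a or not samples_b:
        raise GutshiftError(f"empty group in comparison {group_a!r} vs {group_b!r}")
    if min(len(samples_a), len(samples_b)) < 3:
        warnings.warn("a group has fewer than 3 samples; tests run but power is minimal")
    x_a = abund.values[samples_a].to_numpy(dtype=float)
    x_b = abund.values[samples_b].to_numpy(dtype=float)
    features = abund.values.index
    if len(features) == 0:
        return _empty_differential()

    if x_a.shape[1] + x_b.shape[1] <= EXACT_LIMIT:
        stats = np.empty(len(features))
        pvals = np.empty(len(features))
        for i in range(len(features)):
            stats[i], pvals[i] = mann_whitney(x_a[i], x_b[i], "two_sided")
    else:
        stats, pvals = _mann_whitney_matrix(x_a, x_b)

    qvals = bh_adjust(pvals)
    med_a, med_b = np.median(x_a, axis=1), np.median(x_b, axis=1)
    mean_a, mean_b = x_a.mean(axis=1), x_b.mean(axis=1)
    delta = np.where(med_a != med_b, med_a - med_b, mean_a - mean_b)
    direction = np.where(delta >= 0, 1, -1)
    out = pd.DataFrame(
        {
            "U": stats,
            "p": pvals,
            "q": qvals,
            "direction": direction,
            f"median_{group_a}": med_a,
            f"median_{group_b}": med_b,
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
            "significant": qvals < q_threshold,
        },
        index=features,
    ).rename_axis("feature")
    return out.sort_index()


def _empty_differential() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["U", "p", "q", "direction", "significant"]
    ).rename_axis("feature")


def pathway_calls(
    ko_results: pd.DataFrame,
    pathway_map,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pathway-level calls from per-KO differential results.

    ``pathway_map`` maps KO id -> pathway id (dict or Series; a KO may map
    to several pathways via a list).  Membership counts only the KOs present
    in ``ko_results`` (i.e. detected in the KO abundance matrix).  A pathway
    is retained when n_diff / n_members >= 0.5 ("at least half"); its
    direction is the majority direction of the differential members, or
    ``mixed`` on a tie.
    """
    pairs: list[tuple[str, str]] = []
    items = pathway_map.items() if hasattr(pathway_map, "items") else pathway_map
    for ko, pw in items:
        if isinstance(pw, (list, tuple, set)):
            pairs.extend((ko, p) for p in pw)
        else:
            pairs.append((ko, pw))
    rows = []
    by_pathway: dict[str, list[str]] = {}
    for ko, pw in pairs:
        by_pathway.setdefault(pw, []).append(ko)
    for pw in sorted(by_pathway):
        members = [k for k in by_pathway[pw] if k in ko_results.index]
        if not members:
            warnings.warn(f"pathway {pw!r} has no KO present in the results; skipped")
            continue
        sub = ko_results.loc[members]
        diff = sub[sub["q"] < q_threshold]
        n_members, n_diff = len(members), len(diff)
        fraction = n_diff / n_members
        n_up = int((diff["direction"] > 0).sum())
        n_down = n_diff - n_up
        if n_diff == 0:
            direction = "none"
        elif n_up > n_down:
            direction = "increased"
        elif n_down > n_up:
            direction = "decreased"
        else:
            direction = "mixed"
        rows.append(
            {
                "pathway": pw,
                "n_members": n_members,
                "n_differential": n_diff,
                "fraction": fraction,
                "retained": fraction >= 0.5,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows, columns=["pathway", "n_members", "n_differential", "fraction", "retained", "direction"]).set_index("pathway")
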