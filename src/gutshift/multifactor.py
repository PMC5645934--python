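"""Community-level variance partitioning (PERMANOVA) and per-taxon
multi-factor association.

The study design crosses two binary clinical factors — alcohol dependence
and liver cirrhosis — plus gender.  PERMANOVA on the Bray-Curtis
dissimilarity matrix screens which factors explain community-level
variance; per-taxon associations are then estimated jointly with an
additive linear model

    arcsin(sqrt(abundance_fraction)) ~ dependence + cirrhosis + gender

on variance-stabilized relative abundances, with Benjamini-Hochberg control
across all (taxon, factor) p values.  The joint fit is what disentangles
the two factors: every dependent subject is counted in the dependence term
while the cirrhosis term absorbs the additional cirrhosis-only effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .differential import bh_adjust
from .diversity import DissimilarityMatrix
from .tables_io import GutshiftError, SampleMetadata, AbundanceMatrix

__all__ = [
    "PermanovaResult",
    "permanova",
    "permanova_screen",
    "multifactor_association",
]


@dataclass
class PermanovaResult:
    factor: str
    r2: float
    f_statistic: float
    p: float
    p_adjusted: float | None
    n_permutations: int


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_levels: int) -> tuple[float, float]:
    """(SS_within, SS_total) from squared dissimilarities and group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_levels):
        mask = codes == g
        n_g = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ss_within, ss_total


def permanova(
    d: DissimilarityMatrix,
    factor,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = 0,
    factor_name: str = "factor",
) -> PermanovaResult:
    """One-factor PERMANOVA.

    Pseudo-F from among/within sums of squared dissimilarities; the p value
    counts label permutations with F at least as large as observed, with the
    +1 correction so p >= 1/(n_perm + 1).  R^2 = SS_among / SS_total.
    """
    labels = pd.Series(list(factor), index=d.sample_ids)
    codes, levels = pd.factorize(labels)
    a = len(levels)
    if a < 2:
        raise GutshiftError(f"factor {factor_name!r} has a single level")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise GutshiftError(
            f"factor {factor_name!r} has a level with fewer than 2 samples"
        )
    n = len(codes)
    d2 = d.values.to_numpy(dtype=float) ** 2

    def pseudo_f(c: np.ndarray) -> tuple[float, float]:
        ss_w, ss_t = _permanova_ss(d2, c, a)
        ss_a = ss_t - ss_w
        return (ss_a / (a - 1)) / (ss_w / (n - a)), ss_a / ss_t

    f_obs, r2 = pseudo_f(codes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm, _ = pseudo_f(rng.permutation(codes))
        if f_perm >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermanovaResult(factor_name, float(r2), float(f_obs), float(p), None, n_perm)


def _age_binned(meta: SampleMetadata) -> pd.Series:
    """Dichotomize age at the cohort median so it enters the screen as a
    two-level factor."""
    age = pd.to_numeric(meta.table["age"], errors="coerce")
    if age.isna().any():
        raise GutshiftError("age is missing for some samples")
    cut = float(age.median())
    return pd.Series(np.where(age > cut, "older", "younger"), index=meta.table.index)


def permanova_screen(
    d: DissimilarityMatrix,
    meta: SampleMetadata,
    factors=("dependence", "cirrhosis", "gender", "age"),
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-factor PERMANOVA with BH adjustment across the factor set."""
    order = list(d.sample_ids)
    results = []
    root = np.random.default_rng(seed)
    for factor in factors:
        if factor == "age":
            labels = _age_binned(meta).loc[order]
        else:
            labels = meta.factor_values(factor).loc[order]
        res = permanova(
            d, labels, n_perm=n_perm,
            seed=np.random.default_rng(root.integers(2**31)), factor_name=factor,
        )
        results.append(res)
    padj = bh_adjust([r.p for r in results])
    return pd.DataFrame(
        {
            "R2": [r.r2 for r in results],
            "F": [r.f_statistic for r in results],
            "p": [r.p for r in results],
            "p_adjusted": padj,
            "n_permutations": [r.n_permutations for r in results],
        },
        index=pd.Index([r.factor for r in results], name="factor"),
    )


def multifactor_association(
    abund: AbundanceMatrix,
    meta: SampleMetadata,
    factors=("dependence", "cirrhosis", "gender"),
    min_abund: float = 0.01,
    min_samples: int = 10,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Joint linear association of each taxon with the clinical factors.

    Taxa abundant above ``min_abund`` percent (strict) in at least
    ``min_samples`` samples are retained.  For each, ordinary least squares
    fits arcsin(sqrt(fraction)) on the binary covariates jointly (yes=1,
    M=1); p values are BH-adjusted across all (taxon, factor) pairs.  A
    positive coefficient denotes a direct association between the factor
    and the taxon's abundance.  Factors constant in the data are dropped
    with a warning.
    """
    order = abund.sample_ids
    design = meta.binary_design(factors).loc[order]
    kept_factors = []
    for f in list(design.columns):
        if design[f].nunique() < 2:
            warnings.warn(f"factor {f!r} is constant in the data; dropped from the model")
            design = design.drop(columns=f)
        else:
            kept_factors.append(f)
    if not kept_factors:
        raise GutshiftError("no non-constant factors left in the design")

    values = abund.values
    keep = (values.to_numpy() > min_abund).sum(axis=1) >= min_samples
    values = values.loc[keep]

    x = np.column_stack([np.ones(len(order)), design.to_numpy(dtype=float)])
    y = np.arcsin(np.sqrt(values.to_numpy(dtype=float).T / 100.0))  # samples x taxa
    # One shared design: solve all taxa at once, then per-factor t tests.
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # (1+k) x taxa
    resid = y - x @ beta
    dof = len(order) - x.shape[1]
    if dof < 1:
        raise GutshiftError("not enough samples for the requested model")
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    tval = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pval = 2.0 * scipy.stats.t.sf(np.abs(tval), dof)

    rows = []
    for j, taxon in enumerate(values.index):
        for i, f in enumerate(kept_factors, start=1):
            rows.append(
                {
                    "taxon": taxon,
                    "factor": f,
                    "coefficient": float(beta[i, j]),
                    "p": float(pval[i, j]) if se[i, j] > 0 else 1.0,
                }
            )
    out = pd.DataFrame(rows, columns=["taxon", "factor", "coefficient", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["direction"] = np.where(out["coefficient"] >= 0, 1, -1)
        out["significant"] = out["q"] < q_threshold
    else:
        out["q"] = []
        out["direction"] = []
        out["significant"] = []
    return out.set_index(["taxon", "factor"])
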