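"""Synthetic shotgun-metagenomic cohort generator with planted effects.

Emulates the complete study inputs — gene-level read counts, gene
annotations, sample metadata, and virulence-factor homology hits — for a
three-cohort alcohol study: patients with alcohol dependence syndrome
(ADS, dependence without cirrhosis), patients with alcoholic liver
cirrhosis (ALC, dependence plus cirrhosis), and healthy controls.

The generative model, bottom up:

* each species has a log-normal baseline mean abundance (heavy-tailed, so
  a few Bacteroides/Prevotella-like taxa dominate, as real gut communities
  do), with per-sample log-normal noise;
* clinical effects are multiplicative on the underlying species fractions
  before renormalization (a 4x "fold" enriches the species in every sample
  whose factor is "yes"); compositional spillover onto unplanted taxa is an
  accepted consequence;
* oral (buccal) species are spiked at percent-scale abundance into the
  cirrhosis cohort, mirroring the cirrhosis-specific influx of mouth taxa
  into the gut;
* dominance outliers are planted by scaling one genus to ~70% of a sample;
* genes (with lengths, KO labels and taxon labels) are assigned to species
  and reads are drawn multinomially per sample with probability
  proportional to species fraction x gene weight x gene length, so that
  length-normalized relative abundances recover the species fractions;
* KO-group effects multiply the read-sampling weight of the member genes,
  planting functional shifts (alcohol-metabolism dehydrogenases up in the
  drinking cohorts);
* virulence-factor hits connect Enterobacteriaceae-tagged catalogue genes
  to VF reference ids, so VF enrichment follows the planted
  Enterobacteriaceae expansion under dependence.

Every planted effect is recorded in a :class:`SyntheticTruth` registry so
downstream recovery tests can score themselves against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables_io
from .abundance import aggregate
from .tables_io import (
    AbundanceMatrix,
    CountTable,
    GeneAnnotation,
    GutshiftError,
    HitTable,
    SampleMetadata,
)

__all__ = [
    "EffectSpec",
    "KoEffectSpec",
    "OralSpikeSpec",
    "OutlierSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "StudyData",
    "ALCOHOL_KOS",
    "DEFAULT_ORAL_SPECIES",
    "build_taxonomy",
    "default_effects",
    "default_ko_effects",
    "generate_species_abundance",
    "generate_cohort",
    "spike_outliers",
    "write_study",
    "config_from_yaml",
]

# ---------------------------------------------------------------------------
# Taxonomy roster
# ---------------------------------------------------------------------------

#: Named species per genus; the analysis-relevant taxa are spelled out and
#: the roster is padded with generic "Genus spNN" species up to n_species.
_NAMED_SPECIES = {
    "Bacteroides": [
        "uniformis", "vulgatus", "dorei", "ovatus", "thetaiotaomicron",
        "fragilis", "caccae", "xylanisolvens", "stercoris",
    ],
    "Prevotella": ["copri", "disiens", "stercorea"],
    "Parabacteroides": ["distasonis", "johnsonii", "merdae"],
    "Alistipes": ["shahii", "putredinis", "finegoldii"],
    "Paraprevotella": ["xylaniphila"],
    "Odoribacter": ["splanchnicus"],
    "Faecalibacterium": ["prausnitzii"],
    "Coprococcus": ["eutactus", "comes", "catus"],
    "Roseburia": ["intestinalis", "hominis", "inulinivorans"],
    "Blautia": ["obeum", "wexlerae", "hansenii"],
    "Ruminococcus": ["bromii", "torques", "gnavus"],
    "Eubacterium": ["rectale", "eligens", "hallii"],
    "Clostridium": ["asparagiforme", "methylpentosum", "saccharolyticum", "leptum", "bolteae"],
    "Akkermansia": ["muciniphila"],
    "Phascolarctobacterium": ["faecium"],
    "Dorea": ["longicatena", "formicigenerans"],
    "Collinsella": ["aerofaciens"],
    "Bifidobacterium": ["longum", "breve", "dentium", "animalis", "adolescentis", "bifidum"],
    "Lactobacillus": [
        "salivarius", "gasseri", "antri", "crispatus", "delbrueckii",
        "oris", "ultunensis", "ruminis",
    ],
    "Streptococcus": [
        "salivarius", "thermophilus", "mutans", "parasanguinis",
        "vestibularis", "constellatus",
    ],
    "Veillonella": ["atypica", "dispar", "parvula"],
    "Lactococcus": ["lactis"],
    "Enterococcus": ["faecalis", "faecium"],
    "Escherichia": ["coli", "fergusonii"],
    "Klebsiella": ["pneumoniae", "oxytoca"],
    "Citrobacter": ["koseri", "freundii"],
    "Enterobacter": ["cloacae"],
    "Gordonibacter": ["pamelaeae"],
}

#: Unclassified bins carried as explicit rows (the "uncl." convention).
_UNCLASSIFIED = {"uncl.Clostridiales": 3, "uncl.Lachnospiraceae": 2}

#: Log-scale genus location of baseline mean abundance (arbitrary units;
#: only ratios matter after per-sample renormalization).
_GENUS_LOC = {
    "Bacteroides": 2.5, "Prevotella": 2.3, "Faecalibacterium": 2.2,
    "Blautia": 1.8, "Ruminococcus": 1.5, "Eubacterium": 1.5,
    "Bifidobacterium": 1.5, "Roseburia": 1.3, "Coprococcus": 1.2,
    "Alistipes": 1.2, "Clostridium": 1.0, "Parabacteroides": 1.0,
    "Dorea": 1.0, "Akkermansia": 1.0, "uncl.Clostridiales": 1.0,
    "uncl.Lachnospiraceae": 1.0, "Collinsella": 0.8,
    "Odoribacter": 0.5, "Phascolarctobacterium": 0.5, "Paraprevotella": 0.3,
    "Escherichia": 0.0, "Lactobacillus": -0.5, "Streptococcus": -0.5,
    "Klebsiella": -0.5, "Gordonibacter": -0.5, "Enterococcus": -1.0,
    "Citrobacter": -1.0, "Lactococcus": -1.0, "Enterobacter": -1.0,
    "Veillonella": -1.5,
}
_DEFAULT_LOC = 0.5

#: Mouth-resident species: near-absent from the healthy gut baseline.
ORAL_FLAGGED = (
    "Streptococcus constellatus", "Streptococcus salivarius",
    "Streptococcus parasanguinis", "Streptococcus vestibularis",
    "Veillonella atypica", "Veillonella dispar", "Veillonella parvula",
)
_ORAL_LOC = -3.5

#: The five buccal species whose gut ranks separate cirrhotic from
#: non-cirrhotic alcoholics.
DEFAULT_ORAL_SPECIES = (
    "Streptococcus constellatus", "Streptococcus salivarius",
    "Veillonella atypica", "Veillonella dispar", "Veillonella parvula",
)

ENTEROBACTERIACEAE = ("Escherichia", "Klebsiella", "Citrobacter", "Enterobacter")

#: KEGG Orthology groups of the alcohol-metabolism panel (alcohol, aldehyde
#: and acetaldehyde dehydrogenase families and related reactions); treated
#: as configuration, not hard-coded truth.
ALCOHOL_KOS = (
    "K00001", "K00002", "K00114", "K00121", "K00128", "K00129", "K00138",
    "K01895", "K04021", "K04072", "K04073", "K13951", "K13952", "K13953",
    "K13954", "K13980", "K14028", "K14029", "K18366",
)

_FILL_GENERA = (
    "Bacteroides", "Clostridium", "Ruminococcus", "Eubacterium", "Blautia",
    "Prevotella", "Alistipes", "Roseburia", "Dorea", "Coprococcus",
    "Streptococcus", "Lactobacillus", "Bifidobacterium", "Collinsella",
    "Parabacteroides", "Enterococcus",
)


def build_taxonomy(n_species: int = 300) -> pd.DataFrame:
    """Species -> genus table: all named species first, then generic
    "Genus spNN" filler species cycling over common gut genera."""
    rows = []
    for genus, epithets in _NAMED_SPECIES.items():
        rows.extend((f"{genus} {e}", genus) for e in epithets)
    for genus, k in _UNCLASSIFIED.items():
        rows.extend((f"{genus} sp{i + 1}", genus) for i in range(k))
    if n_species < len(rows):
        rows = rows[:n_species]
    i = 0
    while len(rows) < n_species:
        genus = _FILL_GENERA[i % len(_FILL_GENERA)]
        rows.append((f"{genus} sp{100 + i}", genus))
        i += 1
    df = pd.DataFrame(rows, columns=["species", "genus"]).set_index("species")
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSpec:
    """A planted clinical effect: the listed species are multiplied by
    ``fold`` in every sample whose ``factor`` is yes."""

    species: tuple
    factor: str
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise GutshiftError("effect fold must be positive")
        if self.factor not in ("dependence", "cirrhosis", "gender"):
            raise GutshiftError(f"unknown effect factor {self.factor!r}")


@dataclass(frozen=True)
class KoEffectSpec:
    """A planted functional effect on the read-sampling weight of all genes
    in one KO group."""

    ko: str
    factor: str
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise GutshiftError("KO effect fold must be positive")


@dataclass(frozen=True)
class OralSpikeSpec:
    """Oral-species spike-ins: each listed species is planted into samples
    of ``group`` with probability ``prevalence``, at a relative abundance
    drawn uniformly from ``abundance_range`` (percent)."""

    species: tuple = DEFAULT_ORAL_SPECIES
    group: str = "ALC"
    abundance_range: tuple = (0.5, 4.0)
    prevalence: float = 0.6

    def __post_init__(self) -> None:
        lo, hi = self.abundance_range
        if not (0 < lo <= hi):
            raise GutshiftError("abundance_range must satisfy 0 < lo <= hi")
        if len(self.species) * hi >= 100:
            raise GutshiftError("oral spike-ins cannot exceed 100% of a sample")
        if not (0 <= self.prevalence <= 1):
            raise GutshiftError("prevalence must lie in [0, 1]")


@dataclass(frozen=True)
class OutlierSpec:
    """Dominance outliers: ``count`` patient samples have a single dominant
    genus (cycled from ``genera``; one genus by default, so planted outliers
    share a dominant taxon) scaled to the ``dominance`` fraction."""

    count: int = 3
    genera: tuple = ("Prevotella",)
    dominance: float = 0.70
    remainder_retention: float = 0.3

    def __post_init__(self) -> None:
        if self.count < 0:
            raise GutshiftError("outlier count must be >= 0")
        if not (0 < self.dominance < 1):
            raise GutshiftError("dominance fraction must lie in (0, 1)")
        if not (0 < self.remainder_retention <= 1):
            raise GutshiftError("remainder_retention must lie in (0, 1]")


def default_effects() -> tuple:
    """The study's planted taxonomic signature.

    Dependence: butyrate-producing Clostridiales commensals depleted;
    Enterobacteriaceae plus a Bifidobacterium/Lactobacillus set enriched.
    Cirrhosis: Bacteroidales commensals depleted; a *different*
    Bifidobacterium/Lactobacillus set enriched (the oral influx is planted
    separately as spike-ins).
    """
    dep_down = (
        "Faecalibacterium prausnitzii", "Coprococcus eutactus",
        "Coprococcus comes", "Roseburia intestinalis", "Roseburia hominis",
        "Eubacterium rectale", "uncl.Clostridiales sp1", "uncl.Clostridiales sp2",
    )
    dep_up = (
        "Klebsiella pneumoniae", "Klebsiella oxytoca", "Escherichia coli",
        "Escherichia fergusonii", "Citrobacter koseri", "Citrobacter freundii",
        "Enterobacter cloacae", "Lactococcus lactis", "Bifidobacterium longum",
        "Lactobacillus gasseri", "Lactobacillus salivarius",
    )
    cirr_down = (
        "Bacteroides uniformis", "Bacteroides vulgatus", "Bacteroides dorei",
        "Bacteroides ovatus", "Prevotella copri", "Prevotella disiens",
        "Parabacteroides distasonis", "Parabacteroides johnsonii",
        "Parabacteroides merdae", "Alistipes shahii",
        "Odoribacter splanchnicus", "Paraprevotella xylaniphila",
    )
    cirr_up = (
        "Lactobacillus antri", "Lactobacillus crispatus",
        "Lactobacillus delbrueckii", "Lactobacillus oris",
        "Lactobacillus ultunensis", "Bifidobacterium animalis",
        "Bifidobacterium dentium", "Gordonibacter pamelaeae",
    )
    return (
        EffectSpec(dep_down, "dependence", 0.25),
        EffectSpec(dep_up, "dependence", 4.0),
        EffectSpec(cirr_down, "cirrhosis", 0.25),
        EffectSpec(cirr_up, "cirrhosis", 4.0),
    )


def default_ko_effects() -> tuple:
    """Planted functional signature on the alcohol-metabolism panel: six
    KO groups up under dependence, nine up under cirrhosis, a few down."""
    up_dep = ALCOHOL_KOS[:6]
    up_cirr = ALCOHOL_KOS[6:15]
    down_dep = ALCOHOL_KOS[16:19]
    down_cirr = ALCOHOL_KOS[16:18]
    return tuple(
        [KoEffectSpec(k, "dependence", 3.0) for k in up_dep]
        + [KoEffectSpec(k, "cirrhosis", 3.0) for k in up_cirr]
        + [KoEffectSpec(k, "dependence", 1 / 3) for k in down_dep]
        + [KoEffectSpec(k, "cirrhosis", 1 / 3) for k in down_cirr]
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters.

    Cohort sizes default to the study design (72 ADS / 27 ALC / 60 matched
    controls); ~300 species and 20k catalogue genes keep the catalogue
    desk-scale, and 100k reads/sample (configurable upward) keeps count
    sampling fast while leaving per-species counts deep enough for the
    planted four-fold effects.
    """

    n_ads: int = 72
    n_alc: int = 27
    n_control: int = 60
    n_species: int = 300
    n_genes: int = 20000
    reads_per_sample: int = 100_000
    baseline_sigma: float = 2.0
    sample_sigma: float = 0.5
    max_mean_share: float = 0.04
    detection_limit_percent: float = 1e-3
    effects: tuple = field(default_factory=default_effects)
    ko_effects: tuple = field(default_factory=default_ko_effects)
    oral_spike: OralSpikeSpec | None = field(default_factory=OralSpikeSpec)
    outlier_spec: OutlierSpec = field(default_factory=OutlierSpec)
    n_generic_kos: int = 300
    ko_genes_per_group: int = 20
    n_vf_genes: int = 50
    vf_decoy_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ads", "n_alc", "n_control"):
            if getattr(self, name) < 0:
                raise GutshiftError(f"{name} must be >= 0")
        if self.n_ads + self.n_alc + self.n_control < 2:
            raise GutshiftError("need at least 2 samples")
        if self.n_species < 2 or self.n_genes < self.n_species:
            raise GutshiftError("need n_species >= 2 and n_genes >= n_species")
        if self.outlier_spec.count > self.n_ads + self.n_alc:
            raise GutshiftError("more outliers requested than patient samples")


@dataclass
class SyntheticTruth:
    """Registry of planted effects, keyed so recovery tests can score
    themselves: (species, factor, fold) tuples, outlier sample -> dominant
    genus, and per-sample spiked oral species."""

    species_effects: list = field(default_factory=list)
    ko_effects: list = field(default_factory=list)
    outliers: dict = field(default_factory=dict)
    oral_spikes: dict = field(default_factory=dict)
    vf_genes: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "species_effects": [list(t) for t in self.species_effects],
            "ko_effects": [list(t) for t in self.ko_effects],
            "outliers": self.outliers,
            "oral_spikes": self.oral_spikes,
            "vf_genes": self.vf_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            species_effects=[tuple(t) for t in payload["species_effects"]],
            ko_effects=[tuple(t) for t in payload["ko_effects"]],
            outliers=payload["outliers"],
            oral_spikes=payload["oral_spikes"],
            vf_genes=payload["vf_genes"],
        )


@dataclass
class StudyData:
    """Complete emitted study: counts + annotation + metadata + hits, the
    species/genus abundance matrices implied by the underlying fractions,
    and the truth registry."""

    counts: CountTable
    annotation: GeneAnnotation
    metadata: SampleMetadata
    hits: HitTable
    species_abundance: AbundanceMatrix
    genus_abundance: AbundanceMatrix
    truth: SyntheticTruth
    taxonomy: pd.DataFrame


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _make_metadata(config: SimulationConfig, rng: np.random.Generator) -> SampleMetadata:
    rows = []
    # Gender ratios and age distributions shaped like the study cohorts
    # (ADS overwhelmingly male, controls balanced).
    specs = [
        ("ADS", config.n_ads, 0.95, 44, 10),
        ("ALC", config.n_alc, 0.80, 49, 7),
        ("Control", config.n_control, 0.47, 36, 11),
    ]
    for group, n, male_frac, age_mean, age_sd in specs:
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1}",
                    "group": group,
                    "gender": "M" if rng.random() < male_frac else "F",
                    "age": int(np.clip(round(rng.normal(age_mean, age_sd)), 20, 60)),
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(df)


def _baseline_means(
    config: SimulationConfig, taxonomy: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal baseline mean abundance per species.

    Species carrying a planted effect draw from a narrower, slightly
    elevated band so the signature taxa are reliably detectable (as the
    real signature taxa are); oral-flagged species sit far below the gut
    baseline.
    """
    locs = np.array(
        [_GENUS_LOC.get(g, _DEFAULT_LOC) for g in taxonomy["genus"]], dtype=float
    )
    dev = rng.normal(0.0, config.baseline_sigma, size=len(taxonomy))
    # Signature taxa draw from a narrow low-to-moderate band: reliably
    # detectable (well above the 0.01%-in-10-samples model filter) yet
    # minor enough that the planted folds shift each factor's community-
    # level explained variance by only a few percent, as observed.
    effect_species = {s for eff in config.effects for s in eff.species}
    is_effect = np.array([s in effect_species for s in taxonomy.index])
    dev[is_effect] = rng.normal(0.0, 0.5, size=int(is_effect.sum()))
    locs[is_effect] = np.maximum(locs[is_effect], 1.0)
    is_oral = np.array([s in ORAL_FLAGGED for s in taxonomy.index])
    locs[is_oral] = _ORAL_LOC
    means = np.exp(locs + dev)
    # Cap any single species' baseline mean share: real species-level means
    # top out around a few percent (genus-level dominance is spread over
    # many congeners), and an uncapped log-normal occasionally mints one
    # mega-species that dominates half the cohort.
    for _ in range(4):
        means = np.minimum(means, config.max_mean_share * means.sum())
    return means


def spike_outliers(
    fractions: pd.DataFrame,
    spec: OutlierSpec,
    taxonomy: pd.DataFrame,
    samples: list,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Plant dominance outliers in the given samples.

    ``fractions`` is species x sample (columns summing to 1); the dominant
    genus cycles through ``spec.genera`` and is scaled to the target
    dominance fraction.  The remainder community collapses to a random
    subset of its species (``remainder_retention``), reproducing the low
    richness of real dominated samples.  Modifies a copy; truth entries are
    appended.
    """
    if spec.count == 0:
        return fractions
    if len(samples) < spec.count:
        raise GutshiftError("not enough samples to plant the requested outliers")
    rng = rng or np.random.default_rng(0)
    out = fractions.copy()
    for i, sample in enumerate(samples[: spec.count]):
        genus = spec.genera[i % len(spec.genera)]
        members = taxonomy.index[taxonomy["genus"] == genus]
        members = members.intersection(out.index)
        col = out[sample].copy()
        genus_mass = float(col.loc[members].sum())
        if genus_mass <= 0:
            raise GutshiftError(f"target genus {genus!r} absent from sample {sample!r}")
        if spec.remainder_retention < 1:
            others = col.index.difference(members)
            dropped = others[rng.random(len(others)) >= spec.remainder_retention]
            col.loc[dropped] = 0.0
        # dominance concentrates in a leading congener (as real dominated
        # communities do), collapsing within-genus evenness too
        leader = col.loc[members].idxmax()
        rest_members = members.difference([leader])
        rest_mass = float(col.loc[rest_members].sum())
        if rest_mass > 0:
            col.loc[rest_members] *= 0.2 * genus_mass / rest_mass
            col.loc[leader] = 0.8 * genus_mass
        rest = float(col.sum()) - genus_mass
        if rest <= 0:
            raise GutshiftError(f"no remainder community left in sample {sample!r}")
        alpha = spec.dominance * rest / ((1.0 - spec.dominance) * genus_mass)
        col.loc[members] *= alpha
        out[sample] = col / col.sum()
        truth.outliers[sample] = genus
    return out


def _species_fractions(
    config: SimulationConfig,
    taxonomy: pd.DataFrame,
    meta: SampleMetadata,
    rng: np.random.Generator,
    truth: SyntheticTruth,
) -> pd.DataFrame:
    n_sp = len(taxonomy)
    samples = meta.sample_ids
    means = _baseline_means(config, taxonomy, rng)
    design = meta.binary_design(("dependence", "cirrhosis"))
    weights = means[:, None] * np.exp(
        rng.normal(0.0, config.sample_sigma, size=(n_sp, len(samples)))
    )

    sp_index = {s: i for i, s in enumerate(taxonomy.index)}
    realized = []
    for eff in config.effects:
        present = [s for s in eff.species if s in sp_index]
        idx = [sp_index[s] for s in present]
        yes = design[eff.factor].to_numpy() == 1.0
        if idx and yes.any():
            weights[np.ix_(idx, yes)] *= eff.fold
            realized.extend((s, eff.factor, eff.fold) for s in present)
    truth.species_effects.extend(realized)

    fractions = pd.DataFrame(
        weights / weights.sum(axis=0), index=taxonomy.index, columns=samples
    )

    if config.oral_spike is not None:
        spike = config.oral_spike
        target_samples = meta.group_samples(spike.group)
        present = [s for s in spike.species if s in sp_index]
        lo, hi = spike.abundance_range
        for sample in target_samples:
            chosen = [s for s in present if rng.random() < spike.prevalence]
            if not chosen:
                continue
            targets = rng.uniform(lo, hi, size=len(chosen)) / 100.0
            col = fractions[sample].copy()
            col.loc[chosen] = 0.0
            rest = col.sum()
            col.loc[chosen] = targets * rest / (1.0 - targets.sum())
            fractions[sample] = col / col.sum()
            truth.oral_spikes[sample] = sorted(chosen)

    patient_samples = [s for s in samples if not s.startswith("Control")]
    chosen = [str(s) for s in rng.choice(patient_samples, size=config.outlier_spec.count, replace=False)] if config.outlier_spec.count else []
    fractions = spike_outliers(fractions, config.outlier_spec, taxonomy, chosen, truth, rng)

    # Detection limit: abundances below the limit are unobservable at the
    # study's sequencing depth and are reported as absent.
    arr = fractions.to_numpy()
    arr[arr < config.detection_limit_percent / 100.0] = 0.0
    arr /= arr.sum(axis=0)
    return pd.DataFrame(arr, index=fractions.index, columns=fractions.columns)


def generate_species_abundance(
    config: SimulationConfig,
) -> tuple[AbundanceMatrix, AbundanceMatrix, SampleMetadata, SyntheticTruth]:
    """Species- and genus-level percent abundance matrices with metadata and
    truth — the fast path for statistical calibration and recovery studies
    that do not need the gene layer."""
    rng = np.random.default_rng(config.seed)
    taxonomy = build_taxonomy(config.n_species)
    truth = SyntheticTruth()
    meta = _make_metadata(config, rng)
    fractions = _species_fractions(config, taxonomy, meta, rng, truth)
    species = AbundanceMatrix(100.0 * fractions, level="species")
    genus = aggregate(species, taxonomy["genus"], level="genus")
    return species, genus, meta, truth


def _assign_genes(
    config: SimulationConfig, taxonomy: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Gene table: species assignment (each species gets at least one gene),
    lengths in [300, 3000] bp, per-gene expression-style weights, KO labels
    (alcohol panel first, then a generic KO pool over half the catalogue)."""
    n = config.n_genes
    species = taxonomy.index.to_numpy()
    owner = np.concatenate(
        [species, rng.choice(species, size=n - len(species), replace=True)]
    )
    rng.shuffle(owner)
    lengths = rng.integers(300, 3001, size=n)
    ko = np.array([""] * n, dtype=object)

    free = rng.permutation(n)
    cursor = 0
    for k in ALCOHOL_KOS:
        take = free[cursor : cursor + config.ko_genes_per_group]
        ko[take] = k
        cursor += config.ko_genes_per_group
    generic_pool = [f"K2{i:04d}" for i in range(config.n_generic_kos)]
    remaining = free[cursor:]
    n_generic = len(remaining) // 2
    ko[remaining[:n_generic]] = rng.choice(generic_pool, size=n_generic)

    gene_ids = [f"gene_{i + 1:06d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "length_bp": lengths,
            "ko": ko,
            "species": owner,
            "genus": taxonomy.loc[owner, "genus"].to_numpy(),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return table


def _make_hits(
    config: SimulationConfig,
    genes: pd.DataFrame,
    rng: np.random.Generator,
    truth: SyntheticTruth,
) -> HitTable:
    """Homology hit table linking Enterobacteriaceae-tagged catalogue genes
    to VF reference ids; passing hits plus decoys failing the similarity
    criterion."""
    entero = genes.index[genes["genus"].isin(ENTEROBACTERIACEAE)].to_numpy()
    if len(entero) == 0 or config.n_vf_genes == 0:
        return HitTable()
    rows = []
    for v in range(config.n_vf_genes):
        vf_id = f"VFG{v + 1:04d}"
        k = int(rng.integers(1, 4))
        for g in rng.choice(entero, size=min(k, len(entero)), replace=False):
            rows.append(
                {
                    "catalogue_gene_id": g,
                    "vf_gene_id": vf_id,
                    "evalue": float(10.0 ** rng.uniform(-60, -10)),
                    "percent_identity": float(rng.uniform(81, 99.9)),
                    "coverage_fraction": float(rng.uniform(0.82, 1.0)),
                }
            )
        truth.vf_genes.append(vf_id)
    n_decoys = int(len(rows) * config.vf_decoy_fraction)
    all_genes = genes.index.to_numpy()
    for d in range(n_decoys):
        mode = d % 3  # fail each criterion in turn
        rows.append(
            {
                "catalogue_gene_id": str(rng.choice(all_genes)),
                "vf_gene_id": f"VFG{int(rng.integers(1, config.n_vf_genes + 1)):04d}",
                "evalue": float(10.0 ** rng.uniform(-4, -1)) if mode == 0 else 1e-30,
                "percent_identity": float(rng.uniform(30, 79)) if mode == 1 else 95.0,
                "coverage_fraction": float(rng.uniform(0.1, 0.7)) if mode == 2 else 0.95,
            }
        )
    return HitTable(pd.DataFrame(rows))


def generate_cohort(config: SimulationConfig) -> StudyData:
    """Generate the complete synthetic study.

    Deterministic for a fixed config (identical seed, identical outputs).
    Returns counts, annotation, metadata, hits, the underlying species and
    genus abundance matrices, and the truth registry.
    """
    rng = np.random.default_rng(config.seed)
    taxonomy = build_taxonomy(config.n_species)
    truth = SyntheticTruth()
    meta = _make_metadata(config, rng)
    fractions = _species_fractions(config, taxonomy, meta, rng, truth)

    genes = _assign_genes(config, taxonomy, rng)
    annotation = GeneAnnotation(genes.copy())

    sp_pos = {s: i for i, s in enumerate(taxonomy.index)}
    owner_idx = np.array([sp_pos[s] for s in genes["species"]])
    base_w = genes["length_bp"].to_numpy(dtype=float) * np.exp(
        rng.normal(0.0, 0.5, size=len(genes))
    )

    design = meta.binary_design(("dependence", "cirrhosis"))
    frac_arr = fractions.to_numpy()
    sample_weights = base_w[:, None] * frac_arr[owner_idx, :]

    ko_series = genes["ko"].to_numpy()
    realized_ko = []
    for eff in config.ko_effects:
        gene_mask = ko_series == eff.ko
        yes = design[eff.factor].to_numpy() == 1.0
        if gene_mask.any() and yes.any():
            sample_weights[np.ix_(gene_mask, yes)] *= eff.fold
            realized_ko.append((eff.ko, eff.factor, eff.fold))
    truth.ko_effects.extend(realized_ko)

    probs = sample_weights / sample_weights.sum(axis=0)
    counts = np.empty((len(genes), len(meta.sample_ids)), dtype=np.int64)
    for j in range(probs.shape[1]):
        counts[:, j] = rng.multinomial(config.reads_per_sample, probs[:, j])
    count_table = CountTable(
        pd.DataFrame(counts, index=genes.index, columns=meta.sample_ids)
    )

    hits = _make_hits(config, genes, rng, truth)
    species = AbundanceMatrix(100.0 * fractions, level="species")
    genus = aggregate(species, taxonomy["genus"], level="genus")
    return StudyData(
        counts=count_table,
        annotation=annotation,
        metadata=meta,
        hits=hits,
        species_abundance=species,
        genus_abundance=genus,
        truth=truth,
        taxonomy=taxonomy,
    )


def write_study(study: StudyData, directory) -> dict:
    """Emit the study as TSV/JSON files consumable by every CLI subcommand.

    Returns the mapping of logical name -> path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "annotation": directory / "genes.tsv",
        "metadata": directory / "metadata.tsv",
        "hits": directory / "hits.tsv",
        "species_abundance": directory / "species_abund.tsv",
        "genus_abundance": directory / "genus_abund.tsv",
        "oral_species": directory / "oral_species.txt",
        "truth": directory / "truth.json",
    }
    tables_io.write_count_table(study.counts, paths["counts"])
    tables_io.write_annotation(study.annotation, paths["annotation"])
    tables_io.write_metadata(study.metadata, paths["metadata"])
    tables_io.write_hit_table(study.hits, paths["hits"])
    tables_io.write_abundance(study.species_abundance, paths["species_abundance"])
    tables_io.write_abundance(study.genus_abundance, paths["genus_abundance"])
    paths["oral_species"].write_text("\n".join(DEFAULT_ORAL_SPECIES) + "\n")
    study.truth.to_json(paths["truth"])
    return paths


def config_from_yaml(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML mapping; nested effect lists use
    the field names of the corresponding spec dataclasses."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "effects" in raw:
        raw["effects"] = tuple(
            EffectSpec(tuple(e["species"]), e["factor"], float(e["fold"]))
            for e in raw["effects"]
        )
    if "ko_effects" in raw:
        raw["ko_effects"] = tuple(
            KoEffectSpec(e["ko"], e["factor"], float(e["fold"])) for e in raw["ko_effects"]
        )
    if "oral_spike" in raw and raw["oral_spike"] is not None:
        o = raw["oral_spike"]
        raw["oral_spike"] = OralSpikeSpec(
            species=tuple(o.get("species", DEFAULT_ORAL_SPECIES)),
            group=o.get("group", "ALC"),
            abundance_range=tuple(o.get("abundance_range", (0.5, 8.0))),
            prevalence=float(o.get("prevalence", 0.8)),
        )
    if "outlier_spec" in raw:
        o = raw["outlier_spec"]
        raw["outlier_spec"] = OutlierSpec(
            count=int(o.get("count", 3)),
            genera=tuple(o.get("genera", ("Prevotella", "Bacteroides", "Lactobacillus"))),
            dominance=float(o.get("dominance", 0.70)),
        )
    return SimulationConfig(**raw)
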