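import numpy as np
import pandas as pd
import pytest

import gutshift as gs


@pytest.fixture(scope="session")
def species_cohort():
    """Default study-shaped cohort (72/27/60), species level, with truth."""
    cfg = gs.SimulationConfig(seed=11)
    species, genus, meta, truth = gs.generate_species_abundance(cfg)
    return species, genus, meta, truth


@pytest.fixture(scope="session")
def full_study():
    """Default cohort with the gene layer (counts, annotation, hits)."""
    return gs.generate_cohort(gs.SimulationConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_abundance(values, samples=None, features=None, level="species"):
    values = np.asarray(values, dtype=float)
    features = features or [f"sp{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return gs.AbundanceMatrix(
        pd.DataFrame(values, index=features, columns=samples), level=level
    )


def make_metadata(groups, genders=None):
    ids = [f"{g}_{i}" for i, g in enumerate(groups)]
    df = pd.DataFrame({"group": groups}, index=pd.Index(ids, name="sample_id"))
    if genders is not None:
        df["gender"] = genders
    return gs.SampleMetadata(df)


@pytest.fixture()
def two_group_meta():
    return make_metadata(["ADS"] * 5 + ["Control"] * 5)
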