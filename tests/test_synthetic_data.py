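import numpy as np
import pandas as pd
import pytest

import gutshift as gs
from gutshift.synthetic_data import build_taxonomy


def null_config(seed=0, **kwargs):
    defaults = dict(
        n_ads=30, n_alc=0, n_control=30, n_species=100,
        effects=(), ko_effects=(), oral_spike=None,
        outlier_spec=gs.OutlierSpec(count=0), seed=seed,
    )
    defaults.update(kwargs)
    return gs.SimulationConfig(**defaults)


class TestConfigValidation:
    def test_rejects_negative_cohort(self):
        with pytest.raises(gs.GutshiftError):
            gs.SimulationConfig(n_ads=-1)

    def test_rejects_infeasible_oral_spike(self):
        with pytest.raises(gs.GutshiftError):
            gs.OralSpikeSpec(abundance_range=(10.0, 25.0))  # 5 x 25 % > 100 %

    def test_rejects_bad_dominance(self):
        with pytest.raises(gs.GutshiftError):
            gs.OutlierSpec(dominance=1.2)

    def test_rejects_nonpositive_fold(self):
        with pytest.raises(gs.GutshiftError):
            gs.EffectSpec(("x",), "dependence", 0.0)


class TestGeneration:
    def test_same_seed_bitwise_identical(self):
        a = gs.generate_cohort(gs.SimulationConfig(seed=5, n_species=60, n_genes=600))
        b = gs.generate_cohort(gs.SimulationConfig(seed=5, n_species=60, n_genes=600))
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
        pd.testing.assert_frame_equal(a.hits.hits, b.hits.hits)
        pd.testing.assert_frame_equal(a.metadata.table, b.metadata.table)
        assert a.truth.outliers == b.truth.outliers

    def test_different_seed_differs(self):
        a = gs.generate_cohort(gs.SimulationConfig(seed=5, n_species=60, n_genes=600))
        b = gs.generate_cohort(gs.SimulationConfig(seed=6, n_species=60, n_genes=600))
        assert not a.counts.counts.equals(b.counts.counts)

    def test_normalized_counts_sum_to_100(self, full_study):
        abund = gs.gene_relative_abundance(full_study.counts, full_study.annotation)
        assert np.allclose(abund.values.sum(axis=0), 100.0, atol=1e-9)

    def test_metadata_encodes_cohort_design(self, full_study):
        table = full_study.metadata.table
        assert (table.loc[table["group"] == "ALC", "dependence"] == "yes").all()
        assert (table.loc[table["group"] == "ALC", "cirrhosis"] == "yes").all()
        assert (table.loc[table["group"] == "ADS", "cirrhosis"] == "no").all()
        assert (table["group"].value_counts()[["ADS", "ALC", "Control"]] == [72, 27, 60]).all()

    def test_planted_fourfold_effect_realized_in_expectation(self):
        cfg = gs.SimulationConfig(seed=21)
        species, genus, meta, truth = gs.generate_species_abundance(cfg)
        alc = meta.group_samples("ALC")
        ctrl = meta.group_samples("Control")
        up = [s for s, f, fold in truth.species_effects if f == "cirrhosis" and fold == 4.0]
        ratios = species.values.loc[up, alc].mean(axis=1) / species.values.loc[up, ctrl].mean(axis=1)
        assert 3.0 <= ratios.mean() <= 5.0

    def test_truth_signs_match_empirical_group_means(self):
        cfg = gs.SimulationConfig(seed=13)
        species, genus, meta, truth = gs.generate_species_abundance(cfg)
        ctrl = meta.group_samples("Control")
        for sp, factor, fold in truth.species_effects:
            yes = meta.group_samples(factor)
            ratio = species.values.loc[sp, yes].mean() / species.values.loc[sp, ctrl].mean()
            assert (ratio > 1) == (fold > 1), (sp, factor, fold, ratio)

    def test_gene_layer_recovers_species_fractions(self, full_study):
        gene_abund = gs.gene_relative_abundance(full_study.counts, full_study.annotation)
        species = gs.aggregate(
            gene_abund,
            full_study.annotation.labels(full_study.counts.gene_ids, "species"),
            "species",
        )
        truth_vals = full_study.species_abundance.values.loc[
            species.values.index, species.values.columns
        ]
        corr = np.corrcoef(
            species.values.to_numpy().ravel(), truth_vals.to_numpy().ravel()
        )[0, 1]
        assert corr > 0.98

    def test_oral_spikes_restricted_to_target_group(self, species_cohort):
        species, genus, meta, truth = species_cohort
        assert truth.oral_spikes  # some samples spiked
        assert all(meta.table.loc[s, "group"] == "ALC" for s in truth.oral_spikes)

    def test_null_cohort_has_no_truth_entries(self):
        species, genus, meta, truth = gs.generate_species_abundance(null_config())
        assert not truth.species_effects and not truth.outliers and not truth.oral_spikes


class TestSpikeOutliers:
    def test_realized_dominance_near_target_with_low_richness(self, species_cohort):
        species, genus, meta, truth = species_cohort
        for sample, dom_genus in truth.outliers.items():
            share = genus.values.loc[dom_genus, sample]
            assert 67.0 <= share <= 74.0
            assert gs.shannon(species.values[sample]) < 2.5

    def test_zero_outliers_leave_data_unchanged(self):
        taxonomy = build_taxonomy(20)
        rng = np.random.default_rng(0)
        frac = pd.DataFrame(
            rng.dirichlet(np.ones(20), size=4).T, index=taxonomy.index,
            columns=list("abcd"),
        )
        truth = gs.SyntheticTruth()
        out = gs.synthetic_data.spike_outliers(
            frac, gs.OutlierSpec(count=0), taxonomy, [], truth
        )
        pd.testing.assert_frame_equal(out, frac)
        assert not truth.outliers

    def test_absent_genus_errors(self):
        taxonomy = build_taxonomy(20)
        frac = pd.DataFrame(
            np.ones((20, 3)) / 20, index=taxonomy.index, columns=list("abc")
        )
        prevotella = taxonomy.index[taxonomy["genus"] == "Prevotella"]
        frac.loc[prevotella] = 0.0
        frac /= frac.sum(axis=0)
        with pytest.raises(gs.GutshiftError, match="Prevotella"):
            gs.synthetic_data.spike_outliers(
                frac, gs.OutlierSpec(count=1), taxonomy, ["a"], gs.SyntheticTruth(),
                np.random.default_rng(0),
            )

    def test_two_outliers_in_small_cohort_recovered(self):
        cfg = gs.SimulationConfig(
            n_ads=20, n_alc=0, n_control=0, n_species=80,
            effects=(), ko_effects=(), oral_spike=None,
            outlier_spec=gs.OutlierSpec(count=2), seed=4,
        )
        species, genus, meta, truth = gs.generate_species_abundance(cfg)
        report = gs.detect_outliers(gs.bray_curtis(genus), linkage="ward")
        assert sorted(report.outliers) == sorted(truth.outliers)


class TestRecoveryMonotonicity:
    def test_recovery_rate_increases_with_effect_size(self):
        taxonomy = build_taxonomy(100)
        targets = tuple(taxonomy.index[i] for i in (5, 20, 40, 60, 80))
        rates = []
        for fold in (1.3, 2.0, 4.0):
            hits = total = 0
            for rep in range(15):
                cfg = null_config(
                    seed=rep, effects=(gs.EffectSpec(targets, "dependence", fold),)
                )
                species, genus, meta, truth = gs.generate_species_abundance(cfg)
                diff = gs.differential_features(
                    species, meta, "ADS", "Control", q_threshold=0.01,
                    filter_spec=gs.SPECIES_FILTER,
                )
                planted = {s for s, _, _ in truth.species_effects}
                hits += sum(
                    1 for s in planted if s in diff.index and diff.loc[s, "significant"]
                )
                total += len(planted)
            rates.append(hits / total)
        assert rates[0] <= rates[1] + 0.05
        assert rates[1] <= rates[2] + 0.05
        assert rates[2] > rates[0]


class TestWriteStudy:
    def test_emitted_files_feed_the_whole_pipeline(self, tmp_path):
        cfg = gs.SimulationConfig(seed=3, n_species=80, n_genes=900,
                                  reads_per_sample=20_000, n_ads=12, n_alc=8,
                                  n_control=10, outlier_spec=gs.OutlierSpec(count=1))
        study = gs.generate_cohort(cfg)
        paths = gs.write_study(study, tmp_path / "study")
        counts = gs.tables_io.read_count_table(paths["counts"])
        pd.testing.assert_frame_equal(counts.counts, study.counts.counts)
        meta = gs.tables_io.read_metadata(paths["metadata"])
        assert (meta.table.loc[meta.table["group"] == "ALC", "cirrhosis"] == "yes").all()
        ann = gs.tables_io.read_annotation(paths["annotation"])
        abund = gs.gene_relative_abundance(counts, ann)
        species = gs.aggregate(abund, ann.labels(counts.gene_ids, "species"), "species")
        diff = gs.differential_features(species, meta, "ADS", "Control",
                                        filter_spec=gs.SPECIES_FILTER)
        assert len(diff) > 0
        hits = gs.tables_io.read_hit_table(paths["hits"])
        vf = gs.vf_aggregate(gs.filter_hits(hits), abund)
        assert len(vf.abundance.values) > 0
        truth = gs.SyntheticTruth.from_json(paths["truth"])
        assert truth.outliers == study.truth.outliers
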