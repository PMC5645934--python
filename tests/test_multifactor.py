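import itertools

import numpy as np
import pandas as pd
import pytest

import gutshift as gs
from conftest import make_abundance, make_metadata


def random_dissimilarity(rng, n):
    x = rng.dirichlet(np.ones(30), size=n).T * 100
    return gs.bray_curtis(make_abundance(x, samples=[f"S{i}" for i in range(n)]))


def exhaustive_permanova_p(d, labels):
    """Oracle: pseudo-F over every assignment of the label multiset."""
    labels = np.asarray(labels)
    codes = (labels == labels[np.argsort(labels)[0]]).astype(int)
    n = len(codes)
    d2 = d.values.to_numpy() ** 2

    def pseudo_f(c):
        ss_t = d2.sum() / (2 * n)
        ss_w = 0.0
        for g in (0, 1):
            mask = c == g
            ss_w += d2[np.ix_(mask, mask)].sum() / (2 * mask.sum())
        a = 2
        return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = pseudo_f(codes)
    n_a = int(codes.sum())
    fs = []
    for idx in itertools.combinations(range(n), n_a):
        c = np.zeros(n, dtype=int)
        c[list(idx)] = 1
        fs.append(pseudo_f(c))
    return float((np.array(fs) >= f_obs - 1e-12).mean())


class TestPermanova:
    def test_statistic_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        d = random_dissimilarity(rng, 14)
        labels = ["A"] * 7 + ["B"] * 7
        mine = gs.permanova(d, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values.to_numpy(), ids=d.sample_ids),
            grouping=labels,
            permutations=99,
        )
        assert mine.f_statistic == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_converges_to_exhaustive_permutation_p(self, rng):
        d = random_dissimilarity(rng, 8)
        labels = ["A"] * 4 + ["B"] * 4
        p_exact = exhaustive_permanova_p(d, labels)
        mc = gs.permanova(d, labels, n_perm=9999, seed=1)
        assert mc.p == pytest.approx(p_exact, abs=0.02)

    def test_p_never_below_permutation_floor(self, rng):
        x = rng.lognormal(0, 0.3, size=(20, 12))
        x[:10, :6] *= 50
        x[10:, 6:] *= 50
        abund = make_abundance(100 * x / x.sum(0))
        res = gs.permanova(gs.bray_curtis(abund), ["A"] * 6 + ["B"] * 6, n_perm=99, seed=0)
        assert res.p >= 1 / 100
        assert res.r2 > 0.3

    def test_deterministic_under_fixed_seed(self, rng):
        d = random_dissimilarity(rng, 12)
        labels = ["A"] * 6 + ["B"] * 6
        r1 = gs.permanova(d, labels, n_perm=199, seed=7)
        r2 = gs.permanova(d, labels, n_perm=199, seed=7)
        assert r1.p == r2.p and r1.f_statistic == r2.f_statistic

    def test_duplicating_samples_preserves_r2(self, rng):
        x = rng.dirichlet(np.ones(20), size=8).T * 100
        abund = make_abundance(x)
        labels = ["A"] * 4 + ["B"] * 4
        r1 = gs.permanova(gs.bray_curtis(abund), labels, n_perm=19, seed=0)
        doubled = gs.AbundanceMatrix(
            pd.concat([abund.values, abund.values.add_suffix("_dup")], axis=1),
            level="species",
        )
        r2 = gs.permanova(gs.bray_curtis(doubled), labels * 2, n_perm=19, seed=0)
        assert r2.r2 == pytest.approx(r1.r2, abs=1e-10)

    def test_single_level_factor_errors(self, rng):
        d = random_dissimilarity(rng, 6)
        with pytest.raises(gs.GutshiftError, match="single level"):
            gs.permanova(d, ["A"] * 6)


class TestPermanovaScreen:
    def test_only_planted_factor_passes(self, rng):
        hits = 0
        for rep in range(20):
            rep_rng = np.random.default_rng(1000 + rep)
            n = 40
            x = rep_rng.lognormal(0, 0.5, size=(30, n))
            grp = np.array(["ADS"] * 20 + ["Control"] * 20)
            x[:6, grp == "ADS"] *= 5  # dependence-linked shift only
            abund = make_abundance(100 * x / x.sum(0), samples=[f"S{i}" for i in range(n)])
            meta = gs.SampleMetadata(pd.DataFrame({
                "group": grp,
                "gender": rep_rng.choice(["F", "M"], size=n),
                "age": rep_rng.integers(25, 60, size=n),
            }, index=abund.sample_ids))
            scr = gs.permanova_screen(
                gs.bray_curtis(abund), meta,
                factors=("dependence", "gender", "age"), n_perm=199, seed=rep,
            )
            passed = scr.index[scr["p_adjusted"] < 0.05].tolist()
            hits += passed == ["dependence"]
        assert hits >= 18  # >= 90 % of replicates

    def test_results_invariant_to_sample_order(self, species_cohort):
        species, genus, meta, truth = species_cohort
        d = gs.bray_curtis(species)
        scr = gs.permanova_screen(d, meta, factors=("dependence",), n_perm=99, seed=3)
        rev = species.subset_samples(list(reversed(species.sample_ids)))
        scr2 = gs.permanova_screen(gs.bray_curtis(rev), meta, factors=("dependence",), n_perm=99, seed=3)
        assert scr.loc["dependence", "R2"] == pytest.approx(scr2.loc["dependence", "R2"], abs=1e-12)


class TestMultifactorAssociation:
    def test_cirrhosis_effect_assigned_to_cirrhosis_not_dependence(self, rng):
        meta = make_metadata(["ADS"] * 30 + ["ALC"] * 20 + ["Control"] * 30,
                             genders=list(rng.choice(["F", "M"], size=80)))
        x = rng.lognormal(0, 0.4, size=(40, 80))
        cirr = (meta.table["cirrhosis"] == "yes").to_numpy()
        x[5, cirr] *= 5
        abund = make_abundance(100 * x / x.sum(0), samples=meta.sample_ids)
        out = gs.multifactor_association(abund, meta)
        row = out.loc[("sp5", "cirrhosis")]
        assert row["significant"] and row["coefficient"] > 0
        assert not out.loc[("sp5", "dependence"), "significant"]

    def test_shared_enrichment_attributed_to_dependence(self, rng):
        # planted higher in both patient cohorts: the dependence term carries
        # it while cirrhosis absorbs only the ALC-specific extra (none here)
        meta = make_metadata(["ADS"] * 30 + ["ALC"] * 20 + ["Control"] * 30,
                             genders=list(rng.choice(["F", "M"], size=80)))
        x = rng.lognormal(0, 0.4, size=(40, 80))
        dep = (meta.table["dependence"] == "yes").to_numpy()
        x[7, dep] *= 5
        abund = make_abundance(100 * x / x.sum(0), samples=meta.sample_ids)
        out = gs.multifactor_association(abund, meta)
        row = out.loc[("sp7", "dependence")]
        assert row["significant"] and row["coefficient"] > 0

    def test_null_taxa_calibrated(self, rng):
        meta = make_metadata(["ADS"] * 40 + ["Control"] * 40,
                             genders=list(rng.choice(["F", "M"], size=80)))
        raw_rates = []
        n_sig = 0
        for rep in range(20):
            rep_rng = np.random.default_rng(rep)
            x = rep_rng.lognormal(0, 0.4, size=(50, 80))
            abund = make_abundance(100 * x / x.sum(0), samples=meta.sample_ids)
            out = gs.multifactor_association(abund, meta, factors=("dependence", "gender"))
            raw_rates.append((out["p"] < 0.05).mean())
            n_sig += int(out["significant"].sum())
        assert abs(np.mean(raw_rates) - 0.05) < 0.02
        assert n_sig <= 2  # essentially none after FDR

    def test_rare_taxon_excluded_by_sample_filter(self, rng):
        meta = make_metadata(["ADS"] * 10 + ["Control"] * 10)
        x = np.vstack([rng.uniform(1, 5, size=(3, 20)), np.zeros((1, 20))])
        x[3, 0] = 0.5  # abundant in a single sample only
        abund = make_abundance(100 * x / x.sum(0), samples=meta.sample_ids)
        out = gs.multifactor_association(abund, meta, factors=("dependence",))
        assert "sp3" not in out.index.get_level_values("taxon")

    def test_constant_factor_dropped_with_warning(self, rng):
        meta = make_metadata(["ADS"] * 6 + ["Control"] * 6, genders=["M"] * 12)
        x = rng.uniform(1, 5, size=(5, 12))
        abund = make_abundance(100 * x / x.sum(0), samples=meta.sample_ids)
        with pytest.warns(UserWarning, match="constant"):
            out = gs.multifactor_association(abund, meta, min_samples=3)
        assert "gender" not in out.index.get_level_values("factor")

    def test_direction_agrees_with_mann_whitney_on_planted_taxa(self, species_cohort):
        species, genus, meta, truth = species_cohort
        assoc = gs.multifactor_association(species, meta)
        diff = gs.differential_features(
            species, meta, "dependence", "Control", q_threshold=0.05,
            filter_spec=gs.SPECIES_FILTER,
        )
        dep_species = [s for s, f, _ in truth.species_effects if f == "dependence"]
        checked, agree = 0, 0
        for s in dep_species:
            if (s, "dependence") in assoc.index and s in diff.index:
                checked += 1
                same = np.sign(assoc.loc[(s, "dependence"), "coefficient"]) == np.sign(
                    diff.loc[s, "direction"]
                )
                agree += bool(same)
        assert checked > 0 and agree / checked >= 0.95
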