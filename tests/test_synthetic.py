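"""Synthetic study-data generators: determinism, injected effects and
ground-truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from microfast import community, som, synthetic
from microfast.records import CompositionSet


class TestGenerateReference:
    def test_two_species_divergence_half(self):
        """(2, 200, 0.5): the generated pair differs at ~100 positions
        (expected pairwise Hamming = divergence * length)."""
        ref = synthetic.generate_reference(2, 200, 0.5, seed=1)
        t = list(ref.templates.values())
        assert 80 <= som.hamming(t[0], t[1]) <= 120

    def test_deterministic(self):
        a = synthetic.generate_reference(10, 100, 0.3, seed=5)
        b = synthetic.generate_reference(10, 100, 0.3, seed=5)
        assert a.templates == b.templates
        assert a.taxonomy.equals(b.taxonomy)

    def test_too_few_species_errors(self):
        with pytest.raises(ValueError):
            synthetic.generate_reference(1, 200, 0.1)

    def test_invalid_divergence_errors(self):
        with pytest.raises(ValueError):
            synthetic.generate_reference(5, 200, 0.0)

    def test_taxonomy_covers_expected_phyla(self, small_reference):
        phyla = set(small_reference.taxonomy["phylum"])
        for p in ("Firmicutes", "Bacteroidetes", "Proteobacteria",
                  "Actinobacteria", "Verrucomicrobia"):
            assert p in phyla
        assert (small_reference.taxonomy["domain"] == "eukaryote").any()

    def test_cross_genus_divergence_exceeds_within(self, small_reference):
        tax = small_reference.taxonomy
        tpl = small_reference.templates
        ids = list(tax.index)
        within, across = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = som.hamming(tpl[ids[i]], tpl[ids[j]])
                if tax.loc[ids[i], "genus"] == tax.loc[ids[j], "genus"]:
                    within.append(d)
                else:
                    across.append(d)
        assert max(within) < min(across)


class TestGenerateComposition:
    def _setup(self, multipliers=None, carriers=None, seed=0):
        ref = synthetic.generate_reference(20, 100, 0.3, seed=seed)
        design = synthetic.generate_cohort(n_ra=3, n_mets=2, seed=seed)
        effect = synthetic.EffectConfig(
            phylum_multipliers=multipliers or dict(
                synthetic.DEFAULT_PHYLUM_MULTIPLIERS
            ),
            rare_carriers=carriers or {},
        )
        comp = synthetic.generate_composition(
            design, ref, effect=effect, seed=seed,
            markers=("16S", "ITS"), timepoints=("T0", "T3"),
        )
        return ref, design, comp

    def test_rows_normalized(self):
        _, _, comp = self._setup()
        assert np.allclose(comp.frequencies.sum(axis=1), 1.0, atol=1e-9)

    def test_identity_multipliers_keep_t0_equal_t3(self):
        mult = {p: 1.0 for p in synthetic.DEFAULT_PHYLUM_MULTIPLIERS}
        _, _, comp = self._setup(multipliers=mult)
        t0 = comp.frequencies.loc[comp.meta["timepoint"] == "T0"]
        t3 = comp.frequencies.loc[comp.meta["timepoint"] == "T3"]
        t3 = t3.set_index(t0.index)  # same donor order by construction
        assert np.allclose(t0.to_numpy(), t3.to_numpy())

    def test_multipliers_reorder_phylum_rollup(self):
        mult = {p: 1.0 for p in synthetic.DEFAULT_PHYLUM_MULTIPLIERS}
        mult["Firmicutes"], mult["Bacteroidetes"] = 0.5, 2.0
        ref, _, comp = self._setup(multipliers=mult, seed=2)
        rolled = community.rollup_taxonomy(
            comp.frequencies, ref.taxonomy, "phylum"
        )
        t0 = rolled.loc[comp.meta["timepoint"] == "T0"].mean()
        t3 = rolled.loc[comp.meta["timepoint"] == "T3"].mean()
        assert (t3["Bacteroidetes"] / t0["Bacteroidetes"]) > 1
        assert (t3["Firmicutes"] / t0["Firmicutes"]) < 1
        assert t3["Bacteroidetes"] - t0["Bacteroidetes"] > 0

    def test_rare_species_only_in_configured_ra_t0(self):
        ref, design, comp = self._setup(
            carriers={"RA_01": ["sp_000"]}, seed=3
        )
        f = comp.frequencies["sp_000"]
        carrier_t0 = "RA_01.T0.16S"
        assert f[carrier_t0] == pytest.approx(
            synthetic.DEFAULT_RARE_FREQUENCY, rel=0.01
        )
        assert (f.drop(carrier_t0) == 0).all()

    def test_eukaryote_marker_has_smaller_pool(self):
        ref, _, comp = self._setup()
        its = comp.frequencies.loc[comp.meta["marker"] == "ITS"]
        s16 = comp.frequencies.loc[comp.meta["marker"] == "16S"]
        assert (
            its.gt(0).sum(axis=1).to_numpy()
            < s16.gt(0).sum(axis=1).to_numpy()
        ).all()

    def test_nonpositive_multiplier_errors(self):
        with pytest.raises(ValueError):
            synthetic.EffectConfig(phylum_multipliers={"Firmicutes": 0.0})


class TestSimulateReads:
    def test_zero_error_reads_equal_templates(self, tiny_reference):
        comp = pd.Series(
            {tiny_reference.species_ids[0]: 0.5,
             tiny_reference.species_ids[1]: 0.5}
        )
        rs = synthetic.simulate_reads(comp, tiny_reference, depth=50,
                                      substitution_rate=0.0, seed=0)
        for seq, sp in zip(rs.sequences, rs.true_species):
            assert seq == tiny_reference.templates[sp]

    def test_depth_conserved(self, tiny_reference):
        comp = pd.Series({s: 1 / 8 for s in tiny_reference.species_ids})
        rs = synthetic.simulate_reads(comp, tiny_reference, depth=1000, seed=1)
        assert len(rs) == 1000
        assert len(rs.true_species) == 1000

    def test_mean_mismatches_match_rate(self, small_reference):
        sid = small_reference.species_ids[0]
        comp = pd.Series({sid: 1.0})
        rs = synthetic.simulate_reads(
            comp, small_reference, depth=2000, substitution_rate=0.01, seed=2
        )
        tpl = small_reference.templates[sid]
        mm = np.mean([som.hamming(s, tpl) for s in rs.sequences])
        assert mm == pytest.approx(2.0, abs=0.3)  # 0.01 * 200

    def test_unknown_species_errors(self, tiny_reference):
        with pytest.raises(ValueError):
            synthetic.simulate_reads(
                pd.Series({"ghost": 1.0}), tiny_reference, depth=10
            )

    def test_deterministic(self, tiny_reference):
        comp = pd.Series({s: 1 / 8 for s in tiny_reference.species_ids})
        a = synthetic.simulate_reads(comp, tiny_reference, depth=100, seed=9)
        b = synthetic.simulate_reads(comp, tiny_reference, depth=100, seed=9)
        assert a.sequences == b.sequences and a.true_species == b.true_species


class TestPathwayDb:
    def test_scores_in_unit_interval(self, small_reference):
        db = synthetic.generate_pathway_db(small_reference, 30, seed=0)
        v = db.scores.to_numpy()
        assert (v >= 0).all() and (v <= 1).all()

    def test_deterministic(self, small_reference):
        a = synthetic.generate_pathway_db(small_reference, 30, seed=4)
        b = synthetic.generate_pathway_db(small_reference, 30, seed=4)
        assert a.scores.equals(b.scores) and a.hierarchy.equals(b.hierarchy)

    def test_zero_bias_means_independent_of_phylum(self, small_reference):
        db = synthetic.generate_pathway_db(
            small_reference, 200, seed=5, phylum_bias=0.0
        )
        means = db.scores.mean(axis=1).groupby(
            small_reference.taxonomy["phylum"]
        ).mean()
        assert means.max() - means.min() < 0.05

    def test_bias_raises_biosynthesis_for_target_phyla(self, small_reference):
        db = synthetic.generate_pathway_db(
            small_reference, 40, seed=6, phylum_bias=0.3
        )
        bio = db.hierarchy.index[db.hierarchy["h1"] == "biosynthesis"]
        mean_bio = db.scores[bio].mean(axis=1)
        phyla = small_reference.taxonomy["phylum"]
        biased = mean_bio[phyla.isin(synthetic.BIASED_PHYLA)].mean()
        rest = mean_bio[~phyla.isin(synthetic.BIASED_PHYLA)].mean()
        assert biased > rest + 0.1


class TestClinicalComponents:
    def test_component_ranges(self, small_cohort):
        df = synthetic.generate_clinical_components(small_cohort, seed=0)
        assert df["tjc28"].between(0, 28).all()
        assert df["sjc28"].between(0, 28).all()
        assert (df["esr"] > 0).all()
        assert (df["crp"] >= 0).all()
        assert df["gh"].between(0, 100).all()
        assert df["pga"].between(0, 10).all() and df["ega"].between(0, 10).all()

    def test_identity_effect_stationary(self, small_cohort):
        effect = synthetic.ClinicalEffect(
            multipliers={tp: 1.0 for tp in ("T0", "T1", "T2", "T3")}
        )
        df = synthetic.generate_clinical_components(
            small_cohort, effect=effect, seed=1
        )
        ra = df[df["group"] == "RA"]
        med = ra.groupby("timepoint")["esr"].median()
        assert med.max() / med.min() < 1.5  # noise only, no trend

    def test_improvement_reduces_das28(self, small_cohort):
        from microfast.clinical import das28_esr

        big = synthetic.generate_cohort(n_ra=15, n_mets=2, seed=3)
        df = synthetic.generate_clinical_components(big, seed=2)
        ra = df[df["group"] == "RA"]
        das = ra.apply(
            lambda r: das28_esr(r.tjc28, r.sjc28, r.esr, r.gh), axis=1
        )
        med = das.groupby(ra["timepoint"]).median()
        assert med["T3"] < med["T0"]


class TestCytometry:
    def test_fractions_sum_to_one(self, null_cytometry):
        assert np.allclose(null_cytometry.fractions.sum(axis=1), 1.0,
                           atol=1e-9)

    def test_deterministic(self, small_cohort):
        a = synthetic.generate_cytometry_table(small_cohort, 20, seed=8)
        b = synthetic.generate_cytometry_table(small_cohort, 20, seed=8)
        assert a.fractions.equals(b.fractions)

    def test_effect_lowers_ra_baseline(self):
        design = synthetic.generate_cohort(n_ra=15, n_mets=10, seed=9)
        t = synthetic.generate_cytometry_table(
            design, 20,
            effect=synthetic.CytometryEffect(target_population="pop_003"),
            seed=10,
        )
        t0 = t.meta["timepoint"] == "T0"
        ra = t.fractions.loc[t0 & (t.meta["group"] == "RA"), "pop_003"]
        mets = t.fractions.loc[t0 & (t.meta["group"] == "MetS"), "pop_003"]
        assert ra.mean() < mets.mean()
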