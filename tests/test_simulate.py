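"""Ground-truth recoverability and determinism of the synthetic study."""

import numpy as np
import pytest

from periomics import io
from periomics.simulate import (
    GroundTruth,
    StudyDesign,
    default_truth,
    feature_id,
    generate_metabolome,
    generate_metagenome,
)


class TestDeterminism:
    def test_metabolome_rerun_is_byte_identical(self, tmp_path):
        design = StudyDesign(seed=1)
        truth = default_truth(seed=1, n_carnitine=5, n_bile=5, n_inert=10, n_contaminant=2)
        paths = []
        for run in range(2):
            data = generate_metabolome(design, truth)
            p = tmp_path / f"run{run}.mgf"
            io.write_mgf(data.spectra["Antepartum"], p)
            f = tmp_path / f"run{run}.tsv"
            io.write_feature_table(
                data.tables["Antepartum"], f, tmp_path / f"meta{run}.tsv"
            )
            paths.append((p.read_bytes(), f.read_bytes()))
        assert paths[0] == paths[1]

    def test_metagenome_seed_determinism(self):
        design = StudyDesign(seed=9)
        truth = default_truth(seed=9, n_carnitine=2, n_bile=2, n_inert=2, n_contaminant=1)
        a = generate_metagenome(design, truth)["Antepartum"].counts
        b = generate_metagenome(design, truth)["Antepartum"].counts
        np.testing.assert_array_equal(a, b)


class TestEffectInjection:
    def test_null_truth_gives_equal_arm_distributions(self):
        design = StudyDesign(seed=2)
        truth = default_truth(
            seed=2, n_carnitine=20, n_bile=0, n_inert=20, n_contaminant=2,
            carnitine_fold=1.0, hexose_fold=1.0,
        )
        assert truth.effects == {}
        data = generate_metabolome(design, truth)
        table = data.tables["Antepartum"]
        treat = table.samples["phase"] == "treatment"
        amp = table.areas[:, (treat & (table.samples["arm"] == "AMP")).to_numpy()]
        pbs = table.areas[:, (treat & (table.samples["arm"] == "PBS")).to_numpy()]
        # same generative distribution: pooled mean log-areas agree closely
        ratio = np.log(amp[amp > 0].mean()) - np.log(pbs[pbs > 0].mean())
        assert abs(ratio) < 0.15

    def test_fourfold_carnitine_effect_recovered(self):
        design = StudyDesign(seed=3, dropout=0.0)
        truth = default_truth(
            seed=3, n_carnitine=50, n_bile=0, n_inert=10, n_contaminant=1,
            carnitine_fold=4.0,
        )
        data = generate_metabolome(design, truth)
        table = data.tables["Antepartum"]
        carn = (table.features["mol_class"] == "carnitine").to_numpy()
        treat = (table.samples["phase"] == "treatment").to_numpy()
        amp = table.areas[np.ix_(carn, treat & (table.samples["arm"] == "AMP").to_numpy())]
        pbs = table.areas[np.ix_(carn, treat & (table.samples["arm"] == "PBS").to_numpy())]
        ratio = amp.mean(axis=1) / pbs.mean(axis=1)
        assert 3.0 <= ratio.mean() <= 5.3

    def test_drug_only_in_treated_dams_after_dosing(self, small_metabolome):
        table = small_metabolome.tables["Antepartum"]
        drug = (table.features["mol_class"] == "drug").to_numpy()
        pre_or_control = (
            (table.samples["phase"] == "pre")
            | (table.samples["arm"] == "PBS")
        ).to_numpy() & (table.samples["type"] == "sample").to_numpy()
        assert table.areas[drug][:, pre_or_control].sum() == 0.0
        treated_during = (
            (table.samples["arm"] == "AMP")
            & (table.samples["phase"] == "treatment")
        ).to_numpy()
        assert np.all(table.areas[drug][:, treated_during] > 0)

    def test_blanks_carry_contaminants_only(self, small_metabolome):
        table = small_metabolome.tables["Antepartum"]
        blanks = (table.samples["type"] == "blank").to_numpy()
        contam = (table.features["mol_class"] == "contaminant").to_numpy()
        assert np.all(table.areas[np.ix_(contam, blanks)] > 0)
        assert table.areas[np.ix_(~contam, blanks)].sum() == 0.0


class TestIdentityMap:
    def test_twins_within_pairing_tolerances(self, small_metabolome):
        truth = small_metabolome.truth
        fa = small_metabolome.tables["Antepartum"].features.set_index("feature_id")
        fb = small_metabolome.tables["Postpartum"].features.set_index("feature_id")
        for ia, ib in truth.identity_map("Antepartum", "Postpartum"):
            assert abs(fa.loc[ia, "mz"] - fb.loc[ib, "mz"]) < 0.02
            assert abs(fa.loc[ia, "rt"] - fb.loc[ib, "rt"]) < 0.3

    def test_identity_map_is_one_to_one(self, small_truth):
        pairs = small_truth.identity_map("Antepartum", "Postpartum")
        assert len({a for a, _ in pairs}) == len(pairs)
        assert len({b for _, b in pairs}) == len(pairs)


class TestMetagenome:
    def test_depleted_taxa_lower_in_treated(self):
        hits = 0
        reps = 10
        for seed in range(reps):
            design = StudyDesign(seed=seed, under_depth_fraction=0.0)
            truth = default_truth(seed=seed, n_carnitine=2, n_bile=2, n_inert=2,
                                  n_contaminant=1)
            table = generate_metagenome(design, truth)["Antepartum"]
            depleted = [
                t.taxon_id for t in truth.taxa
                if t.folds.get("Antepartum", 1.0) < 1.0
            ]
            idx = [table.taxon_ids.index(t) for t in depleted]
            props = table.proportions()
            treat = (table.samples["phase"] == "treatment").to_numpy()
            amp = props[np.ix_(idx, treat & (table.samples["arm"] == "AMP").to_numpy())]
            pbs = props[np.ix_(idx, treat & (table.samples["arm"] == "PBS").to_numpy())]
            if np.all(amp.mean(axis=1) < pbs.mean(axis=1)):
                hits += 1
        assert hits >= 0.95 * reps - 1  # >= 9 of 10 replicates

    def test_under_depth_fraction_marked(self, small_metagenome):
        table = small_metagenome["Antepartum"]
        under = table.samples["under_depth"].to_numpy()
        assert np.all(table.depths[under] < 5000)
        assert np.all(table.depths[~under] >= 5000)

    def test_zero_dams_gives_empty_table(self):
        design = StudyDesign(seed=0, dams_per_arm=0, n_blanks=0)
        truth = default_truth(seed=0, n_carnitine=2, n_bile=2, n_inert=2,
                              n_contaminant=1)
        table = generate_metagenome(design, truth)["Antepartum"]
        assert table.counts.shape[1] == 0


class TestValidation:
    def test_negative_fold_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            GroundTruth(molecules=[], effects={"x": {"Antepartum": -1.0}}, taxa=[])

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(dropout=1.5)

    def test_missing_phase_rejected(self):
        with pytest.raises(ValueError, match="pre"):
            StudyDesign(timepoints={
                "Antepartum": [("GD17", "treatment"), ("PND2", "post")],
                "Postpartum": [("PND1", "pre"), ("PND2", "treatment"), ("PND7", "post")],
            })


class TestMarginalCalibration:
    def test_null_welch_pvalues_uniform(self):
        """With no effects, per-feature treated-vs-control Welch p-values on
        log areas are uniform (KS p > 0.01 pooled over features)."""
        from scipy import stats
        from periomics.differential import welch_t

        design = StudyDesign(seed=13, dropout=0.0)
        truth = default_truth(
            seed=13, n_carnitine=40, n_bile=30, n_inert=80, n_contaminant=2,
            carnitine_fold=1.0, bile_fold=1.0, hexose_fold=1.0,
        )
        data = generate_metabolome(design, truth)
        pvals = []
        for cohort, table in data.tables.items():
            treat = (table.samples["phase"] == "treatment").to_numpy()
            amp = (table.samples["arm"] == "AMP").to_numpy() & treat
            pbs = (table.samples["arm"] == "PBS").to_numpy() & treat
            positive = (table.areas[:, amp | pbs] > 0).all(axis=1)
            la = np.log(table.areas[np.ix_(positive, amp)])
            lp = np.log(table.areas[np.ix_(positive, pbs)])
            for i in range(la.shape[0]):
                pvals.append(welch_t(la[i], lp[i])[2])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
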