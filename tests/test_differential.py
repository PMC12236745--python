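"""Dirichlet-CLR differential abundance, log-ratio series, Welch/BH."""

import numpy as np
import pandas as pd
import pytest

from periomics.datasets import TransformedMatrix
from periomics.differential import (
    cross_omics_network,
    dirichlet_clr_test,
    logratio_series,
    normalize_across_cohorts,
    welch_bh,
    welch_t,
)
from conftest import make_taxon_table


class TestWelch:
    def test_handset_values(self):
        t, df, p = welch_t(np.array([1.0, 2, 3]), np.array([7.0, 8, 9]))
        assert t == pytest.approx(-7.348, abs=0.001)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.0018, abs=0.0002)

    def test_equal_groups_p_one(self):
        t, _, p = welch_t(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        assert p == 1.0 and t == 0.0

    def test_bh_step_up(self):
        groups = {
            f"t{i}": (np.array([0.0, 0.0]), np.array([0.0, 0.0]))
            for i in range(4)
        }
        out = welch_bh(groups)
        # splice hand-set p-values through the BH arithmetic
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_never_decreases_p_and_is_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        from statsmodels.stats.multitest import multipletests

        q = multipletests(p, method="fdr_bh")[1]
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestDirichletClr:
    def _null_table(self, rng, n_taxa=40, n_per_group=10, depth=50_000):
        base = rng.dirichlet(np.full(n_taxa, 1.0))
        counts = rng.multinomial(depth, base, size=2 * n_per_group).T
        return make_taxon_table(counts)

    def test_type_one_error_controlled(self):
        """Null tables: <= 7% of taxa at q < 0.05 averaged over replicates."""
        rng = np.random.default_rng(1)
        fracs = []
        for rep in range(10):
            table = self._null_table(rng)
            res = dirichlet_clr_test(
                table, table.samples["arm"].to_numpy(), seed=rep
            )
            fracs.append((res.table["q"] < 0.05).mean())
        assert np.mean(fracs) <= 0.07

    def test_sensitivity_for_eightfold_depletion(self):
        rng = np.random.default_rng(2)
        n_taxa, n = 40, 10
        base = rng.dirichlet(np.full(n_taxa, 5.0))
        depleted = base.copy()
        depleted[:8] /= 8.0
        counts = np.hstack(
            [
                rng.multinomial(50_000, depleted / depleted.sum(), size=n).T,
                rng.multinomial(50_000, base, size=n).T,
            ]
        )
        table = make_taxon_table(counts)
        res = dirichlet_clr_test(table, table.samples["arm"].to_numpy(), seed=0)
        sig = res.table.iloc[:8]
        sens = ((sig["q"] < 0.05) & (sig["direction"] == "down")).mean()
        assert sens >= 0.8

    def test_label_swap_flips_effect_signs(self):
        rng = np.random.default_rng(3)
        table = self._null_table(rng, n_taxa=15, n_per_group=5)
        arms = table.samples["arm"].to_numpy()
        res1 = dirichlet_clr_test(table, arms, seed=9)
        flipped = np.where(arms == "AMP", "PBS", "AMP")
        res2 = dirichlet_clr_test(table, flipped, seed=9)
        np.testing.assert_allclose(
            res1.table["effect"], -res2.table["effect"], atol=1e-12
        )

    def test_small_group_rejected(self):
        table = make_taxon_table(np.array([[5, 5, 5], [3, 3, 3]]),
                                 arms=["AMP", "PBS", "PBS"])
        with pytest.raises(ValueError, match=">= 2"):
            dirichlet_clr_test(table, table.samples["arm"].to_numpy())


class TestLogRatio:
    def test_identical_sets_give_zero(self, toy_feature_table):
        series = logratio_series(toy_feature_table, ["f1", "f2"], ["f1", "f2"])
        study = series.samples[series.samples["type"] == "sample"]
        np.testing.assert_allclose(study["log_ratio"], 0.0)

    def test_per_sample_scaling_invariance(self, small_metabolome):
        table = small_metabolome.tables["Antepartum"]
        up, down = small_metabolome.truth.effect_sets("Antepartum")
        upf = [f"Antepartum_{m}" for m in up]
        downf = [f"Antepartum_{m}" for m in down]
        s1 = logratio_series(table, upf, downf)
        scaled = table.areas * np.exp(
            np.random.default_rng(0).normal(size=table.areas.shape[1])
        )
        from periomics.datasets import FeatureTable

        table2 = FeatureTable(table.features, table.samples, scaled)
        s2 = logratio_series(table2, upf, downf)
        np.testing.assert_allclose(
            s1.samples["log_ratio"], s2.samples["log_ratio"], atol=1e-9
        )

    def test_persistence_contrast_between_cohorts(self):
        """Treatment-phase significance in both cohorts; post-phase
        significance only where effects persist (antepartum)."""
        from periomics.simulate import (
            StudyDesign, default_truth, generate_metabolome, feature_id,
        )

        design = StudyDesign(seed=11)
        truth = default_truth(seed=11, n_carnitine=20, n_bile=15, n_inert=30,
                              n_contaminant=3)
        data = generate_metabolome(design, truth)
        qmap = {}
        for cohort in ("Antepartum", "Postpartum"):
            up, down = truth.effect_sets(cohort)
            series = logratio_series(
                data.tables[cohort],
                [feature_id(cohort, m) for m in up],
                [feature_id(cohort, m) for m in down],
            )
            phases = dict(
                data.tables[cohort]
                .samples[["timepoint", "phase"]]
                .drop_duplicates()
                .to_numpy()
            )
            stats = series.stats.assign(
                phase=[phases[tp] for tp in series.stats["stratum"]]
            )
            qmap[cohort] = stats
        for cohort, stats in qmap.items():
            assert (stats.loc[stats["phase"] == "treatment", "q"] < 0.05).all()
        assert (qmap["Antepartum"].loc[
            qmap["Antepartum"]["phase"] == "post", "q"] < 0.05).any()
        assert not (qmap["Postpartum"].loc[
            qmap["Postpartum"]["phase"] == "post", "q"] < 0.05).any()


class TestNormalizeAcrossCohorts:
    def _series(self, values, phases):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(values))],
                "cohort": "A",
                "arm": "AMP",
                "timepoint": "T",
                "phase": phases,
                "type": "sample",
                "log_ratio": values,
            }
        )
        from periomics.differential import LogRatioSeries

        return LogRatioSeries(samples=df, stats=pd.DataFrame())

    def test_identical_series_zero_shift(self):
        a = self._series([1.0, 2.0, 3.0], ["pre", "treatment", "post"])
        out = normalize_across_cohorts(a, a)
        np.testing.assert_allclose(out.samples["log_ratio"], [1.0, 2.0, 3.0])

    def test_constant_offset_cancels_exactly(self):
        a = self._series([1.0, 2.0, 3.0], ["pre", "treatment", "post"])
        b = self._series([4.0, 5.0, 6.0], ["pre", "treatment", "post"])
        out = normalize_across_cohorts(a, b)
        np.testing.assert_allclose(out.samples["log_ratio"], [1.0, 2.0, 3.0])

    def test_pre_phase_means_align(self):
        rng = np.random.default_rng(4)
        a = self._series(rng.normal(size=6), ["pre"] * 3 + ["post"] * 3)
        b = self._series(rng.normal(size=6) + 2.5, ["pre"] * 3 + ["post"] * 3)
        out = normalize_across_cohorts(a, b)
        pre_a = a.samples.loc[a.samples["phase"] == "pre", "log_ratio"].mean()
        pre_b = out.samples.loc[out.samples["phase"] == "pre", "log_ratio"].mean()
        assert pre_a == pytest.approx(pre_b, abs=1e-12)

    def test_empty_pre_phase_rejected(self):
        a = self._series([1.0], ["post"])
        with pytest.raises(ValueError, match="pre-phase"):
            normalize_across_cohorts(a, a)


class TestCrossOmicsNetwork:
    def _tm(self, x, prefix):
        return TransformedMatrix(
            x, [f"s{i}" for i in range(x.shape[0])],
            [f"{prefix}{j}" for j in range(x.shape[1])],
        )

    def test_duplicated_feature_perfect_edge(self):
        rng = np.random.default_rng(5)
        shared = rng.normal(size=(20, 1))
        metab = self._tm(np.hstack([shared, rng.normal(size=(20, 4))]), "m")
        taxa = self._tm(np.hstack([shared, rng.normal(size=(20, 4))]), "t")
        eff = {"m0": 5.0, "t0": 5.0}
        edges = cross_omics_network(metab, taxa, eff, eff, top_k=5)
        hit = edges[(edges["metabolite"] == "m0") & (edges["taxon"] == "t0")]
        assert len(hit) == 1
        assert hit.iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_blocks_rarely_connect(self):
        rng = np.random.default_rng(6)
        empty = 0
        for _ in range(30):
            metab = self._tm(rng.normal(size=(40, 10)), "m")
            taxa = self._tm(rng.normal(size=(40, 10)), "t")
            edges = cross_omics_network(metab, taxa, {}, {}, top_k=10)
            empty += len(edges) == 0
        assert empty / 30 >= 0.9

    def test_latent_factor_edge_recovered_with_sign(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=40)
        noise = np.sqrt(1 - 0.9**2)
        m = 0.9 * z + noise * rng.normal(size=40)
        t = -0.9 * z + noise * rng.normal(size=40)
        metab = self._tm(np.hstack([m[:, None], rng.normal(size=(40, 6))]), "m")
        taxa = self._tm(np.hstack([t[:, None], rng.normal(size=(40, 6))]), "t")
        edges = cross_omics_network(
            metab, taxa, {"m0": 9.0}, {"t0": 9.0}, top_k=3
        )
        hit = edges[(edges["metabolite"] == "m0") & (edges["taxon"] == "t0")]
        assert len(hit) == 1 and hit.iloc[0]["sign"] == "negative"

    def test_too_few_matched_samples_rejected(self):
        metab = self._tm(np.ones((2, 2)), "m")
        taxa = self._tm(np.ones((2, 2)), "t")
        with pytest.raises(ValueError, match="matched samples"):
            cross_omics_network(metab, taxa, {}, {})
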