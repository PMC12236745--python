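"""Modified cosine, the exhaustive-assignment oracle, cross-cohort tracing."""

import itertools

import numpy as np
import pytest

from periomics.datasets import Spectrum
from periomics.matching import (
    MatchConfig,
    MatchedPair,
    concordance_summary,
    modified_cosine,
    trace_cross_cohort,
)
from conftest import random_spectrum


def brute_force_modified_cosine(a, b, cfg):
    """Exhaustive search over all one-to-one candidate-peak assignments."""
    wa = a.intensity**cfg.intensity_power
    wb = b.intensity**cfg.intensity_power
    denom = np.linalg.norm(wa) * np.linalg.norm(wb)
    shift = a.precursor_mz - b.precursor_mz
    candidates = [
        (i, j)
        for i in range(len(a))
        for j in range(len(b))
        if abs(a.mz[i] - b.mz[j]) <= cfg.fragment_tol
        or abs(a.mz[i] - (b.mz[j] + shift)) <= cfg.fragment_tol
    ]
    best, best_n = 0.0, 0
    for size in range(len(candidates), 0, -1):
        for combo in itertools.combinations(candidates, size):
            rows = [i for i, _ in combo]
            cols = [j for _, j in combo]
            if len(set(rows)) < size or len(set(cols)) < size:
                continue
            total = sum(wa[i] * wb[j] for i, j in combo)
            if total > best:
                best, best_n = total, size
    return (best / denom if denom else 0.0), best_n


def spec(mz, inten, precursor, fid="x"):
    return Spectrum(
        feature_id=fid, precursor_mz=precursor, rt=1.0,
        mz=np.asarray(mz, float), intensity=np.asarray(inten, float),
    )


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        s = random_spectrum(rng, n_peaks=6)
        score, n = modified_cosine(s, s)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert n == 6

    def test_disjoint_support_is_zero(self):
        a = spec([100.0, 150.0], [1.0, 1.0], precursor=300.0)
        b = spec([210.0, 260.0], [1.0, 1.0], precursor=300.0)
        score, n = modified_cosine(a, b)
        assert score == 0.0 and n == 0

    def test_shifted_peak_matches_via_precursor_delta(self):
        """A fragment shifted by exactly the precursor difference counts."""
        a = spec([100.0, 200.0], [1.0, 1.0], precursor=400.0)
        b = spec([100.0, 210.0], [1.0, 1.0], precursor=410.0)
        score, n = modified_cosine(a, b)
        assert n == 2
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_equals_bruteforce_on_handset_case(self):
        cfg = MatchConfig()
        a = spec([100.0, 150.0, 200.0, 250.0], [0.2, 0.9, 0.5, 1.0], precursor=400.0)
        b = spec([100.0, 160.0, 200.0, 250.0], [0.7, 0.3, 0.8, 0.6], precursor=410.0)
        ours = modified_cosine(a, b, cfg)
        oracle = brute_force_modified_cosine(a, b, cfg)
        assert ours[0] == pytest.approx(oracle[0], abs=1e-9)

    def test_equals_bruteforce_on_random_spectra(self):
        """Optimal one-to-one assignment equals exhaustive search, <=6 peaks."""
        rng = np.random.default_rng(42)
        cfg = MatchConfig(fragment_tol=5.0)  # wide tolerance forces conflicts
        for _ in range(150):
            a = random_spectrum(rng, n_peaks=int(rng.integers(2, 7)))
            b = random_spectrum(rng, n_peaks=int(rng.integers(2, 7)))
            ours = modified_cosine(a, b, cfg)
            oracle = brute_force_modified_cosine(a, b, cfg)
            assert ours[0] == pytest.approx(oracle[0], abs=1e-9)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = random_spectrum(rng)
            b = random_spectrum(rng)
            sab, _ = modified_cosine(a, b)
            sba, _ = modified_cosine(b, a)
            assert sab == pytest.approx(sba, abs=1e-12)
            assert 0.0 <= sab <= 1.0

    def test_empty_spectrum_rejected(self):
        a = spec([100.0], [1.0], precursor=200.0)
        b = Spectrum("e", 200.0, 1.0, np.array([]), np.array([]))
        with pytest.raises(ValueError):
            modified_cosine(a, b)


class TestTraceCrossCohort:
    def test_recall_and_precision_on_twin_cohorts(self, small_metabolome):
        data = small_metabolome
        truth = data.truth
        pairs = trace_cross_cohort(
            data.tables["Antepartum"].features,
            data.tables["Postpartum"].features,
            data.spectra["Antepartum"],
            data.spectra["Postpartum"],
            cohort_a="Antepartum",
            cohort_b="Postpartum",
        )
        ident = set(truth.identity_map("Antepartum", "Postpartum"))
        found = {(p.id_a, p.id_b) for p in pairs}
        tp = len(found & ident)
        assert tp / len(ident) >= 0.9
        assert tp / len(found) >= 0.9

    def test_same_cohort_yields_no_pairs(self, small_metabolome):
        table = small_metabolome.tables["Antepartum"]
        pairs = trace_cross_cohort(
            table.features, table.features,
            small_metabolome.spectra["Antepartum"],
            small_metabolome.spectra["Antepartum"],
            cohort_a="Antepartum", cohort_b="Antepartum",
        )
        assert pairs == []

    def test_rt_boundary_is_strict(self):
        import pandas as pd

        fa = pd.DataFrame({"feature_id": ["a"], "mz": [300.0], "rt": [1.0]})
        fb = pd.DataFrame({"feature_id": ["b"], "mz": [300.0], "rt": [1.3]})
        s = spec(np.linspace(60, 290, 8), np.ones(8), precursor=300.0)
        pairs = trace_cross_cohort(
            fa, fb, {"a": s}, {"b": s}, cohort_a="A", cohort_b="B"
        )
        assert pairs == []  # |delta RT| = 0.3 exactly -> excluded

    def test_missing_spectrum_skipped(self, caplog):
        import pandas as pd

        fa = pd.DataFrame({"feature_id": ["a"], "mz": [300.0], "rt": [1.0]})
        fb = pd.DataFrame({"feature_id": ["b"], "mz": [300.0], "rt": [1.1]})
        s = spec(np.linspace(60, 290, 8), np.ones(8), precursor=300.0)
        with caplog.at_level("WARNING", logger="periomics"):
            pairs = trace_cross_cohort(
                fa, fb, {"a": s}, {}, cohort_a="A", cohort_b="B"
            )
        assert pairs == []
        assert "missing spectrum" in caplog.text


class TestConcordance:
    def _pair(self, da, db):
        return MatchedPair(
            id_a="a", cohort_a="A", id_b="b", cohort_b="B",
            delta_mz=0.0, delta_rt=0.0, cosine=0.9, n_matched_peaks=6,
            direction_a=da, direction_b=db,
        )

    def test_hand_labelled_counts(self):
        pairs = [
            self._pair("up", "up"),
            self._pair("down", "down"),
            self._pair("up", "down"),
            self._pair("up", "ns"),
        ]
        assert concordance_summary(pairs) == {
            "matched": 4, "concordant": 2, "up_up": 1, "down_down": 1,
            "discordant": 2,
        }

    def test_empty(self):
        assert concordance_summary([]) == {
            "matched": 0, "concordant": 0, "up_up": 0, "down_down": 0,
            "discordant": 0,
        }

    def test_designed_concordance_fraction_recovered(self):
        rng = np.random.default_rng(11)
        pairs = []
        for _ in range(400):
            if rng.random() < 0.8:
                d = "up" if rng.random() < 0.5 else "down"
                pairs.append(self._pair(d, d))
            else:
                pairs.append(self._pair("up", rng.choice(["down", "ns"])))
        frac = concordance_summary(pairs)["concordant"] / 400
        assert abs(frac - 0.8) <= 0.05
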