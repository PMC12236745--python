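"""Shared fixtures: a scaled-down synthetic study generated once per session."""

import numpy as np
import pandas as pd
import pytest

from periomics.datasets import FeatureTable, Spectrum, TaxonTable
from periomics.simulate import (
    StudyDesign,
    default_truth,
    generate_metabolome,
    generate_metagenome,
)


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(seed=5)


@pytest.fixture(scope="session")
def small_truth():
    return default_truth(seed=5, n_carnitine=20, n_bile=15, n_inert=40, n_contaminant=5)


@pytest.fixture(scope="session")
def small_metabolome(small_design, small_truth):
    return generate_metabolome(small_design, small_truth)


@pytest.fixture(scope="session")
def small_metagenome(small_design, small_truth):
    return generate_metagenome(small_design, small_truth)


@pytest.fixture
def toy_feature_table():
    """Six features with hand-set sample/blank means for blank-filter arithmetic."""
    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "b1", "b2"],
            "cohort": ["A"] * 4,
            "animal": ["a1", "a2", "NA", "NA"],
            "arm": ["AMP", "PBS", "NA", "NA"],
            "timepoint": ["T1", "T1", "NA", "NA"],
            "phase": ["treatment", "treatment", "NA", "NA"],
            "type": ["sample", "sample", "blank", "blank"],
        }
    )
    features = pd.DataFrame(
        {
            "feature_id": [f"f{i}" for i in range(1, 7)],
            "mz": np.linspace(100, 600, 6),
            "rt": np.linspace(1, 6, 6),
        }
    )
    # columns: s1, s2, b1, b2 -> sample means 100, 40, 50, 0, 7, 12;
    # blank means 10, 10, 10, 0, 1, 3
    areas = np.array(
        [
            [100.0, 100.0, 10.0, 10.0],
            [40.0, 40.0, 10.0, 10.0],
            [50.0, 50.0, 10.0, 10.0],
            [0.0, 0.0, 0.0, 0.0],
            [7.0, 7.0, 1.0, 1.0],
            [12.0, 12.0, 3.0, 3.0],
        ]
    )
    return FeatureTable(features, samples, areas)


def make_taxon_table(counts, arms=None, timepoints=None, phases=None):
    """Helper: wrap a taxa x samples count array in a TaxonTable."""
    counts = np.asarray(counts)
    n_taxa, n_samples = counts.shape
    arms = arms if arms is not None else ["AMP"] * (n_samples // 2) + ["PBS"] * (
        n_samples - n_samples // 2
    )
    timepoints = timepoints if timepoints is not None else ["T1"] * n_samples
    phases = phases if phases is not None else ["treatment"] * n_samples
    taxa = pd.DataFrame(
        {
            "taxon_id": [f"t{i}" for i in range(n_taxa)],
            "lineage": [f"d__Bacteria; s__sp{i}" for i in range(n_taxa)],
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(n_samples)],
            "cohort": ["A"] * n_samples,
            "animal": [f"a{j}" for j in range(n_samples)],
            "arm": arms,
            "timepoint": timepoints,
            "phase": phases,
            "type": ["sample"] * n_samples,
        }
    )
    return TaxonTable(taxa, samples, counts)


def random_spectrum(rng, n_peaks=None, precursor=None, feature_id="s"):
    n = int(n_peaks if n_peaks is not None else rng.integers(3, 7))
    return Spectrum(
        feature_id=feature_id,
        precursor_mz=float(precursor if precursor is not None else rng.uniform(200, 800)),
        rt=float(rng.uniform(0.5, 9.5)),
        mz=np.sort(rng.uniform(50, 500, size=n)),
        intensity=rng.uniform(0.05, 1.0, size=n),
    )
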