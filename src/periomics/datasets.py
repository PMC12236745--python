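"""In-memory containers shared across the pipeline.

Three units of data flow through the analysis:

* :class:`Spectrum` — one centroided MS/MS scan (precursor m/z, retention
  time in minutes, stick peak list), the unit of spectral matching and
  diagnostic fragment-ion queries.
* :class:`FeatureTable` — an untargeted-metabolomics peak-area matrix
  (features x samples) with per-feature m/z and RT and per-sample study
  metadata.
* :class:`TaxonTable` — a shallow-metagenomics count matrix
  (taxa x samples) with taxonomy lineage strings.

Containers validate their invariants on construction and reject rather
than coerce; matrices are plain ``numpy`` arrays with pandas DataFrames
for the record blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "FeatureTable",
    "TaxonTable",
    "TransformedMatrix",
    "SAMPLE_COLUMNS",
    "validate_sample_metadata",
]

#: required columns of the sample-metadata block
SAMPLE_COLUMNS = ["sample_id", "cohort", "animal", "arm", "timepoint", "phase", "type"]

_ARMS = {"AMP", "PBS", "NA"}
_TYPES = {"sample", "blank", "qc"}
_PHASES = {"pre", "treatment", "post", "NA"}


@dataclass(frozen=True)
class Spectrum:
    """One MS/MS scan: sorted stick peaks plus precursor context."""

    feature_id: str
    precursor_mz: float
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    cohort: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if np.any(inten < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, intensity=self.intensity * factor)


def validate_sample_metadata(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample id: {dup!r}")
    bad_type = set(samples["type"]) - _TYPES
    if bad_type:
        raise ValueError(f"unknown sample type(s): {sorted(bad_type)}")
    bad_arm = set(samples["arm"].astype(str)) - _ARMS
    if bad_arm:
        raise ValueError(f"unknown arm label(s): {sorted(bad_arm)}")
    bad_phase = set(samples["phase"].astype(str)) - _PHASES
    if bad_phase:
        raise ValueError(f"unknown phase label(s): {sorted(bad_phase)}")
    return samples.reset_index(drop=True)


@dataclass
class FeatureTable:
    """Peak-area matrix (features x samples) with feature and sample records.

    ``features`` requires columns ``feature_id``, ``mz``, ``rt`` (minutes);
    ``samples`` requires :data:`SAMPLE_COLUMNS`.  Unknown extra columns are
    preserved untouched.
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    areas: np.ndarray

    def __post_init__(self) -> None:
        for col in ("feature_id", "mz", "rt"):
            if col not in self.features.columns:
                raise ValueError(f"feature records missing column {col!r}")
        if self.features["feature_id"].duplicated().any():
            dup = self.features.loc[
                self.features["feature_id"].duplicated(), "feature_id"
            ].iloc[0]
            raise ValueError(f"duplicated feature id: {dup!r}")
        self.samples = validate_sample_metadata(self.samples)
        self.features = self.features.reset_index(drop=True)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"area matrix shape {self.areas.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if np.any(self.areas < 0):
            raise ValueError("negative peak area")

    @property
    def feature_ids(self) -> list[str]:
        return self.features["feature_id"].tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def select_samples(self, mask: Sequence[bool] | np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            self.features.copy(),
            self.samples.loc[mask].reset_index(drop=True),
            self.areas[:, mask],
        )

    def select_features(self, mask: Sequence[bool] | np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            self.features.loc[mask].reset_index(drop=True),
            self.samples.copy(),
            self.areas[mask, :],
        )

    def samples_matrix(self) -> np.ndarray:
        """Samples x features orientation used by the statistics modules."""
        return self.areas.T.copy()


@dataclass
class TaxonTable:
    """Taxon (OGU) count matrix (taxa x samples) with lineage strings."""

    taxa: pd.DataFrame
    samples: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        for col in ("taxon_id", "lineage"):
            if col not in self.taxa.columns:
                raise ValueError(f"taxon records missing column {col!r}")
        if self.taxa["taxon_id"].duplicated().any():
            dup = self.taxa.loc[self.taxa["taxon_id"].duplicated(), "taxon_id"].iloc[0]
            raise ValueError(f"duplicated taxon id: {dup!r}")
        self.samples = validate_sample_metadata(self.samples)
        self.taxa = self.taxa.reset_index(drop=True)
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.taxa), len(self.samples)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if np.any(counts < 0):
            raise ValueError("negative count")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)

    @property
    def taxon_ids(self) -> list[str]:
        return self.taxa["taxon_id"].tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def depths(self) -> np.ndarray:
        """Per-sample read depth (column sums)."""
        return self.counts.sum(axis=0)

    def select_samples(self, mask: Sequence[bool] | np.ndarray) -> "TaxonTable":
        mask = np.asarray(mask, dtype=bool)
        return TaxonTable(
            self.taxa.copy(),
            self.samples.loc[mask].reset_index(drop=True),
            self.counts[:, mask],
        )

    def select_taxa(self, mask: Sequence[bool] | np.ndarray) -> "TaxonTable":
        mask = np.asarray(mask, dtype=bool)
        return TaxonTable(
            self.taxa.loc[mask].reset_index(drop=True),
            self.samples.copy(),
            self.counts[mask, :],
        )

    def proportions(self) -> np.ndarray:
        depths = self.depths.astype(float)
        if np.any(depths == 0):
            raise ValueError("sample with zero depth")
        return self.counts / depths


@dataclass
class TransformedMatrix:
    """Samples x features real matrix after a compositional transform.

    ``zero_mask`` records entries that were zero in the source data (set to
    0 in ``values`` under the robust-clr convention); ``transform`` tags
    the transform applied (``"rclr"`` or ``"none"``).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    zero_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    transform: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.zero_mask is None:
            self.zero_mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.zero_mask = np.asarray(self.zero_mask, dtype=bool)
            if self.zero_mask.shape != self.values.shape:
                raise ValueError("zero_mask shape mismatch")
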