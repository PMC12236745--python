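"""Sample- and feature-level quality control.

Metabolomics: blank filtering — a feature is retained only when its mean
peak area across study samples is at least ``blank_fold`` (default 5) times
its mean across blank injections.  Metagenomics: read-depth sample
exclusion, prevalence/abundance taxon filters, and rarefaction for alpha
diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import FeatureTable, TaxonTable

__all__ = [
    "QcConfig",
    "blank_filter",
    "depth_filter",
    "prevalence_abundance_filter",
    "rarefy",
]


@dataclass
class QcConfig:
    """Thresholds for the QC stages.

    ``min_reads`` defaults to the synthetic-scale value (5,000); studies at
    real sequencing depth use 500,000.  ``min_max_rel_abundance`` reads the
    "relative abundance in any sample < 0.0001 %" exclusion as a
    max-over-samples floor of 1e-6 expressed as a fraction.
    """

    blank_fold: float = 5.0
    min_reads: int = 5_000
    min_prevalence: float = 0.10
    min_max_rel_abundance: float = 1e-6
    rarefy: bool = True

    def __post_init__(self) -> None:
        if self.blank_fold <= 1:
            raise ValueError("blank_fold must exceed 1")
        for frac in (self.min_prevalence, self.min_max_rel_abundance):
            if not 0.0 < frac < 1.0:
                raise ValueError(f"fraction out of (0, 1): {frac}")


def blank_filter(
    table: FeatureTable, cfg: QcConfig | None = None
) -> tuple[FeatureTable, list[str]]:
    """Remove features not at least ``blank_fold`` times above blank level.

    A feature is kept iff mean(area | type == sample) >=
    blank_fold * mean(area | type == blank).  Features entirely absent from
    blanks (blank mean exactly 0) are kept unconditionally.  Blank and QC
    injections are dropped from the returned table.
    """
    cfg = cfg or QcConfig()
    types = table.samples["type"].to_numpy()
    is_blank = types == "blank"
    is_sample = types == "sample"
    if not is_blank.any():
        raise ValueError(
            "no blank samples present; skip the blank-filter stage explicitly "
            "instead of running it without blanks"
        )
    sample_mean = table.areas[:, is_sample].mean(axis=1)
    blank_mean = table.areas[:, is_blank].mean(axis=1)
    keep = (blank_mean == 0.0) | (sample_mean >= cfg.blank_fold * blank_mean)
    removed = [fid for fid, k in zip(table.feature_ids, keep) if not k]
    filtered = table.select_features(keep).select_samples(is_sample)
    return filtered, removed


def depth_filter(
    table: TaxonTable, cfg: QcConfig | None = None
) -> tuple[TaxonTable, list[str]]:
    """Discard samples with read depth below ``min_reads``."""
    cfg = cfg or QcConfig()
    keep = table.depths >= cfg.min_reads
    if not keep.any():
        raise ValueError(
            f"all {len(keep)} samples fall below min_reads={cfg.min_reads}"
        )
    removed = [sid for sid, k in zip(table.sample_ids, keep) if not k]
    return table.select_samples(keep), removed


def prevalence_abundance_filter(
    table: TaxonTable, cfg: QcConfig | None = None
) -> tuple[TaxonTable, list[str]]:
    """Exclude rare taxa: prevalence < ``min_prevalence`` or maximum
    relative abundance over samples < ``min_max_rel_abundance``."""
    cfg = cfg or QcConfig()
    props = table.proportions()
    prevalence = (table.counts > 0).mean(axis=1)
    max_rel = props.max(axis=1)
    keep = (prevalence >= cfg.min_prevalence) & (
        max_rel >= cfg.min_max_rel_abundance
    )
    removed = [tid for tid, k in zip(table.taxon_ids, keep) if not k]
    return table.select_taxa(keep), removed


def rarefy(table: TaxonTable, depth: int, seed: int = 0) -> TaxonTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Uses multivariate-hypergeometric draws per sample; deterministic under
    ``seed``.
    """
    depths = table.depths
    if np.any(depths < depth):
        low = int(depths.min())
        raise ValueError(
            f"rarefaction depth {depth} exceeds the shallowest sample ({low})"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(table.counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
    return TaxonTable(table.taxa.copy(), table.samples.copy(), out)


def qc_report(table: FeatureTable, removed: list[str]) -> pd.DataFrame:
    """Per-feature blank-filter decision table."""
    report = pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "decision": ["kept"] * len(table.feature_ids),
        }
    )
    removed_df = pd.DataFrame({"feature_id": removed, "decision": "removed"})
    return pd.concat([report, removed_df], ignore_index=True)
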