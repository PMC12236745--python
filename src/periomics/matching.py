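"""Modified-cosine spectral similarity and cross-cohort feature tracing.

The modified cosine is the molecular-networking similarity between two
MS/MS spectra: fragment peaks may match either directly (|mzA - mzB| <=
fragment tolerance) or shifted by the precursor mass difference, and a
one-to-one peak assignment maximizing the summed intensity products is
scored against the product of the spectra's intensity norms.  Peak
intensities are weighted by ``intensity**intensity_power`` (square root by
default, the networking convention).

Cross-cohort tracing scores all feature pairs whose precursor m/z agree
within tolerance and retains those with |delta RT| < 0.3 min, cosine > 0.7
and at least 5 matched peaks, labelling each retained pair with the
treatment direction of both members and their concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .datasets import Spectrum

__all__ = [
    "MatchConfig",
    "MatchedPair",
    "modified_cosine",
    "trace_cross_cohort",
    "concordance_summary",
]

log = logging.getLogger("periomics")


@dataclass
class MatchConfig:
    fragment_tol: float = 0.02  # Da
    precursor_tol_pair: float = 0.02  # Da
    rt_tol_pair: float = 0.3  # min
    min_cosine: float = 0.7
    min_matched_peaks: int = 5
    intensity_power: float = 0.5
    apply_min_peaks: bool = True

    def __post_init__(self) -> None:
        if min(self.fragment_tol, self.precursor_tol_pair, self.rt_tol_pair) <= 0:
            raise ValueError("tolerances must be positive")
        if not 0.0 < self.min_cosine <= 1.0:
            raise ValueError("min_cosine must be in (0, 1]")


@dataclass(frozen=True)
class MatchedPair:
    id_a: str
    cohort_a: str
    id_b: str
    cohort_b: str
    delta_mz: float
    delta_rt: float
    cosine: float
    n_matched_peaks: int
    direction_a: str = "ns"
    direction_b: str = "ns"

    @property
    def concordant(self) -> bool:
        return self.direction_a == self.direction_b and self.direction_a != "ns"


def modified_cosine(
    a: Spectrum, b: Spectrum, cfg: MatchConfig | None = None
) -> tuple[float, int]:
    """Modified cosine score and number of matched peaks.

    The optimal one-to-one peak assignment over direct and precursor-shifted
    candidate pairs is found exactly (Hungarian algorithm on the candidate
    weight matrix), so the score provably maximizes the assigned sum of
    weight products.  Score is bounded in [0, 1] by Cauchy-Schwarz.
    """
    cfg = cfg or MatchConfig()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("modified cosine requires non-empty spectra")
    wa = a.intensity**cfg.intensity_power
    wb = b.intensity**cfg.intensity_power
    denom = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    if denom == 0.0:
        return 0.0, 0
    shift = a.precursor_mz - b.precursor_mz
    diff = np.abs(a.mz[:, None] - b.mz[None, :])
    diff_shift = np.abs(a.mz[:, None] - (b.mz[None, :] + shift))
    candidate = (diff <= cfg.fragment_tol) | (diff_shift <= cfg.fragment_tol)
    if not candidate.any():
        return 0.0, 0
    weights = np.where(candidate, wa[:, None] * wb[None, :], 0.0)
    rows, cols = linear_sum_assignment(weights, maximize=True)
    used = candidate[rows, cols] & (weights[rows, cols] > 0)
    score = float(weights[rows[used], cols[used]].sum() / denom)
    return min(score, 1.0), int(used.sum())


def trace_cross_cohort(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    spectra_a: dict[str, Spectrum] | list[Spectrum],
    spectra_b: dict[str, Spectrum] | list[Spectrum],
    diff_a: dict[str, str] | None = None,
    diff_b: dict[str, str] | None = None,
    cfg: MatchConfig | None = None,
    cohort_a: str = "A",
    cohort_b: str = "B",
) -> list[MatchedPair]:
    """Trace features across cohorts by spectral similarity.

    ``features_*`` need columns ``feature_id``, ``mz``, ``rt``; ``diff_*``
    map feature ids to treatment directions (``up``/``down``/``ns``) for
    the concordance labels.  Boundary semantics follow the pair filter:
    precursor difference strictly below tolerance, |delta RT| strictly below
    the RT tolerance, cosine strictly above the minimum.
    """
    cfg = cfg or MatchConfig()
    if cohort_a == cohort_b:
        # matches within the same cohort are excluded by construction
        return []
    diff_a = diff_a or {}
    diff_b = diff_b or {}
    spec_a = (
        spectra_a
        if isinstance(spectra_a, dict)
        else {s.feature_id: s for s in spectra_a}
    )
    spec_b = (
        spectra_b
        if isinstance(spectra_b, dict)
        else {s.feature_id: s for s in spectra_b}
    )
    b_mz = features_b["mz"].to_numpy(dtype=float)
    order = np.argsort(b_mz)
    b_sorted = features_b.iloc[order].reset_index(drop=True)
    b_mz_sorted = b_mz[order]

    pairs: list[MatchedPair] = []
    for _, fa in features_a.iterrows():
        lo = np.searchsorted(b_mz_sorted, fa["mz"] - cfg.precursor_tol_pair, "left")
        hi = np.searchsorted(b_mz_sorted, fa["mz"] + cfg.precursor_tol_pair, "right")
        for k in range(lo, hi):
            fb = b_sorted.iloc[k]
            d_mz = float(fa["mz"] - fb["mz"])
            if abs(d_mz) >= cfg.precursor_tol_pair:
                continue
            d_rt = float(fa["rt"] - fb["rt"])
            if abs(d_rt) >= cfg.rt_tol_pair:
                continue
            sa = spec_a.get(str(fa["feature_id"]))
            sb = spec_b.get(str(fb["feature_id"]))
            if sa is None or sb is None:
                log.warning(
                    "missing spectrum for pair (%s, %s); skipped",
                    fa["feature_id"],
                    fb["feature_id"],
                )
                continue
            score, n_matched = modified_cosine(sa, sb, cfg)
            if score <= cfg.min_cosine:
                continue
            if cfg.apply_min_peaks and n_matched < cfg.min_matched_peaks:
                continue
            pairs.append(
                MatchedPair(
                    id_a=str(fa["feature_id"]),
                    cohort_a=cohort_a,
                    id_b=str(fb["feature_id"]),
                    cohort_b=cohort_b,
                    delta_mz=d_mz,
                    delta_rt=d_rt,
                    cosine=score,
                    n_matched_peaks=n_matched,
                    direction_a=diff_a.get(str(fa["feature_id"]), "ns"),
                    direction_b=diff_b.get(str(fb["feature_id"]), "ns"),
                )
            )
    return pairs


def concordance_summary(pairs: list[MatchedPair]) -> dict[str, int]:
    """Count matched pairs by direction concordance.

    ``concordant`` pairs change in the same direction in both cohorts
    (both up or both down, neither non-significant); everything else is
    ``discordant``.
    """
    up_up = sum(1 for p in pairs if p.direction_a == p.direction_b == "up")
    down_down = sum(1 for p in pairs if p.direction_a == p.direction_b == "down")
    concordant = up_up + down_down
    return {
        "matched": len(pairs),
        "concordant": concordant,
        "up_up": up_up,
        "down_down": down_down,
        "discordant": len(pairs) - concordant,
    }
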