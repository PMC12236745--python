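"""Differential abundance and longitudinal log-ratio statistics.

Three statistics cover the study's inference layer:

* :func:`dirichlet_clr_test` — a Dirichlet–CLR Monte-Carlo differential
  abundance test for count compositions: per instance, each sample's
  composition is drawn from Dirichlet(counts + prior), CLR-transformed,
  and Welch-tested between groups; per-taxon p-values are the expectation
  over instances (then BH-adjusted across taxa) and the effect size is the
  median standardized CLR difference.  This is the classic
  Monte-Carlo/CLR construction for two-group differential abundance on
  sparse counts.
* :func:`logratio_series` — the normalization-free longitudinal statistic:
  per sample, ln(sum of treatment-associated features / sum of
  control-associated features), Welch-tested between arms per timepoint
  with BH correction across the timepoint family.
* :func:`cross_omics_network` — a correlation surrogate for multiblock
  integration: top-k features per omics block by |effect|, Pearson r
  across matched samples, edges above |r| > 0.7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import FeatureTable, TaxonTable, TransformedMatrix

__all__ = [
    "DifferentialResult",
    "LogRatioSeries",
    "dirichlet_clr_test",
    "logratio_series",
    "normalize_across_cohorts",
    "welch_bh",
    "welch_t",
    "cross_omics_network",
]

log = logging.getLogger("periomics")


@dataclass
class DifferentialResult:
    """Per-taxon/feature differential abundance summary."""

    table: pd.DataFrame  # columns: id, effect, p, q, direction

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < alpha]

    def directions(self, alpha: float = 0.05) -> dict[str, str]:
        """id -> up/down for q < alpha, ns otherwise."""
        out = {}
        for _, row in self.table.iterrows():
            if row["q"] < alpha:
                out[row["id"]] = row["direction"]
            else:
                out[row["id"]] = "ns"
        return out


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's t statistic, Welch–Satterthwaite df, and two-sided p.

    Degenerate variances fall back to the exact-equality shortcut: if all
    values coincide across groups, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch's t needs >= 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf), float(
            x.size + y.size - 2
        ), 0.0
    se2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_bh(groups: dict[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Repeated Welch's t-tests with Benjamini–Hochberg correction.

    ``groups`` maps stratum labels (e.g. timepoints) to ``(x, y)`` value
    pairs; BH is applied across the stratum family.
    """
    rows = []
    for stratum, (x, y) in groups.items():
        t, df, p = welch_t(np.asarray(x), np.asarray(y))
        rows.append({"stratum": stratum, "t": t, "df": df, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Dirichlet–CLR differential abundance


def dirichlet_clr_test(
    table: TaxonTable,
    groups,
    n_instances: int = 128,
    prior: float = 0.5,
    seed: int = 0,
) -> DifferentialResult:
    """Monte-Carlo Dirichlet–CLR two-group differential abundance test.

    Per instance: sample compositions ~ Dirichlet(counts + prior), CLR
    transform, per-taxon Welch t between the two groups.  p per taxon is
    the mean over instances (the expected p-value), BH-corrected across
    taxa; the effect is the median over instances of the standardized CLR
    difference (group-mean difference over pooled SD).  Instances are
    drawn before the group split, so swapping labels flips effect signs
    exactly.
    """
    labels = np.asarray(groups).astype(str)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two groups, got {list(classes)}")
    ia = labels == classes[0]
    ib = labels == classes[1]
    if ia.sum() < 2 or ib.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    counts = table.counts.astype(float)  # taxa x samples
    n_taxa, n_samples = counts.shape
    rng = np.random.default_rng(seed)

    t_stats = np.empty((n_instances, n_taxa))
    p_vals = np.empty((n_instances, n_taxa))
    effects = np.empty((n_instances, n_taxa))
    alpha = counts + prior
    for m in range(n_instances):
        gam = rng.standard_gamma(alpha.T)  # samples x taxa
        comp = gam / gam.sum(axis=1, keepdims=True)
        clr = np.log(comp)
        clr -= clr.mean(axis=1, keepdims=True)
        xa, xb = clr[ia], clr[ib]
        ma, mb = xa.mean(axis=0), xb.mean(axis=0)
        va = xa.var(axis=0, ddof=1)
        vb = xb.var(axis=0, ddof=1)
        se2 = va / ia.sum() + vb / ib.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ma - mb) / np.sqrt(se2)
            df = se2**2 / (
                (va / ia.sum()) ** 2 / (ia.sum() - 1)
                + (vb / ib.sum()) ** 2 / (ib.sum() - 1)
            )
            pooled = np.sqrt((va + vb) / 2.0)
            eff = np.where(pooled > 0, (ma - mb) / pooled, 0.0)
        t = np.nan_to_num(t, nan=0.0)
        df = np.nan_to_num(df, nan=1.0)
        t_stats[m] = t
        p_vals[m] = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1.0))
        effects[m] = eff

    p_mean = p_vals.mean(axis=0)
    effect_med = np.median(effects, axis=0)
    q = multipletests(p_mean, method="fdr_bh")[1]
    direction = np.where(effect_med > 0, "up", np.where(effect_med < 0, "down", "ns"))
    # effect/direction are oriented as classes[0] relative to classes[1];
    # report with the treated arm (AMP) first when present
    df_out = pd.DataFrame(
        {
            "id": table.taxon_ids,
            "effect": effect_med,
            "p": p_mean,
            "q": q,
            "direction": direction,
        }
    )
    return DifferentialResult(table=df_out)


# ---------------------------------------------------------------------------
# longitudinal log-ratio statistic


@dataclass
class LogRatioSeries:
    """Per-sample aggregated log ratios plus per-timepoint Welch/BH stats."""

    samples: pd.DataFrame  # sample_id, cohort, arm, timepoint, phase, log_ratio
    stats: pd.DataFrame  # stratum (timepoint), t, df, p, q


def _aggregate_ratio(
    matrix: np.ndarray, ids: list[str], up_set: list[str], down_set: list[str]
) -> np.ndarray:
    idx = {f: i for i, f in enumerate(ids)}
    up_idx = [idx[f] for f in up_set if f in idx]
    down_idx = [idx[f] for f in down_set if f in idx]
    if not up_idx or not down_idx:
        raise ValueError("both numerator and denominator sets must be non-empty")
    up_sum = matrix[up_idx, :].sum(axis=0)
    down_sum = matrix[down_idx, :].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(up_sum) - np.log(down_sum)


def logratio_series(
    table: FeatureTable | TaxonTable,
    up_set: list[str],
    down_set: list[str],
) -> LogRatioSeries:
    """Natural-log ratio of summed treatment-associated (numerator) over
    control-associated (denominator) features, per sample, Welch-tested
    between arms per timepoint with BH across timepoints.

    Samples with a zero numerator or denominator sum are dropped with a
    warning.  The statistic is invariant to per-sample global scaling.
    """
    if isinstance(table, TaxonTable):
        matrix, ids = table.counts.astype(float), table.taxon_ids
    else:
        matrix, ids = table.areas, table.feature_ids
    ratios = _aggregate_ratio(matrix, ids, up_set, down_set)
    samples = table.samples.copy()
    samples["log_ratio"] = ratios
    finite = np.isfinite(ratios)
    if not finite.all():
        log.warning(
            "dropping %d sample(s) with zero numerator/denominator sums",
            int((~finite).sum()),
        )
        samples = samples.loc[finite].reset_index(drop=True)
    study = samples[samples["type"] == "sample"]
    tp_order = study["timepoint"].drop_duplicates().tolist()
    tests: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tp in tp_order:
        sub = study[study["timepoint"] == tp]
        x = sub.loc[sub["arm"] == "AMP", "log_ratio"].to_numpy()
        y = sub.loc[sub["arm"] == "PBS", "log_ratio"].to_numpy()
        if x.size >= 2 and y.size >= 2:
            tests[tp] = (x, y)
    stats_df = welch_bh(tests) if tests else pd.DataFrame(
        columns=["stratum", "t", "df", "p", "q"]
    )
    return LogRatioSeries(samples=samples, stats=stats_df)


def normalize_across_cohorts(
    series_a: LogRatioSeries, series_b: LogRatioSeries, pre_phase: str = "pre"
) -> LogRatioSeries:
    """Shift cohort B's ratios so both cohorts share the same pre-treatment
    mean: B <- B - (mean_B,pre - mean_A,pre)."""
    pre_a = series_a.samples.loc[
        series_a.samples["phase"] == pre_phase, "log_ratio"
    ]
    pre_b = series_b.samples.loc[
        series_b.samples["phase"] == pre_phase, "log_ratio"
    ]
    if pre_a.empty or pre_b.empty:
        raise ValueError("both series need pre-phase samples")
    shift = float(pre_b.mean() - pre_a.mean())
    adjusted = series_b.samples.copy()
    adjusted["log_ratio"] = adjusted["log_ratio"] - shift
    return LogRatioSeries(samples=adjusted, stats=series_b.stats.copy())


# ---------------------------------------------------------------------------
# cross-omics correlation network


def cross_omics_network(
    metab: TransformedMatrix,
    taxa: TransformedMatrix,
    metab_effect: dict[str, float],
    taxa_effect: dict[str, float],
    top_k: int = 20,
    r_min: float = 0.7,
) -> pd.DataFrame:
    """Cross-omics Pearson correlation network over matched samples.

    Retains the ``top_k`` features per block by |effect| and emits edges
    with |r| > ``r_min`` and their sign: columns (metabolite, taxon, r,
    sign).
    """
    shared = [s for s in metab.sample_ids if s in set(taxa.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need >= 3 matched samples across blocks")
    mi = [metab.sample_ids.index(s) for s in shared]
    ti = [taxa.sample_ids.index(s) for s in shared]

    def top(ids: list[str], effect: dict[str, float]) -> list[int]:
        scored = [(abs(effect.get(f, 0.0)), i) for i, f in enumerate(ids)]
        scored.sort(key=lambda x: (-x[0], x[1]))
        return [i for _, i in scored[:top_k]]

    m_idx = top(metab.feature_ids, metab_effect)
    t_idx = top(taxa.feature_ids, taxa_effect)
    xm = metab.values[np.ix_(mi, m_idx)]
    xt = taxa.values[np.ix_(ti, t_idx)]
    edges = []
    for a, fi in enumerate(m_idx):
        for b, ti_ in enumerate(t_idx):
            xa, xb = xm[:, a], xt[:, b]
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            if abs(r) > r_min:
                edges.append(
                    {
                        "metabolite": metab.feature_ids[fi],
                        "taxon": taxa.feature_ids[ti_],
                        "r": r,
                        "sign": "positive" if r > 0 else "negative",
                    }
                )
    return pd.DataFrame(edges, columns=["metabolite", "taxon", "r", "sign"])
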