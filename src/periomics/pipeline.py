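"""End-to-end orchestration: simulate -> qc -> stats -> match -> query -> report.

A single YAML-style configuration drives the full analysis at desk scale;
one global seed fans out to per-stage child seeds so individual stages can
be rerun in isolation reproducibly.  The run produces a
:class:`RunManifest` with a config echo, per-artifact digests, and the
headline summary numbers (features kept, taxa kept, significant features
per block, matched and concordant cross-cohort pairs, per-timepoint
q-values, classification labels); rerunning with the same config and seed
reproduces every digest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io, massql, qc
from .composition import permanova, rclr, shannon, wilcoxon_rank_sum
from .differential import dirichlet_clr_test, logratio_series, normalize_across_cohorts
from .matching import MatchConfig, concordance_summary, trace_cross_cohort
from .plsda import cross_validate, fit_plsda, select_vip
from .simulate import GroundTruth, StudyDesign, default_truth, generate_metabolome, generate_metagenome

__all__ = ["RunManifest", "run_pipeline", "default_config"]

log = logging.getLogger("periomics")

_STAGE_SEEDS = {
    "simulate": 11,
    "qc": 23,
    "stats": 37,
    "match": 53,
    "query": 71,
    "report": 97,
}


def _child_seed(seed: int, stage: str) -> int:
    return int((seed * 1_000_003 + _STAGE_SEEDS[stage]) % (2**31 - 1))


def default_config(seed: int = 42, outdir: str = "pipeline_out") -> dict:
    return {
        "seed": seed,
        "outdir": outdir,
        "simulate": {"n_inert": 60, "n_carnitine": 30, "n_bile": 20},
        "qc": {"blank_fold": 5.0, "min_reads": 5000, "min_prevalence": 0.10,
               "min_max_rel_abundance": 1e-6, "blank_filter": True},
        "stats": {"n_permutations": 199, "plsda_components": 2,
                  "plsda_permutations": 0, "vip_threshold": 1.0,
                  "alpha": 0.05},
        "match": {"min_cosine": 0.7, "min_matched_peaks": 5},
    }


@dataclass
class RunManifest:
    config: dict
    seed: int
    digests: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "digests": self.digests,
            "summary": self.summary,
            "timings": {k: round(v, 3) for k, v in self.timings.items()},
        }
        def _coerce(o):
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            if isinstance(o, np.bool_):
                return bool(o)
            # config echo may hold rich objects (e.g. a ground-truth registry)
            return f"<{type(o).__name__}>"

        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True, default=_coerce)
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | None = None) -> RunManifest:
    """Execute the full analysis; any stage failure halts with a
    stage-named error."""
    cfg = default_config()
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed)
    summary: dict = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest.timings[name] = time.perf_counter() - t0
            log.info("stage %s done in %.2fs", name, manifest.timings[name])

        return wrap

    state: dict = {}

    @stage("simulate")
    def _simulate():
        sim_cfg = dict(cfg.get("simulate", {}))
        design = StudyDesign(seed=_child_seed(seed, "simulate"))
        truth = sim_cfg.pop("truth", None) or default_truth(
            seed=design.seed, **sim_cfg
        )
        metab = generate_metabolome(design, truth)
        taxa = generate_metagenome(design, truth)
        state.update(design=design, truth=truth, metab=metab, taxa=taxa)
        for cohort, table in metab.tables.items():
            io.write_feature_table(
                table,
                outdir / f"features_{cohort}.tsv",
                outdir / f"metadata_{cohort}.tsv",
            )
            io.write_mgf(metab.spectra[cohort], outdir / f"spectra_{cohort}.mgf")
        for cohort, table in taxa.items():
            io.write_taxon_table(
                table,
                outdir / f"taxa_{cohort}.tsv",
                outdir / f"taxa_metadata_{cohort}.tsv",
            )

    @stage("qc")
    def _qc():
        qcc = qc.QcConfig(
            blank_fold=cfg["qc"]["blank_fold"],
            min_reads=cfg["qc"]["min_reads"],
            min_prevalence=cfg["qc"]["min_prevalence"],
            min_max_rel_abundance=cfg["qc"]["min_max_rel_abundance"],
        )
        metab_f, taxa_f = {}, {}
        for cohort, table in state["metab"].tables.items():
            if cfg["qc"].get("blank_filter", True):
                filtered, removed = qc.blank_filter(table, qcc)
            else:
                keep = table.samples["type"] == "sample"
                filtered, removed = table.select_samples(keep.to_numpy()), []
            metab_f[cohort] = filtered
            summary.setdefault("features_kept", {})[cohort] = len(
                filtered.feature_ids
            )
            summary.setdefault("features_blank_removed", {})[cohort] = len(removed)
        for cohort, table in state["taxa"].items():
            deep, dropped = qc.depth_filter(table, qcc)
            kept, removed = qc.prevalence_abundance_filter(deep, qcc)
            taxa_f[cohort] = kept
            summary.setdefault("samples_depth_removed", {})[cohort] = len(dropped)
            summary.setdefault("taxa_kept", {})[cohort] = len(kept.taxon_ids)
        state.update(metab_f=metab_f, taxa_f=taxa_f)

    @stage("stats")
    def _stats():
        st = cfg["stats"]
        stats_seed = _child_seed(seed, "stats")
        alpha = st["alpha"]
        directions, diff_taxa, metab_series, taxa_series = {}, {}, {}, {}
        rclr_cache = {}
        for cohort, table in state["metab_f"].items():
            treat = table.select_samples(
                (table.samples["phase"] == "treatment").to_numpy()
            )
            t = rclr(treat.samples_matrix(), treat.sample_ids, treat.feature_ids)
            rclr_cache[cohort] = (t, treat)
            labels = treat.samples["arm"].to_numpy()
            perma = permanova(
                t, labels, n_permutations=st["n_permutations"], seed=stats_seed,
                grouping="arm",
            )
            model = fit_plsda(t, labels, n_components=st["plsda_components"])
            cv = cross_validate(
                t, labels, n_components=st["plsda_components"],
                n_permutations=st["plsda_permutations"], seed=stats_seed,
            )
            directions[cohort] = select_vip(
                model, threshold=st["vip_threshold"], treated_class="AMP"
            )
            n_sig = sum(1 for d in directions[cohort].values() if d != "ns")
            summary.setdefault("metabolome", {})[cohort] = {
                "permanova_p": perma.p_value,
                "plsda_cer": cv.cer,
                "n_vip_significant": n_sig,
            }
            up = [f for f, d in directions[cohort].items() if d == "up"]
            down = [f for f, d in directions[cohort].items() if d == "down"]
            if up and down:
                metab_series[cohort] = logratio_series(table, up, down)
                summary["metabolome"][cohort]["logratio_q"] = dict(
                    zip(
                        metab_series[cohort].stats["stratum"],
                        np.round(metab_series[cohort].stats["q"], 4),
                    )
                )
        for cohort, table in state["taxa_f"].items():
            treat = table.select_samples(
                (table.samples["phase"] == "treatment").to_numpy()
            )
            res = dirichlet_clr_test(
                treat, treat.samples["arm"].to_numpy(), seed=stats_seed
            )
            diff_taxa[cohort] = res
            h = shannon(treat, rarefied=True, seed=stats_seed)
            arms = treat.samples["arm"].to_numpy()
            wil_p = wilcoxon_rank_sum(h[arms == "AMP"], h[arms == "PBS"])
            t = rclr(
                treat.counts.T.astype(float), treat.sample_ids, treat.taxon_ids
            )
            perma = permanova(
                t, arms, n_permutations=st["n_permutations"], seed=stats_seed,
                grouping="arm",
            )
            summary.setdefault("metagenome", {})[cohort] = {
                "permanova_p": perma.p_value,
                "n_differential": int((res.table["q"] < alpha).sum()),
                "shannon_wilcoxon_p": wil_p,
                "shannon_median_AMP": float(np.median(h[arms == "AMP"])),
                "shannon_median_PBS": float(np.median(h[arms == "PBS"])),
            }
            dirs = res.directions(alpha)
            up = [f for f, d in dirs.items() if d == "up"]
            down = [f for f, d in dirs.items() if d == "down"]
            if up and down:
                taxa_series[cohort] = logratio_series(table, up, down)
        cohorts = list(state["metab_f"])
        if len(cohorts) == 2 and all(c in metab_series for c in cohorts):
            normalize_across_cohorts(metab_series[cohorts[0]], metab_series[cohorts[1]])
        state.update(
            directions=directions, diff_taxa=diff_taxa,
            metab_series=metab_series, taxa_series=taxa_series,
            rclr_cache=rclr_cache,
        )

    @stage("match")
    def _match():
        cohorts = list(state["metab_f"])
        if len(cohorts) < 2:
            summary["pairs"] = {"matched": 0}
            return
        ca, cb = cohorts[:2]
        mcfg = MatchConfig(
            min_cosine=cfg["match"]["min_cosine"],
            min_matched_peaks=cfg["match"]["min_matched_peaks"],
        )
        spectra = state["metab"].spectra
        pairs = trace_cross_cohort(
            state["metab_f"][ca].features,
            state["metab_f"][cb].features,
            spectra[ca],
            spectra[cb],
            state["directions"].get(ca, {}),
            state["directions"].get(cb, {}),
            mcfg,
            cohort_a=ca,
            cohort_b=cb,
        )
        io.write_pair_table(pairs, outdir / "matched_pairs.tsv")
        summary["pairs"] = concordance_summary(pairs)
        state["pairs"] = pairs

    @stage("query")
    def _query():
        counts: dict[str, int] = {}
        for cohort, spectra in state["metab"].spectra.items():
            for s in spectra:
                label = massql.classify_bile_acid(s)
                if massql.classify_carnitine(s):
                    label = "Carnitine"
                if label != "none":
                    counts[label] = counts.get(label, 0) + 1
        summary["diagnostic_classifications"] = dict(sorted(counts.items()))

    @stage("report")
    def _report():
        manifest.summary = summary
        for path in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.mgf")):
            manifest.digests[path.name] = _digest(path)
        manifest.to_json(outdir / "manifest.json")

    return manifest
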