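"""Synthetic two-cohort perinatal-antibiotic study generator.

Emulates the design of a two-cohort (antepartum / postpartum dosing)
longitudinal mouse study with paired untargeted LC-MS/MS metabolomics and
shallow shotgun metagenomics, with known ground truth so that every
downstream stage — QC, spectral matching, diagnostic queries, compositional
and longitudinal statistics — has a recoverable answer.

The generated conditions mirror the study design:

* two cohorts x two arms (AMP-treated vs PBS control), 5 dams per arm,
  longitudinal timepoints tagged pre / treatment / post;
* multiplicative treatment effects on designated metabolite classes
  (acylcarnitine-like features up, microbial bile-acid-like features down,
  two hexose-conjugated bile acids up), with cohort-specific persistence:
  antepartum effects decay geometrically into the post phase while
  postpartum effects truncate after the last dosing day;
* the administered drug (ampicillin, C16H19N3O4S, detected as [M+H]+ at
  RT 2.7 min) appearing only in treated dams during and shortly after
  dosing;
* blank injections carrying contaminant features at sample-like levels;
* per-feature MS/MS stick spectra built from chemistry-aware class
  templates (carnitine diagnostic cations, bile-acid water-loss ladders,
  hexose neutral loss), with cross-cohort batch jitter (m/z <= 5 ppm,
  RT sigma 0.05 min, intensity noise, random peak dropout);
* taxon (OGU) tables drawn Dirichlet-multinomial around a baseline
  composition, with shared depleted taxa and cohort-specific enrichments,
  log-normal library sizes and a configurable under-depth sample fraction.

All randomness flows from ``StudyDesign.seed``; identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .datasets import SAMPLE_COLUMNS, FeatureTable, Spectrum, TaxonTable

__all__ = [
    "StudyDesign",
    "Molecule",
    "TaxonSpec",
    "GroundTruth",
    "default_truth",
    "default_taxa",
    "generate_metabolome",
    "generate_metagenome",
    "MetabolomeData",
]

_DEFAULT_TIMEPOINTS: dict[str, list[tuple[str, str]]] = {
    "Antepartum": [
        ("GD14", "pre"),
        ("GD16", "pre"),
        ("GD17", "treatment"),
        ("GD18", "treatment"),
        ("PND2", "post"),
        ("PND7", "post"),
        ("PND14", "post"),
        ("PND21", "post"),
    ],
    "Postpartum": [
        ("PND1", "pre"),
        ("PND2", "treatment"),
        ("PND3", "treatment"),
        ("PND7", "post"),
        ("PND14", "post"),
        ("PND21", "post"),
    ],
}


@dataclass
class StudyDesign:
    """Study layout plus the noise model of the simulated measurements."""

    cohorts: tuple[str, ...] = ("Antepartum", "Postpartum")
    dams_per_arm: int = 5
    arms: tuple[str, str] = ("AMP", "PBS")
    timepoints: dict[str, list[tuple[str, str]]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_TIMEPOINTS.items()}
    )
    n_blanks: int = 3
    seed: int = 0
    #: per-cohort geometric decay of the log-fold effect through the post
    #: phase; antepartum persists (0.6/timepoint), postpartum truncates (0).
    persistence: dict[str, float] = field(
        default_factory=lambda: {"Antepartum": 0.6, "Postpartum": 0.0}
    )
    # metabolome noise model
    baseline_log_mean: float = float(np.log(1e6))
    baseline_log_sigma: float = 1.0
    noise_cv: float = 0.2
    dropout: float = 0.05
    mz_jitter_ppm: float = 4.0
    rt_jitter_sd: float = 0.05
    peak_dropout: float = 0.15
    cohort_scale_sigma: float = 0.3
    # metagenome model
    library_size_median: int = 50_000
    library_size_sigma: float = 0.3
    under_depth_fraction: float = 0.1
    under_depth_median: int = 1_000
    dirichlet_concentration: float = 200.0

    def __post_init__(self) -> None:
        if self.dams_per_arm < 0 or self.n_blanks < 0:
            raise ValueError("counts must be non-negative")
        for frac in (self.dropout, self.peak_dropout, self.under_depth_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction out of [0, 1]: {frac}")
        if self.noise_cv < 0 or self.rt_jitter_sd < 0 or self.mz_jitter_ppm < 0:
            raise ValueError("noise scales must be non-negative")
        for cohort in self.cohorts:
            tps = self.timepoints.get(cohort, [])
            phases = {ph for _, ph in tps}
            if not {"pre", "treatment", "post"} <= phases:
                raise ValueError(
                    f"cohort {cohort!r} needs >=1 pre, treatment and post timepoint"
                )


@dataclass(frozen=True)
class Molecule:
    """One ground-truth molecule shared (as cross-cohort twins) by cohorts."""

    mol_id: str
    mol_class: str  # carnitine | bile_acid | hexose_bile_acid | drug | inert | contaminant
    formula: str | None
    adduct: str
    mz: float
    rt: float
    n_hydroxyl: int = 0
    template_seed: int = 0


@dataclass(frozen=True)
class TaxonSpec:
    taxon_id: str
    lineage: str
    baseline: float  # baseline relative abundance (sums to ~1 over registry)
    folds: dict = field(default_factory=dict)  # cohort -> fold during treatment


@dataclass
class GroundTruth:
    """Molecule and taxon registries with their true treatment effects."""

    molecules: list[Molecule]
    #: molecule id -> {cohort -> multiplicative fold in AMP dams during treatment}
    effects: dict[str, dict[str, float]]
    taxa: list[TaxonSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        for mol_id, per_cohort in self.effects.items():
            for fold in per_cohort.values():
                if fold <= 0:
                    raise ValueError(f"non-positive fold for {mol_id}: {fold}")

    def molecule(self, mol_id: str) -> Molecule:
        return next(m for m in self.molecules if m.mol_id == mol_id)

    def effect_sets(self, cohort: str) -> tuple[list[str], list[str]]:
        """(up, down) molecule ids with fold > 1 / < 1 in ``cohort``."""
        up = [m for m, per in self.effects.items() if per.get(cohort, 1.0) > 1.0]
        down = [m for m, per in self.effects.items() if per.get(cohort, 1.0) < 1.0]
        return up, down

    def identity_map(self, cohort_a: str, cohort_b: str) -> list[tuple[str, str]]:
        """True cross-cohort twin feature ids (one feature per molecule)."""
        return [
            (feature_id(cohort_a, m.mol_id), feature_id(cohort_b, m.mol_id))
            for m in self.molecules
        ]


def feature_id(cohort: str, mol_id: str) -> str:
    return f"{cohort}_{mol_id}"


# ---------------------------------------------------------------------------
# default registries

_CARNITINE = chem.parse_formula("C7H15NO3")
_HEXOSE = chem.parse_formula("C6H12O6")
_WATER = chem.parse_formula("H2O")


def _acylcarnitine_formula(n_carbons: int, n_extra_o: int = 0, unsat: int = 0) -> chem.Formula:
    """Acylcarnitine = carnitine + fatty acid (CnH2nO2) - H2O, optionally
    hydroxylated (+O) or unsaturated (-H2)."""
    acid = chem.Formula(
        {"C": n_carbons, "H": 2 * n_carbons - 2 * unsat, "O": 2 + n_extra_o}
    )
    return chem.conjugate(_CARNITINE, acid, lose_water=True)


def default_truth(
    seed: int = 0,
    n_carnitine: int = 50,
    n_bile: int = 30,
    n_inert: int = 150,
    n_contaminant: int = 10,
    carnitine_fold: float = 8.0,
    bile_fold: float = 0.125,
    hexose_fold: float = 8.0,
    include_drug: bool = True,
    taxa: list[TaxonSpec] | None = None,
) -> GroundTruth:
    """Build the default ground-truth registry.

    Effect classes follow the study's headline biology: acylcarnitine-like
    features rise under treatment in both cohorts, microbially derived
    bile acids fall, and the two hexose-conjugated bile acids (cholic and
    taurocholic acid bound to a hexose via water loss, detected as
    [M+NH4]+) rise.  Inert features carry no effect; contaminants appear
    in blanks.  Retention times of exact-mass isomers are spaced >= 0.8 min
    apart so feature identity is chromatographically resolvable.
    """
    rng = np.random.default_rng([seed, 7919])
    molecules: list[Molecule] = []
    effects: dict[str, dict[str, float]] = {}
    cohorts = ("Antepartum", "Postpartum")

    def add(mol: Molecule, fold: float | None) -> None:
        molecules.append(mol)
        if fold is not None and fold != 1.0:
            effects[mol.mol_id] = {c: fold for c in cohorts}

    # acylcarnitines: distinct acyl lengths x (plain / hydroxy / unsaturated)
    variants = [
        (n, o, u) for n in range(2, 19) for o, u in ((0, 0), (1, 0), (0, 1))
    ][:n_carnitine]
    for i, (n, o, u) in enumerate(variants):
        f = _acylcarnitine_formula(n, o, u)
        add(
            Molecule(
                mol_id=f"carn{i:03d}",
                mol_class="carnitine",
                formula=f.hill(),
                adduct="[M+H]+",
                mz=chem.adduct_mz(f, "[M+H]+"),
                rt=0.0,
                template_seed=int(rng.integers(2**31)),
            ),
            carnitine_fold,
        )

    # unconjugated bile-acid cores across the five hydroxylation states
    for i in range(n_bile):
        n_oh = 1 + i % 5
        f = chem.Formula({"C": 24, "H": 40, "O": n_oh + 2})
        add(
            Molecule(
                mol_id=f"bile{i:03d}",
                mol_class="bile_acid",
                formula=f.hill(),
                adduct="[M+H]+",
                mz=chem.adduct_mz(f, "[M+H]+"),
                rt=0.0,
                n_hydroxyl=n_oh,
                template_seed=int(rng.integers(2**31)),
            ),
            bile_fold,
        )

    # hexose conjugates of cholic and taurocholic acid, ammonium adducts
    for i, (name, aglycone) in enumerate(
        (("hexCA", "C24H40O5"), ("hexTCA", "C26H45NO7S"))
    ):
        f = chem.conjugate(chem.parse_formula(aglycone), _HEXOSE, lose_water=True)
        add(
            Molecule(
                mol_id=name,
                mol_class="hexose_bile_acid",
                formula=f.hill(),
                adduct="[M+NH4]+",
                mz=chem.adduct_mz(f, "[M+NH4]+"),
                rt=0.0,
                n_hydroxyl=3,
                template_seed=int(rng.integers(2**31)),
            ),
            hexose_fold,
        )

    # the administered drug: ampicillin, treated dams only.  A pure-null
    # study (no treatment signal at all) omits it, since drug detection by
    # itself separates the arms.
    amp = chem.parse_formula("C16H19N3O4S")
    drug_seed = int(rng.integers(2**31))
    if include_drug:
        molecules.append(
            Molecule(
                mol_id="drug_amp",
                mol_class="drug",
                formula=amp.hill(),
                adduct="[M+H]+",
                mz=chem.adduct_mz(amp, "[M+H]+"),
                rt=2.7,
                template_seed=drug_seed,
            )
        )

    for i in range(n_inert):
        add(
            Molecule(
                mol_id=f"inert{i:03d}",
                mol_class="inert",
                formula=None,
                adduct="[M+H]+",
                mz=float(rng.uniform(150.0, 900.0)),
                rt=0.0,
                template_seed=int(rng.integers(2**31)),
            ),
            None,
        )
    for i in range(n_contaminant):
        add(
            Molecule(
                mol_id=f"contam{i:03d}",
                mol_class="contaminant",
                formula=None,
                adduct="[M+H]+",
                mz=float(rng.uniform(150.0, 900.0)),
                rt=0.0,
                template_seed=int(rng.integers(2**31)),
            ),
            None,
        )

    molecules = _assign_retention_times(molecules, rng)
    return GroundTruth(
        molecules=molecules,
        effects=effects,
        taxa=default_taxa(seed) if taxa is None else taxa,
        seed=seed,
    )


def _assign_retention_times(
    molecules: list[Molecule], rng: np.random.Generator
) -> list[Molecule]:
    """Assign RTs, spacing exact-mass isomers >= 0.8 min apart."""
    groups: dict[float, list[int]] = {}
    for i, m in enumerate(molecules):
        groups.setdefault(round(m.mz, 1), []).append(i)
    out = list(molecules)
    for idxs in groups.values():
        base = float(rng.uniform(0.6, 1.4))
        for j, i in enumerate(idxs):
            if out[i].rt > 0:  # fixed RT (e.g. the drug)
                continue
            rt = (base + 0.9 * j + float(rng.uniform(-0.05, 0.05)) - 0.5) % 9.0 + 0.5
            out[i] = Molecule(**{**out[i].__dict__, "rt": float(rt)})
    return out


_MURIBACULACEAE = [
    ("Muribaculum intestinale", "g__Muribaculum"),
    ("Muribaculum gordoncarteri", "g__Muribaculum"),
    ("Duncaniella dubosii", "g__Duncaniella"),
    ("Paramuribaculum intestinale", "g__Paramuribaculum"),
    ("Muribaculaceae UBA7173 sp.", "g__UBA7173"),
    ("Muribaculaceae CAG-873 sp.", "g__CAG-873"),
    ("Muribaculaceae CAG-485 sp.", "g__CAG-485"),
    ("Duncaniella muris", "g__Duncaniella"),
]
_ANTE_ENRICHED = [
    ("Enterococcus gallinarum", "f__Enterococcaceae", "g__Enterococcus"),
    ("Paenibacillus cookii", "f__Paenibacillaceae", "g__Paenibacillus"),
    ("Staphylococcus xylosus", "f__Staphylococcaceae", "g__Staphylococcus"),
]
_POST_ENRICHED = [
    ("Prevotella sp.", "f__Prevotellaceae", "g__Prevotella"),
    ("Escherichia coli", "f__Enterobacteriaceae", "g__Escherichia"),
    ("Klebsiella pneumoniae", "f__Enterobacteriaceae", "g__Klebsiella"),
]


def default_taxa(
    seed: int = 0,
    n_background: int = 26,
    depletion_fold: float = 0.125,
    enrichment_fold: float = 8.0,
) -> list[TaxonSpec]:
    """Default taxon registry: abundant shared depleted taxa, cohort-specific
    enrichments, and a log-normal background community."""
    rng = np.random.default_rng([seed, 104729])
    taxa: list[TaxonSpec] = []
    # shared depleted: abundant short-chain-fatty-acid producers
    for i, (species, genus) in enumerate(_MURIBACULACEAE):
        lineage = (
            "d__Bacteria; p__Bacteroidota; c__Bacteroidia; o__Bacteroidales; "
            f"f__Muribaculaceae; {genus}; s__{species}"
        )
        taxa.append(
            TaxonSpec(
                taxon_id=f"OGU{i:03d}",
                lineage=lineage,
                baseline=0.06,
                folds={"Antepartum": depletion_fold, "Postpartum": depletion_fold},
            )
        )
    k = len(taxa)
    for cohort, enriched in (
        ("Antepartum", _ANTE_ENRICHED),
        ("Postpartum", _POST_ENRICHED),
    ):
        for species, fam, genus in enriched:
            lineage = (
                f"d__Bacteria; p__Bacillota; c__Bacilli; o__Lactobacillales; "
                f"{fam}; {genus}; s__{species}"
            )
            taxa.append(
                TaxonSpec(
                    taxon_id=f"OGU{k:03d}",
                    lineage=lineage,
                    baseline=0.01,
                    folds={cohort: enrichment_fold},
                )
            )
            k += 1
    weights = np.exp(rng.normal(0.0, 1.0, size=n_background))
    remaining = 1.0 - sum(t.baseline for t in taxa)
    weights = remaining * weights / weights.sum()
    for i in range(n_background):
        taxa.append(
            TaxonSpec(
                taxon_id=f"OGU{k:03d}",
                lineage=(
                    "d__Bacteria; p__Bacillota; c__Clostridia; o__Lachnospirales; "
                    f"f__Lachnospiraceae; g__Background; s__Background sp{i:03d}"
                ),
                baseline=float(weights[i]),
                folds={},
            )
        )
        k += 1
    return taxa


# ---------------------------------------------------------------------------
# spectra templates


def _template_peaks(mol: Molecule) -> tuple[np.ndarray, np.ndarray]:
    """Class-specific stick-spectrum template (<= 12 peaks).

    Carnitines carry the trimethylammonium (C3H10N+) and dehydrated-core
    acylium (C4H5O2+) diagnostic cations plus acyl-dependent losses; bile
    acids a water-loss ladder [M+H-k*H2O]+ for k = 1..n+2; hexose
    conjugates additionally the aglycone peak after the 162.0528 Da neutral
    loss.  Remaining capacity is filled with reproducible molecule-specific
    fragments so twin spectra share enough peaks for matching.
    """
    prec = mol.mz
    rng = np.random.default_rng([mol.template_seed, 13])
    peaks: list[tuple[float, float]] = [(prec, 0.30)]
    if mol.mol_class == "carnitine":
        tma, acylium = chem.CARNITINE_FRAGMENTS
        peaks += [
            (tma, 0.90),
            (acylium, 1.00),
            (prec - chem.WATER_MASS, 0.35),
            (prec - chem.monoisotopic_mass("C3H9N"), 0.50),
            (prec - chem.monoisotopic_mass("C7H15NO3"), 0.45),
        ]
    elif mol.mol_class in ("bile_acid", "hexose_bile_acid"):
        n = mol.n_hydroxyl
        core = chem.Formula({"C": 24, "H": 40, "O": n + 2})
        core_mh = chem.adduct_mz(core, "[M+H]+")
        if mol.mol_class == "hexose_bile_acid":
            peaks.append((prec - chem.HEXOSE_LOSS, 0.80))
            for k in range(n, n + 3):
                peaks.append((core_mh - k * chem.WATER_MASS, 1.0 - 0.1 * (k - n)))
        else:
            for k in range(1, n + 3):
                peaks.append((prec - k * chem.WATER_MASS, 1.0 - 0.08 * (k - 1)))
    elif mol.mol_class == "drug":
        # beta-lactam fragment series (ammonia loss, thiazolidine fragments)
        peaks += [
            (prec - chem.monoisotopic_mass("NH3"), 0.70),
            (160.0432, 1.00),
            (106.0499, 0.85),
            (114.0371, 0.40),
        ]
    # fill to ~10 peaks with reproducible molecule-specific fragments
    while len(peaks) < 10:
        peaks.append(
            (float(rng.uniform(50.0, max(60.0, prec - 20.0))), float(rng.uniform(0.1, 0.7)))
        )
    peaks = peaks[:12]
    mz = np.array([p[0] for p in peaks])
    inten = np.array([p[1] for p in peaks])
    order = np.argsort(mz)
    return mz[order], inten[order]


def _jitter_spectrum(
    mol: Molecule,
    feat_id: str,
    cohort: str,
    mz_obs: float,
    rt_obs: float,
    design: StudyDesign,
    rng: np.random.Generator,
) -> Spectrum:
    mz, inten = _template_peaks(mol)
    ppm = rng.uniform(-design.mz_jitter_ppm, design.mz_jitter_ppm, size=mz.size)
    mz = mz * (1.0 + ppm * 1e-6)
    # weak peaks are the ones lost to the acquisition noise floor: dropout
    # probability scales down with relative template intensity, keeping the
    # overall dropout rate at or below ``peak_dropout``
    p_drop = design.peak_dropout * (1.0 - inten / inten.max())
    keep = rng.random(mz.size) >= p_drop
    inten = inten * np.exp(rng.normal(0.0, design.noise_cv, size=inten.size))
    if keep.sum() < 2:  # never emit a near-empty spectrum
        keep[:] = True
    return Spectrum(
        feature_id=feat_id,
        precursor_mz=mz_obs,
        rt=rt_obs,
        mz=mz[keep],
        intensity=inten[keep],
        cohort=cohort,
    )


# ---------------------------------------------------------------------------
# metabolome generation


@dataclass
class MetabolomeData:
    tables: dict[str, FeatureTable]
    spectra: dict[str, list[Spectrum]]
    truth: GroundTruth


def _sample_grid(design: StudyDesign, cohort: str) -> pd.DataFrame:
    rows = []
    for arm in design.arms:
        for dam in range(1, design.dams_per_arm + 1):
            animal = f"{cohort[:4]}{arm}{dam:02d}"
            for tp, phase in design.timepoints[cohort]:
                rows.append(
                    {
                        "sample_id": f"{animal}.{tp}",
                        "cohort": cohort,
                        "animal": animal,
                        "arm": arm,
                        "timepoint": tp,
                        "phase": phase,
                        "type": "sample",
                    }
                )
    for b in range(1, design.n_blanks + 1):
        rows.append(
            {
                "sample_id": f"{cohort[:4]}.blank{b:02d}",
                "cohort": cohort,
                "animal": "NA",
                "arm": "NA",
                "timepoint": "NA",
                "phase": "NA",
                "type": "blank",
            }
        )
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def _effect_weight(
    design: StudyDesign, cohort: str, phase: str, tp_index_post: int
) -> float:
    """Exponent on the log-fold effect: 1 during treatment, geometric decay
    (cohort persistence factor) through the post phase, 0 pre-treatment."""
    if phase == "treatment":
        return 1.0
    if phase == "post":
        decay = design.persistence.get(cohort, 0.0)
        return float(decay ** (tp_index_post + 1))
    return 0.0


def generate_metabolome(design: StudyDesign, truth: GroundTruth) -> MetabolomeData:
    """Simulate per-cohort feature tables and MS/MS spectra.

    Baseline peak areas are log-normal per molecule (shared across cohorts
    up to a cohort batch-scale factor); treatment effects are multiplicative
    in AMP dams with cohort-specific persistence; 5 % of entries drop out to
    zero; blanks carry contaminants at sample-like levels.
    """
    base_rng = np.random.default_rng([design.seed, 211])
    baselines = {
        m.mol_id: float(
            np.exp(
                base_rng.normal(design.baseline_log_mean, design.baseline_log_sigma)
            )
        )
        for m in truth.molecules
    }
    drug_level = float(np.exp(design.baseline_log_mean))

    tables: dict[str, FeatureTable] = {}
    spectra: dict[str, list[Spectrum]] = {}
    for ci, cohort in enumerate(design.cohorts):
        rng = np.random.default_rng([design.seed, 307, ci])
        scale = float(np.exp(rng.normal(0.0, design.cohort_scale_sigma)))
        samples = _sample_grid(design, cohort)
        post_index = {}
        k = 0
        for tp, phase in design.timepoints[cohort]:
            if phase == "post":
                post_index[tp] = k
                k += 1

        feats = []
        areas = np.zeros((len(truth.molecules), len(samples)))
        cohort_spectra: list[Spectrum] = []
        for i, mol in enumerate(truth.molecules):
            fid = feature_id(cohort, mol.mol_id)
            mz_obs = mol.mz * (
                1.0 + rng.uniform(-design.mz_jitter_ppm, design.mz_jitter_ppm) * 1e-6
            )
            rt_obs = mol.rt + rng.normal(0.0, design.rt_jitter_sd)
            feats.append(
                {
                    "feature_id": fid,
                    "mz": mz_obs,
                    "rt": rt_obs,
                    "molecule_id": mol.mol_id,
                    "mol_class": mol.mol_class,
                }
            )
            fold = truth.effects.get(mol.mol_id, {}).get(cohort, 1.0)
            for j, row in samples.iterrows():
                if row["type"] == "blank":
                    mean = baselines[mol.mol_id] if mol.mol_class == "contaminant" else 0.0
                elif mol.mol_class == "drug":
                    if row["arm"] != "AMP" or row["phase"] == "pre":
                        mean = 0.0
                    elif row["phase"] == "treatment":
                        mean = drug_level
                    else:
                        mean = drug_level * 0.05 ** (post_index[row["timepoint"]] + 1)
                else:
                    mean = baselines[mol.mol_id] * scale
                    if row["arm"] == "AMP" and fold != 1.0:
                        w = _effect_weight(
                            design,
                            cohort,
                            row["phase"],
                            post_index.get(row["timepoint"], 0),
                        )
                        mean *= fold**w
                if mean > 0:
                    area = mean * float(
                        np.exp(rng.normal(0.0, design.noise_cv))
                    )
                    if row["type"] != "blank" and rng.random() < design.dropout:
                        area = 0.0
                    areas[i, j] = area
            cohort_spectra.append(
                _jitter_spectrum(mol, fid, cohort, mz_obs, rt_obs, design, rng)
            )
        tables[cohort] = FeatureTable(pd.DataFrame(feats), samples, areas)
        spectra[cohort] = cohort_spectra
    return MetabolomeData(tables=tables, spectra=spectra, truth=truth)


# ---------------------------------------------------------------------------
# metagenome generation


def generate_metagenome(design: StudyDesign, truth: GroundTruth) -> dict[str, TaxonTable]:
    """Simulate per-cohort taxon (OGU) count tables.

    Counts follow a Dirichlet-multinomial around the baseline composition;
    treatment fold changes apply to AMP dams during the treatment phase.
    Library sizes are log-normal (median ``library_size_median``); a
    fraction of samples is generated under-depth (flagged in the metadata
    column ``under_depth``) to exercise read-count exclusion.
    """
    if not truth.taxa:
        raise ValueError("taxon registry is empty")
    baseline = np.array([t.baseline for t in truth.taxa], dtype=float)
    baseline = baseline / baseline.sum()
    tables: dict[str, TaxonTable] = {}
    for ci, cohort in enumerate(design.cohorts):
        rng = np.random.default_rng([design.seed, 401, ci])
        samples = _sample_grid(design, cohort)
        samples = samples[samples["type"] == "sample"].reset_index(drop=True)
        folds = np.array(
            [t.folds.get(cohort, 1.0) for t in truth.taxa], dtype=float
        )
        counts = np.zeros((len(truth.taxa), len(samples)), dtype=np.int64)
        under = np.zeros(len(samples), dtype=bool)
        for j, row in samples.iterrows():
            comp = baseline.copy()
            if row["arm"] == "AMP" and row["phase"] == "treatment":
                comp = comp * folds
            comp = comp / comp.sum()
            alpha = comp * design.dirichlet_concentration
            props = rng.dirichlet(alpha)
            under[j] = rng.random() < design.under_depth_fraction
            median = (
                design.under_depth_median if under[j] else design.library_size_median
            )
            depth = int(
                np.exp(rng.normal(np.log(median), design.library_size_sigma))
            )
            counts[:, j] = rng.multinomial(depth, props)
        samples = samples.copy()
        samples["under_depth"] = under
        taxa_df = pd.DataFrame(
            {
                "taxon_id": [t.taxon_id for t in truth.taxa],
                "lineage": [t.lineage for t in truth.taxa],
            }
        )
        tables[cohort] = TaxonTable(taxa_df, samples, counts)
    return tables


def truth_frame(truth: GroundTruth) -> pd.DataFrame:
    """Machine-readable ground-truth sidecar (one row per molecule)."""
    rows = []
    for m in truth.molecules:
        per = truth.effects.get(m.mol_id, {})
        rows.append(
            {
                "molecule_id": m.mol_id,
                "mol_class": m.mol_class,
                "formula": m.formula or "",
                "adduct": m.adduct,
                "mz": m.mz,
                "rt": m.rt,
                "n_hydroxyl": m.n_hydroxyl,
                **{f"fold_{c}": per.get(c, 1.0) for c in ("Antepartum", "Postpartum")},
            }
        )
    return pd.DataFrame(rows)
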