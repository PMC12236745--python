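"""Readers and writers for the pipeline's external artifacts.

Spectra travel as MGF (``BEGIN IONS``/``END IONS`` blocks; ``SCANS`` carries
the feature id, ``RTINSECONDS`` is converted to/from the internal
retention-time unit of minutes).  Tables are tab-separated UTF-8 text with
"." decimals, compatible with molecular-networking exports.  A small shim
maps GNPS classical-networking merged-pairs files onto the internal
matched-pair schema.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .datasets import SAMPLE_COLUMNS, FeatureTable, Spectrum, TaxonTable

__all__ = [
    "MgfParseError",
    "read_mgf",
    "write_mgf",
    "read_feature_table",
    "write_feature_table",
    "read_taxon_table",
    "write_taxon_table",
    "PAIR_COLUMNS",
    "write_pair_table",
    "read_pair_table",
    "read_gnps_merged_pairs",
    "read_config",
    "write_config",
]

log = logging.getLogger("periomics")

PAIR_COLUMNS = [
    "id_A",
    "cohort_A",
    "id_B",
    "cohort_B",
    "delta_mz",
    "delta_rt",
    "cosine",
    "n_matched_peaks",
    "direction_A",
    "direction_B",
    "concordant",
]


class MgfParseError(ValueError):
    """Malformed MGF content (missing END IONS, PEPMASS, non-numeric peak)."""


def read_mgf(path: str | Path, cohort: str = "") -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` objects.

    ``SCANS`` (or ``TITLE`` as fallback) provides the feature id;
    ``RTINSECONDS`` is converted to minutes.  Raises :class:`MgfParseError`
    for blocks violating the format contract, naming the offending block.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    spectra: list[Spectrum] = []
    try:
        with _mgf.MGF(str(path)) as reader:
            for i, entry in enumerate(reader):
                params = entry["params"]
                if "pepmass" not in params or params["pepmass"][0] is None:
                    raise MgfParseError(
                        f"{path.name}: block {i + 1} missing PEPMASS"
                    )
                fid = str(params.get("scans", params.get("title", f"scan{i + 1}")))
                rt_s = params.get("rtinseconds", 0.0)
                spectra.append(
                    Spectrum(
                        feature_id=fid,
                        precursor_mz=float(params["pepmass"][0]),
                        rt=float(rt_s) / 60.0,
                        mz=np.asarray(entry["m/z array"], dtype=float),
                        intensity=np.asarray(entry["intensity array"], dtype=float),
                        cohort=cohort,
                    )
                )
    except MgfParseError:
        raise
    except Exception as exc:  # pyteomics raises assorted errors on bad blocks
        raise MgfParseError(f"{path.name}: malformed MGF ({exc})") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF, one BEGIN IONS block per spectrum.

    Precursor m/z is written at 6 decimals and fragment peaks at 4, so a
    write/read round trip is lossless at the precision the pipeline uses.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"RTINSECONDS={s.rt * 60.0:.4f}\n")
            fh.write(f"SCANS={s.feature_id}\n")
            fh.write(f"TITLE={s.feature_id}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.4f} {inten:.4f}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# delimited tables


def _read_tsv(path: str | Path) -> pd.DataFrame:
    # "NA" is a meaningful metadata label (blank injections), not missing data
    return pd.read_csv(
        path, sep="\t", dtype={"sample_id": str}, keep_default_na=False, na_values=[]
    )


def write_feature_table(
    table: FeatureTable, data_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a feature table as two TSVs: areas (+feature records) and metadata."""
    df = table.features.copy()
    for sid, col in zip(table.sample_ids, table.areas.T):
        df[sid] = col
    df.to_csv(data_path, sep="\t", index=False)
    table.samples.to_csv(metadata_path, sep="\t", index=False)


def read_feature_table(
    data_path: str | Path, metadata_path: str | Path
) -> FeatureTable:
    df = _read_tsv(data_path)
    samples = _read_tsv(metadata_path)
    for col in SAMPLE_COLUMNS:
        if col in samples.columns:
            samples[col] = samples[col].astype(str)
    feat_cols = [c for c in df.columns if c not in set(samples.get("sample_id", []))]
    sample_cols = [c for c in df.columns if c in set(samples.get("sample_id", []))]
    if set(sample_cols) != set(samples["sample_id"]):
        missing = set(samples["sample_id"]) - set(sample_cols)
        raise ValueError(f"feature table missing sample columns: {sorted(missing)}")
    ordered = samples["sample_id"].tolist()
    return FeatureTable(
        df[feat_cols].astype({"feature_id": str}),
        samples,
        df[ordered].to_numpy(dtype=float),
    )


def write_taxon_table(
    table: TaxonTable, data_path: str | Path, metadata_path: str | Path
) -> None:
    df = table.taxa.copy()
    for sid, col in zip(table.sample_ids, table.counts.T):
        df[sid] = col
    df.to_csv(data_path, sep="\t", index=False)
    table.samples.to_csv(metadata_path, sep="\t", index=False)


def read_taxon_table(data_path: str | Path, metadata_path: str | Path) -> TaxonTable:
    df = _read_tsv(data_path)
    samples = _read_tsv(metadata_path)
    for col in SAMPLE_COLUMNS:
        if col in samples.columns:
            samples[col] = samples[col].astype(str)
    taxon_cols = [c for c in df.columns if c not in set(samples.get("sample_id", []))]
    ordered = samples["sample_id"].tolist()
    missing = [s for s in ordered if s not in df.columns]
    if missing:
        raise ValueError(f"taxon table missing sample columns: {missing}")
    return TaxonTable(
        df[taxon_cols].astype({"taxon_id": str}),
        samples,
        df[ordered].to_numpy(),
    )


def write_pair_table(pairs: Sequence, path: str | Path) -> None:
    """Write matched cross-cohort pairs with the canonical column order."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "id_A": p.id_a,
                "cohort_A": p.cohort_a,
                "id_B": p.id_b,
                "cohort_B": p.cohort_b,
                "delta_mz": p.delta_mz,
                "delta_rt": p.delta_rt,
                "cosine": p.cosine,
                "n_matched_peaks": p.n_matched_peaks,
                "direction_A": p.direction_a,
                "direction_B": p.direction_b,
                "concordant": p.concordant,
            }
        )
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pair table missing columns: {missing}")
    return df


def read_gnps_merged_pairs(path: str | Path) -> pd.DataFrame:
    """Import shim for GNPS classical-networking ``merged_pairs.tsv`` files.

    Maps CLUSTERID1/CLUSTERID2/DeltaMZ/Cosine columns onto the internal pair
    schema with unknown directions.
    """
    df = _read_tsv(path)
    required = {"CLUSTERID1", "CLUSTERID2", "Cosine"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"merged-pairs file missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "id_A": df["CLUSTERID1"].astype(str),
            "cohort_A": "",
            "id_B": df["CLUSTERID2"].astype(str),
            "cohort_B": "",
            "delta_mz": df.get("DeltaMZ", np.nan),
            "delta_rt": np.nan,
            "cosine": df["Cosine"],
            "n_matched_peaks": df.get("MatchedPeaks", pd.NA),
            "direction_A": "ns",
            "direction_B": "ns",
            "concordant": False,
        }
    )
    return out[PAIR_COLUMNS]


def read_config(path: str | Path) -> dict:
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
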