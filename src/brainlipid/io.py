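"""File I/O: MGF spectra, feature tables with sidecar metadata, GMT sets, sn-call CSV."""

from __future__ import annotations

import os
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chem import MsmsSpectrum, SnCall


def read_mgf(path: str) -> list[MsmsSpectrum]:
    """Read spectra from a Mascot generic format file (TITLE, PEPMASS, CHARGE, RTINSECONDS)."""
    spectra = []
    with _mgf.read(path) as reader:
        for entry in reader:
            params = entry.get("params", {})
            pepmass = params.get("pepmass", (0.0,))
            charge = params.get("charge")
            polarity = "-"
            if charge:
                polarity = "-" if int(charge[0]) < 0 else "+"
            rt = params.get("rtinseconds")
            spectra.append(
                MsmsSpectrum(
                    precursor_mz=float(pepmass[0]),
                    polarity=polarity,
                    peaks=list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())),
                    retention_time=float(rt) / 60.0 if rt is not None else None,
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[MsmsSpectrum], path: str) -> None:
    entries = []
    for sp in spectra:
        mzs, intens = zip(*sp.peaks) if sp.peaks else ((), ())
        params = {
            "title": sp.title,
            "pepmass": sp.precursor_mz,
            "charge": "1-" if sp.polarity == "-" else "1+",
        }
        if sp.retention_time is not None:
            params["rtinseconds"] = sp.retention_time * 60.0
        entries.append(
            {
                "params": params,
                "m/z array": np.asarray(mzs),
                "intensity array": np.asarray(intens),
            }
        )
    _mgf.write(entries, output=path, file_mode="w")


def write_sn_calls(calls: dict[str, SnCall], path: str) -> pd.DataFrame:
    """Write sn-position calls to CSV: species, call, matched fragments, ppm errors."""
    rows = []
    for name, call in calls.items():
        rows.append(
            {
                "species": name,
                "call": call.call.value,
                "rt_rule_applied": call.rt_rule_applied,
                "evidence": ";".join(m.label for m in call.evidence),
                "ppm_errors": ";".join(f"{m.ppm_error:.2f}" for m in call.evidence),
                "note": call.note,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read gene/lipid sets from a GMT file (set name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_feature_table(table, prefix: str) -> None:
    """Write a FeatureTable as <prefix>_abundance.csv, _features.csv, _samples.csv."""
    table.abundance.to_csv(prefix + "_abundance.csv")
    table.feature_meta.to_csv(prefix + "_features.csv")
    table.sample_meta.to_csv(prefix + "_samples.csv")


def read_feature_table(prefix: str):
    from .preprocess import FeatureTable

    abundance = pd.read_csv(prefix + "_abundance.csv", index_col=0)
    feature_meta = pd.read_csv(prefix + "_features.csv", index_col=0)
    sample_meta = pd.read_csv(prefix + "_samples.csv", index_col=0)
    return FeatureTable(abundance, feature_meta, sample_meta)
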