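"""Readers and writers for the pipeline's file formats.

Feature tables are tab-separated text with the header
``sample_id  group  mz  rt_min  intensity  [m2_mz  m2_intensity  m4_mz
m4_intensity]`` (isotopologue columns optional and blank-tolerant). MS/MS
spectra travel as MGF (PEPMASS = precursor m/z, RTINSECONDS honored);
centroided mzML is also accepted. Ionization-efficiency tables are
two-column delimited text (class_id, ionization_efficiency).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .screening import Feature, Ms2Spectrum

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "load_ie_table",
]

_FEATURE_COLS = ["sample_id", "group", "mz", "rt_min", "intensity",
                 "m2_mz", "m2_intensity", "m4_mz", "m4_intensity"]


def write_feature_table(features: list[Feature], path: str | Path) -> None:
    rows = []
    for f in features:
        row = {
            "sample_id": f.sample_id,
            "group": f.group,
            "mz": f.mz,
            "rt_min": f.rt,
            "intensity": f.intensity,
            "m2_mz": np.nan, "m2_intensity": np.nan,
            "m4_mz": np.nan, "m4_intensity": np.nan,
        }
        if f.isotope_cluster:
            for i, (mz, inten) in enumerate(f.isotope_cluster[1:3], start=1):
                row[f"m{2 * i}_mz"] = mz
                row[f"m{2 * i}_intensity"] = inten
        rows.append(row)
    pd.DataFrame(rows, columns=_FEATURE_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_feature_table(path: str | Path) -> list[Feature]:
    df = pd.read_csv(path, sep="\t")
    missing = {"mz", "rt_min", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    features = []
    for idx, row in df.iterrows():
        try:
            cluster = [(float(row["mz"]), float(row["intensity"]))]
            for k in (2, 4):
                mz_k = row.get(f"m{k}_mz")
                if mz_k is not None and not (
                    isinstance(mz_k, float) and math.isnan(mz_k)
                ):
                    cluster.append(
                        (float(mz_k), float(row.get(f"m{k}_intensity", 0.0)))
                    )
            features.append(
                Feature(
                    mz=float(row["mz"]),
                    rt=float(row["rt_min"]),
                    intensity=float(row["intensity"]),
                    sample_id=str(row.get("sample_id", "")),
                    group=str(row.get("group", "")),
                    isotope_cluster=tuple(cluster) if len(cluster) > 1 else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad feature on line {idx + 2}: {exc}")
    return features


def write_mgf(spectra: list[Ms2Spectrum], path: str | Path) -> None:
    entries = []
    for i, s in enumerate(spectra):
        params = {"title": f"spectrum_{i}", "pepmass": s.precursor_mz}
        if s.rt is not None:
            params["rtinseconds"] = s.rt * 60.0
        entries.append(
            {
                "m/z array": np.array([mz for mz, _ in s.fragments]),
                "intensity array": np.array([it for _, it in s.fragments]),
                "params": params,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    spectra = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pepmass = params["pepmass"]
            precursor = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
            rt = params.get("rtinseconds")
            spectra.append(
                Ms2Spectrum(
                    precursor_mz=precursor,
                    fragments=tuple(
                        zip(
                            (float(x) for x in entry["m/z array"]),
                            (float(x) for x in entry["intensity array"]),
                        )
                    ),
                    rt=float(rt) / 60.0 if rt is not None else None,
                )
            )
    return spectra


def read_mzml(path: str | Path) -> list[Ms2Spectrum]:
    """Centroided MS2 scans from an mzML file."""
    from pyteomics import mzml as _mzml

    spectra = []
    with _mzml.read(str(path)) as reader:
        for scan in reader:
            if scan.get("ms level") != 2:
                continue
            precursor = float(
                scan["precursorList"]["precursor"][0]["selectedIonList"]
                ["selectedIon"][0]["selected ion m/z"]
            )
            rt = None
            scan_info = scan.get("scanList", {}).get("scan", [{}])[0]
            if "scan start time" in scan_info:
                rt = float(scan_info["scan start time"])
            spectra.append(
                Ms2Spectrum(
                    precursor_mz=precursor,
                    fragments=tuple(
                        zip(
                            (float(x) for x in scan["m/z array"]),
                            (float(x) for x in scan["intensity array"]),
                        )
                    ),
                    rt=rt,
                )
            )
    return spectra


def load_ie_table(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    if "class_id" not in cols or "ionization_efficiency" not in cols:
        raise ValueError(
            f"{path}: expected columns class_id, ionization_efficiency"
        )
    out = {}
    for _, row in df.iterrows():
        ie = float(row[cols["ionization_efficiency"]])
        if ie <= 0:
            raise ValueError(f"{path}: non-positive IE for {row[cols['class_id']]}")
        out[str(row[cols["class_id"]])] = ie
    return out
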