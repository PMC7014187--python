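"""Readers and writers for the plain-text formats used throughout the pipeline.

Compound and reaction tables, GMT-like metabolite sets, per-sample peak
lists, the sample manifest, aligned feature tables and distance matrices are
all tab-separated text. An optional mzML reader (via pyteomics) is provided
for real centroided spectra.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_compound_table",
    "write_compound_table",
    "read_reaction_table",
    "write_reaction_table",
    "read_gmt",
    "write_gmt",
    "read_spectrum",
    "write_spectrum",
    "read_mzml_spectrum",
    "read_manifest",
    "write_manifest",
]

_COMPOUND_COLS = ["compound_id", "name", "monoisotopic_mass", "is_xenobiotic", "set_ids"]
_REACTION_COLS = ["reaction_id", "substrates", "products"]


def _split_ids(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    s = str(cell).strip()
    return [tok for tok in s.split(";") if tok] if s else []


def read_compound_table(path: str | Path) -> pd.DataFrame:
    """Read a compound table.

    Columns: compound_id, name, monoisotopic_mass (Da), is_xenobiotic,
    set_ids (semicolon-separated metabolite-set tokens).
    """
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "name": str})
    missing = [c for c in _COMPOUND_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"compound table missing columns: {missing}")
    if df["compound_id"].duplicated().any():
        dups = df.loc[df["compound_id"].duplicated(), "compound_id"].tolist()
        raise ValueError(f"duplicate compound_id values: {dups[:5]}")
    mass = df["monoisotopic_mass"].astype(float)
    if not np.isfinite(mass).all() or (mass <= 0).any() or (mass >= 2000).any():
        raise ValueError("monoisotopic_mass must be finite and in (0, 2000) Da")
    df["monoisotopic_mass"] = mass
    df["is_xenobiotic"] = df["is_xenobiotic"].astype(bool)
    df["set_ids"] = df["set_ids"].map(_split_ids)
    return df[_COMPOUND_COLS]


def write_compound_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["set_ids"] = out["set_ids"].map(";".join)
    out["is_xenobiotic"] = out["is_xenobiotic"].astype(bool)
    out[_COMPOUND_COLS].to_csv(path, sep="\t", index=False)


def read_reaction_table(path: str | Path) -> pd.DataFrame:
    """Read a reaction table: reaction_id, substrates, products (semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REACTION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"reaction table missing columns: {missing}")
    df["substrates"] = df["substrates"].map(_split_ids)
    df["products"] = df["products"].map(_split_ids)
    for _, row in df.iterrows():
        if not row["substrates"] or not row["products"]:
            raise ValueError(f"reaction {row['reaction_id']}: empty substrate or product list")
    return df[_REACTION_COLS]


def write_reaction_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["substrates"] = out["substrates"].map(";".join)
    out["products"] = out["products"].map(";".join)
    out[_REACTION_COLS].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT-like metabolite sets: set_id <TAB> description <TAB> member..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for sid, members in sets.items():
        desc = (descriptions or {}).get(sid, sid)
        lines.append("\t".join([sid, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path, sample_id: str | None = None):
    """Read one centroided peak list (TSV with columns mz, intensity)."""
    from .preprocess import PeakSpectrum

    df = pd.read_csv(path, sep="\t")
    if not {"mz", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: peak list needs 'mz' and 'intensity' columns")
    sid = sample_id if sample_id is not None else Path(path).stem
    return PeakSpectrum(sid, df["mz"].to_numpy(float), df["intensity"].to_numpy(float))


def write_spectrum(spectrum, path: str | Path) -> None:
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity}).to_csv(
        path, sep="\t", index=False)


def read_mzml_spectrum(path: str | Path, sample_id: str | None = None, index: int = 0):
    """Read one centroided spectrum from an mzML file (requires pyteomics)."""
    from pyteomics import mzml as _mzml

    from .preprocess import PeakSpectrum

    with _mzml.MzML(str(path)) as reader:
        for i, spec in enumerate(reader):
            if i == index:
                mz = np.asarray(spec["m/z array"], float)
                inten = np.asarray(spec["intensity array"], float)
                order = np.argsort(mz)
                sid = sample_id if sample_id is not None else Path(path).stem
                return PeakSpectrum(sid, mz[order], inten[order])
    raise IndexError(f"spectrum index {index} not found in {path}")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Sample manifest: sample_id, group, sex, path (path relative to the manifest)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "group", "sex", "path"}
    if not need <= set(df.columns):
        raise ValueError(f"manifest needs columns {sorted(need)}")
    base = Path(path).parent
    df["path"] = [str((base / p)) for p in df["path"]]
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
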