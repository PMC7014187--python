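"""Accurate-mass candidate search under positive-mode adduct corrections.

Each feature's consensus m/z is matched against the compound table assuming
protonated, sodiated, or potassiated ions; every (compound, adduct) pair
whose theoretical m/z lies within an absolute tolerance (default 0.005 Da)
is a candidate. This is the local stand-in for a metabolite search engine
query and deliberately ignores isotopologues, multimers and neutral losses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ADDUCT_SHIFTS", "Candidate", "CandidateSet", "match_mass",
           "search_table", "candidates_to_frame", "frame_to_candidates"]

#: monoisotopic m/z shift of singly charged positive adducts, Da
ADDUCT_SHIFTS: dict[str, float] = {
    "H": 1.00728,
    "Na": 22.98922,
    "K": 38.96316,
}


@dataclass(frozen=True)
class Candidate:
    compound_id: str
    adduct: str
    mass_error: float  # observed minus theoretical, Da


@dataclass
class CandidateSet:
    feature_id: str
    candidates: list[Candidate] = field(default_factory=list)

    def compound_ids(self) -> list[str]:
        return [c.compound_id for c in self.candidates]

    def __len__(self) -> int:
        return len(self.candidates)


def match_mass(mz: float, compounds: pd.DataFrame, tolerance: float = 0.005,
               feature_id: str = "") -> CandidateSet:
    """All (compound, adduct) pairs whose adduct m/z is within ``tolerance`` of ``mz``.

    Results are sorted by absolute mass error (ties by compound id then adduct).
    """
    masses = compounds["monoisotopic_mass"].to_numpy(float)
    ids = compounds["compound_id"].to_numpy(str)
    found: list[Candidate] = []
    for adduct, shift in ADDUCT_SHIFTS.items():
        err = mz - (masses + shift)
        hit = np.abs(err) <= tolerance
        found.extend(Candidate(ids[i], adduct, float(err[i])) for i in np.flatnonzero(hit))
    found.sort(key=lambda c: (abs(c.mass_error), c.compound_id, c.adduct))
    return CandidateSet(feature_id, found)


def search_table(table, compounds: pd.DataFrame, tolerance: float = 0.005
                 ) -> dict[str, CandidateSet]:
    """Candidate search for every feature of an aligned table.

    Uses a sorted-mass binary search per adduct; equivalent to brute-force
    scanning of all (compound, adduct) pairs.
    """
    masses = compounds["monoisotopic_mass"].to_numpy(float)
    ids = compounds["compound_id"].to_numpy(str)
    order = np.argsort(masses, kind="stable")
    ms, cs = masses[order], ids[order]

    out: dict[str, CandidateSet] = {}
    n_cand_records = 0
    for fid, mz in zip(table.feature_ids, table.mz):
        found: list[Candidate] = []
        for adduct, shift in ADDUCT_SHIFTS.items():
            neutral = mz - shift
            lo = np.searchsorted(ms, neutral - tolerance, side="left")
            hi = np.searchsorted(ms, neutral + tolerance, side="right")
            found.extend(Candidate(cs[i], adduct, float(neutral - ms[i]))
                         for i in range(lo, hi))
        found.sort(key=lambda c: (abs(c.mass_error), c.compound_id, c.adduct))
        out[fid] = CandidateSet(fid, found)
        n_cand_records += len(found)
    n_with = sum(1 for c in out.values() if len(c))
    logger.info("candidate search: %d features, %d with >=1 candidate, %d candidate records",
                len(out), n_with, n_cand_records)
    return out


def candidates_to_frame(candidate_map: dict[str, CandidateSet], table=None) -> pd.DataFrame:
    """Flatten a candidate map to a TSV-ready frame."""
    mz_of = dict(zip(table.feature_ids, table.mz)) if table is not None else {}
    rows = [
        {"feature_id": fid, "consensus_mz": mz_of.get(fid, np.nan),
         "compound_id": c.compound_id, "adduct": c.adduct, "mass_error": c.mass_error}
        for fid, cset in candidate_map.items() for c in cset.candidates
    ]
    return pd.DataFrame(rows, columns=["feature_id", "consensus_mz", "compound_id",
                                       "adduct", "mass_error"])


def frame_to_candidates(df: pd.DataFrame, feature_ids=None) -> dict[str, CandidateSet]:
    out = {fid: CandidateSet(fid) for fid in (feature_ids or df["feature_id"].unique())}
    for row in df.itertuples(index=False):
        out.setdefault(row.feature_id, CandidateSet(row.feature_id)).candidates.append(
            Candidate(row.compound_id, row.adduct, float(row.mass_error)))
    return out


def write_candidates(candidate_map: dict[str, CandidateSet], path: str | Path,
                     table=None) -> None:
    candidates_to_frame(candidate_map, table).to_csv(path, sep="\t", index=False)
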