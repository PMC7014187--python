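"""Seeded synthetic study generator: network, cohort, spectra and ground truth.

The generator emulates the statistical structure a context-support
annotation algorithm relies on, at desk scale:

* a compound universe organised into pathways (linear reaction chains with
  occasional cross-links) with uniformly distributed monoisotopic masses;
* a five-group cohort (normal weight, overweight, three obesity stages) of
  20 subjects each with a 10/10 sex split;
* per-subject compound concentrations that are log-normal with a shared
  latent activity factor per pathway, so log-concentrations of compounds in
  the same pathway correlate (Pearson ~ ``rho``, default 0.6);
* a multiplicative concentration decrease of the affected metabolite sets
  in case groups (default multiplier 0.5);
* one to three positive-mode adduct peaks per compound (H+/Na+/K+), with
  intensity proportional to concentration times a compound response factor
  under multiplicative noise, and Gaussian m/z jitter (sigma 0.001 Da);
* optional "decoy" database compounds whose adduct m/z collides with a true
  compound's adduct m/z within the search tolerance (they sit in the
  compound table and the network but emit no peaks, creating ambiguous
  candidate sets);
* fragment peaks at lower m/z whose intensity is a fixed multiple of the
  parent ion's (near-unit intensity correlation, i.e. derivative pairs);
* a reproducible chemical background: uniform-random noise peak positions
  and base intensities drawn once per cohort (real background ions recur in
  every injection, which is what makes rank-based window normalization a
  stable intensity reference), jittered per sample like signal peaks;
* a losartan-like internal standard at m/z 423.169 in every spectrum.

Isotope envelopes, multimers, chromatography and profile-mode signals are
deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .candidates import ADDUCT_SHIFTS
from .preprocess import PeakSpectrum

__all__ = [
    "GroupSpec",
    "CohortDesign",
    "SpectralParams",
    "NetworkTruth",
    "SyntheticTruth",
    "table3_design",
    "generate_network",
    "simulate_cohort",
    "write_cohort",
]

MZ_RANGE = (45.0, 900.0)  # instrument detection range, Da


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_subjects: int
    n_male: int
    n_female: int

    def __post_init__(self):
        if self.n_male + self.n_female != self.n_subjects:
            raise ValueError(f"group {self.label}: n_male + n_female != n_subjects")


@dataclass(frozen=True)
class SetEffect:
    """Multiplicative concentration effect of a metabolite set in case groups."""

    set_id: str
    multiplier: float  # in (0, 1]: disease decreases concentrations
    groups: tuple[str, ...]

    def __post_init__(self):
        if not 0 < self.multiplier <= 1:
            raise ValueError("effect multiplier must be in (0, 1]")


@dataclass(frozen=True)
class CohortDesign:
    groups: tuple[GroupSpec, ...]
    affected: tuple[SetEffect, ...] = ()

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)


def table3_design(affected_set: str | None = None, multiplier: float = 0.5,
                  affected_groups: tuple[str, ...] | None = None) -> CohortDesign:
    """Default cohort shape: 5 groups x 20 subjects, 10 male / 10 female.

    ``affected_set`` (optionally) names one metabolite set whose member
    concentrations are multiplied by ``multiplier`` in the case groups
    (default: every non-normal group).
    """
    labels = ("normal", "overweight", "obesity1", "obesity2", "obesity3")
    groups = tuple(GroupSpec(lb, 20, 10, 10) for lb in labels)
    affected: tuple[SetEffect, ...] = ()
    if affected_set is not None:
        tgt = affected_groups if affected_groups is not None else labels[1:]
        affected = (SetEffect(affected_set, multiplier, tuple(tgt)),)
    return CohortDesign(groups, affected)


@dataclass(frozen=True)
class NetworkTruth:
    """Generator bookkeeping for the compound universe."""

    pathway_of: dict[str, str]          # compound_id -> set_id
    decoy_ids: frozenset[str]           # database-only compounds (emit no peaks)
    decoy_target: dict[str, tuple[str, str, str]]  # decoy -> (target cid, target adduct, decoy adduct)


@dataclass
class SpectralParams:
    """Tunable knobs of the spectral response model (defaults are the reference conditions)."""

    rho: float = 0.6                    # within-pathway correlation of log-concentrations
    log_sigma: float = 0.6              # between-subject biological SD of log-concentration
    compound_spread: float = 1.0        # SD of per-compound baseline log-abundance
    mean_log_intensity: float = float(np.log(1000.0))
    adduct_probs: dict[str, float] = field(
        default_factory=lambda: {"H": 1.0, "Na": 0.4, "K": 0.2})
    adduct_scale: dict[str, float] = field(
        default_factory=lambda: {"H": 1.0, "Na": 0.5, "K": 0.25})
    response_sigma: float = 0.3         # SD of log response factor per (compound, adduct)
    noise_sigma: float = 0.2            # multiplicative measurement noise, log scale
    mz_jitter: float = 0.001            # Gaussian m/z error SD, Da
    # background density matches realistic spectra (~9300 peaks/spectrum):
    # the rank-150 window divisor of the normalization is a mid-order
    # statistic only at a few hundred peaks per 50 Da window
    n_noise_peaks: int = 9000
    noise_log_mean: float = float(np.log(100.0))
    noise_log_sigma: float = 1.0
    fragment_fraction: float = 0.1      # fraction of emitting compounds with a fragment peak
    fragment_multiple: float = 0.5      # fragment intensity as multiple of the parent H+ peak
    internal_standard_mz: float = 423.169
    internal_standard_intensity: float = 5e4
    calibration_ppm: float = 0.0        # per-sample multiplicative m/z drift SD, ppm
    detection_limit: float = 5.0        # peaks below this raw intensity are not detected


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort, for recovery tests."""

    peak_map: pd.DataFrame              # theo_mz, compound_id, adduct, kind
    concentrations: pd.DataFrame        # compounds x samples (linear scale)
    manifest: pd.DataFrame              # sample_id, group, sex
    fragment_parents: dict[str, str]    # fragment compound's parent -> itself (cid -> cid)

    def match_features(self, table, tolerance: float = 0.005) -> pd.DataFrame:
        """Label each aligned feature with the nearest true peak within tolerance.

        Features matching no true m/z are labelled ``noise``.
        """
        theo = self.peak_map.sort_values("theo_mz").reset_index(drop=True)
        tmz = theo["theo_mz"].to_numpy()
        rows = []
        for fid, mz in zip(table.feature_ids, table.mz):
            j = int(np.searchsorted(tmz, mz))
            best, derr = None, np.inf
            for k in (j - 1, j):
                if 0 <= k < len(tmz) and abs(tmz[k] - mz) < derr:
                    best, derr = k, abs(tmz[k] - mz)
            if best is not None and derr <= tolerance:
                r = theo.iloc[best]
                rows.append((fid, mz, r["kind"], r["compound_id"], r["adduct"]))
            else:
                rows.append((fid, mz, "noise", "", ""))
        return pd.DataFrame(rows, columns=["feature_id", "mz", "kind",
                                           "compound_id", "adduct"])

    def derivative_pairs(self, table, tolerance: float = 0.005) -> list[tuple[str, str]]:
        """(parent H+ feature, fragment feature) pairs present in an aligned table."""
        lab = self.match_features(table, tolerance)
        parents = lab[(lab["kind"] == "adduct") & (lab["adduct"] == "H")]
        frags = lab[lab["kind"] == "fragment"]
        pmap = dict(zip(parents["compound_id"], parents["feature_id"]))
        pairs = []
        for row in frags.itertuples(index=False):
            if row.compound_id in pmap:
                pairs.append((pmap[row.compound_id], row.feature_id))
        return pairs


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

def generate_network(
    n_compounds: int,
    n_pathways: int,
    seed: int,
    cross_link_prob: float = 0.15,
    decoy_fraction: float = 0.0,
    xenobiotic_fraction: float = 0.05,
    mass_range: tuple[float, float] = (100.0, 850.0),
    collision_tolerance: float = 0.005,
    min_separation: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]], NetworkTruth]:
    """Generate a compound table, reaction table and metabolite sets.

    Pathways are linear chains of reactions over contiguous compound blocks,
    with occasional cross-link reactions between pathways. Non-decoy masses
    are rejection-sampled so that all adduct m/z values are separated by
    more than ``min_separation``; decoys are then placed within
    ``collision_tolerance`` of a true compound's adduct m/z (in a different
    pathway) to create ambiguous candidate sets.
    """
    if n_compounds < 2 * n_pathways:
        raise ValueError("need n_compounds >= 2 * n_pathways")
    if not 0 <= decoy_fraction < 1:
        raise ValueError("decoy_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    width = len(str(n_compounds))
    cids = [f"C{i + 1:0{width}d}" for i in range(n_compounds)]

    # contiguous pathway blocks, sizes as equal as possible
    bounds = np.linspace(0, n_compounds, n_pathways + 1).round().astype(int)
    pw_width = len(str(n_pathways))
    set_ids = [f"PW{p + 1:0{pw_width}d}" for p in range(n_pathways)]
    pathway_of = {}
    sets: dict[str, list[str]] = {}
    for p, sid in enumerate(set_ids):
        members = cids[bounds[p]:bounds[p + 1]]
        sets[sid] = members
        for c in members:
            pathway_of[c] = sid

    # reactions: chain within each pathway + occasional cross-links
    reactions = []
    rid = 0
    for p, sid in enumerate(set_ids):
        members = sets[sid]
        for a, b in zip(members[:-1], members[1:]):
            rid += 1
            reactions.append((f"R{rid:05d}", [a], [b]))
    if n_pathways > 1:
        n_cross = rng.binomial(n_pathways, cross_link_prob)
        for _ in range(n_cross):
            p1, p2 = rng.choice(n_pathways, size=2, replace=False)
            a = sets[set_ids[p1]][rng.integers(len(sets[set_ids[p1]]))]
            b = sets[set_ids[p2]][rng.integers(len(sets[set_ids[p2]]))]
            rid += 1
            reactions.append((f"R{rid:05d}", [a], [b]))
    reactions_df = pd.DataFrame(reactions, columns=["reaction_id", "substrates", "products"])

    # decoys and their collision targets (target in a different pathway)
    n_decoys = int(round(decoy_fraction * n_compounds))
    decoy_idx = set(rng.choice(n_compounds, size=n_decoys, replace=False).tolist()) \
        if n_decoys else set()
    shifts = list(ADDUCT_SHIFTS.items())

    # rejection-sample non-decoy masses with well-separated adduct m/z values
    masses = np.zeros(n_compounds)
    taken: list[float] = [423.169]  # keep clear of the internal standard
    for i in range(n_compounds):
        if i in decoy_idx:
            continue
        for _ in range(10_000):
            m = rng.uniform(*mass_range)
            ions = [m + s for _, s in shifts]
            if all(abs(x - t) > min_separation for x in ions for t in taken):
                masses[i] = m
                taken.extend(ions)
                break
        else:
            raise RuntimeError("could not place well-separated compound masses; "
                               "reduce n_compounds or min_separation")

    decoy_target: dict[str, tuple[str, str, str]] = {}
    non_decoys = [i for i in range(n_compounds) if i not in decoy_idx]
    for i in sorted(decoy_idx):
        for _ in range(10_000):
            t = int(rng.choice(non_decoys))
            if pathway_of[cids[t]] == pathway_of[cids[i]]:
                continue
            # collide mostly with protonated ions (the commonly observed form)
            t_ad, t_shift = shifts[rng.choice(len(shifts), p=[0.6, 0.25, 0.15])]
            d_ad, d_shift = shifts[rng.integers(len(shifts))]
            eps = rng.uniform(-0.6, 0.6) * collision_tolerance
            m = masses[t] + t_shift - d_shift + eps
            if mass_range[0] <= m <= mass_range[1]:
                masses[i] = m
                decoy_target[cids[i]] = (cids[t], t_ad, d_ad)
                break
        else:
            raise RuntimeError("could not place a decoy compound")

    n_xeno = int(round(xenobiotic_fraction * n_compounds))
    xeno = set(rng.choice(n_compounds, size=n_xeno, replace=False).tolist())

    compounds = pd.DataFrame({
        "compound_id": cids,
        "name": [f"compound-{c}" for c in cids],
        "monoisotopic_mass": masses,
        "is_xenobiotic": [i in xeno for i in range(n_compounds)],
        "set_ids": [[pathway_of[c]] for c in cids],
    })
    truth = NetworkTruth(pathway_of, frozenset(cids[i] for i in decoy_idx), decoy_target)
    return compounds, reactions_df, sets, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    compounds: pd.DataFrame,
    sets: dict[str, list[str]],
    design: CohortDesign,
    params: SpectralParams | None = None,
    seed: int = 0,
    network_truth: NetworkTruth | None = None,
) -> tuple[list[PeakSpectrum], pd.DataFrame, SyntheticTruth]:
    """Simulate one cohort of spectra under the latent-pathway concentration model."""
    params = params if params is not None else SpectralParams()
    rng = np.random.default_rng(seed)

    # --- subjects -----------------------------------------------------------
    labels, groups, sexes = [], [], []
    for g in design.groups:
        labels.extend([g.label] * g.n_subjects)
        sexes.extend(["M"] * g.n_male + ["F"] * g.n_female)
    n_s = len(labels)
    sw = len(str(n_s))
    sample_ids = [f"S{i + 1:0{sw}d}" for i in range(n_s)]
    manifest = pd.DataFrame({"sample_id": sample_ids, "group": labels, "sex": sexes})

    cids = compounds["compound_id"].tolist()
    masses = dict(zip(cids, compounds["monoisotopic_mass"]))
    n_c = len(cids)
    decoys = network_truth.decoy_ids if network_truth is not None else frozenset()

    # --- latent concentrations ----------------------------------------------
    pathway_ids = sorted(sets)
    pw_index = {s: k for k, s in enumerate(pathway_ids)}
    member_of = {c: s for s, mem in sets.items() for c in mem}
    activity = rng.standard_normal((len(pathway_ids), n_s))
    eps = rng.standard_normal((n_c, n_s))
    base = params.mean_log_intensity + params.compound_spread * rng.standard_normal(n_c)
    sr, se = np.sqrt(params.rho), np.sqrt(1.0 - params.rho)
    log_conc = np.empty((n_c, n_s))
    for i, c in enumerate(cids):
        shared = activity[pw_index[member_of[c]]] if c in member_of else \
            rng.standard_normal(n_s)
        log_conc[i] = base[i] + params.log_sigma * (sr * shared + se * eps[i])

    # disease effect: multiplicative decrease in case groups
    group_arr = np.asarray(labels)
    for eff in design.affected:
        in_groups = np.isin(group_arr, list(eff.groups))
        rows = [i for i, c in enumerate(cids) if member_of.get(c) == eff.set_id]
        log_conc[np.ix_(rows, np.flatnonzero(in_groups))] += np.log(eff.multiplier)
    conc = np.exp(log_conc)

    # --- emission structure (fixed across samples) ---------------------------
    emitters = [c for c in cids if c not in decoys]
    emit: list[tuple[str, str, float, float]] = []  # (cid, adduct, theo_mz, resp)
    for c in emitters:
        chosen = [a for a, p in params.adduct_probs.items() if rng.random() < p]
        if not chosen:
            chosen = ["H"]
        for a in chosen:
            theo = masses[c] + ADDUCT_SHIFTS[a]
            if not MZ_RANGE[0] <= theo <= MZ_RANGE[1]:
                continue
            resp = params.adduct_scale[a] * np.exp(
                params.response_sigma * rng.standard_normal())
            emit.append((c, a, theo, resp))

    h_parents = [c for c, a, _, _ in emit if a == "H"]
    n_frag = int(round(params.fragment_fraction * len(h_parents)))
    frag_parents = list(rng.choice(h_parents, size=n_frag, replace=False)) if n_frag else []
    frag_mz = {}
    for c in frag_parents:
        theo = (masses[c] + ADDUCT_SHIFTS["H"]) * rng.uniform(0.45, 0.85)
        frag_mz[c] = max(theo, MZ_RANGE[0] + 1.0)

    peak_rows = [(t, c, a, "adduct") for c, a, t, _ in emit]
    peak_rows += [(frag_mz[c], c, "fragment", "fragment") for c in frag_parents]
    peak_rows.append((params.internal_standard_mz, "", "standard", "standard"))
    peak_map = pd.DataFrame(peak_rows, columns=["theo_mz", "compound_id", "adduct", "kind"])

    # reproducible chemical background: real spectra share a stable population
    # of low-abundance background ions across injections — the property that
    # makes a rank-statistic window divisor a usable intensity reference — so
    # background positions and base intensities are drawn once per cohort and
    # only jittered per sample like any other peak. Positions are kept clear
    # of the theoretical signal m/z values so background features never merge
    # with signal features during alignment.
    theo_all = np.sort(peak_map["theo_mz"].to_numpy())
    noise_mz = np.empty(params.n_noise_peaks)
    filled = 0
    while filled < params.n_noise_peaks:
        draw = rng.uniform(*MZ_RANGE, size=params.n_noise_peaks - filled)
        j = np.searchsorted(theo_all, draw)
        lo = np.abs(draw - theo_all[np.clip(j - 1, 0, theo_all.size - 1)])
        hi = np.abs(draw - theo_all[np.clip(j, 0, theo_all.size - 1)])
        ok = draw[np.minimum(lo, hi) > 0.02]
        noise_mz[filled:filled + ok.size] = ok
        filled += ok.size
    noise_mz.sort()
    noise_base = np.exp(params.noise_log_mean
                        + params.noise_log_sigma * rng.standard_normal(params.n_noise_peaks))

    cindex = {c: i for i, c in enumerate(cids)}

    # --- per-sample spectra ---------------------------------------------------
    spectra: list[PeakSpectrum] = []
    for s in range(n_s):
        mzs, ints = [], []
        h_int: dict[str, float] = {}
        for c, a, theo, resp in emit:
            inten = conc[cindex[c], s] * resp * np.exp(
                params.noise_sigma * rng.standard_normal())
            if a == "H":
                h_int[c] = inten
            if inten < params.detection_limit:
                continue
            mzs.append(theo + params.mz_jitter * rng.standard_normal())
            ints.append(inten)
        for c in frag_parents:
            inten = params.fragment_multiple * h_int[c]
            if inten < params.detection_limit:
                continue
            mzs.append(frag_mz[c] + params.mz_jitter * rng.standard_normal())
            ints.append(inten)
        noise_int = noise_base * np.exp(
            params.noise_sigma * rng.standard_normal(params.n_noise_peaks))
        keep = noise_int >= params.detection_limit
        mzs.extend(noise_mz[keep]
                   + params.mz_jitter * rng.standard_normal(int(keep.sum())))
        ints.extend(noise_int[keep])
        mzs.append(params.internal_standard_mz + params.mz_jitter * rng.standard_normal())
        ints.append(params.internal_standard_intensity
                    * np.exp(0.05 * rng.standard_normal()))

        mz_arr = np.asarray(mzs)
        if params.calibration_ppm:
            mz_arr = mz_arr * (1.0 + params.calibration_ppm * 1e-6 * rng.standard_normal())
        int_arr = np.asarray(ints)
        inside = (mz_arr >= MZ_RANGE[0]) & (mz_arr <= MZ_RANGE[1])
        mz_arr, int_arr = mz_arr[inside], int_arr[inside]
        order = np.argsort(mz_arr)
        mz_arr, int_arr = mz_arr[order], int_arr[order]
        # collapse (vanishingly rare) exact m/z collisions to keep m/z strictly increasing
        dup = np.flatnonzero(np.diff(mz_arr) <= 0)
        while dup.size:
            int_arr[dup] += int_arr[dup + 1]
            mz_arr = np.delete(mz_arr, dup + 1)
            int_arr = np.delete(int_arr, dup + 1)
            dup = np.flatnonzero(np.diff(mz_arr) <= 0)
        spectra.append(PeakSpectrum(sample_ids[s], mz_arr, int_arr))

    conc_df = pd.DataFrame(conc, index=cids, columns=sample_ids)
    truth = SyntheticTruth(peak_map, conc_df, manifest,
                           {c: c for c in frag_parents})
    return spectra, manifest, truth


def write_cohort(outdir: str | Path, spectra: list[PeakSpectrum],
                 manifest: pd.DataFrame, truth: SyntheticTruth | None = None) -> Path:
    """Write one TSV peak list per sample plus the manifest (and truth tables)."""
    from . import io as _io

    outdir = Path(outdir)
    specdir = outdir / "spectra"
    specdir.mkdir(parents=True, exist_ok=True)
    man = manifest.copy()
    man["path"] = [f"spectra/{s.sample_id}.tsv" for s in spectra]
    for s in spectra:
        _io.write_spectrum(s, specdir / f"{s.sample_id}.tsv")
    _io.write_manifest(man, outdir / "manifest.tsv")
    if truth is not None:
        truth.peak_map.to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)
        truth.concentrations.to_csv(outdir / "truth_concentrations.tsv", sep="\t",
                                    index_label="compound_id")
    return outdir / "manifest.tsv"
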