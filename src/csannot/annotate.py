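"""Context-support annotation: the core compound-identification algorithm.

For every mass feature holding at least one accurate-mass candidate, the
algorithm gathers *context support* (CS): the most strongly correlated other
features (|r| ranked, up to 30, excluding near-perfectly correlated
derivative peaks with |r| >= 0.85, and — because several ions of one compound
carry a single context vote — skipping features whose candidate compound set
duplicates an already selected member's). Each candidate compound is scored by how
many CS members have a candidate within N = 1..4 reactions of it in the
metabolic network (S1..S4, cumulative). The score is calibrated against 300
randomly drawn context sets of the same size: a generalized extreme value
distribution fitted to each N's null scores converts the observed count into
a support probability q_N = GEV-CDF(S_N) (the probability a random context
scores lower). Candidates with max_N q_N above 0.95 are provisionally
accepted; candidate sets of accepted features are then restricted to the
accepted compounds and the procedure repeats (six iterations, the context
becoming more competent each round). Finally Z = -Phi^{-1}(max_N q_N) is
computed, candidates with Z < -1.64 are kept, and xenobiotic compounds are
excluded (their biotransformation chemistry yields spurious context).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from sklearn.base import BaseEstimator

from ._gev import fit_gev, gev_cdf
from .candidates import CandidateSet, search_table
from .pathway import DistanceMatrix
from .preprocess import AlignedPeakTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "ContextSupport",
    "AnnotationResult",
    "correlation_matrix",
    "select_context",
    "score_candidate",
    "null_support",
    "run_annotation",
    "ContextAnnotator",
]

N_MAX = 4  # pathway-distance positions scored: N = 1..4


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations over jointly nonzero samples.

    ``r[i, j]`` is NaN when fewer than ``min_pairs`` samples are nonzero in
    both features (zeros are non-detections, not measurements, for the
    purpose of correlation), or when a feature is constant on the complete
    pairs.
    """

    feature_ids: list[str]
    r: np.ndarray
    n_pairs: np.ndarray
    row_ids: list[str] | None = None  # None -> square matrix, rows == columns

    def __post_init__(self):
        self._col_pos = {f: i for i, f in enumerate(self.feature_ids)}
        self._row_pos = self._col_pos if self.row_ids is None else \
            {f: i for i, f in enumerate(self.row_ids)}

    def index_of(self, feature_id: str) -> int:
        return self._col_pos[feature_id]

    def row_index_of(self, feature_id: str) -> int:
        return self._row_pos[feature_id]


@dataclass
class ContextSupport:
    feature_id: str
    members: list[tuple[str, float]]          # (feature_id, r), |r| descending
    derivative_ids: list[tuple[str, float]]   # features with |r| >= derivative threshold


@dataclass
class AnnotationResult:
    annotations: pd.DataFrame       # accepted, non-xenobiotic candidates
    diagnostics: pd.DataFrame       # every scored candidate incl. rejected / xenobiotic
    derivatives: pd.DataFrame       # feature_id, derivative_feature_id, r
    accepted_compounds: list[str]
    iteration_log: list[dict] = field(default_factory=list)


def correlation_matrix(table: AlignedPeakTable, min_pairs: int = 9,
                       rows: list[str] | None = None) -> CorrelationMatrix:
    """Pearson correlation between features using jointly nonzero samples only.

    Vectorized via masked cross-products: with zero as the fill value,
    products over the joint nonzero mask reduce to plain matrix products of
    the intensity matrix and its indicator. When ``rows`` names a feature
    subset, only the rectangular block rows x all-features is computed (the
    full matrix is quadratic in feature count and rarely needed whole).
    """
    X = np.asarray(table.intensities, dtype=float)
    M = (X > 0).astype(float)
    if rows is None:
        ridx = np.arange(X.shape[0])
    else:
        pos = {f: i for i, f in enumerate(table.feature_ids)}
        ridx = np.array([pos[f] for f in rows], dtype=int)
    Xr, Mr = X[ridx], M[ridx]
    n = Mr @ M.T
    sx = Xr @ M.T
    sy = Mr @ X.T
    sxx = (Xr * Xr) @ M.T
    syy = Mr @ (X * X).T
    sxy = Xr @ X.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        denom = np.sqrt(varx * vary)
        r = cov / denom
    eps = 1e-12
    bad = (n < min_pairs) | (varx <= eps * np.maximum(sxx * n, 1.0)) \
        | (vary <= eps * np.maximum(syy * n, 1.0))
    n_const = int((bad & (n >= min_pairs)).sum())
    if n_const:
        logger.debug("correlation: %d entries dropped for zero variance on complete pairs",
                     n_const)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    r[np.arange(ridx.size), ridx] = 1.0
    return CorrelationMatrix(list(table.feature_ids), r, n.astype(int),
                             row_ids=None if rows is None else list(rows))


def select_context(
    feature_id: str,
    corr: CorrelationMatrix,
    candidate_map: dict[str, CandidateSet],
    k: int = 30,
    derivative_r: float = 0.85,
    dedup: bool = True,
) -> ContextSupport:
    """Pick the tested feature's context support from the correlation structure.

    Other features are ranked by |r| (positive or negative, missing
    excluded). Those at |r| >= ``derivative_r`` are flagged as derivatives
    of the tested peak (fragment, adduct, or multi-ion) and excluded from
    the context; of the rest, the top ``k`` possessing at least one
    candidate compound become the CS members.

    With ``dedup`` (default) a feature whose candidate compound set is
    identical to an already selected member's is skipped: several ions of
    one compound — near-perfectly correlated with each other — would
    otherwise enter the context together and cast several copies of a
    single context vote, which a random same-size context cannot mimic and
    which therefore breaks the null calibration of the support scores.
    ``dedup=False`` gives the plain top-k cut.
    """
    row = corr.r[corr.row_index_of(feature_id)]
    absr = np.abs(row)
    valid = np.isfinite(row)
    valid[corr.index_of(feature_id)] = False
    idx = np.flatnonzero(valid)
    order = idx[np.lexsort((idx, -absr[idx]))]  # |r| desc, index asc on ties
    derivatives = [(corr.feature_ids[j], float(row[j]))
                   for j in order if absr[j] >= derivative_r]
    members = []
    seen_keys: set[frozenset] = set()
    for j in order:
        if absr[j] >= derivative_r:
            continue
        fid = corr.feature_ids[j]
        cset = candidate_map.get(fid, CandidateSet(fid))
        if len(cset) == 0:
            continue
        if dedup:
            key = frozenset(cset.compound_ids())
            if key in seen_keys:
                continue
            seen_keys.add(key)
        members.append((fid, float(row[j])))
        if len(members) == k:
            break
    return ContextSupport(feature_id, members, derivatives)


def score_candidate(
    compound_id: str,
    cs: ContextSupport,
    candidate_map: dict[str, CandidateSet],
    dmat: DistanceMatrix,
    count_mode: str = "cumulative",
) -> tuple[int, int, int, int]:
    """Count CS members whose nearest candidate lies within N reactions.

    For each CS member the minimum network distance from the tested
    candidate to *any* of that member's candidate compounds is taken; S_N is
    the number of members with minimum distance in [1, N] (cumulative mode)
    or == N (exact mode). Distance 0 — the member's candidates include the
    tested compound itself — is identity, i.e. evidence of a derivative ion
    rather than of pathway context, and counts toward no S (counting it
    would let a compound's own adduct and fragment peaks certify its
    annotation circularly). Members reachable only through the unreachable
    sentinel likewise contribute nothing.
    """
    ci = dmat.index_of(compound_id)
    drow = dmat.d[ci]
    mins = []
    for fid, _ in cs.members:
        idx = [dmat.index_of(c) for c in candidate_map[fid].compound_ids()]
        mins.append(drow[idx].min() if idx else np.inf)
    mins = np.asarray(mins) if mins else np.empty(0)
    if count_mode == "cumulative":
        return tuple(int(((mins >= 1) & (mins <= n)).sum()) for n in range(1, N_MAX + 1))
    return tuple(int((mins == n).sum()) for n in range(1, N_MAX + 1))


def null_support(
    observed: tuple[int, ...],
    null_scores: np.ndarray,
) -> tuple[list[float], list[tuple[float, float, float] | None]]:
    """Convert observed S_N into tail probabilities against the random-CS null.

    ``null_scores`` has shape (n_rand, N_MAX). A GEV is fitted by maximum
    likelihood to each N's replicate scores and q_N = GEV-CDF(S_N) — the
    probability a random context supports the candidate less than observed.
    Nulls with fewer than six distinct values (too sparse for a stable
    three-parameter continuous fit) fall back to the empirical rule
    q_N = fraction of null scores strictly below the observed one.
    """
    qs, fits = [], []
    for n in range(null_scores.shape[1]):
        col = null_scores[:, n]
        q, params = _tail_prob(float(observed[n]), col, {})
        qs.append(q)
        fits.append(params)
    return qs, fits


# minimum distinct null values for a 3-parameter continuous tail model to be
# meaningful; sparser nulls use the empirical rule
_MIN_DISTINCT_FOR_GEV = 6


def _tail_prob(obs: float, null_col: np.ndarray, cache: dict
               ) -> tuple[float, tuple[float, float, float] | None]:
    u, w = np.unique(null_col, return_counts=True)
    if u.size < _MIN_DISTINCT_FOR_GEV:
        return float((null_col < obs).mean()), None
    key = (u.tobytes(), w.tobytes())
    params = cache.get(key)
    if params is None:
        try:
            params = fit_gev(null_col)
        except Exception:  # pragma: no cover - safety net
            params = None
        cache[key] = params
    if params is None:
        return float((null_col < obs).mean()), None
    # evaluate midway below the observed integer score so the GEV path keeps
    # the same "random context scores strictly lower" semantics as the
    # empirical fallback (counts are discrete; cdf at obs would credit the
    # whole tie mass)
    q = gev_cdf(obs - 0.5, params)
    if not np.isfinite(q):
        return float((null_col < obs).mean()), None
    return min(max(q, 0.0), 1.0), params


def _dedup_null_draw(rng: np.random.Generator, n_rand: int, self_pos: int,
                     gid: np.ndarray, m: int) -> np.ndarray:
    """Random same-size contexts honoring the one-vote-per-candidate-set rule.

    The observed context is built by scanning features in |r| order and
    skipping any whose candidate compound set (group id in ``gid``) was
    already represented. Under the null the scan order is a uniform random
    permutation, so the selected features are: per group, the member with
    the smallest i.i.d. random key, restricted to the ``m`` groups whose
    kept key is smallest. Keys are drawn as integers with the feature index
    packed into the low bits, so one segmented minimum yields both the
    group's rank and its representative feature.
    """
    others = np.delete(np.arange(gid.size), self_pos)
    order = np.argsort(gid[others], kind="stable")
    others = others[order]
    gsorted = gid[others]
    starts = np.flatnonzero(np.r_[True, gsorted[1:] != gsorted[:-1]])
    m = min(m, starts.size)
    width = others.size
    keys = rng.integers(0, 1 << 42, size=(n_rand, width), dtype=np.int64)
    encoded = keys * width + np.arange(width, dtype=np.int64)
    gmin = np.minimum.reduceat(encoded, starts, axis=1)
    sel = np.argpartition(gmin, m - 1, axis=1)[:, :m]
    chosen = np.take_along_axis(gmin, sel, axis=1)
    return others[(chosen % width).astype(np.intp)]


# ---------------------------------------------------------------------------
# full iterative run
# ---------------------------------------------------------------------------

def run_annotation(
    table: AlignedPeakTable,
    candidate_map: dict[str, CandidateSet],
    dmat: DistanceMatrix,
    compounds: pd.DataFrame,
    iterations: int = 6,
    k: int = 30,
    derivative_r: float = 0.85,
    n_rand: int = 300,
    accept_q: float = 0.95,
    z_cut: float = -1.64,
    min_pairs: int = 9,
    count_mode: str = "cumulative",
    null_mode: str = "features",
    dedup_context: bool = True,
    seed: int = 0,
) -> AnnotationResult:
    """Iterative context-support annotation of an aligned feature table.

    Iteration 1 scores every candidate against the full candidate map; a
    candidate is provisionally accepted when max_N q_N > ``accept_q``.
    Before each following iteration the candidate sets of provisionally
    accepted features are restricted to their accepted compounds (rejected
    features keep full sets), context-support membership is recomputed from
    the refined map, and every candidate is re-scored. After the last
    iteration Z = -Phi^{-1}(max_N q_N) is computed; candidates with
    Z < ``z_cut`` that are not xenobiotics form the annotation output
    (xenobiotic hits stay in the diagnostics table).

    ``dedup_context`` applies the one-vote-per-candidate-set rule of
    :func:`select_context` both to the observed context and — via an
    equivalent skip-scan over uniformly permuted features — to the random
    contexts, keeping the calibration exact under the null. It only applies
    to ``null_mode='features'``; compound-universe nulls are unaffected.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if count_mode not in ("cumulative", "exact"):
        raise ValueError("count_mode must be 'cumulative' or 'exact'")
    if null_mode not in ("features", "compounds"):
        raise ValueError("null_mode must be 'features' or 'compounds'")

    rng = np.random.default_rng(seed)
    fids = list(table.feature_ids)
    mz_of = dict(zip(fids, table.mz))
    cindex = {c: i for i, c in enumerate(dmat.ids)}
    names = dict(zip(compounds["compound_id"], compounds["name"]))
    xeno = dict(zip(compounds["compound_id"], compounds["is_xenobiotic"].astype(bool)))

    pool = [f for f in fids if len(candidate_map.get(f, CandidateSet(f))) > 0]
    if not pool:
        logger.warning("annotation: no feature has any candidate")
        return _empty_result()
    # only rows for candidate-bearing features are needed; the full matrix is
    # quadratic in feature count
    corr = correlation_matrix(table, min_pairs=min_pairs, rows=pool)
    P = len(pool)
    n_comp = len(dmat.ids)

    # per-feature eligibility scan, computed once from the correlation
    # structure (refinement never changes r): candidate-bearing,
    # non-derivative pool features in |r|-descending order, plus the
    # derivative listing
    col_of_pool = np.array([corr.index_of(f) for f in pool])
    elig_of: list[np.ndarray] = []
    deriv_rows: list[dict] = []
    for p, f in enumerate(pool):
        row = corr.r[p]
        absr = np.abs(row)
        valid = np.isfinite(row)
        valid[col_of_pool[p]] = False
        didx = np.flatnonzero(valid & (absr >= derivative_r))
        didx = didx[np.lexsort((didx, -absr[didx]))]
        deriv_rows += [{"feature_id": f, "derivative_feature_id": corr.feature_ids[j],
                        "r": float(row[j])} for j in didx]
        sub = absr[col_of_pool]
        pidx = np.flatnonzero(valid[col_of_pool] & (sub < derivative_r))
        elig_of.append(pidx[np.lexsort((col_of_pool[pidx], -sub[pidx]))])

    # iteration state: per-feature unique candidate compound list
    full_compounds = {f: list(dict.fromkeys(candidate_map[f].compound_ids())) for f in pool}
    current = {f: list(v) for f, v in full_compounds.items()}

    gev_cache: dict = {}
    rep_cache: dict[tuple, np.ndarray] = {}
    iteration_log: list[dict] = []
    records: dict[tuple[str, str], dict] = {}

    for it in range(1, iterations + 1):
        flat = np.concatenate([[cindex[c] for c in current[f]] for f in pool])
        lens = np.array([len(current[f]) for f in pool])
        offsets = np.concatenate([[0], np.cumsum(lens)[:-1]])

        # context-support membership for this iteration's candidate map
        if dedup_context and null_mode == "features":
            gmap: dict[frozenset, int] = {}
            gid = np.empty(P, dtype=np.int64)
            for p, f in enumerate(pool):
                gid[p] = gmap.setdefault(frozenset(current[f]), len(gmap))
            members_of = []
            for p in range(P):
                seen: set[int] = set()
                mem: list[int] = []
                for q in elig_of[p]:
                    g = int(gid[q])
                    if g in seen:
                        continue
                    seen.add(g)
                    mem.append(q)
                    if len(mem) == k:
                        break
                members_of.append(np.asarray(mem, dtype=int))
        else:
            gid = None
            members_of = [elig_of[p][:k] for p in range(P)]

        # random context replicates; cached so a feature whose context and
        # candidate-set partition did not change between iterations keeps the
        # same draws rather than resampling
        replicates: dict[str, np.ndarray] = {}
        for p, f in enumerate(pool):
            m = members_of[p].size
            if m == 0:
                continue
            if null_mode == "compounds":
                ckey: tuple = ("c", f, m)
                if ckey not in rep_cache:
                    keys = rng.random((n_rand, n_comp))
                    rep_cache[ckey] = np.argpartition(keys, m - 1, axis=1)[:, :m]
            elif gid is None:
                ckey = ("f", f, m)
                if ckey not in rep_cache:
                    keys = rng.random((n_rand, P - 1))  # exclude the tested feature
                    draw = np.argpartition(keys, m - 1, axis=1)[:, :m]
                    rep_cache[ckey] = draw + (draw >= p)  # skip self
            else:
                ckey = ("d", f, m, gid.tobytes())
                if ckey not in rep_cache:
                    rep_cache[ckey] = _dedup_null_draw(rng, n_rand, p, gid, m)
            replicates[f] = rep_cache[ckey]

        records = {}
        n_prov = 0
        for p, f in enumerate(pool):
            member_pos = members_of[p]
            m = member_pos.size
            for comp in current[f]:
                drow = dmat.d[cindex[comp]]
                if null_mode == "compounds":
                    mind_members = np.array([
                        drow[[cindex[c] for c in current[pool[q]]]].min()
                        for q in member_pos]) if m else np.empty(0)
                    null_mind = drow[replicates[f]] if m else np.empty((n_rand, 0))
                else:
                    mind = np.minimum.reduceat(drow[flat], offsets) if flat.size else \
                        np.full(P, np.inf)
                    mind_members = mind[member_pos] if m else np.empty(0)
                    null_mind = mind[replicates[f]] if m else np.empty((n_rand, 0))

                if count_mode == "cumulative":
                    # distance 0 (identity) is derivative evidence, not
                    # context, so only 1 <= d <= N counts
                    s_obs = tuple(int(((mind_members >= 1) & (mind_members <= n)).sum())
                                  for n in range(1, N_MAX + 1))
                    s_null = np.stack([((null_mind >= 1) & (null_mind <= n)).sum(axis=1)
                                       for n in range(1, N_MAX + 1)], axis=1)
                else:
                    s_obs = tuple(int((mind_members == n).sum()) for n in range(1, N_MAX + 1))
                    s_null = np.stack([(null_mind == n).sum(axis=1)
                                       for n in range(1, N_MAX + 1)], axis=1)

                if m == 0:
                    qs = [0.0] * N_MAX
                else:
                    qs = [_tail_prob(float(s_obs[n]), s_null[:, n], gev_cache)[0]
                          for n in range(N_MAX)]
                maxq = max(qs)
                prov = maxq > accept_q
                n_prov += int(prov)
                records[(f, comp)] = {"S": s_obs, "q": qs, "maxq": maxq,
                                      "provisional": prov}

        iteration_log.append({"iteration": it, "n_provisional": n_prov,
                              "n_candidates": sum(lens)})

        if it < iterations:
            for f in pool:
                acc = [c for c in current[f] if records[(f, c)]["provisional"]]
                if acc:
                    current[f] = acc

    # final assembly ---------------------------------------------------------
    rows = []
    for f in pool:
        scored = {c: records[(f, c)] for c in current[f]}
        for cand in candidate_map[f].candidates:
            rec = scored.get(cand.compound_id)
            if rec is None:
                continue  # eliminated during refinement
            maxq = rec["maxq"]
            z = float(-ndtri(maxq)) if 0.0 < maxq < 1.0 else \
                (-np.inf if maxq >= 1.0 else np.inf)
            is_x = bool(xeno.get(cand.compound_id, False))
            accepted = bool(maxq > accept_q and z < z_cut and not is_x)
            rows.append({
                "feature_id": f, "consensus_mz": mz_of[f],
                "compound_id": cand.compound_id,
                "name": names.get(cand.compound_id, cand.compound_id),
                "adduct": cand.adduct, "mass_error": cand.mass_error,
                **{f"S{n + 1}": rec["S"][n] for n in range(N_MAX)},
                **{f"q{n + 1}": rec["q"][n] for n in range(N_MAX)},
                "Z": z, "accepted": accepted, "is_xenobiotic": is_x,
            })
    cols = ["feature_id", "consensus_mz", "compound_id", "name", "adduct", "mass_error",
            "S1", "S2", "S3", "S4", "q1", "q2", "q3", "q4", "Z", "accepted",
            "is_xenobiotic"]
    diagnostics = pd.DataFrame(rows, columns=cols)
    annotations = diagnostics[diagnostics["accepted"]].reset_index(drop=True)
    if annotations.empty:
        logger.warning("annotation: no feature annotated after %d iterations", iterations)
    derivatives = pd.DataFrame(deriv_rows,
                               columns=["feature_id", "derivative_feature_id", "r"])
    accepted_compounds = sorted(annotations["compound_id"].unique())
    return AnnotationResult(annotations, diagnostics, derivatives,
                            accepted_compounds, iteration_log)


def _empty_result() -> AnnotationResult:
    cols = ["feature_id", "consensus_mz", "compound_id", "name", "adduct", "mass_error",
            "S1", "S2", "S3", "S4", "q1", "q2", "q3", "q4", "Z", "accepted",
            "is_xenobiotic"]
    empty = pd.DataFrame(columns=cols)
    return AnnotationResult(empty.copy(), empty.copy(),
                            pd.DataFrame(columns=["feature_id", "derivative_feature_id",
                                                  "r"]), [], [])


class ContextAnnotator(BaseEstimator):
    """Estimator wrapper around candidate search plus context-support annotation.

    Parameters mirror :func:`run_annotation`; ``fit`` takes an
    :class:`AlignedPeakTable` and exposes the results as fitted attributes
    (``annotations_``, ``diagnostics_``, ``derivatives_``,
    ``accepted_compounds_``).
    """

    def __init__(self, compounds=None, dmat=None, tolerance: float = 0.005,
                 k: int = 30, derivative_r: float = 0.85, n_rand: int = 300,
                 iterations: int = 6, accept_q: float = 0.95, z_cut: float = -1.64,
                 min_pairs: int = 9, count_mode: str = "cumulative",
                 null_mode: str = "features", dedup_context: bool = True,
                 random_state: int = 0):
        self.compounds = compounds
        self.dmat = dmat
        self.tolerance = tolerance
        self.k = k
        self.derivative_r = derivative_r
        self.n_rand = n_rand
        self.iterations = iterations
        self.accept_q = accept_q
        self.z_cut = z_cut
        self.min_pairs = min_pairs
        self.count_mode = count_mode
        self.null_mode = null_mode
        self.dedup_context = dedup_context
        self.random_state = random_state

    def fit(self, X: AlignedPeakTable, y=None):
        if self.compounds is None or self.dmat is None:
            raise ValueError("ContextAnnotator needs a compound table and distance matrix")
        self.candidate_map_ = search_table(X, self.compounds, self.tolerance)
        res = run_annotation(
            X, self.candidate_map_, self.dmat, self.compounds,
            iterations=self.iterations, k=self.k, derivative_r=self.derivative_r,
            n_rand=self.n_rand, accept_q=self.accept_q, z_cut=self.z_cut,
            min_pairs=self.min_pairs, count_mode=self.count_mode,
            null_mode=self.null_mode, dedup_context=self.dedup_context,
            seed=self.random_state)
        self.result_ = res
        self.annotations_ = res.annotations
        self.diagnostics_ = res.diagnostics
        self.derivatives_ = res.derivatives
        self.accepted_compounds_ = res.accepted_compounds
        return self
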