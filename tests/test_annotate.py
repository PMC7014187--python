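import numpy as np
import pandas as pd
import pytest

from csannot.annotate import (
    ContextAnnotator,
    ContextSupport,
    CorrelationMatrix,
    _dedup_null_draw,
    _tail_prob,
    correlation_matrix,
    null_support,
    run_annotation,
    score_candidate,
    select_context,
)
from csannot.candidates import Candidate, CandidateSet, search_table
from csannot.pathway import DistanceMatrix, build_network, distance_matrix
from csannot.preprocess import AlignedPeakTable, align, filter_features, normalize
from csannot.simulate import (
    CohortDesign,
    GroupSpec,
    SpectralParams,
    generate_network,
    simulate_cohort,
)


def _table(X):
    X = np.asarray(X, dtype=float)
    fids = [f"F{i:03d}" for i in range(X.shape[0])]
    return AlignedPeakTable(fids, np.linspace(100, 200, X.shape[0]), X,
                            [f"S{j}" for j in range(X.shape[1])])


# --- correlation ----------------------------------------------------------


def test_correlation_matches_pairwise_oracle():
    rng = np.random.default_rng(0)
    X = rng.lognormal(size=(6, 15))
    X[rng.random(X.shape) < 0.3] = 0.0
    corr = correlation_matrix(_table(X), min_pairs=3)
    for i in range(6):
        for j in range(6):
            got = corr.r[i, j]
            if i == j:
                assert got == 1.0
                continue
            mask = (X[i] > 0) & (X[j] > 0)
            if mask.sum() < 3:
                assert np.isnan(got)
            else:
                exp = np.corrcoef(X[i, mask], X[j, mask])[0, 1]
                assert got == pytest.approx(exp, abs=1e-10)


def test_correlation_min_pairs_boundary():
    rng = np.random.default_rng(1)
    X = np.zeros((2, 20))
    X[0, :12] = rng.lognormal(size=12)   # nonzero in samples 0..11
    X[1, 4:] = rng.lognormal(size=16)    # nonzero in samples 4..19 -> 8 shared
    corr = correlation_matrix(_table(X), min_pairs=9)
    assert np.isnan(corr.r[0, 1])
    assert corr.n_pairs[0, 1] == 8
    X[1, :4] = rng.lognormal(size=4)     # now 12 shared
    corr = correlation_matrix(_table(X), min_pairs=9)
    assert np.isfinite(corr.r[0, 1])


def test_correlation_constant_on_complete_pairs_is_nan():
    X = np.vstack([np.full(12, 5.0), np.arange(1.0, 13.0)])
    corr = correlation_matrix(_table(X), min_pairs=3)
    assert np.isnan(corr.r[0, 1])


def test_rectangular_rows_match_square_matrix():
    rng = np.random.default_rng(2)
    X = rng.lognormal(size=(8, 20))
    X[rng.random(X.shape) < 0.2] = 0.0
    table = _table(X)
    full = correlation_matrix(table, min_pairs=5)
    sub = correlation_matrix(table, min_pairs=5, rows=["F002", "F005"])
    np.testing.assert_allclose(sub.r[0], full.r[2], equal_nan=True)
    np.testing.assert_allclose(sub.r[1], full.r[5], equal_nan=True)
    assert sub.row_index_of("F005") == 1
    assert sub.index_of("F005") == 5


# --- context selection ----------------------------------------------------


def _toy_corr_and_candidates():
    fids = ["A", "B", "C", "D", "E", "F", "G"]
    r = np.full((7, 7), 0.1)
    np.fill_diagonal(r, 1.0)
    # row A: B is a derivative, C..F candidate-bearing context, G missing r
    r[0] = [1.0, 0.99, 0.80, -0.70, 0.60, 0.50, np.nan]
    cands = {
        "C": CandidateSet("C", [Candidate("X1", "H", 0.0)]),
        "D": CandidateSet("D", [Candidate("X2", "H", 0.0)]),
        "E": CandidateSet("E", [Candidate("X1", "Na", 0.001)]),  # same compound as C
        "F": CandidateSet("F", [Candidate("X3", "H", 0.0)]),
        "A": CandidateSet("A", [Candidate("X9", "H", 0.0)]),
        "B": CandidateSet("B", [Candidate("X9", "Na", 0.0)]),
    }
    return CorrelationMatrix(fids, r, np.full((7, 7), 20)), cands


def test_select_context_derivative_and_ranking():
    corr, cands = _toy_corr_and_candidates()
    cs = select_context("A", corr, cands, k=10, dedup=False)
    assert cs.derivative_ids == [("B", 0.99)]
    assert [m for m, _ in cs.members] == ["C", "D", "E", "F"]
    assert cs.members[1][1] == -0.70  # sign of r preserved


def test_select_context_dedup_skips_duplicate_candidate_sets():
    corr, cands = _toy_corr_and_candidates()
    cs = select_context("A", corr, cands, k=10)
    # E carries the same single candidate compound as C and is skipped
    assert [m for m, _ in cs.members] == ["C", "D", "F"]


def test_select_context_k_cut():
    corr, cands = _toy_corr_and_candidates()
    cs = select_context("A", corr, cands, k=2, dedup=False)
    assert [m for m, _ in cs.members] == ["C", "D"]


def test_select_context_ignores_candidate_free_features():
    corr, cands = _toy_corr_and_candidates()
    del cands["D"]
    cs = select_context("A", corr, cands, k=10)
    assert "D" not in [m for m, _ in cs.members]


# --- scoring --------------------------------------------------------------


def _chain_dmat():
    ids = ("A", "B", "C", "D", "E", "U")
    d = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0)))
    d = np.pad(d, ((0, 1), (0, 1)), constant_values=np.inf)
    d[5, 5] = 0.0
    return DistanceMatrix(ids, d)


def test_score_candidate_cumulative_and_exact():
    dmat = _chain_dmat()
    members = [("f1", 0.8), ("f2", 0.7), ("f3", 0.6), ("f4", 0.5), ("f0", 0.4)]
    cmap = {
        "f1": CandidateSet("f1", [Candidate("B", "H", 0.0)]),
        "f2": CandidateSet("f2", [Candidate("C", "H", 0.0)]),
        "f3": CandidateSet("f3", [Candidate("D", "H", 0.0)]),
        "f4": CandidateSet("f4", [Candidate("E", "H", 0.0)]),
        "f0": CandidateSet("f0", [Candidate("A", "H", 0.0)]),  # distance 0
    }
    cs = ContextSupport("t", members, [])
    assert score_candidate("A", cs, cmap, dmat) == (1, 2, 3, 4)
    assert score_candidate("A", cs, cmap, dmat, count_mode="exact") == (1, 1, 1, 1)


def test_score_candidate_distance_zero_and_unreachable_count_nothing():
    dmat = _chain_dmat()
    cmap = {
        "f0": CandidateSet("f0", [Candidate("A", "H", 0.0)]),
        "fu": CandidateSet("fu", [Candidate("U", "H", 0.0)]),
    }
    cs = ContextSupport("t", [("f0", 0.9), ("fu", 0.8)], [])
    assert score_candidate("A", cs, cmap, dmat) == (0, 0, 0, 0)


def test_score_candidate_uses_member_minimum_distance():
    dmat = _chain_dmat()
    cmap = {"f1": CandidateSet("f1", [Candidate("E", "H", 0.0),
                                      Candidate("B", "H", 0.0)])}
    cs = ContextSupport("t", [("f1", 0.9)], [])
    assert score_candidate("A", cs, cmap, dmat) == (1, 1, 1, 1)


# --- calibration ----------------------------------------------------------


def test_null_support_monotone_in_observed_score():
    rng = np.random.default_rng(3)
    nulls = rng.poisson(8.0, size=(300, 4)).astype(float)
    q_lo, _ = null_support((2, 2, 2, 2), nulls)
    q_mid, _ = null_support((8, 8, 8, 8), nulls)
    q_hi, fits = null_support((25, 25, 25, 25), nulls)
    for lo, mid, hi in zip(q_lo, q_mid, q_hi):
        assert lo < mid < hi
    assert all(f is not None for f in fits)  # rich nulls take the GEV path
    assert all(0.0 <= q <= 1.0 for q in q_lo + q_mid + q_hi)


def test_tail_prob_sparse_null_uses_empirical_rule():
    null = np.array([0.0] * 250 + [1.0] * 50)
    q, params = _tail_prob(1.0, null, {})
    assert params is None
    assert q == pytest.approx(250 / 300)


def test_dedup_null_draw_respects_groups_and_self():
    rng = np.random.default_rng(4)
    gid = np.array([0, 0, 1, 2, 2, 3, 4, 4, 4, 5])
    draws = _dedup_null_draw(rng, 200, self_pos=3, gid=gid, m=4)
    assert draws.shape == (200, 4)
    assert not (draws == 3).any()
    for row in draws:
        groups = gid[row]
        assert len(set(groups.tolist())) == len(groups)
    # every non-self feature should appear somewhere across 200 draws
    assert set(np.unique(draws)) <= set(range(10)) - {3}


def test_dedup_null_draw_is_deterministic():
    gid = np.arange(12) // 2
    a = _dedup_null_draw(np.random.default_rng(7), 50, 0, gid, 3)
    b = _dedup_null_draw(np.random.default_rng(7), 50, 0, gid, 3)
    assert np.array_equal(a, b)


# --- full run -------------------------------------------------------------


def _small_cohort(seed=0, rho=0.6):
    compounds, reactions, sets, nt = generate_network(30, 3, seed=seed)
    design = CohortDesign((GroupSpec("a", 10, 5, 5), GroupSpec("b", 10, 5, 5)), ())
    params = SpectralParams(rho=rho, n_noise_peaks=400)
    spectra, manifest, truth = simulate_cohort(compounds, sets, design, params,
                                               seed=seed, network_truth=nt)
    normed = [normalize(s, 50.0, 20) for s in spectra]
    table = filter_features(align(normed, 0.005).with_metadata(manifest), 9)
    cands = search_table(table, compounds, 0.005)
    dmat = distance_matrix(build_network(compounds, reactions),
                           order=compounds["compound_id"].tolist())
    return table, cands, dmat, compounds


def test_run_annotation_deterministic_and_well_formed():
    table, cands, dmat, compounds = _small_cohort()
    kw = dict(iterations=2, n_rand=50, seed=5)
    r1 = run_annotation(table, cands, dmat, compounds, **kw)
    r2 = run_annotation(table, cands, dmat, compounds, **kw)
    pd.testing.assert_frame_equal(r1.diagnostics, r2.diagnostics)
    pd.testing.assert_frame_equal(r1.annotations, r2.annotations)
    d = r1.diagnostics
    assert len(d) > 0
    assert [e["iteration"] for e in r1.iteration_log] == [1, 2]
    qmax = d[["q1", "q2", "q3", "q4"]].max(axis=1)
    finite = d["Z"].replace([np.inf, -np.inf], np.nan).notna()
    # Z is the normal quantile of max q
    from scipy.special import ndtri
    np.testing.assert_allclose(d.loc[finite, "Z"], -ndtri(qmax[finite]), atol=1e-12)


def test_run_annotation_excludes_xenobiotics_from_annotations():
    table, cands, dmat, compounds = _small_cohort()
    compounds = compounds.copy()
    compounds["is_xenobiotic"] = True  # force: nothing may be annotated
    res = run_annotation(table, cands, dmat, compounds, iterations=1, n_rand=50, seed=5)
    assert res.annotations.empty
    assert res.diagnostics["is_xenobiotic"].all()


def test_run_annotation_argument_validation():
    table, cands, dmat, compounds = _small_cohort()
    with pytest.raises(ValueError):
        run_annotation(table, cands, dmat, compounds, iterations=0)
    with pytest.raises(ValueError):
        run_annotation(table, cands, dmat, compounds, count_mode="bogus")
    with pytest.raises(ValueError):
        run_annotation(table, cands, dmat, compounds, null_mode="bogus")


def test_run_annotation_empty_candidate_map():
    table, cands, dmat, compounds = _small_cohort()
    empty = {f: CandidateSet(f) for f in table.feature_ids}
    res = run_annotation(table, empty, dmat, compounds, iterations=1, n_rand=20)
    assert res.annotations.empty and res.diagnostics.empty


def test_context_annotator_matches_function_pipeline():
    table, cands, dmat, compounds = _small_cohort()
    est = ContextAnnotator(compounds=compounds, dmat=dmat, iterations=2,
                           n_rand=50, random_state=5).fit(table)
    ref = run_annotation(table, cands, dmat, compounds, iterations=2,
                         n_rand=50, seed=5)
    pd.testing.assert_frame_equal(est.diagnostics_, ref.diagnostics)
    assert est.accepted_compounds_ == ref.accepted_compounds


def test_context_annotator_requires_reference_data():
    table, *_ = _small_cohort()
    with pytest.raises(ValueError):
        ContextAnnotator().fit(table)
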