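import numpy as np
import pandas as pd
import pytest

from csannot.candidates import ADDUCT_SHIFTS
from csannot.pathway import build_network, distance_matrix
from csannot.preprocess import align
from csannot.simulate import (
    CohortDesign,
    GroupSpec,
    SetEffect,
    SpectralParams,
    generate_network,
    simulate_cohort,
    table3_design,
)

SMALL = SpectralParams(n_noise_peaks=100)


def _design(n=6):
    half = n // 2
    return CohortDesign((GroupSpec("a", n, half, n - half),
                         GroupSpec("b", n, half, n - half)), ())


# --- network generation ---------------------------------------------------


def test_generate_network_is_deterministic():
    a = generate_network(40, 4, seed=3, decoy_fraction=0.2)
    b = generate_network(40, 4, seed=3, decoy_fraction=0.2)
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[1], b[1])
    assert a[2] == b[2] and a[3].decoy_ids == b[3].decoy_ids


def test_pathways_are_chains_with_expected_diameter():
    compounds, reactions, sets, _ = generate_network(10, 2, seed=0,
                                                     cross_link_prob=0.0)
    dmat = distance_matrix(build_network(compounds, reactions),
                           order=compounds["compound_id"].tolist())
    for members in sets.values():
        assert len(members) == 5
        assert dmat.between(members[0], members[-1]) == 4
    # no cross-links -> pathways are disconnected components
    m1, m2 = sets["PW1"], sets["PW2"]
    assert np.isinf(dmat.between(m1[0], m2[0]))


def test_decoys_collide_with_foreign_pathway_adducts():
    compounds, _, _, nt = generate_network(60, 6, seed=1, decoy_fraction=0.3)
    assert len(nt.decoy_ids) == 18
    masses = dict(zip(compounds["compound_id"], compounds["monoisotopic_mass"]))
    for decoy, (target, t_ad, d_ad) in nt.decoy_target.items():
        dist = abs((masses[decoy] + ADDUCT_SHIFTS[d_ad])
                   - (masses[target] + ADDUCT_SHIFTS[t_ad]))
        assert dist <= 0.005
        assert nt.pathway_of[decoy] != nt.pathway_of[target]


def test_non_decoy_adduct_mz_values_are_well_separated():
    compounds, _, _, nt = generate_network(50, 5, seed=2)
    ions = sorted(m + s for m in compounds["monoisotopic_mass"]
                  for s in ADDUCT_SHIFTS.values())
    assert np.diff(ions).min() > 0.02


def test_xenobiotic_fraction():
    compounds, _, _, _ = generate_network(100, 10, seed=0, xenobiotic_fraction=0.05)
    assert int(compounds["is_xenobiotic"].sum()) == 5


def test_generate_network_validation():
    with pytest.raises(ValueError):
        generate_network(10, 6, seed=0)
    with pytest.raises(ValueError):
        generate_network(20, 2, seed=0, decoy_fraction=1.0)


# --- cohort design --------------------------------------------------------


def test_table3_design_shape():
    design = table3_design()
    assert design.n_subjects == 100
    assert [g.label for g in design.groups] == \
        ["normal", "overweight", "obesity1", "obesity2", "obesity3"]
    assert all(g.n_subjects == 20 and g.n_male == 10 and g.n_female == 10
               for g in design.groups)
    assert design.affected == ()
    eff = table3_design(affected_set="PW03").affected
    assert eff[0].set_id == "PW03" and eff[0].multiplier == 0.5
    assert eff[0].groups == ("overweight", "obesity1", "obesity2", "obesity3")


def test_simulate_cohort_deterministic_and_manifest():
    compounds, _, sets, _ = generate_network(20, 2, seed=0)
    s1, m1, _ = simulate_cohort(compounds, sets, _design(), SMALL, seed=4)
    s2, m2, _ = simulate_cohort(compounds, sets, _design(), SMALL, seed=4)
    pd.testing.assert_frame_equal(m1, m2)
    assert len(s1) == 12
    for a, b in zip(s1, s2):
        assert np.array_equal(a.mz, b.mz) and np.array_equal(a.intensity, b.intensity)
    assert m1["group"].value_counts().to_dict() == {"a": 6, "b": 6}
    assert (m1["sex"] == "M").sum() == 6


def test_effect_multiplier_halves_affected_concentrations_exactly():
    compounds, _, sets, _ = generate_network(20, 2, seed=0)
    base = CohortDesign(_design().groups, ())
    hit = CohortDesign(_design().groups, (SetEffect("PW1", 0.5, ("b",)),))
    _, _, t0 = simulate_cohort(compounds, sets, base, SMALL, seed=4)
    _, _, t1 = simulate_cohort(compounds, sets, hit, SMALL, seed=4)
    case = t0.manifest.loc[t0.manifest["group"] == "b", "sample_id"]
    ctrl = t0.manifest.loc[t0.manifest["group"] == "a", "sample_id"]
    affected = sets["PW1"]
    others = sets["PW2"]
    np.testing.assert_allclose(t1.concentrations.loc[affected, case],
                               0.5 * t0.concentrations.loc[affected, case])
    np.testing.assert_allclose(t1.concentrations.loc[affected, ctrl],
                               t0.concentrations.loc[affected, ctrl])
    np.testing.assert_allclose(t1.concentrations.loc[others],
                               t0.concentrations.loc[others])


def test_rho_controls_within_pathway_correlation():
    compounds, _, sets, _ = generate_network(20, 2, seed=1)
    design = _design(20)
    params_hi = SpectralParams(rho=0.8, n_noise_peaks=0)
    _, _, truth = simulate_cohort(compounds, sets, design, params_hi, seed=7)
    logc = np.log(truth.concentrations.to_numpy())
    cid = truth.concentrations.index.tolist()
    pw = {c: ("PW1" if c in sets["PW1"] else "PW2") for c in cid}
    cc = np.corrcoef(logc)
    within, across = [], []
    for i in range(len(cid)):
        for j in range(i + 1, len(cid)):
            (within if pw[cid[i]] == pw[cid[j]] else across).append(cc[i, j])
    assert np.mean(within) > 0.5
    assert abs(np.mean(across)) < 0.3


def test_fragments_track_parent_intensity_in_raw_spectra():
    compounds, _, sets, _ = generate_network(30, 3, seed=2)
    params = SpectralParams(n_noise_peaks=100, fragment_fraction=0.3)
    spectra, manifest, truth = simulate_cohort(compounds, sets, _design(10),
                                               params, seed=5)
    table = align(spectra, 0.005).with_metadata(manifest)
    pairs = truth.derivative_pairs(table)
    assert pairs, "expected at least one parent/fragment pair"
    fpos = {f: i for i, f in enumerate(table.feature_ids)}
    X = table.intensities
    for parent, frag in pairs:
        a, b = X[fpos[parent]], X[fpos[frag]]
        both = (a > 0) & (b > 0)
        if both.sum() < 3:
            continue
        # fragment = 0.5 x parent H+ intensity before detection/jitter
        assert np.corrcoef(a[both], b[both])[0, 1] > 0.99


def test_background_positions_recur_across_samples():
    compounds, _, sets, _ = generate_network(20, 2, seed=3)
    spectra, _, truth = simulate_cohort(compounds, sets, _design(), SMALL, seed=6)
    lab = truth.match_features(align(spectra, 0.005))
    noise_feats = lab["kind"] == "noise"
    table = align(spectra, 0.005)
    counts = table.nonzero_counts()[noise_feats.to_numpy()]
    # the background is a stable ion population, not iid clutter: most noise
    # features are seen in nearly every injection
    assert np.median(counts) >= 10


def test_match_features_labels_standard_and_noise():
    compounds, _, sets, _ = generate_network(20, 2, seed=3)
    spectra, _, truth = simulate_cohort(compounds, sets, _design(), SMALL, seed=6)
    lab = truth.match_features(align(spectra, 0.005))
    near_std = lab.loc[(lab["mz"] - 423.169).abs() < 0.003, "kind"]
    assert (near_std == "standard").any()
    assert (lab["kind"] == "noise").sum() > 50
    assert set(lab["kind"]) <= {"adduct", "fragment", "standard", "noise"}


def test_all_spectra_respect_detection_limit_and_ordering():
    compounds, _, sets, _ = generate_network(20, 2, seed=3)
    spectra, _, _ = simulate_cohort(compounds, sets, _design(), SMALL, seed=6)
    for s in spectra:
        assert np.all(np.diff(s.mz) > 0)
        assert s.intensity.min() >= SMALL.detection_limit
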