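"""Triad distance series, histograms, catalytic-atom RMSD and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from rigidsite import synthetic_data as sd
from rigidsite.active_site import (
    HIS_ASP_PAIR,
    SER_HIS_PAIR,
    PairSpec,
    catalytic_rmsd_series,
    compare_static_structures,
    distance_histogram,
    distance_series,
    summarize,
)
from rigidsite.flexibility import kabsch_superpose
from rigidsite.structure_io import (
    CatalyticAtomSet,
    Trajectory,
    catalytic_atom_set,
    select_atoms,
)


def _triad_traj(n_frames, seed=0, sh=(6.8, 1.1), hd=(2.9, 0.1)):
    ref = sd.generate_toy_protein(10, seed=1)
    spec = sd.TriadDistanceSpec(sh[0], sh[1], hd[0], hd[1],
                                n_frames=n_frames, seed=seed)
    return ref, sd.generate_triad_trajectory(ref, spec)


def test_constant_distance_series(toy_protein, toy_catalytic_set):
    """SDs of zero pin every frame at exactly the specified distances."""
    spec = sd.TriadDistanceSpec(2.7, 0.0, 3.1, 0.0, n_frames=7, seed=0)
    traj = sd.generate_triad_trajectory(toy_protein, spec)
    d = distance_series(traj, toy_catalytic_set, SER_HIS_PAIR)
    np.testing.assert_allclose(d, 2.7, atol=1e-9)
    d2 = distance_series(traj, toy_catalytic_set, HIS_ASP_PAIR)
    np.testing.assert_allclose(d2, 3.1, atol=1e-9)


def test_min_policy_picks_nearer_equivalent_atom():
    """OD1 at 3.4 A and OD2 at 3.0 A from the His nitrogen: the min
    policy reports 3.0."""
    coords = np.zeros((7, 3))
    coords[0] = [0, 0, 0]        # ND1
    coords[1] = [3.4, 0, 0]      # OD1
    coords[2] = [0, 3.0, 0]      # OD2
    coords[3] = [0, 0, 5.0]      # OG
    coords[4] = [1, 1, 1]        # NE2
    coords[5] = [8, 0, 0]        # N (oxy1)
    coords[6] = [0, 8, 0]        # N (oxy2)
    names = ["ND1", "OD1", "OD2", "OG", "NE2", "N", "N"]
    from rigidsite.structure_io import structure_from_arrays
    s = structure_from_arrays(coords, names,
                              ["HIS", "ASP", "ASP", "SER", "HIS",
                               "ILE", "MET"],
                              [5, 4, 4, 3, 5, 1, 2])
    catset = CatalyticAtomSet({"HIS_ND1": 0, "ASP_OD1": 1, "ASP_OD2": 2,
                               "SER_OG": 3, "HIS_NE2": 4,
                               "OXY_N1": 5, "OXY_N2": 6})
    traj = Trajectory(s, s.coords[None].astype(float), np.array([0.0]))
    assert distance_series(traj, catset, HIS_ASP_PAIR)[0] == pytest.approx(3.0)
    fixed = PairSpec(("HIS_ND1",), ("ASP_OD1",), "fixed")
    assert distance_series(traj, catset, fixed)[0] == pytest.approx(3.4)


def test_distance_series_matches_direct_recompute(toy_catalytic_set):
    ref, traj = _triad_traj(1000, seed=3)
    d = distance_series(traj, toy_catalytic_set, SER_HIS_PAIR)
    og, ne2 = toy_catalytic_set["SER_OG"], toy_catalytic_set["HIS_NE2"]
    for k in range(traj.n_frames):
        brute = np.sqrt(((traj.coords[k, og] - traj.coords[k, ne2]) ** 2)
                        .sum())
        assert abs(d[k] - brute) < 1e-12


def test_distances_invariant_under_rigid_transform(toy_catalytic_set, rng):
    ref, traj = _triad_traj(20, seed=4)
    d = distance_series(traj, toy_catalytic_set, SER_HIS_PAIR)
    rot = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
    moved = Trajectory(traj.topology,
                       traj.coords @ rot.T + np.array([10.0, -5.0, 2.0]),
                       traj.times_ps)
    d2 = distance_series(moved, toy_catalytic_set, SER_HIS_PAIR)
    np.testing.assert_allclose(d, d2, atol=1e-9)


def test_histogram_constant_series_single_bin():
    hist = distance_histogram(np.full(100, 2.7), bin_width=0.1)
    assert hist.frequencies.sum() == 100
    assert (hist.frequencies > 0).sum() == 1


@settings(derandomize=True, deadline=None, max_examples=30)
@given(st.lists(st.floats(0.5, 20.0), min_size=1, max_size=200),
       st.sampled_from([0.1, 0.25, 0.5]))
def test_histogram_conserves_counts_and_matches_counting_oracle(values, bw):
    series = np.array(values)
    hist = distance_histogram(series, bin_width=bw)
    assert hist.frequencies.sum() == series.size == hist.n_total
    edges = hist.bin_edges
    for i, count in enumerate(hist.frequencies):
        oracle = np.sum((series >= edges[i] - 1e-12)
                        & (series < edges[i + 1] - 1e-12))
        assert count == oracle


def test_histogram_rejects_empty_and_bad_width():
    with pytest.raises(ValueError):
        distance_histogram(np.array([]), 0.1)
    with pytest.raises(ValueError):
        distance_histogram(np.array([1.0]), -0.1)


def test_catalytic_rmsd_zero_against_itself(toy_protein, toy_catalytic_set):
    traj = Trajectory(toy_protein, toy_protein.coords[None].astype(float),
                      np.array([0.0]))
    series = catalytic_rmsd_series(traj, toy_protein, toy_catalytic_set)
    np.testing.assert_allclose(series, 0.0, atol=1e-9)


def test_catalytic_rmsd_self_mode_removes_rigid_motion(toy_protein,
                                                       toy_catalytic_set,
                                                       rng):
    frames = []
    base = toy_protein.coords.astype(float)
    for k in range(5):
        rot = Rotation.random(
            random_state=np.random.RandomState(k)).as_matrix()
        frames.append(base @ rot.T + rng.normal(size=3) * 5)
    traj = Trajectory(toy_protein, np.stack(frames), np.arange(5.0))
    series = catalytic_rmsd_series(traj, toy_protein, toy_catalytic_set,
                                   fit_mode="self")
    np.testing.assert_allclose(series, 0.0, atol=1e-7)


def test_catalytic_rmsd_equals_per_frame_kabsch_oracle(toy_protein,
                                                       toy_catalytic_set):
    ref, traj = _triad_traj(50, seed=6)
    series = catalytic_rmsd_series(traj, toy_protein, toy_catalytic_set)
    cat = toy_catalytic_set.as_array()
    ref_xyz = toy_protein.coords.astype(float)[cat]
    for k in range(traj.n_frames):
        oracle = kabsch_superpose(traj.coords[k, cat], ref_xyz).rmsd
        assert abs(series[k] - oracle) < 1e-9


def test_self_fit_rmsd_never_exceeds_global_fit(toy_protein,
                                                toy_catalytic_set):
    """Fitting on the measured atoms themselves cannot give a larger
    RMSD than fitting on the whole backbone."""
    ref, traj = _triad_traj(30, seed=8)
    ca = select_atoms(traj, atom_names="CA")
    self_series = catalytic_rmsd_series(traj, toy_protein, toy_catalytic_set,
                                        fit_mode="self")
    global_series = catalytic_rmsd_series(traj, toy_protein,
                                          toy_catalytic_set,
                                          fit_mode="global",
                                          fit_selection=ca)
    assert np.all(self_series <= global_series + 1e-9)


def test_summarize_trivial_and_two_pass_oracle(rng):
    s = summarize(np.array([2.7, 2.7, 2.7]))
    assert s.mean == pytest.approx(2.7)
    assert s.sd == pytest.approx(0.0, abs=1e-12)
    assert s.n == 3
    data = rng.normal(5.0, 2.0, size=1000)
    s = summarize(data)
    mean = sum(data) / len(data)
    var = sum((x - mean) ** 2 for x in data) / len(data)
    assert abs(s.mean - mean) < 1e-12
    assert abs(s.sd - np.sqrt(var)) < 1e-12
    with pytest.raises(ValueError):
        summarize(np.array([]))


@pytest.mark.parametrize("mean,sdev", [(6.8, 1.1), (4.7, 0.6),
                                       (2.9, 0.1), (3.0, 0.2)])
def test_generated_triad_statistics_recover_within_sampling_error(mean, sdev):
    """Means/SDs of generated Ser-His distances agree with the generating
    Gaussian within 3 standard errors, for all four studied parameter
    pairs (wild type and 6B, both triad hydrogen bonds)."""
    n = 20_000
    ref, traj = _triad_traj(n, seed=13, sh=(mean, sdev), hd=(3.0, 0.1))
    catset = catalytic_atom_set(traj, sd.TOY_RESIDUE_MAP)
    s = summarize(distance_series(traj, catset, SER_HIS_PAIR))
    se_mean = sdev / np.sqrt(n)
    se_sd = sdev / np.sqrt(2 * n)
    assert abs(s.mean - mean) < 3 * se_mean + 1e-9
    assert abs(s.sd - sdev) < 3 * se_sd + 1e-9


def test_compare_static_structures_identity(toy_protein, toy_catalytic_set):
    report = compare_static_structures(toy_protein, toy_protein,
                                       toy_catalytic_set, toy_catalytic_set)
    assert report["catalytic_rmsd"] == pytest.approx(0.0, abs=1e-9)
    for pair in report["pairs"].values():
        assert pair["a"] == pytest.approx(pair["b"])


def test_compare_static_structures_reports_crystal_like_distances(
        toy_protein, toy_catalytic_set):
    """On a synthetic structure built with the transition-state-analog
    crystal geometry (Ser OG - His NE2 = 2.7 A, His ND1 - Asp OD = 3.1 A),
    the comparison report returns those distances to 1 decimal place."""
    spec = sd.TriadDistanceSpec(2.7, 0.0, 3.1, 0.0, n_frames=1, seed=0)
    crystal_like = sd.generate_triad_trajectory(toy_protein, spec).frame(0)
    report = compare_static_structures(crystal_like, toy_protein,
                                       toy_catalytic_set, toy_catalytic_set)
    assert round(report["pairs"]["SER_OG-HIS_NE2"]["a"], 1) == 2.7
    assert round(report["pairs"]["HIS_ND1-ASP_OD"]["a"], 1) == 3.1
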