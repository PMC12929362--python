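"""Superposition RMSD, hydrogen-bond detection, summaries, plateaus."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from aptadna import (
    AptadnaError,
    Atom,
    GeometryError,
    HBondCriteria,
    Residue,
    Structure,
    TimeSeries,
    UnitsError,
    build_helix,
    compare_runs,
    detect_plateau,
    find_hbonds,
    hbond_series,
    kabsch_superpose,
    make_noise_trajectory,
    make_plateau_series,
    rmsd_series,
    summarize,
)
from aptadna.synth import NoiseSpec

from _oracles import exhaustive_plateau_onset, quaternion_rmsd


def _random_rigid(rng):
    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
    return rot, rng.normal(scale=10.0, size=3)


# -- Kabsch ----------------------------------------------------------------


def test_kabsch_identity():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    rot, trans, rmsd = kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(rot, np.eye(3), atol=1e-9)
    assert np.allclose(trans, 0, atol=1e-9)


def test_kabsch_recovers_rigid_transform():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(25, 3))
    rot_true, trans_true = _random_rigid(rng)
    moved = pts @ rot_true.T + trans_true
    _rot, _trans, rmsd = kabsch_superpose(moved, pts)
    assert rmsd <= 1e-9


def test_kabsch_agrees_with_quaternion_oracle():
    """SVD-based RMSD matches the independent quaternion eigenvalue method
    on random instances, with and without weights."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(10, 101))
        a = rng.normal(size=(n, 3))
        b = rng.normal(size=(n, 3))
        w = rng.uniform(0.5, 2.0, size=n) if rng.random() < 0.5 else None
        _r, _t, rmsd = kabsch_superpose(a, b, w)
        assert rmsd == pytest.approx(quaternion_rmsd(a, b, w), abs=1e-6)


def test_kabsch_rotation_is_proper():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(8, 3))
    b = a @ np.diag([1.0, 1.0, -1.0])  # reflected copy
    rot, _t, rmsd = kabsch_superpose(a, b)
    assert np.linalg.det(rot) == pytest.approx(1.0)
    assert rmsd > 0.1  # reflection must NOT be matched exactly


def test_kabsch_symmetry():
    rng = np.random.default_rng(4)
    a = rng.normal(size=(12, 3))
    b = rng.normal(size=(12, 3))
    assert kabsch_superpose(a, b)[2] == pytest.approx(
        kabsch_superpose(b, a)[2], rel=1e-12)


def test_kabsch_degenerate_inputs():
    with pytest.raises(GeometryError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(GeometryError):
        kabsch_superpose(line, line)


@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_rmsd_invariant_under_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(15, 3))
    b = rng.normal(size=(15, 3))
    base = kabsch_superpose(a, b)[2]
    rot, trans = _random_rigid(rng)
    assert kabsch_superpose(a @ rot.T + trans, b)[2] == pytest.approx(
        base, rel=1e-9, abs=1e-12)
    assert kabsch_superpose(a, b @ rot.T + trans)[2] == pytest.approx(
        base, rel=1e-9, abs=1e-12)


# -- RMSD series -----------------------------------------------------------


def test_rmsd_series_zero_for_identical_frames(single_u):
    traj = make_noise_trajectory(single_u, NoiseSpec(0.0, 5, seed=0))
    series = rmsd_series(traj, single_u)
    assert series.units == "nm"
    assert np.allclose(series.values, 0.0, atol=1e-12)


def test_rmsd_series_removes_rigid_motion(single_u):
    def drift(i):
        rot = Rotation.from_euler("z", 10.0 * i, degrees=True).as_matrix()
        return rot, np.array([0.0, 0.0, 2.0 * i])

    traj = make_noise_trajectory(single_u, NoiseSpec(0.0, 8, seed=0,
                                                     drift=drift))
    raw_disp = np.linalg.norm(traj.frames[-1].coords - single_u.coords(),
                              axis=1).mean()
    assert raw_disp > 5.0
    series = rmsd_series(traj, single_u)
    assert np.allclose(series.values, 0.0, atol=1e-9)


def test_rmsd_series_noise_matches_analytic_expectation():
    """Gaussian noise σ per coordinate gives post-fit RMSD ≈ σ√3 with the
    6-DOF fitting correction √(1−6/3N)."""
    ref = build_helix("ACGU" * 6)
    n = ref.n_atoms
    sigma = 0.5
    traj = make_noise_trajectory(ref, NoiseSpec(sigma, 100, seed=11))
    series = rmsd_series(traj, ref, mass_weighted=False)
    expected_nm = sigma * np.sqrt(3) * np.sqrt(1 - 6 / (3 * n)) / 10
    assert series.values.mean() == pytest.approx(expected_nm, rel=0.05)


def test_rmsd_series_selection_too_small(single_u):
    traj = make_noise_trajectory(single_u, NoiseSpec(0.0, 2, seed=0))
    with pytest.raises(AptadnaError, match="3"):
        rmsd_series(traj, single_u, selection=lambda a, r: a.name == "P")


# -- hydrogen bonds --------------------------------------------------------


def _inline_donor_acceptor(da_dist_a, h_offset_deg=0.0):
    """Donor O–H pointing at acceptor N, donor–acceptor distance in Å."""
    h_dir = Rotation.from_euler("z", h_offset_deg, degrees=True).apply(
        [1.0, 0, 0])
    donor = Residue("X", "A", 1, [
        Atom("O1", "O", [0.0, 0, 0], 1),
        Atom("H1", "H", 0.96 * h_dir, 2),
    ])
    acceptor = Residue("Y", "A", 2, [
        Atom("N1", "N", [da_dist_a, 0, 0], 3),
    ])
    return Structure([donor, acceptor])


def test_inline_pair_inside_cutoffs_is_one_bond():
    s = _inline_donor_acceptor(3.0)
    bonds = find_hbonds(s)
    assert len(bonds) == 1
    d, h, a = bonds[0]
    assert (d.name, h.name, a.name) == ("O1", "H1", "N1")


def test_distance_cutoff_excludes_pair():
    assert find_hbonds(_inline_donor_acceptor(3.6)) == []


def test_angle_cutoff_excludes_pair():
    assert len(find_hbonds(_inline_donor_acceptor(3.0, h_offset_deg=20))) == 1
    assert find_hbonds(_inline_donor_acceptor(3.0, h_offset_deg=40)) == []


def test_gc_pair_has_three_bonds(gc_pair):
    bonds = find_hbonds(gc_pair)
    assert len(bonds) == 3
    triples = {(d.name, a.name) for d, _h, a in bonds}
    assert ("N1", "N3") in triples  # central imino bond


def test_hbond_count_invariant_under_rigid_motion(gc_pair):
    rng = np.random.default_rng(5)
    rot, trans = _random_rigid(rng)
    moved = gc_pair.coords() @ rot.T + trans
    assert len(find_hbonds(gc_pair, coords=moved)) == 3


def test_hbond_count_monotone_in_thresholds(gc_pair):
    counts_d = [
        len(find_hbonds(gc_pair, HBondCriteria(max_da_dist=d)))
        for d in (0.40, 0.35, 0.32, 0.30, 0.28, 0.25)
    ]
    assert counts_d == sorted(counts_d, reverse=True)
    counts_a = [
        len(find_hbonds(gc_pair, HBondCriteria(max_hda_angle=a)))
        for a in (60, 30, 10, 5, 2)
    ]
    assert counts_a == sorted(counts_a, reverse=True)


def test_hbond_series_constant_then_drop(gc_pair):
    """A static pair counts 3 every frame; pulling the bases 10 Å apart
    drops the count to zero from that frame on."""
    base = gc_pair.coords()
    n_g = len(gc_pair.residues[0].atoms)
    frames = []
    k = 3
    for i in range(6):
        c = base.copy()
        if i >= k:
            c[n_g:] += np.array([25.0, 0, 0])
        frames.append(c)
    from aptadna import Frame, Trajectory

    traj = Trajectory(gc_pair, [Frame(float(i), c)
                                for i, c in enumerate(frames)])
    series = hbond_series(traj)
    assert list(series.values) == [3, 3, 3, 0, 0, 0]


def test_no_donors_warns_and_counts_zero(caplog):
    s = Structure([Residue("X", "A", 1, [
        Atom("C1", "C", [0, 0, 0], 1),
        Atom("C2", "C", [1.5, 0, 0], 2),
        Atom("N1", "N", [4.0, 0, 0], 3),
    ])])
    with caplog.at_level("WARNING", logger="aptadna"):
        assert find_hbonds(s) == []
    assert "donors" in caplog.text


def test_heavy_only_mode_counts_close_pairs():
    s = Structure([
        Residue("X", "A", 1, [Atom("N1", "N", [0, 0, 0], 1)]),
        Residue("Y", "A", 2, [Atom("O1", "O", [3.0, 0, 0], 2)]),
    ])
    bonds = find_hbonds(s, HBondCriteria(heavy_only_mode=True))
    assert len(bonds) >= 1
    assert bonds[0][1] is None


# -- summaries -------------------------------------------------------------


def test_summarize_constant_series():
    ts = TimeSeries(np.arange(5.0), np.full(5, 2.5), units="nm")
    s = summarize(ts)
    assert s.mean == 2.5 and s.sd == 0.0 and s.n == 5


def test_summarize_1_2_3():
    ts = TimeSeries([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
    s = summarize(ts)
    assert s.mean == 2.0 and s.sd == 1.0


def test_summarize_discard_and_errors():
    ts = TimeSeries([0.0, 1.0, 2.0, 3.0], [10.0, 1.0, 2.0, 3.0])
    s = summarize(ts, discard_before=1.0)
    assert s.mean == 2.0 and s.n == 3
    with pytest.raises(AptadnaError):
        summarize(ts, discard_before=3.0)


def test_summarize_recovers_noise_sd():
    rng = np.random.default_rng(2024)
    sigma = 0.7
    ts = TimeSeries(np.arange(1000.0), rng.normal(5.0, sigma, 1000))
    assert summarize(ts).sd == pytest.approx(sigma, rel=0.10)


# -- plateau ---------------------------------------------------------------


def test_plateau_constant_series_onset_at_start():
    ts = TimeSeries(np.arange(0, 100.0, 1.0), np.full(100, 1.0))
    assert detect_plateau(ts).onset_time == 0.0


def test_plateau_ramp_then_constant_matches_oracle():
    ts = make_plateau_series(75.0, 200.0, 0.5, pre_slope=0.02, noise_sd=0.0)
    result = detect_plateau(ts, window=20.0)
    oracle = exhaustive_plateau_onset(ts.times, ts.values, 20.0, 0.005, 0.1)
    assert result.onset_time == oracle
    assert abs(result.onset_time - 75.0) <= 20.0


def test_plateau_monotone_ramp_has_none():
    t = np.arange(0, 100.0, 1.0)
    ts = TimeSeries(t, 0.05 * t)
    assert detect_plateau(ts, window=20.0).onset_time is None


def test_plateau_requires_two_windows():
    ts = TimeSeries(np.arange(0, 30.0, 1.0), np.zeros(30))
    with pytest.raises(AptadnaError):
        detect_plateau(ts, window=20.0)


# -- comparison table ------------------------------------------------------


def _summary(label, units, mean, sd):
    from aptadna import SeriesSummary

    return SeriesSummary(mean=mean, sd=sd, n=100, label=label, units=units)


def test_compare_runs_grid_shape():
    summaries = []
    for mol in ("A6 (300 K)", "A6 (310 K)", "LN-A6 (300 K)", "LN-A6 (310 K)"):
        summaries.append(_summary(mol, "count", 80.0, 5.0))
        summaries.append(_summary(mol, "nm", 0.6, 0.1))
    df = compare_runs(summaries)
    assert df.shape == (4, 4)
    assert list(df.columns) == ["HB mean", "HB SD", "RMSD mean", "RMSD SD"]


def test_compare_runs_single_summary():
    df = compare_runs([_summary("A6 (300 K)", "nm", 0.56, 0.11)])
    assert df.shape == (1, 2)


def test_compare_runs_errors():
    with pytest.raises(AptadnaError):
        compare_runs([
            _summary("A6", "count", 80, 5),
            _summary("A6", "count", 81, 5),
        ])
    with pytest.raises(UnitsError):
        compare_runs([
            _summary("A6", "nm", 0.5, 0.1),
            _summary("A11", "angstrom", 5.0, 1.0),
        ])
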