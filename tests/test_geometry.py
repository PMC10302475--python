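import numpy as np
import pytest

from nucsox.errors import ArgumentError, ConditioningError, StatisticsError
from nucsox import geometry as geo
from nucsox import model_io as mio
from nucsox import synthetic_data as sd
from nucsox.model_io import Atom, DuplexMap, SelectionSpec, Structure, Trajectory

from _oracles import exhaustive_groove_scan, quaternion_rmsd, rigid_transform_structure

P_WINDOW = SelectionSpec("I", tuple(range(13, 20)), ("P",))   # 7-nt dyad window


def random_rotation(rng):
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestSuperpose:
    def test_rigid_motion_recovers_zero_rmsd(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(7, 3))
        mob = ref @ random_rotation(rng).T + rng.normal(size=3)
        _, rmsd = geo.superpose(mob, ref)
        assert rmsd <= 1e-6

    def test_mirror_image_of_chiral_set_keeps_positive_rmsd(self):
        # chiral 4-point set; reflections are disallowed so RMSD stays > 0
        ref = np.array([[0., 0, 0], [3, 0, 0], [0, 2, 0], [0, 0, 1]])
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        _, rmsd = geo.superpose(mirrored, ref)
        assert rmsd > 0.1
        assert abs(rmsd - quaternion_rmsd(mirrored, ref)) <= 1e-9

    def test_matches_quaternion_oracle_on_random_point_sets(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(300):
            a = rng.normal(size=(7, 3)) * rng.uniform(0.5, 5.0)
            b = rng.normal(size=(7, 3)) * rng.uniform(0.5, 5.0)
            _, rmsd = geo.superpose(a, b)
            worst = max(worst, abs(rmsd - quaternion_rmsd(a, b)))
        assert worst <= 1e-6

    def test_count_mismatch_rejected(self):
        with pytest.raises(ArgumentError):
            geo.superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_points_raise_conditioning_error(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ConditioningError):
            geo.superpose(line, line)


class TestPRMSD:
    def test_identity_is_zero(self, toy_duplex):
        assert geo.p_rmsd(toy_duplex, toy_duplex, P_WINDOW) == pytest.approx(0.0, abs=1e-6)

    def test_single_displaced_phosphate_equals_superpose_oracle(self, toy_duplex):
        coords = toy_duplex.coords()
        idx = toy_duplex.atom_index()[("I", 16, "P")]
        coords[idx] += np.array([1.0, 0.0, 0.0])
        moved = toy_duplex.with_coords(coords)
        ref_pts = np.array([a.position for a in mio.select_atoms(toy_duplex, P_WINDOW)])
        mob_pts = np.array([a.position for a in mio.select_atoms(moved, P_WINDOW)])
        expected = quaternion_rmsd(mob_pts, ref_pts)
        assert geo.p_rmsd(moved, toy_duplex, P_WINDOW) == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_rigid_transform_of_frame(self, toy_duplex, deformed_duplex):
        v0 = geo.p_rmsd(deformed_duplex, toy_duplex, P_WINDOW)
        moved = rigid_transform_structure(deformed_duplex, seed=5)
        assert geo.p_rmsd(moved, toy_duplex, P_WINDOW) == pytest.approx(v0, abs=1e-8)

    def test_symmetric_after_optimal_fit(self, toy_duplex, deformed_duplex):
        ab = geo.p_rmsd(deformed_duplex, toy_duplex, P_WINDOW)
        ba = geo.p_rmsd(toy_duplex, deformed_duplex, P_WINDOW)
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_drift_series_monotone_toward_origin_reference(self, toy_duplex, deformed_duplex):
        traj = sd.simulate_trajectory(
            toy_duplex, sd.PerturbationSpec(sigma=0.0, n_frames=8, seed=0,
                                            drift_target=deformed_duplex))
        series = geo.p_rmsd_series(traj, toy_duplex, P_WINDOW, reference_id="start")
        assert np.all(np.diff(series.values) >= -1e-12)

    def test_series_counts_and_pooling(self, toy_duplex):
        traj = sd.simulate_trajectory(
            toy_duplex, sd.PerturbationSpec(sigma=0.1, n_frames=30, seed=1))
        s1 = geo.p_rmsd_series(traj, toy_duplex, P_WINDOW, reference_id="r")
        s2 = geo.p_rmsd_series(traj, toy_duplex, P_WINDOW, reference_id="r")
        assert s1.n == 30
        assert s1.pooled_with(s2).n == 60

    def test_constant_trajectory_all_zero(self, toy_duplex):
        traj = Trajectory([toy_duplex] * 5, frame_interval_ns=0.5)
        series = geo.p_rmsd_series(traj, toy_duplex, P_WINDOW)
        assert np.all(series.values <= 1e-6)


class TestFractionInRange:
    def test_all_inside(self):
        s = np.full(50, 1.5)
        assert geo.fraction_in_range(s) == 1.0

    def test_constructed_28_percent(self):
        # mirrors the shape-reading statistic: 28 of 100 frames in 0.7-2.2 Å
        values = np.concatenate([np.linspace(0.8, 2.1, 28), np.full(72, 5.0)])
        assert geo.fraction_in_range(values) == pytest.approx(0.28)

    def test_bounds_inclusive(self):
        assert geo.fraction_in_range(np.array([0.7, 2.2]), 0.7, 2.2) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ArgumentError):
            geo.fraction_in_range(np.array([]))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ArgumentError):
            geo.fraction_in_range(np.array([1.0]), 2.0, 1.0)

    def test_monotone_in_bounds(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0, 4, size=200)
        f = [geo.fraction_in_range(v, 0.7, hi) for hi in (1.0, 2.2, 3.0)]
        assert f == sorted(f)
        g = [geo.fraction_in_range(v, lo, 2.2) for lo in (1.5, 0.7, 0.1)]
        assert g == sorted(g)


def _rail_fixture():
    """Two straight phosphate rails 11.7 Å apart, offsets aligned so the
    k=3 cross-strand partner sits at the same height."""
    rise = 3.38
    atoms = []
    n = 12
    for i in range(n):
        atoms.append(Atom("P", "DA", i + 1, "I", "P",
                          np.array([0.0, 0.0, rise * i])))
        atoms.append(Atom("C1'", "DA", i + 1, "I", "C",
                          np.array([1.0, 0.0, rise * i])))
    for j in range(n):
        level = n - 1 - j
        atoms.append(Atom("P", "DT", j + 1, "J", "P",
                          np.array([11.7, 0.0, rise * (level - 3)])))
        atoms.append(Atom("C1'", "DT", j + 1, "J", "C",
                          np.array([10.7, 0.0, rise * (level - 3)])))
    s = Structure(atoms, title="rails")
    pairs = [(("I", i + 1, "DA"), ("J", n - i, "DT")) for i in range(n)]
    fwd = [("I", i + 1, "DA") for i in range(n)]
    return s, DuplexMap(pairs=pairs, forward_residues=fwd, dyad_forward_index=n // 2)


class TestGrooveWidths:
    def test_straight_rails_report_rail_separation(self):
        s, dm = _rail_fixture()
        prof = geo.minor_groove_widths(s, dm)
        interior = prof.widths[prof.defined]
        assert np.allclose(interior, 11.7, atol=1e-6)

    def test_fiber_duplex_matches_exhaustive_scan(self, toy_duplex, toy_duplex_map):
        prof = geo.minor_groove_widths(toy_duplex, toy_duplex_map)
        oracle = exhaustive_groove_scan(toy_duplex, toy_duplex_map)
        for pos, w, ok in zip(prof.positions, prof.widths, prof.defined):
            if ok and pos in oracle:
                assert abs(w - oracle[pos]) <= 0.5

    def test_unperturbed_fiber_is_uniform_and_rigid_invariant(self, toy_duplex,
                                                              toy_duplex_map):
        prof = geo.minor_groove_widths(toy_duplex, toy_duplex_map)
        interior = prof.widths[prof.defined]
        assert interior.std() < 0.5
        moved = rigid_transform_structure(toy_duplex, seed=2)
        prof2 = geo.minor_groove_widths(moved, toy_duplex_map)
        assert np.allclose(prof2.widths[prof2.defined], interior, atol=1e-6)

    def test_refined_convention_subtracts_phosphate_radii(self, toy_duplex,
                                                          toy_duplex_map):
        raw = geo.minor_groove_widths(toy_duplex, toy_duplex_map, "raw_pp")
        ref = geo.minor_groove_widths(toy_duplex, toy_duplex_map, "refined")
        d = raw.defined & ref.defined
        assert np.allclose(ref.widths[d],
                           np.maximum(raw.widths[d] - 5.8, 0.0), atol=1e-9)

    def test_undefined_ends_flagged_not_zero_filled(self, toy_duplex, toy_duplex_map):
        prof = geo.minor_groove_widths(toy_duplex, toy_duplex_map)
        assert not prof.defined[-1]
        assert np.isnan(prof.widths[~prof.defined]).all()

    def test_deformed_duplex_reaches_fingerprint_width(self, deformed_duplex,
                                                       toy_duplex_map):
        w = geo.max_groove_width(deformed_duplex, toy_duplex_map, window=(-6, 6))
        assert w == pytest.approx(22.5, abs=0.3)

    def test_max_reduces_over_frames_and_windows(self, deformed_duplex, toy_duplex_map):
        single = geo.max_groove_width(deformed_duplex, toy_duplex_map)
        traj = Trajectory([deformed_duplex] * 3, frame_interval_ns=0.5)
        assert geo.max_groove_width(traj, toy_duplex_map) == pytest.approx(single)
        prof = geo.minor_groove_widths(deformed_duplex, toy_duplex_map)
        assert single == pytest.approx(np.nanmax(prof.widths))

    def test_empty_window_rejected(self, toy_duplex, toy_duplex_map):
        with pytest.raises(ArgumentError):
            geo.max_groove_width(toy_duplex, toy_duplex_map, window=(6, -6))


class TestRMSF:
    def test_static_trajectory_is_zero(self, tiny_structure):
        traj = Trajectory([tiny_structure] * 12, frame_interval_ns=0.5)
        sel = SelectionSpec("X", (1, 2, 3, 4), ("P", "C1'", "C2'"))
        prof = geo.rmsf_profile(traj, sel)
        assert np.allclose(prof.rmsf, 0.0)
        assert np.allclose(prof.temperature_factor, 0.0)

    def test_isotropic_gaussian_matches_closed_form(self):
        # sigma per axis 0.5 Å -> RMSF = 0.5 * sqrt(3); enough atoms that
        # the rigid-body fit absorbs a negligible share of the variance
        rng = np.random.default_rng(9)
        n_res = 40
        atoms = [Atom(nm, "DA", r + 1, "X", nm[0], rng.normal(scale=15.0, size=3))
                 for r in range(n_res) for nm in ("P", "C1'", "C2'")]
        base = Structure(atoms)
        traj = sd.simulate_trajectory(
            base, sd.PerturbationSpec(sigma=0.5, n_frames=10_000, seed=4))
        sel = SelectionSpec("X", tuple(range(1, n_res + 1)), ("P", "C1'", "C2'"))
        prof = geo.rmsf_profile(traj, sel)
        expected = 0.5 * np.sqrt(3.0)
        assert abs(prof.rmsf.mean() - expected) / expected <= 0.02

    def test_temperature_factor_conversion(self):
        prof = geo.FluctuationProfile(atom_keys=[("X", 1, "P")], rmsf=np.array([1.0]))
        assert prof.temperature_factor[0] == pytest.approx(26.3189, abs=1e-3)

    def test_too_few_frames_rejected(self, tiny_structure):
        traj = Trajectory([tiny_structure] * 5, frame_interval_ns=0.5)
        sel = SelectionSpec("X", (1, 2, 3, 4), ("P",))
        with pytest.raises(StatisticsError):
            geo.rmsf_profile(traj, sel)
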