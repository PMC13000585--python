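"""Descriptor computations against analytic and independent oracles."""

import numpy as np
import pytest

from phenoxscreen.descriptors import (
    MsdCurve,
    _sphere_cap_lens_fraction,
    buried_volume,
    compute_msd,
    detect_hbonds,
    detect_transfer_events,
    fit_diffusion,
    hbond_probability,
    steric_map,
)
from phenoxscreen.geometry import build_radical_geometry
from phenoxscreen.library import SubstitutionPattern
from phenoxscreen.synthetic import (
    make_brownian_trajectory,
    make_hbond_scene,
    make_mixture_frame,
    simulate_transfer_trajectory,
)
from phenoxscreen.trajectory import Frame, Trajectory


def _frame(elements, xyz, roles, box=None, mol_ids=None, t=0.0):
    n = len(elements)
    return Frame(
        time_ps=t,
        elements=np.array(elements, dtype=object),
        xyz=np.asarray(xyz, dtype=float),
        molecule_ids=np.arange(n) if mol_ids is None else np.asarray(mol_ids),
        roles=np.array(roles, dtype=object),
        box=None if box is None else np.asarray(box, dtype=float),
    )


def _single_particle_trajectory(positions, dt=1.0):
    frames = [
        _frame(["O"], [p], ["phenoxyl_O"], t=i * dt) for i, p in enumerate(positions)
    ]
    return Trajectory(frames=frames, frame_interval_ps=dt, unwrapped=True)


class TestMsd:
    def test_stationary_particles_zero_msd(self):
        traj = _single_particle_trajectory([[1.0, 2.0, 3.0]] * 10)
        assert np.allclose(compute_msd(traj).msd, 0.0)

    def test_ballistic_closed_form(self):
        d = 0.7
        traj = _single_particle_trajectory([[i * d, 0, 0] for i in range(20)])
        curve = compute_msd(traj)
        lags = np.arange(20)
        assert np.allclose(curve.msd, (lags * d) ** 2)

    def test_origin_averaging_matches_brute_force_double_loop(self, rng):
        pos = rng.normal(size=(12, 3, 3))
        frames = [
            _frame(["O"] * 3, pos[i], ["phenoxyl_O"] * 3, t=float(i))
            for i in range(12)
        ]
        traj = Trajectory(frames=frames, frame_interval_ps=1.0, unwrapped=True)
        curve = compute_msd(traj)
        for lag in range(1, 12):
            vals = [
                np.sum((pos[t + lag, p] - pos[t, p]) ** 2)
                for t in range(12 - lag)
                for p in range(3)
            ]
            assert curve.msd[lag] == pytest.approx(np.mean(vals))

    def test_translation_invariance(self, rng):
        pos = rng.normal(size=(15, 2, 3))
        shifted = pos + np.array([100.0, -50.0, 7.0])
        def mk(p):
            frames = [
                _frame(["O"] * 2, p[i], ["phenoxyl_O"] * 2, t=float(i))
                for i in range(15)
            ]
            return Trajectory(frames=frames, frame_interval_ps=1.0, unwrapped=True)
        assert np.allclose(compute_msd(mk(pos)).msd, compute_msd(mk(shifted)).msd)

    def test_wrapped_trajectory_rejected(self):
        traj = _single_particle_trajectory([[0, 0, 0], [1, 0, 0]])
        traj.unwrapped = False
        with pytest.raises(ValueError, match="unwrap"):
            compute_msd(traj)

    def test_brownian_slope_recovers_planted_diffusivity(self):
        D_true = 0.05
        traj = make_brownian_trajectory(100, D_true, n_frames=500, seed=21)
        D, r2 = fit_diffusion(compute_msd(traj))
        assert D == pytest.approx(D_true, rel=0.10)
        assert r2 > 0.99


class TestFitDiffusion:
    def test_identity_slope(self):
        lags = np.arange(100, dtype=float)
        curve = MsdCurve(lags_ps=lags, msd=6.0 * lags, n_origins=np.full(100, 10))
        D, r2 = fit_diffusion(curve)
        assert D == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_zero_curve(self):
        lags = np.arange(50, dtype=float)
        curve = MsdCurve(lags_ps=lags, msd=np.zeros(50), n_origins=np.full(50, 10))
        assert fit_diffusion(curve)[0] == pytest.approx(0.0, abs=1e-15)

    def test_three_realization_average_recovers_planted(self):
        D_true = 0.03
        vals = []
        for r in range(3):
            traj = make_brownian_trajectory(100, D_true, n_frames=500, seed=30 + r)
            vals.append(fit_diffusion(compute_msd(traj))[0])
        assert np.mean(vals) == pytest.approx(D_true, rel=0.10)

    def test_degenerate_window_rejected(self):
        lags = np.arange(5, dtype=float)
        curve = MsdCurve(lags_ps=lags, msd=lags, n_origins=np.full(5, 2))
        with pytest.raises(ValueError):
            fit_diffusion(curve, fit_window=(0.5, 0.5))


def _hbond_frame(da_dist, angle_deg, box=30.0):
    """Donor O-H and acceptor O with exact D-A distance and D-H-A angle."""
    center = np.full(3, box / 2)
    alpha = np.radians(angle_deg)
    oh = 0.97
    # place H on the x axis so that the angle at H is exactly alpha
    h_x = oh * np.cos(alpha) + np.sqrt(da_dist**2 - (oh * np.sin(alpha)) ** 2)
    hydrogen = center + np.array([h_x, 0.0, 0.0])
    donor = hydrogen + oh * np.array([-np.cos(alpha), np.sin(alpha), 0.0])
    return _frame(
        ["O", "O", "H"],
        [center, donor, hydrogen],
        ["phenoxyl_O", "donor", "other"],
        box=[box] * 3,
        mol_ids=[0, 1, 1],
    )


class TestHbondDetection:
    @pytest.mark.parametrize(
        "dist,angle,expected",
        [
            (2.8, 180.0, True),     # inside both cutoffs
            (3.2, 180.0, False),    # distance fails
            (2.8, 120.0, False),    # angle fails
            (3.001, 180.0, False),  # just outside the distance cutoff
            (2.8, 149.999, False),  # just below the angle cutoff
            (2.99, 150.001, True),  # just inside both
        ],
    )
    def test_cutoff_truth_table(self, dist, angle, expected):
        bonds = detect_hbonds(_hbond_frame(dist, angle))
        assert bool(bonds) == expected

    def test_detection_invariant_under_global_rotation(self, rng):
        frame = _hbond_frame(2.8, 165.0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = _frame(
            frame.elements, (frame.xyz - 15.0) @ q.T + 15.0, frame.roles,
            box=frame.box, mol_ids=frame.molecule_ids,
        )
        assert len(detect_hbonds(rotated)) == len(detect_hbonds(frame))

    def test_matches_mdanalysis_oracle(self):
        """Cross-check every geometry against MDAnalysis' H-bond analysis."""
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.hydrogenbonds import HydrogenBondAnalysis

        for dist, angle in [(2.5, 170.0), (2.8, 155.0), (2.9, 140.0), (3.4, 180.0)]:
            frame = _hbond_frame(dist, angle)
            u = mda.Universe.empty(3, n_residues=3, atom_resindex=np.arange(3),
                                   trajectory=True)
            u.add_TopologyAttr("name", ["OA", "OD", "HD"])
            u.add_TopologyAttr("type", ["O", "O", "H"])
            u.add_TopologyAttr("element", ["O", "O", "H"])
            u.add_TopologyAttr("bonds", [(1, 2)])
            u.dimensions = [30, 30, 30, 90, 90, 90]
            u.load_new(frame.xyz.astype(np.float32)[None])
            hba = HydrogenBondAnalysis(
                u, donors_sel="name OD", hydrogens_sel="name HD",
                acceptors_sel="name OA", d_a_cutoff=3.0, d_h_a_angle_cutoff=150.0,
            )
            hba.run()
            assert len(hba.results.hbonds) == len(detect_hbonds(frame))

    def test_missing_roles_rejected(self):
        frame = _frame(["O"], [[0, 0, 0]], ["other"])
        with pytest.raises(ValueError, match="role"):
            detect_hbonds(frame)


class TestHbondProbability:
    @pytest.mark.parametrize("occ,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_extremes(self, occ, expected):
        scene, _ = make_hbond_scene(n_frames=50, occupancy_true=occ, seed=40)
        assert hbond_probability(scene) == expected

    def test_planted_occupancy_within_binomial_ci(self):
        occ, n = 0.6, 500
        scene, truth = make_hbond_scene(n_frames=n, occupancy_true=occ, seed=41)
        p = hbond_probability(scene)
        assert p == pytest.approx(truth.mean())  # detector agrees with labels
        ci = 2.576 * np.sqrt(occ * (1 - occ) / n)  # 99% binomial CI
        assert abs(p - occ) <= ci

    def test_no_acceptor_sites_rejected(self):
        frames = [_frame(["O"], [[0, 0, 0]], ["donor"])]
        traj = Trajectory(frames=frames, frame_interval_ps=1.0)
        with pytest.raises(ValueError, match="phenoxyl_O"):
            hbond_probability(traj)


class TestBuriedVolume:
    def _two_atom_frame(self, d):
        return _frame(["O", "C"], [[0, 0, 0], [d, 0, 0]],
                      ["phenoxyl_O", "other"])

    def test_empty_probe_is_zero(self):
        frame = self._two_atom_frame(10.0)
        assert buried_volume(frame, 0) == 0.0

    def test_fully_engulfing_atom_is_hundred(self):
        frame = _frame(["O", "C"], [[0, 0, 0], [0.1, 0, 0]],
                       ["phenoxyl_O", "other"])
        pct = buried_volume(frame, 0, probe_radius=1.0,
                            vdw_radii={"O": 1.52, "C": 5.0})
        assert pct == 100.0

    def test_monte_carlo_matches_analytic_lens(self):
        # single carbon 2.0 A from the center: exact two-sphere overlap
        frame = self._two_atom_frame(2.0)
        exact = 100.0 * _sphere_cap_lens_fraction(3.5, 1.70, 2.0)
        mc = buried_volume(frame, 0, method="montecarlo", n_samples=100_000, seed=50)
        assert abs(mc - exact) < 0.5

    def test_grid_and_monte_carlo_agree(self):
        geom = build_radical_geometry(SubstitutionPattern(("Me", "H", "OMe", "H", "H")))
        center = int(geom.select("phenoxyl_O")[0])
        g = buried_volume(geom, center, method="grid", resolution=0.1)
        mc = buried_volume(geom, center, method="montecarlo", n_samples=200_000, seed=51)
        assert abs(g - mc) < 0.5

    def test_monotone_under_atom_addition(self):
        base = self._two_atom_frame(2.5)
        more = _frame(["O", "C", "C"], [[0, 0, 0], [2.5, 0, 0], [-2.0, 0, 0]],
                      ["phenoxyl_O", "other", "other"])
        assert buried_volume(more, 0) >= buried_volume(base, 0)

    def test_rigid_motion_invariance(self, rng):
        geom = build_radical_geometry(SubstitutionPattern(("tBu", "H", "H", "H", "Me")))
        center = int(geom.select("phenoxyl_O")[0])
        ref = buried_volume(geom, center, method="grid", resolution=0.15)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = _frame(geom.elements, geom.xyz @ q.T + np.array([5.0, -3.0, 1.0]),
                       geom.roles, mol_ids=geom.molecule_ids)
        got = buried_volume(moved, center, method="grid", resolution=0.15)
        assert got == pytest.approx(ref, abs=0.3)

    def test_unknown_element_named_in_error(self):
        frame = _frame(["O", "Xe"], [[0, 0, 0], [2, 0, 0]], ["phenoxyl_O", "other"])
        with pytest.raises(ValueError, match="Xe"):
            buried_volume(frame, 0)

    def test_center_must_be_phenoxyl_oxygen(self):
        frame = self._two_atom_frame(2.0)
        with pytest.raises(ValueError, match="phenoxyl_O"):
            buried_volume(frame, 1)


class TestStericMap:
    def test_ortho_tbu_buries_more_than_ortho_h(self):
        bulky = build_radical_geometry(SubstitutionPattern(("tBu", "H", "Me", "H", "tBu")))
        bare = build_radical_geometry(SubstitutionPattern(("H", "H", "Me", "H", "H")))
        m_bulky = steric_map(bulky, grid_step=0.15)
        m_bare = steric_map(bare, grid_step=0.15)
        assert m_bulky.buried_pct > m_bare.buried_pct

    def test_palindrome_map_mirror_symmetric(self):
        geom = build_radical_geometry(SubstitutionPattern(("Me", "H", "H", "H", "Me")))
        m = steric_map(geom, grid_step=0.1)
        h = m.heights
        sym_err = np.nanmax(np.abs(h - h[::-1, :]))  # reflection across the trace
        assert sym_err < 1e-6 or np.isnan(sym_err)

    def test_heights_bounded_by_probe_radius(self):
        geom = build_radical_geometry(SubstitutionPattern(("tBu", "H", "H", "H", "tBu")))
        m = steric_map(geom)
        assert np.nanmax(np.abs(m.heights)) <= 3.5 + 1e-9

    def test_grid_refinement_converges(self):
        geom = build_radical_geometry(SubstitutionPattern(("OMe", "H", "H", "H", "H")))
        coarse = steric_map(geom, grid_step=0.2).buried_pct
        fine = steric_map(geom, grid_step=0.1).buried_pct
        assert abs(coarse - fine) < 0.5


@pytest.fixture(scope="module")
def transfer(library):
    mixture = make_mixture_frame([library[0].pattern], n_radicals=10,
                                 n_hydroperoxides=12, box=40, seed=60)
    traj, events = simulate_transfer_trajectory(mixture, 4.0, n_frames=200, seed=61)
    return traj, events


class TestTransferDetection:
    def test_recovers_planted_counts_exactly(self, transfer):
        traj, events = transfer
        series = detect_transfer_events(traj)
        finite = events[np.isfinite(events)]
        planted = np.array([(finite <= t).sum() for t in series.times_ns])
        assert np.array_equal(series.counts, planted)

    def test_zero_cutoff_finds_nothing(self, transfer):
        series = detect_transfer_events(transfer[0], r_cut=0.0)
        assert np.all(series.counts == 0)

    def test_idempotent_and_conserving(self, transfer):
        traj, _ = transfer
        a = detect_transfer_events(traj)
        b = detect_transfer_events(traj)
        assert np.array_equal(a.counts, b.counts)
        assert np.all(np.diff(a.counts) >= 0)
        assert a.counts[-1] <= 10
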