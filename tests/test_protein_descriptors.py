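"""Domain COMs, bend/twist descriptors, Kabsch superposition, averages."""

import numpy as np
import pytest

from cetptraj.errors import EmptyInputError, GeometryError, ShapeError
from cetptraj.io_core import Trajectory
from cetptraj.protein_descriptors import (
    BendTwistSeries,
    DomainDefinition,
    average_structure,
    bend_twist_series,
    bending_angle,
    center_of_mass,
    kabsch_rmsd,
    twist_angle,
)
from cetptraj.synthetic_data import ScaffoldSpec, build_scaffold
from conftest import make_frame, random_rotation, rigid_motion


class TestCenterOfMass:
    def test_unit_masses(self):
        frame = make_frame([[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(
            center_of_mass(frame, ((1, 2),)), [1, 0, 0]
        )

    def test_weighted(self):
        frame = make_frame([[0, 0, 0], [2, 0, 0]], masses=[1.0, 3.0])
        np.testing.assert_allclose(
            center_of_mass(frame, ((1, 2),)), [1.5, 0, 0]
        )

    def test_zero_mass_forces_geometric(self):
        frame = make_frame([[0, 0, 0], [2, 0, 0]], masses=[0.0, 3.0])
        np.testing.assert_allclose(
            center_of_mass(frame, ((1, 2),)), [1, 0, 0]
        )

    def test_empty_selection(self):
        frame = make_frame([[0, 0, 0]])
        with pytest.raises(EmptyInputError):
            center_of_mass(frame, ((5, 9),))

    def test_scaffold_com_matches_declared_geometry(self):
        frame, domains = build_scaffold(ScaffoldSpec(), seed=3)
        com_c = center_of_mass(frame, domains.central_sheet)
        com_ne = center_of_mass(frame, domains.n_end)
        com_ce = center_of_mass(frame, domains.c_end)
        # axis end COMs are symmetric about the central COM by construction
        np.testing.assert_allclose(
            com_c, 0.5 * (com_ne + com_ce), atol=1e-9
        )


def _point_domains():
    """One site per domain: bend/twist from bare COM geometry."""
    return DomainDefinition(
        n_barrel=((1, 1),), central_sheet=((2, 4),), c_barrel=((5, 5),),
        n_end=((2, 2),), c_end=((4, 4),),
    )


def _frame_for(com_n, com_c, axis_half=5.0):
    return make_frame([
        com_n,
        [-axis_half, 0, 0], [0, 0, 0], [axis_half, 0, 0],
        com_c,
    ])


class TestBendingAngle:
    def test_collinear_is_180(self):
        frame = _frame_for([-20, 0, 0], [20, 0, 0])
        assert bending_angle(frame, _point_domains()) == pytest.approx(180.0)

    def test_right_angle(self):
        # central COM at origin, barrels along x and y
        frame = make_frame([
            [1, 0, 0],
            [0, 0, -1], [0, 0, 0], [0, 0, 1],
            [0, 1, 0],
        ])
        domains = _point_domains()
        assert bending_angle(frame, domains) == pytest.approx(90.0)

    def test_coincident_coms_rejected(self):
        frame = _frame_for([0, 0, 0], [20, 0, 0])
        with pytest.raises(GeometryError):
            bending_angle(frame, _point_domains())


class TestTwistAngle:
    def test_coplanar_same_side_is_zero(self):
        frame = _frame_for([-20, 10, 0], [20, 10, 0])
        assert twist_angle(frame, _point_domains()) == pytest.approx(0.0)

    def test_perpendicular_planes_signed(self):
        up = _frame_for([-20, 10, 0], [20, 0, 10])
        down = _frame_for([-20, 10, 0], [20, 0, -10])
        assert twist_angle(up, _point_domains()) == pytest.approx(90.0)
        assert twist_angle(down, _point_domains()) == pytest.approx(-90.0)

    def test_single_on_axis_barrel_rejected(self):
        frame = _frame_for([-20, 0, 0], [20, 10, 0])
        with pytest.raises(GeometryError):
            twist_angle(frame, _point_domains())


class TestScaffoldRecovery:
    @pytest.mark.parametrize("bend,twist", [
        (139.0, 8.0),      # crystal-structure-like arch and twist
        (118.0, -12.0),    # strongly bent, untwisted
        (90.0, 45.0),
        (165.0, -30.0),
    ])
    def test_prescribed_descriptors_recovered(self, bend, twist):
        frame, domains = build_scaffold(
            ScaffoldSpec(bend_deg=bend, twist_deg=twist), seed=5
        )
        assert bending_angle(frame, domains) == pytest.approx(bend, abs=1e-6)
        assert twist_angle(frame, domains) == pytest.approx(twist, abs=1e-6)

    def test_collinear_limit(self):
        frame, domains = build_scaffold(
            ScaffoldSpec(bend_deg=180.0, twist_deg=0.0), seed=5
        )
        assert bending_angle(frame, domains) == pytest.approx(180.0, abs=1e-6)
        assert twist_angle(frame, domains) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_invariance(self, rng):
        frame, domains = build_scaffold(
            ScaffoldSpec(bend_deg=139.0, twist_deg=8.0), seed=2
        )
        for _ in range(10):
            moved, _, _ = rigid_motion(frame, rng)
            assert bending_angle(moved, domains) == \
                pytest.approx(139.0, abs=1e-9)
            assert twist_angle(moved, domains) == \
                pytest.approx(8.0, abs=1e-9)

    def test_mirror_flips_twist_and_preserves_bend(self):
        frame, domains = build_scaffold(
            ScaffoldSpec(bend_deg=139.0, twist_deg=8.0), seed=2
        )
        mirrored = frame.with_coords(frame.coords * np.array([1, 1, -1.0]))
        assert bending_angle(mirrored, domains) == \
            pytest.approx(139.0, abs=1e-9)
        assert twist_angle(mirrored, domains) == pytest.approx(-8.0, abs=1e-9)


def _quaternion_rmsd_oracle(a, b):
    """Independent minimal-RMSD oracle via the Horn quaternion method:
    the optimal superposition RMSD follows from the largest eigenvalue of
    the 4x4 key matrix — no SVD involved."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.max(np.linalg.eigvalsh(k))
    n = len(a)
    sq = (np.sum(a ** 2) + np.sum(b ** 2) - 2 * lam) / n
    return float(np.sqrt(max(sq, 0.0)))


class TestKabschRMSD:
    def test_self_is_zero(self, rng):
        frame = make_frame(rng.uniform(-10, 10, size=(20, 3)))
        value, _ = kabsch_rmsd(frame, frame)
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_is_zero(self, rng):
        frame = make_frame(rng.uniform(-10, 10, size=(20, 3)))
        moved, _, _ = rigid_motion(frame, rng)
        value, _ = kabsch_rmsd(frame, moved)
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 40))
            a = rng.uniform(-15, 15, size=(n, 3))
            b = a + rng.normal(scale=rng.uniform(0.1, 3.0), size=(n, 3))
            value, _ = kabsch_rmsd(make_frame(a), make_frame(b))
            assert value == pytest.approx(
                _quaternion_rmsd_oracle(a, b), abs=1e-9
            )

    def test_single_displaced_site(self, rng):
        a = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10.0]])
        b = a.copy()
        b[3] += [0, 0, 3.0]
        value, _ = kabsch_rmsd(make_frame(a), make_frame(b))
        assert value == pytest.approx(_quaternion_rmsd_oracle(a, b), abs=1e-9)

    def test_symmetric(self, rng):
        a = rng.uniform(-10, 10, size=(15, 3))
        b = rng.uniform(-10, 10, size=(15, 3))
        va, _ = kabsch_rmsd(make_frame(a), make_frame(b))
        vb, _ = kabsch_rmsd(make_frame(b), make_frame(a))
        assert va == pytest.approx(vb, abs=1e-9)

    def test_count_mismatch(self, rng):
        with pytest.raises(ShapeError):
            kabsch_rmsd(make_frame(rng.uniform(size=(4, 3))),
                        make_frame(rng.uniform(size=(5, 3))))

    def test_too_few_sites(self):
        with pytest.raises(ShapeError):
            kabsch_rmsd(make_frame([[0, 0, 0], [1, 1, 1.0]]),
                        make_frame([[0, 0, 0], [1, 1, 1.0]]))


class TestAverageStructure:
    def test_single_frame_window(self, rng):
        frame = make_frame(rng.uniform(-10, 10, size=(8, 3)))
        avg = average_structure(Trajectory(frames=[frame]))
        np.testing.assert_allclose(avg.coords, frame.coords, atol=1e-12)

    def test_mirror_displaced_pair_gives_midpoint(self):
        # radial, zero-mean displacements keep the Kabsch cross-covariance
        # symmetric, so the superposition is exactly the identity and the
        # average is exactly the midpoint structure
        base = 10.0 * np.vstack([np.eye(3), -np.eye(3)])
        d = np.zeros_like(base)
        d[0, 0] = 1.0
        d[3, 0] = -1.0
        traj = Trajectory(frames=[make_frame(base + d), make_frame(base - d)])
        avg = average_structure(traj)
        np.testing.assert_allclose(avg.coords, base, atol=1e-9)

    def test_rigid_copies_average_to_the_frame(self, rng):
        frame = make_frame(rng.uniform(-10, 10, size=(10, 3)))
        moved = [rigid_motion(frame, rng)[0] for _ in range(4)]
        avg = average_structure(Trajectory(frames=[frame, *moved]))
        np.testing.assert_allclose(avg.coords, frame.coords, atol=1e-9)

    def test_empty_window(self, rng):
        frame = make_frame(rng.uniform(size=(4, 3)))
        with pytest.raises(EmptyInputError):
            average_structure(Trajectory(frames=[frame]), slice(5, 5))


class TestBendTwistSeries:
    def test_constant_scaffold_trajectory(self):
        frame, domains = build_scaffold(
            ScaffoldSpec(bend_deg=139.0, twist_deg=8.0), seed=1
        )
        traj = Trajectory(frames=[frame] * 5)
        series = bend_twist_series(traj, domains)
        np.testing.assert_allclose(series.bend, 139.0, atol=1e-6)
        np.testing.assert_allclose(series.twist, 8.0, atol=1e-6)

    def test_sweep_min_max(self):
        """A bend sweep covering the observed 118°–147° arch range is
        reproduced endpoint-exactly."""
        frames = []
        domains = None
        for bend in np.linspace(118.0, 147.0, 8):
            f, domains = build_scaffold(
                ScaffoldSpec(bend_deg=float(bend), twist_deg=0.0), seed=4
            )
            frames.append(f)
        series = bend_twist_series(Trajectory(frames=frames), domains)
        assert series.bend.min() == pytest.approx(118.0, abs=1e-6)
        assert series.bend.max() == pytest.approx(147.0, abs=1e-6)

    def test_windows_of_a_stationary_series_agree(self, rng):
        """Four windows of a stationary bend series have means within
        3 standard errors of each other (convergence-style check)."""
        bends = 139.0 + rng.normal(0, 4.0, size=2000)
        frames = []
        domains = None
        for b in np.clip(bends, 95, 175):
            f, domains = build_scaffold(
                ScaffoldSpec(bend_deg=float(b), twist_deg=0.0),
                seed=7,
            )
            frames.append(f)
        windows = bend_twist_series(
            Trajectory(frames=frames), domains, n_windows=4
        )
        means = [w.bend.mean() for w in windows]
        se = 4.0 / np.sqrt(500)
        for m in means:
            assert abs(m - np.mean(means)) < 3 * se
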