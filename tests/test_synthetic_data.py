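"""The synthetic generator: target-exact geometry, ground-truth consistency,
determinism, and Markov state sampling."""

import numpy as np
import pytest

from cetptraj.errors import GeometryError, ShapeError
from cetptraj.lipid_geometry import (
    assign_roles,
    compute_chain_vectors,
    inter_chain_angles,
)
from cetptraj.state_classifier import (
    OrientationLabel,
    PairOrientationLabel,
    classification_accuracy,
    classify_orientation,
    classify_trajectory_pair,
)
from cetptraj.synthetic_data import (
    PAIR_TO_SINGLE,
    ScaffoldSpec,
    SyntheticTGSpec,
    TrajectorySpec,
    build_pair_arrangement,
    build_scaffold,
    build_tg,
    generate_trajectory,
)

AXIS = np.array([1.0, 0.0, 0.0])


def realized_angles(frame, topo, axis=AXIS):
    triple = assign_roles(compute_chain_vectors(frame, topo), axis)
    return inter_chain_angles(triple)


class TestBuildTG:
    @pytest.mark.parametrize("a13,a23", [
        (30.0, 135.0),     # tuning fork signature
        (30.0, 30.0),      # trident signature
        (75.0, 85.0),      # random-conformation signature
        (0.0, 180.0),      # degenerate: sn1/sn3 coincident, sn2 opposite
    ])
    def test_target_angles_realized_exactly(self, a13, a23):
        spec = SyntheticTGSpec(target_sn1sn3=a13, target_sn2sn3=a23)
        frame, topo = build_tg(spec, seed=13)
        x13, x23, _ = realized_angles(frame, topo)
        assert x13 == pytest.approx(a13, abs=1e-6)
        assert x23 == pytest.approx(a23, abs=1e-6)

    def test_azimuth_seed_changes_geometry_not_angles(self):
        spec = SyntheticTGSpec()
        f1, t1 = build_tg(spec, seed=1)
        f2, t2 = build_tg(spec, seed=2)
        assert not np.allclose(f1.coords, f2.coords)
        np.testing.assert_allclose(
            realized_angles(f1, t1), realized_angles(f2, t2), atol=1e-9
        )

    def test_cg_variant_bead_names(self):
        spec = SyntheticTGSpec(representation="coarse_grained")
        frame, topo = build_tg(spec, seed=0)
        assert frame.n_sites == 13
        names = set(frame.site_name.tolist())
        assert {"GLY", "ES1", "ES2", "ES3", "D2A", "D2B", "D2C"} <= names
        # D-beads sit exactly at the chain-vector tips
        vecs = compute_chain_vectors(frame, topo)
        np.testing.assert_allclose(
            np.linalg.norm(vecs, axis=1), spec.chain_length, atol=1e-9
        )

    def test_atomistic_double_bond_pair_straddles_tip(self):
        frame, topo = build_tg(SyntheticTGSpec(), seed=0)
        for (i, j) in topo.chain_sites:
            gap = np.linalg.norm(frame.coords[i] - frame.coords[j])
            assert gap == pytest.approx(0.7, abs=1e-9)

    def test_out_of_range_target_rejected(self):
        with pytest.raises(GeometryError):
            SyntheticTGSpec(target_sn1sn3=200.0)


class TestPairArrangement:
    @pytest.mark.parametrize("label", [
        "PARALLEL_NN", "ANTIPARALLEL_NC", "PARALLEL_CC", "ANTIPARALLEL_CN",
    ])
    def test_orientations_classify_to_their_label(self, label):
        frame, (topo_n, topo_c), (start, end) = build_pair_arrangement(
            label, seed=9
        )
        axis = end - start
        o_n = classify_orientation(realized_angles(frame, topo_n, axis)[0])
        o_c = classify_orientation(realized_angles(frame, topo_c, axis)[0])
        expect_n, expect_c = PAIR_TO_SINGLE[PairOrientationLabel(label)]
        assert o_n is expect_n
        assert o_c is expect_c

    def test_half_axis_placement(self):
        frame, (topo_n, topo_c), _ = build_pair_arrangement(
            "PARALLEL_NN", axis_length=60.0, seed=1
        )
        sep = np.linalg.norm(
            frame.coords[topo_c.central_site] - frame.coords[topo_n.central_site]
        )
        assert sep == pytest.approx(30.0, abs=1e-9)

    def test_random_pair_has_no_single_geometry(self):
        with pytest.raises(GeometryError):
            build_pair_arrangement("RANDOM", seed=0)


class TestScaffoldSpec:
    def test_unrealizable_pair_rejected(self):
        with pytest.raises(GeometryError):
            ScaffoldSpec(bend_deg=20.0, twist_deg=45.0)

    def test_straight_with_twist_rejected(self):
        with pytest.raises(GeometryError):
            ScaffoldSpec(bend_deg=180.0, twist_deg=10.0)

    def test_build_deterministic(self):
        f1, _ = build_scaffold(ScaffoldSpec(), seed=8)
        f2, _ = build_scaffold(ScaffoldSpec(), seed=8)
        np.testing.assert_array_equal(f1.coords, f2.coords)


class TestGenerateTrajectory:
    def test_noise_truncation_bounds_the_angles(self):
        """Fork signature 30° with each chain vector rotated ≤ 20° keeps
        every sn1-sn3 angle below 30 + 2·20 = 70 < 75 (head threshold)."""
        spec = TrajectorySpec(
            n_frames=1000,
            state_sequence=["PARALLEL_NN"] * 1000,
            angular_noise_sigma=10.0,
            noise_truncation=20.0,
            seed=42,
        )
        _, truth = generate_trajectory(spec)
        assert truth.sn1sn3_N.max() < 75.0
        assert truth.sn1sn3_C.max() < 75.0

    def test_zero_sigma_realizes_signatures_exactly(self):
        spec = TrajectorySpec(
            n_frames=10, state_sequence=["PARALLEL_NN"] * 10,
            angular_noise_sigma=0.0, seed=3,
        )
        _, truth = generate_trajectory(spec)
        np.testing.assert_allclose(truth.sn1sn3_N, 30.0, atol=1e-6)
        np.testing.assert_allclose(truth.sn2sn3_N, 135.0, atol=1e-6)

    def test_same_seed_bit_identical(self):
        spec = TrajectorySpec(
            n_frames=20, state_sequence=["ANTIPARALLEL_NC"] * 20,
            angular_noise_sigma=10.0, noise_truncation=20.0, seed=5,
        )
        t1, _ = generate_trajectory(spec)
        t2, _ = generate_trajectory(spec)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_legs_states_realize_obtuse_sn1sn3(self):
        spec = TrajectorySpec(
            n_frames=10, state_sequence=["PARALLEL_CC"] * 10,
            angular_noise_sigma=0.0, seed=1,
        )
        _, truth = generate_trajectory(spec)
        assert np.all(truth.sn1sn3_N >= 105.0)
        assert np.all(truth.sn1sn3_C >= 105.0)

    def test_ground_truth_recovery_is_exact_inside_margins(self):
        """With truncation small against every threshold margin, the
        classifier recovers the generator labels perfectly."""
        states = (["PARALLEL_NN"] * 50 + ["ANTIPARALLEL_NC"] * 50 +
                  ["PARALLEL_CC"] * 50 + ["ANTIPARALLEL_CN"] * 50 +
                  ["RANDOM"] * 50)
        spec = TrajectorySpec(
            n_frames=250, state_sequence=states,
            angular_noise_sigma=3.0, noise_truncation=5.0, seed=77,
        )
        _, truth = generate_trajectory(spec)
        o_n, o_c, pairs = classify_trajectory_pair(
            truth.sn1sn3_N, truth.sn1sn3_C
        )
        assert classification_accuracy(o_n, truth.orientation_N) == 1.0
        assert classification_accuracy(o_c, truth.orientation_C) == 1.0
        assert classification_accuracy(pairs, truth.pair) == 1.0

    def test_accuracy_degrades_beyond_the_threshold_margin(self):
        """Untruncated noise far above the 45° head-state margin must
        produce misclassifications."""
        spec = TrajectorySpec(
            n_frames=400, state_sequence=["PARALLEL_NN"] * 400,
            angular_noise_sigma=60.0, noise_truncation=None, seed=21,
        )
        _, truth = generate_trajectory(spec)
        _, _, pairs = classify_trajectory_pair(
            truth.sn1sn3_N, truth.sn1sn3_C
        )
        assert classification_accuracy(pairs, truth.pair) < 1.0

    def test_scaffold_included_when_requested(self):
        spec = TrajectorySpec(
            n_frames=3, state_sequence=["PARALLEL_NN"] * 3,
            angular_noise_sigma=0.0, seed=2,
        )
        traj, truth = generate_trajectory(
            spec, scaffold_spec=ScaffoldSpec(bend_deg=139.0, twist_deg=8.0)
        )
        assert truth.scaffold_domains is not None
        from cetptraj.protein_descriptors import bending_angle
        assert bending_angle(traj[0], truth.scaffold_domains) == \
            pytest.approx(139.0, abs=1e-6)

    def test_bad_transition_matrix_rejected(self):
        with pytest.raises(ShapeError):
            TrajectorySpec(
                n_frames=10,
                transition_matrix=np.array([[0.5, 0.4], [0.5, 0.5]]),
            )

    def test_random_state_samples_the_random_band(self):
        spec = TrajectorySpec(
            n_frames=60, state_sequence=["RANDOM"] * 60,
            angular_noise_sigma=0.0, seed=6,
        )
        _, truth = generate_trajectory(spec)
        in_band_n = (truth.sn1sn3_N >= 75.0) & (truth.sn1sn3_N < 105.0)
        in_band_c = (truth.sn1sn3_C >= 75.0) & (truth.sn1sn3_C < 105.0)
        # exactly one TG per frame sits in the random band
        assert np.all(in_band_n ^ in_band_c)
        assert all(p is PairOrientationLabel.RANDOM for p in truth.pair)
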