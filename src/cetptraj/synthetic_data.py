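"""Synthetic TG/protein geometries and labelled trajectories.

The study conditions this generator emulates: two triolein molecules bound
in a 60 Å protein tunnel, each in a tuning-fork-like, trident or random
conformation, jointly occupying one of five pair-orientation states; a
three-domain protein scaffold with prescribed bend/twist; angular Gaussian
noise on the chain vectors with a hard truncation bound; and per-frame
ground-truth labels known by construction.

Chain vectors are realized in a canonical local frame — sn1 along the
tunnel axis toward the C-terminal side, sn2/sn3 placed by the two target
inter-chain angles in a fixed half-plane — then rotated by a seeded random
azimuth about the axis, so geometries are reproducible yet non-degenerate.
Legs-to-head orientations are the same construction flipped 180° about a
perpendicular axis. Noise rotates each chain vector by |N(0, σ)| degrees
(optionally hard-truncated) about a uniform random perpendicular axis,
preserving chain lengths.

Signature angles: tuning fork (sn1-sn3, sn2-sn3) = (30°, 135°); trident
(30°, 30°); random band sn1-sn3 ∈ (76°, 104°) with sn2-sn3 near 85° —
the observed peak positions for bound triolein. All configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import EmptyInputError, GeometryError, ShapeError
from .io_core import MolecularFrame, Trajectory, TriglycerideTopology, infer_mass
from .lipid_geometry import assign_roles, compute_chain_vectors, inter_chain_angles
from .protein_descriptors import DomainDefinition
from .state_classifier import (
    ConformationLabel,
    OrientationLabel,
    PairOrientationLabel,
    classify_conformation,
)

Conformation = Literal["tuning_fork", "trident", "random"]
Representation = Literal["atomistic", "coarse_grained"]

#: (sn1-sn3, sn2-sn3) signature angles per conformation, degrees
SIGNATURES = {
    "tuning_fork": (30.0, 135.0),
    "trident": (30.0, 30.0),
    "random": (75.0, 85.0),
}

#: sn1-sn3 band sampled for "random"-orientation TGs in trajectories
RANDOM_BAND = (76.0, 104.0)

PAIR_LABELS = (
    PairOrientationLabel.PARALLEL_NN,
    PairOrientationLabel.ANTIPARALLEL_NC,
    PairOrientationLabel.PARALLEL_CC,
    PairOrientationLabel.ANTIPARALLEL_CN,
    PairOrientationLabel.RANDOM,
)

#: pair state -> (TG_N orientation, TG_C orientation); the RANDOM pair is
#: emitted by sampling which TG sits in the random band
PAIR_TO_SINGLE = {
    PairOrientationLabel.PARALLEL_NN:
        (OrientationLabel.HEAD_TO_LEGS, OrientationLabel.HEAD_TO_LEGS),
    PairOrientationLabel.ANTIPARALLEL_NC:
        (OrientationLabel.HEAD_TO_LEGS, OrientationLabel.LEGS_TO_HEAD),
    PairOrientationLabel.PARALLEL_CC:
        (OrientationLabel.LEGS_TO_HEAD, OrientationLabel.LEGS_TO_HEAD),
    PairOrientationLabel.ANTIPARALLEL_CN:
        (OrientationLabel.LEGS_TO_HEAD, OrientationLabel.HEAD_TO_LEGS),
}


@dataclass
class SyntheticTGSpec:
    """Target geometry of one synthetic triolein."""

    conformation: Conformation = "tuning_fork"
    target_sn1sn3: float | None = None
    target_sn2sn3: float | None = None
    chain_length: float = 12.0   # Å, central site to double-bond midpoint
    representation: Representation = "atomistic"

    def __post_init__(self) -> None:
        sig = SIGNATURES.get(self.conformation)
        if sig is None:
            raise ShapeError(f"unknown conformation {self.conformation!r}")
        if self.target_sn1sn3 is None:
            self.target_sn1sn3 = sig[0]
        if self.target_sn2sn3 is None:
            self.target_sn2sn3 = sig[1]
        for a in (self.target_sn1sn3, self.target_sn2sn3):
            if not (0.0 <= a <= 180.0):
                raise GeometryError(f"target angle {a} outside [0, 180]")
        if self.chain_length <= 0:
            raise GeometryError("chain length must be positive")


@dataclass
class ScaffoldSpec:
    """Three-domain protein scaffold with prescribed bend/twist."""

    bend_deg: float = 139.0
    twist_deg: float = 8.0
    domain_site_counts: tuple = (24, 16, 24)
    arm_length: float = 30.0   # Å, central COM to each barrel COM

    def __post_init__(self) -> None:
        if not (0.0 < self.bend_deg <= 180.0):
            raise GeometryError("bend must lie in (0, 180]")
        if not (-90.0 < self.twist_deg < 90.0):
            raise GeometryError("twist must lie in (-90, 90)")
        if self.bend_deg < abs(self.twist_deg):
            raise GeometryError(
                f"bend {self.bend_deg}° < |twist| {abs(self.twist_deg)}°: "
                "no off-axis barrel placement realizes this pair"
            )
        if self.bend_deg == 180.0 and self.twist_deg != 0.0:
            raise GeometryError("a fully straight scaffold cannot twist")
        if len(self.domain_site_counts) != 3 or \
                any(c < 2 for c in self.domain_site_counts):
            raise GeometryError("each domain needs at least 2 sites")
        if self.arm_length <= 0:
            raise GeometryError("arm length must be positive")


@dataclass
class TrajectorySpec:
    """Stochastic structure of a labelled synthetic trajectory."""

    n_frames: int
    state_sequence: Sequence | None = None
    transition_matrix: np.ndarray | None = None
    angular_noise_sigma: float = 10.0   # degrees
    noise_truncation: float | None = 20.0  # degrees, hard bound; None = untruncated
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ShapeError("n_frames must be positive")
        if (self.state_sequence is None) == (self.transition_matrix is None):
            raise ShapeError(
                "provide exactly one of state_sequence / transition_matrix"
            )
        if self.state_sequence is not None and \
                len(self.state_sequence) != self.n_frames:
            raise ShapeError("state_sequence length must equal n_frames")
        if self.transition_matrix is not None:
            t = np.asarray(self.transition_matrix, dtype=float)
            if t.ndim != 2 or t.shape[0] != t.shape[1]:
                raise ShapeError("transition matrix must be square")
            if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
                raise ShapeError("transition matrix rows must sum to 1")
            self.transition_matrix = t
        if self.angular_noise_sigma < 0:
            raise ShapeError("noise sigma must be >= 0")


@dataclass
class GroundTruth:
    """Per-frame generator-side truth for a synthetic trajectory."""

    pair: list                      # PairOrientationLabel per frame
    orientation_N: list
    orientation_C: list
    conformation_N: list
    conformation_C: list
    sn1sn3_N: np.ndarray
    sn2sn3_N: np.ndarray
    sn1sn3_C: np.ndarray
    sn2sn3_C: np.ndarray
    axis: np.ndarray                # declared N->C tunnel axis (unit)
    topologies: tuple = ()          # TriglycerideTopology per TG
    scaffold_domains: DomainDefinition | None = None


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = np.radians(angle_deg)
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _unit_perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random unit vector perpendicular to v."""
    v = v / np.linalg.norm(v)
    r = rng.normal(size=3)
    p = r - np.dot(r, v) * v
    n = np.linalg.norm(p)
    while n < 1e-12:
        r = rng.normal(size=3)
        p = r - np.dot(r, v) * v
        n = np.linalg.norm(p)
    return p / n


def _chain_directions(
    a13: float, a23: float, azimuth_deg: float, flip: bool
) -> np.ndarray:
    """Unit chain directions (raw order: sn1-, sn2-, sn3-destined) in the
    lab frame with the tunnel axis along +x."""
    t3 = np.radians(a13)
    t2 = np.radians(a13 + a23)
    dirs = np.array(
        [
            [1.0, 0.0, 0.0],
            [np.cos(t2), np.sin(t2), 0.0],
            [np.cos(t3), np.sin(t3), 0.0],
        ]
    )
    rot = _rotation_about(np.array([1.0, 0.0, 0.0]), azimuth_deg)
    dirs = dirs @ rot.T
    if flip:
        # 180° about z: head/legs direction reverses along the tunnel axis
        dirs = dirs * np.array([-1.0, -1.0, 1.0])
    return dirs


def _assemble_tg(
    directions: np.ndarray,
    center: np.ndarray,
    chain_length: float,
    representation: Representation,
    residue_id: int,
    chain_id: str,
    index_offset: int = 0,
) -> tuple[MolecularFrame, TriglycerideTopology]:
    """Place TG sites along three unit chain directions from a center."""
    tips = center + chain_length * directions
    esters = center + (chain_length / 3.0) * directions
    if representation == "atomistic":
        names = ["C2", "C1A", "C1B", "C1C"]
        coords = [center, esters[0], esters[1], esters[2]]
        for k, suffix in enumerate("ABC"):
            # two C=C carbons straddling the tip, 0.7 Å apart, perpendicular
            # to the chain so their midpoint is exactly the tip
            perp = _fixed_perpendicular(directions[k])
            coords.append(tips[k] - 0.35 * perp)
            coords.append(tips[k] + 0.35 * perp)
            names.extend([f"C9{suffix}", f"C10{suffix}"])
        topo = TriglycerideTopology(
            central_site=index_offset + 0,
            chain_sites=(
                (index_offset + 4, index_offset + 5),
                (index_offset + 6, index_offset + 7),
                (index_offset + 8, index_offset + 9),
            ),
            ester_sites=(index_offset + 1, index_offset + 2, index_offset + 3),
            representation="atomistic",
        )
    else:
        names = ["GLY", "ES1", "ES2", "ES3"]
        coords = [center, esters[0], esters[1], esters[2]]
        chain_bead_indices = []
        idx = 4
        for k, suffix in enumerate("ABC"):
            coords.append(center + 0.5 * chain_length * directions[k])
            coords.append(tips[k])  # D-bead exactly at the vector tip
            coords.append(center + 1.5 * chain_length * directions[k])
            names.extend([f"C1{suffix}", f"D2{suffix}", f"C3{suffix}"])
            chain_bead_indices.append(index_offset + idx + 1)
            idx += 3
        topo = TriglycerideTopology(
            central_site=index_offset + 0,
            chain_sites=tuple(chain_bead_indices),
            ester_sites=(index_offset + 1, index_offset + 2, index_offset + 3),
            representation="coarse_grained",
        )
    n = len(coords)
    frame = MolecularFrame(
        coords=np.array(coords),
        site_name=np.array(names),
        residue_id=np.full(n, residue_id, dtype=int),
        residue_name=np.full(n, "TGL"),
        chain_id=np.full(n, chain_id),
        mass=np.array([infer_mass(nm) for nm in names]),
    )
    return frame, topo


def _fixed_perpendicular(v: np.ndarray) -> np.ndarray:
    """Deterministic unit perpendicular of v."""
    v = v / np.linalg.norm(v)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(v, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, helper)
    return p / np.linalg.norm(p)


def build_tg(
    spec: SyntheticTGSpec,
    seed: int | np.random.Generator = 0,
    center: np.ndarray | None = None,
    flip: bool = False,
    residue_id: int = 1,
    chain_id: str = "L",
) -> tuple[MolecularFrame, TriglycerideTopology]:
    """Build one TG whose realized sn1-sn3 / sn2-sn3 angles equal the spec
    targets to within 1e-6°, head-to-legs along +x (``flip=True`` for
    legs-to-head)."""
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    azimuth = float(rng.uniform(0.0, 360.0))
    dirs = _chain_directions(
        spec.target_sn1sn3, spec.target_sn2sn3, azimuth, flip
    )
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    return _assemble_tg(
        dirs, center, spec.chain_length, spec.representation,
        residue_id, chain_id,
    )


def _offset_topology(
    topo: TriglycerideTopology, offset: int
) -> TriglycerideTopology:
    """Shift every site index of a TG topology by a constant."""
    if topo.representation == "atomistic":
        chains = tuple((i + offset, j + offset) for i, j in topo.chain_sites)
    else:
        chains = tuple(int(e) + offset for e in topo.chain_sites)
    return TriglycerideTopology(
        central_site=topo.central_site + offset,
        chain_sites=chains,
        ester_sites=tuple(i + offset for i in topo.ester_sites),
        representation=topo.representation,
    )


def concatenate_frames(frames: Sequence[MolecularFrame]) -> MolecularFrame:
    """Stack several frames' sites into one frame."""
    if not frames:
        raise EmptyInputError("nothing to concatenate")
    return MolecularFrame(
        coords=np.vstack([f.coords for f in frames]),
        site_name=np.concatenate([f.site_name for f in frames]),
        residue_id=np.concatenate([f.residue_id for f in frames]),
        residue_name=np.concatenate([f.residue_name for f in frames]),
        chain_id=np.concatenate([f.chain_id for f in frames]),
        mass=np.concatenate([f.mass for f in frames]),
    )


def build_pair_arrangement(
    pair_label: PairOrientationLabel | str,
    axis_length: float = 60.0,
    seed: int | np.random.Generator = 0,
    tg_spec: SyntheticTGSpec | None = None,
) -> tuple[MolecularFrame, tuple, tuple]:
    """Two tuning-fork TGs placed in the tunnel in a prescribed pair state.

    TG_N sits at the quarter point of the axis, TG_C at the three-quarter
    point (half-axis placement: central sites axis_length/2 apart). Returns
    ``(frame, (topo_N, topo_C), (axis_start, axis_end))``.
    """
    pair_label = PairOrientationLabel(pair_label)
    if pair_label is PairOrientationLabel.RANDOM:
        raise GeometryError(
            "the RANDOM pair state has no single defining geometry; "
            "use generate_trajectory for random-band sampling"
        )
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    spec = tg_spec or SyntheticTGSpec(conformation="tuning_fork")
    o_n, o_c = PAIR_TO_SINGLE[pair_label]
    axis_start = np.zeros(3)
    axis_end = np.array([axis_length, 0.0, 0.0])
    frame_n, topo_n = build_tg(
        spec, rng, center=np.array([axis_length / 4.0, 0.0, 0.0]),
        flip=(o_n is OrientationLabel.LEGS_TO_HEAD),
        residue_id=1, chain_id="N",
    )
    frame_c, topo_c = build_tg(
        spec, rng, center=np.array([3.0 * axis_length / 4.0, 0.0, 0.0]),
        flip=(o_c is OrientationLabel.LEGS_TO_HEAD),
        residue_id=2, chain_id="C",
    )
    offset = frame_n.n_sites
    topo_c = _offset_topology(topo_c, offset)
    frame = concatenate_frames([frame_n, frame_c])
    return frame, (topo_n, topo_c), (axis_start, axis_end)


def build_scaffold(
    spec: ScaffoldSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[MolecularFrame, DomainDefinition]:
    """Three rigid point clouds whose COMs realize the prescribed bend and
    twist exactly (to floating-point).

    The protein axis runs along +x between the central sheet's two
    end-cloud COMs. Solving the COM geometry for a bend θ and twist θ_t
    gives barrel polar angles γ with sin²γ = (1 + cos θ)/(1 + cos θ_t);
    realizable whenever θ ≥ |θ_t|.
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    b = np.radians(spec.bend_deg)
    t = np.radians(spec.twist_deg)
    sin2 = (1.0 + np.cos(b)) / (1.0 + np.cos(t))
    if sin2 > 1.0 + 1e-12:
        raise GeometryError(
            f"(bend={spec.bend_deg}°, twist={spec.twist_deg}°) has no "
            "off-axis realization"
        )
    gamma = np.arcsin(np.sqrt(min(sin2, 1.0)))
    L = spec.arm_length
    r_n = L * np.array([-np.cos(gamma), np.sin(gamma), 0.0])
    r_c = L * np.array(
        [np.cos(gamma), np.sin(gamma) * np.cos(t), np.sin(gamma) * np.sin(t)]
    )

    n_n, n_central, n_c = spec.domain_site_counts
    k1 = n_central // 2
    k2 = n_central - k1
    half_sep = max(L / 3.0, 4.0)
    end_n_com = np.array([-half_sep, 0.0, 0.0])
    end_c_com = np.array([half_sep, 0.0, 0.0])
    central_com = (k1 * end_n_com + k2 * end_c_com) / n_central

    def cloud(com: np.ndarray, count: int) -> np.ndarray:
        offsets = rng.normal(scale=1.0, size=(count, 3))
        offsets -= offsets.mean(axis=0)   # COM lands exactly on `com`
        return com + offsets

    coords = np.vstack(
        [
            cloud(central_com + r_n, n_n),
            cloud(end_n_com, k1),
            cloud(end_c_com, k2),
            cloud(central_com + r_c, n_c),
        ]
    )
    n_total = n_n + n_central + n_c
    residue_id = np.arange(1, n_total + 1)
    frame = MolecularFrame(
        coords=coords,
        site_name=np.full(n_total, "CA"),
        residue_id=residue_id,
        residue_name=np.full(n_total, "ALA"),
        chain_id=np.full(n_total, "A"),
        mass=np.full(n_total, 12.011),
    )
    domains = DomainDefinition(
        n_barrel=((1, n_n),),
        central_sheet=((n_n + 1, n_n + n_central),),
        c_barrel=((n_n + n_central + 1, n_total),),
        n_end=((n_n + 1, n_n + k1),),
        c_end=((n_n + k1 + 1, n_n + n_central),),
    )
    return frame, domains


def _sample_states(
    spec: TrajectorySpec, labels: tuple, rng: np.random.Generator
) -> list:
    """Explicit sequence, or a Markov chain started from its stationary
    distribution."""
    if spec.state_sequence is not None:
        return [
            lab if isinstance(lab, PairOrientationLabel)
            else PairOrientationLabel(lab)
            for lab in spec.state_sequence
        ]
    t = spec.transition_matrix
    if t.shape[0] != len(labels):
        raise ShapeError(
            f"transition matrix is {t.shape[0]}x{t.shape[0]}, expected "
            f"{len(labels)} states"
        )
    pi = stationary_distribution(t)
    states = [int(rng.choice(len(labels), p=pi))]
    for _ in range(spec.n_frames - 1):
        states.append(int(rng.choice(len(labels), p=t[states[-1]])))
    return [labels[s] for s in states]


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Left Perron eigenvector of a row-stochastic matrix, normalised."""
    t = np.asarray(transition_matrix, dtype=float)
    w, v = np.linalg.eig(t.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _noisy_directions(
    dirs: np.ndarray,
    sigma: float,
    truncation: float | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rotate each chain direction by |N(0, σ)| (hard-truncated) degrees
    about a uniform random perpendicular axis."""
    if sigma == 0.0:
        return dirs
    out = np.empty_like(dirs)
    for k in range(len(dirs)):
        angle = abs(rng.normal(0.0, sigma))
        if truncation is not None:
            angle = min(angle, truncation)
        axis = _unit_perpendicular(dirs[k], rng)
        out[k] = _rotation_about(axis, angle) @ dirs[k]
    return out


def generate_trajectory(
    traj_spec: TrajectorySpec,
    tg_spec: SyntheticTGSpec | None = None,
    scaffold_spec: ScaffoldSpec | None = None,
    axis_length: float = 60.0,
) -> tuple[Trajectory, GroundTruth]:
    """Labelled two-TG trajectory with truncated-Gaussian angular noise.

    Each frame realizes the frame's pair state as two TG geometries (fork
    signature for head/legs orientations; one TG sampled in the random band
    for the RANDOM pair state), perturbs the chain vectors, and optionally
    prepends a static scaffold. Deterministic for a fixed spec seed.
    """
    rng = np.random.default_rng(traj_spec.seed)
    spec = tg_spec or SyntheticTGSpec(conformation="tuning_fork")
    states = _sample_states(traj_spec, PAIR_LABELS, rng)

    scaffold_frame = None
    scaffold_domains = None
    if scaffold_spec is not None:
        scaffold_frame, scaffold_domains = build_scaffold(scaffold_spec, rng)

    axis = np.array([1.0, 0.0, 0.0])
    centers = (
        np.array([axis_length / 4.0, 0.0, 0.0]),
        np.array([3.0 * axis_length / 4.0, 0.0, 0.0]),
    )
    chain_ids = ("N", "C")

    frames: list[MolecularFrame] = []
    gt_orient = ([], [])
    gt_conf = ([], [])
    gt_angles = ([[], []], [[], []])   # [tg][a13/a23]
    topologies = None

    for state in states:
        if state is PairOrientationLabel.RANDOM:
            which_random = int(rng.integers(0, 2))
            orients = [OrientationLabel.HEAD_TO_LEGS, OrientationLabel.HEAD_TO_LEGS]
            orients[which_random] = OrientationLabel.RANDOM
        else:
            orients = list(PAIR_TO_SINGLE[state])
        tg_frames = []
        tg_topos = []
        for tg_i in (0, 1):
            orient = orients[tg_i]
            if orient is OrientationLabel.RANDOM:
                # shrink the sampled band by the worst-case angle change a
                # truncated noise rotation of both chain vectors can cause,
                # so the RANDOM label stays consistent with the realized
                # angle whenever the noise bound itself is
                lo, hi = RANDOM_BAND
                mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
                if traj_spec.angular_noise_sigma > 0 and \
                        traj_spec.noise_truncation is not None:
                    half = max(0.0, half - 2.0 * traj_spec.noise_truncation)
                a13 = float(rng.uniform(mid - half, mid + half))
                a23 = SIGNATURES["random"][1]
            else:
                a13, a23 = spec.target_sn1sn3, spec.target_sn2sn3
            azimuth = float(rng.uniform(0.0, 360.0))
            dirs = _chain_directions(
                a13, a23, azimuth,
                flip=(orient is OrientationLabel.LEGS_TO_HEAD),
            )
            dirs = _noisy_directions(
                dirs, traj_spec.angular_noise_sigma,
                traj_spec.noise_truncation, rng,
            )
            offset = (scaffold_frame.n_sites if scaffold_frame is not None else 0) \
                + (tg_frames[0].n_sites if tg_frames else 0)
            f, topo = _assemble_tg(
                dirs, centers[tg_i], spec.chain_length, spec.representation,
                residue_id=1000 + tg_i, chain_id=chain_ids[tg_i],
                index_offset=offset,
            )
            tg_frames.append(f)
            tg_topos.append(topo)
            gt_orient[tg_i].append(orient)
        parts = ([scaffold_frame] if scaffold_frame is not None else []) + tg_frames
        frame = concatenate_frames(parts)
        frames.append(frame)
        if topologies is None:
            topologies = tuple(tg_topos)
        for tg_i in (0, 1):
            raw = compute_chain_vectors(frame, topologies[tg_i])
            triple = assign_roles(raw, axis)
            a13r, a23r, _ = inter_chain_angles(triple)
            gt_angles[tg_i][0].append(a13r)
            gt_angles[tg_i][1].append(a23r)
            if gt_orient[tg_i][-1] is OrientationLabel.RANDOM:
                gt_conf[tg_i].append(ConformationLabel.RANDOM)
            elif spec.conformation == "trident":
                gt_conf[tg_i].append(ConformationLabel.TRIDENT)
            else:
                gt_conf[tg_i].append(ConformationLabel.FORK_LIKE)

    traj = Trajectory(frames=frames)
    truth = GroundTruth(
        pair=states,
        orientation_N=gt_orient[0],
        orientation_C=gt_orient[1],
        conformation_N=gt_conf[0],
        conformation_C=gt_conf[1],
        sn1sn3_N=np.array(gt_angles[0][0]),
        sn2sn3_N=np.array(gt_angles[0][1]),
        sn1sn3_C=np.array(gt_angles[1][0]),
        sn2sn3_C=np.array(gt_angles[1][1]),
        axis=axis,
        topologies=topologies,
        scaffold_domains=scaffold_domains,
    )
    return traj, truth
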