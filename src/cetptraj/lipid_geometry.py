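"""Chain-vector geometry of tunnel-bound triglycerides.

A triolein is described by three vectors drawn from its central site (the
central glycerol carbon, or the GLY bead in the coarse-grained mapping) to
each oleoyl chain's C=C double-bond midpoint (or D-bead). The vectors are
role-labelled against the protein's N→C axis: the chain pointing most
C-ward is sn1, the most N-ward is sn2, and the remaining "swing" chain is
sn3. Inter-chain angles of these role-labelled vectors are the raw material
for conformation and orientation classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, GeometryError, ShapeError
from .io_core import MolecularFrame, Trajectory, TriglycerideTopology

#: chains shorter than this are treated as degenerate
MIN_VECTOR_LENGTH = 0.1  # Å


@dataclass
class ChainVectorTriple:
    """Role-assigned chain vectors for one TG in one frame (Å).

    ``role_permutation[r]`` gives the raw chain index assigned to role ``r``
    (0=sn1, 1=sn2, 2=sn3).
    """

    sn1: np.ndarray
    sn2: np.ndarray
    sn3: np.ndarray
    role_permutation: tuple[int, int, int]

    def __post_init__(self) -> None:
        for name in ("sn1", "sn2", "sn3"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.shape != (3,):
                raise ShapeError(f"{name} must be a 3-vector")
            if np.linalg.norm(v) <= MIN_VECTOR_LENGTH:
                raise GeometryError(f"{name} is degenerate (|v| <= 0.1 Å)")
            setattr(self, name, v)
        if sorted(self.role_permutation) != [0, 1, 2]:
            raise ShapeError("role_permutation must permute {0,1,2}")


def compute_chain_vectors(
    frame: MolecularFrame, topo: TriglycerideTopology
) -> np.ndarray:
    """Raw (3, 3) array of chain vectors, one row per chain in topology order.

    Atomistic: tip is the unweighted midpoint of the two C=C atoms (both
    carbons, so the midpoint is their COM). CG: tip is the D-bead.
    """
    topo.validate_against(frame)
    origin = frame.coords[topo.central_site]
    vectors = np.empty((3, 3))
    for k, entry in enumerate(topo.chain_sites):
        if topo.representation == "atomistic":
            i, j = entry
            tip = 0.5 * (frame.coords[i] + frame.coords[j])
        else:
            tip = frame.coords[int(entry)]
        vectors[k] = tip - origin
        if np.linalg.norm(vectors[k]) <= MIN_VECTOR_LENGTH:
            raise GeometryError(
                f"chain {k}: double-bond tip coincides with the central site"
            )
    return vectors


def assign_roles(
    raw_vectors: np.ndarray, protein_axis: np.ndarray
) -> ChainVectorTriple:
    """Label raw chain vectors sn1/sn2/sn3 by projection on the N→C axis.

    sn1 = largest projection (most C-ward), sn2 = smallest (most N-ward),
    sn3 = the remaining chain. Ties break toward the lower raw index for
    sn1 (stable sort).
    """
    raw_vectors = np.asarray(raw_vectors, dtype=np.float64)
    if raw_vectors.shape != (3, 3):
        raise ShapeError("expected 3 chain vectors")
    axis = np.asarray(protein_axis, dtype=np.float64)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise GeometryError("protein axis must be nonzero")
    axis = axis / norm
    proj = raw_vectors @ axis
    order = np.argsort(-proj, kind="stable")  # descending; ties -> lower index
    i1, i3, i2 = int(order[0]), int(order[1]), int(order[2])
    return ChainVectorTriple(
        sn1=raw_vectors[i1],
        sn2=raw_vectors[i2],
        sn3=raw_vectors[i3],
        role_permutation=(i1, i2, i3),
    )


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees in [0, 180] via the arccos of the normalised dot
    product, clipped against rounding overshoot."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("cannot take the angle of a zero vector")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def inter_chain_angles(triple: ChainVectorTriple) -> tuple[float, float, float]:
    """(sn1-sn3, sn2-sn3, sn1-sn2) angles in degrees."""
    return (
        angle_between(triple.sn1, triple.sn3),
        angle_between(triple.sn2, triple.sn3),
        angle_between(triple.sn1, triple.sn2),
    )


@dataclass
class AngleSeries:
    """Per-frame inter-chain angles (degrees) for one TG."""

    sn1sn3: np.ndarray
    sn2sn3: np.ndarray
    sn1sn2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sn1sn3", "sn2sn3", "sn1sn2"):
            a = np.asarray(getattr(self, name), dtype=np.float64)
            if a.ndim != 1:
                raise ShapeError(f"{name} must be 1-D")
            if a.size and (a.min() < 0 or a.max() > 180):
                raise ShapeError(f"{name} angles must lie in [0, 180]")
            setattr(self, name, a)
        if not (len(self.sn1sn3) == len(self.sn2sn3) == len(self.sn1sn2)):
            raise ShapeError("angle series must share one length")

    @property
    def n_frames(self) -> int:
        return len(self.sn1sn3)


def angle_series(
    traj: Trajectory,
    topo: TriglycerideTopology,
    protein_axis: np.ndarray,
    lock_roles_to_first_frame: bool = False,
) -> AngleSeries:
    """Angle series over a trajectory for one TG.

    Roles are re-assigned every frame by default (the swing chain genuinely
    changes identity over time); ``lock_roles_to_first_frame`` freezes the
    frame-0 permutation for sensitivity checks.
    """
    a13, a23, a12 = [], [], []
    locked = None
    for frame in traj:
        raw = compute_chain_vectors(frame, topo)
        if lock_roles_to_first_frame:
            if locked is None:
                locked = assign_roles(raw, protein_axis).role_permutation
            i1, i2, i3 = locked
            triple = ChainVectorTriple(
                sn1=raw[i1], sn2=raw[i2], sn3=raw[i3],
                role_permutation=(i1, i2, i3),
            )
        else:
            triple = assign_roles(raw, protein_axis)
        x13, x23, x12 = inter_chain_angles(triple)
        a13.append(x13)
        a23.append(x23)
        a12.append(x12)
    return AngleSeries(np.array(a13), np.array(a23), np.array(a12))


def angle_histogram(
    series: np.ndarray, bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Probability-mass histogram of an angle series over [0, 180].

    Returns ``(edges, mass)`` with ``len(edges) == len(mass) + 1``; bins are
    half-open [lo, hi) with the last bin closed at 180; masses sum to 1.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.size == 0:
        raise EmptyInputError("cannot histogram an empty angle series")
    n_bins = 180.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_width} must divide 180 evenly")
    edges = np.linspace(0.0, 180.0, int(round(n_bins)) + 1)
    counts, _ = np.histogram(series, bins=edges)
    return edges, counts / counts.sum()
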