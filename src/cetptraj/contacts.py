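"""Protein–lipid contact accounting under a distance cutoff.

A site–site contact is an unordered (protein site, lipid site) pair within
the cutoff (default 5 Å, the standard hydrophobic-contact criterion).
Residue-level contacts collapse site pairs onto protein residues: a residue
is in contact if any of its sites touches any lipid site, evaluated by
default on a time-averaged structure. Comparisons between lipid systems
(e.g. TG-bound vs CE-bound) report common/gained/lost residues and the
percent change under both denominators, since both conventions appear in
the literature. "Site" means heavy atom in atomistic frames and bead in
coarse-grained ones; distances are plain Euclidean (whole-molecule inputs,
no minimum imaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyInputError, GeometryError, ShapeError
from .io_core import MolecularFrame, Trajectory


@dataclass
class ContactResult:
    """Site-pair contacts for one frame at one cutoff."""

    frame_index: int
    cutoff: float
    pairs: list          # list of (a_site, b_site) index tuples
    residue_set: set = field(default_factory=set)

    @property
    def count(self) -> int:
        return len(self.pairs)


def site_contacts(
    frame: MolecularFrame,
    set_a: Sequence[int],
    set_b: Sequence[int],
    cutoff: float = 5.0,
    frame_index: int = 0,
) -> ContactResult:
    """All unordered (a, b) pairs with Euclidean distance ≤ cutoff.

    Uses a k-d tree internally; results are exactly those of the O(N²)
    double loop. The two site sets must be disjoint.
    """
    if cutoff <= 0:
        raise ShapeError(f"cutoff must be positive, got {cutoff}")
    set_a = np.asarray(set_a, dtype=int)
    set_b = np.asarray(set_b, dtype=int)
    if set_a.size == 0 or set_b.size == 0:
        raise EmptyInputError("contact site sets must be non-empty")
    if set(set_a.tolist()) & set(set_b.tolist()):
        raise ShapeError("contact site sets must be disjoint")
    tree_a = cKDTree(frame.coords[set_a])
    tree_b = cKDTree(frame.coords[set_b])
    sparse = tree_a.query_ball_tree(tree_b, r=cutoff)
    pairs = [
        (int(set_a[i]), int(set_b[j]))
        for i, hits in enumerate(sparse)
        for j in hits
    ]
    pairs.sort()
    return ContactResult(frame_index=frame_index, cutoff=cutoff, pairs=pairs)


def residue_partition(
    frame: MolecularFrame, site_indices: Sequence[int]
) -> dict:
    """Map residue id -> site index list over the given protein sites."""
    part: dict = {}
    for idx in site_indices:
        part.setdefault(int(frame.residue_id[idx]), []).append(int(idx))
    return part


def residue_contacts(
    frame: MolecularFrame,
    lipid_sites: Sequence[int],
    protein_partition: Mapping[int, Sequence[int]],
    cutoff: float = 5.0,
) -> set:
    """Residue ids with ≥ 1 site within cutoff of ≥ 1 lipid site.

    Intended for a time-averaged structure; for per-frame robustness use
    :func:`residue_occupancy` instead.
    """
    if not protein_partition:
        raise EmptyInputError("empty residue partition")
    lipid_sites = np.asarray(lipid_sites, dtype=int)
    if lipid_sites.size == 0:
        raise EmptyInputError("empty lipid site set")
    tree = cKDTree(frame.coords[lipid_sites])
    touched = set()
    for res_id, sites in protein_partition.items():
        d, _ = tree.query(frame.coords[np.asarray(sites, dtype=int)], k=1)
        if np.any(d <= cutoff):
            touched.add(int(res_id))
    return touched


def residue_occupancy(
    traj: Trajectory,
    lipid_sites: Sequence[int],
    protein_partition: Mapping[int, Sequence[int]],
    cutoff: float = 5.0,
    min_fraction: float = 0.5,
) -> set:
    """Residues in contact in at least ``min_fraction`` of frames."""
    counts: dict = {}
    for frame in traj:
        for res in residue_contacts(frame, lipid_sites, protein_partition, cutoff):
            counts[res] = counts.get(res, 0) + 1
    n = traj.n_frames
    return {res for res, c in counts.items() if c / n >= min_fraction}


@dataclass
class ContactComparison:
    """Residue-level contact comparison between a reference system (e.g.
    CE-bound) and a query system (e.g. TG-bound)."""

    common: set
    gained: set
    lost: set
    n_ref: int
    n_query: int
    percent_change_ref_denom: float
    percent_change_query_denom: float


def compare_contacts(ref_set: set, query_set: set) -> ContactComparison:
    """Common/gained/lost residues and percent change of contact counts.

    Both denominators are reported: ``100·(n_query−n_ref)/n_ref`` and
    ``100·(n_query−n_ref)/n_query``.
    """
    ref_set, query_set = set(ref_set), set(query_set)
    common = ref_set & query_set
    gained = query_set - ref_set
    lost = ref_set - query_set
    n_ref, n_query = len(ref_set), len(query_set)
    diff = n_query - n_ref
    pct_ref = 100.0 * diff / n_ref if n_ref else float("nan")
    pct_query = 100.0 * diff / n_query if n_query else float("nan")
    return ContactComparison(
        common=common,
        gained=gained,
        lost=lost,
        n_ref=n_ref,
        n_query=n_query,
        percent_change_ref_denom=pct_ref,
        percent_change_query_denom=pct_query,
    )


def contact_timeseries(
    traj: Trajectory,
    lipid_sites: Sequence[int],
    protein_sites: Sequence[int],
    cutoff: float = 5.0,
) -> np.ndarray:
    """Per-frame site-pair contact counts."""
    return np.array(
        [
            site_contacts(f, protein_sites, lipid_sites, cutoff, i).count
            for i, f in enumerate(traj)
        ],
        dtype=int,
    )


def detect_hbonds(
    frame: MolecularFrame,
    donor_sites: Sequence[int],
    hydrogen_sites: Sequence[int],
    acceptor_sites: Sequence[int],
    d_cut: float = 3.5,
    angle_cut: float = 120.0,
) -> list:
    """Geometric hydrogen bonds: donor–acceptor distance ≤ ``d_cut`` Å and
    donor–H···acceptor angle ≥ ``angle_cut`` degrees.

    ``hydrogen_sites[i]`` must be the hydrogen bonded to ``donor_sites[i]``.
    Returns (donor, hydrogen, acceptor) index triples.
    """
    donor_sites = list(donor_sites)
    hydrogen_sites = list(hydrogen_sites)
    if len(donor_sites) != len(hydrogen_sites):
        raise ShapeError(
            "every hydrogen must be mapped to its donor (equal-length lists)"
        )
    triples = []
    for d_idx, h_idx in zip(donor_sites, hydrogen_sites):
        d_pos = frame.coords[d_idx]
        h_pos = frame.coords[h_idx]
        for a_idx in acceptor_sites:
            if a_idx in (d_idx, h_idx):
                continue
            a_pos = frame.coords[a_idx]
            if np.linalg.norm(a_pos - d_pos) > d_cut:
                continue
            v1 = d_pos - h_pos
            v2 = a_pos - h_pos
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                raise GeometryError("coincident donor/hydrogen/acceptor sites")
            cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
            angle = float(np.degrees(np.arccos(cosang)))
            if angle >= angle_cut:
                triples.append((int(d_idx), int(h_idx), int(a_idx)))
    return triples
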