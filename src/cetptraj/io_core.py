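"""Structure/trajectory I/O and the uniform frame model.

All coordinates are Ångström internally; GRO files (nm on disk) are converted
on read/write by biotite. Two trajectory containers are supported:

* multi-model PDB (``MODEL``/``ENDMDL`` records), read and written via biotite
  at the PDB's native 1e-3 Å precision;
* ``xyzcsv`` — a plain-text dialect for per-frame coordinates: a header line
  ``frame,site,x,y,z`` followed by one row per site per frame, Å units,
  frames contiguous and 0-based. Chosen because the study's native binary
  trajectory formats are not text-reviewable; round-trips exactly.

Periodic-boundary images are never unwrapped here: every analysis assumes
whole molecules, and :func:`check_molecule_integrity` raises instead of
silently minimum-imaging.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.gro import GROFile
from biotite.structure.io.pdb import PDBFile

from .errors import (
    BrokenMoleculeError,
    EmptyInputError,
    FormatError,
    ShapeError,
)

logger = logging.getLogger(__name__)

StructureFormat = Literal["pdb", "gro"]
TrajectoryFormat = Literal["multimodel_pdb", "xyzcsv"]

#: elements recognised when inferring a mass from a site name; anything else
#: gets mass 0 (forcing geometric COM downstream) plus a logged warning.
_TWO_LETTER_ELEMENTS = ("CL", "BR", "NA", "MG", "ZN", "FE", "CA")
_ONE_LETTER_ELEMENTS = ("H", "C", "N", "O", "S", "P", "K", "F", "I")


@dataclass
class MolecularFrame:
    """One frame's sites: coordinates plus per-site identity annotations.

    Coordinates are Å. ``mass`` may be 0 for coarse-grained beads whose
    element cannot be inferred; centre-of-mass code must then fall back to
    geometric weighting.
    """

    coords: np.ndarray          # (n, 3) float64, Å
    site_name: np.ndarray       # (n,) str
    residue_id: np.ndarray      # (n,) int, source numbering preserved
    residue_name: np.ndarray    # (n,) str
    chain_id: np.ndarray        # (n,) str
    mass: np.ndarray            # (n,) float, amu; 0 allowed
    box: np.ndarray | None = None   # optional (3,) lengths, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ShapeError("non-finite coordinate component")
        n = len(self.coords)
        for name in ("site_name", "residue_id", "residue_name", "chain_id", "mass"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ShapeError(
                    f"{name} has length {len(arr)}, expected {n} sites"
                )
            setattr(self, name, arr)
        self.mass = self.mass.astype(np.float64)

    @property
    def n_sites(self) -> int:
        return len(self.coords)

    def with_coords(self, coords: np.ndarray) -> "MolecularFrame":
        """Same topology, new coordinates."""
        return MolecularFrame(
            coords=np.asarray(coords, dtype=np.float64),
            site_name=self.site_name,
            residue_id=self.residue_id,
            residue_name=self.residue_name,
            chain_id=self.chain_id,
            mass=self.mass,
            box=self.box,
        )


@dataclass
class Trajectory:
    """Ordered frames sharing one topology. ``time_per_frame`` is metadata
    only (ns); no analysis depends on it."""

    frames: list[MolecularFrame]
    time_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise EmptyInputError("trajectory must contain at least one frame")
        n0 = self.frames[0].n_sites
        for i, f in enumerate(self.frames):
            if f.n_sites != n0:
                raise ShapeError(
                    f"frame {i} has {f.n_sites} sites, expected {n0}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass
class TriglycerideTopology:
    """Index map from one TG molecule to the sites the descriptors need.

    ``chain_sites`` holds, per chain, either the two atomistic C=C atom
    indices or the single coarse-grained D-bead index. Ester sites are kept
    as metadata (they anchor each chain to the glycerol).
    """

    central_site: int
    chain_sites: tuple            # 3 entries: (i, j) pairs or single ints
    ester_sites: tuple            # 3 indices, metadata
    representation: Literal["atomistic", "coarse_grained"]

    def __post_init__(self) -> None:
        if len(self.chain_sites) != 3:
            raise ShapeError("a triglyceride has exactly 3 chains")
        if len(self.ester_sites) != 3:
            raise ShapeError("a triglyceride has exactly 3 ester sites")
        flat = [self.central_site, *self.ester_sites]
        for entry in self.chain_sites:
            if self.representation == "atomistic":
                i, j = entry
                flat.extend((int(i), int(j)))
            else:
                flat.append(int(entry))
        if len(set(flat)) != len(flat):
            raise ShapeError("topology indices must be distinct")
        self._all_indices = tuple(flat)

    def all_sites(self) -> tuple:
        return self._all_indices

    def validate_against(self, frame: MolecularFrame) -> None:
        n = frame.n_sites
        for idx in self._all_indices:
            if not (0 <= idx < n):
                raise ShapeError(f"topology index {idx} out of range for {n} sites")


def infer_mass(site_name: str) -> float:
    """Mass (amu) from the leading characters of a site name.

    Unknown leading element -> 0.0 with a logged warning, which forces
    geometric COM weighting downstream (the CG bead names GLY/ES1/D2A all
    land here deliberately).
    """
    stripped = "".join(c for c in site_name if c.isalpha()).upper()
    if stripped[:2] in _TWO_LETTER_ELEMENTS and stripped[:2] not in ("CA",):
        return float(struc_info.mass(stripped[:2]))
    # "CA"/"CB"... are carbons in protein naming; bare "CA " element records
    # are handled by the PDB reader's element column before reaching here.
    if stripped[:1] in _ONE_LETTER_ELEMENTS:
        return float(struc_info.mass(stripped[:1]))
    logger.warning(
        "cannot infer element for site %r; mass set to 0 (geometric COM)",
        site_name,
    )
    return 0.0


def _frame_from_atom_array(arr: struc.AtomArray) -> MolecularFrame:
    if arr.array_length() == 0:
        raise EmptyInputError("structure contains zero sites")
    if np.any(arr.ins_code != ""):
        bad = np.where(arr.ins_code != "")[0][0]
        raise FormatError(
            f"insertion code {arr.ins_code[bad]!r} at residue "
            f"{int(arr.res_id[bad])}: renumber the structure explicitly; "
            "silent renumbering is refused"
        )
    masses = np.empty(arr.array_length())
    for i in range(arr.array_length()):
        elem = str(arr.element[i]).strip()
        try:
            masses[i] = float(struc_info.mass(elem)) if elem else np.nan
        except KeyError:
            masses[i] = np.nan
        if np.isnan(masses[i]):
            masses[i] = infer_mass(str(arr.atom_name[i]))
    box = None
    if arr.box is not None:
        box = np.diagonal(arr.box).astype(float).copy()
    return MolecularFrame(
        coords=arr.coord.astype(np.float64),
        site_name=arr.atom_name.astype(str),
        residue_id=arr.res_id.astype(int),
        residue_name=arr.res_name.astype(str),
        chain_id=arr.chain_id.astype(str),
        mass=masses,
        box=box,
    )


def _atom_array_from_frame(frame: MolecularFrame) -> struc.AtomArray:
    arr = struc.AtomArray(frame.n_sites)
    arr.coord = frame.coords.astype(np.float32)
    arr.atom_name = frame.site_name.astype("U6")
    arr.res_id = frame.residue_id.astype(int)
    arr.res_name = frame.residue_name.astype("U5")
    arr.chain_id = frame.chain_id.astype("U4")
    arr.element = np.array(
        [_element_guess(n) for n in frame.site_name], dtype="U2"
    )
    arr.hetero = np.zeros(frame.n_sites, dtype=bool)
    return arr


def _element_guess(site_name: str) -> str:
    stripped = "".join(c for c in str(site_name) if c.isalpha()).upper()
    if stripped[:2] in _TWO_LETTER_ELEMENTS and stripped[:2] != "CA":
        return stripped[:2]
    if stripped[:1] in _ONE_LETTER_ELEMENTS:
        return stripped[:1]
    return ""


def read_structure(path, format: StructureFormat) -> MolecularFrame:
    """Read a single-frame structure file into a :class:`MolecularFrame`.

    PDB residue numbering is preserved verbatim; insertion codes are
    rejected rather than silently renumbered.
    """
    path = Path(path)
    try:
        if format == "pdb":
            f = PDBFile.read(str(path))
            arr = f.get_structure(model=1)
        elif format == "gro":
            f = GROFile.read(str(path))
            arr = f.get_structure(model=1)
        else:
            raise FormatError(f"unknown structure format {format!r}")
    except (EmptyInputError, FormatError):
        raise
    except Exception as exc:  # biotite raises varied types per malformed line
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return _frame_from_atom_array(arr)


def read_trajectory(
    path, format: TrajectoryFormat, topology: MolecularFrame
) -> Trajectory:
    """Read a multi-frame file; per-frame site counts must match ``topology``."""
    path = Path(path)
    if format == "multimodel_pdb":
        f = PDBFile.read(str(path))
        try:
            stack = f.get_structure()  # AtomArrayStack, all models
        except Exception as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        frames = []
        for m in range(stack.stack_depth()):
            frame = _frame_from_atom_array(stack[m])
            if frame.n_sites != topology.n_sites:
                raise ShapeError(
                    f"frame {m}: {frame.n_sites} sites, topology has "
                    f"{topology.n_sites}"
                )
            frames.append(frame)
        return Trajectory(frames=frames)
    elif format == "xyzcsv":
        return _read_xyzcsv(path, topology)
    raise FormatError(f"unknown trajectory format {format!r}")


def _read_xyzcsv(path: Path, topology: MolecularFrame) -> Trajectory:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as xyzcsv: {exc}") from exc
    expected = ["frame", "site", "x", "y", "z"]
    if list(df.columns) != expected:
        raise FormatError(
            f"xyzcsv header must be {','.join(expected)}, got "
            f"{','.join(map(str, df.columns))}"
        )
    if len(df) == 0:
        raise EmptyInputError(f"{path} holds zero frames")
    n = topology.n_sites
    frame_ids = df["frame"].to_numpy()
    n_frames = int(frame_ids.max()) + 1
    if sorted(set(frame_ids)) != list(range(n_frames)):
        raise FormatError("xyzcsv frame indices must be contiguous and 0-based")
    frames = []
    for fi in range(n_frames):
        sub = df[frame_ids == fi]
        if len(sub) != n:
            raise ShapeError(
                f"frame {fi}: {len(sub)} rows, topology has {n} sites "
                "(truncated or padded frame)"
            )
        order = sub["site"].to_numpy()
        if sorted(order) != list(range(n)):
            raise FormatError(f"frame {fi}: site indices must be 0..{n-1}")
        coords = np.empty((n, 3))
        coords[order] = sub[["x", "y", "z"]].to_numpy()
        frames.append(topology.with_coords(coords))
    return Trajectory(frames=frames)


def write_trajectory(traj: Trajectory, path, format: TrajectoryFormat) -> None:
    """Write frames; ``read_trajectory ∘ write_trajectory`` is identity on
    coordinates exactly (xyzcsv) or to 1e-3 Å (PDB precision)."""
    path = Path(path)
    if format == "multimodel_pdb":
        arrays = [_atom_array_from_frame(f) for f in traj.frames]
        stack = struc.stack(arrays)
        f = PDBFile()
        f.set_structure(stack)
        f.write(str(path))
    elif format == "xyzcsv":
        rows = []
        for fi, frame in enumerate(traj.frames):
            n = frame.n_sites
            rows.append(
                pd.DataFrame(
                    {
                        "frame": np.full(n, fi, dtype=int),
                        "site": np.arange(n),
                        "x": frame.coords[:, 0],
                        "y": frame.coords[:, 1],
                        "z": frame.coords[:, 2],
                    }
                )
            )
        # %.17g is the shortest formatting guaranteed to round-trip float64
        pd.concat(rows, ignore_index=True).to_csv(
            path, index=False, float_format="%.17g"
        )
    else:
        raise FormatError(f"unknown trajectory format {format!r}")


def check_molecule_integrity(
    frame: MolecularFrame,
    topo: TriglycerideTopology,
    max_bond: float = 10.0,
) -> None:
    """Raise :class:`BrokenMoleculeError` if any bonded pair in the TG
    topology exceeds ``max_bond`` Å — the signature of a molecule split
    across a periodic boundary. No minimum-imaging is ever applied."""
    topo.validate_against(frame)
    c = frame.coords[topo.central_site]
    for k, entry in enumerate(topo.chain_sites):
        if topo.representation == "atomistic":
            i, j = entry
            if np.linalg.norm(frame.coords[i] - frame.coords[j]) > max_bond:
                raise BrokenMoleculeError(
                    f"chain {k}: C=C atom pair separated by more than "
                    f"{max_bond} Å — molecule appears broken across the box"
                )
        es = frame.coords[topo.ester_sites[k]]
        if np.linalg.norm(es - c) > max_bond:
            raise BrokenMoleculeError(
                f"chain {k}: ester site more than {max_bond} Å from the "
                "central site — molecule appears broken across the box"
            )
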