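import numpy as np
import pytest

from cetptraj.io_core import MolecularFrame, Trajectory


TOY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       0.000   1.000   0.000  1.00  0.00           C
END
"""

# same three sites in GRO (positions in nm)
TOY_GRO = """\
toy three-site frame
3
    1ALA     CA    1   0.000   0.000   0.000
    2ALA     CA    2   0.100   0.000   0.000
    3ALA     CA    3   0.000   0.100   0.000
   1.00000   1.00000   1.00000
"""


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def toy_gro(tmp_path):
    p = tmp_path / "toy.gro"
    p.write_text(TOY_GRO)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def make_frame(coords, masses=None, **kw):
    """Minimal frame around bare coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return MolecularFrame(
        coords=coords,
        site_name=kw.get("site_name", np.array(["CA"] * n)),
        residue_id=kw.get("residue_id", np.arange(1, n + 1)),
        residue_name=kw.get("residue_name", np.array(["ALA"] * n)),
        chain_id=kw.get("chain_id", np.array(["A"] * n)),
        mass=np.ones(n) if masses is None else np.asarray(masses, float),
    )


def random_rotation(rng):
    """Uniform proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def rigid_motion(frame, rng):
    """Frame under a random proper rotation + translation, plus (R, t)."""
    rot = random_rotation(rng)
    t = rng.uniform(-50, 50, size=3)
    return frame.with_coords(frame.coords @ rot.T + t), rot, t
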