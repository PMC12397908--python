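import numpy as np
import pytest

from hingeforge.structio import AtomRecord, StructureModel
from hingeforge.synthetic_data import make_hinge_protein


def ca_model(coords, chain="A", element="C", name="CA", resname="ALA"):
    """Build a StructureModel of Cα-like atoms from bare coordinates."""
    return StructureModel(
        [
            AtomRecord(
                chain=chain,
                resnum=i + 1,
                icode="",
                resname=resname,
                name=name,
                element=element,
                coords=np.asarray(xyz, dtype=float),
            )
            for i, xyz in enumerate(coords)
        ]
    )


def quaternion_rmsd(x, y):
    """Independent minimum-RMSD oracle (Kearsley quaternion eigenvalue method)."""
    x = np.asarray(x, float) - np.mean(x, axis=0)
    y = np.asarray(y, float) - np.mean(y, axis=0)
    d = x - y
    s = x + y
    K = np.empty((4, 4))
    K[0, 0] = (d**2).sum()
    K[1, 1] = (d[:, 0] ** 2 + s[:, 1] ** 2 + s[:, 2] ** 2).sum()
    K[2, 2] = (s[:, 0] ** 2 + d[:, 1] ** 2 + s[:, 2] ** 2).sum()
    K[3, 3] = (s[:, 0] ** 2 + s[:, 1] ** 2 + d[:, 2] ** 2).sum()
    K[0, 1] = K[1, 0] = (s[:, 1] * d[:, 2] - d[:, 1] * s[:, 2]).sum()
    K[0, 2] = K[2, 0] = (d[:, 0] * s[:, 2] - s[:, 0] * d[:, 2]).sum()
    K[0, 3] = K[3, 0] = (s[:, 0] * d[:, 1] - d[:, 0] * s[:, 1]).sum()
    K[1, 2] = K[2, 1] = (d[:, 0] * d[:, 1] - s[:, 0] * s[:, 1]).sum()
    K[1, 3] = K[3, 1] = (d[:, 0] * d[:, 2] - s[:, 0] * s[:, 2]).sum()
    K[2, 3] = K[3, 2] = (d[:, 1] * d[:, 2] - s[:, 1] * s[:, 2]).sum()
    lam = np.linalg.eigvalsh(K)[0]
    return float(np.sqrt(max(lam, 0.0) / len(x)))


def random_rigid_transform(rng):
    """A uniformly random proper rotation + translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.normal(0.0, 20.0, size=3)


@pytest.fixture(scope="session")
def hinge_pair():
    """The reference synthetic system: 60+60 residues, 60° hinge, 12-residue tail."""
    return make_hinge_protein(60, 60, 60.0, tail_len=12, seed=1)


@pytest.fixture(scope="session")
def hinge_pair_no_tail():
    return make_hinge_protein(60, 60, 40.0, tail_len=0, seed=2)
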