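import numpy as np
import pytest

from btherm import TruthConfig, generate_base_structure, generate_ensemble

TINY_PDB = """\
REMARK 200  TEMPERATURE           (KELVIN) : 225
REMARK   3   FROM WILSON PLOT           (A**2) : 12.50
REMARK   3   R VALUE            (WORKING SET) : 0.180
REMARK   3   FREE R VALUE                     : 0.210
CRYST1   54.700   58.500   67.200  90.00  90.00  90.00 P 21 21 21
ATOM      1  N   SER A   1      10.000  10.000  10.000  1.00 10.00           N
ATOM      2  CA ASER A   1      11.400  10.000  10.000  0.60 20.00           C
ATOM      3  CA BSER A   1      11.500  10.100  10.000  0.40 25.00           C
ATOM      4  C   SER A   1      12.100  11.300  10.000  1.00 30.00           C
ATOM      5  O   SER A   1      12.000  12.400  10.500  1.00 18.00           O
ATOM      6  OG  SER A   1      12.000   8.700  10.800  1.00 40.00           O
ATOM      7  N   GLY A   2      13.300  11.200   9.400  1.00 12.00           N
ATOM      8  CA  GLY A   2      14.400  12.100   9.200  1.00 14.00           C
ATOM      9  C   GLY A   2      15.600  11.500   8.500  1.00 16.00           C
ATOM     10  O   GLY A   2      15.700  10.300   8.300  1.00 17.00           O
HETATM   11 CA    CA A 301      20.000  20.000  20.000  1.00 15.00          CA
HETATM   12  C1  BEN A 401      24.000  21.000  20.000  1.00 22.00           C
HETATM   13  O   HOH S   1      25.000  25.000  25.000  1.00 30.00           O
HETATM   14  O   HOH S   2      28.000  25.000  25.000  0.00 35.00           O
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    """Hand-written two-residue structure with altlocs, het groups and
    header metadata."""
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture(scope="session")
def base40():
    return generate_base_structure(40, seed=11)


@pytest.fixture(scope="session")
def noiseless_ensemble(base40):
    """9 temperatures x 3 replicates, no noise, identity frames, full
    water retention, per-residue k drawn in [0.004, 0.006]."""
    return generate_ensemble(base40, TruthConfig.noiseless(), seed=21)


@pytest.fixture(scope="session")
def noisy_ensemble(base40):
    """Default study conditions: 5% B noise, 0.05 A coordinate noise,
    replicate rigid frames, temperature-dependent water loss."""
    return generate_ensemble(base40, TruthConfig(), seed=22)


def quaternion_rmsd(moving, reference):
    """Independent superposition oracle (Horn's closed-form quaternion
    method): minimal RMSD over proper rotations + translations."""
    X = np.asarray(moving, float)
    Y = np.asarray(reference, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S = Xc.T @ Yc
    key = np.array([
        [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
        [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
        [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
        [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    msd = ((Xc ** 2).sum() + (Yc ** 2).sum() - 2.0 * lam) / len(X)
    return float(np.sqrt(max(msd, 0.0)))


def random_proper_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
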