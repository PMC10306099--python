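import numpy as np
import pytest

from lanmsm.containers import Atom, Topology, Trajectory


def sample_chain(T, length, rng, start=None):
    """Sample a discrete Markov chain from transition matrix T."""
    T = np.asarray(T, dtype=float)
    cum = np.cumsum(T, axis=1)
    out = np.empty(length, dtype=int)
    if start is None:
        evals, evecs = np.linalg.eig(T.T)
        pi = np.abs(evecs[:, np.argmax(evals.real)].real)
        pi /= pi.sum()
        start = int(np.searchsorted(np.cumsum(pi), rng.random()))
    out[0] = start
    for t in range(1, length):
        out[t] = np.searchsorted(cum[out[t - 1]], rng.random())
    return out


def chain_eigs(T):
    """Sorted eigenvalues (descending modulus) of a transition matrix."""
    ev = np.linalg.eigvals(np.asarray(T, dtype=float))
    return np.sort(np.abs(ev))[::-1]


@pytest.fixture
def two_residue_traj():
    """Two residues, three heavy atoms + a hydrogen, two frames, with
    hand-placed coordinates for distance tests."""
    top = Topology(
        residues=[(1, "THR"), (3, "CYS")],
        atoms=[
            Atom(1, "CA", "C", 1),
            Atom(2, "CB", "C", 1),
            Atom(3, "HB", "H", 1),
            Atom(4, "CA", "C", 3),
            Atom(5, "SG", "S", 3),
        ],
    )
    coords = np.array(
        [
            # frame 0: CB-SG = 7.5, CA1-CA2 = 3.0, CB-CA2 = 9.0
            [[0, 0, 0], [0, 0, -4.0], [0, 0.5, 0], [3.0, 0, 0], [0, 0, 3.5]],
            # frame 1: heavy pair distances CA-CA 4.6, CA-SG 8.0, CB-SG 4.4
            [[0, 0, 0], [8, 4.4, 0], [9, 9, 9], [4.6, 0, 0], [8, 0, 0]],
        ],
        dtype=float,
    )
    return Trajectory(top, coords, source_id="toy")
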