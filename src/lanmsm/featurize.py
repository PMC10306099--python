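"""Trajectory featurization: pairwise residue distances, ring-pair reactive
distances, and per-frame helical content.

The pairwise-distance feature set follows the MSM convention of using all
residue pairs separated in sequence by at least ``min_separation`` (default 2,
i.e. only adjacent pairs are excluded), with the closest-heavy-atom distance
as the default pair metric. Helical content is a dihedral-window assignment:
a residue is helical when its (phi, psi) fall inside a rectangular window
around the ideal alpha-helix region and it belongs to a run of at least
``min_run`` consecutive such residues; the per-frame content is the helical
fraction of interior residues (termini have undefined phi or psi and are
excluded from numerator and denominator).
"""

from __future__ import annotations

import numpy as np

from ._geometry import dihedral
from .containers import FeatureMatrix, RingDefinition, Trajectory

__all__ = [
    "pairwise_residue_distances",
    "ring_pair_distance",
    "helical_content",
    "DEFAULT_PHI_WINDOW",
    "DEFAULT_PSI_WINDOW",
    "DEFAULT_MIN_RUN",
]

DEFAULT_PHI_WINDOW = (-100.0, -30.0)
DEFAULT_PSI_WINDOW = (-80.0, -5.0)
DEFAULT_MIN_RUN = 4


def _pair_min_distance(coords: np.ndarray, idx_i, idx_j) -> np.ndarray:
    """Per-frame minimum distance between two atom groups."""
    diff = coords[:, idx_i, None, :] - coords[:, None, idx_j, :]
    return np.sqrt((diff ** 2).sum(-1)).min(axis=(1, 2))


def pairwise_residue_distances(
    traj: Trajectory, min_separation: int = 2, atom_mode: str = "heavy_min"
) -> FeatureMatrix:
    """Distances for all residue pairs (i, j) with j - i >= min_separation.

    ``atom_mode='heavy_min'`` uses the minimum over non-hydrogen atom pairs;
    ``'ca_ca'`` the Calpha-Calpha distance. Features are ordered
    lexicographically by (i, j) and named ``d_r{i}_r{j}`` using the file's
    residue numbering.
    """
    top = traj.topology
    res = top.residue_indices
    if len(res) < 2 or res[-1] - res[0] < min_separation:
        raise ValueError(
            f"peptide spans residues {res[0] if res else '?'}..{res[-1] if res else '?'}; "
            f"no pair is separated by >= {min_separation}"
        )
    if atom_mode == "heavy_min":
        groups = {}
        for r in res:
            heavy = top.residue_atom_indices(r, heavy_only=True)
            if not heavy:
                raise ValueError(f"residue {r} has no heavy atoms")
            groups[r] = np.array(heavy)
    elif atom_mode == "ca_ca":
        groups = {}
        for r in res:
            if not top.has_atom(r, "CA"):
                raise ValueError(f"residue {r} lacks a CA atom (ca_ca mode)")
            groups[r] = np.array([top.atom_index(r, "CA")])
    else:
        raise ValueError(f"unknown atom_mode {atom_mode!r}")

    names, cols = [], []
    for a, ri in enumerate(res):
        for rj in res[a + 1:]:
            if rj - ri < min_separation:
                continue
            names.append(f"d_r{ri}_r{rj}")
            cols.append(_pair_min_distance(traj.coordinates, groups[ri], groups[rj]))
    return FeatureMatrix(np.column_stack(cols), names, traj.source_id)


def ring_pair_distance(traj: Trajectory, ring: RingDefinition) -> FeatureMatrix:
    """Per-frame reactive distance (Angstrom) for one ring definition."""
    top = traj.topology
    ring.validate_against(top)
    if ring.mode == "cb_sg":
        i = top.atom_index(ring.thr_residue, "CB")
        j = top.atom_index(ring.cys_residue, "SG")
        d = np.linalg.norm(
            traj.coordinates[:, i] - traj.coordinates[:, j], axis=-1
        )
    else:  # heavy_min
        gi = np.array(top.residue_atom_indices(ring.thr_residue, heavy_only=True))
        gj = np.array(top.residue_atom_indices(ring.cys_residue, heavy_only=True))
        d = _pair_min_distance(traj.coordinates, gi, gj)
    return FeatureMatrix(d[:, None], [f"ring_{ring.label}"], traj.source_id)


def _backbone_positions(traj: Trajectory):
    top = traj.topology
    pos = {}
    for r in top.residue_indices:
        for name in ("N", "CA", "C"):
            if not top.has_atom(r, name):
                raise ValueError(f"residue {r} missing backbone atom {name!r}")
        pos[r] = tuple(top.atom_index(r, n) for n in ("N", "CA", "C"))
    return pos


def helical_content(
    traj: Trajectory,
    phi_window=DEFAULT_PHI_WINDOW,
    psi_window=DEFAULT_PSI_WINDOW,
    min_run: int = DEFAULT_MIN_RUN,
):
    """Per-frame helical content plus the per-residue boolean assignment.

    Returns
    -------
    (FeatureMatrix, ndarray)
        A one-column feature matrix named ``helicity`` with values in [0, 1],
        and a boolean array of shape (frames, n_residues - 2) giving the final
        (run-filtered) helix assignment of interior residues.
    """
    top = traj.topology
    res = top.residue_indices
    n = len(res)
    if n < min_run + 2:
        raise ValueError(f"peptide length {n} < min_run + 2 = {min_run + 2}")
    pos = _backbone_positions(traj)
    X = traj.coordinates

    interior = res[1:-1]
    cand = np.ones((traj.n_frames, len(interior)), dtype=bool)
    for k, r in enumerate(interior):
        prev_r, next_r = res[res.index(r) - 1], res[res.index(r) + 1]
        n_i, ca_i, c_i = pos[r]
        phi = dihedral(X[:, pos[prev_r][2]], X[:, n_i], X[:, ca_i], X[:, c_i])
        psi = dihedral(X[:, n_i], X[:, ca_i], X[:, c_i], X[:, pos[next_r][0]])
        cand[:, k] = (
            (phi >= phi_window[0]) & (phi <= phi_window[1])
            & (psi >= psi_window[0]) & (psi <= psi_window[1])
        )

    helical = _run_filter(cand, min_run)
    content = helical.sum(axis=1) / (n - 2)
    fm = FeatureMatrix(content[:, None], ["helicity"], traj.source_id)
    return fm, helical


def _run_filter(cand: np.ndarray, min_run: int) -> np.ndarray:
    """Keep only candidates inside runs of >= min_run consecutive True."""
    f, r = cand.shape
    if min_run <= 1:
        return cand.copy()
    if r < min_run:
        return np.zeros_like(cand)
    out = np.zeros_like(cand)
    for s in range(r - min_run + 1):
        window_all = cand[:, s:s + min_run].all(axis=1)
        out[:, s:s + min_run] |= window_all[:, None]
    return out
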