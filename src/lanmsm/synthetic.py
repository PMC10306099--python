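"""Synthetic conformer ensembles with exactly known ground truth.

The generator emulates ensembles of short peptide trajectories whose frames
interconvert between helix-rich and coil-rich conformers under hidden Markov
kinetics, with designable reactive-pair ("Thr-like" Cbeta to "Cys-like"
Sgamma) distance propensities. A hidden-Markov emission model (rather than a
Langevin toy) is used deliberately: the stationary distribution, implied
timescales and ring-closure probabilities are then available in closed form,

    pi_true        : leading left eigenvector of the hidden transition matrix,
    t_k,true       : -1 / ln lambda_k(hidden_T),
    P_true(cutoff) : sum_h pi_h * Phi((cutoff - mu_h) / sigma_h),

independent of the pipeline under test. Each hidden state emits a backbone
template (ideal helix at phi=-57, psi=-47; extended at phi=-139, psi=+135;
or custom dihedrals) realized by internal-to-Cartesian chain building with
standard bond lengths/angles, plus per-atom Gaussian jitter; ring-pair
Sgamma atoms have their Cbeta-Sgamma distance drawn directly from the
designed Gaussian so that P_true stays closed-form.

What this does *not* emulate: continuous intra-basin diffusion, force-field
energetics, solvent, or dehydro-residue chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.stats import norm

from . import _geometry as geom
from .containers import Atom, FeatureMatrix, Topology, Trajectory

__all__ = [
    "RingGeometry",
    "SyntheticEnsembleSpec",
    "OUSpec",
    "GroundTruth",
    "build_conformer_library",
    "sample_ensemble",
    "true_ring_probability",
    "sample_ou",
    "make_paper_analogue_pair",
]

TEMPLATES = ("ideal_helix", "extended")


@dataclass
class RingGeometry:
    """Designed reactive-pair geometry: per hidden state the mean and sd
    (Angstrom) of the Thr-Cbeta to Cys-Sgamma distance."""
    label: str
    thr_residue: int
    cys_residue: int
    mean: tuple
    sd: tuple


@dataclass
class SyntheticEnsembleSpec:
    """Hidden-state kinetic model plus conformer emission parameters."""
    hidden_T: np.ndarray
    templates: tuple                  # per hidden state: name or dihedral list
    rings: tuple = ()
    n_residues: int = 22
    jitter_sd: float = 0.05           # per-atom Gaussian jitter, Angstrom
    n_traj: int = 20
    traj_length: int = 2000
    frame_spacing: float = 1.0
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self):
        self.hidden_T = np.asarray(self.hidden_T, dtype=float)
        H = self.hidden_T.shape[0]
        if self.hidden_T.shape != (H, H):
            raise ValueError("hidden_T must be square")
        if np.abs(self.hidden_T.sum(axis=1) - 1).max() > 1e-12:
            raise ValueError("hidden_T rows must sum to 1")
        if len(self.templates) != H:
            raise ValueError("one template per hidden state required")
        if self.jitter_sd <= 0:
            raise ValueError("jitter sd must be positive")
        for ring in self.rings:
            if len(ring.mean) != H or len(ring.sd) != H:
                raise ValueError(
                    f"ring {ring.label!r} needs one (mean, sd) per hidden state"
                )
            if ring.thr_residue == ring.cys_residue:
                raise ValueError("ring residues must be distinct")
            for r in (ring.thr_residue, ring.cys_residue):
                if not 1 <= r <= self.n_residues:
                    raise ValueError(f"ring residue {r} outside peptide")
        # irreducibility: unique stationary distribution must exist
        self._pi = _stationary(self.hidden_T)

    @property
    def n_hidden(self) -> int:
        return self.hidden_T.shape[0]

    @property
    def stationary_distribution(self) -> np.ndarray:
        return self._pi.copy()


@dataclass
class OUSpec:
    """Discrete Ornstein-Uhlenbeck process: an analytic tICA test bed.

    Dimension d relaxes with autocorrelation exp(-lag / relaxation_times[d]);
    the observed features are the modes rotated by ``mixing``.
    """
    relaxation_times: tuple
    mixing: np.ndarray | None = None
    noise_sd: tuple | None = None     # None: unit stationary variance
    n_frames: int = 100_000
    seed: int = 0

    def __post_init__(self):
        rt = np.asarray(self.relaxation_times, dtype=float)
        if (rt <= 0).any():
            raise ValueError("relaxation times must be positive")
        if len(set(rt.tolist())) != rt.size:
            raise ValueError("relaxation times must be distinct")


@dataclass
class GroundTruth:
    stationary_distribution: np.ndarray
    eigenvalues: np.ndarray
    implied_timescales: np.ndarray    # -1/ln lambda_k, k >= 2, frames
    ring_probability: dict            # label -> P_true at the ring's cutoff 7.5
    template_helicity: np.ndarray     # jitter-free helical content per state
    mean_helicity: float


def _stationary(T: np.ndarray) -> np.ndarray:
    evals, evecs = scipy.linalg.eig(T, left=True, right=False)
    i = np.argsort(-evals.real)
    lead = evals.real[i]
    if lead.size > 1 and abs(lead[0] - lead[1]) < 1e-12:
        raise ValueError("hidden_T is reducible: stationary distribution not unique")
    pi = np.abs(evecs[:, i[0]].real)
    return pi / pi.sum()


def _template_dihedrals(template, n_residues: int):
    if template == "ideal_helix":
        phi = np.full(n_residues, geom.IDEAL_HELIX[0])
        psi = np.full(n_residues, geom.IDEAL_HELIX[1])
    elif template == "extended":
        phi = np.full(n_residues, geom.EXTENDED[0])
        psi = np.full(n_residues, geom.EXTENDED[1])
    elif isinstance(template, (list, tuple, np.ndarray)):
        arr = np.asarray(template, dtype=float)
        if arr.shape != (n_residues, 2):
            raise ValueError(
                f"custom dihedral list must have shape ({n_residues}, 2)"
            )
        phi, psi = arr[:, 0], arr[:, 1]
    else:
        raise ValueError(f"unknown template {template!r}")
    return phi, psi


def _make_topology(spec: SyntheticEnsembleSpec) -> Topology:
    thr = {r.thr_residue for r in spec.rings}
    cys = {r.cys_residue for r in spec.rings}
    residues, atoms = [], []
    serial = 1
    for r in range(1, spec.n_residues + 1):
        name = "THR" if r in thr else ("CYS" if r in cys else "ALA")
        residues.append((r, name))
        for atom_name, element in (("N", "N"), ("CA", "C"), ("C", "C"),
                                   ("CB", "C")):
            atoms.append(Atom(serial, atom_name, element, r))
            serial += 1
        if r in cys:
            atoms.append(Atom(serial, "SG", "S", r))
            serial += 1
    return Topology(residues, atoms)


def _template_coordinates(spec: SyntheticEnsembleSpec, h: int,
                          topology: Topology) -> np.ndarray:
    """Jitter-free template coordinates for hidden state ``h`` (atoms x 3).

    Sgamma atoms are placed at each ring's designed mean distance from the
    partner Cbeta, along the direction towards the Cys Calpha.
    """
    phi, psi = _template_dihedrals(spec.templates[h], spec.n_residues)
    bb = geom.build_backbone(phi, psi)
    coords = np.zeros((topology.n_atoms, 3))
    for r in range(1, spec.n_residues + 1):
        n_, ca, c = bb[r - 1]
        coords[topology.atom_index(r, "N")] = n_
        coords[topology.atom_index(r, "CA")] = ca
        coords[topology.atom_index(r, "C")] = c
        coords[topology.atom_index(r, "CB")] = geom.place_cb(n_, ca, c)
    for ring in spec.rings:
        cb = coords[topology.atom_index(ring.thr_residue, "CB")]
        ca_cys = coords[topology.atom_index(ring.cys_residue, "CA")]
        u = ca_cys - cb
        u /= np.linalg.norm(u)
        coords[topology.atom_index(ring.cys_residue, "SG")] = (
            cb + ring.mean[h] * u
        )
    return coords


def build_conformer_library(spec: SyntheticEnsembleSpec) -> list:
    """One jitter-free single-frame Trajectory per hidden state."""
    topology = _make_topology(spec)
    out = []
    for h in range(spec.n_hidden):
        coords = _template_coordinates(spec, h, topology)
        out.append(
            Trajectory(topology, coords[None], spec.frame_spacing,
                       source_id=f"{spec.name}_state{h}")
        )
    return out


def _sample_hidden_chain(T, pi, length, rng) -> np.ndarray:
    cum = np.cumsum(T, axis=1)
    states = np.empty(length, dtype=int)
    states[0] = np.searchsorted(np.cumsum(pi), rng.random())
    for t in range(1, length):
        states[t] = np.searchsorted(cum[states[t - 1]], rng.random())
    return states


def _emit_frames(spec, topology, templates_xyz, hidden, rng) -> np.ndarray:
    n_frames = hidden.size
    coords = templates_xyz[hidden] + rng.normal(
        scale=spec.jitter_sd, size=(n_frames, topology.n_atoms, 3)
    )
    for ring in spec.rings:
        i_cb = topology.atom_index(ring.thr_residue, "CB")
        i_ca = topology.atom_index(ring.cys_residue, "CA")
        i_sg = topology.atom_index(ring.cys_residue, "SG")
        mu = np.asarray(ring.mean)[hidden]
        sd = np.asarray(ring.sd)[hidden]
        d = rng.normal(mu, sd)
        u = coords[:, i_ca] - coords[:, i_cb]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        coords[:, i_sg] = coords[:, i_cb] + np.abs(d)[:, None] * u
    return coords


def sample_ensemble(spec: SyntheticEnsembleSpec):
    """Sample the ensemble.

    Returns (trajectories, hidden-state label arrays, GroundTruth). All
    randomness flows from ``spec.seed`` through named substreams (kinetics,
    emission).
    """
    topology = _make_topology(spec)
    templates_xyz = np.stack(
        [_template_coordinates(spec, h, topology) for h in range(spec.n_hidden)]
    )
    pi = spec.stationary_distribution
    rng_kin = np.random.default_rng([spec.seed, 0x6B696E])   # "kin"
    rng_emit = np.random.default_rng([spec.seed, 0x656D69])  # "emi"

    trajectories, hidden_labels = [], []
    for j in range(spec.n_traj):
        hidden = _sample_hidden_chain(spec.hidden_T, pi, spec.traj_length,
                                      rng_kin)
        coords = _emit_frames(spec, topology, templates_xyz, hidden, rng_emit)
        trajectories.append(
            Trajectory(topology, coords, spec.frame_spacing,
                       source_id=f"{spec.name}_traj{j}")
        )
        hidden_labels.append(hidden)

    evals = np.sort(np.abs(scipy.linalg.eigvals(spec.hidden_T)))[::-1].real
    its = -1.0 / np.log(np.clip(evals[1:], 1e-300, 1 - 1e-15))
    truth = GroundTruth(
        stationary_distribution=pi,
        eigenvalues=evals,
        implied_timescales=its,
        ring_probability={
            r.label: true_ring_probability(spec, r.label) for r in spec.rings
        },
        template_helicity=_template_helicity(spec),
        mean_helicity=float(pi @ _template_helicity(spec)),
    )
    return trajectories, hidden_labels, truth


def _template_helicity(spec: SyntheticEnsembleSpec) -> np.ndarray:
    from .featurize import helical_content

    out = np.empty(spec.n_hidden)
    for h, traj in enumerate(build_conformer_library(spec)):
        fm, _ = helical_content(traj)
        out[h] = fm.values[0, 0]
    return out


def true_ring_probability(spec: SyntheticEnsembleSpec, ring_label: str,
                          cutoff: float = 7.5) -> float:
    """Closed-form equilibrium ring probability of the generator:
    sum_h pi_h Phi((cutoff - mu_h) / sigma_h)."""
    for ring in spec.rings:
        if ring.label == ring_label:
            pi = spec.stationary_distribution
            z = (cutoff - np.asarray(ring.mean)) / np.asarray(ring.sd)
            return float(pi @ norm.cdf(z))
    raise KeyError(f"no ring labelled {ring_label!r}")


def sample_ou(spec: OUSpec) -> FeatureMatrix:
    """Sample the discrete OU process x_{t+1} = a x_t + noise, rotated by the
    mixing matrix; dimension d has lag-L autocorrelation exp(-L/relax_d)."""
    from scipy.signal import lfilter

    rt = np.asarray(spec.relaxation_times, dtype=float)
    dim = rt.size
    a = np.exp(-1.0 / rt)
    noise = (np.sqrt(1 - a**2) if spec.noise_sd is None
             else np.asarray(spec.noise_sd, dtype=float))
    rng = np.random.default_rng(spec.seed)
    w = rng.normal(size=(spec.n_frames, dim)) * noise
    x = np.empty_like(w)
    for d in range(dim):
        x[:, d] = lfilter([1.0], [1.0, -a[d]], w[:, d])
    mixing = np.eye(dim) if spec.mixing is None else np.asarray(spec.mixing)
    y = x @ mixing.T
    return FeatureMatrix(y, [f"f{d + 1}" for d in range(dim)], "ou")


def make_paper_analogue_pair(seed: int = 0):
    """Two ensembles mirroring the studied contrast: a "WT-like" peptide
    whose helix does not bring the A' pair (Thr11/Cys14) together, and a
    "Variant1-like" peptide whose longer helix does.

    Both share the hidden relaxation timescale (lambda_2 = 0.95) but have
    mirrored helix/coil occupancies (30% vs 70% helix), and both carry an
    A' (Thr11/Cys14) and a B' (Thr18/Cys21) ring. By construction
    P_true(A') and the mean helicity are higher for the Variant1-like
    ensemble.
    """
    base = dict(
        templates=("ideal_helix", "extended"),
        n_residues=22,
        jitter_sd=0.05,
        n_traj=20,
        traj_length=2000,
    )
    # state 0 = helix, state 1 = coil; rows sum to 1, lambda_2 = 0.95 both
    wt = SyntheticEnsembleSpec(
        hidden_T=[[0.965, 0.035], [0.015, 0.985]],  # pi = (0.3, 0.7)
        rings=(
            RingGeometry("A'", 11, 14, mean=(9.5, 12.0), sd=(1.5, 2.5)),
            RingGeometry("B'", 18, 21, mean=(10.0, 11.0), sd=(2.0, 2.5)),
        ),
        seed=(seed * 1_000_003 + 1) % 2**31,
        name="wt_like",
        **base,
    )
    v1 = SyntheticEnsembleSpec(
        hidden_T=[[0.985, 0.015], [0.035, 0.965]],  # pi = (0.7, 0.3)
        rings=(
            RingGeometry("A'", 11, 14, mean=(5.5, 12.0), sd=(0.8, 2.5)),
            RingGeometry("B'", 18, 21, mean=(6.5, 11.0), sd=(1.0, 2.5)),
        ),
        seed=(seed * 1_000_003 + 2) % 2**31,
        name="variant1_like",
        **base,
    )
    return wt, v1
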