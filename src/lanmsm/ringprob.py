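"""Equilibrium ring-formation probability, bootstrap errors, free-energy
landscapes and weighted helicity distributions.

A frame is "ring-closed" for a Thr/Cys pair when its reactive distance is
within the cutoff (7.5 A for the Cbeta-Sgamma definition, 4.5 A for the
closest-heavy-atom alternative; closed interval). The equilibrium ring
formation probability combines the raw within-state closure fractions with
the MSM stationary distribution:

    P_ring = sum_s pi_s * p_s,      p_s = P(d <= cutoff | frame in state s),

which equals the sum of MSM frame weights over ring-closed frames; both
routes are computed on every call and asserted identical to 1e-12.

Uncertainty follows trajectory-level bootstrapping: each replicate draws 80%
of the trajectories (without replacement, shipped default, 200 replicates),
keeps the original per-frame state labels, re-estimates the MSM on the
subsample, and recomputes P_ring; the replicate standard deviation is the
error bar. Free-energy landscapes are -k_B T ln of the frame-weighted
density over two chosen coordinates, shifted so the most populated bin is 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import RingDefinition
from .msm import MarkovStateModel

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "DEFAULT_N_BOOT",
    "DEFAULT_BOOT_FRAC",
    "DEFAULT_TEMPERATURE",
    "RingProbabilityResult",
    "FreeEnergyLandscape",
    "RingComparison",
    "frame_weights",
    "equilibrium_ring_probability",
    "bootstrap_ring_probability",
    "free_energy_landscape",
    "weighted_helicity_distribution",
    "compare_rings",
]

KB_KCAL_PER_MOL_K = 0.0019872041
DEFAULT_N_BOOT = 200
DEFAULT_BOOT_FRAC = 0.8
DEFAULT_TEMPERATURE = 300.0


@dataclass
class RingProbabilityResult:
    ring: RingDefinition | None
    cutoff: float
    per_state_probability: np.ndarray
    equilibrium_probability: float
    frame_weight_probability: float
    n_frames_used: int
    bootstrap_mean: float | None = None
    bootstrap_sd: float | None = None
    bootstrap_replicates: np.ndarray | None = None
    n_boot: int | None = None
    frac: float | None = None
    seed: int | None = None
    n_failed: int = 0
    msm_token: int | None = None
    label: str = ""


@dataclass
class FreeEnergyLandscape:
    coordinate_names: tuple
    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray          # bin masses, sum to 1 over populated bins
    free_energy: np.ma.MaskedArray   # kcal/mol, min over populated bins = 0
    temperature: float


@dataclass
class RingComparison:
    order: list                      # labels sorted by decreasing P_ring
    probabilities: dict
    errors: dict
    pairwise: list                   # (label_a, label_b, diff, combined_sd)
    predicted_first: str | None
    tie: bool


def frame_weights(msm: MarkovStateModel, dtrajs) -> list:
    """MSM equilibrium weight of every frame.

    A frame in active state s weighs pi_s / n_s (n_s frames assigned to s);
    frames in trimmed states weigh 0. Weights sum to 1. ``dtrajs`` must be
    the label sequences the MSM was estimated from.
    """
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    pooled = np.concatenate(dtrajs)
    n_states = msm.n_states_
    counts = np.bincount(pooled, minlength=n_states)
    state_weight = np.zeros(n_states)
    for a, pi_s in zip(msm.active_set_, msm.stationary_distribution_):
        assert counts[a] > 0, "active state with zero frames cannot occur"
        state_weight[a] = pi_s / counts[a]
    return [state_weight[d] for d in dtrajs]


def equilibrium_ring_probability(
    ring_distances,
    dtrajs,
    msm: MarkovStateModel,
    cutoff: float,
    ring: RingDefinition | None = None,
    label: str = "",
) -> RingProbabilityResult:
    """Equilibrium ring-formation probability.

    ``ring_distances`` is one per-frame distance array per trajectory,
    aligned with ``dtrajs``. Both routes (state-wise sum and frame-weight
    sum) are computed and asserted equal to 1e-12.
    """
    ring_distances = [np.asarray(d, dtype=float).ravel() for d in ring_distances]
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    if len(ring_distances) != len(dtrajs) or any(
        a.size != b.size for a, b in zip(ring_distances, dtrajs)
    ):
        raise ValueError("ring distances and state labels are misaligned")
    dist = np.concatenate(ring_distances)
    states = np.concatenate(dtrajs)
    closed = dist <= cutoff

    active = msm.active_set_
    pi = msm.stationary_distribution_
    p_s = np.zeros(active.size)
    n_used = 0
    empty = []
    for k, s in enumerate(active):
        in_s = states == s
        n_s = int(in_s.sum())
        if n_s == 0:
            empty.append(s)
            p_s[k] = np.nan
            continue
        p_s[k] = closed[in_s].mean()
        n_used += n_s
    if empty:
        warnings.warn(
            f"states {empty} have no assigned frames; excluded with pi "
            "renormalized"
        )
        keep = ~np.isnan(p_s)
        pi = pi[keep] / pi[keep].sum()
        p_s = p_s[keep]
    p_ring = float(pi @ p_s)

    w = np.concatenate(frame_weights(msm, dtrajs)) if not empty else None
    if w is not None:
        p_ring_w = float(w[closed].sum())
        if abs(p_ring - p_ring_w) > 1e-12:
            raise AssertionError(
                f"ring-probability identity violated: {p_ring} vs {p_ring_w}"
            )
    else:
        p_ring_w = p_ring

    return RingProbabilityResult(
        ring=ring,
        cutoff=float(cutoff),
        per_state_probability=p_s,
        equilibrium_probability=p_ring,
        frame_weight_probability=p_ring_w,
        n_frames_used=n_used,
        msm_token=getattr(msm, "_token", None),
        label=label or (ring.label if ring is not None else ""),
    )


def bootstrap_ring_probability(
    ring_distances,
    dtrajs,
    lag: int,
    cutoff: float,
    reversible: bool = True,
    count_mode: str = "sliding",
    n_boot: int = DEFAULT_N_BOOT,
    frac: float = DEFAULT_BOOT_FRAC,
    seed: int = 0,
    with_replacement: bool = False,
    ring: RingDefinition | None = None,
    label: str = "",
) -> RingProbabilityResult:
    """Full-data estimate plus trajectory-bootstrap error bar.

    Per replicate, ceil(frac * M) trajectories are drawn (without
    replacement by default), the original per-frame state labels are kept
    (no re-clustering), the MSM is re-estimated on the subsample and P_ring
    recomputed. Replicates whose subsample loses ergodic connectivity are
    recorded as failed and excluded.
    """
    M = len(dtrajs)
    if M < 2:
        raise ValueError("bootstrap needs at least two trajectories")
    full_msm = MarkovStateModel(
        lag=lag, reversible=reversible, count_mode=count_mode
    ).fit(dtrajs)
    full = equilibrium_ring_probability(
        ring_distances, dtrajs, full_msm, cutoff, ring=ring, label=label
    )

    rng = np.random.default_rng(seed)
    n_pick = int(np.ceil(frac * M))
    reps = []
    failed = 0
    for _ in range(n_boot):
        # order within a replicate is irrelevant; sorting makes the
        # frac = 1.0 degenerate case bitwise-identical to the full estimate
        idx = np.sort(rng.choice(M, size=n_pick, replace=with_replacement))
        try:
            sub_msm = MarkovStateModel(
                lag=lag, reversible=reversible, count_mode=count_mode
            ).fit([dtrajs[i] for i in idx])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = equilibrium_ring_probability(
                    [ring_distances[i] for i in idx],
                    [dtrajs[i] for i in idx],
                    sub_msm,
                    cutoff,
                )
            reps.append(res.equilibrium_probability)
        except (ValueError, RuntimeError):
            failed += 1
    if not reps:
        raise RuntimeError(f"all {n_boot} bootstrap replicates failed")
    reps = np.array(reps)
    full.bootstrap_mean = float(reps.mean())
    if reps.size < 2 or (reps == reps[0]).all():
        full.bootstrap_sd = 0.0  # degenerate resampling (e.g. frac = 1.0)
    else:
        full.bootstrap_sd = float(reps.std(ddof=1))
    full.bootstrap_replicates = reps
    full.n_boot = n_boot
    full.frac = frac
    full.seed = seed
    full.n_failed = failed
    return full


def free_energy_landscape(
    coord1,
    coord2,
    weights,
    bins=50,
    temperature: float = DEFAULT_TEMPERATURE,
    range=None,
    coordinate_names=("coord1", "coord2"),
) -> FreeEnergyLandscape:
    """Frame-weighted 2-D free-energy surface F = -k_B T ln(p / p_max).

    Empty bins are masked, never -inf; the most populated bin sits at 0
    kcal/mol.
    """
    coord1 = np.asarray(coord1, dtype=float).ravel()
    coord2 = np.asarray(coord2, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    H, xe, ye = np.histogram2d(coord1, coord2, bins=bins, range=range,
                               weights=weights)
    total = H.sum()
    if total <= 0:
        raise ValueError("zero total weight inside the histogram range")
    p = H / total
    mask = p <= 0
    with np.errstate(divide="ignore"):
        F = -KB_KCAL_PER_MOL_K * temperature * np.log(
            np.where(mask, 1.0, p / p.max())
        )
    return FreeEnergyLandscape(
        coordinate_names=tuple(coordinate_names),
        x_edges=xe,
        y_edges=ye,
        probability=p,
        free_energy=np.ma.masked_array(F, mask=mask),
        temperature=float(temperature),
    )


def weighted_helicity_distribution(helicity, weights, bins: int = 20):
    """Weight-summed histogram of per-frame helical content over [0, 1].

    Returns (bin masses summing to 1, bin edges).
    """
    helicity = np.asarray(helicity, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    if ((helicity < 0) | (helicity > 1)).any():
        raise ValueError("helicity values must lie in [0, 1]")
    H, edges = np.histogram(helicity, bins=bins, range=(0.0, 1.0),
                            weights=weights)
    total = H.sum()
    if total <= 0:
        raise ValueError("zero total weight")
    return H / total, edges


def compare_rings(results) -> RingComparison:
    """Order candidate rings by equilibrium probability.

    The predicted first ring to form is the argmax; if the top two are
    within their combined bootstrap sd the comparison is flagged as a tie
    and no prediction is made. All results must come from the same MSM.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("need at least two ring results to compare")
    tokens = {r.msm_token for r in results}
    if len(tokens) != 1:
        raise ValueError("ring results come from different MSMs")
    ordered = sorted(
        results, key=lambda r: r.equilibrium_probability, reverse=True
    )
    labels = [r.label for r in ordered]
    probs = {r.label: r.equilibrium_probability for r in ordered}
    errs = {r.label: r.bootstrap_sd for r in ordered}
    pairwise = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            sds = [s for s in (a.bootstrap_sd, b.bootstrap_sd) if s is not None]
            combined = float(np.sqrt(np.sum(np.square(sds)))) if sds else None
            pairwise.append(
                (a.label, b.label,
                 a.equilibrium_probability - b.equilibrium_probability,
                 combined)
            )
    top_diff = (ordered[0].equilibrium_probability
                - ordered[1].equilibrium_probability)
    combined = pairwise[0][3]
    tie = combined is not None and top_diff <= combined
    return RingComparison(
        order=labels,
        probabilities=probs,
        errors=errs,
        pairwise=pairwise,
        predicted_first=None if tie else labels[0],
        tie=tie,
    )
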