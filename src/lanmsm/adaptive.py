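"""Least-counts adaptive sampling controller.

The controller iterates: run short simulations, cluster *all* collected data
with K-means (100 clusters shipped), pick the least-populated clusters
(25 shipped), restart one new simulation from a randomly chosen member frame
of each, repeat. Restarting from rarely visited states accelerates coverage
of the conformational space relative to repeatedly seeding from the same
starting structure; the sampling bias this introduces is later removed by
MSM reweighting.

The controller is engine-agnostic: trajectories are opaque objects produced
by a user-supplied propagator and interpreted only through the supplied
``featurizer`` and ``frame_extractor`` callbacks. In this package the
propagator is the synthetic conformer generator; real MD engines are out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import MicrostateKMeans

__all__ = [
    "DEFAULT_N_CLUSTERS",
    "DEFAULT_N_SELECT",
    "SamplingRound",
    "AdaptiveRun",
    "least_counts_select",
    "pick_seed_frames",
    "run_adaptive",
]

DEFAULT_N_CLUSTERS = 100
DEFAULT_N_SELECT = 25


@dataclass
class SamplingRound:
    """Replay record of one controller round."""
    round_index: int
    counts: np.ndarray                  # per-cluster frame counts
    selected_clusters: list             # least-count selection
    seed_frames: list                   # (trajectory index, frame index)
    rng_seed: int                       # substream seed used this round
    n_clusters: int = 0
    stop_metric: float | None = None


@dataclass
class AdaptiveRun:
    trajectories: list
    rounds: list = field(default_factory=list)
    total_frames: int = 0


def least_counts_select(counts, n_select: int, seed: int = 0) -> list:
    """Indices of the ``n_select`` non-empty clusters with smallest counts.

    Ties at the selection boundary are broken by a seeded uniform choice
    among the tied clusters; the result is deterministic given the seed.
    """
    counts = np.asarray(counts)
    nonempty = np.flatnonzero(counts > 0)
    if nonempty.size == 0:
        raise ValueError("all clusters are empty")
    if n_select > nonempty.size:
        raise ValueError(
            f"n_select={n_select} exceeds {nonempty.size} non-empty clusters"
        )
    order = nonempty[np.argsort(counts[nonempty], kind="stable")]
    boundary_count = counts[order[n_select - 1]]
    below = [int(i) for i in order if counts[i] < boundary_count]
    tied = np.array([i for i in nonempty if counts[i] == boundary_count])
    need = n_select - len(below)
    rng = np.random.default_rng(seed)
    chosen_tied = rng.choice(tied, size=need, replace=False)
    return below + [int(i) for i in chosen_tied]


def pick_seed_frames(dtrajs, selected, seed: int = 0) -> list:
    """One uniformly chosen member frame per selected cluster.

    Returns (trajectory index, frame index) pairs in selection order.
    """
    rng = np.random.default_rng(seed)
    members = {int(c): [] for c in selected}
    for t, d in enumerate(dtrajs):
        d = np.asarray(d)
        for c in members:
            for f in np.flatnonzero(d == c):
                members[c].append((t, int(f)))
    out = []
    for c in selected:
        mem = members[int(c)]
        if not mem:
            raise ValueError(f"selected cluster {c} has no member frames")
        out.append(mem[rng.integers(len(mem))])
    return out


def run_adaptive(
    propagator,
    featurizer,
    frame_extractor,
    initial_seeds,
    rounds: int,
    trajs_per_round: int,
    traj_length: int,
    n_clusters: int = DEFAULT_N_CLUSTERS,
    n_select: int = DEFAULT_N_SELECT,
    seed: int = 0,
    initial_trajectories=(),
    stop_rtol: float | None = None,
) -> AdaptiveRun:
    """Run the least-counts controller.

    Parameters
    ----------
    propagator : callable(seed_structure, length, seed) -> trajectory object
    featurizer : callable(trajectory object) -> (frames, dim) array
    frame_extractor : callable(trajectory object, frame index) -> seed structure
    initial_seeds : starting structures for round 0 (cycled to fill
        ``trajs_per_round``).
    rounds : number of controller rounds; 0 returns the initial data
        unchanged.
    stop_rtol : optional early-stopping threshold on the relative
        total-variation change of the sorted cluster-population distribution
        between successive rounds (a convergence heuristic; the round budget
        is the primary stop).

    The returned round log (counts, selections, seed frames, substream seeds)
    is sufficient to replay the controller decisions bit-exactly.
    """
    master = np.random.default_rng(seed)
    run = AdaptiveRun(trajectories=list(initial_trajectories))
    run.total_frames = sum(featurizer(t).shape[0] for t in run.trajectories)
    seeds = list(initial_seeds)
    prev_pops = None

    for r in range(rounds):
        round_seed = int(master.integers(2**31))
        rng = np.random.default_rng(round_seed)
        new = []
        for j in range(trajs_per_round):
            seed_structure = seeds[j % len(seeds)]
            child = int(rng.integers(2**31))
            try:
                traj = propagator(seed_structure, traj_length, child)
            except Exception as exc:
                raise RuntimeError(f"propagator failed in round {r}: {exc}") from exc
            new.append(traj)
        run.trajectories.extend(new)
        run.total_frames += sum(featurizer(t).shape[0] for t in new)

        # re-cluster all collected data from scratch
        feats = [featurizer(t) for t in run.trajectories]
        pooled = np.vstack(feats)
        k = min(n_clusters, pooled.shape[0])
        km = MicrostateKMeans(n_clusters=k, random_state=round_seed).fit(pooled)
        dtrajs = [km.predict(f) for f in feats]
        counts = np.bincount(np.concatenate(dtrajs), minlength=k)

        sel = least_counts_select(
            counts, min(n_select, int((counts > 0).sum())), seed=round_seed
        )
        frames = pick_seed_frames(dtrajs, sel, seed=round_seed)
        seeds = [frame_extractor(run.trajectories[t], f) for t, f in frames]

        pops = np.sort(counts / counts.sum())[::-1]
        metric = None
        if prev_pops is not None:
            m = min(pops.size, prev_pops.size)
            metric = 0.5 * float(
                np.abs(pops[:m] - prev_pops[:m]).sum()
                + pops[m:].sum() + prev_pops[m:].sum()
            )
        prev_pops = pops

        run.rounds.append(
            SamplingRound(
                round_index=r,
                counts=counts,
                selected_clusters=sel,
                seed_frames=frames,
                rng_seed=round_seed,
                n_clusters=k,
                stop_metric=metric,
            )
        )
        if stop_rtol is not None and metric is not None and metric < stop_rtol:
            break
    return run
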