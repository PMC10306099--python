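"""Config-driven orchestration of the full workflow.

synthesize/ingest -> featurize -> tICA -> K-means -> implied-timescale lag
selection (or fixed lag) -> optional VAMP-2 hyperparameter grid -> MSM ->
ring probabilities with bootstrap errors -> free-energy landscape and
weighted helicity distribution -> manifest.

The configuration is schema-validated (pydantic) before any compute; one
master seed fans out to named per-stage seeds, all recorded in the run
manifest so the run can be replayed bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cluster import MicrostateKMeans
from .containers import RingDefinition
from .decomposition import TICA, feature_tic_correlation
from .featurize import (
    DEFAULT_MIN_RUN,
    DEFAULT_PHI_WINDOW,
    DEFAULT_PSI_WINDOW,
    helical_content,
    pairwise_residue_distances,
    ring_pair_distance,
)
from .msm import (
    MarkovStateModel,
    cross_validated_vamp2,
    implied_timescales,
    select_lag,
)
from .ringprob import (
    DEFAULT_BOOT_FRAC,
    DEFAULT_N_BOOT,
    DEFAULT_TEMPERATURE,
    bootstrap_ring_probability,
    frame_weights,
    free_energy_landscape,
    weighted_helicity_distribution,
)
from .synthetic import SyntheticEnsembleSpec, make_paper_analogue_pair, sample_ensemble
from .trajio import read_pdb_models, write_feature_matrix

__all__ = ["PipelineConfig", "run_pipeline", "PipelineResult"]


class RingConfig(BaseModel):
    thr_residue: int
    cys_residue: int
    mode: Literal["cb_sg", "heavy_min"] = "cb_sg"
    cutoff: Optional[float] = None
    label: str = ""

    def to_ring(self) -> RingDefinition:
        return RingDefinition(self.thr_residue, self.cys_residue, self.mode,
                              self.cutoff, self.label)


class FeaturizeConfig(BaseModel):
    min_separation: int = 2
    atom_mode: Literal["heavy_min", "ca_ca"] = "heavy_min"
    phi_window: tuple[float, float] = DEFAULT_PHI_WINDOW
    psi_window: tuple[float, float] = DEFAULT_PSI_WINDOW
    min_run: int = DEFAULT_MIN_RUN


class TicaConfig(BaseModel):
    lag: int = 10
    n_components: int = 2
    regularization: Optional[float] = None


class ClusterConfig(BaseModel):
    n_clusters: int = 50


class MSMConfig(BaseModel):
    lags: list[int] = Field(default_factory=lambda: [1, 2, 5, 10, 20])
    lag: Optional[int] = None          # fixed lag skips ITS selection
    its_rtol: float = 0.1
    n_timescales: int = 3
    reversible: bool = True
    count_mode: Literal["sliding", "strided"] = "sliding"


class ScoreConfig(BaseModel):
    grid: list[tuple[int, int]] = Field(default_factory=list)
    k: int = 6
    folds: int = 10


class BootstrapConfig(BaseModel):
    n_boot: int = DEFAULT_N_BOOT
    frac: float = DEFAULT_BOOT_FRAC
    with_replacement: bool = False


class SyntheticPairConfig(BaseModel):
    paper_analogue_pair: bool = True
    n_traj: Optional[int] = None
    traj_length: Optional[int] = None


class PipelineConfig(BaseModel):
    """Validated pipeline configuration."""

    trajectories: list[str] = Field(default_factory=list)  # PDB paths
    synthetic: Optional[SyntheticPairConfig] = None
    featurize: FeaturizeConfig = Field(default_factory=FeaturizeConfig)
    tica: TicaConfig = Field(default_factory=TicaConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    msm: MSMConfig = Field(default_factory=MSMConfig)
    score: ScoreConfig = Field(default_factory=ScoreConfig)
    rings: list[RingConfig] = Field(default_factory=list)
    bootstrap: BootstrapConfig = Field(default_factory=BootstrapConfig)
    temperature: float = DEFAULT_TEMPERATURE
    fel_bins: int = 40
    helicity_bins: int = 20
    seed: int = 0
    output_dir: str = "lanmsm_run"

    @model_validator(mode="after")
    def _check(self):
        if not self.trajectories and self.synthetic is None:
            raise ValueError("config needs trajectory paths or a synthetic block")
        if not self.rings and self.synthetic is None:
            raise ValueError("config missing ring definitions")
        return self


class PipelineResult(dict):
    """Mapping ensemble label -> per-ensemble result dict, plus manifest."""


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % 2**31


def run_pipeline(config: PipelineConfig, write_artifacts: bool = True):
    """Execute the full workflow; returns a PipelineResult.

    Artifacts (feature matrices, tables, MSM summary, landscapes, manifest)
    are written under ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    if write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)

    ensembles = _collect_ensembles(config)
    result = PipelineResult()
    digests = {}
    for label, (trajs, rings, truth) in ensembles.items():
        res = _run_one(config, label, trajs, rings,
                       outdir if write_artifacts else None)
        if truth is not None:
            res["ground_truth"] = {
                "stationary_distribution":
                    truth.stationary_distribution.tolist(),
                "implied_timescales": truth.implied_timescales.tolist(),
                "ring_probability": truth.ring_probability,
                "mean_helicity": truth.mean_helicity,
            }
        result[label] = res
        digests[label] = _digest(res)

    manifest = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": config.seed,
        "stage_seeds": {
            s: _stage_seed(config.seed, s)
            for s in ("synthetic", "cluster", "cv", "bootstrap")
        },
        "config": json.loads(config.model_dump_json()),
        "results_digest": digests,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    result.manifest = manifest  # type: ignore[attr-defined]
    if write_artifacts:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return result


def _digest(res: dict) -> str:
    payload = {
        k: res[k]
        for k in ("lag", "ring_probabilities", "mean_helicity")
        if k in res
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=float).encode()
    ).hexdigest()


def _collect_ensembles(config: PipelineConfig) -> dict:
    """label -> (trajectories, ring definitions, ground truth or None)."""
    out = {}
    if config.synthetic is not None:
        seed = _stage_seed(config.seed, "synthetic")
        wt, v1 = make_paper_analogue_pair(seed)
        for spec in (wt, v1):
            if config.synthetic.n_traj is not None:
                spec.n_traj = config.synthetic.n_traj
            if config.synthetic.traj_length is not None:
                spec.traj_length = config.synthetic.traj_length
            trajs, _, truth = sample_ensemble(spec)
            rings = [
                RingDefinition(r.thr_residue, r.cys_residue, "cb_sg",
                               label=r.label)
                for r in spec.rings
            ]
            out[spec.name] = (trajs, rings, truth)
    if config.trajectories:
        trajs = [read_pdb_models(p) for p in config.trajectories]
        rings = [r.to_ring() for r in config.rings]
        out["input"] = (trajs, rings, None)
    return out


def _run_one(config: PipelineConfig, label: str, trajs, rings, outdir):
    fc = config.featurize
    features = [
        pairwise_residue_distances(t, fc.min_separation, fc.atom_mode)
        for t in trajs
    ]
    ring_dists = {
        ring.label: [ring_pair_distance(t, ring) for t in trajs]
        for ring in rings
    }
    helicity = [
        helical_content(t, fc.phi_window, fc.psi_window, fc.min_run)[0]
        for t in trajs
    ]

    tica = TICA(config.tica.lag, config.tica.n_components,
                config.tica.regularization).fit(features)
    projected = [tica.transform(f) for f in features]
    corr = feature_tic_correlation(tica, features)

    n_tics = config.tica.n_components
    n_clusters = config.cluster.n_clusters
    cv_table = None
    if config.score.grid:
        cv_table = cross_validated_vamp2(
            features, config.score.grid,
            lag=config.msm.lag or config.msm.lags[0],
            tica_lag=config.tica.lag, k=config.score.k,
            folds=config.score.folds,
            seed=_stage_seed(config.seed, "cv"),
        )
        best = cv_table.loc[cv_table["mean_score"].idxmax()]
        n_tics, n_clusters = int(best["n_tics"]), int(best["n_clusters"])
        tica = TICA(config.tica.lag, n_tics,
                    config.tica.regularization).fit(features)
        projected = [tica.transform(f) for f in features]

    km = MicrostateKMeans(
        n_clusters=n_clusters,
        random_state=_stage_seed(config.seed, "cluster"),
    ).fit(projected)
    dtrajs = km.predict(projected)

    its_table = None
    lag = config.msm.lag
    if lag is None:
        its_table = implied_timescales(
            dtrajs, config.msm.lags, m=config.msm.n_timescales,
            reversible=config.msm.reversible,
            count_mode=config.msm.count_mode,
        )
        lag = select_lag(its_table, config.msm.its_rtol)

    msm = MarkovStateModel(
        lag=lag, reversible=config.msm.reversible,
        count_mode=config.msm.count_mode,
    ).fit(dtrajs, n_states=n_clusters)
    msm.check_valid()

    boot_seed = _stage_seed(config.seed, "bootstrap")
    ring_results = {}
    for ring in rings:
        dists = [fm.values[:, 0] for fm in ring_dists[ring.label]]
        ring_results[ring.label] = bootstrap_ring_probability(
            dists, dtrajs, lag=lag, cutoff=ring.cutoff,
            reversible=config.msm.reversible,
            count_mode=config.msm.count_mode,
            n_boot=config.bootstrap.n_boot, frac=config.bootstrap.frac,
            seed=boot_seed,
            with_replacement=config.bootstrap.with_replacement,
            ring=ring, label=ring.label,
        )

    weights = np.concatenate(frame_weights(msm, dtrajs))
    hel = np.concatenate([h.values[:, 0] for h in helicity])
    hel_hist, hel_edges = weighted_helicity_distribution(
        hel, weights, bins=config.helicity_bins
    )
    first = rings[0]
    d0 = np.concatenate([fm.values[:, 0] for fm in ring_dists[first.label]])
    fel = free_energy_landscape(
        d0, hel, weights, bins=config.fel_bins,
        temperature=config.temperature,
        coordinate_names=(f"d_{first.label}", "helicity"),
    )

    res = {
        "n_trajectories": len(trajs),
        "n_frames": int(sum(t.n_frames for t in trajs)),
        "n_tics": n_tics,
        "n_clusters": n_clusters,
        "lag": int(lag),
        "tica_eigenvalues": tica.eigenvalues_.tolist(),
        "msm": msm,
        "implied_timescales": its_table,
        "cv_table": cv_table,
        "feature_tic_correlation": corr,
        "ring_results": ring_results,
        "ring_probabilities": {
            k: v.equilibrium_probability for k, v in ring_results.items()
        },
        "ring_errors": {k: v.bootstrap_sd for k, v in ring_results.items()},
        "mean_helicity": float(weights @ hel),
        "helicity_distribution": (hel_hist, hel_edges),
        "free_energy_landscape": fel,
    }
    if outdir is not None:
        _write_artifacts(outdir, label, features, res)
    return res


def _write_artifacts(outdir: Path, label: str, features, res):
    sub = outdir / label
    sub.mkdir(parents=True, exist_ok=True)
    write_feature_matrix(features[0], sub / "features_traj0.csv", "csv")
    res["feature_tic_correlation"].to_csv(sub / "feature_tic_correlation.csv")
    if res["implied_timescales"] is not None:
        res["implied_timescales"].as_frame().to_csv(sub / "implied_timescales.csv")
    if res["cv_table"] is not None:
        res["cv_table"].to_csv(sub / "vamp2_cv.csv", index=False)
    msm = res["msm"]
    summary = {
        "lag": res["lag"],
        "n_tics": res["n_tics"],
        "n_clusters": res["n_clusters"],
        "active_set": msm.active_set_.tolist(),
        "stationary_distribution": msm.stationary_distribution_.tolist(),
        "eigenvalues": msm.eigenvalues_.tolist(),
        "ring_probabilities": res["ring_probabilities"],
        "ring_errors": res["ring_errors"],
        "mean_helicity": res["mean_helicity"],
    }
    (sub / "msm_summary.json").write_text(json.dumps(summary, indent=2))
    hist, edges = res["helicity_distribution"]
    np.savetxt(sub / "helicity_distribution.csv",
               np.column_stack([edges[:-1], edges[1:], hist]),
               delimiter=",", header="bin_left,bin_right,mass", comments="")
    fel = res["free_energy_landscape"]
    np.savetxt(sub / "free_energy_landscape.csv",
               fel.free_energy.filled(np.nan), delimiter=",")
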