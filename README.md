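# lanmsm

Markov-state-model analysis of peptide conformational ensembles for
predicting **lanthipeptide ring-formation site-selectivity**.

Lanthipeptides are ribosomally synthesized peptides cross-linked by
thioether (lanthionine / methyllanthionine) rings, formed when a cysteine
thiol attacks a dehydrated Ser/Thr residue. For promiscuous synthetases such
as ProcM, which ring pattern forms appears to be encoded in the substrate
sequence itself: the solution conformational ensemble of the linear core
peptide determines how often each reactive Thr/Cys pair is close enough to
cyclize. `lanmsm` implements the complete ensemble-analysis pipeline behind
that idea:

1. **Featurization** — all pairwise residue distances with sequence
   separation ≥ 2 (closest-heavy-atom or Cα–Cα), per-ring reactive
   distances (Cβ(Thr)–Sγ(Cys), or closest heavy atom), and per-frame
   α-helical content from backbone (φ, ψ) windows.
2. **tICA** — time-lagged independent component analysis to extract the
   slowest linear collective coordinates.
3. **K-means** microstate discretization (deterministic, seeded).
4. **Markov state model** — transition counting, ergodic trimming, maximum
   likelihood reversible estimation under detailed balance; implied
   timescales t_k(τ) = −τ / ln λ_k(τ) with converged-lag selection; VAMP-2
   scoring (Σ λ_i², first six eigenvalues) with 10-fold cross-validation at
   trajectory granularity for hyperparameter selection.
5. **Least-counts adaptive sampling** — cluster all collected data into 100
   microstates, restart simulations from one random member of each of the 25
   least-populated clusters, repeat.
6. **Ring-formation probability** — the headline statistic

       P_ring = Σ_s π_s · p_s ,

   where π is the MSM stationary distribution and p_s the fraction of
   state-s frames with the reactive pair within the cutoff (7.5 Å Cβ–Sγ by
   default; 4.5 Å closest-heavy-atom alternative). Error bars come from 200
   trajectory bootstrap replicates, each re-estimating the MSM on 80 % of
   the trajectories while keeping the original state labels. MSM frame
   weights also give free-energy landscapes, −k_B T ln p, and weighted
   helicity distributions.

Because no public microsecond MD data accompany this problem, the package
includes a **synthetic conformer-ensemble generator**: hidden-Markov
kinetics between helix-rich and coil-rich conformer templates with
designable Thr–Cys distance propensities, for which the stationary
distribution, implied timescales and ring probabilities are known in closed
form. It is first-class, tested code and the ground truth for every
pipeline stage.

Intended users: computational (bio)chemists studying RiPP cyclization
selectivity, and anyone who wants a small, fully tested, dependency-light
MSM pipeline with exact synthetic ground truth.

## Worked example

Run the built-in synthetic pair — a "WT-like" peptide whose helix leaves the
A′ pair (Thr11/Cys14) apart, and a "Variant1-like" peptide whose longer
helix brings it close:

```yaml
# example.yaml
synthetic:
  paper_analogue_pair: true
  n_traj: 12
  traj_length: 1000
tica: {lag: 10, n_components: 3}
cluster: {n_clusters: 30}
msm: {lag: 5}
bootstrap: {n_boot: 200, frac: 0.8}
seed: 1
output_dir: example_run
```

```text
$ lanmsm run --config example.yaml
wt_like: P_ring {A': 0.0526 +/- 0.0005, B': 0.0903 +/- 0.0007}; mean helicity 0.3202
variant1_like: P_ring {A': 0.6739 +/- 0.0122, B': 0.5853 +/- 0.0105}; mean helicity 0.6643
manifest hash: d7f44374c3e5c86518de4bc81c3e55edac05af934f74f8ebe447b41f3d8ed049
```

Reading the output: each `P_ring` is the MSM-equilibrium probability that
the named Thr/Cys pair is within 7.5 Å (± bootstrap standard deviation);
`mean helicity` is the frame-weight-averaged helical fraction. The
Variant1-like ensemble is both far more helical (0.66 vs 0.32) and far more
likely to close its A′ ring (0.67 vs 0.05) — the designed contrast, whose
closed-form ground-truth values (0.706 and 0.053 for the A′ ring; 0.70 and
0.30 helix occupancy) are recovered within sampling error. The run
directory contains per-ensemble feature matrices, the feature–tIC
correlation table, MSM summary, helicity distribution, free-energy
landscape grid, and a manifest (config hash + per-stage seeds) sufficient
to replay the run bit-exactly.

The same steps are available as a library (`lanmsm.TICA`,
`lanmsm.MicrostateKMeans`, `lanmsm.MarkovStateModel` are scikit-learn-style
estimators) and as individual subcommands: `synth`, `convert`, `inspect`,
`featurize`, `tica`, `cluster`, `its`, `score`, `msm`, `adaptive`,
`ringprob`, `bootstrap`, `fel`, `helicity`, `run`.

## Layout

```
src/lanmsm/
  containers.py     core types: Topology, Trajectory, FeatureMatrix, RingDefinition
  trajio.py         PDB/XYZ reading, CSV + array-container feature persistence
  featurize.py      pairwise distances, ring distances, helical content
  decomposition.py  TICA estimator
  cluster.py        MicrostateKMeans estimator
  msm.py            MarkovStateModel estimator, implied timescales, VAMP-2 CV
  adaptive.py       least-counts adaptive-sampling controller
  ringprob.py       ring probabilities, bootstrap, landscapes, helicity
  synthetic.py      hidden-Markov conformer generator with closed-form truth
  pipeline.py       config-driven orchestration + manifest
  cli.py            click CLI
docs/methods.md     model, assumptions, parameter choices, limitations
```
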