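# Methods

This note documents the models and procedures implemented in `lanmsm`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic test bed does and does not establish.

## The statistic: equilibrium ring-formation probability

Classical MD cannot form chemical bonds, so ring formation is scored
geometrically: a frame is *ring-competent* for a Thr/Cys pair when its
reactive distance is within a cutoff. Two distance definitions are
supported:

* `cb_sg` — the Cβ(Thr)–Sγ(Cys) distance, cutoff **7.5 Å** (default): these
  are the two atoms joined by the thioether bond, and 7.5 Å is the usual
  residue–residue contact scale in folding studies. Dehydrated Thr (Dhb)
  retains its Cβ, so the definition applies unchanged to dehydrated
  peptides.
* `heavy_min` — the minimum over all heavy-atom pairs, cutoff **4.5 Å**, as
  a robustness alternative.

Closure uses a closed interval (d ≤ cutoff); the boundary has measure zero,
but the convention must be fixed for exact tests.

Short adaptively seeded trajectories oversample rare states, so raw closure
fractions are biased. The MSM stationary distribution π removes this bias:

    P_ring = Σ_s π_s p_s ,   p_s = P(d ≤ cutoff | frame in state s).

Equivalently, give every frame in active state s the weight π_s / n_s and
sum weights over ring-competent frames. Both routes are computed on every
call and asserted equal to 1e-12 — a cheap, permanent self-check of the
reweighting arithmetic. States outside the ergodic set get weight zero; an
active state with zero assigned frames cannot occur when the weights are
computed from the same labels the MSM was estimated from (asserted).

`compare_rings` orders candidate rings by P_ring; the argmax is the
predicted first ring to form. If the top two probabilities lie within their
combined bootstrap standard deviation, the comparison is reported as a tie
with no prediction. This prediction concerns solution propensity only: if
the enzyme's own preferences override it (as happens for some substrates),
no amount of ensemble analysis of the free peptide will see that, and
enzyme–peptide modeling is out of scope.

## Uncertainty: trajectory bootstrap

Each of **200** replicates draws **80 %** of the trajectories (rounding up)
*without replacement*, keeps the original per-frame microstate labels (no
re-clustering), re-estimates the MSM on the subsample, and recomputes
P_ring; the replicate standard deviation is the error bar. "Randomly
selected 80 %" cannot be a full-size with-replacement bootstrap, so
without-replacement subsampling is the default; with-replacement drawing is
available as an option. Replicates whose subsample loses ergodic
connectivity are excluded and counted, never imputed. Replicate trajectory
sets are sorted so the degenerate frac = 1.0 case is bitwise-identical
across replicates (sd exactly 0). The sd uses ddof = 1, with an exact-zero
short-circuit when all replicates coincide (a mean over identical floats
can round, and an error bar of 2e-16 is noise masquerading as information).

## Featurization

* **Pairwise distances**: all residue pairs with sequence-number difference
  ≥ 2 (adjacent pairs excluded). The phrase "separated by two or more
  residues" could also mean two residues *in between* (j − i ≥ 3); the less
  restrictive reading is the default and `min_separation` is a parameter.
  The default pair metric is the closest heavy atom (`heavy_min`), the
  common residue-mindist convention in MSM work; `ca_ca` is available for
  speed.
* **Helical content**: residue r is a helix candidate when φ_r ∈
  [−100°, −30°] and ψ_r ∈ [−80°, −5°] — a rectangular window bracketing the
  ideal α-helix point (−57°, −47°) — and counts as helical only inside a
  run of ≥ 4 consecutive candidates (one helical turn). Per-frame content
  is the helical fraction of interior residues; termini lack φ or ψ and are
  excluded from numerator and denominator. No hydrogen-bond (DSSP-style)
  assignment is attempted; the dihedral criterion is explicit and
  configurable, and exact reproduction of any particular helicity histogram
  is not claimed.

## tICA

Solves C_τ v = λ C_0 v with C_τ the symmetrized time-lagged covariance
(lagged pairs pooled within, never across, trajectories) and C_0 the
instantaneous covariance over all frames, regularized on the diagonal by
1e-6 · trace(C_0)/dim unless specified. Choices worth stating explicitly
because conventions differ:

* **Symmetrization** C_τ ← (C_τ + C_τᵀ)/2 assumes reversible dynamics and
  guarantees a real spectrum — standard MSM practice.
* **Scaling**: components are normalized to unit instantaneous variance of
  the projections (eigh's b-orthonormality), *not* kinetic-map scaled. This
  makes downstream K-means geometry well defined.
* **Lag**: default 10 frames; a configuration parameter, since the frame
  interval is an opaque unit (trajectory inputs carry `frame_spacing` but
  it is never assumed to be physical time).

Eigenvalues estimate lag-τ autocorrelations and lie in (−1, 1] up to
sampling noise. The analytic test bed is a discrete Ornstein–Uhlenbeck
process, whose mode autocorrelations are exp(−lag/relaxation time) exactly.

## Microstate clustering

Seeded k-means++ with a single initialization and Lloyd iterations
(scikit-learn backend). Assignment ties break to the lowest center index;
labels are 0-based; per-trajectory boundaries are preserved for transition
counting. Identical input and seed give bitwise-identical centers.

## Markov state model

* **Counting**: sliding window by default (uses all data); strided
  available. No pairs cross trajectory boundaries. The two agree exactly at
  lag 1.
* **Trimming**: estimation restricts to the largest strongly connected
  component of the directed count graph (ties by total counts, then lowest
  state index); trimmed frames get zero weight downstream.
* **Estimator**: maximum-likelihood *reversible* T by the standard
  self-consistent fixed-point iteration on the symmetric flux matrix,
  converged when π changes < 1e-10 in max-norm (cap 10 000 iterations;
  non-convergence raises with the iteration count). Reversibility matches
  the symmetrized tICA and the equilibrium use of π. The non-reversible
  row-normalized estimator is kept for diagnostics; for two states the two
  coincide exactly (every 2-state chain satisfies detailed balance), which
  is used as a test identity.
* **Spectrum**: computed on the π-symmetrized similarity transform
  (reversible: real by construction) and ordered by modulus after λ₁ = 1;
  complex eigenvalues (possible only non-reversibly) are reported by
  modulus with a warning.
* **Implied timescales**: t_k(τ) = −τ/ln λ_k(τ); entries with λ_k ∉ (0, 1)
  are flagged NaN, never silently dropped. `select_lag` returns the
  smallest lag whose top-m timescales each differ from the next larger
  lag's by < 10 % (relative), i.e. the smallest lag at which they have
  converged.
* **VAMP-2**: Σ of squared leading eigenvalues of T. The default counts the
  unit eigenvalue among the **first six** (score ∈ [1, 6]); whether λ₁
  belongs to "the first six" is convention, so `include_stationary=False`
  is available.
* **Cross-validation**: trajectories (never frames) are partitioned into
  **10 folds** by a seeded stream; per fold, tICA, K-means and the MSM are
  refit on training trajectories only (no leakage through cluster
  centers). The test score is 1 + Σ_{i=2..k} ρ_i², where ρ_i is the
  empirical lag-τ autocorrelation, on held-out trajectories, of the i-th
  training eigenfunction (the right eigenvector indexed by the held-out
  frame's state). Held-out frames in trimmed states are dropped; a fold
  with no usable pairs is excluded with a warning. The winning
  hyperparameter point maximizes the mean score.

## Least-counts adaptive sampling

Each round: re-cluster *all* accumulated data from scratch (**100**
clusters), select the **25** non-empty clusters with the fewest frames
(boundary ties broken by a seeded uniform draw), restart one simulation
from a uniformly chosen member frame of each. The controller is
engine-agnostic — it sees trajectories only through `featurizer` and
`frame_extractor` callbacks, and the propagator in this package is the
synthetic generator. "Until convergence" is operationalized as a fixed
round budget, optionally with an early stop when the total-variation
change of the sorted cluster-population distribution between successive
rounds falls below a threshold (a heuristic: sorting makes it insensitive
to relabeling, but it is not a statement about π). The round log (counts,
selections, seed frames, substream seeds) replays the controller's
decisions bit-exactly.

## Free-energy landscapes and helicity distributions

F_bin = −k_B T ln(p_bin / p_max) over a frame-weighted 2-D histogram, with
k_B = 0.0019872041 kcal/(mol·K) and T = 300 K by default (the production
ensemble temperature). Empty bins are masked, never −∞; the most populated
bin sits at 0. Helicity histograms are frame-weight-summed over [0, 1] and
normalized to unit mass.

## Synthetic generator

A hidden Markov chain over conformer states emits jittered backbone
templates; this choice (rather than a Langevin toy) makes every
ground-truth quantity closed-form:

* π_true — leading left eigenvector of the hidden transition matrix
  (irreducibility required and checked);
* true implied timescales — −1/ln λ_k(hidden_T);
* P_true(cutoff) — Σ_h π_h Φ((cutoff − μ_h)/σ_h), because each ring's
  Cβ–Sγ distance is drawn directly from its designed per-state Gaussian
  (the Sγ atom is placed at that distance from the partner Cβ along the
  direction of the Cys Cα). The drawn distance enters as |d|, which
  deviates from the Gaussian law only by the mass below zero (< 1e-10 for
  all shipped parameters).

Templates are built by internal-to-Cartesian (NeRF) chain construction with
standard backbone geometry; the ideal helix (φ = −57°, ψ = −47°) scores
helical content exactly 1 under the default windows and the extended
template (−139°, +135°) exactly 0, which ties the generator's helicity
ground truth to the featurizer's definition. Per-atom Gaussian jitter
(default 0.05 Å) perturbs dihedrals by far less than the window widths.

The paper-analogue pair contrasts a "WT-like" ensemble (30 % helix
occupancy, A′ pair distant even in the helix state) with a "Variant1-like"
ensemble (70 % helix occupancy, A′ pair close in the helix state). The two
specs share the hidden relaxation timescale (λ₂ = 0.95 for both, with
mirrored rates) rather than the full transition matrix — identical matrices
would force identical occupancies and destroy the designed helicity
contrast. A′ closure means: WT (9.5 ± 1.5 Å helix / 12 ± 2.5 Å coil),
Variant1 (5.5 ± 0.8 Å helix / 12 ± 2.5 Å coil), giving closed-form
P_true(A′) of 0.053 vs 0.706 — a contrast comfortably larger than sampling
error at the shipped ensemble size (20 trajectories × 2000 frames by
default; the test suite and acceptance script use 16 × 1200, chosen so the
full pipeline including the 200-replicate bootstrap completes in seconds
while keeping Monte-Carlo error an order of magnitude below the designed
contrast).

**What passing tests show — and don't.** The generator has literally
Markovian hidden kinetics, Gaussian emissions, a perfect correspondence
between hidden states and metastable states, and no intra-basin diffusion,
solvent, or force-field physics. Recovery of its ground truth validates the
*estimators* (counting, trimming, reversible MLE, reweighting, tICA
directions, bootstrap coverage), not the physical realism of any MD
ensemble. Conclusions about real peptides inherit all the usual MD caveats
on top.

## Numerical choices and degenerate inputs

* Row-stochasticity, πT = π, λ₁ = 1 and detailed balance are asserted on
  every estimate (`check_valid`).
* Count matrices with lag ≥ every trajectory length, all-empty clusters,
  rank-deficient covariances without regularization, misaligned
  distance/label arrays, helicity outside [0, 1] and zero in-range weight
  all raise informative errors rather than propagating NaNs.
* Zero-variance features get correlation 0 with a warning in the
  feature–tIC table.
* All randomness flows from explicit seeds: one master seed fans out to
  named per-stage seeds (recorded in the pipeline manifest); synthetic
  specs use named substreams for kinetics and emission.
* The array container stores row-major little-endian float64 with a JSON
  header (byte layout documented in `trajio`); CSV round-trips at 12
  significant digits.

## Known limitations

* The reversible MLE returns a point estimate; no Bayesian MSM posterior,
  hidden-Markov coarse-graining, or Chapman–Kolmogorov plots (Markovianity
  is checked through implied-timescale convergence and the property suite).
* The helix assignment is a dihedral-window heuristic, not DSSP.
* The adaptive-sampling stopping rule is a heuristic; the round budget is
  the primary control.
* Frame spacing is an opaque unit throughout; timescales are reported in
  frames.
* PDB writing covers the standard-residue subset the generator emits; no
  compressed MD formats (DCD/XTC/NetCDF).
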