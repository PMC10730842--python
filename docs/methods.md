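# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `gradcap`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Study design being emulated

A paired two-condition resting-state design: each of `n_subjects` (default
16) contributes one baseline and one drug scan of `n_frames` frames (default
180) at `dt_seconds = 2.0` s, on a parcellation of `n_nodes` nodes (default
350) split evenly over the seven canonical networks VIS, SMN, DAT, VAT, LIM,
FPN, DMN, ordered along the unimodal→transmodal hierarchy at positions
0, 1/6, …, 1.  Thirteen of sixteen subjects carry an 11-dimension
altered-states questionnaire (each dimension an item average in [0, 10]; the
**total is the sum of the 11 dimension scores**, a convention recorded in
`AscScores.total_rule`).

## 2. Generative model

Each frame of a run is

```
x(v, t) = cap_amp · T[s_t](v) + latent_amp · L(v, t) + global_amp · g(t) + noise_sd · ε(v, t)
```

* **CAP states.** `s_t` is an 8-state Markov chain with transition matrix
  `P = ρ·I + (1−ρ)·1πᵀ` (persistence ρ = 0.7 → mean dwell ≈ 6.7 s), so its
  stationary distribution is exactly the target occupancy π.  Baseline
  occupancies: DMN+ .15, DAT+ .12, FPN+ .16, SMN+ .16, VIS+ .12, VAT+ .11,
  GN+ .06, GN− .12.  Topographies `T_k` are network contrasts (DMN−DAT,
  FPN−SMN, VIS−VAT, and a hierarchy-graded global map for GN±) plus
  spatially white per-node texture (SD 0.4 before standardization).  The four
  mirror pairs share (negated) block-plus-texture structure, so within-pair
  spatial correlation is ≈ −0.99.  The texture is what lets correlation
  labelling separate states from the smooth ongoing fluctuations — the
  synthetic analogue of the fine-grained structure of real co-activation
  topographies.  Mirror pairs contrast hierarchy-distant networks so that the
  occupancy-weighted state covariance *reinforces* the hierarchy gradient.
* **Hierarchy-coupled connectivity field.** Every node gets a continuous
  coordinate `u` on the hierarchy axis (its network's position ± 0.08 spread,
  evenly spaced within the network; the `Parcellation` records the constant
  network-level position).  `L` is a Gaussian field with Ornstein–Uhlenbeck
  kernel `corr = exp(−|Δu|/0.15)` over nodes and AR(1) dynamics (φ = 0.6)
  over frames.  The smooth spatial decay is essential: a network-block
  coupling model leaves each node's top-10 % connections entirely inside its
  own block, so row sparsification discards all between-network ordering and
  no hierarchy gradient survives the chain.  With the OU field the exact
  model covariance yields perfectly hierarchy-monotone network means
  (verified in the tests).
* **Global signal and noise.** `g(t)` is AR(1) (φ = 0.6) shared by all
  nodes, amplitude 0.2 at baseline; `ε` is white node noise, SD 1.0.
  Default amplitudes `cap_amp = 0.8`, `latent_amp = 1.6` balance two
  demands: frame labelling needs the CAP term to dominate per-frame spatial
  structure, while the gradient needs the latent field to dominate the
  covariance (`latent/cap ≳ 1.5` keeps the network means monotone).
* **Motion.** Six parameters (rotations already in mm-equivalents) are the
  cumulative sum of N(0, 0.02 mm) derivatives with 0.5 mm spikes at random
  frames (p = 0.03), giving FD ≈ 0.05 mm baseline and ≈ 0.87 mm at spikes.

**Drug condition** (per-subject effect scale `e_s ~ N(1, 0.25)`, truncated):
FPN and SMN hierarchy positions move toward 0.5 by `e_s · 0.20`; global
amplitude rises by `e_s · 0.4`; the chain's stationary occupancy shifts
FPN+ −0.12, SMN+ −0.12, GN+ +0.24 (others renormalized).  Questionnaire
totals are `asc_gain · realized contraction + noise` (drug) vs ≈ 4 points
(baseline), so totals and realized differentiation are negatively coupled.
Effect sizes were chosen so the recovered paired t statistics have the same
order of magnitude as those a 16-subject study of this kind reports (|t| ≈
4–13); with all effects zero the generator is exactly exchangeable across
conditions.

## 3. Preprocessing

Order: drop first 2 frames → censor FD > 0.4 mm plus each offender's
predecessor (mask-based; frames are never deleted, keeping indices aligned
with ground truth) → band-pass 0.01–0.1 Hz → nuisance regression (intercept,
linear/quadratic drift, 6 motion + 6 derivatives, 2 surrogate tissue means)
→ per-node standardization (population 1/N variance).

The band-pass is a **projection**: out-of-band sine/cosine regressors on the
full time grid, evaluated at the retained frames only, are removed by least
squares.  Nuisance regressors are band-passed with the same projection before
regression.  Both steps are then idempotent and commute on processed data, so
re-running the whole chain changes retained values only at machine precision
— the behavior of projection-based filtering with censoring, and the reason a
recursive-filter implementation (which cannot be idempotent and needs gap
interpolation) was not used.  A guard raises a clear error when censoring
plus the stop-band plus the nuisance design would leave fewer than 8 temporal
degrees of freedom.

## 4. Gradients

Chain per scan: Pearson connectivity over retained frames → Fisher z (clip
|r| ≤ 0.999999, diagonal 0) → keep the top `round((1−s)(n−1))` weighted
connections per row (s = 0.90; diagonal excluded; ties broken to the lowest
index; result may be asymmetric) → normalized-angle affinity
`1 − arccos(cos)/π` (symmetrized, unit diagonal; negative z values are
handled by the angle, no sign-censoring) → diffusion embedding with
α = 0.5: `W = A/(d^α dᵀ^α)`, Markov operator `P = D̃⁻¹W`, eigenvectors via
the symmetrized operator, `ψ_ij = v_ij/v_i0` (unit-norm symmetric
eigenvectors), components scaled by `λ/(1−λ)` (the damped automated-time
convention) or `λ^t` for t > 0.  Disconnected affinity graphs raise an error
listing component sizes; near-degenerate leading eigenvalues record a
warning on the result.  Pre-alignment component signs set the
largest-magnitude element positive.

**Alignment.** Each scan's embedding is Procrustes-rotated (orthogonal, no
scaling) onto a template.  The default template is the diffusion embedding of
the generator's *noise-free baseline model covariance*
(`synth.model_covariance`), oriented so the principal component correlates
positively with the hierarchy — the synthetic analogue of aligning to an
external large-sample reference.  This choice matters: building the template
from the cohort's own 16 noisy baseline embeddings (`build_reference`, still
available via `reference_source="cohort_baseline"`) gives the template a
shared rotation error that mixes higher-component condition effects into
component 1 *identically for all subjects*, producing occasional
cohort-coherent sign reversals of the small network contrasts.  An external
(or noise-free) template has no cohort-correlated error, so only per-subject
noise remains and the paired design handles it.

Statistics use per-scan network means of the aligned principal component;
group-average-connectivity gradients are for display only.

## 5. Co-activation patterns

Centroids come either from k-means on stacked frame maps (frames z-scored
across nodes so squared Euclidean distance is monotone in Pearson
correlation; `n_init = 10` restarts; empty clusters re-initialized by the
solver) matched to template topographies by Hungarian assignment on spatial
correlation — or, the pipeline default, directly from the generator's
topographies, mirroring the supervised use of centroids determined on an
external sample.  Every retained frame is assigned to the
highest-correlation centroid (ties to the lowest index with a warning);
censored frames are excluded.  Occurrence rates divide by retained frames by
default; the acquired-frame denominator is a config switch
(`CapConfig.denominator`), since "total volumes per scan" is ambiguous under
censoring.

## 6. Statistics

* Paired two-tailed t (df = n−1); identical pairs return t = 0, p = 1; a
  zero-variance nonzero-mean difference is an error.
* Bonferroni `p_adj = min(1, m·p)` with fixed family sizes: 7 networks,
  8 CAPs, 7 gradient–behavior tests, 3 CAP–behavior tests.
* Spearman ρ (average ranks for ties), two-tailed p, 95 % CI via Fisher z
  with SE `1/√(n−3)`.
* Repeated-measures ANCOVA: OLS `dep ~ C(subject) + C(condition) + fd`
  (type-II F for condition).  A constant FD covariate is dropped with a
  warning, in which case F = t² exactly.
* Cluster-extent threshold: Gaussian noise fields on the node lattice,
  Gaussian-smoothed to the requested FWHM (in voxel units; 0 = none,
  0 < FWHM < 1 voxel is an error), standardized, thresholded two-tailed at
  `voxel_p`; the minimum cluster size is the ceiling of the (1−fwe_p)
  quantile (≥ 1) of the per-iteration maximal 26-connected cluster size,
  over ≥ 1000 iterations.  Node contrast maps threshold per-node paired t at
  the same two-tailed level and keep same-sign 26-connected lattice clusters
  at least that large.

## 7. What the synthetic world does and does not show

Passing tests demonstrate that the estimation chain recovers planted
geometry, dynamics and their couplings at realistic noise, sample size and
scan length, with calibrated type-I error on null cohorts.  They do not
demonstrate robustness to properties real fMRI has and the generator lacks:
spatial smoothness of noise, physiological confounds correlated with the
signal, imperfect parcellations, non-Markovian state dynamics, or
inter-subject anatomical variability.  Two further honest discrepancies:

* **Gradient range.** In this synthetic world the planted contraction shifts
  the leading eigenvalue, and the `λ/(1−λ)` damping rescales the whole
  embedding by a few percent; a paired t on 16 subjects can detect that,
  even though the change is an order of magnitude smaller (relatively) than
  the planted network shifts.  The tests therefore assert the relative-
  magnitude form of range insensitivity rather than strict non-significance.
* **Frame labelling under the full cocktail.** With all fluctuation sources
  at default amplitude and the 0.01–0.1 Hz band-pass smearing short state
  dwells, frame accuracy is far below the ≥ 95 % achieved on pure-state
  frames with white noise; occupancy *contrasts* remain reliably detectable,
  which is what the recovery tests measure.

## 8. Problem sizes

Default study conditions are 16 subjects × 2 conditions, 350 nodes, 180
frames.  The replicate Monte-Carlo recovery check uses 100 planted and 100
null cohorts at these sizes; unit tests use 70–350 nodes and 50–5 000
frames.  `scripts/acceptance.py` uses 30 replicate cohorts per rate by
default (`--replicates` raises it), which bounds a rate estimate's
Monte-Carlo SE at about 9 percentage points while keeping the run to a few
minutes on one CPU.
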