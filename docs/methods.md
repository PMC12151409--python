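# Methods

## Model and procedure

OART is a one-class variant of adaptive resonance learning on feature
vectors in [0,1]^m.  Each feature carries a switch `f[i] ∈ {0,1}` and a
long-term memory `z[i] ∈ [0,1]`.  A *round* presents a shuffled sequence of
acceptable training plans: the memory is initialized to the round's first
plan (all switches on; that plan is not re-presented within the first
epoch, though it reappears in the second epoch's shuffle), and every
subsequent plan triggers a resonance check per active feature,

- resonant (`|x[i] − z[i]| ≤ σ`, boundary inclusive):
  `z[i] ← (1−α)z[i] + αx[i]`, switch stays on;
- non-resonant: switch turns off for the remainder of the round, memory
  frozen at its last resonant value;
- inactive features are neither checked nor updated.

Updates are strictly per-feature, so the vectorized implementation is
bitwise-equal to an independent scalar recursion per feature — the test
suite asserts this on randomized instances, which is the strongest
correctness oracle the dynamics admit.

A round uses two shuffled epochs; if every feature dies mid-round the
remaining presentations are no-ops.  Training runs `E` rounds with fresh
shuffles.  Features surviving at least `γE` rounds are *stable* (`F_σ`);
the threshold comparison carries an absolute 1e-9 slack because `0.9·20`
is 18.000000000000004 in binary floating point and the boundary case
(exactly 18 survivals) must count as stable.  The memory `z̄_σ` averages the
terminal values over **all** rounds, including rounds in which the feature
died (frozen value used) — the averaging rule is applied uniformly rather
than conditioning on survival, keeping `z̄_σ` defined for every feature.

The same `E` per-round shuffles are reused across the whole σ grid (a
single seeded stream).  This makes the σ-nesting property exact rather than
statistical: a feature that never breaks the tighter band follows the
identical memory trajectory under the looser band, hence
`σ₁ ≤ σ₂ ⇒ F_σ₁ ⊆ F_σ₂`, asserted per-feature on survival counts.

An adaptive epoch schedule (`adaptive_epochs=True`) keeps appending
shuffled epochs until the survivor count changes by less than 0.1%
(relative), capped at `max_epochs`; the default is the fixed two-epoch
round, which keeps the nesting argument exact (per-σ adaptive stopping
could break shuffle sharing across σ).

## Parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.1 | learning rate; small so memories drift only slightly toward each resonant plan.  α ∈ [0,1); α = 0 is the frozen-memory limit, for which survival has the closed form `max_k |x_k[i] − x_first[i]| ≤ σ` (tested). |
| γ | 0.9 | survival proportion for stability; high, to keep only features that survive nearly every shuffle. |
| E | 20 | training rounds; conservative — stable-set sizes settle well before 20 rounds on the synthetic data. |
| epochs/round | 2 | the survivor count plateaus during the second pass (see limitations). |
| σ grid | U = {0.01,…,0.99} step 0.02 | vigilance values; the sensitive half Ũ = {0.01,…,0.49} excludes large σ where little feature selection happens. |
| ν grid | {0.01,…,0.99} step 0.01 | OSVM complexity values; one separator per usable (σ, ν). |

## Scoring and attribution

The σ-sum score `Σ_σ Σ_{i∈F_σ} |x[i] − z̄_σ[i]|` is monotone in every
per-feature deviation and satisfies an exact translation identity: adding
δ to one feature (same side of the memory) raises the score by δ times the
number of σ values at which that feature is stable.

Category attribution reports, per σ, the mean deviation over the
category's stable features, averaged over the σ values where the category
has at least one stable feature.  A pooled normalization constant of the
form `1/(|grid|·|F_σ|)` is ill-defined when `|F_σ|` varies with σ, so the
per-σ mean is used; categories with no stable feature at any σ are
reported as absent rather than zero.

The OSVM ensemble fits sklearn's `OneClassSVM` (libsvm, RBF kernel) on the
training deviations per (σ, ν) cell, skipping σ values with empty stable
sets; decision values are summed into `S̄` (positive = acceptable) and
negated at the module boundary so every classifier hands the metrics
module "higher = more anomalous" scores.  The kernel width defaults to the
`scale` policy, `1/(|F_σ|·var Δ)`.  The autoencoder is a single-bottleneck
`MLPRegressor` (tanh activation, L2 weight decay as the regularizer,
width selected by training reconstruction error); its anomaly score is the
per-plan mean squared reconstruction error.

## Normalization

Min-max scaling is fitted on training rows only and applied without
clipping: test values outside the training range keep their excess, since
clipping would shrink exactly the deviations the score must detect.
Degenerate (constant) training columns use denominator 1, i.e.
`scaled = x − min`: training values map to 0 while an out-of-range test
value keeps its offset — the natural convention for zero-filled
absent-feature columns, whose anomalous non-zero values must stand out.

## Metrics

Constrained metrics (Sens80/Spec80/Sens100/Spec100) are computed by an
exact sweep: thresholds at midpoints between consecutive unique scores
plus sentinels, rule "anomalous iff score > threshold", optimum under the
floor constraint; infeasible floors yield 0.  AUC is the Mann–Whitney
probability with ties counted half.  The bootstrap resamples with
replacement *within* each class (B = 100 by default), which keeps both
classes present in every replicate without redraw logic, and reports the
mean with a 95% t-interval, `t₀.₉₇₅,B₋₁ · sd/√B`.

## Synthetic data

The generator emulates the shape of clinical plan-QA tables: 140
acceptable vs 15 unacceptable samples (mirroring the heavy imbalance of
real QA archives), 300 features split 50/25/25% across ROI/dose/machine
categories, 20 planted near-constant features per category (center drawn
uniformly in [0.25, 0.75], within-class half-range τ = 0.02), all other
features iid uniform on [0,1].  Anomalies are drawn from the acceptable
law and then shifted by δ = 0.4 on a fraction ρ = 0.5 of one target
category's planted features (clipped to [0, 1.5]) — near-misses that share
the nuisance structure of acceptable plans.  Uniform rather than Gaussian
noise keeps all values bounded in [0,1], matching min-max-scaled inputs.

The generator emits features **already on the normalized scale**: it
models the data as seen after min-max normalization.  Re-fitting min-max
on a generated training split would stretch every near-constant planted
column onto [0,1] and erase exactly the structure the generator defines,
so the synthetic study pipeline feeds the values to OART directly
(`scale=False`); scaling-specific behavior (degenerate columns, no
clipping) is exercised separately, e.g. with τ = 0 where planted columns
become genuinely degenerate.

With τ = 0.02 and α = 0.1, every planted feature provably survives any
σ ≥ 2τ (memory stays a convex combination of values within ±τ of the
center), and the conservative analytic bound `2τ + 2α < σ` is the one the
recovery checks use; at σ below ≈ 2τ planted features die like noise.
What passing synthetic tests do *not* show: performance on real clinical
features with correlated, clustered, non-uniform distributions, nor
robustness to anomaly mechanisms other than additive category shifts.

## Known limitations

- The two-epoch plateau (survivor count changing < 0.1% during the second
  epoch of every round) does **not** hold universally on the default
  synthetic data: with iid uniform non-stable features, at mid-range
  vigilance (σ ≈ 0.5–0.75) a noise feature occasionally survives the first
  epoch by presentation-order luck and dies in the second (measured ≈ 18%
  of σ-round combinations, all outside the sensitive grid Ũ).  On
  clustered real-world features the plateau is far cleaner; the
  corresponding end-to-end test documents this honestly and fails.
- σ cannot be tuned as a hyper-parameter in a one-class setting (no
  validation signal from the missing class); the grid-sum aggregation is
  the mitigation.
- The study sizes (20 replicates, 300 features, 155 samples) are the
  package's default desk-scale conditions; all are configurable.
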