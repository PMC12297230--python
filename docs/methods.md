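# Methods

This note records the models and procedures `painswarm` implements, the
parameters that matter, and the design choices made where the published
description left the design open.

## 1. The classifier and its fitness

The classifier is a fully connected network with one hidden layer:
`n_input` features → `n_hidden` ReLU units → 2 softmax outputs. Defaults
follow the study design: 256 hidden units, dropout rate 0.5, two output
classes. All weights and biases are flattened into a single real vector in
the fixed order (W1 row-major, b1, W2 row-major, b2); this vector *is* a
particle position, so the optimizer never needs gradients.

Fitness of a parameter vector on data `(X, y)` is

    f(θ) = −(1/n) Σ_i log p_θ(y_i | x_i) + λ (‖W1‖²_F + ‖W2‖²_F),  λ = 0.01.

Numerical choices:

- probabilities are clipped below at 1e−12 before the log, so fitness is
  finite for any finite parameter vector;
- the L2 penalty covers weight matrices only, not biases (the conventional
  reading of "L2 regularization");
- `argmax` ties at prediction time break toward class 0.

**Dropout under swarm training.** Dropout makes the fitness a random
function, which would give each particle a different objective. By default
dropout is therefore disabled during fitness evaluation
(`dropout_mode="off"`), keeping the swarm's objective deterministic. A
fidelity mode (`fixed_mask_per_epoch`) draws one seeded keep-mask shared by
every particle, reproducing dropout's regularising effect without breaking
comparability between particles. Inference never applies dropout; masks use
inverted scaling (survivors multiplied by 1/(1−rate)) so no rescaling is
needed at test time.

## 2. Particle swarm optimizer

Velocity and position updates, per particle and epoch:

    v ← w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x),  clamped to [−v_max, v_max]
    x ← x + v

Defaults: 100 particles, c1 = 0.5, c2 = 0.3, v_max = 0.2, positions
initialised Uniform(0, 1), velocities Uniform(−v_max, v_max), at most 1000
epochs, early-stopping patience 10.

Design choices where the published description is ambiguous or silent:

- **Inertia.** Both a fixed w = 0.9 and a linear 0.9 → 0.4 decay are part of
  the design; the implementation exposes both (`w_mode`), with fixed 0.9 as
  the default and the decay schedule
  `w = (T_max − G)(0.9 − 0.4)/T_max + 0.4` selectable.
- **Random factors.** r1, r2 are scalar draws per particle per epoch (the
  update equations are written with scalar r's); `per_coordinate_r=True`
  switches to per-coordinate draws.
- **Velocity initialisation** is Uniform(−v_max, v_max) — "small random
  values" made concrete by the clamp bound.
- **No position clamping.** [0, 1] is an initialisation range for network
  weights, not a box constraint; positions may leave it.
- **pbest/gbest update asynchronously**: each particle's improvement is
  visible to later particles within the same epoch.
- **Early stopping** monitors, by default, a 20% validation slice carved
  from the training fold; monitoring the held-out test fold (as the original
  stopping rule describes) leaks test information into training, so that
  behaviour is available only explicitly (`monitor_on_test=True`) and is
  labelled in the run fingerprint. "Improvement" means a monitored-loss
  decrease greater than 1e−6; stagnation for `patience` consecutive epochs
  stops the run.
- **Penalty convention.** A non-finite fitness value is replaced by +inf
  with a warning, so constraint-violating or overflowing parameter vectors
  lose every pbest/gbest comparison.

The binary variant replaces the position update with the probabilistic rule
`x_d = 1 with probability sigmoid(v_d)`, a fresh uniform draw per
coordinate. It is exposed for discrete searches (e.g. feature masks) and is
not part of the default classification path.

## 3. Preprocessing chain

Fixed order: drop identifier → integer-cast target → stratified 80/20 split
(seed 42 by default) → SMOTE on the training fold only → z-score
standardisation. Choices:

- **Per-region targets.** The experiment runner fits one binary model per
  anatomical region with that region's *current pain* column as the label
  (nine tasks). All other pain columns — same-region impairment/last-7-days
  outcomes and every other region's outcomes — are excluded from the feature
  set by default, because they are near-proxies of labels; a fidelity flag
  (`include_same_region_outcomes`) restores the same-region companions.
- **SMOTE** is implemented in-package: each synthetic row is
  `x + u(x_nn − x)`, `u ~ U[0,1]`, with `x_nn` one of the k = 5 nearest
  minority neighbours (Euclidean; k shrinks to minority−1 when the class is
  small, and a singleton minority is duplicated with a warning). Originals
  are preserved verbatim; already balanced folds pass through unchanged; the
  test fold is never resampled.
- **Scaler** is fitted on the SMOTE-augmented training matrix (normalisation
  follows resampling in the pipeline order) and applied unchanged to the
  test fold; `scale_before_smote=True` flips that. Constant columns
  standardise to zero with a warning (divide-by-one convention).
- **Missing data** default to the zero-fill convention of the source data
  (`policy="zero"`); `drop_row` is the only alternative.

## 4. Synthetic cohort generator

The generator emulates a 350-person occupational cohort's published summary
statistics so every downstream stage is testable without the original data.

**Dependence model.** Each row draws a latent standard-normal vector with a
specified correlation matrix (Gaussian copula): one coordinate per
continuous/categorical margin, one per region's current-pain outcome, and
one per impairment / last-7-days outcome. Headline published correlations
(age↔experience +0.90, age↔rank +0.897, exercise↔days/week +0.886,
days/week↔hours/day +0.779, knee pain↔exercise days −0.188, hip
pain↔exercise days −0.166, body mass↔knee last-7-days +0.142, plus a 0.5
weight↔height coupling behind the derived BMI) are written into the latent
matrix; unspecified pairs default to 0. Continuous–continuous rank targets
are converted with the copula identity `r = 2·sin(π·ρ/6)`; pairs involving a
thresholded coordinate use the target directly and are attenuated by
discretisation, so for them the guaranteed property is monotonicity (a
larger target yields a larger realised correlation), not exact recovery.
Because age correlates ≈0.9 with both experience and rank while those two
default to 0, the target matrix is not positive semidefinite; it is
projected to the nearest PSD correlation matrix (alternating projections)
with a warning, which proportionally shrinks the conflicting entries.

**Margins.** Continuous variables are truncated normals; ordinal variables
(rank, work days, exercise days) are additionally rounded to integers;
categorical mixes (sex 62/38, college 40/15/25/12/8, extra work 80%,
exercise 55%) come from latent thresholds. The parent (μ, σ) of each
truncated normal is *calibrated* by least squares so the truncated (and
rounded) variable reproduces the published mean and sd — naive
parameterisation by the printed values would bias the mean visibly (e.g.
experience: lower bound 1 truncates ~15% of a N(9.87, 8.56²)). Two published
(mean, sd, min, max) quadruples — age (32.45, 8.23, 24, 73) and experience
(9.87, 8.56, 1, 50) — are *jointly infeasible* for this family: with the
mean that close to the lower bound no truncated normal reaches the printed
sd. Likewise rank's sd 1.23 is unreachable for a rounded truncated normal on
{1..5} at mean 2.45. For these margins the calibration prioritises the mean
(weighted residual) and accepts an sd shortfall of ≈0.08–0.10; feasible
margins calibrate both moments essentially exactly.

**Pain outcomes.** Current pain is the latent coordinate thresholded at the
published prevalence. Impairment and last-7-days indicators are drawn at the
back-solved conditional rate (published marginal frequency divided by
prevalence, clipped to [0, 1] with a warning) and multiplied by the current
indicator — so a row can never report impairment or recent pain without
current pain (structural zero), and the marginal frequencies match the
published ones in expectation. BMI is recomputed from generated weight and
height rather than drawn, preserving the BMI identity exactly; its implied
mean (≈27.3) differs slightly from the printed 27.45, which is why the
margin checks run on weight and height.

**What the generator does not emulate.** The real cohort's joint
feature–outcome dependence beyond the listed pairs, any skewness beyond what
truncation induces, item non-response patterns, and the reported count of
pain-free participants. Passing pipeline tests on synthetic cohorts
therefore demonstrates correctness of the machinery, not the published
accuracy levels, which depend on the original data.

**Separable fixture.** `make_separable_cohort(n, gap, seed)` starts from a
default cohort, computes a fixed unit-norm linear score over six
standardised continuous columns, labels rows by its sign, and shifts each
row ±gap/2 along the score direction — giving linearly separable classes
with margin `gap` (verified by an LP feasibility oracle in the tests) while
remaining schema-valid. `gap = 0` instead assigns independent fair coin
flips (no signal). The label is written to every region's current-pain
column so any region can serve as the target.

## 5. Evaluation

Class 1 is positive; the confusion matrix is `[[TN, FP], [FN, TP]]`.
Precision, recall and F1 are computed per class and macro-averaged; 0/0
ratios are reported as 0 with a warning and *kept* in the macro mean. AUC
uses the rank (Mann–Whitney) formulation with average ranks, so ties count
one half — the probabilistic definition itself; ROC points enumerate
distinct score thresholds from (0, 0) to (1, 1). Correlation reports use
Pearson r; constant columns yield NaN (flagged), never a fabricated 0. The
sample-size calculator returns `max(1, ceil(Z²·P(1−P)/d²))`; at
Z = 1.96, P = 0.65, d = 0.05 this is 350.

## 6. Problem sizes used in the automated checks

The test suite scales the expensive stages down while keeping every
mechanism intact: the optimizer-correctness check runs 30 particles for 200
epochs on a 1-D quadratic; the end-to-end pipeline check trains a 32-unit
hidden layer (546 parameters) with the full 100-particle swarm on a 300-row
margin-3 cohort across five seeds; generator fidelity is checked at
n = 10,000; metric implementations are compared against brute-force oracles
on 200 random instances each. The experiment-runner defaults remain the
study's values (256 hidden units, 100 particles, 1000 epochs, patience 10).

## 7. Known limitations

- PSO over a 256-unit network is a ~10⁴-dimensional search; with desk-scale
  swarms it finds good but not gradient-quality optima, and runtime grows
  linearly in particles × epochs × data size.
- The copula reproduces pairwise, not higher-order, dependence; correlation
  targets involving thresholded variables are attenuated.
- Only binary outcomes per region are supported (no multi-class pain-type
  encoding), and imputation is limited to zero-fill or row dropping.
- Early stopping on a validation slice makes the effective training set
  slightly smaller than the resampled fold; the test-monitored fidelity mode
  restores the original behaviour at the cost of leakage.
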