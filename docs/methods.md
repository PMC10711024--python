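# Methods

This note documents the statistical models, algorithmic choices and known
limitations of `shellopt`. The package reimplements the computational
workflow of a published ultrasound-assisted extraction (UAE) optimization
study of green coconut shell; every constant transcribed from that study
lives in `shellopt/reference.py` and is used only as ground truth for
simulation and as fixtures for contract tests — never as a shortcut inside
a user-facing fit.

## Design and coding

The three process factors are sonication time A (10–30 min), temperature B
(30–40 °C) and the denominator C of the 1:X g/ml solid–solvent ratio
(10–30). The coded transform is the exact affine bijection
`x = (X − center)/half_range`, mapping low/center/high to −1/0/+1.

The Box-Behnken design is the standard three-factor layout: the 12
edge-midpoint runs (all ±1 pairs over each factor pair, third factor at 0)
plus replicated centers. The source study reports 18 runs without stating
the center replication; 12 + 6 is the only BBD decomposition reaching 18,
so `center_reps` defaults to 6. That leaves 8 residual degrees of freedom
for the 10-coefficient quadratic (9 model df), matching the study's ANOVA
layout, with 5 pure-error df from the centers and 3 lack-of-fit df. Run
order is deterministic standard order (edge runs in factor-pair order,
centers last); a seeded shuffle is optional, since the study does not
report randomization.

## Response-surface models and ANOVA

Each response is fit by ordinary least squares on the 10-term coded basis
[1, A, B, C, AB, AC, BC, A², B², C²]. On the BBD this basis is
well-conditioned and near-orthogonal, so coefficients are invariant to run
order and sequential (type I) single-df sums of squares — computed from the
QR decomposition of the model matrix — coincide with partial sums of
squares. ANOVA statistics follow the conventional response-surface
definitions:

* per-term F = term SS / residual MS; model F = (model SS/9)/residual MS;
* pure error from replicated design points only (the center replicates are
  the only replicated point in a 12+6 BBD); lack of fit = residual − pure
  error. With no replicates the lack-of-fit fields are `None`, not zero;
* CV% = 100 · residual SD / mean response;
* predicted R² = 1 − PRESS/SS_total, PRESS computed in closed form from
  leave-one-out residuals e_i/(1 − h_ii). The source study names but never
  defines its "predicted R²"; this is the conventional definition.

The study prints a residual SD of 0.33 and mean 27.24 for yield, implying
CV 1.21%, yet prints CV 1.25% — a rounding inconsistency in the source.
The implementation always computes CV from its own fit.

Tests cross-check the fit against `statsmodels` OLS and the sequential SS
against `statsmodels`' type-1 ANOVA, and PRESS against explicit
leave-one-out refits.

## Network surrogate

The surrogate is a single-hidden-layer feed-forward network with `tansig`
(hyperbolic-tangent sigmoid) hidden units and a linear output layer,
mapping the three factors to the five responses (3-h-5). Choices the source
study leaves unstated, fixed here:

* **Scaling.** Inputs and outputs are min-max scaled to [−1, 1] (tansig's
  range, and the common MATLAB convention). The scalers are serialized with
  the model so the assumption is explicit.
* **Optimizer.** Plain full-batch gradient descent on the MSE with a fixed
  learning rate drawn once per run from [0.5, 1]. A step that would
  increase the training MSE is rejected and the step size halved, so the
  accepted-loss trajectory is non-increasing. No momentum, regularization
  or early stopping (the iteration budget, default 2000, is the only stop).
* **Split.** Seeded random permutation into 70/15/15 train/test/validation
  (nearest-integer, remainder to training): 12/3/3 on an 18-run design.
* **Selection.** For each hidden width in the search range (default 2–8),
  10 independently seeded runs; the winner has the highest validation R²
  (ties: lower validation MSE, then fewer hidden units).

The published weight/bias set of the study's selected 3-4-5 network is
bundled (41 values: 4×3 input-hidden weights, 4 hidden biases, 5×4
hidden-output weights, 5 output biases, row-major with hidden-major
input-hidden rows and output-major hidden-output rows, the orientation the
shapes force). Because the study's scaling and training data are
unpublished, these weights support forward-pass contract tests only — they
cannot reproduce the study's predicted responses in natural units, and
retraining cannot reproduce the weights bit-for-bit.

**Committee surrogate.** With 18 runs, the 3-point validation split is too
small to single out one well-generalizing network, and individual
small-data networks behave erratically in the factor-box corners where the
BBD places no runs. `train_committee` therefore keeps every network from
the architecture search and predicts with their equal-weight mean; measured
on synthetic data, the committee's optimization quality dominates any
single selected network's, and it is the recommended model for
`optimize_process`. `select_architecture` still returns the single best
validator for users following the original protocol.

## Particle swarm optimizer

Maximization is native. The update is the classic inertia-weight form with
independent uniform draws per particle and per dimension (the scalar
notation of the usual equations is ambiguous; independence is the standard
reading). Hyperparameters follow the study: 40 particles, c1 = c2 = 0.5,
inertia linearly *increasing* 0.4 → 0.6 (taken literally, although
decreasing schedules are more common; the schedule is a config field), and
a fixed generation budget (default 2000) as the sole stopping rule.
Boundary handling clamps positions to the box and zeroes the velocity on
clamped dimensions; velocities initialize uniformly in ±0.2 × range.

Two reliability measures address a measured failure mode: with these weak
acceleration constants the swarm contracts quickly, and the extraction
surfaces are multimodal over the factor box (distinct corner and interior
maxima), so a purely random initial swarm collapsed into the wrong basin in
25–75% of runs. (1) The initial swarm is seeded with the 3^M factorial
lattice of the bounds — corners, edge/face midpoints and center — so every
corner basin informs the initial global best; this removed all observed
failures on the five reference surfaces. (2) `optimize` runs several
independently seeded restarts (default 5) and reports the best. Both are
recorded in result metadata.

## Composite fitness and validation

The study "formulated" a fitness maximizing all five responses without
defining it. Here the fitness is the equal-weight sum of min-max-normalized
predicted responses, with the normalization ranges taken from the observed
training-data response ranges and the weights exposed in `FitnessSpec`.
Optimization runs over natural units with the design box as default bounds;
the surrogate scales internally. Degenerate point bounds short-circuit the
swarm and return the model evaluated at the point.

Percent error against confirmatory experiments uses the experimental value
in the denominator — the only convention that reproduces the study's
printed validation errors (2.31, 0.32, 2.35, 0.33, 1.67) — and is rounded
to two decimals only for display.

## Synthetic data

`simulate_bbd_experiment` draws each response as its published surface
value at the design point plus independent homoscedastic Gaussian noise
with SD equal to the published residual SD of that response's fit
(noise_scale rescales all SDs; 0 gives exact surface values). This is the
minimal model consistent with the reported pure-error and lack-of-fit
statistics. It deliberately omits: cross-response noise correlation
(plausible, since all assays share extracts), assay-level replication
below the run level, and any lack of fit of the quadratic itself — so
passing tests demonstrate correctness of the machinery under the assumed
model, not the adequacy of a quadratic for real extraction data.
`sample_surface_dataset` additionally draws uniform off-design points for
surrogate-capacity checks.

## Problem sizes and numerical choices

* Grid oracles for the swarm use 201 points per axis (the discretization
  error at interior maxima of the steepest surface is then below the 1e−3
  comparison tolerance); end-to-end pipeline checks use 20 seeds with the
  full architecture search (70 networks) and 300-generation swarms.
* Exact-recovery assertions use 1e−8 (coefficients), 1e−10 (forward pass
  vs oracle), 1e−12 (coding and scaling round trips).
* Rank deficiency of a design raises rather than silently pseudo-inverting;
  non-finite objective values abort a swarm run with the offending position.
* Ties in architecture selection break toward fewer hidden units;
  ties in the swarm's argmax bookkeeping keep the earlier best.

## Known limitations

* The study's exact optimum (15 min, 33 °C, 1:24; predicted yield 38.41%)
  is not recoverable: the raw 18-run data, the scaling, and the fitness
  definition were never published. The pipeline is instead validated end to
  end on synthetic data, where it attains ≥95% of the true-surface optimum.
  Qualitatively, optima found on synthetic data agree with the study's:
  interior or near-boundary points with shorter time, mildly reduced
  temperature, and a higher solvent ratio than the center.
* The study's predicted optimum responses exceed its own reported observed
  ranges (e.g. yield 38.41% vs a 19.98–36.1% range) — surrogate
  extrapolation in the source, noted here and not "corrected".
* The source prints the flavonoid range identically to the phenolic range
  in one place and its best architecture once as "3-4-2"; the consistent
  readings (distinct ranges; 3-4-5) are adopted. Printed ranges are not
  used as constraints anywhere.
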