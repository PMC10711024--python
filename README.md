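# shellopt

Response-surface and hybrid ANN-PSO optimization of ultrasound-assisted
extraction (UAE) of phytochemicals from green coconut shell.

Green coconut shell is an abundant processing waste rich in phenolics,
flavonoids and tannins. A published UAE optimization study modeled five
extraction responses — yield (%), total phenolics (mg GAE/g), total
flavonoids (mg QE/g), total tannins (mg TAE/g) and DPPH antioxidant
activity (%) — as functions of three process factors: sonication time
(10–30 min), temperature (30–40 °C) and solid–solvent ratio (1:10–1:30
g/ml), using an 18-run Box-Behnken design (BBD), coded second-order
response-surface models, a feed-forward neural-network surrogate, and
particle swarm optimization of all five responses jointly. This package
reimplements that computational workflow as a tested, reusable library
for process scientists who want to reproduce, audit, or reuse the method.

## The method

* **Design** (`shellopt.design`): the 12 edge midpoints of the three-factor
  cube plus 6 replicated centers; factors are coded
  `x = (X - center) / half_range` onto [-1, 1].
* **Response-surface models** (`shellopt.rsm`): for each response, ordinary
  least squares on the 10-term coded basis

  `y = b0 + b1 A + b2 B + b3 C + b12 AB + b13 AC + b23 BC + b11 A² + b22 B² + b33 C²`

  with a full ANOVA: sequential single-df term sums of squares, lack of fit
  against pure error from the center replicates, CV% = 100·s/ȳ, R²,
  adjusted R², and predicted R² = 1 − PRESS/SS_total.
* **Surrogate** (`shellopt.ann`): a 3-h-5 feed-forward network,
  `y = W_ho · tansig(W_ih x + b_h) + b_o`, trained by back-propagation on
  min-max-scaled data with a 70/15/15 train/test/validation split;
  architecture search keeps the best validator, and a committee (ensemble
  mean) over all searched networks is provided for optimization.
* **Optimizer** (`shellopt.pso`): standard PSO, 40 particles,
  `v ← w v + c1 r1 (p_best − x) + c2 r2 (g_best − x)`, with c1 = c2 = 0.5
  and inertia increasing linearly 0.4 → 0.6 over generations.
* **Pipeline** (`shellopt.pipeline`): the maximized fitness is an
  equal-weight sum of min-max-normalized predicted responses over the
  natural factor box; validation reports percent errors
  `100·|experimental − predicted|/|experimental|` against confirmatory runs.
* **Synthetic data** (`shellopt.synthetic_data`): the study's raw 18-run
  table was never published, so simulated experiments draw responses from
  the published coded surfaces plus Gaussian noise at the published
  residual SDs (0.33, 0.54, 0.55, 1.21, 0.31).

## Worked example

Simulate an 18-run BBD experiment, fit the yield surface, and inspect it:

```python
>>> from shellopt import simulate_bbd_experiment, fit_quadratic, anova
>>> ds = simulate_bbd_experiment(seed=11)
>>> surface = fit_quadratic(ds.design, "yield_pct")
>>> round(surface.intercept, 3), [round(float(c), 3) for c in surface.linear]
(26.537, [-3.193, -0.228, 2.737])
>>> report = anova(ds.design, "yield_pct")
>>> round(report.R2, 4), report.df_model, report.df_residual
(0.9983, 9, 8)
```

The intercept is the predicted yield (%) at the design center (20 min,
35 °C, 1:20); the negative time and temperature coefficients and positive
ratio coefficient reproduce the study's finding that shorter, cooler
sonication with more solvent extracts more. The same workflow from a shell:

```sh
$ shellopt simulate --seed 11 --out synth.csv
$ shellopt train-ann synth.csv --hidden 2:8 --seed 2 --out ann.json
$ shellopt optimize --model ann.json --gens 2000 --seed 3 --out opt.json
Optimum process conditions (time min, temp degC, ratio): 10, 34, 30
        response  predicted
       yield_pct      36.11
...
$ shellopt validate --report opt.json --experimental 39.32,41.12,37.00,177.32,69.55
```

`validate` appends a percent-error column computed against the supplied
confirmatory measurements, mirroring the study's validation table.

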