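# geomaxent

Forecasting an invasive species' suitable range under climate scenarios by
combining **geodetector variable screening** with **maximum-entropy species
distribution modelling** — plus the downstream reporting a range-shift study
needs: suitability classification, per-class areas, binary range change,
centroid shifts, and MESS extrapolation diagnostics. A built-in
virtual-species simulator makes the whole workflow testable end to end
without downloading any climate data.

## Who this is for

Spatial ecologists and biogeographers who run the classic
"occurrences + bioclim rasters → MaxEnt → classified suitability maps →
scenario comparison" workflow and want it as a reproducible, scriptable,
seeded library instead of a chain of GUI tools.

## The methods

**Factor detector (geodetector q-statistic).** For a response *y* observed on
a regular fishnet of sampling points and an environmental variable stratified
into *L* classes (Jenks natural breaks, default *L* = 5):

    q = 1 − SSW/SST,  SSW = Σ_h N_h σ_h²,  SST = N σ²

q ∈ [0, 1] is the share of the spatial variance of *y* explained by the
stratification (population variances, so q = 1 exactly on pure strata).
Significance is assessed by a permutation test. Variables with q > 0.1
(strict) are retained; the pipeline can additionally reconcile this with the
jackknife ranking (union rule), as combined screenings do in practice.

**Maximum-entropy model.** A Gibbs distribution over the background
landscape, p_λ(x) ∝ exp(Σ_j λ_j f_j(x)), with feature classes L/Q/P/H/T
(linear, quadratic, pairwise product, hinge, threshold; features min-max
normalised to [0, 1] on the training sample). Weights maximise the
L1-penalised presence log-likelihood

    ℓ(λ) = mean_presence[λ·f(x)] − log Z(λ) − RM · Σ_j β_j |λ_j|

with the published class-default penalty schedules β_j and a global
regularization multiplier RM. Fitting is cyclic coordinate descent with
soft-threshold proximal Newton steps and a monotone line search; at
convergence the KKT conditions hold: every feature's model expectation is
within RM·β_j of its empirical presence mean. Outputs: raw (sums to 1 over
background), logistic, and cloglog (default) transforms; projection clamps
variables to their training range.

**Reporting.** Suitability is cut at 0.1 / 0.3 / 0.6 into unsuitable /
poorly / moderately / highly suitable classes; areas use exact spherical
cell areas (R = 6371 km) in 10⁴ km²; binary maps of two periods yield
gain/loss/unchanged masks and area-weighted centroid shifts (haversine);
MESS computes each cell's minimum percentile-based similarity to a reference
sample, negative exactly where a variable leaves the reference range.

## Worked example

```python
import geomaxent as gm

# a seeded virtual-species world: 60x80 grid, 4 signal + 3 noise variables
sc = gm.default_scenario(seed=1)
stack = gm.make_environment(sc)
truth = gm.make_true_suitability(stack, sc)
occ = gm.sample_occurrences(truth, sc.n_presences, seed=2)

# geodetector screening
selected, qtab = gm.screen_variables(stack, occ, n_permutations=199, seed=3)
print(qtab.round(4).to_string(index=False))

# maximum-entropy fit on a 75/25 split
train, test = gm.split_data(occ, 0.25, seed=4)
model = gm.MaxEnt.from_stack(stack, train, fc="LQHPT", n_knots=20,
                             n_background=10_000, seed=5)
res = model.fit(rm=1.0)
print(res.summary())
```

prints (abridged):

```
variable      q  p_value  L  retained
   temp1 0.0731    0.005  5     False
   temp2 0.0719    0.005  5     False
 precip1 0.1208    0.005  5      True
 precip2 0.1513    0.005  5      True
  noise1 0.0012    0.850  5     False
  noise2 0.0032    0.355  5     False
  noise3 0.0160    0.005  5     False

Maximum-entropy presence/background model
=============================================
presences: 150    background: 4800
feature classes: LQHPT    features: 455 (nonzero: 32)
RM: 1.0    iterations: 177 (converged)
regularized training gain: 1.4698
entropy of fitted background distribution: 7.0064
KKT violation: 9.88e-06
```

Every signal variable's q exceeds every noise variable's q, the two
precipitation variables clear the 0.1 retention threshold, and the fit
converges with the KKT optimality certificate. Continuing:

```python
Xt, valid = gm.extract_values(stack, test.points)
bg = res.predict(model.background, output="raw")
print("test AUC:", round(gm.roc_auc(res.predict(Xt[valid], output="raw"), bg), 4))
# test AUC: 0.9112

suit = res.project(stack, output="cloglog")          # suitability map
areas = gm.area_summary(gm.classify(suit), label="current")
print(areas.as_row())
# {'period': 'current', 'highly': 1.18, 'moderately': 1.08, 'poorly': 1.79, 'total': 4.06}
```

A test AUC of 0.91 against a theoretical ceiling near 0.93 (the AUC of the
true suitability surface itself) shows the model recovers most of the
recoverable structure; the area row is the per-class spherical area of the
classified map in 10⁴ km².

## Command line

The same workflow as a shell tool:

```bash
sdm simulate --out sim --seed 1
sdm geodetect -r sim/temp1.asc -r sim/precip1.asc ... --occurrences sim/occurrences.csv --out q.csv
sdm train -r ... --occurrences sim/occurrences.csv --out model.txt
sdm project -r ... --model model.txt --out suitability.asc
sdm run --config pipeline.yaml --out run/     # everything, from one YAML
```

`sdm run` executes simulate/load → screen → fit → evaluate → project per
scenario → classify → range change + centroids → MESS → report, writing all
artifacts (rasters as `.asc`, tables as CSV, a plain-text report, and a
provenance record with the config hash and seed).

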