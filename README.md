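# occugof

Single-season occupancy models for detection histories with **serially
correlated within-season revisits**, and goodness-of-fit tests that target
that correlation.

Occupancy studies estimate the probability ψ that a sample unit is occupied
while accounting for imperfect detection (probability *p* per revisit).
When survey devices — bat detectors, camera traps, audio recorders — are
deployed over consecutive nights, the standard assumption that revisits are
independent Bernoulli trials can fail: detections come in runs.  This
package is for ecologists and biometricians who need to (a) fit models that
accommodate that correlation and (b) *check* whether a fitted model
accounts for it.

## Models

Detection histories are a trinary tensor `Y[i, j, k]` over units `i`,
stations (spatial replicates) `j` and nights (temporal replicates) `k`,
with missing cells allowed.  Two model families, both with logit-linked
covariates `logit(ψ_i) = X_i β`, `logit(p_ijk) = V_ijk α`:

* **basic** — given occupancy, every surveyed cell is an independent
  Bernoulli(p_ijk) trial (zero-inflated binomial);
* **markov** — detection probability at a station is `p1` if the previous
  night there yielded a detection and `p0` otherwise, with the chain
  equilibrium `p_mean = p0 / (p0 + (1 − p1))` at a station's first night
  (and after gaps).  On the logit scale this is one extra detection-level
  coefficient ("Mark").

Fitting is by maximum likelihood (analytic gradients, zero starting
values); variances come from the inverse finite-difference Hessian, with
Wald intervals back-transformed to the probability scale.

## Goodness of fit

* **MacKenzie–Bailey test** — χ² discrepancy `Σ_c Σ_h (O_h − E_h)²/E_h`
  over counts of unique detection histories per cohort (units sharing one
  missingness pattern), parametric-bootstrap p-value.
* **Join-count χ² test** — the same discrepancy applied to counts of units
  by their number of "black–black" joins (neighbor pairs of detections
  within a station), with two neighborhoods: all night pairs
  (definition 1) or consecutive nights only (definition 2).  Expected
  counts `E_BB = Σ_h E_h · I(joins(h) = BB)` are computed exactly by
  per-station enumeration and cross-station convolution.  This test asks
  specifically whether detections cluster in time more than the fitted
  model predicts.
* **Permutation join-count test** — a model-free screen: shuffle the
  observed 0/1 values across surveyed cells of the naively occupied units
  and compare total joins.

All p-values are resampling-based (proportion of resampled statistics ≥
observed); no asymptotic χ² reference is used.

## Worked example

Simulate 50 units, 4 stations × 4 nights, ψ = 0.8, strong serial
correlation (p0 = 0.2, p1 = 0.8, so p_mean = 0.5), then fit both models
and test them:

```python
from occugof import *
from occugof.models import ModelSpec, fit

cfg = SimConfig(n_units=50, n_spatial=4, n_temporal=4,
                psi=0.8, p0=0.2, p1=0.8, seed=7)
data = simulate_dataset(cfg, 0)
covs = CovariateSet.intercept_only(data)
tests = [("mb", None), ("jc", NeighborScheme.ALL_TEMPORAL),
         ("jc", NeighborScheme.CONSECUTIVE)]
for family in ("basic", "markov"):
    fr = fit(ModelSpec(family), data, covs)
    res = bootstrap_gof(data, covs, fr, tests, n_boot=500, seed=11)
```

Output (printed estimates and p-values):

```
basic  loglik -468.58  psi_hat 0.800  p_hat 0.494
  mb                     stat=65545.70  p=0.176
  jc all_temporal        stat=280.06    p=0.002
  jc consecutive         stat=203.20    p=0.004
markov loglik -384.06  psi_hat 0.803  p0_hat 0.210  p1_hat 0.787  mark 2.63
  mb                     stat=42725.32  p=0.514
  jc all_temporal        stat=16.55     p=0.550
  jc consecutive         stat=8.41      p=0.552
```

The join-count tests flag the basic model (p ≤ 0.004) even though the
omnibus MacKenzie–Bailey test does not (p = 0.176); the Markov model —
the generating model here, with Mark coefficient 2.63 on the logit scale —
passes every test.  This is the qualitative pattern the test was designed
to expose.

The same workflow is available from the shell:

```bash
occugof simulate -n 50 -j 4 -k 4 --psi 0.8 --p0 0.2 --p1 0.8 --seed 7 --out det.csv
occugof gof det.csv --model basic --test jc2 --nboot 500 --seed 11
occugof power-study --scale desk --seed 1 --out study/
```

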