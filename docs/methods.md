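# Methods

## Models and likelihood

A detection history is a trinary tensor `Y[i, j, k]` (0 nondetection, 1
detection, missing) over `N` sample units, `J` stations per unit and `K`
nights per station.  A latent Bernoulli(ψ_i) state `z_i` marks occupancy;
unoccupied units yield all zeros.  Conditional on `z_i = 1`:

* **basic family** — each surveyed cell is Bernoulli(p_ijk) independently;
  the marginal likelihood per unit is the zero-inflated product
  `ψ_i Π p^y (1−p)^(1−y) + (1−ψ_i) I(y ≡ 0)`.
* **markov family** — within a station, nights form a two-state Markov
  chain: detection probability `p1_ijk` after a detection, `p0_ijk` after a
  nondetection.  The first night of a station uses the equilibrium
  probability `p_mean = p0 / (p0 + (1 − p1))` — the stationary detection
  rate of the chain, appropriate for a deployment that starts on a
  "randomly selected night".  Stations are conditionally independent;
  temporal chains never cross stations.

Covariates enter on the logit scale: `logit(ψ) = Xβ`, `logit(p) = Vα`.
The Markov term is a single coefficient added to the detection linear
predictor when the previous night was a detection, so `p0` and `p1` share
all other detection covariates; the cell-wise equilibrium is computed from
the cell-specific `p0` and `p1`.  This is the natural covariate
generalization of the constant-p equilibrium.

Two choices for gappy data are worth stating. A cell whose predecessor
night was not surveyed restarts the chain at `p_mean` (the same
randomly-selected-night argument; deployments with gaps are treated as
fresh equilibrium draws). The simulator and the parametric bootstrap use
the identical rule, so simulated data and likelihood always agree.
Detection-covariate values missing at surveyed cells are rejected, not
imputed.

## Fitting

Maximum likelihood on the unconstrained logit/coefficient scale, starting
from zero (probability 0.5) for every parameter.  The negative
log-likelihood and its *analytic* gradient (hand-derived, including the
equilibrium term's chain rule; verified against finite differences) are
minimized with L-BFGS-B; a Nelder–Mead restart handles optimizer failure.
Parameters are bounded at ±15 on the logit scale: beyond that the
probabilities are numerically 0/1 and the MLE is effectively on the
boundary, so a solution at the bound is flagged non-converged.

The variance matrix is the inverse of a central finite-difference Hessian
of the gradient (step `1e-5·max(1, |θ|)`), with positive definiteness
checked by Cholesky.  A fit is *converged* only if the optimizer
succeeded, the gradient is small, the Hessian is positive definite and no
parameter sits at the bound; non-converged fits are retained with
diagnostics but refused by the interval and GOF machinery.  This screen
mirrors standard practice of discarding fits whose inverse Hessian is not
positive definite.

Wald intervals are computed on the logit scale and back-transformed, so
probability intervals always lie inside (0, 1).

### Batched refitting

Parametric-bootstrap studies refit the same intercept-only model to tens
of thousands of simulated datasets.  For covariate-free models the
likelihood depends on each unit only through sufficient statistics
(detection/nondetection counts; for the Markov family the four transition
counts plus restart-night counts), so replicate datasets are fit
simultaneously by a damped Newton iteration on stacked arrays
(`_fastfit.py`).  The objective is algebraically identical to the general
likelihood; the test suite asserts agreement of estimates and convergence
flags with the general-purpose fitter.  Observed (non-bootstrap) fits
always use the general fitter.

## Goodness-of-fit statistics

Units sharing a missingness pattern form a **cohort**; both χ² statistics
are computed per cohort and summed, which handles unbalanced designs.

**MacKenzie–Bailey**: `Σ_c Σ_h (O_h − E_h)²/E_h` over the *observed*
unique histories, with `E_h = Σ_i ψ̂_i P̂r(h|z=1) + (1−ψ̂_i) I(h=0)`.
Only observed histories are materialized (no pooled remainder category);
we verified that adding the unobserved-mass remainder `N − Σ_obs E_h`
changes nothing detectable at the study designs, because the statistic is
dominated by the `1/E_h` of singleton histories.

**Join-count χ²**: joins are neighbor pairs of detections within one
station — all night pairs (definition 1) or consecutive nights only
(definition 2); a missing night breaks adjacency and pairs never cross
stations.  `E_BB = Σ_h E_h I(joins(h)=BB)` is computed *exactly*: each
station chain's `2^K` histories are enumerated once (probabilities and
join counts), reduced to a probability vector over join counts, and the
station vectors are convolved across stations.  Covariate-free fits give
identical chains, which are enumerated once per cohort.  Chains are capped
at 20 surveyed nights (2^20 histories); longer chains raise an explicit
error.

Guard rails: expected cells below 1e-12 with a zero observed count are
skipped; with a positive observed count the statistic becomes an infinite
sentinel, flagged, and treated as maximal in p-value comparisons.

**Parametric bootstrap**: each replicate redraws occupancy states and all
surveyed cells from the fitted model (same units, missingness,
covariates), refits the same specification from the zero start, and
recomputes the statistic; replicates failing the convergence screen are
discarded from the denominator and counted.  The p-value is the
proportion of converged-replicate statistics ≥ the observed one.  The ≥
convention is used uniformly for bootstrap and permutation p-values (the
conservative choice).  When several statistics are requested for one fit
the replicates are shared.

**Permutation join-count test**: the observed statistic is total joins
over all units.  The constrained randomization permutes the multiset of
observed 0/1 values across the surveyed cells of *naively occupied* units
only (positions and missingness fixed, other units untouched) — without
the constraint, detections would diffuse into never-occupied units and
the observed total would sit spuriously far in the tail.  The reported
p-value is the plain proportion over the requested permutations (the
observed arrangement is not added to numerator or denominator).

Randomness: a single user seed; every replicate uses a deterministic
`SeedSequence` substream keyed by its index, so results are reproducible
and independent of execution order.

## Simulator

`simulate_dataset` draws `z_i ~ Bernoulli(ψ)`, then per occupied unit and
station a chain `y_1 ~ Bernoulli(p_mean)`, `y_k ~ Bernoulli(p1 or p0)`;
`p0 = p1` recovers independent revisits.  An optional missingness pattern
is applied last.  Identical (seed, dataset index, config) gives
bit-identical output.

The generator emulates the designed study conditions: constant ψ and
constant transition probabilities, independent stations, equilibrium first
nights.  It does not emulate detection heterogeneity across units or
nights, spatially correlated stations, observer effects, or
species-misidentification — so passing calibration tests here says the
procedures work when their assumptions hold, not that any particular field
dataset satisfies them.

## Simulation study

`run_study` crosses revisit designs (default (1,16), (4,4), (1,8), (4,2);
N = 50) with the five correlation levels p0/p1 = 0.5/0.5 … 0.1/0.9 (all
with equilibrium 0.5).  Per simulated dataset: the permutation test on the
raw data, then basic and Markov fits, then MB and join-count tests (both
neighborhoods) on each converged fit, with bootstrap replicates shared
across statistics and datasets shared across tests (paired comparisons —
this only reduces comparison variance).  Summaries: rejection proportion
at α = 0.05 with binomial Monte-Carlo SE, mean estimates and bias, ψ-CI
coverage and width, convergence-failure counts, all as tidy CSV.

Default desk-scale settings are 200 datasets × 200 bootstrap replicates ×
199 permutations per cell; `StudyGrid.full_scale()` switches to
500/500/999.  The default generating ψ is 0.8.

## Calibration findings and known limitations

* Join-count bootstrap p-values are well calibrated wherever we checked
  (KS distance from uniform ≈ 0.055 at 300 × 200 under the generating
  model; empirical size 0.02–0.07 across designs and seeds).
* The MacKenzie–Bailey test is **conservative at sparse designs**: at
  16 revisits per unit (2^16 possible histories, N = 50) its bootstrap
  p-values are strongly under-dispersed (empirical size ≈ 0.007; KS ≈
  0.14).  The statistic `≈ Σ 1/E_h` is hypersensitive to the estimated
  parameters, so the bootstrap distribution — which carries the
  generation-parameter variability — is over-dispersed relative to the
  observed statistic's sampling distribution.  The same machinery is well
  calibrated at denser designs ((4,2), (2,2), (1,4): size 0.04–0.06), and
  the Markov-model MB test is calibrated even at (4,4).  Practically:
  prefer the join-count test at long serial deployments, which is the
  design regime it was built for.
* Markov-model convergence failures under strong correlation concentrate
  where the likelihood is genuinely flat (single station, few nights:
  ~20–25% failures at (1,8) with p1−p0 = 0.8), not where general-purpose
  optimizers struggle numerically; analytic gradients eliminate the
  latter class.  Failure counts are therefore optimizer-dependent and
  should not be compared across implementations.
* CI coverage for ψ under a *misspecified* basic fit depends strongly on
  the generating ψ (e.g. at (1,8), p1−p0 = 0.8: coverage ~0.66 at ψ = 0.5
  down to ~0.02 at ψ = 0.9), so coverage figures are only comparable
  between implementations at the same generating ψ.
* No profile-likelihood intervals, random effects, Bayesian fitting,
  multi-season layouts, spatially-Markov replication or asymptotic
  (non-resampling) p-values.
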