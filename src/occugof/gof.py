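"""Goodness-of-fit procedures for occupancy models.

Three assessments are provided:

* the MacKenzie-Bailey test: a chi-square discrepancy over counts of
  unique detection histories, with a parametric-bootstrap p-value;
* a join-count chi-square test: the same discrepancy idea applied to the
  distribution of within-unit "black-black" join counts (neighbor pairs of
  detections), which targets lack of fit from serially correlated
  detections after fitting any occupancy model;
* a constrained-permutation join-count test: a model-free screen that
  shuffles the observed 0/1 values across the surveyed cells of naively
  occupied units and compares total joins.

Neighbors are defined within one station (spatial replicate) of one unit,
either as all pairs of nights (definition 1) or only consecutive nights
(definition 2).  Joins never cross stations.

Both chi-square statistics accumulate over cohorts (units sharing one
missingness pattern), which accommodates unbalanced designs.  P-values are
always the proportion of resampled statistics greater than or equal to the
observed one; no asymptotic reference distribution is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .data import CohortPartition, CovariateSet, DetectionArray, naive_occupancy, partition_cohorts
from ._fastfit import batch_fit_intercept
from .models import (
    FitResult,
    ModelSpec,
    ParamVector,
    _markov_states as _mk_states,
    cell_probs,
    fit,
)
from .simulate import simulate_from_fit

__all__ = [
    "NeighborScheme",
    "HistoryDistribution",
    "JoinCountTable",
    "GofResult",
    "count_joins",
    "mb_expected",
    "mb_statistic",
    "jc_expected",
    "jc_statistic",
    "bootstrap_gof",
    "parametric_bootstrap",
    "permutation_join_test",
]

E_TOL = 1e-12  # below this an expected count is treated as zero
ENUM_CAP = 20  # max surveyed nights per station chain for full enumeration


class NeighborScheme(str, Enum):
    """Which pairs of nights at one station count as neighbors."""

    ALL_TEMPORAL = "all_temporal"  # definition 1: every pair of nights
    CONSECUTIVE = "consecutive_temporal"  # definition 2: adjacent nights only


@dataclass
class HistoryDistribution:
    """Observed and expected unit counts per unique detection history,
    for one cohort."""

    histories: np.ndarray  # (T, J, K) trinary
    o_counts: np.ndarray  # (T,) ints
    e_counts: np.ndarray  # (T,) floats
    prob: np.ndarray  # (T,) cohort-average unconditional history probability
    cohort_size: int


@dataclass
class JoinCountTable:
    """Observed and expected unit counts per attainable join-count level,
    for one cohort."""

    scheme: NeighborScheme
    levels: np.ndarray  # (L,) ints, 0..max attainable BB
    o_counts: np.ndarray  # (L,) ints
    e_counts: np.ndarray  # (L,) floats
    cohort_size: int


@dataclass
class GofResult:
    test: str  # "MB", "JC" or "PERM"
    statistic: float
    p_value: float
    n_resamples_requested: int
    n_resamples_used: int
    n_discarded: int = 0
    scheme: NeighborScheme | None = None
    resample_stats: np.ndarray = field(default_factory=lambda: np.empty(0))
    flagged: bool = False

    def summary(self) -> dict:
        return {
            "test": self.test,
            "scheme": self.scheme.value if self.scheme else None,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n_resamples_requested": int(self.n_resamples_requested),
            "n_resamples_used": int(self.n_resamples_used),
            "n_discarded": int(self.n_discarded),
            "flagged": bool(self.flagged),
        }


# ---------------------------------------------------------------------------
# join counting


def count_joins(history: np.ndarray, scheme: NeighborScheme) -> int:
    """Number of neighbor pairs with detections on both sides (BB joins).

    ``history`` is a (J, K) trinary array; pairs involving a missing cell
    are not neighbor pairs.  Under definition 1 a station with ``s``
    detections contributes ``C(s, 2)`` joins; under definition 2 only
    adjacent-night detection pairs count, and a missing night breaks
    adjacency.
    """
    h = np.atleast_2d(np.asarray(history, dtype=float))
    if scheme == NeighborScheme.ALL_TEMPORAL:
        s = (h == 1).sum(axis=1)
        return int((s * (s - 1) // 2).sum())
    a, b = h[:, :-1], h[:, 1:]
    return int(((a == 1) & (b == 1)).sum())


# ---------------------------------------------------------------------------
# MacKenzie-Bailey expected counts and statistic


def _encode(histories: np.ndarray) -> np.ndarray:
    """Trinary (U, J, K) -> int8 (U, J*K) with -1 for missing."""
    u = histories.reshape(histories.shape[0], -1)
    out = np.where(np.isnan(u), -1, u).astype(np.int8)
    return out


def mb_expected(
    fitres: FitResult,
    data: DetectionArray,
    covs: CovariateSet,
    cohort_members: np.ndarray,
) -> HistoryDistribution:
    """Observed and expected counts of the cohort's unique histories.

    For each observed unique history h the expected count is

        E_h = sum_{i in cohort} psi_i Pr(h | occupied)_i
                                + (1 - psi_i) I(h all zero),

    evaluated at the fitted parameters.  Only histories actually observed
    are materialized; the test statistic needs no others.
    """
    if not fitres.converged:
        raise ValueError("expected counts require a converged fit")
    members = np.asarray(cohort_members, dtype=int)
    sub = data.values[members]
    codes = _encode(sub)
    uniq, first_idx, counts = np.unique(
        codes, axis=0, return_index=True, return_counts=True
    )
    hist = sub[first_idx]  # (T, J, K) trinary
    t_n, u_n = len(uniq), len(members)
    m = sub.shape[1] * sub.shape[2]

    cp = cell_probs(fitres.spec, fitres.estimate, covs)
    psi = cp["psi"][members]
    obs_h = uniq >= 0  # (T, M): all rows share the cohort pattern
    y_h = (uniq == 1).astype(float)

    with np.errstate(divide="ignore"):
        if fitres.spec.family == "basic":
            p = cp["p"][members].reshape(u_n, m)
            lp1, lp0 = np.log(p), np.log1p(-p)
            condlp = (y_h * obs_h) @ lp1.T + ((1.0 - y_h) * obs_h) @ lp0.T
        else:
            states = _mk_states(hist)  # (T, M) conditioning codes from h itself
            condlp = np.zeros((t_n, u_n))
            for s_code, pname in ((0, "p0"), (1, "p1"), (2, "p_mean")):
                pc = cp[pname][members].reshape(u_n, m)
                lp1, lp0 = np.log(pc), np.log1p(-pc)
                sel = obs_h & (states == s_code)
                condlp += (y_h * sel) @ lp1.T + ((1.0 - y_h) * sel) @ lp0.T

    allzero = ~(y_h * obs_h).any(axis=1)
    e = (psi[None, :] * np.exp(condlp)).sum(axis=1) + allzero * (1.0 - psi).sum()
    return HistoryDistribution(
        histories=hist,
        o_counts=counts,
        e_counts=e,
        prob=e / u_n,
        cohort_size=u_n,
    )


def _chisq(o: np.ndarray, e: np.ndarray) -> tuple[float, bool]:
    """Sum of (O-E)^2/E with the zero-expected guard.

    Cells with E below tolerance and O = 0 are skipped; E below tolerance
    with O > 0 yields an infinite sentinel (flagged), which counts as
    maximal in p-value comparisons.
    """
    tiny = e < E_TOL
    if (tiny & (o > 0)).any():
        return math.inf, True
    keep = ~tiny
    return float(((o[keep] - e[keep]) ** 2 / e[keep]).sum()), False


def mb_statistic(
    data: DetectionArray,
    covs: CovariateSet,
    fitres: FitResult,
    partition: CohortPartition | None = None,
) -> float:
    """MacKenzie-Bailey chi-square discrepancy summed over cohorts:
    ``sum_c sum_h (O_h - E_h)^2 / E_h`` over observed unique histories."""
    if partition is None:
        partition = partition_cohorts(data)
    total = 0.0
    for _, members in partition:
        hd = mb_expected(fitres, data, covs, members)
        s, flagged = _chisq(hd.o_counts, hd.e_counts)
        if flagged:
            return math.inf
        total += s
    return total


# ---------------------------------------------------------------------------
# join-count chi-square expected counts and statistic
#
# Stations are conditionally independent given occupancy and joins never
# cross stations, so instead of enumerating all 2^(J*K) unit histories we
# enumerate each station chain's 2^K histories, reduce to a probability
# vector over that chain's join counts, and convolve across stations.


def _chain_table(
    ks: np.ndarray,
    probs: tuple,
    family: str,
    scheme: NeighborScheme,
) -> tuple[np.ndarray, float]:
    """Join-count distribution of one station chain given occupancy.

    ``ks`` are the chronological temporal indices of the chain's surveyed
    nights; ``probs`` holds the per-night probabilities (p,) for the basic
    family or (p0, p1, pm) for the Markov family.  Returns the probability
    vector over join counts 0..max and the probability of the all-zero
    chain history.
    """
    n = len(ks)
    if n == 0:
        return np.ones(1), 1.0
    if n > ENUM_CAP:
        raise ValueError(
            f"station chain has {n} surveyed nights; full enumeration is "
            f"capped at {ENUM_CAP} nights per chain"
        )
    m = 1 << n
    bits = (np.arange(m)[:, None] >> np.arange(n)[None, :]) & 1  # (m, n)

    if family == "basic":
        (p,) = probs
        pmat = np.broadcast_to(p, (m, n))
    else:
        p0, p1, pm = probs
        pmat = np.empty((m, n))
        for b in range(n):
            restart = b == 0 or ks[b - 1] != ks[b] - 1
            if restart:
                pmat[:, b] = pm[b]
            else:
                pmat[:, b] = np.where(bits[:, b - 1] == 1, p1[b], p0[b])
    with np.errstate(divide="ignore"):
        lp = np.where(bits == 1, np.log(pmat), np.log1p(-pmat))
    prob = np.exp(lp.sum(axis=1))

    if scheme == NeighborScheme.ALL_TEMPORAL:
        s = bits.sum(axis=1)
        joins = s * (s - 1) // 2
        max_joins = n * (n - 1) // 2
    else:
        adj = np.flatnonzero(np.diff(ks) == 1)  # consecutive-night pairs
        joins = np.zeros(m, dtype=int)
        for b in adj:
            joins += bits[:, b] & bits[:, b + 1]
        max_joins = len(adj)
    vec = np.bincount(joins, weights=prob, minlength=max_joins + 1)
    return vec, float(prob[0])


def jc_expected(
    fitres: FitResult,
    data: DetectionArray,
    covs: CovariateSet,
    cohort_members: np.ndarray,
    scheme: NeighborScheme,
) -> JoinCountTable:
    """Observed and expected counts of units per join-count level.

    ``E_BB = sum_h E_h I(joins(h) = BB)`` over the full set of possible
    histories on the cohort's surveyed cells.  The sum is computed exactly
    by per-station enumeration and cross-station convolution; identical
    chains (the covariate-free case) are enumerated once.
    """
    if not fitres.converged:
        raise ValueError("expected counts require a converged fit")
    members = np.asarray(cohort_members, dtype=int)
    mask = data.mask[members[0]]  # shared missingness pattern
    cp = cell_probs(fitres.spec, fitres.estimate, covs)
    psi = cp["psi"][members]
    family = fitres.spec.family
    prob_fields = ("p",) if family == "basic" else ("p0", "p1", "p_mean")
    parrs = [cp[f][members] for f in prob_fields]

    def unit_vec(pos: int, cache: dict) -> tuple[np.ndarray, float]:
        vec = np.ones(1)
        az = 1.0
        for j in range(data.n_spatial):
            ks = np.flatnonzero(mask[j])
            probs = tuple(pa[pos, j, ks] for pa in parrs)
            key = (tuple(ks),) + tuple(p.tobytes() for p in probs)
            if key not in cache:
                cache[key] = _chain_table(ks, probs, family, scheme)
            cvec, caz = cache[key]
            vec = np.convolve(vec, cvec)
            az *= caz
        return vec, az

    cache: dict = {}
    # covariate-free fits give every unit the same probabilities; enumerate
    # the history space once and scale
    uniform = all(np.ptp(pa[:, mask], axis=0).max(initial=0.0) == 0.0 for pa in parrs)
    if uniform:
        vec, az = unit_vec(0, cache)
        e = psi.sum() * vec
        e[0] += (1.0 - psi).sum()
    else:
        e = None
        for pos in range(len(members)):
            vec, az = unit_vec(pos, cache)
            contrib = psi[pos] * vec
            contrib[0] += 1.0 - psi[pos]
            e = contrib if e is None else e + contrib

    sub = data.values[members]
    if scheme == NeighborScheme.ALL_TEMPORAL:
        s = (sub == 1).sum(axis=2)
        joins = (s * (s - 1) // 2).sum(axis=1)
    else:
        joins = ((sub[:, :, :-1] == 1) & (sub[:, :, 1:] == 1)).sum(axis=(1, 2))
    o = np.bincount(joins, minlength=len(e)).astype(int)
    return JoinCountTable(
        scheme=scheme,
        levels=np.arange(len(e)),
        o_counts=o,
        e_counts=e,
        cohort_size=len(members),
    )


def jc_statistic(
    data: DetectionArray,
    covs: CovariateSet,
    fitres: FitResult,
    scheme: NeighborScheme,
    partition: CohortPartition | None = None,
) -> float:
    """Join-count chi-square discrepancy summed over cohorts:
    ``sum_c sum_BB (O_BB - E_BB)^2 / E_BB`` over attainable join levels
    with nonzero expected count."""
    if partition is None:
        partition = partition_cohorts(data)
    total = 0.0
    for _, members in partition:
        jt = jc_expected(fitres, data, covs, members, scheme)
        s, flagged = _chisq(jt.o_counts, jt.e_counts)
        if flagged:
            return math.inf
        total += s
    return total


# ---------------------------------------------------------------------------
# parametric bootstrap


def _stat_for(test: tuple, data, covs, fitres, partition) -> float:
    kind, scheme = test
    if kind == "mb":
        return mb_statistic(data, covs, fitres, partition)
    if kind == "jc":
        return jc_statistic(data, covs, fitres, scheme, partition)
    raise ValueError(f"unknown test kind {kind!r}")


def bootstrap_gof(
    data: DetectionArray,
    covs: CovariateSet,
    fitres: FitResult,
    tests: list,
    n_boot: int = 500,
    seed: int | None = None,
) -> dict:
    """Parametric-bootstrap p-values for several statistics at once.

    ``tests`` is a list of ``("mb", None)`` / ``("jc", scheme)`` pairs.
    Each replicate simulates a dataset from the fitted model (same units,
    missingness and covariates; occupancy states redrawn), refits the same
    model specification from the all-zero start, and recomputes every
    requested statistic on the refit, so the replicates are shared across
    statistics.  Replicates whose refit fails the convergence screen are
    discarded from every p-value denominator; their count is reported.

    The p-value is the proportion of converged-replicate statistics
    greater than or equal to the observed statistic.
    """
    if not fitres.converged:
        raise ValueError("parametric bootstrap requires a converged fit")
    partition = partition_cohorts(data)
    observed = {t: _stat_for(t, data, covs, fitres, partition) for t in tests}

    # Every replicate keeps the observed missingness pattern, so the cohort
    # partition carries over.  For covariate-free models the refits are
    # batched through the sufficient-statistic Newton solver; otherwise each
    # replicate goes through the general-purpose fitter.
    sims = [
        simulate_from_fit(
            fitres,
            data,
            covs,
            np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b,))),
        )
        for b in range(n_boot)
    ]
    intercept_only = (
        covs.n_occ == 1
        and covs.n_det == 1
        and (covs.occ_design == 1.0).all()
        and (covs.det_design == 1.0).all()
    )
    boot: dict = {t: [] for t in tests}
    n_discarded = 0
    if intercept_only:
        values = np.stack([s.values for s in sims])
        thetas, conv, vcovs = batch_fit_intercept(fitres.spec.family, values)
        for b in range(n_boot):
            if not conv[b]:
                n_discarded += 1
                continue
            refit = FitResult(
                spec=fitres.spec,
                estimate=ParamVector.from_theta(thetas[b], 1),
                vcov=vcovs[b],
                loglik=np.nan,
                converged=True,
            )
            for t in tests:
                boot[t].append(_stat_for(t, sims[b], covs, refit, partition))
    else:
        for b in range(n_boot):
            refit = fit(fitres.spec, sims[b], covs)
            if not refit.converged:
                n_discarded += 1
                continue
            for t in tests:
                boot[t].append(_stat_for(t, sims[b], covs, refit, partition))

    n_used = n_boot - n_discarded
    if n_used == 0:
        raise RuntimeError("all bootstrap refits failed the convergence screen")
    out = {}
    for t in tests:
        stats = np.asarray(boot[t])
        obs = observed[t]
        out[t] = GofResult(
            test=t[0].upper(),
            scheme=t[1],
            statistic=obs,
            p_value=float((stats >= obs).mean()),
            n_resamples_requested=n_boot,
            n_resamples_used=n_used,
            n_discarded=n_discarded,
            resample_stats=stats,
            flagged=not math.isfinite(obs),
        )
    return out


def parametric_bootstrap(
    test: str,
    data: DetectionArray,
    covs: CovariateSet,
    fitres: FitResult,
    n_boot: int = 500,
    seed: int | None = None,
    scheme: NeighborScheme | None = None,
) -> GofResult:
    """Single-test convenience wrapper around :func:`bootstrap_gof`.

    ``test`` is ``"mb"`` or ``"jc"`` (the latter requires ``scheme``).
    """
    if test == "jc" and scheme is None:
        raise ValueError("the join-count test requires a neighbor scheme")
    key = (test, scheme if test == "jc" else None)
    return bootstrap_gof(data, covs, fitres, [key], n_boot=n_boot, seed=seed)[key]


# ---------------------------------------------------------------------------
# constrained-permutation join-count test


def _pair_indices(
    data: DetectionArray, units: np.ndarray, scheme: NeighborScheme
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat pool of surveyed-cell values for the given units plus the
    neighbor-pair index arrays into that pool."""
    pool_vals = []
    index_of: dict = {}
    a_idx, b_idx = [], []
    for i in units:
        for j in range(data.n_spatial):
            ks = np.flatnonzero(data.mask[i, j])
            local = []
            for k in ks:
                index_of[(i, j, k)] = len(pool_vals)
                pool_vals.append(int(data.values[i, j, k]))
                local.append(k)
            if scheme == NeighborScheme.ALL_TEMPORAL:
                for x in range(len(local)):
                    for y in range(x + 1, len(local)):
                        a_idx.append(index_of[(i, j, local[x])])
                        b_idx.append(index_of[(i, j, local[y])])
            else:
                for x in range(1, len(local)):
                    if local[x] == local[x - 1] + 1:
                        a_idx.append(index_of[(i, j, local[x - 1])])
                        b_idx.append(index_of[(i, j, local[x])])
    return (
        np.asarray(pool_vals, dtype=np.int64),
        np.asarray(a_idx, dtype=np.intp),
        np.asarray(b_idx, dtype=np.intp),
    )


def permutation_join_test(
    data: DetectionArray,
    scheme: NeighborScheme,
    n_perm: int = 999,
    seed: int | None = None,
) -> GofResult:
    """Model-free join-count test via constrained randomization.

    The observed statistic is the total number of BB joins summed over all
    units.  Each permutation shuffles the multiset of observed 0/1 values
    across the surveyed cells of the naively occupied units only (cell
    positions, missingness and the remaining units are untouched), and the
    p-value is the proportion of permutations whose total joins is greater
    than or equal to the observed total.  The constraint prevents
    detections from diffusing into units with no detections at all, which
    would make the observed total spuriously extreme.
    """
    naive = naive_occupancy(data)
    if len(naive) == 0:
        raise ValueError("permutation test requires at least one naively occupied unit")
    observed = sum(count_joins(data.values[i], scheme) for i in range(data.n_units))
    pool, a_idx, b_idx = _pair_indices(data, naive, scheme)

    totals = np.empty(n_perm)
    for r in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        v = rng.permutation(pool)
        totals[r] = int((v[a_idx] * v[b_idx]).sum())
    return GofResult(
        test="PERM",
        scheme=scheme,
        statistic=float(observed),
        p_value=float((totals >= observed).mean()),
        n_resamples_requested=n_perm,
        n_resamples_used=n_perm,
        resample_stats=totals,
    )
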