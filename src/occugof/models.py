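"""Likelihoods and maximum-likelihood fitting for single-season occupancy
models with spatial and temporal within-unit replication.

Two model families are supported.  In the *basic* model every surveyed cell
is an independent Bernoulli trial given the latent occupancy state, so the
data are a zero-inflated binomial:

    logit(psi_i)   = X_i  beta
    logit(p_ijk)   = V_ijk alpha
    Pr(y_i | occ)  = prod_jk p_ijk^y (1 - p_ijk)^(1-y)
    Pr(y_i)        = psi_i Pr(y_i | occ) + (1 - psi_i) I(y_i == 0)

The *Markov* family adds a first-order Markov detection-level term: the
detection probability at a cell is p1 if the previous night at the same
station yielded a detection, p0 if it did not, and the chain's equilibrium
probability p_mean = p0 / (p0 + (1 - p1)) at the first night of a station
(or after a gap of unsurveyed nights, treating the chain as restarting at
equilibrium).  On the logit scale the Markov term is a single coefficient
added to the detection linear predictor when the previous night was a
detection; p0 and p1 therefore share all other detection covariates.

Chains at different stations of the same unit are conditionally
independent: temporal dependence never crosses spatial replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import norm

from .data import CovariateSet, DetectionArray

__all__ = [
    "ModelSpec",
    "ParamVector",
    "FitResult",
    "equilibrium_p",
    "unit_history_prob",
    "neg_loglik",
    "fit",
    "wald_interval",
    "MARK_TERM",
]

MARK_TERM = "Mark"
CLAMP = 15.0  # |logit-scale parameter| bound during optimization

# Markov cell states, derived from the data (the value of the previous
# surveyed night at the same station), not from the parameters.
_PREV_NONDET = 0
_PREV_DET = 1
_FIRST_OR_GAP = 2


def equilibrium_p(p0: float, p1: float) -> float:
    """Equilibrium detection probability of the two-state detection chain.

    For a chain with detection probability ``p1`` after a detection and
    ``p0`` after a nondetection, the stationary probability of detection on
    a randomly selected night is ``p0 / (p0 + (1 - p1))``.  Used for the
    first temporal replicate of every station and after gaps.
    """
    p0 = float(p0)
    p1 = float(p1)
    if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
        raise ValueError("p0 and p1 must be probabilities")
    denom = p0 + (1.0 - p1)
    if denom <= 0.0:
        raise ValueError("equilibrium undefined: p0 + (1 - p1) must be > 0")
    return p0 / denom


@dataclass
class ModelSpec:
    """Model family plus the covariate terms entering each linear predictor.

    ``occ_terms`` / ``det_terms`` name columns of the CovariateSet designs;
    ``None`` means use every column.  For the Markov family the Mark term is
    implicit and always last in the detection coefficient vector.
    """

    family: Literal["basic", "markov"] = "basic"
    occ_terms: tuple | None = None
    det_terms: tuple | None = None

    def __post_init__(self) -> None:
        if self.family not in ("basic", "markov"):
            raise ValueError("family must be 'basic' or 'markov'")

    def coef_names(self, covs: CovariateSet) -> list:
        occ = list(self.occ_terms) if self.occ_terms is not None else list(covs.occ_names)
        det = list(self.det_terms) if self.det_terms is not None else list(covs.det_names)
        names = [f"psi:{t}" for t in occ] + [f"p:{t}" for t in det]
        if self.family == "markov":
            names.append(f"p:{MARK_TERM}")
        return names

    def n_params(self, covs: CovariateSet) -> int:
        return len(self.coef_names(covs))


@dataclass
class ParamVector:
    """Logit-scale coefficients: ``beta`` for occupancy, ``alpha`` for
    detection (Markov coefficient last for the markov family)."""

    beta: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if not (np.isfinite(self.beta).all() and np.isfinite(self.alpha).all()):
            raise ValueError("parameters must be finite")

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.beta, self.alpha])

    @classmethod
    def from_theta(cls, theta: np.ndarray, n_beta: int) -> "ParamVector":
        theta = np.asarray(theta, dtype=float)
        return cls(theta[:n_beta], theta[n_beta:])

    def check(self, spec: ModelSpec, covs: CovariateSet) -> None:
        n_alpha = covs.n_det + (1 if spec.family == "markov" else 0)
        if len(self.beta) != covs.n_occ or len(self.alpha) != n_alpha:
            raise ValueError("parameter vector length does not match model spec")


@dataclass
class FitResult:
    spec: ModelSpec
    estimate: ParamVector
    vcov: np.ndarray | None
    loglik: float
    converged: bool
    coef_names: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def to_table(self) -> dict:
        """Coefficient table (estimate, SE, Wald 95% CI) as plain dicts."""
        theta = self.estimate.theta
        se = (
            np.sqrt(np.diag(self.vcov))
            if self.vcov is not None
            else np.full(theta.shape, np.nan)
        )
        z = norm.ppf(0.975)
        return {
            "coefficients": [
                {
                    "name": nm,
                    "estimate": float(est),
                    "se": float(s),
                    "lower": float(est - z * s),
                    "upper": float(est + z * s),
                }
                for nm, est, s in zip(self.coef_names, theta, se)
            ],
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "diagnostics": {k: v for k, v in self.diagnostics.items() if np.isscalar(v)},
        }


# ---------------------------------------------------------------------------
# internal evaluation context


class _Ctx:
    """Flattened arrays for fast repeated likelihood evaluation.

    Cells are flattened j-major so each station's nights are contiguous.
    ``state`` codes each surveyed cell of the Markov family by what the
    model conditions on there: the previous night's value, or chain
    restart (first night / gap).
    """

    __slots__ = ("y", "obs", "allzero", "X", "V", "state", "n_beta", "family")

    def __init__(self, spec: ModelSpec, data: DetectionArray, covs: CovariateSet):
        covs.check_against(data)
        n, j, k = data.values.shape
        vals = data.values.reshape(n, j * k)
        self.obs = ~np.isnan(vals)
        self.y = np.where(self.obs, vals, 0.0)
        self.allzero = ~(self.y > 0).any(axis=1)
        self.X = covs.occ_design
        self.V = covs.det_design.reshape(n, j * k, covs.n_det)
        self.n_beta = covs.n_occ
        self.family = spec.family
        if spec.family == "markov":
            self.state = _markov_states(data.values)
            has_chain = (self.state != _FIRST_OR_GAP) & self.obs.reshape(n, j, k).reshape(n, j * k)
            if not has_chain.any():
                raise ValueError(
                    "markov family needs at least one pair of consecutive "
                    "surveyed nights (K >= 2 somewhere) to be identifiable"
                )
        else:
            self.state = None


def _markov_states(values: np.ndarray) -> np.ndarray:
    """Per-cell conditioning state for the Markov family, from the data.

    Shape (N, J*K) int8; meaningful only at surveyed cells.
    """
    n, j, k = values.shape
    state = np.full((n, j, k), _FIRST_OR_GAP, dtype=np.int8)
    if k > 1:
        prev = values[:, :, :-1]
        cur = state[:, :, 1:]
        cur[prev == 0] = _PREV_NONDET
        cur[prev == 1] = _PREV_DET
    return state.reshape(n, j * k)


def _log_bernoulli(p: np.ndarray, y: np.ndarray, obs: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(y > 0, np.log(p), np.log1p(-p))
    lp = np.where(obs, lp, 0.0)
    return lp


def _nll_grad(theta: np.ndarray, ctx: _Ctx, want_grad: bool = True):
    """Negative log-likelihood and its analytic gradient."""
    nb = ctx.n_beta
    beta = theta[:nb]
    if ctx.family == "markov":
        alpha, amark = theta[nb:-1], theta[-1]
    else:
        alpha, amark = theta[nb:], 0.0

    eta_psi = ctx.X @ beta
    psi = expit(eta_psi)
    eta0 = ctx.V @ alpha

    if ctx.family == "basic":
        p = expit(eta0)
        cll_cells = _log_bernoulli(p, ctx.y, ctx.obs)
    else:
        p0 = expit(eta0)
        p1 = expit(eta0 + amark)
        denom = p0 + (1.0 - p1)
        pm = p0 / denom
        pc = np.choose(ctx.state, (p0, p1, pm))
        cll_cells = _log_bernoulli(pc, ctx.y, ctx.obs)

    cll = cll_cells.sum(axis=1)

    # log L_i: psi*exp(cll) + (1-psi) for all-zero histories, psi*exp(cll) else
    log_psi = -np.logaddexp(0.0, -eta_psi)   # log(psi)
    log_1mpsi = -np.logaddexp(0.0, eta_psi)  # log(1-psi)
    a = log_psi + cll
    li = np.where(ctx.allzero, np.logaddexp(a, log_1mpsi), a)
    f = -float(li.sum())

    if not want_grad:
        return f

    # d li / d eta_psi and d li / d cll
    with np.errstate(over="ignore"):
        ratio = np.exp(np.clip(log_1mpsi - a, -745.0, 700.0))  # (1-psi)/(psi A)
    w_cll = np.where(ctx.allzero, 1.0 / (1.0 + ratio), 1.0)
    # d li/d eta_psi = (1-psi) - (for all-zero) (1-psi) * [1/(1+ psiA/(1-psi))]
    # derived: li = log(psi A + 1 - psi); d/d eta = psi(1-psi)(A-1)/(psi A + 1-psi)
    #        = (1-psi)*w_cll - psi*(1-w_cll)  [algebraic rearrangement]
    w_psi = np.where(ctx.allzero, (1.0 - psi) * w_cll - psi * (1.0 - w_cll), 1.0 - psi)

    g_beta = -(ctx.X.T @ w_psi)

    if ctx.family == "basic":
        u = np.where(ctx.obs, ctx.y - p, 0.0)  # d cll / d eta0 per cell
        g_alpha = -np.einsum("i,im,imq->q", w_cll, u, ctx.V)
        g = np.concatenate([g_beta, g_alpha])
    else:
        s = ctx.state
        obs = ctx.obs
        d0 = p0 * (1.0 - p0)
        d1 = p1 * (1.0 - p1)
        # derivatives of p_mean wrt the two linear predictors
        dpm_de0 = (1.0 - p1) / denom**2 * d0
        dpm_de1 = p0 / denom**2 * d1
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (ctx.y - pm) / (pm * (1.0 - pm))
        u0 = np.where(obs & (s == _PREV_NONDET), ctx.y - p0, 0.0)
        u1 = np.where(obs & (s == _PREV_DET), ctx.y - p1, 0.0)
        um = np.where(obs & (s == _FIRST_OR_GAP), r, 0.0)
        um = np.where(np.isfinite(um), um, 0.0)
        # chain rule: eta0 feeds p0 directly, p1 (through eta1 = eta0 +
        # amark), and p_mean through both; amark feeds p1 and
        # p_mean-through-p1 only.
        dalpha_cells = u0 + u1 + um * (dpm_de0 + dpm_de1)
        damark_cells = u1 + um * dpm_de1
        g_alpha = -np.einsum("i,im,imq->q", w_cll, dalpha_cells, ctx.V)
        g_amark = -float(np.einsum("i,im->", w_cll, damark_cells))
        g = np.concatenate([g_beta, g_alpha, [g_amark]])

    return f, g


# ---------------------------------------------------------------------------
# public likelihood surface


def cell_probs(spec: ModelSpec, params: ParamVector, covs: CovariateSet) -> dict:
    """Per-cell probabilities implied by the parameters.

    Returns ``psi`` (N,) and, for the basic family, ``p`` (N, J, K); for the
    markov family ``p0``, ``p1`` and ``p_mean`` (each N, J, K), where
    ``p_mean`` is the cell-wise equilibrium of the cell-specific p0 and p1.
    """
    params.check(spec, covs)
    psi = expit(covs.occ_design @ params.beta)
    if spec.family == "basic":
        return {"psi": psi, "p": expit(covs.det_design @ params.alpha)}
    eta0 = covs.det_design @ params.alpha[:-1]
    p0 = expit(eta0)
    p1 = expit(eta0 + params.alpha[-1])
    return {"psi": psi, "p0": p0, "p1": p1, "p_mean": p0 / (p0 + 1.0 - p1)}


def history_cond_logprob(
    spec: ModelSpec,
    params: ParamVector,
    covs: CovariateSet,
    h: np.ndarray,
    units: np.ndarray | None = None,
) -> np.ndarray:
    """log Pr(history h | occupied) for each requested unit.

    ``h`` is a (J, K) trinary array (nan = unsurveyed cell) shared by all
    requested units (they belong to one cohort).  For the Markov family the
    conditioning state at each cell is read off ``h`` itself.
    """
    cp = cell_probs(spec, params, covs)
    h = np.asarray(h, dtype=float)
    obs = ~np.isnan(h)
    y = np.where(obs, h, 0.0)
    if spec.family == "basic":
        p = cp["p"] if units is None else cp["p"][units]
    else:
        state = _markov_states(h[None]).reshape(h.shape)
        p0, p1, pm = cp["p0"], cp["p1"], cp["p_mean"]
        if units is not None:
            p0, p1, pm = p0[units], p1[units], pm[units]
        p = np.where(state == _PREV_DET, p1, np.where(state == _PREV_NONDET, p0, pm))
    with np.errstate(divide="ignore"):
        lp = np.where(y > 0, np.log(p), np.log1p(-p))
    return np.where(obs, lp, 0.0).sum(axis=(-2, -1))


def unit_history_prob(
    spec: ModelSpec,
    params: ParamVector,
    covs: CovariateSet,
    unit: int,
    h: np.ndarray,
    conditional: bool = True,
) -> float:
    """Probability of one detection history for one unit.

    ``conditional=True`` gives Pr(h | occupied); ``conditional=False`` the
    unconditional zero-inflated probability
    ``psi * Pr(h | occ) + (1 - psi) * I(h all zero)``.  Over the full set of
    histories on the unit's surveyed cells the unconditional values sum
    to 1.
    """
    params.check(spec, covs)
    cond = float(np.exp(history_cond_logprob(spec, params, covs, h, np.array([unit]))[0]))
    if conditional:
        return cond
    psi = float(expit(covs.occ_design[unit] @ params.beta))
    h = np.asarray(h, dtype=float)
    allzero = not (h[~np.isnan(h)] > 0).any()
    return psi * cond + (1.0 - psi) * (1.0 if allzero else 0.0)


def neg_loglik(
    spec: ModelSpec,
    params: ParamVector,
    data: DetectionArray,
    covs: CovariateSet,
) -> float:
    """Negative log-likelihood of the full dataset.

    Returns ``inf`` if some unit's observed history has probability zero
    under the parameters.
    """
    params.check(spec, covs)
    return _nll_grad(params.theta, _Ctx(spec, data, covs), want_grad=False)


# ---------------------------------------------------------------------------
# fitting


def _fd_hessian(theta: np.ndarray, ctx: _Ctx) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    d = len(theta)
    H = np.empty((d, d))
    for k in range(d):
        hk = 1e-5 * max(1.0, abs(theta[k]))
        tp = theta.copy()
        tp[k] += hk
        tm = theta.copy()
        tm[k] -= hk
        H[:, k] = (_nll_grad(tp, ctx)[1] - _nll_grad(tm, ctx)[1]) / (2.0 * hk)
    return 0.5 * (H + H.T)


def fit(
    spec: ModelSpec,
    data: DetectionArray,
    covs: CovariateSet | None = None,
    init: ParamVector | None = None,
) -> FitResult:
    """Maximum-likelihood fit by quasi-Newton (L-BFGS-B) with analytic
    gradients, started at zero on the logit scale (probability 0.5), with a
    Nelder-Mead fallback on optimizer failure.

    Logit-scale parameters are bounded at +/-15; a solution at the bound
    means the MLE is effectively on the probability boundary and the fit is
    flagged non-converged.  The variance matrix is the inverse of a
    central-finite-difference Hessian; a non-positive-definite Hessian also
    flags non-convergence (the fit itself is retained with diagnostics).
    """
    if covs is None:
        covs = CovariateSet.intercept_only(data)
    ctx = _Ctx(spec, data, covs)
    n_par = spec.n_params(covs)
    if init is None:
        theta0 = np.zeros(n_par)
    else:
        init.check(spec, covs)
        theta0 = init.theta
    bounds = [(-CLAMP, CLAMP)] * n_par

    res = optimize.minimize(
        _nll_grad,
        theta0,
        args=(ctx,),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500},
    )
    used_fallback = False
    if not res.success:
        nm = optimize.minimize(
            lambda t: _nll_grad(np.clip(t, -CLAMP, CLAMP), ctx, want_grad=False),
            res.x if np.isfinite(res.fun) else theta0,
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        used_fallback = True
        if nm.fun <= res.fun or not np.isfinite(res.fun):
            res = nm
    theta_hat = np.clip(res.x, -CLAMP, CLAMP)
    fval, grad = _nll_grad(theta_hat, ctx)

    at_clamp = bool((np.abs(theta_hat) >= CLAMP - 1e-6).any())
    if at_clamp:
        warnings.warn("MLE at the logit-scale clamp; estimates are boundary values")
    H = _fd_hessian(theta_hat, ctx)
    vcov = None
    hess_pd = False
    try:
        c = cho_factor(H)
        vcov = cho_solve(c, np.eye(len(theta_hat)))
        hess_pd = True
    except np.linalg.LinAlgError:
        pass

    gnorm = float(np.max(np.abs(grad)))
    converged = (
        bool(res.success)
        and hess_pd
        and not at_clamp
        and gnorm < 1e-3 * max(1.0, abs(fval))
    )
    return FitResult(
        spec=spec,
        estimate=ParamVector.from_theta(theta_hat, covs.n_occ),
        vcov=vcov,
        loglik=-fval,
        converged=converged,
        coef_names=spec.coef_names(covs),
        diagnostics={
            "optimizer_success": bool(res.success),
            "used_fallback": used_fallback,
            "grad_norm": gnorm,
            "hessian_pd": hess_pd,
            "at_clamp": at_clamp,
            "n_iter": int(res.get("nit", -1)) if hasattr(res, "get") else -1,
        },
    )


def wald_interval(
    fitres: FitResult,
    quantity: tuple,
    level: float = 0.95,
) -> tuple[float, float]:
    """Asymptotic Wald confidence interval.

    ``quantity`` is one of:

    * ``("coef", name_or_index)`` — interval on the coefficient scale;
    * ``("psi", x)`` — occupancy probability at occupancy profile ``x``
      (length-P vector, intercept included);
    * ``("p", v)`` — detection probability at detection profile ``v``
      (length matching the detection coefficient vector; for the Markov
      family the last entry is the Mark indicator, e.g. 0 for p0, 1 for
      p1).

    Probability intervals are computed on the logit scale and
    back-transformed, so they always lie inside (0, 1).
    """
    if not fitres.converged:
        raise ValueError("Wald intervals require a converged fit")
    kind, profile = quantity
    theta = fitres.estimate.theta
    nb = len(fitres.estimate.beta)
    z = norm.ppf(0.5 + level / 2.0)

    if kind == "coef":
        idx = profile if isinstance(profile, int) else fitres.coef_names.index(profile)
        se = float(np.sqrt(fitres.vcov[idx, idx]))
        return (theta[idx] - z * se, theta[idx] + z * se)

    if kind == "psi":
        x = np.zeros(len(theta))
        x[:nb] = np.asarray(profile, dtype=float)
    elif kind == "p":
        x = np.zeros(len(theta))
        x[nb:] = np.asarray(profile, dtype=float)
    else:
        raise ValueError("quantity kind must be 'coef', 'psi' or 'p'")
    eta = float(x @ theta)
    se = float(np.sqrt(x @ fitres.vcov @ x))
    return (float(expit(eta - z * se)), float(expit(eta + z * se)))
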