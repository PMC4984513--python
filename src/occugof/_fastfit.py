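"""Batched maximum-likelihood refitting for covariate-free models.

Parametric-bootstrap studies refit the same intercept-only model to
thousands of simulated datasets.  For a covariate-free model the
likelihood depends on each unit's history only through a handful of
sufficient statistics (detection counts for the basic family; transition
and chain-restart counts for the Markov family), so whole batches of
replicate datasets can be fit simultaneously with a damped Newton
iteration on stacked arrays.  The objective is algebraically identical to
the dense per-dataset likelihood in :mod:`occugof.models`; this module is
purely a computational reorganization and its results are checked against
the general-purpose fitter in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

CLAMP = 15.0

# sufficient-statistic columns, markov family:
# 0: nondetections after a nondetection   (state 0, y = 0)
# 1: detections after a nondetection      (state 0, y = 1)
# 2: nondetections after a detection      (state 1, y = 0)
# 3: detections after a detection         (state 1, y = 1)
# 4: nondetections at a chain restart     (state 2, y = 0)
# 5: detections at a chain restart        (state 2, y = 1)


def suffstats(family: str, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit sufficient statistics for a batch of datasets.

    ``values`` is (B, N, J, K) trinary (nan = unsurveyed).  Returns
    ``counts`` (B, N, 2) or (B, N, 6) and the all-zero-history indicator
    (B, N).
    """
    obs = ~np.isnan(values)
    y1 = values == 1
    allzero = ~y1.any(axis=(2, 3))
    if family == "basic":
        s = y1.sum(axis=(2, 3))
        m = obs.sum(axis=(2, 3))
        counts = np.stack([m - s, s], axis=-1).astype(float)
        return counts, allzero

    b, n, j, k = values.shape
    state = np.full((b, n, j, k), 2, dtype=np.int8)
    if k > 1:
        prev = values[..., :-1]
        cur = state[..., 1:]
        cur[prev == 0] = 0
        cur[prev == 1] = 1
    counts = np.empty((b, n, 6))
    for s_code in (0, 1, 2):
        sel = obs & (state == s_code)
        counts[..., 2 * s_code] = (sel & ~y1).sum(axis=(2, 3))
        counts[..., 2 * s_code + 1] = (sel & y1).sum(axis=(2, 3))
    return counts, allzero


def _nll_grad_batch(
    family: str, theta: np.ndarray, counts: np.ndarray, allzero: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Value (B,) and gradient (B, d) of the batched negative
    log-likelihood at ``theta`` (B, d)."""
    beta = theta[:, 0:1]
    psi = expit(beta)
    log_psi = -np.logaddexp(0.0, -beta)
    log_1mpsi = -np.logaddexp(0.0, beta)

    with np.errstate(divide="ignore"):
        if family == "basic":
            a0 = theta[:, 1:2]
            p = expit(a0)
            cll = counts[..., 1] * np.log(p) + counts[..., 0] * np.log1p(-p)
            d_det = [counts[..., 1] - (counts[..., 0] + counts[..., 1]) * p]
        else:
            a0 = theta[:, 1:2]
            am = theta[:, 2:3]
            p0 = expit(a0)
            p1 = expit(a0 + am)
            denom = p0 + 1.0 - p1
            pm = p0 / denom
            cll = (
                counts[..., 0] * np.log1p(-p0)
                + counts[..., 1] * np.log(p0)
                + counts[..., 2] * np.log1p(-p1)
                + counts[..., 3] * np.log(p1)
                + counts[..., 4] * np.log1p(-pm)
                + counts[..., 5] * np.log(pm)
            )
            u0 = counts[..., 1] - (counts[..., 0] + counts[..., 1]) * p0
            u1 = counts[..., 3] - (counts[..., 2] + counts[..., 3]) * p1
            rterm = (counts[..., 5] - (counts[..., 4] + counts[..., 5]) * pm) / (
                pm * (1.0 - pm)
            )
            d0 = p0 * (1.0 - p0)
            d1 = p1 * (1.0 - p1)
            dpm_de0 = (1.0 - p1) * d0 / denom**2
            dpm_de1 = p0 * d1 / denom**2
            d_det = [u0 + u1 + rterm * (dpm_de0 + dpm_de1), u1 + rterm * dpm_de1]

    a = log_psi + cll
    li = np.where(allzero, np.logaddexp(a, log_1mpsi), a)
    f = -li.sum(axis=1)

    with np.errstate(over="ignore"):
        ratio = np.exp(np.clip(log_1mpsi - a, -745.0, 700.0))
    w_cll = np.where(allzero, 1.0 / (1.0 + ratio), 1.0)
    w_psi = np.where(allzero, (1.0 - psi) * w_cll - psi * (1.0 - w_cll), 1.0 - psi)

    g = np.empty_like(theta)
    g[:, 0] = -w_psi.sum(axis=1)
    for col, dd in enumerate(d_det, start=1):
        g[:, col] = -(w_cll * dd).sum(axis=1)
    return f, g


def _fd_hessian_batch(
    family: str, theta: np.ndarray, counts: np.ndarray, allzero: np.ndarray
) -> np.ndarray:
    """Central finite differences of the batched gradient: (B, d, d)."""
    b, d = theta.shape
    H = np.empty((b, d, d))
    for k in range(d):
        hk = 1e-5 * np.maximum(1.0, np.abs(theta[:, k]))
        tp = theta.copy()
        tp[:, k] += hk
        tm = theta.copy()
        tm[:, k] -= hk
        gp = _nll_grad_batch(family, tp, counts, allzero)[1]
        gm = _nll_grad_batch(family, tm, counts, allzero)[1]
        H[:, :, k] = (gp - gm) / (2.0 * hk)[:, None]
    return 0.5 * (H + np.swapaxes(H, 1, 2))


def batch_fit_intercept(
    family: str, values: np.ndarray, max_iter: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the intercept-only model to every dataset in a batch.

    ``values`` is (B, N, J, K) trinary.  All fits start from zero on the
    logit scale and are clamped to +/-15.  Returns the parameter matrix
    (B, d) and a converged flag per dataset using the same screen as the
    scalar fitter: small gradient, positive-definite Hessian, estimate not
    at the clamp.  Also returns the inverse-Hessian variance matrices
    (B, d, d), nan-filled where the Hessian is not positive definite.
    """
    counts, allzero = suffstats(family, values)
    b = values.shape[0]
    d = 2 if family == "basic" else 3
    theta = np.zeros((b, d))
    active = np.ones(b, dtype=bool)
    stuck = np.zeros(b, dtype=bool)

    f, g = _nll_grad_batch(family, theta, counts, allzero)
    for _ in range(max_iter):
        active &= np.abs(g).max(axis=1) >= 1e-8 * np.maximum(1.0, np.abs(f))
        if not active.any():
            break
        H = _fd_hessian_batch(family, theta, counts, allzero)
        step = np.zeros_like(theta)
        lam = np.zeros(b)
        need = active.copy()
        for _ in range(8):  # Levenberg damping until a descent direction
            idx = np.flatnonzero(need)
            if idx.size == 0:
                break
            Hl = H[idx] + lam[idx, None, None] * np.eye(d)
            try:
                sol = np.linalg.solve(Hl, g[idx][..., None])[..., 0]
            except np.linalg.LinAlgError:
                sol = np.array(
                    [
                        np.linalg.lstsq(Hl[i], g[idx][i], rcond=None)[0]
                        for i in range(len(idx))
                    ]
                )
            step[idx] = sol
            descent = np.einsum("bd,bd->b", sol, g[idx]) > 0
            ok = idx[descent & np.isfinite(sol).all(axis=1)]
            need[ok] = False
            bad = need & active
            lam[bad] = np.maximum(lam[bad] * 10.0, 1e-4)
        # any replicate still without a descent direction: steepest descent
        rem = np.flatnonzero(need)
        if rem.size:
            step[rem] = g[rem]

        # backtracking line search, vectorized over the batch
        t = np.where(active, 1.0, 0.0)
        improved = ~active
        for _ in range(25):
            trial = np.clip(theta - t[:, None] * step, -CLAMP, CLAMP)
            f_new, g_new = _nll_grad_batch(family, trial, counts, allzero)
            good = active & ~improved & (f_new <= f - 1e-4 * t * np.abs(
                np.einsum("bd,bd->b", step, g)
            ))
            theta[good] = trial[good]
            f[good] = f_new[good]
            g[good] = g_new[good]
            improved |= good
            if (improved | ~active).all():
                break
            t = np.where(improved | ~active, t, t / 2.0)
        newly_stuck = active & ~improved
        stuck |= newly_stuck
        active &= improved

    H = _fd_hessian_batch(family, theta, counts, allzero)
    hess_pd = np.zeros(b, dtype=bool)
    vcov = np.full_like(H, np.nan)
    for i in range(b):
        try:
            np.linalg.cholesky(H[i])
            hess_pd[i] = True
            vcov[i] = np.linalg.inv(H[i])
        except np.linalg.LinAlgError:
            pass
    at_clamp = (np.abs(theta) >= CLAMP - 1e-6).any(axis=1)
    small_grad = np.abs(g).max(axis=1) < 1e-3 * np.maximum(1.0, np.abs(f))
    converged = small_grad & hess_pd & ~at_clamp & ~stuck
    return theta, converged, vcov
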