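"""Simulate detection histories under the Markov occupancy model.

Occupancy states are independent Bernoulli(psi) draws.  Within an occupied
unit each station (spatial replicate) runs an independent two-state
detection chain over nights: the first night is Bernoulli(p_mean) at the
chain's equilibrium, and each later night is Bernoulli(p1) after a
detection or Bernoulli(p0) after a nondetection.  Setting ``p0 == p1``
recovers the basic model of independent Bernoulli revisits.

The same machinery simulates parametric-bootstrap replicates from a fitted
model (cell-specific probabilities, original missingness pattern, chain
restart at equilibrium after unsurveyed gaps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DetectionArray
from .models import FitResult, ModelSpec, cell_probs, equilibrium_p
from .data import CovariateSet

__all__ = ["SimConfig", "simulate_dataset", "simulate_from_fit"]


@dataclass
class SimConfig:
    """Study conditions for one simulation scenario.

    ``missingness`` is an optional boolean (J, K) or (N, J, K) array of
    cells to blank out after generation (True = surveyed).
    """

    n_units: int = 50
    n_spatial: int = 4
    n_temporal: int = 4
    psi: float = 0.8
    p0: float = 0.5
    p1: float = 0.5
    n_datasets: int = 1
    seed: int = 0
    missingness: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("psi", "p0", "p1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p0 + (1.0 - self.p1) <= 0.0:
            raise ValueError("p0 + (1 - p1) must be > 0 for the equilibrium start")
        if min(self.n_units, self.n_spatial, self.n_temporal, self.n_datasets) < 1:
            raise ValueError("n_units, n_spatial, n_temporal, n_datasets must be >= 1")

    @property
    def p_mean(self) -> float:
        return equilibrium_p(self.p0, self.p1)


def _rng_for(seed: int, dataset_index: int) -> np.random.Generator:
    """Deterministic substream: identical (seed, index) gives identical
    output regardless of call order."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(dataset_index,)))


def simulate_dataset(
    cfg: SimConfig,
    dataset_index: int = 0,
    return_z: bool = False,
):
    """Generate one dataset under the configured Markov occupancy model.

    Returns a :class:`DetectionArray`, plus the latent occupancy vector
    ``z`` when ``return_z`` is set.
    """
    rng = _rng_for(cfg.seed, dataset_index)
    n, j, k = cfg.n_units, cfg.n_spatial, cfg.n_temporal
    z = rng.random(n) < cfg.psi
    y = np.zeros((n, j, k))
    # chains vectorized across units and stations
    u = rng.random((n, j, k))
    y[:, :, 0] = u[:, :, 0] < cfg.p_mean
    for t in range(1, k):
        p_t = np.where(y[:, :, t - 1] == 1, cfg.p1, cfg.p0)
        y[:, :, t] = u[:, :, t] < p_t
    y *= z[:, None, None]
    if cfg.missingness is not None:
        m = np.broadcast_to(np.asarray(cfg.missingness, dtype=bool), y.shape)
        y = np.where(m, y, np.nan)
    d = DetectionArray(y)
    return (d, z) if return_z else d


def simulate_from_fit(
    fitres: FitResult,
    data: DetectionArray,
    covs: CovariateSet,
    rng: np.random.Generator,
) -> DetectionArray:
    """One parametric-bootstrap replicate from a fitted model.

    Keeps the observed missingness pattern and covariates; redraws the
    occupancy states and all surveyed cells.  For the Markov family a cell
    whose predecessor night was not surveyed restarts the chain at the
    cell-specific equilibrium probability, matching the likelihood.
    """
    spec: ModelSpec = fitres.spec
    cp = cell_probs(spec, fitres.estimate, covs)
    n, j, k = data.values.shape
    obs = data.mask
    z = rng.random(n) < cp["psi"]
    u = rng.random((n, j, k))
    y = np.zeros((n, j, k))
    if spec.family == "basic":
        y = (u < cp["p"]).astype(float)
    else:
        p0, p1, pm = cp["p0"], cp["p1"], cp["p_mean"]
        y[:, :, 0] = u[:, :, 0] < pm[:, :, 0]
        for t in range(1, k):
            prev_obs = obs[:, :, t - 1]
            p_t = np.where(
                prev_obs & (y[:, :, t - 1] == 1),
                p1[:, :, t],
                np.where(prev_obs, p0[:, :, t], pm[:, :, t]),
            )
            y[:, :, t] = u[:, :, t] < p_t
    y *= z[:, None, None]
    y = np.where(obs, y, np.nan)
    return DetectionArray(y, unit_ids=list(data.unit_ids))
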