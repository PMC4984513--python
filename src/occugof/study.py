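"""Size/power/coverage simulation study for the occupancy GOF tests.

The study grid crosses within-season revisit designs (J stations x K
nights per unit, all with N = 50 units) with five serial-correlation
levels p0/p1 in {0.5/0.5, 0.4/0.6, 0.3/0.7, 0.2/0.8, 0.1/0.9}, all sharing
equilibrium detection probability 0.5.  For every simulated dataset the
constrained-permutation join-count test is run on the raw data, then the
basic and Markov models are fit and the MacKenzie-Bailey and join-count
chi-square tests (both neighbor definitions) are run on each converged
fit, with bootstrap replicates shared across the three statistics of one
fit.  Datasets are shared across models and tests within a cell (paired
comparisons), which only reduces comparison variance.

The headline summaries are, per cell, the proportion of datasets with
p-value below alpha (test size when the fitted family generated the data,
power otherwise) and, per fitted model, the mean estimates, bias, Wald CI
coverage for psi and the convergence-failure count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import CovariateSet
from .gof import NeighborScheme, bootstrap_gof, permutation_join_test
from .models import ModelSpec, fit, wald_interval
from .simulate import SimConfig, simulate_dataset

__all__ = ["StudyGrid", "StudyResult", "run_study"]

DESIGNS = ((1, 16), (4, 4), (1, 8), (4, 2))
LEVELS = ((0.5, 0.5), (0.4, 0.6), (0.3, 0.7), (0.2, 0.8), (0.1, 0.9))

_TEST_KEYS = {
    "mb": ("mb", None),
    "jc1": ("jc", NeighborScheme.ALL_TEMPORAL),
    "jc2": ("jc", NeighborScheme.CONSECUTIVE),
}


@dataclass
class StudyGrid:
    """Configuration of the simulation study.

    Defaults are the desk-scale settings (200 datasets, 200 bootstrap
    replicates, 199 permutations per test); :meth:`full_scale` switches to
    500/500/999.  ``psi`` is the generating occupancy probability, also
    used as the truth when scoring CI coverage.
    """

    designs: tuple = DESIGNS
    levels: tuple = LEVELS
    n_units: int = 50
    psi: float = 0.8
    n_datasets: int = 200
    n_boot: int = 200
    n_perm: int = 199
    alpha: float = 0.05
    seed: int = 0
    models: tuple = ("basic", "markov")
    tests: tuple = ("mb", "jc1", "jc2", "perm")

    def full_scale(self) -> "StudyGrid":
        return replace(self, n_datasets=500, n_boot=500, n_perm=999)


@dataclass
class StudyResult:
    """Tidy per-cell summaries plus the raw per-dataset records."""

    tests: pd.DataFrame
    estimation: pd.DataFrame
    raw_pvalues: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.tests.to_csv(out / "results.csv", index=False)
        self.estimation.to_csv(out / "convergence.csv", index=False)
        if len(self.raw_pvalues):
            self.raw_pvalues.to_csv(out / "pvalues.csv", index=False)

    def plot_power_curves(self, outdir) -> list:
        """Write one power-curve figure per design: rejection proportion
        versus p1 - p0, one line per (model, test).  Requires matplotlib."""
        from pathlib import Path

        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for (j, k), g in self.tests.groupby(["J", "K"]):
            fig, ax = plt.subplots(figsize=(5, 4))
            for (model, test), gg in g.groupby(["model", "test"]):
                gg = gg.sort_values("p1")
                ax.plot(
                    gg["p1"] - gg["p0"],
                    gg["rejection_prop"],
                    marker="o",
                    label=f"{model}/{test}",
                )
            ax.axhline(0.05, color="grey", lw=0.8, ls=":")
            ax.set_xlabel("serial correlation (p1 - p0)")
            ax.set_ylabel("proportion of p-values < 0.05")
            ax.set_title(f"{j} stations x {k} nights")
            ax.set_ylim(-0.02, 1.02)
            ax.legend(fontsize=7)
            path = out / f"power_{j}x{k}.png"
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
            written.append(path)
        return written


def _derived_seed(grid_seed: int, *key: int) -> int:
    """Deterministic 31-bit sub-seed for one grid cell / purpose."""
    ss = np.random.SeedSequence(entropy=grid_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_cell(
    grid: StudyGrid,
    design: tuple,
    level: tuple,
    design_index: int = 0,
    level_index: int = 0,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run one (design, correlation level) cell of the study.

    Returns (test summary rows, estimation summary rows, raw p-value
    records).
    """
    j, k = design
    p0, p1 = level
    cfg = SimConfig(
        n_units=grid.n_units,
        n_spatial=j,
        n_temporal=k,
        psi=grid.psi,
        p0=p0,
        p1=p1,
        seed=_derived_seed(grid.seed, design_index, level_index, 0),
    )
    boot_tests = [_TEST_KEYS[t] for t in grid.tests if t in _TEST_KEYS]
    want_perm = "perm" in grid.tests

    pvals: list = []
    est: list = []
    nonconv = {m: 0 for m in grid.models}
    for b in range(grid.n_datasets):
        data = simulate_dataset(cfg, b)
        covs = CovariateSet.intercept_only(data)
        base = {"J": j, "K": k, "p0": p0, "p1": p1, "dataset": b}

        if want_perm:
            for sch_name, sch in (("jc1", NeighborScheme.ALL_TEMPORAL),
                                  ("jc2", NeighborScheme.CONSECUTIVE)):
                res = permutation_join_test(
                    data,
                    sch,
                    n_perm=grid.n_perm,
                    seed=_derived_seed(grid.seed, design_index, level_index, 1, b),
                )
                pvals.append(base | {"model": "none", "test": f"perm_{sch_name}",
                                     "p_value": res.p_value})

        for m_idx, family in enumerate(grid.models):
            fr = fit(ModelSpec(family=family), data, covs)
            if not fr.converged:
                nonconv[family] += 1
                continue
            psi_hat = float(
                1.0 / (1.0 + np.exp(-fr.estimate.beta[0]))
            )
            lo, hi = wald_interval(fr, ("psi", [1.0]))
            rec = base | {
                "model": family,
                "psi_hat": psi_hat,
                "psi_lo": lo,
                "psi_hi": hi,
            }
            if family == "basic":
                rec["p_hat"] = float(1.0 / (1.0 + np.exp(-fr.estimate.alpha[0])))
            else:
                a0, am = fr.estimate.alpha[0], fr.estimate.alpha[1]
                rec["p0_hat"] = float(1.0 / (1.0 + np.exp(-a0)))
                rec["p1_hat"] = float(1.0 / (1.0 + np.exp(-(a0 + am))))
            est.append(rec)

            if boot_tests:
                results = bootstrap_gof(
                    data,
                    covs,
                    fr,
                    boot_tests,
                    n_boot=grid.n_boot,
                    seed=_derived_seed(grid.seed, design_index, level_index, 2 + m_idx, b),
                )
                for name, key in _TEST_KEYS.items():
                    if key in results:
                        pvals.append(base | {"model": family, "test": name,
                                             "p_value": results[key].p_value})
        if progress and (b + 1) % 20 == 0:
            print(f"  design {design} level {level}: {b + 1}/{grid.n_datasets}")

    pv = pd.DataFrame(pvals)
    test_rows = []
    if len(pv):
        for (model, test), g in pv.groupby(["model", "test"]):
            n = len(g)
            rej = int((g["p_value"] < grid.alpha).sum())
            prop = rej / n
            test_rows.append(
                {
                    "J": j, "K": k, "p0": p0, "p1": p1,
                    "model": model, "test": test,
                    "n_datasets": grid.n_datasets, "n_used": n,
                    "n_reject": rej, "rejection_prop": prop,
                    "mc_se": float(np.sqrt(prop * (1 - prop) / n)) if n else np.nan,
                }
            )

    ed = pd.DataFrame(est)
    est_rows = []
    for family in grid.models:
        g = ed[ed["model"] == family] if len(ed) else ed
        n = len(g)
        row = {
            "J": j, "K": k, "p0": p0, "p1": p1, "model": family,
            "n_converged": n, "n_nonconverged": nonconv[family],
        }
        if n:
            cover = ((g["psi_lo"] <= grid.psi) & (grid.psi <= g["psi_hi"])).mean()
            row |= {
                "mean_psi_hat": float(g["psi_hat"].mean()),
                "psi_bias": float(g["psi_hat"].mean() - grid.psi),
                "coverage_psi": float(cover),
                "mean_ci_width_psi": float((g["psi_hi"] - g["psi_lo"]).mean()),
            }
            for col in ("p_hat", "p0_hat", "p1_hat"):
                if col in g and g[col].notna().any():
                    row[f"mean_{col}"] = float(g[col].mean())
        est_rows.append(row)

    return pd.DataFrame(test_rows), pd.DataFrame(est_rows), pv


def run_study(grid: StudyGrid, progress: bool = False) -> StudyResult:
    """Run every (design, level) cell of the grid and stack the summaries."""
    t_parts, e_parts, p_parts = [], [], []
    for di, design in enumerate(grid.designs):
        for li, level in enumerate(grid.levels):
            if progress:
                print(f"cell: design {design}, p0/p1 {level}")
            t, e, p = run_cell(grid, design, level, di, li, progress=progress)
            t_parts.append(t)
            e_parts.append(e)
            p_parts.append(p)
    return StudyResult(
        tests=pd.concat(t_parts, ignore_index=True),
        estimation=pd.concat(e_parts, ignore_index=True),
        raw_pvalues=pd.concat(p_parts, ignore_index=True),
    )
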