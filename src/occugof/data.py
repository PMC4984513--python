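"""Detection-history containers, covariate designs, and cohort bookkeeping.

A detection history records, for each areal sample unit ``i``, a grid of
binary survey outcomes ``Y[i, j, k]`` over spatial replicates ``j`` (e.g.
detector stations within the unit) and temporal replicates ``k`` (e.g.
consecutive survey nights at a station).  Cells that were never surveyed are
missing; units sharing a missingness pattern form a *cohort*, the grouping
over which goodness-of-fit discrepancies are accumulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectionArray",
    "CovariateSet",
    "CohortPartition",
    "read_detections",
    "write_detections",
    "partition_cohorts",
    "naive_occupancy",
]


@dataclass
class DetectionArray:
    """Dense ``N x J x K`` trinary detection-history tensor.

    ``values`` is a float array holding 0.0 (nondetection), 1.0 (detection)
    or ``nan`` (cell not surveyed).  Temporal index ``k`` is chronological
    within a spatial replicate: consecutive indices are consecutive survey
    occasions, which is what gives the Markov detection model and the
    consecutive-neighbor join counts their meaning.
    """

    values: np.ndarray
    unit_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-d (unit, spatial, temporal) array")
        if not self.unit_ids:
            # zero-padded so the label sort used by the readers preserves order
            w = len(str(self.values.shape[0]))
            self.unit_ids = [f"u{i + 1:0{w}d}" for i in range(self.values.shape[0])]
        if len(self.unit_ids) != self.values.shape[0]:
            raise ValueError("unit_ids length does not match first dimension")
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_spatial(self) -> int:
        return self.values.shape[1]

    @property
    def n_temporal(self) -> int:
        return self.values.shape[2]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell was surveyed."""
        return ~np.isnan(self.values)

    def validate(self) -> None:
        obs = self.mask
        vals = self.values[obs]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("non-missing detection entries must be 0 or 1")
        if not obs.any(axis=(1, 2)).all():
            bad = [self.unit_ids[i] for i in np.flatnonzero(~obs.any(axis=(1, 2)))]
            raise ValueError(f"units with no surveyed cells: {bad}")

    def unit_history(self, i: int) -> np.ndarray:
        """The (J, K) trinary history of one unit."""
        return self.values[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DetectionArray):
            return NotImplemented
        return (
            self.unit_ids == other.unit_ids
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


def read_detections(table: pd.DataFrame | str | Path) -> DetectionArray:
    """Build a :class:`DetectionArray` from long-format records.

    Expected columns: ``unit, spatial, temporal, detection`` with 1-based
    positive integer replicate indices and detection in {0, 1} or blank/NA
    for a surveyed-but-missing record.  Grid dimensions J and K are the
    maximum indices present; cells with no record are missing, which is how
    unbalanced designs (and hence cohorts) arise.

    Units are ordered by a stable sort of their labels so that file row
    order never influences downstream results.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    required = {"unit", "spatial", "temporal", "detection"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")

    df = table.copy()
    for col in ("spatial", "temporal"):
        idx = pd.to_numeric(df[col], errors="raise")
        if (idx < 1).any() or (idx != idx.astype(int)).any():
            raise ValueError(f"{col} indices must be positive integers")
        df[col] = idx.astype(int)

    dup = df.duplicated(subset=["unit", "spatial", "temporal"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["unit", "spatial", "temporal"]].tolist()
        raise ValueError(f"duplicate (unit, spatial, temporal) record: {first}")

    det = pd.to_numeric(df["detection"], errors="coerce")
    bad = det.notna() & ~det.isin([0, 1])
    if bad.any() or (df["detection"].notna() & df["detection"].astype(str).str.strip().ne("")
                     & det.isna() & ~df["detection"].astype(str).str.upper().isin(["NA", "NAN"])).any():
        raise ValueError("detection values must be 0, 1 or NA")

    units = sorted(df["unit"].unique(), key=str)
    n, j_max, k_max = len(units), int(df["spatial"].max()), int(df["temporal"].max())
    values = np.full((n, j_max, k_max), np.nan)
    unit_pos = {u: i for i, u in enumerate(units)}
    rows = df["unit"].map(unit_pos).to_numpy()
    values[rows, df["spatial"].to_numpy() - 1, df["temporal"].to_numpy() - 1] = det.to_numpy()
    return DetectionArray(values, unit_ids=list(units))


def write_detections(d: DetectionArray, path: str | Path) -> None:
    """Write surveyed cells as long-format CSV (1-based indices).

    Missing cells are simply absent, so ``read_detections`` round-trips any
    valid array.
    """
    i, j, k = np.nonzero(d.mask)
    pd.DataFrame(
        {
            "unit": [d.unit_ids[a] for a in i],
            "spatial": j + 1,
            "temporal": k + 1,
            "detection": d.values[i, j, k].astype(int),
        }
    ).to_csv(path, index=False)


@dataclass
class CohortPartition:
    """Partition of units into groups sharing one missing-cell pattern."""

    patterns: list  # list of (J, K) boolean observed-cell masks
    members: list  # list of integer index arrays, parallel to patterns

    def __iter__(self):
        return iter(zip(self.patterns, self.members))

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def sizes(self) -> list:
        return [len(m) for m in self.members]


def partition_cohorts(d: DetectionArray) -> CohortPartition:
    """Group units by identical missingness pattern over the J x K grid.

    Balanced data yield a single cohort of all N units.  Cohort order is
    the order of first appearance in unit order (itself label-sorted), so
    the partition is deterministic.
    """
    obs = d.mask.reshape(d.n_units, -1)
    patterns: list = []
    members: list = []
    seen: dict = {}
    for i in range(d.n_units):
        key = obs[i].tobytes()
        if key not in seen:
            seen[key] = len(patterns)
            patterns.append(obs[i].reshape(d.n_spatial, d.n_temporal).copy())
            members.append([i])
        else:
            members[seen[key]].append(i)
    return CohortPartition(patterns, [np.asarray(m, dtype=int) for m in members])


def naive_occupancy(d: DetectionArray) -> np.ndarray:
    """Indices of units with at least one observed detection."""
    return np.flatnonzero((d.values == 1).any(axis=(1, 2)))


@dataclass
class CovariateSet:
    """Occupancy and detection design matrices on the logit scale.

    ``occ_design`` is N x P with an intercept first column; ``det_design``
    is N x J x K x Q with an intercept first slice.  The Markov detection
    term is *not* a column here — it is data-derived and handled by the
    model family.
    """

    occ_design: np.ndarray
    det_design: np.ndarray
    occ_names: list = field(default_factory=list)
    det_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.occ_design = np.asarray(self.occ_design, dtype=float)
        self.det_design = np.asarray(self.det_design, dtype=float)
        if self.occ_design.ndim != 2 or self.det_design.ndim != 4:
            raise ValueError("occ_design must be 2-d and det_design 4-d")
        if self.occ_design.shape[1] < 1 or self.det_design.shape[3] < 1:
            raise ValueError("designs need at least an intercept column")
        if not self.occ_names:
            self.occ_names = [f"occ{p}" for p in range(self.occ_design.shape[1])]
        if not self.det_names:
            self.det_names = [f"det{q}" for q in range(self.det_design.shape[3])]

    @property
    def n_occ(self) -> int:
        return self.occ_design.shape[1]

    @property
    def n_det(self) -> int:
        return self.det_design.shape[3]

    @classmethod
    def intercept_only(cls, d: DetectionArray) -> "CovariateSet":
        """The covariate-free design: constant psi and constant p."""
        n, j, k = d.values.shape
        return cls(
            np.ones((n, 1)),
            np.ones((n, j, k, 1)),
            occ_names=["(Intercept)"],
            det_names=["(Intercept)"],
        )

    def check_against(self, d: DetectionArray) -> None:
        if self.occ_design.shape[0] != d.n_units:
            raise ValueError("occ_design row count != number of units")
        if self.det_design.shape[:3] != d.values.shape:
            raise ValueError("det_design shape != detection grid shape")
        if np.isnan(self.occ_design).any():
            raise ValueError("missing occupancy covariate values")
        if np.isnan(self.det_design[d.mask]).any():
            raise ValueError("missing detection covariate at a surveyed cell")


def _expand_columns(df: pd.DataFrame, cols: Sequence[str]) -> tuple[np.ndarray, list]:
    """Numeric columns pass through; string/categorical columns become
    baseline-contrast indicators with the alphabetically first level as
    baseline."""
    parts = []
    names: list = []
    for c in cols:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.to_numpy(dtype=float)[:, None])
            names.append(c)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                parts.append((col.astype(str) == lev).to_numpy(dtype=float)[:, None])
                names.append(f"{c}[{lev}]")
    if parts:
        return np.hstack(parts), names
    return np.empty((len(df), 0)), names


def read_covariates(
    d: DetectionArray,
    occ_table: pd.DataFrame | str | Path | None = None,
    det_table: pd.DataFrame | str | Path | None = None,
) -> CovariateSet:
    """Assemble a :class:`CovariateSet` from covariate tables.

    ``occ_table`` is keyed by ``unit``; ``det_table`` by
    ``unit, spatial, temporal`` (1-based).  An intercept column is always
    prepended.  Rows with a missing detection covariate at a surveyed cell
    are rejected rather than imputed.
    """
    base = CovariateSet.intercept_only(d)
    X, occ_names = base.occ_design, list(base.occ_names)
    V, det_names = base.det_design, list(base.det_names)
    unit_pos = {u: i for i, u in enumerate(d.unit_ids)}

    if occ_table is not None:
        if not isinstance(occ_table, pd.DataFrame):
            occ_table = pd.read_csv(occ_table)
        df = occ_table.set_index("unit").reindex(d.unit_ids).reset_index()
        cols = [c for c in df.columns if c != "unit"]
        mat, names = _expand_columns(df, cols)
        if np.isnan(mat).any():
            raise ValueError("missing occupancy covariate for some unit")
        X = np.hstack([X, mat])
        occ_names += names

    if det_table is not None:
        if not isinstance(det_table, pd.DataFrame):
            det_table = pd.read_csv(det_table)
        cols = [c for c in det_table.columns if c not in ("unit", "spatial", "temporal")]
        mat, names = _expand_columns(det_table, cols)
        extra = np.full((d.n_units, d.n_spatial, d.n_temporal, mat.shape[1]), np.nan)
        rows = det_table["unit"].map(unit_pos).to_numpy()
        extra[rows, det_table["spatial"].to_numpy() - 1, det_table["temporal"].to_numpy() - 1, :] = mat
        if np.isnan(extra[d.mask]).any():
            raise ValueError("missing detection covariate at a surveyed cell")
        V = np.concatenate([V, extra], axis=3)
        det_names += names

    covs = CovariateSet(X, V, occ_names=occ_names, det_names=det_names)
    covs.check_against(d)
    return covs
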