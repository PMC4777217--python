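"""Self-organizing map (SOM) clustering of compound profiles.

Compounds are clustered by pairwise Euclidean distance between their
curve-rank activity profiles, or between binary structure fingerprints, on
a rectangular SOM grid.  Training follows the classic sequential algorithm:
at each step a sample pulls its best-matching unit (BMU) and the unit's
grid neighbourhood (Gaussian kernel) towards itself; the learning rate
decays linearly from alpha0 to 0 and the neighbourhood radius from radius0
to 1 over the full step budget.  Each compound is finally labelled by its
BMU as "k<row>.<col>", and an activity and a structure partition can be
intersected into consensus clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: training schedule defaults; steps_per_phase=None scales to 10 * n_samples
DEFAULT_SCHEDULE = {
    "n_phases": 14,
    "steps_per_phase": None,
    "alpha0": 0.05,
    "radius0": 20.0,
}

#: full-scale grid shapes for a ~10K compound library (610 activity units,
#: 999 structure units); desk-scale runs use much smaller grids
ACTIVITY_GRID_FULL = (61, 10)
STRUCTURE_GRID_FULL = (37, 27)


@dataclass
class SOMModel:
    """A trained map: grid geometry, codebook and its training schedule."""

    grid_rows: int
    grid_cols: int
    codebook: np.ndarray  # (rows * cols, n_features), row-major units
    schedule: dict
    seed: int
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    def unit_label(self, unit: int) -> str:
        return f"k{unit // self.grid_cols + 1}.{unit % self.grid_cols + 1}"

    def to_json(self, path) -> None:
        payload = {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "schedule": self.schedule,
            "seed": self.seed,
            "feature_names": self.feature_names,
            "codebook": self.codebook.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SOMModel":
        with open(path) as fh:
            payload = json.load(fh)
        payload["codebook"] = np.asarray(payload["codebook"], dtype=float)
        return cls(**payload)


@dataclass
class ClusterAssignment:
    """compound -> cluster label for one map kind.

    Labels are "k<row>.<col>" (1-based) for single maps; consensus labels
    are "<activity>|<structure>" pairs.  ``singletons`` flags consensus
    clusters of size one.
    """

    labels: dict[str, str]
    map_kind: str  # activity | structure | consensus
    singletons: set[str] = field(default_factory=set)

    def clusters(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for cid, lab in self.labels.items():
            out.setdefault(lab, set()).add(cid)
        return out

    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def _as_matrix(data) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(data, pd.DataFrame):
        return (
            data.to_numpy(dtype=float),
            [str(i) for i in data.index],
            [str(c) for c in data.columns],
        )
    arr = np.asarray(data, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])], [
        str(j) for j in range(arr.shape[1])
    ]


def _linear_init(X: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Deterministic codebook init along the first two principal axes.

    Uses the eigen-decomposition of the feature covariance with a
    sign-canonicalized basis, so the init (and hence training) does not
    depend on sample order.
    """
    mean = X.mean(axis=0)
    Xc = X - mean
    n = max(X.shape[0] - 1, 1)
    cov = (Xc.T @ Xc) / n
    try:
        evals, evecs = np.linalg.eigh(cov)
    except np.linalg.LinAlgError:  # pragma: no cover
        evals, evecs = np.zeros(X.shape[1]), np.eye(X.shape[1])
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    # canonical sign: largest-magnitude component positive
    for j in range(evecs.shape[1]):
        pivot = np.argmax(np.abs(evecs[:, j]))
        if evecs[pivot, j] < 0:
            evecs[:, j] = -evecs[:, j]
    sd = np.sqrt(evals)
    r = np.linspace(-1.0, 1.0, rows) if rows > 1 else np.zeros(1)
    c = np.linspace(-1.0, 1.0, cols) if cols > 1 else np.zeros(1)
    code = np.tile(mean, (rows * cols, 1))
    axis1 = sd[0] * evecs[:, 0] if sd.size >= 1 else np.zeros(X.shape[1])
    axis2 = sd[1] * evecs[:, 1] if sd.size >= 2 else np.zeros(X.shape[1])
    for i in range(rows):
        for j in range(cols):
            code[i * cols + j] += 2.0 * (r[i] * axis1 + c[j] * axis2)
    return code


def train_som(
    data,
    grid_rows: int,
    grid_cols: int,
    schedule: Mapping | None = None,
    seed: int = 0,
    mode: str = "sequential",
    lattice: str = "rectangular",
) -> SOMModel:
    """Train a SOM on a compounds x features matrix.

    ``schedule`` overrides DEFAULT_SCHEDULE keys (n_phases,
    steps_per_phase, alpha0, radius0).  The initial radius is capped at the
    grid diameter.  ``mode="batch"`` replaces the sequential updates with
    order-invariant full-batch updates (one per phase-step of a coarser
    schedule), useful when sample-order invariance matters more than
    fidelity to the classic online algorithm.  Deterministic for a fixed
    seed.
    """
    if lattice == "hexagonal":
        raise NotImplementedError("hexagonal lattices are not implemented")
    if lattice != "rectangular":
        raise ValueError(f"unknown lattice {lattice!r}")
    X, index, features = _as_matrix(data)
    if X.size == 0:
        raise ValueError("data must be non-empty")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contains non-finite features")
    if grid_rows * grid_cols < 2:
        raise ValueError("grid must have at least 2 units")
    sched = dict(DEFAULT_SCHEDULE)
    if schedule:
        sched.update({k: schedule[k] for k in schedule})
    n = X.shape[0]
    steps_per_phase = sched["steps_per_phase"] or 10 * n
    n_phases = int(sched["n_phases"])
    alpha0 = float(sched["alpha0"])
    # grid diameter caps the radius: a 20-unit radius is degenerate on a
    # small desk-scale grid
    diameter = float(np.hypot(grid_rows - 1, grid_cols - 1))
    radius0 = float(min(sched["radius0"], max(diameter, 1.0)))

    coords = np.array(
        [(i, j) for i in range(grid_rows) for j in range(grid_cols)],
        dtype=float,
    )
    # squared grid distances between all unit pairs, computed once
    gd2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    code = _linear_init(X, grid_rows, grid_cols)
    rng = np.random.default_rng(seed)

    if mode == "sequential":
        total = n_phases * steps_per_phase
        order = rng.integers(0, n, size=total)
        # radius shrinks linearly radius0 -> 1 over the first half of the
        # budget and holds at 1 (BMU-only fine-tuning) for the second half;
        # alpha decays linearly to 0 over the whole run
        for t in range(total):
            frac = t / total
            alpha = alpha0 * (1.0 - frac)
            sigma = radius0 + (1.0 - radius0) * min(2.0 * frac, 1.0)
            x = X[order[t]]
            bmu = int(np.argmin(((code - x) ** 2).sum(axis=1)))
            # Gaussian kernel truncated at the current radius: when the
            # radius reaches 1 only the BMU itself updates (fine-tuning)
            h = np.where(
                gd2[bmu] < sigma * sigma,
                np.exp(-gd2[bmu] / (2.0 * sigma * sigma)),
                0.0,
            )
            code += (alpha * h)[:, None] * (x - code)
    elif mode == "batch":
        # canonical sample order: batch updates are order-free mathematically,
        # sorting by id makes them exactly order-invariant numerically too
        X = X[np.argsort(np.asarray(index))]
        iters = max(n_phases, 2)
        for t in range(iters):
            frac = t / max(iters - 1, 1)
            sigma = radius0 + (1.0 - radius0) * frac
            d2 = ((X[:, None, :] - code[None, :, :]) ** 2).sum(-1)
            bmu = np.argmin(d2, axis=1)
            H = np.where(
                gd2[bmu] < sigma * sigma,
                np.exp(-gd2[bmu] / (2.0 * sigma * sigma)),
                0.0,
            )  # (n, units)
            denom = H.sum(axis=0)
            num = H.T @ X
            nz = denom > 1e-12
            code[nz] = num[nz] / denom[nz, None]
    else:
        raise ValueError(f"unknown training mode {mode!r}")

    final_sched = dict(sched)
    final_sched["steps_per_phase"] = steps_per_phase
    final_sched["radius0"] = radius0
    return SOMModel(
        grid_rows=grid_rows, grid_cols=grid_cols, codebook=code,
        schedule=final_sched, seed=seed, feature_names=features,
    )


def assign_clusters(model: SOMModel, data, map_kind: str = "activity") -> ClusterAssignment:
    """Label each compound by its best-matching unit ("k<row>.<col>").

    Distance ties break towards the lowest (row, col) pair; unit order is
    row-major, so numpy's first-argmin is exactly that tie-break.
    """
    X, index, _ = _as_matrix(data)
    if X.shape[1] != model.codebook.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match codebook "
            f"{model.codebook.shape[1]}"
        )
    d2 = ((X[:, None, :] - model.codebook[None, :, :]) ** 2).sum(-1)
    bmu = np.argmin(d2, axis=1)
    labels = {cid: model.unit_label(int(u)) for cid, u in zip(index, bmu)}
    return ClusterAssignment(labels=labels, map_kind=map_kind)


def quantization_error(model: SOMModel, data) -> float:
    """Mean Euclidean distance of each sample to its BMU."""
    X, _, _ = _as_matrix(data)
    d2 = ((X[:, None, :] - model.codebook[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.min(axis=1)).mean())


def consensus_clusters(
    activity: ClusterAssignment, structure: ClusterAssignment
) -> ClusterAssignment:
    """Intersect an activity and a structure partition.

    Two compounds share a consensus cluster only if they share both their
    activity cluster and their structure cluster; the consensus label is
    the ordered pair "<activity>|<structure>".  Singleton consensus
    clusters are retained and flagged in ``singletons``.
    """
    a_set, s_set = set(activity.labels), set(structure.labels)
    if a_set != s_set:
        raise ValueError(
            "activity and structure assignments cover different compounds"
        )
    labels = {
        cid: f"{activity.labels[cid]}|{structure.labels[cid]}" for cid in a_set
    }
    sizes: dict[str, int] = {}
    for lab in labels.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    singles = {lab for lab, n in sizes.items() if n == 1}
    return ClusterAssignment(labels=labels, map_kind="consensus",
                             singletons=singles)
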