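"""Counterpropagation network: competitive SOM layer + Grossberg outstar readout.

The network cascades two layers with independent learning rules.  The first
is a Kohonen self-organizing map: units sit on a lattice (square or
hexagonal, planar or toroidal), each holding a prototype vector; an input is
assigned to the unit whose prototype is nearest in Euclidean distance
(winner-take-all), and the winner together with its lattice neighborhood is
pulled toward the input.  The second is a Grossberg layer trained by the
outstar rule: each SOM unit owns an outgoing weight that is nudged toward the
desired output whenever that unit wins, so after training it approximates the
class mean (here: MCI prevalence) of the inputs quantized onto that unit.
A single output unit carries the MCI score in [0, 1]; thresholding it gives
the binary diagnosis, and sweeping the threshold traces the ROC curve.

Both layers train simultaneously: every presentation applies the SOM update
and the outstar update, with learning rates and neighborhood radius decaying
linearly over the training run.

Random-state contract (relied upon by replay-style verification): a single
``numpy.random.default_rng(seed)`` generator first draws the SOM prototypes
with one ``uniform(size=(units, dim))`` call, then one ``permutation(n)``
per epoch for the presentation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .cohort import (
    Cohort,
    CohortError,
    FeatureSubset,
    ScalingSpec,
    SubjectRecord,
    apply_scaling,
    fit_scaling,
    scale_matrix,
)


class CPNError(ValueError):
    """Invalid network configuration or input."""


# ---------------------------------------------------------------------------
# Lattice geometry


@dataclass(frozen=True)
class LatticeGeometry:
    """SOM output-layer lattice: shape, boundary condition and dimensions.

    Lattice distance is Chebyshev on square lattices and the standard cube
    (axial) distance on hexagonal lattices with odd-row offset coordinates.
    Toroidal lattices use the minimum-image convention: the distance between
    two units is minimized over copies of the second unit shifted by ±rows
    and ±cols.
    """

    shape: Literal["square", "hexagonal"] = "square"
    wrap: Literal["planar", "toroidal"] = "planar"
    rows: int = 8
    cols: int = 8

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise CPNError(f"lattice dims must be >= 1, got {self.rows}x{self.cols}")
        if self.shape not in ("square", "hexagonal"):
            raise CPNError(f"unknown lattice shape {self.shape!r}")
        if self.wrap not in ("planar", "toroidal"):
            raise CPNError(f"unknown wrap {self.wrap!r}")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def unit_coords(self) -> np.ndarray:
        """(units, 2) array of (row, col), row-major unit indexing."""
        r, c = np.divmod(np.arange(self.n_units), self.cols)
        return np.stack([r, c], axis=1)

    def distance_matrix(self) -> np.ndarray:
        """All-pairs lattice distances, (units, units)."""
        coords = self.unit_coords()
        n = self.n_units
        d = np.empty((n, n), dtype=float)
        for a in range(n):
            for b in range(n):
                d[a, b] = self._pair_distance(coords[a], coords[b])
        return d

    def _pair_distance(self, p: np.ndarray, q: np.ndarray) -> float:
        shifts = [0]
        if self.wrap == "toroidal":
            row_shifts = [-self.rows, 0, self.rows]
            col_shifts = [-self.cols, 0, self.cols]
        else:
            row_shifts = col_shifts = [0]
        best = np.inf
        for sr in row_shifts:
            for sc in col_shifts:
                r, c = int(q[0]) + sr, int(q[1]) + sc
                if self.shape == "square":
                    dist = max(abs(r - int(p[0])), abs(c - int(p[1])))
                else:
                    dist = _hex_distance(int(p[0]), int(p[1]), r, c)
                best = min(best, dist)
        return best


def _hex_distance(r1: int, c1: int, r2: int, c2: int) -> int:
    """Hex-grid distance between odd-r offset coordinates via cube coords."""
    x1 = c1 - (r1 - (r1 & 1)) // 2
    x2 = c2 - (r2 - (r2 & 1)) // 2
    z1, z2 = r1, r2
    y1, y2 = -x1 - z1, -x2 - z2
    return max(abs(x1 - x2), abs(y1 - y2), abs(z1 - z2))


# ---------------------------------------------------------------------------
# Layers and schedule


@dataclass
class SOMLayer:
    """Competitive first layer: lattice geometry plus prototype vectors."""

    geometry: LatticeGeometry
    prototypes: np.ndarray  # (units, input_dim)

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        if self.prototypes.ndim != 2:
            raise CPNError("prototypes must be a (units, dim) matrix")
        if self.prototypes.shape[0] != self.geometry.n_units:
            raise CPNError(
                f"prototype count {self.prototypes.shape[0]} does not match "
                f"lattice size {self.geometry.n_units}"
            )

    @property
    def input_dim(self) -> int:
        return self.prototypes.shape[1]


@dataclass
class GrossbergLayer:
    """Supervised readout: one outgoing weight per SOM unit per output."""

    weights: np.ndarray  # (output_dim, units)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise CPNError("readout weights must be a (outputs, units) matrix")
        if not np.all(np.isfinite(self.weights)):
            raise CPNError("readout weights must be finite")


@dataclass(frozen=True)
class TrainingSchedule:
    """Epoch count, initial rates and neighborhood radius, all decaying linearly.

    With ``t`` the presentation counter and ``T = epochs x n_records``:
    alpha(t) = alpha0 (1 - t/T), gamma(t) = gamma0 (1 - t/T); the radius
    shrinks linearly from radius0 to 0 over the first half of training and is
    0 (winner-only updates) thereafter.
    """

    epochs: int = 100
    alpha0: float = 0.5
    gamma0: float = 0.1
    radius0: float = 4.0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise CPNError("epochs must be >= 0")
        if not 0 < self.alpha0 <= 1:
            raise CPNError("alpha0 must lie in (0, 1]")
        if not 0 < self.gamma0 <= 1:
            raise CPNError("gamma0 must lie in (0, 1]")
        if self.radius0 < 0:
            raise CPNError("radius0 must be >= 0")

    def alpha(self, t: int, total: int) -> float:
        return self.alpha0 * (1.0 - t / total)

    def gamma(self, t: int, total: int) -> float:
        return self.gamma0 * (1.0 - t / total)

    def radius(self, t: int, total: int) -> float:
        frac = t / total
        return self.radius0 * (1.0 - 2.0 * frac) if frac < 0.5 else 0.0

    @classmethod
    def default_for(cls, geometry: LatticeGeometry, epochs: int = 100) -> "TrainingSchedule":
        return cls(epochs=epochs, radius0=max(geometry.rows, geometry.cols) / 2)


# ---------------------------------------------------------------------------
# Elementary network operations


def som_activations(x: np.ndarray, som: SOMLayer) -> np.ndarray:
    """Euclidean distance of the input to every unit's prototype."""
    x = np.asarray(x, dtype=float)
    if x.shape != (som.input_dim,):
        raise CPNError(
            f"input dimension {x.shape} does not match SOM input dim "
            f"({som.input_dim},)"
        )
    return np.linalg.norm(som.prototypes - x, axis=1)


def compete(nets: np.ndarray) -> np.ndarray:
    """Winner-take-all: one-hot at the minimum distance, ties to lowest index."""
    nets = np.asarray(nets, dtype=float)
    if nets.size == 0:
        raise CPNError("empty activation vector")
    u = np.zeros(nets.size, dtype=float)
    u[int(np.argmin(nets))] = 1.0
    return u


def neighborhood(
    winner: int, radius: float, geometry: LatticeGeometry,
    distance_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of all units within lattice distance ``radius`` of the winner."""
    if radius < 0:
        raise CPNError("radius must be >= 0")
    d = geometry.distance_matrix() if distance_matrix is None else distance_matrix
    return np.flatnonzero(d[winner] <= radius)


def som_update(
    x: np.ndarray, som: SOMLayer, members: np.ndarray, alpha: float
) -> None:
    """Pull each neighborhood member's prototype a fraction alpha toward x."""
    if not 0 < alpha <= 1:
        raise CPNError("alpha must lie in (0, 1]")
    som.prototypes[members] += alpha * (x - som.prototypes[members])


def grossberg_output(u: np.ndarray, layer: GrossbergLayer) -> np.ndarray:
    """Readout: each output equals its weight to the winning unit."""
    u = np.asarray(u, dtype=float)
    if not (np.isin(u, (0.0, 1.0)).all() and u.sum() == 1.0):
        raise CPNError("u must be one-hot")
    return layer.weights[:, int(np.argmax(u))].copy()


def outstar_update(
    layer: GrossbergLayer, u: np.ndarray, y: np.ndarray, d: np.ndarray, gamma: float
) -> None:
    """Outstar rule: move the winner's outgoing weights toward the target d."""
    if not 0 < gamma <= 1:
        raise CPNError("gamma must lie in (0, 1]")
    winner = int(np.argmax(np.asarray(u)))
    layer.weights[:, winner] += gamma * (np.asarray(d, float) - np.asarray(y, float))


# ---------------------------------------------------------------------------
# Model and training


@dataclass
class CPNModel:
    """A trained counterpropagation classifier for one feature subset."""

    som: SOMLayer
    grossberg: GrossbergLayer
    threshold: float
    scaling: ScalingSpec
    subset: FeatureSubset
    schedule: TrainingSchedule

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise CPNError(f"threshold must lie in [0, 1], got {self.threshold}")
        if self.som.input_dim != len(self.subset):
            raise CPNError("SOM input dim does not match feature subset size")

    def score(self, record: SubjectRecord) -> float:
        """MCI score in [0, 1] for one subject."""
        x = apply_scaling(self.scaling, record)
        nets = som_activations(x, self.som)
        winner = int(np.argmin(nets))
        return float(self.grossberg.weights[0, winner])

    def score_cohort(self, cohort: Cohort) -> np.ndarray:
        x = scale_matrix(self.scaling, cohort)
        # winner per row; prototypes and x both small, full distance matrix is fine
        d2 = ((x[:, None, :] - self.som.prototypes[None, :, :]) ** 2).sum(axis=2)
        winners = np.argmin(d2, axis=1)
        return self.grossberg.weights[0, winners]

    def classify(self, record: SubjectRecord) -> int:
        """1 (MCI) iff the score strictly exceeds the threshold."""
        return int(self.score(record) > self.threshold)

    # -- serialization ------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "format": "cpn-model",
            "version": 1,
            "geometry": {
                "shape": self.som.geometry.shape,
                "wrap": self.som.geometry.wrap,
                "rows": self.som.geometry.rows,
                "cols": self.som.geometry.cols,
            },
            "schedule": {
                "epochs": self.schedule.epochs,
                "alpha0": self.schedule.alpha0,
                "gamma0": self.schedule.gamma0,
                "radius0": self.schedule.radius0,
            },
            "prototypes": self.som.prototypes.tolist(),
            "readout": self.grossberg.weights.tolist(),
            "threshold": self.threshold,
            "scaling": {k: list(v) for k, v in self.scaling.bounds.items()},
            "subset": list(self.subset.names),
        }

    @classmethod
    def from_json_dict(cls, doc: dict) -> "CPNModel":
        if doc.get("format") != "cpn-model":
            raise CPNError("not a CPN model document")
        geom = LatticeGeometry(**doc["geometry"])
        return cls(
            som=SOMLayer(geom, np.array(doc["prototypes"], dtype=float)),
            grossberg=GrossbergLayer(np.array(doc["readout"], dtype=float)),
            threshold=float(doc["threshold"]),
            scaling=ScalingSpec({k: tuple(v) for k, v in doc["scaling"].items()}),
            subset=FeatureSubset(tuple(doc["subset"])),
            schedule=TrainingSchedule(**doc["schedule"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CPNModel":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def train_cpn(
    train: Cohort,
    subset: FeatureSubset,
    geometry: LatticeGeometry | None = None,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
) -> CPNModel:
    """Train a counterpropagation network on a cohort.

    Prototypes start uniform in the unit hypercube, the readout at 0.5
    (maximal uncertainty).  Each epoch presents every training record once in
    a seeded shuffled order; each presentation runs the competitive step, the
    neighborhood SOM update and the outstar readout update with the current
    decayed rates.  Deterministic given the seed.  The returned model carries
    the default threshold 0.5; use the ROC sweep to pick an operating point.
    """
    train.require_both_classes()
    geometry = geometry or LatticeGeometry()
    schedule = schedule or TrainingSchedule.default_for(geometry)

    scaling = fit_scaling(train, subset)
    x = scale_matrix(scaling, train)
    labels = train.labels.astype(float)
    n, k = x.shape

    rng = np.random.default_rng(seed)
    prototypes = rng.uniform(size=(geometry.n_units, k))
    som = SOMLayer(geometry, prototypes)
    grossberg = GrossbergLayer(np.full((1, geometry.n_units), 0.5))
    dist = geometry.distance_matrix()

    total = schedule.epochs * n
    t = 0
    for _ in range(schedule.epochs):
        order = rng.permutation(n)
        for idx in order:
            xi = x[idx]
            nets = np.linalg.norm(som.prototypes - xi, axis=1)
            winner = int(np.argmin(nets))
            members = np.flatnonzero(dist[winner] <= schedule.radius(t, total))
            alpha = schedule.alpha(t, total)
            som.prototypes[members] += alpha * (xi - som.prototypes[members])
            y = grossberg.weights[0, winner]
            grossberg.weights[0, winner] += schedule.gamma(t, total) * (
                labels[idx] - y
            )
            t += 1

    return CPNModel(
        som=som,
        grossberg=grossberg,
        threshold=0.5,
        scaling=scaling,
        subset=subset,
        schedule=schedule,
    )
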