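"""Shared fixtures: reference cohorts, splits, and a naive CPN trainer.

The naive trainer is a deliberately un-vectorized reimplementation of the
counterpropagation training loop (explicit Python loops over units and
components) that consumes the random generator in exactly the documented
order; it serves as an independent replay oracle for the vectorized path.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from cpn_cdss.cohort import Cohort, FeatureSubset, SubjectRecord, fit_scaling, scale_matrix
from cpn_cdss.cpn import LatticeGeometry, TrainingSchedule
from cpn_cdss.synthetic import default_adni_like_spec, generate_cohort


@pytest.fixture(scope="session")
def reference_cohort() -> Cohort:
    """The 331-subject synthetic cohort at the published group profiles."""
    return generate_cohort(default_adni_like_spec(seed=20250925))


def make_record(
    subject_id: str = "S1",
    age: float = 74.0,
    yoe: int = 16,
    mmse: int = 29,
    faq: int = 0,
    gds: int = 1,
    label: int = 0,
) -> SubjectRecord:
    return SubjectRecord(subject_id, age, yoe, mmse, faq, gds, label)


def two_cluster_cohort(
    n_per: int = 10, gap: float = 10.0, seed: int = 0
) -> Cohort:
    """Linearly separable toy cohort: controls low on faq/gds, cases high."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_per):
        records.append(
            make_record(f"C{i}", faq=int(rng.integers(0, 3)),
                        gds=int(rng.integers(0, 3)), label=0)
        )
    for i in range(n_per):
        records.append(
            make_record(f"M{i}", faq=int(gap + rng.integers(0, 3)),
                        gds=int(gap + rng.integers(0, 3)), label=1)
        )
    return Cohort(tuple(records), provenance="synthetic")


def naive_lattice_distance(geometry: LatticeGeometry, a: int, b: int) -> float:
    """Independent lattice metric: explicit shift enumeration, scalar math."""
    ra, ca = divmod(a, geometry.cols)
    rb, cb = divmod(b, geometry.cols)
    if geometry.wrap == "toroidal":
        row_shifts = (-geometry.rows, 0, geometry.rows)
        col_shifts = (-geometry.cols, 0, geometry.cols)
    else:
        row_shifts = col_shifts = (0,)
    best = math.inf
    for sr in row_shifts:
        for sc in col_shifts:
            r, c = rb + sr, cb + sc
            if geometry.shape == "square":
                d = max(abs(r - ra), abs(c - ca))
            else:
                xa = ca - (ra - (ra % 2)) // 2
                xb = c - (r - (r % 2)) // 2
                d = max(abs(xb - xa), abs(r - ra), abs((-xb - r) - (-xa - ra)))
            best = min(best, d)
    return best


def naive_train_cpn(
    train: Cohort,
    subset: FeatureSubset,
    geometry: LatticeGeometry,
    schedule: TrainingSchedule,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Loop-based reference trainer; returns (prototypes, readout weights)."""
    scaling = fit_scaling(train, subset)
    x = scale_matrix(scaling, train)
    labels = [float(r.label) for r in train.records]
    n, k = x.shape
    units = geometry.n_units

    rng = np.random.default_rng(seed)
    w = rng.uniform(size=(units, k))
    z = np.full((1, units), 0.5)

    total = schedule.epochs * n
    t = 0
    for _ in range(schedule.epochs):
        order = rng.permutation(n)
        for idx in order:
            xi = x[idx]
            # competitive step: Euclidean distance, ties to lowest index
            winner, best = 0, math.inf
            for l in range(units):
                s = 0.0
                for i in range(k):
                    s += (xi[i] - w[l, i]) ** 2
                d = math.sqrt(s)
                if d < best:
                    winner, best = l, d
            radius = schedule.radius(t, total)
            alpha = schedule.alpha(t, total)
            for l in range(units):
                if naive_lattice_distance(geometry, winner, l) <= radius:
                    for i in range(k):
                        w[l, i] = w[l, i] + alpha * (xi[i] - w[l, i])
            y = z[0, winner]
            z[0, winner] = z[0, winner] + schedule.gamma(t, total) * (labels[idx] - y)
            t += 1
    return w, z
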