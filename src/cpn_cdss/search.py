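"""Wrapper feature selection around the counterpropagation classifier.

The wrapper treats the trained network itself as the fitness function for a
feature subset: a candidate subset is scored by training CPNs on the
training split and measuring the convex-hull AUC of their ROC on the
held-out test split.  Two search modes are provided: exhaustive enumeration
of all admissible subsets, and backward elimination from the full feature
set.  Admissibility follows two restrictions — at least two features, and at
least one diagnostic instrument (MMSE/FAQ/GDS) among them — each
configurable off.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .cohort import (
    DIAGNOSTIC_FEATURES,
    FEATURES,
    Cohort,
    CohortError,
    FeatureSubset,
)
from .cpn import CPNModel, LatticeGeometry, TrainingSchedule, train_cpn
from . import evaluation as ev


@dataclass(frozen=True)
class FitnessConfig:
    """How each candidate subset is turned into a fitness value.

    For every subset, one network is trained per (geometry, net seed) pair
    and the best convex-hull AUC on the test split wins; the winning model's
    threshold is set to the balanced operating point of its raw ROC.
    """

    geometries: tuple[LatticeGeometry, ...] = (
        LatticeGeometry(shape="square", wrap="toroidal", rows=6, cols=6),
    )
    epochs: int = 30
    alpha0: float = 0.5
    gamma0: float = 0.1
    seeds_per_subset: int = 1

    def schedule_for(self, geometry: LatticeGeometry) -> TrainingSchedule:
        return TrainingSchedule(
            epochs=self.epochs,
            alpha0=self.alpha0,
            gamma0=self.gamma0,
            radius0=max(geometry.rows, geometry.cols) / 2,
        )


@dataclass(frozen=True)
class FeatureSubsetResult:
    """One evaluated subset: fitted model plus held-out test metrics."""

    subset: FeatureSubset
    model: CPNModel
    hull_auc: float
    raw_auc: float
    cm: ev.ConfusionMatrix

    @property
    def accuracy(self) -> float:
        return ev.accuracy(self.cm)

    @property
    def sensitivity(self) -> float:
        return ev.sensitivity(self.cm)

    @property
    def specificity(self) -> float:
        return ev.specificity(self.cm)

    def cui(self) -> ev.CUIReport:
        return ev.cui(self.cm)


def enumerate_subsets(
    features: Sequence[str] = FEATURES,
    min_size: int = 2,
    diagnostic: frozenset[str] | set[str] = DIAGNOSTIC_FEATURES,
    require_diagnostic: bool = True,
) -> list[FeatureSubset]:
    """All admissible subsets in deterministic size-then-lexicographic order."""
    if min_size < 1:
        raise CohortError("min_size must be >= 1")
    if not set(diagnostic) <= set(features):
        raise CohortError("diagnostic set must be a subset of the feature list")
    out: list[FeatureSubset] = []
    for size in range(min_size, len(features) + 1):
        for combo in combinations(features, size):
            if require_diagnostic and not set(combo) & set(diagnostic):
                continue
            out.append(FeatureSubset(combo))
    return out


def _evaluate_subset(
    train: Cohort,
    test: Cohort,
    subset: FeatureSubset,
    config: FitnessConfig,
    seed: int,
) -> FeatureSubsetResult:
    """Train the configured CPN variants on one subset; keep the hull-AUC best."""
    best: FeatureSubsetResult | None = None
    for g_idx, geometry in enumerate(config.geometries):
        for s_idx in range(config.seeds_per_subset):
            net_seed = (seed * 1009 + g_idx * 101 + s_idx) % (2**31)
            model = train_cpn(
                train,
                subset,
                geometry=geometry,
                schedule=config.schedule_for(geometry),
                seed=net_seed,
            )
            curve = ev.roc_sweep(model, test)
            hull = ev.convex_hull(curve)
            model.threshold = ev.balanced_threshold(curve)
            cm = ev.evaluate_at_threshold(model, test)
            result = FeatureSubsetResult(
                subset=subset,
                model=model,
                hull_auc=ev.auc(hull),
                raw_auc=ev.auc(curve),
                cm=cm,
            )
            if best is None or result.hull_auc > best.hull_auc:
                best = result
    assert best is not None
    return best


def evaluate_all_subsets(
    train: Cohort,
    test: Cohort,
    subsets: Sequence[FeatureSubset],
    config: FitnessConfig | None = None,
    seed: int = 0,
) -> list[FeatureSubsetResult]:
    """Evaluate every subset and rank by convex-hull AUC, descending.

    Rank ties are broken by subset size (smaller first) then feature order,
    so reruns with the same seed reproduce the ranking exactly.
    """
    config = config or FitnessConfig()
    results = [
        _evaluate_subset(train, test, s, config, seed + 7919 * i)
        for i, s in enumerate(subsets)
    ]
    order = sorted(
        range(len(results)),
        key=lambda i: (
            -results[i].hull_auc,
            len(results[i].subset),
            results[i].subset.names,
        ),
    )
    return [results[i] for i in order]


def backward_eliminate(
    train: Cohort,
    test: Cohort,
    start: FeatureSubset | None = None,
    config: FitnessConfig | None = None,
    seed: int = 0,
    min_size: int = 2,
    require_diagnostic: bool = True,
) -> list[FeatureSubsetResult]:
    """Backward elimination from the full feature set.

    At every step each admissible single-feature removal is evaluated and the
    one with the highest convex-hull AUC is taken (fitness ties remove the
    candidate whose dropped feature comes first in the canonical order);
    stops when no admissible removal remains.  Returns every evaluated
    subset, starting with the full set, in evaluation order.
    """
    config = config or FitnessConfig()
    current = start or FeatureSubset(FEATURES)
    current.validate(min_size=min_size, require_diagnostic=require_diagnostic)

    trace: list[FeatureSubsetResult] = []
    step = 0
    trace.append(_evaluate_subset(train, test, current, config, seed))
    while True:
        candidates: list[tuple[str, FeatureSubset]] = []
        for dropped in current.names:
            remaining = tuple(n for n in current.names if n != dropped)
            if len(remaining) < min_size:
                continue
            if require_diagnostic and not set(remaining) & DIAGNOSTIC_FEATURES:
                continue
            candidates.append((dropped, FeatureSubset(remaining)))
        if not candidates:
            break
        step += 1
        evaluated = [
            (dropped, _evaluate_subset(train, test, sub, config, seed + 7919 * step + j))
            for j, (dropped, sub) in enumerate(candidates)
        ]
        trace.extend(r for _, r in evaluated)
        # highest fitness wins; ties fall to the earliest-dropped candidate,
        # which is canonical feature order because candidates are generated so
        best_drop = max(evaluated, key=lambda dr: dr[1].hull_auc)
        current = best_drop[1].subset
    return trace
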