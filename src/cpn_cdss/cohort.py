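"""Subject cohorts: data model, CSV I/O, stratified splitting, feature scaling.

A cohort is a flat table of elderly subjects, each carrying five clinical
features routinely available in primary care — age (years), years of
education (YOE), MMSE (0-30, lower = more impaired), FAQ (higher = more
impaired) and GDS (higher = more depressive symptoms) — plus a binary
diagnosis label (0 = cognitively normal control, 1 = mild cognitive
impairment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical feature order used everywhere (CSV columns, subset encoding).
FEATURES: tuple[str, ...] = ("age", "yoe", "mmse", "faq", "gds")

#: Features that constitute a diagnostic instrument (cognitive/functional/
#: affective scales), as opposed to demographic modifiers.
DIAGNOSTIC_FEATURES: frozenset[str] = frozenset({"mmse", "faq", "gds"})

CSV_COLUMNS = ("subject_id", "age", "yoe", "mmse", "faq", "gds", "label")

CONTROL = 0
MCI = 1


class CohortError(ValueError):
    """Invalid cohort data or configuration."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: five clinical features and a binary diagnosis label."""

    subject_id: str
    age: float
    yoe: int
    mmse: int
    faq: int
    gds: int
    label: int

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise CohortError(f"{self.subject_id}: age must be > 0, got {self.age}")
        if not 0 <= self.mmse <= 30:
            raise CohortError(
                f"{self.subject_id}: mmse must lie in [0, 30], got {self.mmse}"
            )
        if self.yoe < 0 or self.faq < 0 or self.gds < 0:
            raise CohortError(f"{self.subject_id}: yoe/faq/gds must be >= 0")
        if self.label not in (CONTROL, MCI):
            raise CohortError(
                f"{self.subject_id}: label must be 0 (control) or 1 (MCI), "
                f"got {self.label}"
            )

    def feature(self, name: str) -> float:
        if name not in FEATURES:
            raise CohortError(f"unknown feature {name!r}")
        return float(getattr(self, name))


@dataclass(frozen=True)
class Cohort:
    """An ordered, non-empty collection of subject records."""

    records: tuple[SubjectRecord, ...]
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        if not self.records:
            raise CohortError("empty cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def n_mci(self) -> int:
        return int(self.labels.sum())

    @property
    def n_control(self) -> int:
        return len(self) - self.n_mci

    def require_both_classes(self) -> None:
        if self.n_mci == 0 or self.n_control == 0:
            raise CohortError(
                "cohort must contain at least one control and one MCI record"
            )

    def feature_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Raw (unscaled) feature matrix, one row per subject."""
        return np.array(
            [[r.feature(n) for n in names] for r in self.records], dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "age": r.age,
                    "yoe": r.yoe,
                    "mmse": r.mmse,
                    "faq": r.faq,
                    "gds": r.gds,
                    "label": r.label,
                }
                for r in self.records
            ],
            columns=list(CSV_COLUMNS),
        )


@dataclass(frozen=True)
class FeatureSubset:
    """An ordered subset of the five candidate features.

    Admissibility mirrors the wrapper-search restrictions: at least two
    features, and (optionally) at least one diagnostic instrument among them.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise CohortError(f"duplicate features in subset {self.names}")
        # canonical order; names outside the five clinical features are kept
        # (useful for generic enumeration) and rejected only when data access
        # actually needs them
        ordered = tuple(f for f in FEATURES if f in self.names) + tuple(
            n for n in self.names if n not in FEATURES
        )
        object.__setattr__(self, "names", ordered)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def validate(self, min_size: int = 2, require_diagnostic: bool = True) -> None:
        if len(self) < min_size:
            raise CohortError(
                f"subset {self.names} smaller than minimum size {min_size}"
            )
        if require_diagnostic and not set(self.names) & DIAGNOSTIC_FEATURES:
            raise CohortError(
                f"subset {self.names} contains no diagnostic instrument"
            )

    def label_for_report(self) -> str:
        pretty = {"age": "Age", "yoe": "YOE", "mmse": "MMSE", "faq": "FAQ", "gds": "GDS"}
        return " + ".join(pretty[n] for n in self.names)


@dataclass(frozen=True)
class ScalingSpec:
    """Per-feature linear min-max scaling learned from a training cohort.

    Each retained feature is mapped so the training minimum goes to 0 and the
    training maximum to 1; out-of-range values (test set) are clipped so the
    network always sees inputs in the unit hypercube.
    """

    bounds: Mapping[str, tuple[float, float]]  # feature -> (min, max)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not hi > lo:
                raise CohortError(
                    f"feature {name!r} is constant on the training set "
                    f"(min = max = {lo}); cannot scale"
                )


def fit_scaling(train: Cohort, subset: FeatureSubset) -> ScalingSpec:
    """Learn min-max bounds for each subset feature from the training cohort."""
    x = train.feature_matrix(subset.names)
    bounds = {}
    for j, name in enumerate(subset.names):
        lo, hi = float(x[:, j].min()), float(x[:, j].max())
        if hi <= lo:
            raise CohortError(
                f"feature {name!r} is constant on the training set "
                f"(min = max = {lo}); cannot scale"
            )
        bounds[name] = (lo, hi)
    return ScalingSpec(bounds)


def apply_scaling(spec: ScalingSpec, record: SubjectRecord) -> np.ndarray:
    """Scale one record into [0, 1]^k, clipping values outside the train range."""
    out = np.empty(len(spec.bounds), dtype=float)
    for j, (name, (lo, hi)) in enumerate(spec.bounds.items()):
        out[j] = (record.feature(name) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def scale_matrix(spec: ScalingSpec, cohort: Cohort) -> np.ndarray:
    """Scale a whole cohort; rows follow cohort order, columns the spec order."""
    names = list(spec.bounds)
    x = cohort.feature_matrix(names)
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# CSV input/output


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    provenance: str = "user-supplied",
) -> Cohort:
    """Read a cohort from a comma-separated UTF-8 file with a header row.

    ``column_map`` maps canonical column names to names used in the file,
    e.g. ``{"yoe": "education_years"}``.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in CSV_COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise CohortError(f"{path}: empty cohort")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row.subject_id),
                    age=float(row.age),
                    yoe=_as_int(row.yoe, "yoe"),
                    mmse=_as_int(row.mmse, "mmse"),
                    faq=_as_int(row.faq, "faq"),
                    gds=_as_int(row.gds, "gds"),
                    label=_as_int(row.label, "label"),
                )
            )
        except (CohortError, TypeError, ValueError) as exc:
            raise CohortError(f"{path}, data row {i + 1}: {exc}") from exc
    return Cohort(tuple(records), provenance=provenance)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the standard comma-separated cohort file (same dialect as reader)."""
    cohort.to_frame().to_csv(path, index=False)


def _as_int(value: object, name: str) -> int:
    f = float(value)  # type: ignore[arg-type]
    if math.isnan(f):
        raise CohortError(f"{name} is missing")
    i = int(round(f))
    if abs(f - i) > 1e-9:
        raise CohortError(f"{name} must be an integer, got {value!r}")
    return i


# ---------------------------------------------------------------------------
# Stratified splitting


def stratified_split(
    cohort: Cohort, test_count: int, seed: int
) -> tuple[Cohort, Cohort]:
    """Split a cohort into disjoint train/test parts, stratified by label.

    The number of MCI subjects in the test set is ``ceil(test_count x MCI
    prevalence)``: the minority (case) stratum is rounded up so the rarer
    class is never under-represented in the held-out evaluation.  For the
    reference cohort of 331 subjects (128 MCI) and a 76-subject test set this
    yields 30 MCI cases and 46 controls.  Membership is drawn without
    replacement with a seeded generator, so the split is deterministic given
    the seed.
    """
    if not 0 < test_count < len(cohort):
        raise CohortError(
            f"test_count must lie strictly between 0 and {len(cohort)}, "
            f"got {test_count}"
        )
    cohort.require_both_classes()
    n_pos_test = math.ceil(test_count * cohort.n_mci / len(cohort))
    n_neg_test = test_count - n_pos_test
    if n_pos_test == 0 or n_neg_test == 0:
        raise CohortError(
            f"test_count {test_count} leaves an empty stratum "
            f"({n_pos_test} MCI / {n_neg_test} controls)"
        )
    if n_pos_test > cohort.n_mci or n_neg_test > cohort.n_control:
        raise CohortError("test_count exceeds a stratum size")

    rng = np.random.default_rng(seed)
    labels = cohort.labels
    test_idx: set[int] = set()
    for lab, n_take in ((MCI, n_pos_test), (CONTROL, n_neg_test)):
        stratum = np.flatnonzero(labels == lab)
        chosen = rng.choice(stratum, size=n_take, replace=False)
        test_idx.update(int(i) for i in chosen)
    train_records = tuple(
        r for i, r in enumerate(cohort.records) if i not in test_idx
    )
    test_records = tuple(r for i, r in enumerate(cohort.records) if i in test_idx)
    return (
        Cohort(train_records, provenance=cohort.provenance),
        Cohort(test_records, provenance=cohort.provenance),
    )
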