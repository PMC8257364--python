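"""Synthetic cohort generation.

Real cohorts of this kind (ADNI-style memory-clinic samples) are
access-controlled, so the package ships a generator that reproduces the
published group-wise marginal structure — per-group mean, standard deviation
and observed range of each clinical feature — for 203 cognitively normal
controls and 128 MCI subjects.  Features are drawn independently within each
group (the published table carries no covariance information) from truncated
normals; integer-valued scales are rounded after truncation.

Truncating (and rounding) a normal changes its moments, severely so for
strongly skewed scales like FAQ, so each feature's parent (pre-truncation)
location and scale are calibrated at generation time: the parent mean is
solved so the post-truncation, post-rounding expectation equals the profile
mean exactly, and the parent scale is chosen to bring the resulting standard
deviation as close to the profile SD as the family allows.  (A truncated
normal on [0, inf) cannot exceed a coefficient of variation of 1, so e.g.
an SD of 4.4 at mean 3.6 is matched only approximately; sample means are the
contract, SDs are best-effort.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, stats
from scipy.special import log_ndtr, logsumexp

from .cohort import CONTROL, FEATURES, MCI, Cohort, CohortError, SubjectRecord


@dataclass(frozen=True)
class FeatureProfile:
    """Marginal distribution of one feature within one diagnostic group."""

    mean: float
    sd: float
    low: float
    high: float
    integer_valued: bool

    def __post_init__(self) -> None:
        if not self.low <= self.mean <= self.high:
            raise CohortError(
                f"profile mean {self.mean} outside range [{self.low}, {self.high}]"
            )
        if self.sd < 0:
            raise CohortError(f"profile sd must be >= 0, got {self.sd}")
        if self.sd > 0 and self.high <= self.low:
            raise CohortError("zero-width range cannot carry sd > 0")


@dataclass(frozen=True)
class GroupProfile:
    """All five feature marginals for one diagnostic group."""

    label: int
    size: int
    features: Mapping[str, FeatureProfile]

    def __post_init__(self) -> None:
        if self.size < 1:
            raise CohortError("group size must be >= 1")
        missing = set(FEATURES) - set(self.features)
        if missing:
            raise CohortError(f"group profile missing features {sorted(missing)}")


@dataclass(frozen=True)
class CohortSpec:
    """A control profile, an MCI profile and the generation seed."""

    control: GroupProfile
    mci: GroupProfile
    seed: int = 0


def default_adni_like_spec(seed: int = 0, scale_n: float = 1.0) -> CohortSpec:
    """The reference study conditions: published group marginals.

    Controls n=203: age 74.1±6.3 in [56.3, 89.1], YOE 16.5±2.6 in [10, 20],
    MMSE 29.1±1.2 in [24, 30], FAQ 0.2±0.6 in [0, 5], GDS 0.8±1.2 in [0, 6].
    MCI n=128: age 74.9±7.2 in [56.3, 88.0], YOE 15.5±3.2 in [4, 20],
    MMSE 27.2±1.7 in [24, 30], FAQ 3.6±4.4 in [0, 20], GDS 1.6±1.5 in [0, 5].

    ``scale_n`` multiplies both group sizes (for large-sample checks of the
    generator itself) without touching the distributions.
    """
    control = GroupProfile(
        label=CONTROL,
        size=max(1, round(203 * scale_n)),
        features={
            "age": FeatureProfile(74.1, 6.3, 56.3, 89.1, integer_valued=False),
            "yoe": FeatureProfile(16.5, 2.6, 10, 20, integer_valued=True),
            "mmse": FeatureProfile(29.1, 1.2, 24, 30, integer_valued=True),
            "faq": FeatureProfile(0.2, 0.6, 0, 5, integer_valued=True),
            "gds": FeatureProfile(0.8, 1.2, 0, 6, integer_valued=True),
        },
    )
    mci = GroupProfile(
        label=MCI,
        size=max(1, round(128 * scale_n)),
        features={
            "age": FeatureProfile(74.9, 7.2, 56.3, 88.0, integer_valued=False),
            "yoe": FeatureProfile(15.5, 3.2, 4, 20, integer_valued=True),
            "mmse": FeatureProfile(27.2, 1.7, 24, 30, integer_valued=True),
            "faq": FeatureProfile(3.6, 4.4, 0, 20, integer_valued=True),
            "gds": FeatureProfile(1.6, 1.5, 0, 5, integer_valued=True),
        },
    )
    return CohortSpec(control=control, mci=mci, seed=seed)


def _realized_moments(
    mu: float, sigma: float, profile: FeatureProfile
) -> tuple[float, float]:
    """Exact mean/SD of the truncated (and, if flagged, rounded) draw."""
    lo, hi = profile.low, profile.high
    if profile.integer_valued:
        k = np.arange(int(lo), int(hi) + 1)
        uppers = (np.clip(k + 0.5, lo, hi) - mu) / sigma
        lowers = (np.clip(k - 0.5, lo, hi) - mu) / sigma
        logp = _log_norm_interval(lowers, uppers)
        if not np.any(np.isfinite(logp)):
            # parent mass entirely outside the range: draws pile at the edge
            return (hi, 0.0) if mu > (lo + hi) / 2 else (lo, 0.0)
        p = np.exp(logp - logsumexp(logp))  # normalize by the range mass
        mean = float(np.sum(k * p))
        var = float(np.sum(k**2 * p)) - mean**2
        return mean, np.sqrt(max(var, 0.0))
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    mean, var = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    if not (np.isfinite(mean) and np.isfinite(var)):
        return (hi, 0.0) if mu > (lo + hi) / 2 else (lo, 0.0)
    return float(mean), float(np.sqrt(var))


def _log_norm_interval(lo_z: np.ndarray, hi_z: np.ndarray) -> np.ndarray:
    """log(Phi(hi_z) - Phi(lo_z)) elementwise, tail-accurate.

    Intervals on the right half-line are reflected so log_ndtr is always
    evaluated on its accurate (left-tail) side.
    """
    flip = (hi_z + lo_z) > 0
    a = np.where(flip, -lo_z, hi_z)  # the larger cdf argument after reflection
    b = np.where(flip, -hi_z, lo_z)
    la, lb = log_ndtr(a), log_ndtr(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = la + np.log1p(-np.exp(lb - la))
    out[~np.isfinite(la)] = -np.inf
    return out


def _solve_parent_mu(sigma: float, profile: FeatureProfile) -> float:
    """Parent location whose realized mean hits the profile mean (monotone).

    The bracket is widened geometrically: when sigma dwarfs the range the
    truncated density is an exponential tilt ~exp(mu x / sigma^2), so the
    location needed to push the mean toward an edge grows like sigma^2/span.
    """
    span = profile.high - profile.low

    def gap(mu: float) -> float:
        return _realized_moments(mu, sigma, profile)[0] - profile.mean

    step = sigma + span
    lo = profile.low - step
    hi = profile.high + step
    for _ in range(200):
        if gap(lo) < 0:
            break
        lo -= step
        step *= 2
    else:
        raise CohortError("cannot bracket parent location (lower)")
    step = sigma + span
    for _ in range(200):
        if gap(hi) > 0:
            break
        hi += step
        step *= 2
    else:
        raise CohortError("cannot bracket parent location (upper)")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def _calibrate_parent(profile: FeatureProfile) -> tuple[float, float]:
    """Parent (mu, sigma): realized mean exact, realized SD as close as possible."""
    if not profile.low < profile.mean < profile.high:
        raise CohortError(
            f"cannot calibrate: mean {profile.mean} must lie strictly inside "
            f"({profile.low}, {profile.high})"
        )

    def sd_gap(log_sigma: float) -> float:
        sigma = float(np.exp(log_sigma))
        mu = _solve_parent_mu(sigma, profile)
        return (_realized_moments(mu, sigma, profile)[1] - profile.sd) ** 2

    span = profile.high - profile.low
    res = optimize.minimize_scalar(
        sd_gap,
        bounds=(np.log(max(profile.sd, 1e-2) / 10), np.log(10 * span)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    sigma = float(np.exp(res.x))
    return _solve_parent_mu(sigma, profile), sigma


_PARENT_CACHE: dict[FeatureProfile, tuple[float, float]] = {}


def _draw_feature(
    profile: FeatureProfile, n: int, rng: np.random.Generator
) -> np.ndarray:
    if profile.sd == 0:
        values = np.full(n, float(profile.mean))
    else:
        if profile not in _PARENT_CACHE:
            _PARENT_CACHE[profile] = _calibrate_parent(profile)
        mu, sigma = _PARENT_CACHE[profile]
        a = (profile.low - mu) / sigma
        b = (profile.high - mu) / sigma
        values = stats.truncnorm.rvs(
            a, b, loc=mu, scale=sigma, size=n, random_state=rng
        )
    values = np.clip(values, profile.low, profile.high)
    if profile.integer_valued:
        values = np.rint(values)
    return values


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a synthetic cohort: controls first, then MCI, deterministic by seed."""
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    for group, tag in ((spec.control, "C"), (spec.mci, "M")):
        columns = {
            name: _draw_feature(group.features[name], group.size, rng)
            for name in FEATURES
        }
        for i in range(group.size):
            records.append(
                SubjectRecord(
                    subject_id=f"SYN-{tag}{i + 1:04d}",
                    age=float(columns["age"][i]),
                    yoe=int(columns["yoe"][i]),
                    mmse=int(columns["mmse"][i]),
                    faq=int(columns["faq"][i]),
                    gds=int(columns["gds"][i]),
                    label=group.label,
                )
            )
    return Cohort(tuple(records), provenance="synthetic")
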