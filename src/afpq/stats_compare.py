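"""Replicate aggregation, Kruskal-Wallis comparison, and feature assembly.

Each breath test is repeated (by default five times per airway model, each
with an independently seeded inlet particle profile); metrics are reported
as mean +/- sample SD over the replicates, and models are compared per
metric with a Kruskal-Wallis one-way rank ANOVA. Because the usual design
(4 models x 5 replicates) sits near the edge of validity of the chi-squared
approximation to the H statistic, an exact permutation p-value is computed
automatically whenever the pooled sample is small (N <= 12) and is then
preferred.

Significance flags follow the convention "*" for p < 0.05 and "**" for
p < 0.01. No multiple-testing correction is applied across metrics; the
output metadata says so explicitly so users can apply their own.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ReplicateSet",
    "KWResult",
    "FeatureVector",
    "FEATURE_NAMES",
    "summarize_replicates",
    "kruskal_wallis",
    "build_feature_vector",
    "EXACT_PERMUTATION_MAX_N",
]

EXACT_PERMUTATION_MAX_N = 12


@dataclass(frozen=True)
class ReplicateSet:
    """Values of one metric across the replicates of one model."""

    model_label: str
    metric_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValidationError("a replicate set needs at least 2 values")
        if not np.all(np.isfinite(v)):
            raise ValidationError("replicate values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis comparison across groups for one metric."""

    h: float
    p_value: float  # primary p: exact permutation when computed, else chi2
    p_chi2: float
    p_exact: float | None
    group_sizes: tuple[int, ...]
    tie_correction_applied: bool
    stars: str
    multiple_testing_correction: str = "none"


def summarize_replicates(rs: ReplicateSet) -> tuple[float, float]:
    """(mean, sample SD) with the n-1 denominator."""
    return float(rs.values.mean()), float(rs.values.std(ddof=1))


def _h_from_ranks(ranks: np.ndarray, sizes: tuple[int, ...], tie_divisor: float) -> float:
    n = ranks.size
    h = 0.0
    start = 0
    for s in sizes:
        rsum = ranks[start : start + s].sum()
        h += rsum * rsum / s
        start += s
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_divisor


def _tie_divisor(pooled: np.ndarray) -> float:
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    t = float(((counts**3 - counts)).sum())
    denom = n**3 - n
    return 1.0 - t / denom if denom > 0 else 1.0


def _exact_permutation_p(pooled: np.ndarray, sizes: tuple[int, ...], h_obs: float) -> float:
    """Exact permutation p: fraction of group assignments with H >= observed.

    Enumerates every ordered assignment of the pooled values to groups of
    the given sizes (feasible for N <= 12). H is monotone in
    S = sum_j R_j^2 / n_j, so the recursion only carries that running sum.
    """
    ranks = [float(r) for r in stats.rankdata(pooled)]
    divisor = _tie_divisor(pooled)
    n = pooled.size
    # H >= h_obs - tol  <=>  S >= s_min
    s_min = ((h_obs - 1e-9) * divisor + 3.0 * (n + 1)) * (n * (n + 1)) / 12.0
    count = 0
    total = 0

    def recurse(remaining: tuple[int, ...], gi: int, s: float) -> None:
        nonlocal count, total
        if gi == len(sizes):
            total += 1
            if s >= s_min:
                count += 1
            return
        size = sizes[gi]
        for combo in itertools.combinations(remaining, size):
            rsum = sum(ranks[i] for i in combo)
            picked = set(combo)
            left = tuple(i for i in remaining if i not in picked)
            recurse(left, gi + 1, s + rsum * rsum / size)

    recurse(tuple(range(n)), 0, 0.0)
    return count / total


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def kruskal_wallis(groups: list[ReplicateSet]) -> KWResult:
    """Rank-based one-way comparison of >= 2 replicate sets.

    Ties are handled with average ranks and the standard tie-correction
    divisor. All-identical data yields H = 0, p = 1 (not an error). For
    pooled N <= ``EXACT_PERMUTATION_MAX_N`` the exact permutation p is also
    computed and becomes the primary ``p_value``.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [g.values for g in groups]
    sizes = tuple(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    n = pooled.size

    if np.all(pooled == pooled[0]):
        return KWResult(0.0, 1.0, 1.0, 1.0 if n <= EXACT_PERMUTATION_MAX_N else None,
                        sizes, True, "")

    h, p_chi2 = stats.kruskal(*arrays)
    h, p_chi2 = float(h), float(p_chi2)
    ties = np.unique(pooled).size < n

    p_exact = None
    if n <= EXACT_PERMUTATION_MAX_N:
        p_exact = _exact_permutation_p(pooled, sizes, h)
    p_primary = p_exact if p_exact is not None else p_chi2
    return KWResult(
        h=h,
        p_value=p_primary,
        p_chi2=p_chi2,
        p_exact=p_exact,
        group_sizes=sizes,
        tie_correction_applied=ties,
        stars=_stars(p_primary),
    )


# ---------------------------------------------------------------------------
# feature assembly

_PROFILE_DIRECTIONS = ("horizontal", "vertical", "radial", "circumferential")

FEATURE_NAMES: tuple[str, ...] = (
    "fd_entire",
    "fd_roi",
    "lambda_entire",
    "lambda_roi",
    "alpha_width",
    "f_width",
    "asymmetry",
    "d0",
    "d1",
    "d2",
) + tuple(
    f"{d}_{stat}"
    for d in _PROFILE_DIRECTIONS
    for stat in ("mean", "var", "n_spikes", "spike_locs")
)


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-order named feature set of one fingerprint image.

    Missing metrics are explicit ``None`` entries (the vector length never
    changes), so downstream classifiers see a stable schema. ``provenance``
    carries free-form metadata (module, parameters) per feature.
    """

    names: tuple[str, ...]
    values: tuple[object, ...]
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))

    def __len__(self) -> int:
        return len(self.names)


def build_feature_vector(
    metrics: dict[str, object], provenance: dict | None = None
) -> FeatureVector:
    """Assemble the fixed-order feature vector from named metric results.

    ``metrics`` maps feature names (see ``FEATURE_NAMES``) to values; unknown
    names raise, absent names become ``None``. Input dict ordering never
    affects the output ordering.
    """
    if not metrics:
        raise ValidationError("at least one metric must be present")
    unknown = set(metrics) - set(FEATURE_NAMES)
    if unknown:
        raise ValidationError(f"unknown feature names: {sorted(unknown)}")
    values = tuple(metrics.get(name) for name in FEATURE_NAMES)
    return FeatureVector(FEATURE_NAMES, values, provenance or {})
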