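"""Seeded generators of synthetic exhaled-aerosol fingerprints and fixtures.

Real exhaled-aerosol fingerprints are the particle patterns an airway's
expiratory flow deposits on the mouth-exit plane: qualitatively, a pair of
vortex-like accumulations, a central stripe, an asymmetric background, and —
for diseased airways — a crescent-shaped void and/or shifted accumulation
hot spots. This module emulates those qualitative features with a seeded
truncated-Gaussian mixture so that every downstream metric can be exercised
and validated without a fluid solver. It makes no claim of physiological
fidelity beyond those named pattern features.

Two families of outputs:

* ``generate_fingerprint`` / ``generate_severity_series`` — particle clouds
  on the circular mouth-exit disk, with disease perturbations planted by
  construction (void depletion, hot-spot attenuation);
* analytic fixtures with closed-form dimensions — the Sierpinski carpet
  (box dimension log8/log3) and deterministic 2x2 multiplicative cascades
  (generalized dimensions ``D_q = log2(sum w_i^q) / (1 - q)``).

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .particle_io import ConcentrationMap, ParticleCloud, RasterImage

__all__ = [
    "VoidSpec",
    "HotspotSpec",
    "FingerprintParams",
    "SeverityLevel",
    "DEFAULT_SEVERITY_LEVELS",
    "TRAPPED_FRACTION_AT_FULL_CONSTRICTION",
    "generate_fingerprint",
    "generate_severity_series",
    "severity_params",
    "generate_sierpinski_carpet",
    "generate_deterministic_cascade",
    "model_params",
]


@dataclass(frozen=True)
class VoidSpec:
    """Annular-sector ("crescent") depletion region.

    ``theta_deg``/``r`` give the sector centre in polar coordinates (theta
    counterclockwise from +x, r normalized to the disk radius);
    ``theta_width_deg``/``r_width`` its angular and radial extent; particles
    sampled inside it are thinned with probability ``depletion``.
    """

    theta_deg: float = 135.0
    r: float = 0.94
    theta_width_deg: float = 70.0
    r_width: float = 0.12
    depletion: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depletion <= 1.0:
            raise ValidationError("void depletion must lie in [0, 1]")
        if self.theta_width_deg <= 0 or self.r_width <= 0:
            raise ValidationError("void widths must be positive")
        if not 0.0 <= self.r <= 1.0 + 1e-12:
            raise ValidationError("void radial centre must lie inside the unit disk")

    def contains(self, x: np.ndarray, y: np.ndarray, radius_mm: float) -> np.ndarray:
        """Boolean membership for points in mm coordinates."""
        rn = np.hypot(x, y) / radius_mm
        theta = np.degrees(np.arctan2(y, x)) % 360.0
        dth = (theta - self.theta_deg + 180.0) % 360.0 - 180.0
        return (np.abs(dth) <= self.theta_width_deg / 2.0) & (
            np.abs(rn - self.r) <= self.r_width / 2.0
        )


@dataclass(frozen=True)
class HotspotSpec:
    """Localized excess accumulation (a concentration hot spot).

    ``center`` is in normalized [0,1]^2 coordinates of the disk's bounding
    square (x/X rightward, y/Y upward); ``excess_weight`` is the mixture
    weight added on top of the base components before renormalization.
    """

    center: tuple[float, float] = (0.2, 0.65)
    spread_mm: float = 1.2
    excess_weight: float = 0.0

    def __post_init__(self) -> None:
        cx, cy = self.center
        if (cx - 0.5) ** 2 + (cy - 0.5) ** 2 > 0.25 + 1e-12:
            raise ValidationError("hotspot centre must lie inside the unit disk")
        if self.spread_mm <= 0:
            raise ValidationError("hotspot spread must be positive")
        if self.excess_weight < 0:
            raise ValidationError("hotspot excess weight must be >= 0")


@dataclass(frozen=True)
class FingerprintParams:
    """Parameters of one synthetic breath-test fingerprint.

    The base pattern is a mixture of two swirled Gaussian vortex
    accumulations, a vertical central stripe, and a uniform background, all
    truncated to the closed disk. Mixture weights are normalized internally;
    ``vortex_balance`` splits ``vortex_weight`` between the left and right
    vortex (0.5 = symmetric), providing the left/right asymmetry knob.
    """

    n_particles: int = 100_000
    disk_diameter_mm: float = 20.0
    vortex_centers: tuple[tuple[float, float], tuple[float, float]] = (
        (0.32, 0.40),
        (0.70, 0.38),
    )
    vortex_spread_mm: float = 2.0
    vortex_weight: float = 0.55
    stripe_weight: float = 0.25
    background_weight: float = 0.20
    vortex_balance: float = 0.55
    swirl_rad: float = 1.8
    stripe_sigma_frac: float = 0.05
    void_spec: VoidSpec | None = None
    hotspot_spec: HotspotSpec | None = None
    seed: int = 0
    model_label: str = ""
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValidationError("n_particles must be >= 1")
        if self.disk_diameter_mm <= 0 or self.vortex_spread_mm <= 0:
            raise ValidationError("lengths must be positive")
        for w in (self.vortex_weight, self.stripe_weight, self.background_weight):
            if w < 0:
                raise ValidationError("mixture weights must be >= 0")
        if not 0.0 <= self.vortex_balance <= 1.0:
            raise ValidationError("vortex_balance must lie in [0, 1]")
        for cx, cy in self.vortex_centers:
            if (cx - 0.5) ** 2 + (cy - 0.5) ** 2 > 0.25 + 1e-12:
                raise ValidationError("vortex centres must lie inside the unit disk")

    def component_weights(self) -> np.ndarray:
        """Normalized weights (vortex L, vortex R, stripe, background, hotspot)."""
        hs = self.hotspot_spec.excess_weight if self.hotspot_spec else 0.0
        w = np.array(
            [
                self.vortex_weight * self.vortex_balance,
                self.vortex_weight * (1.0 - self.vortex_balance),
                self.stripe_weight,
                self.background_weight,
                hs,
            ]
        )
        total = w.sum()
        if total <= 0:
            raise ValidationError("at least one mixture weight must be positive")
        return w / total

    def to_mm(self, center: tuple[float, float]) -> tuple[float, float]:
        d = self.disk_diameter_mm
        return ((center[0] - 0.5) * d, (center[1] - 0.5) * d)


@dataclass(frozen=True)
class SeverityLevel:
    """Graded airway-constriction level of the asthma severity series.

    ``constriction_fractions = (c_dep, c_ext)``: ``c_dep`` maps to the void
    depletion (and the attenuation of any hot spot fed by the constricted
    branch), ``c_ext`` to the void's angular/radial extent scale.
    """

    label: str
    constriction_fractions: tuple[float, float]

    def __post_init__(self) -> None:
        for c in self.constriction_fractions:
            if not 0.0 <= c <= 1.0:
                raise ValidationError("constriction fractions must lie in [0, 1]")


DEFAULT_SEVERITY_LEVELS: tuple[SeverityLevel, ...] = (
    SeverityLevel("D0", (0.0, 0.0)),
    SeverityLevel("D1", (0.3, 0.25)),
    SeverityLevel("D2", (0.6, 0.5)),
    SeverityLevel("D3", (0.9, 0.75)),
)

#: Fraction of the inhaled bolus retained in the airway at full constriction.
#: Obstructed airways trap aerosol by impaction, so the exhaled count shrinks
#: with severity instead of being redistributed over the exit plane.
TRAPPED_FRACTION_AT_FULL_CONSTRICTION = 0.3


# ---------------------------------------------------------------------------
# particle-cloud sampling


def _sample_components(
    params: FingerprintParams, rng: np.random.Generator, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``m`` candidate points from the (unthinned) mixture; keep in-disk."""
    R = params.disk_diameter_mm / 2.0
    weights = params.component_weights()
    comp = rng.choice(5, size=m, p=weights)
    x = np.empty(m)
    y = np.empty(m)

    for k, center in enumerate(params.vortex_centers):
        idx = np.flatnonzero(comp == k)
        if idx.size == 0:
            continue
        cx, cy = params.to_mm(center)
        off = rng.normal(0.0, params.vortex_spread_mm, size=(idx.size, 2))
        # swirl: rotate each offset about the vortex centre by an angle that
        # decays with distance, turning the blob into a vortex-like smear
        rr = np.hypot(off[:, 0], off[:, 1])
        ang = params.swirl_rad * np.exp(-((rr / (2.0 * params.vortex_spread_mm)) ** 2))
        if k == 1:
            ang = -ang  # counter-rotating pair
        ca, sa = np.cos(ang), np.sin(ang)
        x[idx] = cx + ca * off[:, 0] - sa * off[:, 1]
        y[idx] = cy + sa * off[:, 0] + ca * off[:, 1]

    idx = np.flatnonzero(comp == 2)  # central stripe
    if idx.size:
        x[idx] = rng.normal(0.0, params.stripe_sigma_frac * params.disk_diameter_mm, idx.size)
        y[idx] = rng.uniform(-R, R, idx.size)

    idx = np.flatnonzero(comp == 3)  # uniform background over the disk
    if idx.size:
        rad = R * np.sqrt(rng.uniform(0.0, 1.0, idx.size))
        th = rng.uniform(0.0, 2.0 * np.pi, idx.size)
        x[idx] = rad * np.cos(th)
        y[idx] = rad * np.sin(th)

    idx = np.flatnonzero(comp == 4)  # hot spot
    if idx.size:
        hs = params.hotspot_spec
        assert hs is not None
        cx, cy = params.to_mm(hs.center)
        x[idx] = rng.normal(cx, hs.spread_mm, idx.size)
        y[idx] = rng.normal(cy, hs.spread_mm, idx.size)

    keep = x * x + y * y <= R * R
    return x[keep], y[keep]


def generate_fingerprint(params: FingerprintParams) -> ParticleCloud:
    """Sample exactly ``n_particles`` points of one synthetic fingerprint.

    Candidates are drawn from the mixture and, if a void is specified,
    rejection-thinned inside it with probability ``depletion``; sampling
    repeats until the requested count is reached, so the void region holds a
    fraction ``(1-d) m / (1 - d m)`` of the particles in expectation, where
    ``m`` is the base mixture mass of the void. Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    R = params.disk_diameter_mm / 2.0
    void = params.void_spec
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    got = 0
    while got < params.n_particles:
        m = max(int((params.n_particles - got) * 1.4) + 64, 64)
        x, y = _sample_components(params, rng, m)
        if void is not None and void.depletion > 0.0:
            inside = void.contains(x, y, R)
            if inside.any():
                u = rng.uniform(0.0, 1.0, x.size)
                drop = inside & (u < void.depletion)
                x, y = x[~drop], y[~drop]
        xs.append(x)
        ys.append(y)
        got += x.size
    x = np.concatenate(xs)[: params.n_particles]
    y = np.concatenate(ys)[: params.n_particles]
    return ParticleCloud(
        x,
        y,
        params.disk_diameter_mm,
        model_label=params.model_label,
        replicate_id=params.replicate_id,
    )


def severity_params(base: FingerprintParams, level: SeverityLevel) -> FingerprintParams:
    """Parameters of one severity level derived from a base fingerprint.

    A choked branch both empties the crescent (depletion ``c_dep``, angular
    extent scaled by ``1 + c_ext``) and stops feeding its accumulation hot
    spot, whose excess weight is attenuated by ``1 - c_dep``. The crescent
    stays a thin outer arc (its radial band is untouched) so that severity
    widens the visible void without invading the hot-spot region. The
    exhaled particle count also shrinks with constriction (impaction
    trapping): ``n = n_base * (1 - TRAPPED_FRACTION_AT_FULL_CONSTRICTION *
    c_dep)``.
    """
    c_dep, c_ext = level.constriction_fractions
    if c_dep == 0.0:
        return replace(base, model_label=level.label or base.model_label)
    void = base.void_spec or VoidSpec()
    void = replace(
        void,
        depletion=c_dep,
        theta_width_deg=min(void.theta_width_deg * (1.0 + c_ext), 360.0),
    )
    hotspot = base.hotspot_spec
    if hotspot is not None and hotspot.excess_weight > 0:
        hotspot = replace(hotspot, excess_weight=hotspot.excess_weight * (1.0 - c_dep))
    n = max(1, int(round(
        base.n_particles * (1.0 - TRAPPED_FRACTION_AT_FULL_CONSTRICTION * c_dep)
    )))
    return replace(
        base,
        void_spec=void,
        hotspot_spec=hotspot,
        n_particles=n,
        model_label=level.label or base.model_label,
    )


def generate_severity_series(
    base: FingerprintParams,
    levels: list[SeverityLevel] | tuple[SeverityLevel, ...] = DEFAULT_SEVERITY_LEVELS,
) -> list[ParticleCloud]:
    """One cloud per severity level, sharing the base seed.

    Depletion must be non-decreasing along the series (strictly increasing
    after the first all-zero level), so in-void particle counts are
    non-increasing in expectation.
    """
    if not levels:
        raise ValidationError("severity level list is empty")
    deps = [lv.constriction_fractions[0] for lv in levels]
    if any(b < a for a, b in zip(deps, deps[1:])):
        raise ValidationError("severity depletion must be non-decreasing along the series")
    if len(levels) > 1 and any(a == b and a > 0 for a, b in zip(deps, deps[1:])):
        raise ValidationError("positive depletion must increase strictly along the series")
    return [generate_fingerprint(severity_params(base, lv)) for lv in levels]


# ---------------------------------------------------------------------------
# analytic fixtures


def generate_sierpinski_carpet(levels: int, *, max_levels: int = 8) -> RasterImage:
    """Sierpinski carpet of side ``3**levels`` pixels (8**levels filled).

    The carpet's box-counting dimension is log8/log3 ~ 1.8928 exactly.
    """
    if levels < 1:
        raise ValidationError("levels must be >= 1")
    if levels > max_levels:
        raise ValidationError(f"levels={levels} exceeds the memory budget ({max_levels})")
    motif = np.ones((3, 3), dtype=np.uint8)
    motif[1, 1] = 0
    grid = np.ones((1, 1), dtype=np.uint8)
    for _ in range(levels):
        grid = np.kron(grid, motif)
    return RasterImage(grid, 1.0, mask_diameter_mm=None, label=f"sierpinski-{levels}")


def generate_deterministic_cascade(
    weights: tuple[float, float, float, float], depth: int
) -> ConcentrationMap:
    """Deterministic 2x2 multiplicative cascade of side ``2**depth``.

    Each dyadic quadrant at level k carries the product of its weight path;
    total mass is 1. The generalized dimensions have the closed form
    ``D_q = log2(sum_i w_i^q) / (1 - q)`` for q != 1, which makes this the
    reference fixture for the multifractal estimator.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,) or np.any(w < 0):
        raise ValidationError("weights must be four non-negative fractions")
    if abs(w.sum() - 1.0) > 1e-12:
        raise ValidationError("weights must sum to 1 within 1e-12")
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    if depth > 12:
        raise ValidationError("depth > 12 exceeds the memory budget")
    cell = w.reshape(2, 2)
    grid = np.ones((1, 1))
    for _ in range(depth):
        grid = np.kron(grid, cell)
    return ConcentrationMap(
        grid, 1.0, mask_diameter_mm=None, label=f"cascade-{depth}", normalization="mass"
    )


# ---------------------------------------------------------------------------
# airway-model templates (qualitative pattern features of models A-D)


def model_params(
    model: str,
    *,
    n_particles: int = 100_000,
    seed: int = 0,
    replicate_id: int = 0,
    disk_diameter_mm: float = 20.0,
) -> FingerprintParams:
    """Fingerprint parameters emulating the four airway conditions.

    A: healthy baseline (vortex pair, central stripe, mild asymmetry).
    B: large carina tumor — left vortex nearly vanishes, stripe washes out,
       accumulation disturbed in both lower regions.
    C: small bronchial tumor — milder left-side disturbance with a shifted
       lower-left accumulation spot.
    D: asthma — baseline pattern plus an upper-left crescent void and a hot
       spot at normalized (0.2, 0.65).
    """
    base = FingerprintParams(
        n_particles=n_particles,
        disk_diameter_mm=disk_diameter_mm,
        seed=seed,
        model_label=model,
        replicate_id=replicate_id,
    )
    if model == "A":
        return base
    if model == "B":
        return replace(
            base,
            vortex_balance=0.12,
            vortex_weight=0.40,
            stripe_weight=0.12,
            background_weight=0.48,
            vortex_spread_mm=2.8,
            hotspot_spec=HotspotSpec(center=(0.62, 0.22), spread_mm=1.6, excess_weight=0.10),
        )
    if model == "C":
        return replace(
            base,
            vortex_balance=0.38,
            stripe_weight=0.18,
            background_weight=0.27,
            hotspot_spec=HotspotSpec(center=(0.30, 0.24), spread_mm=1.4, excess_weight=0.08),
        )
    if model == "D":
        return replace(
            base,
            void_spec=VoidSpec(depletion=0.65),
            hotspot_spec=HotspotSpec(center=(0.2, 0.65), spread_mm=1.2, excess_weight=0.12),
        )
    raise ValidationError(f"unknown model template {model!r} (expected A, B, C or D)")
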