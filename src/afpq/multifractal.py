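"""Direct-method (Chhabra-style) multifractal analysis of grayscale maps.

A concentration map is treated as a measure: at each box size eps the box
masses ``P_i(eps)`` are the in-box sums renormalized to total 1 (empty boxes
are dropped; their logs are never evaluated). A family of exponents q then
re-weights the measure,

    mu_i(q, eps) = P_i^q / sum_j P_j^q,

so q > 1 amplifies the most singular (densest) boxes and q < 1 accentuates
the sparsest. Three scaling regressions against log eps give, per q:

* singularity strength  alpha(q) = slope of sum_i mu_i log P_i,
* spectrum value        f(q)     = slope of sum_i mu_i log mu_i,
* generalized dimension D_q      = slope of log sum_i P_i^q / (q - 1),
  with the information-dimension limit (slope of sum P log P) at q = 1.

The f(alpha) ~ alpha curve is the multifractal spectrum; its width and
asymmetry summarize how strongly multifractal a pattern is. For a uniform
(mono- or non-fractal) measure D_q is flat and the spectrum collapses to a
point; multiplicative cascades reproduce their closed-form spectra exactly
on dyadic scales, which is how this estimator is validated.

All q-sums are accumulated in the log domain (``logsumexp``) so extreme q
never overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import ComputationError, ValidationError
from .particle_io import ConcentrationMap

__all__ = [
    "MeasureGrid",
    "MultifractalSpectrum",
    "SpectrumSummary",
    "default_q_grid",
    "box_masses",
    "normalized_measure",
    "spectrum",
    "spectrum_summary",
]

MIN_SCALES = 4
Q_ONE_TOL = 1e-9


@dataclass(frozen=True)
class MeasureGrid:
    """Per-scale box masses of a measure (only non-empty boxes retained)."""

    scales: np.ndarray  # box sizes, pixels
    log_masses: list[np.ndarray]  # ln P_i per scale, sum exp = 1

    def masses(self, k: int) -> np.ndarray:
        return np.exp(self.log_masses[k])


@dataclass(frozen=True)
class MultifractalSpectrum:
    q_grid: np.ndarray
    alpha: np.ndarray
    f_alpha: np.ndarray
    d_q: np.ndarray
    tau: np.ndarray  # (q - 1) D_q
    r_squared: np.ndarray  # per-q diagnostics of the D_q scaling fit
    scales: np.ndarray

    def at_q(self, q: float) -> tuple[float, float, float]:
        """(alpha, f, D) interpolated at q."""
        return (
            float(np.interp(q, self.q_grid, self.alpha)),
            float(np.interp(q, self.q_grid, self.f_alpha)),
            float(np.interp(q, self.q_grid, self.d_q)),
        )


@dataclass(frozen=True)
class SpectrumSummary:
    """Shape descriptors of one f(alpha) spectrum.

    ``asymmetry`` is the signed skew of the curve around alpha(q=0):
    positive when the left (dense, q > 0) branch is the longer one. It is
    ``None`` (flagged undefined) for point spectra.
    """

    alpha_width: float
    f_width: float
    asymmetry: float | None
    d0: float
    d1: float
    d2: float
    point_spectrum: bool


def default_q_grid(q_min: float = -5.0, q_max: float = 5.0, q_step: float = 0.25) -> np.ndarray:
    n = int(round((q_max - q_min) / q_step))
    return q_min + q_step * np.arange(n + 1)


def _analysis_grid(cmap: ConcentrationMap) -> np.ndarray:
    """Analyzed region: inscribed square for disk-masked maps, else full grid."""
    if cmap.mask_diameter_mm is None:
        return cmap.grid
    h, w = cmap.grid.shape
    half_px = int(np.floor(cmap.mask_diameter_mm / (2.0 * np.sqrt(2.0)) / cmap.pixel_size_mm))
    ci, cj = h // 2, w // 2
    return cmap.grid[max(ci - half_px, 0) : ci + half_px, max(cj - half_px, 0) : cj + half_px]


def _default_scales(shape: tuple[int, int]) -> np.ndarray:
    lim = min(shape) // 4
    scales = []
    eps = 2
    while eps <= lim:
        scales.append(eps)
        eps *= 2
    if len(scales) < MIN_SCALES:
        raise ValidationError(f"region of shape {shape} too small for {MIN_SCALES} scales")
    return np.asarray(scales, dtype=int)


def _block_sums(grid: np.ndarray, eps: int) -> np.ndarray:
    """Sums over an eps-aligned partition (ragged edge blocks included)."""
    h, w = grid.shape
    rows = np.arange(0, h, eps)
    cols = np.arange(0, w, eps)
    return np.add.reduceat(np.add.reduceat(grid, rows, axis=0), cols, axis=1)


def box_masses(
    cmap: ConcentrationMap | np.ndarray,
    scales: np.ndarray | list[int] | None = None,
) -> MeasureGrid:
    """Normalized box masses of the map at each scale (empty boxes dropped)."""
    grid = _analysis_grid(cmap) if isinstance(cmap, ConcentrationMap) else np.asarray(cmap, float)
    total = grid.sum()
    if not total > 0:
        raise ComputationError("zero-mass map: no measure to analyze")
    if scales is None:
        scales = _default_scales(grid.shape)
    scales = np.asarray(sorted(int(s) for s in scales), dtype=int)
    if scales[0] < 1 or scales[-1] > min(grid.shape):
        raise ValidationError("scales must satisfy 1 <= eps <= min(H, W)")
    log_masses = []
    for eps in scales:
        p = _block_sums(grid, int(eps)).ravel()
        p = p[p > 0] / total
        log_masses.append(np.log(p))
    return MeasureGrid(scales, log_masses)


def normalized_measure(masses: MeasureGrid, q: float) -> list[np.ndarray]:
    """Per-scale re-weighted measure mu_i(q, eps) = P_i^q / sum_j P_j^q."""
    if not np.isfinite(q):
        raise ValidationError("q must be finite")
    out = []
    for ln_p in masses.log_masses:
        out.append(np.exp(q * ln_p - logsumexp(q * ln_p)))
    return out


def _regress(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.allclose(y, y[0]):
        return 0.0, 1.0  # flat series: zero slope, exact fit
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def spectrum(
    cmap: ConcentrationMap | np.ndarray,
    q_grid: np.ndarray | None = None,
    scales: np.ndarray | list[int] | None = None,
    *,
    r2_warn: float = 0.9,
) -> MultifractalSpectrum:
    """Estimate alpha(q), f(q) and D_q by direct scaling regressions.

    A per-q R^2 below ``r2_warn`` on the D_q fit emits a warning (poor
    scaling — the result may not be meaningful) but is not an error.
    """
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.size < 2 or q_grid.min() >= 0 or q_grid.max() <= 0:
        raise ValidationError("q_grid must span negative and positive exponents")
    masses = box_masses(cmap, scales)
    if masses.scales.size < MIN_SCALES:
        raise ValidationError(f"need at least {MIN_SCALES} scales")
    log_eps = np.log(masses.scales.astype(float))

    # degenerate measure: a single occupied box at every scale
    if all(lp.size == 1 for lp in masses.log_masses):
        z = np.zeros_like(q_grid)
        return MultifractalSpectrum(
            q_grid, z, z.copy(), z.copy(), z.copy(), np.ones_like(q_grid), masses.scales
        )

    alpha = np.empty_like(q_grid)
    f_q = np.empty_like(q_grid)
    d_q = np.empty_like(q_grid)
    tau = np.empty_like(q_grid)
    r2 = np.empty_like(q_grid)
    for k, q in enumerate(q_grid):
        a_series = np.empty(log_eps.size)
        f_series = np.empty(log_eps.size)
        s_series = np.empty(log_eps.size)
        for m, ln_p in enumerate(masses.log_masses):
            ln_s = logsumexp(q * ln_p)
            mu = np.exp(q * ln_p - ln_s)
            a_series[m] = float(mu @ ln_p)
            f_series[m] = q * a_series[m] - ln_s
            s_series[m] = ln_s
        alpha[k], _ = _regress(log_eps, a_series)
        f_q[k], _ = _regress(log_eps, f_series)
        if abs(q - 1.0) < Q_ONE_TOL:
            # information-dimension limit: D_1 = slope of sum P log P
            d_q[k], r2[k] = _regress(log_eps, a_series)
            tau[k] = 0.0
        else:
            slope, r2[k] = _regress(log_eps, s_series)
            tau[k] = slope
            d_q[k] = slope / (q - 1.0)
        if r2[k] < r2_warn:
            warnings.warn(
                f"poor scaling fit at q={q:g} (R^2={r2[k]:.3f})", RuntimeWarning, stacklevel=2
            )
    return MultifractalSpectrum(q_grid, alpha, f_q, d_q, tau, r2, masses.scales)


def spectrum_summary(spec: MultifractalSpectrum, *, point_tol: float = 0.05) -> SpectrumSummary:
    """Widths, asymmetry and the low-order dimensions D0, D1, D2."""
    a_min, a_max = float(spec.alpha.min()), float(spec.alpha.max())
    width = a_max - a_min
    f_width = float(spec.f_alpha.max() - spec.f_alpha.min())
    a0, _, d0 = spec.at_q(0.0)
    _, _, d1 = spec.at_q(1.0)
    _, _, d2 = spec.at_q(2.0)
    point = width <= point_tol
    asym = None if point else float(((a_max - a0) - (a0 - a_min)) / width)
    # sign convention: alpha decreases with q, so the q>0 (dense) branch is
    # the alpha < alpha(0) side; positive asymmetry = longer sparse branch
    return SpectrumSummary(
        alpha_width=width,
        f_width=f_width,
        asymmetry=asym,
        d0=d0,
        d1=d1,
        d2=d2,
        point_spectrum=point,
    )
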