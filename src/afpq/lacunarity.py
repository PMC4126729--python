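"""Sliding-box (gliding-box) lacunarity of binary images.

Lacunarity quantifies the heterogeneity of how a pattern fills space: for
each box size eps an eps x eps window glides over the image and the filled
pixels inside it are counted; the per-size lacunarity is the squared
coefficient of variation of those counts,

    lambda(eps) = (sigma(eps) / mu(eps))**2,

and the aggregate Lambda is the mean of lambda(eps) over the E box sizes.
Translation-invariant patterns at scale eps (all-filled images, a
checkerboard sampled at its period) give lambda = 0 exactly; clumpy
patterns give large values. The (sigma/mu)^2 convention (rather than
1 + (sigma/mu)^2) is fixed here; every comparative statement is invariant
to that monotone shift.

For disk-masked images the gliding window is restricted to the square
inscribed in the mask, so the circular boundary does not inject artificial
heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, ValidationError
from .fractal_dimension import default_scales
from .particle_io import RasterImage

__all__ = ["LacunaritySeries", "sliding_box_counts", "lacunarity_series"]


@dataclass(frozen=True)
class LacunaritySeries:
    """Per-size lacunarity values and their aggregate."""

    box_sizes: np.ndarray
    lambda_eps: np.ndarray
    mu: np.ndarray  # mean filled pixels per box, per size
    sigma: np.ndarray  # SD (population) of filled pixels per box, per size
    aggregate: float  # Lambda: mean of lambda_eps over the E sizes

    @property
    def n_sizes(self) -> int:
        return int(np.asarray(self.box_sizes).size)


def _inscribed_square(image: RasterImage) -> np.ndarray:
    """Crop to the axis-aligned square inscribed in the circular mask."""
    if image.mask_diameter_mm is None:
        return image.grid
    h, w = image.grid.shape
    half_px = int(np.floor(image.mask_diameter_mm / (2.0 * np.sqrt(2.0)) / image.pixel_size_mm))
    ci, cj = h // 2, w // 2
    i0, i1 = max(ci - half_px, 0), min(ci + half_px, h)
    j0, j1 = max(cj - half_px, 0), min(cj + half_px, w)
    return image.grid[i0:i1, j0:j1]


def _window_sums(grid: np.ndarray, eps: int, stride: int) -> np.ndarray:
    """Summed-area-table window sums for every eps-box at the given stride."""
    c = np.zeros((grid.shape[0] + 1, grid.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(grid, axis=0), axis=1, out=c[1:, 1:])
    s = c[eps:, eps:] - c[:-eps, eps:] - c[eps:, :-eps] + c[:-eps, :-eps]
    return s[::stride, ::stride]


def sliding_box_counts(
    image: RasterImage, eps: int, stride: int = 1, *, restrict_to_mask: bool = True
) -> np.ndarray:
    """Filled-pixel counts of every gliding eps-box (row-major 2-D array)."""
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    grid = _inscribed_square(image) if restrict_to_mask else image.grid
    if eps < 1 or eps > min(grid.shape):
        raise ValidationError(
            f"box size {eps} invalid for analyzed region of shape {grid.shape}"
        )
    return _window_sums(grid.astype(np.int64), int(eps), int(stride))


def lacunarity_series(
    image: RasterImage,
    box_sizes: np.ndarray | list[int] | None = None,
    stride: int = 1,
    *,
    restrict_to_mask: bool = True,
) -> LacunaritySeries:
    """Per-size lacunarity and the aggregate Lambda.

    Box sizes default to the same dyadic series the fractal-dimension module
    uses, for comparability of the two measures.
    """
    grid = _inscribed_square(image) if restrict_to_mask else image.grid
    if grid.sum() == 0:
        raise ComputationError("lacunarity undefined for an all-empty region (mu = 0)")
    if box_sizes is None:
        box_sizes = default_scales(grid.shape)
        box_sizes = box_sizes[box_sizes >= 1]
    sizes = np.asarray(sorted(int(s) for s in box_sizes), dtype=int)
    if sizes.size == 0:
        raise ValidationError("no box sizes given")

    lam = np.empty(sizes.size)
    mus = np.empty(sizes.size)
    sds = np.empty(sizes.size)
    for k, eps in enumerate(sizes):
        counts = sliding_box_counts(image, int(eps), stride, restrict_to_mask=restrict_to_mask)
        mu = counts.mean()
        sd = counts.std()  # population SD over box positions
        if mu == 0:
            raise ComputationError(f"no filled pixels seen by any box at eps={eps}")
        mus[k], sds[k] = mu, sd
        lam[k] = (sd / mu) ** 2
    return LacunaritySeries(sizes, lam, mus, sds, aggregate=float(lam.mean()))
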