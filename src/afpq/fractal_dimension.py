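"""Box-counting fractal dimension of binary occupancy images.

The box-counting dimension D_B measures how the number of grid boxes N(eps)
that contain at least one filled pixel grows as the box size eps shrinks:
D_B is the magnitude of the slope of the least-squares regression of
log N(eps) on log eps. Whole-image, rectangular-ROI, and tiled local-grid
(default 6x6) variants are provided; local grids can be expressed as a
beta-ratio map ``beta(i) = FD_case(i) / FD_baseline(i)`` against a baseline
image, which localizes where a pattern's complexity deviates from normal.

Conventions (the upstream image-analysis tooling this mirrors does not
publish its exact settings, so ours are declared):

* default scale series: dyadic eps = 2, 4, ..., min(H, W)//4, extended to
  min(H, W)//2 when fewer than five scales would result;
* N(eps) is minimized over the four corner-anchored grid offsets to reduce
  grid-placement bias;
* regression in natural log, unweighted; R^2 is always reported so poor
  scaling fits are visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ComputationError, DegenerateSeriesError, ValidationError
from .particle_io import RasterImage

__all__ = [
    "BoxCountSeries",
    "FractalFit",
    "LocalFDGrid",
    "default_scales",
    "box_count",
    "fit_fd",
    "fd_entire",
    "fd_roi",
    "local_fd_grid",
]

MIN_SCALES = 5


@dataclass(frozen=True)
class BoxCountSeries:
    """Occupied-box counts per box size (after offset minimization)."""

    scales: np.ndarray  # strictly increasing box sizes, pixels
    counts: np.ndarray  # occupied boxes per scale
    grid_offsets_used: int

    def __post_init__(self) -> None:
        s = np.asarray(self.scales, dtype=int)
        c = np.asarray(self.counts, dtype=np.int64)
        if s.size != c.size or s.size == 0:
            raise ValidationError("scales and counts must be equal-length, non-empty")
        if np.any(np.diff(s) <= 0):
            raise ValidationError("scales must be strictly increasing")
        object.__setattr__(self, "scales", s)
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class FractalFit:
    """Fitted box-counting dimension with regression diagnostics."""

    d_b: float
    r_squared: float
    fit_range: tuple[int, int]
    n_scales: int


@dataclass(frozen=True)
class LocalFDGrid:
    """Tiled local fractal dimensions; ``None`` marks undefined tiles."""

    fits: list[list[FractalFit | None]]
    tile_shape: tuple[int, int]  # tiling (rows, cols)
    beta: np.ndarray | None = None  # ratio vs baseline, NaN where undefined

    def d_b_array(self) -> np.ndarray:
        out = np.full(self.tile_shape, np.nan)
        for i, rowfits in enumerate(self.fits):
            for j, f in enumerate(rowfits):
                if f is not None:
                    out[i, j] = f.d_b
        return out


def default_scales(shape: tuple[int, int]) -> np.ndarray:
    """Dyadic box sizes 2..min/4, extended to min/2 if fewer than 5 scales."""
    lim4 = min(shape) // 4
    lim2 = min(shape) // 2
    scales = []
    eps = 2
    while eps <= lim4:
        scales.append(eps)
        eps *= 2
    while len(scales) < MIN_SCALES and eps <= lim2:
        scales.append(eps)
        eps *= 2
    if len(scales) < MIN_SCALES:
        # tiny tiles: fall back to including eps=1 (pixel count itself)
        scales = [1] + scales
    if len(scales) < MIN_SCALES:
        raise ValidationError(
            f"image of shape {shape} too small for {MIN_SCALES} box-count scales"
        )
    return np.asarray(scales, dtype=int)


def _occupied_boxes(rows: np.ndarray, cols: np.ndarray, eps: int, oy: int, ox: int) -> int:
    bi = (rows + oy) // eps
    bj = (cols + ox) // eps
    return np.unique(bi * (bj.max() + 1 if bj.size else 1) + bj).size


def box_count(
    image: RasterImage,
    scales: np.ndarray | list[int] | None = None,
    *,
    offsets: str = "corners",
) -> BoxCountSeries:
    """Count occupied boxes per scale, minimized over grid offsets.

    ``offsets="corners"`` anchors the box grid at each of the four image
    corners and takes the minimum count per scale (grid-placement bias
    reduction); ``offsets="none"`` uses only the top-left anchoring.
    Only in-mask filled pixels exist by the image invariant, so boxes wholly
    outside the mask never count and straddling boxes count in-mask content
    only.
    """
    grid = image.grid
    h, w = grid.shape
    if scales is None:
        scales = default_scales(grid.shape)
    scales = np.asarray(sorted(int(s) for s in scales), dtype=int)
    if scales.size and (scales[0] < 1 or scales[-1] > min(h, w) // 2):
        raise ValidationError("box sizes must satisfy 1 <= eps <= min(H, W)/2")
    if scales.size < MIN_SCALES:
        raise ValidationError(f"need at least {MIN_SCALES} scales, got {scales.size}")
    if offsets not in ("corners", "none"):
        raise ValidationError("offsets must be 'corners' or 'none'")

    rows, cols = np.nonzero(grid)
    if rows.size == 0:
        raise ValidationError("cannot box-count an empty image")

    counts = np.empty(scales.size, dtype=np.int64)
    n_off = 1
    for k, eps in enumerate(scales):
        if offsets == "corners":
            sy = (-h) % eps
            sx = (-w) % eps
            offs = {(0, 0), (0, sx), (sy, 0), (sy, sx)}
        else:
            offs = {(0, 0)}
        n_off = max(n_off, len(offs))
        counts[k] = min(_occupied_boxes(rows, cols, int(eps), oy, ox) for oy, ox in offs)
    return BoxCountSeries(scales, counts, grid_offsets_used=n_off)


def fit_fd(series: BoxCountSeries) -> FractalFit:
    """D_B = -slope of the log-log regression of counts on box size."""
    if series.scales.size < MIN_SCALES:
        raise ValidationError(f"need at least {MIN_SCALES} scales to fit")
    if np.all(series.counts == series.counts[0]):
        raise DegenerateSeriesError(
            "box counts are constant across scales; no dimension is defined"
        )
    res = stats.linregress(np.log(series.scales), np.log(series.counts))
    return FractalFit(
        d_b=float(-res.slope),
        r_squared=float(res.rvalue**2),
        fit_range=(int(series.scales[0]), int(series.scales[-1])),
        n_scales=int(series.scales.size),
    )


def fd_entire(
    image: RasterImage, scales: np.ndarray | list[int] | None = None
) -> FractalFit:
    """Whole-image box-counting dimension."""
    return fit_fd(box_count(image, scales))


def fd_roi(
    image: RasterImage,
    roi: tuple[int, int, int, int],
    scales: np.ndarray | list[int] | None = None,
) -> FractalFit:
    """Box-counting dimension of a rectangular crop ``(x0, y0, x1, y1)``.

    Pixel coordinates, half-open; equals ``fd_entire`` of the cropped
    subimage.
    """
    return fit_fd(box_count(_crop(image, roi), scales))


def _crop(image: RasterImage, roi: tuple[int, int, int, int]) -> RasterImage:
    x0, y0, x1, y1 = (int(v) for v in roi)
    h, w = image.grid.shape
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValidationError(f"ROI {roi} is not a valid half-open rectangle in {w}x{h}")
    if min(x1 - x0, y1 - y0) < 32:
        raise ValidationError("ROI side must be >= 32 px")
    sub = image.grid[y0:y1, x0:x1]
    if sub.sum() == 0:
        raise ComputationError("ROI crop contains no filled pixels")
    return RasterImage(
        sub, image.pixel_size_mm, mask_diameter_mm=None, label=image.label
    )


def local_fd_grid(
    image: RasterImage,
    tiles: tuple[int, int] = (6, 6),
    baseline: "LocalFDGrid | None" = None,
    *,
    min_filled: int = 2,
) -> LocalFDGrid:
    """Per-tile fractal dimensions on an ``R x C`` partition of the image.

    Tiles with fewer than ``min_filled`` filled pixels are reported as
    undefined (``None``), never as zero — a zero would silently corrupt any
    beta-ratio map built from the grid. When a ``baseline`` grid is given,
    ``beta[i, j] = d_b / baseline_d_b`` where both are defined, NaN elsewhere.
    """
    nr, nc = tiles
    if nr < 1 or nc < 1:
        raise ValidationError("tile counts must be >= 1")
    h, w = image.grid.shape
    if h // nr < 32 or w // nc < 32:
        raise ValidationError(
            f"tiles of {h // nr}x{w // nc} px are too small for a 5-scale fit"
        )
    row_edges = np.linspace(0, h, nr + 1).astype(int)
    col_edges = np.linspace(0, w, nc + 1).astype(int)
    fits: list[list[FractalFit | None]] = []
    for i in range(nr):
        rowfits: list[FractalFit | None] = []
        for j in range(nc):
            sub = image.grid[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            if int(sub.sum()) < min_filled:
                rowfits.append(None)
                continue
            tile = RasterImage(sub, image.pixel_size_mm, mask_diameter_mm=None)
            try:
                rowfits.append(fit_fd(box_count(tile)))
            except DegenerateSeriesError:
                rowfits.append(None)
        fits.append(rowfits)

    beta = None
    if baseline is not None:
        if baseline.tile_shape != (nr, nc):
            raise ValidationError("baseline tile shape differs")
        ours = LocalFDGrid(fits, (nr, nc)).d_b_array()
        theirs = baseline.d_b_array()
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = ours / theirs
    return LocalFDGrid(fits, (nr, nc), beta=beta)
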