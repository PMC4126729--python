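"""Particle-cloud containers and image I/O.

The measurement plane is the circular mouth-exit cross-section. Particles
live in physical millimetre coordinates with the origin at the disk centre,
x rightward and y upward. Raster grids cover the disk's bounding square
``[-R, R]^2``; row 0 is the *top* of the image (y = +R), i.e. the usual
image convention with an explicit y-flip, and pixel bins are half-open
``[edge, edge)`` except that points exactly on the closed-disk boundary are
folded into the outermost in-mask pixel.

Three derived grids are produced from a cloud:

* binary occupancy (``RasterImage``) — input to fractal/lacunarity analysis;
* relative concentration (``ConcentrationMap``) — per-pixel ratio of local
  to overall particle concentration, so the in-mask mean is exactly 1;
* signed concentration difference against a baseline (``DifferenceMap``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ValidationError

__all__ = [
    "ParticleCloud",
    "RasterImage",
    "ConcentrationMap",
    "DifferenceMap",
    "read_particles",
    "write_particles",
    "rasterize",
    "concentration_map",
    "difference_map",
    "write_raster_png",
    "read_raster_png",
    "write_concentration_tiff",
    "read_concentration_tiff",
]

_MASK_TOL = 1e-9


@dataclass(frozen=True)
class ParticleCloud:
    """Labelled 2-D particle positions on the circular mouth-exit plane.

    Parameters
    ----------
    x, y : ndarray of float
        Positions in mm, origin at the disk centre.
    diameter_mm : float
        Diameter of the circular sampling plane (mask).
    model_label : str
        Airway-model tag (e.g. ``"A"``..``"D"`` or a severity label).
    replicate_id : int
        Index of the breath-test replicate this cloud belongs to.
    tags : ndarray of int, optional
        Per-point subset tag (e.g. particles released from a region of
        interest and tracked separately).
    """

    x: np.ndarray
    y: np.ndarray
    diameter_mm: float
    model_label: str = ""
    replicate_id: int = 0
    tags: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValidationError("x and y must be 1-D arrays of equal length")
        if self.diameter_mm <= 0:
            raise ValidationError("diameter_mm must be positive")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValidationError("particle coordinates must be finite")
        r2 = x * x + y * y
        rmax2 = (self.diameter_mm / 2.0) ** 2 * (1.0 + _MASK_TOL)
        if np.any(r2 > rmax2):
            bad = int(np.argmax(r2 > rmax2))
            raise ValidationError(
                f"particle {bad} at r={np.sqrt(r2[bad]):.6g} mm lies outside "
                f"the closed disk of diameter {self.diameter_mm} mm"
            )
        if self.tags is not None:
            tags = np.asarray(self.tags)
            if tags.shape != x.shape:
                raise ValidationError("tags must match the number of points")
            object.__setattr__(self, "tags", tags)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    def translated(self, dx: float, dy: float) -> "ParticleCloud":
        """Shifted copy (validation re-applied; use for interior shifts)."""
        return replace(self, x=self.x + dx, y=self.y + dy)


@dataclass(frozen=True)
class RasterImage:
    """Binary occupancy grid with physical pixel size and optional disk mask.

    ``mask_diameter_mm=None`` means the full rectangle is valid (used for
    analytic fixtures such as the Sierpinski carpet).
    """

    grid: np.ndarray
    pixel_size_mm: float
    mask_diameter_mm: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or min(g.shape) < 3:
            raise ValidationError("grid must be 2-D with side >= 3")
        g = (g != 0).astype(np.uint8)
        object.__setattr__(self, "grid", g)
        if self.pixel_size_mm <= 0:
            raise ValidationError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def mask_array(self) -> np.ndarray:
        """Boolean in-mask pixel map (pixel centres inside the closed disk)."""
        if self.mask_diameter_mm is None:
            return np.ones(self.grid.shape, dtype=bool)
        return _disk_mask(self.grid.shape, self.pixel_size_mm, self.mask_diameter_mm)

    def filled_count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class ConcentrationMap:
    """Grayscale grid of local-to-overall concentration ratios.

    For ``normalization="ratio"`` (maps built from particle clouds) the mean
    over in-mask pixels is exactly 1 by construction. ``normalization="mass"``
    marks maps that are plain non-negative measures (e.g. multiplicative
    cascades with total mass 1); the multifractal machinery renormalizes per
    scale, so both kinds are valid inputs there.
    """

    grid: np.ndarray
    pixel_size_mm: float
    mask_diameter_mm: float | None = None
    total_particles: int = 0
    label: str = ""
    normalization: str = "ratio"

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2 or min(g.shape) < 2:
            raise ValidationError("grid must be 2-D")
        if np.any(~np.isfinite(g)) or np.any(g < 0):
            raise ValidationError("concentration values must be finite and >= 0")
        object.__setattr__(self, "grid", g)
        if self.pixel_size_mm <= 0:
            raise ValidationError("pixel_size_mm must be positive")
        if self.normalization not in ("ratio", "mass"):
            raise ValidationError("normalization must be 'ratio' or 'mass'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def mask_array(self) -> np.ndarray:
        if self.mask_diameter_mm is None:
            return np.ones(self.grid.shape, dtype=bool)
        return _disk_mask(self.grid.shape, self.pixel_size_mm, self.mask_diameter_mm)


@dataclass(frozen=True)
class DifferenceMap:
    """Signed elementwise difference of two concentration maps (case - baseline)."""

    grid: np.ndarray
    pixel_size_mm: float
    mask_diameter_mm: float | None
    case_label: str
    baseline_label: str


# ---------------------------------------------------------------------------
# geometry helpers


def _disk_mask(shape: tuple[int, int], pixel_size: float, diameter: float) -> np.ndarray:
    h, w = shape
    r = diameter / 2.0
    # pixel-centre coordinates; grid covers [-w*p/2, w*p/2] x [-h*p/2, h*p/2]
    xc = (np.arange(w) + 0.5) * pixel_size - w * pixel_size / 2.0
    yc = h * pixel_size / 2.0 - (np.arange(h) + 0.5) * pixel_size
    xx, yy = np.meshgrid(xc, yc)
    return xx * xx + yy * yy <= r * r * (1.0 + 1e-12)


def _bin_indices(
    cloud: ParticleCloud, resolution: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map particles to (row, col) pixels; boundary points folded inward.

    Particles in pixels whose centre falls outside the disk (only possible in
    the thin boundary ring) are pulled radially to r = R - pixel so that the
    occupancy and concentration grids respect the mask invariant while every
    particle is still counted.
    """
    R = cloud.radius_mm
    p = cloud.diameter_mm / resolution
    mask = _disk_mask((resolution, resolution), p, cloud.diameter_mm)

    x, y = cloud.x.copy(), cloud.y.copy()
    for _ in range(2):  # one fold suffices; second pass is a safety net
        col = np.clip(np.floor((x + R) / p).astype(int), 0, resolution - 1)
        row = np.clip(np.floor((R - y) / p).astype(int), 0, resolution - 1)
        out = ~mask[row, col]
        if not out.any():
            break
        r = np.hypot(x[out], y[out])
        scale = np.where(r > 0, (R - p) / np.maximum(r, 1e-300), 0.0)
        x[out] *= scale
        y[out] *= scale
    return row, col, mask


# ---------------------------------------------------------------------------
# particle text I/O


def read_particles(
    path: str | Path,
    diameter_mm: float,
    *,
    delimiter: str = ",",
    x_col: str = "x_mm",
    y_col: str = "y_mm",
    model_col: str = "model",
    replicate_col: str = "replicate",
    tag_col: str | None = None,
    on_out_of_mask: str = "error",
) -> ParticleCloud:
    """Load a particle cloud from delimited text.

    ``on_out_of_mask`` controls points outside the closed disk: ``"error"``
    (strict, names the offending row), or ``"drop"``.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty particle file: {path}") from None
    if df.empty:
        raise ValidationError(f"particle file has no data rows: {path}")
    for col in (x_col, y_col):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r} in {path}")
    x = pd.to_numeric(df[x_col], errors="coerce").to_numpy()
    y = pd.to_numeric(df[y_col], errors="coerce").to_numpy()
    bad = np.flatnonzero(~(np.isfinite(x) & np.isfinite(y)))
    if bad.size:
        raise ValidationError(f"non-numeric coordinates at data row {bad[0]} in {path}")

    R = diameter_mm / 2.0
    r = np.hypot(x, y)
    out = r > R * (1.0 + _MASK_TOL)
    if out.any():
        if on_out_of_mask == "error":
            i = int(np.argmax(out))
            raise ValidationError(
                f"data row {i} in {path} lies outside the mask "
                f"(r={r[i]:.6g} mm > R={R:.6g} mm)"
            )
        if on_out_of_mask == "drop":
            keep = ~out
            x, y = x[keep], y[keep]
            df = df.loc[keep]
        else:
            raise ValidationError("on_out_of_mask must be 'error' or 'drop'")

    model = df[model_col].iloc[0] if model_col in df.columns else ""
    model = "" if pd.isna(model) else str(model)
    rep = int(df[replicate_col].iloc[0]) if replicate_col in df.columns else 0
    tags = df[tag_col].to_numpy() if tag_col and tag_col in df.columns else None
    return ParticleCloud(x, y, diameter_mm, model_label=model, replicate_id=rep, tags=tags)


def write_particles(cloud: ParticleCloud, path: str | Path, *, delimiter: str = ",") -> Path:
    """Write a cloud as delimited text (x_mm, y_mm, model, replicate[, tag])."""
    path = Path(path)
    data = {
        "x_mm": cloud.x,
        "y_mm": cloud.y,
        "model": np.repeat(cloud.model_label, cloud.n),
        "replicate": np.repeat(cloud.replicate_id, cloud.n),
    }
    if cloud.tags is not None:
        data["tag"] = cloud.tags
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# rasterization


def rasterize(cloud: ParticleCloud, resolution: int = 512) -> RasterImage:
    """Binary occupancy grid: pixel is 1 iff >= 1 particle centre falls in it."""
    if resolution < 8:
        raise ValidationError("resolution must be >= 8")
    if cloud.n == 0:
        raise ValidationError("cannot rasterize an empty cloud")
    row, col, _ = _bin_indices(cloud, resolution)
    grid = np.zeros((resolution, resolution), dtype=np.uint8)
    grid[row, col] = 1
    return RasterImage(
        grid,
        cloud.diameter_mm / resolution,
        mask_diameter_mm=cloud.diameter_mm,
        label=cloud.model_label,
    )


def concentration_map(cloud: ParticleCloud, resolution: int = 512) -> ConcentrationMap:
    """Relative concentration: per-pixel count over the mean in-mask count.

    The in-mask mean of the result is exactly 1 (every particle is counted in
    an in-mask pixel, see :func:`_bin_indices`).
    """
    if resolution < 8:
        raise ValidationError("resolution must be >= 8")
    if cloud.n == 0:
        raise ValidationError("cannot build a concentration map from an empty cloud")
    row, col, mask = _bin_indices(cloud, resolution)
    counts = np.zeros((resolution, resolution), dtype=np.int64)
    np.add.at(counts, (row, col), 1)
    n_cells = int(mask.sum())
    ratio = counts.astype(float) * (n_cells / cloud.n)
    ratio[~mask] = 0.0
    return ConcentrationMap(
        ratio,
        cloud.diameter_mm / resolution,
        mask_diameter_mm=cloud.diameter_mm,
        total_particles=cloud.n,
        label=cloud.model_label,
    )


def difference_map(case: ConcentrationMap, baseline: ConcentrationMap) -> DifferenceMap:
    """Signed concentration disparity ``case - baseline`` (elementwise)."""
    if case.shape != baseline.shape:
        raise ValidationError("grid shapes differ")
    if abs(case.pixel_size_mm - baseline.pixel_size_mm) > 1e-12:
        raise ValidationError("pixel sizes differ")
    if case.mask_diameter_mm != baseline.mask_diameter_mm:
        raise ValidationError("masks differ")
    return DifferenceMap(
        case.grid - baseline.grid,
        case.pixel_size_mm,
        case.mask_diameter_mm,
        case_label=case.label,
        baseline_label=baseline.label,
    )


# ---------------------------------------------------------------------------
# image persistence (PNG for binary, float TIFF for grayscale, JSON sidecar)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster_png(image: RasterImage, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray((image.grid * 255).astype(np.uint8), mode="L").save(path)
    meta = {
        "pixel_size_mm": image.pixel_size_mm,
        "mask_diameter_mm": image.mask_diameter_mm,
        "label": image.label,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_raster_png(path: str | Path) -> RasterImage:
    path = Path(path)
    grid = np.asarray(Image.open(path).convert("L")) > 127
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return RasterImage(
        grid.astype(np.uint8),
        meta.get("pixel_size_mm", 1.0),
        mask_diameter_mm=meta.get("mask_diameter_mm"),
        label=meta.get("label", ""),
    )


def write_concentration_tiff(cmap: ConcentrationMap, path: str | Path) -> Path:
    # 32-bit float keeps the ratio lossless, which the mean==1 invariant needs
    path = Path(path)
    tifffile.imwrite(path, cmap.grid.astype(np.float32))
    meta = {
        "pixel_size_mm": cmap.pixel_size_mm,
        "mask_diameter_mm": cmap.mask_diameter_mm,
        "total_particles": cmap.total_particles,
        "label": cmap.label,
        "normalization": cmap.normalization,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_concentration_tiff(path: str | Path) -> ConcentrationMap:
    path = Path(path)
    grid = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return ConcentrationMap(
        grid,
        meta.get("pixel_size_mm", 1.0),
        mask_diameter_mm=meta.get("mask_diameter_mm"),
        total_particles=meta.get("total_particles", 0),
        label=meta.get("label", ""),
        normalization=meta.get("normalization", "ratio"),
    )
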