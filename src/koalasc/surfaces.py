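"""Posterior density surfaces and forest-category overlays.

The retained (z, s) snapshots from the sampler are converted into a pixel
raster of male density: each pixel's value is the mean, over snapshots, of
the number of included activity centres falling in the pixel, divided by the
pixel area in hectares. Summing value x pixel area over the raster therefore
recovers the posterior mean of N exactly — a bookkeeping identity used as a
standing invariant check.

Category overlays assign pixels to forest polygons (harvest areas, old
growth, riparian-ridge exclusions, regrowth classes) by the
pixel-centre-in-polygon rule, average pixel densities per polygon, and
summarise each category by the mean over its polygons with a standard error
from the among-polygon variation. Density at single-pixel scale is
indicative only; it is meaningful averaged over contiguous blocks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely import contains_xy

from .model import StateSpace
from .sampler import Snapshots

__all__ = [
    "DensityRaster",
    "CategoryMap",
    "rasterize_density",
    "category_density",
    "write_esri_ascii",
    "read_esri_ascii",
    "read_categories",
]


@dataclass
class DensityRaster:
    """Pixel grid of male density (males per hectare).

    ``values[iy, ix]`` is the pixel with lower-left corner at
    (x0 + ix * pixel_size, y0 + iy * pixel_size); row index increases
    northward. The grid starts at the state-space's lower-left corner and
    extends far enough to cover it (the last row/column may overhang).
    """

    x0: float
    y0: float
    pixel_size: float
    values: np.ndarray  # (ny, nx)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def pixel_ha(self) -> float:
        return self.pixel_size ** 2 / 1e4

    def total_individuals(self) -> float:
        """Sum of value x pixel area (ha): the posterior mean abundance."""
        return float(self.values.sum() * self.pixel_ha)

    def centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (ny, nx) of pixel-centre coordinates."""
        cx = self.x0 + (np.arange(self.nx) + 0.5) * self.pixel_size
        cy = self.y0 + (np.arange(self.ny) + 0.5) * self.pixel_size
        return np.meshgrid(cx, cy)


@dataclass
class CategoryMap:
    """Labelled planar polygons (forest age class / prescription / harvest)."""

    polygons: list[BaseGeometry]
    categories: list[str]

    def __post_init__(self) -> None:
        if len(self.polygons) != len(self.categories):
            raise ValueError("one category label per polygon")
        if not self.polygons:
            raise ValueError("category map needs at least one polygon")
        for i, (poly, cat) in enumerate(zip(self.polygons, self.categories)):
            if not cat:
                raise ValueError(f"polygon {i} has an empty category label")
            if not poly.is_valid:
                raise ValueError(f"polygon {i} ({cat}) is invalid (self-intersecting?)")


def rasterize_density(
    snapshots: Snapshots, state_space: StateSpace, pixel_size: float
) -> DensityRaster:
    """Average included-centre counts per pixel over snapshots, as males/ha.

    Default usage is a 100 m pixel: well below the 400 m detector spacing but
    no finer than the resolution at which activity-centre density is
    interpretable.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if snapshots.n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    nx = int(np.ceil(state_space.width / pixel_size - 1e-9))
    ny = int(np.ceil(state_space.height / pixel_size - 1e-9))
    x_edges = state_space.xmin + np.arange(nx + 1) * pixel_size
    y_edges = state_space.ymin + np.arange(ny + 1) * pixel_size
    inc = snapshots.z.astype(bool)
    xs = snapshots.x[inc]
    ys = snapshots.y[inc]
    hist, _, _ = np.histogram2d(xs, ys, bins=[x_edges, y_edges])
    pixel_ha = pixel_size ** 2 / 1e4
    values = hist.T / (snapshots.n_snapshots * pixel_ha)  # (ny, nx), row = y
    return DensityRaster(
        x0=state_space.xmin, y0=state_space.ymin,
        pixel_size=pixel_size, values=values,
    )


def category_density(raster: DensityRaster, cat_map: CategoryMap) -> pd.DataFrame:
    """Mean density and among-polygon standard error per forest category.

    Pixels belong to a polygon when their centre falls inside it. Polygons
    containing no pixel centres are excluded with a warning. Categories with
    a single polygon have an undefined SE (NaN).
    """
    cx, cy = raster.centres()
    per_polygon: list[tuple[str, float]] = []
    for i, (poly, cat) in enumerate(zip(cat_map.polygons, cat_map.categories)):
        inside = contains_xy(poly, cx.ravel(), cy.ravel())
        if not inside.any():
            warnings.warn(
                f"polygon {i} ({cat}) contains no pixel centres; excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        per_polygon.append((cat, float(raster.values.ravel()[inside].mean())))
    if not per_polygon:
        raise ValueError("no polygon contains any pixel centre")
    df = pd.DataFrame(per_polygon, columns=["category", "polygon_mean"])
    out = (
        df.groupby("category")["polygon_mean"]
        .agg(
            mean_density="mean",
            n_polygons="count",
            se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
        )
        .reset_index()
    )
    return out


def write_esri_ascii(raster: DensityRaster, path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid, rows written north to south per the format."""
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.nx}\n")
        fh.write(f"nrows {raster.ny}\n")
        fh.write(f"xllcorner {raster.x0:.6f}\n")
        fh.write(f"yllcorner {raster.y0:.6f}\n")
        fh.write(f"cellsize {raster.pixel_size:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in raster.values[::-1]:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_esri_ascii(path) -> DensityRaster:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)[::-1]
    return DensityRaster(
        x0=header["xllcorner"], y0=header["yllcorner"],
        pixel_size=header["cellsize"], values=values,
    )


def read_categories(path, cell_size: float | None = None) -> CategoryMap:
    """Read a category map from GeoJSON, or from a gridded CSV fallback.

    GeoJSON: polygon features each carrying a ``category`` property.
    CSV fallback: columns x, y, category — cell-centre labels on a regular
    grid with spacing ``cell_size`` (required), each expanded to its square
    cell polygon.
    """
    path = str(path)
    if path.endswith((".geojson", ".json")):
        with open(path) as fh:
            gj = json.load(fh)
        polys, cats = [], []
        for feat in gj.get("features", []):
            props = feat.get("properties") or {}
            if "category" not in props:
                raise ValueError(f"{path}: feature without a 'category' property")
            polys.append(shapely_shape(feat["geometry"]))
            cats.append(str(props["category"]))
        return CategoryMap(polys, cats)
    if cell_size is None:
        raise ValueError("gridded CSV categories require cell_size")
    from shapely.geometry import box

    df = pd.read_csv(path)
    for col in ("x", "y", "category"):
        if col not in df.columns:
            raise ValueError(f"{path}: gridded CSV needs columns x, y, category")
    half = cell_size / 2.0
    polys = [box(x - half, y - half, x + half, y + half)
             for x, y in zip(df["x"], df["y"])]
    return CategoryMap(polys, [str(c) for c in df["category"]])
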