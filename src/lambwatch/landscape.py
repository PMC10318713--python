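"""Synthetic landscapes: covariate rasters and selection-driven point sets.

A landscape is a :class:`CovariateStack` — named single-band rasters on a
shared metric grid.  Continuous fields (elevation, ruggedness, snow depth,
heat load, crown cover, slope) are smoothed white noise (Gaussian blur of
iid normals) standardized to mean 0, sd 1.  Distance layers hold the
Euclidean distance (m) from each cell centre to synthetic linear features
(roads, trails: random polylines) or patch features (escape terrain, barren
ground, herbaceous cover: unions of random discs).

Rasters serialize as ESRI ASCII grids (plain text), and all coordinates are
plain projected metres — no geographic (lat/lon) handling anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "Raster",
    "CovariateStack",
    "CONTINUOUS_COVARIATES",
    "FEATURE_COVARIATES",
    "simulate_landscape",
    "simulate_selected_points",
]

CONTINUOUS_COVARIATES = (
    "elevation",
    "ruggedness",
    "snow_depth",
    "heat_load",
    "crown_cover",
    "slope",
)
#: feature name -> distance-raster name
FEATURE_COVARIATES = {
    "road": "dist_road",
    "trail": "dist_trail",
    "escape_terrain": "dist_escape_terrain",
    "barren": "dist_barren",
    "herbaceous": "dist_herbaceous",
}


@dataclass
class Raster:
    """Single-band raster; row 0 is the northern edge, metric CRS."""

    values: np.ndarray  # (nrows, ncols)
    x_min: float
    y_min: float
    resolution: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_max(self) -> float:
        return self.x_min + self.shape[1] * self.resolution

    @property
    def y_max(self) -> float:
        return self.y_min + self.shape[0] * self.resolution

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nrows, ncols = self.shape
        xs = self.x_min + (np.arange(ncols) + 0.5) * self.resolution
        ys = self.y_max - (np.arange(nrows) + 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def value_at(self, x, y) -> np.ndarray:
        """Value of the cell containing each point (no interpolation)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_min) / self.resolution).astype(int)
        row = np.floor((self.y_max - y) / self.resolution).astype(int)
        nrows, ncols = self.shape
        # Points exactly on the max edge belong to the last cell.
        col = np.where((x == self.x_max), ncols - 1, col)
        row = np.where((y == self.y_min), nrows - 1, row)
        bad = (col < 0) | (col >= ncols) | (row < 0) | (row >= nrows)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"point ({x.flat[i]}, {y.flat[i]}) outside raster extent")
        return self.values[row, col]

    def to_ascii(self, path) -> None:
        nrows, ncols = self.shape
        header = (
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {self.x_min}\nyllcorner {self.y_min}\n"
            f"cellsize {self.resolution}\nNODATA_value -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.6g")

    @classmethod
    def from_ascii(cls, path) -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        return cls(
            values=values,
            x_min=meta["xllcorner"],
            y_min=meta["yllcorner"],
            resolution=meta["cellsize"],
        )


@dataclass
class CovariateStack:
    """Named rasters on one shared grid, plus the generating feature geometries."""

    layers: dict[str, Raster]
    features: dict[str, shapely.Geometry] | None = None

    def __post_init__(self) -> None:
        first = next(iter(self.layers.values()))
        for name, r in self.layers.items():
            if r.shape != first.shape or r.resolution != first.resolution:
                raise ValueError(f"layer {name} is not on the shared grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def extract(self, x, y) -> pd.DataFrame:
        """Covariate values at points, one column per layer."""
        return pd.DataFrame({name: r.value_at(x, y) for name, r in self.layers.items()})


def _random_polyline(
    rng: np.random.Generator, extent: tuple[float, float, float, float]
) -> LineString:
    """A wandering polyline crossing the extent (a synthetic road or trail)."""
    x0, y0, x1, y1 = extent
    n_seg = int(rng.integers(4, 9))
    if rng.uniform() < 0.5:  # west-east crossing
        xs = np.linspace(x0, x1, n_seg)
        ys = gaussian_filter(rng.uniform(y0, y1, size=n_seg), sigma=1.0, mode="nearest")
    else:  # south-north crossing
        ys = np.linspace(y0, y1, n_seg)
        xs = gaussian_filter(rng.uniform(x0, x1, size=n_seg), sigma=1.0, mode="nearest")
    return LineString(np.column_stack([xs, ys]))


def _random_patches(
    rng: np.random.Generator, extent: tuple[float, float, float, float], n: int
) -> shapely.Geometry:
    x0, y0, x1, y1 = extent
    radius_scale = 0.06 * min(x1 - x0, y1 - y0)
    discs = [
        Point(rng.uniform(x0, x1), rng.uniform(y0, y1)).buffer(
            float(rng.uniform(0.5, 1.5)) * radius_scale
        )
        for _ in range(n)
    ]
    return shapely.unary_union(discs)


def simulate_landscape(
    extent: tuple[float, float, float, float] = (0.0, 0.0, 8000.0, 8000.0),
    resolution: float = 50.0,
    seed: int = 0,
    smooth_sigma_cells: float = 6.0,
) -> CovariateStack:
    """Generate the default eleven-layer covariate stack.

    ``extent`` is (x_min, y_min, x_max, y_max) in metres and must cover at
    least 1 km²; ``resolution`` must divide both extent sides.
    """
    x0, y0, x1, y1 = extent
    if (x1 - x0) <= 0 or (y1 - y0) <= 0 or (x1 - x0) * (y1 - y0) < 1e6:
        raise ValueError("extent must be a rectangle of area >= 1 km^2")
    for side in (x1 - x0, y1 - y0):
        if abs(side / resolution - round(side / resolution)) > 1e-9:
            raise ValueError("resolution must divide the extent")
    ncols = round((x1 - x0) / resolution)
    nrows = round((y1 - y0) / resolution)
    rng = np.random.default_rng(seed)

    layers: dict[str, Raster] = {}
    for name in CONTINUOUS_COVARIATES:
        field = gaussian_filter(rng.normal(size=(nrows, ncols)), sigma=smooth_sigma_cells)
        field = (field - field.mean()) / field.std()
        layers[name] = Raster(field, x0, y0, resolution)

    grid = Raster(np.zeros((nrows, ncols)), x0, y0, resolution)
    gx, gy = grid.cell_centers()
    cell_points = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
    features: dict[str, shapely.Geometry] = {}
    for feat, layer_name in FEATURE_COVARIATES.items():
        if feat in ("road", "trail"):
            geom = _random_polyline(rng, extent)
        else:
            geom = _random_patches(rng, extent, n=int(rng.integers(3, 7)))
        features[feat] = geom
        dist = shapely.distance(cell_points, geom).reshape(nrows, ncols)
        layers[layer_name] = Raster(dist, x0, y0, resolution)
    return CovariateStack(layers=layers, features=features)


def simulate_selected_points(
    stack: CovariateStack,
    true_betas: dict[str, float],
    n_used: int,
    domain: Polygon,
    seed: int = 0,
    candidate_density_per_cell: float = 1.0,
) -> pd.DataFrame:
    """Sample used points with selection probability proportional to exp(x·beta).

    Candidates are the stack's cell centres inside ``domain`` (each jittered
    uniformly within its cell so repeated draws do not coincide); weights
    are exp of the linear predictor over the named covariates (values as
    stored, i.e. standardized for continuous layers, metres for distance
    layers unless the caller transformed them).
    """
    unknown = set(true_betas) - set(stack.names)
    if unknown:
        raise KeyError(f"betas reference unknown covariates: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    first = next(iter(stack.layers.values()))
    gx, gy = first.cell_centers()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains(domain, shapely.points(pts))
    pts = pts[inside]
    if len(pts) == 0:
        raise ValueError("domain contains no candidate cells")
    eta = np.zeros(len(pts))
    for name, beta in true_betas.items():
        eta += beta * stack.layers[name].value_at(pts[:, 0], pts[:, 1])
    eta -= eta.max()
    w = np.exp(eta)
    if w.sum() <= 0:
        raise ValueError("all candidate weights are zero")
    p = w / w.sum()
    idx = rng.choice(len(pts), size=n_used, replace=True, p=p)
    jitter = rng.uniform(-0.5, 0.5, size=(n_used, 2)) * first.resolution
    out = pts[idx] + jitter
    return pd.DataFrame({"x": out[:, 0], "y": out[:, 1]})
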