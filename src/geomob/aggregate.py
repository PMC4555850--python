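"""Population-level aggregation of per-user context models.

Each fitted user model induces a spatial density

    p(x | u) = sum_k  occupancy_k * N(x; mu_k, Sigma_k)

and the population-level location density is the user-weighted mixture

    p(x) = sum_n  p(x | u_n) p(u_n),

with p(u_n) either proportional to the user's event count (default) or
uniform.  The pairwise transition surface evaluated at a finite set of
locations (e.g. city centres) is

    p(x_d, x_o) = sum_n p(u_n) sum_{i != j}
        occupancy_i * A_{ij} * N(x_o; mu_i, Sigma_i) * N(x_d; mu_j, Sigma_j),

with within-context pairs i = j excluded by default because flows between
distinct places are the quantity of interest.  Densities are per square
degree; grids store cell-centre values on an even lon/lat lattice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import DEFAULT_BBOX

logger = logging.getLogger(__name__)

DEFAULT_RESOLUTION = 0.05  # degrees


@dataclass
class ProbabilityGrid:
    """Raster of the aggregate location density p(x) at cell centres."""

    lon_axis: np.ndarray   # ascending cell-centre longitudes
    lat_axis: np.ndarray   # ascending cell-centre latitudes
    values: np.ndarray     # (n_lat, n_lon) density per degree^2
    resolution: float      # degrees

    @property
    def cell_area(self) -> float:
        return self.resolution ** 2

    def total_mass(self) -> float:
        return float(self.values.sum() * self.cell_area)

    def to_dataframe(self) -> pd.DataFrame:
        lon, lat = np.meshgrid(self.lon_axis, self.lat_axis)
        return pd.DataFrame({"lon": lon.ravel(), "lat": lat.ravel(),
                             "p": self.values.ravel()})

    def to_csv(self, path) -> None:
        """Long-format export: one `lon,lat,p` row per cell."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "ProbabilityGrid":
        """Read a `lon,lat,p` table back onto its (assumed even) lattice."""
        df = pd.read_csv(path)
        lon_axis = np.array(sorted(df["lon"].unique()))
        lat_axis = np.array(sorted(df["lat"].unique()))
        res = float(np.median(np.diff(lon_axis))) if len(lon_axis) > 1 else (
            float(np.median(np.diff(lat_axis))))
        values = (df.pivot_table(index="lat", columns="lon", values="p",
                                 fill_value=0.0)
                  .reindex(index=lat_axis, columns=lon_axis, fill_value=0.0)
                  .to_numpy())
        return cls(lon_axis=lon_axis, lat_axis=lat_axis, values=values,
                   resolution=res)

    def to_esri_ascii(self, path) -> None:
        """ESRI-ASCII-style raster (row 1 = northernmost) for GIS use."""
        with open(path, "w") as fh:
            fh.write(f"ncols {len(self.lon_axis)}\n")
            fh.write(f"nrows {len(self.lat_axis)}\n")
            fh.write(f"xllcorner {self.lon_axis[0] - self.resolution / 2:.10f}\n")
            fh.write(f"yllcorner {self.lat_axis[0] - self.resolution / 2:.10f}\n")
            fh.write(f"cellsize {self.resolution:.10f}\n")
            fh.write("NODATA_value -9999\n")
            for row in self.values[::-1]:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


@dataclass
class ODMatrix:
    """Aggregate origin-destination surface evaluated at named locations.

    ``values[d, o]`` is the (density or normalized probability) mass of a
    transition from origin ``o`` to destination ``d``.
    """

    locations: list          # of (name, lon, lat)
    values: np.ndarray       # (n, n), entry (destination, origin)
    normalized: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def names(self) -> list:
        return [loc[0] for loc in self.locations]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.names, columns=self.names)
        df.index.name = "destination"
        df.to_csv(path, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, locations=None, normalized=False) -> "ODMatrix":
        df = pd.read_csv(path, index_col=0)
        names = list(df.columns)
        if locations is None:
            locations = [(n, np.nan, np.nan) for n in names]
        return cls(locations=locations, values=df.to_numpy(dtype=float),
                   normalized=normalized)


def user_weights(models, scheme: str = "photo_count") -> np.ndarray:
    """Simplex of user weights p(u_n).

    ``photo_count``: proportional to the user's event count.  ``uniform``:
    1/N.
    """
    if len(models) == 0:
        raise ValueError("need at least one model")
    if scheme == "photo_count":
        w = np.array([m.n_events for m in models], dtype=float)
    elif scheme == "uniform":
        w = np.ones(len(models))
    else:
        raise ValueError(f"unknown weighting scheme: {scheme!r}")
    return w / w.sum()


def _gaussian_pdf_grid(lon_grid, lat_grid, mean, cov):
    """Bivariate normal density on broadcastable lon/lat arrays."""
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[1, 0], cov[0, 0]]]) / det
    dx = lon_grid - mean[0]
    dy = lat_grid - mean[1]
    maha = inv[0, 0] * dx * dx + 2.0 * inv[0, 1] * dx * dy + inv[1, 1] * dy * dy
    return np.exp(-0.5 * maha) / (2.0 * np.pi * np.sqrt(det))


class UserLocationDensity:
    """The mixture density p(x | u): occupancy-weighted Gaussian emissions."""

    def __init__(self, model, mixture_weights: str = "occupancy"):
        self.model = model
        if mixture_weights == "occupancy":
            self.weights = model.occupancy
        elif mixture_weights == "stationary":
            self.weights = stationary_distribution(model.transition)
        else:
            raise ValueError(f"unknown mixture_weights: {mixture_weights!r}")

    def __call__(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        out = np.zeros(np.broadcast(lon, lat).shape)
        for k in range(self.model.k):
            if self.weights[k] > 0:
                out += self.weights[k] * _gaussian_pdf_grid(
                    lon, lat, self.model.means[k], self.model.covariances[k])
        return out


def user_location_density(model, mixture_weights: str = "occupancy"):
    """Callable density p(x | u) over (lon, lat); integrates to 1."""
    return UserLocationDensity(model, mixture_weights)


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Left stationary vector of a row-stochastic matrix (largest eigenvalue)."""
    w, v = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def aggregate_location_grid(models, weights=None, bbox=DEFAULT_BBOX,
                            resolution: float = DEFAULT_RESOLUTION,
                            mixture_weights: str = "occupancy") -> ProbabilityGrid:
    """Evaluate p(x) = sum_n w_n p(x | u_n) on an even lon/lat lattice.

    The grid integrates to ~1 when the bbox covers every state's +-5 sigma
    support; a warning is logged when more than 2% of the mass falls
    outside.
    """
    if weights is None:
        weights = user_weights(models)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(models):
        raise ValueError("weights must match models")
    lon_min, lat_min, lon_max, lat_max = bbox
    lon_axis = np.arange(lon_min + resolution / 2, lon_max, resolution)
    lat_axis = np.arange(lat_min + resolution / 2, lat_max, resolution)
    lon_grid, lat_grid = np.meshgrid(lon_axis, lat_axis)
    values = np.zeros_like(lon_grid)
    for w, m in zip(weights, models):
        if w > 0:
            values += w * UserLocationDensity(m, mixture_weights)(lon_grid, lat_grid)
    grid = ProbabilityGrid(lon_axis=lon_axis, lat_axis=lat_axis,
                           values=values, resolution=resolution)
    mass = grid.total_mass()
    if abs(mass - 1.0) > 0.02:
        logger.warning("grid mass %.4f deviates from 1 by more than 2%%; "
                       "bbox may exclude substantial density", mass)
    return grid


def aggregate_transition(models, weights=None, locations=None,
                         exclude_self: bool = True, normalized: bool = True,
                         mixture_weights: str = "occupancy") -> ODMatrix:
    """Aggregate transition surface p(x_d, x_o) at a finite location set.

    ``locations`` is a list of (name, lon, lat).  The per-user term couples
    origin density under state i with destination density under state j via
    occupancy_i * A_{ij}; within-context pairs (i = j) are excluded by
    default so the matrix measures between-place flows and has an exactly
    zero diagonal contribution from each i = j term.
    """
    if locations is None or len(locations) < 2:
        raise ValueError("need at least 2 locations")
    if weights is None:
        weights = user_weights(models)
    weights = np.asarray(weights, dtype=float)
    lons = np.array([loc[1] for loc in locations], dtype=float)
    lats = np.array([loc[2] for loc in locations], dtype=float)
    n = len(locations)
    values = np.zeros((n, n))
    for w, m in zip(weights, models):
        if w == 0 or m.k < 1:
            continue
        occ = (m.occupancy if mixture_weights == "occupancy"
               else stationary_distribution(m.transition))
        # G[k, l] = N(location l; mu_k, Sigma_k)
        G = np.empty((m.k, n))
        for k in range(m.k):
            G[k] = _gaussian_pdf_grid(lons, lats, m.means[k], m.covariances[k])
        coupling = occ[:, None] * m.transition  # (i, j)
        if exclude_self:
            coupling = coupling.copy()
            np.fill_diagonal(coupling, 0.0)
        # entry (d, o) = sum_{i,j} coupling[i, j] G[i, o] G[j, d]
        values += w * (G.T @ (coupling.T @ G))
    if exclude_self:
        # a flow from a place to itself is not a between-place journey
        np.fill_diagonal(values, 0.0)
    meta = {"weight_scheme": "explicit", "exclude_self": exclude_self,
            "mixture_weights": mixture_weights, "normalized": normalized}
    if normalized:
        total = values.sum()
        if total > 0:
            values = values / total
    return ODMatrix(locations=list(locations), values=values,
                    normalized=normalized, meta=meta)


def symmetric_flow(od: ODMatrix) -> np.ndarray:
    """F = V + V^T, the bidirectional flow proxy between location pairs."""
    v = od.values
    if v.shape[0] != v.shape[1]:
        raise ValueError("OD matrix must be square")
    return v + v.T
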