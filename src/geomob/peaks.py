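"""Peak detection on the aggregate density and matching against a city list.

Local maxima of p(x) are found with a sliding rectangular maximum filter:
a cell is a peak iff its value equals the maximum over the window centred
on it and exceeds a threshold phi.  Window sizes are given in km
(east-west d_x, north-south d_y) and converted to odd cell counts using
1 deg lat = 111.32 km and 1 deg lon = 111.32 * cos(mid-latitude) km.
Detected peaks are matched one-to-one to a catalogue of named cities
within a radius (default 15 km), yielding precision, recall and F-measure;
a parameter sweep traces the precision-recall tradeoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .aggregate import ProbabilityGrid
from .geo import KM_PER_DEG, haversine_km

DEFAULT_MATCH_RADIUS_KM = 15.0
#: endpoint (d_x, d_y) window sizes of the default sweep, km
SWEEP_WINDOW_MIN = (18.0, 28.0)
SWEEP_WINDOW_MAX = (90.0, 140.0)
SWEEP_N_WINDOWS = 10
SWEEP_PHI_RANGE = (1e-3, 1e-4)
SWEEP_N_PHI = 20


@dataclass
class CityCatalog:
    """Named reference locations with coordinates and population."""

    entries: list  # of (name, lon, lat, population)

    def __post_init__(self):
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("city names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list:
        return [e[0] for e in self.entries]

    @property
    def coords(self) -> np.ndarray:
        return np.array([[e[1], e[2]] for e in self.entries], dtype=float)

    def locations(self) -> list:
        return [(e[0], e[1], e[2]) for e in self.entries]

    @classmethod
    def from_csv(cls, path) -> "CityCatalog":
        df = pd.read_csv(path)
        return cls(entries=[(r["name"], float(r["lon"]), float(r["lat"]),
                             float(r["population"]))
                            for _, r in df.iterrows()])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.entries, columns=["name", "lon", "lat", "population"]
                     ).to_csv(path, index=False)

    @classmethod
    def from_world(cls, world) -> "CityCatalog":
        """Catalogue of a synthetic world's anchors (weight as population)."""
        return cls(entries=[(a[0], a[1], a[2], a[3]) for a in world.anchors])


@dataclass
class PeakSet:
    """Detected local maxima: (lon, lat, value) at grid cell centres."""

    peaks: list          # of (lon, lat, value)
    window_km: tuple     # (d_x, d_y)
    threshold: float

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def coords(self) -> np.ndarray:
        return np.array([[p[0], p[1]] for p in self.peaks], dtype=float
                        ).reshape(-1, 2)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.peaks, columns=["lon", "lat", "value"]
                     ).to_csv(path, index=False, float_format="%.12g")


@dataclass
class MatchResult:
    """One-to-one peak/city matching scores."""

    precision: float
    recall: float
    f_measure: float
    matched: list  # of (peak_index, city_name, distance_km)


def window_cells(grid: ProbabilityGrid, window_km) -> tuple:
    """(rows, cols) window size in cells, rounded up to odd counts."""
    d_x, d_y = window_km
    if d_x <= 0 or d_y <= 0:
        raise ValueError("window dimensions must be positive")
    lat0 = 0.5 * (grid.lat_axis[0] + grid.lat_axis[-1])
    km_per_cell_x = KM_PER_DEG * np.cos(np.radians(lat0)) * grid.resolution
    km_per_cell_y = KM_PER_DEG * grid.resolution
    nx = int(np.ceil(d_x / km_per_cell_x))
    ny = int(np.ceil(d_y / km_per_cell_y))
    if nx % 2 == 0:
        nx += 1
    if ny % 2 == 0:
        ny += 1
    return ny, nx


def maximum_filter_peaks(grid: ProbabilityGrid, window_km,
                         phi: float) -> PeakSet:
    """Cells that attain their centred-window maximum and exceed phi.

    On plateaus (several equal-valued cells sharing one window) only the
    lexicographically smallest (lat index, lon index) cell is kept, so the
    peak set is deterministic.
    """
    ny, nx = window_cells(grid, window_km)
    values = grid.values
    filt = ndimage.maximum_filter(values, size=(ny, nx), mode="constant",
                                  cval=-np.inf)
    cand = np.argwhere((values >= filt) & (values > phi))  # lex-sorted rows
    kept = []
    hy, hx = ny // 2, nx // 2
    for iy, ix in cand:
        v = values[iy, ix]
        duplicate = False
        for ky, kx in kept:
            if abs(ky - iy) <= hy and abs(kx - ix) <= hx and values[ky, kx] == v:
                duplicate = True
                break
        if not duplicate:
            kept.append((iy, ix))
    peaks = [(float(grid.lon_axis[ix]), float(grid.lat_axis[iy]),
              float(values[iy, ix])) for iy, ix in kept]
    return PeakSet(peaks=peaks, window_km=tuple(window_km), threshold=phi)


def match_to_catalog(peaks: PeakSet, catalog: CityCatalog,
                     radius_km: float = DEFAULT_MATCH_RADIUS_KM) -> MatchResult:
    """Greedy distance-ascending one-to-one matching of peaks to cities.

    precision = matched / n_peaks (0 when no peaks); recall =
    matched / n_cities; F = 2PR/(P+R).
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    if len(catalog) == 0:
        raise ValueError("empty catalogue")
    n_peaks = len(peaks)
    if n_peaks == 0:
        return MatchResult(precision=0.0, recall=0.0, f_measure=0.0, matched=[])
    pc = peaks.coords
    cc = catalog.coords
    dist = haversine_km(pc[:, 0][:, None], pc[:, 1][:, None],
                        cc[None, :, 0], cc[None, :, 1])
    pairs = [(dist[i, j], i, j) for i in range(n_peaks) for j in range(len(catalog))
             if dist[i, j] <= radius_km]
    pairs.sort()
    used_peaks, used_cities, matched = set(), set(), []
    for d, i, j in pairs:
        if i not in used_peaks and j not in used_cities:
            used_peaks.add(i)
            used_cities.add(j)
            matched.append((i, catalog.names[j], float(d)))
    m = len(matched)
    precision = m / n_peaks
    recall = m / len(catalog)
    f = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return MatchResult(precision=precision, recall=recall, f_measure=f,
                       matched=matched)


def default_windows(n: int = SWEEP_N_WINDOWS) -> list:
    """n (d_x, d_y) pairs linearly interpolated between the sweep endpoints."""
    fr = np.linspace(0.0, 1.0, n)
    return [(SWEEP_WINDOW_MIN[0] + f * (SWEEP_WINDOW_MAX[0] - SWEEP_WINDOW_MIN[0]),
             SWEEP_WINDOW_MIN[1] + f * (SWEEP_WINDOW_MAX[1] - SWEEP_WINDOW_MIN[1]))
            for f in fr]


def default_thresholds(n: int = SWEEP_N_PHI) -> np.ndarray:
    """n thresholds log-spaced over the default phi interval."""
    lo, hi = SWEEP_PHI_RANGE
    return np.logspace(np.log10(lo), np.log10(hi), n)


def sweep(grid: ProbabilityGrid, catalog: CityCatalog, windows=None,
          thresholds=None,
          radius_km: float = DEFAULT_MATCH_RADIUS_KM) -> pd.DataFrame:
    """Full factorial sweep over window sizes and thresholds.

    Returns a table with columns d_x, d_y, r (= sqrt(d_x d_y)), phi,
    n_peaks, precision, recall, f_measure.  The argmax-F row is
    ``best_row(table)``.
    """
    if windows is None:
        windows = default_windows()
    if thresholds is None:
        thresholds = default_thresholds()
    if len(windows) == 0 or len(thresholds) == 0:
        raise ValueError("sweep ranges must be non-empty")
    rows = []
    for (d_x, d_y) in windows:
        for phi in thresholds:
            ps = maximum_filter_peaks(grid, (d_x, d_y), phi)
            mr = match_to_catalog(ps, catalog, radius_km)
            rows.append((d_x, d_y, float(np.sqrt(d_x * d_y)), phi, len(ps),
                         mr.precision, mr.recall, mr.f_measure))
    return pd.DataFrame(rows, columns=["d_x", "d_y", "r", "phi", "n_peaks",
                                       "precision", "recall", "f_measure"])


def best_row(table: pd.DataFrame) -> pd.Series:
    """The sweep row with the highest F-measure (first on ties)."""
    return table.loc[table["f_measure"].idxmax()]


def identify_cities(grid: ProbabilityGrid, catalog: CityCatalog,
                    window_km=(54.0, 84.0), phi: float = 2.78e-3,
                    radius_km: float = DEFAULT_MATCH_RADIUS_KM):
    """City identification at a fixed operating point.

    Convenience wrapper: detect peaks with the given window/threshold and
    score them against the catalogue.  Returns (PeakSet, MatchResult).
    """
    ps = maximum_filter_peaks(grid, window_km, phi)
    return ps, match_to_catalog(ps, catalog, radius_km)
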