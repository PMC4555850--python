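"""Synthetic trajectory generator.

Produces populations of ground-truth context trajectories with the
statistical structure the downstream inference assumes: a shared set of
"anchor" locations (stand-ins for major cities), per-user latent contexts
with isotropic Gaussian spatial emissions, sparse Markov switching between
contexts, heavy-tailed per-user event counts and heavy-tailed inter-event
time gaps.  Mixing many short within-context displacements with rare long
between-context jumps yields the Lévy-flight-like displacement distribution
observed in real geo-tagged photo streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geo import deg_arc_km, haversine_km

#: UK-like default bounding box (lon_min, lat_min, lon_max, lat_max), degrees.
DEFAULT_BBOX = (-8.65, 49.84, 1.77, 60.86)

#: Epoch at which every simulated event stream starts (arbitrary, fixed).
_T0 = np.datetime64("2010-01-01T00:00:00")


class AnchorPlacementError(RuntimeError):
    """Raised when anchors cannot be placed at the required separation."""


@dataclass(frozen=True)
class AnchorWorld:
    """A shared set of weighted anchor locations inside a bounding box.

    Anchors play the role of a country's major population centres: per-user
    latent contexts are centred on a subset of them, with selection
    probability proportional to the anchor weight.
    """

    anchors: tuple  # of (name, lon, lat, weight)
    bbox: tuple     # (lon_min, lat_min, lon_max, lat_max) degrees
    seed: int

    def __post_init__(self):
        lon_min, lat_min, lon_max, lat_max = self.bbox
        if not self.anchors:
            raise ValueError("world needs at least one anchor")
        w = np.array([a[3] for a in self.anchors], dtype=float)
        if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("anchor weights must be positive and sum to 1")
        for _, lon, lat, _ in self.anchors:
            if not (lon_min <= lon <= lon_max and lat_min <= lat <= lat_max):
                raise ValueError("anchor outside bbox")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def names(self) -> list:
        return [a[0] for a in self.anchors]

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat)."""
        return np.array([[a[1], a[2]] for a in self.anchors], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([a[3] for a in self.anchors], dtype=float)

    def locations(self) -> list:
        """[(name, lon, lat), ...] — the shape peak matching expects."""
        return [(a[0], a[1], a[2]) for a in self.anchors]


@dataclass(frozen=True)
class GroundTruthUser:
    """True generative parameters of one simulated user."""

    user_id: str
    means: np.ndarray        # (K, 2) lon/lat degrees
    covariances: np.ndarray  # (K, 2, 2) degrees^2
    transition: np.ndarray   # (K, K) row-stochastic
    initial: np.ndarray      # (K,) simplex
    n_events: int
    hidden_path: np.ndarray = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.means.shape[0]

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "n_events": int(self.n_events),
            "hidden_path": None if self.hidden_path is None else self.hidden_path.tolist(),
        }


def make_world(n_anchors: int, bbox: Sequence[float] = DEFAULT_BBOX, seed: int = 0,
               min_separation_deg: float = 1.0, max_attempts: int = 10_000) -> AnchorWorld:
    """Place ``n_anchors`` anchors uniformly in ``bbox`` by rejection sampling.

    Every pair of anchors is at least ``min_separation_deg`` degrees of
    great-circle arc apart, so that density-based clustering at the default
    neighbourhood radius can always separate contexts and aggregate density
    peaks are resolvable.  Anchor weights are drawn heavy-tailed (lognormal,
    normalized), mimicking a city-size distribution.
    """
    if n_anchors < 1:
        raise ValueError("n_anchors must be >= 1")
    lon_min, lat_min, lon_max, lat_max = bbox
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError("bbox is degenerate")
    rng = np.random.default_rng(seed)
    min_km = deg_arc_km(min_separation_deg)
    placed = []
    attempts = 0
    while len(placed) < n_anchors:
        if attempts >= max_attempts:
            raise AnchorPlacementError(
                f"could not place {n_anchors} anchors at {min_separation_deg} deg "
                f"separation in {bbox} after {max_attempts} attempts")
        attempts += 1
        lon = rng.uniform(lon_min, lon_max)
        lat = rng.uniform(lat_min, lat_max)
        if all(haversine_km(lon, lat, p[0], p[1]) >= min_km for p in placed):
            placed.append((lon, lat))
    w = rng.lognormal(mean=0.0, sigma=1.0, size=n_anchors)
    w /= w.sum()
    anchors = tuple((f"anchor_{i:02d}", placed[i][0], placed[i][1], float(w[i]))
                    for i in range(n_anchors))
    return AnchorWorld(anchors=anchors, bbox=tuple(bbox), seed=seed)


def sample_inter_event_times(n: int, log_mean: float = np.log(24.0),
                             log_sd: float = 1.5, seed: int = 0,
                             rng: np.random.Generator = None) -> np.ndarray:
    """Draw ``n`` positive lognormal inter-event gaps in hours.

    The lognormal captures the observed heavy tail of gaps between
    consecutive geo-tagged uploads (most a few hours or days apart, a few
    much longer) while keeping closed-form quantiles.  Defaults: median
    24 h, log-sd 1.5.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.lognormal(mean=log_mean, sigma=log_sd, size=n)


def _timestamps_from_gaps(gaps_hours: np.ndarray) -> np.ndarray:
    """Strictly increasing datetime64[s] timestamps starting at the epoch."""
    cum = np.concatenate([[0.0], np.cumsum(gaps_hours)]) * 3600.0
    secs = np.maximum.accumulate(np.ceil(cum).astype(np.int64) +
                                 np.arange(cum.size))  # strict increase
    return _T0 + secs.astype("timedelta64[s]")


def simulate_user(world: AnchorWorld, k: int, n_events: int,
                  self_prob: float = 0.9, emission_sd: float = 0.1,
                  seed: int = 0, user_id: str = "u0",
                  gap_log_mean: float = np.log(24.0), gap_log_sd: float = 1.5,
                  rng: np.random.Generator = None):
    """Simulate one user's trajectory from a k-context Markov chain.

    ``k`` distinct anchors are chosen with probability proportional to
    their weight and become the context means.  The transition matrix has
    ``self_prob`` on the diagonal and uniform off-diagonal mass; emissions
    are isotropic Gaussians with standard deviation ``emission_sd``
    degrees.  Returns ``(events DataFrame, GroundTruthUser)``.
    """
    if not (1 <= k <= world.n_anchors):
        raise ValueError(f"k={k} must be in [1, {world.n_anchors}]")
    if not (0.0 <= self_prob <= 1.0):
        raise ValueError("self_prob must be a probability")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    idx = rng.choice(world.n_anchors, size=k, replace=False, p=world.weights)
    means = world.coords[idx]
    cov = np.tile(np.eye(2) * emission_sd ** 2, (k, 1, 1))
    if k == 1:
        trans = np.ones((1, 1))
    else:
        off = (1.0 - self_prob) / (k - 1)
        trans = np.full((k, k), off)
        np.fill_diagonal(trans, self_prob)
    initial = np.full(k, 1.0 / k)

    path = np.empty(n_events, dtype=np.int64)
    path[0] = rng.choice(k, p=initial)
    for t in range(1, n_events):
        path[t] = rng.choice(k, p=trans[path[t - 1]])

    noise = rng.standard_normal((n_events, 2)) * emission_sd
    xy = means[path] + noise
    gaps = sample_inter_event_times(n_events - 1, gap_log_mean, gap_log_sd, rng=rng)
    ts = _timestamps_from_gaps(gaps)

    events = pd.DataFrame({
        "user_id": user_id,
        "lon": xy[:, 0],
        "lat": xy[:, 1],
        "timestamp": pd.to_datetime(ts, utc=True),
    })
    truth = GroundTruthUser(user_id=user_id, means=means, covariances=cov,
                            transition=trans, initial=initial,
                            n_events=n_events, hidden_path=path)
    return events, truth


def simulate_population(world: AnchorWorld, n_users: int,
                        photo_log_mean: float = np.log(200.0),
                        photo_log_sd: float = 1.0,
                        k_range: tuple = (2, 6),
                        self_prob: float = 0.9, emission_sd: float = 0.1,
                        gap_log_mean: float = np.log(24.0), gap_log_sd: float = 1.5,
                        seed: int = 0):
    """Simulate a population of users over a shared anchor world.

    Per-user event counts are lognormal (heavy-tailed, like real per-user
    photo counts); the per-user context count k is uniform on ``k_range``
    (clipped to the anchor count).  Users whose events all fall on one
    calendar day arise naturally and are left in, so ingest filters have
    work to do.  Returns ``(event table, list of GroundTruthUser)``.
    """
    if n_users < 1:
        raise ValueError("n_users must be >= 1")
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(n_users)

    counts = np.maximum(1, np.round(
        master.lognormal(photo_log_mean, photo_log_sd, size=n_users))).astype(int)
    k_lo, k_hi = k_range
    k_hi = min(k_hi, world.n_anchors)
    k_lo = min(k_lo, k_hi)
    ks = master.integers(k_lo, k_hi + 1, size=n_users)

    frames, truths = [], []
    for i in range(n_users):
        uid = f"user_{i:05d}"
        rng = np.random.default_rng(child_seeds[i])
        ev, truth = simulate_user(world, int(ks[i]), int(counts[i]),
                                  self_prob=self_prob, emission_sd=emission_sd,
                                  gap_log_mean=gap_log_mean, gap_log_sd=gap_log_sd,
                                  user_id=uid, rng=rng)
        frames.append(ev)
        truths.append(truth)
    table = pd.concat(frames, ignore_index=True)
    return table, truths


def write_events_csv(events: pd.DataFrame, path) -> None:
    """Write the event table as CSV with ISO-8601 UTC timestamps."""
    out = events.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, columns=["user_id", "lon", "lat", "timestamp"],
               float_format="%.10f")


def write_events_jsonl(events: pd.DataFrame, path) -> None:
    """Write the event table as JSON-lines with the same keys as the CSV."""
    with open(path, "w") as fh:
        for row in events.itertuples(index=False):
            ts = pd.Timestamp(row.timestamp).strftime("%Y-%m-%dT%H:%M:%SZ")
            fh.write(json.dumps({"user_id": row.user_id, "lon": row.lon,
                                 "lat": row.lat, "timestamp": ts}) + "\n")


def write_ground_truth(truths, world: AnchorWorld, path, params: dict = None) -> None:
    """Serialize ground truth (world, per-user parameters) as JSON."""
    doc = {
        "world": {"anchors": [list(a) for a in world.anchors],
                  "bbox": list(world.bbox), "seed": world.seed},
        "params": params or {},
        "users": [t.to_dict() for t in truths],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
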