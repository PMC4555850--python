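"""Run configuration: every tunable of the pipeline, with field defaults.

Defaults follow the standard parameterization of this pipeline: DBSCAN
eps = 0.5 coordinate units with MinPts = 2% of a user's events (floor 2),
15 km city matching, the (18,28)..(90,140) km window sweep with thresholds
between 1e-3 and 1e-4, and 100 null-model trials.  The config is
serialized into every run directory so outputs are self-describing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import clustering, hmm, peaks
from .aggregate import DEFAULT_RESOLUTION
from .synthetic import DEFAULT_BBOX


@dataclass
class RunConfig:
    seed: int = 0

    # paths
    events_path: str = None
    polygon_path: str = None
    catalog_path: str = None
    out_dir: str = "run"

    # DBSCAN
    eps: float = clustering.DEFAULT_EPS
    min_fraction: float = clustering.DEFAULT_MIN_FRACTION
    min_pts_floor: int = clustering.MIN_PTS_FLOOR

    # HMM
    max_iter: int = hmm.DEFAULT_MAX_ITER
    rel_tol: float = hmm.DEFAULT_REL_TOL
    cov_floor: float = hmm.COV_FLOOR
    init_diag: float = hmm.INIT_DIAG

    # grid
    bbox: tuple = DEFAULT_BBOX
    resolution: float = DEFAULT_RESOLUTION

    # aggregation
    weight_scheme: str = "photo_count"
    mixture_weights: str = "occupancy"
    exclude_self: bool = True

    # peaks
    window_km: tuple = (54.0, 84.0)
    phi: float = 2.78e-3
    match_radius_km: float = peaks.DEFAULT_MATCH_RADIUS_KM
    sweep_windows: int = peaks.SWEEP_N_WINDOWS
    sweep_thresholds: int = peaks.SWEEP_N_PHI

    # comparison
    n_trials: int = 100
    reference_path: str = None

    # synthetic generation (used by the `simulate` stage)
    n_users: int = 200
    n_anchors: int = 10
    k_range: tuple = (2, 6)
    self_prob: float = 0.9
    emission_sd: float = 0.1
    photo_log_mean: float = 5.298317366548036  # ln 200
    photo_log_sd: float = 1.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bbox"] = list(self.bbox)
        d["window_km"] = list(self.window_km)
        d["k_range"] = list(self.k_range)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("bbox", "window_km", "k_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)
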