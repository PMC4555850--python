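"""End-to-end pipeline: ingest -> per-user models -> aggregation -> peaks.

Stages are individually callable; :func:`run_pipeline` chains them and
writes every artifact (filtered events, per-user models, density grid,
peaks, sweep table, OD matrix, reports) together with the config and seed
into a run directory.  One master seed is expanded into per-stage
substreams so any stage can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate, compare, ingest, peaks as peaks_mod, synthetic
from .config import RunConfig
from .hmm import ContextHMM, write_models_json, write_states_csv, write_transitions_csv

logger = logging.getLogger(__name__)

_STAGE_SEEDS = {"simulate": 0, "fit": 1, "compare": 2}


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGE_SEEDS[stage],))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def fit_population(trajectories, config: RunConfig = None, min_events: int = 10):
    """Fit a context HMM per trajectory; returns (results list, fitted UserModels).

    Trajectories shorter than ``min_events`` cannot support clustering plus
    EM and are skipped (logged).
    """
    config = config or RunConfig()
    results = []
    for traj in trajectories:
        if len(traj) < min_events:
            logger.info("fit: skipping %s (%d events < %d)",
                        traj.user_id, len(traj), min_events)
            continue
        model = ContextHMM(traj, eps=config.eps, min_fraction=config.min_fraction)
        res = model.fit(max_iter=config.max_iter, rel_tol=config.rel_tol,
                        cov_floor=config.cov_floor)
        logger.info("fit: %s T=%d K=%d iter=%d loglik=%.2f", traj.user_id,
                    len(traj), res.k, res.n_iter, res.log_likelihood)
        results.append(res)
    return results, [r.params for r in results]


def run_pipeline(config: RunConfig, events: pd.DataFrame = None) -> Path:
    """Execute the full pipeline and write artifacts to ``config.out_dir``.

    ``events`` may be passed directly (e.g. fresh from the simulator);
    otherwise ``config.events_path`` is read.  Returns the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log_handler = logging.FileHandler(out / "run.log")
    logging.getLogger("geomob").addHandler(log_handler)
    try:
        # ingest
        try:
            if events is None:
                if config.events_path is None:
                    raise ValueError("no events supplied and no events_path configured")
                events = ingest.read_events(config.events_path)
            n_raw = len(events)
            if config.polygon_path is not None:
                events = ingest.filter_by_region(events, config.polygon_path)
            events = ingest.filter_single_day_users(events)
            logger.info("ingest: %d of %d events retained", len(events), n_raw)
            trajectories = ingest.split_trajectories(events)
        except Exception as e:
            raise PipelineError(f"ingest: {e}") from e
        synthetic.write_events_csv(events, out / "events_filtered.csv")
        ingest.write_displacements(
            ingest.population_displacements(trajectories), out / "displacements.csv")

        # per-user clustering + HMM
        try:
            results, models = fit_population(trajectories, config)
            if not models:
                raise ValueError("no user had enough events to fit")
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"fit: {e}") from e
        write_models_json(models, out / "models.json")
        write_states_csv(models, out / "hmm_states.csv")
        write_transitions_csv(models, out / "hmm_tmat.csv")

        # aggregation
        try:
            weights = aggregate.user_weights(models, config.weight_scheme)
            grid = aggregate.aggregate_location_grid(
                models, weights, bbox=config.bbox, resolution=config.resolution,
                mixture_weights=config.mixture_weights)
        except Exception as e:
            raise PipelineError(f"aggregate: {e}") from e
        grid.to_csv(out / "marginals_prob.csv")

        # peaks + sweep (needs a catalogue)
        report = {"seed": config.seed, "n_users_fit": len(models),
                  "grid_mass": grid.total_mass()}
        catalog = None
        if config.catalog_path is not None:
            catalog = peaks_mod.CityCatalog.from_csv(config.catalog_path)
        if catalog is not None:
            try:
                peak_set, match = peaks_mod.identify_cities(
                    grid, catalog, window_km=config.window_km, phi=config.phi,
                    radius_km=config.match_radius_km)
                table = peaks_mod.sweep(
                    grid, catalog,
                    windows=peaks_mod.default_windows(config.sweep_windows),
                    thresholds=peaks_mod.default_thresholds(config.sweep_thresholds),
                    radius_km=config.match_radius_km)
            except Exception as e:
                raise PipelineError(f"peaks: {e}") from e
            peak_set.to_csv(out / "peaks.csv")
            table.to_csv(out / "sweep.csv", index=False, float_format="%.12g")
            best = peaks_mod.best_row(table)
            report["fixed_point"] = {"precision": match.precision,
                                     "recall": match.recall,
                                     "f_measure": match.f_measure,
                                     "n_peaks": len(peak_set)}
            report["best_sweep"] = {k: float(best[k]) for k in
                                    ("d_x", "d_y", "r", "phi", "precision",
                                     "recall", "f_measure")}

            # OD matrix over the catalogue's locations
            try:
                od = aggregate.aggregate_transition(
                    models, weights, locations=catalog.locations(),
                    exclude_self=config.exclude_self, normalized=True,
                    mixture_weights=config.mixture_weights)
            except Exception as e:
                raise PipelineError(f"aggregate: {e}") from e
            od.to_csv(out / "marginals_tmat.csv")

            # optional comparison against a reference OD matrix
            if config.reference_path is not None:
                try:
                    ref = aggregate.ODMatrix.from_csv(config.reference_path)
                    nc = compare.null_comparison(
                        od.values, ref.values, n_trials=config.n_trials,
                        seed=stage_seed(config.seed, "compare"))
                    tau, p = compare.kendall_tau(od.values.ravel(),
                                                 ref.values.ravel())
                except Exception as e:
                    raise PipelineError(f"compare: {e}") from e
                nc.to_json(out / "null_comparison.json")
                report["comparison"] = {"tau": tau, "p_value": p,
                                        "exceedance": nc.exceedance,
                                        "d_est": nc.d_est}
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    finally:
        logging.getLogger("geomob").removeHandler(log_handler)
        log_handler.close()
    return out


def simulate_to_dir(config: RunConfig, out_dir=None) -> Path:
    """Generate a synthetic population and write events + ground truth."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(config.seed, "simulate")
    world = synthetic.make_world(config.n_anchors, config.bbox, seed=seed)
    events, truths = synthetic.simulate_population(
        world, config.n_users, photo_log_mean=config.photo_log_mean,
        photo_log_sd=config.photo_log_sd, k_range=config.k_range,
        self_prob=config.self_prob, emission_sd=config.emission_sd, seed=seed)
    synthetic.write_events_csv(events, out / "events.csv")
    synthetic.write_ground_truth(truths, world, out / "ground_truth.json",
                                 params=config.to_dict())
    peaks_mod.CityCatalog.from_world(world).to_csv(out / "catalog.csv")
    return out
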