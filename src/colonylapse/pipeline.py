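"""End-to-end orchestration: simulate/quantify -> metrics -> diffstats -> enrich.

The pipeline is a pure function of (inputs, config, seed): rerunning with
the same configuration produces identical output files.  Each stage logs
one line with its input/output record counts so filter accounting (e.g.
how many strains survive the minimum-replicate rule) can be audited.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import curves as gm
from . import diffstats as ds
from . import enrichment as en
from . import io as cio
from . import simulate as sim

__all__ = ["run_pipeline", "metrics_from_curves", "diffstats_from_metrics"]

log = logging.getLogger("colonylapse")


def metrics_from_curves(
    meta: pd.DataFrame,
    values: np.ndarray,
    times: np.ndarray,
    *,
    max_hours: float = gm.DEFAULT_MAX_HOURS,
    smooth_window: int = gm.DEFAULT_SMOOTH_WINDOW,
) -> pd.DataFrame:
    """Curve pipeline stage; drops dead colonies and logs the counts."""
    metrics = gm.compute_metrics(meta, values, times,
                                 max_hours=max_hours, smooth_window=smooth_window)
    n_dead = int(metrics["excluded"].sum())
    log.info("metrics: %d colonies in, %d excluded (dead), %d out",
             len(metrics), n_dead, len(metrics) - n_dead)
    return metrics[~metrics["excluded"]].drop(columns="excluded").reset_index(drop=True)


def diffstats_from_metrics(
    metrics: pd.DataFrame,
    *,
    min_reps: int = ds.DEFAULT_MIN_REPLICATES,
    q_cutoff: float = ds.DEFAULT_Q_CUTOFF,
) -> tuple[pd.DataFrame, ds.NominationSets]:
    """Merge duplicates, apply the replicate filter, test, nominate."""
    merged = ds.merge_duplicates(metrics)
    filtered = ds.filter_replicates(merged, min_reps)
    n_strains_in = merged["strain_id"].nunique()
    n_strains_out = filtered["strain_id"].nunique()
    log.info("replicate filter (>=%d per condition): %d strains in, %d retained",
             min_reps, n_strains_in, n_strains_out)
    results = ds.differential_table(filtered)
    sets = ds.nominate(results, q_cutoff)
    log.info("nomination at q<%g: %s", q_cutoff, sets.counts())
    return results, sets


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run every stage described by ``config`` and write result CSVs.

    Config keys (all optional unless noted):
      simulate:    SimConfig field overrides (runs the simulator entry)
      curves_csv:  path to a long-format curves CSV (file entry)
      metrics:     {max_hours, smooth_window}
      diffstats:   {min_reps, q_cutoff}
      enrich:      {gmt, universe (optional path), q_cutoff}
      seed:        master seed (folded into the simulator)

    Returns a summary dict with stage outputs and nomination counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cio.config_hash(config)
    summary: dict[str, Any] = {"config_hash": cfg_hash}

    if "simulate" in config:
        sim_kwargs = dict(config["simulate"])
        if "seed" in config and "seed" not in sim_kwargs:
            sim_kwargs["seed"] = int(config["seed"])
        sc = sim.SimConfig(**sim_kwargs)
        exp = sim.simulate_curves(sc)
        meta, values, times = exp.meta, exp.values, exp.times
        cio.write_table(exp.labels, out_dir / "labels.csv", cfg_hash)
        log.info("simulate: %d strains, %d colonies, %d frames",
                 sc.n_strains, len(meta), times.size)
        summary["labels"] = exp.labels
    elif "curves_csv" in config:
        meta, values, times = cio.read_curves(config["curves_csv"])
        log.info("curves: read %d colonies x %d timepoints", len(meta), times.size)
    else:
        raise ValueError("config needs a 'simulate' section or a 'curves_csv' path")

    mopts = config.get("metrics", {})
    metrics = metrics_from_curves(meta, values, times,
                                  max_hours=mopts.get("max_hours", gm.DEFAULT_MAX_HOURS),
                                  smooth_window=mopts.get("smooth_window", gm.DEFAULT_SMOOTH_WINDOW))
    cio.write_table(metrics, out_dir / "metrics.csv", cfg_hash)
    summary["metrics"] = metrics

    dopts = config.get("diffstats", {})
    results, sets = diffstats_from_metrics(
        metrics,
        min_reps=dopts.get("min_reps", ds.DEFAULT_MIN_REPLICATES),
        q_cutoff=dopts.get("q_cutoff", ds.DEFAULT_Q_CUTOFF))
    cio.write_table(results, out_dir / "diffstats.csv", cfg_hash)
    summary["results"] = results
    summary["nominations"] = sets
    summary["counts"] = sets.counts()

    eopts = config.get("enrich")
    if eopts:
        sets_gmt = en.read_gmt(eopts["gmt"])
        if "universe" in eopts:
            universe = set(Path(eopts["universe"]).read_text().split())
        else:
            universe = set(results["strain_id"].unique())
        table = en.enrich(set(sets.union), sets_gmt, universe,
                          q_cutoff=eopts.get("q_cutoff", 0.05))
        cio.write_table(table, out_dir / "enrichment.csv", cfg_hash)
        log.info("enrichment: %d terms tested, %d significant",
                 len(table), int(table["significant"].sum()) if len(table) else 0)
        summary["enrichment"] = table
    return summary
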