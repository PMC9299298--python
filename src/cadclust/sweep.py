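"""Parameter sweeps: a Cartesian grid of config overrides, each cell run
with several replicates under derived seeds, aggregated into one summary row
per cell (mean and standard deviation of each summary statistic)."""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .analysis import summarize_run
from .config import RunConfig
from .engine import RunSchedule, run

__all__ = ["SweepSpec", "run_sweep", "derived_seed", "run_config"]

log = logging.getLogger(__name__)

STAT_KEYS = [
    "max_cluster_size", "mean_cluster_size", "fraction_trans", "fraction_cis",
    "kd_cis", "msd_alpha_short", "msd_alpha_long", "mean_lifetime",
    "nnd", "size_cv",
]


@dataclass
class SweepSpec:
    base: RunConfig
    axes: Dict[str, Sequence] = field(default_factory=dict)
    replicates: int = 5  # matches the 5-simulation averaging of the study design

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")

    def cells(self) -> List[dict]:
        if not self.axes:
            return [{}]
        names = list(self.axes)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.axes[n] for n in names))
        ]


def derived_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-run seed from (base seed, cell, replicate)."""
    ss = np.random.SeedSequence([int(base_seed), int(cell_index), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def run_config(config: RunConfig, keep_snapshots: bool = True):
    """Execute one configured run (thin wrapper tying config to engine)."""
    schedule = RunSchedule(
        duration=config.duration,
        snapshot_interval=config.snapshot_interval,
        trajectory_interval=config.trajectory_interval,
        seed=config.seed,
    )
    return run(
        config.domain(),
        config.kinetic_params(),
        schedule,
        obstruction=config.actin_obstruction,
        binding=config.actin_binding,
        keep_snapshots=keep_snapshots,
        convergence_tol=config.convergence_tol,
        convergence_window=config.convergence_window,
    )


def run_sweep(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """Execute the grid x replicates; one row per cell with mean/std of each
    summary statistic.  A failed replicate is logged and skipped, not fatal."""
    rows = []
    for cell_idx, overrides in enumerate(spec.cells()):
        stats: Dict[str, list] = {k: [] for k in STAT_KEYS}
        n_ok = 0
        n_failed = 0
        for rep in range(spec.replicates):
            seed = derived_seed(spec.base.seed, cell_idx, rep)
            cfg = spec.base.replace(seed=seed, **overrides)
            try:
                result = run_config(cfg)
                summary = summarize_run(result)
            except Exception:  # noqa: BLE001 - a cell must not kill the sweep
                log.exception("sweep cell %d replicate %d failed", cell_idx, rep)
                n_failed += 1
                continue
            n_ok += 1
            for k in STAT_KEYS:
                stats[k].append(summary.get(k, float("nan")))
        row = {"cell": cell_idx, **overrides, "n_ok": n_ok, "n_failed": n_failed}
        for k in STAT_KEYS:
            vals = np.asarray(stats[k], dtype=float)
            good = vals[np.isfinite(vals)]
            row[f"{k}_mean"] = float(good.mean()) if good.size else float("nan")
            row[f"{k}_std"] = float(good.std(ddof=0)) if good.size else float("nan")
        rows.append(row)
        if progress:
            log.info("cell %d/%d done", cell_idx + 1, len(spec.cells()))
    return pd.DataFrame(rows)
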