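"""Parameter-scan harness: single runs, grids over the key-parameter table,
replicate management, and condition summaries.

A *run* is one simulation of a scenario to ``tEnd`` with a derived seed; a
*scan* is the cross product of parameter value lists times a replicate count.
Results land in one flat table (CSV), one row per completed run, from which
the condition summaries (length statistics, regional cofilin fractions,
dispersion) are recomputed deterministically.
"""

from __future__ import annotations

import itertools
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ModelConfigError
from .engine import EngineParams
from .model import ModelParams, build_model
from .observables import (AmountRecorder, ComplexSizeRecorder,
                          cofilin_region_fractions, extract_filament_complexes,
                          length_stats, orientation_dispersion, render_snapshot)

logger = logging.getLogger("actinsim")

#: Key-parameter value lists of the base study design.  The full cross
#: product over two surfaces has 2·2·2·2·2·3·2 = 192 combinations.
TABLE1_GRID: Dict[str, list] = {
    "nActin": [250, 500],
    "nCofilin": [400, 800],
    "nIntegrin": [100, 200],
    "rCofRegAppearance": [0.5, 2.0],
    "rCofRegDisappearance": [0.5, 2.0],
    "sigmaAngle": [7.5, 15.0, 30.0],
    "surface": ["planar", "pillars"],
}


def run_seed(base_seed: int, run_index: int, replicate: int) -> int:
    """Deterministic per-run seed below 2**31."""
    return int((base_seed * 1_000_003 + run_index * 10_007 + replicate * 101 + 1)
               % (2 ** 31))


@dataclass
class RunResult:
    """One completed run: parameters, seed, and derived observables."""

    params: ModelParams
    seed: int
    state: object
    amounts: pd.DataFrame
    complexes: pd.DataFrame
    summary: dict


def run_scenario(params: ModelParams, seed: Optional[int] = None,
                 engine_params: Optional[EngineParams] = None,
                 snapshot_dir: Optional[Path] = None,
                 n_snapshots: int = 4) -> RunResult:
    """Build and execute one scenario; returns time series plus a summary.

    The summary's regional cofilin fractions are time averages (ratio of
    summed counts) over the second half of the recording, which damps the
    fluctuation of instantaneous counts in small systems.
    """
    if seed is not None:
        params = params.with_(seed=seed)
    state = build_model(params, engine_params=engine_params)
    amounts = AmountRecorder()
    sizes = ComplexSizeRecorder()
    recorders: List = [amounts, sizes]
    if snapshot_dir is not None:
        snapshot_dir = Path(snapshot_dir)
        snapshot_dir.mkdir(parents=True, exist_ok=True)
        recorders.append(_SnapshotRecorder(snapshot_dir, params.tEnd, n_snapshots))
    t0 = _time.perf_counter()
    state.run(params.tEnd, recorders=recorders)
    runtime = _time.perf_counter() - t0

    complexes = extract_filament_complexes(state)
    stats = length_stats(complexes, params.constants.actin_diameter)
    disp = orientation_dispersion(complexes)
    rcs = cofilin_region_fractions(state)
    am = amounts.to_frame()
    half = am[am["time"] >= params.tEnd / 2.0]
    on_t = int(half["cofilin_on_structures"].sum())
    on_a = int(half["active_cofilin_on_structures"].sum())
    bt_t = int(half["cofilin_between"].sum())
    bt_a = int(half["active_cofilin_between"].sum())
    summary = {
        "seed": params.seed,
        "t_end": params.tEnd,
        "runtime_s": runtime,
        "n_complexes": stats.n_complexes,
        "avg_len_particles": stats.avg_main_particles,
        "max_len_particles": stats.max_main_particles,
        "avg_len_um": stats.avg_main_um,
        "max_len_um": stats.max_main_um,
        "dispersion_pct": disp,
        "frac_active_on": on_a / on_t if on_t else None,
        "frac_active_between": bt_a / bt_t if bt_t else None,
        "final_frac_active_on": rcs.fraction_on_structures,
        "final_frac_active_between": rcs.fraction_between,
        "cofilin_share_on": rcs.share_on_structures,
        "mean_active_cofilin": float(am["active_cofilin"].mean()),
        "final_active_cofilin": int(am["active_cofilin"].iloc[-1]),
        "final_focal_integrin": int(am["focal_integrin"].iloc[-1]),
    }
    logger.info("run seed=%s t_end=%s finished in %.1fs: avg_len=%s active_cof=%s",
                params.seed, params.tEnd, runtime,
                summary["avg_len_particles"], summary["final_active_cofilin"])
    return RunResult(params, params.seed, state, am, sizes.to_frame(), summary)


class _SnapshotRecorder:
    """Writes PNG snapshots at start, end and evenly spaced midpoints."""

    def __init__(self, out_dir: Path, t_end: float, n_mid: int):
        times = np.linspace(0.0, t_end, n_mid + 2) if t_end > 0 else np.array([0.0])
        self.pending = list(times)
        self.out_dir = out_dir

    def __call__(self, state):
        while self.pending and state.time >= self.pending[0] - 1e-9:
            t = self.pending.pop(0)
            render_snapshot(state, self.out_dir / f"snapshot_t{t:06.1f}.png")


@dataclass
class ScanSpec:
    """Cross product of parameter value lists, replicated.

    Seeds are derived deterministically from (base_seed, run index,
    replicate); completed runs present in ``out_dir/results.csv`` are skipped
    on re-execution (resumable scans).
    """

    grid: Dict[str, list] = field(default_factory=lambda: dict(TABLE1_GRID))
    replicates: int = 5
    base_seed: int = 0
    out_dir: Optional[Path] = None
    base_params: ModelParams = field(default_factory=ModelParams)
    engine_params: Optional[EngineParams] = None


_PARAM_COLS = ["nActin", "nCofilin", "nIntegrin", "rCofRegAppearance",
               "rCofRegDisappearance", "rCofilinReactivation", "pSevering",
               "pCofDeactAtInt", "sigmaAngle", "surface", "tEnd"]


def _run_key(overrides: dict, replicate: int) -> str:
    items = ",".join(f"{k}={overrides[k]}" for k in sorted(overrides))
    return f"{items}|rep={replicate}"


def run_parameter_scan(spec: ScanSpec) -> pd.DataFrame:
    """Execute every grid combination × replicate; one row per run.

    Invalid combinations (both cofilin-regulation mechanisms enabled) are
    skipped with a logged reason, not errors.
    """
    keys = sorted(spec.grid)
    combos = [dict(zip(keys, vals))
              for vals in itertools.product(*(spec.grid[k] for k in keys))]
    out_path = Path(spec.out_dir) / "results.csv" if spec.out_dir else None
    done: Dict[str, dict] = {}
    if out_path is not None and out_path.exists():
        prior = pd.read_csv(out_path)
        done = {row["run_key"]: row.to_dict() for _, row in prior.iterrows()}
        logger.info("scan resume: %d completed runs found", len(done))
    rows: List[dict] = []
    for run_idx, overrides in enumerate(combos):
        try:
            params = spec.base_params.with_(**overrides)
            params.validate()
        except (ModelConfigError, TypeError) as err:
            logger.warning("skipping combination %s: %s", overrides, err)
            continue
        for rep in range(spec.replicates):
            key = _run_key(overrides, rep)
            if key in done:
                rows.append(done[key])
                continue
            seed = run_seed(spec.base_seed, run_idx, rep)
            result = run_scenario(params, seed=seed,
                                  engine_params=spec.engine_params)
            row = {"run_key": key, "replicate": rep}
            for col in _PARAM_COLS:
                row[col] = getattr(params, col)
            row.update(result.summary)
            rows.append(row)
            if out_path is not None:
                out_path.parent.mkdir(parents=True, exist_ok=True)
                pd.DataFrame(rows).to_csv(out_path, index=False)
    return pd.DataFrame(rows)


def summarize_conditions(results: pd.DataFrame,
                         condition_pairs: Sequence[dict]) -> pd.DataFrame:
    """Per-condition summary table (one row per requested condition).

    Each condition is a dict of column → value filters; replicates matching a
    condition are averaged.  Missing conditions yield a row of NaNs, not an
    error.  Deterministic and idempotent on the same results table.
    """
    out = []
    for cond in condition_pairs:
        sel = results
        for col, val in cond.items():
            if col not in sel.columns:
                sel = sel.iloc[0:0]
                break
            sel = sel[sel[col] == val]
        row = dict(cond)
        row["n_runs"] = len(sel)
        for col in ("frac_active_on", "frac_active_between",
                    "avg_len_particles", "max_len_particles",
                    "avg_len_um", "max_len_um", "dispersion_pct",
                    "mean_active_cofilin"):
            row[col] = float(sel[col].mean()) if len(sel) else float("nan")
        out.append(row)
    return pd.DataFrame(out)
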