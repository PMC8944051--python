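"""Factorial sweeps: parameter sample x strategies x inheritance modes.

One random parameter sample is reused for every strategy x mode cell so
results are comparable across cells.  The solo-use pilot runs that fix
the insecticide order for sequences and rotations are shared within
each inheritance mode.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import MODES
from .params import ModelParams, sample_parameters
from .simulate import MAX_GENERATIONS, determine_order, run_batch
from .strategies import STRATEGIES, StrategySpec

__all__ = ["ExperimentConfig", "run_experiment", "run_sweep_cells"]


@dataclass
class ExperimentConfig:
    n_samples: int
    seed: int
    strategies: tuple = STRATEGIES
    modes: tuple = MODES
    max_gen: int = MAX_GENERATIONS
    out_dir: "str | Path | None" = None   # if set, one CSV per cell + manifest
    resume: bool = True                   # reuse completed cell files

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        for s in self.strategies:
            StrategySpec.of(s)
        unknown = set(self.modes) - set(MODES)
        if unknown:
            raise ValueError(f"unknown inheritance modes: {sorted(unknown)}")


def run_sweep_cells(
    params: ModelParams,
    strategies=STRATEGIES,
    modes=MODES,
    max_gen: int = MAX_GENERATIONS,
    progress=None,
):
    """Yield (mode, strategy, BatchResult) for every cell, sharing pilots per mode."""
    for mode in modes:
        order = None
        if any(StrategySpec.of(s).name in ("sequences", "rotations") for s in strategies):
            order = determine_order(params, mode, max_gen=max_gen)
        for strategy in strategies:
            res = run_batch(params, strategy, mode, max_gen=max_gen, order_first=order)
            if progress is not None:
                progress(mode, StrategySpec.of(strategy).name)
            yield mode, StrategySpec.of(strategy).name, res


def run_experiment(cfg: ExperimentConfig, progress=None) -> pd.DataFrame:
    """Run the full sweep; returns the long results table.

    One row per (parameter set, strategy, mode) carrying the sampled
    parameters, the three measures with their outcome classes and
    encodings, the first-broken locus and the extinction generation.
    With ``out_dir`` set, each cell is written to its own CSV as it
    completes and, when ``resume`` is on, cells whose file already
    exists under a matching manifest are loaded instead of recomputed.
    """
    params = sample_parameters(cfg.n_samples, cfg.seed)
    pframe = params.to_frame()
    pframe.insert(0, "sample_id", np.arange(cfg.n_samples))

    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    manifest = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "n_samples": cfg.n_samples, "seed": cfg.seed,
            "strategies": list(cfg.strategies), "modes": list(cfg.modes),
            "max_gen": cfg.max_gen,
            "params_sha256": hashlib.sha256(
                pframe.to_csv(index=False).encode()).hexdigest(),
        }
        man_path = out_dir / "manifest.json"
        if man_path.exists():
            previous = json.loads(man_path.read_text())
            if previous != manifest:
                raise ValueError(
                    f"{man_path} belongs to a different experiment; "
                    "use a fresh output directory"
                )
        else:
            man_path.write_text(json.dumps(manifest, indent=2))

    frames = []
    for mode in cfg.modes:
        order = None
        for strategy in cfg.strategies:
            name = StrategySpec.of(strategy).name
            cell_path = out_dir / f"results_{mode}_{name}.csv" if out_dir else None
            if cell_path is not None and cfg.resume and cell_path.exists():
                cell = pd.read_csv(cell_path, keep_default_na=False)
            else:
                if order is None and name in ("sequences", "rotations"):
                    order = determine_order(params, mode, max_gen=cfg.max_gen)
                res = run_batch(params, strategy, mode, max_gen=cfg.max_gen,
                                order_first=order)
                cell = pd.concat([pframe, res.to_frame()], axis=1)
                if cell_path is not None:
                    cell.to_csv(cell_path, index=False)
            frames.append(cell)
            if progress is not None:
                progress(mode, name)
    return pd.concat(frames, ignore_index=True)
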