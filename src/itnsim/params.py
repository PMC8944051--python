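"""The 17-parameter framework of the two-locus resistance model.

One :class:`ModelParams` holds the inputs of a single simulation run (or,
with array-valued fields, a whole batch of runs).  The fields are:

========  ==============================================================
``N``     starting population size and carrying capacity (both sexes)
``b``     intrinsic birth rate (per-generation growth factor)
``d``     adult death rate (fraction of breeding adults dying)
``x_f``   female exposure (fraction of females receiving a dose)
``x_m``   male exposure
``m1``    effectiveness of insecticide 1 (kill rate of dosed susceptibles)
``m2``    effectiveness of insecticide 2
``f0_A``  initial resistance-allele frequency at locus A
``f0_B``  initial resistance-allele frequency at locus B
``r_A``   resistance restoration at locus A (return to baseline fitness
          under dosing); ``r_B`` likewise
``hr_A``  dominance of restoration in heterozygotes; ``hr_B`` likewise
``c_A``   resistance cost (mortality of non-dosed carriers); ``c_B``
``hc_A``  dominance of the cost in heterozygotes; ``hc_B``
========  ==============================================================

Insecticide 1 acts on locus A and insecticide 2 on locus B.  Random
sampling follows the published ranges: population size, initial frequency
and resistance cost are drawn log-uniformly, the birth rate from a
standard lognormal (no meaningful upper limit), everything else uniformly
on [0, 1].  Initial frequencies are clamped to [1/N, 1e-2] so every run
starts with at least one resistance copy and at most a 1% frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

__all__ = ["FIELD_ORDER", "ModelParams", "sample_parameters", "validate_params"]

#: Sampling and serialisation order of the 17 parameters (fixed so a
#: single RNG stream yields a reproducible sample).
FIELD_ORDER = (
    "N", "b", "d", "x_f", "x_m", "m1", "m2",
    "f0_A", "f0_B", "r_A", "r_B", "hr_A", "hr_B",
    "c_A", "c_B", "hc_A", "hc_B",
)

_UNIT_FIELDS = (
    "d", "x_f", "x_m", "m1", "m2", "f0_A", "f0_B",
    "r_A", "r_B", "hr_A", "hr_B", "c_A", "c_B", "hc_A", "hc_B",
)

F0_CEILING = 1e-2
COST_LO, COST_HI = 1e-3, 10 ** -0.5


@dataclass
class ModelParams:
    """One parameter set (scalars) or a batch of sets (equal-length arrays)."""

    N: np.ndarray
    b: np.ndarray
    d: np.ndarray
    x_f: np.ndarray
    x_m: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    f0_A: np.ndarray
    f0_B: np.ndarray
    r_A: np.ndarray
    r_B: np.ndarray
    hr_A: np.ndarray
    hr_B: np.ndarray
    c_A: np.ndarray
    c_B: np.ndarray
    hc_A: np.ndarray
    hc_B: np.ndarray

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            setattr(self, f.name, np.atleast_1d(np.asarray(getattr(self, f.name), dtype=float)))
        n = {getattr(self, f.name).shape[0] for f in dc_fields(self)}
        if len(n) != 1:
            raise ValueError(f"parameter fields have inconsistent lengths: {sorted(n)}")

    def __len__(self) -> int:
        return self.N.shape[0]

    def __getitem__(self, idx) -> "ModelParams":
        if np.isscalar(idx) or isinstance(idx, (int, np.integer)):
            idx = [idx]
        return ModelParams(**{name: getattr(self, name)[idx] for name in FIELD_ORDER})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({name: getattr(self, name) for name in FIELD_ORDER})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ModelParams":
        missing = [name for name in FIELD_ORDER if name not in df.columns]
        if missing:
            raise ValueError(f"missing parameter columns: {missing}")
        return cls(**{name: df[name].to_numpy(dtype=float) for name in FIELD_ORDER})

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{name: d[name] for name in FIELD_ORDER})

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        """Load a parameter configuration from a YAML or JSON file.

        Keys are exactly the field names; values may be scalars (one
        run) or equal-length lists (a batch).  The result is validated.
        """
        import json
        from pathlib import Path

        import yaml

        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        missing = [name for name in FIELD_ORDER if name not in data]
        if missing:
            raise ValueError(f"missing parameter keys: {missing}")
        return validate_params(cls.from_dict(data))


def sample_parameters(n: int, seed: int) -> ModelParams:
    """Draw ``n`` parameter sets over the published ranges.

    N is log-uniform on [1e2, 1e9]; f0_A/f0_B log-uniform on [1e-9, 1e-2]
    then clamped to [1/N, 1e-2]; c_A/c_B log-uniform on [1e-3, 10**-0.5];
    b ~ lognormal(mu=0, sigma=1); all remaining parameters uniform on
    [0, 1].  The same (n, seed) always yields a bit-identical sample.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {seed!r}")
    rng = np.random.default_rng(int(seed))
    draws: dict[str, np.ndarray] = {}
    for name in FIELD_ORDER:
        if name == "N":
            draws[name] = 10.0 ** rng.uniform(2.0, 9.0, size=n)
        elif name == "b":
            draws[name] = rng.lognormal(mean=0.0, sigma=1.0, size=n)
        elif name in ("f0_A", "f0_B"):
            draws[name] = 10.0 ** rng.uniform(-9.0, np.log10(F0_CEILING), size=n)
        elif name in ("c_A", "c_B"):
            draws[name] = 10.0 ** rng.uniform(np.log10(COST_LO), np.log10(COST_HI), size=n)
        else:
            draws[name] = rng.uniform(0.0, 1.0, size=n)
    for locus in ("A", "B"):
        draws[f"f0_{locus}"] = _clamp_f0(draws[f"f0_{locus}"], draws["N"])
    return ModelParams(**draws)


def _clamp_f0(f0: np.ndarray, N: np.ndarray) -> np.ndarray:
    # at least one copy (1/N), at most the 1e-2 ceiling; if N < 100 the
    # interval is empty and the one-copy floor wins
    lo = 1.0 / N
    hi = np.maximum(lo, F0_CEILING)
    return np.clip(f0, lo, hi)


def validate_params(p: ModelParams) -> ModelParams:
    """Validate ranges and apply the initial-frequency clamp.

    Raises ``ValueError`` naming the offending field; returns the
    (possibly f0-clamped) parameter set otherwise.
    """
    def _check(name: str, arr: np.ndarray, lo: float, hi: float) -> None:
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"parameter {name} contains non-finite values")
        if np.any(arr < lo) or np.any(arr > hi):
            raise ValueError(f"parameter {name} outside [{lo}, {hi}]")

    if not np.all(np.isfinite(p.N)) or np.any(p.N < 2):
        raise ValueError("parameter N must be finite and >= 2")
    if not np.all(np.isfinite(p.b)) or np.any(p.b < 0):
        raise ValueError("parameter b must be finite and >= 0")
    for name in _UNIT_FIELDS:
        _check(name, getattr(p, name), 0.0, 1.0)
    p.f0_A = _clamp_f0(p.f0_A, p.N)
    p.f0_B = _clamp_f0(p.f0_B, p.N)
    return p
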