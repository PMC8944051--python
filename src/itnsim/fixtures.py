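"""Deterministic oracle cases for validating the recursion end-to-end.

Every case embeds its expected output computed from an independent
closed form or first principle, so the whole package is testable with
no external data:

* haploid solo-use cases — mitochondrial-only inheritance with no adult
  survival (d = 1) and full exposure of both sexes reduces to classical
  haploid selection: the resistant/susceptible frequency ratio grows
  geometrically by w_R/w_S per generation, so the break generation has
  the closed form ceil(log(q0/p0) / log(w_R/w_S));
* neutral cases — no exposure, no costs: allele frequencies must not
  move at all;
* demographic fixed-point cases — insecticide-free, cost-free
  populations started at carrying capacity must stay there;
* planted-rule tables — synthetic labelled feature tables whose label
  depends on known thresholds, for partition-tree recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "HaploidCase", "make_haploid_cases", "make_neutral_params",
    "make_fixed_point_params", "make_planted_rule_table", "make_oracle_cases",
]


def _base_params(n: int) -> dict:
    # b = 2.5 keeps the logistic map parameter b*wbar inside the stable
    # band for any mean fitness, so these cases never crash demographically
    return {
        "N": np.full(n, 1e8), "b": np.full(n, 2.5), "d": np.full(n, 1.0),
        "x_f": np.ones(n), "x_m": np.ones(n),
        "m1": np.full(n, 0.8), "m2": np.zeros(n),
        "f0_A": np.full(n, 1e-3), "f0_B": np.full(n, 1e-3),
        "r_A": np.ones(n), "r_B": np.zeros(n),
        "hr_A": np.zeros(n), "hr_B": np.zeros(n),
        "c_A": np.zeros(n), "c_B": np.zeros(n),
        "hc_A": np.zeros(n), "hc_B": np.zeros(n),
    }


@dataclass(frozen=True)
class HaploidCase:
    """A solo-use haploid selection case with its closed-form break time."""

    params: ModelParams
    expected_break: int


def haploid_break_time(f0: float, m: float, r: float) -> int:
    """Closed-form first generation the haploid resistant frequency exceeds 1/2.

    With fitnesses w_R = 1 - m(1 - r) and w_S = 1 - m, the odds p/q are
    multiplied by lam = w_R/w_S each generation; the frequency first
    exceeds 0.5 at the smallest t with (f0/(1-f0)) * lam**t > 1.
    """
    lam = (1.0 - m * (1.0 - r)) / (1.0 - m)
    if lam <= 1.0:
        raise ValueError("no selection for resistance; allele never breaks")
    t = int(np.ceil(np.log((1.0 - f0) / f0) / np.log(lam)))
    # guard the ceiling against an exact boundary
    odds = f0 / (1.0 - f0)
    while odds * lam ** t <= 1.0:
        t += 1
    while t > 1 and odds * lam ** (t - 1) > 1.0:
        t -= 1
    return t


def make_haploid_cases(n: int = 100, seed: int = 20260928) -> HaploidCase:
    """Randomised solo-use cases with exact expected break generations.

    Drawn so the population persists (large N, growth exceeding the kill
    rate) and the break happens well inside the 500-generation horizon:
    m in [0.3, 0.5], r in [0.8, 1], f0 log-uniform in [1e-6, 1e-3].
    Insecticide 2 is inert (m2 = 0) so locus B never moves.
    """
    rng = np.random.default_rng(seed)
    base = _base_params(n)
    base["m1"] = rng.uniform(0.3, 0.5, size=n)
    base["r_A"] = rng.uniform(0.8, 1.0, size=n)
    base["f0_A"] = 10.0 ** rng.uniform(-6, -3, size=n)
    params = ModelParams(**base)
    expected = np.array([
        haploid_break_time(f0, m, r)
        for f0, m, r in zip(base["f0_A"], base["m1"], base["r_A"])
    ])
    return HaploidCase(params=params, expected_break=expected)


def make_neutral_params(n: int = 20, seed: int = 7) -> ModelParams:
    """No exposure, no costs: allele frequencies are expected constant."""
    rng = np.random.default_rng(seed)
    base = _base_params(n)
    base.update(
        b=rng.uniform(0.5, 2.0, size=n), d=rng.uniform(0.0, 0.9, size=n),
        x_f=np.zeros(n), x_m=np.zeros(n),
        m1=rng.uniform(0, 1, size=n), m2=rng.uniform(0, 1, size=n),
        f0_A=10.0 ** rng.uniform(-4, -2, size=n),
        f0_B=10.0 ** rng.uniform(-4, -2, size=n),
        r_A=rng.uniform(0, 1, size=n), r_B=rng.uniform(0, 1, size=n),
        hr_A=rng.uniform(0, 1, size=n), hr_B=rng.uniform(0, 1, size=n),
    )
    base["N"] = np.full(n, 1e6)
    base["d"] = rng.uniform(0.0, 0.5, size=n)
    return ModelParams(**base)


def make_fixed_point_params(n: int = 10, seed: int = 11) -> ModelParams:
    """Insecticide-free, cost-free, demographically stable (b < 2 + d).

    Expected female and male trajectories: constant at N/2.
    """
    rng = np.random.default_rng(seed)
    base = _base_params(n)
    d = rng.uniform(0.1, 0.9, size=n)
    base.update(
        N=10.0 ** rng.uniform(3, 8, size=n),
        d=d, b=d + rng.uniform(0.2, 1.5, size=n),
        x_f=np.zeros(n), x_m=np.zeros(n),
    )
    return ModelParams(**base)


def make_planted_rule_table(
    n: int = 50_000, seed: int = 3, cut_x: float = 0.3, cut_b: float | None = None
) -> pd.DataFrame:
    """Feature table with a planted label rule for tree recovery.

    Label is 'X' iff x_f > cut_x (and, when ``cut_b`` is given, a second
    nested rule: 'R' iff additionally b < cut_b), else '='.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "x_f": rng.uniform(0, 1, size=n),
        "b": rng.lognormal(0, 1, size=n),
        "m1": rng.uniform(0, 1, size=n),
        "m2": rng.uniform(0, 1, size=n),
    })
    label = np.where(df["x_f"] > cut_x, "X", "=")
    if cut_b is not None:
        label = np.where((df["x_f"] > cut_x) & (df["b"] < cut_b), "R", label)
    df["label"] = label
    return df


def make_oracle_cases(seed: int = 20260928) -> dict:
    """The full deterministic fixture set keyed by oracle family."""
    return {
        "haploid": make_haploid_cases(seed=seed),
        "neutral": make_neutral_params(seed=seed % 1009),
        "fixed_point": make_fixed_point_params(seed=seed % 2003),
        "planted_rule": make_planted_rule_table(n=5000, seed=seed % 4001),
    }
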