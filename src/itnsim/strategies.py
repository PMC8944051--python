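"""Deployment strategies and their per-generation insecticide niches.

Five strategies are compared:

* ``sequences`` — one insecticide in sole use; switches permanently to
  the second once the in-use insecticide's resistance allele first
  exceeds 50% frequency (the lower, "non-strategy" benchmark).
* ``rotations`` — the in-use insecticide switches every 36 generations
  (the recommended three-year net replacement cycle at 12 generations
  per year).
* ``mosaics`` — both insecticides 50% in use; an exposed mosquito
  encounters one or the other with equal chance.
* ``mixtures`` — an exposed mosquito encounters both insecticides at a
  reduced dose rate k chosen so the mixture's initial kill of exposed
  susceptibles equals the (m1 + m2)/2 average kill of the solo
  strategies (like-for-like initial control).
* ``maximum`` — the mixture with k = 1 (full dose of both; the upper
  benchmark).

For sequences and rotations the insecticide order puts the
first-to-break insecticide first, determined by pilot solo-use runs.
A sex with exposure x meets the no-insecticide niche with probability
1 - x and the strategy's niche(s) with the remaining x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STRATEGIES", "COMPARED_STRATEGIES", "StrategySpec", "mixture_rate",
    "niche_probabilities", "rotation_in_use",
]

#: All five strategies, in presentation order.
STRATEGIES = ("sequences", "rotations", "mosaics", "mixtures", "maximum")
#: Strategies entering the 10%-rule comparison (the maximum benchmark
#: would mask the others and is excluded).
COMPARED_STRATEGIES = ("sequences", "rotations", "mosaics", "mixtures")

GENERATIONS_PER_YEAR = 12


@dataclass(frozen=True)
class StrategySpec:
    """A strategy identifier with its tunable deployment constants."""

    name: str
    rotation_period: int = 36
    break_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.name!r}; expected one of {STRATEGIES}")
        if self.rotation_period < 1:
            raise ValueError("rotation_period must be >= 1")
        if not 0.0 < self.break_threshold < 1.0:
            raise ValueError("break_threshold must lie in (0, 1)")

    @classmethod
    def of(cls, spec: "str | StrategySpec") -> "StrategySpec":
        return spec if isinstance(spec, StrategySpec) else cls(spec)


def mixture_rate(m1, m2):
    """Mixture dose rate k equating initial control with the solo average.

    Solves 1 - (1 - k m1)(1 - k m2) = (m1 + m2)/2 for the root in (0, 1]:

        k = [m1 + m2 - sqrt((m1+m2)^2 - 2 m1 m2 (m1+m2))] / (2 m1 m2).

    The radicand equals (m1+m2)(m1(1-m2) + m2(1-m1)) and is non-negative
    on [0,1]^2 (a floating-point clamp is applied).  When m1*m2 = 0 the
    expression is 0/0; the identity's limit gives k = 1/2.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if np.any((m1 < 0) | (m1 > 1) | (m2 < 0) | (m2 > 1)):
        raise ValueError("insecticide effectiveness must lie in [0, 1]")
    s = m1 + m2
    radicand = np.maximum(s ** 2 - 2.0 * m1 * m2 * s, 0.0)
    # equivalent rationalised root s / (s + sqrt(radicand)): no
    # cancellation for small m1*m2, and the m1*m2 -> 0 limit k = 1/2
    # emerges continuously (s = 0 is the only special case)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(s > 0.0, s / (s + np.sqrt(radicand)), 0.5)
    return k if k.ndim else float(k)


def rotation_in_use(generation: int, period: int) -> int:
    """0-based index (0 = first in order) of the rotation block at a 1-based generation."""
    return ((generation - 1) // period) % 2


def niche_probabilities(
    spec: StrategySpec,
    exposure: np.ndarray,
    in_use_first: np.ndarray,
) -> np.ndarray:
    """Per-run niche distribution for one sex, shape (n, 4).

    Columns follow ('-', '1', '2', 'mix').  ``exposure`` is the sex's
    dosing probability x; ``in_use_first`` is a boolean array, True where
    the currently deployed solo insecticide is insecticide 1 (used by
    sequences and rotations; ignored by the simultaneous strategies).
    """
    x = np.atleast_1d(np.asarray(exposure, dtype=float))
    n = x.shape[0]
    probs = np.zeros((n, 4))
    probs[:, 0] = 1.0 - x
    if spec.name in ("sequences", "rotations"):
        first = np.broadcast_to(np.asarray(in_use_first, dtype=bool), (n,))
        probs[:, 1] = np.where(first, x, 0.0)
        probs[:, 2] = np.where(first, 0.0, x)
    elif spec.name == "mosaics":
        probs[:, 1] = x / 2.0
        probs[:, 2] = x / 2.0
    else:  # mixtures, maximum
        probs[:, 3] = x
    return probs
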