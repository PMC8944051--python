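"""Headline summaries of the full strategy x inheritance sweep.

These are the sweep-level statistics the strategy comparison turns on:
how often the mitochondrially-inherited resistance breaks first under
mixed inheritance, how much of the low-exposure parameter space shows
only unmeasurable allele-frequency movement, and how dominant extinction
becomes once the intrinsic birth rate enters the unstable regime.
"""

from __future__ import annotations

import numpy as np

from .analysis import data_type_fraction, first_break_locus_fraction
from .genetics import MODES
from .params import ModelParams
from .strategies import COMPARED_STRATEGIES, STRATEGIES

__all__ = ["headline_summaries"]

LOW_EXPOSURE = 0.3
HIGH_BIRTH = 3.0
HIGH_EFFECTIVENESS = 0.8


def headline_summaries(cells: dict, params: ModelParams) -> dict:
    """Sweep summary statistics, as percentages.

    ``cells`` maps (mode, strategy) to the cell's
    :class:`~itnsim.simulate.BatchResult`; every statistic averages the
    per-strategy fractions over its strategies.  Keys:

    * ``mito_first_pct_MN`` — share of determinable first-to-break
      events under mixed inheritance won by the mitochondrial locus,
      over all five strategies.
    * ``mito_first_pct_MN_high_m1`` — the same among runs where the
      mitochondrial locus's insecticide has effectiveness above 0.8.
    * ``unmeasured_movement_pct_low_exposure_<mode>`` — share of
      first-to-break outcomes that are toward- or away-from-threshold
      (movement too slow to measure) where female exposure is below
      0.3, over the four compared strategies.
    * ``extinction_pct_first_high_exposure_high_birth_<mode>`` — share
      of first-to-break outcomes ending in extinction where female
      exposure exceeds 0.3 and the birth rate exceeds 3.
    * ``extinction_pct_second_high_birth_<mode>`` — share of
      second-to-break outcomes ending in extinction where the birth
      rate exceeds 3.
    """
    low_x = params.x_f < LOW_EXPOSURE
    high_xb = (params.x_f > LOW_EXPOSURE) & (params.b > HIGH_BIRTH)
    high_b = params.b > HIGH_BIRTH
    high_m1 = params.m1 > HIGH_EFFECTIVENESS

    def mn_cells(strategies):
        return [cells[("MN", s)] for s in strategies]

    out = {
        "mito_first_pct_MN":
            100.0 * first_break_locus_fraction(mn_cells(STRATEGIES), "A"),
        "mito_first_pct_MN_high_m1":
            100.0 * first_break_locus_fraction(mn_cells(STRATEGIES), "A", subset=high_m1),
    }
    for mode in MODES:
        compared = [cells[(mode, s)] for s in COMPARED_STRATEGIES]
        out[f"unmeasured_movement_pct_low_exposure_{mode}"] = 100.0 * data_type_fraction(
            compared, "first", ("toward", "away"), subset=low_x)
        out[f"extinction_pct_first_high_exposure_high_birth_{mode}"] = \
            100.0 * data_type_fraction(compared, "first", "extinction", subset=high_xb)
        out[f"extinction_pct_second_high_birth_{mode}"] = 100.0 * data_type_fraction(
            compared, "second", "extinction", subset=high_b)
    return {k: float(np.round(v, 4)) for k, v in out.items()}
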