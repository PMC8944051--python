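"""The per-generation recursion and threshold measures.

A run iterates, for up to 500 generations: niche profile -> sex-specific
fitness -> selection -> random mating -> logistic population update,
then measures the population allele frequencies and the female count.
Three measures are latched at their first crossing:

* first-to-break   — first generation either resistance allele exceeds 50%;
* second-to-break  — first generation the other allele exceeds 50%;
* control-failure  — first generation the female population recovers to
  the 80%-of-initial line after previously having dropped below it.

A run terminates at extinction (female count below one individual) or at
the generation cap.  Unmeasured measures are classified by the net
change between the start and the end of the run: ``toward`` (moving in
the resistance direction), ``away`` (the opposite; ties count as away),
or ``extinction`` which overrides both.  The nominal encodings 1000
(toward), 1500 (away) and 2000 (extinction) rank the unmeasured classes
beyond any measurable time.

Everything is vectorised across a batch of parameter sets; a batch of
size n is bit-identical to n single runs because the recursion never
couples runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import DemographyConfig, calibrate_recruitment, update_population
from .genetics import (
    GenotypeSpace, InheritanceMode, build_genotype_space, genotype_fitness,
    initial_frequencies, mate, apply_selection,
)
from .params import ModelParams
from .strategies import StrategySpec, mixture_rate, rotation_in_use

__all__ = [
    "MEASURES", "DATA_TYPES", "NOMINAL_CODES", "BatchResult",
    "run_batch", "run_simulation", "determine_order",
]

MEASURES = ("first", "second", "control")
DATA_TYPES = ("measured", "toward", "away", "extinction")
#: Nominal values of the unmeasured outcome classes, ranked beyond the
#: 500-generation horizon from shortest to longest.
NOMINAL_CODES = {"toward": 1000.0, "away": 1500.0, "extinction": 2000.0}

MAX_GENERATIONS = 500
CONTROL_FRACTION = 0.8


@dataclass
class BatchResult:
    """Measures and outcome classes for a batch of runs."""

    mode: str
    strategy: str
    t_first: np.ndarray        # generation of first break; 0 = unmeasured
    t_second: np.ndarray
    t_control: np.ndarray
    which_first: np.ndarray    # 'A' / 'B' / '' (indeterminate or none)
    extinct_at: np.ndarray     # generation; 0 = no extinction
    dtype_first: np.ndarray    # entries of DATA_TYPES
    dtype_second: np.ndarray
    dtype_control: np.ndarray
    order_first: np.ndarray    # insecticide used first (1 or 2)
    compensating: np.ndarray   # b <= d: recruitment compensates the birth deficit
    trajectories: dict | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.t_first.shape[0]

    def encode(self, measure: str) -> np.ndarray:
        """Encoded measure: generation count, or the nominal class code."""
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
        t = getattr(self, f"t_{measure}").astype(float)
        dtype = getattr(self, f"dtype_{measure}")
        out = t.copy()
        for name, code in NOMINAL_CODES.items():
            out[dtype == name] = code
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "strategy": self.strategy,
            "mode": self.mode,
            "t_first": self.t_first,
            "t_second": self.t_second,
            "t_control": self.t_control,
            "dtype_first": self.dtype_first,
            "dtype_second": self.dtype_second,
            "dtype_control": self.dtype_control,
            "code_first": self.encode("first"),
            "code_second": self.encode("second"),
            "code_control": self.encode("control"),
            "which_first": self.which_first,
            "extinct_at": self.extinct_at,
            "order_first": self.order_first,
            "compensating": self.compensating,
        })
        return df


def _sex_weight_vectors(
    space: GenotypeSpace, p: ModelParams, strategy: StrategySpec, solo: int | None
) -> dict:
    """Time-invariant fitness vectors per sex; the loop only selects among them."""
    w_minus = genotype_fitness(space, p, "-")
    w_1 = genotype_fitness(space, p, "1")
    w_2 = genotype_fitness(space, p, "2")
    out = {}
    for sex, x in (("f", p.x_f), ("m", p.x_m)):
        keep = (1.0 - x)[:, None] * w_minus
        if solo is not None:
            w_use = w_1 if solo == 1 else w_2
            out[sex] = {"fixed": keep + x[:, None] * w_use}
        elif strategy.name in ("sequences", "rotations"):
            out[sex] = {"use1": keep + x[:, None] * w_1,
                        "use2": keep + x[:, None] * w_2}
        elif strategy.name == "mosaics":
            out[sex] = {"fixed": keep + (x / 2.0)[:, None] * (w_1 + w_2)}
        else:  # mixtures, maximum
            k = mixture_rate(p.m1, p.m2) if strategy.name == "mixtures" else 1.0
            w_mix = genotype_fitness(space, p, "mix", k)
            out[sex] = {"fixed": keep + x[:, None] * w_mix}
    return out


def _slice_cfg(cfg: DemographyConfig, idx: np.ndarray) -> DemographyConfig:
    return DemographyConfig(K_sex=cfg.K_sex[idx], b=cfg.b[idx], d=cfg.d[idx])


def run_batch(
    p: ModelParams,
    strategy: "str | StrategySpec",
    mode: "str | InheritanceMode",
    max_gen: int = MAX_GENERATIONS,
    order_first: np.ndarray | None = None,
    record_trajectories: bool = False,
    _solo: int | None = None,
) -> BatchResult:
    """Run one strategy x inheritance cell over a batch of parameter sets.

    ``order_first`` fixes which insecticide the sequences/rotations
    deployment starts with (1 or 2, per run); if omitted it is derived
    from pilot solo-use runs (first-to-break goes first).  The private
    ``_solo`` switch runs a constant single-insecticide deployment, used
    for those pilots.
    """
    spec = StrategySpec.of(strategy)
    mode = InheritanceMode.from_code(mode)
    space = build_genotype_space(mode)
    n = len(p)
    thr = spec.break_threshold

    needs_order = _solo is None and spec.name in ("sequences", "rotations")
    if needs_order and order_first is None:
        order_first = determine_order(p, mode, spec, max_gen)
    if order_first is None:
        order_first = np.ones(n, dtype=np.int8)
    order_first = np.asarray(order_first, dtype=np.int8)

    cfg = calibrate_recruitment(p)
    W = _sex_weight_vectors(space, p, spec, _solo)
    wA = space.allele_weight("A")
    wB = space.allele_weight("B")

    F0 = initial_frequencies(space, p)
    Ff = F0.copy()
    Fm = F0.copy()
    Nf = cfg.K_sex.copy()
    Nm = cfg.K_sex.copy()
    ctrl_line = CONTROL_FRACTION * cfg.K_sex

    t_A = np.zeros(n, dtype=np.int32)
    t_B = np.zeros(n, dtype=np.int32)
    t_control = np.zeros(n, dtype=np.int32)
    dropped = np.zeros(n, dtype=bool)
    extinct_at = np.zeros(n, dtype=np.int32)
    last_fA = p.f0_A.copy()
    last_fB = p.f0_B.copy()
    # sequences state: currently deployed insecticide is the first in
    # order until its allele first breaks, then the second permanently
    seq_on_first = np.ones(n, dtype=bool)

    traj = {"freq_A": [], "freq_B": [], "N_f": [], "N_m": []} if record_trajectories else None

    active = np.arange(n)
    for gen in range(1, max_gen + 1):
        if active.size == 0:
            break
        sub = active
        if _solo is not None or spec.name in ("mosaics", "mixtures", "maximum"):
            Wf, Wm = W["f"]["fixed"][sub], W["m"]["fixed"][sub]
        else:
            if spec.name == "rotations":
                block = rotation_in_use(gen, spec.rotation_period)
                in_use = order_first[sub] if block == 0 else (3 - order_first[sub])
                use1 = in_use == 1
            else:  # sequences
                in_use = np.where(seq_on_first[sub], order_first[sub], 3 - order_first[sub])
                use1 = in_use == 1
            Wf = np.where(use1[:, None], W["f"]["use1"][sub], W["f"]["use2"][sub])
            Wm = np.where(use1[:, None], W["m"]["use1"][sub], W["m"]["use2"][sub])

        post_f, wbar_f = apply_selection(Ff[sub], Wf)
        post_m, wbar_m = apply_selection(Fm[sub], Wm)
        off = mate(space, post_f, post_m)
        Nf_n, Nm_n, Ff_n, Fm_n = update_population(
            Nf[sub], Nm[sub], post_f, post_m, wbar_f, wbar_m, off, _slice_cfg(cfg, sub)
        )
        Nf[sub], Nm[sub], Ff[sub], Fm[sub] = Nf_n, Nm_n, Ff_n, Fm_n

        ext = Nf_n < 1.0
        extinct_at[sub[ext]] = gen

        live = sub[~ext]
        if live.size:
            cf = np.maximum(Nf[live], 0.0)
            cm = np.maximum(Nm[live], 0.0)
            tot = cf + cm
            wt_f = (cf / tot)[:, None]
            wt_m = (cm / tot)[:, None]
            blended = wt_f * Ff[live] + wt_m * Fm[live]
            fA = blended @ wA
            fB = blended @ wB
            last_fA[live] = fA
            last_fB[live] = fB

            newA = (t_A[live] == 0) & (fA > thr)
            newB = (t_B[live] == 0) & (fB > thr)
            t_A[live[newA]] = gen
            t_B[live[newB]] = gen

            rec = (t_control[live] == 0) & dropped[live] & (Nf[live] >= ctrl_line[live])
            t_control[live[rec]] = gen
            dropped[live] |= Nf[live] < ctrl_line[live]

            if spec.name == "sequences" and _solo is None:
                on_first = seq_on_first[live]
                first_is_1 = order_first[live] == 1
                first_broken = np.where(first_is_1, t_A[live] > 0, t_B[live] > 0)
                seq_on_first[live[on_first & first_broken]] = False

        if record_trajectories:
            for key, arr in (("freq_A", last_fA), ("freq_B", last_fB), ("N_f", Nf), ("N_m", Nm)):
                row = np.full(n, np.nan)
                row[sub] = arr[sub]
                traj[key].append(row)

        if _solo is not None:
            # pilots only need the target allele's crossing time
            target_done = (t_A if _solo == 1 else t_B)[sub] > 0
            done = ext | target_done
        else:
            # a later crash reclassifies the whole run as extinction, so
            # runs must play out to the horizon even once all measures
            # have latched
            done = ext
        active = sub[~done]

    return _assemble_result(
        p, spec, mode, t_A, t_B, t_control, extinct_at, dropped,
        last_fA, last_fB, order_first, p.b <= p.d,
        {k: np.array(v) for k, v in traj.items()} if traj else None,
    )


def _assemble_result(p, spec, mode, t_A, t_B, t_control, extinct_at, dropped,
                     last_fA, last_fB, order_first, compensating, traj) -> BatchResult:
    n = t_A.shape[0]
    extinct = extinct_at > 0
    big = np.iinfo(np.int32).max
    tA_ = np.where(t_A > 0, t_A, big)
    tB_ = np.where(t_B > 0, t_B, big)
    t_first = np.minimum(tA_, tB_)
    t_second = np.maximum(tA_, tB_)
    first_crossed = t_first < big
    second_crossed = t_second < big
    t_first = np.where(first_crossed, t_first, 0).astype(np.int32)
    t_second = np.where(second_crossed, t_second, 0).astype(np.int32)

    which_first = np.full(n, "", dtype="<U1")
    which_first[(t_A > 0) & ((t_B == 0) | (t_A < t_B))] = "A"
    which_first[(t_B > 0) & ((t_A == 0) | (t_B < t_A))] = "B"

    # net allele-frequency change start -> end; movement below the noise
    # band counts as no movement, and no movement ties to 'away'
    eps = 1e-12
    dA = last_fA - p.f0_A
    dB = last_fB - p.f0_B

    # extinction is a run-level outcome: a population that crashes has
    # escaped resistance (and control failure) altogether, so it
    # overrides an earlier threshold crossing for every measure —
    # successful measurement and extinction are mutually exclusive
    dtype_first = np.full(n, "measured", dtype="<U10")
    dtype_first[extinct] = "extinction"
    um = ~first_crossed & ~extinct
    rising_any = np.maximum(dA, dB) > eps
    dtype_first[um & rising_any] = "toward"
    dtype_first[um & ~rising_any] = "away"

    dtype_second = np.full(n, "measured", dtype="<U10")
    dtype_second[extinct] = "extinction"
    um2 = ~second_crossed & ~extinct
    # the lagging allele decides: the unbroken locus if one has broken,
    # else the slower-moving of the two
    lag_delta = np.where(t_A > 0, dB, np.where(t_B > 0, dA, np.minimum(dA, dB)))
    dtype_second[um2 & (lag_delta > eps)] = "toward"
    dtype_second[um2 & ~(lag_delta > eps)] = "away"

    dtype_control = np.full(n, "measured", dtype="<U10")
    dtype_control[extinct] = "extinction"
    um3 = (t_control == 0) & ~extinct
    dtype_control[um3 & dropped] = "toward"
    dtype_control[um3 & ~dropped] = "away"

    return BatchResult(
        mode=mode.code, strategy=spec.name,
        t_first=t_first, t_second=t_second, t_control=t_control,
        which_first=which_first, extinct_at=extinct_at,
        dtype_first=dtype_first, dtype_second=dtype_second,
        dtype_control=dtype_control, order_first=order_first,
        compensating=compensating, trajectories=traj,
    )


def determine_order(
    p: ModelParams,
    mode: "str | InheritanceMode",
    spec: "str | StrategySpec" = "sequences",
    max_gen: int = MAX_GENERATIONS,
) -> np.ndarray:
    """First-deployed insecticide (1 or 2) per run: the first-to-break goes first.

    Each insecticide is piloted in constant solo use under the same
    parameters; the one whose resistance allele crosses the break
    threshold earlier is deployed first.  Ties and double non-breaks
    default to insecticide 1.
    """
    spec = StrategySpec.of(spec)
    pilot1 = run_batch(p, spec, mode, max_gen=max_gen, _solo=1)
    pilot2 = run_batch(p, spec, mode, max_gen=max_gen, _solo=2)

    def target_time(pilot: BatchResult, locus: str) -> np.ndarray:
        big = np.iinfo(np.int32).max
        t = np.full(len(pilot), big, dtype=np.int64)
        first = (pilot.t_first > 0) & np.isin(pilot.which_first, (locus, ""))
        t[first] = pilot.t_first[first]
        other = (pilot.which_first != locus) & (pilot.which_first != "") & (pilot.t_second > 0)
        t[other] = pilot.t_second[other]
        return t

    tA = target_time(pilot1, "A")
    tB = target_time(pilot2, "B")
    return np.where(tB < tA, 2, 1).astype(np.int8)


def run_simulation(
    p: ModelParams,
    strategy: "str | StrategySpec",
    mode: "str | InheritanceMode",
    max_gen: int = MAX_GENERATIONS,
    record_trajectories: bool = False,
) -> BatchResult:
    """Single-run convenience wrapper around :func:`run_batch`."""
    if len(p) != 1:
        raise ValueError("run_simulation expects a single parameter set; use run_batch")
    return run_batch(p, strategy, mode, max_gen=max_gen,
                     record_trajectories=record_trajectories)
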