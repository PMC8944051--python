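"""Logistic population dynamics with overlapping generations.

Each sex is tracked separately with carrying capacity K = N/2.  The
population count follows a discrete logistic driven by the intrinsic
birth rate b, with density dependence attributed to offspring only
(larval competition in breeding sites) and measured against the
post-selection female pool that produces them:

    births   = b * A_f * (1 - A_f / K),
    N_s'     = A_s + births,

where A_s = wbar_s * N_s are the post-selection adults of sex s.  The
adult death rate d does not change the count — at the insecticide-free
equilibrium recruitment replaces deaths exactly, which is what keeps an
unexposed population constant at its carrying capacity for every b and
d — but it sets the composition of the next generation: a fraction
(1 - d) of adults survives with the post-selection adult genotype
frequencies, and the recruited remainder

    R_s = d * A_s + births

carries the offspring frequencies.  Equivalently, the per-generation
female map is N -> wbar*N*(1 + b*(1 - wbar*N/K)), a logistic map with
multiplier mu = wbar*(1 + b): stable below mu = 3, bounded oscillations
and chaos up to mu = 4, and for mu > 4 the overshoot escapes below zero
— recorded as extinction when the female count drops under one
individual.  For an unexposed population that threshold is b = 3; this
boom-and-crash behaviour at extreme birth rates is an intended property
of the model, not a numerical artefact.  The births term is deliberately
not clamped at zero for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = ["DemographyConfig", "calibrate_recruitment", "recruit", "update_population"]


@dataclass
class DemographyConfig:
    """Demographic constants for a batch of runs."""

    K_sex: np.ndarray  # carrying capacity per sex, N/2
    b: np.ndarray
    d: np.ndarray


def calibrate_recruitment(p: ModelParams) -> DemographyConfig:
    """Demographic configuration with the carrying-capacity calibration.

    The density term vanishes at the carrying capacity by construction,
    so at the insecticide-free equilibrium recruitment is exactly d*K —
    replacing the dying adults and keeping both sexes at N/2 for every
    birth and death rate.
    """
    return DemographyConfig(K_sex=p.N / 2.0, b=p.b.copy(), d=p.d.copy())


def recruit(A_f: np.ndarray, A_s: np.ndarray, cfg: DemographyConfig) -> np.ndarray:
    """Recruited offspring of one sex: R_s = d*A_s + b*A_f*(1 - A_f/K).

    Unclamped; a strongly overshooting female pool makes the births term
    negative (the crash regime).
    """
    births = cfg.b * A_f * (1.0 - A_f / cfg.K_sex)
    return cfg.d * A_s + births


def update_population(
    N_f: np.ndarray,
    N_m: np.ndarray,
    freq_f_post: np.ndarray,
    freq_m_post: np.ndarray,
    wbar_f: np.ndarray,
    wbar_m: np.ndarray,
    freq_off: np.ndarray,
    cfg: DemographyConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One demographic step; returns (N_f', N_m', freq_f', freq_m').

    Post-selection adults A_s = N_s * wbar_s; a fraction (1 - d)
    survives with the adult frequencies; recruitment d*A_s + births
    joins with the offspring frequencies.  If the male mean fitness is
    zero no offspring are produced and the recruited compartment keeps
    the adult frequencies.  Negative births contribute no offspring to
    the frequency blend; the count arithmetic keeps the crash.
    """
    A_f = N_f * wbar_f
    A_m = N_m * wbar_m
    no_fathers = wbar_m <= 0.0
    births = cfg.b * A_f * (1.0 - A_f / cfg.K_sex)
    births = np.where(no_fathers, 0.0, births)

    S_f = (1.0 - cfg.d) * A_f
    S_m = (1.0 - cfg.d) * A_m
    # the whole recruited pool (death replacement + the density-dependent
    # birth surplus) is newborn; without fathers it is empty
    R_f = np.where(no_fathers, 0.0, cfg.d * A_f + births)
    R_m = np.where(no_fathers, 0.0, cfg.d * A_m + births)
    N_f_next = S_f + R_f
    N_m_next = S_m + R_m

    def blend(S, R, f_adult):
        w_off = np.maximum(R, 0.0)  # negative recruitment adds no offspring
        tot = S + w_off
        safe = np.where(tot > 0.0, tot, 1.0)[:, None]
        out = (S[:, None] * f_adult + w_off[:, None] * freq_off) / safe
        return np.where(tot[:, None] > 0.0, out, f_adult)

    return (
        N_f_next, N_m_next,
        blend(S_f, R_f, freq_f_post),
        blend(S_m, R_m, freq_m_post),
    )
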