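"""Genotype spaces, fitness, selection and random mating.

Each of the two resistance loci is either nuclear (diploid genotypes
ss/Rs/RR) or mitochondrial (maternally inherited, effectively haploid:
S/R).  The three studied combinations are NN, MN (locus A mitochondrial,
locus B nuclear) and MM, with 9, 6 and 4 joint genotypes respectively.

Genotype ordering is locus A major, locus B minor, susceptible first:
for NN the order is (ss,ss), (ss,Rs), (ss,RR), (Rs,ss), ..., (RR,RR).

Fitness is multiplicative survival across the niche's hazards.  Against a
present insecticide j (dosed at rate ``delta``, 1 for solo niches and the
mixture rate k for the combined niche) a genotype g survives with

    s_j(g) = 1 - delta * m_j * (1 - rho_i(g) * r_i),

where ``rho`` is the genotype's resistance expression at the targeted
locus i (0 for susceptibles, the dominance ``hr`` for nuclear
heterozygotes, 1 for RR or haploid R).  When a locus's insecticide is
absent from the niche its carriers pay the fitness cost

    q_i(g) = 1 - gamma_i(g) * c_i,

with ``gamma`` the cost expression (0 / hc / 1).  The four niches
multiply the applicable factors: '-' -> qA*qB, '1' -> s1*qB,
'2' -> qA*s2, 'mix' -> s1*s2 at delta = k (both loci dosed, no costs).

All public functions are vectorised over a batch of n parameter sets;
frequency vectors have shape (n, G).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "NUCLEAR", "MITOCHONDRIAL", "MODES", "InheritanceMode", "GenotypeSpace",
    "build_genotype_space", "initial_frequencies", "genotype_fitness",
    "sex_fitness", "apply_selection", "mate", "allele_frequencies",
]

NUCLEAR = "nuclear"
MITOCHONDRIAL = "mitochondrial"

#: The three studied locus-inheritance combinations.
MODES = ("NN", "MN", "MM")

NICHES = ("-", "1", "2", "mix")

_NUC_LABELS = ("ss", "Rs", "RR")
_MITO_LABELS = ("S", "R")

# Nuclear transmission: offspring genotype distribution given parent
# genotypes, free recombination between loci.  T3[gf, gm, go].
_P_GAMETE = np.array([0.0, 0.5, 1.0])
_T_NUC = np.empty((3, 3, 3))
for _gf in range(3):
    for _gm in range(3):
        _pf, _pm = _P_GAMETE[_gf], _P_GAMETE[_gm]
        _T_NUC[_gf, _gm] = (
            (1 - _pf) * (1 - _pm),
            _pf * (1 - _pm) + (1 - _pf) * _pm,
            _pf * _pm,
        )
# Mitochondrial transmission: offspring haplotype equals the mother's.
_T_MITO = np.zeros((2, 2, 2))
_T_MITO[0, :, 0] = 1.0
_T_MITO[1, :, 1] = 1.0


@dataclass(frozen=True)
class InheritanceMode:
    """Per-locus mode of inheritance for loci A and B."""

    mode_A: str
    mode_B: str

    @classmethod
    def from_code(cls, code: "str | InheritanceMode") -> "InheritanceMode":
        if isinstance(code, InheritanceMode):
            return code
        if code not in MODES:
            raise ValueError(f"unknown inheritance mode {code!r}; expected one of {MODES}")
        to_mode = {"N": NUCLEAR, "M": MITOCHONDRIAL}
        return cls(to_mode[code[0]], to_mode[code[1]])

    @property
    def code(self) -> str:
        return ("M" if self.mode_A == MITOCHONDRIAL else "N") + (
            "M" if self.mode_B == MITOCHONDRIAL else "N"
        )


@dataclass(frozen=True)
class GenotypeSpace:
    """Enumerated joint genotypes for one inheritance combination.

    ``code_A``/``code_B`` give, per genotype, the per-locus state index:
    the number of resistance alleles for a nuclear locus (0/1/2) or the
    haplotype (0=S, 1=R) for a mitochondrial locus.
    """

    mode: InheritanceMode
    labels: tuple[str, ...]
    code_A: np.ndarray = field(repr=False)
    code_B: np.ndarray = field(repr=False)
    transmission: np.ndarray = field(repr=False)  # (G, G, G): mother, father, offspring

    @property
    def size(self) -> int:
        return len(self.labels)

    def _locus(self, locus: str):
        if locus == "A":
            return self.mode.mode_A, self.code_A
        return self.mode.mode_B, self.code_B

    def resistance_expression(self, locus: str, hr: np.ndarray) -> np.ndarray:
        """rho per genotype, shape (n, G); ``hr`` is the batch dominance."""
        mode, code = self._locus(locus)
        hr = np.atleast_1d(np.asarray(hr, dtype=float))[:, None]
        if mode == MITOCHONDRIAL:
            return np.broadcast_to((code == 1).astype(float), (hr.shape[0], self.size)).copy()
        return (code == 2).astype(float) + (code == 1) * hr

    def cost_expression(self, locus: str, hc: np.ndarray) -> np.ndarray:
        """gamma per genotype, shape (n, G); same 0/h/1 pattern as rho."""
        return self.resistance_expression(locus, hc)

    def allele_weight(self, locus: str) -> np.ndarray:
        """Per-genotype contribution to the locus allele frequency.

        Nuclear: Rs counts 1/2, RR counts 1.  Mitochondrial: carrier
        frequency (R counts 1).
        """
        mode, code = self._locus(locus)
        return code / 2.0 if mode == NUCLEAR else code.astype(float)


def _locus_states(mode: str):
    if mode == NUCLEAR:
        return _NUC_LABELS, np.arange(3), _T_NUC
    if mode == MITOCHONDRIAL:
        return _MITO_LABELS, np.arange(2), _T_MITO
    raise ValueError(f"unknown locus inheritance {mode!r}")


def build_genotype_space(mode: "str | InheritanceMode") -> GenotypeSpace:
    """Enumerate the joint genotypes of an inheritance combination."""
    mode = InheritanceMode.from_code(mode)
    labels_A, codes_A, T_A = _locus_states(mode.mode_A)
    labels_B, codes_B, T_B = _locus_states(mode.mode_B)
    nA, nB = len(codes_A), len(codes_B)
    labels = tuple(f"{la}/{lb}" for la in labels_A for lb in labels_B)
    code_A = np.repeat(codes_A, nB)
    code_B = np.tile(codes_B, nA)
    # joint transmission factorises across loci (unlinked / independent
    # mechanisms); build T[(af,bf),(am,bm),(ao,bo)] = T_A * T_B
    T = np.einsum("ijk,lmn->iljmkn", T_A, T_B).reshape(nA * nB, nA * nB, nA * nB)
    code_A.setflags(write=False)
    code_B.setflags(write=False)
    T.setflags(write=False)
    return GenotypeSpace(mode, labels, code_A, code_B, T)


def initial_frequencies(space: GenotypeSpace, p: ModelParams) -> np.ndarray:
    """Starting genotype frequencies, shape (n, G).

    Hardy–Weinberg proportions within each nuclear locus at the initial
    allele frequency, haplotype frequencies for mitochondrial loci, and
    linkage equilibrium between the loci.
    """
    def marginal(locus: str, f0: np.ndarray) -> np.ndarray:
        mode, code = space._locus(locus)
        f0 = f0[:, None]
        if mode == MITOCHONDRIAL:
            return np.where(code == 1, f0, 1.0 - f0)
        return np.where(
            code == 2, f0 ** 2,
            np.where(code == 1, 2.0 * f0 * (1.0 - f0), (1.0 - f0) ** 2),
        )

    return marginal("A", p.f0_A) * marginal("B", p.f0_B)


def genotype_fitness(
    space: GenotypeSpace, p: ModelParams, niche: str, dose_rate: "float | np.ndarray" = 1.0
) -> np.ndarray:
    """Fitness of every genotype in one insecticide niche, shape (n, G)."""
    if niche not in NICHES:
        raise ValueError(f"unknown niche {niche!r}; expected one of {NICHES}")
    delta = np.atleast_1d(np.asarray(dose_rate, dtype=float))
    if np.any(delta <= 0) or np.any(delta > 1):
        raise ValueError("dose rate must lie in (0, 1]")
    delta = delta[:, None]

    rho_A = space.resistance_expression("A", p.hr_A)
    rho_B = space.resistance_expression("B", p.hr_B)
    gam_A = space.cost_expression("A", p.hc_A)
    gam_B = space.cost_expression("B", p.hc_B)
    s1 = 1.0 - delta * p.m1[:, None] * (1.0 - rho_A * p.r_A[:, None])
    s2 = 1.0 - delta * p.m2[:, None] * (1.0 - rho_B * p.r_B[:, None])
    qA = 1.0 - gam_A * p.c_A[:, None]
    qB = 1.0 - gam_B * p.c_B[:, None]
    if niche == "-":
        return qA * qB
    if niche == "1":
        return s1 * qB
    if niche == "2":
        return qA * s2
    return s1 * s2


def sex_fitness(
    space: GenotypeSpace,
    p: ModelParams,
    niche_probs: np.ndarray,
    mix_rate: "float | np.ndarray" = 1.0,
) -> np.ndarray:
    """Expected fitness over a sex's niche distribution, shape (n, G).

    ``niche_probs`` has shape (n, 4) with columns in :data:`NICHES` order
    ('-', '1', '2', 'mix'); each row must sum to 1.  ``mix_rate`` is the
    dose rate of the combined niche (ignored when its probability is 0).
    """
    niche_probs = np.atleast_2d(np.asarray(niche_probs, dtype=float))
    if niche_probs.shape[1] != len(NICHES):
        raise ValueError(f"niche_probs must have {len(NICHES)} columns")
    if np.any(niche_probs < -1e-12) or np.any(np.abs(niche_probs.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("niche probabilities must be non-negative and sum to 1")
    w = np.zeros((niche_probs.shape[0], space.size))
    for j, niche in enumerate(NICHES):
        pj = niche_probs[:, j]
        if not np.any(pj > 0):
            continue
        rate = mix_rate if niche == "mix" else 1.0
        w += pj[:, None] * genotype_fitness(space, p, niche, rate)
    return w


def apply_selection(freq: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Post-selection frequencies and mean fitness.

    Returns ``(freq * w / wbar, wbar)``; where ``wbar`` is 0 (total kill)
    the frequencies are left unchanged and the caller must treat the sex
    as dead.
    """
    wbar = np.einsum("ng,ng->n", freq, w)
    safe = np.where(wbar > 0.0, wbar, 1.0)[:, None]
    post = np.where(wbar[:, None] > 0.0, freq * w / safe, freq)
    return post, wbar


def mate(space: GenotypeSpace, freq_f: np.ndarray, freq_m: np.ndarray) -> np.ndarray:
    """Offspring genotype frequencies from random mating, shape (n, G).

    The cross-product of maternal and paternal post-selection frequency
    vectors gives the mating-pair matrix; each pair contributes its
    Mendelian (nuclear) / maternal (mitochondrial) offspring distribution.
    Offspring frequencies are identical for daughters and sons.  Linkage
    disequilibrium in the parents is propagated, not erased.
    """
    n, G = freq_f.shape
    pairs = (freq_f[:, :, None] * freq_m[:, None, :]).reshape(n, G * G)
    return pairs @ space.transmission.reshape(G * G, G)


def allele_frequencies(
    space: GenotypeSpace,
    freq_f: np.ndarray,
    freq_m: np.ndarray,
    N_f: np.ndarray,
    N_m: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Population resistance-allele frequencies (freq_A, freq_B).

    Count-weighted over the sexes.  Nuclear loci count heterozygotes as
    one half; mitochondrial loci report the carrier frequency across all
    individuals of both sexes.
    """
    total = N_f + N_m
    if np.any(total <= 0):
        raise ValueError("allele frequencies undefined for an empty population")
    wf = (N_f / total)[:, None]
    wm = (N_m / total)[:, None]
    blended = wf * freq_f + wm * freq_m
    fA = blended @ space.allele_weight("A")
    fB = blended @ space.allele_weight("B")
    return fA, fB
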