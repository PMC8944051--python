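# Methods

## Scope

`itnsim` implements a deterministic model of selection at two
insecticide-resistance loci in a mosquito population under five ITN
deployment strategies, with logistic population dynamics, a
17-parameter random-sweep harness, and the downstream analyses
(soft-cutoff strategy classification, permutation-test recursive
partitioning, probability-of-resistance, binned trend curves). The
model describes the evolutionary pressure of selection only: there is
no mutation, migration or drift, so it speaks to how fast a
*pre-existing* rare resistance allele spreads, not to how long one
takes to arise.

## Parameters and sampling

The 17 parameters (`itnsim.params.ModelParams`) and their sampling
ranges: population size N log-uniform on [1e2, 1e9]; intrinsic birth
rate b lognormal(0, 1) (no meaningful upper limit; the majority of
draws are demographically stable); adult death rate, exposures,
effectivenesses, restorations and all dominance coefficients uniform on
[0, 1]; initial allele frequencies log-uniform on [1e-9, 1e-2] then
clamped to [1/N, 1e-2]; costs log-uniform on [1e-3, 10^-0.5]. The clamp
reads the admissible initial-frequency range as "at least one copy, at
most 1%": a stated bound of "N/100" cannot be a frequency for N > 100,
but N/100 *copies* of the allele is exactly the 1% ceiling, so the two
bounds are 1/N and 1e-2. Fields are drawn in a fixed order from one
seeded generator, so a sample is reproducible bit-for-bit.

## Fitness

Survival factors multiply across the hazards present in an
individual's niche. Against insecticide j at dose rate δ, genotype g
survives with s_j(g) = 1 − δ·m_j·(1 − ρ_i(g)·r_i); restoration r scales
down the *killed fraction*, and the expression ρ is 0/h^r/1 for nuclear
ss/Rs/RR and 0/1 for mitochondrial S/R (the haploid states take the
homozygote values; dominance parameters are inert at a mitochondrial
locus). A locus whose insecticide is absent from the niche imposes its
cost: q_i(g) = 1 − γ_i(g)·c_i with γ the same 0/h^c/1 pattern. The four
niches combine as: none → q_A·q_B; insecticide 1 only → s_1·q_B;
2 only → q_A·s_2; both (mixture, dose k) → s_1·s_2 with δ = k and no
costs (both loci are dosed). Males use the identical construction with
the male exposure x_m: the parameter set defines a male dosing
probability, so males are dosable; note that selection on a
mitochondrial locus in males has no transgenerational effect, because
fathers do not transmit it.

Two design points were genuinely open and are resolved here as the
package's own choices: costs are read per-insecticide ("non-dosed"
means the niche lacks *that locus's* insecticide, so an individual in
the insecticide-1 niche pays the locus-B cost), and the mixture's
reduced dose scales the encounter-level effectiveness *before*
restoration applies (k is a property of the niche, not the genotype).

## Mating and inheritance

Post-selection female and male genotype-frequency vectors are crossed
into a mating matrix; each pair contributes offspring by independent
Mendelian segregation per nuclear locus (loci unlinked, r = 1/2 — no
linkage map is specified for the two loci, and a mitochondrial–nuclear
pair is unlinked by mechanism) and by maternal transmission at
mitochondrial loci. Offspring frequencies are identical for daughters
and sons (equal sex ratio). The transmission tensor is exact, so
selection-built linkage disequilibrium propagates rather than being
erased; runs start at linkage equilibrium and Hardy–Weinberg
proportions at the initial allele frequencies.

## Population dynamics

Each sex is a continuous count with carrying capacity K = N/2. With
post-selection adults A_s = w̄_s·N_s, the next census is

    N_s' = A_s + b·A_f·(1 − A_f/K),

i.e. a discrete logistic driven by the post-selection females, with
density dependence attributed to offspring only (larval competition).
The adult death rate d does not change the census — at the
insecticide-free equilibrium the recruited pool d·A_s + births exactly
replaces dying adults, which is what holds an unexposed population at
its carrying capacity for *every* b and d — but it sets the next
generation's gene-pool composition: surviving adults (1 − d)·A_s keep
the post-selection adult frequencies, the recruited pool carries the
offspring frequencies (negative birth terms contribute no offspring to
the blend). If the male mean fitness is zero, no offspring are
produced at all.

This form was chosen over alternatives (Beverton–Holt recruitment; a
death-debited logistic) because it is the only simple logistic
consistent with three facts at once: an unexposed population must stay
at K for any birth/death combination, including b < d; populations
under mild pressure must persist rather than drain deterministically;
and the female map multiplier must be w̄·(1 + b), whose logistic-map
escape at multiplier 4 produces the observed boom-and-crash extinctions
precisely above b ≈ 3 in unexposed populations. The birth term is
deliberately unclamped: an overshooting female pool goes negative and
the run is recorded as extinct when the female count drops below one
individual. Exposure *stabilises* this regime (it lowers the
multiplier), and resistance that restores mean fitness can tip a
depressed b > 3 population back into the crash — rescue followed by
collapse.

## Strategies

Sequences deploy the first-in-order insecticide until its resistance
allele first exceeds 50%, then switch permanently. Rotations switch
every 36 generations (three years at 12 generations/year; only used
for reporting conversions). Mosaics put x/2 on each solo niche.
Mixtures use the combined niche at rate k with

    k = (m₁ + m₂) / [(m₁ + m₂) + sqrt((m₁ + m₂)² − 2·m₁·m₂·(m₁ + m₂))],

the root of the control-equivalence identity
1 − (1 − k·m₁)(1 − k·m₂) = (m₁ + m₂)/2 written in rationalised form —
numerically stable for small m₁·m₂ and yielding the continuity limit
k = 1/2 when either effectiveness is zero. Maximum is the mixture at
k = 1. For sequences and rotations the insecticide order puts the
first-to-break first, decided per parameter set by two pilot solo-use
runs (ties and double non-breaks default to insecticide 1); rotations
start the first 36-generation block with that insecticide at
generation 1. Insecticides are never withdrawn after their allele
breaks except by the sequence switch; break flags latch at the first
crossing even if the frequency later falls back.

## Measures and outcome classes

Allele frequencies (count-weighted over the sexes; heterozygotes count
one half, mitochondrial frequency is the carrier frequency over both
sexes) and the female count are evaluated after the full generation
update; threshold times are 1-based first-crossing generations.
First-/second-to-break latch at >50% allele frequency; control failure
latches at the first recovery to ≥80% of N/2 after a previous drop
below that line.

Extinction (female count < 1) terminates the run and is a *run-level*
outcome: it overrides every measure, including an earlier crossing,
because a crashed population has escaped resistance and control failure
altogether. Successful measurement and extinction are therefore
mutually exclusive, and the nominal codes — toward 1000, away 1500,
extinction 2000 — rank the unmeasured classes beyond any measurable
time. Unmeasured, non-extinct measures are classed by the net
allele-frequency change between start and end: first-to-break follows
the faster-moving locus, second-to-break the lagging one (the unbroken
locus if one broke). Net changes within 1e-12 count as no movement,
and no movement ties to 'away'; the control measure is 'away' if the
population never dropped below the 80% line, 'toward' if it dropped
and had not recovered.

## Analyses

Strategy comparison encodes each run as its measured generation count
or nominal code and applies a soft 10% rule on the relative difference
|a − b|/max(a, b) over the four compared strategies (the maximum
benchmark would mask the rest and is excluded): the best strategy and
all within 10% of it win if every member is separated from every
non-member by more than 10%, else '='. The relative (not absolute)
difference is used because the rule is applied to encoded values
spanning generations and nominal codes; the denominator choice is
isolated in one helper. Per-strategy labels (most /
equal-most-with-some / equal-most-all / not-most) are reported
alongside rather than resolving the soft rule's intransitivity.

The partition tree is a transparent re-implementation of
conditional-inference-style recursive partitioning: per node and
feature, the test statistic is the maximum Pearson chi-square over a
quantile grid of candidate cutpoints (at most 100), its null
distribution obtained from 499 label permutations; p-values are
Bonferroni-corrected over features and the most significant feature
splits at its statistic-maximising cutpoint. Growth stops at
alpha = 0.05 (the source analysis reports p-values but no alpha; 0.05
is this package's choice) or when a child would hold less than 5% of
the full data. Exact leaf-for-leaf agreement with any reference tree
library is a non-goal; the contract is recovery of dominant splits,
which the tests pin with planted rules.

Trend curves round the x variable to 101 equally spaced grid points,
take per-bin means with ±1.96·SE intervals, and smooth mean and bounds
with a backward-tail moving average of length 5 (early bins average
their available predecessors; empty or single-point bins yield missing
values that are skipped inside other windows, never interpolated).

## Problem sizes and numerical choices

The sweep harness reuses one parameter sample across all 15
strategy × inheritance cells. The replication experiment and the
acceptance script use 50,000 parameter sets — a scale a vectorised
single-CPU run completes in minutes while keeping Monte-Carlo error on
the summary fractions near two tenths of a point. The engine is
vectorised across runs (the recursion never couples them; a batch is
bit-identical to independent single runs), keeps the four niche fitness
vectors precomputed per cell, and retires runs only at extinction or
the 500-generation horizon. All counts are continuous; frequency
vectors renormalise only through selection and blending and are
conserved to 1e-12.

## What the synthetic fixtures do and do not show

The oracle fixtures (`itnsim.fixtures`) are constructed cases with
embedded expected outputs: haploid solo-use runs whose break
generations have a geometric-selection closed form (full exposure, no
adult survival, birth rate chosen so the logistic map stays in its
stable band for any mean fitness); neutral runs whose frequencies must
not move; demographically stable fixed-point runs; and labelled tables
with planted threshold rules for the tree. They validate the
recursion's arithmetic, transmission and calibration exactly — they do
not emulate field data, and passing them says nothing about parameter
values that describe any real vector population.

## Known limitations

The originally published framework's per-genotype fitness expressions
and explicit population-update equations are not publicly stated in
closed form; the fitness algebra and logistic form above are the
reconstruction most consistent with the parameters' verbal definitions
and with the reported sweep behaviour, and the replication suite
documents where the reconstruction's summary statistics land relative
to the reported ones. The mitochondrial-first fraction under
mixed inheritance reproduces the reported value almost exactly, and
the high-birth-rate extinction fractions land within about six points;
the low-exposure unmeasured-movement fractions differ more (the
reconstruction breaks nuclear resistance somewhat more often at low
female exposure), and its mitochondrial-first fraction responds more
steeply to the mitochondrial insecticide's effectiveness. The model has
no spatial structure, no ITN decay or coverage dynamics, no seasonality,
no stochasticity, and one adult-survival parameter in place of age
structure.
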