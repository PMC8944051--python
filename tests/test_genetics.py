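import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itnsim import (
    allele_frequencies, apply_selection, build_genotype_space,
    genotype_fitness, initial_frequencies, mate, sex_fitness,
)
from tests.conftest import single_params


def brute_force_offspring(space, freq_f, freq_m):
    """Independent oracle: enumerate every mating pair and transmit each
    locus by first principles (Mendelian gametes / maternal haplotype)."""

    def locus_transmission(mode, gf, gm, go):
        if mode == "mitochondrial":
            return 1.0 if go == gf else 0.0
        pf, pm = gf / 2.0, gm / 2.0
        probs = {
            0: (1 - pf) * (1 - pm),
            1: pf * (1 - pm) + (1 - pf) * pm,
            2: pf * pm,
        }
        return probs[go]

    G = space.size
    out = np.zeros(G)
    for i in range(G):          # mother
        for j in range(G):      # father
            w = freq_f[i] * freq_m[j]
            if w == 0:
                continue
            for o in range(G):  # offspring
                out[o] += w * locus_transmission(
                    space.mode.mode_A, space.code_A[i], space.code_A[j], space.code_A[o]
                ) * locus_transmission(
                    space.mode.mode_B, space.code_B[i], space.code_B[j], space.code_B[o]
                )
    return out


class TestGenotypeSpace:
    @pytest.mark.parametrize("mode, size", [("NN", 9), ("MN", 6), ("MM", 4)])
    def test_sizes(self, mode, size):
        assert build_genotype_space(mode).size == size

    def test_mixed_mode_expression_levels(self):
        space = build_genotype_space("MN")
        rho_A = space.resistance_expression("A", np.array([0.7]))[0]
        rho_B = space.resistance_expression("B", np.array([0.3]))[0]
        assert set(np.round(rho_A, 12)) == {0.0, 1.0}          # haploid locus
        assert set(np.round(rho_B, 12)) == {0.0, 0.3, 1.0}     # dominance-scaled

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            build_genotype_space("NX")


class TestFitness:
    def test_susceptible_survival_is_one_minus_kill(self):
        space = build_genotype_space("NN")
        p = single_params(m1=0.8, c_B=0.2)
        w = genotype_fitness(space, p, "1")[0]
        # fully susceptible genotype: survival 1 - m1, no cost at B (ss)
        idx = space.labels.index("ss/ss")
        assert w[idx] == pytest.approx(0.2)

    def test_full_restoration_cancels_kill(self):
        space = build_genotype_space("NN")
        p = single_params(m1=0.8, r_A=1.0, c_B=0.0)
        w = genotype_fitness(space, p, "1")[0]
        assert w[space.labels.index("RR/ss")] == pytest.approx(1.0)

    def test_heterozygote_partial_restoration(self):
        space = build_genotype_space("NN")
        p = single_params(m1=1.0, r_A=0.8, hr_A=0.5, c_B=0.0)
        w = genotype_fitness(space, p, "1")[0]
        # 1 - 1*(1 - 0.5*0.8) = 0.4: dominance scales the restored fraction
        assert w[space.labels.index("Rs/ss")] == pytest.approx(0.4)

    def test_haploid_carrier_pays_full_cost(self):
        space = build_genotype_space("MM")
        p = single_params(c_A=0.1, c_B=0.0)
        w = genotype_fitness(space, p, "-")[0]
        assert w[space.labels.index("R/S")] == pytest.approx(0.9)

    def test_mixture_dose_scales_kill(self):
        space = build_genotype_space("NN")
        p = single_params(m1=0.8, m2=0.6)
        w = genotype_fitness(space, p, "mix", dose_rate=0.5)[0]
        idx = space.labels.index("ss/ss")
        assert w[idx] == pytest.approx((1 - 0.5 * 0.8) * (1 - 0.5 * 0.6))

    def test_invalid_niche_and_dose(self):
        space = build_genotype_space("NN")
        p = single_params()
        with pytest.raises(ValueError, match="niche"):
            genotype_fitness(space, p, "both")
        with pytest.raises(ValueError, match="dose"):
            genotype_fitness(space, p, "mix", dose_rate=0.0)


class TestSexFitness:
    def test_unexposed_sex_sees_only_costs(self):
        space = build_genotype_space("NN")
        p = single_params(c_A=0.2, c_B=0.1, m1=0.9)
        probs = np.array([[1.0, 0.0, 0.0, 0.0]])
        w = sex_fitness(space, p, probs)
        np.testing.assert_allclose(w, genotype_fitness(space, p, "-"))

    def test_mosaic_weighted_average(self):
        space = build_genotype_space("NN")
        p = single_params(m1=0.8, m2=0.8)
        # x = 0.5 split half-half across the two solo niches
        probs = np.array([[0.5, 0.25, 0.25, 0.0]])
        w = sex_fitness(space, p, probs)[0]
        assert w[space.labels.index("ss/ss")] == pytest.approx(0.6)

    def test_profile_must_normalise(self):
        space = build_genotype_space("NN")
        with pytest.raises(ValueError, match="sum to 1"):
            sex_fitness(space, single_params(), np.array([[0.5, 0.2, 0.1, 0.0]]))


class TestSelection:
    def test_uniform_fitness_is_neutral(self, rng):
        f = rng.dirichlet(np.ones(9), size=3)
        post, wbar = apply_selection(f, np.full((3, 9), 0.7))
        np.testing.assert_allclose(post, f)
        np.testing.assert_allclose(wbar, 0.7)

    def test_lethal_genotype_removed(self):
        post, wbar = apply_selection(np.array([[0.5, 0.5]]), np.array([[1.0, 0.0]]))
        np.testing.assert_allclose(post, [[1.0, 0.0]])
        assert wbar[0] == pytest.approx(0.5)

    def test_hand_computed_three_genotypes(self):
        f = np.array([[0.25, 0.5, 0.25]])
        w = np.array([[1.0, 0.5, 0.25]])
        post, wbar = apply_selection(f, w)
        assert wbar[0] == pytest.approx(0.5625)
        np.testing.assert_allclose(post[0], [4 / 9, 4 / 9, 1 / 9], atol=1e-12)

    def test_total_kill_signalled_by_zero_mean(self):
        post, wbar = apply_selection(np.array([[0.3, 0.7]]), np.zeros((1, 2)))
        assert wbar[0] == 0.0
        np.testing.assert_allclose(post, [[0.3, 0.7]])  # left untouched for the caller


class TestMating:
    def test_monomorphic_parents(self):
        space = build_genotype_space("NN")
        f = np.zeros((1, 9))
        f[0, 0] = 1.0
        np.testing.assert_allclose(mate(space, f, f), f)

    def test_hardy_weinberg_from_arbitrary_genotypes(self):
        # one segregating nuclear locus: offspring must land on HWE of the
        # parental allele frequencies whatever the parental genotype mix
        space = build_genotype_space("NN")
        f = np.zeros((1, 9))
        f[0, space.labels.index("ss/ss")] = 0.4   # allele freq at A: 0.3
        f[0, space.labels.index("Rs/ss")] = 0.2
        f[0, space.labels.index("RR/ss")] = 0.4
        off = mate(space, f, f)[0]
        p = 0.4 + 0.2 / 2
        assert off[space.labels.index("ss/ss")] == pytest.approx((1 - p) ** 2, abs=1e-12)
        assert off[space.labels.index("Rs/ss")] == pytest.approx(2 * p * (1 - p), abs=1e-12)
        assert off[space.labels.index("RR/ss")] == pytest.approx(p ** 2, abs=1e-12)

    def test_maternal_inheritance_exact(self):
        space = build_genotype_space("MM")
        mothers = np.array([[0.7, 0.0, 0.3, 0.0]])  # 30% R at locus A, all S at B
        fathers = np.array([[0.0, 0.0, 1.0, 0.0]])  # all R at locus A
        off = mate(space, mothers, fathers)[0]
        freq_A = off @ space.allele_weight("A")
        assert freq_A == pytest.approx(0.3, abs=1e-15)

    def test_mixed_mode_transmission(self):
        space = build_genotype_space("MN")
        mother = np.zeros((1, 6))
        mother[0, space.labels.index("R/Rs")] = 1.0
        father = np.zeros((1, 6))
        father[0, space.labels.index("S/ss")] = 1.0
        off = mate(space, mother, father)[0]
        assert off[space.labels.index("R/Rs")] == pytest.approx(0.5)
        assert off[space.labels.index("R/ss")] == pytest.approx(0.5)

    @pytest.mark.parametrize("mode", ["NN", "MN", "MM"])
    def test_matches_brute_force_with_linkage_disequilibrium(self, mode, rng):
        # correlated parental vectors: mating must propagate, not erase, LD
        space = build_genotype_space(mode)
        for _ in range(5):
            f_f = rng.dirichlet(np.ones(space.size) * 0.3)
            f_m = rng.dirichlet(np.ones(space.size) * 0.3)
            got = mate(space, f_f[None, :], f_m[None, :])[0]
            expected = brute_force_offspring(space, f_f, f_m)
            np.testing.assert_allclose(got, expected, atol=1e-13)
            assert got.sum() == pytest.approx(1.0, abs=1e-12)


class TestAlleleFrequencies:
    def test_fixed_resistant(self):
        space = build_genotype_space("NN")
        f = np.zeros((1, 9))
        f[0, space.labels.index("RR/RR")] = 1.0
        fA, fB = allele_frequencies(space, f, f, np.array([10.0]), np.array([10.0]))
        assert fA[0] == 1.0 and fB[0] == 1.0

    def test_heterozygotes_count_half(self):
        space = build_genotype_space("NN")
        f = np.zeros((1, 9))
        for lab, v in (("ss/ss", 0.25), ("Rs/ss", 0.5), ("RR/ss", 0.25)):
            f[0, space.labels.index(lab)] = v
        fA, _ = allele_frequencies(space, f, f, np.array([5.0]), np.array([5.0]))
        assert fA[0] == pytest.approx(0.5)

    def test_count_weighting_across_sexes(self):
        space = build_genotype_space("MM")
        females = np.zeros((1, 4))
        females[0, space.labels.index("R/S")] = 1.0
        males = np.zeros((1, 4))
        males[0, space.labels.index("S/S")] = 1.0
        fA, _ = allele_frequencies(space, females, males,
                                   np.array([100.0]), np.array([300.0]))
        assert fA[0] == pytest.approx(0.25)

    def test_empty_population_rejected(self):
        space = build_genotype_space("MM")
        f = np.full((1, 4), 0.25)
        with pytest.raises(ValueError, match="empty"):
            allele_frequencies(space, f, f, np.array([0.0]), np.array([0.0]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 32 - 1), st.sampled_from(["NN", "MN", "MM"]))
def test_selection_and_mating_conserve_frequency_mass(seed, mode):
    rng = np.random.default_rng(seed)
    space = build_genotype_space(mode)
    f = rng.dirichlet(np.ones(space.size), size=2)
    w = rng.uniform(0, 1, size=(2, space.size))
    w[:, 0] = np.maximum(w[:, 0], 1e-3)  # keep mean fitness positive
    post, _ = apply_selection(f, w)
    off = mate(space, post, post[::-1])
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(off.sum(axis=1), 1.0, atol=1e-12)


def test_initial_frequencies_are_hwe_and_linkage_equilibrium():
    space = build_genotype_space("NN")
    p = single_params(f0_A=0.01, f0_B=0.2)
    F = initial_frequencies(space, p)[0]
    iA = {0: 0.99 ** 2, 1: 2 * 0.01 * 0.99, 2: 0.01 ** 2}
    iB = {0: 0.8 ** 2, 1: 2 * 0.2 * 0.8, 2: 0.2 ** 2}
    for g in range(space.size):
        assert F[g] == pytest.approx(iA[space.code_A[g]] * iB[space.code_B[g]], abs=1e-15)
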