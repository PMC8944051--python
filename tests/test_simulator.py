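import numpy as np
import pytest

from itnsim import run_batch, run_simulation, sample_parameters
from itnsim.fixtures import make_neutral_params
from tests.conftest import single_params


class TestClosedFormOracle:
    def test_haploid_selection_break_generation(self):
        # mitochondrial-only, no adult survival, full exposure: the
        # resistant/susceptible odds grow by w_R/w_S = 5 per generation
        # from 1e-3, crossing 1/2 at generation ceil(ln(999)/ln(5)) = 5
        p = single_params(N=1e8, b=2.5, d=1.0, x_f=1.0, x_m=1.0,
                          m1=0.8, m2=0.0, f0_A=1e-3, r_A=1.0)
        res = run_batch(p, "sequences", "MM", order_first=np.array([1]))
        assert res.t_first[0] == 5
        assert res.which_first[0] == "A"
        assert res.dtype_first[0] == "measured"


class TestNeutrality:
    def test_frequencies_invariant_without_selection(self):
        p = make_neutral_params(n=10, seed=3)
        res = run_batch(p, "mosaics", "MN", max_gen=50, record_trajectories=True)
        fA = res.trajectories["freq_A"]
        fB = res.trajectories["freq_B"]
        np.testing.assert_allclose(fA[-1], p.f0_A, atol=1e-12)
        np.testing.assert_allclose(fB[-1], p.f0_B, atol=1e-12)
        assert np.all(np.isin(res.dtype_first, ("away",)))  # zero net change ties to away


class TestOutcomes:
    def test_no_births_means_extinction(self):
        p = single_params(b=0.0, d=0.9, x_f=1.0, x_m=1.0, m1=0.9, m2=0.9)
        res = run_batch(p, "mixtures", "NN")
        assert res.dtype_first[0] == "extinction"
        assert res.extinct_at[0] > 0

    def test_extinction_overrides_an_earlier_crossing(self):
        # resistance breaks, restores mean fitness and tips the b > 3
        # logistic into its crash regime: the run ends as an extinction
        # even though a crossing time was recorded on the way
        p = single_params(N=1e6, b=5.0, d=0.5, x_f=0.9, x_m=0.9,
                          m1=0.85, m2=0.0, f0_A=1e-3, r_A=1.0)
        res = run_batch(p, "sequences", "MM", order_first=np.array([1]))
        assert res.t_first[0] > 0
        assert res.extinct_at[0] > res.t_first[0]
        assert res.dtype_first[0] == "extinction"

    def test_second_break_never_precedes_first(self):
        p = sample_parameters(300, seed=123)
        res = run_batch(p, "mosaics", "MN")
        both = (res.t_first > 0) & (res.t_second > 0)
        assert np.all(res.t_second[both] >= res.t_first[both])

    def test_control_failure_requires_drop_then_recovery(self):
        # strong initial kill depresses the females below 80% of N/2;
        # resistance restores fitness and the population recovers
        p = single_params(N=1e6, b=2.0, d=0.5, x_f=0.8, x_m=0.8,
                          m1=0.9, m2=0.0, f0_A=1e-2, r_A=1.0, hr_A=1.0)
        res = run_batch(p, "sequences", "MM", order_first=np.array([1]),
                        record_trajectories=True)
        Nf = res.trajectories["N_f"][:, 0]
        line = 0.8 * p.N[0] / 2
        t = res.t_control[0]
        assert t > 0
        assert Nf[t - 1] >= line            # recovered at the latched generation
        assert np.min(Nf[: t - 1]) < line   # after having dropped below

    def test_maximum_kills_at_least_as_hard_as_mixtures(self):
        # the full-dose benchmark's survival never exceeds the
        # reduced-dose mixture's, genotype by genotype
        from itnsim import build_genotype_space, genotype_fitness, mixture_rate

        p = sample_parameters(50, seed=7)
        space = build_genotype_space("NN")
        k = mixture_rate(p.m1, p.m2)
        w_mix = genotype_fitness(space, p, "mix", k)
        w_max = genotype_fitness(space, p, "mix", 1.0)
        assert np.all(w_max <= w_mix + 1e-12)


class TestDeterminismAndBatching:
    def test_bit_identical_reruns(self):
        p = sample_parameters(40, seed=5)
        a = run_batch(p, "rotations", "MN", max_gen=120)
        b = run_batch(p, "rotations", "MN", max_gen=120)
        for field in ("t_first", "t_second", "t_control", "which_first",
                      "extinct_at", "dtype_first", "dtype_second", "dtype_control"):
            np.testing.assert_array_equal(getattr(a, field), getattr(b, field))

    def test_batch_equals_independent_single_runs(self):
        p = sample_parameters(12, seed=9)
        batch = run_batch(p, "mixtures", "MM", max_gen=150)
        for i in range(len(p)):
            single = run_simulation(p[i], "mixtures", "MM", max_gen=150)
            assert single.t_first[0] == batch.t_first[i]
            assert single.t_second[0] == batch.t_second[i]
            assert single.dtype_first[0] == batch.dtype_first[i]
            assert single.extinct_at[0] == batch.extinct_at[i]

    def test_run_simulation_rejects_batches(self):
        with pytest.raises(ValueError, match="single"):
            run_simulation(sample_parameters(2, seed=1), "mixtures", "NN")


class TestEncoding:
    def test_nominal_codes(self):
        p = sample_parameters(400, seed=21)
        res = run_batch(p, "mosaics", "NN", max_gen=80)
        enc = res.encode("first")
        assert np.all(enc[res.dtype_first == "measured"] == res.t_first[res.dtype_first == "measured"])
        assert np.all(enc[res.dtype_first == "toward"] == 1000)
        assert np.all(enc[res.dtype_first == "away"] == 1500)
        assert np.all(enc[res.dtype_first == "extinction"] == 2000)

    def test_unknown_measure_rejected(self):
        p = single_params()
        res = run_batch(p, "mosaics", "NN", max_gen=5)
        with pytest.raises(ValueError, match="measure"):
            res.encode("third")


class TestSequencesSwitching:
    def test_second_insecticide_selects_only_after_switch(self):
        # insecticide 2 comes into use only once allele A has broken, so
        # allele B starts rising from its initial frequency at that point
        p = single_params(N=1e8, b=2.5, d=1.0, x_f=1.0, x_m=1.0,
                          m1=0.5, m2=0.5, f0_A=1e-3, f0_B=1e-3,
                          r_A=1.0, r_B=1.0, c_A=0.0, c_B=0.0)
        res = run_batch(p, "sequences", "MM", order_first=np.array([1]),
                        record_trajectories=True)
        tA = res.t_first[0]
        fB = res.trajectories["freq_B"][:, 0]
        assert res.which_first[0] == "A"
        np.testing.assert_allclose(fB[: tA], p.f0_B[0], atol=1e-12)
        assert fB[tA + 1] > p.f0_B[0]
        assert res.t_second[0] > tA
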