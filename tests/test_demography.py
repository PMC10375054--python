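"""Neutrality tests, mismatch-distribution model and fitting, expansion dating."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mitopop as mp
from mitopop.demography import (
    FS_SIGNIFICANCE_LEVEL,
    _subset_stats,
    raggedness,
    tajima_constants,
)
from mitopop.errors import ConfigurationError, UndefinedStatisticError
from mitopop.simulate import (
    mismatch_from_genealogy,
    mutation_counts,
    simulate_genealogy,
)

from conftest import random_alignment


class TestTajimasD:
    def test_constants_hand_evaluated_n5(self):
        # a1 = 1 + 1/2 + 1/3 + 1/4 = 25/12, a2 = 1 + 1/4 + 1/9 + 1/16
        c = tajima_constants(5)
        assert c["a1"] == pytest.approx(25 / 12)
        assert c["a2"] == pytest.approx(1 + 0.25 + 1 / 9 + 1 / 16)
        assert c["b1"] == pytest.approx(6 / 12)
        assert c["b2"] == pytest.approx(2 * 33 / (9 * 5 * 4))

    def test_toy_alignment_matches_hand_formula(self):
        aln = mp.SequenceAlignment(
            ("a", "b", "c", "d", "e"),
            ("P",) * 5,
            ("AAAAA", "AAAAT", "AAATT", "AAAAA", "GAAAA"),
        )
        n, s, k_hat = _subset_stats(aln)
        assert (n, s) == (5, 3)
        # k_hat by direct pair count: pairs and their differences
        assert k_hat == pytest.approx(14 / 10)
        c = tajima_constants(5)
        expected = (k_hat - s / c["a1"]) / math.sqrt(
            c["e1"] * s + c["e2"] * s * (s - 1)
        )
        assert mp.tajimas_d(aln) == pytest.approx(expected, rel=1e-12)

    def test_no_segregating_sites_is_nan(self):
        aln = mp.SequenceAlignment(
            tuple("abcd"), ("P",) * 4, ("AAAA",) * 4
        )
        with pytest.warns(UserWarning):
            assert math.isnan(mp.tajimas_d(aln))

    def test_small_sample_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            mp.tajimas_d_from_stats(3, 2, 1.0)

    def test_agrees_with_dendropy(self):
        import dendropy
        from dendropy.calculate import popgenstat

        aln = mp.simulate_coalescent(
            mp.CoalescentParams(n_per_deme=(12,), theta=4.0, seed=9)
        ).alignment
        mat = dendropy.DnaCharacterMatrix.from_dict(
            dict(zip(aln.ids, aln.sequences))
        )
        assert mp.tajimas_d(aln) == pytest.approx(
            popgenstat.tajimas_d(mat), rel=1e-12
        )

    def test_neutral_simulations_center_near_zero(self):
        rng = np.random.default_rng(31)
        ds = []
        for _ in range(1000):
            gen = simulate_genealogy(30, rng)
            muts = mutation_counts(gen, 5.0, rng)
            s, k_hat, _ = mp.simulate.branch_statistics(gen, muts)
            if s > 0:
                ds.append(mp.tajimas_d_from_stats(30, s, k_hat))
        assert abs(np.mean(ds)) < 0.15


class TestTajimaDPvalue:
    def test_central_value_has_large_p(self):
        p = mp.tajima_d_pvalue(0.0, n=30, s_obs=10, n_sims=400, seed=1)
        assert p > 0.5

    def test_expansion_fixture_is_significant(self):
        rng = np.random.default_rng(77)
        gen = simulate_genealogy(40, rng, tau_event=0.02, growth_factor=100.0)
        muts = mutation_counts(gen, 60.0, rng)
        s, k_hat, _ = mp.simulate.branch_statistics(gen, muts)
        d = mp.tajimas_d_from_stats(40, s, k_hat)
        assert d < -1.5
        p = mp.tajima_d_pvalue(d, n=40, s_obs=s, n_sims=400, seed=2)
        assert p < 0.05

    def test_reproducible_given_seed(self):
        p1 = mp.tajima_d_pvalue(-1.0, n=20, s_obs=8, n_sims=300, seed=9)
        p2 = mp.tajima_d_pvalue(-1.0, n=20, s_obs=8, n_sims=300, seed=9)
        assert p1 == p2


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k) by exhaustive enumeration over integer partitions (oracle)."""
    from collections import Counter

    def partitions(m, maxpart=None):
        if maxpart is None:
            maxpart = m
        if m == 0:
            yield ()
            return
        for p in range(min(m, maxpart), 0, -1):
            for rest in partitions(m - p, p):
                yield (p,) + rest

    pk = np.zeros(n + 1)
    rising = np.prod([theta + i for i in range(n)])
    for lam in partitions(n):
        mult = Counter(lam)
        weight = math.factorial(n) / (
            np.prod([part for part in lam])
            * np.prod([math.factorial(m) for m in mult.values()])
        )
        pk[len(lam)] += weight * theta ** len(lam) / rising
    return pk


class TestFusFs:
    def test_single_haplotype_is_positive_infinity(self):
        assert mp.fus_fs(10, 1, 2.0) == float("inf")

    def test_n4_theta1_exact_enumeration(self):
        # |s(4,k)| = (6, 11, 6, 1); rising factorial 1*2*3*4 = 24
        probs = np.array([6, 11, 6, 1]) / 24
        for k in (2, 3, 4):
            s_prime = probs[k - 1 :].sum()
            expected = math.log(s_prime / (1 - s_prime))
            assert mp.fus_fs(4, k, 1.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("theta", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_matches_partition_enumeration(self, n, theta):
        pk = ewens_k_distribution(n, theta)
        for k in range(2, n + 1):
            s_prime = pk[k:].sum()
            expected = math.log(s_prime / (1 - s_prime))
            assert mp.fus_fs(n, k, theta) == pytest.approx(expected, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            mp.fus_fs(5, 6, 1.0)
        with pytest.raises(UndefinedStatisticError):
            mp.fus_fs(5, 3, 0.0)

    def test_large_sample_is_finite(self):
        # Stirling recursion must stay stable at study-scale n
        fs = mp.fus_fs(390, 84, 1.3)
        assert math.isfinite(fs)
        assert fs < 0  # many haplotypes for small theta -> excess of alleles


class TestFsPvalue:
    def test_expansion_fixture_is_significant(self):
        rng = np.random.default_rng(55)
        gen = simulate_genealogy(40, rng, tau_event=0.02, growth_factor=100.0)
        muts = mutation_counts(gen, 60.0, rng)
        s, k_hat, k_obs = mp.simulate.branch_statistics(gen, muts)
        fs = mp.fus_fs(40, k_obs, k_hat)
        assert fs < 0
        p = mp.fs_pvalue(fs, 40, k_hat, n_sims=400, seed=3)
        assert p < FS_SIGNIFICANCE_LEVEL

    def test_reproducible_given_seed(self):
        p1 = mp.fs_pvalue(-1.0, 15, 2.0, n_sims=200, seed=4)
        p2 = mp.fs_pvalue(-1.0, 15, 2.0, n_sims=200, seed=4)
        assert p1 == p2

    def test_null_fs_has_moderate_p(self):
        # Fs computed at roughly the null centre should not be significant
        p = mp.fs_pvalue(0.0, 15, 2.0, n_sims=400, seed=5)
        assert 0.1 < p < 0.95


class TestMismatchObserved:
    def test_monomorphic_point_mass_at_zero(self):
        aln = mp.SequenceAlignment(("a", "b", "c"), ("P",) * 3, ("AAAA",) * 3)
        obs = mp.mismatch_observed(aln)
        assert obs.tolist() == [1.0]

    def test_pair_three_differences(self):
        aln = mp.SequenceAlignment(("a", "b"), ("P", "P"), ("AAAAA", "TTTAA"))
        obs = mp.mismatch_observed(aln)
        assert obs.tolist() == [0.0, 0.0, 0.0, 1.0]

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_pair_enumeration(self, seed):
        import itertools

        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=int(rng.integers(2, 8)), L=8)
        obs = mp.mismatch_observed(aln)
        diffs = [
            sum(1 for x, y in zip(a, b) if x != y)
            for a, b in itertools.combinations(aln.sequences, 2)
        ]
        expected = np.bincount(diffs, minlength=len(obs)) / len(diffs)
        assert np.allclose(obs, expected)
        assert obs.sum() == pytest.approx(1.0, abs=1e-9)


class TestMismatchExpected:
    def test_reduces_to_geometric_equilibrium(self):
        theta = 1.0
        e = mp.mismatch_expected(0.0, theta, theta, 60)
        i = np.arange(61)
        geometric = theta**i / (1 + theta) ** (i + 1)
        assert np.abs(e - geometric).max() < 1e-12

    @given(
        st.floats(0, 20),
        st.floats(0, 10),
        st.floats(0, 1000),
        st.integers(2, 40),
    )
    def test_normalised_and_nonnegative(self, tau, theta0, theta1, d_max):
        e = mp.mismatch_expected(tau, theta0, theta1, d_max)
        assert (e >= 0).all()
        assert e.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_numerical_integration(self):
        # independent route: integrate Poisson(i; s) against the
        # piecewise-exponential coalescence-time density of a pair
        from scipy.integrate import quad

        tau, th0, th1, d_max = 1.5, 0.5, 100.0, 30

        def class_prob(i):
            recent, _ = quad(
                lambda s: (1 / th1)
                * math.exp(-s / th1)
                * math.exp(-s)
                * s**i
                / math.factorial(i),
                0,
                tau,
            )
            ancestral, _ = quad(
                lambda w: (1 / th0)
                * math.exp(-w / th0)
                * math.exp(-(tau + w))
                * (tau + w) ** i
                / math.factorial(i),
                0,
                80,
            )
            return recent + math.exp(-tau / th1) * ancestral

        oracle = np.array([class_prob(i) for i in range(d_max + 1)])
        oracle /= oracle.sum()
        ours = mp.mismatch_expected(tau, th0, th1, d_max)
        assert np.abs(ours - oracle).max() < 1e-10


class TestFit:
    def test_recovers_exact_model_input(self):
        obs = mp.mismatch_expected(1.0, 0.5, 50.0, 20)
        fit = mp.fit_sudden_expansion(obs)
        assert fit.ssd < 1e-12
        assert abs(fit.tau - 1.0) / 1.0 < 0.10

    def test_ssd_zero_at_fitted_params(self):
        obs = mp.mismatch_expected(2.0, 1.0, 100.0, 25)
        fit = mp.fit_sudden_expansion(obs)
        refit_exp = mp.mismatch_expected(fit.tau, fit.theta0, fit.theta1, 25)
        assert np.sum((obs - refit_exp) ** 2) == pytest.approx(fit.ssd, abs=1e-15)

    def test_degenerate_single_class_returns_boundary(self):
        with pytest.warns(UserWarning):
            fit = mp.fit_sudden_expansion(np.array([1.0, 0.0]))
        assert fit.tau == 0.0

    def test_ssd_invariant_to_zero_padding(self):
        obs = mp.mismatch_expected(1.0, 0.5, 50.0, 12)
        fit = mp.fit_sudden_expansion(obs)
        padded = np.concatenate([obs, np.zeros(6)])
        fit_padded = mp.fit_sudden_expansion(padded / padded.sum())
        assert fit_padded.ssd == pytest.approx(fit.ssd, abs=1e-8)

    def test_raggedness_formula(self):
        # x = (0.5, 0.3, 0.2), appended 0: (0.2)^2 + (0.1)^2 + (0.2)^2
        assert raggedness([0.5, 0.3, 0.2]) == pytest.approx(0.04 + 0.01 + 0.04)


class TestGofBootstrap:
    def test_reproducible_given_seed(self):
        obs = mp.mismatch_expected(1.5, 0.5, 50.0, 10)
        fit = mp.fit_sudden_expansion(obs)
        with pytest.warns(UserWarning):
            p1 = mp.gof_bootstrap(fit, 20, n_boot=30, seed=7)
            p2 = mp.gof_bootstrap(fit, 20, n_boot=30, seed=7)
        assert p1 == p2

    def test_gross_misfit_has_small_p(self):
        # strongly bimodal observed vector: no unimodal expansion curve fits
        obs = np.zeros(21)
        obs[0] = 0.5
        obs[20] = 0.5
        fit = mp.fit_sudden_expansion(obs)
        p_ssd, _ = mp.gof_bootstrap(fit, 50, n_boot=100, seed=8)
        assert p_ssd < 0.05

    def test_calibration_under_the_fitted_model(self):
        # data generated under an expansion model, fitted, then bootstrapped:
        # the SSD p-value should be roughly uniform (well above 0.05 in the
        # large majority of trials)
        rng = np.random.default_rng(101)
        ps = []
        for t in range(60):
            gen = simulate_genealogy(40, rng, tau_event=0.05, growth_factor=50.0)
            muts = mutation_counts(gen, 40.0, rng)
            obs = mismatch_from_genealogy(gen, muts)
            if len(obs) < 2:
                obs = np.append(obs, 0.0)
            fit = mp.fit_sudden_expansion(obs)
            p_ssd, _ = mp.gof_bootstrap(fit, 40, n_boot=99, seed=1000 + t)
            ps.append(p_ssd)
        assert np.mean(np.asarray(ps) > 0.05) >= 0.78


class TestExpansionTime:
    def test_zero_tau_is_time_zero(self):
        est = mp.expansion_time(0.0, "3.1%/Myr", 683)
        assert est.t_years == 0.0

    def test_arithmetic_oracle(self):
        est = mp.expansion_time(1.0, 3.1e-8, 683, 1.0)
        assert est.t_years == pytest.approx(1.0 / (2 * 683 * 3.1e-8), rel=1e-12)
        assert est.t_years == pytest.approx(23615, rel=1e-3)

    def test_doubling_length_halves_time(self):
        t1 = mp.expansion_time(1.0, 3.1e-8, 683).t_years
        t2 = mp.expansion_time(1.0, 3.1e-8, 1366).t_years
        assert t2 == pytest.approx(t1 / 2)

    def test_rate_string_parsing(self):
        from mitopop.demography import parse_rate

        assert parse_rate("3.1%/Myr") == pytest.approx(3.1e-8)
        assert parse_rate("3.1% per million years") == pytest.approx(3.1e-8)
        assert parse_rate(2e-8) == 2e-8
        with pytest.raises(ConfigurationError):
            parse_rate("fast")

    def test_pairwise_convention_doubles_time(self):
        per_lineage = mp.expansion_time(1.0, 3.1e-8, 683).t_years
        pairwise = mp.expansion_time(
            1.0, 3.1e-8, 683, rate_convention="pairwise"
        ).t_years
        assert pairwise == pytest.approx(2 * per_lineage)

    def test_zero_rate_with_positive_tau_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            mp.expansion_time(1.0, 0.0, 683)


def test_neutrality_table_on_expansion_data():
    ds = mp.simulate_fujian_like(seed=1)
    df = mp.neutrality_tests(ds.alignment, n_sims=200, seed=42)
    assert len(df) == 6
    # expansion signal: Tajima's D and Fu's Fs negative in every deme
    assert (df["tajimas_d"] < 0).all()
    assert (df["fus_fs"] < 0).all()
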