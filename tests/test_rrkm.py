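"""State counting, orbiting-TS barriers, RRKM rates, KIE, tunneling."""

import itertools
import math
import warnings

import numpy as np
import pytest

from beamkin.constants import AMU_TO_KG, CM1_TO_EV, EV_TO_J, H_EV_S
from beamkin.collisions import langevin_sigma, relative_velocity
from beamkin.rrkm import (
    OrbitTS,
    StateCount,
    adduct_population,
    beyer_swinehart,
    centrifugal_barrier,
    kie_ratio,
    load_frequencies,
    orbital_L,
    rrkm_k,
    survival_weight,
    wigner_factor,
)


def enumerate_counts(frequencies, grain, e_max):
    """Brute-force harmonic state count: all quantum-number tuples with
    sum(v_i nu_i) <= e_max, binned on the same grain as the recursion."""
    n_bins = int(e_max / grain) + 1
    counts = np.zeros(n_bins)
    maxima = [int(e_max / f) for f in frequencies]
    for quanta in itertools.product(*(range(m + 1) for m in maxima)):
        e = sum(v * f for v, f in zip(quanta, frequencies))
        if e <= e_max:
            idx = int(e / grain)
            if idx < n_bins:
                counts[idx] += 1
    return counts


class TestBeyerSwinehart:
    def test_single_mode_ladder(self):
        sc = beyer_swinehart([100.0], grain=10.0, e_max=1000.0)
        for e_cm1 in (0, 95, 250, 505, 999):
            expected = 1 + e_cm1 // 100
            assert sc.sum_at(e_cm1 * CM1_TO_EV) == expected

    def test_zero_point_level_is_counted(self):
        sc = beyer_swinehart([100.0, 700.0], grain=10.0, e_max=2000.0)
        assert sc.sum_at(0.0) == 1.0

    def test_three_mode_count_matches_exhaustive_enumeration(self):
        freqs, grain, e_max = [100.0, 150.0, 300.0], 10.0, 600.0
        sc = beyer_swinehart(freqs, grain, e_max)
        counts = enumerate_counts(freqs, grain, e_max)
        assert sc.sum_at(600.0 * CM1_TO_EV) == counts.sum()
        assert np.array_equal(sc.sums, np.cumsum(counts))

    @pytest.mark.parametrize("seed", range(4))
    def test_random_small_systems_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_modes = rng.integers(1, 5)
        grain, e_max = 10.0, 3000.0
        # the recursion counts on the grain lattice, so the enumeration
        # oracle is exact for frequencies that are grain multiples
        freqs = sorted(np.round(rng.uniform(80.0, 900.0, n_modes) / grain) * grain)
        sc = beyer_swinehart(freqs, grain, e_max)
        counts = enumerate_counts(freqs, grain, e_max)
        assert np.array_equal(sc.sums, np.cumsum(counts))

    def test_union_of_mode_sets_is_discrete_convolution(self):
        grain, e_max = 10.0, 2000.0
        a, b = [110.0, 450.0], [230.0]
        bins = int(e_max / grain) + 1
        counts = lambda f: beyer_swinehart(f, grain, e_max).densities * (grain * CM1_TO_EV)
        conv = np.convolve(counts(a), counts(b))[:bins]
        assert np.allclose(counts(a + b), conv)

    def test_density_integrates_to_sum_of_states(self):
        sc = beyer_swinehart([120.0, 500.0, 1100.0], grain=10.0, e_max=4000.0)
        running = np.cumsum(sc.densities) * sc.grain
        assert np.allclose(running, sc.sums, rtol=1e-12)
        assert np.all(np.diff(sc.sums) >= 0)

    def test_coarse_grain_warns_but_counts(self):
        with pytest.warns(UserWarning, match="resolution"):
            sc = beyer_swinehart([50.0], grain=80.0, e_max=800.0)
        assert sc.sum_at(0.0) >= 1.0

    def test_state_count_invariants_enforced(self):
        with pytest.raises(ValueError):
            StateCount(0.0, np.array([0.0]), np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            StateCount(
                0.01, np.array([0.0, 0.01]), np.array([2.0, 1.0]), np.array([1.0, 1.0])
            )


class TestOrbitingTS:
    def test_orbital_l_zero_velocity(self):
        assert orbital_L(28.0, 0.0, 100.0) == 0.0

    def test_orbital_l_square_root_law_in_sigma(self):
        base = orbital_L(28.0, 500.0, 100.0)
        assert orbital_L(28.0, 500.0, 400.0) == pytest.approx(2.0 * base, rel=1e-12)

    def test_orbital_l_hand_value_for_study_masses(self):
        mu = 165.0 * 34.0 / 199.0
        v = relative_velocity(0.1, mu)
        L = orbital_L(mu, v, 100.0)
        expected = mu * AMU_TO_KG * v * math.sqrt(100.0 / math.pi) * 1e-10
        assert L == pytest.approx(expected, rel=1e-12)
        assert L == pytest.approx(2.2e-32, rel=0.05)  # ~200 hbar: a heavy-ion collision

    def test_zero_l_has_no_barrier(self):
        assert centrifugal_barrier(0.0, 5.0, 1.0, 28.0) == 0.0

    def test_quartic_scaling_in_l(self):
        b1 = centrifugal_barrier(1e-32, 5.0, 1.0, 28.0)
        b2 = centrifugal_barrier(2e-32, 5.0, 1.0, 28.0)
        assert b2 == pytest.approx(16.0 * b1, rel=1e-12)

    @pytest.mark.parametrize("e_cm", [0.05, 0.1, 0.5, 2.0])
    def test_langevin_self_consistency_closes_the_unit_chain(self, e_cm):
        # L at b_max of the Langevin cross section must place the
        # centrifugal barrier exactly at the collision energy
        alpha, q, mu = 5.0, 1.0, 165.0 * 34.0 / 199.0
        sigma_l = langevin_sigma(alpha, q, e_cm)
        v = relative_velocity(e_cm, mu)
        L = orbital_L(mu, v, sigma_l)
        assert centrifugal_barrier(L, alpha, q, mu) == pytest.approx(e_cm, rel=1e-6)
        assert OrbitTS(L, alpha, q, mu).barrier == pytest.approx(e_cm, rel=1e-6)


class TestRRKMRate:
    def _toy_counts(self):
        # coprime grain steps (9, 14) keep every bin above the Frobenius
        # energy populated, so rho(E) is nonzero on the whole test grid
        grain, e_max = 10.0, 16000.0
        reactant = beyer_swinehart([90.0, 140.0], grain, e_max)
        ts = beyer_swinehart([150.0], grain, e_max)
        return reactant, ts

    def test_zero_below_threshold(self):
        reactant, ts = self._toy_counts()
        assert rrkm_k(0.2, 0.5, reactant, ts) == 0.0

    def test_matches_enumeration_oracle(self):
        grain = 10.0
        reactant, ts = self._toy_counts()
        e0 = 0.3
        for e in (0.8, 1.2, 1.6):
            counts_r = enumerate_counts([90.0, 140.0], grain, e / CM1_TO_EV + grain)
            rho = counts_r[int(e / (grain * CM1_TO_EV))] / (grain * CM1_TO_EV)
            counts_t = enumerate_counts([150.0], grain, (e - e0) / CM1_TO_EV + grain)
            w = counts_t[: int((e - e0) / (grain * CM1_TO_EV)) + 1].sum()
            expected = w / (H_EV_S * rho)
            assert rrkm_k(e, e0, reactant, ts) == pytest.approx(expected, rel=1e-9)

    def test_nondecreasing_in_energy(self):
        # a molecule-sized system: losing one mode to the reaction
        # coordinate, the TS slightly looser than the reactant
        grain, e_max = 10.0, 20000.0
        reactant = beyer_swinehart(
            [90.0, 140.0, 230.0, 370.0, 555.0, 710.0, 1050.0, 1420.0], grain, e_max
        )
        ts = beyer_swinehart(
            [110.0, 160.0, 260.0, 410.0, 600.0, 780.0, 1100.0], grain, e_max
        )
        grid = np.linspace(0.4, 1.8, 30)
        k = rrkm_k(grid, 0.3, reactant, ts)
        assert np.all(np.diff(k) >= 0.0)

    def test_path_degeneracy_scales_linearly(self):
        reactant, ts = self._toy_counts()
        assert rrkm_k(1.0, 0.3, reactant, ts, symmetry=2.0) == pytest.approx(
            2.0 * rrkm_k(1.0, 0.3, reactant, ts), rel=1e-12
        )

    def test_vanishing_reactant_density_is_an_error(self):
        grain, e_max = 10.0, 16000.0
        sparse = beyer_swinehart([1000.0], grain, e_max)
        ts = beyer_swinehart([150.0], grain, e_max)
        # 0.05 eV (~403 cm^-1) falls between the ZPE level and the first
        # excited state of a 1000 cm^-1 oscillator: no states in that bin
        with pytest.raises(ValueError, match="density"):
            rrkm_k(0.05, 0.01, sparse, ts)


class TestKIE:
    def test_identical_rates_give_unity(self):
        k = np.array([1.0, 2.0, 3.0])
        assert np.allclose(kie_ratio(k, k), 1.0)

    def test_lighter_isotopologue_is_faster_above_both_thresholds(self):
        # common TS; the light reactant's higher-frequency mode gives it a
        # larger ZPE, hence the lower 0 K barrier: E0_light < E0_heavy
        grain, e_max = 10.0, 30000.0
        shared = [90.0, 140.0]
        light = beyer_swinehart(shared + [3000.0], grain, e_max)
        heavy = beyer_swinehart(shared + [2200.0], grain, e_max)
        ts = beyer_swinehart([250.0, 700.0], grain, e_max)
        barrier_el = 1.0
        zpe = lambda fs: 0.5 * sum(fs) * CM1_TO_EV
        zpe_ts = zpe([250.0, 700.0])
        e0_light = barrier_el + zpe_ts - zpe(shared + [3000.0])
        e0_heavy = barrier_el + zpe_ts - zpe(shared + [2200.0])
        assert e0_light < e0_heavy
        grid = np.linspace(e0_heavy + 0.05, e0_heavy + 1.0, 12)
        ratio = kie_ratio(
            rrkm_k(grid, e0_light, light, ts), rrkm_k(grid, e0_heavy, heavy, ts)
        )
        assert np.all(ratio > 1.0)

    def test_zero_heavy_rate_flagged_as_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            ratio = kie_ratio(np.array([1.0, 1.0]), np.array([2.0, 0.0]))
        assert ratio[0] == pytest.approx(0.5)
        assert np.isnan(ratio[1])

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            kie_ratio(np.ones(3), np.ones(4))


class TestWigner:
    @pytest.mark.parametrize(
        "freq, digits, expected",
        [(169.0, 2, 1.03), (140.0, 2, 1.02), (857.0, 1, 1.7)],
    )
    def test_printed_factors_at_room_temperature(self, freq, digits, expected):
        assert round(wigner_factor(freq, 298.0), digits) == expected

    def test_no_imaginary_frequency_means_no_tunneling(self):
        assert wigner_factor(0.0, 298.0) == 1.0

    def test_always_at_least_unity(self):
        for f in (10.0, 446.0, 2000.0):
            assert wigner_factor(f) >= 1.0

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            wigner_factor(169.0, 0.0)


class TestAdductPopulation:
    def test_identical_candidates_split_evenly(self):
        sc = beyer_swinehart([90.0, 140.0], 10.0, 16000.0)
        assert np.allclose(adduct_population([sc, sc], 1.0), [0.5, 0.5])

    def test_single_candidate_takes_all(self):
        sc = beyer_swinehart([90.0, 140.0], 10.0, 16000.0)
        assert np.allclose(adduct_population([sc], 1.0), [1.0])

    def test_three_candidates_match_enumeration_ratios(self):
        grain, e_max, e = 10.0, 16000.0, 1.2
        sets = [[90.0, 140.0], [110.0, 130.0], [70.0, 90.0]]
        counts = [beyer_swinehart(f, grain, e_max) for f in sets]
        idx = int(e / (grain * CM1_TO_EV))
        rhos = [
            enumerate_counts(f, grain, e / CM1_TO_EV + grain)[idx] for f in sets
        ]
        expected = np.array(rhos) / sum(rhos)
        assert np.allclose(adduct_population(counts, e), expected)

    def test_fractions_sum_to_one_and_rescale_invariant(self):
        a = beyer_swinehart([90.0, 140.0], 10.0, 16000.0)
        b = beyer_swinehart([110.0, 130.0], 10.0, 16000.0)
        frac = adduct_population([a, b], 1.0)
        assert frac.sum() == pytest.approx(1.0)
        scaled = StateCount(a.grain, a.energies, a.sums * 7.0, a.densities * 7.0)
        scaled_b = StateCount(b.grain, b.energies, b.sums * 7.0, b.densities * 7.0)
        assert np.allclose(adduct_population([scaled, scaled_b], 1.0), frac)

    def test_all_zero_densities_rejected(self):
        sparse = beyer_swinehart([2000.0], 10.0, 20000.0)
        with pytest.raises(ValueError):
            adduct_population([sparse, sparse], 0.05)


class TestSurvivalWeight:
    def test_limits_and_hand_value(self):
        assert survival_weight(0.0, 1e-4) == 0.0
        assert survival_weight(1e9, 1e-4) == pytest.approx(1.0)
        assert survival_weight(1e4, 1e-4) == pytest.approx(1.0 - math.exp(-1.0))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            survival_weight(-1.0, 1e-4)
        with pytest.raises(ValueError):
            survival_weight(1.0, 0.0)


class TestFrequencyFiles:
    def test_roundtrip_with_comments(self, tmp_path):
        path = tmp_path / "freqs.txt"
        path.write_text("# toy frequencies\n100.5\n 250 # bend\n\n3000\n")
        assert load_frequencies(path) == [100.5, 250.0, 3000.0]

    def test_bad_line_reported(self, tmp_path):
        path = tmp_path / "freqs.txt"
        path.write_text("100\nnot-a-number\n")
        with pytest.raises(ValueError, match="line 2"):
            load_frequencies(path)
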