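"""Windowed free-energy perturbation estimator and its error propagation."""
import warnings

import numpy as np
import pytest

from fepkit.constants import kt_kcal
from fepkit.fep import (
    FEPWindow,
    fep_profile,
    propagate_profile_error,
    apply_stationary_corrections,
    window_error,
    zwanzig_increment,
)

T = 303.0
KT = kt_kcal(T)


def windows_from_samples(sample_sets, e_qm0=None):
    e_qm0 = e_qm0 if e_qm0 is not None else [0.0] * len(sample_sets)
    return [
        FEPWindow(i, float(i), e0, np.asarray(s, dtype=float))
        for i, (s, e0) in enumerate(zip(sample_sets, e_qm0))
    ]


class TestZwanzigIncrement:
    def test_two_sample_hand_computation(self):
        # paired ΔE samples {0, kT·ln4}: term = −kT·ln((1 + 1/4)/2)
        de = np.array([0.0, KT * np.log(4.0)])
        expected = -KT * np.log((1.0 + 0.25) / 2.0)
        assert zwanzig_increment(de, T) == pytest.approx(expected, rel=1e-12)

    def test_constant_delta_e_returns_the_constant(self):
        assert zwanzig_increment(np.full(100, 2.5), T) == pytest.approx(2.5)

    def test_gaussian_closed_form(self):
        # ΔE ~ N(μ, σ²) → increment → μ − σ²/(2kT)
        rng = np.random.default_rng(7)
        mu, sigma, n = 1.0, 0.8, 100_000
        de = rng.normal(mu, sigma, n)
        est = zwanzig_increment(de, T)
        se = window_error(de, T)
        assert abs(est - (mu - sigma**2 / (2 * KT))) < 3 * se

    def test_overflow_safe_for_huge_energies(self):
        for de in ([1e4, 1e4], [-1e4, -1e4], [-1e4, 1e4]):
            val = zwanzig_increment(np.array(de), T)
            assert np.isfinite(val)

    def test_conventions_agree_only_at_zero(self):
        zero = np.zeros(10)
        assert zwanzig_increment(zero, T) == zwanzig_increment(zero, T, "as_printed") == 0.0
        de = np.array([0.0, 1.0])
        z = zwanzig_increment(de, T, "zwanzig")
        p = zwanzig_increment(de, T, "as_printed")
        assert z != p
        # the printed form flips the sign of the exponent: g_p(ΔE) = g_z(−ΔE)
        assert p == pytest.approx(zwanzig_increment(-de, T, "zwanzig"), rel=1e-12)


class TestProfile:
    def test_constant_interaction_reduces_to_qm_differences(self):
        e0 = [0.0, 3.0, 5.0, 1.0]
        wins = windows_from_samples([[7.0] * 5] * 4, e0)
        prof = fep_profile(wins, T)
        assert np.allclose(prof.dg, np.array(e0) - e0[0])
        assert prof.dg[0] == 0.0 and prof.stderr[0] == 0.0

    def test_invariant_under_common_energy_shifts(self, rng):
        samples = [rng.normal(0, 1, 50) for _ in range(4)]
        e0 = [0.0, 1.0, 2.0, 3.0]
        base = fep_profile(windows_from_samples(samples, e0), T)
        shifted = fep_profile(
            windows_from_samples([s + 13.0 for s in samples], [e + 7.0 for e in e0]), T
        )
        assert np.allclose(base.dg, shifted.dg, atol=1e-9)

    def test_paired_samples_take_priority(self):
        # paired route: ΔE fixed at {0, kT ln4} irrespective of window means
        w0 = FEPWindow(0, 0.0, 0.0, np.array([5.0, 5.0]),
                       samples_next=np.array([5.0, 5.0 + KT * np.log(4.0)]))
        w1 = FEPWindow(1, 1.0, 0.0, np.array([100.0, 200.0]))
        prof = fep_profile([w0, w1], T)
        assert prof.dg[1] == pytest.approx(-KT * np.log(1.25 / 2.0))

    def test_single_window_profile_is_zero(self):
        prof = fep_profile(windows_from_samples([[1.0, 2.0]]), T)
        assert prof.dg.tolist() == [0.0]

    def test_unordered_windows_rejected(self):
        wins = windows_from_samples([[0.0]] * 3)
        wins[2].s = -1.0
        with pytest.raises(ValueError, match="ordered"):
            fep_profile(wins, T)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            FEPWindow(0, 0.0, 0.0, np.array([]))


class TestWindowError:
    def test_zero_variance_gives_zero_error(self):
        assert window_error(np.full(100, 1.3), T) == 0.0

    def test_inverse_sqrt_n_scaling(self):
        # a 10-block error estimate is itself noisy, so average the n vs 4n
        # ratio over replicates before comparing with the ideal factor 2
        rng = np.random.default_rng(11)
        n = 4000
        ratios = []
        for _ in range(20):
            pop = rng.normal(0, 0.5, 4 * n)
            ratios.append(window_error(pop[:n], T) / window_error(pop, T))
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.25)

    def test_block_averaging_inflates_correlated_error(self):
        rng = np.random.default_rng(5)
        rho, n = 0.9, 20_000
        eps = np.empty(n)
        eps[0] = rng.normal()
        for k in range(1, n):
            eps[k] = rho * eps[k - 1] + rng.normal(0, np.sqrt(1 - rho**2))
        de = 0.3 * eps
        blocked = window_error(de, T, blocks=10)
        y = np.exp(-de / KT)
        naive = KT * y.std(ddof=1) / np.sqrt(n) / y.mean()
        assert blocked >= naive

    def test_small_sample_fallback_warns(self):
        with pytest.warns(UserWarning, match="fewer than 20"):
            window_error(np.array([0.0, 1.0, 2.0]), T)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            window_error(np.array([1.0]), T)


class TestProfileErrorPropagation:
    def test_single_window(self):
        assert np.allclose(propagate_profile_error([0.7]), [0.0, 0.7])

    def test_pythagorean_pair(self):
        assert propagate_profile_error([3.0, 4.0])[-1] == pytest.approx(5.0)

    def test_matches_brute_force_quadrature(self, rng):
        errs = rng.uniform(0, 2, 15)
        cum = propagate_profile_error(errs)
        for j in range(len(errs) + 1):
            assert cum[j] == pytest.approx(np.sqrt(np.sum(errs[:j] ** 2)))

    def test_negative_errors_rejected(self):
        with pytest.raises(ValueError):
            propagate_profile_error([-0.1])


class TestStationaryCorrections:
    def _profile(self):
        wins = windows_from_samples([[0.0] * 5] * 3, [0.0, 10.0, 2.0])
        return fep_profile(wins, T)

    def test_equal_corrections_leave_barriers_unchanged(self):
        prof = self._profile()
        labels = {"R": 0, "TS": 1, "P": 2}
        corr = apply_stationary_corrections(prof, {k: 4.2 for k in labels}, labels, "R")
        assert corr["TS"] - corr["R"] == pytest.approx(10.0)

    def test_ts_correction_lowers_barrier(self):
        prof = self._profile()
        labels = {"R": 0, "TS": 1}
        corr = apply_stationary_corrections(
            prof, {"R": 0.0, "TS": -1.2}, labels, "R"
        )
        assert corr["TS"] == pytest.approx(10.0 - 1.2)

    def test_unknown_label_raises(self):
        prof = self._profile()
        with pytest.raises(KeyError):
            apply_stationary_corrections(prof, {"R": 0.0}, {"R": 0, "TS": 1}, "R")

    def test_zpe_difference_from_synthetic_hessians(self):
        # corrections supplied by the harmonic module equal the hand-computed
        # ZPE difference between reactant and TS fixtures
        from fepkit.constants import HESS_EV_TO_S2, C_CM_S, WAVENUMBER_TO_KCAL
        from fepkit.thermo import HessianBlock, normal_modes, zpe

        def k_for(nu, m):
            return (nu * 2 * np.pi * C_CM_S) ** 2 / HESS_EV_TO_S2 * m

        m = 12.0
        h_r = HessianBlock(np.diag([k_for(1500.0, m), 0, 0]), np.array([m]))
        h_ts = HessianBlock(np.diag([-k_for(800.0, m), k_for(900.0, m), 0]), np.array([m]))
        z_r = zpe(normal_modes(h_r))
        z_ts = zpe(normal_modes(h_ts))
        assert z_r == pytest.approx(0.5 * 1500.0 * WAVENUMBER_TO_KCAL, rel=1e-9)
        assert z_ts == pytest.approx(0.5 * 900.0 * WAVENUMBER_TO_KCAL, rel=1e-9)

        prof = self._profile()
        labels = {"R": 0, "TS": 1}
        corr = apply_stationary_corrections(prof, {"R": z_r, "TS": z_ts}, labels, "R")
        assert corr["TS"] - prof.dg[1] == pytest.approx(z_ts - z_r)
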