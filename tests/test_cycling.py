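"""Cycle bookkeeping: KCl, eutectic factors, dilution, growth fits, yields."""

import math

import numpy as np
import pandas as pd
import pytest

from tripletrep.cycling import (
    AmplificationFit,
    CycleProtocol,
    EutecticCalibration,
    cumulative_dilution,
    effective_amplification,
    eutectic_concentration,
    eutectic_factor,
    fit_growth,
    kcl_increment,
    kcl_trajectory,
    per_cycle_exponent,
    triplet_consumption,
    yield_from_gel,
)


class TestKcl:
    def test_acid_spike_increment(self):
        # 0.75 ul of 0.1 M HCl into 125 ul deposits 0.6 mM KCl per cycle
        proto = CycleProtocol(n_cycles=4)
        assert kcl_increment(proto) == pytest.approx(0.6)

    def test_four_cycles_no_dilution(self):
        proto = CycleProtocol(n_cycles=4, kcl0=1.8)
        traj = kcl_trajectory(proto)
        assert traj["kcl_mM"].iloc[-1] == pytest.approx(4.2)

    def test_twofold_dilution_after_cycle_four(self):
        proto = CycleProtocol(
            n_cycles=5, kcl0=1.8, dilution_fold=2.0, dilution_interval=4
        )
        traj = kcl_trajectory(proto)
        assert bool(traj["diluted_after"].iloc[3])
        assert traj["kcl_out_mM"].iloc[3] == pytest.approx(2.1)
        assert traj["kcl_mM"].iloc[4] == pytest.approx(2.7)

    def test_affine_without_dilution(self):
        proto = CycleProtocol(n_cycles=10, kcl0=0.9)
        traj = kcl_trajectory(proto)
        diffs = np.diff(traj["kcl_mM"])
        assert np.allclose(diffs, kcl_increment(proto))


class TestEutectic:
    def test_replication_buffer_calibration(self):
        # 8.8-fold transition for a 50x pre-concentrated buffer -> 440-fold
        assert eutectic_factor(EutecticCalibration(50, 8.8)) == pytest.approx(440)

    def test_extension_buffer_calibration(self):
        assert eutectic_factor(EutecticCalibration(1, 10)) == pytest.approx(10)

    def test_identity_transition(self):
        assert eutectic_factor(EutecticCalibration(7, 1)) == pytest.approx(7)

    def test_duplex_concentration(self):
        # 4 nM duplex concentrates to 1.76 uM in the eutectic phase
        conc = eutectic_concentration(4.0, EutecticCalibration(50, 8.8))
        assert conc == pytest.approx(1760.0)

    def test_zero_and_linear(self):
        cal = EutecticCalibration(1, 10)
        assert eutectic_concentration(0.0, cal) == 0.0
        assert eutectic_concentration(2.5, cal) == pytest.approx(25.0)


class TestDilution:
    def test_three_fold_every_five_cycles(self):
        proto = CycleProtocol(n_cycles=40, dilution_fold=3, dilution_interval=5)
        assert cumulative_dilution(proto, 5, 40) == pytest.approx(3**7)

    def test_two_fold_every_four_cycles(self):
        proto = CycleProtocol(n_cycles=21, dilution_fold=2, dilution_interval=4)
        assert cumulative_dilution(proto, 0, 21) == pytest.approx(32)

    def test_empty_range(self):
        proto = CycleProtocol(n_cycles=40, dilution_fold=3, dilution_interval=5)
        assert cumulative_dilution(proto, 12, 12) == 1.0

    def test_multiplicative_over_concatenated_ranges(self):
        proto = CycleProtocol(n_cycles=40, dilution_fold=3, dilution_interval=5)
        for mid in (7, 10, 23, 35):
            assert cumulative_dilution(proto, 5, mid) * cumulative_dilution(
                proto, mid, 40
            ) == pytest.approx(cumulative_dilution(proto, 5, 40))


class TestAmplification:
    def test_product_of_intensity_and_dilution(self):
        assert effective_amplification(30, 3**7) == pytest.approx(65610)
        assert effective_amplification(30, 2000) == pytest.approx(60000)
        assert effective_amplification(1, 1) == 1.0

    def test_per_cycle_exponent(self):
        # 60,000-fold over 35 cycles is 1.37-fold per cycle
        assert per_cycle_exponent(60000, 35) == pytest.approx(1.37, abs=0.005)
        assert per_cycle_exponent(65610, 35) == pytest.approx(1.373, abs=0.0005)
        assert per_cycle_exponent(1, 12) == 1.0

    def test_exponent_invariant_to_factorization(self):
        for a, b in [(30, 2000), (60, 1000), (6, 10000)]:
            assert per_cycle_exponent(
                effective_amplification(a, b), 35
            ) == pytest.approx(per_cycle_exponent(60000, 35))


class TestFitGrowth:
    def test_noiseless_exponential(self):
        x = np.arange(5)
        fit = fit_growth((x, np.exp(0.38 * x)))
        assert fit.growth_exponent == pytest.approx(0.38, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.fold_per_cycle == pytest.approx(math.exp(0.38))

    def test_second_strand_exponent(self):
        x = np.arange(5)
        fit = fit_growth((x, np.exp(0.20 * x)))
        assert fit.growth_exponent == pytest.approx(0.20, abs=1e-9)

    def test_constant_trajectory(self):
        fit = fit_growth((np.arange(6), np.ones(6)))
        assert fit.growth_exponent == pytest.approx(0.0, abs=1e-12)

    def test_plateau_excluded_from_window(self):
        x = np.arange(10)
        copies = np.minimum(np.exp(0.38 * x), np.exp(0.38 * 4))
        fit = fit_growth((x, copies))
        assert fit.window[1] <= 5
        assert fit.growth_exponent == pytest.approx(0.38, abs=1e-9)

    def test_window_override(self):
        x = np.arange(10)
        copies = np.exp(0.3 * x)
        fit = fit_growth(pd.DataFrame({"cycle": x, "copies": copies}), window=(2, 6))
        assert fit.window == (2, 6)
        assert fit.growth_exponent == pytest.approx(0.3, abs=1e-9)

    def test_nonpositive_copies_rejected(self):
        with pytest.raises(ValueError):
            fit_growth((np.arange(4), np.array([1.0, 0.0, 2.0, 3.0])), window=(0, 3))

    def test_fold_per_cycle_consistent(self):
        fit = AmplificationFit(growth_exponent=0.38, r_squared=1.0, window=(0, 4))
        assert fit.fold_per_cycle == math.exp(0.38)


class TestConsumptionAndGel:
    def test_single_product(self):
        # one 30-nt product at 10 pmol consumes 100 of 1000 supplied triplets
        table = pd.DataFrame({"length_nt": [30], "yield": [10.0]})
        assert triplet_consumption(table, 1000.0) == pytest.approx(10.0)

    def test_empty_table(self):
        table = pd.DataFrame({"length_nt": [], "yield": []})
        assert triplet_consumption(table, 1000.0) == 0.0

    def test_additivity(self):
        one = pd.DataFrame({"length_nt": [30], "yield": [10.0]})
        split = pd.DataFrame({"length_nt": [30, 30], "yield": [4.0, 6.0]})
        assert triplet_consumption(one, 500.0) == pytest.approx(
            triplet_consumption(split, 500.0)
        )

    def test_pentamer_register_floor(self):
        # a 14-nt (3n+5 register) product counts floor(14/3) = 4 triplets
        table = pd.DataFrame({"length_nt": [14], "yield": [1.0]})
        assert triplet_consumption(table, 100.0) == pytest.approx(4.0)

    def test_nonpositive_supply_rejected(self):
        with pytest.raises(ValueError):
            triplet_consumption(pd.DataFrame({"length_nt": [9], "yield": [1.0]}), 0.0)

    def test_gel_yield_ratios(self):
        assert yield_from_gel(2.0, 20.0, 1.0, 10.0, 5.0) == pytest.approx(5.0)
        assert yield_from_gel(1.0, 10.0, 1.0, 10.0, 5.0) == pytest.approx(5.0)
        assert yield_from_gel(0.5, 10.0, 1.0, 10.0, 5.0) == pytest.approx(2.5)

    def test_gel_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            yield_from_gel(1.0, 10.0, 0.0, 10.0, 5.0)
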