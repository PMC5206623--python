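"""Forward-model tests: presets, Markov dynamics, noise model, bleaching."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import alexfret as af
from alexfret.simulate import SPECIES


class TestPresets:
    def test_l662_n_is_80_20_mixture(self):
        cfg = af.preset("L662-N")
        assert [w for _, w in cfg.states] == [0.8, 0.2]
        assert [e for e, _ in cfg.states] == [0.28, 0.52]

    @pytest.mark.parametrize("name,expected_e", [
        ("H589-N", 0.38), ("H589-P", 0.49), ("L662-P", 0.52)])
    def test_single_state_presets(self, name, expected_e):
        cfg = af.preset(name)
        assert len(cfg.states) == 1
        assert cfg.states[0][0] == expected_e

    def test_donor_only_preset_species(self):
        cfg = af.preset("DONOR-ONLY")
        assert cfg.species_fractions == {"donor_only": 1.0, "acceptor_only": 0.0,
                                         "double": 0.0}

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="L662-N"):
            af.preset("NOPE")

    def test_preset_deterministic(self):
        a = af.preset("H589-N", seed=3)
        b = af.preset("H589-N", seed=3)
        assert a == b

    def test_brightness_calibrated_for_s_057(self):
        # corrected S of doubles is I_D0/(I_D0+I_A0) with gamma=1
        cfg = af.preset("L662-N")
        assert cfg.I_D0 / (cfg.I_D0 + cfg.I_A0) == pytest.approx(0.57, abs=1e-4)


class TestConfigValidation:
    def test_species_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            af.SimulationConfig(species_fractions={
                "donor_only": 0.5, "acceptor_only": 0.5, "double": 0.5})

    def test_true_e_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            af.SimulationConfig(states=((1.2, 1.0),))

    def test_zero_length_simulation_rejected(self):
        with pytest.raises(ValueError):
            af.SimulationConfig(n_cycles=0)

    def test_negative_camera_params_rejected(self):
        with pytest.raises(ValueError):
            af.CameraModel(gain=0.0)
        with pytest.raises(ValueError):
            af.CameraModel(excess_noise=0.9)


class TestMarkovStatePath:
    def test_zero_rates_constant_path(self):
        path = af.markov_state_path(0.0, 0.0, 0.001, 1000, rng=1)
        assert np.all(path == path[0])

    @pytest.mark.parametrize("k12,k21", [(1.0, 1.0), (2.0, 1.0)])
    def test_stationary_occupancy(self, k12, k21):
        n = 10 ** 6
        path = af.markov_state_path(k12, k21, 0.001, n, rng=7)
        expect = k12 / (k12 + k21)
        # serial correlation inflates the variance of the occupancy estimate:
        # effective sample size ~ n * dt * (k12+k21) independent dwells
        se = math.sqrt(expect * (1 - expect) / (n * 0.001 * (k12 + k21)))
        assert abs(path.mean() - expect) < 3 * se

    def test_negative_rates_error(self):
        with pytest.raises(ValueError, match="nonnegative"):
            af.markov_state_path(-1.0, 1.0, 0.1, 10)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_path_is_binary_and_seeded(self, seed):
        a = af.markov_state_path(3.0, 2.0, 0.05, 200, rng=seed)
        b = af.markov_state_path(3.0, 2.0, 0.05, 200, rng=seed)
        assert set(np.unique(a)) <= {0, 1}
        assert np.array_equal(a, b)


class TestSimulateTraces:
    def test_leakage_only_noise_free(self):
        """E=0 with 10% leakage: F_DA is exactly 10% of F_DD."""
        cfg = af.SimulationConfig(
            n_molecules=1, n_cycles=20,
            species_fractions={"donor_only": 0, "acceptor_only": 0, "double": 1.0},
            states=((0.0, 1.0),), I_D0=1000.0, I_A0=0.0, l_true=0.1, d_true=0.0,
            shot_noise=False, camera=af.CameraModel(excess_noise=1.0), seed=0)
        tr = af.simulate_traces(cfg)[0]
        assert np.allclose(tr.F_DD_raw, 1000.0)
        assert np.allclose(tr.F_DA_raw, 100.0)

    def test_mean_brightness_with_noise(self):
        cfg = af.SimulationConfig(
            n_molecules=1, n_cycles=10 ** 4,
            species_fractions={"donor_only": 0, "acceptor_only": 0, "double": 1.0},
            states=((0.5, 1.0),), I_D0=1000.0, I_A0=800.0, l_true=0.0, d_true=0.0,
            camera=af.CameraModel(gain=1.0, excess_noise=1.0, read_noise_sd=0.0),
            seed=12)
        tr = af.simulate_traces(cfg)[0]
        se = math.sqrt(500.0 / 10 ** 4)
        assert abs(tr.F_DD_raw.mean() - 500.0) < 3 * se

    def test_donor_only_preset_faa_is_background(self):
        cfg = af.preset("DONOR-ONLY", n_molecules=3, shot_noise=False,
                        camera=af.CameraModel(excess_noise=1.0))
        for tr in af.simulate_traces(cfg):
            assert np.allclose(tr.F_AA_raw, cfg.background["acceptor"])

    def test_energy_conservation(self, noise_free_double):
        """Without distortions, FRET term + F_DD = I_D0 every frame."""
        tr = noise_free_double
        assert np.allclose(tr.F_DA_raw + tr.F_DD_raw, 1000.0)

    def test_seed_determinism_byte_identical(self):
        cfg = af.preset("H589-N", seed=42, n_molecules=5, n_cycles=50)
        a = af.simulate_traces(cfg)
        b = af.simulate_traces(cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.F_DD_raw, y.F_DD_raw)
            assert np.array_equal(x.F_DA_raw, y.F_DA_raw)
            assert np.array_equal(x.F_AA_raw, y.F_AA_raw)

    def test_acceptor_bleach_dequenches_donor(self):
        cfg = af.SimulationConfig(
            n_molecules=50, n_cycles=200,
            species_fractions={"donor_only": 0, "acceptor_only": 0, "double": 1.0},
            states=((0.5, 1.0),), I_D0=1000.0, I_A0=800.0, shot_noise=False,
            camera=af.CameraModel(excess_noise=1.0),
            bleach_tau_A=10.0, bleach_tau_D=math.inf, seed=3)
        for tr in af.simulate_traces(cfg):
            ba = tr.truth.bleach_cycle_A
            if ba is not None and 0 < ba < tr.n_cycles:
                assert tr.F_DD_raw[ba:].mean() > tr.F_DD_raw[:ba].mean()

    def test_bleach_times_are_exponential(self):
        """KS test of simulated bleach times against the configured lifetime."""
        cfg = af.SimulationConfig(
            n_molecules=1000, n_cycles=2,
            species_fractions={"donor_only": 0, "acceptor_only": 0, "double": 1.0},
            states=((0.3, 1.0),), bleach_tau_A=30.0, seed=21)
        times = [tr.truth.bleach_time_A for tr in af.simulate_traces(cfg)]
        _, p = stats.kstest(times, "expon", args=(0, 30.0))
        assert p > 0.01

    def test_fast_exchange_collapses_to_stationary_mean(self):
        cfg = af.SimulationConfig(
            n_molecules=2, n_cycles=30, frame_time=0.1,
            species_fractions={"donor_only": 0, "acceptor_only": 0, "double": 1.0},
            states=((0.2, 0.5), (0.6, 0.5)),
            exchange=af.Exchange("markov", k12=1000.0, k21=1000.0),
            shot_noise=False, camera=af.CameraModel(excess_noise=1.0), seed=0)
        for tr in af.simulate_traces(cfg):
            assert np.allclose(tr.truth.true_E, 0.4)


def test_truth_species_match_fractions():
    cfg = af.preset("L662-N", seed=8, n_molecules=600, n_cycles=10)
    counts = {s: 0 for s in SPECIES}
    for tr in af.simulate_traces(cfg):
        counts[tr.truth.species] += 1
    for s in SPECIES:
        assert abs(counts[s] / 600 - cfg.species_fractions[s]) < 0.08
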