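"""Photobleaching change points, trace selection, anti-correlation."""

import math

import numpy as np
import pytest

import alexfret as af
from alexfret import qc as afqc


class TestDetectSteps:
    def test_constant_noisy_series_no_steps(self):
        rng = np.random.default_rng(0)
        x = 1000 + rng.normal(0, 5, 500)
        assert afqc.detect_steps(x) == []

    def test_single_step_localized(self):
        rng = np.random.default_rng(1)
        x = np.where(np.arange(500) < 250, 1000.0, 0.0) + rng.normal(0, 5, 500)
        pts = afqc.detect_steps(x)
        assert len(pts) == 1
        assert abs(pts[0] - 250) <= 1

    def test_two_steps_localized(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([np.full(150, 1000.0), np.full(150, 500.0),
                            np.full(200, 0.0)]) + rng.normal(0, 5, 500)
        pts = afqc.detect_steps(x)
        assert len(pts) == 2
        assert abs(pts[0] - 150) <= 1 and abs(pts[1] - 300) <= 1

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="at least 10"):
            afqc.detect_steps(np.zeros(5))

    @pytest.mark.parametrize("snr", [10.0, 20.0])
    def test_step_detection_accuracy_at_snr(self, snr):
        """>=95% of single bleach steps found within +/-1 frame."""
        rng = np.random.default_rng(3)
        amp = 1000.0
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            k = rng.integers(50, 450)
            x = np.where(np.arange(500) < k, amp, 0.0) + rng.normal(0, amp / snr, 500)
            pts = afqc.detect_steps(x)
            if len(pts) == 1 and abs(pts[0] - k) <= 1:
                hits += 1
        assert hits / n_rep >= 0.95


class TestAnticorrelation:
    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(0)
        f_dd = 500 + rng.normal(0, 30, 200)
        f_da = 1000.0 - f_dd
        assert afqc.anticorrelation(f_dd, f_da) == pytest.approx(-1.0)

    def test_static_molecule_uncorrelated(self):
        cfg = af.SimulationConfig(
            n_molecules=20, n_cycles=400,
            species_fractions={"donor_only": 0, "acceptor_only": 0, "double": 1},
            states=((0.4, 1.0),), I_D0=1500.0, I_A0=1100.0, seed=5)
        rs = [afqc.anticorrelation(t.F_DD_raw, t.F_DA_raw)
              for t in af.simulate_traces(cfg)]
        # null r has SD 1/sqrt(n); allow 2/sqrt(n) per molecule, most must pass
        bound = 2 / math.sqrt(400)
        assert np.mean([abs(r) <= bound for r in rs]) >= 0.9

    def test_slow_exchange_strongly_anticorrelated(self):
        cfg = af.preset("L662-N", seed=9, n_molecules=20, n_cycles=300,
                        exchange=af.Exchange("markov", k12=0.5, k21=2.0),
                        bleach_tau_D=math.inf, bleach_tau_A=math.inf)
        rs = [afqc.anticorrelation(t.F_DD_raw, t.F_DA_raw)
              for t in af.simulate_traces(cfg) if t.truth.species == "double"]
        assert all(r < -0.5 for r in rs)

    def test_zero_variance_flagged_nan(self):
        r = afqc.anticorrelation(np.full(30, 5.0), np.arange(30.0))
        assert math.isnan(r)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            afqc.anticorrelation(np.zeros(10), np.zeros(10))


class TestSelectMolecules:
    def test_low_counts_rejected(self):
        rng = np.random.default_rng(0)
        tr = af.AlexTrace(0, 300 + rng.normal(0, 10, 100),
                          200 + rng.normal(0, 10, 100),
                          800 + rng.normal(0, 10, 100))
        _, reports = afqc.select_molecules([tr], min_mean_counts=1000)
        assert not reports[0].accepted
        assert "low_counts" in reports[0].reasons

    def test_two_acceptor_steps_rejected_multi_step(self):
        rng = np.random.default_rng(1)
        faa = np.concatenate([np.full(100, 1200.0), np.full(100, 600.0),
                              np.full(100, 0.0)]) + rng.normal(0, 10, 300)
        tr = af.AlexTrace(0, 1200 + rng.normal(0, 10, 300),
                          400 + rng.normal(0, 10, 300), faa)
        _, reports = afqc.select_molecules([tr])
        assert "multi_step_acceptor" in reports[0].reasons

    def test_intensity_up_step_rejected_as_aggregation(self):
        rng = np.random.default_rng(2)
        dd = np.concatenate([np.full(150, 1200.0), np.full(150, 2400.0)]) \
            + rng.normal(0, 10, 300)
        tr = af.AlexTrace(0, dd, 300 + rng.normal(0, 10, 300),
                          np.zeros(300) + rng.normal(0, 5, 300))
        _, reports = afqc.select_molecules([tr])
        assert "step_up" in reports[0].reasons

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            afqc.select_molecules([])

    def test_selection_is_idempotent(self, factors_and_background):
        _, bg = factors_and_background
        traces = af.simulate_traces(af.preset("H589-N", seed=17, n_molecules=60))
        accepted, _ = afqc.select_molecules(traces, background=bg)
        again, reports = afqc.select_molecules(accepted, background=bg)
        assert [t.molecule_id for t in again] == [t.molecule_id for t in accepted]
        assert all(r.accepted for r in reports)

    def test_accepted_count_in_plausible_range(self, factors_and_background):
        """Default conditions keep a few hundred of 400 simulated traces."""
        _, bg = factors_and_background
        traces = af.simulate_traces(af.preset("L662-N", seed=23))
        accepted, _ = afqc.select_molecules(traces, background=bg)
        assert 236 <= len(accepted) <= 406

    def test_bleach_frames_match_truth(self, factors_and_background):
        _, bg = factors_and_background
        traces = af.simulate_traces(af.preset("H589-N", seed=19, n_molecules=80))
        _, reports = afqc.select_molecules(traces, background=bg)
        for tr, rep in zip(traces, reports):
            t = tr.truth
            if t.species == "double" and t.bleach_cycle_A is not None \
                    and rep.bleach_frame_A is not None:
                assert abs(rep.bleach_frame_A - t.bleach_cycle_A) <= 1

    def test_donor_dequench_after_acceptor_bleach(self, factors_and_background):
        """Every accepted double with E>=0.2 shows a donor rise at acceptor bleach."""
        _, bg = factors_and_background
        traces = af.simulate_traces(af.preset("L662-P", seed=29, n_molecules=120))
        accepted, reports = afqc.select_molecules(traces, background=bg)
        by_id = {r.molecule_id: r for r in reports}
        checked = 0
        for tr in accepted:
            t = tr.truth
            rep = by_id[tr.molecule_id]
            ba = rep.bleach_frame_A
            if (t.species == "double" and t.true_E[0] >= 0.2 and ba is not None
                    and 10 < ba < tr.n_cycles - 10
                    and (t.bleach_cycle_D is None or t.bleach_cycle_D > ba + 10)):
                assert tr.F_DD_raw[ba + 1:ba + 11].mean() > tr.F_DD_raw[ba - 10:ba].mean()
                checked += 1
        assert checked >= 10
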