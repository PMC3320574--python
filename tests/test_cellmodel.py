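"""Paced heart-cell surrogate: dynamics, convergence protocol, invariants."""

import numpy as np
import pytest

from cgpgwas.cellmodel import (
    DEFAULT_BASELINES,
    DEFAULT_CONSTANTS,
    CellState,
    PacingProtocol,
    baseline_vector,
    derivatives,
    desk_roster,
    run_pacing,
    simulate_population,
    single_beat,
    surrogate_roster,
)
from cgpgwas.features import extract_features, extract_trace_features
from cgpgwas.gpmap import ParameterTable


def _table(values, names):
    values = np.atleast_2d(np.asarray(values, float))
    return ParameterTable(
        values=values, names=names,
        baselines=np.array([DEFAULT_BASELINES[n] for n in names]),
        nonpositive_flags=(values <= 0).any(axis=1),
    )


class TestDerivatives:
    def test_release_trigger_closed_at_rest(self):
        # v = 0 shuts the release flux regardless of SR load
        lo = derivatives(CellState(0.0, 1.0, 0.08, 500.0), 10.0)
        hi = derivatives(CellState(0.0, 1.0, 0.08, 5000.0), 10.0)
        # Cai dynamics must not see the SR load except through the leak:
        # remove the leak and the two rates coincide
        lo2 = derivatives(CellState(0.0, 1.0, 0.08, 500.0), 10.0, {"gleak": 0.0})
        hi2 = derivatives(CellState(0.0, 1.0, 0.08, 5000.0), 10.0, {"gleak": 0.0})
        assert lo2.Cai == pytest.approx(hi2.Cai, abs=1e-15)
        assert hi.Cai > lo.Cai  # leak is all that differs

    def test_leak_term_is_linear_in_gleak(self):
        s = CellState(0.0, 1.0, 0.05, 900.0)
        base = derivatives(s, 10.0, {"vNCX": 0.0, "vpCa": 0.0, "Vup": 0.0})
        dbl = derivatives(s, 10.0, {"vNCX": 0.0, "vpCa": 0.0, "Vup": 0.0,
                                    "gleak": 2 * DEFAULT_BASELINES["gleak"]})
        assert dbl.Cai == pytest.approx(2 * base.Cai, rel=1e-12)

    def test_quiescent_fixed_point_after_calibration(self):
        # let the unstimulated cell settle, then check all rates are small
        proto = PacingProtocol(bcl=300.0, stim_amplitude=0.0)
        beat = run_pacing(None, proto)
        assert beat.status == "converged"
        v, h, Cai, CaSR = beat.beat_initial_state
        rates = derivatives(CellState(v, h, Cai, CaSR), 10.0)  # outside stimulus
        assert abs(rates.v) < 1e-6
        assert abs(rates.h) < 1e-3
        assert abs(rates.Cai) < 1e-4
        assert abs(rates.CaSR) < 2e-2

    def test_calcium_conservation_in_closed_subsystem(self, rng):
        # with no sarcolemmal extrusion the buffered calcium content
        # d/dt [Cai_tot + CaSR_tot / lam] vanishes identically
        p = {"vNCX": 0.0, "vpCa": 0.0}
        full = dict(DEFAULT_BASELINES)
        full.update(DEFAULT_CONSTANTS)
        Kcam = full["off_rate"] / full["on_rate"]
        for _ in range(50):
            s = CellState(rng.uniform(0, 1), rng.uniform(0, 1),
                          rng.uniform(0.01, 1.0), rng.uniform(100, 2000))
            r = derivatives(s, 10.0, p)
            dcai_tot = r.Cai * (1 + full["Bcam"] * Kcam / (Kcam + s.Cai) ** 2)
            dcasr_tot = r.CaSR * (1 + full["Bcsqn"] * full["Kcsqn"]
                                  / (full["Kcsqn"] + s.CaSR) ** 2)
            assert dcai_tot + dcasr_tot / full["lam"] == pytest.approx(0.0, abs=1e-12)


class TestPacing:
    def test_baseline_converges_at_300ms(self):
        beat = run_pacing(None, PacingProtocol(bcl=300.0))
        assert beat.status == "converged"
        # regression: the calibrated baseline settles in 7 beats
        assert beat.beats_to_convergence == 7

    def test_all_three_pacing_rates_converge_at_baseline(self):
        for bcl in (100.0, 200.0, 300.0):
            assert run_pacing(None, PacingProtocol(bcl=bcl)).status == "converged"

    def test_no_stimulus_converges_second_beat_at_rest(self):
        beat = run_pacing(None, PacingProtocol(bcl=300.0, stim_amplitude=0.0))
        assert beat.status == "converged"
        assert beat.beats_to_convergence == 2
        assert np.all(np.abs(beat.voltage + 80.0) < 1.0)

    def test_nonrepolarizing_cell_fails(self):
        bad = {"tau_close": DEFAULT_BASELINES["tau_close"] * 1e6}
        beat = run_pacing(bad, PacingProtocol(bcl=300.0, max_sim_time=60_000.0))
        assert beat.status == "failure"

    def test_determinism_bit_for_bit(self):
        a = run_pacing({"Vup": 0.007}, PacingProtocol(bcl=300.0))
        b = run_pacing({"Vup": 0.007}, PacingProtocol(bcl=300.0))
        assert np.array_equal(a.voltage, b.voltage)
        assert np.array_equal(a.calcium, b.calcium)
        assert a.beats_to_convergence == b.beats_to_convergence

    def test_protocol_equivalence_reintegrating_converged_state(self):
        proto = PacingProtocol(bcl=300.0)
        beat = run_pacing(None, proto)
        again = run_pacing(None, proto, initial_state=beat.beat_initial_state)
        assert again.status == "converged"
        # the protocol's own convergence metric: beat-initial state and
        # per-state trajectory integrals agree within rel_tol
        assert np.allclose(again.beat_initial_state, beat.beat_initial_state,
                           rtol=proto.rel_tol, atol=1e-12)
        for a, b in ((again.voltage, beat.voltage), (again.calcium, beat.calcium)):
            ia, ib = np.trapezoid(a, beat.time), np.trapezoid(b, beat.time)
            assert abs(ia - ib) <= proto.rel_tol * abs(ib)

    def test_monotonicity_spot_checks(self):
        # acute single-beat response from the converged baseline state:
        # more potassium conductance shortens the action potential, stronger
        # SERCA uptake speeds calcium-transient relaxation
        proto = PacingProtocol(bcl=300.0)
        beat = run_pacing(None, proto)
        base = extract_features(beat)
        gk_up = {k: DEFAULT_BASELINES[k] * 1.2 for k in ("gK1", "gKto", "gKur")}
        b1 = single_beat(gk_up, proto, beat.beat_initial_state)
        f1 = extract_trace_features(b1.time, b1.voltage, "ap")
        assert f1["apd90"] < base["apd90"]
        b2 = single_beat({"Vup": DEFAULT_BASELINES["Vup"] * 1.2}, proto,
                         beat.beat_initial_state)
        f2 = extract_trace_features(b2.time, b2.calcium, "ct")
        assert f2["ctd50"] < base["ctd50"]

    def test_invalid_protocol_rejected(self):
        with pytest.raises(Exception):
            PacingProtocol(bcl=2.0, stim_duration=3.0)


class TestSimulatePopulation:
    def test_empty_table_gives_empty_result(self):
        table = _table(np.empty((0, 2)), ["gNa", "Vup"])
        out = simulate_population(table, [PacingProtocol(bcl=300.0)])
        assert out[300.0] == []

    def test_identical_rows_identical_waveforms(self):
        names = ["gNa", "Vup"]
        vals = [[DEFAULT_BASELINES["gNa"], DEFAULT_BASELINES["Vup"]]] * 2
        out = simulate_population(_table(vals, names), [PacingProtocol(bcl=300.0)])
        a, b = out[300.0]
        assert np.array_equal(a.voltage, b.voltage)
        assert np.array_equal(a.calcium, b.calcium)

    def test_nonpositive_parameter_marked_failure_without_integration(self):
        table = _table([[-1.0, DEFAULT_BASELINES["Vup"]]], ["gNa", "Vup"])
        out = simulate_population(table, [PacingProtocol(bcl=300.0)])
        beat = out[300.0][0]
        assert beat.status == "failure"
        assert "non-positive" in beat.failure_reason

    def test_small_perturbations_all_converge_with_small_spread(self, rng):
        names = [s.name for s in desk_roster()]
        base = np.array([DEFAULT_BASELINES[n] for n in names])
        vals = base * (1 + rng.uniform(-0.01, 0.01, size=(30, len(names))))
        out = simulate_population(_table(vals, names), [PacingProtocol(bcl=300.0)])
        feats = []
        for beat in out[300.0]:
            assert beat.status == "converged"
            feats.append(extract_features(beat)["apd90"])
        feats = np.array(feats)
        assert feats.std() < 0.1 * feats.mean()


def test_rosters_expose_calibrated_baselines():
    full = surrogate_roster()
    assert len(full) == 17
    assert {s.name for s in desk_roster()} <= {s.name for s in full}
    for s in full:
        assert s.baseline == DEFAULT_BASELINES[s.name]
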