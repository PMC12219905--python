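"""Bloch-engine physics: pulses, relaxation, full-sequence simulation."""

import numpy as np
import pytest

from molli_ptnn import (
    SequenceParams,
    SpinState,
    TiConfig,
    analytic_ll_oracle,
    apply_rf_pulse,
    build_schedule,
    free_relax,
    make_sech_pulse,
    make_sinc_pulse,
    simulate_molli_signal,
    simulate_molli_signals,
    synthesize_triggers,
)
from molli_ptnn.bloch import SignalVector, _apply_affine, _pulse_propagator


class TestFreeRelax:
    def test_zero_duration_is_identity(self, params):
        st = SpinState.equilibrium(params)
        st.M[:] = [0.4, -0.3, 0.2]
        out = free_relax(st, 0.0, 1000.0, 50.0)
        assert np.array_equal(out.M, st.M)

    def test_inversion_null_at_t1_ln2(self, params):
        st = SpinState.equilibrium(params)
        st.M[:, 2] = -1.0
        out = free_relax(st, 1000.0 * np.log(2.0), 1000.0, 50.0)
        assert np.allclose(out.M[:, 2], 0.0, atol=1e-12)

    def test_transverse_e_folding(self, params):
        st = SpinState.equilibrium(params)
        st.M[:] = [1.0, 0.0, 0.0]
        out = free_relax(st, 45.0, 1000.0, 45.0)
        assert np.allclose(np.hypot(out.M[:, 0], out.M[:, 1]), np.exp(-1.0))

    def test_negative_duration_rejected(self, params):
        with pytest.raises(ValueError):
            free_relax(SpinState.equilibrium(params), -1.0, 1000.0, 45.0)


class TestRFPulses:
    def test_zero_amplitude_pulse_equals_free_relaxation(self, params):
        n = 98
        from molli_ptnn.bloch import RFPulse

        null_pulse = RFPulse(name="null", step_us=5.0,
                             omega1=np.zeros(n, complex), freq_mod=np.zeros(n))
        st = SpinState.equilibrium(params)
        st.M[:] = [0.5, 0.1, -0.4]
        a = apply_rf_pulse(st, null_pulse, 800.0, 60.0)
        b = free_relax(st, n * 5e-3, 800.0, 60.0)
        assert np.allclose(a.M, b.M, atol=1e-12)

    def test_sech_inversion_efficiency(self, params):
        st = SpinState.equilibrium(params)
        pulse = params.inversion_pulse()
        # without relaxation: > 99% inversion on resonance
        no_relax = apply_rf_pulse(st, pulse, 1e9, 1e9)
        assert no_relax.M[params.n_isochromats // 2, 2] < -0.99
        # with relaxation: slightly degraded but still near-complete
        relaxed = apply_rf_pulse(st, pulse, 1000.0, 200.0)
        assert relaxed.M[params.n_isochromats // 2, 2] < -0.95

    def test_sech_against_finer_time_step(self, params):
        """1 us integration is the reference for the 5 us default."""
        st = SpinState.equilibrium(params)
        coarse = apply_rf_pulse(st, make_sech_pulse(step_us=5.0), 1000.0, 200.0)
        fine = apply_rf_pulse(st, make_sech_pulse(step_us=1.0), 1000.0, 200.0)
        assert np.allclose(coarse.M, fine.M, atol=1e-4)

    def test_sinc_excitation_center_flip(self, params):
        """Short-pulse limit: on-resonance tip equals the nominal flip angle."""
        st = SpinState.equilibrium(params)
        out = apply_rf_pulse(st, params.excitation_pulse(), 1e9, 1e9)
        center = params.n_isochromats // 2
        mxy = np.hypot(out.M[center, 0], out.M[center, 1])
        assert mxy == pytest.approx(np.sin(np.deg2rad(35.0)), rel=0.01)
        # far off-slice isochromats are barely excited
        edge = np.hypot(out.M[0, 0], out.M[0, 1])
        assert edge < 0.05 * mxy

    def test_slice_profile_sums_coherently(self, params):
        st = SpinState.equilibrium(params)
        out = apply_rf_pulse(st, params.excitation_pulse(), 1e9, 1e9)
        # refocused profile: slice-summed signal ~ (in-slice count) * sin(35 deg)
        assert out.transverse_signal > 8 * np.sin(np.deg2rad(35.0))

    def test_magnitude_never_exceeds_equilibrium(self, params):
        for T1, T2 in [(700.0, 50.0), (1000.0, 45.0), (1600.0, 200.0),
                       (600.0, 600.0)]:
            st = SpinState.equilibrium(params)
            out = apply_rf_pulse(st, params.inversion_pulse(), T1, T2)
            assert np.all(np.linalg.norm(out.M, axis=1) <= 1.0 + 1e-9)
            out = apply_rf_pulse(out, params.excitation_pulse(), T1, T2)
            assert np.all(np.linalg.norm(out.M, axis=1) <= 1.0 + 1e-9)

    def test_invalid_relaxation_times(self, params):
        with pytest.raises(ValueError):
            apply_rf_pulse(SpinState.equilibrium(params),
                           params.excitation_pulse(), -1.0, 45.0)


def test_batched_propagator_matches_direct_integration(params):
    """The affine-composed pulse operator is the step integrator, exactly."""
    pos = params.isochromat_positions_mm()
    st = SpinState.equilibrium(params)
    st.M[:] = [0.3, -0.2, 0.5]
    for pulse in (params.excitation_pulse(), params.inversion_pulse()):
        direct = apply_rf_pulse(st, pulse, 1000.0, 45.0)
        A, b = _pulse_propagator(pulse, np.array([1000.0]), np.array([45.0]), pos)
        batch = _apply_affine(A, b, st.M[None])[0]
        assert np.allclose(direct.M, batch, atol=1e-12)


class TestFullSimulation:
    def test_eight_nonnegative_magnitudes(self, schedule_533, params):
        sig = simulate_molli_signal(schedule_533, params, 1000.0, 45.0)
        assert sig.magnitudes.shape == (8,)
        assert np.all(sig.magnitudes >= 0)
        assert np.array_equal(sig.effective_tis, schedule_533.effective_tis)

    def test_ideal_mode_matches_closed_form_recursion(self, ideal_params):
        for rr in (800.0, 1000.0, 1200.0):
            sched = build_schedule(
                "5(3)3", synthesize_triggers(rr, 0.0, 12, seed=0))
            for t1 in (600.0, 1000.0, 1600.0, 2000.0):
                sim = simulate_molli_signals(sched, ideal_params, [t1], [100.0])[0]
                oracle = analytic_ll_oracle(sched, t1).magnitudes
                rel = np.abs(sim - oracle) / np.maximum(np.abs(oracle), 1e-9)
                assert rel.max() < 1e-6

    def test_oracle_null_and_recovery_limit(self):
        t1 = 900.0
        cfg = TiConfig(ti_offsets_per_group=(t1 * np.log(2.0), 180.0))
        sched = build_schedule(
            "5(3)3", synthesize_triggers(5000.0, 0.0, 12, seed=0), cfg)
        oracle = analytic_ll_oracle(sched, t1)
        # first sample at TI = T1 ln2 nulls exactly
        assert oracle.magnitudes[0] == pytest.approx(0.0, abs=1e-12)
        # longest first-group TI (4 long RRs ~ 22 T1) is fully recovered
        assert oracle.magnitudes[4] == pytest.approx(1.0, abs=1e-6)

    def test_no_hidden_randomness(self, schedule_533, params):
        a = simulate_molli_signals(schedule_533, params, [1000.0], [45.0])
        b = simulate_molli_signals(schedule_533, params, [1000.0], [45.0])
        assert np.array_equal(a, b)

    def test_rf_step_convergence(self, schedule_533):
        coarse = simulate_molli_signals(
            schedule_533, SequenceParams(rf_step_us=5.0), [1000.0], [45.0])[0]
        fine = simulate_molli_signals(
            schedule_533, SequenceParams(rf_step_us=2.5), [1000.0], [45.0])[0]
        assert np.max(np.abs(coarse - fine) / fine) < 1e-4

    def test_recovery_monotone_beyond_null(self, schedule_533, params):
        # group-1 TIs 1100..4100 ms are past the null for these T1s
        for t1 in (700.0, 1000.0, 1300.0):
            sig = simulate_molli_signal(schedule_533, params, t1, 150.0)
            assert np.all(np.diff(sig.magnitudes[1:5]) > 0)

    def test_batch_equals_singletons(self, schedule_533, params):
        t1s, t2s = np.array([700.0, 1300.0]), np.array([50.0, 180.0])
        batch = simulate_molli_signals(schedule_533, params, t1s, t2s)
        for i in range(2):
            single = simulate_molli_signal(schedule_533, params,
                                           t1s[i], t2s[i]).magnitudes
            assert np.allclose(batch[i], single, atol=1e-12)


def test_signal_vector_validation():
    with pytest.raises(ValueError):
        SignalVector(magnitudes=np.ones(8) * 0.5, effective_tis=np.arange(1, 9),
                     normalized=True)  # norm != 1
    v = SignalVector(magnitudes=np.array([3.0, 1.0]),
                     effective_tis=np.array([200.0, 100.0]))
    assert np.array_equal(v.sorted().magnitudes, [1.0, 3.0])


def test_sequence_params_validation():
    with pytest.raises(ValueError):
        SequenceParams(n_isochromats=20)      # must be odd
    with pytest.raises(ValueError):
        SequenceParams(center_line_index=62)  # out of range
    with pytest.raises(ValueError):
        SequenceParams(rf_step_us=3.0)        # does not divide 490 us


def test_pulse_waveform_export(params, tmp_path):
    from molli_ptnn.io import export_pulse_csv

    path = tmp_path / "sinc.csv"
    export_pulse_csv(params.excitation_pulse(), path)
    table = np.loadtxt(path, delimiter=",", skiprows=1)
    assert table.shape == (98, 3)
    assert table[:, 0].max() < 490.0
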