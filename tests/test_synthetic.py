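"""Stimulus generators and oscillator simulation against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crestvib import (
    ForcingSignal,
    OscillatorParams,
    lorentzian_response,
    make_chirp,
    make_forcing,
    render_video,
    simulate_response,
    track_objects,
)
from crestvib.errors import (
    InvalidParameterError,
    OutOfBoundsError,
    OverdampedError,
)
from crestvib.synthetic import chirp_instantaneous_frequency
from crestvib.tracking import ROI, TrackConfig


class TestOscillatorParams:
    def test_derived_quantities(self):
        p = OscillatorParams(f_r=26.3, Q=6.2)
        assert p.delta_f == pytest.approx(26.3 / 6.2)
        assert p.zeta == pytest.approx(1 / 12.4)
        # undamped frequency placed so the forced-response peak is at f_r
        assert p.f_undamped == pytest.approx(26.3 / np.sqrt(1 - 1 / (2 * 6.2**2)))
        assert p.f_damped < p.f_undamped

    @pytest.mark.parametrize("kwargs", [
        dict(f_r=-1, Q=5), dict(f_r=26, Q=0.4), dict(f_r=26, Q=5, gain=0),
    ])
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(InvalidParameterError):
            OscillatorParams(**kwargs)


class TestChirp:
    def test_protocol_duration_and_ramp(self):
        c = make_chirp(0.0, 80.0, 1.33, fs=240.0)
        assert c.duration == pytest.approx(80 / 1.33, abs=1 / 240)
        f = chirp_instantaneous_frequency(c)
        i = int(round(10.0 * c.fs))
        assert f[i] == pytest.approx(13.3, abs=0.01)

    def test_zero_crossings_match_phase_integral(self):
        # cycles completed = integral of f(t) = (f_end^2 - f_start^2)/(2*rate)
        c = make_chirp(10.0, 120.0, 1.83, fs=480.0)
        assert c.duration == pytest.approx(110 / 1.83, abs=1 / 480)
        crossings = int(np.sum(np.diff(np.signbit(c.u)) != 0))
        cycles = (120.0**2 - 10.0**2) / (2 * 1.83)
        assert abs(crossings - 2 * cycles) <= 2

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            make_chirp(0, 80, -1.0)
        with pytest.raises(InvalidParameterError):
            make_chirp(0, 80, 1.33, fs=100.0)  # Nyquist violation


class TestMakeForcing:
    def test_sine_is_single_line(self):
        s = make_forcing("sine", dict(frequency=4.95, amplitude=1.0), fs=240, duration=60)
        spec = np.abs(np.fft.rfft(s.u))
        freqs = np.fft.rfftfreq(len(s.u), 1 / 240)
        assert freqs[np.argmax(spec)] == pytest.approx(4.95, abs=1 / 60)
        # everything off the line is leakage, orders of magnitude down
        top = np.max(spec)
        off = spec[np.abs(freqs - 4.95) > 1.0]
        assert np.max(off) < 0.01 * top

    def test_white_noise_rms_exact(self):
        w = make_forcing("white_noise", dict(rms=1.0), fs=240, duration=300, seed=1)
        assert w.rms == pytest.approx(1.0, abs=0.01)

    def test_impulse_train_spacing_rounds_to_sample(self):
        tr = make_forcing("impulse_train", dict(rate=26.7), fs=2400, duration=2, seed=1)
        assert tr.params["period_samples"] == round(2400 / 26.7) == 90

    def test_impulse_train_rate_above_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_forcing("impulse_train", dict(rate=1500.0), fs=2400, duration=1)

    def test_seeded_outputs_reproducible(self):
        a = make_forcing("white_noise", dict(rms=1.0), fs=240, duration=5, seed=7)
        b = make_forcing("white_noise", dict(rms=1.0), fs=240, duration=5, seed=7)
        assert np.array_equal(a.u, b.u)


class TestLorentzian:
    def test_peak_identity_and_off_peak_value(self):
        # H(f_r) = Q^2 and H(2 f_r) = 2/(9 + 4/Q^2)
        Q = 6.2
        fr = 26.3
        df = fr / Q
        assert lorentzian_response(fr, fr, df) == pytest.approx(Q**2)
        assert lorentzian_response(2 * fr, fr, df) == pytest.approx(
            2 / (9 + 4 / Q**2), rel=1e-12)
        assert lorentzian_response(2 * fr, fr, df) == pytest.approx(0.2197, abs=5e-4)

    def test_zero_frequency_is_zero(self):
        assert lorentzian_response(0.0, 26.3, 4.24) == 0.0


class TestSimulateResponse:
    def test_transfer_envelope_at_resonance(self, male_params, study_chirp):
        trial = simulate_response(male_params, study_chirp, mode="transfer")
        f = chirp_instantaneous_frequency(study_chirp)
        i = int(np.argmin(np.abs(f - male_params.f_r)))
        window = trial.response[i - 120:i + 120]
        assert np.max(np.abs(window)) == pytest.approx(
            male_params.gain * male_params.Q**2, rel=0.01)

    def test_transfer_requires_chirp(self, male_params):
        s = make_forcing("sine", dict(frequency=5.0), fs=240, duration=5)
        with pytest.raises(InvalidParameterError):
            simulate_response(male_params, s, mode="transfer")

    def test_ode_rejects_overdamped(self):
        # bypass the dataclass guard to exercise the ODE-mode check
        p = OscillatorParams(f_r=26.3, Q=0.6)
        with pytest.raises(OverdampedError):
            p.f_undamped  # radicand <= 0 for Q <= 1/sqrt(2)

    def test_ode_ringdown_decay_to_a_few_percent(self, male_params):
        # amplitude after 0.2 s of free decay: exp(-pi*f*0.2/Q) ~ 7%
        imp = make_forcing("impulse", dict(width=0.005, magnitude=50.0, center=0.1),
                           fs=2400, duration=1.5)
        trial = simulate_response(male_params, imp, mode="ode")
        x = trial.response
        i0 = int(np.argmax(np.abs(x)))
        a0 = abs(x[i0])
        i1 = i0 + int(0.2 * 2400)
        a1 = np.max(np.abs(x[i1:i1 + 2400 // 20]))  # max over ~half a cycle
        expected = np.exp(-np.pi * male_params.f_undamped * 0.2 / male_params.Q)
        assert a1 / a0 == pytest.approx(expected, rel=0.15)
        assert 0.02 < a1 / a0 < 0.12  # "a few percent"

    def test_ode_free_decay_frequency_matches_closed_form(self, male_params):
        imp = make_forcing("impulse", dict(width=0.003, magnitude=1.0, center=0.05),
                           fs=2400, duration=1.0)
        x = simulate_response(male_params, imp, mode="ode").response
        seg = x[int(0.12 * 2400):]
        crossings = np.where(np.diff(np.signbit(seg)) != 0)[0]
        # zero-crossing frequency over the first 20 crossings
        span = (crossings[20] - crossings[0]) / 2400
        f_meas = 10.0 / span
        assert f_meas == pytest.approx(male_params.f_damped, rel=0.005)

    def test_noise_is_seeded_and_reproducible(self, male_params, study_chirp):
        a = simulate_response(male_params, study_chirp, noise_sd=0.05,
                              noise_kind="multiplicative", seed=3)
        b = simulate_response(male_params, study_chirp, noise_sd=0.05,
                              noise_kind="multiplicative", seed=3)
        c = simulate_response(male_params, study_chirp, noise_sd=0.05,
                              noise_kind="multiplicative", seed=4)
        assert np.array_equal(a.response, b.response)
        assert not np.array_equal(a.response, c.response)


class TestRenderVideo:
    def test_static_blob_centroid(self):
        traj = np.tile([[100.0, 50.5]], (5, 1))
        frames = render_video(traj, frame_size=(120, 200), blob_radius=4.0)
        series = track_objects(frames, TrackConfig(rois=[ROI(80, 30, 60, 50)]))[0]
        assert np.allclose(series.x, 100.0, atol=0.05)
        assert np.allclose(series.y, 50.5, atol=0.05)

    def test_two_blobs_in_disjoint_rois_independent(self):
        t1 = np.tile([[50.0, 40.0]], (4, 1))
        t2 = np.tile([[150.0, 80.0]], (4, 1))
        frames = render_video([t1, t2], frame_size=(120, 200), blob_radius=3.0)
        cfg = TrackConfig(rois=[ROI(30, 20, 40, 40), ROI(130, 60, 40, 40)])
        s1, s2 = track_objects(frames, cfg)
        assert np.allclose(s1.x, 50.0, atol=0.05) and np.allclose(s1.y, 40.0, atol=0.05)
        assert np.allclose(s2.x, 150.0, atol=0.05) and np.allclose(s2.y, 80.0, atol=0.05)

    def test_out_of_bounds_reports_first_frame(self):
        traj = np.array([[100.0, 50.0], [100.0, 50.0], [100.0, 2.0]])
        with pytest.raises(OutOfBoundsError, match="frame 2"):
            render_video(traj, frame_size=(120, 200), blob_radius=4.0)


@settings(deadline=None, max_examples=25)
@given(f_r=st.floats(5.0, 50.0), q=st.floats(2.0, 20.0))
def test_lorentzian_peak_value_is_q_squared(f_r, q):
    assert lorentzian_response(f_r, f_r, f_r / q) == pytest.approx(q * q, rel=1e-9)
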