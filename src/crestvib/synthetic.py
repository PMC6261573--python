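"""Synthetic stimuli, oscillator responses, and rendered video with known ground truth.

The experimental system is a feather crest clamped at its base and driven
through that base — mechanically a base-excited, lightly damped cantilever
whose fundamental mode behaves as a single-degree-of-freedom damped harmonic
oscillator.  Every stimulus protocol used on real crests is emulated here
with a known resonant frequency ``f_r`` and quality factor ``Q`` so that the
downstream estimators can be validated by parameter recovery:

* linear frequency sweeps (chirps, e.g. 0-80 Hz at 1.33 Hz/s),
* single short force impulses (air-vortex impacts),
* periodic trains of broadband bursts at ~25-27 Hz (train-rattling playback),
* equal-rms Gaussian white noise (playback control),
* ~5 Hz sinusoidal forcing (wing-shaking),

all observed at a 240 frames/s video rate with additive measurement noise.

Two synthesis modes are provided.  ``transfer`` mode defines the response
directly from the empirical Lorentzian transfer function, so that the sweep
pipeline's fit model is exact by construction; ``ode`` mode integrates a
physical second-order linear oscillator and is used for impulse and
forced-response protocols where the transient dynamics matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import (
    InvalidParameterError,
    OutOfBoundsError,
    OverdampedError,
    ResolutionError,
)

#: Default RNG seed used when none is supplied.
DEFAULT_SEED = 20181128

#: Video observation rate of the high-speed camera (frames per second).
VIDEO_FS = 240.0

#: Minimum internal integration rate for ODE-mode simulation (Hz).
INTERNAL_FS_MIN = 2000.0


def lorentzian_response(f_d, f_r: float, delta_f: float, scale: float = 1.0):
    """Empirical Lorentzian drive transfer function of a resonant cantilever.

    H(f_d) = (f_r/f_d) / [ (f_r/f_d - f_d/f_r)^2 + (delta_f/f_r)^2 ]

    where ``f_r`` is the resonant frequency and ``delta_f`` the full width at
    half maximum of the spectral power.  At ``f_d = f_r`` this evaluates to
    ``Q**2`` with ``Q = f_r/delta_f``.  Defined as 0 at ``f_d = 0``.
    """
    f_d = np.asarray(f_d, dtype=float)
    out = np.zeros_like(f_d)
    nz = f_d > 0
    u = f_r / f_d[nz]
    out[nz] = u / ((u - 1.0 / u) ** 2 + (delta_f / f_r) ** 2)
    return scale * out


@dataclass(frozen=True)
class OscillatorParams:
    """Ground-truth description of a crest's fundamental vibrational mode.

    Parameters
    ----------
    f_r
        Resonant frequency (Hz): drive frequency of maximal forced response.
    Q
        Quality factor ``f_r / delta_f`` (dimensionless, > 0.5 i.e. underdamped).
    gain
        Static response scale applied to the transfer function (dimensionless).
    label
        Free-text identifier (e.g. crest id).
    """

    f_r: float
    Q: float
    gain: float = 1.0
    label: str = ""

    def __post_init__(self):
        if not self.f_r > 0:
            raise InvalidParameterError(f"f_r must be positive, got {self.f_r}")
        if not self.Q > 0.5:
            raise InvalidParameterError(f"Q must exceed 0.5 (underdamped), got {self.Q}")
        if not self.gain > 0:
            raise InvalidParameterError(f"gain must be positive, got {self.gain}")

    @property
    def delta_f(self) -> float:
        """Full width at half maximum of the spectral power peak (Hz)."""
        return self.f_r / self.Q

    @property
    def zeta(self) -> float:
        """Damping ratio of the equivalent second-order system, 1/(2Q)."""
        return 1.0 / (2.0 * self.Q)

    @property
    def f_undamped(self) -> float:
        """Undamped natural frequency f_n (Hz).

        Chosen as f_r / sqrt(1 - 1/(2 Q^2)) so that the forced-response
        amplitude peak of the second-order system sits exactly at f_r,
        making f_r mean the same thing in both synthesis modes.
        """
        rad = 1.0 - 1.0 / (2.0 * self.Q**2)
        if rad <= 0:
            raise OverdampedError(f"Q={self.Q} too small for a forced-response peak")
        return self.f_r / math.sqrt(rad)

    @property
    def f_damped(self) -> float:
        """Damped free-oscillation (ring-down) frequency f_n*sqrt(1 - zeta^2) (Hz)."""
        return self.f_undamped * math.sqrt(1.0 - self.zeta**2)

    @property
    def tau(self) -> float:
        """Amplitude e-folding time of free decay, Q/(pi*f_undamped) (s)."""
        return self.Q / (math.pi * self.f_undamped)


@dataclass
class ForcingSignal:
    """A forcing/base-displacement waveform on a uniform time grid."""

    t: np.ndarray
    u: np.ndarray
    fs: float
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.t.shape != self.u.shape:
            raise InvalidParameterError("t and u must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
                raise InvalidParameterError("t must be uniform with spacing 1/fs")

    @property
    def duration(self) -> float:
        return len(self.t) / self.fs

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.u**2)))


@dataclass
class SweepTrial:
    """Paired drive/response series for one trial (sweep or other protocol)."""

    drive: ForcingSignal
    response: np.ndarray
    truth: OscillatorParams | None = None
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != self.drive.t.shape:
            raise InvalidParameterError("drive and response must share the time grid")

    @property
    def t(self) -> np.ndarray:
        return self.drive.t

    @property
    def fs(self) -> float:
        return self.drive.fs


def make_chirp(
    f_start: float,
    f_end: float,
    sweep_rate: float,
    amplitude: float = 1.0,
    fs: float = VIDEO_FS,
) -> ForcingSignal:
    """Linear frequency sweep: f(t) = f_start + sweep_rate * t.

    Duration is ``(f_end - f_start) / sweep_rate``; the phase is the integral
    of the instantaneous frequency.  ``fs`` must satisfy Nyquist for ``f_end``.
    """
    if sweep_rate <= 0:
        raise InvalidParameterError("sweep_rate must be positive")
    if fs <= 0:
        raise InvalidParameterError("fs must be positive")
    if not (f_end > f_start >= 0):
        raise InvalidParameterError("need f_end > f_start >= 0")
    if fs <= 2 * f_end:
        raise InvalidParameterError(f"fs={fs} violates Nyquist for f_end={f_end}")
    duration = (f_end - f_start) / sweep_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phase = 2 * np.pi * (f_start * t + 0.5 * sweep_rate * t**2)
    u = amplitude * np.sin(phase)
    return ForcingSignal(
        t=t, u=u, fs=fs, kind="chirp",
        params=dict(f_start=f_start, f_end=f_end, sweep_rate=sweep_rate,
                    amplitude=amplitude),
    )


def chirp_instantaneous_frequency(forcing: ForcingSignal) -> np.ndarray:
    """Instantaneous drive frequency of a chirp forcing, per sample (Hz)."""
    if forcing.kind != "chirp":
        raise InvalidParameterError("instantaneous frequency defined for chirp forcing")
    p = forcing.params
    return p["f_start"] + p["sweep_rate"] * forcing.t


def make_forcing(
    kind: str,
    params: dict,
    fs: float,
    duration: float,
    seed: int | None = None,
) -> ForcingSignal:
    """Construct a non-chirp stimulus waveform on a uniform grid.

    Supported kinds and their parameters:

    ``impulse``
        ``width`` (s, Gaussian sigma of the pulse), ``magnitude``, optional
        ``center`` (s, default 3 widths in).  Models a single vortex impact.
    ``impulse_train``
        ``rate`` (Hz repetition), ``burst_width`` (s, default 8 ms),
        ``carrier_bandwidth`` (Hz, default 500 — the burst carrier is noise
        low-passed to this bandwidth, broadband relative to the repetition
        rate but finite like a mechanical click), ``magnitude``.  One
        Gaussian-windowed burst realization repeated periodically, the
        period rounded to the nearest whole sample.
    ``white_noise``
        ``rms`` target root-mean-square amplitude (scaled exactly).
    ``sine``
        ``frequency`` (Hz), ``amplitude``, optional ``phase`` (rad).
    """
    if fs <= 0 or duration <= 0:
        raise InvalidParameterError("fs and duration must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)

    if kind == "impulse":
        width = float(params["width"])
        mag = float(params["magnitude"])
        if width <= 0:
            raise InvalidParameterError("impulse width must be positive")
        if width < 2.0 / fs:
            raise ResolutionError(f"impulse width {width}s unresolvable at fs={fs}")
        center = float(params.get("center", 3.0 * width))
        u = mag * np.exp(-0.5 * ((t - center) / width) ** 2)
    elif kind == "impulse_train":
        rate = float(params["rate"])
        if rate <= 0:
            raise InvalidParameterError("repetition rate must be positive")
        if rate >= fs / 2:
            raise InvalidParameterError(f"repetition rate {rate} >= Nyquist {fs / 2}")
        burst_width = float(params.get("burst_width", 0.008))
        mag = float(params.get("magnitude", 1.0))
        period = int(round(fs / rate))
        u = np.zeros(n)
        half = max(int(round(3 * burst_width * fs)), 1)
        win = np.exp(-0.5 * (np.arange(-half, half + 1) / (burst_width * fs)) ** 2)
        # one broadband burst realization repeated every period: rattle notes
        # are temporally coherent, so the train is strictly periodic and its
        # spectrum is a line comb at harmonics of the repetition rate
        carrier = rng.standard_normal(len(win))
        bw = float(params.get("carrier_bandwidth", 500.0))
        if bw < fs / 2:
            sos = signal.butter(4, bw, btype="low", fs=fs, output="sos")
            carrier = signal.sosfiltfilt(sos, carrier)
        burst = win * carrier
        for start in range(0, n, period):
            lo, hi = start - half, start + half + 1
            blo, bhi = max(0, -lo), len(win) - max(0, hi - n)
            u[max(lo, 0):min(hi, n)] += burst[blo:bhi]
        prms = float(np.sqrt(np.mean(u**2)))
        if prms > 0:
            u *= mag / prms  # normalize train rms to `magnitude`
        params = dict(params, period_samples=period)
    elif kind == "white_noise":
        rms = float(params["rms"])
        if rms <= 0:
            raise InvalidParameterError("target rms must be positive")
        u = rng.standard_normal(n)
        u *= rms / np.sqrt(np.mean(u**2))
    elif kind == "sine":
        f = float(params["frequency"])
        if f >= fs / 2:
            raise InvalidParameterError(f"sine frequency {f} >= Nyquist {fs / 2}")
        amp = float(params.get("amplitude", 1.0))
        phase = float(params.get("phase", 0.0))
        u = amp * np.sin(2 * np.pi * f * t + phase)
    else:
        raise InvalidParameterError(f"unknown forcing kind {kind!r}")

    return ForcingSignal(t=t, u=u, fs=fs, kind=kind, params=dict(params))


def _second_order_system(params: OscillatorParams):
    """State-space (A, B, C, D) of x'' + 2*zeta*wn*x' + wn^2 x = wn^2 u."""
    wn = 2 * np.pi * params.f_undamped
    z = params.zeta
    A = np.array([[0.0, 1.0], [-wn**2, -2 * z * wn]])
    B = np.array([[0.0], [wn**2]])
    C = np.array([[1.0, 0.0]])
    D = np.array([[0.0]])
    return A, B, C, D


def _integrate_ode(params: OscillatorParams, forcing: ForcingSignal) -> np.ndarray:
    """Integrate the second-order oscillator; returns response on forcing grid.

    Runs internally at >= INTERNAL_FS_MIN by integer upsampling (linear
    interpolation of the forcing), then decimates back with an anti-aliasing
    FIR filter to emulate camera-rate observation.
    """
    if params.Q <= 0.5:
        raise OverdampedError(f"Q={params.Q}: ODE mode requires an underdamped system")
    fs = forcing.fs
    factor = max(1, math.ceil(INTERNAL_FS_MIN / fs))
    fs_int = fs * factor
    if fs_int < 10 * params.f_undamped:
        raise ResolutionError(
            f"internal rate {fs_int} Hz too coarse for f_n={params.f_undamped:.1f} Hz"
        )
    if factor > 1:
        n_fine = len(forcing.u) * factor
        t_fine = np.arange(n_fine) / fs_int
        u = np.interp(t_fine, forcing.t, forcing.u)
    else:
        u = forcing.u
    sys_d = signal.cont2discrete(_second_order_system(params), 1.0 / fs_int, method="foh")
    Ad, Bd, Cd, Dd = sys_d[0], sys_d[1], sys_d[2], sys_d[3]
    # scalar-friendly recursion via lfilter on the equivalent difference equation
    num, den = signal.ss2tf(Ad, Bd, Cd, Dd)
    x = signal.lfilter(num[0], den, u)
    if factor > 1:
        x = signal.decimate(x, factor, ftype="fir", zero_phase=True)
        x = x[: len(forcing.u)]
    return params.gain * x


def simulate_response(
    params: OscillatorParams,
    forcing: ForcingSignal,
    mode: str = "transfer",
    noise_sd: float = 0.0,
    noise_kind: str = "additive",
    seed: int | None = None,
) -> SweepTrial:
    """Simulate the crest's motion under a forcing protocol.

    ``transfer`` mode (chirp forcing only) sets the response envelope at the
    instantaneous drive frequency to ``gain * H(f_d)`` with H the Lorentzian
    transfer function — the estimation pipeline's fit model holds exactly by
    construction.  ``ode`` mode integrates the physical second-order system
    (damping ratio 1/(2Q), undamped frequency placed so the forced-response
    peak is at ``f_r``).

    Measurement noise is applied last and is seeded: ``additive`` draws
    N(0, noise_sd) per sample; ``multiplicative`` scales each sample by
    ``1 + noise_sd * N(0, 1)``.
    """
    if mode == "transfer":
        if forcing.kind != "chirp":
            raise InvalidParameterError("transfer mode requires chirp forcing")
        f_inst = chirp_instantaneous_frequency(forcing)
        env = lorentzian_response(f_inst, params.f_r, params.delta_f, params.gain)
        x = env * forcing.u
    elif mode == "ode":
        x = _integrate_ode(params, forcing)
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")

    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
        if noise_kind == "additive":
            x = x + noise_sd * rng.standard_normal(len(x))
        elif noise_kind == "multiplicative":
            x = x * (1.0 + noise_sd * rng.standard_normal(len(x)))
        else:
            raise InvalidParameterError(f"unknown noise_kind {noise_kind!r}")

    return SweepTrial(drive=forcing, response=x, truth=params,
                      noise_sd=noise_sd, seed=seed)


def render_video(
    trajectories: np.ndarray | Sequence[np.ndarray],
    frame_size: tuple[int, int] = (120, 200),
    blob_radius: float = 4.0,
    background_noise_sd: float = 0.0,
    peak_intensity: float = 0.8,
    seed: int | None = None,
) -> np.ndarray:
    """Render bright Gaussian blobs following trajectories on a dark background.

    Parameters
    ----------
    trajectories
        Either an (n_frames, 2) array of (x, y) pixel positions for one
        object, or a sequence of such arrays for several objects.
    frame_size
        (height, width) in pixels.
    blob_radius
        Gaussian sigma of each blob (px).
    background_noise_sd
        Additive Gaussian intensity noise (fraction of full scale), seeded.

    Returns float frames in [0, 1], shape (n_frames, height, width);
    coordinates use image convention (origin top-left, x right, y down,
    0-based pixel centers).
    """
    if isinstance(trajectories, np.ndarray) and trajectories.ndim == 2:
        trajectories = [trajectories]
    trajectories = [np.asarray(tr, dtype=float) for tr in trajectories]
    h, w = frame_size
    margin = 3.0 * blob_radius
    n_frames = len(trajectories[0])
    for tr in trajectories:
        if len(tr) != n_frames:
            raise InvalidParameterError("all trajectories must have equal length")
        bad = np.where(
            (tr[:, 0] < margin) | (tr[:, 0] > w - 1 - margin)
            | (tr[:, 1] < margin) | (tr[:, 1] > h - 1 - margin)
        )[0]
        if len(bad):
            raise OutOfBoundsError(
                f"trajectory exits frame (margin {margin:.1f}px) first at frame {bad[0]}"
            )
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.zeros((n_frames, h, w))
    for tr in trajectories:
        dx = xx[None, :, :] - tr[:, 0, None, None]
        dy = yy[None, :, :] - tr[:, 1, None, None]
        frames += peak_intensity * np.exp(-(dx**2 + dy**2) / (2 * blob_radius**2))
    if background_noise_sd > 0:
        rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
        frames += background_noise_sd * rng.standard_normal(frames.shape)
    return np.clip(frames, 0.0, 1.0)
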