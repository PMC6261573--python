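"""Ring-down analysis of impulse (vortex-impact) responses.

After a short force impulse an underdamped crest oscillates freely at its
natural frequency ``f_o`` with an exponentially decaying amplitude,

    x(t) = A0 * exp(-(t - t0)/tau) * sin(2*pi*f_o*(t - t0) + phase) + offset.

The natural frequency measured this way cross-checks the sweep-derived
resonance parameters through

    f_o = f_r * sqrt(1 - 1/(2 Q^2))

(the printed relation; an alternative flag selects the textbook damped-free
frequency convention sqrt(1 - 1/(4 Q^2)), which differs by O(f_r/Q^2), well
inside the +/- 0.4*delta_f agreement bound observed on real crests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import hilbert

from .errors import FitFailureError, InsufficientDataError, InvalidParameterError
from .sweep import ResonanceFit


@dataclass
class RingDownFit:
    """Fitted exponentially decaying sinusoid."""

    f_o: float      # natural frequency, Hz
    tau: float      # amplitude e-folding time, s
    A0: float       # initial amplitude (same units as the input series)
    phase: float    # rad
    offset: float   # baseline
    r2_adj: float
    t_start: float  # fit segment start (s, in the input series' time base)

    def envelope(self, t):
        """Amplitude envelope A0*exp(-t/tau) at time t after t_start."""
        return self.A0 * np.exp(-np.asarray(t, dtype=float) / self.tau)


def _ringdown_model(t, A0, tau, f_o, phase, offset):
    return A0 * np.exp(-t / tau) * np.sin(2 * np.pi * f_o * t + phase) + offset


def fit_ringdown(
    series: np.ndarray,
    fs: float,
    t_start: float | None = None,
    min_cycles: float = 5.0,
    min_r2: float = 0.2,
    maxfev: int = 20_000,
) -> RingDownFit:
    """Fit a decaying sinusoid to the post-impulse segment of a motion series.

    ``t_start`` defaults to the first sample after the absolute maximum of
    the mean-removed series.  Initialization: ``f_o`` from the FFT peak of
    the segment, ``tau`` from a straight-line fit to the log of the
    analytic-signal envelope.  Requires at least ``min_cycles`` oscillation
    cycles after ``t_start``; incoherent input (adjusted R^2 below
    ``min_r2``) raises FitFailureError.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 16:
        raise InsufficientDataError("series too short for a ring-down fit")
    centered = x - np.mean(x)
    if t_start is None:
        i0 = int(np.argmax(np.abs(centered))) + 1
    else:
        i0 = int(round(t_start * fs))
    if i0 >= len(x) - 8:
        raise InsufficientDataError("post-impulse segment too short")
    seg = x[i0:]
    t = np.arange(len(seg)) / fs
    offset0 = float(np.mean(seg))
    y = seg - offset0

    # frequency init from the rectangular-window FFT peak (a Hann window would
    # null the decaying burst sitting at the segment's leading edge); bins
    # below two cycles over the segment are excluded as un-oscillatory
    spec = np.abs(np.fft.rfft(y, n=4 * len(y)))
    freqs = np.fft.rfftfreq(4 * len(y), d=1.0 / fs)
    kmin = int(np.searchsorted(freqs, 2.0 * fs / len(y)))
    k = int(np.argmax(spec[kmin:])) + kmin
    f0 = float(freqs[k])
    if f0 <= 0:
        raise FitFailureError("no oscillatory component found")
    n_cycles = t[-1] * f0
    if n_cycles < min_cycles:
        raise InsufficientDataError(
            f"only {n_cycles:.1f} cycles after t_start; need >= {min_cycles}"
        )

    analytic = hilbert(y)
    env = np.abs(analytic)
    # trim edges where the Hilbert envelope is unreliable
    m = len(env)
    sl = slice(m // 20, m - max(m // 20, 1))
    env_t, env_v = t[sl], env[sl]
    pos = env_v > env_v.max() * 1e-6
    slope, intercept = np.polyfit(env_t[pos], np.log(env_v[pos]), 1)
    tau0 = -1.0 / slope if slope < 0 else t[-1]
    tau0 = float(np.clip(tau0, 2.0 / (fs), 10 * t[-1]))
    A00 = float(np.exp(intercept))
    phase0 = float(np.angle(analytic[0]) + np.pi / 2)

    p0 = [A00, tau0, f0, phase0, offset0]
    try:
        popt, _ = curve_fit(
            _ringdown_model, t, seg, p0=p0, maxfev=maxfev,
            bounds=([0, 1.0 / fs, 0.1 * f0, -2 * np.pi, -np.inf],
                    [np.inf, np.inf, min(10 * f0, fs / 2), 2 * np.pi, np.inf]),
        )
    except RuntimeError as exc:
        raise FitFailureError(f"ring-down fit did not converge: {exc}") from exc
    resid = seg - _ringdown_model(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((seg - seg.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    n, p = len(seg), 5
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    if r2_adj < min_r2:
        raise FitFailureError(
            f"no coherent ring-down: adjusted R^2 = {r2_adj:.3f} < {min_r2}"
        )
    A0f, tauf, fof, phasef, offsetf = (float(v) for v in popt)
    return RingDownFit(f_o=fof, tau=tauf, A0=A0f, phase=phasef, offset=offsetf,
                       r2_adj=float(min(r2_adj, 1.0)), t_start=i0 / fs)


def predict_fo(f_r: float, Q: float, convention: str = "as_printed") -> float:
    """Natural frequency predicted from resonance parameters.

    ``as_printed``: f_r * sqrt(1 - 1/(2 Q^2)) — relates the forced-response
    peak to the free-oscillation frequency as used on the real crests.
    ``damped_free``: f_r * sqrt(1 - 1/(4 Q^2)) — the textbook damped natural
    frequency of a system whose undamped frequency is f_r.
    """
    if convention == "as_printed":
        rad = 1.0 - 1.0 / (2.0 * Q**2)
    elif convention == "damped_free":
        rad = 1.0 - 1.0 / (4.0 * Q**2)
    else:
        raise InvalidParameterError(f"unknown convention {convention!r}")
    if rad <= 0:
        raise InvalidParameterError(f"Q={Q} <= 1/sqrt(2): radicand non-positive")
    return f_r * math.sqrt(rad)


def consistency_check(
    fit: ResonanceFit,
    ring: RingDownFit,
    convention: str = "as_printed",
) -> float:
    """|measured f_o - predicted f_o| in units of the fitted delta_f."""
    predicted = predict_fo(fit.f_r, fit.Q, convention=convention)
    return abs(ring.f_o - predicted) / fit.delta_f


def decay_fraction(ring: RingDownFit | float, t: float) -> float:
    """Fraction of the initial amplitude remaining after time t, exp(-t/tau).

    Accepts a RingDownFit or a bare tau (s).  For an oscillator with quality
    factor Q ringing at frequency f, tau = Q/(pi*f), so 0.2 s of free decay
    leaves exp(-0.2*pi*f/Q) of the initial amplitude — a few percent at the
    resonance parameters typical of crests.
    """
    if t < 0:
        raise InvalidParameterError("t must be non-negative")
    tau = ring.tau if isinstance(ring, RingDownFit) else float(ring)
    if tau <= 0:
        raise InvalidParameterError("tau must be positive")
    return math.exp(-t / tau)
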