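"""Transfer-function estimation from frequency sweeps and Lorentzian resonance fits.

A slow linear chirp drives the sample through its resonance while both the
drive (shaker mount) and the response (crest flag) are tracked on video.
Hann-windowed short-time FFTs of both series give, per time slice, the
instantaneous drive frequency ``f_d`` (the drive spectrum's peak bin), the
drive magnitude ``A_d`` there and the response magnitude ``A`` at the same
bin.  The drive transfer function ``H(f_d) = A/A_d`` is then smoothed with a
cubic Savitzky-Golay filter over a 1.3 Hz span and each spectral peak fitted
with the Lorentzian resonance model

    H(f_d) = scale * (f_r/f_d) / [ (f_r/f_d - f_d/f_r)^2 + (delta_f/f_r)^2 ]

whose parameters are the resonant frequency ``f_r`` and the full width at
half maximum of the spectral power ``delta_f``; the quality factor is
``Q = f_r / delta_f``.  A multiplicative ``scale`` is fitted because the
measured amplitude ratio carries an unknown static gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, get_window, savgol_filter

from .errors import (
    DegenerateFitError,
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
    NoResonanceError,
    WeakDriveError,
)
from .synthetic import SweepTrial, lorentzian_response


@dataclass
class TransferFunction:
    """Drive-frequency grid with raw and smoothed H = A/A_d values."""

    f_d: np.ndarray
    H_raw: np.ndarray
    H_smooth: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.f_d = np.asarray(self.f_d, dtype=float)
        self.H_raw = np.asarray(self.H_raw, dtype=float)
        self.H_smooth = np.asarray(self.H_smooth, dtype=float)
        if not (len(self.f_d) == len(self.H_raw) == len(self.H_smooth)):
            raise InvalidParameterError("f_d, H_raw, H_smooth must share length")
        if len(self.f_d) > 1 and not np.all(np.diff(self.f_d) > 0):
            raise InvalidParameterError("f_d must be strictly increasing")


@dataclass(frozen=True)
class Peak:
    index: int
    frequency: float
    height: float
    prominence: float
    dominant: bool = False


@dataclass
class ResonanceFit:
    """Fitted Lorentzian resonance parameters for one spectral peak.

    ``Q = f_r / delta_f`` holds exactly (it is a derived property).
    """

    f_r: float
    delta_f: float
    scale: float
    se_f_r: float
    se_delta_f: float
    r2_adj: float
    window: tuple[float, float]
    secondary_peaks: list[Peak] = field(default_factory=list)

    @property
    def Q(self) -> float:
        return self.f_r / self.delta_f

    def predict(self, f_d):
        return lorentzian_response(f_d, self.f_r, self.delta_f, self.scale)


def sweep_spectra(
    drive: np.ndarray,
    response: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap_frac: float = 0.75,
    zero_pad_factor: int = 8,
    smooth_span_hz: float = 1.3,
    weak_drive_factor: float = 10.0,
) -> TransferFunction:
    """Estimate H(f_d) = A/A_d from paired drive/response motion series.

    Parameters
    ----------
    drive, response
        Detrended 1-D motion series on a shared uniform time grid.
    window_s
        Hann analysis window length (s).  1 s resolves a 1.33 Hz/s sweep to
        about 1 Hz while keeping ~1 Hz spectral resolution.
    overlap_frac
        Fractional overlap between consecutive slices.
    zero_pad_factor
        FFT zero-padding for sub-bin peak placement of f_d.
    smooth_span_hz
        Savitzky-Golay smoothing span (cubic), matched to the 1.3 Hz window
        used on the real data.
    weak_drive_factor
        A slice whose drive peak magnitude is below this multiple of the
        slice's median drive magnitude raises WeakDriveError.
    """
    drive = np.asarray(drive, dtype=float)
    response = np.asarray(response, dtype=float)
    if drive.shape != response.shape:
        raise InvalidParameterError("drive and response must share the time grid")
    nwin = int(round(window_s * fs))
    if len(drive) < 2 * nwin:
        raise InsufficientDataError("series shorter than two analysis windows")
    if not 0 <= overlap_frac < 1:
        raise InvalidParameterError("overlap_frac must be in [0, 1)")
    hop = max(1, int(round(nwin * (1 - overlap_frac))))
    win = get_window("hann", nwin)
    nfft = int(zero_pad_factor) * nwin
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)

    fd_list, H_list = [], []
    for i, start in enumerate(range(0, len(drive) - nwin + 1, hop)):
        dseg = drive[start:start + nwin] * win
        rseg = response[start:start + nwin] * win
        D = np.abs(np.fft.rfft(dseg, n=nfft))
        k = int(np.argmax(D))
        floor = np.median(D)
        if D[k] < weak_drive_factor * floor:
            raise WeakDriveError(
                f"drive peak indistinct from noise floor in slice {i} "
                f"(t={start / fs:.2f}s): peak/median={D[k] / max(floor, 1e-30):.1f}"
            )
        A = np.abs(np.fft.rfft(rseg, n=nfft))[k]
        fd_list.append(freqs[k])
        H_list.append(A / D[k])

    fd = np.asarray(fd_list)
    H = np.asarray(H_list)
    order = np.argsort(fd, kind="stable")
    fd, H = fd[order], H[order]
    # average duplicate grid points so the grid is strictly increasing
    uniq, inv = np.unique(fd, return_inverse=True)
    H_mean = np.bincount(inv, weights=H) / np.bincount(inv)
    fd, H = uniq, H_mean

    if len(fd) < 5:
        raise InsufficientDataError("too few distinct drive-frequency points")
    spacing = float(np.median(np.diff(fd)))
    span_pts = int(round(smooth_span_hz / spacing))
    if span_pts % 2 == 0:
        span_pts += 1
    span_pts = max(span_pts, 5)
    span_pts = min(span_pts, len(fd) - (1 - len(fd) % 2))
    H_smooth = savgol_filter(H, span_pts, polyorder=3) if span_pts > 3 else H.copy()
    H_smooth = np.clip(H_smooth, 0.0, None)

    return TransferFunction(
        f_d=fd, H_raw=H, H_smooth=H_smooth,
        meta=dict(window_s=window_s, overlap_frac=overlap_frac, fs=fs,
                  zero_pad_factor=zero_pad_factor, smooth_span_hz=smooth_span_hz,
                  savgol_points=span_pts),
    )


def sweep_spectra_trial(trial: SweepTrial, **kwargs) -> TransferFunction:
    """Convenience wrapper: estimate H directly from a synthetic SweepTrial."""
    return sweep_spectra(trial.drive.u, trial.response, trial.fs, **kwargs)


def locate_peaks(tf: TransferFunction, min_prominence_frac: float = 0.05) -> list[Peak]:
    """Local maxima of H_smooth with prominence above a fraction of the global max.

    Returns peaks sorted by height, tallest (the dominant peak) first.
    Raises NoResonanceError when nothing rises above the floor.
    """
    if not 0 < min_prominence_frac <= 1:
        raise InvalidParameterError("min_prominence_frac must be in (0, 1]")
    hmax = float(tf.H_smooth.max(initial=0.0))
    if hmax <= 0:
        raise NoResonanceError("transfer function is identically zero")
    idx, props = find_peaks(tf.H_smooth, prominence=min_prominence_frac * hmax)
    if len(idx) == 0:
        raise NoResonanceError("no peak above the prominence floor")
    order = np.argsort(tf.H_smooth[idx])[::-1]
    peaks = []
    for rank, j in enumerate(order):
        i = idx[j]
        peaks.append(Peak(index=int(i), frequency=float(tf.f_d[i]),
                          height=float(tf.H_smooth[i]),
                          prominence=float(props["prominences"][j]),
                          dominant=(rank == 0)))
    return peaks


def _half_power_width(tf: TransferFunction, peak: Peak) -> float:
    """FWHM of the spectral power around a peak (amplitude crossing H_max/sqrt(2))."""
    target = peak.height / np.sqrt(2.0)
    H, f = tf.H_smooth, tf.f_d
    i = peak.index
    lo = f[0]
    for j in range(i, 0, -1):
        if H[j - 1] < target:
            lo = np.interp(target, [H[j - 1], H[j]], [f[j - 1], f[j]])
            break
    hi = f[-1]
    for j in range(i, len(H) - 1):
        if H[j + 1] < target:
            hi = np.interp(target, [H[j + 1], H[j]], [f[j + 1], f[j]])
            break
    width = hi - lo
    if width <= 0:
        width = peak.frequency / 5.0
    return float(width)


def _lorentz_model(f, f_r, delta_f, scale):
    return lorentzian_response(f, f_r, delta_f, scale)


def fit_lorentzian(
    tf: TransferFunction,
    peak: Peak | None = None,
    window_halfwidth: float | None = None,
    min_prominence_frac: float = 0.05,
    xtol: float = 1e-8,
    maxfev: int = 10_000,
) -> ResonanceFit:
    """Fit the Lorentzian resonance model to the smoothed transfer function.

    The dominant peak is fitted by default; other located peaks are attached
    as ``secondary_peaks``.  The fit window is ``peak ± max(3*delta_f0, 10 Hz)``
    unless ``window_halfwidth`` overrides it, with ``delta_f0`` the measured
    half-power width used for initialization.
    """
    peaks = locate_peaks(tf, min_prominence_frac=min_prominence_frac)
    if peak is None:
        peak = peaks[0]
    secondary = [p for p in peaks if p.index != peak.index]

    df0 = _half_power_width(tf, peak)
    if window_halfwidth is None:
        window_halfwidth = max(3.0 * df0, 10.0)
    f_lo = peak.frequency - window_halfwidth
    f_hi = peak.frequency + window_halfwidth
    mask = (tf.f_d >= f_lo) & (tf.f_d <= f_hi)
    f = tf.f_d[mask]
    H = tf.H_smooth[mask]
    if len(f) < 10:
        raise InsufficientDataError(f"only {len(f)} grid points in fit window")

    q0 = peak.frequency / df0
    scale0 = peak.height / q0**2  # model max ~ scale * Q^2
    p0 = [peak.frequency, df0, scale0]
    spacing = float(np.median(np.diff(tf.f_d)))
    bounds = ([f_lo, spacing / 10.0, 0.0], [f_hi, np.inf, np.inf])
    try:
        popt, pcov = curve_fit(
            _lorentz_model, f, H, p0=p0, bounds=bounds, xtol=xtol, maxfev=maxfev,
        )
    except RuntimeError as exc:
        resid = H - _lorentz_model(f, *p0)
        raise FitFailureError(
            f"Lorentzian fit did not converge (initial rms residual "
            f"{np.sqrt(np.mean(resid**2)):.3g}): {exc}"
        ) from exc
    f_r, delta_f, scale = (float(v) for v in popt)
    if delta_f < 2 * spacing:
        raise DegenerateFitError(
            f"fitted width {delta_f:.3g} Hz below 2 grid spacings ({2 * spacing:.3g} Hz)"
        )
    resid = H - _lorentz_model(f, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((H - H.mean()) ** 2))
    n, p = len(f), 3
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return ResonanceFit(
        f_r=f_r, delta_f=delta_f, scale=scale,
        se_f_r=float(se[0]), se_delta_f=float(se[1]),
        r2_adj=float(min(r2_adj, 1.0)),
        window=(float(f_lo), float(f_hi)),
        secondary_peaks=secondary,
    )


def fit_sweep_trial(trial: SweepTrial, **kwargs) -> ResonanceFit:
    """One-call pipeline: SweepTrial -> transfer function -> dominant-peak fit."""
    spectra_keys = {"window_s", "overlap_frac", "zero_pad_factor",
                    "smooth_span_hz", "weak_drive_factor"}
    spectra_kwargs = {k: v for k, v in kwargs.items() if k in spectra_keys}
    fit_kwargs = {k: v for k, v in kwargs.items() if k not in spectra_keys}
    tf = sweep_spectra_trial(trial, **spectra_kwargs)
    return fit_lorentzian(tf, **fit_kwargs)
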