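"""State-free dFC estimators: tapered sliding-window correlation and
wavelet-coherence dFC.

Sliding window (SW)
    A rectangular window of 60 TRs is convolved with a Gaussian taper
    (sigma = 3 TRs, truncated at +-3 sigma), giving a 78-TR tapered window
    that steps by 30 TRs; each window yields the taper-weighted Pearson
    correlation matrix of the ROI time courses.  On 1,200 TRs this grid
    has exactly 38 windows.

Time-frequency (TF)
    Magnitude-squared wavelet transform coherence (WTC) between every ROI
    pair from continuous Morlet (omega0 = 6) transforms at 101
    logarithmically spaced scales, smoothed in time (Gaussian, width
    proportional to scale) and across scales (boxcar of 0.6 octave), then
    averaged per time point over the scales admitted by the cone of
    influence.  The result is a per-TR dFC matrix with values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .containers import DfcMatrix, ParcellatedTimeSeries
from .errors import ParameterError

#: Morlet nondimensional frequency; Fourier period = FOURIER_FACTOR * scale.
OMEGA0 = 6.0
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))


@dataclass
class TaperedWindow:
    """Gaussian-tapered rectangular window for windowed correlation."""

    weights: np.ndarray
    nominal_len_tr: int
    sigma_tr: float
    step_tr: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 1 or np.any(w < 0):
            raise ParameterError("window weights must be a nonnegative vector")
        if not np.allclose(w, w[::-1]):
            raise ParameterError("window weights must be symmetric")
        if self.step_tr < 1:
            raise ParameterError("step_tr must be a positive integer")

    @property
    def length(self) -> int:
        return self.weights.size

    @property
    def center(self) -> float:
        """Offset of the window centre from its first sample, in TRs."""
        return (self.length - 1) / 2.0


def make_tapered_window(
    nominal_len_tr: int = 60, sigma_tr: float = 3.0, step_tr: int = 30
) -> TaperedWindow:
    """Convolve a rectangle of ``nominal_len_tr`` TRs with a Gaussian taper.

    The Gaussian kernel is truncated at +-3 sigma (length 2*3*sigma + 1), and
    the full convolution extends the support to W = nominal + kernel - 1
    (78 TRs for the defaults).  Weights are normalized to sum to one.
    ``sigma_tr = 0`` leaves the rectangle untouched.
    """
    if nominal_len_tr < 2:
        raise ParameterError("nominal_len_tr must be at least 2")
    if sigma_tr < 0:
        raise ParameterError("sigma_tr must be nonnegative")
    rect = np.ones(nominal_len_tr)
    if sigma_tr > 0:
        half = int(np.ceil(3 * sigma_tr))
        x = np.arange(-half, half + 1, dtype=float)
        kernel = np.exp(-0.5 * (x / sigma_tr) ** 2)
        weights = np.convolve(rect, kernel, mode="full")
    else:
        weights = rect
    weights = weights / weights.sum()
    return TaperedWindow(weights, nominal_len_tr, sigma_tr, step_tr)


def window_starts(n_timepoints: int, window: TaperedWindow) -> np.ndarray:
    """Start indices of every fully contained window position."""
    w, step = window.length, window.step_tr
    if n_timepoints < w:
        raise ParameterError(f"series of {n_timepoints} TRs shorter than window ({w})")
    n_win = (n_timepoints - w) // step + 1
    return np.arange(n_win) * step


def weighted_correlation(segment: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Pearson correlation of the columns of ``segment`` under observation
    weights (the taper)."""
    w = weights / weights.sum()
    mu = w @ segment
    xc = segment - mu
    cov = xc.T @ (w[:, None] * xc)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    # numerical clipping only; weighted covariance is exactly symmetric
    return np.clip((corr + corr.T) / 2.0, -1.0, 1.0)


def sliding_window_dfc(
    ts: ParcellatedTimeSeries, window: TaperedWindow | None = None
) -> DfcMatrix:
    """Tapered sliding-window correlation dFC; one FC matrix per window.

    Time stamps are the (possibly fractional) window-centre TR indices.
    """
    if window is None:
        window = make_tapered_window()
    starts = window_starts(ts.n_timepoints, window)
    values = np.empty((starts.size, ts.n_rois, ts.n_rois))
    for k, s in enumerate(starts):
        values[k] = weighted_correlation(ts.values[s : s + window.length], window.weights)
    stamps = starts + window.center
    return DfcMatrix(ts.subject_id, "SW", stamps, values)


def sliding_window_grid(n_timepoints: int, window: TaperedWindow | None = None) -> np.ndarray:
    """The window-centre time stamps the SW method produces for a series."""
    if window is None:
        window = make_tapered_window()
    return window_starts(n_timepoints, window) + window.center


def _morlet_scales(n_timepoints: int, tr_seconds: float, n_scales: int) -> np.ndarray:
    """Wavelet scales (time units) log-spaced between Fourier periods
    2*TR and T*TR/4."""
    dt = tr_seconds
    min_period, max_period = 2.0 * dt, n_timepoints * dt / 4.0
    if max_period <= min_period:
        raise ParameterError(
            "series too short to span the wavelet scale range; "
            "use a longer series or fewer/narrower scales"
        )
    if n_scales < 2:
        raise ParameterError("need at least 2 scales")
    periods = np.geomspace(min_period, max_period, n_scales)
    return periods / FOURIER_FACTOR


def _cwt(signal: np.ndarray, scales_time: np.ndarray, dt: float) -> np.ndarray:
    """Continuous Morlet transform, rows = scales, columns = time."""
    # pywt's cmorB-C with B=2, C=omega0/(2*pi) matches the analytic Morlet
    center_freq = OMEGA0 / (2.0 * np.pi)
    wavelet = f"cmor2.0-{center_freq:.8f}"
    # pywt scale s maps to frequency C/(s*dt); our scale s_t (time units)
    # has center frequency omega0/(2*pi*s_t)  =>  s = s_t/dt
    coeffs, _ = pywt.cwt(signal, scales_time / dt, wavelet, sampling_period=dt)
    return coeffs


def _smooth(field: np.ndarray, scales_time: np.ndarray, dt: float, dj: float) -> np.ndarray:
    """Smoothing operator for coherence: Gaussian in time with width equal to
    the wavelet scale, boxcar across 0.6 octave of scales."""
    out = np.empty_like(field)
    for k, s in enumerate(scales_time):
        out[k] = gaussian_filter1d(field[k], sigma=s / dt, mode="nearest")
    width = max(1, int(round(0.6 / dj)))
    if width > 1:
        out = uniform_filter1d(out, size=width, axis=0, mode="nearest")
    return out


def wavelet_coherence_dfc(
    ts: ParcellatedTimeSeries,
    n_scales: int = 101,
    coi_mask: bool = True,
    squared: bool = True,
) -> DfcMatrix:
    """Scale-averaged wavelet transform coherence between every ROI pair.

    Coherence at each (scale, time) cell is the smoothed cross-spectrum
    magnitude (squared by default) over the smoothed auto-spectra, which
    lies in [0, 1] by Cauchy-Schwarz.  With ``coi_mask`` each time point
    averages only over the scales whose cone of influence (e-folding
    distance sqrt(2)*scale from either edge) admits it; edge points that no
    scale admits fall back to the unmasked average.
    """
    t_len, r = ts.n_timepoints, ts.n_rois
    dt = ts.tr_seconds
    scales = _morlet_scales(t_len, dt, n_scales)
    dj = np.log2(scales[-1] / scales[0]) / (n_scales - 1)

    coeffs = np.empty((r, n_scales, t_len), dtype=complex)
    for a in range(r):
        coeffs[a] = _cwt(ts.values[:, a], scales, dt)

    # scale-normalized smoothed auto-spectra
    inv_s = 1.0 / scales[:, None]
    auto = np.empty((r, n_scales, t_len))
    for a in range(r):
        auto[a] = _smooth(np.abs(coeffs[a]) ** 2 * inv_s, scales, dt, dj)

    if coi_mask:
        dist = np.minimum(np.arange(t_len), np.arange(t_len)[::-1]) * dt
        admit = (np.sqrt(2.0) * scales)[:, None] <= dist[None, :]
    else:
        admit = np.ones((n_scales, t_len), dtype=bool)
    n_admit = admit.sum(axis=0)

    values = np.empty((t_len, r, r))
    idx = np.arange(r)
    values[:, idx, idx] = 1.0
    for a in range(r):
        for b in range(a):
            cross = _smooth(coeffs[a] * np.conj(coeffs[b]) * inv_s, scales, dt, dj)
            wtc = np.abs(cross) ** 2 / (auto[a] * auto[b])
            if not squared:
                wtc = np.sqrt(wtc)
            wtc = np.clip(wtc, 0.0, 1.0)
            masked_mean = np.where(
                n_admit > 0,
                (wtc * admit).sum(axis=0) / np.maximum(n_admit, 1),
                wtc.mean(axis=0),
            )
            values[:, a, b] = masked_mean
            values[:, b, a] = masked_mean
    stamps = np.arange(t_len, dtype=float)
    return DfcMatrix(ts.subject_id, "TF", stamps, values)
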