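"""Acceleration feature extraction: static/dynamic split, ODBA, tailbeats.

The raw signal on each axis is separated into a *static* component — the
low-frequency gravitational part reflecting body posture, estimated with a
3-s centred box smoother — and a *dynamic* component (raw minus static)
generated by body movement.  Overall dynamic body acceleration (ODBA) is
the sum of the absolute dynamic values across the three axes and serves as
an activity/energy proxy.  Tailbeat frequency and signal-strength amplitude
are taken from a continuous wavelet transform (complex Morlet mother
wavelet) of the dynamic sway axis, since routine swimming shows regular
lateral oscillations, one per tail-beat.

All per-epoch summaries live on non-overlapping 1-s epochs.  The standard
feature table has 44 fixed columns (per-axis static/dynamic means, ODBA,
Amp, Hz, then SD/skewness/kurtosis/max/min of the seven signals) plus one
amplitude column per wavelet frequency bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import pywt

from sharketho.io import TriaxialSeries

#: default Morlet bandwidth/centre parameters (pywt "cmorB-C" convention)
MORLET_BANDWIDTH = 1.5
MORLET_CENTER_FREQ = 1.0


def default_freq_grid(n_bins: int = 25, f_lo: float = 0.2, f_hi: float = 10.0) -> np.ndarray:
    """Log-spaced wavelet frequency grid, 0.2–10 Hz by default."""
    return np.geomspace(f_lo, f_hi, n_bins)


@dataclass
class DecomposedSeries:
    """Static/dynamic decomposition of a tri-axial series, plus ODBA."""

    static_x: np.ndarray
    static_y: np.ndarray
    static_z: np.ndarray
    dynamic_x: np.ndarray
    dynamic_y: np.ndarray
    dynamic_z: np.ndarray
    odba: np.ndarray
    rate_hz: float


@dataclass
class SwaySpectrum:
    """Per-epoch wavelet spectrum of the dynamic sway axis.

    ``amplitude[e, k]`` is the mean wavelet signal-strength amplitude (g) of
    epoch ``e`` at ``freq_grid[k]``; ``dominant_freq``/``dominant_amp`` give
    the per-epoch dominant cycle.  ``degenerate`` flags epochs with no
    measurable oscillation, where the dominant frequency is pinned to the
    lowest grid frequency by convention.
    """

    freq_grid: np.ndarray
    amplitude: np.ndarray
    dominant_freq: np.ndarray
    dominant_amp: np.ndarray
    degenerate: np.ndarray


def _box_smooth(arr: np.ndarray, window: int) -> np.ndarray:
    # centred moving average; edges shrink to the available samples rather
    # than padding with fabricated data
    s = pd.Series(arr).rolling(window, center=True, min_periods=1).mean()
    return s.to_numpy()


def split_static_dynamic(series: TriaxialSeries, window_s: float = 3.0) -> DecomposedSeries:
    """Separate posture (static) from movement (dynamic) by box smoothing.

    The static estimate is a centred moving average over an odd window of
    ``round(window_s * rate_hz)`` samples (forced odd; 91 samples for 3 s at
    30 Hz).  Dynamic acceleration is the remainder, so
    ``static + dynamic == raw`` to machine precision on every sample.
    """
    window = int(round(window_s * series.rate_hz))
    if window < 3:
        raise ValueError(f"smoothing window of {window} samples is too short (need >= 3)")
    if window % 2 == 0:
        window += 1
    if series.n_samples < window:
        raise ValueError(
            f"series of {series.n_samples} samples is shorter than one "
            f"{window}-sample smoothing window"
        )
    sx = _box_smooth(series.x, window)
    sy = _box_smooth(series.y, window)
    sz = _box_smooth(series.z, window)
    dx, dy, dz = series.x - sx, series.y - sy, series.z - sz
    return DecomposedSeries(
        static_x=sx, static_y=sy, static_z=sz,
        dynamic_x=dx, dynamic_y=dy, dynamic_z=dz,
        odba=np.abs(dx) + np.abs(dy) + np.abs(dz),
        rate_hz=series.rate_hz,
    )


def compute_odba(decomposed: DecomposedSeries) -> np.ndarray:
    """Per-sample ODBA: ``|dx| + |dy| + |dz|`` in g."""
    return (
        np.abs(decomposed.dynamic_x)
        + np.abs(decomposed.dynamic_y)
        + np.abs(decomposed.dynamic_z)
    )


@lru_cache(maxsize=8)
def _cwt_gain(rate_hz: float, grid_key: tuple) -> np.ndarray:
    """Empirical modulus gain of the CWT for a unit-amplitude sinusoid.

    The raw complex-Morlet CWT modulus scales with wavelet scale; dividing
    by this per-frequency gain makes a pure sinusoid of amplitude *a* read
    back as *a* on the matching frequency bin (flat-response calibration).
    """
    grid = np.array(grid_key)
    wavelet = pywt.ContinuousWavelet(f"cmor{MORLET_BANDWIDTH}-{MORLET_CENTER_FREQ}")
    fc = pywt.central_frequency(wavelet)
    gains = np.empty(grid.size)
    for i, f in enumerate(grid):
        # long enough for several cycles of the slowest wavelet
        dur = max(8.0, 12.0 / f)
        t = np.arange(0.0, dur, 1.0 / rate_hz)
        ref = np.sin(2 * np.pi * f * t)
        coef, _ = pywt.cwt(ref, [fc * rate_hz / f], wavelet, sampling_period=1.0 / rate_hz)
        mid = np.abs(coef[0])
        lo, hi = len(mid) // 4, 3 * len(mid) // 4
        gains[i] = mid[lo:hi].mean()
    return gains


def sway_wavelet(
    dynamic_sway: np.ndarray,
    rate_hz: float,
    freq_grid: np.ndarray | None = None,
    epoch_s: float = 1.0,
) -> SwaySpectrum:
    """Morlet CWT of the dynamic sway axis, summarised per 1-s epoch.

    Returns per-epoch mean wavelet amplitude on each grid frequency, with
    the modulus rescaled so a pure sinusoid of amplitude ``a`` yields a peak
    amplitude of about ``a``.  The per-epoch dominant cycle is the argmax
    over the grid; exact ties break to the lower frequency.  Epochs whose
    peak amplitude is negligible (< 1e-6 g) are flagged degenerate and
    pinned to the lowest grid frequency.
    """
    dynamic_sway = np.asarray(dynamic_sway, dtype=float)
    if dynamic_sway.size == 0:
        raise ValueError("empty sway signal")
    if freq_grid is None:
        freq_grid = default_freq_grid()
    freq_grid = np.sort(np.asarray(freq_grid, dtype=float))
    if freq_grid[0] <= 0 or freq_grid[-1] >= rate_hz / 2:
        raise ValueError("freq_grid must lie strictly inside (0, Nyquist)")
    wavelet = pywt.ContinuousWavelet(f"cmor{MORLET_BANDWIDTH}-{MORLET_CENTER_FREQ}")
    fc = pywt.central_frequency(wavelet)
    scales = fc * rate_hz / freq_grid
    coef, _ = pywt.cwt(dynamic_sway, scales, wavelet, sampling_period=1.0 / rate_hz)
    modulus = np.abs(coef) / _cwt_gain(float(rate_hz), tuple(freq_grid))[:, None]

    per = int(round(epoch_s * rate_hz))
    n_epochs = max(1, dynamic_sway.size // per)
    if dynamic_sway.size >= per:
        amp = modulus[:, : n_epochs * per].reshape(freq_grid.size, n_epochs, per).mean(axis=2).T
    else:
        amp = modulus.mean(axis=1)[None, :]
    dom_idx = np.argmax(amp, axis=1)  # first (lowest-frequency) argmax on ties
    dom_amp = amp[np.arange(n_epochs), dom_idx]
    degenerate = dom_amp < 1e-6
    dom_idx = np.where(degenerate, 0, dom_idx)
    return SwaySpectrum(
        freq_grid=freq_grid,
        amplitude=amp,
        dominant_freq=freq_grid[dom_idx],
        dominant_amp=amp[np.arange(n_epochs), dom_idx],
        degenerate=degenerate,
    )


def _epoch_moments(blocks: np.ndarray) -> dict[str, np.ndarray]:
    """Row-wise mean/SD/skewness/kurtosis/max/min for an (epochs, samples) array.

    Skewness is the sample g1 (``m3 / m2**1.5``) and kurtosis the excess
    kurtosis (``m4 / m2**2 - 3``), matching :func:`scipy.stats.skew` /
    ``kurtosis`` defaults; constant epochs map to 0 rather than NaN.
    """
    mean = blocks.mean(axis=1)
    centred = blocks - mean[:, None]
    m2 = (centred**2).mean(axis=1)
    m3 = (centred**3).mean(axis=1)
    m4 = (centred**4).mean(axis=1)
    const = m2 == 0
    safe_m2 = np.where(const, 1.0, m2)
    return {
        "": mean,
        "SD": blocks.std(axis=1, ddof=1),
        "Skew": np.where(const, 0.0, m3 / safe_m2**1.5),
        "Kurt": np.where(const, 0.0, m4 / safe_m2**2 - 3.0),
        "Max": blocks.max(axis=1),
        "Min": blocks.min(axis=1),
    }


FIXED_COLUMNS = (
    ["Xstat", "Ystat", "Zstat", "Xdyn", "Ydyn", "Zdyn", "ODBA", "Amp", "Hz"]
    + [f"{s}SD" for s in ("Xstat", "Ystat", "Zstat", "Xdyn", "Ydyn", "Zdyn", "ODBA")]
    + [f"{s}Skew" for s in ("Xstat", "Ystat", "Zstat", "Xdyn", "Ydyn", "Zdyn", "ODBA")]
    + [f"{s}Kurt" for s in ("Xstat", "Ystat", "Zstat", "Xdyn", "Ydyn", "Zdyn", "ODBA")]
    + [f"{s}Max" for s in ("Xstat", "Ystat", "Zstat", "Xdyn", "Ydyn", "Zdyn", "ODBA")]
    + [f"{s}Min" for s in ("Xstat", "Ystat", "Zstat", "Xdyn", "Ydyn", "Zdyn", "ODBA")]
)


def extract_features(
    series: TriaxialSeries,
    window_s: float = 3.0,
    freq_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-second feature table used to train the behaviour classifiers.

    Columns, per 1-s epoch:

    ==============  ======================================================
    Xstat..Zstat    mean static acceleration per axis (posture)
    Xdyn..Zdyn      mean dynamic acceleration per axis (movement)
    ODBA            mean overall dynamic body acceleration
    Amp             wavelet amplitude of the dominant sway cycle
    Hz              dominant tailbeat frequency from the sway axis
    *SD/*Skew/...   SD, skewness, kurtosis, max, min of the seven signals
                    (three static, three dynamic, ODBA)
    W0.20Hz ...     wavelet amplitude at each grid frequency
    ==============  ======================================================

    Deterministic: identical input yields an identical frame.
    """
    if freq_grid is None:
        freq_grid = default_freq_grid()
    dec = split_static_dynamic(series, window_s=window_s)
    spec = sway_wavelet(dec.dynamic_z, series.rate_hz, freq_grid=freq_grid)
    per = int(round(series.rate_hz))
    n = series.n_epochs
    signals = {
        "Xstat": dec.static_x, "Ystat": dec.static_y, "Zstat": dec.static_z,
        "Xdyn": dec.dynamic_x, "Ydyn": dec.dynamic_y, "Zdyn": dec.dynamic_z,
        "ODBA": dec.odba,
    }
    out = {}
    for name, sig in signals.items():
        blocks = sig[: n * per].reshape(n, per)
        for suffix, vals in _epoch_moments(blocks).items():
            out[f"{name}{suffix}"] = vals
    out["Amp"] = spec.dominant_amp[:n]
    out["Hz"] = spec.dominant_freq[:n]
    frame = pd.DataFrame(out, columns=FIXED_COLUMNS)
    for k, f in enumerate(spec.freq_grid):
        frame[f"W{f:.2f}Hz"] = spec.amplitude[:n, k]
    return frame
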