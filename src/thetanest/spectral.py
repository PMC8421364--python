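"""Time-frequency power and cross-channel coherence via the Morlet CWT.

The continuous wavelet transform follows the classic Torrence & Compo
formulation: a complex Morlet mother wavelet (center frequency parameter
``omega0 = 6``) applied in the Fourier domain at logarithmically spaced
scales.  Wavelet power is rectified by dividing energy by scale so that
spectral peaks are comparable across frequencies, and the cone of influence
is flagged (not trimmed) so time bookkeeping stays aligned with session
annotations.

Wavelet (squared) coherence is the ratio of the smoothed cross-spectrum to
the smoothed auto-spectra; without smoothing it is identically one, so a
time window (default one theta cycle) and a scale window (default 0.6
octave) are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .recording import LFPRecording

OMEGA0 = 6.0
#: Fourier wavelength factor for the Morlet wavelet at omega0 = 6
FOURIER_FACTOR = 4 * np.pi / (OMEGA0 + np.sqrt(2 + OMEGA0**2))
#: reconstruction constant (Torrence & Compo Table 2, Morlet omega0 = 6)
C_DELTA = 0.776


@dataclass
class WaveletSpectrum:
    """Rectified wavelet amplitude of a single channel.

    ``power`` holds the scale-rectified modulus ``|W(s, t)| / sqrt(s)`` so
    that ``power**2`` is energy divided by scale (the standard bias
    correction).  ``in_coi`` flags time-frequency samples inside the cone of
    influence, where edge effects are non-negligible.
    """

    power: np.ndarray  # (n_freqs, n_times), >= 0
    freqs: np.ndarray  # Hz, strictly increasing
    times: np.ndarray  # seconds
    scales: np.ndarray  # wavelet scales, one per frequency
    in_coi: np.ndarray  # bool, (n_freqs, n_times)
    normalization: str = "energy/scale"

    def total_energy(self, dt: float) -> float:
        """Variance estimate from the rectified scalogram (inverse-transform
        normalization, Morlet reconstruction constant)."""
        dj = _mean_dj(self.freqs)
        return float(dj * dt / (C_DELTA * self.power.shape[1]) * np.sum(self.power**2))


@dataclass
class CoherenceSpectrum:
    """Squared wavelet coherence between two channels, values in [0, 1].

    Undefined points (zero power in either signal) are NaN, not zero.
    """

    coherence: np.ndarray  # (n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray
    smoothing_spec: str = ""

    def time_average(self) -> np.ndarray:
        """Per-frequency average coherence over time (NaN-aware)."""
        return np.nanmean(self.coherence, axis=1)


def log_freq_grid(f_min: float, f_max: float, n: int = 48) -> np.ndarray:
    """Logarithmically spaced frequency grid, ascending."""
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    return np.geomspace(f_min, f_max, n)


def _mean_dj(freqs: np.ndarray) -> float:
    """Mean scale step in octaves for a (log-spaced) frequency grid."""
    if len(freqs) < 2:
        return 1.0
    return float(np.log2(freqs[-1] / freqs[0]) / (len(freqs) - 1))


def preprocess(raw: LFPRecording, target_fs: float = 1000.0) -> LFPRecording:
    """Downsample (anti-alias filtered) to ``target_fs`` and z-score.

    Each channel ends up with mean 0 and SD 1 over the full trace.  A
    constant channel cannot be z-scored and is rejected by name.
    """
    if target_fs > raw.fs:
        raise ValueError(f"target_fs {target_fs} exceeds recording fs {raw.fs}")
    x = raw.samples
    if target_fs < raw.fs:
        ratio = raw.fs / target_fs
        if abs(ratio - round(ratio)) < 1e-9:
            q = int(round(ratio))
            # scipy caps the per-stage decimation factor; chain if needed
            while q > 1:
                step = min(q, 10)
                x = signal.decimate(x, step, axis=1, ftype="fir", zero_phase=True)
                q //= step
        else:
            up, down = (np.array([target_fs, raw.fs]) /
                        np.gcd(int(target_fs), int(raw.fs))).astype(int)
            x = signal.resample_poly(x, up, down, axis=1)
    sd = x.std(axis=1)
    for i, s in enumerate(sd):
        if s == 0:
            raise ValueError(
                f"channel {raw.channel_labels[i]!r} is constant and cannot be z-scored"
            )
    x = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return LFPRecording(x, target_fs, list(raw.channel_labels), raw.t0)


def _morlet_cwt(x: np.ndarray, fs: float, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Complex Morlet CWT computed in the Fourier domain.

    Returns ``(W, scales)`` with ``W`` of shape ``(n_freqs, n_samples)``.
    """
    x = np.asarray(x, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    if np.any(freqs > fs / 2):
        raise ValueError(
            f"requested frequency {freqs.max():g} Hz above Nyquist {fs / 2:g} Hz"
        )
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    n = len(x)
    dt = 1.0 / fs
    scales = 1.0 / (FOURIER_FACTOR * freqs)
    # zero-pad to the next power of two to limit wrap-around
    n_fft = int(2 ** np.ceil(np.log2(2 * n)))
    xf = np.fft.fft(x, n_fft)
    omega = 2 * np.pi * np.fft.fftfreq(n_fft, dt)
    W = np.empty((len(freqs), n), dtype=complex)
    pos = omega > 0
    for k, s in enumerate(scales):
        psi_hat = np.zeros(n_fft)
        psi_hat[pos] = (np.pi**-0.25) * np.sqrt(2 * np.pi * s / dt) * np.exp(
            -0.5 * (s * omega[pos] - OMEGA0) ** 2
        )
        W[k] = np.fft.ifft(xf * psi_hat)[:n]
    return W, scales


def _coi_mask(n: int, fs: float, scales: np.ndarray) -> np.ndarray:
    """Boolean cone-of-influence mask: True where edge effects matter.

    The e-folding time of the Morlet wavelet at scale ``s`` is ``sqrt(2) s``.
    """
    t_edge = np.minimum(np.arange(n), np.arange(n)[::-1]) / fs
    return t_edge[None, :] < (np.sqrt(2.0) * scales)[:, None]


def cwt_power(
    x: np.ndarray, fs: float, freqs: np.ndarray, t0: float = 0.0
) -> WaveletSpectrum:
    """Rectified Morlet wavelet amplitude of one channel.

    Amplitude is the modulus of the wavelet coefficient divided by the
    square root of the scale, so squared amplitude is energy/scale.
    """
    W, scales = _morlet_cwt(x, fs, freqs)
    power = np.abs(W) / np.sqrt(scales)[:, None]
    times = t0 + np.arange(len(x)) / fs
    return WaveletSpectrum(
        power=power,
        freqs=np.asarray(freqs, dtype=float),
        times=times,
        scales=scales,
        in_coi=_coi_mask(len(x), fs, scales),
    )


def _smooth(arr: np.ndarray, n_time: int, n_scale: int) -> np.ndarray:
    """Boxcar smoothing in time (per scale) then across scales."""
    out = uniform_filter1d(arr, size=max(n_time, 1), axis=1, mode="nearest")
    if n_scale > 1:
        out = uniform_filter1d(out, size=n_scale, axis=0, mode="nearest")
    return out


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    time_window_s: float | None = None,
    scale_octaves: float = 0.6,
    t0: float = 0.0,
) -> CoherenceSpectrum:
    """Squared wavelet coherence of two equally sampled channels.

    Smoothing defaults: boxcar over one theta cycle (1/7 s) in time and 0.6
    octave in scale.  Time-frequency points where either auto-spectrum
    vanishes are returned as NaN.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("channels must have equal length")
    if time_window_s is None:
        time_window_s = 1.0 / 7.0
    n_time = int(round(time_window_s * fs))
    freqs = np.asarray(freqs, dtype=float)
    dj = _mean_dj(freqs)
    n_scale = int(round(scale_octaves / dj)) if len(freqs) > 1 else 1
    if n_time <= 1 and n_scale <= 1:
        raise ValueError(
            "smoothing window must exceed one sample: unsmoothed wavelet "
            "coherence is identically 1"
        )
    Wx, scales = _morlet_cwt(x, fs, freqs)
    Wy, _ = _morlet_cwt(y, fs, freqs)
    inv_s = (1.0 / scales)[:, None]
    sxx = _smooth(np.abs(Wx) ** 2 * inv_s, n_time, n_scale)
    syy = _smooth(np.abs(Wy) ** 2 * inv_s, n_time, n_scale)
    sxy_r = _smooth((Wx * np.conj(Wy)).real * inv_s, n_time, n_scale)
    sxy_i = _smooth((Wx * np.conj(Wy)).imag * inv_s, n_time, n_scale)
    denom = sxx * syy
    floor = np.finfo(float).tiny * 1e4
    coh = np.full_like(denom, np.nan)
    ok = denom > floor
    coh[ok] = (sxy_r[ok] ** 2 + sxy_i[ok] ** 2) / denom[ok]
    np.clip(coh, 0.0, 1.0, out=coh)
    times = t0 + np.arange(len(x)) / fs
    return CoherenceSpectrum(
        coherence=coh,
        freqs=freqs,
        times=times,
        smoothing_spec=f"boxcar {n_time} samples x {n_scale} scales "
        f"({time_window_s:g} s, {scale_octaves:g} octave)",
    )


def grand_average_coherence(
    spectra: list[CoherenceSpectrum],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and SEM of time-averaged coherence across recordings.

    Returns ``(freqs, mean, sem)``.  All spectra must share one grid.
    """
    if not spectra:
        raise ValueError("need at least one coherence spectrum")
    freqs = spectra[0].freqs
    for sp in spectra[1:]:
        if sp.freqs.shape != freqs.shape or not np.allclose(sp.freqs, freqs):
            raise ValueError("coherence spectra must share a frequency grid")
    stack = np.vstack([sp.time_average() for sp in spectra])
    mean = stack.mean(axis=0)
    if len(spectra) == 1:
        sem = np.zeros_like(mean)
    else:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return freqs, mean, sem
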