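"""Empirical mode decomposition, theta-band partition, theta-cycle detection.

EMD separates the signal into intrinsic mode functions (IMFs) by iterative
sifting: subtract the mean of the cubic-spline envelopes through the local
maxima and minima until the standard SD stop criterion is met.  Each IMF is
characterized by its amplitude-weighted mean instantaneous frequency (from
the analytic-signal phase derivative); the theta trace is the sum of IMFs
with mean frequency in the closed band [5, 12] Hz, the low-frequency trace
collects IMFs below 5 Hz plus the non-oscillatory residual, and the
supra-theta trace collects IMFs above 12 Hz.  By construction the three
partitions reconstruct the input exactly.

Theta cycles are delimited trough-to-trough on the theta trace and accepted
when their period lies in [71, 200] ms (14 Hz down to 5 Hz) and the segment
has exactly one intervening local maximum — the "single sinusoidal wave"
reading.  Phase zero is the first trough of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, hilbert

__all__ = [
    "IMFSet",
    "ThetaDecomposition",
    "ThetaCycle",
    "emd",
    "band_partition",
    "detect_theta_cycles",
]

THETA_BAND = (5.0, 12.0)  # Hz, closed interval
PERIOD_BOUNDS_MS = (71.0, 200.0)


@dataclass
class IMFSet:
    """Intrinsic mode functions plus the non-oscillatory residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    mean_inst_freq: np.ndarray  # Hz, one per IMF
    fs: float

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass
class ThetaDecomposition:
    """Three-way partition of a trace by IMF mean frequency."""

    theta: np.ndarray
    low: np.ndarray
    supra: np.ndarray
    theta_imf_indices: list[int] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return self.theta + self.low + self.supra


@dataclass(frozen=True)
class ThetaCycle:
    """One accepted theta cycle, trough-anchored.

    The cycle spans the half-open sample range ``[start_idx, end_idx)``
    delimited by consecutive troughs; ``trough_idx`` is the first trough
    (the zero-phase reference) and coincides with ``start_idx``.
    """

    start_idx: int
    trough_idx: int
    end_idx: int
    period_ms: float

    def __post_init__(self) -> None:
        if not self.start_idx <= self.trough_idx < self.end_idx:
            raise ValueError("cycle indices must satisfy start <= trough < end")

    def midpoint_idx(self) -> int:
        return (self.start_idx + self.end_idx) // 2


# ---------------------------------------------------------------------------
# EMD
# ---------------------------------------------------------------------------

def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (plateau midpoints).

    ``find_peaks`` requires a strict rise on both sides of a (possibly
    flat) extremum, so the flat triples a median deglitch produces around
    smooth extrema are reported once, never as both a maximum and a
    minimum.
    """
    maxima, _ = find_peaks(x)
    minima, _ = find_peaks(-x)
    return maxima, minima


def _mirror_envelope(x: np.ndarray, idx: np.ndarray) -> CubicSpline:
    """Cubic-spline envelope through extrema with mirrored boundary points."""
    n = len(x)
    n_mirror = min(2, len(idx))
    left_t = -idx[:n_mirror][::-1]
    right_t = 2 * (n - 1) - idx[-n_mirror:][::-1]
    t = np.concatenate([left_t, idx, right_t]).astype(float)
    v = np.concatenate([x[idx[:n_mirror]][::-1], x[idx], x[idx[-n_mirror:]][::-1]])
    # guard against duplicated knots at the boundary
    t, keep = np.unique(t, return_index=True)
    return CubicSpline(t, v[keep])


def _sift(x: np.ndarray, sd_threshold: float, max_sifts: int) -> np.ndarray | None:
    """Extract one IMF by sifting; None if x has too few extrema."""
    h = x.copy()
    n = len(x)
    grid = np.arange(n)
    for _ in range(max_sifts):
        maxima, minima = _extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            return None
        upper = _mirror_envelope(h, maxima)(grid)
        lower = _mirror_envelope(h, minima)(grid)
        mean_env = 0.5 * (upper + lower)
        h_new = h - mean_env
        denom = np.sum(h**2)
        sd = np.sum(mean_env**2) / denom if denom > 0 else 0.0
        h = h_new
        if sd < sd_threshold:
            break
    return h


def mean_instantaneous_frequency(
    imf: np.ndarray, fs: float, weighted: bool = True
) -> float:
    """Amplitude-weighted mean frequency from the analytic-signal phase.

    Weighting by the instantaneous amplitude makes the estimate robust to
    phase noise where the mode is weak; the unweighted mean is available.
    """
    analytic = hilbert(imf)
    phase = np.unwrap(np.angle(analytic))
    inst_f = np.gradient(phase) * fs / (2 * np.pi)
    inst_f = np.clip(inst_f, 0.0, None)
    if weighted:
        w = np.abs(analytic)
        total = w.sum()
        if total == 0:
            return 0.0
        return float(np.sum(inst_f * w) / total)
    return float(inst_f.mean())


def emd(
    x: np.ndarray,
    fs: float,
    max_imfs: int = 12,
    sd_threshold: float = 0.2,
    max_sifts: int = 10,
    weighted_freq: bool = True,
) -> IMFSet:
    """Empirical mode decomposition of a 1-D signal.

    Sifting uses cubic-spline envelopes with mirrored-extrema boundary
    extension and the standard SD stop criterion (threshold 0.2, max 10
    sifts per mode).  A monotonic input yields zero IMFs with the residual
    equal to the input.  The IMFs plus residual reconstruct the input
    exactly (the residual is defined as the remainder).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if len(x) < 100:
        raise ValueError(f"signal too short for EMD ({len(x)} < 100 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        imf = _sift(residual, sd_threshold, max_sifts)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
        maxima, minima = _extrema(residual)
        if len(maxima) + len(minima) < 3:
            break
    freqs = np.array(
        [mean_instantaneous_frequency(imf, fs, weighted_freq) for imf in imfs]
    )
    return IMFSet(imfs=imfs, residual=residual, mean_inst_freq=freqs, fs=fs)


def band_partition(imfset: IMFSet, band: tuple[float, float] = THETA_BAND
                   ) -> ThetaDecomposition:
    """Partition IMFs into theta / low / supra-theta traces.

    IMFs with mean instantaneous frequency inside the closed band [5, 12] Hz
    (boundary values included — closed-interval convention) sum to the theta
    trace; slower IMFs plus the residual form the low trace; faster IMFs the
    supra-theta trace.
    """
    lo, hi = band
    n = len(imfset.residual)
    theta = np.zeros(n)
    low = imfset.residual.copy()
    supra = np.zeros(n)
    theta_idx: list[int] = []
    for i, (imf, f) in enumerate(zip(imfset.imfs, imfset.mean_inst_freq)):
        if lo <= f <= hi:
            theta += imf
            theta_idx.append(i)
        elif f < lo:
            low += imf
        else:
            supra += imf
    return ThetaDecomposition(theta=theta, low=low, supra=supra,
                              theta_imf_indices=theta_idx)


# ---------------------------------------------------------------------------
# theta-cycle detection
# ---------------------------------------------------------------------------

def detect_theta_cycles(
    theta: np.ndarray,
    fs: float,
    period_bounds_ms: tuple[float, float] = PERIOD_BOUNDS_MS,
    return_rejected: bool = False,
):
    """Trough-to-trough theta cycles with a sinusoidal-wave acceptance rule.

    Local extrema are found on the theta trace after a 3-sample median
    deglitch.  A candidate cycle spans consecutive troughs; it is accepted
    iff its period lies within ``period_bounds_ms`` (inclusive) and exactly
    one local maximum falls between the two troughs.  Degenerate input
    yields an empty list.  With ``return_rejected`` a parallel list of
    ``(start_idx, end_idx, reason)`` tuples is returned.
    """
    theta = np.asarray(theta, dtype=float)
    cycles: list[ThetaCycle] = []
    rejected: list[tuple[int, int, str]] = []
    if len(theta) < 3 or np.all(theta == theta[0]):
        return (cycles, rejected) if return_rejected else cycles
    smooth = median_filter(theta, size=3, mode="nearest")
    maxima, minima = _extrema(smooth)
    lo_ms, hi_ms = period_bounds_ms
    for a, b in zip(minima, minima[1:]):
        period_ms = (b - a) / fs * 1000.0
        n_max_between = int(np.sum((maxima > a) & (maxima < b)))
        if not lo_ms <= period_ms <= hi_ms:
            rejected.append((int(a), int(b), f"period {period_ms:.1f} ms out of bounds"))
        elif n_max_between != 1:
            rejected.append((int(a), int(b), f"{n_max_between} maxima between troughs"))
        else:
            cycles.append(ThetaCycle(int(a), int(a), int(b), period_ms))
    return (cycles, rejected) if return_rejected else cycles
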