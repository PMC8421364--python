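"""Theta-nested spectral components (tSCs).

Each accepted theta cycle is summarized by its spectral signature: the mean
rectified wavelet amplitude of the supra-theta trace over the cycle's
samples, on a 10-200 Hz grid.  Pooled signatures are reduced by PCA to five
dimensions (the explained-variance fraction is reported) and unmixed by
FastICA; the back-projected, unit-normalized independent components are the
tSCs, labeled tSC1..tSC5 in order of ascending spectral peak frequency.

A cycle's strength on a tSC is the inner product of its signature with the
component; per-tSC thresholds on the strength distribution mark the cycles
that express the component ("events").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA, FastICA

from .decomposition import ThetaCycle
from .recording import SessionAnnotation
from .spectral import cwt_power, log_freq_grid

__all__ = [
    "SpectralSignature",
    "TSCSet",
    "StrengthMatrix",
    "default_tsc_grid",
    "cycle_spectral_signature",
    "cycle_signatures",
    "extract_tscs",
    "tsc_strengths",
    "export_tsc_raster",
]


def default_tsc_grid(n: int = 48) -> np.ndarray:
    """Log-spaced 10-200 Hz frequency grid for spectral signatures."""
    return log_freq_grid(10.0, 200.0, n)


@dataclass
class SpectralSignature:
    """Mean wavelet amplitude of one theta cycle over the frequency grid."""

    amplitude: np.ndarray  # >= 0, length n_freqs
    freqs: np.ndarray
    cycle: ThetaCycle


@dataclass
class TSCSet:
    """Extracted tSCs and the transform bookkeeping.

    Components are unit-L2-norm rows of ``components`` with positive peak,
    ordered by ascending spectral peak frequency (ties by total energy).
    """

    components: np.ndarray  # (n_components, n_freqs)
    freqs: np.ndarray
    explained_variance_pca: float
    mean_signature: np.ndarray  # centering vector used before PCA
    seed: int

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def peak_freqs(self) -> np.ndarray:
        return self.freqs[np.argmax(self.components, axis=1)]


@dataclass
class StrengthMatrix:
    """Per-cycle tSC strengths, thresholds and event flags."""

    strengths: np.ndarray  # (n_cycles, n_components)
    threshold_per_tsc: np.ndarray
    events: np.ndarray  # bool, same shape as strengths


# ---------------------------------------------------------------------------
# spectral signatures
# ---------------------------------------------------------------------------

def cycle_spectral_signature(
    supra: np.ndarray,
    cycle: ThetaCycle,
    fs: float,
    freqs: np.ndarray | None = None,
) -> SpectralSignature | None:
    """Wavelet signature of one cycle with symmetric context padding.

    The supra-theta segment is padded by one cycle length on each side
    before the transform to avoid edge bias, then the amplitude is averaged
    over time within ``[start_idx, end_idx)``.  Returns None (flagged
    absent) for cycles too short to support the lowest-frequency wavelet.
    """
    if freqs is None:
        freqs = default_tsc_grid()
    freqs = np.asarray(freqs, dtype=float)
    n = len(supra)
    if cycle.start_idx < 0 or cycle.end_idx > n:
        raise ValueError("cycle indices outside the signal")
    width = cycle.end_idx - cycle.start_idx
    if width < 2:
        return None
    lo = max(0, cycle.start_idx - width)
    hi = min(n, cycle.end_idx + width)
    spec = cwt_power(supra[lo:hi], fs, freqs)
    a, b = cycle.start_idx - lo, cycle.end_idx - lo
    amplitude = spec.power[:, a:b].mean(axis=1)
    return SpectralSignature(amplitude, freqs, cycle)


def cycle_signatures(
    supra: np.ndarray,
    cycles: Sequence[ThetaCycle],
    fs: float,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, list[ThetaCycle]]:
    """Signatures for many cycles from one full-trace wavelet transform.

    Computing the CWT once over the whole supra-theta trace and averaging
    per cycle is equivalent to the padded per-cycle transform away from the
    trace edges and far cheaper.  Returns ``(matrix, kept_cycles)`` with one
    row per kept cycle.
    """
    if freqs is None:
        freqs = default_tsc_grid()
    freqs = np.asarray(freqs, dtype=float)
    spec = cwt_power(np.asarray(supra, dtype=float), fs, freqs)
    rows, kept = [], []
    for cyc in cycles:
        if cyc.end_idx - cyc.start_idx < 2:
            continue
        rows.append(spec.power[:, cyc.start_idx: cyc.end_idx].mean(axis=1))
        kept.append(cyc)
    if not rows:
        return np.empty((0, len(freqs))), []
    return np.vstack(rows), kept


# ---------------------------------------------------------------------------
# PCA + ICA extraction
# ---------------------------------------------------------------------------

def _negative_energy_fraction(comps: np.ndarray) -> float:
    """Fraction of component energy below zero after sign-fixing.

    tSCs are amplitude spectra: the generative model mixes non-negative
    spectral templates, so among candidate ICA rotations the physically
    meaningful one back-projects to nearly non-negative components, while
    spurious rotations carry large negative lobes.
    """
    c = comps.copy()
    for row in c:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    total = float(np.sum(c**2))
    if total == 0:
        return 0.0
    return float(np.sum(np.minimum(c, 0.0) ** 2) / total)


def _polish_rotation(comps: np.ndarray, n_sweeps: int = 8,
                     n_angles: int = 64) -> np.ndarray:
    """Orthogonal refinement toward non-negative components.

    Greedy Jacobi sweeps over pairwise plane rotations, each step keeping
    the rotation that most reduces the negative energy fraction.  An
    orthogonal rotation of the (whitened-space) components is within the
    ICA solution ambiguity; the non-negativity of amplitude spectra is the
    physically grounded disambiguator (non-negative ICA).  Deterministic.
    """
    C = comps.copy()
    k = C.shape[0]
    angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)[1:]
    for _ in range(n_sweeps):
        improved = False
        for i in range(k):
            for j in range(i + 1, k):
                best = _negative_energy_fraction(C)
                best_t = 0.0
                for t in angles:
                    c, s = np.cos(t), np.sin(t)
                    R = np.eye(k)
                    R[i, i] = c
                    R[j, j] = c
                    R[i, j] = -s
                    R[j, i] = s
                    neg = _negative_energy_fraction(R @ C)
                    if neg < best - 1e-12:
                        best, best_t = neg, t
                if best_t:
                    c, s = np.cos(best_t), np.sin(best_t)
                    R = np.eye(k)
                    R[i, i] = c
                    R[j, j] = c
                    R[i, j] = -s
                    R[j, i] = s
                    C = R @ C
                    improved = True
        if not improved:
            break
    return C


def extract_tscs(
    signatures: np.ndarray,
    n_components: int = 5,
    seed: int = 0,
    log_transform: bool = False,
    n_restarts: int = 10,
    freqs: np.ndarray | None = None,
) -> TSCSet:
    """Extract tSCs from pooled spectral signatures by PCA + FastICA.

    Signatures are centered, reduced to ``n_components`` principal
    components (explained-variance fraction reported), and unmixed by
    fixed-point ICA.  FastICA is a local optimizer, so it is restarted
    ``n_restarts`` times from seeds derived from ``seed`` and the solution
    whose back-projected components are closest to non-negative is kept
    (tSCs are amplitude spectra; spurious rotations carry large negative
    lobes) — restarts that fail to converge are skipped.  The independent
    directions are back-projected to the frequency grid, sign-fixed so the
    spectral peak is positive, normalized to unit L2 norm, and ordered by
    peak frequency.  Deterministic under a fixed seed.
    """
    X = np.asarray(signatures, dtype=float)
    if X.ndim != 2:
        raise ValueError("signatures must be a 2-D array (cycles x freqs)")
    if X.shape[0] < 50:
        raise ValueError(
            f"need at least 50 signatures to extract components, got {X.shape[0]}"
        )
    if freqs is None:
        freqs = default_tsc_grid(X.shape[1])
    if log_transform:
        X = np.log1p(X)
    mean = X.mean(axis=0)
    Xc = X - mean
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(Xc)
    explained = float(pca.explained_variance_ratio_.sum())
    # sign convention based on the loading vectors only (not the samples),
    # so replicated datasets follow identical ICA trajectories
    for k, row in enumerate(pca.components_):
        if row[np.argmax(np.abs(row))] < 0:
            pca.components_[k] = -row
            scores[:, k] = -scores[:, k]

    import warnings
    from sklearn.exceptions import ConvergenceWarning

    # PCA scores are uncorrelated; whiten them explicitly so the ICA input
    # (and hence the whole fit) is invariant to sample replication —
    # FastICA's internal whitening SVD is not
    std = scores.std(axis=0)
    std[std == 0] = 1.0
    white = scores / std

    best_comps: np.ndarray | None = None
    best_neg = np.inf
    last_err: Exception | None = None
    for attempt in range(n_restarts):
        # n_components is implied by the whitened input's dimensionality
        ica = FastICA(
            random_state=seed + 1000 * attempt,
            whiten=False,
            max_iter=2000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                ica.fit(white)
            except ConvergenceWarning as err:  # skip non-converged restarts
                last_err = err
                continue
        cand = _polish_rotation(
            (std[:, None] * ica.mixing_).T @ pca.components_
        )
        neg = _negative_energy_fraction(cand)
        if neg < best_neg:
            best_neg, best_comps = neg, cand
    if best_comps is None:
        raise RuntimeError(
            f"FastICA failed to converge in {n_restarts} restarts: {last_err}"
        )
    comps = best_comps
    # sign-fix: spectral peak positive
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    norms = np.linalg.norm(comps, axis=1)
    norms[norms == 0] = 1.0
    comps = comps / norms[:, None]
    peak_f = freqs[np.argmax(comps, axis=1)]
    energy = (comps**2).sum(axis=1)
    order = np.lexsort((energy, peak_f))
    comps = comps[order]
    return TSCSet(
        components=comps,
        freqs=np.asarray(freqs, dtype=float),
        explained_variance_pca=explained,
        mean_signature=mean,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# strengths and events
# ---------------------------------------------------------------------------

def _bimodal_threshold(s: np.ndarray, max_iter: int = 100) -> float:
    """1-D two-means (Otsu/Lloyd) threshold between the two strength modes."""
    t = float(s.mean())
    for _ in range(max_iter):
        lo, hi = s[s <= t], s[s > t]
        if not len(lo) or not len(hi):
            break
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < 1e-12:
            break
        t = t_new
    return t


def tsc_strengths(
    signatures: np.ndarray,
    tscs: TSCSet,
    threshold_rule: str = "bimodal",
    percentile: float = 95.0,
) -> StrengthMatrix:
    """Similarity strengths (inner products) and thresholded events.

    ``threshold_rule``:

    * ``"bimodal"`` (default) — per-tSC two-means split of that tSC's own
      strength distribution.  Cycles expressing a component form a separate
      strength mode, so the threshold between the class means separates
      expressing from non-expressing cycles;
    * ``"mean+2sd"`` — mean plus two standard deviations (marks only the
      extreme tail; appropriate when components are rare outliers);
    * ``"percentile"`` — per-tSC percentile threshold (``percentile``).
    """
    X = np.asarray(signatures, dtype=float)
    if X.shape[1] != tscs.components.shape[1]:
        raise ValueError("signature and component frequency grids differ")
    strengths = X @ tscs.components.T
    if threshold_rule == "bimodal":
        thr = np.array([_bimodal_threshold(col) for col in strengths.T])
    elif threshold_rule == "mean+2sd":
        thr = strengths.mean(axis=0) + 2.0 * strengths.std(axis=0)
    elif threshold_rule == "percentile":
        thr = np.percentile(strengths, percentile, axis=0)
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    events = strengths > thr
    return StrengthMatrix(strengths, thr, events)


def export_tsc_raster(
    strengths: StrengthMatrix,
    cycles: Sequence[ThetaCycle],
    fs: float,
    annotation: SessionAnnotation | None = None,
    t0: float = 0.0,
) -> pd.DataFrame:
    """Per-cycle, per-tSC event table with timestamps and context labels.

    One row per detected event, ordered by time then component index.  An
    empty event matrix yields an empty table with the header.
    """
    if strengths.events.shape[0] != len(cycles):
        raise ValueError("event matrix rows must match the cycle list")
    rows = []
    for i, cyc in enumerate(cycles):
        t = t0 + cyc.trough_idx / fs
        corridor = annotation.label_at(t, "corridor") if annotation else None
        sector = annotation.label_at(t, "sector") if annotation else None
        for j in np.flatnonzero(strengths.events[i]):
            rows.append(
                (i, f"tSC{j + 1}", t, float(strengths.strengths[i, j]),
                 corridor, sector)
            )
    return pd.DataFrame(
        rows,
        columns=["cycle", "tsc", "time_s", "strength", "corridor", "sector"],
    )
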