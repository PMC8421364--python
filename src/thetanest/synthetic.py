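"""Synthetic two-channel LFPs with known theta-gamma structure.

The generator produces the statistical structure the downstream analysis
assumes, with full ground truth so every stage has a recovery test:

* a theta carrier (default 7 Hz) with slow sinusoidal frequency drift,
  zero phase at each trough;
* gamma bursts from 2-5 spectral families (Gaussian-windowed sinusoids,
  a few cycles long) nested at family-specific theta phases, emitted per
  theta cycle with probability given by the active context's mixing weight;
* broadband 1/f noise obtained by spectral shaping of white noise;
* directional inter-channel coupling realized as a delayed additive copy of
  the source channel's oscillatory content plus independent noise, so the
  true direction and lag are unambiguous;
* stable bivariate VAR processes with known coefficients, plus the
  closed-form Geweke causality of the true model, as oracles for the
  causality estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .causality import geweke_spectral_gc
from .recording import LFPRecording, SessionAnnotation, Interval, tile_contexts

__all__ = [
    "GammaFamily",
    "SynthConfig",
    "GroundTruth",
    "VARSpec",
    "default_gamma_families",
    "default_context_mixes",
    "generate_theta_gamma_lfp",
    "generate_var_process",
    "true_spectral_gc",
]


@dataclass(frozen=True)
class GammaFamily:
    """One gamma spectral family nested in the theta rhythm."""

    center_f: float  # Hz
    bandwidth: float  # Hz (spectral FWHM-like width of the burst atom)
    preferred_phase: float  # radians from the theta trough
    amplitude: float = 1.0  # a.u., relative to unit theta amplitude


def default_gamma_families() -> list[GammaFamily]:
    """Five families spanning slow to fast gamma (30-200 Hz).

    The two highest sit near 80 Hz (high gamma) and 140 Hz (fast gamma),
    the bands most diagnostic in the amygdalo-hippocampal analysis.
    Amplitudes rise with frequency so that the per-cycle spectral-signature
    contrast of each family is comparable: higher-frequency burst atoms are
    shorter (fixed cycle count) and would otherwise contribute much less
    mean wavelet amplitude over a theta cycle.
    """
    return [
        GammaFamily(35.0, 10.0, 0.5 * np.pi, 1.0),
        GammaFamily(55.0, 14.0, 1.0 * np.pi, 1.2),
        GammaFamily(80.0, 20.0, 1.5 * np.pi, 1.5),
        GammaFamily(110.0, 26.0, 0.25 * np.pi, 1.8),
        GammaFamily(140.0, 32.0, 1.75 * np.pi, 2.2),
    ]


def default_context_mixes(
    n_families: int,
    corridors: tuple[str, ...] = ("c1", "c2", "c3", "c4"),
    sectors: tuple[str, ...] = ("s1", "s2", "s3", "s4"),
    base: float = 0.08,
    dominant: float = 0.6,
) -> dict[str, np.ndarray]:
    """One mixing-weight vector per corridor/sector context.

    Each context carries a low base rate for every family plus one dominant
    family.  The rates keep expression sparse — each component appears in a
    minority of theta cycles, as observed for theta-nested gamma motifs in
    vivo.  The dominant family rotates with the context index; the
    chemosensory context ``c3s3`` is pinned to the fastest family
    (urine-associated fast gamma).  Several contexts therefore share a
    motif, as corridors sharing a stimulus class do in vivo.
    """
    mixes: dict[str, np.ndarray] = {}
    i = 0
    for c in corridors:
        for s in sectors:
            w = np.full(n_families, base)
            w[i % n_families] = dominant
            mixes[c + s] = w
            i += 1
    if "c3s3" in mixes and n_families >= 2:
        w = np.full(n_families, base)
        w[n_families - 1] = dominant
        mixes["c3s3"] = w
    return mixes


@dataclass
class SynthConfig:
    """Parameters of the synthetic theta-gamma session."""

    duration_s: float = 160.0
    fs: float = 1000.0
    theta_f0: float = 7.0  # Hz
    theta_drift: float = 1.0  # Hz peak-to-peak slow drift
    theta_drift_period_s: float = 20.0
    gamma_families: list[GammaFamily] = field(default_factory=default_gamma_families)
    context_mixes: dict[str, np.ndarray] | None = None
    corridors: tuple[str, ...] = ("c1", "c2", "c3", "c4")
    sectors: tuple[str, ...] = ("s1", "s2", "s3", "s4")
    coupling_direction: str = "AtoB"  # {"AtoB", "BtoA", "bidirectional", "none"}
    coupling_lag_ms: float = 8.0
    noise_exponent: float = 1.0  # 1/f slope
    snr: float = 2.0  # oscillatory-content variance / noise variance
    burst_phase_jitter: float = 0.15  # radians (SD)
    channel_labels: tuple[str, str] = ("PMCo", "CA1")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.gamma_families:
            f_max = max(g.center_f for g in self.gamma_families)
            if self.fs <= 2 * f_max:
                raise ValueError(
                    f"fs={self.fs} Hz must exceed twice the highest gamma "
                    f"family frequency ({f_max} Hz)"
                )
        if self.coupling_direction not in ("AtoB", "BtoA", "bidirectional", "none"):
            raise ValueError(
                f"unknown coupling_direction {self.coupling_direction!r}"
            )
        if self.context_mixes is None:
            self.context_mixes = default_context_mixes(
                len(self.gamma_families), self.corridors, self.sectors
            )
        for label, w in self.context_mixes.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (len(self.gamma_families),):
                raise ValueError(
                    f"context {label!r}: expected {len(self.gamma_families)} "
                    f"weights, got {w.shape}"
                )
            if np.any((w < 0) | (w > 1)):
                raise ValueError(f"context {label!r}: weights must lie in [0, 1]")
            self.context_mixes[label] = w
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class GroundTruth:
    """Everything the generator injected, for downstream recovery tests."""

    theta_instantaneous_freq: np.ndarray  # Hz per sample
    burst_events: list[tuple[float, int, float]]  # (time_s, family, theta phase)
    true_direction: str
    true_lag_ms: float
    template_freqs: np.ndarray  # Hz grid of the family templates
    family_templates: np.ndarray  # (n_families, n_freqs), non-negative
    context_weights: dict[str, np.ndarray]
    theta_phase: np.ndarray  # radians per sample, 0 at troughs
    component_variances: dict[str, float]  # theta/gamma/noise of channel A


def _one_over_f_noise(n: int, fs: float, exponent: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f**exponent amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n)
    return shaped / shaped.std()


def _theta_carrier(cfg: SynthConfig, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Theta trace with slow drift: returns (theta, inst_freq, phase).

    Phase is measured from the trough: theta = -cos(phase).
    """
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    drift_phase = rng.uniform(0, 2 * np.pi)
    inst_freq = cfg.theta_f0 + 0.5 * cfg.theta_drift * np.sin(
        2 * np.pi * t / cfg.theta_drift_period_s + drift_phase
    )
    phase = 2 * np.pi * np.cumsum(inst_freq) / cfg.fs
    phase -= phase[0]
    theta = -np.cos(phase)
    return theta, inst_freq, phase


def _family_sigma_t(family: GammaFamily) -> float:
    """Time SD of the Gaussian burst envelope from its spectral width."""
    return 1.0 / (np.pi * family.bandwidth)


def _render_bursts(
    cfg: SynthConfig,
    phase: np.ndarray,
    annotation: SessionAnnotation,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[float, int, float]]]:
    """Place context-weighted gamma bursts at their preferred theta phases."""
    n = len(phase)
    t = np.arange(n) / cfg.fs
    gamma = np.zeros(n)
    events: list[tuple[float, int, float]] = []
    n_cycles = int(phase[-1] // (2 * np.pi))
    for i in range(n_cycles):
        cycle_phase0 = 2 * np.pi * i
        t_center_cycle = float(np.interp(cycle_phase0 + np.pi, phase, t))
        context = annotation.context_at(t_center_cycle)
        if context is None or context not in cfg.context_mixes:
            continue
        weights = cfg.context_mixes[context]
        for k, fam in enumerate(cfg.gamma_families):
            if fam.amplitude == 0 or rng.random() >= weights[k]:
                continue
            jitter = rng.normal(0.0, cfg.burst_phase_jitter)
            target = cycle_phase0 + (fam.preferred_phase + jitter) % (2 * np.pi)
            tc = float(np.interp(target, phase, t))
            sigma_t = _family_sigma_t(fam)
            lo = max(0, int((tc - 4 * sigma_t) * cfg.fs))
            hi = min(n, int((tc + 4 * sigma_t) * cfg.fs) + 1)
            if hi <= lo:
                continue
            tt = t[lo:hi] - tc
            amp = fam.amplitude * rng.uniform(0.75, 1.25)
            burst = amp * np.exp(-0.5 * (tt / sigma_t) ** 2) * np.cos(
                2 * np.pi * fam.center_f * tt + rng.uniform(0, 2 * np.pi)
            )
            gamma[lo:hi] += burst
            events.append((tc, k, float((fam.preferred_phase + jitter) % (2 * np.pi))))
    return gamma, events


def _family_templates(cfg: SynthConfig, n_freqs: int = 96
                      ) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.geomspace(10.0, 200.0, n_freqs)
    templates = np.empty((len(cfg.gamma_families), n_freqs))
    for k, fam in enumerate(cfg.gamma_families):
        sigma_f = fam.bandwidth / 2.0
        templates[k] = np.exp(-0.5 * ((freqs - fam.center_f) / sigma_f) ** 2)
    return freqs, templates


def _delay(x: np.ndarray, lag_samples: int) -> np.ndarray:
    if lag_samples == 0:
        return x.copy()
    out = np.zeros_like(x)
    out[lag_samples:] = x[:-lag_samples]
    return out


def generate_theta_gamma_lfp(
    config: SynthConfig,
) -> tuple[LFPRecording, SessionAnnotation, GroundTruth]:
    """Generate a two-channel theta-gamma session with ground truth.

    Channel coupling: for direction A->B, channel B is channel A's
    oscillatory (theta + gamma) content delayed by ``coupling_lag_ms`` plus
    independent 1/f noise (mirror for B->A).  With ``bidirectional`` each
    channel receives the delayed content of the other in addition to its
    own; with ``none`` the channels carry independent content.  Identical
    config (including seed) gives bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    sector_dur = cfg.duration_s / (len(cfg.corridors) * len(cfg.sectors))
    annotation = tile_contexts(cfg.corridors, cfg.sectors, sector_dur)
    if "c3" in cfg.corridors and "s3" in cfg.sectors:
        ci = list(cfg.corridors).index("c3")
        si = list(cfg.sectors).index("s3")
        onset = (ci * len(cfg.sectors) + si) * sector_dur
        annotation = SessionAnnotation(
            annotation.intervals
            + [Interval(onset, onset + sector_dur, "stimulus", "urine")]
        )

    theta_a, inst_freq, phase_a = _theta_carrier(cfg, rng)
    gamma_a, events_a = _render_bursts(cfg, phase_a, annotation, rng)
    content_a = theta_a + gamma_a

    lag = int(round(cfg.coupling_lag_ms * cfg.fs / 1000.0))
    if cfg.coupling_direction in ("none", "bidirectional"):
        theta_b, _, phase_b = _theta_carrier(cfg, rng)
        gamma_b, _ = _render_bursts(cfg, phase_b, annotation, rng)
        content_b = theta_b + gamma_b
    if cfg.coupling_direction == "AtoB":
        sig_a = content_a
        sig_b = _delay(content_a, lag)
    elif cfg.coupling_direction == "BtoA":
        # mirror: B carries the generated content, A the delayed copy
        sig_b = content_a
        sig_a = _delay(content_a, lag)
    elif cfg.coupling_direction == "none":
        sig_a, sig_b = content_a, content_b
    else:  # bidirectional
        sig_a = content_a + _delay(content_b, lag)
        sig_b = content_b + _delay(content_a, lag)

    noise_sd_a = np.sqrt(np.var(sig_a) / cfg.snr)
    noise_sd_b = np.sqrt(np.var(sig_b) / cfg.snr)
    noise_a = noise_sd_a * _one_over_f_noise(n, cfg.fs, cfg.noise_exponent, rng)
    noise_b = noise_sd_b * _one_over_f_noise(n, cfg.fs, cfg.noise_exponent, rng)
    samples = np.vstack([sig_a + noise_a, sig_b + noise_b])
    rec = LFPRecording(samples, cfg.fs, list(cfg.channel_labels))

    template_freqs, templates = _family_templates(cfg)
    truth = GroundTruth(
        theta_instantaneous_freq=inst_freq,
        burst_events=events_a,
        true_direction=cfg.coupling_direction,
        true_lag_ms=cfg.coupling_lag_ms,
        template_freqs=template_freqs,
        family_templates=templates,
        context_weights=dict(cfg.context_mixes),
        theta_phase=phase_a,
        component_variances={
            "theta": float(np.var(theta_a)),
            "gamma": float(np.var(gamma_a)),
            "noise": float(np.var(noise_a)),
        },
    )
    return rec, annotation, truth


def simulate_proportion_table(
    n_subjects: int = 8,
    base_p: float = 0.3,
    shift_sector: str | None = "s3",
    shift: float = 0.2,
    n_windows: int = 40,
    subject_sd: float = 0.05,
    direction: str = "AtoB",
    seed: int = 0,
) -> "pd.DataFrame":
    """Synthetic per-context causality-proportion table with a known effect.

    Each (subject, corridor, sector) cell draws a binomial count of
    significant windows out of ``n_windows`` at probability ``base_p`` plus
    a subject-level random offset (SD ``subject_sd``) and, in
    ``shift_sector``, the injected ``shift``.  The oracle for power tests
    of the sector contrast.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for si in range(n_subjects):
        offset = rng.normal(0.0, subject_sd)
        for corridor in ("c1", "c2", "c3", "c4"):
            for sector in ("s1", "s2", "s3", "s4"):
                p = base_p + offset + (shift if sector == shift_sector else 0.0)
                p = min(max(p, 0.01), 0.99)
                k = rng.binomial(n_windows, p)
                prop = k / n_windows
                rows.append((f"subj{si}", corridor, sector, direction,
                             n_windows, prop, float(np.arcsin(np.sqrt(prop)))))
    return pd.DataFrame(
        rows, columns=["subject", "corridor", "sector", "direction",
                       "n_windows", "proportion", "transformed"],
    )


def cycle_family_membership(
    truth: GroundTruth, cycles, fs: float, n_families: int | None = None
) -> np.ndarray:
    """Ground-truth burst membership per detected cycle.

    Maps each injected burst event to the detected cycle containing its
    center time; returns a boolean ``(n_cycles, n_families)`` matrix — the
    oracle for event-detection recovery tests.
    """
    if n_families is None:
        n_families = 1 + max((k for _, k, _ in truth.burst_events), default=0)
    starts = np.array([c.start_idx for c in cycles])
    ends = np.array([c.end_idx for c in cycles])
    member = np.zeros((len(cycles), n_families), dtype=bool)
    for t_burst, fam, _ in truth.burst_events:
        s = t_burst * fs
        j = int(np.searchsorted(starts, s, side="right")) - 1
        if 0 <= j < len(cycles) and starts[j] <= s < ends[j]:
            member[j, fam] = True
    return member


# ---------------------------------------------------------------------------
# VAR oracles
# ---------------------------------------------------------------------------

@dataclass
class VARSpec:
    """A known bivariate VAR process for causality validation."""

    order: int
    coefficient_matrices: np.ndarray  # (order, 2, 2)
    noise_covariance: np.ndarray  # (2, 2) SPD
    n_samples: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.coefficient_matrices = np.asarray(
            self.coefficient_matrices, dtype=float
        ).reshape(self.order, 2, 2)
        self.noise_covariance = np.asarray(self.noise_covariance, dtype=float)
        sig = self.noise_covariance
        if sig.shape != (2, 2) or not np.allclose(sig, sig.T):
            raise ValueError("noise covariance must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(sig) <= 0):
            raise ValueError("noise covariance must be positive-definite")
        if self.order > 0 and self.spectral_radius() >= 1.0:
            raise ValueError(
                f"unstable VAR specification: companion spectral radius "
                f"{self.spectral_radius():.4f} >= 1"
            )

    def spectral_radius(self) -> float:
        p = self.order
        if p == 0:
            return 0.0
        comp = np.zeros((2 * p, 2 * p))
        comp[:2] = np.hstack(list(self.coefficient_matrices))
        if p > 1:
            comp[2:, :-2] = np.eye(2 * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


def generate_var_process(spec: VARSpec, burn_in: int = 1000) -> LFPRecording:
    """Simulate a realization of the specified VAR (fs is nominally 1 kHz).

    A burn-in is discarded so the returned samples come from the stationary
    distribution.  Reproducible under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(spec.noise_covariance)
    total = spec.n_samples + burn_in
    eps = rng.standard_normal((total, 2)) @ chol.T
    x = np.zeros((total, 2))
    p = spec.order
    A = spec.coefficient_matrices
    for t in range(p, total):
        acc = eps[t].copy()
        for k in range(p):
            acc += A[k] @ x[t - k - 1]
        x[t] = acc
    return LFPRecording(x[burn_in:].T, 1000.0, ["x", "y"])


def true_spectral_gc(
    spec: VARSpec, freqs: np.ndarray, fs: float = 1000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Geweke causality spectra of the true model (x->y, y->x).

    Evaluated directly from the specified transfer function and noise
    covariance; no estimation is involved.
    """
    coeffs = spec.coefficient_matrices if spec.order else np.zeros((0, 2, 2))
    return geweke_spectral_gc(coeffs, spec.noise_covariance, freqs, fs)
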