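"""Windowed spectral Granger causality between two LFP channels.

The directed influence between the two recording sites is quantified with
Geweke's frequency-domain decomposition of Granger causality.  For each
1-s window a bivariate VAR model is fitted by ordinary least squares with
the order chosen by an information criterion; the spectral causality in each
direction is computed from the transfer function ``H = A(f)^-1`` and the
noise covariance after rotating away the instantaneous correlation, which
splits the destination spectrum exactly into intrinsic and causal parts:

    S_xx = sigma_xx |H_xx + (sigma_xy/sigma_xx) H_xy|^2
         + (sigma_yy - sigma_xy^2/sigma_xx) |H_xy|^2
    f_{y->x}(lambda) = ln(1 + causal / intrinsic)
Windows are classified by direction (A->B, B->A, both, none) from the
significance of the band-integrated causality, and per-context proportions
of each label feed an arcsine-square-root transformed mixed-effects
contrast across the corridor/sector layout of the session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .recording import LFPRecording, SessionAnnotation

__all__ = [
    "CausalityConfig",
    "VARModel",
    "CausalityWindow",
    "fit_var",
    "geweke_spectral_gc",
    "spectral_granger",
    "time_domain_gc",
    "classify_window",
    "sliding_windows",
    "analyze_windows",
    "causality_ratio_by_context",
    "compare_ratios",
]


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class CausalityConfig:
    """Parameters of the windowed causality analysis."""

    window_s: float = 1.0
    step_s: float | None = None  # None -> non-overlapping (step = window)
    max_order: int = 20
    order_criterion: str = "aic"  # {"aic", "bic"}
    band: tuple[float, float] = (5.0, 12.0)  # theta
    alpha: float = 0.05
    null_method: str = "permutation"  # {"asymptotic", "permutation"}
    n_permutations: int = 200
    n_freqs: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.order_criterion not in ("aic", "bic"):
            raise ValueError(f"unknown order criterion {self.order_criterion!r}")
        if self.null_method not in ("asymptotic", "permutation"):
            raise ValueError(f"unknown null method {self.null_method!r}")

    def validate_for_fs(self, fs: float) -> None:
        if self.window_s * fs <= 10 * self.max_order:
            raise ValueError(
                f"window of {self.window_s} s at {fs} Hz is too short for "
                f"max_order={self.max_order} (need window*fs > 10*max_order)"
            )


@dataclass
class VARModel:
    """Bivariate VAR fitted to one window."""

    order: int
    coeffs: np.ndarray  # (order, 2, 2); coeffs[k][i, j]: x_j(t-k-1) -> x_i(t)
    sigma: np.ndarray  # residual covariance, (2, 2)
    n_obs: int
    stable: bool
    rss: np.ndarray | None = None  # per-equation residual sum of squares

    def is_usable(self) -> bool:
        return self.stable and np.all(np.isfinite(self.sigma))


@dataclass
class CausalityWindow:
    """Per-window spectral GC result and directionality label."""

    t_start: float
    t_end: float
    freqs: np.ndarray | None
    gc_ab: np.ndarray | None  # A -> B spectrum
    gc_ba: np.ndarray | None  # B -> A spectrum
    peak_freq_ab: float | None
    peak_freq_ba: float | None
    p_ab: float | None
    p_ba: float | None
    label: str  # {"AtoB", "BtoA", "both", "none", "unfit"}
    var_order: int | None
    stable: bool

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


# ---------------------------------------------------------------------------
# VAR estimation
# ---------------------------------------------------------------------------

def _lag_matrix(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of lagged values (with intercept) and the response.

    ``x`` is (n_samples, 2).  Returns ``(X, Y)`` with ``X`` of shape
    ``(n - order, 1 + 2*order)``.
    """
    n = x.shape[0]
    rows = n - order
    X = np.empty((rows, 1 + 2 * order))
    X[:, 0] = 1.0
    for k in range(1, order + 1):
        X[:, 1 + 2 * (k - 1): 1 + 2 * k] = x[order - k: n - k]
    return X, x[order:]


def _companion_stable(coeffs: np.ndarray) -> bool:
    p = coeffs.shape[0]
    comp = np.zeros((2 * p, 2 * p))
    comp[:2] = np.hstack(list(coeffs))
    if p > 1:
        comp[2:, :-2] = np.eye(2 * (p - 1))
    return bool(np.max(np.abs(np.linalg.eigvals(comp))) < 1.0)


def _ols_var(x: np.ndarray, order: int) -> VARModel | None:
    """OLS fit of a bivariate VAR(order); None if regressors are deficient."""
    X, Y = _lag_matrix(x, order)
    n = X.shape[0]
    try:
        beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    except np.linalg.LinAlgError:
        return None
    if rank < X.shape[1]:
        return None
    resid = Y - X @ beta
    sigma = resid.T @ resid / (n - X.shape[1])
    coeffs = np.stack(
        [beta[1 + 2 * k: 3 + 2 * k].T for k in range(order)]
    ) if order else np.zeros((0, 2, 2))
    rss = np.sum(resid**2, axis=0)
    return VARModel(order, coeffs, sigma, n, _companion_stable(coeffs) if order else True,
                    rss=rss)


def fit_var(segment: np.ndarray, config: CausalityConfig, fs: float) -> VARModel | None:
    """Fit a bivariate VAR to a window, selecting the order by AIC/BIC.

    ``segment`` is (n_samples, 2) or (2, n_samples).  Returns None for
    degenerate windows (constant channel, rank-deficient design, no stable
    fit), which the caller marks "unfit" rather than raising.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 2:
        raise ValueError("segment must be two-dimensional")
    if x.shape[0] == 2 and x.shape[1] != 2:
        x = x.T
    if not np.all(np.isfinite(x)):
        return None
    if np.any(x.std(axis=0) == 0):
        return None
    config.validate_for_fs(fs)
    n = x.shape[0]
    best_p = 0
    best_ic = np.inf
    n_eff = n - config.max_order  # common sample for fair IC comparison
    for p in range(1, config.max_order + 1):
        model = _ols_var(x[config.max_order - p:], p)
        if model is None:
            continue
        sign, logdet = np.linalg.slogdet(model.sigma)
        if sign <= 0:
            continue
        k_params = 2 * (1 + 2 * p)
        if config.order_criterion == "bic":
            ic = logdet + k_params * np.log(n_eff) / n_eff
        else:
            ic = logdet + 2 * k_params / n_eff
        if ic < best_ic:
            best_ic, best_p = ic, p
    if best_p == 0:
        return None
    # refit the selected order on the full window so residual statistics
    # refer to the same sample as downstream significance tests
    best = _ols_var(x, best_p)
    if best is None or not best.is_usable():
        return None
    return best


# ---------------------------------------------------------------------------
# Geweke spectral decomposition
# ---------------------------------------------------------------------------

def geweke_spectral_gc(
    coeffs: np.ndarray,
    sigma: np.ndarray,
    freqs: np.ndarray,
    fs: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Geweke spectral Granger causality of a bivariate VAR.

    Parameters
    ----------
    coeffs
        Coefficient matrices, shape ``(order, 2, 2)``.
    sigma
        Innovation covariance, shape ``(2, 2)``, symmetric positive-definite.
    freqs
        Frequencies (Hz) at which to evaluate the spectra.
    fs
        Sampling rate (Hz) the coefficients refer to.

    Returns
    -------
    (gc_xy, gc_yx)
        ``gc_xy[f]`` is the causality channel 0 -> channel 1 at ``freqs[f]``
        and ``gc_yx`` the reverse direction.  Both are non-negative; a
        direction with no cross-coefficients and diagonal noise is exactly 0.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if sigma.shape != (2, 2):
        raise ValueError("noise covariance must be 2x2")
    det = np.linalg.det(sigma)
    if det <= 0 or sigma[0, 0] <= 0 or sigma[1, 1] <= 0:
        raise ValueError("noise covariance must be symmetric positive-definite")
    order = coeffs.shape[0]
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, order + 1)) / fs)
    # A(f) = I - sum_k A_k e^{-2pi i f k / fs}
    A = np.tile(np.eye(2, dtype=complex), (len(freqs), 1, 1))
    for k in range(order):
        A -= z[:, k, None, None] * coeffs[k]
    # explicit 2x2 inverse preserves exact structural zeros of A
    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
    H = np.empty_like(A)
    H[:, 0, 0] = A[:, 1, 1] / det
    H[:, 0, 1] = -A[:, 0, 1] / det
    H[:, 1, 0] = -A[:, 1, 0] / det
    H[:, 1, 1] = A[:, 0, 0] / det
    gc = np.empty((2, len(freqs)))
    for src, dst in ((0, 1), (1, 0)):
        # causality src -> dst.  Rotate the innovations so the destination
        # noise is uncorrelated with the source noise; the destination
        # spectrum then splits exactly into intrinsic + causal parts:
        #   S_dd = sigma_dd |H_dd + (sigma_ds/sigma_dd) H_ds|^2
        #        + (sigma_ss - sigma_ds^2/sigma_dd) |H_ds|^2
        # The additive form is numerically stable (no cancellation) and
        # non-negative by construction.
        sig_dd = sigma[dst, dst]
        sig_ss = sigma[src, src]
        sig_ds = sigma[dst, src]
        sig_partial = sig_ss - sig_ds**2 / sig_dd
        h_intr = H[:, dst, dst] + (sig_ds / sig_dd) * H[:, dst, src]
        intrinsic = sig_dd * np.abs(h_intr) ** 2
        causal = sig_partial * np.abs(H[:, dst, src]) ** 2
        idx = 0 if (src, dst) == (0, 1) else 1
        with np.errstate(divide="ignore", invalid="ignore"):
            gc[idx] = np.log1p(
                np.where(intrinsic > 0, causal / intrinsic, np.inf)
            )
    return gc[0], gc[1]


def spectral_granger(
    model: VARModel, freqs: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Directional GC spectra of a fitted window model (A->B, B->A)."""
    if not model.stable:
        raise ValueError("spectral decomposition requires a stable VAR model")
    return geweke_spectral_gc(model.coeffs, model.sigma, freqs, fs)


def time_domain_gc(
    x: np.ndarray, order: int, restricted_order: int | None = None
) -> tuple[np.ndarray, VARModel | None]:
    """Time-domain Granger causality (log residual-variance ratio).

    The restricted (single-channel) process implied by dropping the other
    channel is ARMA, so its AR approximation needs more lags than the full
    bivariate model; by default four times ``order`` (at least 20, capped
    by sample size) is used, which makes the Geweke identity — mean
    spectral GC over [0, Nyquist] equals time-domain GC — hold closely.
    Returns ``([gc_ab, gc_ba], unrestricted model)``.
    """
    x = np.asarray(x, dtype=float)
    full = _ols_var(x, order)
    if full is None:
        return np.array([np.nan, np.nan]), None
    if restricted_order is None:
        restricted_order = min(max(4 * order, 20), x.shape[0] // 10)
    out = np.empty(2)
    for idx, dst in ((0, 1), (1, 0)):
        X, Y = _lag_matrix(x[:, dst: dst + 1], restricted_order)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        var_r = float(np.sum(resid**2)) / (X.shape[0] - X.shape[1])
        out[idx] = np.log(var_r / full.sigma[dst, dst])
    return out, full


# ---------------------------------------------------------------------------
# window classification
# ---------------------------------------------------------------------------

def _asymptotic_pvalues(segment: np.ndarray, model: VARModel) -> tuple[float, float]:
    """F-test of the cross-lag block per direction (restricted vs full)."""
    x = segment
    p = model.order
    pvals = []
    for src, dst in ((0, 1), (1, 0)):
        X, Y = _lag_matrix(x[:, dst: dst + 1], p)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        rss_r = float(np.sum((Y - X @ beta) ** 2))
        rss_f = float(model.rss[dst])
        n = model.n_obs
        k_full = 1 + 2 * p
        df2 = n - k_full
        f_stat = max(rss_r - rss_f, 0.0) / p / (rss_f / df2)
        pvals.append(float(stats.f.sf(f_stat, p, df2)))
    return pvals[0], pvals[1]


def _permutation_pvalues(
    segment: np.ndarray,
    model: VARModel,
    band_gc: tuple[float, float],
    freqs: np.ndarray,
    band_mask: np.ndarray,
    fs: float,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation null from circular time-shifts of the source channel.

    Each shift destroys the temporal alignment while preserving both
    marginal autocorrelation structures; the band-integrated GC is
    recomputed at the fitted order.
    """
    n = segment.shape[0]
    p = model.order
    counts = np.ones(2)  # add-one correction
    min_shift = max(p + 1, int(0.1 * n))
    shifts = rng.integers(min_shift, n - min_shift, size=n_perm)
    for s in shifts:
        perm = segment.copy()
        perm[:, 0] = np.roll(segment[:, 0], int(s))
        m = _ols_var(perm, p)
        if m is None or not m.is_usable():
            continue
        g_ab, g_ba = geweke_spectral_gc(m.coeffs, m.sigma, freqs[band_mask], fs)
        counts[0] += g_ab.mean() >= band_gc[0]
        counts[1] += g_ba.mean() >= band_gc[1]
    denom = n_perm + 1
    return counts[0] / denom, counts[1] / denom


def classify_window(
    segment: np.ndarray,
    t_start: float,
    config: CausalityConfig,
    fs: float,
    rng: np.random.Generator | None = None,
) -> CausalityWindow:
    """Fit, decompose and label one analysis window.

    Each direction is tested at ``alpha / 2`` (Bonferroni over the two
    directions) so the per-window rate of any spurious directionality is
    controlled at ``alpha``.  The label is ``both`` when both directions
    reach significance in the configured band, ``none`` when neither does,
    and the peak frequency is reported only for significant directions.
    """
    x = np.asarray(segment, dtype=float)
    if x.shape[0] == 2 and x.shape[1] != 2:
        x = x.T
    t_end = t_start + x.shape[0] / fs
    model = fit_var(x, config, fs)
    if model is None:
        return CausalityWindow(t_start, t_end, None, None, None, None, None,
                               None, None, "unfit", None, False)
    lo, hi = config.band
    freqs = np.linspace(lo, hi, config.n_freqs)
    gc_ab, gc_ba = spectral_granger(model, freqs, fs)
    band_mask = np.ones(len(freqs), dtype=bool)
    if config.null_method == "asymptotic":
        p_ab, p_ba = _asymptotic_pvalues(x, model)
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        p_ab, p_ba = _permutation_pvalues(
            x, model, (gc_ab.mean(), gc_ba.mean()), freqs, band_mask, fs,
            config.n_permutations, rng,
        )
    sig_ab = p_ab < config.alpha / 2
    sig_ba = p_ba < config.alpha / 2
    label = {(True, True): "both", (True, False): "AtoB",
             (False, True): "BtoA", (False, False): "none"}[(sig_ab, sig_ba)]
    peak_ab = float(freqs[np.argmax(gc_ab)]) if sig_ab else None
    peak_ba = float(freqs[np.argmax(gc_ba)]) if sig_ba else None
    return CausalityWindow(t_start, t_end, freqs, gc_ab, gc_ba, peak_ab,
                           peak_ba, p_ab, p_ba, label, model.order, model.stable)


def sliding_windows(n_samples: int, fs: float, config: CausalityConfig,
                    t0: float = 0.0) -> list[tuple[int, int, float]]:
    """Window sample ranges ``(start, stop, t_start)`` over a trace."""
    w = int(round(config.window_s * fs))
    step = int(round((config.step_s or config.window_s) * fs))
    if step <= 0 or w <= 0:
        raise ValueError("window and step must be positive")
    return [(s, s + w, t0 + s / fs) for s in range(0, n_samples - w + 1, step)]


def analyze_windows(
    rec: LFPRecording, config: CausalityConfig
) -> list[CausalityWindow]:
    """Run the windowed causality analysis over a two-channel recording."""
    if rec.n_channels != 2:
        raise ValueError("causality analysis requires exactly two channels")
    rng = np.random.default_rng(config.seed)
    x = rec.samples.T
    out = []
    for s, e, t_start in sliding_windows(rec.n_samples, rec.fs, config, rec.t0):
        out.append(classify_window(x[s:e], t_start, config, rec.fs, rng))
    return out


# ---------------------------------------------------------------------------
# context-wise proportions and the mixed-model contrast
# ---------------------------------------------------------------------------

def arcsin_sqrt(p: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing transform ``arcsin(sqrt(p))`` for proportions."""
    return np.arcsin(np.sqrt(p))


def causality_ratio_by_context(
    windows: Sequence[CausalityWindow],
    annotation: SessionAnnotation,
    subject: str = "s0",
    both_counts_each: bool = True,
    movement_only: bool = False,
) -> pd.DataFrame:
    """Per-(subject, corridor, sector, direction) proportion of causal windows.

    A window belongs to the corridor/sector containing its midpoint.  The
    proportion per direction is computed over the fit windows of that
    context; windows labeled ``both`` count toward both directions by
    default.  Contexts with no fit windows produce no rows (a proportion is
    absent, not zero).  The arcsine-square-root transform is included as
    column ``transformed``.
    """
    rows: dict[tuple[str, str], list[str]] = {}
    for w in windows:
        if w.label == "unfit":
            continue
        t = w.midpoint
        if movement_only and not annotation.in_movement(t):
            continue
        corridor = annotation.label_at(t, "corridor")
        sector = annotation.label_at(t, "sector")
        if corridor is None or sector is None:
            continue
        rows.setdefault((corridor, sector), []).append(w.label)
    records = []
    for (corridor, sector), labels in sorted(rows.items()):
        n = len(labels)
        for direction in ("AtoB", "BtoA"):
            if both_counts_each:
                k = sum(lab in (direction, "both") for lab in labels)
            else:
                k = sum(lab == direction for lab in labels)
            p = k / n
            records.append((subject, corridor, sector, direction, n, p,
                            float(arcsin_sqrt(p))))
    return pd.DataFrame(
        records,
        columns=["subject", "corridor", "sector", "direction", "n_windows",
                 "proportion", "transformed"],
    )


@dataclass
class ContrastReport:
    """Mixed-model omnibus test and Tukey-adjusted pairwise sector contrasts."""

    f_stat: float
    df_num: int
    df_den: int
    p_omnibus: float
    contrasts: pd.DataFrame  # pair, estimate, t, df, p_tukey
    fallback_fixed_effects: bool = False


def compare_ratios(
    table: pd.DataFrame,
    direction: str | None = None,
    alpha: float = 0.05,
) -> ContrastReport:
    """Sector effect on transformed causality proportions.

    Fits a linear mixed model ``transformed ~ C(sector) + C(corridor)`` with
    a random intercept per subject, reports a Wald F-type omnibus test for
    the sector effect and all pairwise sector contrasts with Tukey
    (studentized-range) adjustment.  Falls back to a fixed-effects OLS fit
    (flagged) when the mixed model is singular.
    """
    import statsmodels.formula.api as smf

    df = table.copy()
    if direction is not None:
        df = df[df["direction"] == direction]
    if df["subject"].nunique() < 2:
        raise ValueError("mixed-model contrast needs at least two subjects")
    if df["sector"].nunique() < 2:
        raise ValueError("need at least two sectors to contrast")
    import warnings

    fallback = False
    fit = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(
                    "transformed ~ C(sector) + C(corridor)", df,
                    groups=df["subject"],
                ).fit(reml=True, method=method)
            if not np.all(np.isfinite(fit.bse_fe)):
                fit = None
                continue
            break
        except (np.linalg.LinAlgError, ValueError):
            fit = None
    if fit is not None:
        params = fit.fe_params
        cov = fit.cov_params().iloc[: len(params), : len(params)]
    else:
        fit = smf.ols("transformed ~ C(sector) + C(corridor)", df).fit()
        params = fit.params
        cov = fit.cov_params()
        fallback = True
    sectors = sorted(df["sector"].unique())
    names = list(params.index)
    k = len(sectors)
    n_obs = len(df)
    n_fixed = len(params)
    df_den = n_obs - n_fixed - (0 if fallback else df["subject"].nunique() - 1)

    def sector_vector(sector: str) -> np.ndarray:
        v = np.zeros(n_fixed)
        name = f"C(sector)[T.{sector}]"
        if name in names:
            v[names.index(name)] = 1.0
        return v

    # omnibus Wald F on the sector dummies
    L = np.array([sector_vector(s) for s in sectors[1:]])
    beta = np.asarray(params)
    V = np.asarray(cov)
    w = L @ beta
    f_stat = float(w @ np.linalg.solve(L @ V @ L.T, w) / L.shape[0])
    p_omnibus = float(stats.f.sf(f_stat, L.shape[0], df_den))

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = sector_vector(sectors[j]) - sector_vector(sectors[i])
            est = float(c @ beta)
            se = float(np.sqrt(c @ V @ c))
            t = est / se if se > 0 else np.nan
            p_tukey = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df_den))
            rows.append((f"{sectors[i]}-{sectors[j]}", est, t, df_den, p_tukey,
                         p_tukey < alpha))
    contrasts = pd.DataFrame(
        rows, columns=["pair", "estimate", "t", "df", "p_tukey", "significant"]
    )
    return ContrastReport(f_stat, L.shape[0], df_den, p_omnibus, contrasts, fallback)
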