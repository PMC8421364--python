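"""VAR fitting, Geweke spectral decomposition, window classification,
context ratio tables and the mixed-model contrast."""

import numpy as np
import pandas as pd
import pytest

from thetanest.causality import (
    CausalityConfig,
    arcsin_sqrt,
    causality_ratio_by_context,
    classify_window,
    compare_ratios,
    fit_var,
    geweke_spectral_gc,
    spectral_granger,
    time_domain_gc,
)
from thetanest.recording import Interval, SessionAnnotation
from thetanest.synthetic import (
    VARSpec,
    generate_var_process,
    simulate_proportion_table,
    true_spectral_gc,
)


def resonant_var2(r=0.95, f0=7.0, fs=200.0, a21=0.6, a22=0.5):
    """Unidirectional VAR(2): channel 0 resonates near f0 and drives 1."""
    th = 2 * np.pi * f0 / fs
    A = np.zeros((2, 2, 2))
    A[0, 0, 0] = 2 * r * np.cos(th)
    A[1, 0, 0] = -r * r
    A[0, 1, 0] = a21
    A[0, 1, 1] = a22
    return VARSpec(2, A, np.eye(2), n_samples=50_000, seed=1)


class TestFitVar:
    def test_recovers_known_var2(self):
        spec = resonant_var2()
        x = generate_var_process(spec).samples.T[:10_000]
        cfg = CausalityConfig(window_s=40.0, max_order=8,
                              order_criterion="bic")
        model = fit_var(x, cfg, 200.0)
        assert model.order == 2
        # coefficient error within 3 SE (SE ~ 1/sqrt(n) for unit-variance VAR)
        se = 3.0 / np.sqrt(len(x))
        assert np.all(np.abs(model.coeffs - spec.coefficient_matrices) < 10 * se)

    def test_matches_statsmodels_var(self):
        # independent reference estimator on the same data
        from statsmodels.tsa.api import VAR as SmVAR

        x = generate_var_process(resonant_var2()).samples.T[:5000]
        cfg = CausalityConfig(window_s=25.0, max_order=4, order_criterion="bic")
        model = fit_var(x, cfg, 200.0)
        sm_fit = SmVAR(x).fit(maxlags=model.order, trend="c")
        sm_coeffs = sm_fit.coefs  # (order, 2, 2)
        assert np.allclose(model.coeffs, sm_coeffs, atol=1e-6)

    def test_white_noise_small_order(self):
        rng = np.random.default_rng(0)
        cfg = CausalityConfig(window_s=4.0, max_order=8, order_criterion="bic")
        model = fit_var(rng.standard_normal((1000, 2)), cfg, 250.0)
        assert model.order <= 2

    def test_constant_segment_unfit(self):
        cfg = CausalityConfig(window_s=4.0, max_order=4)
        assert fit_var(np.ones((1000, 2)), cfg, 250.0) is None

    def test_window_too_short_rejected(self):
        cfg = CausalityConfig(window_s=0.1, max_order=20)
        with pytest.raises(ValueError, match="too short"):
            fit_var(np.random.default_rng(0).standard_normal((25, 2)), cfg, 250.0)


class TestGewekeSpectra:
    def test_structural_zero_direction(self):
        spec = resonant_var2()
        freqs = np.linspace(0.5, 50, 64)
        gc_xy, gc_yx = true_spectral_gc(spec, freqs, 200.0)
        assert np.all(gc_yx == 0.0)
        assert gc_xy.max() > 0.1

    def test_symmetric_model_identical_spectra(self):
        A = np.zeros((1, 2, 2))
        A[0] = [[0.4, 0.3], [0.3, 0.4]]
        spec = VARSpec(1, A, np.eye(2))
        gc_xy, gc_yx = true_spectral_gc(spec, np.linspace(1, 80, 32), 200.0)
        assert np.allclose(gc_xy, gc_yx)

    def test_resonance_peak_location(self):
        # pole of the driving channel fixes the causality peak
        spec = resonant_var2(r=0.95, f0=7.0)
        freqs = np.linspace(1, 30, 400)
        gc_xy, _ = true_spectral_gc(spec, freqs, 200.0)
        # pole angle of the AR(2) factor
        pole_f = 200.0 * np.angle(np.roots([1, -spec.coefficient_matrices[0, 0, 0],
                                            -spec.coefficient_matrices[1, 0, 0]])[0]
                                  ) / (2 * np.pi)
        assert abs(freqs[np.argmax(gc_xy)] - abs(pole_f)) < 0.5

    def test_singular_noise_rejected(self):
        with pytest.raises(ValueError, match="positive-definite"):
            geweke_spectral_gc(np.zeros((1, 2, 2)), np.ones((2, 2)),
                               np.array([1.0]), 100.0)

    def test_geweke_identity(self):
        # mean spectral GC over [0, Nyquist] ~ time-domain GC
        x = generate_var_process(resonant_var2()).samples.T
        cfg = CausalityConfig(window_s=250.0, max_order=6, order_criterion="bic")
        model = fit_var(x, cfg, 200.0)
        freqs = np.linspace(0, 100, 2049)[1:]
        s_xy, s_yx = spectral_granger(model, freqs, 200.0)
        td, _ = time_domain_gc(x, model.order)
        assert s_xy.mean() == pytest.approx(td[0], rel=0.05)

    def test_scaling_and_offset_invariance(self):
        x = generate_var_process(resonant_var2()).samples.T[:5000]
        cfg = CausalityConfig(window_s=25.0, max_order=4)
        freqs = np.linspace(1, 50, 32)
        g1 = spectral_granger(fit_var(x, cfg, 200.0), freqs, 200.0)
        x2 = x * np.array([10.0, 0.3]) + np.array([5.0, -2.0])
        g2 = spectral_granger(fit_var(x2, cfg, 200.0), freqs, 200.0)
        assert np.allclose(g1[0], g2[0], atol=1e-8)
        assert np.allclose(g1[1], g2[1], atol=1e-8)


class TestClassifyWindow:
    def test_permutation_and_asymptotic_agree_on_strong_coupling(self):
        x = generate_var_process(resonant_var2(a21=0.8)).samples.T[:1000]
        for method in ("asymptotic", "permutation"):
            cfg = CausalityConfig(window_s=5.0, max_order=6, null_method=method,
                                  n_permutations=100, seed=0)
            w = classify_window(x, 0.0, cfg, 200.0)
            assert w.label in ("AtoB", "both")
            assert w.peak_freq_ab is not None

    def test_unfit_label_for_degenerate_window(self):
        cfg = CausalityConfig(window_s=4.0, max_order=4)
        w = classify_window(np.ones((1000, 2)), 0.0, cfg, 250.0)
        assert w.label == "unfit"
        assert w.peak_freq_ab is None


class TestRatioTable:
    def make_windows(self, labels, t0=0.0, dt=1.0):
        from thetanest.causality import CausalityWindow

        return [
            CausalityWindow(t0 + i * dt, t0 + (i + 1) * dt, None, None, None,
                            None, None, None, None, lab, 2, True)
            for i, lab in enumerate(labels)
        ]

    def annotation(self):
        return SessionAnnotation([
            Interval(0.0, 4.0, "corridor", "c1"),
            Interval(0.0, 2.0, "sector", "s1"),
            Interval(2.0, 4.0, "sector", "s2"),
            Interval(0.0, 3.0, "movement", "moving"),
        ])

    def test_proportions_and_transform(self):
        wins = self.make_windows(["AtoB", "none", "both", "BtoA"])
        table = causality_ratio_by_context(wins, self.annotation())
        r = table[(table.sector == "s1") & (table.direction == "AtoB")].iloc[0]
        assert r.proportion == pytest.approx(0.5)  # AtoB out of {AtoB, none}
        assert r.transformed == pytest.approx(np.arcsin(np.sqrt(0.5)))
        r2 = table[(table.sector == "s2") & (table.direction == "BtoA")].iloc[0]
        assert r2.proportion == pytest.approx(1.0)  # both + BtoA

    def test_both_exclusive_counting(self):
        wins = self.make_windows(["both", "none"])
        t = causality_ratio_by_context(wins, self.annotation(),
                                       both_counts_each=False)
        assert t[t.direction == "AtoB"].proportion.iloc[0] == pytest.approx(0.0)

    def test_unfit_and_movement_filter(self):
        wins = self.make_windows(["AtoB", "unfit", "AtoB", "AtoB"])
        t = causality_ratio_by_context(wins, self.annotation(),
                                       movement_only=True)
        # window 3 (midpoint 3.5 s) outside movement; window 1 unfit
        n = t[t.sector == "s1"].n_windows.iloc[0]
        assert n == 1
        assert "s2" in set(t.sector)
        assert t[t.sector == "s2"].n_windows.iloc[0] == 1

    def test_empty_context_absent_not_zero(self):
        wins = self.make_windows(["AtoB"])  # only s1 covered
        t = causality_ratio_by_context(wins, self.annotation())
        assert set(t.sector) == {"s1"}


class TestArcsinSqrt:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0, 0.0), (0.25, np.pi / 6), (1.0, np.pi / 2)],
    )
    def test_closed_form(self, p, expected):
        assert arcsin_sqrt(p) == pytest.approx(expected, abs=1e-12)


class TestCompareRatios:
    def test_null_data_no_significance(self):
        rows = []
        for s in range(4):
            for c in ("c1", "c2"):
                for sec in ("s1", "s2", "s3", "s4"):
                    rows.append((f"subj{s}", c, sec, "AtoB", 10, 0.3,
                                 float(np.arcsin(np.sqrt(0.3)))))
        table = pd.DataFrame(rows, columns=[
            "subject", "corridor", "sector", "direction", "n_windows",
            "proportion", "transformed"])
        report = compare_ratios(table)
        assert not report.contrasts.significant.any()

    def test_detects_injected_sector_shift(self):
        table = simulate_proportion_table(n_subjects=8, shift=0.2, seed=3)
        report = compare_ratios(table)
        row = report.contrasts[report.contrasts.pair == "s2-s3"].iloc[0]
        assert row.significant
        assert report.p_omnibus < 0.05

    def test_report_exposes_sector_transitions(self):
        table = simulate_proportion_table(seed=0)
        report = compare_ratios(table)
        assert "s2-s3" in set(report.contrasts.pair)
        assert report.df_num == 3

    def test_needs_two_subjects(self):
        table = simulate_proportion_table(n_subjects=1, seed=0)
        with pytest.raises(ValueError, match="two subjects"):
            compare_ratios(table)
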