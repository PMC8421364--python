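"""Shared fixtures: synthetic sessions and derived analysis products.

The expensive full-length session (160 s) and its decomposition are built
once per test session and shared; smaller fixtures are cheap and local.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from thetanest import (
    SynthConfig,
    generate_theta_gamma_lfp,
    preprocess,
)
from thetanest.decomposition import band_partition, detect_theta_cycles, emd
from thetanest.synthetic import cycle_family_membership
from thetanest.tsc import cycle_signatures, default_tsc_grid

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def default_session():
    """Preprocessed 160-s synthetic session with ground truth (seed 5)."""
    cfg = SynthConfig(duration_s=160.0, seed=5)
    rec, annotation, truth = generate_theta_gamma_lfp(cfg)
    rec = preprocess(rec, 1000.0)
    return rec, annotation, truth, cfg


@pytest.fixture(scope="session")
def decomposed_session(default_session):
    """EMD decomposition, cycles and spectral signatures of channel A."""
    rec, annotation, truth, cfg = default_session
    x = rec.samples[0]
    decomp = band_partition(emd(x, rec.fs))
    cycles = detect_theta_cycles(decomp.theta, rec.fs)
    grid = default_tsc_grid()
    signatures, kept = cycle_signatures(decomp.supra, cycles, rec.fs, grid)
    membership = cycle_family_membership(truth, kept, rec.fs, 5)
    return {
        "rec": rec,
        "annotation": annotation,
        "truth": truth,
        "decomp": decomp,
        "cycles": kept,
        "signatures": signatures,
        "grid": grid,
        "membership": membership,
    }


def empirical_family_templates(
    signatures: np.ndarray, membership: np.ndarray
) -> np.ndarray:
    """Measurement-space family templates from ground-truth membership.

    Mean signature of cycles expressing exactly one family, relative to
    the mean signature of burst-free cycles.
    """
    n_fam = membership.shape[1]
    baseline = signatures[membership.sum(axis=1) == 0].mean(axis=0)
    out = np.empty((n_fam, signatures.shape[1]))
    for k in range(n_fam):
        pure = membership[:, k] & (membership.sum(axis=1) == 1)
        out[k] = signatures[pure].mean(axis=0) - baseline
    return out


def match_components(
    components: np.ndarray, templates: np.ndarray
) -> tuple[np.ndarray, dict[int, int]]:
    """Optimal 1-1 matching of components to templates by |correlation|.

    Returns per-template matched |r| and the template -> component map.
    """
    k_c, k_t = components.shape[0], templates.shape[0]
    C = np.corrcoef(np.vstack([components, templates]))[:k_c, k_c:]
    rows, cols = linear_sum_assignment(-np.abs(C))
    corr = np.empty(k_t)
    mapping: dict[int, int] = {}
    for r, c in zip(rows, cols):
        corr[c] = abs(C[r, c])
        mapping[c] = r
    return corr, mapping
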