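"""Context-wise tSC strength profiles, clustering and bootstrap support.

For every behavioural context (area x corridor x sector; 2 x 4 x 4 = 32 by
default) the grand-average strength of each tSC over that context's theta
cycles gives a 5-vector; the stacked matrix (contexts as rows) is
max-normalized per context and clustered hierarchically on Euclidean
distance.  The cophenetic correlation measures how faithfully the tree
represents the original dissimilarities, and a cycle-resampling bootstrap
scores how often a given pair of contexts are each other's first merge
partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage, leaves_list
from scipy.spatial.distance import pdist

from .decomposition import ThetaCycle
from .recording import SessionAnnotation

__all__ = [
    "ContextProfile",
    "ClusterResult",
    "BootstrapSupport",
    "context_strength_matrix",
    "profile_distance",
    "cluster_profiles",
    "bootstrap_cluster_support",
]

LOW_SUPPORT_CYCLES = 10


@dataclass
class ContextProfile:
    """Per-context grand-average tSC strengths, one row per context."""

    matrix: np.ndarray  # (n_contexts, n_components)
    context_labels: list[str]
    n_cycles: np.ndarray  # cycles contributing to each row
    normalization: str = "max"
    low_support: np.ndarray | None = None  # rows with < LOW_SUPPORT_CYCLES


@dataclass
class ClusterResult:
    """Hierarchical clustering of context profiles."""

    linkage_tree: np.ndarray  # scipy linkage matrix
    cophenetic_correlation: float
    leaf_order: np.ndarray
    pairwise_distances: np.ndarray  # condensed
    labels: list[str]
    method: str

    def cut(self, n_clusters: int) -> np.ndarray:
        return fcluster(self.linkage_tree, n_clusters, criterion="maxclust")


@dataclass
class BootstrapSupport:
    """Fraction of bootstrap trees in which a context pair merges first."""

    pair: tuple[str, str]
    n_iter: int
    support: float
    seed: int
    n_redraws: int = 0


def _normalize_rows(matrix: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "max":
        scale = matrix.max(axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        return matrix / scale
    if normalization == "zscore":
        mu = matrix.mean(axis=1, keepdims=True)
        sd = matrix.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (matrix - mu) / sd
    if normalization == "none":
        return matrix.copy()
    raise ValueError(f"unknown normalization {normalization!r}")


def assign_cycle_contexts(
    cycles: Sequence[ThetaCycle],
    annotation: SessionAnnotation,
    fs: float,
    t0: float = 0.0,
    movement_only: bool = False,
) -> list[str | None]:
    """Context label (e.g. ``'c3s3'``) per cycle by its trough timestamp."""
    out: list[str | None] = []
    for cyc in cycles:
        t = t0 + cyc.trough_idx / fs
        if movement_only and not annotation.in_movement(t):
            out.append(None)
            continue
        out.append(annotation.context_at(t))
    return out


def context_strength_matrix(
    strengths: np.ndarray,
    contexts: Sequence[str | None],
    area: str | None = None,
    normalization: str = "max",
    context_order: Sequence[str] | None = None,
) -> ContextProfile:
    """Grand-average tSC strength per context.

    ``strengths`` is the (n_cycles x n_components) strength matrix and
    ``contexts`` the per-cycle context labels (None = unassigned, skipped).
    Contexts with zero cycles are absent from the result (their rows are
    not zero-filled); rows built from fewer than 10 cycles are flagged
    low-support.  When ``area`` is given it prefixes the row labels
    (``'P-c3s3'`` style), so profiles from the two recording sites can be
    stacked into the full 32-row matrix.
    """
    strengths = np.asarray(strengths, dtype=float)
    if strengths.shape[0] != len(contexts):
        raise ValueError("one context label per cycle required")
    groups: dict[str, list[int]] = {}
    for i, ctx in enumerate(contexts):
        if ctx is not None:
            groups.setdefault(ctx, []).append(i)
    labels = list(context_order) if context_order is not None else sorted(groups)
    rows, counts, kept = [], [], []
    for ctx in labels:
        idx = groups.get(ctx, [])
        if not idx:
            continue
        rows.append(strengths[idx].mean(axis=0))
        counts.append(len(idx))
        kept.append(f"{area}-{ctx}" if area else ctx)
    if not rows:
        raise ValueError("no cycle could be assigned to any context")
    matrix = _normalize_rows(np.vstack(rows), normalization)
    counts_arr = np.asarray(counts)
    return ContextProfile(
        matrix=matrix,
        context_labels=kept,
        n_cycles=counts_arr,
        normalization=normalization,
        low_support=counts_arr < LOW_SUPPORT_CYCLES,
    )


def stack_profiles(profiles: Sequence[ContextProfile]) -> ContextProfile:
    """Stack per-area profiles into one matrix (e.g. the 32-context view)."""
    if not profiles:
        raise ValueError("nothing to stack")
    return ContextProfile(
        matrix=np.vstack([p.matrix for p in profiles]),
        context_labels=sum((p.context_labels for p in profiles), []),
        n_cycles=np.concatenate([p.n_cycles for p in profiles]),
        normalization=profiles[0].normalization,
        low_support=np.concatenate(
            [np.zeros(len(p.context_labels), bool) if p.low_support is None
             else p.low_support for p in profiles]
        ),
    )


def profile_distance(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Euclidean distance between two (normalized) context rows."""
    a, b = np.asarray(row_a, float), np.asarray(row_b, float)
    if a.shape != b.shape:
        raise ValueError("rows must have equal length")
    return float(np.linalg.norm(a - b))


def cluster_profiles(profile: ContextProfile, method: str = "average") -> ClusterResult:
    """Agglomerative clustering of context rows on Euclidean distance.

    Average linkage (UPGMA) by default; single/complete/ward accepted.
    Reports the cophenetic correlation between original and tree-implied
    distances.  Deterministic given the input.
    """
    X = profile.matrix
    if X.shape[0] < 3:
        raise ValueError("clustering needs at least three contexts")
    if not np.all(np.isfinite(X)):
        raise ValueError("profile matrix contains non-finite rows")
    dist = pdist(X, metric="euclidean")
    Z = linkage(dist, method=method)
    if np.allclose(dist, 0):
        coph_corr = 1.0  # degenerate: all rows identical
    else:
        coph_corr, _ = cophenet(Z, dist)
    return ClusterResult(
        linkage_tree=Z,
        cophenetic_correlation=float(coph_corr),
        leaf_order=leaves_list(Z),
        pairwise_distances=dist,
        labels=list(profile.context_labels),
        method=method,
    )


def first_merge_partners(result: ClusterResult, a: str, b: str) -> bool:
    """True iff leaves ``a`` and ``b`` merge before either joins any other
    leaf (i.e. the two singletons are joined directly)."""
    ia, ib = result.labels.index(a), result.labels.index(b)
    for left, right, _, _ in result.linkage_tree:
        left, right = int(left), int(right)
        if {left, right} == {ia, ib}:
            return True
        if left in (ia, ib) or right in (ia, ib):
            return False
    return False


def bootstrap_cluster_support(
    strengths: np.ndarray,
    contexts: Sequence[str | None],
    pair: tuple[str, str],
    n_iter: int = 1000,
    seed: int = 0,
    normalization: str = "max",
    method: str = "average",
    areas: Sequence[str | None] | None = None,
) -> BootstrapSupport:
    """Bootstrap support for a context pair being first merge partners.

    Each iteration resamples cycles with replacement within every context
    (preserving context sizes), rebuilds the normalized profile matrix,
    re-clusters it, and scores whether the two contexts of ``pair`` merge
    as singletons.  Iterations in which a context loses all its cycles are
    redrawn (counted; capped at 10x ``n_iter``).  Deterministic under seed.
    """
    if n_iter < 100:
        raise ValueError("bootstrap needs n_iter >= 100")
    strengths = np.asarray(strengths, dtype=float)
    if areas is None:
        areas = [None] * len(contexts)
    keys = [
        (f"{ar}-{ctx}" if ar else ctx) if ctx is not None else None
        for ar, ctx in zip(areas, contexts)
    ]
    groups: dict[str, np.ndarray] = {}
    for i, key in enumerate(keys):
        if key is not None:
            groups.setdefault(key, []).append(i)  # type: ignore[arg-type]
    groups = {k: np.asarray(v) for k, v in groups.items()}
    for name in pair:
        if name not in groups:
            raise ValueError(f"context {name!r} has no cycles")
    labels = sorted(groups)
    rng = np.random.default_rng(seed)
    hits = 0
    redraws = 0
    done = 0
    while done < n_iter:
        rows = []
        ok = True
        for ctx in labels:
            idx = groups[ctx]
            take = rng.integers(0, len(idx), size=len(idx))
            sel = strengths[idx[take]]
            if not len(sel):
                ok = False
                break
            rows.append(sel.mean(axis=0))
        if not ok:
            redraws += 1
            if redraws > 10 * n_iter:
                raise RuntimeError("bootstrap exceeded the redraw budget")
            continue
        matrix = _normalize_rows(np.vstack(rows), normalization)
        prof = ContextProfile(matrix, labels, np.ones(len(labels), int),
                              normalization)
        result = cluster_profiles(prof, method=method)
        hits += first_merge_partners(result, pair[0], pair[1])
        done += 1
    return BootstrapSupport(pair=pair, n_iter=n_iter, support=hits / n_iter,
                            seed=seed, n_redraws=redraws)
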