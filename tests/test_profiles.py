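"""Context strength profiles, clustering, bootstrap support."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thetanest.profiles import (
    ContextProfile,
    bootstrap_cluster_support,
    cluster_profiles,
    context_strength_matrix,
    first_merge_partners,
    profile_distance,
    stack_profiles,
)


def planted_strengths(mixes: dict, n_per_context=300, noise=0.08, seed=0):
    rng = np.random.default_rng(seed)
    strengths, contexts = [], []
    for name, m in mixes.items():
        for _ in range(n_per_context):
            strengths.append(np.asarray(m) + noise * rng.standard_normal(len(m)))
            contexts.append(name)
    return np.vstack(strengths), contexts


TWO_BLOCK = {
    **{f"a{i}": [1.0, 0.9, 0.1, 0.1, 0.1] for i in range(4)},
    **{f"b{i}": [0.1, 0.1, 0.2, 0.9, 1.0] for i in range(4)},
}

UNIQUE_PAIR = {
    "ctxA": [1.0, 0.9, 0.1, 0.1, 0.1],
    "ctxB": [1.0, 0.9, 0.1, 0.1, 0.1],  # identical to A
    "ctxC": [0.1, 1.0, 0.8, 0.1, 0.1],
    "ctxD": [0.1, 0.1, 1.0, 0.8, 0.1],
    "ctxE": [0.1, 0.1, 0.1, 0.9, 1.0],  # maximally different from A
    "ctxF": [0.9, 0.1, 0.1, 0.1, 1.0],
}


class TestContextStrengthMatrix:
    def test_homogeneous_cycles_identical_rows(self):
        strengths = np.tile([2.0, 1.0, 0.5, 0.2, 0.1], (40, 1))
        contexts = ["c1s1"] * 10 + ["c1s2"] * 10 + ["c2s1"] * 10 + ["c2s2"] * 10
        prof = context_strength_matrix(strengths, contexts)
        assert np.allclose(prof.matrix, prof.matrix[0])
        assert prof.matrix.max() == pytest.approx(1.0)  # max-normalized

    def test_zero_cycle_context_absent(self):
        strengths = np.ones((5, 3))
        contexts = ["c1s1"] * 5
        prof = context_strength_matrix(strengths, contexts,
                                       context_order=["c1s1", "c1s2"])
        assert prof.context_labels == ["c1s1"]

    def test_low_support_flag(self):
        strengths = np.ones((12, 2))
        contexts = ["a"] * 9 + ["b"] * 3
        prof = context_strength_matrix(strengths, contexts)
        assert prof.low_support.tolist() == [True, True]

    def test_argmax_matches_dominant_mix(self):
        strengths, contexts = planted_strengths(
            {f"ctx{i}": np.eye(5)[i % 5] + 0.1 for i in range(10)},
            n_per_context=50)
        prof = context_strength_matrix(strengths, contexts)
        hits = sum(
            int(np.argmax(row) == int(lab[3:]) % 5)
            for lab, row in zip(prof.context_labels, prof.matrix))
        assert hits >= 0.9 * len(prof.context_labels)

    def test_area_prefix_and_stack_to_32(self):
        strengths = np.ones((16, 5))
        contexts = [f"c{c}s{s}" for c in range(1, 5) for s in range(1, 5)]
        p = context_strength_matrix(strengths, contexts, area="P")
        c = context_strength_matrix(strengths, contexts, area="C")
        full = stack_profiles([p, c])
        assert full.matrix.shape == (32, 5)
        assert "P-c3s3" in full.context_labels
        assert "C-c3s3" in full.context_labels


class TestProfileDistance:
    def test_identity_and_closed_form(self):
        assert profile_distance([1, 2, 3], [1, 2, 3]) == 0.0
        assert profile_distance([3, 0, 0, 0, 0], [0, 4, 0, 0, 0]) == 5.0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=5, max_size=5),
           st.lists(st.floats(-5, 5), min_size=5, max_size=5),
           st.lists(st.floats(-5, 5), min_size=5, max_size=5))
    def test_symmetry_and_triangle(self, a, b, c):
        dab = profile_distance(a, b)
        assert dab == profile_distance(b, a)
        assert dab <= profile_distance(a, c) + profile_distance(c, b) + 1e-9


class TestClusterProfiles:
    def test_identical_rows_merge_first_at_zero(self):
        mat = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        prof = ContextProfile(mat, ["a", "b", "c"], np.ones(3, int))
        res = cluster_profiles(prof)
        assert first_merge_partners(res, "a", "b")
        assert res.linkage_tree[0, 2] == 0.0

    def test_planted_two_block_exact_cut(self):
        strengths, contexts = planted_strengths(TWO_BLOCK, seed=1)
        prof = context_strength_matrix(strengths, contexts)
        res = cluster_profiles(prof)
        cut = res.cut(2)
        blocks = {}
        for lab, cl in zip(prof.context_labels, cut):
            blocks.setdefault(lab[0], set()).add(cl)
        assert blocks["a"].isdisjoint(blocks["b"])
        assert len(blocks["a"]) == len(blocks["b"]) == 1
        assert res.cophenetic_correlation > 0.9

    def test_row_order_invariance(self):
        strengths, contexts = planted_strengths(UNIQUE_PAIR, n_per_context=50,
                                                seed=2)
        prof = context_strength_matrix(strengths, contexts)
        res1 = cluster_profiles(prof)
        perm = np.array([3, 1, 4, 0, 5, 2])
        prof2 = ContextProfile(prof.matrix[perm],
                               [prof.context_labels[i] for i in perm],
                               prof.n_cycles[perm])
        res2 = cluster_profiles(prof2)
        # identical tree up to leaf relabeling: same cophenetic distances
        from scipy.cluster.hierarchy import cophenet

        d1 = cophenet(res1.linkage_tree)
        d2 = cophenet(res2.linkage_tree)

        def dist_lookup(res, d):
            labels = res.labels
            n = len(labels)
            out = {}
            k = 0
            for i in range(n):
                for j in range(i + 1, n):
                    out[frozenset((labels[i], labels[j]))] = d[k]
                    k += 1
            return out

        m1, m2 = dist_lookup(res1, d1), dist_lookup(res2, d2)
        for key in m1:
            assert m1[key] == pytest.approx(m2[key], rel=1e-9)

    def test_nan_rows_rejected(self):
        prof = ContextProfile(np.array([[1.0, np.nan], [0, 1], [1, 0]]),
                              ["a", "b", "c"], np.ones(3, int))
        with pytest.raises(ValueError, match="non-finite"):
            cluster_profiles(prof)

    def test_too_few_contexts_rejected(self):
        prof = ContextProfile(np.ones((2, 3)), ["a", "b"], np.ones(2, int))
        with pytest.raises(ValueError, match="three"):
            cluster_profiles(prof)


class TestBootstrapSupport:
    def test_same_mix_pair_high_support(self):
        strengths, contexts = planted_strengths(UNIQUE_PAIR, seed=3)
        bs = bootstrap_cluster_support(strengths, contexts, ("ctxA", "ctxB"),
                                       n_iter=300, seed=0)
        assert bs.support >= 0.95

    def test_maximally_different_pair_low_support(self):
        strengths, contexts = planted_strengths(UNIQUE_PAIR, seed=3)
        bs = bootstrap_cluster_support(strengths, contexts, ("ctxA", "ctxE"),
                                       n_iter=300, seed=0)
        assert bs.support <= 0.05

    def test_duplicated_context_support_one(self):
        # a context "paired with itself": duplicate its cycles under a new label
        mixes = dict(UNIQUE_PAIR)
        strengths, contexts = planted_strengths(
            {k: v for k, v in mixes.items() if k != "ctxB"}, seed=4)
        dup_idx = [i for i, c in enumerate(contexts) if c == "ctxA"]
        strengths = np.vstack([strengths, strengths[dup_idx]])
        contexts = contexts + ["ctxA2"] * len(dup_idx)
        bs = bootstrap_cluster_support(strengths, contexts, ("ctxA", "ctxA2"),
                                       n_iter=300, seed=0)
        assert bs.support == pytest.approx(1.0)

    def test_seed_determinism_and_validation(self):
        strengths, contexts = planted_strengths(UNIQUE_PAIR, n_per_context=30,
                                                seed=5)
        a = bootstrap_cluster_support(strengths, contexts, ("ctxA", "ctxB"),
                                      n_iter=100, seed=9)
        b = bootstrap_cluster_support(strengths, contexts, ("ctxA", "ctxB"),
                                      n_iter=100, seed=9)
        assert a.support == b.support
        with pytest.raises(ValueError, match="n_iter"):
            bootstrap_cluster_support(strengths, contexts, ("ctxA", "ctxB"),
                                      n_iter=10, seed=0)
        with pytest.raises(ValueError, match="no cycles"):
            bootstrap_cluster_support(strengths, contexts, ("ctxA", "nope"),
                                      n_iter=100, seed=0)
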