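import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarcosig import (
    GeneSignature,
    annotate_clusters,
    cluster_samples,
    dendrogram_text,
    hypergeometric_enrichment,
    intersection_test,
    top_fraction,
)


def hypergeom_tail_enumeration(k, K, n, N):
    """Exhaustive-enumeration oracle for P(X >= k): iterate all C(N, n) draws
    from a universe whose first K items are successes."""
    hits = 0
    for draw in itertools.combinations(range(N), n):
        if sum(1 for i in draw if i < K) >= k:
            hits += 1
    return hits / comb(N, n)


def naive_agglomerate(points, method="complete"):
    """O(n^3) agglomerative clustering oracle.

    Returns the merge history as (merged_leaf_sets, height) pairs, using
    max (complete) inter-cluster euclidean distance.
    """
    clusters = [{i} for i in range(len(points))]
    history = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = max(
                    float(np.linalg.norm(points[a] - points[b]))
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
        history.append((frozenset(merged), dist))
    return history


def linkage_history(Z, n):
    """Convert a scipy linkage matrix to (merged_leaf_sets, height) pairs."""
    members = {i: frozenset([i]) for i in range(n)}
    history = []
    for step, (left, right, height, _) in enumerate(Z):
        merged = members[int(left)] | members[int(right)]
        members[n + step] = merged
        history.append((merged, float(height)))
    return history


class TestTopFraction:
    def _table(self, scores):
        s = pd.Series(scores)
        from sarcosig import rank_scores

        return pd.DataFrame({"score": s, "rank": rank_scores(s)})

    def test_exact_division(self, rng):
        scores = pd.Series(rng.standard_normal(8),
                           index=[f"s{i}" for i in range(8)])
        assert len(top_fraction(scores, 0.25)) == 2

    def test_ceiling_rule_134(self, rng):
        scores = pd.Series(rng.standard_normal(134),
                           index=[f"s{i:03d}" for i in range(134)])
        assert len(top_fraction(scores, 0.25)) == 34

    def test_floor_method(self, rng):
        scores = pd.Series(rng.standard_normal(134),
                           index=[f"s{i:03d}" for i in range(134)])
        assert len(top_fraction(scores, 0.25, method="floor")) == 33

    def test_tie_broken_lexicographically(self):
        scores = pd.Series({"d": 5.0, "b": 4.0, "a": 4.0, "c": 1.0})
        assert top_fraction(scores, 0.5) == {"d", "a"}

    def test_accepts_score_table(self):
        table = self._table({"d": 5.0, "b": 4.0, "a": 4.0, "c": 1.0})
        assert top_fraction(table, 0.5) == {"d", "a"}

    def test_monotone_in_fraction(self, rng):
        scores = pd.Series(rng.standard_normal(23),
                           index=[f"s{i}" for i in range(23)])
        previous = set()
        for fraction in (0.1, 0.25, 0.5, 0.75, 1.0):
            current = top_fraction(scores, fraction)
            assert previous <= current
            previous = current
        assert previous == set(scores.index)

    def test_idempotent_on_selection(self, rng):
        scores = pd.Series(rng.standard_normal(12),
                           index=[f"s{i}" for i in range(12)])
        top = top_fraction(scores, 0.5)
        assert top_fraction(scores[sorted(top)], 1.0) == top

    def test_bad_fraction(self, rng):
        scores = pd.Series([1.0], index=["s"])
        for fraction in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                top_fraction(scores, fraction)

    def test_empty_table(self):
        with pytest.raises(ValueError, match="empty"):
            top_fraction(pd.Series(dtype=float), 0.25)


class TestHypergeometricEnrichment:
    def test_zero_successes_certain(self):
        assert hypergeometric_enrichment(0, 4, 5, 10).pvalue == 1.0

    def test_degenerate_universe(self):
        assert hypergeometric_enrichment(5, 10, 5, 10).pvalue == pytest.approx(1.0)

    def test_worked_example(self):
        # N=10, K=4, n=5, k=3: tail = (C(4,3)C(6,2) + C(4,4)C(6,1)) / C(10,5)
        res = hypergeometric_enrichment(3, 4, 5, 10)
        assert res.pvalue == pytest.approx(66 / 252, abs=1e-12)
        assert res.pvalue == pytest.approx(
            hypergeom_tail_enumeration(3, 4, 5, 10), abs=1e-12
        )

    def test_bound_violations(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(5, 4, 5, 10)  # k > K
        with pytest.raises(ValueError):
            hypergeometric_enrichment(1, 4, 11, 10)  # n > N
        with pytest.raises(ValueError):
            hypergeometric_enrichment(1, 11, 5, 10)  # K > N
        with pytest.raises(ValueError):
            hypergeometric_enrichment(-1, 4, 5, 10)

    def test_tail_non_increasing_in_k(self):
        for K, n, N in [(4, 5, 10), (6, 6, 12), (3, 7, 11)]:
            tail = [hypergeometric_enrichment(k, K, n, N).pvalue
                    for k in range(min(K, n) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(tail, tail[1:]))

    def test_stable_at_large_n(self):
        res = hypergeometric_enrichment(90, 200, 100, 800)
        assert 0 < res.pvalue < 1e-40

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_matches_enumeration(self, data):
        N = data.draw(st.integers(min_value=1, max_value=9))
        K = data.draw(st.integers(min_value=0, max_value=N))
        n = data.draw(st.integers(min_value=0, max_value=N))
        k = data.draw(st.integers(min_value=0, max_value=min(K, n)))
        expected = hypergeom_tail_enumeration(k, K, n, N)
        assert hypergeometric_enrichment(k, K, n, N).pvalue == pytest.approx(
            expected, abs=1e-12
        )


class TestIntersectionTest:
    def test_zero_overlap(self):
        universe = {f"s{i}" for i in range(20)}
        a, b = {"s0", "s1"}, {"s5", "s6"}
        assert intersection_test(a, b, universe).pvalue == 1.0

    def test_full_overlap_of_full_sets(self):
        universe = {f"s{i}" for i in range(6)}
        res = intersection_test(universe, universe, universe)
        assert res.pvalue == pytest.approx(1.0)

    def test_symmetric_and_matches_enumeration(self, rng):
        universe = [f"s{i}" for i in range(12)]
        a = set(rng.choice(universe, size=5, replace=False))
        b = set(rng.choice(universe, size=4, replace=False))
        res_ab = intersection_test(a, b, universe)
        res_ba = intersection_test(b, a, universe)
        assert res_ab.pvalue == pytest.approx(res_ba.pvalue, abs=1e-12)
        expected = hypergeom_tail_enumeration(len(a & b), len(a), len(b), 12)
        assert res_ab.pvalue == pytest.approx(expected, abs=1e-12)

    def test_set_outside_universe(self):
        with pytest.raises(ValueError, match="universe"):
            intersection_test({"x"}, {"s0"}, {"s0", "s1"})


@pytest.fixture
def clusterable(rng):
    """12 samples in two well-separated blobs over 6 signature genes."""
    genes = [f"G{i:03d}" for i in range(6)]
    blob1 = rng.standard_normal((6, 6)) * 0.05
    blob2 = rng.standard_normal((6, 6)) * 0.05 + 10.0
    x = pd.DataFrame(np.hstack([blob1, blob2]), index=genes,
                     columns=[f"s{i:02d}" for i in range(12)])
    sig = GeneSignature("all", {g: 1 for g in genes})
    return x, sig


class TestClusterSamples:
    def test_k_equals_n_singletons(self, clusterable):
        x, sig = clusterable
        ca = cluster_samples(x, sig, k=x.shape[1])
        assert len(set(ca.labels)) == x.shape[1]

    def test_separated_blobs(self, clusterable):
        x, sig = clusterable
        ca = cluster_samples(x, sig, k=2, standardize=False)
        first = set(ca.labels.iloc[:6])
        second = set(ca.labels.iloc[6:])
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_matches_naive_oracle(self, rng):
        for _ in range(5):
            x = pd.DataFrame(rng.standard_normal((5, 6)),
                             index=[f"G{i}" for i in range(5)],
                             columns=[f"s{i}" for i in range(6)])
            sig = GeneSignature("all", {g: 1 for g in x.index})
            ca = cluster_samples(x, sig, k=2, standardize=False)
            points = [x.iloc[:, j].to_numpy() for j in range(6)]
            expected = naive_agglomerate(points)
            got = linkage_history(ca.linkage, 6)
            for (set_e, h_e), (set_g, h_g) in zip(expected, got):
                assert set_e == set_g
                assert h_g == pytest.approx(h_e, abs=1e-8)

    def test_column_order_invariant(self, rng):
        x = pd.DataFrame(rng.standard_normal((6, 8)),
                         index=[f"G{i}" for i in range(6)],
                         columns=[f"s{i}" for i in range(8)])
        sig = GeneSignature("all", {g: 1 for g in x.index})
        ca1 = cluster_samples(x, sig, k=3)
        shuffled = x[list(rng.permutation(x.columns))]
        ca2 = cluster_samples(shuffled, sig, k=3)
        part1 = {frozenset(m) for m in ca1.clusters.values()}
        part2 = {frozenset(m) for m in ca2.clusters.values()}
        assert part1 == part2

    def test_k_too_large(self, clusterable):
        x, sig = clusterable
        with pytest.raises(ValueError, match="k="):
            cluster_samples(x, sig, k=x.shape[1] + 1)

    def test_no_usable_genes(self, clusterable):
        x, _ = clusterable
        sig = GeneSignature("off", {"ZZZ": 1})
        with pytest.raises(ValueError, match="no usable"):
            cluster_samples(x, sig, k=2)

    def test_dendrogram_text(self, clusterable):
        x, sig = clusterable
        ca = cluster_samples(x, sig, k=2)
        text = dendrogram_text(ca.linkage, x.columns)
        assert text.endswith(";")
        for sample in x.columns:
            assert sample in text


class TestAnnotateClusters:
    def test_single_cluster_all_p_one(self, clusterable):
        x, sig = clusterable
        ca = cluster_samples(x, sig, k=1)
        ann = pd.Series(["A"] * 6 + ["B"] * 6, index=x.columns)
        table = annotate_clusters(ca, ann)
        assert np.allclose(table["pvalue"], 1.0)

    def test_pure_cluster_tail(self, clusterable):
        # 5 MUSCLE among N=20 with K=5: pure cluster of 5 has p = 1/C(20,5)
        x, sig = clusterable
        genes = x.index
        rng = np.random.default_rng(0)
        wide = pd.DataFrame(rng.standard_normal((6, 20)), index=genes,
                            columns=[f"s{i:02d}" for i in range(20)])
        wide.iloc[:, :5] += 50.0  # tight, distant blob
        sig_all = GeneSignature("all", {g: 1 for g in genes})
        ca = cluster_samples(wide, sig_all, k=2, standardize=False)
        ann = pd.Series(["MUSCLE"] * 5 + ["RMS"] * 15, index=wide.columns)
        table = annotate_clusters(ca, ann)
        muscle_cluster = ca.labels.iloc[0]
        row = table[(table["cluster"] == muscle_cluster)
                    & (table["label"] == "MUSCLE")].iloc[0]
        assert row["k"] == 5 and row["n"] == 5
        assert row["pvalue"] == pytest.approx(1 / comb(20, 5), rel=1e-9)
        assert row["dominant"]

    def test_absent_label_p_one(self, clusterable):
        x, sig = clusterable
        ca = cluster_samples(x, sig, k=2, standardize=False)
        ann = pd.Series(["A"] * 6 + ["B"] * 6, index=x.columns)
        table = annotate_clusters(ca, ann)
        zero_rows = table[table["k"] == 0]
        assert not zero_rows.empty
        assert np.allclose(zero_rows["pvalue"], 1.0)

    def test_unannotated_sample_rejected(self, clusterable):
        x, sig = clusterable
        ca = cluster_samples(x, sig, k=2)
        ann = pd.Series(["A"] * 11, index=x.columns[:11])
        with pytest.raises(ValueError, match="unannotated"):
            annotate_clusters(ca, ann)


class TestParameterRecovery:
    def test_enrichment_p_decreases_with_planted_delta(self):
        """Median top-quartile enrichment p drops as the planted shift grows."""
        from statistics import median

        from sarcosig import CohortConfig, signature_score, simulate_expression

        genes = [f"G{i + 1:04d}" for i in range(20)]
        sig = GeneSignature("up20", {g: 1 for g in genes})

        def pvalue(seed, delta):
            config = CohortConfig(
                n_genes=20, subtypes=[("PLANTED", 40), ("NULL", 40)],
                noise_sd=1.0, planted_effects=[("up20", "PLANTED", delta)],
                seed=seed,
            )
            matrix, annotation, _ = simulate_expression(config, [sig])
            scores = signature_score(matrix, sig)
            top = top_fraction(scores, 0.25)
            planted = set(annotation[annotation == "PLANTED"].index)
            return hypergeometric_enrichment(
                len(top & planted), len(planted), len(top), len(scores)
            ).pvalue

        medians = [
            median(pvalue(1000 * d + r, d * 0.25) for r in range(15))
            for d in range(3)  # deltas 0, 0.25, 0.5
        ]
        assert medians[0] > medians[1] > medians[2]
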