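import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rxbench import (
    Fingerprint,
    IndicationFeatures,
    IndicationMapping,
    IndicationResult,
    InsufficientDataError,
    InvalidInputError,
    InteractionMatrix,
    benchmark_mapping,
    build_similarity_lists,
    chem_similarity_features,
    compare_mappings,
    compute_indication_features,
    correlate_performance,
    spearman,
    tanimoto,
)


def _rank_then_pearson(x, y):
    """Independent oracle: average-rank both sequences, then Pearson."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2  # average of 1-based positions
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_increasing(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [v**3 for v in x]) == pytest.approx(1.0)

    def test_reversed(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, list(reversed(x))) == pytest.approx(-1.0)

    def test_tie_hand_value(self):
        # ranks (1,2,3,4) vs (1.5,1.5,3,4): Pearson = 4.5/sqrt(5*4.5)
        expected = 4.5 / np.sqrt(5 * 4.5)
        assert spearman([1, 2, 3, 4], [1, 1, 3, 4]) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(0.9486, abs=1e-4)

    def test_constant_rejected(self):
        with pytest.raises(InsufficientDataError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            spearman([1, 2], [1, 2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            spearman([1, 2, 3], [1, 2])

    @given(
        st.lists(st.integers(0, 20), min_size=3, max_size=40),
        st.integers(0, 2**32 - 1),
    )
    def test_agrees_with_rank_pearson_oracle(self, xs, seed):
        rng = np.random.default_rng(seed)
        ys = rng.integers(0, 20, size=len(xs)).tolist()
        if len(set(xs)) < 2 or len(set(ys)) < 2:
            return
        assert spearman(xs, ys) == pytest.approx(
            _rank_then_pearson(xs, ys), abs=1e-12
        )


class TestChemSimilarityFeatures:
    def test_two_drugs_all_equal_single_tanimoto(self):
        a = Fingerprint({1, 2, 3}, 64)
        b = Fingerprint({2, 3, 4, 5}, 64)
        t = tanimoto(a, b)
        assert chem_similarity_features([a, b]) == (t, t, t)

    def test_three_identical(self):
        fp = Fingerprint({7, 8}, 64)
        assert chem_similarity_features([fp, fp, fp]) == (1.0, 1.0, 1.0)

    def test_hand_enumerated_triple(self):
        # pairwise Tanimotos: AB = 3/6 = 0.5, AC = 2/10 = 0.2, BC = 1/10 = 0.1
        a = Fingerprint({1, 2, 3, 4, 5}, 64)
        b = Fingerprint({1, 2, 3, 6}, 64)
        c = Fingerprint({4, 5, 6, 7, 8, 9, 10}, 64)
        assert tanimoto(a, b) == pytest.approx(0.5)
        assert tanimoto(a, c) == pytest.approx(0.2)
        assert tanimoto(b, c) == pytest.approx(0.1)
        max_pair, avg_avg, avg_max = chem_similarity_features([a, b, c])
        assert max_pair == pytest.approx(0.5)
        assert avg_avg == pytest.approx(np.mean([0.35, 0.3, 0.15]))  # 0.26667
        assert avg_max == pytest.approx(np.mean([0.5, 0.5, 0.2]))  # 0.4

    def test_order_invariant(self, rng):
        fps = [
            Fingerprint(frozenset(map(int, rng.choice(64, 8, replace=False))), 64)
            for _ in range(5)
        ]
        base = chem_similarity_features(fps)
        shuffled = [fps[i] for i in rng.permutation(5)]
        assert chem_similarity_features(shuffled) == pytest.approx(base)

    def test_single_drug_rejected(self):
        with pytest.raises(InsufficientDataError):
            chem_similarity_features([Fingerprint({1}, 64)])


def _result(ind, n_drugs, nia, ranks=None):
    return IndicationResult(
        indication_id=ind,
        n_drugs=n_drugs,
        ranks=ranks or {},
        nia=dict(nia),
        nndcg={k: 0.0 for k in nia},
        nndcg_overall=0.0,
        ia={k: 0.0 for k in nia},
    )


def _features(ind, n_drugs, value):
    return IndicationFeatures(
        indication_id=ind,
        n_drugs=n_drugs,
        ia={10: value},
        chem_max_pair=value / 100,
        chem_avg_avg=value / 200,
        chem_avg_max=value / 150,
    )


class TestCorrelatePerformance:
    def test_identity_features_give_perfect_correlation(self):
        results, features = [], []
        for i, v in enumerate([10.0, 30.0, 50.0, 80.0]):
            ind = f"i{i}"
            results.append(_result(ind, n_drugs=2 + i, nia={10: v}))
            features.append(_features(ind, n_drugs=2 + i, value=v))
        table = correlate_performance(results, features)
        row = table.loc["nia_top10"]
        for col in ("n_drugs", "ia", "chem_max_pair", "chem_avg_avg", "chem_avg_max"):
            assert row[col] == pytest.approx(1.0)

    def test_min_drugs_filter(self):
        results, features = [], []
        sizes = [2, 3, 5, 6, 9]
        for i, (size, v) in enumerate(zip(sizes, [5.0, 15.0, 30.0, 60.0, 90.0])):
            ind = f"i{i}"
            results.append(_result(ind, n_drugs=size, nia={10: v}))
            features.append(_features(ind, n_drugs=size, value=v))
        table = correlate_performance(results, features, min_drugs=5)
        assert table.attrs["n_indications"] == 3  # sizes 5, 6, 9 survive

    def test_too_few_after_filter(self):
        results = [_result(f"i{i}", 2, {10: float(i)}) for i in range(3)]
        features = [_features(f"i{i}", 2, float(i)) for i in range(3)]
        with pytest.raises(InsufficientDataError):
            correlate_performance(results, features, min_drugs=3)

    def test_planted_tightness_drives_positive_correlation(self):
        # indications with tighter signature clusters also get tighter
        # fingerprint clusters: nIA should correlate positively with
        # chem_avg_max
        rng = np.random.default_rng(17)
        n_ind, per, n_prot = 6, 4, 30
        n_bg = 20
        n = n_ind * per + n_bg
        ids = [f"c{i:03d}" for i in range(n)]
        scores = rng.random((n, n_prot))
        fps, assoc = {}, []
        for k in range(n_ind):
            noise = 0.02 + 0.12 * k  # looser clusters for later indications
            shared_n = max(2, 20 - 3 * k)  # and less-shared fingerprints
            archetype = rng.random(n_prot)
            shared = frozenset(map(int, rng.choice(512, shared_n, replace=False)))
            for d in range(per):
                i = k * per + d
                scores[i] = np.clip(archetype + rng.normal(0, noise, n_prot), 0, 1)
                own = frozenset(map(int, rng.choice(512, 24 - shared_n, replace=False)))
                fps[ids[i]] = Fingerprint(shared | own, 512)
                assoc.append((ids[i], f"ind{k}"))
        for i in range(n_ind * per, n):
            fps[ids[i]] = Fingerprint(
                frozenset(map(int, rng.choice(512, 24, replace=False))), 512
            )
        matrix = InteractionMatrix(ids, [f"p{j}" for j in range(n_prot)], scores)
        mapping = IndicationMapping(assoc, drug_library=ids)
        lists = build_similarity_lists(matrix)
        summary = benchmark_mapping(mapping, lists, cutoff=6, rank_cutoffs=(10,))
        feats = compute_indication_features(mapping, lists, fps, (10,))
        table = correlate_performance(summary.results, feats)
        assert table.loc["nia_top10", "chem_avg_max"] > 0


class TestCompareMappings:
    def test_identity_comparison(self):
        results = [
            _result("i1", 3, {10: 40.0}, ranks={"d1": 4, "d2": 90, "d3": 7}),
            _result("i2", 2, {10: 0.0}, ranks={"d4": 200, "d5": 35}),
        ]
        cmp = compare_mappings(results, results, [("i1", "i1"), ("i2", "i2")],
                               rank_cutoffs=(10,))
        assert cmp.better_a == cmp.better_b == 0
        assert cmp.equal == 5
        assert cmp.mean_rank_delta == 0.0
        assert (cmp.indication_deltas["nia_top10_delta"] == 0).all()

    def test_worked_rank_improvement_example(self):
        # a drug ranked 44 in mapping A and 7 in mapping B counts toward B,
        # with a signed delta of 37
        ra = [_result("prostate_A", 2, {10: 0.0}, ranks={"enza": 44})]
        rb = [_result("prostate_B", 2, {10: 50.0}, ranks={"enza": 7})]
        cmp = compare_mappings(ra, rb, [("prostate_A", "prostate_B")],
                               rank_cutoffs=(10,))
        assert (cmp.better_a, cmp.better_b, cmp.equal) == (0, 1, 0)
        assert cmp.mean_rank_delta == pytest.approx(37.0)
        assert cmp.topk_counts[10] == (0, 1)  # only B ranks it top-10

    def test_toy_three_way_counts(self):
        ra = [_result("i", 3, {10: 0.0}, ranks={"a": 5, "b": 20, "c": 8})]
        rb = [_result("j", 3, {10: 0.0}, ranks={"a": 9, "b": 3, "c": 8})]
        cmp = compare_mappings(ra, rb, [("i", "j")], rank_cutoffs=(10,))
        assert (cmp.better_a, cmp.better_b, cmp.equal) == (1, 1, 1)

    def test_antisymmetric_under_swap(self):
        ra = [_result("i", 3, {10: 30.0}, ranks={"a": 5, "b": 20, "c": 8})]
        rb = [_result("j", 3, {10: 60.0}, ranks={"a": 9, "b": 3, "c": 1})]
        fwd = compare_mappings(ra, rb, [("i", "j")], rank_cutoffs=(10,))
        rev = compare_mappings(rb, ra, [("j", "i")], rank_cutoffs=(10,))
        assert (fwd.better_a, fwd.better_b) == (rev.better_b, rev.better_a)
        assert fwd.equal == rev.equal
        assert fwd.mean_rank_delta == pytest.approx(-rev.mean_rank_delta)

    def test_partition_conservation(self):
        ra = [_result("i", 4, {10: 0.0}, ranks={c: r for c, r in
                                                zip("abcd", [1, 5, 9, 2])})]
        rb = [_result("j", 4, {10: 0.0}, ranks={c: r for c, r in
                                                zip("abcd", [3, 5, 2, 2])})]
        cmp = compare_mappings(ra, rb, [("i", "j")], rank_cutoffs=(10,))
        assert cmp.better_a + cmp.better_b + cmp.equal == len(cmp.shared_ranks) == 4

    def test_non_bijective_match_rejected(self):
        ra = [_result("i1", 2, {10: 0.0}), _result("i2", 2, {10: 0.0})]
        rb = [_result("j1", 2, {10: 0.0})]
        with pytest.raises(InvalidInputError):
            compare_mappings(ra, rb, [("i1", "j1"), ("i2", "j1")])
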