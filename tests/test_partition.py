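"""Ratio parsing, apportionment (with brute-force oracle), stratified draws."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitsite.partition import (
    Partition,
    SplitRatio,
    allocate_counts,
    parse_ratio,
    stratified_partition,
    train_test_indices,
)


class TestParseRatio:
    @pytest.mark.parametrize(
        "text,shares",
        [
            ("8:1:1", (8, 1, 1)),
            ("6:1:1:1:1", (6, 1, 1, 1, 1)),
            ("1:1", (1, 1)),
            ("4:3:2:1", (4, 3, 2, 1)),
        ],
    )
    def test_valid_ratios(self, text, shares):
        ratio = parse_ratio(text)
        assert ratio.shares == shares
        assert str(ratio) == text

    @pytest.mark.parametrize(
        "text,where",
        [("8::1", "position 2"), ("0:1", "position 1"), ("-1:2", "position 1"), ("a:1", "position 1")],
    )
    def test_invalid_tokens_name_the_position(self, text, where):
        with pytest.raises(ValueError, match=where):
            parse_ratio(text)

    def test_single_share_rejected(self):
        with pytest.raises(ValueError):
            parse_ratio("5")


def brute_force_apportionment(n, shares):
    """Enumerate all count vectors (sum n, all >= 1); minimize L1 distance to
    the exact quotas; break ties toward the lexicographically greatest."""
    quotas = [n * s / sum(shares) for s in shares]
    best, best_obj = None, None
    for cuts in itertools.combinations(range(1, n), len(shares) - 1):
        parts, prev = [], 0
        for c in cuts:
            parts.append(c - prev)
            prev = c
        parts.append(n - prev)
        obj = sum(abs(c - q) for c, q in zip(parts, quotas))
        if best is None or obj < best_obj - 1e-12 or (abs(obj - best_obj) <= 1e-12 and parts > best):
            best_obj = obj if best is None else min(obj, best_obj)
            best = parts
    return best


class TestAllocateCounts:
    @pytest.mark.parametrize(
        "n,shares,expected",
        [
            (1000, (8, 1, 1), [800, 100, 100]),
            (10, (1, 1, 1), [4, 3, 3]),
            (10, (4, 3, 2, 1), [4, 3, 2, 1]),
            (64, (1, 1, 1, 1), [16, 16, 16, 16]),
        ],
    )
    def test_known_allocations(self, n, shares, expected):
        assert allocate_counts(n, SplitRatio(shares)) == expected

    def test_fewer_samples_than_clients_rejected(self):
        with pytest.raises(ValueError):
            allocate_counts(2, SplitRatio((1, 1, 1)))

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            k = int(rng.integers(2, 5))
            shares = tuple(int(s) for s in rng.integers(1, 10, k))
            n = int(rng.integers(k, 31))
            assert allocate_counts(n, SplitRatio(shares)) == brute_force_apportionment(n, shares), (
                n,
                shares,
            )

    def test_exhaustive_small_cases_match_oracle(self):
        for shares in itertools.product(range(1, 5), repeat=3):
            for n in range(3, 31):
                assert allocate_counts(n, SplitRatio(shares)) == brute_force_apportionment(n, shares)

    @given(
        n=st.integers(10, 5000),
        shares=st.lists(st.integers(1, 50), min_size=2, max_size=8).map(tuple),
    )
    @settings(max_examples=150, derandomize=True)
    def test_sum_preservation_and_minimum(self, n, shares):
        counts = allocate_counts(n, SplitRatio(shares))
        assert sum(counts) == n
        assert min(counts) >= 1


class TestStratifiedPartition:
    def test_disjoint_and_covering_over_random_cases(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            shares = tuple(int(s) for s in rng.integers(1, 9, k))
            n = int(rng.integers(max(k, 10), 400))
            labels = rng.integers(0, 2, n) if rng.random() < 0.7 else None
            part = stratified_partition(labels, n, SplitRatio(shares), seed=int(rng.integers(1 << 16)))
            joined = np.concatenate(part.by_client)
            assert np.array_equal(np.sort(joined), np.arange(n))
            assert part.sizes() == allocate_counts(n, SplitRatio(shares))

    def test_balanced_binary_classes_stay_balanced_per_client(self):
        labels = np.repeat([0, 1], 500)
        part = stratified_partition(labels, 1000, parse_ratio("8:1:1"), seed=1)
        assert part.sizes() == [800, 100, 100]
        for ix, size in zip(part.by_client, part.sizes()):
            pos = labels[ix].sum()
            assert abs(pos - size / 2) <= 1

    def test_deterministic_per_seed(self):
        labels = np.random.default_rng(0).integers(0, 2, 120)
        a = stratified_partition(labels, 120, parse_ratio("7:2:1"), seed=9)
        b = stratified_partition(labels, 120, parse_ratio("7:2:1"), seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.by_client, b.by_client))
        c = stratified_partition(labels, 120, parse_ratio("7:2:1"), seed=10)
        assert not all(np.array_equal(x, y) for x, y in zip(a.by_client, c.by_client))

    def test_unlabeled_minimal_case(self):
        part = stratified_partition(None, 9, parse_ratio("1:1:1"), seed=0)
        assert part.sizes() == [3, 3, 3]

    def test_rare_class_assigned_round_robin_with_warning(self):
        labels = np.zeros(100, dtype=int)
        labels[:2] = 1  # 2 samples of class 1 for 3 clients
        with pytest.warns(UserWarning, match="round-robin"):
            part = stratified_partition(labels, 100, parse_ratio("1:1:1"), seed=3)
        joined = np.concatenate(part.by_client)
        assert np.array_equal(np.sort(joined), np.arange(100))

    def test_json_roundtrip(self):
        part = stratified_partition(None, 50, parse_ratio("4:1"), seed=2)
        restored = Partition.from_json(part.to_json())
        assert restored.sizes() == part.sizes()
        assert all(np.array_equal(x, y) for x, y in zip(restored.by_client, part.by_client))
        assert str(restored.ratio) == "4:1"

    def test_partition_invariants_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            Partition([np.array([0, 1]), np.array([1, 2])], parse_ratio("1:1"), seed=0)
        with pytest.raises(ValueError, match="cover"):
            Partition([np.array([0]), np.array([2])], parse_ratio("1:1"), seed=0)


class TestTrainTestSplit:
    def test_stratified_eighty_twenty(self):
        labels = np.repeat([0, 1], 250)
        train_idx, test_idx = train_test_indices(labels, 500, 0.2, seed=0)
        assert train_idx.size == 400 and test_idx.size == 100
        assert set(train_idx) & set(test_idx) == set()
        assert abs(labels[test_idx].sum() - 50) <= 1

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            train_test_indices(None, 100, 0.0)
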