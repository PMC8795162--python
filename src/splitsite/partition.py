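"""Split-ratio parsing and sample-to-end-system assignment.

A split ratio like ``"8:1:1"`` states the relative data shares of the
participating end-systems.  Integer counts are derived by largest-remainder
(Hamilton) apportionment: every client receives the floor of its exact quota
``n * share_i / sum(shares)`` and the leftover samples go to the clients with
the largest fractional remainders, ties broken toward the lower client index.
A final repair step guarantees every client at least one sample by donating
from the largest allocation (ties toward the higher index, which keeps the
result the lexicographically-greatest L1-optimal apportionment).

Partitions are drawn stratified by class label by default, so that even an
extreme ratio such as 8:1:1 leaves every hospital with both classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplitRatio",
    "Partition",
    "parse_ratio",
    "allocate_counts",
    "stratified_partition",
    "train_test_indices",
]


@dataclass(frozen=True)
class SplitRatio:
    """Ordered positive integer shares; client 1 receives ``shares[0]``."""

    shares: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (2 <= len(self.shares) <= 16):
            raise ValueError(f"ratio must have between 2 and 16 shares, got {len(self.shares)}")
        if any((not isinstance(s, (int, np.integer))) or s < 1 for s in self.shares):
            raise ValueError(f"every share must be a positive integer, got {self.shares}")
        object.__setattr__(self, "shares", tuple(int(s) for s in self.shares))

    @property
    def n_clients(self) -> int:
        return len(self.shares)

    def __str__(self) -> str:
        return ":".join(str(s) for s in self.shares)


def parse_ratio(text: str) -> SplitRatio:
    """Parse ``"8:1:1"`` into a :class:`SplitRatio`, in written order."""
    tokens = str(text).split(":")
    shares = []
    for pos, tok in enumerate(tokens, start=1):
        tok = tok.strip()
        if not tok:
            raise ValueError(f"empty share at position {pos} in ratio {text!r}")
        try:
            value = int(tok)
        except ValueError:
            raise ValueError(f"non-integer share {tok!r} at position {pos} in ratio {text!r}") from None
        if value < 1:
            raise ValueError(f"share must be >= 1 at position {pos} in ratio {text!r}, got {value}")
        shares.append(value)
    return SplitRatio(tuple(shares))


def _largest_remainder(n: int, weights: np.ndarray) -> np.ndarray:
    """Hamilton apportionment of ``n`` by nonnegative integer ``weights``.

    Exact integer arithmetic throughout so remainder ties are genuine ties,
    broken toward the lower index.  No minimum-count guarantee here.
    """
    weights = np.asarray(weights, dtype=np.int64)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative integers")
    total = int(weights.sum())
    if total <= 0:
        raise ValueError("weights must have a positive sum")
    scaled = int(n) * weights
    counts = scaled // total
    remainders = scaled % total
    leftover = int(n) - int(counts.sum())
    if leftover > 0:
        # descending remainder, ties toward the lower index
        order = np.lexsort((np.arange(len(weights)), -remainders))
        counts[order[:leftover]] += 1
    return counts.astype(int)


def _repair_min_one(counts: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """Raise zero allocations to one, donating optimally.

    Each donated sample comes from the client whose count most exceeds its
    exact quota ``n * weight / total`` (smallest objective increase for the
    L1 apportionment criterion); ties go to the higher index so earlier
    clients keep their allocation, yielding the lexicographically-greatest
    optimal repaired apportionment.  Comparisons use exact integers.
    """
    counts = counts.copy()
    weights = np.asarray(weights, dtype=np.int64)
    total = int(weights.sum())
    for i in np.flatnonzero(counts == 0):
        # overhang_j proportional to counts_j - quota_j, scaled by total;
        # donating from any client at-or-below quota costs the same (+1 in
        # the L1 objective), so non-positive overhangs are equivalent
        overhang = np.maximum(counts * total - int(n) * weights, 0)
        overhang[counts < 2] = -1
        best = overhang.max()
        if best < 0:
            raise ValueError("cannot guarantee one sample per client")
        donor = np.flatnonzero(overhang == best)[-1]
        counts[donor] -= 1
        counts[i] += 1
    return counts


def allocate_counts(n_samples: int, ratio: SplitRatio) -> list[int]:
    """Integer sample counts per client for ``n_samples`` under ``ratio``.

    Largest-remainder apportionment with remainder ties broken toward the
    lower client index; every client is guaranteed at least one sample.
    """
    k = ratio.n_clients
    if n_samples < k:
        raise ValueError(f"need at least {k} samples for {k} clients, got {n_samples}")
    shares = np.asarray(ratio.shares, dtype=np.int64)
    counts = _largest_remainder(n_samples, shares)
    counts = _repair_min_one(counts, shares, n_samples)
    assert counts.sum() == n_samples
    return [int(c) for c in counts]


@dataclass
class Partition:
    """Disjoint, covering assignment of sample indices to end-systems."""

    by_client: list[np.ndarray]
    ratio: SplitRatio
    seed: int
    stratified: bool = False
    n_samples: int = field(init=False)

    def __post_init__(self) -> None:
        self.by_client = [np.asarray(ix, dtype=int) for ix in self.by_client]
        allidx = np.concatenate(self.by_client) if self.by_client else np.array([], dtype=int)
        n = allidx.size
        if len(np.unique(allidx)) != n:
            raise ValueError("client index lists overlap")
        if n == 0 or not np.array_equal(np.sort(allidx), np.arange(n)):
            raise ValueError("client index lists must exactly cover 0..n-1")
        if any(ix.size < 1 for ix in self.by_client):
            raise ValueError("every client needs at least one sample")
        expected = allocate_counts(n, self.ratio)
        sizes = [ix.size for ix in self.by_client]
        if sizes != expected:
            raise ValueError(f"client sizes {sizes} do not follow the apportionment {expected}")
        self.n_samples = n

    @property
    def n_clients(self) -> int:
        return len(self.by_client)

    def sizes(self) -> list[int]:
        return [ix.size for ix in self.by_client]

    # -- JSON round trip ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "ratio": str(self.ratio),
                "seed": self.seed,
                "stratified": self.stratified,
                "clients": {str(i + 1): ix.tolist() for i, ix in enumerate(self.by_client)},
            },
            indent=None,
        )

    @classmethod
    def from_json(cls, text: str) -> "Partition":
        d = json.loads(text)
        clients = [np.asarray(d["clients"][str(i + 1)], dtype=int) for i in range(len(d["clients"]))]
        return cls(clients, parse_ratio(d["ratio"]), int(d["seed"]), bool(d["stratified"]))


def stratified_partition(
    labels: np.ndarray | None,
    n_samples: int,
    ratio: SplitRatio,
    seed: int,
) -> Partition:
    """Assign ``n_samples`` indices to clients following ``ratio``.

    With ``labels`` given the assignment is stratified: classes are dealt out
    class by class (largest class first) by apportioning each class over the
    clients' remaining capacities, which keeps every client's class mix
    within about one sample of the global proportions.  A class with fewer
    samples than clients is assigned round-robin (with a warning) to the
    clients with the most remaining capacity.

    Deterministic given ``seed``.
    """
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape[0] != n_samples:
            raise ValueError(f"labels length {labels.shape[0]} != n_samples {n_samples}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0x9A27,)))
    capacities = np.asarray(allocate_counts(n_samples, ratio), dtype=int)
    k = ratio.n_clients
    assigned: list[list[np.ndarray]] = [[] for _ in range(k)]

    if labels is None:
        perm = rng.permutation(n_samples)
        offsets = np.concatenate([[0], np.cumsum(capacities)])
        for j in range(k):
            assigned[j].append(perm[offsets[j] : offsets[j + 1]])
    else:
        classes, counts = np.unique(labels, return_counts=True)
        remaining = capacities.copy()
        for cls in classes[np.argsort(-counts, kind="stable")]:
            idx = rng.permutation(np.flatnonzero(labels == cls))
            if idx.size < k:
                warnings.warn(
                    f"class {cls!r} has {idx.size} samples for {k} clients; assigning round-robin",
                    stacklevel=2,
                )
                order = np.lexsort((np.arange(k), -remaining))
                for pos, sample in enumerate(idx):
                    j = order[pos % k]
                    if remaining[j] < 1:
                        j = int(np.argmax(remaining))
                    assigned[j].append(np.asarray([sample]))
                    remaining[j] -= 1
                continue
            share = _largest_remainder(idx.size, remaining)
            offsets = np.concatenate([[0], np.cumsum(share)])
            for j in range(k):
                assigned[j].append(idx[offsets[j] : offsets[j + 1]])
            remaining -= share

    by_client = [
        np.sort(np.concatenate(parts)) if parts else np.array([], dtype=int) for parts in assigned
    ]
    return Partition(by_client, ratio, seed, stratified=labels is not None)


def train_test_indices(
    labels: np.ndarray | None,
    n_samples: int,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Carve a stratified held-out split before any client partitioning.

    Uses the same apportionment machinery with a two-way ratio, so the test
    set size is the largest-remainder rounding of ``test_fraction``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    # two-way ratio in smallest integer terms at 1/1000 resolution
    q = int(round(test_fraction * 1000))
    from math import gcd

    g = gcd(1000 - q, q)
    two_way = SplitRatio(((1000 - q) // g, q // g))
    part = stratified_partition(labels, n_samples, two_way, seed)
    return part.by_client[0], part.by_client[1]
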