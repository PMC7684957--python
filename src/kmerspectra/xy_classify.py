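"""Partition of the k-mer universe by XY-dinucleotide content.

For a fixed ordered dinucleotide XY (16 choices over {A,C,G,T}²), every
k-mer is classified by how many times XY occurs in it as a substring,
counting overlapping occurrences (so "AAA" contains two "AA").  Two schemes
are supported:

* three-way — class 0 (no occurrence), class 1 (exactly one), class 2
  (two or more); the convention used for 8-mers.
* two-way — class 0 (none) vs class 1 (one or more); used for 6-mers,
  whose universe is too small to resolve a ≥2 class in short genomes.

The partition sizes have closed-form linear recurrences (pattern-avoidance
counting), which serve as an independent oracle for the enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .kmer_core import _BASES, decode_kmer, encode_kmer

__all__ = [
    "DINUCLEOTIDES",
    "SubsetPartition",
    "count_xy_occurrences",
    "classify_kmer",
    "build_partition",
    "partition_sizes",
    "zero_class_size_recurrence",
    "theoretical_subset_gc",
    "reverse_complement_pair",
]

#: The 16 ordered dinucleotide pairs, each defining one classification.
DINUCLEOTIDES: tuple[str, ...] = tuple(x + y for x in _BASES for y in _BASES)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement_pair(xy: str) -> str:
    """Reverse complement of a dinucleotide (CG->CG, TA->TA, AA->TT, ...)."""
    return xy.translate(_COMPLEMENT)[::-1]


def _check_xy(xy: str) -> str:
    xy = xy.upper()
    if len(xy) != 2 or any(c not in _BASES for c in xy):
        raise ValueError(f"xy must be a 2-letter DNA word over ACGT, got {xy!r}")
    return xy


def count_xy_occurrences(kmer: str, xy: str) -> int:
    """Number of (possibly overlapping) occurrences of xy in kmer, step 1."""
    xy = _check_xy(xy)
    kmer = kmer.upper()
    if any(c not in _BASES for c in kmer):
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    return sum(1 for i in range(len(kmer) - 1) if kmer[i : i + 2] == xy)


def classify_kmer(kmer: str, xy: str, scheme: str = "three-way") -> int:
    """Class label of one k-mer: occurrences capped at 2 (three-way) or 1 (two-way)."""
    occ = count_xy_occurrences(kmer, xy)
    if scheme == "three-way":
        return min(occ, 2)
    if scheme == "two-way":
        return min(occ, 1)
    raise ValueError(f"unknown scheme {scheme!r}")


@lru_cache(maxsize=32)
def _universe_codes(k: int) -> np.ndarray:
    """(4^k, k) array of base codes of every k-mer in lexicographic order."""
    if not 1 <= k <= 13:
        raise ValueError(f"full enumeration supported for k in [1, 13], got {k}")
    ranks = np.arange(4**k, dtype=np.int64)
    cols = [(ranks >> (2 * (k - 1 - j))) & 3 for j in range(k)]
    return np.stack(cols, axis=1).astype(np.int8)


@lru_cache(maxsize=None)
def occurrence_vector(k: int, xy: str) -> np.ndarray:
    """Overlapping-occurrence count of xy in every k-mer, indexed by rank."""
    xy = _check_xy(xy)
    codes = _universe_codes(k)
    x, y = (encode_kmer(c) for c in xy)
    occ = np.zeros(4**k, dtype=np.int16)
    for j in range(k - 1):
        occ += (codes[:, j] == x) & (codes[:, j + 1] == y)
    return occ


@dataclass(frozen=True)
class SubsetPartition:
    """Assignment of all 4^k k-mers to classes for one XY pair and scheme.

    ``labels[rank]`` is the class (0/1/2 three-way, 0/1 two-way) of the
    k-mer with that lexicographic rank.
    """

    k: int
    xy: str
    scheme: str
    labels: np.ndarray

    @property
    def n_classes(self) -> int:
        return 3 if self.scheme == "three-way" else 2

    def members(self, cls: int) -> np.ndarray:
        """Boolean mask over the universe selecting one class."""
        return self.labels == cls

    def sizes(self) -> tuple[int, ...]:
        return tuple(int((self.labels == c).sum()) for c in range(self.n_classes))

    def class_of(self, kmer: str) -> int:
        return int(self.labels[encode_kmer(kmer)])


@lru_cache(maxsize=None)
def build_partition(k: int, xy: str, scheme: str = "three-way") -> SubsetPartition:
    """Enumerate all 4^k k-mers and assign each its XY class."""
    xy = _check_xy(xy)
    if scheme not in ("three-way", "two-way"):
        raise ValueError(f"unknown scheme {scheme!r}")
    occ = occurrence_vector(k, xy)
    cap = 2 if scheme == "three-way" else 1
    labels = np.minimum(occ, cap).astype(np.int8)
    labels.setflags(write=False)
    return SubsetPartition(k=k, xy=xy, scheme=scheme, labels=labels)


def partition_sizes(k: int, xy: str, scheme: str = "three-way") -> tuple[int, ...]:
    """Exact class sizes by full enumeration, e.g. (8, CG) -> (40545, 21468, 3523)."""
    return build_partition(k, xy, scheme).sizes()


def zero_class_size_recurrence(k: int, xy: str) -> int:
    """XY0 class size by linear recurrence — an oracle independent of enumeration.

    Counting length-k words avoiding the factor XY: for X != Y the count
    b(k) satisfies b(1)=4, b(2)=15, b(k) = 4 b(k-1) - b(k-2); for X == Y,
    a(1)=4, a(2)=15, a(k) = 3 a(k-1) + 3 a(k-2) (a word avoiding XX either
    appends a non-X base to any shorter word, or an X after a non-X).
    """
    xy = _check_xy(xy)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    prev2, prev1 = 4, 15  # k = 1, 2
    if k == 1:
        return prev2
    if k == 2:
        return prev1
    same = xy[0] == xy[1]
    for _ in range(k - 2):
        cur = 3 * prev1 + 3 * prev2 if same else 4 * prev1 - prev2
        prev2, prev1 = prev1, cur
    return prev1


def theoretical_subset_gc(k: int, xy: str, cls: int, scheme: str = "two-way") -> float:
    """Mean G+C percentage, 100*(#G + #C)/k, over the k-mers of one class.

    E.g. the 6-mers containing at least one CG average 65.34% G+C while the
    CG-free 6-mers average 43.75% — the combinatorial backbone of the link
    between CpG depletion and genomic G+C content.
    """
    part = build_partition(k, xy, scheme)
    mask = part.members(cls)
    if not mask.any():
        raise ValueError(f"class {cls} of {xy} {scheme} partition at k={k} is empty")
    codes = _universe_codes(k)
    gc_counts = ((codes == encode_kmer("C")) | (codes == encode_kmer("G"))).sum(axis=1)
    return float(100.0 * gc_counts[mask].mean() / k)
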