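"""K-mer counting and k-mer frequency spectra.

A k-mer spectrum is the histogram of occurrence frequencies over the full
4^k k-mer universe: for each frequency value ``i`` it records ``N_i``, the
number of distinct k-mers observed exactly ``i`` times, and the relative
motif number ``RMN_i = N_i / 4**k``.  Counting slides a window of k bp along
the sequence in steps of 1 bp on the given strand only; no
reverse-complement canonicalization is performed, because strand-specific
dinucleotide depletion (CpG, TpA) is exactly the signal downstream analysis
quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "KmerCountTable",
    "Spectrum",
    "count_kmers",
    "build_spectrum",
    "random_center_frequency",
    "minimum_k",
    "encode_kmer",
    "decode_kmer",
]

_BASES = "ACGT"

# 256-entry byte -> base-code lookup; non-ACGT (incl. IUPAC ambiguity) -> -1.
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_kmer(kmer: str) -> int:
    """Map a k-mer over {A,C,G,T} to its rank in lexicographic order."""
    code = 0
    for ch in kmer.upper():
        idx = _BASES.find(ch)
        if idx < 0:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer {kmer!r}")
        code = code * 4 + idx
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


@dataclass
class KmerCountTable:
    """Occurrence counts of every k-mer of one sequence (or pooled records).

    ``counts`` is a dense ``int64`` array of length ``4**k`` indexed by the
    lexicographic rank of the k-mer, so zero-count k-mers are always
    materialized.  ``n_windows`` is the number of valid (ACGT-only) windows
    scanned; it equals ``counts.sum()``.
    """

    k: int
    counts: np.ndarray
    n_windows: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise ValueError(
                f"counts must have length 4**k = {4**self.k}, got {self.counts.shape}"
            )

    def count_of(self, kmer: str) -> int:
        return int(self.counts[encode_kmer(kmer)])

    def as_dict(self, nonzero_only: bool = True) -> dict[str, int]:
        idx = np.nonzero(self.counts)[0] if nonzero_only else range(4**self.k)
        return {decode_kmer(int(i), self.k): int(self.counts[i]) for i in idx}


@dataclass
class Spectrum:
    """Frequency-block histogram of a k-mer set.

    ``blocks[i]`` is ``N_i``, the number of member k-mers with occurrence
    count ``i`` (the zero-frequency block is always materialized).  ``rmn``
    normalizes by the full universe size ``4**k`` regardless of subset size,
    so subset spectra of one genome are directly comparable.
    """

    k: int
    blocks: dict[int, int]
    subset_label: str = "total"
    _rmn: dict[int, float] = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def rmn(self) -> dict[int, float]:
        if self._rmn is None:
            denom = float(4**self.k)
            self._rmn = {i: n / denom for i, n in self.blocks.items()}
        return self._rmn

    @property
    def n_members(self) -> int:
        return int(sum(self.blocks.values()))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (frequency, N_i) arrays over 0..max observed frequency."""
        fmax = max(self.blocks) if self.blocks else 0
        freqs = np.arange(fmax + 1)
        ns = np.zeros(fmax + 1, dtype=np.int64)
        for i, n in self.blocks.items():
            ns[i] = n
        return freqs, ns


def _encode_windows(sequence: str, k: int) -> np.ndarray:
    """Integer codes of every valid window; invalid windows are dropped."""
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n_pos = len(codes) - k + 1
    if n_pos <= 0:
        return np.empty(0, dtype=np.int64)
    window = np.zeros(n_pos, dtype=np.int64)
    bad = np.zeros(n_pos, dtype=bool)
    for j in range(k):
        col = codes[j : j + n_pos]
        window = window * 4 + np.where(col < 0, 0, col)
        bad |= col < 0
    return window[~bad]


def count_kmers(
    sequences: str | Iterable[str],
    k: int,
    source_id: str = "",
) -> KmerCountTable:
    """Count every k bp window, sliding by 1 bp, over one or more sequences.

    Counting is case-insensitive and single-strand.  Windows containing any
    non-ACGT character are skipped and do not contribute to ``n_windows``.
    When several sequences are given (e.g. chromosomes of one genome) their
    counts are pooled without creating artificial junction windows.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = np.zeros(4**k, dtype=np.int64)
    total_len = 0
    n_windows = 0
    for seq in sequences:
        total_len += len(seq)
        if len(seq) < k:
            continue
        window = _encode_windows(seq, k)
        n_windows += window.size
        counts += np.bincount(window, minlength=4**k)
    label = source_id or "<sequence>"
    if total_len == 0:
        raise ValueError(f"empty sequence input for {label!r}")
    if n_windows == 0:
        raise ValueError(
            f"no valid length-{k} window in {label!r} "
            f"(total length {total_len} bp after ambiguity handling)"
        )
    return KmerCountTable(k=k, counts=counts, n_windows=n_windows, source_id=source_id)


def build_spectrum(
    table: KmerCountTable,
    members: str | Iterable[str] | np.ndarray = "total",
    subset_label: str | None = None,
) -> Spectrum:
    """Histogram the counts of exactly the member k-mers into frequency blocks.

    ``members`` is ``"total"`` for the whole universe, an iterable of k-mer
    strings, or a boolean mask / integer index array over the universe.  The
    zero-frequency block is included, so ``sum(N_i)`` equals the member-set
    size and, for the total set, ``sum(RMN_i) == 1``.
    """
    if isinstance(members, str):
        if members != "total":
            raise ValueError("members must be 'total', a k-mer iterable, or an index array")
        values = table.counts
        label = subset_label or "total"
    elif isinstance(members, np.ndarray):
        values = table.counts[members]
        label = subset_label or "subset"
    else:
        idx = np.array([encode_kmer(m) for m in members], dtype=np.int64)
        if idx.size == 0:
            raise ValueError("empty member set")
        values = table.counts[idx]
        label = subset_label or "subset"
    if values.size == 0:
        raise ValueError("empty member set")
    blocks = np.bincount(values)
    return Spectrum(
        k=table.k,
        blocks={int(i): int(n) for i, n in enumerate(blocks) if n > 0 or i == 0},
        subset_label=label,
    )


def random_center_frequency(L: int, k: int) -> float:
    """Expected per-k-mer count, (L - k + 1)/4^k, for an i.i.d. uniform sequence.

    This is the reference "random center" against which depleted subsets are
    judged: a subset whose modal frequency sits well below it is under
    directional selection rather than random usage.
    """
    if L < k:
        raise ValueError(f"sequence length L={L} shorter than k={k}")
    return (L - k + 1) / 4**k


def minimum_k(L: int) -> float:
    """Smallest informative window length for a sequence of L bp: 0.7*log4(L)."""
    if L <= 1:
        raise ValueError(f"L must be > 1, got {L}")
    return 0.7 * math.log(L, 4)
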