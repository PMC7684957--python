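"""Square-root-normalized spectrum statistics and per-genome profiles.

Raw k-mer frequency spectra are skewed (roughly chi-square-like with few
degrees of freedom), so their mean and SD are not independent location and
dispersion descriptors.  All frequencies are therefore square-root
transformed before computing the mean x̄ and the sample SD; on that scale
two dimensionless ratios compare each k-mer subset against the total set:

* separability  δ_i = x̄ / x̄_i  — how far below the whole-genome mean the
  subset's frequencies sit (δ > 1: the subset is depleted / selected);
* conservatism  ρ_i = SD / SD_i — how tightly the subset's frequencies are
  concentrated (ρ > 1: more conservative usage than the genome at large).

Both are invariant under rescaling all counts by a positive constant, so
genomes of different sizes are comparable.

A :class:`GenomeProfile` bundles these statistics for the total set and all
16 XY partitions, the genome's G+C content, the background separability
(the mean δ of the 14 XY1 subsets other than CG1 and TA1) and the CG/TA
selection flags derived from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.signal import find_peaks

from .kmer_core import KmerCountTable, Spectrum, build_spectrum, count_kmers
from .xy_classify import DINUCLEOTIDES, build_partition

__all__ = [
    "SubsetStats",
    "GenomeProfile",
    "sqrt_transform",
    "spectrum_mean_sd",
    "separability",
    "conservatism",
    "subset_stats",
    "profile_genome",
    "profile_counts",
    "gc_content",
    "modality",
]


def sqrt_transform(counts) -> np.ndarray:
    """Element-wise square root of non-negative frequencies (0 maps to 0)."""
    arr = np.asarray(counts, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("negative frequency passed to sqrt_transform")
    return np.sqrt(arr)


def spectrum_mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (divisor N-1) of a frequency vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values, got {arr.size}")
    return float(arr.mean()), float(arr.std(ddof=1))


def separability(total_mean: float, subset_mean: float) -> float:
    """δ = x̄_total / x̄_subset; NaN (never inf) when the subset mean is 0."""
    if subset_mean == 0:
        return math.nan
    return total_mean / subset_mean


def conservatism(total_sd: float, subset_sd: float) -> float:
    """ρ = SD_total / SD_subset; NaN (never inf) when the subset SD is 0."""
    if subset_sd == 0:
        return math.nan
    return total_sd / subset_sd


@dataclass(frozen=True)
class SubsetStats:
    """Mean, SD, separability and conservatism of one subset's spectrum."""

    subset_label: str
    n_members: int
    mean: float
    sd: float
    delta: float
    rho: float

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.delta) or math.isnan(self.rho))


def subset_stats(
    values: np.ndarray,
    total_mean: float,
    total_sd: float,
    label: str,
) -> SubsetStats:
    """Statistics of one subset's (already transformed) frequency vector."""
    if values.size < 2:
        return SubsetStats(label, int(values.size), math.nan, math.nan, math.nan, math.nan)
    mean, sd = spectrum_mean_sd(values)
    return SubsetStats(
        subset_label=label,
        n_members=int(values.size),
        mean=mean,
        sd=sd,
        delta=separability(total_mean, mean),
        rho=conservatism(total_sd, sd),
    )


def gc_content(sequences: str | Iterable[str]) -> float:
    """G+C percentage over ACGT bases only (ambiguity codes ignored)."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = acgt = 0
    for seq in sequences:
        s = seq.upper()
        for b in "ACGT":
            n = s.count(b)
            acgt += n
            if b in "GC":
                gc += n
    if acgt == 0:
        raise ValueError("no ACGT bases in input")
    return 100.0 * gc / acgt


@dataclass
class GenomeProfile:
    """Per-genome bundle of spectrum statistics across all XY partitions.

    ``stats`` maps ``"total"`` and ``(xy, class)`` keys to
    :class:`SubsetStats`.  ``background_delta1`` is the mean separability of
    the 14 XY1 subsets excluding CG1 and TA1 — the per-genome background
    against which CG/TA selection intensity is judged.  ``flags`` holds the
    four selection calls (values True/False, or None when undefined).
    """

    genome_id: str
    k: int
    scheme: str
    gc_content: float
    stats: dict
    background_delta1: float
    flags: dict = field(default_factory=dict)
    include_zero_members: bool = True
    sqrt_scale: bool = True

    def delta(self, xy: str, cls: int) -> float:
        return self.stats[(xy, cls)].delta

    def rho(self, xy: str, cls: int) -> float:
        return self.stats[(xy, cls)].rho

    @property
    def n_classes(self) -> int:
        return 3 if self.scheme == "three-way" else 2

    def to_rows(self) -> list[dict]:
        """One flat record per subset, suitable for a DataFrame/TSV export."""
        rows = []
        for key, st in self.stats.items():
            xy, cls = ("total", -1) if key == "total" else key
            rows.append(
                {
                    "genome_id": self.genome_id,
                    "xy": xy,
                    "class": cls,
                    "n_members": st.n_members,
                    "mean": st.mean,
                    "sd": st.sd,
                    "delta": st.delta,
                    "rho": st.rho,
                }
            )
        return rows

    def metadata(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "k": self.k,
            "scheme": self.scheme,
            "gc_content": self.gc_content,
            "background_delta1": self.background_delta1,
            "include_zero_members": self.include_zero_members,
            "sqrt_scale": self.sqrt_scale,
            "flags": self.flags,
        }


def background_delta1(deltas: Mapping[str, float]) -> float:
    """Mean separability of the 14 XY1 spectra excluding CG1 and TA1."""
    vals = [d for xy, d in deltas.items() if xy not in ("CG", "TA") and not math.isnan(d)]
    if not vals:
        return math.nan
    return float(np.mean(vals))


def profile_counts(
    table: KmerCountTable,
    scheme: str | None = None,
    gc: float = math.nan,
    include_zero_members: bool = True,
    sqrt_scale: bool = True,
    inhibition_margin: float = 0.05,
) -> GenomeProfile:
    """Build a :class:`GenomeProfile` from an existing count table.

    ``include_zero_members`` controls whether never-observed k-mers enter a
    subset's N (the default keeps them, matching "N is the total number of
    k-mers in the subset"); ``sqrt_scale=False`` computes the statistics on
    raw frequencies for comparison.
    """
    from .selection_analysis import selection_flags  # deferred: avoids cycle

    k = table.k
    if scheme is None:
        scheme = "three-way" if k >= 8 else "two-way"
    counts = table.counts.astype(float)
    values = sqrt_transform(counts) if sqrt_scale else counts

    observed = counts > 0
    total_values = values if include_zero_members else values[observed]
    total_mean, total_sd = spectrum_mean_sd(total_values)

    stats: dict = {
        "total": SubsetStats("total", int(total_values.size), total_mean, total_sd, 1.0, 1.0)
    }
    for xy in DINUCLEOTIDES:
        part = build_partition(k, xy, scheme)
        for cls in range(part.n_classes):
            mask = part.members(cls)
            if not include_zero_members:
                mask = mask & observed
            stats[(xy, cls)] = subset_stats(
                values[mask], total_mean, total_sd, f"{xy}{cls}"
            )

    bg = background_delta1({xy: stats[(xy, 1)].delta for xy in DINUCLEOTIDES})
    profile = GenomeProfile(
        genome_id=table.source_id,
        k=k,
        scheme=scheme,
        gc_content=gc,
        stats=stats,
        background_delta1=bg,
        include_zero_members=include_zero_members,
        sqrt_scale=sqrt_scale,
    )
    profile.flags = selection_flags(profile, margin=inhibition_margin)
    return profile


def profile_genome(
    sequences: str | Iterable[str],
    k: int,
    scheme: str | None = None,
    genome_id: str = "",
    include_zero_members: bool = True,
    sqrt_scale: bool = True,
    inhibition_margin: float = 0.05,
) -> GenomeProfile:
    """Count k-mers once, then profile every XY class against the total set."""
    seqs = [sequences] if isinstance(sequences, str) else list(sequences)
    table = count_kmers(seqs, k, source_id=genome_id)
    return profile_counts(
        table,
        scheme=scheme,
        gc=gc_content(seqs),
        include_zero_members=include_zero_members,
        sqrt_scale=sqrt_scale,
        inhibition_margin=inhibition_margin,
    )


def modality(
    spectrum: Spectrum,
    bandwidth: int = 5,
    min_prominence: float = 0.05,
) -> int:
    """Number of peaks of the spectrum after moving-average smoothing.

    The RMN histogram is smoothed with a centered moving average of width
    ``bandwidth`` (bins on the raw frequency axis) and local maxima with
    prominence at least ``min_prominence`` times the smoothed maximum are
    counted.  Boundary peaks (e.g. a mass of never-observed k-mers at
    frequency 0) count: the histogram is zero-padded at both ends.
    """
    _, ns = spectrum.as_arrays()
    if ns.sum() == 0:
        return 0
    y = ns.astype(float) / 4**spectrum.k
    if bandwidth > 1:
        kernel = np.ones(bandwidth) / bandwidth
        y = np.convolve(y, kernel, mode="same")
    padded = np.concatenate([[0.0], y, [0.0]])
    peaks, _ = find_peaks(padded, prominence=min_prominence * padded.max())
    return int(len(peaks))
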