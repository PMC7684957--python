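"""First-order Markov genome simulator with tunable CG/TA depletion.

Real genomes deviate from independence mostly at the dinucleotide level —
CpG is depleted in vertebrates (deamination of methylated cytosine), TpA in
many microbial genomes.  A first-order Markov chain is the minimal model
that controls dinucleotide content: starting from an independence matrix
matched to a target base composition, the C→G transition probability is
multiplied by ``cg_factor`` and the T→A transition by ``ta_factor`` (both
in (0, 1]) and rows are renormalized.  Depletion of CG pulls the realized
stationary G+C below the target; depletion of TA pushes it above — the same
mechanistic coupling between dinucleotide selection and G+C content that
the downstream correlation screens are designed to detect.

Groups of genomes with factors graded across a range (optionally with cg
and ta anti-correlated, the mutual-inhibition scenario) provide known-truth
inputs for parameter-recovery and correlation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MarkovSpec", "build_spec", "generate", "make_group"]

_BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class MarkovSpec:
    """Parameters of one synthetic genome.

    ``transition[i, j]`` is P(next base j | current base i) over base order
    A, C, G, T; ``initial`` is the distribution of the first base.  The
    realized stationary distribution (left Perron eigenvector of the
    transition matrix) is recorded at construction.
    """

    length: int
    transition: np.ndarray
    initial: np.ndarray
    cg_factor: float = 1.0
    ta_factor: float = 1.0
    gc_target: float = 0.5
    seed: int = 0
    stationary: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (4, 4):
            raise ValueError("transition must be 4x4")
        if (self.transition < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1 within 1e-12")
        if self.stationary is None:
            self.stationary = _stationary(self.transition)

    @property
    def stationary_gc(self) -> float:
        return float(self.stationary[1] + self.stationary[2])

    def dinucleotide_probability(self, xy: str) -> float:
        """Stationary probability of observing xy at a random position."""
        i, j = _IDX[xy[0].upper()], _IDX[xy[1].upper()]
        return float(self.stationary[i] * self.transition[i, j])


def _stationary(P: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = np.abs(pi)
    return pi / pi.sum()


def build_spec(
    cg_factor: float = 1.0,
    ta_factor: float = 1.0,
    gc_target: float = 0.5,
    length: int = 1_000_000,
    seed: int = 0,
) -> MarkovSpec:
    """Construct a depleted-dinucleotide Markov spec.

    The base matrix has identical rows equal to the composition
    (A, C, G, T) = ((1-g)/2, g/2, g/2, (1-g)/2) for ``g = gc_target`` — an
    i.i.d. sequence when both factors are 1.  Depletion then scales the C→G
    and T→A entries and renormalizes the two affected rows.
    """
    if not 0 < cg_factor <= 1 or not 0 < ta_factor <= 1:
        raise ValueError("cg_factor and ta_factor must lie in (0, 1]")
    if not 0.2 < gc_target < 0.8:
        raise ValueError(
            f"gc_target {gc_target} outside the supported range (0.2, 0.8); "
            "strong depletion at extreme compositions makes rows degenerate"
        )
    if length < 10:
        raise ValueError("length must be >= 10 bp")
    g = gc_target
    base_row = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    P = np.tile(base_row, (4, 1))
    P[_IDX["C"], _IDX["G"]] *= cg_factor
    P[_IDX["T"], _IDX["A"]] *= ta_factor
    P /= P.sum(axis=1, keepdims=True)
    return MarkovSpec(
        length=length,
        transition=P,
        initial=base_row.copy(),
        cg_factor=cg_factor,
        ta_factor=ta_factor,
        gc_target=gc_target,
        seed=seed,
    )


def generate(spec: MarkovSpec) -> str:
    """Sample one first-order Markov sequence of ``spec.length`` bp.

    Deterministic given ``spec.seed``.  The chain is advanced with
    pre-drawn uniforms against per-row cumulative thresholds.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.length)
    # cumulative thresholds per row; python-level loop kept simple — the
    # state space is 4 and lengths are at most a few Mb.
    cum = np.cumsum(spec.transition, axis=1)
    cum[:, -1] = 1.0  # guard against cumulative round-off
    cum_rows = [tuple(row) for row in cum]
    init_cum = tuple(np.cumsum(spec.initial / spec.initial.sum()))

    def pick(thresholds, x):
        if x < thresholds[0]:
            return 0
        if x < thresholds[1]:
            return 1
        if x < thresholds[2]:
            return 2
        return 3

    out = np.empty(spec.length, dtype=np.uint8)
    state = pick(init_cum, u[0])
    out[0] = state
    for i in range(1, spec.length):
        state = pick(cum_rows[state], u[i])
        out[i] = state
    lut = np.frombuffer("ACGT".encode("ascii"), dtype=np.uint8)
    return lut[out].tobytes().decode("ascii")


def make_group(
    n: int,
    cg_range: tuple[float, float] = (1.0, 0.2),
    ta_range: tuple[float, float] | None = None,
    gc_target: float = 0.5,
    length: int = 1_000_000,
    seed: int = 0,
    anti_correlate: bool = False,
) -> tuple[list[str], list[MarkovSpec]]:
    """Generate ``n`` genomes with depletion factors graded across ranges.

    ``cg_range=(a, b)`` spaces cg_factor linearly from a to b across the
    group; ``ta_range=None`` keeps ta_factor at 1.  With
    ``anti_correlate=True`` the ta factors run across ``ta_range`` in the
    opposite direction to the cg grading (mutual-inhibition scenario).
    Per-genome seeds are derived deterministically from the group seed.
    Returns (sequences, specs); the specs carry the true parameters for
    parameter-recovery checks.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 genomes, got {n}")
    cg_factors = np.linspace(cg_range[0], cg_range[1], n)
    if ta_range is None:
        ta_factors = np.ones(n)
    else:
        ta_factors = np.linspace(ta_range[0], ta_range[1], n)
        if anti_correlate:
            ta_factors = ta_factors[::-1]
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    specs = [
        build_spec(
            cg_factor=float(cg_factors[i]),
            ta_factor=float(ta_factors[i]),
            gc_target=gc_target,
            length=length,
            seed=int(child_seeds[i]),
        )
        for i in range(n)
    ]
    return [generate(s) for s in specs], specs
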