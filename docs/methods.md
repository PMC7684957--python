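# Methods

## K-mer spectra

For a sequence of length L, occurrence counts of all 4^k k-mers are taken
with a k bp window sliding 1 bp at a time on the given strand only.  No
reverse-complement canonicalization is applied: strand-specific
dinucleotide depletion is the object of study, and merging strands would
average CG against itself but AA against TT.  Windows containing any
non-ACGT character are skipped and do not count toward the number of valid
windows, which keeps the invariant `sum(counts) == n_windows` exact on
soft-masked or ambiguous input; counting is case-insensitive.  Multi-record
input (chromosomes of one genome) is pooled without concatenation, so no
artificial junction windows are created.

The spectrum records `N_i`, the number of distinct k-mers with count `i`,
including the zero block, and normalizes by the universe size:
`RMN_i = N_i / 4^k`.  The denominator is the full universe even for subset
spectra, so the spectra of subsets of one genome are directly comparable.
The expected per-k-mer count of an i.i.d. uniform sequence,
`(L − k + 1)/4^k`, serves as the random reference point; `0.7·log4(L)`
estimates the smallest k at which a sequence of length L can populate the
universe informatively.

## XY-dinucleotide partition

For an ordered pair XY over {A, C, G, T} (16 classifications; XY and YX are
distinct), each k-mer is labeled by its number of overlapping occurrences
of XY: three-way 0 / 1 / ≥2 (the 8-mer convention) or two-way 0 / ≥1 (the
6-mer convention).  The scheme is a parameter, not a function of k: the
group analyses use the three-way scheme at k = 6 when the ≥2 class is
needed.  Overlap counting is the only convention consistent with the
closed-form class sizes (e.g. 44 631 same-letter-free 8-mers).

Class-0 sizes obey linear recurrences that serve as an oracle independent
of enumeration: words avoiding XY with X ≠ Y satisfy
`b(k) = 4·b(k−1) − b(k−2)` (b(1) = 4, b(2) = 15); words avoiding XX satisfy
`a(k) = 3·a(k−1) + 3·a(k−2)` (a word avoiding XX ends either in a non-X
base appended to any shorter avoiding word, or in X appended after a
non-X).  Subset mean G+C is an exact enumeration average; for the 6-mer
two-way split it is 65.3446 % (CG1), 43.7536 % (CG0), 34.6554 % (TA1),
56.2464 % (TA0).  Reports quote these truncated to two decimals.

## Spectrum statistics

Raw count spectra are right-skewed (χ²-like with few degrees of freedom),
so location and dispersion are entangled.  All frequencies are square-root
transformed before computing the mean and the sample SD (divisor N − 1);
a raw-scale mode is kept behind a flag for comparison.  N includes
never-observed (zero-count) members of a subset by default — the subset is
a fixed combinatorial object, and dropping unobserved members would make N
depend on genome size.  The observed-only convention is available as an
option and is echoed into all output metadata, since for heavily depleted
subsets the two conventions differ materially.

Separability `δ_i = x̄/x̄_i` and conservatism `ρ_i = SD/SD_i` compare each
subset with the total set; both equal 1 for the total set by construction
and are invariant under rescaling all counts by a positive constant
(numerator and denominator scale by √c under the transform), which makes
genomes of different sizes comparable.  Subsets with fewer than two usable
members, or with zero mean or SD, are reported as undefined (NaN) rather
than infinite, and flags derived from undefined inputs are None, not False.

Per genome, the background `δ̄₁` is the mean δ of the 14 XY1 subsets other
than CG1 and TA1.  CG (or TA) selection is **obvious** when δ_XY1 exceeds
δ̄₁, and **strongly inhibited** when δ_XY1 < δ̄₁·(1 − m).  The margin m has
no canonical value; the default 0.05 treats a 5 % shortfall against a
background whose null scatter is below 1 % (see calibration) as clearly
below background.  It is configurable and the raw δ values are always
reported alongside the flags so any threshold can be re-applied.

Modality is a display-level heuristic: the RMN histogram on the raw
frequency axis is smoothed with a centered moving average (default width
5 bins) and local maxima with prominence ≥ 5 % of the smoothed maximum are
counted; the histogram is zero-padded so a boundary peak at frequency 0 (a
mass of never-observed k-mers) counts.  The defaults suppress Poisson
noise on ~10^5-bp inputs while resolving peaks separated by a few SDs;
statistics are never computed from the smoothed histogram.

## Group analysis

Across a group of genome profiles the package computes, with
pairwise-complete handling of undefined values:

* Pearson r with two-tailed p for the stated δ–ρ pairs of the CG and TA
  families (δ1–ρ1, δ2–ρ2, δ1–δ2, ρ1–ρ2, δ0–ρ0).  Pearson is used because
  the relationship screened for is linear; no multiple-testing correction
  is applied and the number of tests is part of the report.
* Variance of each XY separability per class, with two-tailed
  variance-ratio F-tests of CG against GC/CC/GG and TA against AT/AA/TT
  (larger variance in the numerator; p = 2·SF capped at 1).
* Group mean and two-sided 95 % t-interval (df = n − 1) of every δ and ρ.
  The interval is the standard small-sample choice; nothing heavier is
  warranted for group sizes in the tens.
* Pearson r/p of δ/ρ of the CG and TA classes against genomic G+C content
  (G+C counted over ACGT bases only).

Correlations with fewer than three complete pairs or a zero-variance
variable are reported as undefined with the reason, never silently
dropped.  Display ordering sorts genomes by δ_CG1 ascending.

## Synthetic genomes

The generator is a first-order Markov chain — the minimal model with
controllable dinucleotide content.  The base matrix has identical rows
matched to a target composition ((1−g)/2, g/2, g/2, (1−g)/2) for
`gc_target = g`, i.e. an i.i.d. sequence when undisturbed; the C→G entry
is multiplied by `cg_factor` and T→A by `ta_factor` (both in (0, 1]) and
the affected rows are renormalized.  The realized stationary distribution
(left Perron eigenvector) is recorded on the spec.  Renormalization
partially offsets the nominal factor: at g = 0.5 and cg_factor = 0.2 the
stationary CG probability is 0.3125 of its independence value, not 0.2 —
the exact value is asserted in the tests.  Depleting CG lowers stationary
G+C and depleting TA raises it, which is the mechanism behind the
G+C-correlation analyses.

Defaults emulate the study conditions at desk scale: `gc_target = 0.5`,
genomes of 1 Mb for 6-mer analyses (≈ 244 expected counts per 6-mer, well
into the regime where subset spectra are resolved), groups of 20 genomes
with cg_factor graded linearly 1.0 → 0.2, and an anti-correlated cg/ta
grading for the mutual-inhibition scenario.  Per-genome seeds derive
deterministically from the group seed (`numpy.random.SeedSequence`).  What
the generator does **not** emulate: isochore/repeat structure, coding
constraint, higher-order composition, and inter-chromosome heterogeneity.
Passing tests therefore demonstrate that the pipeline recovers planted
first-order dinucleotide selection, not that any real genome exhibits it.

## Test problem sizes and calibration

Null calibration uses three fixed-seed uniform 1 Mb genomes at k = 6:
every subset δ falls in (0.97, 1.03) (observed scatter < 0.5 %), and the
total-set δ and ρ are exactly 1.  Parameter recovery uses the 20-genome
graded group at L = 1 Mb, k = 6, three-way scheme: δ_CG1 rank-recovers the
true depletion (|Spearman ρ| > 0.9) and the δ_CG1–δ_CG2 and δ_CG1–ρ_CG1
correlations exceed 0.9 and 0.8.  The mutual-inhibition group uses 20
genomes at 500 kb.  Modality reconstruction uses cg_factor = 0.1 at
L = 2 Mb, k = 8: the total spectrum has ≥ 2 peaks while each CG class
spectrum is unimodal.  These sizes resolve every effect tested while
keeping the whole suite around a quarter of a minute of simulation time.

## Known limitations

* k ≤ 13 for partition enumeration and dense counting (memory is 8·4^k
  bytes per count table); disk-backed counting is out of scope.
* The modality heuristic reports peak counts, not a mixture fit; closely
  spaced components merge under the default bandwidth.
* The F-test assumes approximate normality of the separabilities within a
  group; for strongly graded (non-exchangeable) groups it is a screen, not
  a calibrated test.
* The Markov generator cannot hit an arbitrary realized G+C under strong
  depletion; `gc_target` sets the pre-depletion composition and the
  realized stationary value is recorded alongside.
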