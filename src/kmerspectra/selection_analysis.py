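"""Group-level screening of CG and TA independent selection.

A genome's CG (or TA) selection intensity is its CG1 (TA1) separability
δ; selection is called *obvious* when δ exceeds the genome's own background
δ̄₁ (the mean δ of the other 14 XY1 subsets), and *strongly inhibited* when
δ falls a configurable margin below that background.  Across a group of
genomes the module computes the δ–ρ correlation structure (Pearson, two-
tailed), variance screens with F-tests of the CG set against GC/CC/GG and
the TA set against AT/AA/TT, t-based 95% confidence intervals of every δ
and ρ, and correlations of the selection intensities with genomic G+C
content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTable",
    "selection_flags",
    "group_correlations",
    "separability_variance_screen",
    "group_point_estimates",
    "gc_correlation",
    "order_by_cg1",
    "analyze_group",
]

#: δ–ρ pairs screened per genome group, for CG and TA alike.
CORRELATION_PAIRS: tuple[tuple[tuple[str, int, str], tuple[str, int, str]], ...] = tuple(
    (("%s" % xy, a, qa), ("%s" % xy, b, qb))
    for xy in ("CG", "TA")
    for (a, qa), (b, qb) in [
        ((1, "delta"), (1, "rho")),
        ((2, "delta"), (2, "rho")),
        ((1, "delta"), (2, "delta")),
        ((1, "rho"), (2, "rho")),
        ((0, "delta"), (0, "rho")),
    ]
)

_F_TEST_GROUPS = {"CG": ("GC", "CC", "GG"), "TA": ("AT", "AA", "TT")}


def _param(profile, xy: str, cls: int, quantity: str) -> float:
    st = profile.stats.get((xy, cls))
    if st is None:
        return math.nan
    return st.delta if quantity == "delta" else st.rho


def _param_name(xy: str, cls: int, quantity: str) -> str:
    return f"{quantity}_{xy}{cls}"


def selection_flags(profile, margin: float = 0.05) -> dict:
    """CG/TA selection calls for one genome.

    obvious      — δ_XY1 above the background δ̄₁;
    strong inhibition — δ_XY1 below δ̄₁·(1 − margin).

    Returns True/False per flag, or None when δ_XY1 or the background is
    undefined (never silently False).
    """
    bg = profile.background_delta1
    flags: dict = {}
    for xy in ("CG", "TA"):
        d = _param(profile, xy, 1, "delta")
        if math.isnan(d) or math.isnan(bg):
            flags[f"{xy}_obvious"] = None
            flags[f"strong_{xy}_inhibition"] = None
        else:
            flags[f"{xy}_obvious"] = bool(d > bg)
            flags[f"strong_{xy}_inhibition"] = bool(d < bg * (1.0 - margin))
    return flags


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int, str]:
    """Pairwise-complete Pearson r with two-tailed p; reports why undefined."""
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return math.nan, math.nan, n, f"only {n} complete pairs (need >= 3)"
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return math.nan, math.nan, n, "zero variance in one variable"
    r, p = sps.pearsonr(xs, ys)
    return float(r), float(p), n, ""


@dataclass
class GroupTable:
    """Correlation / variance / point-estimate report for one genome group."""

    group_id: str
    members: list[str]
    correlations: pd.DataFrame = field(default_factory=pd.DataFrame)
    variances: pd.DataFrame = field(default_factory=pd.DataFrame)
    f_tests: pd.DataFrame = field(default_factory=pd.DataFrame)
    point_estimates: pd.DataFrame = field(default_factory=pd.DataFrame)
    gc_correlations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def correlation(self, pair: str) -> tuple[float, float]:
        row = self.correlations.set_index("pair").loc[pair]
        return float(row["r"]), float(row["p"])


def group_correlations(profiles: Sequence, group_id: str = "group") -> pd.DataFrame:
    """Pearson r (two-tailed p) for every stated δ–ρ pair across the group.

    Pairs involving class 2 are reported as undefined under the two-way
    scheme rather than dropped, so the report shape is scheme-independent.
    """
    if len(profiles) < 3:
        raise ValueError(f"need at least 3 profiles, got {len(profiles)}")
    rows = []
    for (xy, ca, qa), (_, cb, qb) in CORRELATION_PAIRS:
        x = np.array([_param(p, xy, ca, qa) for p in profiles])
        y = np.array([_param(p, xy, cb, qb) for p in profiles])
        r, p, n, reason = _pearson(x, y)
        rows.append(
            {
                "pair": f"{_param_name(xy, ca, qa)}-{_param_name(xy, cb, qb)}",
                "r": r,
                "p": p,
                "n": n,
                "note": reason,
            }
        )
    return pd.DataFrame(rows)


def separability_variance_screen(
    profiles: Sequence, cls: int = 1, group_id: str = "group"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variance of each XY separability across the group, plus F-tests.

    The F-test compares the CG variance against each of GC/CC/GG and the TA
    variance against each of AT/AA/TT (the paired/complementary sets, whose
    composition is closest), two-tailed, larger variance in the numerator.
    """
    from .xy_classify import DINUCLEOTIDES

    if len(profiles) < 3:
        raise ValueError(f"need at least 3 profiles, got {len(profiles)}")
    series: dict[str, np.ndarray] = {}
    var_rows = []
    for xy in DINUCLEOTIDES:
        vals = np.array([_param(p, xy, cls, "delta") for p in profiles])
        vals = vals[~np.isnan(vals)]
        series[xy] = vals
        var_rows.append(
            {
                "xy": xy,
                "class": cls,
                "n": int(vals.size),
                "variance": float(vals.var(ddof=1)) if vals.size >= 2 else math.nan,
            }
        )
    variances = pd.DataFrame(var_rows)

    f_rows = []
    for focal, others in _F_TEST_GROUPS.items():
        for other in others:
            a, b = series[focal], series[other]
            row = {"focal": focal, "other": other, "class": cls,
                   "n_focal": int(a.size), "n_other": int(b.size)}
            if a.size < 2 or b.size < 2:
                row.update(F=math.nan, p=math.nan, note="too few genomes")
            else:
                va, vb = a.var(ddof=1), b.var(ddof=1)
                if va == 0 and vb == 0:
                    row.update(F=math.nan, p=math.nan, note="both variances zero")
                else:
                    if va >= vb:
                        F, dfn, dfd = (va / vb if vb > 0 else math.inf), a.size - 1, b.size - 1
                    else:
                        F, dfn, dfd = vb / va, b.size - 1, a.size - 1
                    p = min(1.0, 2.0 * float(sps.f.sf(F, dfn, dfd)))
                    row.update(F=float(F), p=p, note="")
            f_rows.append(row)
    return variances, pd.DataFrame(f_rows)


def group_point_estimates(profiles: Sequence, alpha: float = 0.05) -> pd.DataFrame:
    """Group mean and two-sided (1-alpha) t-interval of every δ and ρ."""
    if len(profiles) < 2:
        raise ValueError(f"need at least 2 profiles, got {len(profiles)}")
    from .xy_classify import DINUCLEOTIDES

    n_classes = max(p.n_classes for p in profiles)
    rows = []
    for xy in DINUCLEOTIDES:
        for cls in range(n_classes):
            for quantity in ("delta", "rho"):
                vals = np.array([_param(p, xy, cls, quantity) for p in profiles])
                vals = vals[~np.isnan(vals)]
                row = {"parameter": _param_name(xy, cls, quantity), "n": int(vals.size)}
                if vals.size < 2:
                    row.update(mean=math.nan, ci_low=math.nan, ci_high=math.nan)
                else:
                    m = float(vals.mean())
                    se = float(vals.std(ddof=1) / math.sqrt(vals.size))
                    tcrit = float(sps.t.ppf(1 - alpha / 2, vals.size - 1))
                    row.update(mean=m, ci_low=m - tcrit * se, ci_high=m + tcrit * se)
                rows.append(row)
    return pd.DataFrame(rows)


def gc_correlation(profiles: Sequence) -> pd.DataFrame:
    """Pearson r/p of each selection parameter against genomic G+C content."""
    if len(profiles) < 3:
        raise ValueError(f"need at least 3 profiles, got {len(profiles)}")
    gc = np.array([p.gc_content for p in profiles])
    rows = []
    for xy in ("CG", "TA"):
        for cls in (1, 2):
            for quantity in ("delta", "rho"):
                vals = np.array([_param(p, xy, cls, quantity) for p in profiles])
                r, pval, n, reason = _pearson(vals, gc)
                rows.append(
                    {
                        "parameter": _param_name(xy, cls, quantity),
                        "r": r,
                        "p": pval,
                        "n": n,
                        "note": reason,
                    }
                )
    return pd.DataFrame(rows)


def order_by_cg1(profiles: Sequence) -> list:
    """Profiles sorted by δ_CG1 ascending (the standard display ordering)."""
    return sorted(profiles, key=lambda p: (math.isnan(_param(p, "CG", 1, "delta")),
                                           _param(p, "CG", 1, "delta")))


def analyze_group(profiles: Sequence, group_id: str = "group") -> GroupTable:
    """Full group report: correlations, variance screen, CIs, G+C relations."""
    variances, ftests = separability_variance_screen(profiles, cls=1, group_id=group_id)
    table = GroupTable(
        group_id=group_id,
        members=[p.genome_id for p in profiles],
        correlations=group_correlations(profiles, group_id),
        variances=variances,
        f_tests=ftests,
        point_estimates=group_point_estimates(profiles),
        gc_correlations=gc_correlation(profiles),
    )
    return table
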