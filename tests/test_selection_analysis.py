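"""Selection flags and group-level correlation / variance / CI analysis."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import kmerspectra as ks
from kmerspectra.spectrum_stats import GenomeProfile, SubsetStats


def make_profile(genome_id="g", gc=50.0, background=1.0, **params):
    """Stub profile from named parameters like delta_CG1=1.4, rho_CG2=2.0."""
    stats = {"total": SubsetStats("total", 4096, 1.0, 1.0, 1.0, 1.0)}
    for xy in ks.DINUCLEOTIDES:
        for cls in (0, 1, 2):
            d = params.get(f"delta_{xy}{cls}", 1.0)
            r = params.get(f"rho_{xy}{cls}", 1.0)
            stats[(xy, cls)] = SubsetStats(f"{xy}{cls}", 100, 1.0, 1.0, d, r)
    prof = GenomeProfile(
        genome_id=genome_id, k=6, scheme="three-way", gc_content=gc,
        stats=stats, background_delta1=background,
    )
    prof.flags = ks.selection_flags(prof)
    return prof


class TestSelectionFlags:
    def test_obvious_and_strong_inhibition(self):
        prof = make_profile(delta_CG1=1.4, delta_TA1=0.9, background=1.0)
        flags = ks.selection_flags(prof)
        assert flags["CG_obvious"] is True
        assert flags["TA_obvious"] is False
        assert flags["strong_TA_inhibition"] is True  # 0.9 < 1.0 * 0.95
        assert flags["strong_CG_inhibition"] is False

    def test_boundary_sets_no_flags(self):
        prof = make_profile(delta_CG1=1.0, delta_TA1=1.0, background=1.0)
        flags = ks.selection_flags(prof)
        assert not any(flags.values())

    def test_margin_is_configurable(self):
        prof = make_profile(delta_TA1=0.9, background=1.0)
        assert ks.selection_flags(prof, margin=0.15)["strong_TA_inhibition"] is False

    def test_undefined_inputs_give_none_not_false(self):
        prof = make_profile(delta_CG1=math.nan)
        flags = ks.selection_flags(prof)
        assert flags["CG_obvious"] is None
        assert flags["strong_CG_inhibition"] is None

    def test_depleted_synthetic_genome_flagged(self, depleted_genome):
        _, prof = depleted_genome
        assert prof.flags["CG_obvious"] is True


class TestGroupCorrelations:
    def test_identical_delta_rho_gives_r_one(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1.0, 2.0, 10)
        profiles = [make_profile(genome_id=f"g{i}", delta_CG1=v, rho_CG1=v)
                    for i, v in enumerate(vals)]
        frame = ks.group_correlations(profiles).set_index("pair")
        assert frame.loc["delta_CG1-rho_CG1", "r"] == pytest.approx(1.0)

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ks.group_correlations([make_profile(), make_profile()])

    def test_constant_variable_reported_undefined_with_reason(self):
        profiles = [make_profile(genome_id=f"g{i}", delta_CG1=1.0) for i in range(5)]
        frame = ks.group_correlations(profiles).set_index("pair")
        row = frame.loc["delta_CG1-rho_CG1"]
        assert math.isnan(row["r"]) and row["note"] != ""

    def test_p_values_match_permutation_estimate(self):
        """Analytic two-tailed p agrees with a permutation test at n = 20."""
        rng = np.random.default_rng(10)
        x = rng.normal(size=20)
        y = 0.6 * x + rng.normal(size=20)
        profiles = [make_profile(genome_id=f"g{i}", delta_CG1=1.5 + 0.1 * xi,
                                 rho_CG1=1.5 + 0.1 * yi)
                    for i, (xi, yi) in enumerate(zip(x, y))]
        frame = ks.group_correlations(profiles).set_index("pair")
        r_obs, p_analytic = frame.loc["delta_CG1-rho_CG1", ["r", "p"]]
        perm_rng = np.random.default_rng(11)
        n_perm = 1000
        hits = sum(
            abs(sps.pearsonr(x, perm_rng.permutation(y)).statistic) >= abs(r_obs)
            for _ in range(n_perm)
        )
        p_perm = hits / n_perm
        mc_err = 3 * math.sqrt(max(p_perm, 1 / n_perm) / n_perm)
        assert abs(p_analytic - p_perm) < max(mc_err, 0.02)


class TestVarianceScreen:
    def test_identical_profiles_zero_variance(self):
        profiles = [make_profile(genome_id=f"g{i}") for i in range(5)]
        variances, ftests = ks.separability_variance_screen(profiles)
        assert (variances["variance"] == 0).all()
        assert ftests["note"].eq("both variances zero").all()

    def test_equal_variance_null_f_near_one(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(1.5, 0.1, 200), rng.normal(1.5, 0.1, 200)
        profiles = [make_profile(genome_id=f"g{i}", delta_CG1=ai, delta_GC1=bi)
                    for i, (ai, bi) in enumerate(zip(a, b))]
        _, ftests = ks.separability_variance_screen(profiles)
        row = ftests.set_index(["focal", "other"]).loc[("CG", "GC")]
        assert row["F"] == pytest.approx(1.0, rel=0.3)
        assert row["p"] > 0.05

    def test_cg_graded_group_has_excess_cg_variance(self, graded_group):
        profiles, _ = graded_group
        variances, ftests = ks.separability_variance_screen(profiles)
        v = variances.set_index("xy")["variance"]
        assert v["CG"] > v["GC"]
        row = ftests.set_index(["focal", "other"]).loc[("CG", "GC")]
        assert row["p"] < 0.05


class TestPointEstimates:
    def test_constant_values_zero_width(self):
        profiles = [make_profile(genome_id=f"g{i}", delta_CG1=1.0) for i in range(3)]
        frame = ks.group_point_estimates(profiles).set_index("parameter")
        row = frame.loc["delta_CG1"]
        assert row["mean"] == 1.0
        assert row["ci_low"] == row["ci_high"] == 1.0

    def test_two_point_interval_uses_t_quantile(self):
        """{0, 2}: mean 1, SE 1, t(0.975, df=1) = 12.706 -> CI = 1 ± 12.706."""
        profiles = [make_profile(genome_id="a", delta_CG1=0.0),
                    make_profile(genome_id="b", delta_CG1=2.0)]
        frame = ks.group_point_estimates(profiles).set_index("parameter")
        row = frame.loc["delta_CG1"]
        assert row["mean"] == pytest.approx(1.0)
        assert row["ci_high"] == pytest.approx(1 + 12.706, abs=0.001)
        assert row["ci_low"] == pytest.approx(1 - 12.706, abs=0.001)

    def test_interval_covers_group_mean(self):
        frame = ks.group_point_estimates(
            [make_profile(genome_id=f"g{i}", delta_CG1=v)
             for i, v in enumerate([1.0, 1.2, 1.4, 1.6])]
        ).set_index("parameter")
        row = frame.loc["delta_CG1"]
        assert row["ci_low"] <= row["mean"] <= row["ci_high"]

    def test_ci_coverage_on_simulated_groups(self):
        """~95% nominal coverage: >= 90% of 100 simulated groups cover truth."""
        rng = np.random.default_rng(17)
        covered = 0
        for _ in range(100):
            vals = rng.normal(1.5, 0.2, 8)
            m = vals.mean()
            se = vals.std(ddof=1) / math.sqrt(len(vals))
            t = sps.t.ppf(0.975, len(vals) - 1)
            covered += (m - t * se) <= 1.5 <= (m + t * se)
        assert covered >= 90


class TestGcCorrelation:
    def test_constant_gc_reported_undefined(self):
        profiles = [make_profile(genome_id=f"g{i}", gc=42.0,
                                 delta_CG1=1.0 + 0.1 * i) for i in range(5)]
        frame = ks.gc_correlation(profiles).set_index("parameter")
        row = frame.loc["delta_CG1"]
        assert math.isnan(row["r"]) and "variance" in row["note"]

    def test_signs_on_anti_correlated_group(self, anti_group):
        profiles, _ = anti_group
        frame = ks.gc_correlation(profiles).set_index("parameter")
        assert frame.loc["delta_CG1", "r"] < 0
        assert frame.loc["delta_TA1", "r"] > 0


class TestOrdering:
    def test_sorted_by_cg1_ascending(self):
        profiles = [make_profile(genome_id=f"g{i}", delta_CG1=v)
                    for i, v in enumerate([1.5, 0.9, 1.2])]
        ordered = ks.order_by_cg1(profiles)
        assert [p.genome_id for p in ordered] == ["g1", "g2", "g0"]


def test_analyze_group_full_report(graded_group):
    profiles, _ = graded_group
    table = ks.analyze_group(profiles, group_id="graded")
    assert len(table.members) == 20
    assert not table.correlations.empty
    assert (table.correlations["r"].dropna().abs() <= 1).all()
    assert (table.f_tests["p"].dropna() <= 1).all()
    est = table.point_estimates.dropna()
    assert (est["ci_low"] <= est["mean"]).all() and (est["mean"] <= est["ci_high"]).all()
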