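"""Population statistics: summaries, inclusion rule, log-normality, groups,
axial orientation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_

from cereplaq._exceptions import DomainError
from cereplaq import stats as st
from cereplaq.morphometry import MorphRecord


def records_with_sphericity(values, region="all"):
    return [MorphRecord(object_id=i, region=region, sphericity=float(s))
            for i, s in enumerate(values)]


def axes_in_cap(rng, n, alpha_deg, about=(1.0, 0.0, 0.0)):
    """Unit axes uniform over the spherical cap of semi-angle alpha."""
    c = rng.uniform(math.cos(math.radians(alpha_deg)), 1.0, n)
    s = np.sqrt(1 - c * c)
    phi = rng.uniform(0, 2 * np.pi, n)
    local = np.stack([c, s * np.cos(phi), s * np.sin(phi)], axis=1)
    p = np.asarray(about) / np.linalg.norm(about)
    helper = np.array([0.0, 1.0, 0.0]) if abs(p[0]) > 0.9 else np.array([1.0, 0, 0])
    e1 = np.cross(p, helper); e1 /= np.linalg.norm(e1)
    e2 = np.cross(p, e1)
    return local @ np.stack([p, e1, e2])


class TestSummarize:
    def test_constant_sample_flagged(self):
        s = st.summarize([1.0, 1.0, 1.0])
        assert (s.mean, s.std, s.skewness) == (1.0, 0.0, 0.0)
        assert s.skewness_flag

    def test_symmetric_sample_zero_skew(self):
        assert st.summarize([1.0, 2.0, 3.0]).skewness == pytest.approx(0.0)

    def test_outlier_gives_positive_skew_matching_moment_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        s = st.summarize(x)
        n, m = len(x), x.mean()
        g1 = ((x - m) ** 3).mean() / (((x - m) ** 2).mean()) ** 1.5
        adj = math.sqrt(n * (n - 1)) / (n - 2) * g1
        assert s.skewness == pytest.approx(adj, rel=1e-12)
        assert s.skewness > 0

    def test_empty_errors(self):
        with pytest.raises(DomainError):
            st.summarize([])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st_.lists(st_.floats(-1e3, 1e3), min_size=2, max_size=50))
    def test_matches_brute_force_moments(self, values):
        s = st.summarize(values)
        x = np.asarray(values)
        assert s.mean == pytest.approx(x.sum() / len(x), abs=1e-9)
        var = ((x - x.mean()) ** 2).sum() / (len(x) - 1)
        assert s.std == pytest.approx(math.sqrt(var), abs=1e-9)
        qs = sorted(s.quantiles.values())
        assert qs == sorted(qs)  # non-decreasing


class TestSelectElongated:
    def test_cutoff_uses_reported_population_values(self):
        # with mean 0.82 and std 0.07 the cutoff is 0.89
        recs = records_with_sphericity([0.85, 0.95, 0.889, 0.891])
        summary = st.StatsSummary(n=4, mean=0.82, std=0.07, skewness=0.0, quantiles={0.5: 0.82})
        kept = st.select_elongated(recs, summary)
        assert [r.sphericity for r in kept] == [0.85, 0.889]

    def test_degenerate_all_equal_gives_empty(self):
        recs = records_with_sphericity([0.8] * 5)
        kept = st.select_elongated(recs, st.summarize([r.sphericity for r in recs]))
        assert kept == []  # strict inequality at cutoff == mean

    def test_gaussian_fraction_matches_phi_of_one(self):
        rng = np.random.default_rng(2024)
        s = rng.normal(0.82, 0.07, 500)
        s = np.clip(s, 1e-3, 1.0)
        recs = records_with_sphericity(s)
        kept = st.select_elongated(recs, st.summarize(list(s)))
        frac = len(kept) / len(recs)
        assert abs(frac - 0.8413) <= 0.04

    def test_filter_is_idempotent_subset(self):
        rng = np.random.default_rng(8)
        recs = records_with_sphericity(rng.uniform(0.5, 1.0, 40))
        summary = st.summarize([r.sphericity for r in recs])
        once = st.select_elongated(recs, summary)
        twice = st.select_elongated(once, summary)
        assert twice == once
        assert set(id(r) for r in once) <= set(id(r) for r in recs)


class TestLogNormalCheck:
    def test_lognormal_sample_small_ks(self):
        rng = np.random.default_rng(77)
        v = rng.lognormal(math.log(1000), 1.2, 500)
        assert st.lognormal_check(v).ks_statistic <= 0.06

    def test_uniform_sample_larger_ks(self):
        rng = np.random.default_rng(77)
        ln = st.lognormal_check(rng.lognormal(math.log(1000), 1.2, 500)).ks_statistic
        un = st.lognormal_check(rng.uniform(1e3, 2e3, 500)).ks_statistic
        assert un > ln

    def test_reference_density_is_moment_matched(self):
        rng = np.random.default_rng(1)
        chk = st.lognormal_check(rng.lognormal(7.0, 1.0, 200))
        logs = np.log(rng.lognormal(7.0, 1.0, 200))  # fresh draw, same family
        assert chk.log_std > 0
        centers = 0.5 * (chk.hist_bin_edges[:-1] + chk.hist_bin_edges[1:])
        peak = chk.reference_density.max()
        assert peak == pytest.approx(1 / (chk.log_std * math.sqrt(2 * math.pi)), rel=0.01)

    def test_degenerate_and_domain_errors(self):
        with pytest.raises(DomainError):
            st.lognormal_check([100.0] * 50)
        with pytest.raises(DomainError):
            st.lognormal_check([1.0, -2.0] * 10)
        with pytest.raises(DomainError):
            st.lognormal_check([1.0] * 5)


class TestCompareGroups:
    def test_identical_tiny_groups_p_one(self):
        _, p = st.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_3v3_exact_minimum(self):
        # 20 arrangements of 3+3; the two extreme ones give p = 0.1
        _, p = st.compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert p == pytest.approx(0.1)

    def test_insufficient_n_errors(self):
        with pytest.raises(DomainError):
            st.compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_large_sample_separation_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.82, 0.07, 60)
        b = rng.normal(0.94, 0.05, 60)
        _, p = st.compare_groups(a, b)
        assert p < 0.05

    def test_exact_and_asymptotic_agree_moderately(self):
        rng = np.random.default_rng(6)
        a = list(rng.normal(0, 1, 8))
        b = list(rng.normal(0.5, 1, 8))
        _, p_exact = st.compare_groups(a, b)
        _, p_asym = st.compare_groups(a + a[:1], b + b[:1])  # push onto asymptotic path
        assert 0 < p_exact <= 1 and 0 < p_asym <= 1


class TestOrientationSummary:
    def test_identical_axes_zero_deviation(self):
        recs = []
        for i in range(10):
            recs.append(MorphRecord(object_id=i, region="h", sphericity=0.8,
                                    principal_axis=(1.0, 0.0, 0.0)))
        out = st.orientation_summary(recs)["h"]
        assert out.deviation_p50_deg == pytest.approx(0.0, abs=1e-6)
        assert out.deviation_p90_deg == pytest.approx(0.0, abs=1e-6)

    def test_uniform_cap_percentile_order_statistics(self):
        # uniform axes in a 30-degree cone: F(t) = (1-cos t)/(1-cos 30),
        # 90th percentile deviation = 28.4 degrees
        rng = np.random.default_rng(11)
        axes = axes_in_cap(rng, 200, 30.0)
        recs = [MorphRecord(object_id=i, region="h", sphericity=0.8,
                            principal_axis=tuple(a)) for i, a in enumerate(axes)]
        out = st.orientation_summary(recs)["h"]
        assert 25.0 <= out.deviation_p90_deg <= 30.0
        assert abs(np.dot(out.mean_axis, [1.0, 0.0, 0.0])) >= 0.98

    def test_sign_flips_leave_statistics_unchanged(self):
        rng = np.random.default_rng(12)
        axes = axes_in_cap(rng, 60, 40.0, about=(0.0, 1.0, 0.0))
        flips = rng.random(60) < 0.5
        flipped = axes * np.where(flips, -1.0, 1.0)[:, None]
        out1 = st.orientation_summary(
            [MorphRecord(object_id=i, region="v", sphericity=0.8,
                         principal_axis=tuple(a)) for i, a in enumerate(axes)])["v"]
        out2 = st.orientation_summary(
            [MorphRecord(object_id=i, region="v", sphericity=0.8,
                         principal_axis=tuple(a)) for i, a in enumerate(flipped)])["v"]
        assert abs(np.dot(out1.mean_axis, out2.mean_axis)) == pytest.approx(1.0, abs=1e-9)
        assert out1.deviation_p90_deg == pytest.approx(out2.deviation_p90_deg, abs=1e-9)
        np.testing.assert_allclose(out1.hist_counts, out2.hist_counts)

    def test_tie_flagged_records_ignored_and_empty_group_skipped(self):
        recs = [MorphRecord(object_id=0, region="h", sphericity=0.8,
                            principal_axis=(1.0, 0.0, 0.0), axis_tie_flag=True)]
        assert st.orientation_summary(recs) == {}

    def test_orientation_tensor_matches_characteristic_polynomial(self):
        """Tensor eigen-decomposition vs cubic-root reference solver."""
        rng = np.random.default_rng(13)
        axes = rng.standard_normal((30, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        t = st.orientation_tensor(axes)
        # reference: roots of the characteristic polynomial of t
        c2 = -np.trace(t)
        c1 = 0.5 * (np.trace(t) ** 2 - np.trace(t @ t))
        c0 = -np.linalg.det(t)
        roots = np.sort(np.roots([1.0, c2, c1, c0]).real)
        evals = np.sort(np.linalg.eigvalsh(t))
        assert np.allclose(roots, evals, atol=1e-10)
        mean = st.mean_axis_of(axes)
        assert t @ mean == pytest.approx(evals[-1] * mean, abs=1e-10)

    def test_histogram_counts_both_antipodal_clusters(self):
        rng = np.random.default_rng(14)
        axes = axes_in_cap(rng, 50, 10.0)  # near +DV
        out = st.orientation_summary(
            [MorphRecord(object_id=i, region="h", sphericity=0.8,
                         principal_axis=tuple(a)) for i, a in enumerate(axes)])["h"]
        az_centers = 0.5 * (out.hist_azimuth_edges[:-1] + out.hist_azimuth_edges[1:])
        counts_by_az = out.hist_counts.sum(axis=1)
        near_zero = counts_by_az[np.abs(az_centers) < 30].sum()
        near_180 = counts_by_az[np.abs(np.abs(az_centers) - 180) < 30].sum()
        assert near_zero > 0 and near_180 > 0  # paired clusters at 0 and +-180
        assert near_zero + near_180 == 2 * 50
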