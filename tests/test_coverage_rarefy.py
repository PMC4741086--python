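"""Coverage estimation, completeness curves, rarefaction/extrapolation.

The q = 0 rarefaction formula is checked against an exhaustive oracle that
averages the number of distinct taxa over every possible subsample (all
C(n, m) index subsets) of small toy samples.
"""

import itertools

import numpy as np
import pytest

from divadj import (
    completeness_curve,
    coverage_at_m,
    coverage_at_n,
    coverage_based_curve,
    default_size_grid,
    from_abundances,
    hill_empirical,
    invert_coverage,
    rarefy_extrapolate,
    shannon_asymptotic,
    simpson_asymptotic,
)
from divadj.exceptions import (
    InsufficientDataError,
    UnreachableCoverageError,
    UnsupportedOrderError,
)


def exhaustive_expected_richness(abundances, m):
    """Oracle: mean distinct-taxon count over all C(n, m) subsamples."""
    individuals = [taxon for taxon, x in enumerate(abundances) for _ in range(x)]
    subsets = itertools.combinations(range(len(individuals)), m)
    total, count = 0, 0
    for subset in subsets:
        total += len({individuals[i] for i in subset})
        count += 1
    return total / count


class TestCoverage:
    def test_adjusted_swine_published(self, swine_adj):
        assert round(100 * coverage_at_n(swine_adj), 1) == 41.0

    def test_adjusted_reclaimed_published(self, reclaimed_adj):
        assert round(100 * coverage_at_n(reclaimed_adj), 1) == 48.6

    @pytest.mark.parametrize(
        "fixture, expected", [("swine_adj", 62.9), ("reclaimed_adj", 74.7)]
    )
    def test_extrapolated_to_10000_published(self, request, fixture, expected):
        sample = request.getfixturevalue(fixture)
        assert round(100 * coverage_at_m(sample, 10_000), 1) == expected

    def test_no_singletons_means_complete(self):
        assert coverage_at_n(from_abundances([5, 3, 2])) == 1.0

    def test_m1_closed_form(self, swine_adj):
        # C(n-k, 1)/C(n-1, 1) = (n-k)/(n-1), so the rarefied-coverage sum
        # collapses to a ratio of moments at m = 1
        n = swine_adj.n_adjusted
        ks, fs = swine_adj.adjusted.arrays()
        expected = 1 - float(np.sum(fs * (ks / n) * (n - ks) / (n - 1)))
        assert coverage_at_m(swine_adj, 1) == pytest.approx(expected, rel=1e-9)

    def test_continuous_at_observed_size(self, swine_adj):
        # the extrapolation formula at m* = 0 equals the observed-size value
        n = swine_adj.n_adjusted
        fc = swine_adj.adjusted
        f1, f2 = fc.f(1), fc.f(2)
        ratio = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
        assert 1 - (f1 / n) * ratio == pytest.approx(coverage_at_n(swine_adj), rel=1e-12)

    def test_monotone_and_bounded(self, swine_adj):
        grid = default_size_grid(swine_adj.n_adjusted, 12_000)
        cov = [coverage_at_m(swine_adj, int(m)) for m in grid]
        assert all(b >= a - 1e-12 for a, b in zip(cov, cov[1:]))
        assert all(0.0 <= c <= 1.0 for c in cov)

    def test_bad_size_rejected(self, swine_adj):
        with pytest.raises(InsufficientDataError):
            coverage_at_m(swine_adj, 0)


class TestRarefyQ0:
    @pytest.mark.parametrize("abund", [(3, 1, 1, 2), (4, 3, 2, 1), (6, 4, 2)])
    def test_interpolation_matches_exhaustive_oracle(self, abund):
        fc = from_abundances(list(abund))
        n = fc.n
        assert n <= 12
        for m in range(1, n + 1):
            (pt,) = rarefy_extrapolate(fc, 0, [m])
            assert pt.value == pytest.approx(
                exhaustive_expected_richness(abund, m), rel=1e-10
            )

    def test_m1_is_one_taxon(self, swine_adj, reclaimed_adj):
        for sample in (swine_adj, reclaimed_adj):
            (pt,) = rarefy_extrapolate(sample, 0, [1])
            assert pt.value == pytest.approx(1.0, rel=1e-9)

    def test_observed_point(self, swine_adj):
        n = swine_adj.n_adjusted
        (pt,) = rarefy_extrapolate(swine_adj, 0, [n])
        assert pt.value == swine_adj.adjusted.s_obs
        assert pt.segment == "observed"

    def test_extrapolation_approaches_adjusted_chao1(self, swine_adj):
        from divadj import chao1_adjusted

        (pt,) = rarefy_extrapolate(swine_adj, 0, [60 * swine_adj.n_adjusted])
        assert pt.value == pytest.approx(chao1_adjusted(swine_adj).estimate, rel=0.01)


class TestRarefyQ1Q2:
    def test_q1_continuous_at_observed_size(self, swine_adj):
        n = swine_adj.n_adjusted
        vals = {m: rarefy_extrapolate(swine_adj, 1, [m])[0].value for m in (n - 1, n, n + 1)}
        emp = hill_empirical(swine_adj.adjusted, 1.0)
        assert vals[n] == pytest.approx(emp, rel=1e-9)
        assert vals[n - 1] == pytest.approx(emp, rel=1e-3)
        assert vals[n + 1] == pytest.approx(emp, rel=1e-3)

    def test_q1_extrapolation_converges_to_asymptote(self, swine_adj):
        (pt,) = rarefy_extrapolate(swine_adj, 1, [400 * swine_adj.n_adjusted])
        assert pt.value == pytest.approx(shannon_asymptotic(swine_adj), rel=0.01)

    def test_q2_observed_equals_empirical(self, swine_adj):
        n = swine_adj.n_adjusted
        (pt,) = rarefy_extrapolate(swine_adj, 2, [n])
        assert round(pt.value) == 2742
        assert pt.value == pytest.approx(hill_empirical(swine_adj.adjusted, 2.0), rel=1e-12)

    def test_q2_limit_is_asymptote(self, swine_adj):
        (pt,) = rarefy_extrapolate(swine_adj, 2, [50_000_000])
        assert pt.value == pytest.approx(simpson_asymptotic(swine_adj), rel=1e-3)
        assert round(simpson_asymptotic(swine_adj)) == 6404

    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_curves_non_decreasing(self, swine_adj, q):
        pts = rarefy_extrapolate(swine_adj, q, default_size_grid(swine_adj.n_adjusted))
        vals = [pt.value for pt in pts]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_unsupported_order(self, swine_adj):
        with pytest.raises(UnsupportedOrderError):
            rarefy_extrapolate(swine_adj, 3, [10])


class TestCoverageStandardization:
    def test_inverting_observed_coverage_recovers_observed_point(self, swine_adj):
        target = coverage_at_n(swine_adj)
        m = invert_coverage(swine_adj, target)
        assert m == swine_adj.n_adjusted

    def test_target_0629_lands_near_10000(self, swine_adj):
        m = invert_coverage(swine_adj, 0.629)
        assert abs(m - 10_000) < 60

    def test_monotone_targets_give_monotone_sizes(self, reclaimed_adj):
        targets = np.linspace(0.30, 0.74, 12)
        sizes = [invert_coverage(reclaimed_adj, float(t)) for t in targets]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_inversion_returns_smallest_size(self, swine_adj):
        for target in (0.30, 0.45, 0.55):
            m = invert_coverage(swine_adj, target)
            assert coverage_at_m(swine_adj, m) >= target
            if m > 1:
                assert coverage_at_m(swine_adj, m - 1) < target

    def test_curve_points_reach_targets(self, swine_adj):
        targets = [0.3, 0.41, 0.55, 0.629]
        pts = coverage_based_curve(swine_adj, 0, targets)
        for pt, t in zip(pts, targets):
            assert pt.coverage >= t - 1e-9
        vals = [pt.value for pt in pts]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_unreachable_target_rejected(self, swine_adj):
        with pytest.raises(UnreachableCoverageError):
            invert_coverage(swine_adj, 1.0)


class TestCompletenessCurve:
    def test_segments_and_published_endpoint(self, swine_adj):
        pts = completeness_curve(swine_adj, [1, swine_adj.n_adjusted, 10_000])
        assert [pt.segment for pt in pts] == ["interpolated", "observed", "extrapolated"]
        assert round(100 * pts[1].coverage, 1) == 41.0
        assert round(100 * pts[2].coverage, 1) == 62.9

    def test_default_grid_spans_double_n(self, swine_adj):
        pts = completeness_curve(swine_adj)
        assert pts[-1].m == 2 * swine_adj.n_adjusted
        cov = [pt.coverage for pt in pts]
        assert all(b >= a - 1e-12 for a, b in zip(cov, cov[1:]))


class TestTwoSampleOrdering:
    """Adjusted swine diversity exceeds adjusted reclaimed-water diversity at
    every common size and every common coverage, for q = 0, 1, 2."""

    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_size_standardized(self, swine_adj, reclaimed_adj, q):
        grid = default_size_grid(min(swine_adj.n_adjusted, reclaimed_adj.n_adjusted), 10_000)
        sw = rarefy_extrapolate(swine_adj, q, grid)
        rw = rarefy_extrapolate(reclaimed_adj, q, grid)
        for a, b in zip(sw, rw):
            if a.m >= 2:  # both curves start at 1 taxon for m = 1
                assert a.value > b.value

    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_coverage_standardized(self, swine_adj, reclaimed_adj, q):
        targets = np.linspace(0.15, 0.62, 8)
        sw = coverage_based_curve(swine_adj, q, targets)
        rw = coverage_based_curve(reclaimed_adj, q, targets)
        for a, b in zip(sw, rw):
            assert a.value > b.value
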