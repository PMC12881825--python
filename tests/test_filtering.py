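"""Filter 1/2 semantics and whisker-bounded boxplot statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mspscan.filtering import (Params, SiteStats, filter1_control_sites,
                               filter2_differentiating, group_percentiles,
                               differentiating_sites)
from mspscan.errors import ConfigError

from conftest import make_table


def brute_force_boxstats(values):
    """Independent oracle: sort, type-7 interpolation, fence scan."""
    xs = sorted(v for v in values if not math.isnan(v))
    n = len(xs)
    if n == 0:
        return None

    def q(frac):
        h = (n - 1) * frac
        lo, hi = math.floor(h), math.ceil(h)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    p25, p50, p75 = q(0.25), q(0.5), q(0.75)
    iqr = p75 - p25
    p0 = min(x for x in xs if x >= p25 - 1.5 * iqr)
    p100 = max(x for x in xs if x <= p75 + 1.5 * iqr)
    return p0, p25, p50, p75, p100, n


class TestGroupPercentiles:
    def test_constant_vector_collapses_to_one_value(self):
        b = group_percentiles([0, 0, 0, 0])
        assert (b.p0, b.p25, b.p50, b.p75, b.p100) == (0, 0, 0, 0, 0)
        assert b.n == 4 and b.iqr == 0

    def test_type7_quartiles_and_fences(self):
        b = group_percentiles([10, 20, 30, 40])
        assert (b.p25, b.p50, b.p75) == (17.5, 25.0, 32.5)
        assert b.iqr == 15.0
        assert (b.p0, b.p100) == (10.0, 40.0)

    def test_extreme_outlier_excluded_from_whisker(self):
        b = group_percentiles([0, 0, 0, 100])
        assert (b.p25, b.p75) == (0.0, 25.0)
        # upper fence 25 + 1.5*25 = 62.5, so 100 is an outlier
        assert b.p100 == 0.0
        assert b.p0 == 0.0

    def test_missing_values_are_dropped(self):
        with_nan = group_percentiles([float("nan"), 10, 20, 30])
        without = group_percentiles([10, 20, 30])
        assert with_nan == without

    def test_degenerate_sizes(self):
        empty = group_percentiles([])
        assert empty.n == 0 and math.isnan(empty.p50)
        one = group_percentiles([42.0])
        assert (one.p0, one.p25, one.p50, one.p75, one.p100) == (42.0,) * 5

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 21))
            vals = rng.uniform(0, 100, size=n)
            n_miss = int(rng.integers(0, max(1, int(0.3 * n)) + 1))
            vals[rng.choice(n, size=n_miss, replace=False)] = np.nan
            got = group_percentiles(vals)
            expected = brute_force_boxstats(vals)
            if expected is None:
                assert got.n == 0
                continue
            assert (got.p0, got.p25, got.p50, got.p75, got.p100, got.n) == \
                pytest.approx(expected, abs=1e-12)


def table_with_controls(meths, covs, groups=None):
    rows = []
    for i, (m, c) in enumerate(zip(meths, covs)):
        rows.append(("chr1", 100, "+", f"c{i+1}", c, m))
    rows.append(("chr1", 100, "+", "d1", 10, 90.0))
    groups = groups or {f"c{i+1}": "control" for i in range(len(meths))}
    groups["d1"] = "disease"
    return make_table(rows, groups)


class TestFilter1:
    def test_all_controls_below_ceiling_keeps_site(self):
        t = table_with_controls([5.0, 8.0, 0.0], [5, 5, 5])
        assert len(filter1_control_sites(t, Params())) == 1

    def test_one_control_above_ceiling_removes_site(self):
        t = table_with_controls([5.0, 12.0, 0.0], [5, 5, 5])
        assert len(filter1_control_sites(t, Params())) == 0

    def test_exactly_at_ceiling_is_kept(self):
        t = table_with_controls([10.0, 0.0, 0.0], [5, 5, 5])
        assert len(filter1_control_sites(t, Params())) == 1

    def test_too_few_assessable_controls_removes_site(self):
        # coverages (2,2,5): one assessable < ceil(0.5*3)=2
        t = table_with_controls([0.0, 0.0, 0.0], [2, 2, 5])
        assert len(filter1_control_sites(t, Params())) == 0

    def test_low_coverage_control_cannot_veto(self):
        # the methylated control is below the coverage gate
        t = table_with_controls([0.0, 0.0, 95.0], [5, 5, 2])
        assert len(filter1_control_sites(t, Params())) == 1

    @given(max_meth=st.sampled_from([2.0, 5.0, 10.0, 20.0]),
           min_cov=st.sampled_from([1, 3, 5, 8]))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_tightening_thresholds_never_grows_survivor_set(self, max_meth,
                                                            min_cov):
        rng = np.random.default_rng(7)
        rows = []
        for pos in range(0, 60, 3):
            for i in range(3):
                rows.append(("chr1", pos, "+", f"c{i+1}",
                             int(rng.integers(0, 10)),
                             float(rng.uniform(0, 30))))
            rows.append(("chr1", pos, "+", "d1", 10, 95.0))
        t = make_table(rows, {"c1": "control", "c2": "control",
                              "c3": "control", "d1": "disease"})

        def survivors(mm, mc):
            kept = filter1_control_sites(
                t, Params(max_ctrl_meth=mm, min_ctrl_cov=mc))
            return set(map(tuple, kept.itertuples(index=False)))

        base = survivors(max_meth, min_cov)
        assert survivors(max_meth / 2, min_cov) <= base

    @given(min_cov=st.sampled_from([1, 3, 5, 8]))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_raising_coverage_gate_shrinks_set_without_methylated_controls(
            self, min_cov):
        # with every control below the ceiling the gate acts purely as a
        # quorum, so raising it is monotone; a methylated control can
        # instead be rescued into unassessability, which is intended
        rng = np.random.default_rng(8)
        rows = []
        for pos in range(0, 60, 3):
            for i in range(3):
                rows.append(("chr1", pos, "+", f"c{i+1}",
                             int(rng.integers(0, 10)),
                             float(rng.uniform(0, 9))))
            rows.append(("chr1", pos, "+", "d1", 10, 95.0))
        t = make_table(rows, {"c1": "control", "c2": "control",
                              "c3": "control", "d1": "disease"})

        def survivors(mc):
            kept = filter1_control_sites(t, Params(min_ctrl_cov=mc))
            return set(map(tuple, kept.itertuples(index=False)))

        assert survivors(min_cov + 2) <= survivors(min_cov)


class TestFilter2:
    def box(self, *vals):
        return group_percentiles(vals)

    def test_clear_hypermethylation_passes(self):
        s = SiteStats("chr1", 1, "+", self.box(0, 0, 0), self.box(80, 80, 80))
        assert filter2_differentiating(s)

    def test_median_below_control_whisker_fails(self):
        s = SiteStats("chr1", 1, "+", self.box(5, 20), self.box(15, 15))
        assert not filter2_differentiating(s)

    def test_tie_fails(self):
        s = SiteStats("chr1", 1, "+", self.box(10.0), self.box(10.0))
        assert not filter2_differentiating(s)

    def test_no_disease_data_fails(self):
        s = SiteStats("chr1", 1, "+", self.box(0.0), self.box())
        assert not filter2_differentiating(s)


class TestFilterChain:
    def test_filter2_survivors_subset_of_filter1(self, rng):
        rows = []
        groups = {"c1": "control", "c2": "control", "d1": "disease",
                  "d2": "disease"}
        for pos in range(0, 300, 5):
            for s in groups:
                rows.append(("chr1", pos, "+", s, int(rng.integers(0, 12)),
                             float(rng.uniform(0, 100))))
        t = make_table(rows, groups)
        params = Params()
        f1 = set(map(tuple, filter1_control_sites(t, params)
                     .itertuples(index=False)))
        stats, _ = differentiating_sites(t, params)
        f2 = {(s.chrom, s.pos, s.strand) for s in stats}
        assert f2 <= f1

    def test_clean_separation_always_passes_both_filters(self):
        rows = [("chr1", 50, "+", "c1", 5, 0.0),
                ("chr1", 50, "+", "c2", 5, 0.0),
                ("chr1", 50, "+", "d1", 5, 60.0)]
        t = make_table(rows, {"c1": "control", "c2": "control",
                              "d1": "disease"})
        stats, _ = differentiating_sites(t, Params())
        assert len(stats) == 1


def test_invalid_params_rejected():
    with pytest.raises(ConfigError):
        Params(min_primer_len=30, max_primer_len=24)
    with pytest.raises(ConfigError):
        Params(min_amplicon_len=500, max_amplicon_len=400)
    with pytest.raises(ConfigError):
        Params(min_cpgs=0)
    with pytest.raises(ConfigError):
        Params(min_ctrls_frac=0.0)
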