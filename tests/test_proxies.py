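"""Covariate preparation: period interpolation, min-max merging, splines,
and the generation table."""

import numpy as np
import pytest

from paleodyn.errors import ValidationError
from paleodyn.proxies import (
    GenerationTable,
    PeriodScoreTable,
    ProxySeries,
    build_generation_table,
    interpolate_period_scores,
    normalize_and_merge,
    spline_smooth,
)
from paleodyn.smoothing import dense_spline_solve, smooth_series, spar_to_lambda
from paleodyn.spd import SPDSeries


class TestPeriodScores:
    def test_midpoint_linear_interpolation(self):
        table = PeriodScoreTable(np.array([0.0, 200.0]), np.array([200.0, 400.0]),
                                 np.array([0.0, 1.0]))
        s = interpolate_period_scores(table)
        # midpoints at 100 and 300; AD 200 is halfway
        assert s.interp(200.0) == pytest.approx(0.5)
        assert s.interp(100.0) == pytest.approx(0.0)
        assert s.interp(300.0) == pytest.approx(1.0)

    def test_single_period_constant(self):
        s = interpolate_period_scores(
            PeriodScoreTable(np.array([100.0]), np.array([300.0]), np.array([0.7]))
        )
        assert np.all(s.value == 0.7)

    def test_tent_matches_direct_formula(self):
        table = PeriodScoreTable(np.array([0.0, 100.0, 200.0]),
                                 np.array([100.0, 200.0, 300.0]),
                                 np.array([0.0, 1.0, 0.0]))
        s = interpolate_period_scores(table)
        mids = np.array([50.0, 150.0, 250.0])
        expected = np.interp(s.grid, mids, table.score)
        np.testing.assert_allclose(s.value, expected, atol=1e-12)
        # passes exactly through every period-midpoint score
        np.testing.assert_allclose(s.interp(mids), table.score, atol=1e-12)

    def test_overlapping_periods_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            PeriodScoreTable(np.array([0.0, 150.0]), np.array([200.0, 400.0]),
                             np.array([0.0, 1.0]))


class TestMinMaxMerge:
    def test_minmax_image(self):
        s = ProxySeries(np.array([0.0, 1.0, 2.0]), np.array([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(s.minmax().value, [0.0, 0.5, 1.0])

    def test_symmetric_merge(self):
        a = ProxySeries(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        b = ProxySeries(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        np.testing.assert_allclose(normalize_and_merge(a, b).value, [0.5, 0.5])

    def test_self_merge_idempotent(self):
        a = ProxySeries(np.arange(5.0), np.array([3.0, 1.0, 4.0, 1.0, 5.0]))
        np.testing.assert_allclose(normalize_and_merge(a, a).value, a.minmax().value,
                                   atol=1e-12)

    def test_merge_bounds(self):
        rng = np.random.default_rng(0)
        a = ProxySeries(np.arange(20.0), rng.normal(size=20))
        b = ProxySeries(np.arange(0.5, 19.0), rng.normal(size=19))
        m = normalize_and_merge(a, b)
        assert m.value.min() >= 0.0 and m.value.max() <= 1.0

    def test_constant_series_rejected(self):
        a = ProxySeries(np.arange(3.0), np.ones(3))
        with pytest.raises(ValidationError, match="constant"):
            a.minmax()


class TestSplineSmooth:
    def test_straight_line_unchanged(self):
        t = np.arange(30.0)
        y = 2.0 + 0.3 * t
        for spar in (0.1, 0.65, 1.0):
            s = spline_smooth(ProxySeries(t, y), spar=spar)
            np.testing.assert_allclose(s.value, y, atol=1e-8)

    def test_large_penalty_converges_to_ols_line(self):
        """A line has zero roughness, so the penalty limit is the LS line;
        the fit approaches it monotonically as spar rises."""
        rng = np.random.default_rng(1)
        t = np.arange(50.0)
        y = 1.0 + 0.1 * t + rng.normal(0, 0.5, size=50)
        line = np.polyval(np.polyfit(t, y, 1), t)
        heavy = smooth_series(t, y, lam=1e4)
        np.testing.assert_allclose(heavy, line, atol=1e-4)
        devs = [np.abs(smooth_series(t, y, spar=s) - line).max()
                for s in (0.2, 0.65, 1.0)]
        assert devs[2] < devs[1] < devs[0]

    def test_rss_nondecreasing_in_spar_and_oracle_match(self):
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 100.0)
        y = np.sin(2 * np.pi * t / 40.0) + rng.normal(0, 0.3, size=t.size)
        rss_prev = -1.0
        for spar in (0.2, 0.45, 0.65, 0.9):
            f = smooth_series(t, y, spar=spar)
            rss = float(np.sum((y - f) ** 2))
            assert rss >= rss_prev - 1e-10
            rss_prev = rss
            # independent dense penalised least-squares solve
            lam = spar_to_lambda(t, spar)
            oracle = dense_spline_solve(t, y, lam)
            np.testing.assert_allclose(f, oracle, atol=1e-6)

    def test_linearity_in_data(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 60.0)
        y1, y2 = rng.normal(size=60), rng.normal(size=60)
        lam = spar_to_lambda(t, 0.65)
        combo = smooth_series(t, 2.0 * y1 - 0.5 * y2, lam=lam)
        parts = 2.0 * smooth_series(t, y1, lam=lam) - 0.5 * smooth_series(t, y2, lam=lam)
        np.testing.assert_allclose(combo, parts, atol=1e-8)

    def test_spar_out_of_range(self):
        s = ProxySeries(np.arange(10.0), np.arange(10.0) ** 2)
        with pytest.raises(ValidationError, match="spar"):
            spline_smooth(s, spar=1.5)


class TestGenerationTable:
    def make_spd(self, values, years=None):
        years = np.arange(100.0, 1451.0) if years is None else years
        return SPDSeries(grid=years, value=values, normalized=True, n_bins=1)

    def covs(self):
        g = np.arange(100.0, 1451.0)
        c = ProxySeries(g, np.linspace(0, 1, g.size))
        return c, c, c

    def test_constant_spd_zero_growth(self):
        spd = self.make_spd(np.full(1351, 0.5))
        t = build_generation_table(spd, *self.covs())
        assert np.allclose(t.column("R")[:-1], 0.0)

    def test_doubling_gives_log2(self):
        years = np.arange(100.0, 1451.0)
        value = 0.001 * 2.0 ** ((years - 100.0) / 25.0)
        t = build_generation_table(self.make_spd(value), *self.covs())
        np.testing.assert_allclose(t.column("R")[:-1], np.log(2.0), rtol=1e-9)

    def test_row_and_rate_counts(self):
        t = build_generation_table(self.make_spd(np.full(1351, 0.5)), *self.covs(),
                                   step=25, window=(100, 1450))
        assert len(t) == (1450 - 100) // 25 + 1 == 55
        assert t.n_rates == 54

    def test_growth_rates_telescope(self):
        rng = np.random.default_rng(4)
        value = np.exp(rng.normal(size=1351).cumsum() * 0.01)
        t = build_generation_table(self.make_spd(value), *self.covs())
        X = t.column("X")
        assert np.nansum(t.column("R")) == pytest.approx(X[-1] - X[0], abs=1e-10)

    def test_nonpositive_spd_named_year(self):
        value = np.full(1351, 0.5)
        value[100] = 0.0  # AD 200
        with pytest.raises(ValidationError, match="AD 200"):
            build_generation_table(self.make_spd(value), *self.covs())

    def test_csv_roundtrip(self, tmp_path):
        t = build_generation_table(self.make_spd(np.full(1351, 0.5)), *self.covs())
        p = tmp_path / "table.csv"
        t.to_csv(p)
        back = GenerationTable.from_csv(p)
        np.testing.assert_allclose(back.column("X"), t.column("X"), rtol=1e-12)
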