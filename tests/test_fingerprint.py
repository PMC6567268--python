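import numpy as np
import pandas as pd
import pytest
from scipy import stats

from angioprint.fingerprint import (
    compare_groups,
    compare_parameters,
    compare_slopes,
    fit_fingerprint,
    mann_whitney_normal,
    per_unit_lines,
)


def points_df(xy, unit="u1", stack="s1"):
    return pd.DataFrame(
        [
            {"unit_id": unit, "stack_id": stack, "k": k, "vol_pct": x, "nhv95": y}
            for k, (x, y) in enumerate(xy, start=1)
        ]
    )


EXACT_LINE = points_df([(2, 10), (4, 8), (6, 6), (8, 4), (10, 2), (12, 0)])


class TestFitFingerprint:
    def test_exact_line_recovers_all_parameters(self):
        line = fit_fingerprint(EXACT_LINE)
        assert line.slope == pytest.approx(-1.0)
        assert line.r2 == pytest.approx(1.0)
        assert (line.a, line.b) == (pytest.approx(2.0), pytest.approx(10.0))
        assert (line.e, line.f) == (pytest.approx(12.0), pytest.approx(0.0))
        assert (line.d, line.g) == (pytest.approx(10.0), pytest.approx(10.0))

    def test_horizontal_line(self):
        line = fit_fingerprint(points_df([(2, 5), (4, 5), (6, 5), (8, 5)]))
        assert line.slope == 0.0
        assert line.g == pytest.approx(0.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_fingerprint(points_df([(3, 1), (3, 2)]))

    def test_parameter_identities_and_shift_equivariance(self, rng):
        x = rng.uniform(1, 10, size=12)
        y = 8 - 0.7 * x + rng.normal(0, 0.4, size=12)
        df = points_df(list(zip(x, y)))
        df["k"] = np.tile(np.arange(1, 7), 2)
        base = fit_fingerprint(df)
        assert base.d == pytest.approx(base.e - base.a)
        assert base.g == pytest.approx(base.b - base.f)
        shifted = df.assign(nhv95=df.nhv95 + 3.25)
        moved = fit_fingerprint(shifted)
        assert moved.slope == pytest.approx(base.slope)
        assert moved.r2 == pytest.approx(base.r2)
        assert moved.d == pytest.approx(base.d)
        assert moved.g == pytest.approx(base.g)
        assert moved.b == pytest.approx(base.b + 3.25)
        assert moved.f == pytest.approx(base.f + 3.25)

    def test_noisy_slope_recovered_within_three_standard_errors(self):
        # OLS sampling-distribution oracle: 3 SE covers ~99.7% of replicates
        rng = np.random.default_rng(7)
        x = np.tile(np.linspace(2, 12, 6), 3)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = 9 - 0.8 * x + rng.normal(0, 0.5, size=x.size)
            res = stats.linregress(x, y)
            df = points_df(list(zip(x, y)))
            df["k"] = np.tile(np.arange(1, 7), 3)
            line = fit_fingerprint(df)
            assert line.slope == pytest.approx(res.slope)
            hits += abs(line.slope - (-0.8)) <= 3 * res.stderr
        assert hits >= 0.95 * n_rep

    def test_per_unit_lines_pool_each_units_stacks(self):
        df = pd.concat(
            [
                points_df([(2, 10), (6, 6), (12, 0)], unit="u1", stack="s1"),
                points_df([(2, 10.4), (6, 6.4), (12, 0.4)], unit="u1", stack="s2"),
                points_df([(2, 8), (6, 6), (12, 3)], unit="u2", stack="s3"),
            ]
        )
        lines = per_unit_lines(df)
        assert list(lines.unit_id) == ["u1", "u2"]
        assert lines.loc[0, "n_points"] == 6
        assert lines.loc[0, "slope"] == pytest.approx(-1.0)


class TestCompareSlopes:
    def test_identical_groups_give_f_zero(self):
        res = compare_slopes(EXACT_LINE, EXACT_LINE.copy())
        assert res.slope_F == pytest.approx(0.0, abs=1e-9)
        assert res.slope_p == pytest.approx(1.0)

    def test_noiseless_separation(self):
        a = points_df([(x, 10 - x) for x in range(1, 7)])
        b = points_df([(x, 20 - 3 * x) for x in range(1, 7)])
        res = compare_slopes(a, b)
        assert res.slope_p == pytest.approx(0.0, abs=1e-12)

    def test_type_i_error_calibrated_for_iid_noise(self):
        # Monte Carlo under the null: equal slopes, Gaussian scatter
        rng = np.random.default_rng(42)
        x = np.tile(np.linspace(2, 12, 6), 4)
        n_rep, rejections = 1000, 0
        for _ in range(n_rep):
            ya = 9 - 0.8 * x + rng.normal(0, 0.6, x.size)
            yb = 9 - 0.8 * x + rng.normal(0, 0.6, x.size)
            df_a = pd.DataFrame({"vol_pct": x, "nhv95": ya, "k": np.tile(np.arange(1, 7), 4)})
            df_b = pd.DataFrame({"vol_pct": x, "nhv95": yb, "k": np.tile(np.arange(1, 7), 4)})
            rejections += compare_slopes(df_a, df_b).slope_p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_f_statistic_matches_explicit_rss_formula(self, rng):
        x = np.tile(np.linspace(1, 6, 6), 2)
        ya = 5 - x + rng.normal(0, 0.3, 12)
        yb = 6 - 1.4 * x + rng.normal(0, 0.3, 12)
        a = pd.DataFrame({"vol_pct": x, "nhv95": ya, "k": np.tile(np.arange(1, 7), 2)})
        b = pd.DataFrame({"vol_pct": x, "nhv95": yb, "k": np.tile(np.arange(1, 7), 2)})
        res = compare_slopes(a, b)
        # independent oracle via direct least squares
        xx = np.concatenate([x, x])
        yy = np.concatenate([ya, yb])
        g = np.repeat([0.0, 1.0], 12)
        X_f = np.column_stack([np.ones(24), xx, g, xx * g])
        X_r = X_f[:, :3]
        rss = lambda X: np.sum((yy - X @ np.linalg.lstsq(X, yy, rcond=None)[0]) ** 2)
        F = (rss(X_r) - rss(X_f)) / (rss(X_f) / 20)
        assert res.slope_F == pytest.approx(F)
        assert res.slope_p == pytest.approx(stats.f.sf(F, 1, 20))


class TestMannWhitney:
    def test_closed_form_u_mean_variance(self):
        u, z, p = mann_whitney_normal([1, 2, 3, 4], [5, 6, 7, 8], use_continuity=False)
        assert u == 0.0
        assert z == pytest.approx(-8 / np.sqrt(16 * 9 / 12))
        assert p == pytest.approx(0.0209, abs=2e-4)

    def test_continuity_correction_shrinks_z(self):
        _, z_cc, _ = mann_whitney_normal([1, 2, 3, 4], [5, 6, 7, 8], use_continuity=True)
        assert z_cc == pytest.approx((-8 + 0.5) / np.sqrt(12))

    def test_matches_scipy_asymptotic_without_ties(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(0.5, size=7)
        u, z, p = mann_whitney_normal(x, y, use_continuity=True)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_tie_correction_toggle(self):
        x, y = [1, 1, 2, 2], [2, 2, 3, 3]
        _, z_plain, _ = mann_whitney_normal(x, y, use_continuity=False)
        _, z_tie, _ = mann_whitney_normal(x, y, use_continuity=False, tie_correction=True)
        assert abs(z_tie) > abs(z_plain)  # smaller variance with ties removed


class TestCompareParameters:
    def make_lines(self, offsets):
        return pd.DataFrame(
            {
                "a": 2.0 + offsets,
                "b": 10.0 + offsets,
                "d": 8.0 + offsets,
                "e": 10.0 + offsets,
                "f": 1.0 + offsets,
                "g": 9.0 + offsets,
            }
        )

    def test_identical_groups_show_nothing(self, rng):
        lines = self.make_lines(rng.normal(0, 0.5, 4))
        res = compare_parameters(lines, lines.copy())
        for name in ("a", "d", "e"):
            assert res[name].statistic == pytest.approx(0.0)
            assert res[name].p_value == pytest.approx(1.0)
            assert not res[name].significant
        for name in ("b", "f", "g"):
            assert not res[name].significant

    def test_test_selection_follows_parameter_roles(self, rng):
        la = self.make_lines(rng.normal(0, 0.5, 4))
        lb = self.make_lines(rng.normal(1, 0.5, 4))
        res = compare_parameters(la, lb)
        assert {res[p].test for p in ("a", "d", "e")} == {"t"}
        assert {res[p].test for p in ("b", "f", "g")} == {"mann-whitney"}

    def test_zero_variance_groups_flagged_degenerate(self):
        la = self.make_lines(np.zeros(2))
        lb = self.make_lines(np.ones(2))
        res = compare_parameters(la, lb)
        assert res["a"].degenerate
        assert res["a"].p_value == 0.0
        assert np.isinf(res["a"].statistic)

    def test_compare_groups_bundles_slope_and_parameters(self):
        a = pd.concat(
            [points_df([(x, 10 - x) for x in range(2, 8)], unit=f"u{i}") for i in range(3)]
        )
        b = pd.concat(
            [points_df([(x, 12 - 2 * x + 0.01 * i) for x in range(2, 8)], unit=f"v{i}") for i in range(3)]
        )
        res = compare_groups(a, b)
        assert res.slope_p < 0.05
        assert set(res.parameters) == {"a", "b", "d", "e", "f", "g"}
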