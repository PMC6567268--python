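"""Near-linear angioarchitecture fingerprints and group statistics.

Plotting the normalized dispersion nHv95 of each progressively reconstituted
architecture against its Vol% yields, for microvascular networks, a
near-linear descending set of points.  The ordinary-least-squares line through
them is the *fingerprint* of the angioarchitecture, summarized by seven
interdependent parameters:

====  ==========================================================
a     X (Vol%) of the left-end point — amount of the largest vessels
b     Y (nHv95) of the left-end point — dispersion of the largest vessels
c     slope — rate of change of intervascular distances with caliber
d     X-projection length (e − a) — amount contributed by smaller vessels
e     X of the right-end point — amount of the total analyzed vasculature
f     Y of the right-end point — dispersion of the total vasculature
g     Y-projection length (b − f) — dispersion contributed by smaller vessels
====  ==========================================================

Group comparisons follow the field's convention: an ANCOVA-style F-test for
the equality of pooled regression slopes; unpaired t-tests for amounts and
X-projections (a, d, e); Mann–Whitney with normal approximation for
dispersion values and Y-projections (b, f, g).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "POINT_COLUMNS",
    "PARAM_TESTS",
    "FingerprintLine",
    "ParamTest",
    "GroupComparison",
    "as_points",
    "fit_fingerprint",
    "per_unit_lines",
    "compare_slopes",
    "mann_whitney_normal",
    "compare_parameters",
    "compare_groups",
    "plot_fingerprint",
]

#: Canonical columns of a fingerprint-points table.
POINT_COLUMNS = ("unit_id", "stack_id", "k", "vol_pct", "nhv95")

#: Which statistical test each line parameter receives; the slope itself is
#: tested inferentially by the pooled F-test (per-unit slopes stay available
#: descriptively via :func:`per_unit_lines`).
PARAM_TESTS = {"a": "t", "d": "t", "e": "t", "b": "mw", "f": "mw", "g": "mw"}


@dataclass(frozen=True)
class FingerprintLine:
    """OLS fingerprint line with the seven derived parameters a–g.

    ``a``/``e`` are the mean Vol% of the first (k = 1) and last
    (k = n_classes) architectures over the unit's stacks; ``b``/``f`` are the
    fitted line evaluated there; ``d = e - a`` and ``g = b - f``.
    """

    slope: float
    intercept: float
    r2: float
    a: float
    b: float
    d: float
    e: float
    f: float
    g: float
    n_points: int


def as_points(points) -> pd.DataFrame:
    """Coerce a points table (DataFrame, records, or (x, y, k) tuples)."""
    if isinstance(points, pd.DataFrame):
        df = points.copy()
    else:
        rows = list(points)
        if rows and not hasattr(rows[0], "keys") and len(rows[0]) == 3:
            df = pd.DataFrame(rows, columns=["vol_pct", "nhv95", "k"])
        else:
            df = pd.DataFrame(rows)
    missing = {"vol_pct", "nhv95", "k"} - set(df.columns)
    if missing:
        raise ValueError(f"points table missing columns {sorted(missing)}")
    return df


def fit_fingerprint(points, endpoint_y: str = "line") -> FingerprintLine:
    """Fit the fingerprint line and read off parameters a–g.

    ``endpoint_y='line'`` (default) evaluates b and f on the fitted line at
    the observed endpoint X positions; ``'raw'`` takes the mean observed
    nhv95 of the endpoint architectures instead.
    """
    df = as_points(points).dropna(subset=["vol_pct", "nhv95"])
    x = df["vol_pct"].to_numpy(dtype=float)
    y = df["nhv95"].to_numpy(dtype=float)
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 points with >= 2 distinct vol_pct values")
    if np.ptp(y) == 0:
        # horizontal data: OLS slope is exactly 0 and the fit is perfect
        slope, intercept, r2 = 0.0, float(y[0]), 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    kmin, kmax = int(df["k"].min()), int(df["k"].max())
    a = float(df.loc[df["k"] == kmin, "vol_pct"].mean())
    e = float(df.loc[df["k"] == kmax, "vol_pct"].mean())
    if endpoint_y == "line":
        b = intercept + slope * a
        f = intercept + slope * e
    elif endpoint_y == "raw":
        b = float(df.loc[df["k"] == kmin, "nhv95"].mean())
        f = float(df.loc[df["k"] == kmax, "nhv95"].mean())
    else:
        raise ValueError("endpoint_y must be 'line' or 'raw'")
    return FingerprintLine(
        slope=slope, intercept=intercept, r2=r2,
        a=a, b=b, d=e - a, e=e, f=f, g=b - f, n_points=len(x),
    )


def per_unit_lines(points, endpoint_y: str = "line") -> pd.DataFrame:
    """One fingerprint line per unit (animal), pooling all its stacks' points."""
    df = as_points(points)
    if "unit_id" not in df.columns:
        raise ValueError("points table needs a unit_id column")
    rows = []
    for unit, sub in df.groupby("unit_id", sort=True):
        line = fit_fingerprint(sub, endpoint_y=endpoint_y)
        rows.append(
            {
                "unit_id": unit,
                "slope": line.slope,
                "intercept": line.intercept,
                "r2": line.r2,
                "a": line.a,
                "b": line.b,
                "d": line.d,
                "e": line.e,
                "f": line.f,
                "g": line.g,
                "n_points": line.n_points,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ParamTest:
    """Outcome of a single between-group parameter comparison."""

    parameter: str
    test: str
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class GroupComparison:
    """Slope F-test plus per-parameter statistics for two groups."""

    slope_F: float
    slope_p: float
    n_points: int
    parameters: dict[str, ParamTest] = field(default_factory=dict)

    @property
    def slope_significant(self) -> bool:
        return self.slope_p < 0.05


def compare_slopes(points_a, points_b) -> GroupComparison:
    """ANCOVA-style F-test for equality of the two groups' pooled slopes.

    All points of each group (units pooled) enter one regression; the full
    model (separate slopes and intercepts) is tested against the reduced
    model (common slope, separate intercepts) with F on (1, n - 4) df.
    """
    dfa, dfb = as_points(points_a), as_points(points_b)
    if len(dfa) < 3 or len(dfb) < 3:
        raise ValueError("each group needs >= 3 points")
    x = np.concatenate([dfa["vol_pct"], dfb["vol_pct"]]).astype(float)
    y = np.concatenate([dfa["nhv95"], dfb["nhv95"]]).astype(float)
    g = np.concatenate([np.zeros(len(dfa)), np.ones(len(dfb))])
    n = len(y)
    if n <= 4:
        raise ValueError("need more than 4 points in total for the slope F-test")
    X_red = np.column_stack([np.ones(n), x, g])
    X_full = np.column_stack([X_red, x * g])
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    rss_f, rss_r = float(full.ssr), float(red.ssr)
    df2 = n - 4
    if rss_f <= 1e-12 * max(rss_r, 1.0):
        # noiseless separation: identical slopes -> F = 0, different -> F -> inf
        if rss_r - rss_f <= 1e-12 * max(rss_r, 1.0):
            F, p = 0.0, 1.0
        else:
            F, p = math.inf, 0.0
    else:
        F = max(0.0, (rss_r - rss_f) / (rss_f / df2))
        p = float(stats.f.sf(F, 1, df2))
    return GroupComparison(slope_F=F, slope_p=p, n_points=n)


def mann_whitney_normal(
    x, y, use_continuity: bool = True, tie_correction: bool = False
) -> tuple[float, float, float]:
    """Two-sided Mann–Whitney U with the normal (Gaussian) approximation.

    Returns ``(U, z, p)`` where U is the first sample's U statistic.  The
    continuity correction is applied by default; the tie correction is off by
    default (ties are measure-zero for continuous indices) — both toggleable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 * (n1 + n2 + 1) / 12.0
    if tie_correction:
        nt = n1 + n2
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        var -= n1 * n2 * ((counts**3 - counts).sum()) / (12.0 * nt * (nt - 1))
    if var <= 0:
        return float(u1), 0.0, 1.0
    num = u1 - mu
    if use_continuity and num != 0:
        num -= 0.5 * np.sign(num)
    z = num / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(u1), float(z), min(p, 1.0)


def _t_test(x, y) -> ParamTest:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t-test needs >= 2 units per group")
    pooled_var = np.var(x, ddof=1) * (len(x) - 1) + np.var(y, ddof=1) * (len(y) - 1)
    if pooled_var == 0:
        if x.mean() == y.mean():
            return ParamTest("", "t", 0.0, 1.0, False, degenerate=True)
        return ParamTest("", "t", math.inf, 0.0, True, degenerate=True)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return ParamTest("", "t", float(t), float(p), bool(p < 0.05))


def compare_parameters(
    params_a: pd.DataFrame,
    params_b: pd.DataFrame,
    use_continuity: bool = True,
    tie_correction: bool = False,
    alpha: float = 0.05,
) -> dict[str, ParamTest]:
    """Compare per-unit line parameters between two groups.

    Amounts and X-projections (a, d, e) use the two-sided unpaired t-test;
    dispersion values and Y-projections (b, f, g) and the per-unit slopes use
    the two-sided Mann–Whitney test with normal approximation.  Differences
    are flagged when p < ``alpha``.
    """
    out: dict[str, ParamTest] = {}
    for param, kind in PARAM_TESTS.items():
        if param not in params_a.columns or param not in params_b.columns:
            continue
        xa = params_a[param].to_numpy(dtype=float)
        xb = params_b[param].to_numpy(dtype=float)
        if kind == "t":
            res = _t_test(xa, xb)
            out[param] = ParamTest(param, "t", res.statistic, res.p_value,
                                   bool(res.p_value < alpha), res.degenerate)
        else:
            u, z, p = mann_whitney_normal(
                xa, xb, use_continuity=use_continuity, tie_correction=tie_correction
            )
            out[param] = ParamTest(param, "mann-whitney", z, p, bool(p < alpha))
    return out


def compare_groups(points_a, points_b, endpoint_y: str = "line") -> GroupComparison:
    """Full two-group comparison: pooled slope F-test + per-unit parameters."""
    slopes = compare_slopes(points_a, points_b)
    lines_a = per_unit_lines(points_a, endpoint_y=endpoint_y)
    lines_b = per_unit_lines(points_b, endpoint_y=endpoint_y)
    params = compare_parameters(lines_a, lines_b)
    return GroupComparison(
        slope_F=slopes.slope_F,
        slope_p=slopes.slope_p,
        n_points=slopes.n_points,
        parameters=params,
    )


def plot_fingerprint(points, line: FingerprintLine | None = None, ax=None, label=None):
    """Scatter the fingerprint points and overlay the fitted line.

    Matplotlib is imported lazily; returns the axes used.
    """
    import matplotlib.pyplot as plt

    df = as_points(points)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(df["vol_pct"], df["nhv95"], s=18, alpha=0.7, label=label)
    if line is None:
        line = fit_fingerprint(df)
    xs = np.linspace(df["vol_pct"].min(), df["vol_pct"].max(), 50)
    ax.plot(xs, line.intercept + line.slope * xs, lw=1.5)
    ax.set_xlabel("signal amount (Vol %)")
    ax.set_ylabel("spatial dispersion (nHv 95%)")
    return ax
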