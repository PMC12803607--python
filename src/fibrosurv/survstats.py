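"""Nonparametric survival estimators and descriptive statistics.

Kaplan–Meier product-limit curves, the two-group Mantel–Haenszel log-rank
test (the workhorse of the fibrosis cutpoint scan), restricted cubic spline
bases, group comparisons for table-one reporting, the logit-scale Pearson
correlation, and half-up percentage rounding matching printed clinical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "SplineBasis",
    "km_estimate",
    "logrank_test",
    "rcs_basis",
    "rcs_knots",
    "compare_groups",
    "logit_correlation",
    "proportion_percent",
]


def _check_surv_input(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must align")
    if np.any(times < 0):
        raise ValueError("negative follow-up time")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return times, events.astype(int)


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S(0) = 1 and the
    curve is non-increasing.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    group_label: str | None = None

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, group_label: str | None = None) -> KMCurve:
    """Kaplan–Meier estimator under right censoring.

    Censored subjects leave the risk set just after their recorded time, so
    a censoring tied with an event keeps the subject at risk for it.
    """
    times, events = _check_surv_input(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    uniq, first = np.unique(t_sorted, return_index=True)
    n = len(t_sorted)
    d = np.zeros(len(uniq), dtype=int)
    np.add.at(d, np.searchsorted(uniq, t_sorted), e_sorted)
    at_risk = n - first  # subjects with time >= uniq[j]
    keep = d > 0
    ev_times = uniq[keep]
    d_ev = d[keep]
    r_ev = at_risk[keep]
    surv = np.cumprod(1.0 - d_ev / r_ev)
    return KMCurve(
        event_times=ev_times,
        at_risk=r_ev,
        n_events=d_ev,
        survival=surv,
        group_label=group_label,
    )


@dataclass
class LogRankResult:
    """Two-group Mantel–Haenszel log-rank test (1 df)."""

    chi_square: float
    df: int
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]

    def __post_init__(self) -> None:
        if self.chi_square < 0:
            raise ValueError("chi-square must be non-negative")


def logrank_test(times, events, group) -> LogRankResult:
    """Log-rank comparison of two survival curves.

    At every distinct event time j the observed events in group 1 are
    compared with the conditional hypergeometric expectation
    E1j = dj * n1j / nj; the statistic is (sum O1j - sum E1j)^2 / sum Vj
    with Vj the hypergeometric variance, referred to chi-square with 1 df.
    """
    times, events = _check_surv_input(times, events)
    group = np.asarray(group)
    if group.shape != times.shape:
        raise ValueError("group must align with times")
    gvals = np.unique(group)
    if len(gvals) != 2:
        raise ValueError("logrank_test requires exactly two non-empty groups")
    g1 = group == gvals[1]

    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    in1 = g1[order]
    uniq, first = np.unique(t, return_index=True)
    j = np.searchsorted(uniq, t)
    d = np.zeros(len(uniq))
    d1 = np.zeros(len(uniq))
    np.add.at(d, j, e)
    np.add.at(d1, j, e & in1)
    n_at = len(t) - first
    # group-1 subjects still at risk at each unique time
    n1_at = in1.sum() - np.concatenate([[0], np.cumsum(np.bincount(j, weights=in1))[:-1]])

    keep = d > 0
    dj, d1j, nj, n1j = d[keep], d1[keep], n_at[keep].astype(float), n1_at[keep]
    e1 = dj * n1j / nj
    with np.errstate(invalid="ignore", divide="ignore"):
        v = dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    v = np.where(nj > 1, v, 0.0)
    u = float(np.sum(d1j - e1))
    var = float(np.sum(v))
    if var == 0.0:
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = u * u / var
        p = float(stats.chi2.sf(chi2, df=1))
    o1 = float(d1j.sum())
    total = float(dj.sum())
    return LogRankResult(
        chi_square=chi2,
        df=1,
        p_value=max(p, np.finfo(float).tiny),
        observed=(total - o1, o1),
        expected=(total - float(e1.sum()), float(e1.sum())),
    )


# ---------------------------------------------------------------------------
# restricted cubic splines (Harrell parameterisation)

_DEFAULT_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


@dataclass
class SplineBasis:
    """Restricted cubic spline basis: linear beyond the boundary knots.

    ``transform(x)`` returns columns [x, C_1(x), ..., C_{k-2}(x)] where the
    nonlinear terms are truncated-cubic combinations scaled by the squared
    knot span, following the standard rms parameterisation.
    """

    knots: np.ndarray

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if len(self.knots) < 3 or np.any(np.diff(self.knots) <= 0):
            raise ValueError("need at least 3 strictly increasing knots")

    @property
    def n_nonlinear(self) -> int:
        return len(self.knots) - 2

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = self.knots
        k = len(t)
        span2 = (t[-1] - t[0]) ** 2
        cols = [x]
        for j in range(k - 2):
            cube = lambda u: np.clip(u, 0.0, None) ** 3
            cj = (
                cube(x - t[j])
                - cube(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + cube(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
            ) / span2
            cols.append(cj)
        return np.column_stack(cols)


def rcs_knots(x, n_knots: int = 4) -> np.ndarray:
    """Default knot placement at the conventional quantiles."""
    if n_knots not in _DEFAULT_KNOT_QUANTILES:
        raise ValueError("n_knots must be 3, 4 or 5")
    x = np.asarray(x, dtype=float)
    knots = np.quantile(x[~np.isnan(x)], _DEFAULT_KNOT_QUANTILES[n_knots])
    if len(np.unique(knots)) < n_knots:
        raise ValueError("too few distinct values for the requested knots")
    return knots


def rcs_basis(x, n_knots: int = 4, knots=None) -> SplineBasis:
    """Restricted cubic spline basis for a covariate vector."""
    if knots is None:
        knots = rcs_knots(x, n_knots)
    return SplineBasis(knots=np.asarray(knots, dtype=float))


# ---------------------------------------------------------------------------
# descriptive comparisons and reporting arithmetic


def compare_groups(values, group, kind: str) -> dict:
    """Two-group comparison dispatched by the *declared* variable type.

    kind='mean'      -> t-test, descriptives mean (SD)
    kind='median'    -> Mann-Whitney U, descriptives median [IQR]
    kind='categorical' -> chi-squared on the contingency table, n (%)
    """
    values = np.asarray(values)
    group = np.asarray(group)
    gvals = np.unique(group)
    if len(gvals) != 2:
        raise ValueError("compare_groups requires exactly two groups")
    mask_ok = ~(np.asarray(values, dtype=object) == None)  # noqa: E711
    if values.dtype.kind in "fiu":
        mask_ok = ~np.isnan(values.astype(float))
    a = values[(group == gvals[0]) & mask_ok]
    b = values[(group == gvals[1]) & mask_ok]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a group has no observed values")
    if kind == "mean":
        a = a.astype(float)
        b = b.astype(float)
        stat, p = stats.ttest_ind(a, b)
        desc = {
            str(gvals[0]): (float(a.mean()), float(a.std(ddof=1))),
            str(gvals[1]): (float(b.mean()), float(b.std(ddof=1))),
        }
    elif kind == "median":
        a = a.astype(float)
        b = b.astype(float)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        desc = {
            str(g): (
                float(np.median(v)),
                (float(np.quantile(v, 0.25)), float(np.quantile(v, 0.75))),
            )
            for g, v in ((gvals[0], a), (gvals[1], b))
        }
    elif kind == "categorical":
        cats = np.unique(np.concatenate([a, b]))
        table = np.array(
            [[(a == c).sum() for c in cats], [(b == c).sum() for c in cats]]
        )
        if table.shape[1] < 2 or np.array_equal(table[0] * len(b), table[1] * len(a)):
            # identical composition (or a single category): no association
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        desc = {
            str(g): {str(c): (int((v == c).sum()), 100.0 * (v == c).mean()) for c in cats}
            for g, v in ((gvals[0], a), (gvals[1], b))
        }
    else:
        raise ValueError("kind must be 'mean', 'median' or 'categorical'")
    return {"kind": kind, "statistic": float(stat), "p_value": float(p), "groups": desc}


def logit_correlation(
    x_percent, y, clamp_epsilon: float | None = None
) -> dict:
    """Pearson correlation of logit(x/100) with y, with a Fisher-z CI.

    Percentages at the 0/100 boundary have no logit; they are either an
    error or, when ``clamp_epsilon`` is given, clamped into
    [epsilon, 100 - epsilon] first.
    """
    x = np.asarray(x_percent, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if clamp_epsilon is not None:
        if not 0 < clamp_epsilon < 50:
            raise ValueError("clamp_epsilon must lie in (0, 50)")
        x = np.clip(x, clamp_epsilon, 100.0 - clamp_epsilon)
    if np.any((x <= 0) | (x >= 100)):
        raise ValueError("percentages at or beyond 0/100 require a clamp_epsilon")
    lx = np.log(x / 100.0) - np.log(1.0 - x / 100.0)
    if np.std(lx) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(lx, y)
    n = len(x)
    if n <= 3:
        raise ValueError("need more than 3 observations for a Fisher-z interval")
    z = np.arctanh(r)
    half = 1.959963984540054 / np.sqrt(n - 3)
    return {
        "r": float(r),
        "ci95": (float(np.tanh(z - half)), float(np.tanh(z + half))),
        "p_value": float(p),
        "n": n,
    }


def proportion_percent(count: int, n: int, decimals: int = 2) -> float:
    """100*count/n rounded half-up, as clinical tables print percentages."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100) * Decimal(count) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))
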