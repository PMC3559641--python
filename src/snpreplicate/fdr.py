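"""Storey-style q-values and observed/expected P-value bin diagnostics.

Under the global null, P-values are Uniform(0,1); comparing observed counts
per P-value range against ``m * width`` is a quick visual check of whether
any signal is present.  The q-value of a test is the minimum false discovery
rate at which it would be called significant; it needs an estimate of the
null proportion pi0, obtained from the right tail of the P-value histogram:

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)),

either at a single fixed lambda or by extrapolating a cubic smoother of
pi0(lambda) over a lambda grid to its upper end (Storey's recipe).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: interior bin edges; bins are [0, .001], (.001, .01], (.01, .05], (.05, .1], (.1, 1]
DEFAULT_BIN_EDGES = (0.001, 0.01, 0.05, 0.1)

#: Storey (2002) default lambda grid
DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.05, 0.901, 0.05), 2))


def _check_edges(bin_edges) -> np.ndarray:
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size == 0:
        raise ValidationError("bin edges must be a non-empty 1-D sequence")
    if not (np.all(np.diff(edges) > 0) and edges[0] > 0 and edges[-1] < 1):
        raise ValidationError(
            "bin edges must be strictly increasing interior points of (0,1)"
        )
    return edges


def bin_intervals(bin_edges=DEFAULT_BIN_EDGES) -> list[tuple[float, float]]:
    """(low, high] intervals, ascending; the lowest is closed at 0."""
    edges = _check_edges(bin_edges)
    bounds = np.concatenate([[0.0], edges, [1.0]])
    return list(zip(bounds[:-1], bounds[1:]))


def expected_bin_counts(m: int, bin_edges=DEFAULT_BIN_EDGES) -> np.ndarray:
    """Expected P-value counts per bin under uniformity: m * bin width, unrounded."""
    if m < 0:
        raise ValidationError("m must be nonnegative")
    return np.array([m * (hi - lo) for lo, hi in bin_intervals(bin_edges)])


def round_half_up(x: float, decimals: int) -> float:
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


def format_expected(x: float) -> str:
    """Display rounding for expected counts: nearest integer >= 10, one
    decimal >= 1, two decimals below 1 (all round-half-up)."""
    if x >= 10:
        return str(int(round_half_up(x, 0)))
    if x >= 1:
        return f"{round_half_up(x, 1):.1f}"
    return f"{round_half_up(x, 2):.2f}"


@dataclass(frozen=True)
class PValueBinTable:
    """Observed vs expected P-value counts per range.

    ``bins`` are ascending (low, high] intervals tiling [0,1]; ``q_range``
    holds the (min, max) q-value among the P-values in each bin, or None
    for empty bins (or when no q-values were supplied).
    """

    bins: tuple[tuple[float, float], ...]
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    m: int
    q_range: tuple[tuple[float, float] | None, ...]

    def __post_init__(self) -> None:
        if sum(self.observed) != self.m:
            raise ValidationError("observed counts must sum to m")
        if abs(sum(self.expected) - self.m) > 1e-9 * max(self.m, 1):
            raise ValidationError("unrounded expected counts must sum to m")

    def to_rows(self, descending: bool = True) -> list[dict]:
        """Render-ready rows (the conventional layout lists large P first)."""
        idx = range(len(self.bins) - 1, -1, -1) if descending else range(len(self.bins))
        rows = []
        for i in idx:
            lo, hi = self.bins[i]
            qr = self.q_range[i]
            rows.append(
                {
                    "p_range": f"{hi:g}-{lo:g}" if lo > 0 else f"<={hi:g}",
                    "observed": self.observed[i],
                    "expected": format_expected(self.expected[i]),
                    "q_min": None if qr is None else qr[0],
                    "q_max": None if qr is None else qr[1],
                }
            )
        return rows


def pvalue_bin_table(
    p_values, bin_edges=DEFAULT_BIN_EDGES, q_values=None
) -> PValueBinTable:
    """Tabulate observed and expected P-value counts per range.

    Binning is lower-open/upper-closed, with the lowest bin closed at 0, so
    a boundary value such as p = 0.05 falls in the (0.01, 0.05] bin.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValidationError("p-values must lie in [0,1]")
    edges = _check_edges(bin_edges)
    intervals = bin_intervals(bin_edges)
    which = np.searchsorted(edges, p, side="left")
    observed = np.bincount(which, minlength=len(intervals))
    expected = expected_bin_counts(p.size, bin_edges)
    q_range: list[tuple[float, float] | None] = [None] * len(intervals)
    if q_values is not None:
        q = np.asarray(q_values, dtype=float)
        if q.shape != p.shape:
            raise ValidationError("q_values must parallel p_values")
        for i in range(len(intervals)):
            sel = q[which == i]
            if sel.size:
                q_range[i] = (float(sel.min()), float(sel.max()))
    return PValueBinTable(
        bins=tuple(intervals),
        observed=tuple(int(c) for c in observed),
        expected=tuple(float(e) for e in expected),
        m=int(p.size),
        q_range=tuple(q_range),
    )


def pi0_estimate(
    p_values,
    lambda_grid=None,
    method: str = "spline",
) -> float:
    """Estimate the proportion of true nulls from the P-value right tail.

    ``method='fixed'`` evaluates pi0(lambda) at a single lambda (the only
    grid element, or 0.5 by default); ``method='spline'`` fits a cubic
    least-squares smoother of pi0(lambda) over the grid and takes its value
    at the largest lambda.  The estimate is clipped to (0, 1], with a floor
    of 1/m when the raw estimate is nonpositive.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("pi0 estimation needs at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0,1]")
    m = p.size
    if method == "fixed":
        grid = np.asarray(lambda_grid if lambda_grid is not None else [0.5], float)
        if grid.size != 1:
            raise ValidationError("fixed method takes a single lambda")
        lam = float(grid[0])
        if not 0 < lam < 1:
            raise ValidationError("lambda must lie in (0,1)")
        pi0 = (p > lam).sum() / (m * (1 - lam))
    elif method == "spline":
        grid = np.asarray(
            lambda_grid if lambda_grid is not None else DEFAULT_LAMBDA_GRID, float
        )
        if grid.size < 4 or not ((grid > 0) & (grid < 1)).all():
            raise ValidationError("spline method needs >= 4 lambdas in (0,1)")
        pi0_lam = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in grid])
        coef = np.polynomial.polynomial.polyfit(grid, pi0_lam, deg=3)
        pi0 = float(np.polynomial.polynomial.polyval(grid.max(), coef))
    else:
        raise ValidationError(f"unknown pi0 method {method!r}")
    if pi0 <= 0:
        pi0 = 1.0 / m
    return float(min(pi0, 1.0))


@dataclass(frozen=True)
class QValueSet:
    """P-values with their q-values and the pi0 used to compute them."""

    p_values: tuple[float, ...]
    q_values: tuple[float, ...]
    pi0: float
    lambda_grid: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.pi0 <= 1:
            raise ValidationError(f"pi0 must lie in (0,1], got {self.pi0}")


def qvalues(p_values, pi0: float = 1.0) -> QValueSet:
    """Step-up q-values: q(i) = min_{j >= i} pi0 * m * p(j) / j on sorted p.

    With pi0 = 1 this is exactly the Benjamini-Hochberg adjusted p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("qvalues needs at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0,1]")
    if not 0 < pi0 <= 1:
        raise ValidationError(f"pi0 must lie in (0,1], got {pi0}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return QValueSet(
        p_values=tuple(float(x) for x in p),
        q_values=tuple(float(x) for x in q),
        pi0=float(pi0),
    )


def storey_qvalues(p_values, lambda_grid=None, method: str = "spline") -> QValueSet:
    """Convenience: estimate pi0 then compute q-values from it."""
    pi0 = pi0_estimate(p_values, lambda_grid=lambda_grid, method=method)
    qs = qvalues(p_values, pi0)
    grid = tuple(
        float(x)
        for x in (
            lambda_grid
            if lambda_grid is not None
            else ([0.5] if method == "fixed" else DEFAULT_LAMBDA_GRID)
        )
    )
    return QValueSet(qs.p_values, qs.q_values, pi0, lambda_grid=grid)
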