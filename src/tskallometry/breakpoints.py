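"""Breakpoint detection by intersection of firing strengths.

A phase-transition point is where two adjacent normalized firing
strengths cross: below it one local model dominates the blend, above it
the other. The criterion is non-statistical — no starting values, no
profile likelihood — just root-finding on the difference of two smooth
weight curves. For a two-rule Gaussian partition the crossing also has a
closed form (the tau quadratic, see :mod:`tskallometry.asymptotics`),
which is used as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .partition import GAUSSIAN_GEOMETRIC, FuzzyPartition

__all__ = ["BreakpointSet", "find_breakpoints", "dominance_intervals"]

GRID_POINTS = 10_001  # dense enough that smooth Gaussian weights cannot hide a crossing
_BISECT_TOL = 1e-10


@dataclass(frozen=True)
class BreakpointSet:
    """Sorted crossing points plus per-phase dominance intervals.

    ``intervals`` is a list of ``(lo, hi, rule_index)`` triples covering
    the scanned domain; ``rule_index`` is 0-based.
    """

    points: np.ndarray
    intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))

    def __len__(self) -> int:
        return len(self.points)


def _bisect(g, lo: float, hi: float) -> float:
    """Refine a bracketed sign change of g to _BISECT_TOL."""
    glo = g(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo < _BISECT_TOL:
            return mid
        gm = g(mid)
        if gm == 0.0:
            return mid
        if (glo < 0) == (gm < 0):
            lo, glo = mid, gm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _analytic_two_rule(partition: FuzzyPartition) -> np.ndarray:
    """Closed-form crossings of a q=2 Gaussian partition (tau(u) = 0)."""
    (t1, t2), (l1, l2) = partition.theta, partition.lam
    if l1 == l2:
        return np.array([0.5 * (t1 + t2)]) if t1 != t2 else np.array([])
    psi = (l2**2 - l1**2) / (2.0 * (l1 * l2) ** 2)
    b = (l2**2 * t1 - l1**2 * t2) / (l1**2 - l2**2)
    # tau = psi * (u + b)^2 + xi; crossing where tau = 0.
    xi = _xi(t1, t2, l1, l2)
    rhs = -xi / psi
    if rhs < 0:
        return np.array([])
    r = np.sqrt(rhs)
    return np.sort(np.array([-b - r, -b + r]))


def _xi(t1: float, t2: float, l1: float, l2: float) -> float:
    num = (l2**2 * t1 - l1**2 * t2) ** 2 - (l1**2 - l2**2) * (
        (l1 * t2) ** 2 - (l2 * t1) ** 2
    )
    return num / (2.0 * (l1**2 - l2**2) * (l1 * l2) ** 2)


def find_breakpoints(
    partition: FuzzyPartition,
    domain: tuple,
    grid_points: int = GRID_POINTS,
) -> BreakpointSet:
    """Locate crossings of adjacent dominant firing strengths on ``domain``.

    Scans a dense grid for changes of the argmax firing strength and
    refines each crossing by bisection on the difference of the two
    implicated weights. An empty result is a valid outcome: it means the
    partition behaves as a single phase over the domain (the q = 1 or
    no-crossing case). For two-rule Gaussian partitions the numeric roots
    are checked against the closed-form tau roots.
    """
    lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        raise ValueError("domain must be a non-degenerate (lo, hi) interval")
    if partition.q == 1:
        return BreakpointSet(points=np.array([]), intervals=[(lo, hi, 0)])

    grid = np.linspace(lo, hi, grid_points)
    w = partition.firing(grid)
    dom = np.argmax(w, axis=1)
    switches = np.flatnonzero(np.diff(dom) != 0)

    points, pairs = [], []
    for s in switches:
        i, j = int(dom[s]), int(dom[s + 1])

        def g(u, i=i, j=j):
            fw = partition.firing(np.atleast_1d(u))[0]
            return fw[i] - fw[j]

        root = _bisect(g, grid[s], grid[s + 1])
        points.append(root)
        pairs.append((i, j))

    points_arr = np.asarray(points)
    if (
        partition.q == 2
        and partition.family == GAUSSIAN_GEOMETRIC
        and len(points_arr)
    ):
        analytic = _analytic_two_rule(partition)
        inside = analytic[(analytic > lo) & (analytic < hi)]
        if len(inside) == len(points_arr) and not np.allclose(
            np.sort(inside), np.sort(points_arr), atol=1e-8
        ):
            raise AssertionError(
                "analytic and numeric two-rule breakpoints disagree beyond 1e-8"
            )

    # Dominance intervals between consecutive crossings.
    edges = [lo, *points_arr.tolist(), hi]
    intervals = []
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        rule = int(np.argmax(partition.firing(np.atleast_1d(mid))[0]))
        intervals.append((a, b, rule))
    return BreakpointSet(points=points_arr, intervals=intervals)


def dominance_intervals(
    partition: FuzzyPartition,
    domain: tuple,
    data: np.ndarray | None = None,
    grid_points: int = GRID_POINTS,
):
    """Label dominance realms and (optionally) the data share in each.

    Returns a list of dicts ``{lo, hi, rule, fraction}``; ``fraction``
    is the share of ``data`` falling in the interval (None without data).
    """
    bps = find_breakpoints(partition, domain, grid_points)
    out = []
    n = len(data) if data is not None else 0
    for lo, hi, rule in bps.intervals:
        frac = None
        if data is not None and n:
            d = np.asarray(data, dtype=float)
            # Closed on the right edge only for the final interval.
            last = hi == bps.intervals[-1][1]
            inside = (d >= lo) & ((d <= hi) if last else (d < hi))
            frac = float(inside.sum() / n)
        out.append({"lo": lo, "hi": hi, "rule": rule, "fraction": frac})
    return out
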