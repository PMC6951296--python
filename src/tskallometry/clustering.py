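"""Subtractive clustering (Chiu's method) for fuzzy rule induction.

The number of rules q and the membership centers are induced from data
by density-based center selection: every point receives a "potential"

    P_i = sum_j exp(-(4 / r_a^2) ||z_i - z_j||^2)

on min-max-normalized coordinates, the highest-potential point becomes a
center, its influence is subtracted with a slightly wider kernel
(r_b = squash * r_a), and the process repeats until the remaining
potential falls below a rejection threshold. The cluster radius r_a is
the single tuning knob: smaller radii yield more rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SCConfig", "ClusterResult", "subtractive_cluster", "widths_from_radius"]

# Chunk size for the O(n^2) potential accumulation; bounds peak memory.
_CHUNK = 2048


@dataclass(frozen=True)
class SCConfig:
    """Parameters of the subtractive-clustering run.

    r_a is expressed in normalized-unit space (data min-max scaled to
    [0, 1] per dimension when ``normalize`` is on). ``squash`` is the
    ratio r_b / r_a of the subtraction kernel to the potential kernel;
    ``accept_ratio`` / ``reject_ratio`` bound the acceptance band as
    fractions of the first (largest) potential.
    """

    r_a: float = 0.5
    squash: float = 1.25
    accept_ratio: float = 0.5
    reject_ratio: float = 0.15
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.r_a <= 0:
            raise ValueError("r_a must be positive")
        if self.squash < 1:
            raise ValueError("squash must be >= 1")
        if not (0 < self.reject_ratio < self.accept_ratio <= 1):
            raise ValueError("need 0 < reject_ratio < accept_ratio <= 1")


@dataclass(frozen=True)
class ClusterResult:
    """Selected centers (original coordinates) and their potentials."""

    centers: np.ndarray  # (q, d), de-normalized
    potentials: np.ndarray  # (q,), in selection order
    q: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", len(self.centers))


def _potentials(z: np.ndarray, gamma: float) -> np.ndarray:
    """P_i = sum_j exp(-gamma * ||z_i - z_j||^2), chunked over rows."""
    n = len(z)
    out = np.empty(n)
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        d2 = cdist(z[lo:hi], z, "sqeuclidean")
        out[lo:hi] = np.exp(-gamma * d2).sum(axis=1)
    return out


def subtractive_cluster(points: np.ndarray, cfg: SCConfig | None = None) -> ClusterResult:
    """Run subtractive clustering on an (n, d) point array.

    Deterministic for a fixed input order; ties in maximal potential are
    broken by lowest index. Degenerate all-identical inputs yield a
    single center.
    """
    cfg = cfg or SCConfig()
    z = np.atleast_2d(np.asarray(points, dtype=float))
    if z.ndim != 2 or len(z) < 1:
        raise ValueError("points must be a non-empty (n, d) array")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite coordinates")

    lo, span = z.min(axis=0), np.ptp(z, axis=0)
    if cfg.normalize:
        # Constant dimensions carry no clustering information; give them
        # unit span so normalization maps them to a single value.
        safe_span = np.where(span > 0, span, 1.0)
        zn = (z - lo) / safe_span
    else:
        zn = z

    gamma_a = 4.0 / cfg.r_a**2
    r_b = cfg.squash * cfg.r_a
    gamma_b = 4.0 / r_b**2

    pot = _potentials(zn, gamma_a)
    centers: list[np.ndarray] = []
    center_pots: list[float] = []
    first_pot = None

    while True:
        k = int(np.argmax(pot))  # argmax takes the lowest index on ties
        p_k = pot[k]
        if first_pot is None:
            first_pot = p_k
            accepted = True
        elif p_k > cfg.accept_ratio * first_pot:
            accepted = True
        elif p_k < cfg.reject_ratio * first_pot:
            break
        else:
            # Gray zone: accept if the candidate is far enough from the
            # existing centers relative to its potential (Chiu's rule),
            # otherwise zero it out and try the next best point.
            d_min = min(np.linalg.norm(zn[k] - c) for c in centers)
            if d_min / cfg.r_a + p_k / first_pot >= 1.0:
                accepted = True
            else:
                pot[k] = 0.0
                continue
        if accepted:
            centers.append(zn[k].copy())
            center_pots.append(float(p_k))
            d2 = np.sum((zn - zn[k]) ** 2, axis=1)
            pot = pot - p_k * np.exp(-gamma_b * d2)
            if len(centers) >= len(z):
                break

    c = np.asarray(centers)
    if cfg.normalize:
        c = c * np.where(span > 0, span, 1.0) + lo
    return ClusterResult(centers=c, potentials=np.asarray(center_pots))


def widths_from_radius(cfg: SCConfig, per_dimension_range) -> np.ndarray:
    """Map the cluster radius to Gaussian membership widths per dimension.

    A cluster of normalized radius r_a corresponds to the potential
    kernel exp(-(4/r_a^2) d^2); matching it to a Gaussian membership
    exp(-d^2 / (2 lambda^2)) gives lambda = r_a * range / sqrt(8) in the
    original units of each dimension.
    """
    rng = np.atleast_1d(np.asarray(per_dimension_range, dtype=float))
    if np.any(rng <= 0):
        raise ValueError("per-dimension ranges must be positive")
    return cfg.r_a * rng / np.sqrt(8.0)
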