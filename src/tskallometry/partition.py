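"""Fuzzy partitions: membership functions and normalized firing strengths.

Two membership families cover the two model spaces:

* ``gaussian_geometric`` -- Gaussian membership in log coordinates,
  mu_k(u) = exp(-((u - theta_k)/lambda_k)^2 / 2), used by the polyphasic
  loglinear (PLA) model whose input domain is all of R;

* ``composite_lognormal_arithmetic`` -- a composite log-normal degree
  mu_i(x) = (e^{h_i(x)} - 1)/(e - 1) with h_i(x) the Gaussian core
  evaluated at ln x, used by the arithmetic-space complex-allometry
  (MPCA) model. The composition forces the degree to vanish as x -> 0+,
  matching the zero-intercept constraint of the response.

Normalized firing strengths are the membership weights rescaled to sum
to one at every point; they are the mixing weights of the local linear
sub-models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FuzzyPartition",
    "membership_gaussian",
    "membership_composite_lognormal",
    "firing_strengths",
]

GAUSSIAN_GEOMETRIC = "gaussian_geometric"
COMPOSITE_LOGNORMAL = "composite_lognormal_arithmetic"
_FAMILIES = (GAUSSIAN_GEOMETRIC, COMPOSITE_LOGNORMAL)


@dataclass(frozen=True)
class FuzzyPartition:
    """q fuzzy rules: centers theta_k, widths lambda_k, membership family.

    Centers are stored sorted ascending; callers must apply the same
    permutation to any per-rule consequents. For the composite family
    the centers live on the ln-x axis (the Gaussian core's coordinate).
    """

    theta: np.ndarray
    lam: np.ndarray
    family: str = GAUSSIAN_GEOMETRIC

    def __post_init__(self) -> None:
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        if theta.shape != lam.shape or theta.ndim != 1:
            raise ValueError("theta and lam must be 1-D arrays of equal length")
        if np.any(lam <= 0):
            raise ValueError("all widths lambda_k must be positive")
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown membership family {self.family!r}")
        order = np.argsort(theta, kind="stable")
        object.__setattr__(self, "theta", theta[order])
        object.__setattr__(self, "lam", lam[order])

    @property
    def q(self) -> int:
        return len(self.theta)

    def log_core(self, point) -> np.ndarray:
        """ln of the Gaussian core, shape (n, q): -((t - theta)/lam)^2 / 2.

        ``t`` is the point itself for the geometric family and ln(point)
        for the composite family.
        """
        p = np.atleast_1d(np.asarray(point, dtype=float))
        if self.family == COMPOSITE_LOGNORMAL:
            if np.any(p <= 0):
                raise ValueError("composite family requires positive points")
            p = np.log(p)
        zscore = (p[:, None] - self.theta[None, :]) / self.lam[None, :]
        return -0.5 * zscore**2

    def membership(self, point) -> np.ndarray:
        """Membership degrees, shape (n, q), each in [0, 1]."""
        core = np.exp(self.log_core(point))
        if self.family == GAUSSIAN_GEOMETRIC:
            return core
        return np.expm1(core) / (np.e - 1.0)

    def firing(self, point) -> np.ndarray:
        """Normalized firing strengths, shape (n, q), rows sum to one."""
        log_core = self.log_core(point)
        if self.family == GAUSSIAN_GEOMETRIC:
            # Log-domain softmax: finite even when every membership
            # underflows far from all centers.
            shifted = log_core - log_core.max(axis=1, keepdims=True)
            w = np.exp(shifted)
        else:
            w = np.expm1(np.exp(log_core))
            bad = w.sum(axis=1) <= 0.0
            if np.any(bad):
                # expm1(h) ~ h as h -> 0, so the normalized limit equals
                # the softmax of the log cores.
                sub = log_core[bad]
                w[bad] = np.exp(sub - sub.max(axis=1, keepdims=True))
        return w / w.sum(axis=1, keepdims=True)


def membership_gaussian(u, theta_k: float, lam_k: float):
    """Gaussian membership degree exp(-((u - theta_k)/lam_k)^2 / 2)."""
    if lam_k <= 0:
        raise ValueError("lam_k must be positive")
    u = np.asarray(u, dtype=float)
    return np.exp(-0.5 * ((u - theta_k) / lam_k) ** 2)


def membership_composite_lognormal(x, theta_i: float, lam_i: float):
    """Composite log-normal degree (e^{h_i(x)} - 1)/(e - 1).

    h_i(x) = exp(-((ln x - theta_i)/lam_i)^2 / 2) is the Gaussian core in
    ln x. The degree is 1 at ln x = theta_i and tends to 0 as x -> 0+.
    """
    if lam_i <= 0:
        raise ValueError("lam_i must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be positive")
    h = np.exp(-0.5 * ((np.log(x) - theta_i) / lam_i) ** 2)
    return np.expm1(h) / (np.e - 1.0)


def firing_strengths(point, partition: FuzzyPartition) -> np.ndarray:
    """Normalized firing strengths at ``point`` (scalar -> shape (q,))."""
    w = partition.firing(point)
    return w[0] if np.isscalar(point) or np.ndim(point) == 0 else w
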