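"""Seeded generators for allometric data with known ground truth.

The generator emulates q-phase loglinear allometry with Gaussian fuzzy
blending: the log covariate u is drawn uniformly over a range (field
allometry datasets are dense on the log scale), the log response is the
blended surface v_TSK(u | truth) plus Gaussian noise — homoscedastic or
with the log-linear heteroscedastic scale ln(sigma + k u) — and the pair
is returned on the arithmetic scale (x, y) = (e^u, e^v), making the
noise multiplicative in the original units. Identical seeds reproduce
identical datasets bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .breakpoints import find_breakpoints
from .dataset import AllometricDataset
from .fitting import (
    GEOMETRIC,
    HOMOSCEDASTIC,
    LOG_LINEAR_HET,
    ConsequentSet,
    TSKModel,
    VarianceModel,
)
from .partition import FuzzyPartition

__all__ = ["GeneratorSpec", "generate", "default_biphasic_spec"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth for a synthetic q-phase loglinear allometry.

    Defaults describe a biphasic relation with well-separated phases:
    centers (1.8, 6.2) log units, widths 1.35, exponents (0.9, 1.2) and
    intercepts chosen so the two phase lines (and, widths being equal,
    the firing strengths) cross at u = 4.0, with homoscedastic log-scale
    noise sigma = 0.3 — dispersion of the order seen in large field
    datasets of leaf or body allometry.

    ``u_dist`` selects how the log covariate is sampled:

    * ``uniform`` — uniform over ``u_range``;
    * ``lognormal`` — Gaussian in u (lognormal x), mimicking
      size-frequency skew, centered on the middle of ``u_range``;
    * ``cohorts`` — an equal mixture of Gaussian size cohorts centered
      at the phase centers with spread ``cohort_sd``. This is how
      biphasic data arise in the field (e.g., juvenile and adult
      cohorts) and is the mode under which density-based rule induction
      is well posed.
    """

    theta: tuple = (1.8, 6.2)
    lam: tuple = (1.35, 1.35)
    alpha: tuple = (0.9, 1.2)
    ln_beta: tuple = (-1.0, -2.2)
    noise: str = HOMOSCEDASTIC
    sigma: float = 0.3
    k: float = 0.0
    n: int = 5000
    u_range: tuple = (0.0, 8.0)
    u_dist: str = "uniform"
    cohort_sd: float = 1.15
    seed: int = 0

    @property
    def q(self) -> int:
        return len(self.theta)

    def truth_model(self) -> TSKModel:
        return TSKModel(
            partition=FuzzyPartition(
                theta=np.asarray(self.theta, dtype=float),
                lam=np.asarray(self.lam, dtype=float),
            ),
            consequents=ConsequentSet(
                intercept=np.asarray(self.ln_beta, dtype=float),
                slope=np.asarray(self.alpha, dtype=float),
            ),
            variance=VarianceModel(self.noise, self.sigma, self.k),
            space=GEOMETRIC,
        )


def default_biphasic_spec(seed: int = 0, **overrides) -> GeneratorSpec:
    """The default two-phase study conditions with a chosen seed."""
    return GeneratorSpec(seed=seed, **overrides)


def generate(spec: GeneratorSpec) -> tuple[AllometricDataset, dict]:
    """Draw a dataset from the spec; return it with a truth record.

    The truth record carries the generating parameters plus the implied
    firing-strength crossings over ``u_range``.
    """
    model = spec.truth_model()
    lo, hi = spec.u_range
    if not hi > lo:
        raise ValueError("u_range must be a nondegenerate interval")
    if spec.noise == LOG_LINEAR_HET:
        arg = spec.sigma + spec.k * np.array([lo, hi])
        if np.min(arg) <= 1.0:
            raise ValueError("heteroscedastic spec violates sigma + k*u > 1 on u_range")
    elif spec.noise != HOMOSCEDASTIC:
        raise ValueError(f"unknown noise kind {spec.noise!r}")

    rng = np.random.default_rng(spec.seed)
    if spec.u_dist == "uniform":
        u = rng.uniform(lo, hi, size=spec.n)
    elif spec.u_dist == "lognormal":
        u = rng.normal(0.5 * (lo + hi), (hi - lo) / 6.0, size=spec.n)
    elif spec.u_dist == "cohorts":
        comp = rng.integers(0, spec.q, size=spec.n)
        u = rng.normal(np.asarray(spec.theta)[comp], spec.cohort_sd)
    else:
        raise ValueError(f"unknown u_dist {spec.u_dist!r}")
    sd = model.variance.sd(u) if spec.sigma > 0 else np.zeros(spec.n)
    v = model.predict(u) + rng.normal(0.0, 1.0, size=spec.n) * sd
    ds = AllometricDataset(x=np.exp(u), y=np.exp(v))

    bps = find_breakpoints(model.partition, (lo, hi)) if spec.q > 1 else None
    truth = {
        "theta": list(spec.theta),
        "lam": list(spec.lam),
        "alpha": list(spec.alpha),
        "ln_beta": list(spec.ln_beta),
        "noise": spec.noise,
        "sigma": spec.sigma,
        "k": spec.k,
        "n": spec.n,
        "u_range": list(spec.u_range),
        "u_dist": spec.u_dist,
        "cohort_sd": spec.cohort_sd,
        "seed": spec.seed,
        "breakpoints_u": [] if bps is None else bps.points.tolist(),
    }
    return ds, truth
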