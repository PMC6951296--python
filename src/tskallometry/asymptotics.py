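"""Two-rule asymptotics: the tau decomposition and the power-law limit.

For a two-rule Gaussian partition the firing strengths are logistic in

    tau(u) = ln mu_2(u) - ln mu_1(u),

which expands as tau(u) = psi(lam) * phi(u) + xi with

    psi = (lam_2^2 - lam_1^2) / (2 (lam_1 lam_2)^2),
    phi(u) = (u + (lam_2^2 th_1 - lam_1^2 th_2)/(lam_1^2 - lam_2^2))^2 >= 0,

and xi a constant. The sign of psi therefore decides which rule
dominates as u -> infinity: psi > 0 sends tau to +inf (rule 2 wins),
psi < 0 sends it to -inf (rule 1 wins). The retransformed mean response
then approaches Huxley's simple power law beta_i x^alpha_i * delta of
the dominant rule. Equal widths are the degenerate case: tau is affine
in u and the dominant rule follows from the sign of its slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .partition import GAUSSIAN_GEOMETRIC, FuzzyPartition

__all__ = ["TauDecomposition", "tau_decompose", "asymptotic_power_law", "AsymptoticPowerLaw"]


@dataclass(frozen=True)
class TauDecomposition:
    """tau(u) = psi * phi(u) + xi for a two-rule Gaussian partition."""

    psi: float
    xi: float
    offset: float  # phi(u) = (u + offset)^2
    degenerate: bool = False  # equal widths: tau affine, psi = 0
    lin_slope: float = 0.0  # tau = lin_slope * u + lin_const when degenerate
    lin_const: float = 0.0

    def phi(self, u) -> np.ndarray:
        return (np.asarray(u, dtype=float) + self.offset) ** 2

    def tau(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.degenerate:
            return self.lin_slope * u + self.lin_const
        return self.psi * self.phi(u) + self.xi


def tau_decompose(partition: FuzzyPartition) -> TauDecomposition:
    """Decompose the log membership ratio of a q=2 Gaussian partition."""
    if partition.q != 2 or partition.family != GAUSSIAN_GEOMETRIC:
        raise ValueError("tau decomposition is defined for q=2 Gaussian partitions")
    (t1, t2), (l1, l2) = partition.theta, partition.lam
    if l1 == l2:
        # tau = ((t2 - t1) u + (t1^2 - t2^2)/2) / lam^2
        return TauDecomposition(
            psi=0.0,
            xi=0.0,
            offset=0.0,
            degenerate=True,
            lin_slope=(t2 - t1) / l1**2,
            lin_const=(t1**2 - t2**2) / (2.0 * l1**2),
        )
    psi = (l2**2 - l1**2) / (2.0 * (l1 * l2) ** 2)
    offset = (l2**2 * t1 - l1**2 * t2) / (l1**2 - l2**2)
    num = (l2**2 * t1 - l1**2 * t2) ** 2 - (l1**2 - l2**2) * (
        (l1 * t2) ** 2 - (l2 * t1) ** 2
    )
    xi = num / (2.0 * (l1**2 - l2**2) * (l1 * l2) ** 2)
    return TauDecomposition(psi=psi, xi=xi, offset=offset)


@dataclass(frozen=True)
class AsymptoticPowerLaw:
    """The large-x power law E^inf(y|x) = beta_inf * x^alpha_inf."""

    beta_inf: float
    alpha_inf: float
    psi: float
    dominant_rule: int  # 0-based index of the rule that wins at infinity


def asymptotic_power_law(model, cf=None) -> AsymptoticPowerLaw:
    """Large-x limit of the retransformed two-rule mean response.

    Returns the Huxley-form parameters of the dominant rule, with the
    correction factor absorbed into beta_inf. When both widths and
    centers coincide the firing strengths are constant 1/2 and the limit
    is the blend of the two local models.
    """
    from .fitting import GEOMETRIC

    if model.space != GEOMETRIC:
        raise ValueError("asymptotics are derived for the geometric-space model")
    if model.q != 2:
        raise ValueError("asymptotic analysis covers the two-rule case only")
    dec = tau_decompose(model.partition)
    delta = float(cf) if cf is not None else 1.0
    a, b = model.consequents.intercept, model.consequents.slope

    if dec.degenerate:
        if dec.lin_slope > 0:
            rule = 1
        elif dec.lin_slope < 0:
            rule = 0
        else:
            # Identical memberships: constant half-half blend.
            ln_beta = 0.5 * (a[0] + a[1])
            alpha = 0.5 * (b[0] + b[1])
            return AsymptoticPowerLaw(float(np.exp(ln_beta)) * delta, float(alpha), 0.0, -1)
    else:
        rule = 1 if dec.psi > 0 else 0

    return AsymptoticPowerLaw(
        beta_inf=float(np.exp(a[rule])) * delta,
        alpha_inf=float(b[rule]),
        psi=dec.psi if not dec.degenerate else 0.0,
        dominant_rule=rule,
    )
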