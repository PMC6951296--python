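"""Consequent and variance estimation for TSK allometric models.

A first-order TSK model blends q local linear sub-models ("consequents")
with normalized firing strengths:

    v_TSK(u) = sum_i  theta^i(u) * (ln beta_i + alpha_i * u)      (PLA)
    w_TSK(x) = sum_i  theta^i(x) * (c_i1 + c_i2 * x)              (MPCA)

Consequents are linear in the parameters, so the least-squares problem
is an ordinary linear regression on the expanded design matrix with
columns [theta^i(z), theta^i(z) * z] per rule. Maximum likelihood adds a
Gaussian error model whose standard deviation is either a constant sigma
(homoscedastic) or the covariate-dependent form ln(sigma + k*u) with the
constraint sigma + k*u > 1 over the fitted data range (heteroscedastic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import statsmodels.api as sm

from .breakpoints import BreakpointSet, find_breakpoints
from .clustering import SCConfig, subtractive_cluster, widths_from_radius
from .dataset import AllometricDataset
from .metrics import MetricsBundle, performance_metrics
from .partition import COMPOSITE_LOGNORMAL, GAUSSIAN_GEOMETRIC, FuzzyPartition

__all__ = [
    "ConsequentSet",
    "VarianceModel",
    "TSKModel",
    "TamaFit",
    "FitReport",
    "tsk_output",
    "fit_consequents_ls",
    "fit_consequents_rls",
    "fit_ml",
    "fit_tama",
    "fit_tsk",
]

GEOMETRIC = "geometric"
ARITHMETIC = "arithmetic"

HOMOSCEDASTIC = "homoscedastic"
LOG_LINEAR_HET = "log_linear_het"

LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ConsequentSet:
    """Per-rule linear sub-models: intercepts and slopes.

    Geometric space: intercept = ln beta_i, slope = alpha_i (the phase's
    allometric exponent). Arithmetic space: intercept = c_i1, slope = c_i2.
    """

    intercept: np.ndarray
    slope: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.intercept, dtype=float))
        b = np.atleast_1d(np.asarray(self.slope, dtype=float))
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("intercept and slope must be 1-D of equal length")
        object.__setattr__(self, "intercept", a)
        object.__setattr__(self, "slope", b)

    @property
    def q(self) -> int:
        return len(self.intercept)

    def evaluate(self, z) -> np.ndarray:
        """Local model values f^i(z), shape (n, q)."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        return self.intercept[None, :] + self.slope[None, :] * z[:, None]


@dataclass(frozen=True)
class VarianceModel:
    """Gaussian residual scale: constant or log-linear in the covariate.

    ``homoscedastic``: sd(u) = sigma (k is 0).
    ``log_linear_het``: sd(u) = ln(sigma + k*u), valid only while
    sigma + k*u > 1 so the scale stays positive.
    """

    kind: str = HOMOSCEDASTIC
    sigma: float = 1.0
    k: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (HOMOSCEDASTIC, LOG_LINEAR_HET):
            raise ValueError(f"unknown variance kind {self.kind!r}")
        if self.kind == HOMOSCEDASTIC and self.k != 0.0:
            raise ValueError("homoscedastic model requires k = 0")

    def sd(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.kind == HOMOSCEDASTIC:
            return np.full(u.shape, self.sigma)
        arg = self.sigma + self.k * u
        if np.any(arg <= 1.0):
            raise ValueError("sigma + k*u must exceed 1 over the evaluated range")
        return np.log(arg)


@dataclass(frozen=True)
class TSKModel:
    """A fitted TSK allometric model: partition + consequents + variance."""

    partition: FuzzyPartition
    consequents: ConsequentSet
    variance: VarianceModel = field(default_factory=VarianceModel)
    space: str = GEOMETRIC

    def __post_init__(self) -> None:
        if self.space not in (GEOMETRIC, ARITHMETIC):
            raise ValueError(f"unknown space {self.space!r}")
        expected = GAUSSIAN_GEOMETRIC if self.space == GEOMETRIC else COMPOSITE_LOGNORMAL
        if self.partition.family != expected:
            raise ValueError(
                f"space {self.space!r} requires membership family {expected!r}"
            )
        if self.partition.q != self.consequents.q:
            raise ValueError("partition and consequents disagree on q")

    @property
    def q(self) -> int:
        return self.partition.q

    def predict(self, point) -> np.ndarray:
        """Blended mean response (v for geometric space, y for arithmetic)."""
        p = np.atleast_1d(np.asarray(point, dtype=float))
        w = self.partition.firing(p)
        out = np.sum(w * self.consequents.evaluate(p), axis=1)
        return out if np.ndim(point) else out[0]

    def to_dict(self) -> dict:
        return {
            "space": self.space,
            "family": self.partition.family,
            "q": self.q,
            "theta": self.partition.theta.tolist(),
            "lam": self.partition.lam.tolist(),
            "consequents": [
                {"intercept": float(a), "slope": float(b)}
                for a, b in zip(self.consequents.intercept, self.consequents.slope)
            ],
            "variance": {
                "kind": self.variance.kind,
                "sigma": float(self.variance.sigma),
                "k": float(self.variance.k),
            },
            "log_convention": "natural",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TSKModel":
        return cls(
            partition=FuzzyPartition(
                theta=np.asarray(d["theta"], dtype=float),
                lam=np.asarray(d["lam"], dtype=float),
                family=d["family"],
            ),
            consequents=ConsequentSet(
                intercept=np.array([c["intercept"] for c in d["consequents"]]),
                slope=np.array([c["slope"] for c in d["consequents"]]),
            ),
            variance=VarianceModel(**d["variance"]),
            space=d["space"],
        )


def tsk_output(point, model: TSKModel):
    """General TSK output sum_i theta^i(point) f^i(point)."""
    return model.predict(point)


def _design(z: np.ndarray, partition: FuzzyPartition) -> np.ndarray:
    """Expanded design matrix, columns [theta^i, theta^i * z] per rule."""
    w = partition.firing(z)
    return np.concatenate([w, w * z[:, None]], axis=1)


def _check_identifiable(z: np.ndarray, partition: FuzzyPartition) -> None:
    n, q = len(z), partition.q
    if n < 2 * q:
        raise ValueError(f"need n >= 2q observations (n={n}, q={q})")
    w = partition.firing(z)
    dead = np.flatnonzero(w.max(axis=0) < 1e-12)
    if dead.size:
        raise ValueError(
            f"rule(s) {[int(i) + 1 for i in dead]} fire nowhere on the data; "
            "design matrix is rank deficient"
        )


def fit_consequents_ls(
    ds: AllometricDataset, partition: FuzzyPartition, space: str = GEOMETRIC
) -> ConsequentSet:
    """Batch least-squares consequents (the normal-equations minimizer)."""
    z, t = (ds.u, ds.v) if space == GEOMETRIC else (ds.x, ds.y)
    _check_identifiable(z, partition)
    X = _design(z, partition)
    coef, _, rank, _ = np.linalg.lstsq(X, t, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix: a rule fires nowhere")
    q = partition.q
    return ConsequentSet(intercept=coef[:q], slope=coef[q:])


def fit_consequents_rls(
    ds: AllometricDataset,
    partition: FuzzyPartition,
    space: str = GEOMETRIC,
    p0: float = 1e8,
) -> ConsequentSet:
    """Recursive least squares, one observation at a time.

    Provided for parity with sequential identification schemes; with a
    diffuse prior (large ``p0``) it converges to the batch solution.
    """
    z, t = (ds.u, ds.v) if space == GEOMETRIC else (ds.x, ds.y)
    _check_identifiable(z, partition)
    X = _design(z, partition)
    m = X.shape[1]
    theta = np.zeros(m)
    P = np.eye(m) * p0
    for xi, ti in zip(X, t):
        Px = P @ xi
        gain = Px / (1.0 + xi @ Px)
        theta = theta + gain * (ti - xi @ theta)
        P = P - np.outer(gain, Px)
    q = partition.q
    return ConsequentSet(intercept=theta[:q], slope=theta[q:])


def _nll(resid: np.ndarray, sd: np.ndarray) -> float:
    """Full Gaussian negative log-likelihood, constants included."""
    return float(np.sum(0.5 * LOG2PI + np.log(sd) + 0.5 * (resid / sd) ** 2))


def _wls(X: np.ndarray, t: np.ndarray, sd: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X / sd[:, None], t / sd, rcond=None)
    return coef


def fit_ml(
    ds: AllometricDataset,
    partition: FuzzyPartition,
    variance_kind: str = HOMOSCEDASTIC,
    space: str = GEOMETRIC,
):
    """Maximum-likelihood consequents and variance parameters.

    For fixed variance parameters the Gaussian likelihood is maximized
    in the consequents by weighted least squares, so the variance
    parameters are profiled: a closed form for the homoscedastic case
    and a 2-D Nelder-Mead search over (sigma, k) for the heteroscedastic
    one, warm-started at the homoscedastic optimum (sigma_het = e^sd,
    k = 0) and constrained to sigma + k*u > 1 over the data hull.

    Returns ``(ConsequentSet, VarianceModel, neg_log_lik)``.
    """
    z, t = (ds.u, ds.v) if space == GEOMETRIC else (ds.x, ds.y)
    _check_identifiable(z, partition)
    X = _design(z, partition)
    n, q = len(z), partition.q

    coef_ls, *_ = np.linalg.lstsq(X, t, rcond=None)
    resid = t - X @ coef_ls
    sigma_hat = float(np.sqrt(np.mean(resid**2)))
    nll_hom = _nll(resid, np.full(n, sigma_hat))

    if variance_kind == HOMOSCEDASTIC:
        cons = ConsequentSet(intercept=coef_ls[:q], slope=coef_ls[q:])
        return cons, VarianceModel(HOMOSCEDASTIC, sigma_hat, 0.0), nll_hom

    if variance_kind != LOG_LINEAR_HET:
        raise ValueError(f"unknown variance kind {variance_kind!r}")

    def profile_nll(params: np.ndarray) -> float:
        sigma, k = params
        arg = sigma + k * z
        if np.min(arg) <= 1.0 + 1e-9:
            return 1e12 * (1.0 + max(0.0, 1.0 - np.min(arg)))
        sd = np.log(arg)
        coef = _wls(X, t, sd)
        return _nll(t - X @ coef, sd)

    x0 = np.array([np.exp(sigma_hat), 0.0])
    res = scipy.optimize.minimize(
        profile_nll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    if not res.success and res.fun > nll_hom + 1e-6:
        raise RuntimeError(
            f"heteroscedastic ML did not converge: {res.message} "
            f"(final simplex value {res.fun:.6g})"
        )
    sigma, k = res.x
    sd = np.log(sigma + k * z)
    coef = _wls(X, t, sd)
    cons = ConsequentSet(intercept=coef[:q], slope=coef[q:])
    nll = _nll(t - X @ coef, sd)
    return cons, VarianceModel(LOG_LINEAR_HET, float(sigma), float(k)), nll


def variance_wald_ci(
    ds: AllometricDataset,
    model: TSKModel,
    level: float = 0.95,
    space: str | None = None,
) -> dict:
    """Wald intervals for (sigma, k) from the profile-likelihood Hessian.

    The interval for k is the heteroscedasticity check: when it excludes
    zero, residual variability changes with the covariate.
    """
    import scipy.stats

    space = space or model.space
    z, t = (ds.u, ds.v) if space == GEOMETRIC else (ds.x, ds.y)
    X = _design(z, model.partition)
    if model.variance.kind != LOG_LINEAR_HET:
        raise ValueError("Wald intervals implemented for the heteroscedastic model")

    def profile_nll(params: np.ndarray) -> float:
        sigma, k = params
        arg = sigma + k * z
        if np.min(arg) <= 1.0:
            return np.inf
        sd = np.log(arg)
        coef = _wls(X, t, sd)
        return _nll(t - X @ coef, sd)

    p = np.array([model.variance.sigma, model.variance.k])
    h = np.maximum(1e-5, 1e-5 * np.abs(p))
    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            pp = p.copy()
            pp[i] += h[i]
            pp[j] += h[j]
            fpp = profile_nll(pp)
            pp = p.copy()
            pp[i] += h[i]
            pp[j] -= h[j]
            fpm = profile_nll(pp)
            pp = p.copy()
            pp[i] -= h[i]
            pp[j] += h[j]
            fmp = profile_nll(pp)
            pp = p.copy()
            pp[i] -= h[i]
            pp[j] -= h[j]
            fmm = profile_nll(pp)
            H[i, j] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    cov = np.linalg.inv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    zcrit = scipy.stats.norm.ppf(0.5 + level / 2)
    return {
        "sigma": (float(p[0] - zcrit * se[0]), float(p[0] + zcrit * se[0])),
        "k": (float(p[1] - zcrit * se[1]), float(p[1] + zcrit * se[1])),
        "se": {"sigma": float(se[0]), "k": float(se[1])},
    }


@dataclass(frozen=True)
class TamaFit:
    """Ordinary log-log regression (the traditional analysis method)."""

    alpha: float
    ln_beta: float
    se_alpha: float
    se_ln_beta: float
    t_alpha: float
    t_ln_beta: float
    ci_alpha: tuple
    ci_ln_beta: tuple
    residuals: np.ndarray
    resid_se: float
    r2: float
    metrics: MetricsBundle

    def predict(self, u) -> np.ndarray:
        return self.ln_beta + self.alpha * np.asarray(u, dtype=float)


def fit_tama(ds: AllometricDataset) -> TamaFit:
    """OLS of v on u: slope alpha, intercept ln(beta), Wald summaries."""
    if ds.n < 3:
        raise ValueError("TAMA regression needs at least 3 observations")
    if np.ptp(ds.u) == 0:
        raise ValueError("constant covariate: slope is unidentified")
    X = sm.add_constant(ds.u)
    res = sm.OLS(ds.v, X).fit()
    ci = res.conf_int(alpha=0.05)
    v_hat = res.fittedvalues
    return TamaFit(
        alpha=float(res.params[1]),
        ln_beta=float(res.params[0]),
        se_alpha=float(res.bse[1]),
        se_ln_beta=float(res.bse[0]),
        t_alpha=float(res.tvalues[1]),
        t_ln_beta=float(res.tvalues[0]),
        ci_alpha=(float(ci[1, 0]), float(ci[1, 1])),
        ci_ln_beta=(float(ci[0, 0]), float(ci[0, 1])),
        residuals=np.asarray(res.resid),
        resid_se=float(np.sqrt(res.ssr / res.df_resid)),
        r2=float(res.rsquared),
        metrics=performance_metrics(ds.v, v_hat, n_params=2),
    )


@dataclass(frozen=True)
class FitReport:
    """End-to-end result of a TSK fit."""

    model: TSKModel
    residuals: np.ndarray
    neg_log_lik: float
    breakpoints: BreakpointSet
    metrics: MetricsBundle
    r_a: float
    cf: object | None = None

    @property
    def q(self) -> int:
        return self.model.q


def fit_tsk(
    ds: AllometricDataset,
    r_a: float,
    space: str = GEOMETRIC,
    variance_kind: str = HOMOSCEDASTIC,
    estimator: str = "ls",
    sc_config: SCConfig | None = None,
) -> FitReport:
    """Full pipeline: cluster -> partition -> consequents -> diagnostics.

    Clustering runs on the joint (input, output) pairs of the chosen
    space: (u, v) for the geometric PLA model, (x, y) for the arithmetic
    MPCA model. Only the input coordinate of each cluster center becomes
    a membership center; widths derive from the cluster radius. For the
    MPCA family the membership core operates on ln x, so center
    x-coordinates are mapped through the logarithm and the width is set
    from the range of ln x.
    """
    cfg = sc_config or SCConfig(r_a=r_a)
    if cfg.r_a != r_a:
        cfg = SCConfig(r_a, cfg.squash, cfg.accept_ratio, cfg.reject_ratio, cfg.normalize)

    if space == GEOMETRIC:
        pts = np.column_stack([ds.u, ds.v])
        family = GAUSSIAN_GEOMETRIC
        z_in, target = ds.u, ds.v
        theta_axis = ds.u
    elif space == ARITHMETIC:
        pts = np.column_stack([ds.x, ds.y])
        family = COMPOSITE_LOGNORMAL
        z_in, target = ds.x, ds.y
        theta_axis = ds.u  # membership core lives on ln x
    else:
        raise ValueError(f"unknown space {space!r}")

    clusters = subtractive_cluster(pts, cfg)
    centers_in = clusters.centers[:, 0]
    theta = np.log(centers_in) if space == ARITHMETIC else centers_in
    span = np.ptp(theta_axis)
    if span == 0:
        raise ValueError("degenerate dataset: covariate has zero range")
    lam = np.full(clusters.q, widths_from_radius(cfg, span)[0])
    partition = FuzzyPartition(theta=theta, lam=lam, family=family)

    if estimator == "ls":
        cons = fit_consequents_ls(ds, partition, space)
        pred = _design(z_in, partition) @ np.concatenate([cons.intercept, cons.slope])
        resid = target - pred
        sigma = float(np.sqrt(np.mean(resid**2)))
        variance = VarianceModel(HOMOSCEDASTIC, sigma, 0.0)
        nll = _nll(resid, np.full(ds.n, sigma))
        n_var_params = 1
        if variance_kind == LOG_LINEAR_HET:
            raise ValueError("heteroscedastic variance requires estimator='ml'")
    elif estimator == "ml":
        cons, variance, nll = fit_ml(ds, partition, variance_kind, space)
        pred = _design(z_in, partition) @ np.concatenate([cons.intercept, cons.slope])
        resid = target - pred
        n_var_params = 1 if variance.kind == HOMOSCEDASTIC else 2
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    model = TSKModel(partition=partition, consequents=cons, variance=variance, space=space)
    domain = (float(z_in.min()), float(z_in.max()))
    bps = find_breakpoints(partition, domain)
    mets = performance_metrics(
        target, model.predict(z_in), n_params=2 * model.q + n_var_params, nll=nll
    )
    return FitReport(
        model=model,
        residuals=resid,
        neg_log_lik=nll,
        breakpoints=bps,
        metrics=mets,
        r_a=r_a,
    )


def fit_tsk_at_q(
    ds: AllometricDataset,
    target_q: int,
    radii=None,
    space: str = GEOMETRIC,
    variance_kind: str = HOMOSCEDASTIC,
    estimator: str = "ls",
) -> FitReport:
    """Scan the clustering radius until the rule count hits ``target_q``.

    The rule count is controlled only indirectly through the cluster
    radius, so analyses targeting a given phase count explore radii
    interactively; this helper automates that exploration over an
    ascending grid (default 0.26:0.60:0.04) and returns the first fit
    with the requested q. Raises if no radius on the grid produces it.
    """
    if radii is None:
        radii = np.arange(0.26, 0.61, 0.04)
    for r_a in radii:
        report = fit_tsk(ds, float(r_a), space, variance_kind, estimator)
        if report.q == target_q:
            return report
    raise ValueError(f"no radius in the grid produced q = {target_q}")
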