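"""Model-performance and diagnostic statistics.

Reproducibility of a fitted mean response is primarily judged by Lin's
concordance correlation coefficient (CCC), which penalizes both
dispersion and location shift, with the conventional agreement classes
poor (< 0.90), moderate, good and excellent (>= 0.99). The bundle also
carries the coefficient of determination, standard error of estimate,
mean prediction error, mean percent standard error and AIC. The
Breusch-Pagan auxiliary regression of squared residuals on the covariate
screens for heteroscedasticity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "MetricsBundle",
    "concordance_ccc",
    "reproducibility_class",
    "performance_metrics",
    "breusch_pagan",
]


def reproducibility_class(ccc: float) -> str:
    if ccc < 0.90:
        return "poor"
    if ccc < 0.95:
        return "moderate"
    if ccc < 0.99:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class MetricsBundle:
    ccc: float
    r2: float
    see: float
    mpe: float
    mpse: float
    aic: float
    reproducibility_class: str

    def to_dict(self) -> dict:
        return {
            "ccc": self.ccc,
            "r2": self.r2,
            "see": self.see,
            "mpe": self.mpe,
            "mpse": self.mpse,
            "aic": self.aic,
            "reproducibility_class": self.reproducibility_class,
        }


def concordance_ccc(obs, pred) -> float:
    """Lin's concordance correlation coefficient (population moments).

    rho_c = 2 cov(o, p) / (var(o) + var(p) + (mean(o) - mean(p))^2).
    """
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or o.size < 2:
        raise ValueError("obs and pred must be equal-length 1-D arrays, n >= 2")
    mo, mp = o.mean(), p.mean()
    vo, vp = o.var(), p.var()  # 1/n moments
    denom = vo + vp + (mo - mp) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: zero total variance")
    cov = np.mean((o - mo) * (p - mp))
    return float(2.0 * cov / denom)


def performance_metrics(
    obs,
    pred,
    n_params: int,
    relative_to: str = "pred",
    nll: float | None = None,
) -> MetricsBundle:
    """Compute the full metrics bundle for observed vs predicted values.

    MPE and MPSE are percentage relative errors; the denominator
    convention is selectable (``relative_to`` = "pred" or "obs") since
    both appear in the forestry literature. AIC uses the Gaussian
    log-likelihood (a closed form from the residual sum of squares when
    ``nll`` is not supplied).
    """
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    n = o.size
    if n <= n_params:
        raise ValueError("need more observations than parameters")
    denom = p if relative_to == "pred" else o
    if np.any(denom == 0):
        raise ValueError("MPE/MPSE undefined: zero denominator value")
    err = o - p
    sse = float(np.sum(err**2))
    sst = float(np.sum((o - o.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else np.nan)
    see = float(np.sqrt(sse / (n - n_params)))
    mpe = float(100.0 / n * np.sum(err / denom))
    mpse = float(100.0 / n * np.sum(np.abs(err) / denom))
    if nll is None:
        # Profile Gaussian likelihood; sigma^2 = SSE/n.
        if sse == 0:
            nll = -np.inf
        else:
            nll = 0.5 * n * (np.log(2 * np.pi) + np.log(sse / n) + 1.0)
    aic = float(2.0 * n_params + 2.0 * nll)
    ccc = concordance_ccc(o, p)
    return MetricsBundle(
        ccc=ccc,
        r2=float(r2),
        see=see,
        mpe=mpe,
        mpse=mpse,
        aic=aic,
        reproducibility_class=reproducibility_class(ccc),
    )


def breusch_pagan(residuals, u, form: str = "studentized"):
    """Breusch-Pagan test of residual variance depending linearly on u.

    Auxiliary OLS of squared residuals on the covariate; the null is a
    vanishing slope (homoscedasticity). ``form`` selects the studentized
    (Koenker) statistic n * R^2_aux (default) or the original chi-square
    scaling ESS_aux / (2 * sigma_hat^4).

    Returns ``(statistic, df, p_value)`` with one degree of freedom.
    """
    e = np.asarray(residuals, dtype=float)
    x = np.asarray(u, dtype=float)
    if e.shape != x.shape or e.size < 3:
        raise ValueError("residuals and u must be equal-length, n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: auxiliary slope unidentified")
    e2 = e**2
    xc = x - x.mean()
    yc = e2 - e2.mean()
    slope = float(xc @ yc / (xc @ xc))
    fitted_c = slope * xc
    ess = float(fitted_c @ fitted_c)
    tss = float(yc @ yc)
    n = e.size
    if form == "studentized":
        stat = n * (ess / tss) if tss > 0 else 0.0
    elif form == "original":
        sigma2 = float(np.mean(e2))
        stat = ess / (2.0 * sigma2**2)
    else:
        raise ValueError(f"unknown form {form!r}")
    p = float(scipy.stats.chi2.sf(stat, df=1))
    return float(stat), 1, p
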