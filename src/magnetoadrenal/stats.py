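"""Statistical machinery shared by every pipeline stage.

Gamma GLM with identity link (heart-rate AUC comparison), beta regression
with a logit mean link (freezing behavior), beta maximum likelihood with
tail probabilities (serum outlier screening), pooled/Welch two-sample
t-tests, and Cullen–Frey skewness–kurtosis diagnostics for distribution
shortlisting.

Model fitting delegates to statsmodels / scipy; this module owns the
result contracts, edge handling and conventions (which link, which df,
which tail) used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "GammaGlmFit",
    "BetaRegFit",
    "BetaFit",
    "TTestResult",
    "SkewKurtSummary",
    "fit_gamma_glm_identity",
    "fit_beta_regression",
    "fit_beta_mle",
    "tail_prob",
    "t_test",
    "cullen_frey",
]


def _as_design(design) -> np.ndarray:
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


@dataclass
class GammaGlmFit:
    """Gamma GLM (identity link) fit summary."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    dispersion: float
    df_resid: float
    converged: bool
    names: list[str] = field(default_factory=list)
    degenerate_dispersion: bool = False

    def to_dict(self) -> dict:
        return {
            "model": "gamma_glm_identity",
            "names": list(self.names),
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "t_statistics": self.t_statistics.tolist(),
            "p_values": self.p_values.tolist(),
            "dispersion": float(self.dispersion),
            "df_resid": float(self.df_resid),
            "converged": bool(self.converged),
            "degenerate_dispersion": bool(self.degenerate_dispersion),
        }


def fit_gamma_glm_identity(response, design, names=None) -> GammaGlmFit:
    """Fit a gamma GLM with identity link by IRLS.

    ``response`` must be strictly positive; ``design`` is the full design
    matrix (include the intercept column explicitly).  Dispersion is the
    Pearson estimate; Wald tests use the t distribution on the residual
    degrees of freedom, matching how GLM coefficient tests are reported
    for a gamma family with estimated dispersion.
    """
    y = np.asarray(response, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("response must be a nonempty 1-D array")
    if np.any(y <= 0):
        raise ValueError("gamma GLM requires strictly positive responses")
    X = _as_design(design)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]

    # perfect linear fit (e.g. constant response): IRLS cannot estimate a
    # dispersion; report the least-squares solution with dispersion 0
    beta_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
    if np.max(np.abs(y - X @ beta_ls)) < 1e-10 * max(np.max(np.abs(y)), 1.0):
        k = X.shape[1]
        zeros = np.zeros(k)
        return GammaGlmFit(
            coefficients=np.asarray(beta_ls, dtype=float),
            standard_errors=zeros, t_statistics=zeros,
            p_values=np.full(k, np.nan), dispersion=0.0,
            df_resid=float(y.size - k), converged=True,
            names=list(names), degenerate_dispersion=True,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Identity()))
        res = model.fit(scale="X2")

    mu = res.fittedvalues
    if np.any(mu <= 0):
        raise RuntimeError("gamma GLM produced non-positive fitted means")

    df_resid = float(res.df_resid)
    dispersion = float(res.scale)
    degenerate = dispersion < 1e-12
    se = np.asarray(res.bse, dtype=float)
    coef = np.asarray(res.params, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, 0.0)
    if df_resid > 0 and not degenerate:
        pvals = 2.0 * sps.t.sf(np.abs(tstat), df_resid)
    else:
        pvals = np.full_like(tstat, np.nan)
    return GammaGlmFit(
        coefficients=coef,
        standard_errors=se,
        t_statistics=np.asarray(tstat, dtype=float),
        p_values=np.asarray(pvals, dtype=float),
        dispersion=dispersion,
        df_resid=df_resid,
        converged=bool(res.converged),
        names=list(names),
        degenerate_dispersion=degenerate,
    )


@dataclass
class BetaRegFit:
    """Beta regression fit: logit mean model plus precision phi."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    z_statistics: np.ndarray
    p_values: np.ndarray
    precision: float
    log_likelihood: float
    converged: bool
    names: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_values[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "model": "beta_regression_logit",
            "names": list(self.names),
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "z_statistics": self.z_statistics.tolist(),
            "p_values": self.p_values.tolist(),
            "precision": float(self.precision),
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
        }


def _beta_start_values(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    # Deterministic start: OLS on the logit scale; phi from the
    # method-of-moments variance of the logit residuals.
    eta = np.log(y / (1.0 - y))
    beta0, *_ = np.linalg.lstsq(X, eta, rcond=None)
    mu = 1.0 / (1.0 + np.exp(-(X @ beta0)))
    resid_var = max(np.var(eta - X @ beta0, ddof=X.shape[1]), 1e-6)
    # var(logit y) ~ 1 / (phi mu (1-mu)) to first order
    phi0 = max(np.mean(1.0 / (resid_var * mu * (1.0 - mu))), 1.0)
    return np.concatenate([beta0, [np.log(phi0)]])


def fit_beta_regression(response, design, names=None, maxiter=500) -> BetaRegFit:
    """Joint MLE of a logit-link beta regression with constant precision.

    Responses must be strictly inside (0, 1) — callers apply boundary
    compression first.  Starts from logit-scale least squares and a
    moment estimate of the precision; standard errors come from the
    observed information at the optimum.
    """
    y = np.asarray(response, dtype=float)
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise ValueError("beta regression requires responses strictly in (0, 1)")
    X = _as_design(design)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]

    model = BetaModel(y, X, exog_precision=np.ones((y.size, 1)), link_precision=sm.families.links.Log())
    start = _beta_start_values(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=start, maxiter=maxiter, disp=False)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(start_params=res.params, method="bfgs", maxiter=maxiter, disp=False)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        raise RuntimeError(
            "beta regression failed to converge: " + repr(res.mle_retvals)
        )
    k = X.shape[1]
    coef = np.asarray(res.params[:k], dtype=float)
    se = np.asarray(res.bse[:k], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, coef / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    phi = float(np.exp(res.params[k]))
    return BetaRegFit(
        coefficients=coef,
        standard_errors=se,
        z_statistics=z,
        p_values=p,
        precision=phi,
        log_likelihood=float(res.llf),
        converged=converged,
        names=list(names),
    )


@dataclass
class BetaFit:
    """Two-parameter beta distribution MLE on (0, 1)."""

    alpha: float
    beta: float
    log_likelihood: float

    def to_dict(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "beta": float(self.beta),
            "log_likelihood": float(self.log_likelihood),
        }


def fit_beta_mle(values) -> BetaFit:
    """Beta(alpha, beta) maximum likelihood on values strictly in (0, 1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for a beta fit")
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("beta MLE requires values strictly in (0, 1)")
    a, b, loc, scale = sps.beta.fit(x, floc=0.0, fscale=1.0)
    ll = float(np.sum(sps.beta.logpdf(x, a, b)))
    return BetaFit(alpha=float(a), beta=float(b), log_likelihood=ll)


def tail_prob(fit: BetaFit, x: float, two_sided: bool = True) -> float:
    """Tail probability of ``x`` under the fitted beta distribution.

    Two-sided (default): min(CDF, survival) — how extreme the value is
    toward either boundary.  One-sided returns the upper tail.
    """
    cdf = float(sps.beta.cdf(x, fit.alpha, fit.beta))
    if two_sided:
        return min(cdf, 1.0 - cdf)
    return 1.0 - cdf


@dataclass
class TTestResult:
    statistic: float
    df: float
    p_value: float
    variant: str
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return {
            "t": float(self.statistic),
            "df": float(self.df),
            "p": float(self.p_value),
            "variant": self.variant,
            "n1": self.n1,
            "n2": self.n2,
        }


def t_test(a, b, variant: str = "welch") -> TTestResult:
    """Two-sample t-test, pooled or Welch (Satterthwaite df).

    If both groups have zero variance and equal means the statistic is 0
    and p is 1 by convention.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        df = float(x.size + y.size - 2)
        if np.mean(x) == np.mean(y):
            return TTestResult(0.0, df, 1.0, variant, x.size, y.size)
        return TTestResult(np.inf * np.sign(np.mean(x) - np.mean(y)), df, 0.0, variant, x.size, y.size)
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(x.size + y.size - 2)
    else:
        df = float(res.df)
    return TTestResult(float(res.statistic), df, float(res.pvalue), variant, x.size, y.size)


# Reference loci on the (skewness^2, kurtosis) plane. Kurtosis is the
# classical (non-excess) kind. Gamma: kurt = 3 + 1.5 s^2; lognormal is
# traced over a sigma grid.
_POINT_REFERENCES = {
    "normal": (0.0, 3.0),
    "uniform": (0.0, 1.8),
    "exponential": (4.0, 9.0),
}


@dataclass
class SkewKurtSummary:
    skewness: float
    kurtosis: float
    boot_skew2: np.ndarray
    boot_kurtosis: np.ndarray
    reference_distances: dict

    @property
    def skewness_squared(self) -> float:
        return self.skewness ** 2

    def nearest_reference(self) -> str:
        return min(self.reference_distances, key=self.reference_distances.get)

    def to_dict(self) -> dict:
        return {
            "skewness": float(self.skewness),
            "kurtosis": float(self.kurtosis),
            "n_boot": int(self.boot_skew2.size),
            "reference_distances": {k: float(v) for k, v in self.reference_distances.items()},
            "nearest_reference": self.nearest_reference(),
        }


def _unbiased_skew_kurt(x: np.ndarray) -> tuple[float, float]:
    s = float(sps.skew(x, bias=False))
    k = float(sps.kurtosis(x, fisher=False, bias=False))
    return s, k


def cullen_frey(values, n_boot: int = 200, seed: int | None = 0) -> SkewKurtSummary:
    """Skewness–kurtosis summary with bootstrap cloud and reference loci.

    The classical diagnostic for shortlisting candidate distributions:
    the sample's (skewness^2, kurtosis) point is compared with the loci
    of the normal, uniform and exponential (points), the gamma and
    lognormal (curves), and the beta family (a region, summarised here
    by its distance to the nearest boundary when outside).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values")
    if np.ptp(x) == 0.0:
        raise ValueError("constant input: skewness/kurtosis undefined")
    s, k = _unbiased_skew_kurt(x)
    s2 = s * s

    rng = np.random.default_rng(seed)
    bs2 = np.empty(n_boot)
    bk = np.empty(n_boot)
    for i in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        if np.ptp(xb) == 0.0:
            bs2[i], bk[i] = np.nan, np.nan
            continue
        sb, kb = _unbiased_skew_kurt(xb)
        bs2[i], bk[i] = sb * sb, kb

    dist = {}
    for name, (rs2, rk) in _POINT_REFERENCES.items():
        dist[name] = float(np.hypot(s2 - rs2, k - rk))
    # gamma locus: kurt = 3 + 1.5 s^2
    dist["gamma"] = abs(k - (3.0 + 1.5 * s2))
    # lognormal locus traced over sigma
    sig2 = np.linspace(1e-4, 1.5, 400) ** 2
    w = np.exp(sig2)
    ln_skew2 = (w + 2.0) ** 2 * (w - 1.0)
    ln_kurt = w**4 + 2 * w**3 + 3 * w**2 - 3.0
    dist["lognormal"] = float(np.min(np.hypot(s2 - ln_skew2, k - ln_kurt)))
    # beta region: between the impossibility boundary kurt = s^2 + 1 and
    # the gamma locus; distance 0 when inside
    lo, hi = s2 + 1.0, 3.0 + 1.5 * s2
    if lo <= k <= hi:
        dist["beta"] = 0.0
    else:
        dist["beta"] = float(min(abs(k - lo), abs(k - hi)))
    return SkewKurtSummary(
        skewness=s,
        kurtosis=k,
        boot_skew2=bs2,
        boot_kurtosis=bk,
        reference_distances=dist,
    )
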