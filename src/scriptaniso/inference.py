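"""Statistical engines for the selection and transformation analyses.

* Random-intercept linear mixed models (script family, or ancestry group, as
  the grouping factor), fitted by REML for reported estimates and by ML when
  models are compared by AIC.
* Fixed-effect inference uses the grouped-data degrees-of-freedom convention
  df = N - q - (k - 1), with q groups and k fixed-effect parameters
  (the convention of the classic nested-regression software for these models,
  so that printed dfs match e.g. 109 = 116 - 7 for an intercept-only model
  over 116 scripts in 7 families).
* The default-prior (JZS) one-sample Bayes factor in favor of the null,
  evaluated by adaptive quadrature.
* Rank and product-moment correlations with two-tailed p values.

Estimation is deterministic: no randomness enters any fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats
import statsmodels.api as sm

Method = Literal["REML", "ML"]

#: Conventional Cauchy prior scale on the standardized effect size.
DEFAULT_PRIOR_SCALE = np.sqrt(2.0) / 2.0


@dataclass
class GroupedObservations:
    """A per-script measure with its grouping label and optional binary covariate."""

    y: np.ndarray
    group: np.ndarray
    x: Optional[np.ndarray] = None
    unit: str = "proportion"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.group = np.asarray(self.group)
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=float)
            if len(self.x) != len(self.y):
                raise ValueError("x and y lengths differ")
        if len(self.group) != len(self.y):
            raise ValueError("group and y lengths differ")

    @property
    def n_groups(self) -> int:
        return len(np.unique(self.group))


@dataclass
class FixedEffect:
    name: str
    estimate: float
    se: float
    t: float
    df: int
    p: float
    ci95: tuple[float, float]


@dataclass
class LmmFit:
    """A fitted random-intercept model."""

    effects: list[FixedEffect]
    method: Method
    aic: float
    loglik: float
    group_var: float
    resid_var: float
    n_obs: int
    n_groups: int
    boundary: bool = False

    @property
    def intercept(self) -> FixedEffect:
        return self.effects[0]

    @property
    def covariate(self) -> FixedEffect:
        if len(self.effects) < 2:
            raise ValueError("model has no covariate")
        return self.effects[1]


def _fit_mixed(y: np.ndarray, exog: np.ndarray, names: list[str], groups: np.ndarray, method: Method) -> LmmFit:
    n = len(y)
    q = len(np.unique(groups))
    k = exog.shape[1]
    df = n - q - (k - 1)
    if df < 1:
        raise ValueError(f"non-positive residual df ({df})")
    model = sm.MixedLM(y, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=(method == "REML"))
        # the default optimizer can silently diverge when the between-group
        # variance is exactly on the boundary; fall back to a derivative-free fit
        scale_y = max(float(np.std(y)), 1e-12)
        bad = (not res.converged) or (not np.all(np.isfinite(res.bse_fe))) or np.any(
            np.asarray(res.bse_fe) > 1e3 * scale_y
        )
        if bad:
            res = model.fit(reml=(method == "REML"), method="powell")
        llf = float(res.llf)
    group_var = float(np.atleast_2d(res.cov_re)[0, 0])
    resid_var = float(res.scale)
    boundary = group_var <= 1e-8 * max(resid_var, 1e-12)
    tcrit = stats.t.ppf(0.975, df)
    effects = []
    for i, name in enumerate(names):
        est = float(res.fe_params[i])
        se = float(res.bse_fe[i])
        if np.isfinite(se) and se > 0:
            tval = est / se
        else:  # degenerate (zero-variance) data: point estimate is exact
            se, tval = 0.0, np.nan
        p = float(2.0 * stats.t.sf(abs(tval), df)) if np.isfinite(tval) else np.nan
        effects.append(
            FixedEffect(
                name=name,
                estimate=est,
                se=se,
                t=float(tval),
                df=int(df),
                p=p,
                ci95=(est - tcrit * se, est + tcrit * se),
            )
        )
    # parameter count for AIC: fixed effects + group variance + residual variance
    n_params = k + 2
    aic = float(-2.0 * llf + 2.0 * n_params)
    return LmmFit(
        effects=effects,
        method=method,
        aic=aic,
        loglik=llf,
        group_var=group_var,
        resid_var=resid_var,
        n_obs=n,
        n_groups=q,
        boundary=boundary,
    )


def fit_intercept_model(obs: GroupedObservations, method: Method = "REML") -> LmmFit:
    """Null model: y = mu + b_group + eps with a random intercept per group."""
    if obs.n_groups < 2:
        raise ValueError("need at least 2 groups for a mixed fit")
    if len(obs.y) < 3:
        raise ValueError("need at least 3 observations")
    exog = np.ones((len(obs.y), 1))
    return _fit_mixed(obs.y, exog, ["intercept"], obs.group, method)


def fit_status_model(obs: GroupedObservations, method: Method = "REML") -> LmmFit:
    """Adds the binary covariate (e.g. live = 1, extinct = 0) as a fixed effect."""
    if obs.x is None:
        raise ValueError("observations carry no covariate")
    levels = np.unique(obs.x)
    if len(levels) < 2:
        raise ValueError("covariate has a single level")
    if obs.n_groups < 2:
        raise ValueError("need at least 2 groups for a mixed fit")
    exog = np.column_stack([np.ones(len(obs.y)), obs.x])
    return _fit_mixed(obs.y, exog, ["intercept", "x"], obs.group, method)


def compare_aic(null_fit: LmmFit, alt_fit: LmmFit) -> tuple[str, float]:
    """Compare two ML fits by AIC; returns ('null'|'alt', alt_aic - null_aic)."""
    if null_fit.method != "ML" or alt_fit.method != "ML":
        raise ValueError("AIC comparison requires both fits by ML")
    delta = alt_fit.aic - null_fit.aic
    return ("alt" if delta < 0 else "null", float(delta))


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BayesFactorResult:
    bf01: float
    t: float
    n: int
    prior_scale: float

    @property
    def bf10(self) -> float:
        return 1.0 / self.bf01


def _jzs_integrand(g: np.ndarray, t: float, n: int, r: float) -> np.ndarray:
    """Marginal likelihood integrand over the variance-scale mixing parameter g.

    The Cauchy prior on the standardized effect is the inverse-gamma(1/2, 1/2)
    scale mixture of normals; the integrand combines the marginal t density
    at mixing value g with that density.
    """
    g = np.asarray(g, dtype=float)
    nu = n - 1
    w = 1.0 + n * g * r * r
    dens = w ** (-0.5) * (1.0 + t * t / (nu * w)) ** (-(nu + 1) / 2.0)
    # inverse-gamma(1/2, 1/2) pdf
    prior = (2.0 * np.pi) ** (-0.5) * g ** (-1.5) * np.exp(-1.0 / (2.0 * g))
    return dens * prior


def jzs_bf01_from_t(t: float, n: int, prior_scale: float = DEFAULT_PRIOR_SCALE) -> BayesFactorResult:
    """JZS Bayes factor in favor of the point null, from a one-sample t statistic."""
    if n < 2:
        raise ValueError("need n >= 2")
    nu = n - 1

    def integrand_z(z: float) -> float:
        g = z / (1.0 - z)
        return float(_jzs_integrand(g, t, n, prior_scale)) / (1.0 - z) ** 2

    num, _ = integrate.quad(integrand_z, 0.0, 1.0, limit=200)
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    bf10 = num / den
    return BayesFactorResult(bf01=1.0 / bf10, t=float(t), n=int(n), prior_scale=float(prior_scale))


def jzs_bf01(values: Sequence[float], prior_scale: float = DEFAULT_PRIOR_SCALE) -> BayesFactorResult:
    """JZS one-sample Bayes factor for the null that the mean of ``values`` is 0."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero or non-finite variance")
    t = v.mean() / (sd / np.sqrt(len(v)))
    return jzs_bf01_from_t(float(t), len(v), prior_scale)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    return x, y


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-tailed p."""
    x, y = _check_pair(x, y)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def product_moment_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation with two-tailed p."""
    x, y = _check_pair(x, y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def format_p(p: float) -> str:
    """Report p to 3 decimals, with 'p < .001' below that."""
    if p < 0.001:
        return "p < .001"
    return f"p = {p:.3f}".replace("0.", ".")
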