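"""Mixed models for dichotomous abundance-response analysis.

The central model is a binomial GLMM with logit link and a single
random-intercept grouping factor (species):

    logit P(y_ij = 1) = x_ij' beta + u_j,      u_j ~ N(0, sigma^2)

The marginal likelihood integrates the random intercept out of each group's
Bernoulli likelihood:

    L(beta, sigma) = prod_j  integral  prod_i Bernoulli(y_ij | expit(x'beta + sigma v))
                                       phi(v) dv

Each group integral is one-dimensional; it is approximated by a Laplace
approximation around the conditional mode of v, optionally refined with
adaptive Gauss-Hermite quadrature (AGQ) centred and scaled at that mode.
The approximate marginal log-likelihood is maximised over (beta, sigma)
with sigma bounded below by zero; at sigma = 0 the Laplace likelihood is
exact and equals the plain logistic-regression likelihood.

Wald inference (z = beta_hat / SE, two-sided normal p) uses the observed
information, computed as a finite-difference Hessian of the marginal
log-likelihood at the optimum.

Gaussian responses (the continuous-slope sensitivity models and the
water-temperature warming trend) are delegated to statsmodels' linear
mixed-effects implementation behind the same result container.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

logger = logging.getLogger(__name__)

_SEPARATION_BOUND = 15.0  # |beta| beyond this on a logit scale flags separation


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one mixed-model fit.

    Parameters
    ----------
    response
        Column holding the response (binary 0/1 for the binomial family,
        continuous for gaussian).
    fixed_terms
        Predictor columns entered as main effects.
    interaction
        Optional pair of columns whose product is entered as an interaction
        (main effects are added automatically if absent).
    grouping
        Random-intercept factor (one grouping factor only).
    family
        ``"binomial"`` (logit link) or ``"gaussian"``.
    scale_predictors
        If True, numeric predictors are z-scored (mean 0, SD 1, ddof=1)
        before fitting — except those listed in ``unscaled_terms``.  The
        range-position predictor is conventionally left on its natural 0-1
        scale.
    """

    response: str
    fixed_terms: tuple[str, ...] | list[str]
    interaction: tuple[str, str] | None = None
    grouping: str = "species"
    family: str = "binomial"
    scale_predictors: bool = False
    unscaled_terms: tuple[str, ...] = ("position",)

    def __post_init__(self):
        if self.family not in ("binomial", "gaussian"):
            raise ValueError("family must be 'binomial' or 'gaussian'")
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))


@dataclass
class MixedModelFit:
    """Result of one mixed-model fit.

    ``coefficients`` is a tidy frame with columns
    ``term, estimate, se, z, p``.  ``random_intercept_sd`` is the estimated
    SD of the grouping-factor intercepts.  ``predictions`` is populated by
    :func:`predict_probability` when requested.
    """

    spec: ModelSpec
    coefficients: pd.DataFrame
    random_intercept_sd: float
    log_likelihood: float
    n_obs: int
    n_groups: int
    converged: bool
    method: str
    warnings: list[str] = field(default_factory=list)
    predictions: pd.DataFrame | None = None
    # fitting internals kept for prediction: design column names, the
    # centring/scaling applied to each term, covariance of fixed effects,
    # and observed ranges of numeric predictors (extrapolation check).
    design_names: list[str] = field(default_factory=list)
    scale_info: dict = field(default_factory=dict)
    cov_fixed: np.ndarray | None = None
    data_ranges: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "se"])


# ---------------------------------------------------------------------------
# design matrices


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Build the fixed-effects design matrix for ``spec`` on ``data``.

    Returns ``(y, X, names, scale_info, group_codes, group_labels, ranges)``.
    Categorical terms are dummy-coded with the first (sorted) level as
    reference; numeric terms are optionally z-scored.  The interaction
    column is the product of the two (possibly scaled) component columns.
    """
    terms = list(spec.fixed_terms)
    if spec.interaction is not None:
        for t in spec.interaction:
            if t not in terms:
                terms.append(t)

    needed = [spec.response, spec.grouping] + terms
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"data missing columns: {missing}")
    df = data[needed].dropna()
    if len(df) == 0:
        raise ValueError("no complete rows to fit")

    y = df[spec.response].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    scale_info: dict = {}
    ranges: dict = {}
    term_cols: dict[str, np.ndarray] = {}

    for t in terms:
        s = df[t]
        if _is_categorical(s):
            levels = sorted(pd.unique(s.astype(str)))
            if len(levels) < 2:
                raise ValueError(f"categorical term {t!r} has a single level")
            if len(levels) > 2 and spec.interaction and t in spec.interaction:
                raise ValueError("interaction with >2-level categorical not supported")
            for lev in levels[1:]:
                col = (s.astype(str) == lev).to_numpy(dtype=float)
                cols.append(col)
                nm = f"{t}[{lev}]"
                names.append(nm)
                term_cols[t] = col  # last (only, for 2-level) dummy
            scale_info[t] = ("categorical", levels)
        else:
            v = s.to_numpy(dtype=float)
            ranges[t] = (float(np.min(v)), float(np.max(v)), float(np.median(v)))
            if spec.scale_predictors and t not in spec.unscaled_terms:
                mu, sd = float(np.mean(v)), float(np.std(v, ddof=1))
                if sd == 0.0:
                    raise ValueError(f"cannot scale constant predictor {t!r}")
                v = (v - mu) / sd
                scale_info[t] = ("scaled", mu, sd)
            else:
                scale_info[t] = ("identity",)
            cols.append(v)
            names.append(t)
            term_cols[t] = v

    if spec.interaction is not None:
        a, b = spec.interaction
        cols.append(term_cols[a] * term_cols[b])
        names.append(f"{a}:{b}")

    X = np.column_stack(cols)
    group_labels, group_codes = np.unique(df[spec.grouping].to_numpy(), return_inverse=True)
    return y, X, names, scale_info, group_codes, group_labels, ranges


def _design_row(values: dict, names, scale_info, spec: ModelSpec) -> np.ndarray:
    """One design row from raw predictor values, applying stored scaling."""
    comp: dict[str, float] = {}
    row = []
    for nm in names:
        if nm == "intercept":
            row.append(1.0)
        elif ":" in nm:
            a, b = nm.split(":")
            row.append(comp[a] * comp[b])
        elif "[" in nm:
            t, lev = nm[:-1].split("[")
            val = float(str(values[t]) == lev)
            comp[t] = val
            row.append(val)
        else:
            info = scale_info[nm]
            v = float(values[nm])
            if info[0] == "scaled":
                v = (v - info[1]) / info[2]
            comp[nm] = v
            row.append(v)
    return np.array(row)


# ---------------------------------------------------------------------------
# binomial GLMM: Laplace / AGQ marginal likelihood


def _conditional_modes(y, eta0, sigma, gidx, n_groups, tol=1e-11, max_iter=100):
    """Newton solve for the per-group mode of the conditional density of v.

    h_j(v) = sum_i [y eta - log(1+e^eta)] - v^2/2 - log(2 pi)/2 with
    eta = eta0 + sigma v.  h is strictly concave with h'' <= -1, so plain
    Newton (with a conservative step clip) converges quickly.  Returns the
    modes and the negated curvature -h''(v_hat) per group.
    """
    v = np.zeros(n_groups)
    curv = np.ones(n_groups)
    for _ in range(max_iter):
        eta = eta0 + sigma * v[gidx]
        p = expit(eta)
        grad = sigma * np.bincount(gidx, weights=y - p, minlength=n_groups) - v
        w = np.bincount(gidx, weights=p * (1.0 - p), minlength=n_groups)
        curv = sigma * sigma * w + 1.0
        step = grad / curv
        np.clip(step, -5.0, 5.0, out=step)
        v += step
        if np.max(np.abs(grad)) < tol:
            break
    return v, curv


def _group_loglik_terms(y, eta, gidx, n_groups):
    ll = y * eta - np.logaddexp(0.0, eta)
    return np.bincount(gidx, weights=ll, minlength=n_groups)


def glmm_marginal_loglik(y, X, group_codes, beta, sigma, method="laplace", agq_nodes=15):
    """Approximate marginal log-likelihood of the logit random-intercept model.

    ``method`` is ``"laplace"`` or ``"agq"`` (adaptive Gauss-Hermite with
    ``agq_nodes`` nodes, at least 10 recommended).  Exposed so the
    approximation can be verified against independent dense integration.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    gidx = np.asarray(group_codes)
    n_groups = int(gidx.max()) + 1 if len(gidx) else 0
    beta = np.asarray(beta, float)
    sigma = abs(float(sigma))

    eta0 = X @ beta
    vhat, curv = _conditional_modes(y, eta0, sigma, gidx, n_groups)
    eta_hat = eta0 + sigma * vhat[gidx]
    h_hat = (
        _group_loglik_terms(y, eta_hat, gidx, n_groups)
        - 0.5 * vhat**2
        - 0.5 * np.log(2.0 * np.pi)
    )
    if method == "laplace":
        return float(np.sum(h_hat + 0.5 * np.log(2.0 * np.pi) - 0.5 * np.log(curv)))
    if method != "agq":
        raise ValueError("method must be 'laplace' or 'agq'")

    nodes, weights = hermgauss(agq_nodes)
    s = 1.0 / np.sqrt(curv)
    acc = np.zeros(n_groups)
    sqrt2 = np.sqrt(2.0)
    for x_k, w_k in zip(nodes, weights):
        v_k = vhat + sqrt2 * s * x_k
        eta = eta0 + sigma * v_k[gidx]
        h_k = (
            _group_loglik_terms(y, eta, gidx, n_groups)
            - 0.5 * v_k**2
            - 0.5 * np.log(2.0 * np.pi)
        )
        acc += w_k * np.exp(h_k - h_hat + x_k * x_k)
    return float(np.sum(h_hat + np.log(sqrt2 * s * acc)))


def _numeric_hessian(f, x, rel_step=1e-4):
    n = len(x)
    h = rel_step * (np.abs(x) + 1.0)
    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        f0 = f(x)
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    method: str = "laplace",
    agq_nodes: int = 15,
    max_iter: int = 500,
) -> MixedModelFit:
    """Fit a binomial (logit) GLMM with a single random intercept.

    The optimiser starts deterministically from the no-random-effect
    logistic fit (IRLS) with a modest initial sigma.  Non-convergence and
    apparent complete separation are flagged in ``fit.warnings`` rather
    than raised; the reporting pipeline skips unconverged fits.
    """
    if spec.family != "binomial":
        raise ValueError("fit_glmm requires family='binomial'")
    y, X, names, scale_info, gidx, glabels, ranges = build_design(data, spec)
    uy = np.unique(y)
    if not np.all(np.isin(uy, [0.0, 1.0])):
        raise ValueError("binomial response must be coded 0/1")
    n_groups = len(glabels)
    if n_groups < 2:
        raise ValueError("need at least 2 groups for a random intercept")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    x0 = np.concatenate([glm.params, [0.5]])

    def nll(theta):
        return -glmm_marginal_loglik(
            y, X, gidx, theta[:-1], theta[-1], method=method, agq_nodes=agq_nodes
        )

    p = X.shape[1]
    bounds = [(None, None)] * p + [(0.0, None)]
    res = minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-8},
    )
    theta = res.x
    beta_hat, sigma_hat = theta[:-1], float(theta[-1])
    ll = -float(res.fun)
    fit_warnings: list[str] = []
    converged = bool(res.success)
    if not converged:
        fit_warnings.append(f"optimizer did not converge: {res.message}")
        logger.warning("fit_glmm: %s", res.message)
    if np.max(np.abs(beta_hat)) > _SEPARATION_BOUND:
        fit_warnings.append("possible complete separation (|beta| > 15)")
        logger.warning("fit_glmm: possible complete separation")

    # observed information; near the sigma >= 0 boundary the sigma row of
    # the Hessian is one-sided, so profile it out and report SEs for beta
    # at sigma fixed.
    if sigma_hat > 1e-4:
        H = _numeric_hessian(nll, theta)
        try:
            cov = np.linalg.inv(H)
            cov_beta = cov[:p, :p]
        except np.linalg.LinAlgError:
            fit_warnings.append("singular information matrix")
            cov_beta = np.full((p, p), np.nan)
    else:
        Hb = _numeric_hessian(lambda b: nll(np.concatenate([b, [sigma_hat]])), beta_hat)
        try:
            cov_beta = np.linalg.inv(Hb)
        except np.linalg.LinAlgError:
            fit_warnings.append("singular information matrix")
            cov_beta = np.full((p, p), np.nan)

    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta_hat / se
    pvals = 2.0 * norm.sf(np.abs(z))
    coefs = pd.DataFrame(
        {"term": names, "estimate": beta_hat, "se": se, "z": z, "p": pvals}
    )
    return MixedModelFit(
        spec=spec,
        coefficients=coefs,
        random_intercept_sd=sigma_hat,
        log_likelihood=ll,
        n_obs=len(y),
        n_groups=n_groups,
        converged=converged,
        method=method,
        warnings=fit_warnings,
        design_names=names,
        scale_info=scale_info,
        cov_fixed=cov_beta,
        data_ranges=ranges,
    )


# ---------------------------------------------------------------------------
# gaussian mixed models (statsmodels backend)


def fit_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    reml: bool = False,
) -> MixedModelFit:
    """Fit a gaussian linear mixed model with a single random intercept.

    Maximum likelihood by default (REML optional).  t statistics are
    computed as estimate/SE with two-sided normal p-values.  With a single
    group the model degenerates and an OLS fit is returned instead, with a
    note in ``fit.warnings``.
    """
    if spec.family != "gaussian":
        spec = replace(spec, family="gaussian")
    y, X, names, scale_info, gidx, glabels, ranges = build_design(data, spec)
    n_groups = len(glabels)
    fit_warnings: list[str] = []

    if n_groups < 2:
        fit_warnings.append("single group: fell back to ordinary least squares")
        logger.info("fit_lmm: single group, OLS fallback")
        ols = sm.OLS(y, X).fit()
        est, se_, llf = ols.params, ols.bse, float(ols.llf)
        sd_re, converged = 0.0, True
        cov_beta = np.asarray(ols.cov_params())
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=gidx)
            res = model.fit(reml=reml, maxiter=500)
        p = X.shape[1]
        est = np.asarray(res.fe_params)
        se_ = np.asarray(res.bse_fe)
        llf = float(res.llf)
        sd_re = float(np.sqrt(max(float(np.asarray(res.cov_re)[0, 0]), 0.0)))
        converged = bool(res.converged)
        try:
            cov_beta = np.asarray(res.cov_params())[:p, :p]
        except (np.linalg.LinAlgError, ValueError):
            cov_beta = np.diag(se_**2)  # variance-component Hessian singular
        if not converged:
            fit_warnings.append(
                "LMM optimizer flagged non-convergence (often a zero-variance boundary)"
            )

    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se_
    pvals = 2.0 * norm.sf(np.abs(z))
    coefs = pd.DataFrame({"term": names, "estimate": est, "se": se_, "z": z, "p": pvals})
    return MixedModelFit(
        spec=spec,
        coefficients=coefs,
        random_intercept_sd=sd_re,
        log_likelihood=llf,
        n_obs=len(y),
        n_groups=n_groups,
        converged=converged,
        method="reml" if reml else "ml",
        warnings=fit_warnings,
        design_names=names,
        scale_info=scale_info,
        cov_fixed=cov_beta,
        data_ranges=ranges,
    )


# ---------------------------------------------------------------------------
# predictions and the continuous-slope sensitivity check


def predict_probability(
    fit: MixedModelFit,
    positions: np.ndarray | None = None,
    at: dict | None = None,
    n_grid: int = 101,
) -> pd.DataFrame:
    """Population-level predicted probabilities over a range-position grid.

    The random intercept is set to its population mean (0); the linear
    predictor x'beta is transformed through the inverse logit with a
    delta-method 95% CI computed on the linear-predictor scale.  ``at``
    supplies raw values for other predictors (defaults: observed median for
    numeric terms, reference level for categoricals).  Values outside the
    fitted range are allowed and flagged as extrapolation.
    """
    if not fit.converged:
        raise ValueError("predictions require a converged fit")
    if fit.spec.family != "binomial":
        raise ValueError("predict_probability applies to binomial fits")
    if positions is None:
        positions = np.linspace(0.0, 1.0, n_grid)
    positions = np.asarray(positions, float)
    at = dict(at or {})

    defaults: dict = {}
    for t, info in fit.scale_info.items():
        if info[0] == "categorical":
            defaults[t] = info[1][0]
        elif t in fit.data_ranges:
            defaults[t] = fit.data_ranges[t][2]  # median
    defaults.update(at)

    beta = fit.coefficients["estimate"].to_numpy()
    rows = []
    for pos in positions:
        values = dict(defaults)
        values["position"] = pos
        x = _design_row(values, fit.design_names, fit.scale_info, fit.spec)
        eta = float(x @ beta)
        var = float(x @ fit.cov_fixed @ x)
        half = 1.959963984540054 * np.sqrt(max(var, 0.0))
        lo_r, hi_r, _ = fit.data_ranges.get("position", (0.0, 1.0, 0.5))
        rows.append(
            {
                "position": pos,
                "probability": float(expit(eta)),
                "ci_low": float(expit(eta - half)),
                "ci_high": float(expit(eta + half)),
                "extrapolated": bool(pos < lo_r or pos > hi_r),
            }
        )
    grid = pd.DataFrame(rows)
    fit.predictions = grid
    return grid


@dataclass
class SlopeSensitivity:
    """Binomial fit, its gaussian (continuous-slope) analogue, and whether
    the two position coefficients agree in sign."""

    binomial: MixedModelFit
    gaussian: MixedModelFit
    sign_agreement: bool


def slope_sensitivity(
    data: pd.DataFrame,
    spec: ModelSpec,
    slope_column: str = "slope",
) -> SlopeSensitivity:
    """Refit the binomial model with the continuous regression slope as the
    response (gaussian family) and compare position-coefficient signs."""
    bin_fit = fit_glmm(data, spec)
    gspec = replace(spec, response=slope_column, family="gaussian")
    lin_fit = fit_lmm(data, gspec)
    agree = np.sign(bin_fit.coef("position")) == np.sign(lin_fit.coef("position"))
    return SlopeSensitivity(binomial=bin_fit, gaussian=lin_fit, sign_agreement=bool(agree))
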