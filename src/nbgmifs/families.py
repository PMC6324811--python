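"""Poisson and negative binomial (NB) likelihood primitives.

Both families use a log link with an optional log-exposure offset, so the
mean model is a rate model::

    mu_i = c_i * exp(gamma0 + x_i' gamma + z_i' beta)

The NB distribution is parameterised by its mean ``mu`` and heterogeneity
``alpha`` (the inverse of the classical dispersion ``phi``), so that
``Var(Y) = mu + alpha * mu**2``.  ``alpha -> 0`` recovers the Poisson.
Everything is computed in log space via ``gammaln``; the Gamma-function
ratios in the NB mass function overflow for counts above ~170 otherwise.
"""

from __future__ import annotations

import numpy as np
from numpy.linalg import solve
from scipy.special import gammaln

#: Smallest admissible heterogeneity; keeps every NB formula defined while
#: being numerically indistinguishable from a Poisson model.
ALPHA_FLOOR = 1e-8


class ConvergenceError(RuntimeError):
    """Inner maximum-likelihood fit failed to converge.

    Carries the last iterate in ``last_params`` so callers can inspect or
    restart from it.
    """

    def __init__(self, message: str, last_params: np.ndarray | None = None):
        super().__init__(message)
        self.last_params = last_params


def _validate_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)) or not np.all(np.isfinite(y)):
        raise ValueError("counts must be finite non-negative integers")
    return y


def nb_log_pmf(y, mu, alpha):
    """Log of the NB mass function at count ``y`` with mean ``mu``.

    Parameters
    ----------
    y : int or array
        Non-negative integer count(s).
    mu : float or array
        Positive mean(s).
    alpha : float
        Positive heterogeneity; ``Var(Y) = mu + alpha*mu**2``.

    Returns
    -------
    float or ndarray
        ``log f(y; mu, alpha)``, finite for all valid inputs.
    """
    y = _validate_counts(np.asarray(y))
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        raise ValueError("mu must be positive and finite")
    if not np.isscalar(alpha) or alpha <= 0:
        raise ValueError("alpha must be a positive scalar")
    inv = 1.0 / alpha
    if alpha < 1e-5:
        # gammaln(y + 1/a) - gammaln(1/a) loses ~1e-5 absolute precision for
        # 1/a >~ 1e6; y is integral, so the Gamma ratio is the exact finite
        # sum  y*log(1/a) + sum_{j<y} log1p(j*a),  which cancels y*log(a*mu)
        # down to y*log(mu) and stays accurate into the Poisson limit.
        ratio = _gammaln_ratio_smalla(y, alpha)
        ylogmu = np.where(y > 0, y * np.log(mu), 0.0)
        out = ratio - gammaln(y + 1.0) - (y + inv) * np.log1p(alpha * mu) + ylogmu
        return out if out.ndim else float(out)
    # y*log(alpha*mu) with y == 0 must contribute exactly 0
    ylog = np.where(y > 0, y * (np.log(alpha) + np.log(mu)), 0.0)
    out = (
        gammaln(y + inv)
        - gammaln(y + 1.0)
        - gammaln(inv)
        - (y + inv) * np.log1p(alpha * mu)
        + ylog
    )
    return out if out.ndim else float(out)


def _gammaln_ratio_smalla(y, alpha):
    """``gammaln(y + 1/a) - gammaln(1/a) - y*log(1/a)`` for integral y."""
    y_int = np.asarray(y, dtype=int)
    ymax = int(y_int.max(initial=0))
    csum = np.concatenate([[0.0], np.cumsum(np.log1p(alpha * np.arange(ymax)))])
    return csum[y_int]


def poisson_log_pmf(y, mu):
    """Poisson log mass function, ``y*log(mu) - mu - log(y!)``."""
    y = _validate_counts(np.asarray(y))
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    ylog = np.where(y > 0, y * np.log(mu), 0.0)
    out = ylog - mu - gammaln(y + 1.0)
    return out if out.ndim else float(out)


def nb_loglik(y, mu, alpha) -> float:
    """NB log-likelihood: sum of :func:`nb_log_pmf` over observations."""
    return float(np.sum(nb_log_pmf(y, mu, alpha)))


def poisson_loglik(y, mu) -> float:
    """Poisson log-likelihood: sum of :func:`poisson_log_pmf`."""
    return float(np.sum(poisson_log_pmf(y, mu)))


def expanded_score(y, mu, alpha, expanded_design):
    """Gradient of the log-likelihood over an expanded [X : -X] design.

    The working residual is ``(y - mu) / (1 + alpha*mu)`` for the NB family
    (``alpha = 0`` gives the Poisson case), and the score for each expanded
    column is its inner product with that residual.  The two halves of the
    result are exact negations of each other by construction of the design.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha is None:
        alpha = 0.0
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    expanded_design = np.asarray(expanded_design, dtype=float)
    if expanded_design.shape[0] != y.shape[0]:
        raise ValueError("expanded design row count does not match y")
    resid = (y - mu) / (1.0 + alpha * mu)
    return expanded_design.T @ resid


def nb_score_expanded(y, mu, alpha, expanded_design):
    """NB score over the expanded design; ``alpha`` must be positive."""
    if not alpha > 0:
        raise ValueError("alpha must be positive for the NB score")
    return expanded_score(y, mu, alpha, expanded_design)


def poisson_score_expanded(y, mu, expanded_design):
    """Poisson score over the expanded design (NB score at ``alpha = 0``)."""
    return expanded_score(y, mu, 0.0, expanded_design)


def estimate_alpha_mom(y, mu, floor: float = ALPHA_FLOOR) -> float:
    """Method-of-moments heterogeneity estimate from fitted means.

    Solves ``Var(Y) = mu + alpha*mu**2`` in the moment sense:

        alpha_hat = sum[(y - mu)^2 - mu] / sum[mu^2]

    clipped below at ``floor`` so downstream NB formulas stay defined when
    the data are equi- or under-dispersed.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have the same length")
    if y.size < 2:
        raise ValueError("at least two observations are required")
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    return max(float(num / den), floor)


def estimate_alpha_pearson(
    y, mu, n_mean_params: int = 1, floor: float = ALPHA_FLOOR, alpha_max: float = 1e6
) -> float:
    """Moment estimate of alpha from the NB Pearson chi-square equation.

    Solves for the heterogeneity that makes the Pearson statistic of the NB
    variance function match the residual degrees of freedom:

        sum (y - mu)^2 / (mu * (1 + alpha*mu))  =  N - n_mean_params

    This df-aware form stays consistent as the mean model grows: fitted
    models with many parameters need a larger alpha to explain the same
    residual spread, which prevents the estimate from collapsing to zero
    purely through overfitting.  Clipped to ``[floor, alpha_max]``.
    """
    from scipy.optimize import brentq

    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.size < 2:
        raise ValueError("at least two observations are required")
    n = y.size
    dof = max(n - n_mean_params, 1)

    def excess(a):
        return float(np.sum((y - mu) ** 2 / (mu * (1.0 + a * mu)))) - dof

    if excess(floor) <= 0:
        return floor
    hi = 1.0
    while excess(hi) > 0:
        hi *= 4.0
        if hi > alpha_max:
            return alpha_max
    return float(brentq(excess, floor, hi, xtol=1e-10))


def estimate_alpha_ml(
    y, mu, floor: float = ALPHA_FLOOR, alpha_max: float = 1e3
) -> float:
    """Maximum-likelihood heterogeneity given fixed fitted means.

    One-dimensional maximisation of the NB log-likelihood over
    ``log(alpha)`` with ``mu`` held at its current fitted values; the floor
    is always evaluated explicitly so equi-dispersed data return it.
    """
    from scipy.optimize import minimize_scalar

    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)

    def nll(log_a):
        a = float(np.exp(log_a))
        inv = 1.0 / a
        ylog = np.where(y > 0, y * (np.log(a) + np.log(mu)), 0.0)
        return -float(
            np.sum(
                gammaln(y + inv)
                - gammaln(y + 1.0)
                - gammaln(inv)
                - (y + inv) * np.log1p(a * mu)
                + ylog
            )
        )

    res = minimize_scalar(
        nll, bounds=(np.log(floor), np.log(alpha_max)), method="bounded"
    )
    if nll(np.log(floor)) < res.fun:
        return floor
    return float(np.exp(res.x))


def nb_sample(mu, alpha, rng) -> np.ndarray:
    """Draw NB counts via the gamma-Poisson mixture.

    ``Y | G ~ Poisson(G)`` with ``G ~ Gamma(shape=1/alpha, scale=alpha*mu)``
    has ``E[Y] = mu`` and ``Var[Y] = mu + alpha*mu**2``.  At or below the
    alpha floor the draw degenerates to a plain Poisson.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha <= ALPHA_FLOOR:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Inner (unpenalized) maximum-likelihood fits
# ---------------------------------------------------------------------------


def _loglik_eta(y, eta, family, alpha, const):
    """Log-likelihood as a function of the linear predictor; ``const`` holds
    the eta-independent terms so repeated evaluation is cheap."""
    if family == "poisson":
        return float(np.sum(y * eta - np.exp(eta))) + const
    inv = 1.0 / alpha
    return float(np.sum(y * eta - (y + inv) * np.log1p(alpha * np.exp(eta)))) + const


def _loglik_const(y, family, alpha):
    if family == "poisson":
        return float(-np.sum(gammaln(y + 1.0)))
    if alpha < 1e-5:  # precise small-alpha path (y*log(alpha) cancels)
        return float(np.sum(_gammaln_ratio_smalla(y, alpha) - gammaln(y + 1.0)))
    inv = 1.0 / alpha
    ylog = np.where(y > 0, y * np.log(alpha), 0.0)
    return float(
        np.sum(gammaln(y + inv) - gammaln(y + 1.0) - gammaln(inv) + ylog)
    )


def fit_unpenalized_mle(
    y,
    design,
    offset,
    family: str = "negbin",
    alpha: float | None = None,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Newton fit of the intercept and unpenalized coefficients.

    ``design`` is the N x (1+J) matrix [1 : Xu]; ``offset`` absorbs both the
    log exposure and any fixed penalized contribution, so this maximises the
    log-likelihood over (gamma0, gamma) only.  Convergence requires the
    infinity norm of the gradient to fall below ``tol``.

    Returns ``(theta, loglik)`` where ``theta[0]`` is the intercept.

    Raises
    ------
    ConvergenceError
        After ``max_iter`` Newton iterations without meeting ``tol``; the
        exception carries the last iterate.
    """
    y = np.asarray(y, dtype=float)
    A = np.asarray(design, dtype=float)
    offset = np.asarray(offset, dtype=float)
    n, p = A.shape
    if family == "negbin":
        if alpha is None or alpha <= 0:
            raise ValueError("negbin fit requires a positive alpha")
    elif family != "poisson":
        raise ValueError(f"unknown family {family!r}")
    const = _loglik_const(y, family, alpha)
    if start is not None:
        theta = np.array(start, dtype=float)
    else:
        # moment start: intercept at log of the offset-adjusted mean
        theta = np.zeros(p)
        theta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    eta = A @ theta + offset
    ll = _loglik_eta(y, eta, family, alpha, const)
    for _ in range(max_iter):
        mu = np.exp(eta)
        if family == "poisson":
            resid = y - mu
            w = mu
        else:
            denom = 1.0 + alpha * mu
            resid = (y - mu) / denom
            w = mu * (1.0 + alpha * y) / denom**2
        grad = A.T @ resid
        if np.max(np.abs(grad)) < tol:
            return theta, ll
        hess = A.T @ (A * w[:, None])
        try:
            step = solve(hess, grad)
        except np.linalg.LinAlgError:
            step = grad / max(np.max(w) * n, 1.0)
        # backtracking: accept the first step that does not decrease ll
        t = 1.0
        for _ in range(40):
            cand = theta + t * step
            eta_c = A @ cand + offset
            ll_c = _loglik_eta(y, eta_c, family, alpha, const)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                break
            t *= 0.5
        theta, eta, ll = cand, eta_c, ll_c
    # final gradient check before giving up
    mu = np.exp(eta)
    resid = (y - mu) if family == "poisson" else (y - mu) / (1.0 + alpha * mu)
    if np.max(np.abs(A.T @ resid)) < tol:
        return theta, ll
    raise ConvergenceError(
        f"inner MLE did not converge in {max_iter} iterations", last_params=theta
    )


def fit_nb_mle(
    y,
    design,
    offset,
    alpha_max: float = 1e3,
    start: np.ndarray | None = None,
):
    """Full NB maximum likelihood over (gamma0, gamma, alpha >= floor).

    Profiles the heterogeneity: for each candidate ``alpha`` the mean
    coefficients are refit by :func:`fit_unpenalized_mle`, and the profile
    log-likelihood is maximised over ``log(alpha)`` on
    ``[log ALPHA_FLOOR, log alpha_max]`` with a bounded scalar search.  The
    boundary value is always evaluated explicitly, which keeps the fit
    well-behaved when the data are actually Poisson (alpha on the boundary).

    Returns ``(theta, alpha, loglik)``.
    """
    from scipy.optimize import minimize_scalar

    y = np.asarray(y, dtype=float)
    cache = {"theta": start}

    def profile(log_a: float) -> float:
        a = float(np.exp(log_a))
        try:
            theta, ll = fit_unpenalized_mle(
                y, design, offset, "negbin", alpha=a, start=cache["theta"]
            )
        except ConvergenceError as err:  # keep the search going
            theta = err.last_params
            eta = np.asarray(design) @ theta + offset
            ll = _loglik_eta(y, eta, "negbin", a, _loglik_const(y, "negbin", a))
        cache["theta"] = theta
        return -ll

    lo, hi = np.log(ALPHA_FLOOR), np.log(alpha_max)
    res = minimize_scalar(profile, bounds=(lo, hi), method="bounded")
    best_log_a, best_nll = res.x, res.fun
    nll_floor = profile(lo)
    if nll_floor < best_nll:
        best_log_a, best_nll = lo, nll_floor
    alpha = float(np.exp(best_log_a))
    theta, ll = fit_unpenalized_mle(
        y, design, offset, "negbin", alpha=alpha, start=cache["theta"]
    )
    return theta, alpha, ll
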