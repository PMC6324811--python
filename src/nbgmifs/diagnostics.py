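"""Over-dispersion diagnostics: Poisson vs negative binomial.

Before fitting a penalized model one should decide whether the count
outcome is over-dispersed (Var(Y) > E(Y)), in which case the NB family is
preferred over the Poisson.  This module provides four standard checks on
the *unpenalized* mean model (offset + forced-in covariates only):

* a boundary likelihood-ratio test of ``alpha = 0`` (the null puts the
  heterogeneity on the parameter boundary, so the reference distribution is
  the mixture 0.5*chi2_0 + 0.5*chi2_1; the plain chi2_1 p-value is also
  reported since it is the conservative convention some software prints),
* the Cameron–Trivedi auxiliary-regression score test,
* a Lagrange multiplier test built from the squared excess-variance sum,
* the Pearson dispersion statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CountDataset
from .families import fit_nb_mle, fit_unpenalized_mle, poisson_loglik, nb_loglik


@dataclass
class TestResult:
    """Outcome of a dispersion test."""

    __test__ = False  # a result container, not a pytest class

    statistic: float
    p_value: float
    test_name: str
    null_hypothesis: str
    df: int | str = 1
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise ValueError("test statistic must be finite")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def _design(data: CountDataset) -> np.ndarray:
    return np.column_stack([np.ones(data.n_obs), data.X_unpenalized])


def _poisson_fit(data: CountDataset):
    A = _design(data)
    theta, ll = fit_unpenalized_mle(data.y, A, data.offset, family="poisson")
    mu = np.exp(A @ theta + data.offset)
    return theta, mu, ll


def boundary_lr_test(data: CountDataset) -> TestResult:
    """Boundary likelihood-ratio test of ``alpha = 0`` (Poisson vs NB).

    Fits the same mean model under both families by full maximum likelihood
    and forms ``2 * (l_NB - l_Poisson)``.  Reports the boundary-mixture
    p-value as ``p_value`` and the plain chi2_1 p-value in
    ``extra["p_chi2_1"]``.
    """
    A = _design(data)
    _, mu_p, ll_p = _poisson_fit(data)
    theta_nb, alpha, ll_nb = fit_nb_mle(data.y, A, data.offset)
    stat = 2.0 * (ll_nb - ll_p)
    # at the alpha floor the NB and Poisson log-likelihoods agree only to
    # O(alpha * sum(y^2)); allow that much numerical slack in the nesting
    if stat < -1e-4:
        raise RuntimeError(f"NB fit worse than nested Poisson (LR = {stat:.3g})")
    stat = max(stat, 0.0)
    p_chi2 = float(stats.chi2.sf(stat, df=1))
    p_mix = float(0.5 * stats.chi2.sf(stat, df=1) + (0.5 if stat <= 0 else 0.0))
    return TestResult(
        statistic=stat,
        p_value=p_mix,
        test_name="boundary_lr",
        null_hypothesis="alpha = 0 (Poisson)",
        df="boundary-mixture",
        extra={
            "p_chi2_1": p_chi2,
            "alpha_hat": float(alpha),
            "loglik_poisson": ll_p,
            "loglik_negbin": ll_nb,
        },
    )


def score_test_overdispersion(data: CountDataset) -> TestResult:
    """Cameron–Trivedi auxiliary-regression score test.

    Regresses ``((y - mu)^2 - y) / mu`` on ``mu`` without intercept after a
    Poisson fit; the t statistic has N - 1 degrees of freedom and the
    one-sided p-value tests against over-dispersion.
    """
    _, mu, _ = _poisson_fit(data)
    if np.any(mu <= 0):
        raise FloatingPointError("fitted Poisson mean reached zero")
    y = data.y
    z = ((y - mu) ** 2 - y) / mu
    sxx = float(np.sum(mu**2))
    b = float(np.sum(z * mu)) / sxx
    resid = z - b * mu
    n = data.n_obs
    dof = n - 1
    s2 = float(np.sum(resid**2)) / dof
    se = np.sqrt(s2 / sxx)
    t = b / se
    return TestResult(
        statistic=float(t),
        p_value=float(stats.t.sf(t, df=dof)),
        test_name="score_overdispersion",
        null_hypothesis="no over-dispersion (Var = mu)",
        df=dof,
        extra={"slope": b},
    )


def lagrange_multiplier_test(data: CountDataset) -> TestResult:
    """Lagrange multiplier test from the squared excess-variance sum.

    ``LM = (sum[(y - mu)^2 - y])^2 / (2 * sum(mu^2))`` referred to chi2_1.
    """
    _, mu, _ = _poisson_fit(data)
    if np.any(mu <= 0):
        raise FloatingPointError("fitted Poisson mean reached zero")
    num = float(np.sum((data.y - mu) ** 2 - data.y))
    stat = num**2 / (2.0 * float(np.sum(mu**2)))
    return TestResult(
        statistic=stat,
        p_value=float(stats.chi2.sf(stat, df=1)),
        test_name="lagrange_multiplier",
        null_hypothesis="no over-dispersion (Var = mu)",
        df=1,
    )


def pearson_dispersion(data: CountDataset) -> float:
    """Pearson chi-square over residual degrees of freedom.

    Values clearly above 1.0 signal possible over-dispersion of the count
    outcome relative to the fitted Poisson model.
    """
    theta, mu, _ = _poisson_fit(data)
    dof = data.n_obs - theta.size
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    return float(np.sum((data.y - mu) ** 2 / mu) / dof)


def diagnose(data: CountDataset, alpha_level: float = 0.05) -> pd.DataFrame:
    """Run all dispersion diagnostics and recommend a family.

    Returns a tidy table with one row per test plus the Pearson dispersion;
    the recommendation is ``"negbin"`` when the boundary LR mixture p-value
    falls below ``alpha_level``, else ``"poisson"``.
    """
    lr = boundary_lr_test(data)
    sc = score_test_overdispersion(data)
    lm = lagrange_multiplier_test(data)
    disp = pearson_dispersion(data)
    rows = [
        {
            "test": r.test_name,
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "null": r.null_hypothesis,
        }
        for r in (lr, sc, lm)
    ]
    rows.append(
        {
            "test": "pearson_dispersion",
            "statistic": disp,
            "df": "",
            "p_value": np.nan,
            "null": "dispersion = 1",
        }
    )
    table = pd.DataFrame(rows)
    table.attrs["recommendation"] = "negbin" if lr.p_value < alpha_level else "poisson"
    table.attrs["p_chi2_1"] = lr.extra["p_chi2_1"]
    return table
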