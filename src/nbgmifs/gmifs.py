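"""Monotone incremental forward stagewise (GMIFS) paths for count models.

The estimator targets over-dispersed count outcomes with more predictors
than observations (P > N), where classical Poisson/NB maximum likelihood is
undefined.  Penalized predictors are standardized and duplicated with their
negations into an expanded design [X : -X]; at each step the single expanded
coefficient with the steepest log-likelihood ascent is incremented by a
small ``epsilon``, while the intercept, any unpenalized covariates and (for
the NB family) the heterogeneity ``alpha`` are refit.  The resulting
monotone solution path plays the role of an L1 regularization path; a final
model is chosen by minimum AIC, BIC or cross-validated prediction error.

Organisation follows the model/results idiom: :class:`CountGMIFS` holds the
data and family, ``fit()`` returns a :class:`GMIFSResults` carrying the full
path with selection, prediction, summary and plotting attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CountDataset
from .families import (
    ALPHA_FLOOR,
    ConvergenceError,
    _loglik_const,
    _loglik_eta,
    estimate_alpha_ml,
    estimate_alpha_mom,
    estimate_alpha_pearson,
    fit_unpenalized_mle,
)

ALPHA_UPDATES = ("pearson", "plain", "ml", "fixed")


def _update_alpha(method: str, y, mu, n_mean_params: int, current: float) -> float:
    if method == "pearson":
        return estimate_alpha_pearson(y, mu, n_mean_params=n_mean_params)
    if method == "plain":
        return estimate_alpha_mom(y, mu)
    if method == "ml":
        return estimate_alpha_ml(y, mu)
    return current  # fixed

logger = logging.getLogger("nbgmifs")

CRITERIA = ("aic", "bic", "cv")


@dataclass
class ExpandedDesign:
    """Standardized penalized design and its negated duplicate.

    ``X_std`` has column mean 0 and sd 1; the expanded matrix is
    ``[X_std : -X_std]`` so every coefficient update can be a non-negative
    increment regardless of sign.  Scaling constants are retained for
    back-transformation to the original predictor scale.
    """

    X_std: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray

    @property
    def n_features(self) -> int:
        return self.X_std.shape[1]

    @property
    def expanded(self) -> np.ndarray:
        return np.hstack([self.X_std, -self.X_std])

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} penalized columns, got {X_new.shape[1]}"
            )
        return (X_new - self.column_means) / self.column_sds


def expand_covariates(X_penalized) -> ExpandedDesign:
    """Column-standardize the penalized design and store scaling constants.

    Raises
    ------
    ValueError
        If any column is constant (zero sd), naming the offending column.
    """
    X = np.atleast_2d(np.asarray(X_penalized, dtype=float))
    if X.shape[1] == 0:
        return ExpandedDesign(X, np.empty(0), np.empty(0))
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    bad = np.where(sds <= 0)[0]
    if bad.size:
        raise ValueError(f"constant penalized column(s) at index {bad.tolist()}")
    return ExpandedDesign((X - means) / sds, means, sds)


def information_criteria(loglik: float, df: int, n_obs: int) -> tuple[float, float]:
    """AIC = -2l + 2 df and BIC = -2l + log(N) df."""
    aic = -2.0 * loglik + 2.0 * df
    bic = -2.0 * loglik + np.log(n_obs) * df
    return aic, bic


@dataclass
class ModelParams:
    """Parameters of a fitted count model.

    ``beta`` is on the scale indicated by ``standardized``; use
    :meth:`GMIFSResults.coef_original` for original-scale coefficients.
    """

    gamma0: float
    gamma: np.ndarray
    beta: np.ndarray
    alpha: float
    family: str
    standardized: bool = True


@dataclass
class SelectedModel:
    """A model chosen from a GMIFS path by an information criterion or CV."""

    step: int
    criterion: str
    criterion_value: float
    params: ModelParams
    loglik: float
    df: int
    nonzero: int


class CountGMIFS:
    """Penalized Poisson / negative binomial regression model.

    Parameters
    ----------
    y : array-like
        Non-negative integer counts, length N.
    X_penalized : array-like, optional
        N x K matrix of predictors subject to selection; standardized
        internally.
    X_unpenalized : array-like, optional
        N x J matrix of covariates forced into the model, not standardized.
    exposure : array-like, optional
        Positive exposures entering as a log offset (rate model); default 1.
    family : {"negbin", "poisson"}
        Response distribution.  ``negbin`` estimates the heterogeneity
        ``alpha`` (Var = mu + alpha*mu^2) by method of moments at every step.

    Examples
    --------
    >>> model = CountGMIFS(y, X_penalized=X, family="negbin")
    >>> res = model.fit()
    >>> best = res.select("bic")
    """

    def __init__(
        self,
        y,
        X_penalized=None,
        X_unpenalized=None,
        exposure=None,
        family: str = "negbin",
        feature_names=None,
        unpenalized_names=None,
    ):
        if family not in ("poisson", "negbin"):
            raise ValueError(f"unknown family {family!r}")
        self.data = CountDataset(
            y=np.asarray(y),
            exposure=exposure,
            X_unpenalized=X_unpenalized,
            X_penalized=X_penalized,
            feature_names=feature_names,
            unpenalized_names=unpenalized_names,
        )
        self.family = family

    @classmethod
    def from_dataset(cls, data: CountDataset, family: str = "negbin") -> "CountGMIFS":
        model = cls.__new__(cls)
        if family not in ("poisson", "negbin"):
            raise ValueError(f"unknown family {family!r}")
        model.data = data
        model.family = family
        return model

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str,
        penalized: list[str],
        unpenalized: list[str] | None = None,
        exposure: str | None = None,
        family: str = "negbin",
    ) -> "CountGMIFS":
        """Build the model from columns of a tidy DataFrame."""
        unpenalized = list(unpenalized or [])
        return cls(
            y=df[response].to_numpy(),
            X_penalized=df[list(penalized)].to_numpy(dtype=float),
            X_unpenalized=df[unpenalized].to_numpy(dtype=float) if unpenalized else None,
            exposure=df[exposure].to_numpy(dtype=float) if exposure else None,
            family=family,
            feature_names=list(penalized),
            unpenalized_names=unpenalized,
        )

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        epsilon: float = 0.001,
        tau: float = 1e-5,
        max_steps: int = 50_000,
        max_nonzero: int | None = None,
        alpha_update: str = "pearson",
        verbose: bool = False,
    ) -> "GMIFSResults":
        """Run the incremental forward stagewise path.

        At step ``s``: pick the expanded coefficient with the largest
        gradient of the log-likelihood, increment it by ``epsilon``, refit
        (gamma0, gamma) by maximum likelihood holding beta fixed, and (NB
        only) re-estimate ``alpha`` by the moment scheme selected with
        ``alpha_update``.  Stops when successive log-likelihoods differ by
        less than ``tau``, when the number of nonzero differenced
        coefficients exceeds ``max_nonzero`` (default N - 1), or at
        ``max_steps``.

        ``alpha_update`` chooses the per-step heterogeneity re-estimate:
        ``"pearson"`` (default) solves the NB Pearson chi-square equation at
        the current residual degrees of freedom, which stays stable as the
        model grows; ``"plain"`` is the plain moment ratio
        sum[(y-mu)^2-mu]/sum[mu^2]; ``"ml"`` maximises the likelihood in
        alpha at fixed means; ``"fixed"`` keeps the initial estimate.
        """
        if epsilon <= 0 or tau <= 0:
            raise ValueError("epsilon and tau must be positive")
        if alpha_update not in ALPHA_UPDATES:
            raise ValueError(f"alpha_update must be one of {ALPHA_UPDATES}")
        data, family = self.data, self.family
        y, offset_base = data.y, data.offset
        n, J = data.n_obs, data.X_unpenalized.shape[1]
        if n < 2:
            raise ValueError("at least two observations are required")
        if max_nonzero is None:
            max_nonzero = n - 1
        scaler = expand_covariates(data.X_penalized)
        Xs = scaler.X_std
        K = scaler.n_features
        A = np.column_stack([np.ones(n), data.X_unpenalized])

        # step 0: beta = 0, unpenalized MLE, alpha init by method of moments
        alpha = 1.0 if family == "negbin" else 0.0
        theta, _ = fit_unpenalized_mle(
            y, A, offset_base, "poisson" if family == "poisson" else "negbin",
            alpha=alpha if family == "negbin" else None,
        )
        eta = A @ theta + offset_base
        if family == "negbin":
            alpha = _update_alpha(alpha_update if alpha_update != "fixed" else "plain",
                                  y, np.exp(eta), J + 1, alpha)
            theta, _ = fit_unpenalized_mle(
                y, A, offset_base, family, alpha=alpha, start=theta
            )
            eta = A @ theta + offset_base
        const = _loglik_const(y, family, alpha if family == "negbin" else None)
        ll = _loglik_eta(y, eta, family, alpha if family == "negbin" else None, const)

        rec_ll = [ll]
        rec_alpha = [alpha]
        rec_theta = [theta.copy()]
        rec_nonzero = [0]
        update_indices: list[int] = []
        stop_reason = "k0" if K == 0 else "max_steps"

        if K > 0:
            counts = np.zeros(2 * K, dtype=np.int64)
            dcount = np.zeros(K, dtype=np.int64)
            eta_pen = np.zeros(n)
            nz = 0
            for s in range(1, max_steps + 1):
                mu = np.exp(eta)
                resid = (y - mu) / (1.0 + alpha * mu) if family == "negbin" else y - mu
                g = Xs.T @ resid
                ge = np.concatenate([g, -g])
                m = int(np.argmax(ge))  # ties -> lowest expanded index
                col, sign = m % K, (1 if m < K else -1)
                counts[m] += 1
                d_old = dcount[col]
                dcount[col] += sign
                if d_old == 0 and dcount[col] != 0:
                    nz += 1
                elif d_old != 0 and dcount[col] == 0:
                    nz -= 1
                eta_pen += (sign * epsilon) * Xs[:, col]
                try:
                    theta, _ = fit_unpenalized_mle(
                        y, A, offset_base + eta_pen, family,
                        alpha=alpha if family == "negbin" else None, start=theta,
                    )
                except ConvergenceError as err:
                    raise ConvergenceError(
                        f"inner refit failed at GMIFS step {s}", err.last_params
                    ) from err
                eta = A @ theta + offset_base + eta_pen
                if family == "negbin":
                    alpha = _update_alpha(alpha_update, y, np.exp(eta), nz + J + 1, alpha)
                    const = _loglik_const(y, family, alpha)
                ll_new = _loglik_eta(
                    y, eta, family, alpha if family == "negbin" else None, const
                )
                if not np.isfinite(ll_new):
                    raise FloatingPointError(
                        f"non-finite log-likelihood at GMIFS step {s}"
                    )
                update_indices.append(m)
                rec_ll.append(ll_new)
                rec_alpha.append(alpha)
                rec_theta.append(theta.copy())
                rec_nonzero.append(nz)
                if verbose and s % 100 == 0:
                    logger.info(
                        "gmifs step=%d loglik=%.6f nonzero=%d alpha=%.4g",
                        s, ll_new, nz, alpha,
                    )
                if abs(ll_new - ll) < tau:
                    stop_reason = "tol"
                    break
                ll = ll_new
                if nz > max_nonzero:
                    stop_reason = "max_nonzero"
                    break

        thetas = np.array(rec_theta)
        lls = np.asarray(rec_ll)
        nonzeros = np.asarray(rec_nonzero)
        df = nonzeros + J + 1 + (1 if family == "negbin" else 0)
        aic = -2.0 * lls + 2.0 * df
        bic = -2.0 * lls + np.log(n) * df
        return GMIFSResults(
            model=self,
            scaler=scaler,
            epsilon=epsilon,
            tau=tau,
            update_indices=np.asarray(update_indices, dtype=np.int64),
            loglik=lls,
            alpha=np.asarray(rec_alpha),
            gamma0=thetas[:, 0],
            gamma=thetas[:, 1:],
            nonzero=nonzeros,
            df=df,
            aic=aic,
            bic=bic,
            stop_reason=stop_reason,
        )


@dataclass
class GMIFSResults:
    """A fitted GMIFS path: per-step states plus selection and prediction.

    Step 0 is the intercept/unpenalized-only model; step ``s`` has
    ``sum(|expanded beta|) = s * epsilon`` exactly (one increment per step).
    """

    model: CountGMIFS
    scaler: ExpandedDesign
    epsilon: float
    tau: float
    update_indices: np.ndarray  # expanded column updated at steps 1..S
    loglik: np.ndarray
    alpha: np.ndarray
    gamma0: np.ndarray
    gamma: np.ndarray
    nonzero: np.ndarray
    df: np.ndarray
    aic: np.ndarray
    bic: np.ndarray
    stop_reason: str = "tol"

    @property
    def n_steps(self) -> int:
        """Number of increment steps S (the path stores S + 1 records)."""
        return len(self.update_indices)

    @property
    def family(self) -> str:
        return self.model.family

    def beta_expanded(self, step: int | None = None) -> np.ndarray:
        """Non-negative expanded coefficients (length 2K) at ``step``."""
        step = self.n_steps if step is None else step
        if not 0 <= step <= self.n_steps:
            raise IndexError(f"step {step} outside path 0..{self.n_steps}")
        K = self.scaler.n_features
        return (
            np.bincount(self.update_indices[:step], minlength=2 * K).astype(float)
            * self.epsilon
        )

    def beta(self, step: int | None = None) -> np.ndarray:
        """Differenced coefficients beta_k - beta_{K+k}, standardized scale."""
        be = self.beta_expanded(step)
        K = self.scaler.n_features
        return be[:K] - be[K:]

    def params(self, step: int | None = None) -> ModelParams:
        step = self.n_steps if step is None else step
        return ModelParams(
            gamma0=float(self.gamma0[step]),
            gamma=self.gamma[step].copy(),
            beta=self.beta(step),
            alpha=float(self.alpha[step]),
            family=self.family,
            standardized=True,
        )

    def coef_original(self, step: int | None = None) -> tuple[float, np.ndarray, np.ndarray]:
        """Back-transform to the original predictor scale.

        Returns ``(gamma0, gamma, beta)`` with ``beta_orig = beta_std / sd``
        and the intercept shifted by ``-sum(beta_std * mean / sd)``.
        """
        step = self.n_steps if step is None else step
        b_std = self.beta(step)
        if b_std.size:
            b_orig = b_std / self.scaler.column_sds
            g0 = float(self.gamma0[step]) - float(
                np.sum(b_std * self.scaler.column_means / self.scaler.column_sds)
            )
        else:
            b_orig, g0 = b_std, float(self.gamma0[step])
        return g0, self.gamma[step].copy(), b_orig

    # -- selection ---------------------------------------------------------

    def select(
        self,
        criterion: str = "aic",
        folds: int | None = None,
        metric: str = "mae",
        seed: int = 0,
    ) -> SelectedModel:
        """Pick the path step minimising AIC, BIC or CV prediction error.

        Ties break toward the earlier (sparser) step.  ``criterion="cv"``
        refits the path on cross-validation folds and minimises the per-step
        mean held-out error (fold paths truncated to the shortest).
        """
        if criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if self.n_steps + 1 == 0:  # unreachable, but keep the contract explicit
            raise ValueError("empty path")
        if criterion == "aic":
            values, step = self.aic, int(np.argmin(self.aic))
        elif criterion == "bic":
            values, step = self.bic, int(np.argmin(self.bic))
        else:
            curve = cv_curve(
                self.model, folds=folds, metric=metric, seed=seed,
                epsilon=self.epsilon, tau=self.tau,
            )
            values, step = curve, int(np.argmin(curve))
            step = min(step, self.n_steps)
        return SelectedModel(
            step=step,
            criterion=criterion,
            criterion_value=float(values[step]),
            params=self.params(step),
            loglik=float(self.loglik[step]),
            df=int(self.df[step]),
            nonzero=int(self.nonzero[step]),
        )

    # -- prediction --------------------------------------------------------

    def predict(
        self,
        X_penalized=None,
        X_unpenalized=None,
        exposure=None,
        step: int | None = None,
    ) -> np.ndarray:
        """Predicted means ``mu = c * exp(g0 + Xu g + Xp_std b)``.

        New penalized columns are standardized with the *training* scaling
        constants.  Omitted blocks default to the training data.
        """
        data = self.model.data
        Xp = data.X_penalized if X_penalized is None else np.atleast_2d(
            np.asarray(X_penalized, dtype=float)
        )
        n_new = Xp.shape[0]
        Xu = data.X_unpenalized if X_unpenalized is None else np.atleast_2d(
            np.asarray(X_unpenalized, dtype=float)
        )
        if X_penalized is None and X_unpenalized is not None:
            raise ValueError("provide X_penalized alongside X_unpenalized")
        if X_penalized is not None and X_unpenalized is None:
            if data.X_unpenalized.shape[1] > 0:
                raise ValueError("model has unpenalized covariates; provide X_unpenalized")
            Xu = np.empty((n_new, 0))
        if Xu.shape[0] != n_new:
            raise ValueError("X_unpenalized row count mismatch")
        if Xu.shape[1] != data.X_unpenalized.shape[1]:
            raise ValueError(
                f"expected {data.X_unpenalized.shape[1]} unpenalized columns"
            )
        if exposure is None:
            c = data.exposure if X_penalized is None else np.ones(n_new)
        else:
            c = np.asarray(exposure, dtype=float)
            if c.shape != (n_new,):
                raise ValueError("exposure length mismatch")
            if np.any(c <= 0):
                raise ValueError("exposures must be positive")
        p = self.params(step)
        eta = p.gamma0 + Xu @ p.gamma + np.log(c)
        if self.scaler.n_features:
            eta = eta + self.scaler.transform(Xp) @ p.beta
        return np.exp(eta)

    # -- reporting ---------------------------------------------------------

    def path_frame(self) -> pd.DataFrame:
        """Tidy per-step table (step, updated feature, loglik, alpha, ...)."""
        K = self.scaler.n_features
        names = self.model.data.feature_names
        updated = [""]
        for m in self.update_indices:
            k = int(m) % K
            updated.append(("+" if m < K else "-") + names[k])
        return pd.DataFrame(
            {
                "step": np.arange(self.n_steps + 1),
                "updated": updated,
                "loglik": self.loglik,
                "alpha": self.alpha,
                "gamma0": self.gamma0,
                "nonzero": self.nonzero,
                "df": self.df,
                "aic": self.aic,
                "bic": self.bic,
            }
        )

    def summary(self) -> str:
        """Plain-text summary of the path and criterion minima."""
        data = self.model.data
        aic_step = int(np.argmin(self.aic))
        bic_step = int(np.argmin(self.bic))
        lines = [
            "GMIFS count regression path",
            "===========================",
            f"family:            {self.family}",
            f"observations:      {data.n_obs}",
            f"penalized K:       {self.scaler.n_features}",
            f"unpenalized J:     {data.X_unpenalized.shape[1]}",
            f"epsilon / tau:     {self.epsilon:g} / {self.tau:g}",
            f"steps run:         {self.n_steps} (stop: {self.stop_reason})",
            f"final loglik:      {self.loglik[-1]:.4f}",
        ]
        if self.family == "negbin":
            lines.append(f"final alpha:       {self.alpha[-1]:.4f}")
        lines += [
            f"AIC minimum:       {self.aic[aic_step]:.3f} at step {aic_step} "
            f"({self.nonzero[aic_step]} nonzero)",
            f"BIC minimum:       {self.bic[bic_step]:.3f} at step {bic_step} "
            f"({self.nonzero[bic_step]} nonzero)",
        ]
        return "\n".join(lines)

    def plot_paths(self, ax=None, criterion: str | None = None):
        """Coefficient trajectories (differenced, standardized scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        K = self.scaler.n_features
        S = self.n_steps
        traj = np.zeros((S + 1, K))
        beta = np.zeros(K)
        for s, m in enumerate(self.update_indices, start=1):
            beta = beta.copy()
            beta[int(m) % K] += self.epsilon if m < K else -self.epsilon
            traj[s] = beta
        ax.plot(np.arange(S + 1), traj, lw=0.8)
        ax.set_xlabel("GMIFS step")
        ax.set_ylabel("standardized coefficient")
        if criterion in ("aic", "bic"):
            values = self.aic if criterion == "aic" else self.bic
            ax.axvline(int(np.argmin(values)), ls="--", color="k", lw=1)
        return ax


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _prediction_error(y, mu, metric: str) -> float:
    if metric == "mae":
        return float(np.mean(np.abs(y - mu)))
    if metric == "mse":
        return float(np.mean((y - mu) ** 2))
    raise ValueError(f"unknown metric {metric!r}")


def _fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    idx = np.tile(np.arange(folds), n // folds + 1)[:n]
    rng.shuffle(idx)
    return idx


def _fold_fit(model: CountGMIFS, train, epsilon, tau, max_steps):
    data = model.data
    sub = CountGMIFS(
        y=data.y[train],
        X_penalized=data.X_penalized[train],
        X_unpenalized=data.X_unpenalized[train],
        exposure=data.exposure[train],
        family=model.family,
    )
    return sub.fit(epsilon=epsilon, tau=tau, max_steps=max_steps)


def cross_validate(
    model: CountGMIFS,
    folds: int | None = None,
    criterion: str = "aic",
    metric: str = "mae",
    seed: int = 0,
    epsilon: float = 0.001,
    tau: float = 1e-5,
    max_steps: int = 50_000,
) -> float:
    """Cross-validated prediction error of a selection rule.

    For each fold: fit the GMIFS path on the training portion, apply the
    selection ``criterion`` (aic or bic) within that fold, and score the
    held-out observations with ``metric``.  ``folds=None`` means N-fold
    (leave-one-out).  Deterministic for a given ``seed``.
    """
    data = model.data
    n = data.n_obs
    folds = n if folds is None else folds
    if folds > n:
        raise ValueError("folds cannot exceed the number of observations")
    assign = _fold_assignment(n, folds, seed)
    errors = np.empty(folds)
    for f in range(folds):
        test = assign == f
        train = ~test
        if np.var(data.y[test]) == 0 and test.sum() > 1:
            logger.warning("fold %d has zero response variance; retained", f)
        res = _fold_fit(model, train, epsilon, tau, max_steps)
        sel = res.select(criterion)
        mu = res.predict(
            X_penalized=data.X_penalized[test],
            X_unpenalized=data.X_unpenalized[test],
            exposure=data.exposure[test],
            step=sel.step,
        )
        errors[f] = _prediction_error(data.y[test], mu, metric)
    return float(np.mean(errors))


def cv_curve(
    model: CountGMIFS,
    folds: int | None = None,
    metric: str = "mae",
    seed: int = 0,
    epsilon: float = 0.001,
    tau: float = 1e-5,
    max_steps: int = 50_000,
) -> np.ndarray:
    """Per-step mean held-out prediction error across folds.

    Fold paths are truncated to the shortest fold path so the average at
    each step is over all folds.  Used by ``select("cv")``.
    """
    data = model.data
    n = data.n_obs
    folds = n if folds is None else folds
    assign = _fold_assignment(n, folds, seed)
    per_fold = []
    for f in range(folds):
        test = assign == f
        res = _fold_fit(model, ~test, epsilon, tau, max_steps)
        y_test = data.y[test]
        Xu_test = data.X_unpenalized[test]
        log_c = np.log(data.exposure[test])
        K = res.scaler.n_features
        Xs_test = res.scaler.transform(data.X_penalized[test]) if K else None
        errs = np.empty(res.n_steps + 1)
        eta_pen = np.zeros(test.sum())
        for s in range(res.n_steps + 1):
            if s > 0:
                m = int(res.update_indices[s - 1])
                sign = epsilon if m < K else -epsilon
                eta_pen += sign * Xs_test[:, m % K]
            eta = res.gamma0[s] + Xu_test @ res.gamma[s] + log_c + eta_pen
            errs[s] = _prediction_error(y_test, np.exp(eta), metric)
        per_fold.append(errs)
    s_min = min(len(e) for e in per_fold)
    return np.mean([e[:s_min] for e in per_fold], axis=0)
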