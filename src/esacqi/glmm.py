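"""Maximum-likelihood random-intercept logistic regression.

The longitudinal model behind the attitude analysis: repeated yearly
binary outcomes (AQPA) nested within physicians,

    logit P(y_ij = 1 | u_i) = x_ij' beta + u_i,      u_i ~ N(0, sigma_u^2),

with observations j (years) at level 1 and physicians i at level 2.  The
marginal likelihood integrates the physician random intercept out of the
Bernoulli likelihood by Gauss-Hermite quadrature; clusters here hold at
most a handful of Bernoulli observations, so a fixed 31-node rule is
accurate well beyond the optimizer's tolerance.  Estimation maximizes the
marginal log-likelihood with analytic gradients (L-BFGS-B, sigma_u bounded
at 0); standard errors come from the inverse of a finite-difference
Hessian of the marginal log-likelihood at the optimum.

The interface follows the statsmodels Model/Results convention:

>>> model = RandomInterceptLogit.from_dataframe(
...     data, outcome="aqpa", exposure="score",
...     covariates=["on_call", "night_shifts", "mean_panel_k"],
...     group="physician_id")
>>> res = model.fit()
>>> res.params, res.bse, res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

__all__ = [
    "RandomInterceptLogit",
    "RandomInterceptLogitResults",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails and no trustworthy estimates exist."""


def _cluster_sum(values: np.ndarray, groups: np.ndarray, n_groups: int) -> np.ndarray:
    """Sum rows of (N,) or (N, G) arrays within clusters -> (m,) or (m, G)."""
    if values.ndim == 1:
        return np.bincount(groups, weights=values, minlength=n_groups)
    out = np.empty((n_groups, values.shape[1]))
    for g in range(values.shape[1]):
        out[:, g] = np.bincount(groups, weights=values[:, g], minlength=n_groups)
    return out


class RandomInterceptLogit:
    """Logistic regression with a Gaussian random intercept per group.

    Parameters
    ----------
    endog : array-like of 0/1, length N
    exog : array-like (N, k), including the constant column
    groups : array-like length N, cluster labels (physicians)
    exog_names : column names for reporting
    n_quad : number of Gauss-Hermite quadrature nodes
    """

    def __init__(
        self,
        endog,
        exog,
        groups,
        exog_names: Optional[Sequence[str]] = None,
        n_quad: int = 31,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        if set(np.unique(self.endog)) - {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if self.endog.min() == self.endog.max():
            raise ValueError("outcome is constant; the model is not identified")
        labels, self.group_index = np.unique(np.asarray(groups), return_inverse=True)
        self.n_groups = len(labels)
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups (physicians)")
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        if len(self.exog_names) != self.exog.shape[1]:
            raise ValueError("exog_names length does not match exog columns")
        # physicists' Hermite rule: integral of f against exp(-x^2);
        # substituting u = sqrt(2) sigma x turns it into an expectation
        # against N(0, sigma^2) with weights w / sqrt(pi)
        self._nodes, w = hermgauss(n_quad)
        self._log_weights = np.log(w) - 0.5 * np.log(np.pi)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        exposure: str,
        covariates: Sequence[str] = (),
        group: str = "physician_id",
        n_quad: int = 31,
    ) -> "RandomInterceptLogit":
        """Build from a long-format table (one row per physician-year).

        The design matrix is [const, exposure, *covariates]; the exposure
        coefficient is always ``params[1]``.
        """
        cols = [outcome, exposure, *covariates, group]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"model data missing columns: {missing}")
        clean = data.dropna(subset=cols)
        X = np.column_stack(
            [np.ones(len(clean)), clean[exposure].to_numpy(dtype=float)]
            + [clean[c].to_numpy(dtype=float) for c in covariates]
        )
        names = ["const", exposure, *covariates]
        model = cls(
            clean[outcome].to_numpy(dtype=float),
            X,
            clean[group].to_numpy(),
            exog_names=names,
            n_quad=n_quad,
        )
        model.exposure_name = exposure
        return model

    # ---- likelihood machinery -------------------------------------------

    def _cluster_loglik(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-cluster log f_ig at each node and per-cluster log-likelihood."""
        beta, sigma = params[:-1], params[-1]
        eta = self.exog @ beta  # (N,)
        u = np.sqrt(2.0) * sigma * self._nodes  # (G,)
        s = eta[:, None] + u[None, :]  # (N, G)
        # log Bernoulli pmf: y*s - log(1 + exp(s)), stable via logaddexp
        row_ll = self.endog[:, None] * s - np.logaddexp(0.0, s)
        f = _cluster_sum(row_ll, self.group_index, self.n_groups)  # (m, G)
        li = logsumexp(f + self._log_weights[None, :], axis=1)  # (m,)
        return f, li

    def loglike(self, params: np.ndarray) -> float:
        """Marginal log-likelihood at params = (beta..., sigma_u)."""
        _, li = self._cluster_loglik(np.asarray(params, dtype=float))
        return float(li.sum())

    def score(self, params: np.ndarray) -> np.ndarray:
        """Analytic gradient of :meth:`loglike`."""
        params = np.asarray(params, dtype=float)
        beta, sigma = params[:-1], params[-1]
        f, li = self._cluster_loglik(params)
        # posterior node weights per cluster
        r = np.exp(f + self._log_weights[None, :] - li[:, None])  # (m, G)
        eta = self.exog @ beta
        u = np.sqrt(2.0) * sigma * self._nodes
        p = expit(eta[:, None] + u[None, :])  # (N, G)
        resid = self.endog[:, None] - p  # (N, G)
        # beta block: sum_i sum_g r_ig sum_{j in i} resid_ijg x_ij
        row_weight = (r[self.group_index, :] * resid).sum(axis=1)  # (N,)
        g_beta = self.exog.T @ row_weight
        # sigma: chain through u_g = sqrt(2) sigma x_g
        c = _cluster_sum(resid, self.group_index, self.n_groups)  # (m, G)
        g_sigma = float((r * c * (np.sqrt(2.0) * self._nodes)[None, :]).sum())
        return np.append(g_beta, g_sigma)

    def _start_params(self) -> np.ndarray:
        import statsmodels.api as sm

        try:
            logit = sm.Logit(self.endog, self.exog).fit(disp=0, maxiter=200)
            beta0 = np.asarray(logit.params, dtype=float)
            if not np.all(np.isfinite(beta0)):
                raise ValueError
        except Exception:
            beta0 = np.zeros(self.exog.shape[1])
        return np.append(beta0, 0.5)

    def fit(
        self,
        start_params: Optional[np.ndarray] = None,
        maxiter: int = 500,
        ftol: float = 1e-10,
        gtol: float = 1e-6,
        fix_sigma: Optional[float] = None,
    ) -> "RandomInterceptLogitResults":
        """Maximize the marginal likelihood; returns a results object.

        Convergence is declared when successive log-likelihood changes
        fall below the tolerance (ftol, relative scale ~1e-10, i.e. well
        under 1e-8 in absolute log-likelihood units for these data sizes)
        with a small gradient.  Non-convergence is flagged on the results
        object; clearly pathological fits (non-finite likelihood) raise
        :class:`ConvergenceError`.

        ``fix_sigma`` holds the random-intercept SD fixed (e.g. at 0,
        which reduces the model to ordinary logistic regression) and
        profiles only the fixed effects.
        """
        x0 = (
            np.asarray(start_params, dtype=float)
            if start_params is not None
            else self._start_params()
        )
        k = self.exog.shape[1]
        if fix_sigma is not None:
            if fix_sigma < 0:
                raise ValueError("fix_sigma must be >= 0")
            x0 = np.append(x0[:k], float(fix_sigma))
            bounds = [(None, None)] * k + [(fix_sigma, fix_sigma)]
        else:
            bounds = [(None, None)] * k + [(0.0, None)]
        res = minimize(
            lambda p: -self.loglike(p),
            x0,
            jac=lambda p: -self.score(p),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
        )
        if not np.isfinite(res.fun):
            raise ConvergenceError("marginal likelihood is not finite at optimum")
        params = res.x
        # |beta| runaway is the classic separation signature
        separated = bool(np.abs(params[:-1]).max() > 30)
        cov = self._cov_params(params, sigma_fixed=fix_sigma is not None)
        bse = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        converged = bool(res.success) and not separated and np.all(
            np.isfinite(bse[: k])
        ) and bse[1 if k > 1 else 0] > 0
        return RandomInterceptLogitResults(
            model=self,
            params=params[:-1].copy(),
            sigma_u=float(params[-1]),
            cov_params=cov,
            bse=bse,
            llf=float(-res.fun),
            converged=converged,
            separated=separated,
            optimizer_message=str(res.message),
        )

    def _cov_params(
        self, params: np.ndarray, sigma_fixed: bool = False
    ) -> np.ndarray:
        """Inverse observed information via central differences of the score.

        With ``sigma_fixed`` only the fixed-effect block is inverted; the
        sigma row/column of the returned covariance is NaN.
        """
        n = len(params)
        if sigma_fixed:
            k = n - 1
            Hb = np.zeros((k, k))
            for j in range(k):
                h = 1e-5 * max(1.0, abs(params[j]))
                up, dn = params.copy(), params.copy()
                up[j] += h
                dn[j] -= h
                Hb[:, j] = (self.score(up)[:k] - self.score(dn)[:k]) / (2 * h)
            Hb = (Hb + Hb.T) / 2.0
            try:
                cov_b = np.linalg.inv(-Hb)
            except np.linalg.LinAlgError:
                cov_b = np.linalg.pinv(-Hb)
            cov = np.full((n, n), np.nan)
            cov[:k, :k] = cov_b
            return cov
        H = np.zeros((n, n))
        at_boundary = params[-1] < 1e-6
        for j in range(n):
            h = 1e-5 * max(1.0, abs(params[j]))
            up, dn = params.copy(), params.copy()
            up[j] += h
            dn[j] -= h
            if j == n - 1 and at_boundary:
                dn[j] = max(dn[j], 0.0)
                H[:, j] = (self.score(up) - self.score(dn)) / (up[j] - dn[j])
            else:
                H[:, j] = (self.score(up) - self.score(dn)) / (2 * h)
        H = (H + H.T) / 2.0
        info = -H
        try:
            cov = np.linalg.inv(info)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        return cov


@dataclass
class RandomInterceptLogitResults:
    """Fitted random-intercept logit: estimates, uncertainty, diagnostics."""

    model: RandomInterceptLogit
    params: np.ndarray  # fixed-effect coefficients (log-odds scale)
    sigma_u: float  # random-intercept SD
    cov_params: np.ndarray  # joint (beta, sigma) covariance
    bse: np.ndarray  # joint standard errors
    llf: float
    converged: bool
    separated: bool = False
    optimizer_message: str = ""
    _param_series: pd.Series = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._param_series = pd.Series(self.params, index=self.model.exog_names)

    @property
    def beta(self) -> pd.Series:
        return self._param_series

    @property
    def bse_beta(self) -> pd.Series:
        return pd.Series(self.bse[: len(self.params)], index=self.model.exog_names)

    @property
    def sigma_u_se(self) -> float:
        return float(self.bse[-1])

    def coef(self, name: str) -> tuple[float, float]:
        """(estimate, standard error) for one named coefficient."""
        idx = self.model.exog_names.index(name)
        return float(self.params[idx]), float(self.bse[idx])

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = self.bse[: len(self.params)]
        return pd.DataFrame(
            {
                "lower": self.params - z * se,
                "upper": self.params + z * se,
            },
            index=self.model.exog_names,
        )

    def wald_pvalues(self) -> pd.Series:
        from scipy.stats import norm

        se = self.bse[: len(self.params)]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / se
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.model.exog_names)

    def summary(self) -> str:
        """Plain-text coefficient table in the statsmodels style."""
        ci = self.conf_int()
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse[: len(self.params)],
                "[0.025": ci["lower"],
                "0.975]": ci["upper"],
                "P>|z|": self.wald_pvalues(),
            },
            index=self.model.exog_names,
        )
        lines = [
            "Random-intercept logistic regression (Gauss-Hermite ML)",
            f"Groups: {self.model.n_groups}   Obs: {len(self.model.endog)}   "
            f"Log-likelihood: {self.llf:.4f}",
            f"sigma_u: {self.sigma_u:.4f} (se {self.sigma_u_se:.4f})   "
            f"converged: {self.converged}",
            tab.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
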