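"""Full empirical-Bayes gamma-Poisson shrinker (MGPS).

Observed pair counts are modelled as a ~ Poisson(lambda * E) with the
reporting-rate ratio lambda drawn from a two-component gamma mixture prior

    lambda ~ w * Gamma(alpha1, beta1) + (1 - w) * Gamma(alpha2, beta2)

(shape/rate parameterization).  Marginally each component is negative
binomial, so the prior is fitted by maximizing the marginal likelihood over
all tables at one MedDRA level with an EM algorithm (the M-step maximizes
each component's weighted negative-binomial likelihood by L-BFGS in
log-parameter space; this expectation/conditional-maximization scheme is
deterministic given the fixed initialization).

Given the fitted prior, the posterior of lambda for a table with count a and
expectation E is again a two-component gamma mixture with components
Gamma(alpha_j + a, beta_j + E).  Reported quantities:

* EBGM = 2**E[log2 lambda | a] = exp(E[ln lambda | a]), the posterior
  geometric mean,
* EB05, the 5th percentile of the posterior mixture, found by bracketed
  root-finding on the mixture CDF.

Small counts are shrunk toward the prior mean; as a grows with E fixed the
posterior concentrates and EBGM approaches the raw ratio a/E.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import optimize, special
from scipy import stats as sps


def _nb_logpmf(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """log P(a | alpha, beta, E): negative-binomial marginal of the
    gamma-Poisson component."""
    return (
        special.gammaln(a + alpha)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * (np.log(beta) - np.log(beta + e))
        + a * (np.log(e) - np.log(beta + e))
    )


def _nb_grad(a, e, alpha, beta):
    dalpha = special.digamma(a + alpha) - special.digamma(alpha) + np.log(beta) - np.log(beta + e)
    dbeta = alpha / beta - (alpha + a) / (beta + e)
    return dalpha, dbeta


class GammaPoissonShrinker:
    """Two-component gamma-mixture empirical-Bayes shrinker.

    Parameters are the EM starting point; fitted values land in the
    trailing-underscore attributes (``alpha1_``, ``beta1_``, ``alpha2_``,
    ``beta2_``, ``w_``, ``loglik_``, ``n_iter_``, ``converged_``).
    """

    def __init__(
        self,
        alpha1: float = 0.2,
        beta1: float = 0.1,
        alpha2: float = 2.0,
        beta2: float = 4.0,
        w: float = 1.0 / 3.0,
        tol: float = 1e-8,
        max_iter: int = 500,
    ):
        self.alpha1 = alpha1
        self.beta1 = beta1
        self.alpha2 = alpha2
        self.beta2 = beta2
        self.w = w
        self.tol = tol
        self.max_iter = max_iter

    # ------------------------------------------------------------------ fit
    def fit(self, a, e) -> "GammaPoissonShrinker":
        """Fit the mixture prior to counts ``a`` with expectations ``e``.

        EM iterations move the parameters into the right basin quickly but
        crawl along the likelihood ridge of weakly separated mixtures, so the
        fit finishes with a direct quasi-Newton maximization of the marginal
        log-likelihood (analytic gradient, logit/log-transformed parameters).
        Both stages are deterministic given the fixed starting point.
        """
        a = np.asarray(a, dtype=float)
        e = np.asarray(e, dtype=float)
        if a.shape != e.shape or a.ndim != 1:
            raise ValueError("a and e must be 1-D arrays of equal length")
        if len(a) < 2:
            raise ValueError("need at least two tables to fit the prior")
        if np.any(e <= 0):
            raise ValueError("all expectations must be positive")
        p1 = np.array([self.alpha1, self.beta1], dtype=float)
        p2 = np.array([self.alpha2, self.beta2], dtype=float)
        w = float(self.w)
        prev_ll = -np.inf
        self.converged_ = False
        n_em = 0
        for it in range(1, self.max_iter + 1):
            n_em = it
            lp1 = np.log(w) + _nb_logpmf(a, e, *p1)
            lp2 = np.log1p(-w) + _nb_logpmf(a, e, *p2)
            m = np.maximum(lp1, lp2)
            ll = float(np.sum(m + np.log(np.exp(lp1 - m) + np.exp(lp2 - m))))
            if abs(ll - prev_ll) < self.tol:
                self.converged_ = True
                prev_ll = ll
                break
            if abs(ll - prev_ll) < 1e-4:  # ridge crawl: hand over to the polish
                prev_ll = ll
                break
            prev_ll = ll
            r1 = 1.0 / (1.0 + np.exp(lp2 - lp1))  # responsibility of comp. 1
            w = float(np.clip(np.mean(r1), 1e-10, 1 - 1e-10))
            p1 = self._mstep(a, e, r1, p1)
            p2 = self._mstep(a, e, 1.0 - r1, p2)

        # direct polish of the marginal likelihood
        def negll(theta):
            la1, lb1, la2, lb2, u = theta
            alpha1, beta1 = np.exp(la1), np.exp(lb1)
            alpha2, beta2 = np.exp(la2), np.exp(lb2)
            wv = 1.0 / (1.0 + np.exp(-u))
            lp1 = np.log(wv) + _nb_logpmf(a, e, alpha1, beta1)
            lp2 = np.log1p(-wv) + _nb_logpmf(a, e, alpha2, beta2)
            m = np.maximum(lp1, lp2)
            ll_i = m + np.log(np.exp(lp1 - m) + np.exp(lp2 - m))
            r1 = 1.0 / (1.0 + np.exp(lp2 - lp1))
            da1, db1 = _nb_grad(a, e, alpha1, beta1)
            da2, db2 = _nb_grad(a, e, alpha2, beta2)
            grad = -np.array(
                [
                    np.sum(r1 * da1) * alpha1,
                    np.sum(r1 * db1) * beta1,
                    np.sum((1 - r1) * da2) * alpha2,
                    np.sum((1 - r1) * db2) * beta2,
                    np.sum(r1 - wv),
                ]
            )
            return -float(np.sum(ll_i)), grad

        theta0 = np.array(
            [np.log(p1[0]), np.log(p1[1]), np.log(p2[0]), np.log(p2[1]),
             np.log(w) - np.log1p(-w)]
        )
        res = optimize.minimize(
            negll, theta0, jac=True, method="L-BFGS-B",
            bounds=[(-12.0, 12.0)] * 4 + [(-16.0, 16.0)],
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        la1, lb1, la2, lb2, u = res.x
        self.alpha1_, self.beta1_ = float(np.exp(la1)), float(np.exp(lb1))
        self.alpha2_, self.beta2_ = float(np.exp(la2)), float(np.exp(lb2))
        self.w_ = float(1.0 / (1.0 + np.exp(-u)))
        self.loglik_ = -float(res.fun)
        self.n_iter_ = n_em + int(res.nit)
        self.converged_ = bool(res.success) or self.converged_
        return self

    @staticmethod
    def _mstep(a, e, r, start):
        def negll(logp):
            alpha, beta = np.exp(logp)
            val = -np.sum(r * _nb_logpmf(a, e, alpha, beta))
            da, db = _nb_grad(a, e, alpha, beta)
            grad = -np.array([np.sum(r * da) * alpha, np.sum(r * db) * beta])
            return val, grad

        res = optimize.minimize(
            negll,
            np.log(start),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-12.0, 12.0)] * 2,
        )
        return np.exp(res.x)

    # ------------------------------------------------------ posterior scores
    @property
    def prior_mean_(self) -> float:
        self._check_fitted()
        return self.w_ * self.alpha1_ / self.beta1_ + (1 - self.w_) * self.alpha2_ / self.beta2_

    def _check_fitted(self):
        if not hasattr(self, "alpha1_"):
            raise RuntimeError("shrinker is not fitted; call fit(a, e) first")

    def _posterior(self, a, e):
        """Posterior mixture weights and gamma parameters for each table."""
        self._check_fitted()
        a = np.atleast_1d(np.asarray(a, dtype=float))
        e = np.atleast_1d(np.asarray(e, dtype=float))
        lp1 = np.log(self.w_) + _nb_logpmf(a, e, self.alpha1_, self.beta1_)
        lp2 = np.log1p(-self.w_) + _nb_logpmf(a, e, self.alpha2_, self.beta2_)
        q1 = 1.0 / (1.0 + np.exp(lp2 - lp1))
        return q1, a + self.alpha1_, e + self.beta1_, a + self.alpha2_, e + self.beta2_

    def ebgm(self, a, e):
        """Posterior geometric mean exp(E[ln lambda | a])."""
        scalar = np.ndim(a) == 0
        q1, s1, r1, s2, r2 = self._posterior(a, e)
        mean_log = q1 * (special.digamma(s1) - np.log(r1)) + (1 - q1) * (
            special.digamma(s2) - np.log(r2)
        )
        out = np.exp(mean_log)
        return float(out[0]) if scalar else out

    def quantile(self, q: float, a, e, xtol: float = 1e-9):
        """Quantile of the posterior mixture by bracketed root-finding."""
        scalar = np.ndim(a) == 0
        q1, s1, r1, s2, r2 = self._posterior(a, e)
        out = np.empty_like(q1)
        for i in range(len(out)):
            g1 = sps.gamma(s1[i], scale=1.0 / r1[i])
            g2 = sps.gamma(s2[i], scale=1.0 / r2[i])
            # numerically degenerate mixtures collapse to one component
            if q1[i] >= 1.0 - 1e-12:
                out[i] = g1.ppf(q)
                continue
            if q1[i] <= 1e-12:
                out[i] = g2.ppf(q)
                continue
            lo = min(g1.ppf(q), g2.ppf(q))
            hi = max(g1.ppf(q), g2.ppf(q))
            if hi - lo < xtol:
                out[i] = 0.5 * (lo + hi)
                continue
            f = lambda x: q1[i] * g1.cdf(x) + (1 - q1[i]) * g2.cdf(x) - q
            # the mixture quantile is bracketed by the component quantiles
            out[i] = optimize.brentq(f, lo, hi, xtol=xtol)
        return float(out[0]) if scalar else out

    def eb05(self, a, e):
        """5th posterior percentile of the reporting-rate ratio."""
        return self.quantile(0.05, a, e)

    # ------------------------------------------------------------- protocol
    def get_params(self, deep: bool = True) -> dict:
        return {
            "alpha1": self.alpha1, "beta1": self.beta1,
            "alpha2": self.alpha2, "beta2": self.beta2,
            "w": self.w, "tol": self.tol, "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "GammaPoissonShrinker":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self
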