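"""Negative binomial and Gaussian random-intercept mixed models, plus test utilities.

The central model: within-cell-line viability ranks R_ik (shRNA i, cell line
k) of one gene's retained shRNAs follow

    R_ik | u_k  ~  NB(mu_ik, theta),      mu_ik = exp(beta0 + beta * X_k + u_k)

with X_k the binary mutant status of cell line k and u_k ~ N(0, sigma^2)
i.i.d. random intercepts capturing cell-line heterogeneity.  The NB2 shape
theta gives variance mu + mu^2/theta.  The marginal likelihood integrates
u_k out per cell line by adaptive Gauss-Hermite quadrature centered at the
per-cluster mode with curvature scaling; one node reproduces the Laplace
approximation.  Self-dependency is a one-sided Wald test of H0: beta = 0
against H1: beta < 0 (mutant lines more depleted, i.e. lower ranks).

Model / Results classes follow the statsmodels convention: construct from
data, ``fit()`` returns a results object carrying estimates, standard
errors, the maximized log-likelihood and a ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

__all__ = [
    "GlmmObservations",
    "NegativeBinomialMixedModel",
    "GaussianMixedModel",
    "MixedModelResults",
    "nb_pmf",
    "nb_logpmf",
    "nb_glmm_marginal_loglik",
    "fit_nb_glmm",
    "fit_gaussian_lmm",
    "wald_one_sided_p",
    "bh_adjust",
    "hypergeom_overlap_p",
    "simulate_nb_glmm",
]

_SIGMA_FLOOR = 1e-6  # below this the random intercept is treated as exactly zero
_LOG_SIGMA_ZERO = -30.0


# ------------------------------------------------------------------ NB pmf


def nb_logpmf(r, mu, theta):
    """Log NB2 pmf with mean ``mu`` and shape ``theta`` (variance mu + mu^2/theta)."""
    r = np.asarray(r, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return (
        special.gammaln(r + theta)
        - special.gammaln(theta)
        - special.gammaln(r + 1.0)
        + theta * (np.log(theta) - np.log(mu + theta))
        + r * (np.log(mu) - np.log(mu + theta))
    )


def nb_pmf(r, mu, theta):
    """NB2 probability mass f(r; mu, theta), computed in log space.

    f(r) = Gamma(r+theta) / (Gamma(theta) r!) * (theta/(mu+theta))^theta
           * (mu/(mu+theta))^r
    """
    r_arr = np.asarray(r)
    if not np.all(np.equal(np.mod(r_arr, 1), 0)) or np.any(r_arr < 0):
        raise ValueError("r must be a non-negative integer")
    if np.any(np.asarray(mu) <= 0) or np.any(np.asarray(theta) <= 0):
        raise ValueError("mu and theta must be positive")
    return np.exp(nb_logpmf(r_arr, mu, theta))


# ------------------------------------------------------- observation bundle


@dataclass
class GlmmObservations:
    """Flat per-observation arrays for one gene's test.

    ``ranks`` are positive integers; ``mutant`` is the 0/1 status of each
    observation's cell line (constant within a line); ``cluster`` indexes
    cell lines 0..l-1.
    """

    ranks: np.ndarray
    mutant: np.ndarray
    cluster: np.ndarray
    cluster_labels: list

    @classmethod
    def from_arrays(cls, ranks, mutant, groups):
        ranks = np.asarray(ranks, dtype=float)
        mutant = np.asarray(mutant, dtype=float)
        groups = np.asarray(groups)
        if not (ranks.shape == mutant.shape == groups.shape):
            raise ValueError("ranks, mutant and groups must have equal length")
        labels, cluster = np.unique(groups, return_inverse=True)
        for k in range(len(labels)):
            xs = np.unique(mutant[cluster == k])
            if len(xs) > 1:
                raise ValueError(f"mutant status not constant within cell line {labels[k]!r}")
        return cls(ranks=ranks, mutant=mutant, cluster=cluster, cluster_labels=list(labels))

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    @property
    def cluster_x(self) -> np.ndarray:
        x = np.zeros(self.n_clusters)
        x[self.cluster] = self.mutant  # constant within cluster
        return x


# ------------------------------------------------- marginal log-likelihood


def _cluster_modes(r, eta, kidx, n_clusters, theta, sigma2, max_iter=100, tol=1e-10):
    """Newton mode-finding for the per-cluster integrands (concave in u)."""
    u = np.zeros(n_clusters)
    for _ in range(max_iter):
        mu = np.exp(eta + u[kidx])
        g = np.bincount(kidx, weights=r - (r + theta) * mu / (mu + theta), minlength=n_clusters) - u / sigma2
        h = np.bincount(kidx, weights=(r + theta) * theta * mu / (mu + theta) ** 2, minlength=n_clusters) + 1.0 / sigma2
        step = g / h
        np.clip(step, -4.0, 4.0, out=step)
        u += step
        if np.max(np.abs(g)) < tol:
            break
    mu = np.exp(eta + u[kidx])
    h = np.bincount(kidx, weights=(r + theta) * theta * mu / (mu + theta) ** 2, minlength=n_clusters) + 1.0 / sigma2
    return u, h


def nb_glmm_marginal_loglik(params, obs: GlmmObservations, n_quad: int = 1) -> float:
    """Marginal log-likelihood at params = (beta0, beta, log theta, log sigma).

    Each cell line's integral over its random intercept is evaluated by
    adaptive Gauss-Hermite quadrature centered at the cluster mode with
    curvature scaling; ``n_quad=1`` is the Laplace approximation.  The
    sigma -> 0 limit is handled analytically (u identically zero).
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameters")
    beta0, beta, log_theta, log_sigma = params
    theta = math.exp(log_theta)
    sigma = math.exp(log_sigma)
    r = obs.ranks
    kidx = obs.cluster
    eta = beta0 + beta * obs.mutant
    if sigma < _SIGMA_FLOOR:
        return float(np.sum(nb_logpmf(r, np.exp(eta), theta)))

    sigma2 = sigma * sigma
    n_clusters = obs.n_clusters
    u_hat, h = _cluster_modes(r, eta, kidx, n_clusters, theta, sigma2)

    nodes, weights = hermgauss(n_quad)
    sd = 1.0 / np.sqrt(h)  # curvature scale per cluster
    log_terms = np.empty((n_quad, n_clusters))
    for j, (z, w) in enumerate(zip(nodes, weights)):
        u = u_hat + math.sqrt(2.0) * sd * z
        joint = (
            np.bincount(kidx, weights=nb_logpmf(r, np.exp(eta + u[kidx]), theta), minlength=n_clusters)
            - 0.5 * u * u / sigma2
            - 0.5 * math.log(2.0 * math.pi * sigma2)
        )
        log_terms[j] = math.log(w) + z * z + joint
    ll_k = special.logsumexp(log_terms, axis=0) + 0.5 * math.log(2.0) + np.log(sd)
    return float(np.sum(ll_k))


# ------------------------------------------------------------- results


class MixedModelResults:
    """Estimates and inference from a fitted random-intercept mixed model."""

    def __init__(self, model, beta0, beta, theta, sigma2, se_beta, loglik, converged, n_quad, extra=None):
        self.model = model
        self.beta0 = beta0
        self.beta = beta
        self.theta = theta
        self.sigma2 = sigma2
        self.se_beta = se_beta
        self.loglik = loglik
        self.llf = loglik
        self.converged = converged
        self.n_quad = n_quad
        self.extra = extra or {}

    @property
    def params(self) -> dict:
        return {"beta0": self.beta0, "beta": self.beta, "theta": self.theta, "sigma2": self.sigma2}

    @property
    def pvalue_one_sided(self) -> float:
        """One-sided Wald p for H1: beta < 0."""
        return wald_one_sided_p(self.beta, self.se_beta)

    def summary(self) -> str:
        kind = type(self.model).__name__
        lines = [
            f"{kind} results",
            "=" * 46,
            f"{'intercept (beta0)':<28}{self.beta0: .6g}",
            f"{'mutant effect (beta)':<28}{self.beta: .6g}",
            f"{'se(beta)':<28}{self.se_beta: .6g}",
        ]
        if self.theta is not None:
            lines.append(f"{'NB shape (theta)':<28}{self.theta: .6g}")
        lines += [
            f"{'random-intercept var':<28}{self.sigma2: .6g}",
            f"{'log-likelihood':<28}{self.loglik: .6g}",
            f"{'one-sided p (beta < 0)':<28}{self.pvalue_one_sided: .4g}",
            f"{'converged':<28}{self.converged}",
        ]
        return "\n".join(lines)


# ------------------------------------------------------------- NB model


class NegativeBinomialMixedModel:
    """NB random-intercept model for one gene's shRNA ranks.

    Parameters
    ----------
    endog : array of positive integer ranks, one entry per (shRNA, cell line)
        observation.
    mutant : 0/1 array, the alteration status of each observation's cell line.
    groups : array of cell-line labels (the random-effect grouping).
    """

    def __init__(self, endog, mutant, groups):
        self.obs = GlmmObservations.from_arrays(endog, mutant, groups)
        if np.any(self.obs.ranks < 1):
            raise ValueError("ranks must be positive integers")
        if np.ptp(self.obs.ranks) == 0:
            raise ValueError("degenerate observations: all ranks equal")
        x = self.obs.cluster_x
        if not (np.any(x == 0) and np.any(x == 1)):
            raise ValueError("need both mutant and wild-type cell lines")

    # -- likelihood ---------------------------------------------------
    def loglike(self, params, n_quad: int = 1) -> float:
        return nb_glmm_marginal_loglik(params, self.obs, n_quad=n_quad)

    def _start_params(self) -> np.ndarray:
        r = self.obs.ranks
        x = self.obs.mutant
        m0 = r[x == 0].mean()
        m1 = r[x == 1].mean()
        beta0 = math.log(max(m0, 0.5))
        beta = math.log(max(m1, 0.5)) - beta0
        mean, var = r.mean(), r.var()
        theta = mean * mean / (var - mean) if var > mean else 100.0
        theta = min(max(theta, 0.05), 1e4)
        # between-cell-line spread of log mean ranks
        sums = np.bincount(self.obs.cluster, weights=r, minlength=self.obs.n_clusters)
        cnts = np.bincount(self.obs.cluster, minlength=self.obs.n_clusters)
        logmeans = np.log(np.maximum(sums / np.maximum(cnts, 1), 0.5))
        sigma = max(float(np.std(logmeans)), 0.05)
        return np.array([beta0, beta, math.log(theta), math.log(sigma)])

    def fit(self, n_quad: int = 1, maxiter: int = 500, gtol: float = 1e-6) -> MixedModelResults:
        """Maximize the marginal likelihood over (beta0, beta, log theta, log sigma).

        A profile fit with sigma fixed at zero is always computed as well; if
        it attains at least the same likelihood the boundary solution
        (sigma^2 = 0) is returned.  se(beta) comes from the inverse observed
        information (central finite differences) at the optimum.
        """
        start = self._start_params()

        def neg4(p):
            try:
                return -self.loglike(p, n_quad=n_quad)
            except (OverflowError, FloatingPointError):
                return 1e12

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res4 = optimize.minimize(neg4, start, method="L-BFGS-B", options={"maxiter": maxiter, "gtol": gtol})

        def neg3(p3):
            p = np.array([p3[0], p3[1], p3[2], _LOG_SIGMA_ZERO])
            try:
                return -self.loglike(p, n_quad=n_quad)
            except (OverflowError, FloatingPointError):
                return 1e12

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res3 = optimize.minimize(neg3, start[:3], method="L-BFGS-B", options={"maxiter": maxiter, "gtol": gtol})

        if -res3.fun >= -res4.fun - 1e-8:
            params = np.array([res3.x[0], res3.x[1], res3.x[2], _LOG_SIGMA_ZERO])
            loglik = -res3.fun
            free = [0, 1, 2]
            converged = bool(res3.success)
            hess_fun = lambda q: neg3(q)
            hess_at = res3.x
        else:
            params = res4.x
            loglik = -res4.fun
            free = [0, 1, 2, 3]
            converged = bool(res4.success)
            hess_fun = lambda q: neg4(q)
            hess_at = res4.x

        se_beta, ok = _se_from_hessian(hess_fun, hess_at, index=1)
        if not ok:
            converged = False
        beta0, beta, log_theta = params[0], params[1], params[2]
        sigma2 = 0.0 if params[3] <= _LOG_SIGMA_ZERO + 1.0 else math.exp(2.0 * params[3])
        return MixedModelResults(
            model=self,
            beta0=float(beta0),
            beta=float(beta),
            theta=float(math.exp(log_theta)),
            sigma2=float(sigma2),
            se_beta=float(se_beta),
            loglik=float(loglik),
            converged=converged,
            n_quad=n_quad,
        )


def _se_from_hessian(negloglik, x, index, rel_step=1e-4):
    """Standard error of one parameter from a central-difference Hessian."""
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                f0 = negloglik(x)
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (negloglik(xp) - 2.0 * f0 + negloglik(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                H[i, j] = H[j, i] = (negloglik(xpp) - negloglik(xpm) - negloglik(xmp) + negloglik(xmm)) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        var = cov[index, index]
        if var > 0:
            return math.sqrt(var), True
    except np.linalg.LinAlgError:
        pass
    cov = np.linalg.pinv(H)
    var = abs(cov[index, index])
    return math.sqrt(max(var, 1e-12)), False


# ------------------------------------------------------------ Gaussian LMM


class GaussianMixedModel:
    """Gaussian random-intercept model for continuous logFC responses.

    Used by the ablation variants that skip the rank transform.  The ML fit
    profiles the fixed effects by GLS at each variance-component value;
    the marginal likelihood is exact (no quadrature).
    """

    def __init__(self, endog, mutant, groups):
        self.obs = GlmmObservations.from_arrays(endog, mutant, groups)
        x = self.obs.cluster_x
        if not (np.any(x == 0) and np.any(x == 1)):
            raise ValueError("need both mutant and wild-type cell lines")
        counts = np.bincount(self.obs.cluster, minlength=self.obs.n_clusters)
        if np.any(counts == 0):
            raise ValueError("singular grouping: empty cluster")

    def _profile(self, su2, se2):
        """GLS fixed effects + exact ML loglik for given variance components."""
        y = self.obs.ranks  # continuous here
        x = self.obs.mutant
        kidx = self.obs.cluster
        n_clusters = self.obs.n_clusters
        nk = np.bincount(kidx, minlength=n_clusters).astype(float)
        lam = su2 / (se2 + nk * su2)  # shrinkage per cluster

        X = np.column_stack([np.ones_like(y), x])
        # V^{-1} = (I - lam_k J_k)/se2 per cluster
        Xs = np.vstack([np.bincount(kidx, weights=X[:, j], minlength=n_clusters) for j in range(2)]).T
        ys = np.bincount(kidx, weights=y, minlength=n_clusters)
        XtVX = (X.T @ X - (Xs * lam[:, None]).T @ Xs) / se2
        XtVy = (X.T @ y - (Xs * lam[:, None]).T @ ys) / se2
        coef = np.linalg.solve(XtVX, XtVy)
        resid = y - X @ coef
        rs = np.bincount(kidx, weights=resid, minlength=n_clusters)
        quad = (resid @ resid - lam @ (rs * rs)) / se2
        logdet = (nk - 1.0) * math.log(se2) + np.log(se2 + nk * su2)
        ll = -0.5 * (len(y) * math.log(2.0 * math.pi) + logdet.sum() + quad)
        cov = np.linalg.inv(XtVX)
        return coef, cov, float(ll)

    def loglike(self, params) -> float:
        """Marginal loglik at params = (beta0, beta, log sigma_u, log sigma_e)."""
        beta0, beta, log_su, log_se = params
        su2, se2 = math.exp(2 * log_su), math.exp(2 * log_se)
        y = self.obs.ranks
        x = self.obs.mutant
        kidx = self.obs.cluster
        n_clusters = self.obs.n_clusters
        nk = np.bincount(kidx, minlength=n_clusters).astype(float)
        lam = su2 / (se2 + nk * su2)
        resid = y - beta0 - beta * x
        rs = np.bincount(kidx, weights=resid, minlength=n_clusters)
        quad = (resid @ resid - lam @ (rs * rs)) / se2
        logdet = (nk - 1.0) * math.log(se2) + np.log(se2 + nk * su2)
        return float(-0.5 * (len(y) * math.log(2.0 * math.pi) + logdet.sum() + quad))

    def fit(self, sigma_zero: bool = False, maxiter: int = 200) -> MixedModelResults:
        y = self.obs.ranks
        resid_var = max(float(np.var(y)), 1e-8)

        def neg(p):
            su2 = 0.0 if sigma_zero else math.exp(2.0 * p[0])
            se2 = math.exp(2.0 * p[-1])
            try:
                return -self._profile(su2, se2)[2]
            except np.linalg.LinAlgError:
                return 1e12

        if sigma_zero:
            start = np.array([0.5 * math.log(resid_var)])
        else:
            start = np.array([0.5 * math.log(resid_var / 2.0), 0.5 * math.log(resid_var / 2.0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(neg, start, method="Nelder-Mead", options={"maxiter": maxiter * 10, "xatol": 1e-10, "fatol": 1e-12})
        su2 = 0.0 if sigma_zero else math.exp(2.0 * res.x[0])
        se2 = math.exp(2.0 * res.x[-1])
        if not sigma_zero:
            # compare against the sigma_u = 0 boundary
            res0 = optimize.minimize(
                lambda p: -self._profile(0.0, math.exp(2.0 * p[0]))[2],
                np.array([0.5 * math.log(resid_var)]),
                method="Nelder-Mead",
                options={"maxiter": maxiter * 10, "xatol": 1e-10, "fatol": 1e-12},
            )
            if -res0.fun >= -res.fun - 1e-10:
                su2, se2, res = 0.0, math.exp(2.0 * res0.x[0]), res0
        coef, cov, ll = self._profile(su2, se2)
        return MixedModelResults(
            model=self,
            beta0=float(coef[0]),
            beta=float(coef[1]),
            theta=None,
            sigma2=float(su2),
            se_beta=float(math.sqrt(cov[1, 1])),
            loglik=ll,
            converged=bool(res.success),
            n_quad=0,
            extra={"resid_var": se2},
        )


# -------------------------------------------------------- function surface


def fit_nb_glmm(obs: GlmmObservations | None = None, n_quad: int = 1, *, ranks=None, mutant=None, groups=None, **kw) -> MixedModelResults:
    """Functional wrapper around :class:`NegativeBinomialMixedModel`."""
    if obs is not None:
        model = NegativeBinomialMixedModel.__new__(NegativeBinomialMixedModel)
        model.obs = obs
    else:
        model = NegativeBinomialMixedModel(ranks, mutant, groups)
    return NegativeBinomialMixedModel.fit(model, n_quad=n_quad, **kw)


def fit_gaussian_lmm(values, mutant, groups, **kw) -> MixedModelResults:
    """Functional wrapper around :class:`GaussianMixedModel`."""
    return GaussianMixedModel(values, mutant, groups).fit(**kw)


def wald_one_sided_p(beta_hat: float, se: float) -> float:
    """Lower-tail Wald p-value Phi(beta_hat / se) for H1: beta < 0."""
    if not se > 0:
        raise ValueError("standard error must be positive")
    return float(stats.norm.cdf(beta_hat / se))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_overlap_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric enrichment P(X >= k).

    X counts reference-set members (K of N in the universe) in a hit list of
    size n.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError("inconsistent hypergeometric counts")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def simulate_nb_glmm(beta0, beta, theta, sigma, n_mutant, n_wildtype, n_shrnas, rng) -> GlmmObservations:
    """Draw one dataset from the NB random-intercept model (for recovery studies)."""
    l = n_mutant + n_wildtype
    x = np.array([1.0] * n_mutant + [0.0] * n_wildtype)
    u = rng.normal(0.0, sigma, size=l)
    mu = np.exp(beta0 + beta * x + u)
    ranks = rng.negative_binomial(theta, theta / (theta + mu[:, None]), size=(l, n_shrnas))
    flat = ranks.reshape(-1).astype(float)
    flat = np.maximum(flat, 1.0)  # ranks are positive
    cluster = np.repeat(np.arange(l), n_shrnas)
    return GlmmObservations(
        ranks=flat,
        mutant=x[cluster],
        cluster=cluster,
        cluster_labels=list(range(l)),
    )
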