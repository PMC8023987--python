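"""Independent reference computations used to validate the implementation.

Everything here deliberately avoids the package's own likelihood code paths:
densities come from scipy, integrals from quadrature or Monte Carlo, and
mixed-model fits from statsmodels.
"""

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import multivariate_normal, norm


def patient_density_gh(y, t, centre, params, transform="sqrt", degree=3,
                       n_nodes=120):
    """Mixture density of one patient's outcome vector by Gauss-Hermite
    integration over the (intercept, slope) random effects."""
    y = np.asarray(y, float)
    X = np.column_stack([t ** k for k in range(degree + 1)])
    D = params.chol_D @ params.chol_D.T
    L = params.chol_D
    q = L.shape[0]
    sigma = params.sigma
    nodes, weights = hermegauss(n_nodes)   # weight exp(-u^2/2)
    weights = weights / np.sqrt(2 * np.pi)
    total = 0.0
    pis = params.class_probs
    for g, pi in enumerate(pis):
        mean0 = X @ params.beta[g]
        if params.gamma.size:
            mean0 = mean0 + params.gamma[0] * centre
        acc = 0.0
        if q == 2:
            for a, wa in zip(nodes, weights):
                for b, wb in zip(nodes, weights):
                    bvec = L @ np.array([a, b])
                    mu = mean0 + bvec[0] + bvec[1] * t
                    acc += wa * wb * np.prod(norm.pdf(y, mu, sigma))
        else:
            for a, wa in zip(nodes, weights):
                mu = mean0 + (L[0, 0] * a)
                acc += wa * np.prod(norm.pdf(y, mu, sigma))
        total += pi * acc
    return total


def patient_density_mc(y, t, centre, params, degree=3, n_draws=1_000_000,
                       seed=0):
    """Same integral by plain Monte Carlo over the random effects."""
    from scipy.stats import qmc
    y = np.asarray(y, float)
    X = np.column_stack([t ** k for k in range(degree + 1)])
    L = params.chol_D
    q = L.shape[0]
    sigma = params.sigma
    sob = qmc.Sobol(q, scramble=True, seed=seed).random(n_draws)
    u = norm.ppf(np.clip(sob, 1e-12, 1 - 1e-12))
    b = u @ L.T
    total = 0.0
    for g, pi in enumerate(params.class_probs):
        mean0 = X @ params.beta[g]
        if params.gamma.size:
            mean0 = mean0 + params.gamma[0] * centre
        mu = mean0[None, :] + b[:, :1] + (b[:, 1:2] * t[None, :] if q == 2
                                          else 0.0)
        total += pi * np.exp(
            norm.logpdf(y[None, :], mu, sigma).sum(1)).mean()
    return total


def patient_density_dense(y, t, centre, params, degree=3):
    """Closed-form marginal density via the dense T x T covariance."""
    y = np.asarray(y, float)
    X = np.column_stack([t ** k for k in range(degree + 1)])
    q = params.chol_D.shape[0]
    Z = np.column_stack([np.ones_like(t), t])[:, :q]
    D = params.chol_D @ params.chol_D.T
    V = Z @ D @ Z.T + params.sigma ** 2 * np.eye(len(t))
    total = 0.0
    for g, pi in enumerate(params.class_probs):
        mu = X @ params.beta[g]
        if params.gamma.size:
            mu = mu + params.gamma[0] * centre
        total += pi * multivariate_normal.pdf(y, mean=mu, cov=V)
    return total


def gee_independence_sandwich(y, X, groups):
    """Brute-force robust covariance of an independence-working logistic GEE:
    A^{-1} B A^{-1} with A the Fisher information of the working model and B
    the outer product of cluster score sums."""
    from scipy.special import expit
    import statsmodels.api as sm

    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    beta = np.asarray(glm.params)
    mu = expit(X @ beta)
    Amat = X.T @ (X * (mu * (1 - mu))[:, None])
    B = np.zeros_like(Amat)
    for gid in np.unique(groups):
        m = groups == gid
        s = X[m].T @ (y[m] - mu[m])
        B += np.outer(s, s)
    Ainv = np.linalg.inv(Amat)
    return beta, Ainv @ B @ Ainv
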