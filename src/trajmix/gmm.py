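"""Growth mixture model: a finite mixture of linear mixed models.

Each latent class g has its own polynomial mean trajectory in time on the
transformed outcome scale; individuals deviate from their class curve through
a shared random intercept (+ slope) structure and i.i.d. residual noise.
Marginalizing the random effects gives, per patient i and class g,

    y*_i | class g  ~  N( X_i beta_g + W_i gamma ,  Z_i D Z_i' + sigma^2 I )

and the observed-data log-likelihood sums log SUM_g pi_g N_g over patients.
Estimation is direct quasi-Newton maximization (L-BFGS with an analytic
gradient) of the marginal likelihood over an unconstrained parameterization
(multinomial-logit class intercepts, Cholesky factor of D, log sigma), with
multiple starts to cope with multimodality.  Visits with a missing outcome
are dropped from the patient's vectors, which is ignorable under MAR when the
missingness predictors are in the mean model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .cohort import Cohort, inverse_transform, transform_outcome

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GMMSpec:
    """Model definition: number of classes, time polynomial, transform,
    random-effects structure, and common (non-class-specific) covariates."""

    n_classes: int = 2
    time_degree: int = 3
    transform: str = "sqrt"
    random_effects: str = "intercept+slope"   # or 'intercept'
    covariates: tuple[str, ...] = ()          # baseline columns; 'centre' -> A indicator
    outcome: str = "pga"

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.time_degree < 1:
            raise ValueError("need n_classes >= 1 and time_degree >= 1")
        if self.random_effects not in ("intercept", "intercept+slope"):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")

    @property
    def q(self) -> int:
        return 2 if self.random_effects == "intercept+slope" else 1

    def n_params(self) -> int:
        d, G, c, q = self.time_degree, self.n_classes, len(self.covariates), self.q
        return (G - 1) + G * (d + 1) + c + q * (q + 1) // 2 + 1


@dataclass
class GMMParams:
    """Unpacked parameters on the raw (unscaled-time) scale."""

    theta: np.ndarray      # (G-1,) class-membership logits, class G reference
    beta: np.ndarray       # (G, d+1) class mean-curve coefficients
    gamma: np.ndarray      # (c,) common covariate effects
    chol_D: np.ndarray     # (q, q) lower Cholesky factor of D
    log_sigma: float

    @property
    def class_probs(self) -> np.ndarray:
        return softmax(np.append(self.theta, 0.0))

    @property
    def D(self) -> np.ndarray:
        return self.chol_D @ self.chol_D.T

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))


@dataclass
class GMMFit:
    spec: GMMSpec
    params: GMMParams
    loglik: float
    n_params: int
    bic: float
    entropy: float | None
    posterior: pd.DataFrame          # index patient_id, columns class_1..class_G
    modal_class: pd.Series           # 1-based
    mean_posterior_by_class: np.ndarray
    convergence: dict
    n_patients: int
    n_dropped: int
    max_time: float

    def to_json(self, path, posterior_path=None) -> None:
        """Serialize fit (JSON) with the posterior matrix as a CSV sidecar."""
        obj = {
            "spec": asdict(self.spec),
            "params": {
                "theta": self.params.theta.tolist(),
                "beta": self.params.beta.tolist(),
                "gamma": self.params.gamma.tolist(),
                "chol_D": self.params.chol_D.tolist(),
                "log_sigma": self.params.log_sigma,
            },
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "entropy": self.entropy,
            "class_probs": self.params.class_probs.tolist(),
            "mean_posterior_by_class": [
                None if not np.isfinite(v) else float(v)
                for v in self.mean_posterior_by_class
            ],
            "convergence": self.convergence,
            "n_patients": self.n_patients,
            "n_dropped": self.n_dropped,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
        if posterior_path is not None:
            post = self.posterior.copy()
            post["modal_class"] = self.modal_class
            post.to_csv(posterior_path)


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class PreparedData:
    """Padded per-patient design arrays for batched likelihood evaluation."""

    y: np.ndarray          # (N, T) transformed outcome, 0 where padded
    mask: np.ndarray       # (N, T) 1 = real visit
    X: np.ndarray          # (N, T, d+1) scaled-time polynomial basis
    W: np.ndarray          # (N, T, c) covariates
    Z: np.ndarray          # (N, T, q) scaled-time RE design
    n_i: np.ndarray        # (N,) visits per patient
    patient_ids: list
    time_scale: float
    n_dropped: int
    max_time: float


def _covariate_matrix(baseline: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for name in covariates:
        if name == "centre":
            cols.append((baseline["centre"] == "A").astype(float).to_numpy())
        else:
            cols.append(baseline[name].astype(float).to_numpy())
    if not cols:
        return np.zeros((len(baseline), 0))
    return np.column_stack(cols)


def prepare_data(cohort: Cohort, spec: GMMSpec) -> PreparedData:
    """Build padded arrays; patients with zero non-missing outcomes are
    excluded (their count is recorded)."""
    visits = cohort.visits
    ycol = spec.outcome
    usable = visits[visits[ycol].notna()]
    ids_all = list(cohort.baseline["patient_id"])
    counts = usable.groupby("patient_id").size()
    kept = [pid for pid in ids_all if counts.get(pid, 0) > 0]
    n_dropped = len(ids_all) - len(kept)
    if not kept:
        raise ValueError("no patient has a non-missing outcome")

    N = len(kept)
    T = int(counts.loc[kept].max())
    d, q, c = spec.time_degree, spec.q, len(spec.covariates)
    scale = max(float(usable["t"].max()), 1e-9)

    y = np.zeros((N, T))
    mask = np.zeros((N, T))
    X = np.zeros((N, T, d + 1))
    Z = np.zeros((N, T, q))
    groups = {pid: g for pid, g in usable.groupby("patient_id")}
    for i, pid in enumerate(kept):
        g = groups[pid]
        t = g["t"].to_numpy(float)
        n = len(t)
        ts = t / scale
        y[i, :n] = transform_outcome(g[ycol].to_numpy(float), spec.transform)
        mask[i, :n] = 1.0
        for k in range(d + 1):
            X[i, :n, k] = ts ** k
        Z[i, :n, 0] = 1.0
        if q == 2:
            Z[i, :n, 1] = ts

    base = cohort.baseline.set_index("patient_id").loc[kept].reset_index()
    Wb = _covariate_matrix(base, spec.covariates)
    W = np.broadcast_to(Wb[:, None, :], (N, T, c)).copy()
    W *= mask[:, :, None]
    return PreparedData(
        y=y, mask=mask, X=X, W=W, Z=Z, n_i=mask.sum(1),
        patient_ids=kept, time_scale=scale, n_dropped=n_dropped,
        max_time=float(usable["t"].max()),
    )


# ---------------------------------------------------------------------------
# parameter packing (internal, scaled-time space)


def _raw_to_internal(params: GMMParams, scale: float, spec: GMMSpec) -> np.ndarray:
    pw = scale ** np.arange(spec.time_degree + 1)
    beta_int = params.beta * pw[None, :]
    S = np.diag([1.0, scale][: spec.q])
    L_int = S @ params.chol_D
    return _pack(params.theta, beta_int, params.gamma, L_int,
                 params.log_sigma, spec)


def _internal_to_raw(x: np.ndarray, scale: float, spec: GMMSpec) -> GMMParams:
    theta, beta_int, gamma, L_int, log_sigma = _unpack(x, spec)
    pw = scale ** np.arange(spec.time_degree + 1)
    beta = beta_int / pw[None, :]
    Sinv = np.diag([1.0, 1.0 / scale][: spec.q])
    return GMMParams(theta=theta, beta=beta, gamma=gamma,
                     chol_D=Sinv @ L_int, log_sigma=float(log_sigma))


def _pack(theta, beta, gamma, L, log_sigma, spec: GMMSpec) -> np.ndarray:
    q = spec.q
    tril = L[np.tril_indices(q)]
    return np.concatenate([np.ravel(theta), np.ravel(beta), np.ravel(gamma),
                           tril, [log_sigma]])


def _unpack(x, spec: GMMSpec):
    G, d, c, q = spec.n_classes, spec.time_degree, len(spec.covariates), spec.q
    i = 0
    theta = x[i:i + G - 1]; i += G - 1
    beta = x[i:i + G * (d + 1)].reshape(G, d + 1); i += G * (d + 1)
    gamma = x[i:i + c]; i += c
    L = np.zeros((q, q))
    ntril = q * (q + 1) // 2
    L[np.tril_indices(q)] = x[i:i + ntril]; i += ntril
    log_sigma = float(x[i])
    return theta, beta, gamma, L, log_sigma


# ---------------------------------------------------------------------------
# likelihood and gradient (batched over patients)


def _loglik_terms(x, data: PreparedData, spec: GMMSpec):
    """Per-patient, per-class Gaussian log-densities and class log-priors.

    The marginal covariance V_i = Z_i D Z_i' + sigma^2 I has low-rank
    structure, so determinants and solves reduce to q x q algebra via the
    Woodbury identity (q = 1 or 2 random effects); no dense T x T matrix is
    ever formed.
    """
    theta, beta, gamma, L, log_sigma = _unpack(x, spec)
    sigma2 = np.exp(2.0 * log_sigma)
    logpi = np.append(theta, 0.0)
    logpi = logpi - logsumexp(logpi)
    q = spec.q

    A = np.einsum("itq,itr->iqr", data.Z, data.Z)          # (N, q, q)
    K = sigma2 * np.eye(q)[None] + L.T @ A @ L             # (N, q, q)
    Kinv = np.linalg.inv(K)
    sign, logdetK = np.linalg.slogdet(K)
    if np.any(sign <= 0):
        raise FloatingPointError("singular marginal covariance")
    logdet = (data.n_i - q) * np.log(sigma2) + logdetK

    base_mean = np.einsum("itc,c->it", data.W, gamma) if gamma.size \
        else np.zeros_like(data.y)
    G = spec.n_classes
    N, T = data.y.shape
    R = np.empty((G, N, T))
    for g in range(G):
        R[g] = (data.y - base_mean - data.X @ beta[g]) * data.mask
    ZL = data.Z @ L                                        # (N, T, q)
    ZtR = np.einsum("itq,git->giq", ZL, R)                 # L' Z' r
    d = np.einsum("ipq,giq->gip", Kinv, ZtR)
    alpha = (R - np.einsum("itp,gip->git", ZL, d)) / sigma2
    quad = np.einsum("git,git->gi", R, alpha)
    logN = -0.5 * (data.n_i[None, :] * _LOG2PI + logdet[None, :] + quad)
    aux = {"A": A, "Kinv": Kinv, "L": L, "sigma2": sigma2}
    return logpi, logN, alpha, aux, R


def _loglik_and_grad(x, data: PreparedData, spec: GMMSpec):
    logpi, logN, alpha, aux, R = _loglik_terms(x, data, spec)
    theta, beta, gamma, L, log_sigma = _unpack(x, spec)
    sigma2 = aux["sigma2"]
    A, Kinv = aux["A"], aux["Kinv"]
    G = spec.n_classes

    joint = logpi[:, None] + logN            # (G, N)
    ll_i = logsumexp(joint, axis=0)
    ll = float(ll_i.sum())
    w = np.exp(joint - ll_i[None, :])        # responsibilities (G, N)

    pi = np.exp(logpi)
    g_theta = (w.sum(1) - len(data.n_i) * pi)[:G - 1]

    g_beta = np.stack([
        np.einsum("i,itp,it->p", w[g], data.X, alpha[g]) for g in range(G)
    ])
    if gamma.size:
        g_gamma = sum(
            np.einsum("i,itc,it->c", w[g], data.W, alpha[g]) for g in range(G)
        )
    else:
        g_gamma = np.zeros(0)

    # S = sum_i Z_i' M_i Z_i with M = 0.5(sum_g w_g a a' - V^{-1}), using
    # Z'V^{-1}Z = (A - AL Kinv (AL)')/sigma^2
    Zta = np.einsum("itq,git->giq", data.Z, alpha)
    awa = np.einsum("gi,giq,gir->iqr", w, Zta, Zta)
    AL = A @ L
    ZVZ = (A - AL @ Kinv @ AL.transpose(0, 2, 1)) / sigma2
    S = 0.5 * (awa - ZVZ).sum(0)
    g_L = (2.0 * S @ L)[np.tril_indices(spec.q)]

    # trace of M over the real (unpadded) diagonal
    a2 = np.einsum("gi,git,git->i", w, alpha, alpha)
    trVinv = (data.n_i - np.einsum(
        "ipq,qr,irs,sp->i", Kinv, L.T, A, L)) / sigma2
    g_logsig = float(sigma2 * (a2 - trVinv).sum())

    grad = np.concatenate([g_theta, g_beta.ravel(), g_gamma, g_L, [g_logsig]])
    return ll, grad


def marginal_loglik(params: GMMParams, cohort: Cohort, spec: GMMSpec) -> float:
    """Observed-data log-likelihood of ``params`` on ``cohort``."""
    data = prepare_data(cohort, spec)
    x = _raw_to_internal(params, data.time_scale, spec)
    ll, _ = _loglik_and_grad(x, data, spec)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood")
    return ll


def posterior_probs(params: GMMParams, cohort: Cohort, spec: GMMSpec) -> pd.DataFrame:
    """Posterior class-membership probabilities p_ig by Bayes' rule."""
    data = prepare_data(cohort, spec)
    x = _raw_to_internal(params, data.time_scale, spec)
    logpi, logN, *_ = _loglik_terms(x, data, spec)
    joint = logpi[:, None] + logN
    norm = logsumexp(joint, axis=0)
    if not np.all(np.isfinite(norm)):
        bad = [data.patient_ids[i] for i in np.nonzero(~np.isfinite(norm))[0]]
        raise FloatingPointError(f"zero mixture density for patients {bad}")
    post = np.exp(joint - norm[None, :]).T
    return pd.DataFrame(
        post, index=pd.Index(data.patient_ids, name="patient_id"),
        columns=[f"class_{g + 1}" for g in range(spec.n_classes)],
    )


# ---------------------------------------------------------------------------
# diagnostics


def entropy(posterior) -> float:
    """Relative entropy of the posterior matrix: 1 means perfect allocation,
    0 means uninformative (uniform) posteriors.  Defined for G >= 2."""
    P = np.asarray(posterior, dtype=float)
    n, G = P.shape
    if G < 2:
        raise ValueError("entropy is undefined for a single class")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log(P), 0.0)
    return 1.0 - float(terms.sum()) / (n * np.log(G))


def mean_posterior_by_class(posterior, modal_class) -> np.ndarray:
    """Mean posterior probability of class g among patients modally in g;
    NaN where a class has no members."""
    P = np.asarray(posterior, dtype=float)
    modal = np.asarray(modal_class, dtype=int)
    G = P.shape[1]
    out = np.full(G, np.nan)
    for g in range(G):
        members = modal == g + 1
        if members.any():
            out[g] = P[members, g].mean()
    return out


def bic(loglik: float, n_params: int, n_patients: int) -> float:
    """-2 loglik + k ln(n); n is the number of patients, not visits."""
    return -2.0 * loglik + n_params * np.log(n_patients)


# ---------------------------------------------------------------------------
# fitting


def _single_class_start(data: PreparedData, spec: GMMSpec, rng) -> np.ndarray:
    """OLS polynomial fit ignoring clustering, as a G=1 start."""
    m = data.mask.astype(bool)
    Xf = data.X[m]
    yf = data.y[m]
    Wf = data.W[m]
    Xd = np.column_stack([Xf, Wf]) if Wf.shape[1] else Xf
    coef, *_ = np.linalg.lstsq(Xd, yf, rcond=None)
    resid_sd = float(np.std(yf - Xd @ coef))
    d = spec.time_degree
    beta = np.tile(coef[:d + 1], (spec.n_classes, 1))
    gamma = coef[d + 1:]
    L = np.diag([max(0.5 * resid_sd, 1e-3), 0.1 * max(resid_sd, 1e-2)][: spec.q])
    return _pack(np.zeros(spec.n_classes - 1), beta, gamma, L,
                 np.log(max(resid_sd / np.sqrt(2), 1e-3)), spec)


def _kmeans_start(data: PreparedData, spec: GMMSpec, rng) -> np.ndarray | None:
    """Start from k-means on per-patient OLS (intercept, slope) summaries."""
    from sklearn.cluster import KMeans

    G = spec.n_classes
    feats = np.zeros((len(data.n_i), 2))
    for i in range(len(data.n_i)):
        m = data.mask[i].astype(bool)
        t = data.Z[i, m, -1] if spec.q == 2 else data.X[i, m, 1]
        yv = data.y[i, m]
        if m.sum() >= 2 and np.ptp(t) > 0:
            A = np.column_stack([np.ones(m.sum()), t])
            c, *_ = np.linalg.lstsq(A, yv, rcond=None)
            feats[i] = c
        else:
            feats[i] = (yv.mean(), 0.0)
    km = KMeans(n_clusters=G, n_init=3,
                random_state=int(rng.integers(2 ** 31))).fit(feats)
    lab = km.labels_
    if len(np.unique(lab)) < G:
        return None
    d = spec.time_degree
    beta = np.zeros((G, d + 1))
    for g in range(G):
        m = (data.mask.astype(bool)) & (lab == g)[:, None]
        Xg, yg = data.X[m], data.y[m]
        ridge = 1e-6 * np.eye(d + 1)
        beta[g] = np.linalg.solve(Xg.T @ Xg + ridge, Xg.T @ yg)
    pi = np.bincount(lab, minlength=G) / len(lab)
    theta = np.log(np.clip(pi[:-1], 1e-6, None) / max(pi[-1], 1e-6))
    yf = data.y[data.mask.astype(bool)]
    sd = max(float(np.std(yf)) / 2, 1e-2)
    L = np.diag([0.7 * sd, 0.1 * sd][: spec.q])
    gamma = np.zeros(len(spec.covariates))
    return _pack(theta, beta, gamma, L, np.log(sd), spec)


def fit_gmm(cohort: Cohort, spec: GMMSpec, n_starts: int = 30, seed: int = 0,
            tol: float = 1e-6, max_iter: int = 500) -> GMMFit:
    """Maximize the marginal likelihood from multiple starts.

    Starts: a k-means-on-summaries start plus perturbations of a single-class
    fit.  The best converged solution is kept; if no start converges within
    ``max_iter`` the best solution found is returned with converged=False.
    Classes are re-ordered by descending class probability, so the reported
    class order is deterministic.
    """
    data = prepare_data(cohort, spec)
    N = len(data.patient_ids)
    if N < spec.n_params():
        raise ValueError(
            f"{N} patients < {spec.n_params()} parameters; model not estimable"
        )
    rng = np.random.default_rng(seed)

    def objective(x):
        ll, g = _loglik_and_grad(x, data, spec)
        return -ll, -g

    starts: list[tuple[int, np.ndarray]] = []
    base = _single_class_start(data, spec, rng)
    if spec.n_classes == 1:
        starts.append((0, base))
    else:
        km = _kmeans_start(data, spec, rng)
        if km is not None:
            starts.append((0, km))
        while len(starts) < max(n_starts, 1):
            pert = base + rng.normal(0.0, 0.25, size=base.size) \
                * np.maximum(np.abs(base), 0.2)
            starts.append((len(starts), pert))
        starts = starts[:max(n_starts, 1)]

    best = None
    best_start = -1
    n_iter_best = 0
    for sidx, x0 in starts:
        try:
            res = minimize(
                objective, x0, jac=True, method="L-BFGS-B",
                options={"maxiter": max_iter, "ftol": tol * 1e-2,
                         "gtol": 1e-4},
            )
        except (np.linalg.LinAlgError, FloatingPointError):
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or -res.fun > -best.fun:
            best, best_start, n_iter_best = res, sidx, int(res.nit)
    if best is None:
        raise FloatingPointError("likelihood non-finite at every start")

    ll = -float(best.fun)
    params = _internal_to_raw(best.x, data.time_scale, spec)
    params = _canonicalize(params)

    post = posterior_probs(params, cohort, spec)
    modal = pd.Series(
        np.argmax(post.to_numpy(), axis=1) + 1, index=post.index,
        name="modal_class",
    )
    G = spec.n_classes
    k = spec.n_params()
    ent = entropy(post.to_numpy()) if G >= 2 else None
    fit = GMMFit(
        spec=spec, params=params, loglik=ll, n_params=k,
        bic=bic(ll, k, N), entropy=ent,
        posterior=post, modal_class=modal,
        mean_posterior_by_class=mean_posterior_by_class(
            post.to_numpy(), modal.to_numpy()),
        convergence={
            "converged": bool(best.success)
            or float(np.abs(best.jac).max()) < 1e-3,
            "iterations": n_iter_best,
            "n_starts": len(starts),
            "best_start_seed": int(best_start),
            "max_abs_grad": float(np.abs(best.jac).max()),
        },
        n_patients=N, n_dropped=data.n_dropped, max_time=data.max_time,
    )
    return fit


def _canonicalize(params: GMMParams) -> GMMParams:
    """Sort classes by descending class probability (resolves label switching)."""
    pi = params.class_probs
    order = np.argsort(-pi, kind="stable")
    pi_s = pi[order]
    theta = np.log(pi_s[:-1] / pi_s[-1]) if len(pi) > 1 else np.zeros(0)
    return GMMParams(
        theta=theta, beta=params.beta[order], gamma=params.gamma,
        chol_D=params.chol_D, log_sigma=params.log_sigma,
    )


# ---------------------------------------------------------------------------
# predicted trajectories


def _numeric_hessian(x, data, spec, eps=1e-5):
    p = len(x)
    H = np.zeros((p, p))
    for j in range(p):
        xp = x.copy(); xp[j] += eps
        xm = x.copy(); xm[j] -= eps
        _, gp = _loglik_and_grad(xp, data, spec)
        _, gm = _loglik_and_grad(xm, data, spec)
        H[:, j] = (gp - gm) / (2 * eps)
    return 0.5 * (H + H.T)


def predict_trajectory(fit: GMMFit, g: int, time_grid, cohort: Cohort,
                       centre: float = 0.0, ci: str = "bootstrap",
                       n_boot: int = 500, seed: int = 0,
                       level: float = 0.95) -> pd.DataFrame:
    """Predicted median outcome curve for class ``g`` (1-based) with a CI.

    The class mean on the transformed scale is back-transformed; under a
    monotone transform this is the median on the original scale.  The CI is a
    parametric bootstrap from the asymptotic normal of the parameters
    (``ci='bootstrap'``) or a delta-method interval (``ci='delta'``).
    A warning flag marks grid points beyond the observed follow-up.
    """
    t = np.asarray(time_grid, float)
    spec = fit.spec
    d = spec.time_degree
    Xg = np.column_stack([t ** k for k in range(d + 1)])

    def curve(params: GMMParams):
        eta = Xg @ params.beta[g - 1]
        if params.gamma.size:
            eta = eta + params.gamma[0] * centre
        return inverse_transform(np.clip(eta, 0.0, None)
                                 if spec.transform == "sqrt" else eta,
                                 spec.transform)

    med = curve(fit.params)
    data = prepare_data(cohort, spec)
    x_hat = _raw_to_internal(fit.params, data.time_scale, spec)
    H = _numeric_hessian(x_hat, data, spec)
    cov = np.linalg.pinv(-H)
    # guard: project to PSD
    evals, evecs = np.linalg.eigh(cov)
    cov = (evecs * np.clip(evals, 0.0, None)) @ evecs.T

    alpha = 1.0 - level
    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(x_hat, cov, size=n_boot,
                                        method="svd")
        curves = np.stack([
            curve(_internal_to_raw(xb, data.time_scale, spec)) for xb in draws
        ])
        lo = np.quantile(curves, alpha / 2, axis=0)
        hi = np.quantile(curves, 1 - alpha / 2, axis=0)
    elif ci == "delta":
        from scipy.stats import norm
        eps = 1e-6
        Jac = np.zeros((len(t), len(x_hat)))
        for j in range(len(x_hat)):
            xp = x_hat.copy(); xp[j] += eps
            xm = x_hat.copy(); xm[j] -= eps
            Jac[:, j] = (curve(_internal_to_raw(xp, data.time_scale, spec))
                         - curve(_internal_to_raw(xm, data.time_scale, spec))
                         ) / (2 * eps)
        se = np.sqrt(np.clip(np.einsum("tp,pq,tq->t", Jac, cov, Jac), 0, None))
        z = norm.ppf(1 - alpha / 2)
        lo, hi = med - z * se, med + z * se
    else:
        raise ValueError(f"unknown ci method {ci!r}")

    return pd.DataFrame({
        "t": t, "median": med, "lower": lo, "upper": hi,
        "extrapolated": t > fit.max_time,
    })
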