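"""Posterior-probability-weighted L1 logistic regression.

Identifies baseline predictors of severe-trajectory class membership.  Class
assignment is uncertain, so each patient contributes two fractional rows —
(y=1, weight p_severe) and (y=0, weight 1-p_severe) — the probabilistic
completion of the latent label; one-hot posteriors reduce it to ordinary
modal-class classification.

The weighted penalized objective

    min  -(1/W) SUM_i w_i [ y_i log p_i + (1-y_i) log(1-p_i) ]  +  lambda ||beta||_1

(intercept unpenalized, predictors standardized by weighted mean/SD) is
solved by cyclic coordinate descent on the IRLS quadratic approximation with
warm starts along a descending lambda grid; KKT conditions are checked at
every solution.  Lambda is chosen by patient-level 10-fold cross-validation
(loss: 1-AUC, deviance or misclassification), coefficients are re-fitted with
pairwise interactions of the retained predictors, and results are pooled
across imputed datasets by majority retention and coefficient averaging.
No standard errors are produced: they are unreliable for penalized fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .gmm import GMMFit

PREDICTOR_COLUMNS = [
    "pga0", "cmas0", "das0", "age_at_diagnosis", "time_to_first_visit",
    "arthritis", "abnormal_respiration", "calcinosis", "lipodystrophy",
    "ulceration",
]
DIAGNOSIS_REFERENCE = "definite_jdm"

_PMIN = 1e-5


@dataclass
class LassoTask:
    X: np.ndarray                  # (n_rows, p) raw-scale predictors
    y: np.ndarray
    w: np.ndarray                  # row weights >= 0
    feature_names: list[str]
    patient_ids: np.ndarray        # per row
    modal_severe: np.ndarray       # per row, for stratified folds
    dropped_constant: list[str] = field(default_factory=list)


@dataclass
class LassoResult:
    lambda_path: np.ndarray
    cv_curve: np.ndarray | None
    selected_lambda: float | None
    intercept: float
    coef: pd.Series                # original predictor scale
    odds_ratios: pd.Series
    loss: str | None = None


@dataclass
class PooledLasso:
    retained: list[str]
    pooled_coef: pd.Series
    pooled_or: pd.Series
    intercept: float
    per_imputation: list[LassoResult]
    retention_counts: pd.Series


# ---------------------------------------------------------------------------
# task construction


def build_design(baseline: pd.DataFrame) -> pd.DataFrame:
    """Predictor matrix: diagnosis dummies (reference = definite JDM) plus the
    first-visit clinical features.  Autoantibody status is deliberately not a
    predictor (too incomplete)."""
    df = baseline.set_index("patient_id")[PREDICTOR_COLUMNS].astype(float)
    dummies = pd.get_dummies(baseline.set_index("patient_id")["diagnosis"],
                             prefix="dx", dtype=float)
    ref = f"dx_{DIAGNOSIS_REFERENCE}"
    if ref in dummies.columns:
        dummies = dummies.drop(columns=[ref])
    return pd.concat([dummies, df], axis=1)


def build_weighted_response(fit: GMMFit) -> pd.DataFrame:
    """Two fractional rows per patient from a 2-class fit (class 2 = target)."""
    if fit.spec.n_classes != 2:
        raise ValueError("the predictive stage is defined for a 2-class model")
    p2 = fit.posterior["class_2"]
    rows = []
    for pid, p in p2.items():
        for y, w in ((1.0, float(p)), (0.0, float(1.0 - p))):
            if w >= 1e-12:
                rows.append((pid, y, w))
    return pd.DataFrame(rows, columns=["patient_id", "y", "w"])


def make_task(design: pd.DataFrame, weighted: pd.DataFrame) -> LassoTask:
    """Join the per-patient design onto the fractional response rows; rows of
    patients with a missing predictor (pre-imputation use) are dropped."""
    merged = weighted.merge(design, left_on="patient_id", right_index=True,
                            how="inner").dropna()
    names = [c for c in merged.columns if c not in ("patient_id", "y", "w")]
    X = merged[names].to_numpy(float)
    # constant columns carry no information and break standardization
    keep, dropped = [], []
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) > 0:
            keep.append(j)
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(f"dropping constant predictors: {dropped}")
    p_sev = merged.loc[merged["y"] == 1].set_index("patient_id")["w"]
    modal = merged["patient_id"].map((p_sev > 0.5).astype(int)).fillna(0)
    return LassoTask(
        X=X[:, keep], y=merged["y"].to_numpy(float),
        w=merged["w"].to_numpy(float),
        feature_names=[names[j] for j in keep],
        patient_ids=merged["patient_id"].to_numpy(),
        modal_severe=modal.to_numpy(int),
        dropped_constant=dropped,
    )


# ---------------------------------------------------------------------------
# core solver


def _standardize(X, w):
    wn = w / w.sum()
    mu = wn @ X
    sd = np.sqrt(wn @ (X - mu) ** 2)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def lambda_max(X_std, y, w) -> float:
    """Smallest penalty at which every slope is exactly zero (KKT threshold)."""
    W = w.sum()
    ybar = (w @ y) / W
    return float(np.abs((w * (y - ybar)) @ X_std).max() / W)


def default_lambda_grid(lmax: float, n: int = 100, ratio: float = 1e-3):
    return np.geomspace(lmax, lmax * ratio, n)


from numba import njit


@njit(cache=False)
def _cd_quadratic(Xs, v, z, b0, beta, lam, max_sweeps=1000, tol=1e-9):
    """Cyclic coordinate descent for the penalized weighted least squares
    subproblem; v are normalized working weights, z the working response."""
    n, p = Xs.shape
    vsum = v.sum()
    denom = np.zeros(p)
    for j in range(p):
        for i in range(n):
            denom[j] += v[i] * Xs[i, j] * Xs[i, j]
    eta = b0 + Xs @ beta
    for _ in range(max_sweeps):
        delta = 0.0
        acc = 0.0
        for i in range(n):
            acc += v[i] * (z[i] - eta[i])
        step = acc / vsum
        for i in range(n):
            eta[i] += step
        delta = max(delta, abs(step))
        b0 = b0 + step
        for j in range(p):
            if denom[j] <= 0.0:
                continue
            rho = 0.0
            for i in range(n):
                rho += v[i] * Xs[i, j] * (z[i] - eta[i] + Xs[i, j] * beta[j])
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / denom[j]
            if new != beta[j]:
                diff = new - beta[j]
                for i in range(n):
                    eta[i] += Xs[i, j] * diff
                delta = max(delta, abs(diff))
                beta[j] = new
        if delta < tol:
            break
    return b0, beta, eta


def _fit_std(Xs, y, w, lam, b0=0.0, beta=None, max_irls=100, tol=1e-8):
    """Penalized weighted logistic fit at one lambda, standardized scale."""
    n, p = Xs.shape
    W = w.sum()
    wn = w / W
    beta = np.zeros(p) if beta is None else beta.copy()
    for _ in range(max_irls):
        eta = b0 + Xs @ beta
        pr = np.clip(expit(eta), _PMIN, 1 - _PMIN)
        v = wn * pr * (1 - pr)
        z = eta + (y - pr) / (pr * (1 - pr))
        b0_new, beta_new, _ = _cd_quadratic(Xs, v, z, b0, beta.copy(), lam)
        step = max(abs(b0_new - b0), np.abs(beta_new - beta).max(initial=0.0))
        b0, beta = b0_new, beta_new
        if step < tol:
            return b0, beta, True
    return b0, beta, False


def objective(Xs, y, w, lam, b0, beta) -> float:
    W = w.sum()
    pr = np.clip(expit(b0 + Xs @ beta), _PMIN, 1 - _PMIN)
    nll = -(w @ (y * np.log(pr) + (1 - y) * np.log(1 - pr))) / W
    return float(nll + lam * np.abs(beta).sum())


def kkt_violation(Xs, y, w, lam, b0, beta) -> float:
    """Largest violation of the subgradient optimality conditions."""
    W = w.sum()
    pr = np.clip(expit(b0 + Xs @ beta), _PMIN, 1 - _PMIN)
    g = -((w * (y - pr)) @ Xs) / W
    viol = np.where(beta != 0, np.abs(g + lam * np.sign(beta)),
                    np.clip(np.abs(g) - lam, 0.0, None))
    return float(max(viol.max(initial=0.0), abs((w @ (y - pr)) / W)))


def lasso_path(task: LassoTask, lambda_grid=None, check_kkt: bool = True):
    """Solve along a descending lambda grid with warm starts.

    Returns (lambda_grid, intercepts, coefs) with coefficients reported on
    the original predictor scale.
    """
    if len(np.unique(task.y[task.w > 0])) < 2:
        raise ValueError("need both outcome values with positive weight")
    Xs, mu, sd = _standardize(task.X, task.w)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(lambda_max(Xs, task.y, task.w))
    lambda_grid = np.asarray(lambda_grid, float)
    p = Xs.shape[1]
    B = np.zeros((len(lambda_grid), p))
    b0s = np.zeros(len(lambda_grid))
    b0, beta = float(np.log(
        np.clip((task.w @ task.y) / task.w.sum(), _PMIN, 1 - _PMIN)
        / np.clip(1 - (task.w @ task.y) / task.w.sum(), _PMIN, 1 - _PMIN))), \
        np.zeros(p)
    for i, lam in enumerate(lambda_grid):
        b0, beta, ok = _fit_std(Xs, task.y, task.w, lam, b0, beta)
        if not ok:
            raise RuntimeError(f"coordinate descent failed at lambda={lam:g}")
        if check_kkt and kkt_violation(Xs, task.y, task.w, lam, b0, beta) \
                > lam + 1e-6:
            raise RuntimeError(f"KKT violated at lambda={lam:g}")
        B[i] = beta
        b0s[i] = b0
    coefs = B / sd[None, :]
    intercepts = b0s - coefs @ mu
    return lambda_grid, intercepts, coefs


# ---------------------------------------------------------------------------
# cross-validation


def _weighted_auc(y, score, w) -> float:
    """Weighted probability that a positive outranks a negative (ties 1/2)."""
    order = np.argsort(score, kind="mergesort")
    y, s, w = y[order], score[order], w[order]
    wneg = np.where(y == 0, w, 0.0)
    wpos = np.where(y == 1, w, 0.0)
    cneg = np.concatenate([[0.0], np.cumsum(wneg)])
    # tie groups share the average "negatives below" count
    _, start, inv = np.unique(s, return_index=True, return_inverse=True)
    group_w = np.zeros(len(start))
    np.add.at(group_w, inv, wneg)
    below = cneg[start][inv]          # negative weight strictly below the tie
    num = float(np.sum(wpos * (below + 0.5 * group_w[inv])))
    den = float(wpos.sum() * wneg.sum())
    if den == 0:
        raise ValueError("AUC undefined: one outcome class has zero weight")
    return num / den


def _fold_losses(y, w, eta, loss):
    pr = np.clip(expit(eta), _PMIN, 1 - _PMIN)
    if loss == "auc":
        return 1.0 - _weighted_auc(y, eta, w)
    if loss == "deviance":
        return float(-2.0 * (w @ (y * np.log(pr) + (1 - y) * np.log(1 - pr)))
                     / w.sum())
    if loss == "misclassification":
        return float((w @ (y != (pr > 0.5))) / w.sum())
    raise ValueError(f"unknown loss {loss!r}")


def _patient_folds(task: LassoTask, n_folds, rng):
    """Partition patients into stratified folds; both fractional rows of a
    patient share a fold."""
    pids, idx = np.unique(task.patient_ids, return_index=True)
    strata = task.modal_severe[idx]
    fold_of = {}
    for s in np.unique(strata):
        members = pids[strata == s]
        members = members[rng.permutation(len(members))]
        for i, pid in enumerate(members):
            fold_of[pid] = i % n_folds
    return np.array([fold_of[p] for p in task.patient_ids])


def cv_select_lambda(task: LassoTask, n_folds: int = 10, loss: str = "auc",
                     seed: int = 0, lambda_grid=None):
    """Out-of-fold loss curve over lambda; minimizer wins, ties to sparser.

    Folds are stratified by modal class at the patient level.  A fold ending
    up with a single outcome class triggers one re-randomization, then an
    error.
    """
    if n_folds < 2:
        raise ValueError("need n_folds >= 2")
    Xs, _, _ = _standardize(task.X, task.w)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(lambda_max(Xs, task.y, task.w))
    rng = np.random.default_rng(seed)
    for attempt in range(2):
        folds = _patient_folds(task, n_folds, rng)
        ok = all(
            len(np.unique(task.y[(folds != f) & (task.w > 0)])) == 2
            and len(np.unique(task.y[(folds == f) & (task.w > 0)])) == 2
            for f in range(n_folds)
        )
        if ok:
            break
    else:
        raise RuntimeError("a fold contains a single outcome class")

    losses = np.zeros((n_folds, len(lambda_grid)))
    for f in range(n_folds):
        tr = folds != f
        te = ~tr
        sub = LassoTask(
            X=task.X[tr], y=task.y[tr], w=task.w[tr],
            feature_names=task.feature_names,
            patient_ids=task.patient_ids[tr],
            modal_severe=task.modal_severe[tr],
        )
        grid, b0s, coefs = lasso_path(sub, lambda_grid, check_kkt=False)
        eta_te = b0s[:, None] + coefs @ task.X[te].T
        for i in range(len(grid)):
            losses[f, i] = _fold_losses(task.y[te], task.w[te], eta_te[i], loss)
    curve = losses.mean(0)
    best = curve.min()
    # ties -> larger lambda (grid is descending, so the first index)
    sel = int(np.nonzero(curve <= best + 1e-12)[0][0])
    return float(lambda_grid[sel]), curve, np.asarray(lambda_grid)


def fit_lasso_cv(task: LassoTask, n_folds: int = 10, loss: str = "auc",
                 seed: int = 0, lambda_grid=None) -> LassoResult:
    """CV-selected lambda, then the full-data fit at that lambda."""
    lam, curve, grid = cv_select_lambda(task, n_folds, loss, seed, lambda_grid)
    _, b0s, coefs = lasso_path(task, grid)
    i = int(np.argmin(np.abs(grid - lam)))
    coef = pd.Series(coefs[i], index=task.feature_names)
    return LassoResult(
        lambda_path=np.asarray(grid), cv_curve=curve, selected_lambda=lam,
        intercept=float(b0s[i]), coef=coef, odds_ratios=np.exp(coef),
        loss=loss,
    )


# ---------------------------------------------------------------------------
# interactions, pooling, prediction


def add_interactions(task: LassoTask, retained: list[str]) -> LassoTask:
    """Append all pairwise products of the retained predictors."""
    if len(retained) < 2:
        raise ValueError("need >= 2 retained predictors for interactions")
    idx = {n: task.feature_names.index(n) for n in retained}
    cols, names = [], []
    for a in range(len(retained)):
        for b in range(a + 1, len(retained)):
            na, nb = retained[a], retained[b]
            cols.append(task.X[:, idx[na]] * task.X[:, idx[nb]])
            names.append(f"{na}:{nb}")
    return LassoTask(
        X=np.column_stack([task.X] + cols), y=task.y, w=task.w,
        feature_names=task.feature_names + names,
        patient_ids=task.patient_ids, modal_severe=task.modal_severe,
        dropped_constant=task.dropped_constant,
    )


def fit_with_interactions(task: LassoTask, retained: list[str],
                          n_folds: int = 10, loss: str = "auc",
                          seed: int = 0) -> LassoResult:
    """Re-run CV selection and fitting with pairwise interaction columns."""
    return fit_lasso_cv(add_interactions(task, retained), n_folds, loss, seed)


def pool_over_imputations(results: list[LassoResult]) -> PooledLasso:
    """Majority retention (> m/2 non-zero) with coefficients averaged over the
    imputations where they are non-zero; no standard errors."""
    if len(results) < 2:
        raise ValueError("need >= 2 imputation results to pool")
    names = list(results[0].coef.index)
    for r in results[1:]:
        if list(r.coef.index) != names:
            raise ValueError("inconsistent predictor sets across imputations")
    m = len(results)
    C = np.stack([r.coef.to_numpy() for r in results])
    nz = C != 0
    counts = nz.sum(0)
    retained_mask = counts > m / 2
    with np.errstate(invalid="ignore"):
        mean_nonzero = np.nansum(np.where(nz, C, np.nan), axis=0) \
            / np.maximum(counts, 1)
    pooled = np.where(retained_mask, mean_nonzero, 0.0)
    coef = pd.Series(pooled, index=names)
    retained = [n for n, r in zip(names, retained_mask) if r]
    return PooledLasso(
        retained=retained,
        pooled_coef=coef[retained],
        pooled_or=np.exp(coef[retained]),
        intercept=float(np.mean([r.intercept for r in results])),
        per_imputation=results,
        retention_counts=pd.Series(counts, index=names),
    )


def predicted_probability_grid(pooled: PooledLasso, combinations: pd.DataFrame,
                               design: pd.DataFrame,
                               weights: pd.Series | None = None) -> pd.DataFrame:
    """Predicted severe-class probability for each covariate combination.

    Covariates not in ``combinations`` are held at their (weighted) medians
    computed from ``design``.
    """
    unknown = set(combinations.columns) - set(design.columns)
    if unknown:
        raise KeyError(f"unknown covariates: {sorted(unknown)}")
    if weights is None:
        med = design.median()
    else:
        w = weights.reindex(design.index).to_numpy(float)
        med = design.apply(
            lambda col: _weighted_median(col.to_numpy(float), w))
    out = combinations.copy().reset_index(drop=True)
    eta = np.full(len(out), pooled.intercept)
    for name, c in pooled.pooled_coef.items():
        if ":" in name:
            a, b = name.split(":", 1)
            xa = out[a].to_numpy(float) if a in out else np.full(len(out), med[a])
            xb = out[b].to_numpy(float) if b in out else np.full(len(out), med[b])
            eta += c * xa * xb
        else:
            x = out[name].to_numpy(float) if name in out \
                else np.full(len(out), med[name])
            eta += c * x
    out["probability"] = expit(eta)
    return out


def _weighted_median(x, w):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(x[order][np.searchsorted(cw, 0.5 * cw[-1])])
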