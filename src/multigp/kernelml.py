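"""Kernel machine-learning predictors and population-specific tuning.

Three predictors take raw 0/1/2 dosage rows as features (no
standardization):

* **KRR** — kernel ridge regression by its closed form
  alpha = (K + lambda I)^-1 y_c, prediction k' alpha, no intercept.
* **SVR** — epsilon-insensitive support vector regression (dual quadratic
  program with box constraints, solved by libsvm through scikit-learn,
  which is also how the predictions behind the tuned hyperparameter tables
  were produced in practice).
* **AdaBoost.R2** — Drucker-style boosting with KRR base learners, linear
  max-normalized loss, and the log-weighted MEAN combination
  f(x) = sum_t log(1/eps_t) f_t(x) / sum_t log(1/eps_t). Weighted fitting
  is realized by bootstrap resampling under the current sample
  distribution, since the KRR closed form has no native sample weights.

Hyperparameters are tuned population-specifically: each target population's
reference set is split into five groups; models are trained on the joint
training set (plus whole auxiliary populations in the multi-population
scenario) and scored by the Pearson correlation on each population's
held-out group separately, so different populations may choose different
hyperparameter combinations from the same grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from sklearn.metrics.pairwise import linear_kernel, rbf_kernel
from sklearn.svm import SVR as _SklearnSVR

logger = logging.getLogger("multigp.kernelml")

__all__ = [
    "KernelModel",
    "BoostEnsemble",
    "TuningResult",
    "rbf_gram",
    "fit_krr",
    "fit_svr",
    "fit_adaboost_r2",
    "tune_population_specific",
    "default_grid",
]


def rbf_gram(X_rows: np.ndarray, X_cols: np.ndarray, gamma: float) -> np.ndarray:
    """K_ij = exp(-gamma ||x_i - x_j||^2)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return rbf_kernel(np.asarray(X_rows, float), np.asarray(X_cols, float), gamma=gamma)


def _gram(kernel: str, A: np.ndarray, B: np.ndarray, gamma: float | None) -> np.ndarray:
    if kernel == "rbf":
        return rbf_gram(A, B, gamma)
    if kernel == "linear":
        return linear_kernel(A, B)
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclass
class KernelModel:
    kind: str                          # "krr" | "svr"
    kernel: str                        # "rbf" | "linear"
    gamma: float | None
    C: float | None = None
    epsilon: float | None = None
    lam: float | None = None
    alpha: np.ndarray | None = None    # KRR dual weights or SVR (a_hat - a)
    b: float = 0.0
    support: np.ndarray | None = None  # training rows the duals attach to
    _svr: object = field(default=None, repr=False)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, float)
        if self.kind == "svr":
            return self._svr.predict(X_new)
        k = _gram(self.kernel, X_new, self.support, self.gamma)
        return k @ self.alpha


def fit_krr(y_c: np.ndarray, X: np.ndarray, kernel: str = "rbf",
            lam: float = 1.0, gamma: float | None = None) -> KernelModel:
    """Closed-form kernel ridge: alpha = (K + lambda I)^-1 y_c, no intercept."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, float)
    y = np.asarray(y_c, float)
    K = _gram(kernel, X, X, gamma)
    A = K + lam * np.eye(len(y))
    try:
        alpha = sla.solve(A, y, assume_a="pos")
    except np.linalg.LinAlgError:
        raise ValueError("K + lambda I is singular (duplicate rows with lambda = 0?); use lambda > 0")
    return KernelModel(kind="krr", kernel=kernel, gamma=gamma, lam=lam,
                       alpha=alpha, support=X)


def fit_svr(y_c: np.ndarray, X: np.ndarray, kernel: str = "rbf", C: float = 1.0,
            gamma: float | None = None, epsilon: float = 0.1) -> KernelModel:
    """Epsilon-insensitive SVR; f(x) = sum_i (a_hat_i - a_i) K(x, x_i) + b.

    The dual box constraints keep every |a_hat_i - a_i| <= C; the intercept
    comes from the KKT conditions on unbounded support vectors. epsilon is
    not reported alongside the tuned C/gamma tables, so it defaults to 0.1
    on the y_c scale.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    X = np.asarray(X, float)
    m = _SklearnSVR(kernel=kernel, C=C, epsilon=epsilon, tol=1e-6,
                    gamma=gamma if kernel == "rbf" else "scale")
    m.fit(X, np.asarray(y_c, float))
    alpha = np.zeros(len(X))
    alpha[m.support_] = m.dual_coef_[0]
    return KernelModel(kind="svr", kernel=kernel, gamma=gamma, C=C, epsilon=epsilon,
                       alpha=alpha, b=float(m.intercept_[0]), support=X, _svr=m)


# ---------------------------------------------------------------------------
# AdaBoost.R2 with KRR base learners
# ---------------------------------------------------------------------------

@dataclass
class BoostEnsemble:
    learners: list[KernelModel]
    eps_t: list[float]                 # error rates eps_t = Lbar/(1 - Lbar)
    avg_loss: list[float]              # Lbar_t
    weights_D: np.ndarray              # final sample distribution
    single_learner_warning: bool = False

    @property
    def log_weights(self) -> np.ndarray:
        return np.log(1.0 / np.asarray(self.eps_t))

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        w = self.log_weights
        preds = np.array([f.predict(X_new) for f in self.learners])
        return (w @ preds) / w.sum()


def fit_adaboost_r2(
    y_c: np.ndarray,
    X: np.ndarray,
    base_params: dict,
    M: int = 50,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> BoostEnsemble:
    """AdaBoost.R2 with the linear max-normalized loss.

    Per iteration: resample n cases with the current distribution D_t, fit
    KRR, compute L_t(i) = |y_i - f_t(x_i)| / max_j |y_j - f_t(x_j)|, the
    average loss Lbar_t = sum_i L_t(i) D_t(i), the error rate
    eps_t = Lbar_t / (1 - Lbar_t), then reweight
    D_{t+1}(i) = D_t(i) eps_t^{1 - L_t(i)} / Z_t. Boosting stops early once
    Lbar_t >= 0.5 (such a learner is discarded, unless it is the first, in
    which case it is kept alone with a warning) or once a learner fits
    perfectly (kept, with its weight capped through an error-rate floor).
    """
    if M < 1:
        raise ValueError("need at least one base learner")
    rng = np.random.default_rng(seed) if rng is None else rng
    X = np.asarray(X, float)
    y = np.asarray(y_c, float)
    n = len(y)
    D = np.full(n, 1.0 / n)

    learners: list[KernelModel] = []
    eps_list: list[float] = []
    loss_list: list[float] = []
    warned = False
    for t in range(M):
        take = rng.choice(n, size=n, replace=True, p=D)
        f = fit_krr(y[take], X[take], **base_params)
        err = np.abs(y - f.predict(X))
        max_err = err.max()
        if max_err <= 0:
            # perfect fit: keep with capped weight, nothing left to boost
            learners.append(f)
            loss_list.append(0.0)
            eps_list.append(1e-10)
            break
        L = err / max_err
        Lbar = float(L @ D)
        if Lbar >= 0.5:
            if not learners:
                logger.warning("first learner has average loss %.3f >= 0.5; "
                               "ensemble collapses to that single learner", Lbar)
                learners.append(f)
                loss_list.append(Lbar)
                eps_list.append(max(Lbar / (1.0 - Lbar), 1.0 - 1e-10)
                                if Lbar < 1.0 else 1.0 - 1e-10)
                warned = True
            break
        eps = max(Lbar / (1.0 - Lbar), 1e-10)
        learners.append(f)
        loss_list.append(Lbar)
        eps_list.append(eps)
        D = D * eps ** (1.0 - L)
        D = D / D.sum()
    return BoostEnsemble(learners=learners, eps_t=eps_list, avg_loss=loss_list,
                         weights_D=D, single_learner_warning=warned)


# ---------------------------------------------------------------------------
# population-specific hyperparameter tuning
# ---------------------------------------------------------------------------

@dataclass
class TuningResult:
    per_population: dict[str, dict]    # pop -> {"params": ..., "score": ...}
    grid: list[dict]
    scores: pd.DataFrame               # rows = grid combos, columns = populations
    folds_seed: int


def default_grid(method: str) -> list[dict]:
    """Grids spanning the magnitudes of the tuned-hyperparameter tables."""
    gammas = [5e-5, 1e-4, 2e-4]
    lams = [1e-4, 1e-3, 1e-2, 0.05, 0.1, 0.5, 1, 2, 2.5, 3, 4, 5]
    if method == "SVR":
        return [{"kernel": "rbf", "C": c, "gamma": g}
                for c in (1, 2, 3, 4, 5) for g in gammas]
    if method == "KRR":
        return [{"kernel": "rbf", "lam": l, "gamma": g} for l in lams for g in gammas]
    if method == "AdaBoost.R2":
        return [{"kernel": "rbf", "lam": l, "gamma": g} for l in lams for g in gammas]
    raise ValueError(f"no grid for method {method!r}")


def _fit_method(method: str, params: dict, y: np.ndarray, X: np.ndarray, seed: int):
    if method == "SVR":
        return fit_svr(y, X, **params)
    if method == "KRR":
        return fit_krr(y, X, **params)
    if method == "AdaBoost.R2":
        return fit_adaboost_r2(y, X, base_params=params, seed=seed)
    raise ValueError(f"unknown machine-learning method {method!r}")


def tune_population_specific(
    y_c: pd.Series,
    X: np.ndarray,
    individuals: list[str],
    population: pd.Series,
    method: str,
    grid: list[dict],
    target_populations: list[str],
    auxiliary_populations: list[str] = (),
    folds: int = 5,
    seed: int = 0,
) -> TuningResult:
    """Per-population grid search over joint-training rotations.

    Each target population's individuals (those with y_c) are split into
    ``folds`` groups; per rotation the joint training set is the union of
    all target populations' training groups plus every auxiliary
    population's full reference. Scores are Pearson correlations on each
    target population's held-out group, averaged over rotations; the argmax
    (ties broken by grid order) is chosen per population. Constant
    predictions in a held-out group score 0 for that rotation (logged).
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rng = np.random.default_rng(seed)
    row = {s: i for i, s in enumerate(individuals)}
    ref_ids = [s for s in y_c.index]
    pop_of = {s: population.loc[s] for s in ref_ids}

    fold_of: dict[str, np.ndarray] = {}
    members: dict[str, list[str]] = {}
    for pop in target_populations:
        ids = [s for s in ref_ids if pop_of[s] == pop]
        if len(ids) < 5 * folds:
            raise ValueError(f"population {pop} has {len(ids)} reference animals; "
                             f"needs >= {5 * folds} for tuning")
        members[pop] = ids
        lab = np.resize(np.arange(folds), len(ids))
        rng.shuffle(lab)
        fold_of[pop] = lab
    aux_ids = [s for s in ref_ids if pop_of[s] in set(auxiliary_populations)]

    scores = np.zeros((len(grid), len(target_populations)))
    for g, params in enumerate(grid):
        per_rot = np.zeros((folds, len(target_populations)))
        for f in range(folds):
            train, test_by_pop = list(aux_ids), {}
            for pop in target_populations:
                lab = fold_of[pop]
                ids = members[pop]
                train += [s for s, l in zip(ids, lab) if l != f]
                test_by_pop[pop] = [s for s, l in zip(ids, lab) if l == f]
            Xtr = X[[row[s] for s in train]]
            ytr = y_c.loc[train].to_numpy(dtype=float)
            model = _fit_method(method, params, ytr, Xtr, seed=seed + 7 * f)
            for pi, pop in enumerate(target_populations):
                ids = test_by_pop[pop]
                pred = model.predict(X[[row[s] for s in ids]])
                obs = y_c.loc[ids].to_numpy(dtype=float)
                if np.std(pred) == 0 or np.std(obs) == 0:
                    logger.info("constant predictions for %s in rotation %d; score 0", pop, f)
                    per_rot[f, pi] = 0.0
                else:
                    per_rot[f, pi] = np.corrcoef(obs, pred)[0, 1]
        scores[g] = per_rot.mean(axis=0)

    chosen = {}
    for pi, pop in enumerate(target_populations):
        best = int(np.argmax(scores[:, pi]))    # argmax takes the first maximum
        chosen[pop] = {"params": grid[best], "score": float(scores[best, pi])}
    return TuningResult(
        per_population=chosen,
        grid=list(grid),
        scores=pd.DataFrame(scores, columns=target_populations),
        folds_seed=seed,
    )
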