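"""Single- and multi-trait GBLUP with genomic REML and matrix bending.

ST-GBLUP fits y_c = 1 mu + a + e with a ~ N(0, G sigma2_a) on the reference
individuals and predicts validation individuals through the off-diagonal
blocks of the joint G. MT-GBLUP treats the same trait recorded in different
populations as distinct correlated traits ("populations as traits"):
a ~ N(0, M ⊗ G) with M the between-population genetic (co)variance matrix.
Because no individual is recorded in two populations, residual covariances
between population-traits are not estimable and are fixed at zero.

For more than two populations M is assembled from bivariate fits of every
population pair and bent to positive definiteness by an unweighted
eigenvalue-floor procedure (small.positive = 1e-4, max.iter = 10000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .genostats import GRM

logger = logging.getLogger("multigp.gblup")

__all__ = [
    "MultiTraitVC",
    "GblupFit",
    "vstruct_reml",
    "fit_st_gblup",
    "fit_mt_gblup",
    "estimate_pairwise_vc",
    "assemble_and_bend",
    "bend_matrix",
    "heritability",
    "genetic_correlation",
]

G_STABILIZER = 1e-6


@dataclass
class MultiTraitVC:
    M: np.ndarray                  # genetic (co)variance across population-traits
    R: np.ndarray                  # residual (co)variances (off-diagonals fixed 0)
    labels: list[str]

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        k = len(self.labels)
        if self.M.shape != (k, k) or self.R.shape != (k, k):
            raise ValueError("M and R must be k x k for k population-traits")
        if not (np.allclose(self.M, self.M.T) and np.allclose(self.R, self.R.T)):
            raise ValueError("M and R must be symmetric")
        if np.any(np.diag(self.M) < 0) or np.any(np.diag(self.R) < 0):
            raise ValueError("variances must be non-negative")

    def correlation(self, i: int, j: int) -> float:
        return genetic_correlation(self.M, i, j)


@dataclass
class GblupFit:
    mu: pd.Series                  # overall mean(s); one entry per population-trait
    a_hat: pd.Series               # predicted additive value per individual (own trait)
    vc: object                     # (sigma2_a, sigma2_e) tuple or MultiTraitVC
    model: str                     # "st" | "mt"

    def predict(self, ids: list[str], population: pd.Series | None = None) -> np.ndarray:
        """mu + a_hat for the requested individuals (their own population-trait)."""
        a = self.a_hat.loc[ids].to_numpy()
        if self.model == "st":
            return float(self.mu.iloc[0]) + a
        pops = population.loc[ids]
        return self.mu.loc[pops].to_numpy() + a


# ---------------------------------------------------------------------------
# generic REML for V(theta) = sum_i theta_i V_i
# ---------------------------------------------------------------------------

def vstruct_reml(
    y: np.ndarray,
    X: np.ndarray,
    V_list: list[np.ndarray],
    start: np.ndarray,
    positive: np.ndarray,
    max_iter: int = 100,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Average-information REML for a linear covariance structure.

    ``positive`` flags which components are variances (kept strictly
    positive); unflagged components (covariances) are unconstrained. When
    the AI step produces an inadmissible V (negative variance or indefinite
    covariance) the step is halved, down to a damped EM-like step.
    Returns (theta, -2 log restricted likelihood at the optimum).
    """
    n, p = X.shape
    theta = np.asarray(start, dtype=float).copy()
    floor = 1e-8 * float(np.var(y))

    def build(th):
        V = sum(t * Vi for t, Vi in zip(th, V_list))
        return V

    def m2ll_and_parts(th):
        V = build(th)
        cf = sla.cho_factor(V, lower=True, check_finite=False)
        Vinv_X = sla.cho_solve(cf, X, check_finite=False)
        XtViX = X.T @ Vinv_X
        cfx = sla.cho_factor(XtViX, lower=True, check_finite=False)
        Vinv_y = sla.cho_solve(cf, y, check_finite=False)
        beta = sla.cho_solve(cfx, X.T @ Vinv_y, check_finite=False)
        Py = Vinv_y - Vinv_X @ beta
        logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
        logdet_X = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        m2ll = logdet_V + logdet_X + float(y @ Py)
        return m2ll, cf, Vinv_X, cfx, Py

    prev = np.inf
    for it in range(max_iter):
        try:
            m2ll, cf, Vinv_X, cfx, Py = m2ll_and_parts(theta)
        except np.linalg.LinAlgError:
            raise RuntimeError(f"covariance structure not positive definite at iteration {it}, theta={theta}")

        k = len(V_list)
        ViPy = [Vi @ Py for Vi in V_list]
        # tr(P V_i) = tr(V^-1 V_i) - tr((X'V^-1X)^-1 X'V^-1 V_i V^-1 X)
        trPV = np.empty(k)
        for i, Vi in enumerate(V_list):
            VinvVi = sla.cho_solve(cf, Vi, check_finite=False)
            t1 = float(np.trace(VinvVi))
            Mx = Vinv_X.T @ Vi @ Vinv_X
            t2 = float(np.trace(sla.cho_solve(cfx, Mx, check_finite=False)))
            trPV[i] = t1 - t2
        score = -0.5 * (trPV - np.array([float(Py @ f) for f in ViPy]))

        # P f_i for the AI matrix
        PF = []
        for f in ViPy:
            Vinv_f = sla.cho_solve(cf, f, check_finite=False)
            beta_f = sla.cho_solve(cfx, X.T @ Vinv_f, check_finite=False)
            PF.append(Vinv_f - Vinv_X @ beta_f)
        AI = 0.5 * np.array([[float(ViPy[i] @ PF[j]) for j in range(k)] for i in range(k)])
        AI = 0.5 * (AI + AI.T)

        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = score * theta ** 2 / n      # damped EM-like direction

        new = None
        scale = 1.0
        for _ in range(12):
            cand = theta + scale * step
            bad = positive & (cand <= floor)
            if not bad.any():
                try:
                    sla.cho_factor(build(cand), lower=True, check_finite=False)
                    new = cand
                    break
                except np.linalg.LinAlgError:
                    pass
            scale *= 0.5
        if new is None:
            logger.info("AI step rejected at iteration %d; damped EM step", it)
            new = theta + (score * theta ** 2 / n)
            new[positive] = np.maximum(new[positive], floor)

        rel = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), floor))
        theta = new
        if abs(prev - m2ll) < tol_loglik or rel < tol_param:
            return theta, m2ll
        prev = m2ll
    raise RuntimeError(f"REML did not converge in {max_iter} iterations; theta={theta}")


# ---------------------------------------------------------------------------
# ST-GBLUP
# ---------------------------------------------------------------------------

def fit_st_gblup(
    y_c: pd.Series,
    grm: GRM,
    vc: tuple[float, float] | None = None,
    estimate_vc: bool = True,
) -> GblupFit:
    """Single-trait GBLUP: y_c = 1 mu + a + e, a ~ N(0, G sigma2_a).

    ``y_c`` is indexed by reference individual ids (a subset of the GRM).
    Variance components are estimated by AI-REML on the reference set unless
    supplied. Predictions cover every individual in the GRM, validation
    animals included, via the off-diagonal G blocks.
    """
    ref = list(y_c.index)
    if vc is None and estimate_vc and len(ref) < 30:
        raise ValueError("need >= 30 records to estimate variance components")
    ridx = grm.index(ref)
    Gr = grm.G[np.ix_(ridx, ridx)] + G_STABILIZER * np.eye(len(ridx))
    logger.debug("added %g diagonal stabilizer to G", G_STABILIZER)
    y = y_c.to_numpy(dtype=float)
    X = np.ones((len(ref), 1))
    if vc is None and np.var(y) == 0:
        # degenerate constant response: no genetic signal to estimate
        return GblupFit(mu=pd.Series([float(y[0])], index=["mu"]),
                        a_hat=pd.Series(0.0, index=grm.individuals),
                        vc=(0.0, 0.0), model="st")
    if vc is None:
        vy = float(np.var(y))
        theta, _ = vstruct_reml(
            y, X, [Gr, np.eye(len(ref))],
            start=np.array([0.3 * vy, 0.7 * vy]),
            positive=np.array([True, True]),
        )
        sigma2_a, sigma2_e = float(theta[0]), float(theta[1])
    else:
        sigma2_a, sigma2_e = vc
    V = sigma2_a * Gr + sigma2_e * np.eye(len(ref))
    try:
        cfv = sla.cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        raise ValueError("G (plus stabilizer) is not positive semi-definite")
    Vinv_1 = sla.cho_solve(cfv, X, check_finite=False)
    mu = float(((X.T @ sla.cho_solve(cfv, y, check_finite=False))
                / (X.T @ Vinv_1).ravel()).item())
    Py = sla.cho_solve(cfv, y - mu, check_finite=False)
    a_all = sigma2_a * (grm.G[:, ridx] @ Py)
    return GblupFit(
        mu=pd.Series([mu], index=["mu"]),
        a_hat=pd.Series(a_all, index=grm.individuals),
        vc=(sigma2_a, sigma2_e),
        model="st",
    )


# ---------------------------------------------------------------------------
# MT-GBLUP (populations as traits)
# ---------------------------------------------------------------------------

def fit_mt_gblup(
    y_c: pd.Series,
    population: pd.Series,
    grm: GRM,
    vc: MultiTraitVC,
) -> GblupFit:
    """Multi-trait GBLUP with one population-trait record per individual.

    ``population`` labels every individual in the GRM; ``y_c`` covers the
    reference individuals. Each record belongs to its individual's own
    population-trait; foreign population-traits are structurally missing.
    Predictions are the individual's additive value on its own trait.
    """
    k = len(vc.labels)
    for mat, name in ((vc.M, "M"), (vc.R, "R")):
        w = np.linalg.eigvalsh(mat)
        if w.min() <= 0:
            raise ValueError(
                f"{name} is not positive definite (min eigenvalue {w.min():.3g}); "
                "apply assemble_and_bend first"
            )
    lut = {lab: i for i, lab in enumerate(vc.labels)}
    ref = list(y_c.index)
    ridx = grm.index(ref)
    tr_ref = np.array([lut[population.loc[i]] for i in ref])
    Gr = grm.G[np.ix_(ridx, ridx)] + G_STABILIZER * np.eye(len(ridx))

    V = vc.M[np.ix_(tr_ref, tr_ref)] * Gr
    V[np.arange(len(ref)), np.arange(len(ref))] += np.diag(vc.R)[tr_ref]
    X = np.zeros((len(ref), k))
    X[np.arange(len(ref)), tr_ref] = 1.0
    present = np.flatnonzero(X.sum(axis=0) > 0)
    X = X[:, present]
    y = y_c.to_numpy(dtype=float)
    cfv = sla.cho_factor(V, lower=True, check_finite=False)
    Vinv_X = sla.cho_solve(cfv, X, check_finite=False)
    XtViX = X.T @ Vinv_X
    mu_hat = np.linalg.solve(XtViX, X.T @ sla.cho_solve(cfv, y, check_finite=False))
    Py = sla.cho_solve(cfv, y - X @ mu_hat, check_finite=False)

    tr_all = np.array([lut[population.loc[i]] for i in grm.individuals])
    C = vc.M[np.ix_(tr_all, tr_ref)] * grm.G[:, ridx]
    a_all = C @ Py
    mu_full = pd.Series(0.0, index=vc.labels)
    mu_full.iloc[present] = mu_hat
    return GblupFit(
        mu=mu_full,
        a_hat=pd.Series(a_all, index=grm.individuals),
        vc=vc,
        model="mt",
    )


# ---------------------------------------------------------------------------
# pairwise bivariate variance components
# ---------------------------------------------------------------------------

def estimate_pairwise_vc(
    y_c: pd.Series,
    population: pd.Series,
    grm: GRM,
    pop_i: str,
    pop_j: str,
) -> dict:
    """Bivariate genomic REML for one population pair.

    Residual covariance is fixed at zero (no individual carries both
    population-traits). Returns genetic variances, the covariance, residual
    variances and the genetic correlation; |correlation| > 1 after
    convergence is clamped to +/-0.999 and flagged.
    """
    ids = [s for s in y_c.index if population.loc[s] in (pop_i, pop_j)]
    pops = np.array([population.loc[s] for s in ids])
    for pop in (pop_i, pop_j):
        if (pops == pop).sum() < 30:
            raise ValueError(f"population {pop} has fewer than 30 genotyped records")
    idx = grm.index(ids)
    G = grm.G[np.ix_(idx, idx)] + G_STABILIZER * np.eye(len(ids))
    mi = (pops == pop_i).astype(float)
    mj = (pops == pop_j).astype(float)
    V_ai = G * np.outer(mi, mi)
    V_aj = G * np.outer(mj, mj)
    V_aij = G * (np.outer(mi, mj) + np.outer(mj, mi))
    V_ei = np.diag(mi)
    V_ej = np.diag(mj)
    y = y_c.loc[ids].to_numpy(dtype=float)
    X = np.column_stack([mi, mj])
    vy_i = float(np.var(y[mi == 1]))
    vy_j = float(np.var(y[mj == 1]))

    # bounded quasi-Newton on (log variances, atanh correlation): the
    # correlation stays inside (-1, 1) where V is guaranteed admissible,
    # which an unconstrained covariance walk does not ensure
    def unpack(x):
        s_ai, s_aj, s_ei, s_ej = np.exp(x[[0, 1, 3, 4]])
        r = np.tanh(x[2])
        return s_ai, s_aj, r * np.sqrt(s_ai * s_aj), s_ei, s_ej

    def m2ll(x):
        s_ai, s_aj, s_aij, s_ei, s_ej = unpack(x)
        V = s_ai * V_ai + s_aj * V_aj + s_aij * V_aij + s_ei * V_ei + s_ej * V_ej
        try:
            cf = sla.cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e12
        Vinv_X = sla.cho_solve(cf, X, check_finite=False)
        XtViX = X.T @ Vinv_X
        Vinv_y = sla.cho_solve(cf, y, check_finite=False)
        beta = np.linalg.solve(XtViX, X.T @ Vinv_y)
        Py = Vinv_y - Vinv_X @ beta
        return (2.0 * np.sum(np.log(np.diag(cf[0])))
                + np.linalg.slogdet(XtViX)[1] + float(y @ Py))

    from scipy.optimize import minimize

    x0 = np.log([0.3 * vy_i, 0.3 * vy_j, 1.0, 0.7 * vy_i, 0.7 * vy_j])
    x0[2] = 0.0
    res = minimize(m2ll, x0, method="L-BFGS-B",
                   options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8})
    if not np.isfinite(res.fun):
        raise RuntimeError("bivariate REML failed to evaluate the likelihood")
    s_ai, s_aj, s_aij, s_ei, s_ej = unpack(res.x)
    r = s_aij / np.sqrt(s_ai * s_aj)
    clamped = False
    if abs(r) > 0.999:
        logger.warning("estimated genetic correlation %.3f at the boundary; "
                       "clamped to +/-0.999", r)
        r = float(np.sign(r) * 0.999)
        s_aij = r * float(np.sqrt(s_ai * s_aj))
        clamped = True
    return {
        "sigma2_a": {pop_i: s_ai, pop_j: s_aj},
        "sigma_a_cov": s_aij,
        "sigma2_e": {pop_i: s_ei, pop_j: s_ej},
        "correlation": r,
        "clamped": clamped,
    }


# ---------------------------------------------------------------------------
# assembly and bending
# ---------------------------------------------------------------------------

def bend_matrix(M: np.ndarray, small_positive: float = 1e-4,
                max_iter: int = 10000) -> np.ndarray:
    """Unweighted bending: raise eigenvalues below ``small_positive`` to it
    and reconstruct, iterating until the spectrum clears the floor.

    Already-positive-definite input is returned unchanged (elementwise)."""
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T):
        raise ValueError("can only bend a symmetric matrix")
    if np.linalg.eigvalsh(M).min() >= small_positive:
        return M.copy()                        # fixed point: PD input unchanged
    out = 0.5 * (M + M.T)
    for _ in range(max_iter):
        w, U = np.linalg.eigh(out)
        if w.min() >= small_positive - 1e-12:  # tolerance for eigh round-off
            return out
        out = U @ np.diag(np.maximum(w, small_positive)) @ U.T
        out = 0.5 * (out + out.T)
    w = np.linalg.eigvalsh(out)
    raise RuntimeError(f"bending did not reach positive definiteness; final spectrum {w}")


def assemble_and_bend(
    pairwise: dict[tuple[str, str], dict],
    labels: list[str],
    small_positive: float = 1e-4,
    max_iter: int = 10000,
) -> MultiTraitVC:
    """Assemble the full genetic (co)variance matrix M from bivariate fits.

    Diagonals are the arithmetic mean of the variance estimates across every
    bivariate analysis involving that population; off-diagonals come from
    the corresponding pair. M is then bent to positive definiteness;
    residual variances are likewise averaged, with off-diagonals fixed 0.
    """
    k = len(labels)
    need = {frozenset(p) for p in pairwise}
    want = {frozenset((a, b)) for i, a in enumerate(labels) for b in labels[i + 1:]}
    if want - need:
        raise ValueError(f"missing bivariate fits for pairs {sorted(tuple(sorted(p)) for p in (want - need))}")
    M = np.zeros((k, k))
    R = np.zeros((k, k))
    diag_a = {lab: [] for lab in labels}
    diag_e = {lab: [] for lab in labels}
    lut = {lab: i for i, lab in enumerate(labels)}
    for (a, b), fit in pairwise.items():
        M[lut[a], lut[b]] = M[lut[b], lut[a]] = fit["sigma_a_cov"]
        for lab in (a, b):
            diag_a[lab].append(fit["sigma2_a"][lab])
            diag_e[lab].append(fit["sigma2_e"][lab])
    for lab in labels:
        M[lut[lab], lut[lab]] = float(np.mean(diag_a[lab]))
        R[lut[lab], lut[lab]] = float(np.mean(diag_e[lab]))
    M_bent = bend_matrix(M, small_positive=small_positive, max_iter=max_iter)
    if not np.array_equal(M_bent, M):
        logger.info("genetic (co)variance matrix bent to positive definiteness")
    return MultiTraitVC(M=M_bent, R=R, labels=list(labels))


# ---------------------------------------------------------------------------
# derived genetic parameters
# ---------------------------------------------------------------------------

def heritability(sigma2_a: float, sigma2_e: float) -> float:
    """h2 = sigma2_a / (sigma2_a + sigma2_e), rounded half-up to 2 decimals.

    This is the two-component ratio used when a table prints only the
    additive and residual variances of a repeatability model."""
    if sigma2_a < 0 or sigma2_e < 0:
        raise ValueError("variances must be non-negative")
    den = sigma2_a + sigma2_e
    if den == 0:
        raise ValueError("zero denominator")
    return float(Decimal(sigma2_a / den).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def genetic_correlation(M: np.ndarray, i: int, j: int) -> float:
    """sigma_aij / sqrt(sigma2_ai * sigma2_aj)."""
    vi, vj = M[i, i], M[j, j]
    if vi <= 0 or vj <= 0:
        raise ValueError("genetic variances must be positive")
    return float(M[i, j] / np.sqrt(vi * vj))
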