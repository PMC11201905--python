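"""Pedigree relationships, repeatability-model REML/BLUP, corrected phenotypes.

The response variable for every genomic predictor downstream is the
*corrected phenotype* y_c = EBV + mean estimated residual over a sow's
parities. EBV come from a single-trait repeatability model fitted per
population:

    y = X b + Z a + W pe + e,
    a ~ N(0, A sigma2_a),  pe ~ N(0, I sigma2_pe),  e ~ N(0, I sigma2_e),

with herd-year-season as the fixed effect, A the pedigree numerator
relationship matrix (tabular method), and variance components estimated by
average-information REML with an EM fallback step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

logger = logging.getLogger("multigp.pedmodel")

__all__ = [
    "PedigreeRelationship",
    "VarianceComponentsSingle",
    "RepeatabilityModelSpec",
    "BlupSolution",
    "CorrectedPhenotypes",
    "build_A_matrix",
    "reml_repeatability",
    "blup_repeatability",
    "corrected_phenotypes",
    "derive_corrected_phenotypes",
]

UNKNOWN = {"0", "", ".", "NA", "nan"}


@dataclass
class PedigreeRelationship:
    A: np.ndarray
    order: dict[str, int]          # individual id -> row index

    def index(self, ids: list[str]) -> np.ndarray:
        return np.array([self.order[i] for i in ids])


@dataclass
class VarianceComponentsSingle:
    sigma2_a: float
    sigma2_pe: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if min(self.sigma2_a, self.sigma2_pe, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_pe + self.sigma2_e

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.total

    @property
    def repeatability(self) -> float:
        return (self.sigma2_a + self.sigma2_pe) / self.total


@dataclass
class RepeatabilityModelSpec:
    """Design of the repeatability model for one population and trait.

    ``z_idx`` maps each record to its animal's row in A; ``w_idx`` maps each
    record to a permanent-environment level (the sow). ``animal_ids`` spans
    the whole pedigree so non-phenotyped ancestors contribute through A.
    """

    X: np.ndarray                  # (n_records, p) fixed-effect incidence
    z_idx: np.ndarray              # (n_records,) int, animal index
    w_idx: np.ndarray              # (n_records,) int, pe level index
    y: np.ndarray                  # (n_records,)
    animal_ids: list[str]
    pe_ids: list[str]
    fixed_labels: list[str]
    record_individual: list[str]
    vc: VarianceComponentsSingle | None = None

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (self.X.shape[0] == self.z_idx.size == self.w_idx.size == n):
            raise ValueError("X, Z_a, W_pe and y must agree on the record count")

    @classmethod
    def from_phenotypes(cls, records: pd.DataFrame,
                        pedigree_rel: PedigreeRelationship) -> "RepeatabilityModelSpec":
        """Build the incidence structures from (individual, hys, value) records.

        Fixed effects: intercept plus herd-year-season dummies with the
        first level dropped (identifiability constraint).
        """
        records = records.reset_index(drop=True)
        ids = records["individual"].astype(str).tolist()
        missing = sorted({i for i in ids if i not in pedigree_rel.order})
        if missing:
            raise ValueError(f"phenotyped individuals absent from pedigree: {missing[:5]}")
        hys_levels = list(pd.unique(records["hys"].astype(str)))
        p = len(hys_levels)
        X = np.zeros((len(records), p))
        X[:, 0] = 1.0
        lut = {h: k for k, h in enumerate(hys_levels)}
        for r, h in enumerate(records["hys"].astype(str)):
            k = lut[h]
            if k > 0:
                X[r, k] = 1.0
        sows = list(dict.fromkeys(ids))
        sow_lut = {s: k for k, s in enumerate(sows)}
        animal_ids = list(pedigree_rel.order)
        return cls(
            X=X,
            z_idx=np.array([pedigree_rel.order[i] for i in ids]),
            w_idx=np.array([sow_lut[i] for i in ids]),
            y=records["value"].to_numpy(dtype=float),
            animal_ids=animal_ids,
            pe_ids=sows,
            fixed_labels=["intercept"] + hys_levels[1:],
            record_individual=ids,
        )


@dataclass
class BlupSolution:
    fixed: pd.Series
    ebv: pd.Series
    pe: pd.Series
    residuals: pd.DataFrame        # individual, residual (one row per record)
    vc: VarianceComponentsSingle


@dataclass
class CorrectedPhenotypes:
    values: pd.DataFrame           # individual, y_c, ebv, mean_residual, n_records


# ---------------------------------------------------------------------------
# A matrix (tabular / recursive method)
# ---------------------------------------------------------------------------

def _topological_order(ped: pd.DataFrame) -> list[str]:
    parents = {}
    for _, row in ped.iterrows():
        i = str(row["id"])
        s, d = str(row["sire"]), str(row["dam"])
        parents[i] = (None if s in UNKNOWN else s, None if d in UNKNOWN else d)
    order: list[str] = []
    state: dict[str, int] = {}     # 0 = visiting, 1 = done

    for start in parents:
        if state.get(start) == 1:
            continue
        stack = [start]
        while stack:
            node = stack[-1]
            if state.get(node) == 1:
                stack.pop()
                continue
            state.setdefault(node, 0)
            pending = [p for p in parents.get(node, (None, None))
                       if p is not None and state.get(p) != 1]
            cyclic = [p for p in pending if state.get(p) == 0]
            if cyclic:
                raise ValueError(f"pedigree cycle: {node} is its own ancestor via {cyclic[0]}")
            if pending:
                stack.extend(pending)
            else:
                state[node] = 1
                order.append(node)
                stack.pop()
    return order


def build_A_matrix(pedigree: pd.DataFrame) -> PedigreeRelationship:
    """Numerator relationship matrix by the tabular method.

    Unknown parents ("0", empty, NA) are treated as unrelated,
    non-inbred founders. Raises on pedigree cycles.
    """
    ped = pedigree.astype(str)
    order = _topological_order(ped)
    idx = {i: k for k, i in enumerate(order)}
    parent_of = {str(r["id"]): (str(r["sire"]), str(r["dam"])) for _, r in ped.iterrows()}

    n = len(order)
    A = np.zeros((n, n))
    for k, ind in enumerate(order):
        s, d = parent_of.get(ind, ("0", "0"))
        si = idx.get(s) if s not in UNKNOWN else None
        di = idx.get(d) if d not in UNKNOWN else None
        if k > 0:
            row = np.zeros(k)
            if si is not None:
                row += 0.5 * A[si, :k]
            if di is not None:
                row += 0.5 * A[di, :k]
            A[k, :k] = row
            A[:k, k] = row
        inb = 0.5 * A[si, di] if (si is not None and di is not None) else 0.0
        A[k, k] = 1.0 + inb
    return PedigreeRelationship(A=A, order=idx)


# ---------------------------------------------------------------------------
# REML (average information with EM fallback)
# ---------------------------------------------------------------------------

def _moment_start(spec: RepeatabilityModelSpec, vy: float) -> VarianceComponentsSingle:
    """Moment-based starting values: the within-sow variance of records (after
    removing fixed-effect least-squares estimates) approximates sigma2_e; the
    remainder is split between the additive and permanent-environment parts."""
    try:
        b, *_ = np.linalg.lstsq(spec.X, spec.y, rcond=None)
        resid = spec.y - spec.X @ b
        df_w = pd.DataFrame({"s": spec.w_idx, "r": resid})
        within = float(df_w.groupby("s")["r"].var(ddof=1).dropna().mean())
        total = float(np.var(resid, ddof=1))
        if not np.isfinite(within) or within <= 0 or within >= total:
            raise ValueError
        between = total - within
        return VarianceComponentsSingle(
            max(0.6 * between, 0.01 * vy),
            max(0.4 * between, 0.01 * vy),
            within,
        )
    except Exception:
        return VarianceComponentsSingle(0.2 * vy, 0.1 * vy, 0.7 * vy)


class _MMEWork:
    """Precomputed cross-products of [X Z W]: the only vc-dependent parts of
    the coefficient matrix are the 1/sigma2 scalings, so everything else is
    assembled once."""

    def __init__(self, spec: RepeatabilityModelSpec):
        X, y, z, w = spec.X, spec.y, spec.z_idx, spec.w_idx
        n, p = X.shape
        q_a, q_pe = len(spec.animal_ids), len(spec.pe_ids)
        self.spec, self.p, self.q_a, self.q_pe, self.n = spec, p, q_a, q_pe, n
        dim = p + q_a + q_pe
        C0 = np.zeros((dim, dim))
        C0[:p, :p] = X.T @ X
        XtZ = np.zeros((p, q_a))
        np.add.at(XtZ.T, z, X)
        XtW = np.zeros((p, q_pe))
        np.add.at(XtW.T, w, X)
        C0[:p, p:p + q_a] = XtZ
        C0[p:p + q_a, :p] = XtZ.T
        C0[:p, p + q_a:] = XtW
        C0[p + q_a:, :p] = XtW.T
        np.add.at(C0, (p + z, p + z), 1.0)
        np.add.at(C0, (p + q_a + w, p + q_a + w), 1.0)
        np.add.at(C0, (p + z, p + q_a + w), 1.0)
        np.add.at(C0, (p + q_a + w, p + z), 1.0)
        self.C0 = C0
        self.Wty = np.concatenate([
            X.T @ y,
            np.bincount(z, weights=y, minlength=q_a),
            np.bincount(w, weights=y, minlength=q_pe),
        ])

    def coefficient(self, A_inv: np.ndarray, vc: VarianceComponentsSingle):
        p, q_a = self.p, self.q_a
        C = self.C0 / vc.sigma2_e
        C[p:p + q_a, p:p + q_a] += A_inv / vc.sigma2_a
        if self.q_pe:
            di = np.arange(p + q_a, p + q_a + self.q_pe)
            C[di, di] += 1.0 / vc.sigma2_pe
        return C, self.Wty / vc.sigma2_e

    def crossprod(self, F: np.ndarray) -> np.ndarray:
        """[X Z W]' F for record-level columns F."""
        spec = self.spec
        cols = []
        for f in F.T:
            cols.append(np.concatenate([
                spec.X.T @ f,
                np.bincount(spec.z_idx, weights=f, minlength=self.q_a),
                np.bincount(spec.w_idx, weights=f, minlength=self.q_pe),
            ]))
        return np.column_stack(cols)

    def expand(self, theta: np.ndarray) -> np.ndarray:
        """Record-level fitted values [X Z W] theta."""
        spec, p, q_a = self.spec, self.p, self.q_a
        return (spec.X @ theta[:p] + theta[p:p + q_a][spec.z_idx]
                + theta[p + q_a:][spec.w_idx])


def reml_repeatability(
    spec: RepeatabilityModelSpec,
    pedigree_rel: PedigreeRelationship,
    start: VarianceComponentsSingle | None = None,
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
    fix_pe_at: float | None = None,
) -> VarianceComponentsSingle:
    """AI-REML for (sigma2_a, sigma2_pe, sigma2_e) of the repeatability model.

    Each iteration factorizes the mixed-model equations once; the average
    information matrix is built from working variates. An AI step that would
    push a variance negative has that component clamped to a tenth of its
    current value (a boundary component then decays geometrically), and if
    the AI matrix itself is not invertible an EM step is taken instead
    (logged). Convergence: change in -2 log restricted likelihood below
    ``tol_loglik`` or maximum relative parameter change below ``tol_param``.

    ``fix_pe_at`` holds the permanent-environment variance constant — the
    single-record design where pe is unidentifiable.
    """
    counts = np.bincount(spec.w_idx, minlength=len(spec.pe_ids))
    if fix_pe_at is None and (counts >= 2).sum() == 0:
        raise ValueError("permanent environment not identifiable: no sow has repeated records")
    XtX = spec.X.T @ spec.X
    if np.linalg.matrix_rank(XtX) < spec.X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient after the drop-first constraint")

    A_inv = np.linalg.inv(pedigree_rel.A)
    sign, logdet_A = np.linalg.slogdet(pedigree_rel.A)
    if sign <= 0:
        raise ValueError("A matrix is not positive definite")
    work = _MMEWork(spec)

    n, p = spec.X.shape
    q_a, q_pe = work.q_a, work.q_pe
    vy = float(np.var(spec.y))
    vc = start or _moment_start(spec, vy)
    if fix_pe_at is not None:
        vc = VarianceComponentsSingle(vc.sigma2_a, max(fix_pe_at, 1e-10), vc.sigma2_e)
    free = np.array([True, fix_pe_at is None, True])
    yty = float(spec.y @ spec.y)

    trajectory: list[tuple[float, float, float, float]] = []
    prev_m2ll = np.inf
    floor = 1e-10 * vy

    for it in range(max_iter):
        C, rhs = work.coefficient(A_inv, vc)
        try:
            cf = sla.cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"MME factorization failed at iteration {it}: {err}")
        theta = sla.cho_solve(cf, rhs, check_finite=False)
        b = theta[:p]
        a_hat = theta[p:p + q_a]
        pe_hat = theta[p + q_a:]
        e_hat = spec.y - work.expand(theta)

        wty_theta = float(work.Wty @ theta)
        yPy = (yty - wty_theta) / vc.sigma2_e
        logdet_C = 2.0 * np.sum(np.log(np.diag(cf[0])))
        m2ll = (logdet_C + q_a * np.log(vc.sigma2_a) + logdet_A
                + q_pe * np.log(vc.sigma2_pe) + n * np.log(vc.sigma2_e) + yPy)
        trajectory.append((vc.sigma2_a, vc.sigma2_pe, vc.sigma2_e, m2ll))

        # inverse blocks for traces (dpotri reuses the Cholesky factor)
        Cinv, info = sla.lapack.dpotri(cf[0], lower=True)
        if info != 0:
            raise RuntimeError(f"dpotri failed with info={info} at iteration {it}")
        Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T
        Caa = Cinv[p:p + q_a, p:p + q_a]
        Cpp = Cinv[p + q_a:, p + q_a:]
        t_a = float(np.sum(A_inv * Caa))
        t_pe = float(np.trace(Cpp))

        # scores dL/d(sigma2_i) = -0.5 [tr(P V_i) - y'P V_i P y]
        tr_PVa = (q_a - t_a / vc.sigma2_a) / vc.sigma2_a
        tr_PVpe = (q_pe - t_pe / vc.sigma2_pe) / vc.sigma2_pe
        tr_P = (n - p - q_a - q_pe + t_a / vc.sigma2_a + t_pe / vc.sigma2_pe) / vc.sigma2_e
        f_a = a_hat[spec.z_idx] / vc.sigma2_a
        f_pe = pe_hat[spec.w_idx] / vc.sigma2_pe
        f_e = e_hat / vc.sigma2_e
        Py = f_e
        score = -0.5 * np.array([
            tr_PVa - float(Py @ f_a),
            tr_PVpe - float(Py @ f_pe),
            tr_P - float(Py @ f_e),
        ])

        # average information from working variates: AI_ij = 0.5 f_i' P f_j
        F = np.column_stack([f_a, f_pe, f_e])
        theta_F = sla.cho_solve(cf, work.crossprod(F) / vc.sigma2_e, check_finite=False)
        PF = (F - np.column_stack([work.expand(t) for t in theta_F.T])) / vc.sigma2_e
        AI = 0.5 * (F.T @ PF)
        AI = 0.5 * (AI + AI.T)

        cur = np.array([vc.sigma2_a, vc.sigma2_pe, vc.sigma2_e])
        new = cur.copy()
        try:
            AI_f = AI[np.ix_(free, free)]
            step = np.linalg.solve(AI_f, score[free])
            cand = cur[free] + step
            if not np.all(np.isfinite(cand)):
                raise np.linalg.LinAlgError
            # clamp offending components toward the boundary instead of
            # discarding the whole step
            low = cand <= floor
            cand[low] = np.maximum(0.1 * cur[free][low], floor)
            new[free] = cand
        except np.linalg.LinAlgError:
            logger.info("AI matrix not usable at iteration %d; EM fallback", it)
            em = np.array([
                (float(a_hat @ (A_inv @ a_hat)) + t_a) / q_a,
                (float(pe_hat @ pe_hat) + t_pe) / q_pe,
                (yty - wty_theta) / (n - p),
            ])
            new[free] = np.maximum(em[free], floor)

        # relative change with a variance-scale floor so a component pinned
        # at the boundary cannot stall convergence
        rel = np.max(np.abs(new - cur) / np.maximum(np.maximum(new, cur), 1e-4 * vy))
        vc = VarianceComponentsSingle(*new)
        if abs(prev_m2ll - m2ll) < tol_loglik or rel < tol_param:
            return vc
        prev_m2ll = m2ll

    raise RuntimeError(
        "REML did not converge in "
        f"{max_iter} iterations; trajectory tail (sa2, spe2, se2, -2logL): {trajectory[-3:]}"
    )


# ---------------------------------------------------------------------------
# BLUP and corrected phenotypes
# ---------------------------------------------------------------------------

def blup_repeatability(
    spec: RepeatabilityModelSpec,
    pedigree_rel: PedigreeRelationship,
    vc: VarianceComponentsSingle | None = None,
) -> BlupSolution:
    """Solve Henderson's mixed-model equations at given variance components."""
    vc = vc or spec.vc
    if vc is None:
        raise ValueError("variance components required (fit REML first)")
    if vc.sigma2_a <= 0 or vc.sigma2_e <= 0 or vc.sigma2_pe <= 0:
        raise ValueError("variance components must be strictly positive for BLUP")
    A_inv = np.linalg.inv(pedigree_rel.A)
    work = _MMEWork(spec)
    C, rhs = work.coefficient(A_inv, vc)
    p, q_a = work.p, work.q_a
    try:
        theta = sla.cho_solve(sla.cho_factor(C, lower=True, check_finite=False), rhs,
                              check_finite=False)
    except np.linalg.LinAlgError as err:
        raise RuntimeError(f"singular MME coefficient matrix: {err}")
    b = theta[:p]
    a_hat = theta[p:p + q_a]
    pe_hat = theta[p + q_a:]
    resid = spec.y - work.expand(theta)
    return BlupSolution(
        fixed=pd.Series(b, index=spec.fixed_labels),
        ebv=pd.Series(a_hat, index=spec.animal_ids),
        pe=pd.Series(pe_hat, index=spec.pe_ids),
        residuals=pd.DataFrame({"individual": spec.record_individual, "residual": resid}),
        vc=vc,
    )


def corrected_phenotypes(blup: BlupSolution) -> CorrectedPhenotypes:
    """y_c = EBV + mean of the sow's estimated residuals across parities.

    Pedigree members without records carry an EBV but no residual and are
    excluded (logged); downstream prediction only uses genotyped sows with
    records anyway.
    """
    by_sow = blup.residuals.groupby("individual", sort=False)["residual"]
    mean_res = by_sow.mean()
    n_rec = by_sow.size()
    skipped = len(blup.ebv) - len(mean_res)
    if skipped:
        logger.info("%d pedigree members have EBV but no records; no y_c for them", skipped)
    ebv = blup.ebv.loc[mean_res.index]
    out = pd.DataFrame({
        "individual": mean_res.index,
        "y_c": ebv.to_numpy() + mean_res.to_numpy(),
        "ebv": ebv.to_numpy(),
        "mean_residual": mean_res.to_numpy(),
        "n_records": n_rec.to_numpy(),
    }).reset_index(drop=True)
    return CorrectedPhenotypes(values=out)


def derive_corrected_phenotypes(
    pedigree: pd.DataFrame,
    phenotypes,
    trait: str,
    vc: dict[str, VarianceComponentsSingle] | None = None,
) -> tuple[pd.DataFrame, dict[str, VarianceComponentsSingle]]:
    """Per-population pipeline: A matrix -> REML -> BLUP -> y_c.

    Returns a table (individual, population, y_c, ebv, mean_residual) over
    all populations present in the phenotype table, and the variance
    components used for each. Each population is handled with its own
    pedigree, matching the absence of cross-population pedigree links.
    """
    records = phenotypes.for_trait(trait)
    out, used = [], {}
    for pop in pd.unique(records["population"]):
        sub = records[records["population"] == pop]
        ped_pop = pedigree[pedigree["population"] == pop] if "population" in pedigree else pedigree
        rel = build_A_matrix(ped_pop)
        spec = RepeatabilityModelSpec.from_phenotypes(sub, rel)
        pop_vc = (vc or {}).get(pop) or reml_repeatability(spec, rel)
        used[pop] = pop_vc
        blup = blup_repeatability(spec, rel, pop_vc)
        yc = corrected_phenotypes(blup).values.copy()
        yc.insert(1, "population", pop)
        out.append(yc)
    return pd.concat(out, ignore_index=True), used
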