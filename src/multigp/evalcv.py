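"""Replicated cross-validation and the three evaluation metrics.

Accuracy of phenotype prediction is assessed by replicated k-fold CV
(default 10 replicates of fivefold). Per replicate, each target
population's genotyped individuals are partitioned independently into
folds; the joint reference of a fold is the union of the target
populations' training folds, plus whole auxiliary populations in the
multi-population scenario. The identical plan is served to every method.

Metrics per validation fold per population:

* predictive ability — Pearson r between corrected phenotypes and
  predictions;
* centered MSE — mean squared difference after centering both vectors by
  their own validation-fold means;
* bias — the ordinary least-squares slope of y_c on predictions (1 means
  unbiased).

Point estimates are means over all replicate-folds; the reported standard
error is the per-replicate across-fold SE averaged over replicates.
Methods are compared by paired two-sided t-tests on replicate means with
Bonferroni-adjusted P-values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("multigp.evalcv")

__all__ = [
    "CVPlan",
    "CVReport",
    "make_cv_plan",
    "predictive_ability",
    "mse_centered",
    "bias_slope",
    "summarize_cv",
    "compare_methods",
]


@dataclass
class CVPlan:
    replicates: int
    folds: int
    assignment: pd.DataFrame      # replicate, population, individual, fold
    seed: int

    def fold_members(self, replicate: int, fold: int) -> dict[str, list[str]]:
        """Validation individuals per target population for one fold."""
        sel = self.assignment[(self.assignment["replicate"] == replicate)
                              & (self.assignment["fold"] == fold)]
        return {p: g["individual"].tolist() for p, g in sel.groupby("population")}

    def training_members(self, replicate: int, fold: int) -> list[str]:
        sel = self.assignment[(self.assignment["replicate"] == replicate)
                              & (self.assignment["fold"] != fold)]
        return sel["individual"].tolist()


@dataclass
class CVReport:
    """Per-fold metrics, their aggregated table, and pairwise method tests."""

    per_fold: pd.DataFrame
    summary: pd.DataFrame
    comparisons: pd.DataFrame

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_fold.to_csv(out / "per_fold.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        self.comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
        with (out / "summary.txt").open("w") as fh:
            fh.write(self.summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
            fh.write("\n")


def make_cv_plan(
    populations: dict[str, list[str]],
    replicates: int = 10,
    folds: int = 5,
    seed: int = 1,
) -> CVPlan:
    """Independent random fold partition per replicate per target population.

    ``populations`` maps each *target* population label to its genotyped
    individuals; auxiliary populations are never assigned folds (they join
    every training set whole, handled by the caller). Fold sizes within a
    population differ by at most one.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pop, ids in populations.items():
        if len(ids) < folds:
            raise ValueError(f"population {pop} has {len(ids)} individuals; "
                             f"cannot form {folds} folds")
        for rep in range(replicates):
            lab = np.resize(np.arange(folds), len(ids))
            rng.shuffle(lab)
            for ind, f in zip(ids, lab):
                rows.append((rep, pop, ind, int(f)))
    plan = pd.DataFrame(rows, columns=["replicate", "population", "individual", "fold"])
    sizes = plan.groupby(["replicate", "population", "fold"]).size()
    if (sizes == 0).any():
        raise ValueError("empty CV fold")
    return CVPlan(replicates=replicates, folds=folds, assignment=plan, seed=seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def predictive_ability(y_c_val: np.ndarray, pred_val: np.ndarray) -> float:
    """Sample Pearson correlation; nan (with a warning) if either vector is
    constant."""
    y = np.asarray(y_c_val, float)
    p = np.asarray(pred_val, float)
    if y.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(y) == 0 or np.std(p) == 0:
        logger.warning("constant vector; predictive ability undefined")
        return float("nan")
    return float(np.corrcoef(y, p)[0, 1])


def mse_centered(y_c_val: np.ndarray, pred_val: np.ndarray) -> float:
    """MSE after centering both vectors by their own validation means."""
    y = np.asarray(y_c_val, float)
    p = np.asarray(pred_val, float)
    if y.size < 2:
        raise ValueError("need at least 2 pairs")
    return float(np.mean(((p - p.mean()) - (y - y.mean())) ** 2))


def bias_slope(y_c_val: np.ndarray, pred_val: np.ndarray) -> float:
    """OLS slope of y_c on predictions; 1 = unbiased. nan if predictions are
    constant (zero variance)."""
    y = np.asarray(y_c_val, float)
    p = np.asarray(pred_val, float)
    vp = np.var(p)
    if vp == 0:
        logger.warning("zero prediction variance; bias slope undefined")
        return float("nan")
    return float(np.cov(y, p, ddof=1)[0, 1] / np.var(p, ddof=1))


# ---------------------------------------------------------------------------
# aggregation and method comparison
# ---------------------------------------------------------------------------

def summarize_cv(per_fold: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-fold metrics into the reported table.

    ``per_fold`` columns: method, population, trait, replicate, fold, then
    one column per metric. For each metric the point estimate is the mean
    over all replicate-folds; the SE is the within-replicate across-fold
    standard error (sd/sqrt(folds)) averaged over replicates. Missing cells
    are tolerated with reduced n (flagged in the log).
    """
    keys = ["method", "population", "trait"]
    metric_cols = [c for c in per_fold.columns
                   if c not in keys + ["replicate", "fold"]]
    out = []
    for name, grp in per_fold.groupby(keys):
        row = dict(zip(keys, name))
        row["n_cells"] = len(grp)
        for mcol in metric_cols:
            vals = grp[mcol]
            n_missing = int(vals.isna().sum())
            if n_missing:
                logger.warning("%s: %d missing %s cells", name, n_missing, mcol)
            row[mcol] = float(vals.mean())
            per_rep = grp.groupby("replicate")[mcol].apply(
                lambda v: v.std(ddof=1) / np.sqrt(v.notna().sum())
            )
            row[f"{mcol}_se"] = float(per_rep.mean())
        out.append(row)
    return pd.DataFrame(out)


def replicate_means(per_fold: pd.DataFrame, metric: str = "predictive_ability") -> pd.DataFrame:
    """Mean of a metric per (method, population, trait, replicate)."""
    return (per_fold.groupby(["method", "population", "trait", "replicate"])[metric]
            .mean().reset_index())


def compare_methods(rep_means: pd.DataFrame, metric: str = "predictive_ability") -> pd.DataFrame:
    """Paired t-tests between methods on replicate means, Bonferroni-adjusted.

    ``rep_means`` as produced by :func:`replicate_means`. Within each
    (population, trait), every method pair is tested with a paired
    two-sided t-test across replicates; raw P-values are multiplied by the
    number of pairs and capped at 1. Exact ties (zero variance of the
    differences) are reported without a test.
    """
    rows = []
    for (pop, trait), grp in rep_means.groupby(["population", "trait"]):
        wide = grp.pivot(index="replicate", columns="method", values=metric)
        methods = list(wide.columns)
        pairs = list(itertools.combinations(methods, 2))
        n_cmp = len(pairs)
        for a, b in pairs:
            d = (wide[a] - wide[b]).dropna()
            if np.allclose(d.var(ddof=1) if len(d) > 1 else 0.0, 0.0):
                rows.append({"population": pop, "trait": trait, "method_a": a,
                             "method_b": b, "mean_diff": float(d.mean()),
                             "p_raw": np.nan, "p_adj": np.nan, "tie": True})
                continue
            t = stats.ttest_rel(wide[a], wide[b], nan_policy="omit")
            rows.append({"population": pop, "trait": trait, "method_a": a,
                         "method_b": b, "mean_diff": float(d.mean()),
                         "p_raw": float(t.pvalue),
                         "p_adj": float(min(1.0, t.pvalue * n_cmp)), "tie": False})
    return pd.DataFrame(rows)
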