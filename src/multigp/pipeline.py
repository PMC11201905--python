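"""Scenario runner: QC -> corrected phenotypes -> G -> tuning -> replicated CV.

Ties the modules into the two study designs:

* **two-population** — two genetically linked populations are jointly
  predicted; both are fold-split and their training folds pooled into one
  joint reference.
* **multi-population** — additional populations with different genetic
  backgrounds are added *whole* to every joint reference; predictions are
  still made only for the target populations.

Variance components are estimated once on the complete dataset and reused
across CV folds; hyperparameters of the kernel methods are tuned
population-specifically before CV. The identical fold plan is served to
every method, and everything downstream of the seed is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bayeshe, evalcv, genostats, gblup, kernelml, pedmodel
from .dataio import GenotypeSet, PhenotypeTable, ScenarioConfig

logger = logging.getLogger("multigp.pipeline")

__all__ = ["run_scenario", "ScenarioData"]

ML_METHODS = ("SVR", "KRR", "AdaBoost.R2")
# desk-scale chain for the horseshoe inside CV (the printed full schedule is
# 50000/20000/50; pass chain overrides to use it)
BAYES_CHAIN = {"iterations": 5000, "burnin": 2000, "thin": 10}


@dataclass
class ScenarioData:
    """Everything run_scenario derived before cross-validation began."""

    genotypes: GenotypeSet
    y_c: pd.Series                    # corrected phenotypes of genotyped reference sows
    population: pd.Series             # population label per genotyped individual
    grm: genostats.GRM
    st_vc: tuple[float, float]
    mt_vc: gblup.MultiTraitVC | None
    tuned: dict[str, kernelml.TuningResult]


def _corrected_for_trait(pedigree, phenotypes, trait, vc=None) -> pd.DataFrame:
    yc, _ = pedmodel.derive_corrected_phenotypes(pedigree, phenotypes, trait, vc=vc)
    return yc


def prepare_scenario(
    cfg: ScenarioConfig,
    genotypes: GenotypeSet,
    pedigree: pd.DataFrame,
    phenotypes: PhenotypeTable,
    trait: str,
    pedigree_vc=None,
) -> ScenarioData:
    """Stages shared by every method: QC, y_c, G, variance components, tuning."""
    pops_used = list(cfg.target_populations) + list(cfg.auxiliary_populations)
    have = set(genotypes.populations)
    missing = [p for p in pops_used if p not in have]
    if missing:
        raise ValueError(f"populations {missing} absent from the genotype data")

    logger.info("QC: maf >= 0.05, call rates >= 0.90")
    gs = genostats.qc_filter(genotypes)
    gs = genostats.mean_impute(gs)
    keep = np.isin(gs.population, pops_used)
    gs = gs.subset(individuals=keep)

    logger.info("deriving corrected phenotypes for trait %s", trait)
    yc_tab = _corrected_for_trait(pedigree, phenotypes, trait, vc=pedigree_vc)
    yc_tab = yc_tab[yc_tab["individual"].isin(gs.individuals)
                    & yc_tab["population"].isin(pops_used)]
    y_c = pd.Series(yc_tab["y_c"].to_numpy(), index=yc_tab["individual"].tolist())
    population = pd.Series(gs.population, index=gs.individuals)

    for pop in cfg.target_populations:
        n = int((population.loc[y_c.index] == pop).sum())
        if n < cfg.folds:
            raise ValueError(f"population {pop} has {n} genotyped phenotyped sows; "
                             f"fewer than {cfg.folds} folds")

    logger.info("building VanRaden G over %d individuals x %d markers",
                gs.n_individuals, gs.n_markers)
    grm = genostats.vanraden_g(gs, freq_source="combined")

    # variance components once, on the complete dataset
    st_fit = gblup.fit_st_gblup(y_c, grm)
    st_vc = st_fit.vc
    logger.info("ST variance components on complete data: sigma2_a=%.4f sigma2_e=%.4f",
                *st_vc)

    mt_vc = None
    if "MT-GBLUP" in cfg.methods:
        pairwise = {}
        for i, a in enumerate(pops_used):
            for b in pops_used[i + 1:]:
                pairwise[(a, b)] = gblup.estimate_pairwise_vc(y_c, population, grm, a, b)
        mt_vc = gblup.assemble_and_bend(pairwise, pops_used)
        logger.info("MT genetic (co)variance matrix assembled over %s", pops_used)

    tuned = {}
    ref_rows = {s: i for i, s in enumerate(gs.individuals)}
    X = gs.dosages
    for m in cfg.methods:
        if m in ML_METHODS:
            grid = cfg.grids.get(m) or kernelml.default_grid(m)
            logger.info("tuning %s over %d grid points", m, len(grid))
            tuned[m] = kernelml.tune_population_specific(
                y_c, X, gs.individuals, population, m, grid,
                cfg.target_populations, cfg.auxiliary_populations,
                folds=5, seed=cfg.seed,
            )
    return ScenarioData(genotypes=gs, y_c=y_c, population=population, grm=grm,
                        st_vc=st_vc, mt_vc=mt_vc, tuned=tuned)


def _fold_predictor(method: str, data: ScenarioData, train_ids, seed,
                    bayes_chain=None):
    """Fit one method on the joint reference; return predict(val_ids, pop).

    GBLUP and the horseshoe fit once per fold (the model does not depend on
    which population is being predicted); the kernel methods refit per
    target population with that population's tuned hyperparameters.
    """
    y_tr = data.y_c.loc[train_ids]
    row = {s: i for i, s in enumerate(data.genotypes.individuals)}
    if method == "ST-GBLUP":
        fit = gblup.fit_st_gblup(y_tr, data.grm, vc=data.st_vc)
        return lambda val_ids, pop: fit.predict(val_ids)
    if method == "MT-GBLUP":
        fit = gblup.fit_mt_gblup(y_tr, data.population, data.grm, data.mt_vc)
        return lambda val_ids, pop: fit.predict(val_ids, data.population)
    Xtr = data.genotypes.dosages[[row[s] for s in train_ids]]
    if method == "BayesHE":
        chain = dict(BAYES_CHAIN, **(bayes_chain or {}))
        summ = bayeshe.gibbs_bayeshe(y_tr.to_numpy(dtype=float), Xtr,
                                     seed=seed, **chain)
        return lambda val_ids, pop: bayeshe.predict_bayeshe(
            summ, data.genotypes.dosages[[row[s] for s in val_ids]])

    y_arr = y_tr.to_numpy(dtype=float)

    def predict(val_ids, pop):
        params = data.tuned[method].per_population[pop]["params"]
        model = kernelml._fit_method(method, params, y_arr, Xtr, seed)
        return model.predict(data.genotypes.dosages[[row[s] for s in val_ids]])

    return predict


def run_scenario(
    cfg: ScenarioConfig,
    genotypes: GenotypeSet,
    pedigree: pd.DataFrame,
    phenotypes: PhenotypeTable,
    trait: str = "TNB",
    out_dir=None,
    pedigree_vc=None,
    bayes_chain=None,
    prepared: ScenarioData | None = None,
) -> evalcv.CVReport:
    """Full pipeline for one trait; returns (and optionally writes) the CV report.

    ``pedigree_vc`` may supply per-population repeatability-model variance
    components to skip the REML stage; ``bayes_chain`` overrides the
    horseshoe chain schedule.
    """
    data = prepared or prepare_scenario(cfg, genotypes, pedigree, phenotypes,
                                        trait, pedigree_vc)
    targets = {
        pop: [s for s in data.y_c.index if data.population.loc[s] == pop]
        for pop in cfg.target_populations
    }
    aux_ids = [s for s in data.y_c.index
               if data.population.loc[s] in set(cfg.auxiliary_populations)]
    plan = evalcv.make_cv_plan(targets, replicates=cfg.replicates,
                               folds=cfg.folds, seed=cfg.seed)
    logger.info("CV: %d replicates x %d folds, seed %d; methods %s",
                cfg.replicates, cfg.folds, cfg.seed, cfg.methods)

    rows = []
    for rep in range(cfg.replicates):
        for fold in range(cfg.folds):
            train = plan.training_members(rep, fold) + aux_ids
            val_by_pop = plan.fold_members(rep, fold)
            for method in cfg.methods:
                predictor = _fold_predictor(method, data, train,
                                            seed=cfg.seed + 1000 * rep + fold,
                                            bayes_chain=bayes_chain)
                for pop, val_ids in val_by_pop.items():
                    pred = predictor(val_ids, pop)
                    obs = data.y_c.loc[val_ids].to_numpy(dtype=float)
                    rows.append({
                        "method": method, "population": pop, "trait": trait,
                        "replicate": rep, "fold": fold,
                        "predictive_ability": evalcv.predictive_ability(obs, pred),
                        "mse": evalcv.mse_centered(obs, pred),
                        "bias": evalcv.bias_slope(obs, pred),
                    })
    per_fold = pd.DataFrame(rows)
    summary = evalcv.summarize_cv(per_fold)
    rep_means = evalcv.replicate_means(per_fold)
    comparisons = (evalcv.compare_methods(rep_means)
                   if len(cfg.methods) > 1 else pd.DataFrame())
    report = evalcv.CVReport(per_fold=per_fold, summary=summary, comparisons=comparisons)
    if out_dir is not None:
        report.write(out_dir)
        logger.info("report written to %s", out_dir)
    return report
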