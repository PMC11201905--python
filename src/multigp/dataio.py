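"""Containers and on-disk formats for genotypes, pedigrees and phenotypes.

The analysis operates on three tables:

* a dosage matrix (individuals x markers, alternate-allele counts 0/1/2,
  ``nan`` for missing) with a marker map and a population label per
  individual (:class:`GenotypeSet`);
* a pedigree (id, sire, dam, population) as CSV;
* a repeated-record phenotype table (individual, population, parity,
  contemporary group, trait, value) (:class:`PhenotypeTable`).

Genotypes are read either from VCF (alternate-allele count of the GT field)
or from a human-readable tab-separated dosage table whose first two columns
are the individual id and the population label and whose remaining columns
are markers. Every writer here has a paired reader that round-trips
losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("multigp")

MISSING = np.nan

#: methods understood by the scenario runner
KNOWN_METHODS = ("ST-GBLUP", "MT-GBLUP", "BayesHE", "SVR", "KRR", "AdaBoost.R2")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeSet:
    """Dosage matrix plus marker map, individual ids and population labels.

    ``dosages`` holds alternate-allele counts as floats so missing cells can
    be ``nan``; after QC and mean imputation the matrix is dense {0,1,2} (or
    fractional if unrounded means are kept).
    """

    dosages: np.ndarray                  # (n_individuals, n_markers)
    markers: pd.DataFrame                # columns: marker, chrom, pos, ref, alt
    individuals: list[str]
    population: np.ndarray               # (n_individuals,) of str labels

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.population = np.asarray(self.population, dtype=object)
        if len(self.individuals) != len(set(self.individuals)):
            raise ValueError("individual identifiers must be unique")
        if self.dosages.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage entry at individual {bad[0]}, marker {bad[1]} is "
                f"{self.dosages[tuple(bad)]}; entries must be 0, 1, 2 or missing"
            )
        chrom = self.markers["chrom"].to_numpy()
        pos = self.markers["pos"].to_numpy()
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"marker positions on chromosome {c} must be strictly increasing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p)
        return list(seen)

    def subset(self, individuals: np.ndarray | None = None,
               markers: np.ndarray | None = None) -> "GenotypeSet":
        """Return a new set restricted to boolean/integer index selections."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        mk = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        if ind.dtype == bool:
            ind = np.flatnonzero(ind)
        if mk.dtype == bool:
            mk = np.flatnonzero(mk)
        return GenotypeSet(
            dosages=self.dosages[np.ix_(ind, mk)],
            markers=self.markers.iloc[mk].reset_index(drop=True),
            individuals=[self.individuals[i] for i in ind],
            population=self.population[ind],
        )


@dataclass
class PhenotypeTable:
    """Repeated-parity records: one row per (individual, parity, trait)."""

    records: pd.DataFrame  # columns: individual, population, parity, hys, trait, value

    REQUIRED = ("individual", "population", "parity", "hys", "trait", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        dup = self.records.duplicated(subset=["individual", "parity", "trait"])
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicate (individual, parity, trait) records"
            )

    def for_trait(self, trait: str) -> pd.DataFrame:
        out = self.records[self.records["trait"] == trait]
        if out.empty:
            raise KeyError(f"no records for trait {trait!r}")
        return out.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.records["trait"]))


@dataclass
class ScenarioConfig:
    """Which populations are predicted, with which methods, under which CV."""

    scenario: str                                   # "two_population" | "multi_population"
    target_populations: list[str]
    auxiliary_populations: list[str] = field(default_factory=list)
    methods: list[str] = field(default_factory=lambda: ["ST-GBLUP", "MT-GBLUP"])
    replicates: int = 10
    folds: int = 5
    seed: int = 1
    grids: dict = field(default_factory=dict)       # method -> list of param dicts

    def __post_init__(self) -> None:
        if self.scenario not in ("two_population", "multi_population"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        overlap = set(self.target_populations) & set(self.auxiliary_populations)
        if overlap:
            raise ValueError(f"populations {sorted(overlap)} are both target and auxiliary")
        if self.scenario == "two_population" and self.auxiliary_populations:
            raise ValueError("two_population scenario admits no auxiliary populations")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        for m in self.methods:
            if m not in KNOWN_METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {KNOWN_METHODS}")
        ml = {"SVR", "KRR", "AdaBoost.R2"}
        for m in self.methods:
            if m in ml and not self.grids.get(m):
                raise ValueError(f"machine-learning method {m} requested without a hyperparameter grid")


# ---------------------------------------------------------------------------
# dosage table / pedigree / phenotype CSV round-trip
# ---------------------------------------------------------------------------

def write_dosage_table(gs: GenotypeSet, path: str | Path) -> None:
    """Tab-separated dosages: id, population, then one column per marker."""
    df = pd.DataFrame(gs.dosages, columns=gs.markers["marker"])
    df.insert(0, "population", gs.population)
    df.insert(0, "id", gs.individuals)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_table(path: str | Path, markers: pd.DataFrame | None = None) -> GenotypeSet:
    """Read the tab-separated dosage dialect written by :func:`write_dosage_table`.

    If ``markers`` (a marker map with columns marker/chrom/pos/ref/alt) is not
    supplied, a single-chromosome map with unit spacing is fabricated from the
    header so the matrix remains usable for G-matrix and kernel work.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.columns[0] != "id" or df.columns[1] != "population":
        raise ValueError(f"{path}: first two columns must be 'id' and 'population'")
    names = list(df.columns[2:])
    if markers is None:
        markers = default_marker_map(names)
    elif list(markers["marker"]) != names:
        raise ValueError(f"{path}: marker columns do not match the supplied marker map")
    return GenotypeSet(
        dosages=df[names].to_numpy(dtype=float),
        markers=markers.reset_index(drop=True),
        individuals=df["id"].astype(str).tolist(),
        population=df["population"].astype(str).to_numpy(),
    )


def default_marker_map(names: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({
        "marker": list(names),
        "chrom": "1",
        "pos": np.arange(1, len(names) + 1),
        "ref": "A",
        "alt": "B",
    })


def write_marker_map(markers: pd.DataFrame, path: str | Path) -> None:
    markers.to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_pedigree(pedigree: pd.DataFrame, path: str | Path) -> None:
    pedigree.to_csv(path, index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(path, dtype=str, keep_default_na=False)
    need = {"id", "sire", "dam"}
    if not need <= set(ped.columns):
        raise ValueError(f"{path}: pedigree needs columns {sorted(need)}")
    return ped


def write_phenotypes(pt: PhenotypeTable, path: str | Path) -> None:
    pt.records.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, dtype={"individual": str, "population": str, "hys": str})
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(gs: GenotypeSet, path: str | Path, phased_haplotypes: np.ndarray | None = None) -> None:
    """Write dosages as a minimal VCF 4.2 with GT fields.

    Without ``phased_haplotypes`` (a (2n, m) binary array, rows 2i and 2i+1
    being individual i's haplotypes), heterozygotes are emitted unphased as
    0/1; with it, genotypes are phased (``|``).
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gs.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gs.individuals) + "\n")
        for j, row in gs.markers.iterrows():
            calls = []
            for i in range(gs.n_individuals):
                d = gs.dosages[i, j]
                if np.isnan(d):
                    calls.append("./.")
                elif phased_haplotypes is not None:
                    a, b = phased_haplotypes[2 * i, j], phased_haplotypes[2 * i + 1, j]
                    calls.append(f"{int(a)}|{int(b)}")
                else:
                    calls.append({0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}[d])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['marker']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path, populations: Mapping[str, str] | None = None) -> GenotypeSet:
    """Read a VCF into a :class:`GenotypeSet`; dosage = alternate-allele count.

    Missing GT ("./.") becomes a missing dosage. ``populations`` maps sample
    id -> population label (default: single population "pop1").
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    meta = {"marker": [], "chrom": [], "pos": [], "ref": [], "alt": []}
    for lineno, variant in enumerate(vcf, start=1):
        gts = variant.genotype.array()
        if gts.shape[1] > 3:
            raise ValueError(f"{path}: mixed or non-diploid ploidy at record {lineno}")
        alleles = gts[:, :2]
        dos = np.where((alleles < 0).any(axis=1), np.nan,
                       alleles.clip(min=0).sum(axis=1).astype(float))
        if np.nanmax(dos, initial=0.0) > 2:
            raise ValueError(f"{path}: multi-allelic dosage at record {lineno}")
        rows.append(dos)
        meta["marker"].append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        meta["chrom"].append(variant.CHROM)
        meta["pos"].append(variant.POS)
        meta["ref"].append(variant.REF)
        meta["alt"].append(variant.ALT[0] if variant.ALT else ".")
    if not rows:
        raise ValueError(f"{path}: no variant records")
    pop = np.array([populations.get(s, "pop1") if populations else "pop1" for s in samples],
                   dtype=object)
    return GenotypeSet(
        dosages=np.asarray(rows, dtype=float).T,
        markers=pd.DataFrame(meta),
        individuals=samples,
        population=pop,
    )


def read_genotypes(path: str | Path, format: str = "dosage_table", **kw) -> GenotypeSet:
    """Dispatch reader: ``format`` is ``"vcf"`` or ``"dosage_table"``."""
    if format == "vcf":
        return read_vcf(path, **kw)
    if format == "dosage_table":
        return read_dosage_table(path, **kw)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# scenario configuration (flat key: value YAML, unknown keys rejected)
# ---------------------------------------------------------------------------

_SCENARIO_KEYS = {"scenario", "target_populations", "auxiliary_populations",
                  "methods", "cv", "grids"}


def read_scenario_config(path: str | Path) -> ScenarioConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario config must be a mapping")
    unknown = set(raw) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cv = raw.get("cv", {})
    return ScenarioConfig(
        scenario=raw["scenario"],
        target_populations=list(raw["target_populations"]),
        auxiliary_populations=list(raw.get("auxiliary_populations", [])),
        methods=list(raw.get("methods", ["ST-GBLUP", "MT-GBLUP"])),
        replicates=int(cv.get("replicates", 10)),
        folds=int(cv.get("folds", 5)),
        seed=int(cv.get("seed", 1)),
        grids={k: list(v) for k, v in raw.get("grids", {}).items()},
    )


def write_scenario_config(cfg: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "scenario": cfg.scenario,
        "target_populations": cfg.target_populations,
        "auxiliary_populations": cfg.auxiliary_populations,
        "methods": cfg.methods,
        "cv": {"replicates": cfg.replicates, "folds": cfg.folds, "seed": cfg.seed},
        "grids": cfg.grids,
    }))


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(level=getattr(logging, level.upper()),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
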