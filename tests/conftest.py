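import numpy as np
import pandas as pd
import pytest

from multigp import genostats, simdata


@pytest.fixture(scope="session")
def small_sim():
    """Two populations x 150 sows, 600 SNPs; shared across read-only tests."""
    cfg = simdata.SimulationConfig(n_per_pop=150, n_snp=600, n_qtl=100,
                                   founder_haplotypes=120, seed=101)
    return simdata.simulate(cfg)


@pytest.fixture(scope="session")
def small_qc(small_sim):
    gs = genostats.qc_filter(small_sim.genotypes)
    return genostats.mean_impute(gs)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def kinship_oracle(pedigree: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Independent recursive-kinship oracle: A = 2 * coancestry matrix.

    Memoized pairwise kinship phi(i, j) with the textbook recursion; kept
    deliberately separate from the tabular construction it checks.
    """
    parents = {}
    for _, r in pedigree.astype(str).iterrows():
        s = None if r["sire"] in ("0", "", "nan") else r["sire"]
        d = None if r["dam"] in ("0", "", "nan") else r["dam"]
        parents[r["id"]] = (s, d)
    ids = list(parents)
    memo = {}

    # generation depth so recursion always descends to older animals
    depth = {}
    def _depth(i):
        if i is None:
            return -1
        if i not in depth:
            s, d = parents.get(i, (None, None))
            depth[i] = 1 + max(_depth(s), _depth(d))
        return depth[i]

    def phi(a, b):
        if a is None or b is None:
            return 0.0
        if (a, b) in memo:
            return memo[(a, b)]
        if a == b:
            s, d = parents.get(a, (None, None))
            v = 0.5 * (1.0 + phi(s, d))
        else:
            if _depth(a) < _depth(b):
                a, b = b, a
            s, d = parents.get(a, (None, None))
            v = 0.5 * (phi(s, b) + phi(d, b))
        memo[(a, b)] = memo[(b, a)] = v
        return v

    n = len(ids)
    A = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            A[i, j] = 2.0 * phi(a, b)
    return A, {i: k for k, i in enumerate(ids)}


def hudson_fst(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int) -> float:
    """Hudson's FST estimator from two populations' allele frequencies."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())
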