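"""Weighted sum statistic (Madsen & Browning) for rare-variant burden testing.

Variants below a MAF cutoff are combined into a per-individual genetic
score: each variant's minor-allele count is divided by a weight
``w_i = sqrt(n_i q_i (1 - q_i))`` where ``q_i = (m_i^U + 1) / (2 n_i^U + 2)``
is the pseudocounted minor allele frequency estimated in the unaffected.
Individuals are ranked by score (midranks for ties) and the statistic is
the rank sum of the cases.  Significance comes from ``k`` phenotype
permutations: weights, scores and ranks are recomputed for each
permutation (the unaffected set changes), the observed rank sum is
standardized by the permutation mean and sample SD (k-1 denominator), and
the one-sided upper-tail normal probability is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, DegenerateDataError, InputError, PhenotypeVector, TestResult

__all__ = ["WssConfig", "wss_test", "wss_maf_sweep"]


@dataclass
class WssConfig:
    maf_cutoff: float = 0.05
    k: int = 1000

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InputError("permutation count k must be >= 1")
        if not 0 < self.maf_cutoff <= 0.5:
            raise InputError("maf_cutoff must be in (0, 0.5]")


def _phenotype_array(y) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        return y.values
    return PhenotypeVector(np.asarray(y)).values


def _wss_x(
    mut: np.ndarray,
    nonmiss: np.ndarray,
    unique_rows: np.ndarray,
    group_counts: np.ndarray,
    group_onehot: np.ndarray,
    perm_cases: np.ndarray,
) -> np.ndarray:
    """Case rank-sums for each row of ``perm_cases`` (k, n).

    Individuals with identical mutation-count rows always share a score,
    so scoring and ranking are done on the ``unique_rows`` (u, m) and
    expanded through ``group_counts``; weights are recomputed per
    assignment from its control set.
    """
    ctrl = (~perm_cases).astype(np.float32)
    n_u = ctrl @ nonmiss.astype(np.float32)  # (k, m) control genotypes per variant
    m_u = ctrl @ mut.astype(np.float32)  # (k, m) control minor alleles
    q = (m_u + 1.0) / (2.0 * n_u + 2.0)
    n_i = nonmiss.sum(axis=0).astype(np.float32)  # (m,)
    w = np.sqrt(n_i * q * (1.0 - q))  # (k, m)
    scores_u = unique_rows.astype(np.float32) @ (1.0 / w).T  # (u, k)
    case_groups = perm_cases.astype(np.float32) @ group_onehot  # (k, u)

    x = np.empty(perm_cases.shape[0])
    for t in range(perm_cases.shape[0]):
        s = scores_u[:, t]
        order = np.argsort(s, kind="stable")
        so = s[order]
        cg = group_counts[order].astype(float)
        # merge exact score ties across distinct genotype rows -> midranks
        new = np.empty(so.size, dtype=bool)
        new[0] = True
        np.not_equal(so[1:], so[:-1], out=new[1:])
        gid = np.cumsum(new) - 1
        tot = np.bincount(gid, weights=cg)
        start = np.concatenate(([0.0], np.cumsum(tot)[:-1]))
        midrank = (start + (tot + 1.0) / 2.0)[gid]
        x[t] = float(np.dot(midrank, case_groups[t, order]))
    return x


def wss_test(
    genotypes: np.ndarray,
    y,
    cfg: Optional[WssConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> TestResult:
    """WSS burden test of a variant set against a binary phenotype.

    ``genotypes`` is an (n_samples, n_variants) minor-allele dosage matrix
    (-1 = missing).  Missing genotypes contribute no mutation counts and
    are excluded from the per-variant totals entering the weights.
    """
    cfg = cfg or WssConfig()
    rng = rng or np.random.default_rng()
    G = np.asarray(genotypes)
    if G.ndim != 2:
        raise InputError("genotype matrix must be 2-D (samples x variants)")
    yv = _phenotype_array(y)
    keep = yv != MISSING
    G = G[keep]
    yv = yv[keep]
    n = G.shape[0]

    nonmiss = G != MISSING
    with np.errstate(invalid="ignore"):
        maf = np.where(
            nonmiss.sum(axis=0) > 0,
            np.clip(G, 0, None).sum(axis=0) / np.maximum(2 * nonmiss.sum(axis=0), 1),
            0.0,
        )
    maf = np.minimum(maf, 1 - maf)
    sel = (maf > 0) & (maf < cfg.maf_cutoff)
    if not sel.any():
        raise InputError(
            f"no polymorphic variant below the MAF cutoff {cfg.maf_cutoff:g}"
        )
    mut = np.where(nonmiss[:, sel], np.clip(G[:, sel], 0, None), 0).astype(np.int16)
    nm = nonmiss[:, sel]

    unique_rows, inverse = np.unique(mut, axis=0, return_inverse=True)
    group_counts = np.bincount(inverse)
    group_onehot = np.zeros((n, unique_rows.shape[0]), dtype=np.float32)
    group_onehot[np.arange(n), inverse] = 1.0

    case = yv == 1
    x_obs = _wss_x(mut, nm, unique_rows, group_counts, group_onehot, case[None, :])[0]

    x_perm = np.empty(cfg.k)
    chunk = 256
    for start in range(0, cfg.k, chunk):
        size = min(chunk, cfg.k - start)
        perms = np.empty((size, n), dtype=bool)
        for t in range(size):
            perms[t] = rng.permutation(case)
        x_perm[start : start + size] = _wss_x(
            mut, nm, unique_rows, group_counts, group_onehot, perms
        )

    sd = float(np.std(x_perm, ddof=1))
    if sd == 0.0:
        return TestResult(
            statistic=0.0, df=None, p=1.0, method="wss", n=n, flag="constant-scores"
        )
    z = (x_obs - float(np.mean(x_perm))) / sd
    return TestResult(
        statistic=float(z), df=None, p=float(stats.norm.sf(z)), method="wss", n=n
    )


def wss_maf_sweep(
    genotypes: np.ndarray,
    y,
    cfg: Optional[WssConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Cumulative-inclusion WSS sweep over ascending-MAF variant sets.

    Variants are sorted by MAF ascending and included one threshold at a
    time; each row reports the MAF cutoff, the number of variants included
    and the WSS P value for that set.
    """
    cfg = cfg or WssConfig()
    rng = rng or np.random.default_rng()
    G = np.asarray(genotypes)
    yv = _phenotype_array(y)
    nonmiss = G != MISSING
    counts = np.maximum(2 * nonmiss.sum(axis=0), 1)
    maf = np.clip(G, 0, None).sum(axis=0) / counts
    maf = np.minimum(maf, 1 - maf)
    poly = maf > 0
    order = np.argsort(maf[poly], kind="stable")
    cols = np.flatnonzero(poly)[order]
    sorted_maf = maf[cols]

    rows = []
    for i in range(1, cols.size + 1):
        if i < cols.size and sorted_maf[i] == sorted_maf[i - 1]:
            continue  # include whole ties before testing
        subset = G[:, cols[:i]]
        res = wss_test(
            subset, yv, WssConfig(maf_cutoff=0.5, k=cfg.k), rng=rng
        )
        rows.append(
            {
                "maf_cutoff": float(sorted_maf[i - 1]),
                "n_variants": i,
                "z": res.statistic,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
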