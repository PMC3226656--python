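"""Genome-wide sliding-window CDH scan and regional all-pairs scan.

The sliding window pairs each index SNP with the following ``window_n``
SNPs on the same chromosome (windows never span chromosomes and truncate
at the end), reports the minimal pair P value addressed to the index SNP,
and Bonferroni-corrects it by the number of tests actually performed in
that window.  For a chromosome of N polymorphic SNPs the exact total is
``sum_i min(n, N - i) = n*N - n*(n+1)/2`` for ``N > n``.

The regional scan tests all unordered pairs and corrects the minimal P by
``m*(m-1)/2`` for ``m`` analyzed SNPs.  Its counting kernel accumulates
the collapsed 2x2 tables for every pair at once via boolean matrix
products, so regions of tens of SNPs by tens of thousands of samples run
in milliseconds; the per-pair P values come from the same chi-square /
Fisher switching rule as :func:`cdhtest.cdh.cdh_test`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .cdh import TAGGING, CollapseMode, cdh_test, test_2x2
from .core import (
    MISSING,
    GenotypeVector,
    InputError,
    PhenotypeVector,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "ScanRecord",
    "RegionScanResult",
    "expected_test_count",
    "sliding_window_scan",
    "pairwise_region_scan",
]


@dataclass
class ScanConfig:
    window_n: int = 100
    mode: CollapseMode = field(default=TAGGING)
    exact_threshold: int = 5
    maf_range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.window_n < 1:
            raise InputError("window_n must be >= 1")


@dataclass
class ScanRecord:
    """Best pair for one index SNP: minimal raw P over its window and the
    Bonferroni correction by the tests actually performed."""

    chrom: str
    pos: int
    snp_id: str
    partner_id: str
    partner_pos: int
    n_tests: int
    p_raw: float
    p_bonf: float
    method: str


@dataclass
class RegionScanResult:
    snp1_id: str
    snp2_id: str
    p_raw: float
    p_bonf: float
    n_tests: int
    method: str


def expected_test_count(n_snps: int, window_n: int) -> int:
    """Exact number of pair tests on one chromosome with end truncation."""
    if n_snps < 2:
        return 0
    n = min(window_n, n_snps - 1)
    return n * n_snps - n * (n + 1) // 2


def _check_sorted(genotypes: Sequence[GenotypeVector]) -> None:
    for a, b in zip(genotypes, genotypes[1:]):
        if a.chrom == b.chrom and b.pos < a.pos:
            raise InputError(
                f"SNPs not sorted by position: {a.snp_id}@{a.pos} precedes "
                f"{b.snp_id}@{b.pos} on chromosome {a.chrom}"
            )


def _usable(genotypes: Sequence[GenotypeVector], cfg: ScanConfig) -> List[GenotypeVector]:
    kept = []
    for g in genotypes:
        if g.maf == 0.0:
            logger.info("skipping monomorphic SNP %s", g.snp_id)
            continue
        if cfg.maf_range is not None:
            lo, hi = cfg.maf_range
            if not lo <= g.maf <= hi:
                logger.info("skipping SNP %s outside MAF range", g.snp_id)
                continue
        kept.append(g)
    return kept


def sliding_window_scan(
    genotypes: Sequence[GenotypeVector],
    y: PhenotypeVector,
    cfg: Optional[ScanConfig] = None,
) -> List[ScanRecord]:
    """CDH scan of every SNP against its following ``window_n`` SNPs.

    Monomorphic SNPs (and SNPs outside ``maf_range``, if set) are excluded
    before windowing, so the Bonferroni factor counts only performed tests.
    """
    cfg = cfg or ScanConfig()
    if len(genotypes) < 2:
        raise InputError("need at least 2 SNPs to scan")
    _check_sorted(genotypes)
    kept = _usable(genotypes, cfg)

    by_chrom: dict = {}
    for g in kept:
        by_chrom.setdefault(g.chrom, []).append(g)

    records: List[ScanRecord] = []
    for chrom, snps in by_chrom.items():
        for i, gi in enumerate(snps):
            partners = snps[i + 1 : i + 1 + cfg.window_n]
            if not partners:
                continue
            best_p, best_g, best_method = np.inf, None, ""
            for gj in partners:
                res = cdh_test(
                    gi, gj, y, mode=cfg.mode, exact_threshold=cfg.exact_threshold
                )
                if res.p < best_p:
                    best_p, best_g, best_method = res.p, gj, res.method
            records.append(
                ScanRecord(
                    chrom=chrom,
                    pos=gi.pos,
                    snp_id=gi.snp_id,
                    partner_id=best_g.snp_id,
                    partner_pos=best_g.pos,
                    n_tests=len(partners),
                    p_raw=float(best_p),
                    p_bonf=float(min(1.0, best_p * len(partners))),
                    method=best_method,
                )
            )
        logger.info("chromosome %s: %d index SNPs scanned", chrom, len(snps))
    return records


def _pair_p_matrix(
    G: np.ndarray, case: np.ndarray, mode: CollapseMode, exact_threshold: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Raw CDH P values (and method codes) for all SNP pairs of a region.

    Returns (p, is_exact) upper-triangular matrices.  The collapsed 2x2
    for pair (i, j) is accumulated over samples with both genotypes (and
    phenotype) observed, via products of per-dosage indicator matrices.
    """
    m = G.shape[1]
    ind = [np.ascontiguousarray((G == d), dtype=np.float32) for d in (0, 1, 2)]
    nm = np.ascontiguousarray(G != MISSING, dtype=np.float32)

    def counts(mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        a = [x[mask] for x in ind]
        risk = a[2].T @ a[0] + a[0].T @ a[2] + a[1].T @ a[1]
        if mode.mode == "causal":
            risk += a[2].T @ a[1] + a[1].T @ a[2] + a[2].T @ a[2]
        tot = nm[mask].T @ nm[mask]
        # float32 products are exact for counts < 2^24; go back to integers
        return np.rint(risk).astype(np.int64), np.rint(tot).astype(np.int64)

    risk_case, tot_case = counts(case)
    risk_ctrl, tot_ctrl = counts(~case)

    a = risk_case.astype(np.float64)
    b = (tot_case - risk_case).astype(np.float64)
    c = risk_ctrl.astype(np.float64)
    d = (tot_ctrl - risk_ctrl).astype(np.float64)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        r1, r2 = a + b, c + d
        c1, c2 = a + c, b + d
        stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
        min_exp = (
            np.minimum(r1, r2) * np.minimum(c1, c2) / np.where(n > 0, n, 1.0)
        )
    stat = np.where(np.isfinite(stat), stat, 0.0)
    p = stats.chi2.sf(stat, 1)
    p = np.where(c1 == 0, 1.0, p)  # no risk carriers at all
    needs_exact = (min_exp < exact_threshold) & (c1 > 0)
    iu = np.triu_indices(m, k=1)
    exact = np.zeros((m, m), dtype=bool)
    for i, j in zip(*iu):
        if needs_exact[i, j]:
            t = np.array(
                [[a[i, j], b[i, j]], [c[i, j], d[i, j]]], dtype=np.int64
            )
            p[i, j] = test_2x2(t, exact_threshold=exact_threshold).p
            exact[i, j] = True
    return p, exact


def pairwise_region_scan(
    genotypes,
    y: PhenotypeVector,
    mode: CollapseMode = TAGGING,
    exact_threshold: int = 5,
) -> RegionScanResult:
    """All-pairs CDH over a region; minimal P Bonferroni-corrected by
    ``m*(m-1)/2`` tests for ``m`` analyzed (polymorphic) SNPs.

    ``genotypes`` may be a sequence of :class:`GenotypeVector` or an
    (n_samples, m) dosage matrix.
    """
    if isinstance(genotypes, np.ndarray):
        gvs = [
            GenotypeVector(genotypes[:, j], snp_id=f"snp{j}")
            for j in range(genotypes.shape[1])
        ]
    else:
        gvs = list(genotypes)
    gvs = [g for g in gvs if g.maf > 0.0]
    if len(gvs) < 2:
        raise InputError("need at least 2 polymorphic SNPs")
    ok_y = y.values != MISSING
    G = np.column_stack([g.values for g in gvs])[ok_y]
    case = (y.values == 1)[ok_y]

    p, exact = _pair_p_matrix(G, case, mode, exact_threshold)
    m = len(gvs)
    iu = np.triu_indices(m, k=1)
    flat = p[iu]
    best = int(np.argmin(flat))
    i, j = int(iu[0][best]), int(iu[1][best])
    n_tests = m * (m - 1) // 2
    return RegionScanResult(
        snp1_id=gvs[i].snp_id,
        snp2_id=gvs[j].snp_id,
        p_raw=float(flat[best]),
        p_bonf=float(min(1.0, flat[best] * n_tests)),
        n_tests=n_tests,
        method="fisher_exact" if exact[i, j] else "pearson_chi2",
    )
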