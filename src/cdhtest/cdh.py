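"""The collapsed double heterozygosity (CDH) test.

Two physically close low-frequency loss-of-function variants acting
recessively and as compound heterozygotes (CH) produce a characteristic
3x3 cross-genotype pattern: the risk genotypes are the two rare
homozygotes and the double heterozygote.  Collapsing those cells against
everything else yields a 2x2 case/control table and a 1-df chi-square
test that concentrates the association signal.

Two collapsing rules are provided:

* ``causal`` -- for directly genotyped causal variants: every genotype
  carrying two or more minor alleles is risk-collapsed (the "lower
  triangle": cells (2,0), (0,2), (1,1), (2,1), (1,2), (2,2) in dosage
  indices).
* ``tagging`` -- for marker SNPs in LD with unobserved causal alleles:
  only (2,0), (0,2) and (1,1) are risk-collapsed.  The remaining
  double-minor genotypes join the reference group, because a chromosome
  carrying both tag alleles does not tag a causal allele when the causal
  alleles sit on different haplotypes.

With both MAFs below ~5% and negligible LD the extra three cells are
essentially unpopulated, so the tagging rule can also be used on causal
data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Tuple

import numpy as np

from .core import (
    DegenerateDataError,
    GenotypeVector,
    PairCounts,
    PhenotypeVector,
    TestResult,
    cross_tabulate,
    fisher_exact_2x2,
    pearson_chi2,
)

__all__ = [
    "CAUSAL_RISK_CELLS",
    "TAGGING_RISK_CELLS",
    "CollapseMode",
    "CAUSAL",
    "TAGGING",
    "get_mode",
    "CollapsedTable",
    "collapse",
    "test_2x2",
    "cdh_test",
]

Cell = Tuple[int, int]

CAUSAL_RISK_CELLS: FrozenSet[Cell] = frozenset(
    {(2, 0), (0, 2), (1, 1), (2, 1), (1, 2), (2, 2)}
)
TAGGING_RISK_CELLS: FrozenSet[Cell] = frozenset({(2, 0), (0, 2), (1, 1)})


@dataclass(frozen=True)
class CollapseMode:
    """A named set of risk cells in the 3x3 dosage-by-dosage table."""

    mode: str
    risk_cells: FrozenSet[Cell]

    def mask(self) -> np.ndarray:
        m = np.zeros((3, 3), dtype=bool)
        for i, j in self.risk_cells:
            m[i, j] = True
        return m


CAUSAL = CollapseMode("causal", CAUSAL_RISK_CELLS)
TAGGING = CollapseMode("tagging", TAGGING_RISK_CELLS)
_MODES = {"causal": CAUSAL, "tagging": TAGGING}


def get_mode(name: str) -> CollapseMode:
    try:
        return _MODES[name]
    except KeyError:
        raise ValueError(f"unknown collapse mode {name!r}; use 'causal' or 'tagging'")


@dataclass
class CollapsedTable:
    """2x2 counts: rows (case, control) x columns (risk, reference)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("collapsed table must be 2x2")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def collapse(pc: PairCounts, mode: CollapseMode) -> CollapsedTable:
    """Collapse 3x3 case/control counts to the 2x2 risk/reference table."""
    m = mode.mask()
    risk_d = int(pc.D[m].sum())
    risk_u = int(pc.U[m].sum())
    return CollapsedTable(
        np.array(
            [
                [risk_d, int(pc.D.sum()) - risk_d],
                [risk_u, int(pc.U.sum()) - risk_u],
            ]
        )
    )


def test_2x2(counts, exact_threshold: int = 5, exact_rule: str = "expected") -> TestResult:
    """1-df Pearson chi-square on a 2x2 table, switching to Fisher's exact
    test for sparse tables.

    ``exact_rule="expected"`` switches when the smallest expected cell
    count falls below ``exact_threshold`` (Cochran's convention);
    ``"observed"`` switches on the smallest observed cell instead, the
    rule phrased in terms of "the number of individuals in the smallest
    cell".  The observed rule keeps the chi-square in play for strongly
    associated sparse-margin tables and is noticeably less conservative
    at stringent significance thresholds.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    n = t.sum()
    if n == 0:
        raise DegenerateDataError("empty table")
    if exact_rule == "expected":
        crit = np.outer(t.sum(axis=1), t.sum(axis=0)).min() / n
    elif exact_rule == "observed":
        crit = t.min()
    else:
        raise ValueError("exact_rule must be 'expected' or 'observed'")
    if crit < exact_threshold:
        return fisher_exact_2x2(np.asarray(counts))
    try:
        return pearson_chi2(t)
    except DegenerateDataError:
        # an empty margin at large n (e.g. nobody in the reference column)
        return fisher_exact_2x2(np.asarray(counts))


def cdh_test(
    g1: GenotypeVector,
    g2: GenotypeVector,
    y: PhenotypeVector,
    mode: CollapseMode = CAUSAL,
    exact_threshold: int = 5,
    exact_rule: str = "expected",
) -> TestResult:
    """CDH test of one SNP pair.

    Cross-tabulates, collapses per ``mode`` and runs the 2x2 test.  When no
    individual carries a risk genotype the result is flagged
    ``"no-risk-genotypes"`` with p = 1 rather than skipped, so that scan
    bookkeeping stays exact.  A risk column populated in only one phenotype
    class falls through to Fisher's exact test.
    """
    pc = cross_tabulate(g1, g2, y)
    ct = collapse(pc, mode)
    if ct.counts[:, 0].sum() == 0:
        return TestResult(
            statistic=0.0,
            df=1,
            p=1.0,
            method="pearson_chi2",
            n=pc.total,
            flag="no-risk-genotypes",
        )
    res = test_2x2(ct.counts, exact_threshold=exact_threshold, exact_rule=exact_rule)
    res.n = pc.total
    return res
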