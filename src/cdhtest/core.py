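"""Shared contingency-table machinery for case/control genotype tests.

Conventions used throughout the package:

* Genotypes are minor-allele dosages in ``{0, 1, 2}``; ``-1`` marks missing.
  Vectors are re-oriented to the minor allele at construction (MAF <= 0.5);
  an exact tie at 0.5 keeps the input allele order.
* Phenotypes are binary, ``1`` = case and ``0`` = control; ``-1`` marks
  missing.
* No Yates continuity correction is applied anywhere: the power theory for
  the collapsed tests is built on the plain Pearson statistic.
* Missing data are handled pairwise complete-case per test, and every
  result carries the usable sample count ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

MISSING: int = -1

__all__ = [
    "MISSING",
    "InputError",
    "DegenerateDataError",
    "GenotypeVector",
    "PhenotypeVector",
    "PairCounts",
    "TestResult",
    "cross_tabulate",
    "pearson_chi2",
    "fisher_exact_2x2",
    "single_snp_2df",
    "cochran_armitage_trend",
]


class InputError(ValueError):
    """Malformed or inconsistent input."""


class DegenerateDataError(InputError):
    """Input is formally valid but carries no testable information."""


def _as_dosage(values: Sequence, allowed=(0, 1, 2)) -> np.ndarray:
    """Coerce to an int8 dosage array, mapping NaN to the missing marker."""
    arr = np.asarray(values)
    if arr.dtype.kind == "f":
        nan = np.isnan(arr)
        if not np.all(nan | (arr == np.round(arr))):
            raise InputError("dosage entries must be integral or NaN")
        arr = np.where(nan, MISSING, arr)
    out = np.asarray(arr).astype(np.int8)
    ok = np.isin(out, tuple(allowed) + (MISSING,))
    if not ok.all():
        bad = np.unique(np.asarray(out)[~ok])
        raise InputError(
            f"entries must be in {sorted(allowed)} or missing (-1/NaN); got {bad.tolist()}"
        )
    return out


@dataclass
class GenotypeVector:
    """Per-sample minor-allele dosage for one biallelic SNP.

    ``chrom``/``pos`` are optional and only consumed by the genome scanner.
    """

    values: np.ndarray
    snp_id: str = ""
    chrom: str = ""
    pos: int = 0
    maf: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = _as_dosage(self.values)
        obs = self.values[self.values != MISSING]
        freq = float(obs.mean()) / 2.0 if obs.size else 0.0
        if freq > 0.5:  # orient to the minor allele; a tie keeps input order
            keep = self.values != MISSING
            self.values = np.where(keep, 2 - self.values, MISSING).astype(np.int8)
            freq = 1.0 - freq
        self.maf = freq

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n_observed(self) -> int:
        return int((self.values != MISSING).sum())


@dataclass
class PhenotypeVector:
    """Binary case/control status per sample (1 = case, 0 = control)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_dosage(self.values, allowed=(0, 1))
        obs = self.values[self.values != MISSING]
        if obs.size == 0 or not ((obs == 1).any() and (obs == 0).any()):
            raise DegenerateDataError(
                "phenotype must contain at least one case and one control"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def case_mask(self) -> np.ndarray:
        return self.values == 1

    @property
    def n_cases(self) -> int:
        return int((self.values == 1).sum())


@dataclass
class PairCounts:
    """3x3 cross-genotype counts; rows index SNP1 dosage, columns SNP2.

    ``D`` holds cases, ``U`` controls.
    """

    D: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.int64)
        self.U = np.asarray(self.U, dtype=np.int64)
        if self.D.shape != (3, 3) or self.U.shape != (3, 3):
            raise InputError("PairCounts matrices must be 3x3")
        if (self.D < 0).any() or (self.U < 0).any():
            raise InputError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.D.sum() + self.U.sum())


@dataclass
class TestResult:
    """Outcome of a contingency test.

    ``df`` is ``None`` for exact tests.  ``flag`` records degenerate
    conditions (e.g. ``"no-risk-genotypes"``) that callers may want to
    surface.
    """

    statistic: float
    df: Optional[int]
    p: float
    method: str
    n: Optional[int] = None
    flag: Optional[str] = None


def cross_tabulate(
    g1: GenotypeVector, g2: GenotypeVector, y: PhenotypeVector
) -> PairCounts:
    """Tabulate joint genotype counts separately for cases and controls.

    Samples missing any of the three values are excluded (pairwise
    complete-case).
    """
    if not (len(g1) == len(g2) == len(y)):
        raise InputError(
            f"length mismatch: genotypes {len(g1)}/{len(g2)}, phenotype {len(y)}"
        )
    ok = (g1.values != MISSING) & (g2.values != MISSING) & (y.values != MISSING)
    if not ok.any():
        raise DegenerateDataError("no sample with complete genotypes and phenotype")
    idx = 9 * y.values[ok].astype(np.int64) + 3 * g1.values[ok] + g2.values[ok]
    counts = np.bincount(idx, minlength=18)
    return PairCounts(D=counts[9:].reshape(3, 3), U=counts[:9].reshape(3, 3))


def _drop_empty_margins(table: np.ndarray) -> np.ndarray:
    t = table[table.sum(axis=1) > 0, :]
    return t[:, t.sum(axis=0) > 0]


def pearson_chi2(table) -> TestResult:
    """Pearson chi-square on a count table, no continuity correction.

    Rows/columns with zero marginal are dropped before the degrees of
    freedom are computed; if fewer than two non-empty rows or columns
    remain the table is degenerate.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise InputError("expected a 2-D count table")
    if (t < 0).any():
        raise InputError("counts must be nonnegative")
    t = _drop_empty_margins(t)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise DegenerateDataError("fewer than 2 non-empty rows or columns")
    res = stats.chi2_contingency(t, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p=float(res.pvalue),
        method="pearson_chi2",
        n=int(t.sum()),
    )


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities (fixed margins) of all
    tables no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InputError("Fisher exact test requires a 2x2 table")
    if (t < 0).any():
        raise InputError("counts must be nonnegative")
    if t.dtype.kind == "f":
        if not np.all(t == np.round(t)):
            raise InputError("counts must be integers")
        t = t.astype(np.int64)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    stat = float(odds) if np.isfinite(odds) else float("inf")
    if np.isnan(odds):
        stat = 0.0
    return TestResult(statistic=stat, df=None, p=float(p), method="fisher_exact", n=int(t.sum()))


def _tabulate_single(g: GenotypeVector, y: PhenotypeVector) -> np.ndarray:
    if len(g) != len(y):
        raise InputError("genotype/phenotype length mismatch")
    ok = (g.values != MISSING) & (y.values != MISSING)
    if not ok.any():
        raise DegenerateDataError("no sample with complete genotype and phenotype")
    idx = 3 * y.values[ok].astype(np.int64) + g.values[ok]
    c = np.bincount(idx, minlength=6)
    return np.array([c[3:], c[:3]])  # rows: cases, controls


def single_snp_2df(g: GenotypeVector, y: PhenotypeVector) -> TestResult:
    """Genotypic 2x3 chi-square for one SNP (2 df, reduced if a class is absent)."""
    return pearson_chi2(_tabulate_single(g, y))


def cochran_armitage_trend(g: GenotypeVector, y: PhenotypeVector) -> TestResult:
    """Cochran-Armitage trend test with dosage scores (0, 1, 2), 1 df."""
    table = _tabulate_single(g, y)
    r = table[0].astype(float)  # cases per genotype class
    n_k = table.sum(axis=0).astype(float)
    s = np.array([0.0, 1.0, 2.0])
    N = n_k.sum()
    R = r.sum()
    if R == 0 or R == N:
        raise DegenerateDataError("phenotype has a single class")
    var_term = N * (s * s * n_k).sum() - (s * n_k).sum() ** 2
    if var_term <= 0:
        raise DegenerateDataError("zero genotype variance")
    num = N * (N * (s * r).sum() - R * (s * n_k).sum()) ** 2
    den = R * (N - R) * var_term
    stat = num / den
    return TestResult(
        statistic=float(stat),
        df=1,
        p=float(stats.chi2.sf(stat, 1)),
        method="trend",
        n=int(N),
    )
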