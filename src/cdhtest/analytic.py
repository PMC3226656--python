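"""Closed-form power theory for the recessive + compound-heterozygote model.

For two independent low-frequency SNPs in Hardy-Weinberg equilibrium with
minor allele frequencies ``q1`` and ``q2``, the joint genotype frequencies
are the outer product of the per-SNP HWE vectors::

    R[i, j] = HWE(q1)[i] * HWE(q2)[j],    HWE(q) = ((1-q)^2, 2q(1-q), q^2)

The disease model puts penetrance ``alpha * beta`` (baseline prevalence
times genotype relative risk, GRR) on a declared set of risk genotypes and
``alpha`` elsewhere.  Expected case counts at total (population-based)
sample size ``n`` are ``n * R * F`` elementwise, control counts
``n * R * (1 - F)``.  The "expected P value" of a test is the chi-square
upper-tail probability of the Pearson statistic evaluated on these
expected (real-valued) tables -- the noncentrality-style construction used
to compare the collapsed 1-df test against the single-SNP 2-df test.

A useful identity: with ``q1 = q2`` the compound-heterozygote genotype is
exactly 4 times more frequent than either single-SNP rare homozygote,
which is what drives the power advantage of collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .cdh import CAUSAL, CollapseMode

__all__ = [
    "ModelError",
    "PairFrequencyModel",
    "FrequencyMatrix",
    "PenetranceModel",
    "ExpectedCounts",
    "hwe_genotype_freqs",
    "hwe_pair_frequencies",
    "ch_to_homozygote_ratio",
    "joint_penetrance",
    "expected_counts",
    "expected_cdh_chi2",
    "expected_cdh_p",
    "expected_single_snp_chi2",
    "expected_single_snp_p",
    "grr_threshold",
]

LOG10E = float(np.log10(np.e))


class ModelError(ValueError):
    """Invalid model parameters."""


@dataclass(frozen=True)
class PairFrequencyModel:
    """Minor allele frequencies of two independent HWE SNPs."""

    q1: float
    q2: float

    def __post_init__(self) -> None:
        for q in (self.q1, self.q2):
            if not 0.0 < q <= 0.5:
                raise ModelError(f"MAF must be in (0, 0.5], got {q}")


@dataclass
class FrequencyMatrix:
    """3x3 joint genotype frequencies summing to 1."""

    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (3, 3):
            raise ModelError("frequency matrix must be 3x3")
        if (self.R < 0).any() or abs(self.R.sum() - 1.0) > 1e-12:
            raise ModelError("frequencies must be nonnegative and sum to 1")


@dataclass
class PenetranceModel:
    """Baseline prevalence ``alpha`` with GRR ``beta`` on the risk cells."""

    alpha: float
    beta: float
    mode: CollapseMode = field(default=CAUSAL)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ModelError("alpha must be in (0, 1)")
        if self.beta < 0:
            raise ModelError("beta must be nonnegative")
        if self.alpha * self.beta > 1.0:
            raise ModelError(
                f"risk penetrance alpha*beta = {self.alpha * self.beta:.3g} exceeds 1"
            )


@dataclass
class ExpectedCounts:
    """Expected (real-valued) 3x3 case and control counts at size ``n``."""

    D: np.ndarray
    U: np.ndarray
    n: float


def hwe_genotype_freqs(q: float) -> np.ndarray:
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def hwe_pair_frequencies(m: PairFrequencyModel) -> FrequencyMatrix:
    """Joint genotype frequencies of two independent HWE SNPs."""
    return FrequencyMatrix(np.outer(hwe_genotype_freqs(m.q1), hwe_genotype_freqs(m.q2)))


def ch_to_homozygote_ratio(m: PairFrequencyModel) -> float:
    """Frequency of the compound heterozygote over the SNP1 rare homozygote.

    Equals ``4 q2 (1-q1) / (q1 (1-q2))``; exactly 4 whenever ``q1 = q2``.
    """
    R = hwe_pair_frequencies(m).R
    if R[2, 0] == 0:
        raise ModelError("SNP1 homozygote frequency is zero")
    return float(R[1, 1] / R[2, 0])


def joint_penetrance(p: PenetranceModel) -> np.ndarray:
    """3x3 penetrance matrix: ``alpha*beta`` on risk cells, ``alpha`` elsewhere."""
    F = np.full((3, 3), p.alpha)
    F[p.mode.mask()] = p.alpha * p.beta
    return F


def expected_counts(R: FrequencyMatrix, F: np.ndarray, n: float) -> ExpectedCounts:
    """Expected case/control counts: ``D = n R*F``, ``U = n R*(1-F)``."""
    F = np.asarray(F, dtype=float)
    if F.shape != R.R.shape:
        raise ModelError("shape mismatch between R and F")
    D = n * R.R * F
    U = n * R.R * (1.0 - F)
    return ExpectedCounts(D=D, U=U, n=float(n))


def _pearson_stat(table: np.ndarray) -> tuple[float, int]:
    """Pearson statistic and df on a real-valued table (empty margins dropped)."""
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0, :]
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ModelError("degenerate expected table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    if stat < 1e-12:  # float noise from the expected-count products
        stat = 0.0
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, df


def _expected_collapsed(
    m: PairFrequencyModel, p: PenetranceModel, n: float, mode: CollapseMode
) -> np.ndarray:
    ec = expected_counts(hwe_pair_frequencies(m), joint_penetrance(p), n)
    mask = mode.mask()
    risk_d = ec.D[mask].sum()
    risk_u = ec.U[mask].sum()
    return np.array(
        [[risk_d, ec.D.sum() - risk_d], [risk_u, ec.U.sum() - risk_u]]
    )


def expected_cdh_chi2(
    m: PairFrequencyModel,
    p: PenetranceModel,
    n: float,
    mode: CollapseMode = CAUSAL,
) -> float:
    """Expected 1-df CDH chi-square on the collapsed expected counts."""
    stat, _ = _pearson_stat(_expected_collapsed(m, p, n, mode))
    return stat


def expected_cdh_p(
    m: PairFrequencyModel,
    p: PenetranceModel,
    n: float,
    mode: CollapseMode = CAUSAL,
    log10: bool = False,
) -> float:
    """Expected CDH P value (chi-square tail at 1 df of the expected statistic).

    With ``log10=True`` returns log10(P), which does not underflow for
    extreme statistics.
    """
    stat = expected_cdh_chi2(m, p, n, mode)
    if log10:
        return float(stats.chi2.logsf(stat, 1) * LOG10E)
    return float(stats.chi2.sf(stat, 1))


def expected_single_snp_chi2(
    q: float, p: PenetranceModel, n: float
) -> tuple[float, int]:
    """Expected 2x3 single-SNP chi-square (partner SNP marginalized out).

    The partner is modeled at the same frequency ``q`` so the comparison
    with the collapsed test is at matched parameters.
    """
    m = PairFrequencyModel(q, q)
    ec = expected_counts(hwe_pair_frequencies(m), joint_penetrance(p), n)
    table = np.array([ec.D.sum(axis=1), ec.U.sum(axis=1)])
    return _pearson_stat(table)


def expected_single_snp_p(
    q: float, p: PenetranceModel, n: float, log10: bool = False
) -> float:
    """Expected single-SNP P value (chi-square tail at 2 df)."""
    stat, df = expected_single_snp_chi2(q, p, n)
    if log10:
        return float(stats.chi2.logsf(stat, df) * LOG10E)
    return float(stats.chi2.sf(stat, df))


def grr_threshold(
    q: float,
    alpha: float,
    n: float,
    target_p: float,
    test: str = "cdh",
    mode: CollapseMode = CAUSAL,
    tol: float = 1e-3,
) -> float:
    """Smallest GRR at which the expected P reaches ``target_p`` (bisection).

    The nominal search bracket is [1, 50], capped at ``1/alpha`` where the
    penetrance model stops being valid.
    """
    if test not in ("cdh", "single"):
        raise ValueError("test must be 'cdh' or 'single'")
    if target_p >= 1.0:
        return 1.0
    log_target = float(np.log10(target_p))

    def log_p(beta: float) -> float:
        pen = PenetranceModel(alpha=alpha, beta=beta, mode=mode)
        if test == "cdh":
            return expected_cdh_p(PairFrequencyModel(q, q), pen, n, mode, log10=True)
        return expected_single_snp_p(q, pen, n, log10=True)

    lo, hi = 1.0, min(50.0, 1.0 / alpha)
    if log_p(hi) - log_target > 0:
        raise ModelError(
            f"expected P does not reach {target_p:g} for GRR in [{lo}, {hi:g}]"
        )
    return float(optimize.brentq(lambda b: log_p(b) - log_target, lo, hi, xtol=tol))
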