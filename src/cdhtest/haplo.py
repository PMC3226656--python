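"""Two-locus haplotype inference, LD statistics, and the cis/trans follow-up.

The EM algorithm estimates four haplotype frequencies from unphased
two-SNP genotypes.  Only the double-heterozygote genotype class is
phase-ambiguous: it is fractionally assigned to the coupling
(ab/AB, "cis") and repulsion (aB/Ab, "trans") resolutions each E-step in
proportion to their current likelihood.

After a significant collapsed-pair signal, the follow-up question is
whether the double heterozygotes driving it are true compound
heterozygotes (CH: the two minor alleles on opposite chromosomes) rather
than cis double heterozygotes (DH: both on one chromosome, phenotypically
a single-allele carrier under the CH model).  ``ch_vs_dh_test`` contrasts
case/control frequencies between CH- and DH-assigned double heterozygotes.

Note a structural limitation at exactly two loci: every double
heterozygote shares the same cis/trans posterior, so hard max-posterior
assignment puts all of them in one class and the CH-vs-DH table cannot be
formed from unphased genotypes alone.  The test therefore accepts a
per-individual ``trans_mask`` carrying phase information (from statistical
phasing over a wider marker set, or from a phased generator); without it
the EM path raises a degenerate-data error explaining the situation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .cdh import test_2x2
from .core import (
    MISSING,
    DegenerateDataError,
    GenotypeVector,
    InputError,
    PhenotypeVector,
    TestResult,
)
from .simulate import HaplotypeModel

__all__ = [
    "ConvergenceError",
    "EMResult",
    "LDStats",
    "em_two_locus",
    "ld_stats",
    "trans_posterior",
    "assign_diplotypes",
    "ch_vs_dh_test",
]

# haplotype index: bit 1 = minor allele at locus 1, bit 0 = minor at locus 2
_HAP_DOSAGE1 = np.array([0, 0, 1, 1])
_HAP_DOSAGE2 = np.array([0, 1, 0, 1])


class ConvergenceError(RuntimeError):
    """EM failed to converge; ``last`` carries the final iterate."""

    def __init__(self, message: str, last: HaplotypeModel):
        super().__init__(message)
        self.last = last


@dataclass
class EMResult:
    model: HaplotypeModel
    loglik_trace: List[float]
    n_iter: int
    converged: bool


@dataclass
class LDStats:
    r2: float
    dprime: float
    model: HaplotypeModel
    flag: Optional[str] = None


def _genotype_counts(g1: GenotypeVector, g2: GenotypeVector) -> np.ndarray:
    if len(g1) != len(g2):
        raise InputError("genotype length mismatch")
    ok = (g1.values != MISSING) & (g2.values != MISSING)
    if ok.sum() < 10:
        raise InputError("need at least 10 samples with both genotypes observed")
    idx = 3 * g1.values[ok].astype(np.int64) + g2.values[ok]
    return np.bincount(idx, minlength=9).reshape(3, 3)


def _genotype_probs(freqs: np.ndarray) -> np.ndarray:
    """P(genotype i, j) from random union of two haplotypes."""
    probs = np.zeros((3, 3))
    for h in range(4):
        for k in range(4):
            i = _HAP_DOSAGE1[h] + _HAP_DOSAGE1[k]
            j = _HAP_DOSAGE2[h] + _HAP_DOSAGE2[k]
            probs[i, j] += freqs[h] * freqs[k]
    return probs


def _loglik(counts: np.ndarray, freqs: np.ndarray) -> float:
    probs = _genotype_probs(freqs)
    mask = counts > 0
    if (probs[mask] <= 0).any():
        return -np.inf
    return float((counts[mask] * np.log(probs[mask])).sum())


def em_two_locus(
    g1: GenotypeVector,
    g2: GenotypeVector,
    tol: float = 1e-8,
    max_iter: int = 1000,
    full_output: bool = False,
):
    """Maximum-likelihood two-locus haplotype frequencies by EM.

    Initialized at linkage-equilibrium product frequencies; converged when
    the largest frequency change is below ``tol``.  With no double
    heterozygotes present the first M-step is already the closed-form
    counting solution.
    """
    counts = _genotype_counts(g1, g2)
    n = counts.sum()
    p1 = (counts * np.arange(3)[:, None]).sum() / (2 * n)
    p2 = (counts * np.arange(3)[None, :]).sum() / (2 * n)
    freqs = np.array(
        [(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p2), p1 * p2], dtype=float
    )

    # haplotype contributions from the eight unambiguous genotype classes
    base = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if (i, j) == (1, 1):
                continue
            c = counts[i, j]
            if c == 0:
                continue
            a1 = (1 if i >= 1 else 0, 1 if i == 2 else 0)  # locus-1 alleles
            a2 = (1 if j >= 1 else 0, 1 if j == 2 else 0)  # locus-2 alleles
            base[2 * a1[0] + a2[0]] += c
            base[2 * a1[1] + a2[1]] += c
    n_dh = counts[1, 1]

    trace = [_loglik(counts, freqs)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cis = freqs[0] * freqs[3]
        trans = freqs[1] * freqs[2]
        w = 0.5 if cis + trans == 0 else cis / (cis + trans)
        c = base.copy()
        c[0] += n_dh * w
        c[3] += n_dh * w
        c[1] += n_dh * (1 - w)
        c[2] += n_dh * (1 - w)
        new = c / (2 * n)
        delta = float(np.abs(new - freqs).max())
        freqs = new
        trace.append(_loglik(counts, freqs))
        if delta < tol:
            converged = True
            break
    model = HaplotypeModel(freqs)
    if not converged:
        raise ConvergenceError(
            f"EM did not converge in {max_iter} iterations", last=model
        )
    if full_output:
        return EMResult(model=model, loglik_trace=trace, n_iter=it, converged=True)
    return model


def ld_stats(hm: HaplotypeModel) -> LDStats:
    """r^2 and D' from haplotype frequencies; monomorphic loci are flagged
    and reported as r^2 = 0 by convention."""
    flag = None
    if hm.p1 in (0.0, 1.0) or hm.p2 in (0.0, 1.0):
        flag = "monomorphic"
    return LDStats(r2=hm.r2, dprime=hm.dprime, model=hm, flag=flag)


def trans_posterior(hm: HaplotypeModel) -> float:
    """Probability that a double heterozygote is trans (CH) under ``hm``."""
    cis = hm.freqs[0] * hm.freqs[3]
    trans = hm.freqs[1] * hm.freqs[2]
    if cis + trans == 0:
        raise DegenerateDataError("double-heterozygote probability is zero")
    return float(trans / (cis + trans))


def assign_diplotypes(
    g1: GenotypeVector, g2: GenotypeVector, hm: HaplotypeModel
) -> pd.DataFrame:
    """Most-probable ordered haplotype pair per sample with its posterior.

    All genotype classes except the double heterozygote are phase-certain
    (posterior 1); double heterozygotes get the shared cis/trans posterior.
    Missing genotypes yield a row of -1 haplotypes with posterior NaN.
    """
    n = len(g1)
    h1 = np.full(n, -1, dtype=int)
    h2 = np.full(n, -1, dtype=int)
    post = np.full(n, np.nan)
    ok = (g1.values != MISSING) & (g2.values != MISSING)
    d1 = g1.values
    d2 = g2.values
    lo1 = (d1 == 2).astype(int)
    hi1 = (d1 >= 1).astype(int)
    lo2 = (d2 == 2).astype(int)
    hi2 = (d2 >= 1).astype(int)
    h1[ok] = (2 * hi1 + hi2)[ok]
    h2[ok] = (2 * lo1 + lo2)[ok]
    post[ok] = 1.0
    dh = ok & (d1 == 1) & (d2 == 1)
    if dh.any():
        pt = trans_posterior(hm)
        if pt >= 0.5:  # repulsion: aB / Ab
            h1[dh], h2[dh], post[dh] = 1, 2, pt
        else:  # coupling: ab / AB
            h1[dh], h2[dh], post[dh] = 0, 3, 1 - pt
    return pd.DataFrame({"hap1": h1, "hap2": h2, "posterior": post})


def ch_vs_dh_test(
    g1: GenotypeVector,
    g2: GenotypeVector,
    y: PhenotypeVector,
    hm: Optional[HaplotypeModel] = None,
    trans_mask: Optional[np.ndarray] = None,
    exact_threshold: int = 5,
) -> TestResult:
    """Contrast case/control frequencies between CH (trans) and DH (cis)
    double heterozygotes.

    ``trans_mask`` marks, per sample, whether the two minor alleles sit on
    opposite chromosomes; it is required in practice (see module note).
    Without it, double heterozygotes are hard-assigned by the EM posterior,
    which at two loci places all of them in one class and raises.
    """
    if not (len(g1) == len(g2) == len(y)):
        raise InputError("length mismatch")
    ok = (g1.values != MISSING) & (g2.values != MISSING) & (y.values != MISSING)
    dh = ok & (g1.values == 1) & (g2.values == 1)
    if not dh.any():
        raise DegenerateDataError("no double heterozygotes present")

    if trans_mask is None:
        hm = hm if hm is not None else em_two_locus(g1, g2)
        is_trans = np.full(len(g1), trans_posterior(hm) >= 0.5)
    else:
        is_trans = np.asarray(trans_mask, dtype=bool)
        if is_trans.shape != (len(g1),):
            raise InputError("trans_mask must have one entry per sample")

    ch = dh & is_trans
    cis = dh & ~is_trans
    if not ch.any() or not cis.any():
        raise DegenerateDataError(
            "only one of the CH/DH classes is populated; at two loci the "
            "cis/trans split requires phase information (trans_mask)"
        )
    case = y.values == 1
    table = np.array(
        [
            [int((ch & case).sum()), int((cis & case).sum())],
            [int((ch & ~case).sum()), int((cis & ~case).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("CH-vs-DH table has an empty margin")
    return test_2x2(table, exact_threshold=exact_threshold)
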