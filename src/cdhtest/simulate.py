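"""Synthetic genotype/phenotype generation under the recessive + CH model.

Three generators cover the study designs used throughout the package:

* independent HWE SNP pairs at chosen minor allele frequencies, with a
  binary phenotype whose probability is ``alpha*grr`` on the risk
  genotypes and ``alpha`` elsewhere;
* LD-linked pairs drawn from explicit two-locus haplotype frequencies,
  including a constructor that hits a target r^2 between a low-frequency
  causal SNP and a (usually commoner) tagging SNP;
* multi-SNP regions assembled from a founder-haplotype pool, giving
  realistic intra-region LD, with a subset of low-frequency variants
  flagged causal under the recessive-set model (risk for carriers of any
  causal homozygote or a compound heterozygote across two causal sites).

Reproducibility: every public generator takes an explicit
``numpy.random.Generator``; the replicate loops derive one substream per
(seed, setting, replicate) so runs replay bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cdh import CAUSAL, TAGGING, CollapseMode, cdh_test
from .core import (
    DegenerateDataError,
    GenotypeVector,
    InputError,
    PhenotypeVector,
    cochran_armitage_trend,
)

__all__ = [
    "FeasibilityError",
    "HaplotypeModel",
    "product_haplotypes",
    "max_r2",
    "haplotypes_for_target_r2",
    "simulate_hwe_pair",
    "simulate_two_locus",
    "simulate_linked_quartet",
    "simulate_phenotype_ch",
    "SimConfig",
    "uniform_maf_sampler",
    "chip_maf_sampler",
    "power_table",
    "RegionModel",
    "RegionData",
    "recessive_set_exposure",
    "simulate_region",
    "region_benchmark",
]

MafSampler = Callable[[np.random.Generator], float]


class FeasibilityError(ValueError):
    """Requested LD is not attainable for the given allele frequencies."""

    def __init__(self, message: str, r2_max: float):
        super().__init__(message)
        self.r2_max = r2_max


@dataclass
class HaplotypeModel:
    """Two-locus haplotype frequencies, ordered (ab, aB, Ab, AB).

    Index bit 1 (value 2) is the minor allele at locus 1, bit 0 the minor
    allele at locus 2.  ``r2`` and ``dprime`` are derived properties.
    """

    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,):
            raise InputError("need 4 haplotype frequencies")
        if (self.freqs < -1e-12).any() or abs(self.freqs.sum() - 1.0) > 1e-9:
            raise InputError("haplotype frequencies must be nonnegative and sum to 1")
        self.freqs = np.clip(self.freqs, 0.0, 1.0)

    @property
    def p1(self) -> float:
        """Minor allele frequency at locus 1."""
        return float(self.freqs[2] + self.freqs[3])

    @property
    def p2(self) -> float:
        """Minor allele frequency at locus 2."""
        return float(self.freqs[1] + self.freqs[3])

    @property
    def d(self) -> float:
        """Coefficient of linkage disequilibrium D = f_AB - p1 p2."""
        return float(self.freqs[3] - self.p1 * self.p2)

    @property
    def r2(self) -> float:
        p1, p2 = self.p1, self.p2
        den = p1 * (1 - p1) * p2 * (1 - p2)
        if den <= 0:
            return 0.0
        return float(self.d**2 / den)

    @property
    def dprime(self) -> float:
        d = self.d
        p1, p2 = self.p1, self.p2
        if d == 0:
            return 0.0
        if d > 0:
            dmax = min(p1 * (1 - p2), (1 - p1) * p2)
        else:
            dmax = min(p1 * p2, (1 - p1) * (1 - p2))
        return float(abs(d) / dmax) if dmax > 0 else 0.0


def product_haplotypes(q1: float, q2: float) -> HaplotypeModel:
    """Linkage-equilibrium haplotype frequencies (r^2 = 0)."""
    return HaplotypeModel(
        np.array(
            [
                (1 - q1) * (1 - q2),
                (1 - q1) * q2,
                q1 * (1 - q2),
                q1 * q2,
            ]
        )
    )


def max_r2(q_causal: float, q_tag: float) -> float:
    """Largest r^2 attainable with positive D for the given MAF pair."""
    d_max = min(q_causal * (1 - q_tag), (1 - q_causal) * q_tag)
    den = q_causal * (1 - q_causal) * q_tag * (1 - q_tag)
    return float(d_max**2 / den)


def haplotypes_for_target_r2(
    q_causal: float, q_tag: float, r2_target: float
) -> HaplotypeModel:
    """Haplotype frequencies achieving ``r2_target`` with positive coupling.

    The causal minor allele is placed preferentially on tag-minor-allele
    haplotypes (D > 0); at the feasibility bound it rides exclusively on
    them.  Raises :class:`FeasibilityError` (carrying the attainable
    maximum) when the target exceeds the bound imposed by the allele
    frequencies.
    """
    if not (0 < q_causal <= 0.5 and 0 < q_tag <= 0.5):
        raise InputError("allele frequencies must be in (0, 0.5]")
    if not 0 <= r2_target <= 1:
        raise InputError("r2 must be in [0, 1]")
    bound = max_r2(q_causal, q_tag)
    if r2_target > bound + 1e-12:
        raise FeasibilityError(
            f"r2 = {r2_target:g} infeasible for MAFs ({q_causal:g}, {q_tag:g}); "
            f"maximum attainable is {bound:.6g}",
            r2_max=bound,
        )
    den = q_causal * (1 - q_causal) * q_tag * (1 - q_tag)
    d = float(np.sqrt(min(r2_target, bound) * den))
    f_ab_minor = q_causal * q_tag + d
    freqs = np.array(
        [
            (1 - q_causal) * (1 - q_tag) + d,
            (1 - q_causal) * q_tag - d,
            q_causal * (1 - q_tag) - d,
            f_ab_minor,
        ]
    )
    return HaplotypeModel(np.clip(freqs, 0.0, None) / np.clip(freqs, 0.0, None).sum())


def simulate_hwe_pair(
    q1: float, q2: float, n: int, rng: np.random.Generator
) -> Tuple[GenotypeVector, GenotypeVector]:
    """Independent HWE dosages: binomial(2, q) per SNP per sample."""
    for q in (q1, q2):
        if not 0 < q <= 0.5:
            raise InputError("MAF must be in (0, 0.5]")
    g1 = rng.binomial(2, q1, size=n).astype(np.int8)
    g2 = rng.binomial(2, q2, size=n).astype(np.int8)
    return GenotypeVector(g1, snp_id="S1"), GenotypeVector(g2, snp_id="S2")


def simulate_two_locus(
    hm: HaplotypeModel,
    n: int,
    rng: np.random.Generator,
    return_haplotypes: bool = False,
):
    """Draw two haplotypes per individual from ``hm`` and form dosages.

    Returns ``(g1, g2)`` or ``(g1, g2, haps)`` where ``haps`` is the
    (n, 2) array of haplotype indices (0..3) per individual.
    """
    haps = rng.choice(4, size=(n, 2), p=hm.freqs)
    g1 = GenotypeVector((haps >= 2).sum(axis=1).astype(np.int8))
    g2 = GenotypeVector((haps % 2).sum(axis=1).astype(np.int8))
    if return_haplotypes:
        return g1, g2, haps
    return g1, g2


def simulate_linked_quartet(
    hm1: HaplotypeModel, hm2: HaplotypeModel, n: int, rng: np.random.Generator
) -> Tuple[GenotypeVector, GenotypeVector, GenotypeVector, GenotypeVector]:
    """Two independent causal/tag pairs: returns (S1, S3, S2, S4).

    S1/S2 are the causal SNPs, S3/S4 their respective tags; the two pairs
    are drawn independently so S1 and S2 are unlinked.
    """
    s1, s3 = simulate_two_locus(hm1, n, rng)
    s2, s4 = simulate_two_locus(hm2, n, rng)
    s1.snp_id, s3.snp_id, s2.snp_id, s4.snp_id = "S1", "S3", "S2", "S4"
    return s1, s3, s2, s4


def _risk_mask_for(risk_cells) -> np.ndarray:
    if isinstance(risk_cells, CollapseMode):
        return risk_cells.mask()
    m = np.zeros((3, 3), dtype=bool)
    for i, j in risk_cells:
        m[i, j] = True
    return m


def simulate_phenotype_ch(
    g1: GenotypeVector,
    g2: GenotypeVector,
    alpha: float,
    grr: float,
    risk_cells=CAUSAL,
    rng: Optional[np.random.Generator] = None,
) -> PhenotypeVector:
    """Bernoulli phenotype: probability ``alpha*grr`` on risk genotypes.

    ``risk_cells`` may be a :class:`~cdhtest.cdh.CollapseMode` or an
    iterable of (dosage1, dosage2) cells.
    """
    if alpha * grr > 1:
        raise InputError(f"alpha*grr = {alpha * grr:g} exceeds 1")
    if rng is None:
        rng = np.random.default_rng()
    mask3 = _risk_mask_for(risk_cells)
    d1 = np.clip(g1.values, 0, 2)
    d2 = np.clip(g2.values, 0, 2)
    at_risk = mask3[d1, d2]
    at_risk &= (g1.values >= 0) & (g2.values >= 0)
    p = np.where(at_risk, alpha * grr, alpha)
    return PhenotypeVector((rng.random(len(g1)) < p).astype(np.int8))


@dataclass
class SimConfig:
    """Replicate-level settings for the power/type-I simulations."""

    n_individuals: int = 10_213
    n_reps: int = 2_000
    rng_seed: int = 0
    thresholds: Tuple[float, ...] = (0.05, 5e-8, 5e-11)


def uniform_maf_sampler(low: float = 0.01, high: float = 0.05) -> MafSampler:
    """MAF sampler uniform on [low, high] -- the low-frequency band."""

    def sample(rng: np.random.Generator) -> float:
        return float(rng.uniform(low, high))

    return sample


def chip_maf_sampler(
    rare_fraction: float = 0.45,
    rare: Tuple[float, float] = (0.01, 0.05),
    common: Tuple[float, float] = (0.05, 0.5),
) -> MafSampler:
    """Chip-like MAF spectrum: a rare band mixed with a common band."""

    def sample(rng: np.random.Generator) -> float:
        lo, hi = rare if rng.random() < rare_fraction else common
        return float(rng.uniform(lo, hi))

    return sample


def _p_or_one(func) -> float:
    try:
        return func().p
    except DegenerateDataError:
        return 1.0


def power_table(
    config: SimConfig,
    grr_list: Sequence[float],
    maf_sampler: Optional[MafSampler] = None,
    mode: CollapseMode = CAUSAL,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Monte-Carlo type-I error / power of CDH and per-SNP trend tests.

    For each GRR and replicate: draw (q1, q2) from ``maf_sampler``
    (default uniform on [0.01, 0.05]), simulate an independent HWE pair
    for ``config.n_individuals`` samples and a phenotype under the
    recessive+CH model, then run the Cochran-Armitage trend test on each
    SNP and the CDH test on the pair.

    Returns a long-format DataFrame with columns
    ``grr, test, threshold, percent`` where ``percent`` is the percentage
    of replicates with P <= threshold.
    """
    sampler = maf_sampler or uniform_maf_sampler()
    records = []
    for gi, grr in enumerate(grr_list):
        pvals = {"snp1_trend": [], "snp2_trend": [], "cdh": []}
        for rep in range(config.n_reps):
            rng = np.random.default_rng([config.rng_seed, gi, rep])
            q1, q2 = sampler(rng), sampler(rng)
            g1, g2 = simulate_hwe_pair(q1, q2, config.n_individuals, rng)
            y = simulate_phenotype_ch(g1, g2, alpha, grr, mode, rng)
            pvals["snp1_trend"].append(_p_or_one(lambda: cochran_armitage_trend(g1, y)))
            pvals["snp2_trend"].append(_p_or_one(lambda: cochran_armitage_trend(g2, y)))
            pvals["cdh"].append(_p_or_one(lambda: cdh_test(g1, g2, y, mode)))
        for test, ps in pvals.items():
            arr = np.asarray(ps)
            for thr in config.thresholds:
                records.append(
                    {
                        "grr": grr,
                        "test": test,
                        "threshold": thr,
                        "percent": 100.0 * float((arr <= thr).mean()),
                    }
                )
    return pd.DataFrame.from_records(records)


@dataclass
class RegionModel:
    """A synthetic multi-SNP region under the recessive-set model.

    Individuals are assembled from two draws of a founder-haplotype pool
    (``n_founders`` haplotypes with Dirichlet(1) frequencies), which gives
    block-like intra-region LD; a per-gamete ``mutation_rate`` perturbs
    transmitted haplotypes.  ``portion_causal`` is the fraction of SNPs
    with pool MAF < 0.05 flagged causal (at least one when positive).
    """

    m: int = 38
    n_founders: int = 20
    mutation_rate: float = 0.002
    portion_causal: float = 0.08
    grr: float = 10.0
    alpha: float = 0.05
    maf_sampler: Optional[MafSampler] = None
    phase_aware: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.portion_causal <= 1:
            raise InputError("portion_causal must be in [0, 1]")
        if self.alpha * self.grr > 1:
            raise InputError("alpha*grr exceeds 1")


@dataclass
class RegionData:
    """Output of :func:`simulate_region`."""

    genotypes: np.ndarray  # (n, m) int8 dosages
    causal_mask: np.ndarray  # (m,) bool
    phenotype: PhenotypeVector
    pool_maf: np.ndarray  # (m,) founder-pool allele frequencies
    haplotypes: Optional[Tuple[np.ndarray, np.ndarray]] = None


def recessive_set_exposure(
    causal_genotypes: np.ndarray,
    haplotypes: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> np.ndarray:
    """Risk-carrier mask under the recessive-set model.

    An individual is exposed if homozygous for any causal variant, or a
    (compound) heterozygote at two or more distinct causal variants.  By
    default the CH condition is genotype-level (phase not checked --
    matching what an unphased test can see); pass per-chromosome causal
    haplotypes to require minor alleles on opposite homologues.
    """
    gc = np.asarray(causal_genotypes)
    if gc.ndim == 1:
        gc = gc[:, None]
    if gc.shape[1] == 0:
        return np.zeros(gc.shape[0], dtype=bool)
    hom = (gc == 2).any(axis=1)
    if haplotypes is None:
        ch = (gc == 1).sum(axis=1) >= 2
    else:
        hap_a, hap_b = haplotypes
        ch = hap_a.any(axis=1) & hap_b.any(axis=1)
    return hom | ch


def region_benchmark(
    n_regions: int = 300,
    n: int = 10_000,
    rm: Optional[RegionModel] = None,
    k_permutations: int = 1000,
    threshold: float = 5e-8,
    seed: int = 0,
) -> dict:
    """Head-to-head power of regional CDH vs WSS on synthetic regions.

    For each region: simulate under the recessive-set model, mask the
    causal variants, run (a) the all-pairs CDH scan over the remaining
    SNPs with m(m-1)/2 Bonferroni correction and (b) WSS over the
    remaining variants with MAF < 0.05 using ``k_permutations``
    phenotype permutations.  Power is the fraction of regions whose
    (corrected) P value is at or below ``threshold``.
    """
    from .scan import pairwise_region_scan
    from .wss import WssConfig, wss_test

    rm = rm or RegionModel(portion_causal=0.09)
    cdh_hits = 0
    wss_hits = 0
    wss_skipped = 0
    for r in range(n_regions):
        rng = np.random.default_rng([seed, r])
        region = simulate_region(rm, n, rng)
        keep = ~region.causal_mask
        g_obs = region.genotypes[:, keep]
        res = pairwise_region_scan(g_obs, region.phenotype, mode=TAGGING)
        if res.p_bonf <= threshold:
            cdh_hits += 1
        try:
            wres = wss_test(
                g_obs,
                region.phenotype,
                WssConfig(maf_cutoff=0.05, k=k_permutations),
                rng,
            )
            if wres.p <= threshold:
                wss_hits += 1
        except InputError:  # no observed variant below the MAF cutoff
            wss_skipped += 1
    return {
        "n_regions": n_regions,
        "cdh_power": cdh_hits / n_regions,
        "wss_power": wss_hits / n_regions,
        "wss_skipped": wss_skipped,
    }


def _greedy_founder_subset(
    founder_freq: np.ndarray, target_maf: float, rng: np.random.Generator
) -> np.ndarray:
    """Pick founder haplotypes whose total frequency approaches the target."""
    sel = np.zeros(founder_freq.size, dtype=bool)
    total = 0.0
    for f in rng.permutation(founder_freq.size):
        if total + founder_freq[f] <= target_maf + 1e-12:
            sel[f] = True
            total += founder_freq[f]
    if total == 0.0:  # no founder rare enough: put it on the rarest one
        sel[int(np.argmin(founder_freq))] = True
    return sel


def simulate_region(
    rm: RegionModel, n: int, rng: np.random.Generator
) -> RegionData:
    """Simulate one region: genotypes, causal flags and phenotype."""
    sampler = rm.maf_sampler or chip_maf_sampler()
    K, m = rm.n_founders, rm.m
    founder_freq = rng.dirichlet(np.ones(K))
    founders = np.zeros((K, m), dtype=np.int8)
    pool_maf = np.zeros(m)
    for j in range(m):
        sel = _greedy_founder_subset(founder_freq, sampler(rng), rng)
        founders[sel, j] = 1
        pool_maf[j] = float(founder_freq[sel].sum())

    causal = np.zeros(m, dtype=bool)
    if rm.portion_causal > 0:
        rare = (pool_maf > 0) & (pool_maf < 0.05)
        if not rare.any():
            raise InputError("no SNP with MAF < 0.05 available to flag as causal")
        n_causal = max(1, int(round(rm.portion_causal * int(rare.sum()))))
        picks = rng.choice(np.flatnonzero(rare), size=n_causal, replace=False)
        causal[picks] = True

    idx = rng.choice(K, size=2 * n, p=founder_freq)
    H = founders[idx].copy()
    if rm.mutation_rate > 0:
        H ^= (rng.random(H.shape) < rm.mutation_rate).astype(np.int8)
    hap_a, hap_b = H[0::2], H[1::2]
    G = (hap_a + hap_b).astype(np.int8)

    haps = (hap_a[:, causal], hap_b[:, causal]) if rm.phase_aware else None
    exposed = recessive_set_exposure(G[:, causal], haps)
    p = np.where(exposed, rm.alpha * rm.grr, rm.alpha)
    y = PhenotypeVector((rng.random(n) < p).astype(np.int8))
    return RegionData(
        genotypes=G,
        causal_mask=causal,
        phenotype=y,
        pool_maf=pool_maf,
        haplotypes=(hap_a, hap_b) if rm.phase_aware else None,
    )
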