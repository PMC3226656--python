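"""Readers, writers, cohort assembly and deterministic fixture bundles.

Supported formats:

* VCF (v4.x subset: CHROM, POS, ID, REF, ALT, GT), plain or bgzipped,
  read through cyvcf2.  Biallelic records only; multiallelic sites are
  skipped and counted.  Phased (``|``) and unphased (``/``) separators are
  both accepted, phase is ignored; missing GT becomes a missing dosage.
* PLINK-style transposed text: a header line ``CHROM POS ID <sample...>``
  followed by one row per SNP with dosages 0/1/2/NA.
* Phenotype: two-column TSV with header, ``sample_id<TAB>status`` with
  status in {0, 1, NA}.

Coordinates are 1-based throughout, mirroring VCF.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import MISSING, GenotypeVector, InputError, PhenotypeVector
from .simulate import (
    HaplotypeModel,
    RegionModel,
    haplotypes_for_target_r2,
    simulate_hwe_pair,
    simulate_linked_quartet,
    simulate_phenotype_ch,
    simulate_region,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "read_genotypes",
    "read_phenotype",
    "write_vcf",
    "write_phenotype",
    "load_cohort",
    "make_fixtures",
]


@dataclass
class Cohort:
    """Aligned genotypes and phenotype for a set of samples."""

    samples: List[str]
    genotypes: List[GenotypeVector]
    phenotype: PhenotypeVector
    meta: Dict = field(default_factory=dict)

    def genotype(self, snp_id: str) -> GenotypeVector:
        for g in self.genotypes:
            if g.snp_id == snp_id:
                return g
        raise KeyError(f"SNP {snp_id!r} not in cohort")


def _read_vcf(path: str) -> Tuple[List[str], List[GenotypeVector], Dict]:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    genos: List[GenotypeVector] = []
    skipped_multiallelic = 0
    for i, var in enumerate(vcf):
        try:
            if len(var.ALT) != 1:
                skipped_multiallelic += 1
                continue
            dosage = var.gt_types.astype(np.int8)  # 0/1/2 = alt count, 3 = missing
            dosage[dosage == 3] = MISSING
            snp_id = var.ID or f"{var.CHROM}:{var.POS}"
            genos.append(
                GenotypeVector(dosage, snp_id=snp_id, chrom=var.CHROM, pos=var.POS)
            )
        except Exception as exc:  # pragma: no cover - malformed records
            raise InputError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
    summary = {"skipped_multiallelic": skipped_multiallelic, "source": str(path)}
    if skipped_multiallelic:
        logger.warning(
            "%s: skipped %d multiallelic records", path, skipped_multiallelic
        )
    return samples, genos, summary


def _read_plink_text(path: str) -> Tuple[List[str], List[GenotypeVector], Dict]:
    genos: List[GenotypeVector] = []
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 4 or header[0].lstrip("#").upper() != "CHROM":
            raise InputError(f"{path}: expected header 'CHROM POS ID <samples...>'")
        samples = header[3:]
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 3 + len(samples):
                raise InputError(
                    f"{path}:{lineno}: expected {3 + len(samples)} fields, got {len(fields)}"
                )
            chrom, pos, snp_id = fields[0], fields[1], fields[2]
            try:
                dosage = np.array(
                    [MISSING if v.upper() == "NA" else int(v) for v in fields[3:]],
                    dtype=np.int8,
                )
                genos.append(
                    GenotypeVector(dosage, snp_id=snp_id, chrom=chrom, pos=int(pos))
                )
            except (ValueError, InputError) as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
    return samples, genos, {"source": str(path)}


def read_genotypes(
    path, fmt: Optional[str] = None
) -> Tuple[List[str], List[GenotypeVector], Dict]:
    """Read biallelic genotypes as minor-allele dosage vectors.

    ``fmt`` is ``"vcf"`` or ``"plink"``; by default it is inferred from the
    file extension.  Returns (sample ids, genotype vectors, summary).
    """
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "plink"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "plink":
        return _read_plink_text(path)
    raise InputError(f"unknown genotype format {fmt!r}")


def read_phenotype(path) -> Dict[str, int]:
    """Read a two-column phenotype TSV (sample_id, status in {0,1,NA})."""
    status: Dict[str, int] = {}
    n_na = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise InputError(f"{path}: empty phenotype file")
        rows = [line for line in fh if line.strip()]
    if not rows:
        raise InputError(f"{path}: phenotype file has a header but no rows")
    for lineno, line in enumerate(rows, start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
        sid, val = fields[0], fields[1].strip().upper()
        if sid in status:
            raise InputError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        if val == "NA":
            status[sid] = MISSING
            n_na += 1
        elif val in ("0", "1"):
            status[sid] = int(val)
        else:
            raise InputError(
                f"{path}:{lineno}: status must be 0, 1 or NA; got {fields[1]!r}"
            )
    if n_na:
        logger.info("%s: %d samples with missing phenotype", path, n_na)
    return status


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path, samples: List[str], genotypes: List[GenotypeVector]) -> None:
    """Write dosage vectors as a minimal VCF (GT only, REF=A/ALT=G)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cdhtest\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for g in genotypes:
            if len(g) != len(samples):
                raise InputError(
                    f"SNP {g.snp_id}: {len(g)} genotypes for {len(samples)} samples"
                )
            gts = "\t".join(_GT[int(v)] for v in g.values)
            fh.write(
                f"{g.chrom or '1'}\t{g.pos or 1}\t{g.snp_id}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def write_phenotype(path, samples: List[str], y: PhenotypeVector) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\n")
        for sid, val in zip(samples, y.values):
            fh.write(f"{sid}\t{'NA' if val == MISSING else int(val)}\n")


def load_cohort(
    genotype_path, phenotype_path, fmt: Optional[str] = None
) -> Cohort:
    """Load and align genotypes with phenotype by sample id."""
    samples, genos, summary = read_genotypes(genotype_path, fmt=fmt)
    if len(set(samples)) != len(samples):
        raise InputError(f"{genotype_path}: duplicated sample ids")
    status = read_phenotype(phenotype_path)
    unknown = [s for s in status if s not in set(samples)]
    if unknown:
        logger.warning(
            "%d phenotype ids not present in genotype file (ignored)", len(unknown)
        )
    values = np.array([status.get(s, MISSING) for s in samples], dtype=np.int8)
    y = PhenotypeVector(values)
    summary["n_samples"] = len(samples)
    summary["n_snps"] = len(genos)
    return Cohort(samples=samples, genotypes=genos, phenotype=y, meta=summary)


def _sample_ids(n: int) -> List[str]:
    return [f"s{i:05d}" for i in range(n)]


def make_fixtures(outdir, seed: int) -> Dict:
    """Write a deterministic small VCF + phenotype bundle for testing.

    Produces three scenarios with truth metadata in ``truth.json``:

    a. ``causal_pair``  -- two independent low-frequency causal SNPs with a
       recessive+CH effect (q = 0.05/0.04, GRR 6, alpha 0.05, n = 2000);
    b. ``tagging_quartet`` -- the same design observed through two tagging
       SNPs at target r^2 = 0.5 per causal/tag pair;
    c. ``null_region`` -- a 20-SNP founder-haplotype region with a
       phenotype independent of all genotypes (n = 600).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth: Dict = {"seed": seed}

    # (a) causal pair
    rng = np.random.default_rng([seed, 0])
    n = 3000
    q1, q2, grr, alpha = 0.05, 0.04, 8.0, 0.05
    g1, g2 = simulate_hwe_pair(q1, q2, n, rng)
    y = simulate_phenotype_ch(g1, g2, alpha, grr, rng=rng)
    g1.snp_id, g1.chrom, g1.pos = "snpA", "1", 10_000
    g2.snp_id, g2.chrom, g2.pos = "snpB", "1", 12_000
    samples = _sample_ids(n)
    write_vcf(outdir / "causal_pair.vcf", samples, [g1, g2])
    write_phenotype(outdir / "causal_pair.pheno.tsv", samples, y)
    truth["causal_pair"] = {
        "q1": q1, "q2": q2, "grr": grr, "alpha": alpha, "n": n,
        "snp_ids": ["snpA", "snpB"],
    }

    # (b) tagging quartet
    rng = np.random.default_rng([seed, 1])
    r2 = 0.5
    hm1 = haplotypes_for_target_r2(0.05, 0.08, r2)
    hm2 = haplotypes_for_target_r2(0.04, 0.06, r2)
    s1, s3, s2, s4 = simulate_linked_quartet(hm1, hm2, n, rng)
    yq = simulate_phenotype_ch(s1, s2, alpha, grr, rng=rng)
    for g, (sid, pos) in zip(
        (s1, s3, s2, s4),
        (("causal1", 20_000), ("tag1", 21_000), ("causal2", 25_000), ("tag2", 26_000)),
    ):
        g.snp_id, g.chrom, g.pos = sid, "1", pos
    quartet = sorted((s1, s3, s2, s4), key=lambda g: g.pos)
    write_vcf(outdir / "tagging_quartet.vcf", samples, quartet)
    write_phenotype(outdir / "tagging_quartet.pheno.tsv", samples, yq)
    truth["tagging_quartet"] = {
        "r2_target": r2,
        "r2_model": [hm1.r2, hm2.r2],
        "causal_ids": ["causal1", "causal2"],
        "tag_ids": ["tag1", "tag2"],
        "grr": grr, "alpha": alpha, "n": n,
    }

    # (c) null region
    rng = np.random.default_rng([seed, 2])
    n_region = 600
    rm = RegionModel(m=20, grr=1.0, portion_causal=0.0)
    region = simulate_region(rm, n_region, rng)
    region_samples = _sample_ids(n_region)
    gvs = [
        GenotypeVector(
            region.genotypes[:, j], snp_id=f"r{j:02d}", chrom="2", pos=5_000 * (j + 1)
        )
        for j in range(rm.m)
    ]
    write_vcf(outdir / "null_region.vcf", region_samples, gvs)
    write_phenotype(outdir / "null_region.pheno.tsv", region_samples, region.phenotype)
    truth["null_region"] = {"m": rm.m, "n": n_region, "grr": 1.0}

    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
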