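"""Phased-genotype (VCF) and phenotype-table input.

Phase analysis needs observed phase: a heterozygous genotype enters the
diplotype coding only when its GT field is phased (``|`` separator) and,
when phase-set (PS) tags are present, two variants are phase-comparable
for a sample only if they share one phase set.  Homozygous calls are
phase-unambiguous and always usable.  Samples failing these rules are
dropped from the pair analysis (complete-case; counts are logged) — no
imputation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "PhasedGenotypeMatrix",
    "read_phased_vcf",
    "diplotypes_for_pair",
    "read_phenotypes",
    "align_samples",
]


@dataclass
class PhasedGenotypeMatrix:
    """Per-variant, per-sample phased allele calls.

    ``calls`` has shape (n_variants, n_samples, 2) with allele indices
    (0 = REF, 1.. = ALT order in the record) and -1 for missing;
    ``phased`` marks GTs carrying the ``|`` separator; ``phase_set`` holds
    PS tags (-1 where absent).  Coordinates are 1-based as in the source.
    """

    samples: list[str]
    variants: pd.DataFrame  # id, chrom, pos, ref, alts, n_alleles
    calls: np.ndarray
    phased: np.ndarray
    phase_set: np.ndarray

    def variant_index(self, variant_id: str) -> int:
        hits = np.nonzero((self.variants["id"] == variant_id).to_numpy())[0]
        if len(hits) == 0:
            raise KeyError(f"variant {variant_id!r} not found in VCF")
        return int(hits[0])


def read_phased_vcf(
    path: str,
    variant_ids: list[str] | None = None,
    region: str | None = None,
) -> PhasedGenotypeMatrix:
    """Read phased genotypes from a VCF (plain text or BGZF).

    ``variant_ids`` restricts to the named records (error if any is
    absent); ``region`` restricts by ``chrom[:start-end]`` (requires an
    index for compressed files).
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    rows = []
    call_rows = []
    phased_rows = []
    ps_rows = []
    records = vf.fetch(region=region) if region else vf
    wanted = set(variant_ids) if variant_ids else None
    for rec in records:
        vid = rec.id or f"{rec.chrom}:{rec.pos}"
        if wanted is not None and vid not in wanted:
            continue
        alts = rec.alts or ()
        calls = np.full((len(samples), 2), -1, dtype=np.int64)
        phased = np.zeros(len(samples), dtype=bool)
        ps = np.full(len(samples), -1, dtype=np.int64)
        for si, name in enumerate(samples):
            s = rec.samples[name]
            gt = s.get("GT")
            if gt is None or all(a is None for a in gt):
                continue
            if len(gt) == 1:
                raise ValueError(
                    f"haploid GT for sample {name} at {vid}: haploid mode "
                    "is not part of the diploid VCF path"
                )
            if len(gt) != 2:
                raise ValueError(f"malformed GT for sample {name} at {vid}: {gt}")
            calls[si] = [(-1 if a is None else a) for a in gt]
            phased[si] = bool(s.phased)
            if "PS" in s and s["PS"] is not None:
                ps[si] = int(s["PS"])
        rows.append(
            {
                "id": vid, "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alts": ",".join(alts),
                "n_alleles": 1 + len(alts),
            }
        )
        call_rows.append(calls)
        phased_rows.append(phased)
        ps_rows.append(ps)
    if wanted is not None:
        found = {r["id"] for r in rows}
        missing = wanted - found
        if missing:
            raise KeyError(f"variants not found in VCF: {sorted(missing)}")
    if not rows:
        raise ValueError(f"no variants read from {path}")
    return PhasedGenotypeMatrix(
        samples=samples,
        variants=pd.DataFrame(rows),
        calls=np.stack(call_rows),
        phased=np.stack(phased_rows),
        phase_set=np.stack(ps_rows),
    )


def diplotypes_for_pair(
    matrix: PhasedGenotypeMatrix,
    variant_a: str,
    variant_b: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-locus diplotypes for a biallelic variant pair.

    Returns ``(cohort, kept)`` where ``cohort`` is the (n_kept, 2, 2)
    haplotype array and ``kept`` is the boolean retention mask over the
    matrix's samples.  Dropped: missing calls, unphased heterozygotes,
    and double heterozygotes whose two variants carry different phase
    sets.  Multi-allelic records are rejected on this path.
    """
    ia = matrix.variant_index(variant_a)
    ib = matrix.variant_index(variant_b)
    for i in (ia, ib):
        if matrix.variants.loc[i, "n_alleles"] != 2:
            raise ValueError(
                f"variant {matrix.variants.loc[i, 'id']} is multi-allelic; "
                "use the multi-allelic coding path (rop.coding.encode_multiallelic)"
            )
    ca, cb = matrix.calls[ia], matrix.calls[ib]
    pha, phb = matrix.phased[ia], matrix.phased[ib]
    psa, psb = matrix.phase_set[ia], matrix.phase_set[ib]
    missing = (ca < 0).any(axis=1) | (cb < 0).any(axis=1)
    het_a = ~missing & (ca[:, 0] != ca[:, 1])
    het_b = ~missing & (cb[:, 0] != cb[:, 1])
    unphased = (het_a & ~pha) | (het_b & ~phb)
    ps_conflict = (
        het_a & het_b & (psa >= 0) & (psb >= 0) & (psa != psb)
    )
    kept = ~(missing | unphased | ps_conflict)
    n_drop = int((~kept).sum())
    if n_drop:
        logger.warning(
            "dropped %d/%d samples for pair (%s, %s): %d missing, "
            "%d unphased heterozygous, %d phase-set conflicts",
            n_drop, len(kept), variant_a, variant_b,
            int(missing.sum()), int((unphased & ~missing).sum()),
            int((ps_conflict & ~unphased & ~missing).sum()),
        )
    cohort = np.stack([ca[kept], cb[kept]], axis=2)  # (n, 2 haplotypes, 2 loci)
    return cohort.astype(np.int64), kept


def read_phenotypes(path: str, sep: str = "\t") -> pd.DataFrame:
    """Phenotype/covariate table with a mandatory ``sample_id`` column."""
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ValueError("phenotype table must contain a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in phenotype table: {dups}")
    return df.set_index("sample_id")


def align_samples(
    genotype_samples: list[str],
    kept: np.ndarray,
    phenotypes: pd.DataFrame,
    response: str,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Inner-join genotype and phenotype samples on id.

    Returns ``(order, joined, mask)``: the positional indices into the
    *kept* genotype rows for joined samples, the joined phenotype frame,
    and the mask over kept genotype samples.  Rows with missing response
    are dropped with a logged count.
    """
    if response not in phenotypes.columns:
        raise ValueError(f"response column {response!r} not in phenotype table")
    geno_ids = [s for s, k in zip(genotype_samples, kept) if k]
    pheno = phenotypes.loc[phenotypes.index.intersection(geno_ids)]
    n_na = int(pheno[response].isna().sum())
    if n_na:
        logger.warning("dropping %d sample(s) with missing response", n_na)
        pheno = pheno.loc[pheno[response].notna()]
    if len(pheno) == 0:
        raise ValueError("0 samples after joining genotypes and phenotypes")
    if not pd.api.types.is_numeric_dtype(pheno[response]):
        raise ValueError(f"response column {response!r} is not numeric")
    pos = {s: i for i, s in enumerate(geno_ids)}
    order = np.array([pos[s] for s in pheno.index], dtype=np.int64)
    logger.info(
        "joined %d samples (%d genotyped, %d phenotyped)",
        len(pheno), len(geno_ids), len(phenotypes),
    )
    mask = np.zeros(len(geno_ids), dtype=bool)
    mask[order] = True
    return order, pheno, mask
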