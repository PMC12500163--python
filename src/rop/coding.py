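"""Phasetype coding for two-locus diplotypes.

Phase refers to the assignment of alleles at two loci to the two homologous
chromosomes.  For biallelic loci with alleles {A, a} and {B, b} (capital =
alternative allele) an individual's *diplotype* is the unordered pair of
two-locus haplotypes; ten distinct diplotypes exist, four of which realise
cis relations and four trans relations.  Analogous to the additive genotype
coding at a single locus, *phasetypes* count, per individual, how many of
the two haplotype pairings realise a given cis or trans allele
configuration.  Each phasetype takes values in {0, 1, 2}:

    Cis_ij    = number of haplotypes carrying alleles (i, j) together,
    Trans_ij  = number of cross-chromosome pairings with i on one
                homologue and j on the other.

The coding satisfies exact linear identities that make association tests of
a phase term invariant to which allele pair is designated the reference::

    Cis_AB + Cis_Ab = Trans_AB + Trans_Ab = G_A
    Cis_AB + Cis_aB = Trans_AB + Trans_aB = G_B
    sum of the four cis counts = sum of the four trans counts = 2

where G_A, G_B are the additive genotypes (alternative-allele counts) and
D_A, D_B the dominance indicators (1 iff heterozygous).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Allele-pair index order used everywhere (first allele of the pair refers
#: to locus A, second to locus B; capital = alternative allele).
PAIR_KEYS: tuple[str, ...] = ("AB", "aB", "Ab", "ab")

#: Column order of the per-sample phasetype table.
PHASETYPE_COLUMNS: tuple[str, ...] = (
    "GA", "DA", "GB", "DB",
    "Cis_AB", "Cis_aB", "Cis_Ab", "Cis_ab",
    "Trans_AB", "Trans_aB", "Trans_Ab", "Trans_ab",
)


@dataclass(frozen=True)
class BiallelicDiplotype:
    """Unordered pair of two-locus haplotypes.

    Each haplotype is a pair of 0/1 allele indicators ``(locusA, locusB)``
    where 1 marks the alternative allele.  Haplotype order is canonicalised
    so that ``(h1, h2)`` and ``(h2, h1)`` compare and hash equal.
    """

    hap1: tuple[int, int]
    hap2: tuple[int, int]

    def __post_init__(self) -> None:
        h1 = (int(self.hap1[0]), int(self.hap1[1]))
        h2 = (int(self.hap2[0]), int(self.hap2[1]))
        for h in (h1, h2):
            if h[0] not in (0, 1) or h[1] not in (0, 1):
                raise ValueError(f"allele indicators must be 0/1, got {h}")
        if h1 < h2:
            h1, h2 = h2, h1
        object.__setattr__(self, "hap1", h1)
        object.__setattr__(self, "hap2", h2)

    @property
    def name(self) -> str:
        """Conventional label such as ``'AB/ab'``."""
        def hap_name(h: tuple[int, int]) -> str:
            return ("A" if h[0] else "a") + ("B" if h[1] else "b")
        return f"{hap_name(self.hap1)}/{hap_name(self.hap2)}"

    def as_array(self) -> np.ndarray:
        """(2, 2) int array: [haplotype, locus]."""
        return np.array([self.hap1, self.hap2], dtype=np.int64)


def all_diplotypes() -> list[BiallelicDiplotype]:
    """The ten distinct diplotypes over two biallelic loci."""
    haps = [(a, b) for a in (0, 1) for b in (0, 1)]
    seen: dict[BiallelicDiplotype, None] = {}
    for i, h1 in enumerate(haps):
        for h2 in haps[i:]:
            seen.setdefault(BiallelicDiplotype(h1, h2), None)
    return list(seen)


@dataclass(frozen=True)
class PhasetypeCode:
    """Full additive/dominance/phasetype coding of one diplotype.

    ``cis`` and ``trans`` are mappings over the four allele pairs
    ``('AB', 'aB', 'Ab', 'ab')``; each count lies in {0, 1, 2}.
    """

    GA: int
    GB: int
    DA: int
    DB: int
    cis: Mapping[str, int]
    trans: Mapping[str, int]

    def as_series(self) -> pd.Series:
        vals = [self.GA, self.DA, self.GB, self.DB]
        vals += [self.cis[k] for k in PAIR_KEYS]
        vals += [self.trans[k] for k in PAIR_KEYS]
        return pd.Series(vals, index=list(PHASETYPE_COLUMNS), dtype=np.int64)


def encode_diplotype(d: BiallelicDiplotype) -> PhasetypeCode:
    """Encode a diplotype into genotypes, dominance terms and phasetypes.

    The domain is total: every one of the ten diplotypes maps to a unique
    coding row.
    """
    a1, b1 = d.hap1
    a2, b2 = d.hap2
    alleles_a = {"A": (a1, a2), "a": (1 - a1, 1 - a2)}
    alleles_b = {"B": (b1, b2), "b": (1 - b1, 1 - b2)}
    cis = {}
    trans = {}
    for key in PAIR_KEYS:
        ia = alleles_a[key[0]]
        ib = alleles_b[key[1]]
        cis[key] = ia[0] * ib[0] + ia[1] * ib[1]
        trans[key] = ia[0] * ib[1] + ia[1] * ib[0]
    ga = a1 + a2
    gb = b1 + b2
    return PhasetypeCode(
        GA=ga, GB=gb, DA=int(ga == 1), DB=int(gb == 1), cis=cis, trans=trans
    )


def reencode_reference(
    code: PhasetypeCode, ref_a: str = "A", ref_b: str = "B"
) -> PhasetypeCode:
    """Re-express a coding with different designated reference alleles.

    Counts never change under re-referencing — only which allele pair the
    index labels point at.  Choosing ``ref_a='a'`` relabels locus A so the
    new "alternative" allele is the old reference: genotype counts flip
    (``GA -> 2 - GA``) and the cis/trans index labels permute accordingly.
    Applying the same swap twice is the identity.
    """
    if ref_a not in ("A", "a") or ref_b not in ("B", "b"):
        raise ValueError("ref_a must be 'A' or 'a'; ref_b must be 'B' or 'b'")
    swap_a = ref_a == "a"
    swap_b = ref_b == "b"

    def relabel(key: str) -> str:
        ka, kb = key[0], key[1]
        if swap_a:
            ka = "a" if ka == "A" else "A"
        if swap_b:
            kb = "b" if kb == "B" else "B"
        return ka + kb

    cis = {key: code.cis[relabel(key)] for key in PAIR_KEYS}
    trans = {key: code.trans[relabel(key)] for key in PAIR_KEYS}
    ga = 2 - code.GA if swap_a else code.GA
    gb = 2 - code.GB if swap_b else code.GB
    return PhasetypeCode(GA=ga, GB=gb, DA=code.DA, DB=code.DB, cis=cis, trans=trans)


def verify_identities(code: PhasetypeCode) -> list[str]:
    """Names of violated linear identities (empty list = all hold).

    Checks the dominance definitions, the genotype/phasetype marginal sums,
    the total-count conservation, and the cross-expression of ``Cis_ab``
    through the intercept, the genotypes and ``Cis_AB``.
    """
    violations = []
    c, t = code.cis, code.trans
    if code.DA != int(code.GA == 1):
        violations.append("DA = 1[GA == 1]")
    if code.DB != int(code.GB == 1):
        violations.append("DB = 1[GB == 1]")
    if not (c["AB"] + c["Ab"] == t["AB"] + t["Ab"] == code.GA):
        violations.append("Cis_AB + Cis_Ab = Trans_AB + Trans_Ab = GA")
    if not (c["AB"] + c["aB"] == t["AB"] + t["aB"] == code.GB):
        violations.append("Cis_AB + Cis_aB = Trans_AB + Trans_aB = GB")
    if sum(c[k] for k in PAIR_KEYS) != 2:
        violations.append("sum(cis) = 2")
    if sum(t[k] for k in PAIR_KEYS) != 2:
        violations.append("sum(trans) = 2")
    if c["ab"] != 2 - code.GA - code.GB + c["AB"]:
        violations.append("Cis_ab = 2 - GA - GB + Cis_AB")
    return violations


# ---------------------------------------------------------------------------
# Vectorised cohort-level coding
# ---------------------------------------------------------------------------

def cohort_array(diplotypes: Iterable[BiallelicDiplotype]) -> np.ndarray:
    """Stack diplotypes into an (n, 2, 2) int array [sample, haplotype, locus]."""
    return np.array([d.as_array() for d in diplotypes], dtype=np.int64)


def phasetype_table(cohort: np.ndarray | Sequence[BiallelicDiplotype]) -> pd.DataFrame:
    """Per-sample coding table with the canonical column order.

    Parameters
    ----------
    cohort
        Either an (n, 2, 2) 0/1 array ``[sample, haplotype, locus]`` or a
        sequence of :class:`BiallelicDiplotype`.
    """
    H = cohort if isinstance(cohort, np.ndarray) else cohort_array(cohort)
    if H.ndim != 3 or H.shape[1:] != (2, 2):
        raise ValueError(f"expected (n, 2, 2) haplotype array, got {H.shape}")
    a1, b1 = H[:, 0, 0], H[:, 0, 1]
    a2, b2 = H[:, 1, 0], H[:, 1, 1]
    ga = a1 + a2
    gb = b1 + b2
    cols = {
        "GA": ga,
        "DA": (ga == 1).astype(np.int64),
        "GB": gb,
        "DB": (gb == 1).astype(np.int64),
        "Cis_AB": a1 * b1 + a2 * b2,
        "Cis_aB": (1 - a1) * b1 + (1 - a2) * b2,
        "Cis_Ab": a1 * (1 - b1) + a2 * (1 - b2),
        "Cis_ab": (1 - a1) * (1 - b1) + (1 - a2) * (1 - b2),
        "Trans_AB": a1 * b2 + a2 * b1,
        "Trans_aB": (1 - a1) * b2 + (1 - a2) * b1,
        "Trans_Ab": a1 * (1 - b2) + a2 * (1 - b1),
        "Trans_ab": (1 - a1) * (1 - b2) + (1 - a2) * (1 - b1),
    }
    return pd.DataFrame(cols, columns=list(PHASETYPE_COLUMNS))


def haploid_cis_code(hap: tuple[int, int]) -> dict[str, int]:
    """Cis counts for a single haplotype (haploid extension, e.g. male X).

    With one homologue there is a single allele pairing: the cis count of
    the carried pair is 1 and trans relations are undefined.  This mode is
    an extension beyond the diploid coding, provided for completeness.
    """
    a, b = (int(hap[0]), int(hap[1]))
    if a not in (0, 1) or b not in (0, 1):
        raise ValueError("allele indicators must be 0/1")
    key = ("A" if a else "a") + ("B" if b else "b")
    return {k: int(k == key) for k in PAIR_KEYS}


# ---------------------------------------------------------------------------
# Multi-allelic extension
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiallelicPhasetypeCode:
    """Phasetype coding for a pair of multi-allelic markers.

    Allele sets are ordered tuples of labels; the first label of each set is
    the designated reference.  ``cis[(i, j)]`` counts haplotypes carrying
    allele i at marker A together with allele j at marker B;
    ``trans[(i, j)]`` counts cross-homologue co-occurrence.  Additive and
    dominance genotypes are recorded per allele (including the reference,
    whose terms are redundant given the others).
    """

    alleles_a: tuple[str, ...]
    alleles_b: tuple[str, ...]
    GA: Mapping[str, int]
    DA: Mapping[str, int]
    GB: Mapping[str, int]
    DB: Mapping[str, int]
    cis: Mapping[tuple[str, str], int]
    trans: Mapping[tuple[str, str], int]

    def nonreference_pairs(self) -> list[tuple[str, str]]:
        return [
            (i, j) for i in self.alleles_a[1:] for j in self.alleles_b[1:]
        ]


def encode_multiallelic(
    hap1: tuple[str, str],
    hap2: tuple[str, str],
    alleles_a: Sequence[str],
    alleles_b: Sequence[str],
) -> MultiallelicPhasetypeCode:
    """Encode one individual's pair of multi-allelic haplotypes.

    ``hap1`` and ``hap2`` are (marker-A allele, marker-B allele) label
    pairs.  Raises ``ValueError`` naming any label not in the declared
    allele sets.
    """
    alleles_a = tuple(alleles_a)
    alleles_b = tuple(alleles_b)
    for hap in (hap1, hap2):
        if hap[0] not in alleles_a:
            raise ValueError(f"unknown marker-A allele label: {hap[0]!r}")
        if hap[1] not in alleles_b:
            raise ValueError(f"unknown marker-B allele label: {hap[1]!r}")
    ga = {ai: (hap1[0] == ai) + (hap2[0] == ai) for ai in alleles_a}
    gb = {bj: (hap1[1] == bj) + (hap2[1] == bj) for bj in alleles_b}
    cis = {}
    trans = {}
    for ai in alleles_a:
        for bj in alleles_b:
            cis[(ai, bj)] = int(hap1 == (ai, bj)) + int(hap2 == (ai, bj))
            trans[(ai, bj)] = int(hap1[0] == ai and hap2[1] == bj) + int(
                hap2[0] == ai and hap1[1] == bj
            )
    return MultiallelicPhasetypeCode(
        alleles_a=alleles_a,
        alleles_b=alleles_b,
        GA={k: int(v) for k, v in ga.items()},
        DA={k: int(v == 1) for k, v in ga.items()},
        GB={k: int(v) for k, v in gb.items()},
        DB={k: int(v == 1) for k, v in gb.items()},
        cis=cis,
        trans=trans,
    )


def multiallelic_design(
    codes: Sequence[MultiallelicPhasetypeCode],
) -> pd.DataFrame:
    """Design-matrix columns for the multi-allelic model.

    One additive + dominance column per non-reference allele of each marker
    and one cis + trans column per non-reference allele pair (reference
    terms are omitted: they are linearly dependent on the rest).
    """
    if not codes:
        raise ValueError("empty cohort")
    first = codes[0]
    for c in codes:
        if c.alleles_a != first.alleles_a or c.alleles_b != first.alleles_b:
            raise ValueError("all codes must share the same allele sets")
    cols: dict[str, list[int]] = {}
    for ai in first.alleles_a[1:]:
        cols[f"GA[{ai}]"] = [c.GA[ai] for c in codes]
        cols[f"DA[{ai}]"] = [c.DA[ai] for c in codes]
    for bj in first.alleles_b[1:]:
        cols[f"GB[{bj}]"] = [c.GB[bj] for c in codes]
        cols[f"DB[{bj}]"] = [c.DB[bj] for c in codes]
    for ai, bj in first.nonreference_pairs():
        cols[f"Cis[{ai},{bj}]"] = [c.cis[(ai, bj)] for c in codes]
    for ai, bj in first.nonreference_pairs():
        cols[f"Trans[{ai},{bj}]"] = [c.trans[(ai, bj)] for c in codes]
    return pd.DataFrame(cols, dtype=np.float64)


def block_to_marker(
    haplotype_calls: np.ndarray,
    phased: np.ndarray | None = None,
) -> tuple[np.ndarray, tuple[str, ...], pd.DataFrame, np.ndarray]:
    """Collapse a phased variant window into one multi-allelic marker.

    Each distinct haplotype string over the window becomes one allele of a
    synthetic marker; the most frequent haplotype is the reference (ties
    broken lexicographically on the string, so the labelling is
    deterministic).

    Parameters
    ----------
    haplotype_calls
        (n_samples, n_variants, 2) 0/1 array of phased allele calls,
        variants in genomic order.
    phased
        Optional (n_samples, n_variants) boolean mask; samples with any
        unphased heterozygote in the window are excluded (homozygous calls
        are phase-unambiguous and always kept).

    Returns
    -------
    labels : (n_kept, 2) array of haplotype-string allele labels
    allele_set : labels ordered reference-first then by descending frequency
    freq_table : DataFrame with allele, count, frequency
    kept : boolean mask of retained samples
    """
    H = np.asarray(haplotype_calls)
    if H.ndim != 3 or H.shape[2] != 2:
        raise ValueError(f"expected (n, n_variants, 2) array, got {H.shape}")
    n, _, _ = H.shape
    kept = np.ones(n, dtype=bool)
    if phased is not None:
        het = H[:, :, 0] != H[:, :, 1]
        bad = (het & ~np.asarray(phased, dtype=bool)).any(axis=1)
        if bad.any():
            import logging

            logging.getLogger(__name__).warning(
                "excluding %d sample(s) with unphased heterozygotes in block",
                int(bad.sum()),
            )
        kept = ~bad
    Hk = H[kept]
    strings = np.apply_along_axis(
        lambda v: "".join(map(str, v)), 2, Hk.transpose(0, 2, 1)
    )  # (n_kept, 2)
    counts = Counter(strings.ravel().tolist())
    if len(counts) < 2:
        raise ValueError("monomorphic block: a single distinct haplotype")
    # reference = most frequent, ties lexicographic; rest by descending count
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    allele_set = tuple(k for k, _ in ordered)
    total = 2 * Hk.shape[0]
    freq_table = pd.DataFrame(
        {
            "allele": allele_set,
            "count": [counts[k] for k in allele_set],
            "frequency": [counts[k] / total for k in allele_set],
        }
    )
    return strings, allele_set, freq_table, kept
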