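"""Variant sites and their trio inheritance categories.

A :class:`VariantSite` is one biallelic parental locus.  Genotypes are encoded
as the number of alternate alleles (0, 1, 2); the string forms ``0/0``, ``0/1``
and ``1/1`` are accepted at the boundaries.  The inheritance *category* of a
site is a pure function of the two parental genotypes and determines both how
the locus is used (fetal-fraction estimation vs. genotyping) and its evaluation
group.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: genotype integers in canonical order (hom-ref, het, hom-alt)
GENOTYPES = (0, 1, 2)

GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}
_GT_FROM_STRING = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2}


def parse_genotype(gt) -> int:
    """Coerce a genotype given as int 0/1/2 or a VCF-style string to an int."""
    if isinstance(gt, str):
        try:
            return _GT_FROM_STRING[gt]
        except KeyError:
            raise ValueError(f"unsupported genotype string: {gt!r}") from None
    gt = int(gt)
    if gt not in GENOTYPES:
        raise ValueError(f"genotype must be 0, 1 or 2 alt alleles, got {gt}")
    return gt


class VarType(str, enum.Enum):
    SNP = "SNP"
    INDEL = "INDEL"


class Category(str, enum.Enum):
    """Trio inheritance category of a biallelic site."""

    MATERNAL_ONLY_HET = "MATERNAL_ONLY_HET"
    PATERNAL_ONLY_HET = "PATERNAL_ONLY_HET"
    DOUBLE_HET = "DOUBLE_HET"
    FETAL_INFORMATIVE = "FETAL_INFORMATIVE"
    UNINFORMATIVE = "UNINFORMATIVE"


#: categories on which fetal genotypes are scored
CALLING_CATEGORIES = (
    Category.MATERNAL_ONLY_HET,
    Category.PATERNAL_ONLY_HET,
    Category.DOUBLE_HET,
)


def classify_site(g_mother, g_father) -> Category:
    """Classify a site from the parental genotypes.

    Total on valid genotypes: a heterozygous mother with a homozygous father is
    maternal-only het (and vice versa), two heterozygotes are double-het,
    opposite homozygotes are fetal-informative (every paternal-allele fragment
    in plasma is fetal-derived) and identical homozygotes are uninformative.
    """
    gm = parse_genotype(g_mother)
    gf = parse_genotype(g_father)
    m_het, f_het = gm == 1, gf == 1
    if m_het and f_het:
        return Category.DOUBLE_HET
    if m_het:
        return Category.MATERNAL_ONLY_HET
    if f_het:
        return Category.PATERNAL_ONLY_HET
    return Category.FETAL_INFORMATIVE if gm != gf else Category.UNINFORMATIVE


@dataclass(frozen=True)
class VariantSite:
    """One biallelic variant locus with both parental genotypes."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    g_mother: int
    g_father: int
    var_type: VarType = field(init=False)
    category: Category = field(init=False)
    site_id: str = field(init=False)

    def __post_init__(self):
        if not (_ALLELE_RE.match(self.ref) and _ALLELE_RE.match(self.alt)):
            raise ValueError(f"alleles must be non-empty over ACGT: {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        object.__setattr__(self, "g_mother", parse_genotype(self.g_mother))
        object.__setattr__(self, "g_father", parse_genotype(self.g_father))
        vt = VarType.SNP if len(self.ref) == 1 and len(self.alt) == 1 else VarType.INDEL
        object.__setattr__(self, "var_type", vt)
        object.__setattr__(self, "category", classify_site(self.g_mother, self.g_father))
        object.__setattr__(self, "site_id", f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}")

    @property
    def paternal_specific_allele(self) -> str | None:
        """At a fetal-informative site, the allele carried only by the father.

        Returns ``"REF"``/``"ALT"``, or None for other categories.
        """
        if self.category is not Category.FETAL_INFORMATIVE:
            return None
        return "ALT" if self.g_father == 2 else "REF"

    @property
    def maternal_allele(self) -> str | None:
        """The allele a homozygous mother carries (None if she is het)."""
        if self.g_mother == 1:
            return None
        return "ALT" if self.g_mother == 2 else "REF"
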