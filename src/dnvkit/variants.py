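"""Core domain objects shared across the pipeline.

A :class:`VariantSite` is one biallelic SNV with per-sample
:class:`GenotypeCall` objects and an annotation bundle (gene symbol,
consequence class, population allele frequency, CADD PHRED).  A
:class:`Pedigree` holds the trio structure of the cohort.

Coordinate convention: all positions are 1-based (VCF style) everywhere
inside the package; BED input is converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

#: consequence classes used throughout the pipeline
CLASSES = ("missense", "nonsense", "splice", "synonymous")

#: sentinel for a population allele frequency reported as absent from the
#: reference population.  Distinct from 0.0 and from ``None`` (unannotated);
#: an absent variant passes any MAF ceiling.
AF_ABSENT = "absent"

_BASES = frozenset("ACGT")

#: ordered mapping of VEP consequence terms to the four analysis classes.
#: Order encodes priority when a variant carries several terms.
VEP_CLASS_MAP = (
    ("splice_donor_variant", "splice"),
    ("splice_acceptor_variant", "splice"),
    ("stop_gained", "nonsense"),
    ("missense_variant", "missense"),
    ("splice_region_variant", "splice"),
    ("stop_retained_variant", "synonymous"),
    ("synonymous_variant", "synonymous"),
)


def classify_consequence(terms: str) -> str:
    """Collapse a VEP consequence string (``&``-joined terms) into one of
    the four analysis classes, or ``"other"``."""
    parts = set(terms.replace(",", "&").split("&"))
    for term, cls in VEP_CLASS_MAP:
        if term in parts:
            return cls
    return "other"


@dataclass
class GenotypeCall:
    """One sample's call at a site: genotype plus read support.

    ``ad_ref + ad_alt`` must equal ``dp`` when both are present; per-strand
    alt depths must sum to ``ad_alt`` when present.
    """

    genotype: str  # homref | het | homalt | missing
    gq: Optional[int] = None
    dp: Optional[int] = None
    ad_ref: Optional[int] = None
    ad_alt: Optional[int] = None
    ad_alt_fwd: Optional[int] = None
    ad_alt_rev: Optional[int] = None
    ad_ref_fwd: Optional[int] = None
    ad_ref_rev: Optional[int] = None
    min_base_q: Optional[int] = None

    def __post_init__(self) -> None:
        if self.genotype not in ("homref", "het", "homalt", "missing"):
            raise ValueError(f"invalid genotype {self.genotype!r}")
        if (
            self.dp is not None
            and self.ad_ref is not None
            and self.ad_alt is not None
            and self.ad_ref + self.ad_alt > self.dp
        ):
            raise ValueError(
                f"AD sum {self.ad_ref + self.ad_alt} exceeds DP {self.dp}"
            )
        if (
            self.ad_alt_fwd is not None
            and self.ad_alt_rev is not None
            and self.ad_alt is not None
            and self.ad_alt_fwd + self.ad_alt_rev != self.ad_alt
        ):
            raise ValueError("per-strand alt depths do not sum to ad_alt")

    @property
    def alt_fraction(self) -> Optional[float]:
        """Alt-allele read fraction from AD (not DP, which may count other
        alleles); ``None`` when AD is unavailable or depth is zero."""
        if self.ad_ref is None or self.ad_alt is None:
            return None
        total = self.ad_ref + self.ad_alt
        if total == 0:
            return None
        return self.ad_alt / total

    def is_missing(self) -> bool:
        return self.genotype == "missing"


@dataclass
class VariantSite:
    """One biallelic SNV with per-sample calls and annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    consequence_class: str = "other"
    population_af: object = None  # float, AF_ABSENT, or None (unannotated)
    cadd_phred: Optional[float] = None
    calls: dict = field(default_factory=dict)  # sample id -> GenotypeCall

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"non-SNV alleles {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if isinstance(self.population_af, float) and not (
            0.0 <= self.population_af <= 1.0
        ):
            raise ValueError(f"population_af {self.population_af} outside [0,1]")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def copy(self) -> "VariantSite":
        return replace(self, calls={s: replace(c) for s, c in self.calls.items()})


@dataclass(frozen=True)
class Trio:
    family_id: str
    proband: str
    father: str
    mother: str

    @property
    def members(self) -> tuple:
        return (self.proband, self.father, self.mother)


@dataclass
class Pedigree:
    """Trio pedigree: per family, a proband and two parents, with reported
    sexes and affected flags.  Probands are affected, parents unaffected."""

    trios: list  # list[Trio]
    sex: dict = field(default_factory=dict)  # sample -> "male"|"female"|"unknown"
    affected: dict = field(default_factory=dict)  # sample -> bool

    def __post_init__(self) -> None:
        for trio in self.trios:
            if len(set(trio.members)) != 3:
                raise ValueError(f"family {trio.family_id}: members not distinct")
            if self.affected and not self.affected.get(trio.proband, True):
                raise ValueError(f"proband {trio.proband} not flagged affected")
            for parent in (trio.father, trio.mother):
                if self.affected and self.affected.get(parent, False):
                    raise ValueError(f"parent {parent} flagged affected")

    @property
    def probands(self) -> list:
        return [t.proband for t in self.trios]

    @property
    def samples(self) -> list:
        out = []
        for t in self.trios:
            out.extend(t.members)
        return out

    def __len__(self) -> int:
        return len(self.trios)


@dataclass
class GeneSetLibrary:
    """GMT-style library: term id -> (term name, set of gene symbols)."""

    terms: dict  # term id -> (name, frozenset of upper-cased symbols)

    def genes(self) -> set:
        out = set()
        for _, members in self.terms.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.terms)
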