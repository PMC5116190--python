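"""Core domain types for the canine MHC (DLA) class II family analysis.

The analysis unit is a nuclear family (dam, sire, offspring) genotyped at the
three tightly linked class II loci DLA-DRB1, DLA-DQA1 and DLA-DQB1 on
chromosome 12.  Genotypes are unordered allele pairs per locus; three-locus
haplotypes are ordered (DRB1, DQA1, DQB1) allele triples.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Locus", "Role", "Provenance", "AlleleCall", "GenotypeRecord", "Family",
    "AlleleSequence", "Haplotype", "HaplotypePair", "COMPOSITE_DQB1",
]

#: Name of the composite allele representing the duplicated-DQB1 haplotype
#: (two DQB1 copies, alleles 01303 + 01701, analysed as one allele).
COMPOSITE_DQB1 = "013017"


class Locus(str, enum.Enum):
    DRB1 = "DRB1"
    DQA1 = "DQA1"
    DQB1 = "DQB1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Role(str, enum.Enum):
    DAM = "dam"
    SIRE = "sire"
    OFFSPRING = "offspring"


class Provenance(str, enum.Enum):
    """How a haplotype assignment was obtained."""
    HOMOZYGOUS_DIRECT = "homozygous_direct"
    INFERRED_FROM_KNOWN = "inferred_from_known"
    SUBTRACTION = "subtraction"
    PEDIGREE_INFERRED = "pedigree_inferred"


@dataclass(frozen=True, order=True)
class AlleleCall:
    """One allele at one locus.

    ``composite`` marks the duplicated-DQB1 pair handled as a single allele
    (name ``013017``); it is only valid at DQB1.
    """
    locus: Locus
    name: str
    composite: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("allele name must be non-empty")
        if self.composite and self.locus is not Locus.DQB1:
            raise ValueError(
                f"composite allele only permitted at DQB1, got {self.locus}")


def _canonical_pair(pair):
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass
class GenotypeRecord:
    """One individual: identity, family role, and unordered allele pairs.

    A locus absent from ``genotype`` means missing data at that locus.  Allele
    pairs are stored lexicographically sorted; phase is unknown.
    """
    individual_id: str
    family_id: str
    role: Role
    breed: str = ""
    sex: Optional[str] = None
    genotype: dict = field(default_factory=dict)  # Locus -> (AlleleCall, AlleleCall)

    def __post_init__(self) -> None:
        self.genotype = {
            loc: _canonical_pair(pair) for loc, pair in self.genotype.items()
        }

    def allele_names(self, locus: Locus):
        """Unordered pair of allele names at *locus*, or ``None`` if missing."""
        pair = self.genotype.get(locus)
        if pair is None:
            return None
        return (pair[0].name, pair[1].name)

    def is_heterozygous(self, locus: Locus) -> Optional[bool]:
        pair = self.genotype.get(locus)
        if pair is None:
            return None
        return pair[0].name != pair[1].name


@dataclass
class Family:
    """A dam x sire pair and all their sampled offspring.

    Multiple litters of the same parental pair are merged into one family.
    """
    family_id: str
    dam: GenotypeRecord
    sire: GenotypeRecord
    offspring: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.offspring:
            raise ValueError(f"family {self.family_id} has no offspring")

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)


@dataclass
class AlleleSequence:
    """Exon-2 sequence of one allele (amino acid, optionally nucleotide)."""
    allele: AlleleCall
    aa_seq: str
    nt_seq: Optional[str] = None

    def residue(self, codon_position: int) -> str:
        """Residue at a 1-based codon position of the exon-2 peptide."""
        if codon_position < 1 or codon_position > len(self.aa_seq):
            raise IndexError(
                f"codon {codon_position} outside sequence of "
                f"{self.allele.locus}*{self.allele.name} "
                f"(length {len(self.aa_seq)})")
        return self.aa_seq[codon_position - 1]


@dataclass(frozen=True, order=True)
class Haplotype:
    """Ordered three-locus haplotype (DRB1, DQA1, DQB1 allele names)."""
    drb1: str
    dqa1: str
    dqb1: str

    def __post_init__(self) -> None:
        if not (self.drb1 and self.dqa1 and self.dqb1):
            raise ValueError("haplotype fields must be non-empty")

    def allele(self, locus: Locus) -> str:
        return {Locus.DRB1: self.drb1, Locus.DQA1: self.dqa1,
                Locus.DQB1: self.dqb1}[locus]

    def __str__(self) -> str:
        return f"{self.drb1}/{self.dqa1}/{self.dqb1}"


@dataclass
class HaplotypePair:
    """Resolved pair of three-locus haplotypes for one individual."""
    individual_id: str
    haplotypes: tuple            # (Haplotype, Haplotype), sorted
    provenance: tuple = (Provenance.HOMOZYGOUS_DIRECT,) * 2

    def __post_init__(self) -> None:
        h1, h2 = self.haplotypes
        if h2 < h1:
            self.haplotypes = (h2, h1)
            self.provenance = tuple(reversed(self.provenance))

    def alleles_at(self, locus: Locus):
        """Unordered allele-name pair implied at *locus*."""
        h1, h2 = self.haplotypes
        a, b = h1.allele(locus), h2.allele(locus)
        return (a, b) if a <= b else (b, a)

    def matches_genotype(self, genotype_names: dict) -> bool:
        """True if the per-locus allele multisets equal *genotype_names*
        (mapping Locus -> sorted name pair)."""
        return all(self.alleles_at(loc) == tuple(sorted(pair))
                   for loc, pair in genotype_names.items())
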