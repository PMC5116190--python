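"""Family assembly and Mendelian-consistency validation.

A *family* is one dam x sire pair with all their sampled offspring; multiple
litters of the same pair are merged.  A parent may appear in several families
(different mates), and an individual may be offspring in one family and
parent in another.
"""
from __future__ import annotations

from typing import Iterable, Optional

from .types import Family, GenotypeRecord, Locus, Role

__all__ = ["assemble_families", "validate_mendelian", "mendelian_flags"]

OK = "ok"
INCOMPATIBLE = "incompatible"
EXCLUDED_RECOMBINANT = "excluded_recombinant"


def assemble_families(records: Iterable, *, return_orphans: bool = False):
    """Group genotype records into dam x sire families.

    Offspring of repeated dam x sire pairs (multiple litters) are merged into
    one family, keyed by the parental pair rather than the input family_id.
    Offspring whose family lacks a genotyped dam or sire are excluded as
    orphans (returned separately when ``return_orphans``).
    """
    records = list(records)
    dams, sires, kids = {}, {}, {}
    by_id = {}
    for rec in records:
        by_id[rec.individual_id] = rec
        if rec.role is Role.DAM:
            prev = dams.get(rec.family_id)
            if prev is not None and prev.individual_id != rec.individual_id:
                raise ValueError(f"family {rec.family_id} has two dams")
            dams[rec.family_id] = rec
        elif rec.role is Role.SIRE:
            prev = sires.get(rec.family_id)
            if prev is not None and prev.individual_id != rec.individual_id:
                raise ValueError(f"family {rec.family_id} has two sires")
            sires[rec.family_id] = rec
        else:
            kids.setdefault(rec.family_id, []).append(rec)

    merged = {}   # (dam_id, sire_id) -> (dam, sire, [offspring])
    orphans = []
    for fam_id in sorted(kids):
        dam, sire = dams.get(fam_id), sires.get(fam_id)
        if dam is None or sire is None:
            orphans.extend(kids[fam_id])
            continue
        key = (dam.individual_id, sire.individual_id)
        if key not in merged:
            merged[key] = (dam, sire, [])
        merged[key][2].extend(kids[fam_id])
    # parent rows with no offspring rows at all are silently dropped

    families = [
        Family(family_id=f"{dam_id}x{sire_id}", dam=dam, sire=sire,
               offspring=offs)
        for (dam_id, sire_id), (dam, sire, offs) in sorted(merged.items())
    ]
    if return_orphans:
        return families, orphans
    return families


def _compatible(pair, dam_pair, sire_pair) -> bool:
    a, b = pair
    return ((a in dam_pair and b in sire_pair)
            or (b in dam_pair and a in sire_pair))


def validate_mendelian(family: Family, locus: Locus,
                       recombinant_alleles: Optional[set] = None) -> dict:
    """Per-offspring Mendelian status at one locus.

    Returns ``{offspring_id: status}`` with status one of ``ok``,
    ``incompatible`` (the pair cannot be formed from one maternal plus one
    paternal allele) or ``excluded_recombinant`` (the offspring carries an
    allele listed in *recombinant_alleles*; that locus is dropped for that
    individual only).  Parents must both be genotyped at *locus*.
    """
    dam_pair = family.dam.allele_names(locus)
    sire_pair = family.sire.allele_names(locus)
    if dam_pair is None or sire_pair is None:
        raise ValueError(
            f"both parents of family {family.family_id} must be genotyped "
            f"at {locus.value}")
    recomb = recombinant_alleles or set()
    status = {}
    for kid in family.offspring:
        pair = kid.allele_names(locus)
        if pair is None:
            continue
        if recomb & set(pair):
            status[kid.individual_id] = EXCLUDED_RECOMBINANT
        elif _compatible(pair, dam_pair, sire_pair):
            status[kid.individual_id] = OK
        else:
            status[kid.individual_id] = INCOMPATIBLE
    return status


def mendelian_flags(families, loci=tuple(Locus),
                    recombinant_alleles: Optional[set] = None):
    """Flatten non-ok validation statuses over families and loci.

    Yields ``(family_id, individual_id, locus, status)`` rows suitable for
    :func:`famsel.io.write_validation_report`.
    """
    for family in families:
        for locus in loci:
            if (family.dam.allele_names(locus) is None
                    or family.sire.allele_names(locus) is None):
                continue
            for ind, status in validate_mendelian(
                    family, locus, recombinant_alleles).items():
                if status != OK:
                    yield (family.family_id, ind, locus, status)
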