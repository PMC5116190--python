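"""Three-locus haplotype determination.

Under strong linkage disequilibrium the DRB1/DQA1/DQB1 alleles travel as
haplotype blocks, so unphased three-locus genotypes can usually be resolved
without statistical phasing:

1. individuals homozygous at all three loci carry one haplotype twice;
2. heterozygous individuals are decomposed into two haplotypes already seen
   in the homozygotes;
3. rare haplotypes occurring only in heterozygotes are recovered by
   subtraction: when exactly one decomposition pairs a known haplotype with
   a novel remainder, the remainder is registered as a new haplotype.

Steps 2-3 iterate to a fixed point (a newly registered rare haplotype can
unlock further individuals).  Individuals admitting two or more valid
decompositions are reported unresolved, never guessed.  Pedigree information
(``infer_missing_parent``) and linked microsatellites
(``map_microsatellites``) supply further assignments.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

from .types import (GenotypeRecord, Haplotype, HaplotypePair, Locus,
                    Provenance)

__all__ = ["enumerate_decompositions", "infer_haplotypes",
           "infer_missing_parent", "map_microsatellites"]

LOCI = (Locus.DRB1, Locus.DQA1, Locus.DQB1)


def _genotype_names(genotype) -> Optional[dict]:
    out = {}
    for locus in LOCI:
        pair = genotype.get(locus)
        if pair is None:
            return None
        out[locus] = tuple(sorted(p.name for p in pair))
    return out


def enumerate_decompositions(names: dict) -> List[Tuple[Haplotype, Haplotype]]:
    """All unordered splits of a three-locus genotype into haplotype pairs.

    ``names`` maps each locus to its sorted allele-name pair.  At most four
    distinct unordered pairs exist (two phase choices at DQA1 and DQB1
    relative to DRB1).
    """
    (d1, d2) = names[Locus.DRB1]
    (a1, a2) = names[Locus.DQA1]
    (b1, b2) = names[Locus.DQB1]
    seen, out = set(), []
    for aa, ab in ((a1, a2), (a2, a1)):
        for ba, bb in ((b1, b2), (b2, b1)):
            h1 = Haplotype(d1, aa, ba)
            h2 = Haplotype(d2, ab, bb)
            key = (h1, h2) if h1 <= h2 else (h2, h1)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def infer_haplotypes(genotypes: Dict[str, dict],
                     known_panel: Optional[Iterable] = None):
    """Resolve three-locus haplotype pairs for a population.

    Parameters
    ----------
    genotypes
        ``{individual_id: {Locus: (AlleleCall, AlleleCall)}}``; individuals
        missing any of the three loci are reported unresolved.
    known_panel
        Optional haplotypes treated as already established (e.g. from a
        reference panel) before step 1.

    Returns
    -------
    resolved : dict ``{individual_id: HaplotypePair}``
    unresolved : dict ``{individual_id: list of candidate pairs}``
        Candidates are the valid decompositions at the fixed point (empty
        list for individuals with missing loci).
    """
    panel = set(known_panel or ())
    names_of = {}
    resolved: Dict[str, HaplotypePair] = {}
    unresolved: Dict[str, list] = {}

    # step 1: fully homozygous individuals define haplotypes directly
    for ind in sorted(genotypes):
        names = _genotype_names(genotypes[ind])
        if names is None:
            unresolved[ind] = []
            continue
        names_of[ind] = names
        if all(a == b for a, b in names.values()):
            hap = Haplotype(names[Locus.DRB1][0], names[Locus.DQA1][0],
                            names[Locus.DQB1][0])
            panel.add(hap)
            resolved[ind] = HaplotypePair(
                ind, (hap, hap),
                (Provenance.HOMOZYGOUS_DIRECT,) * 2)

    pending = [i for i in sorted(names_of) if i not in resolved]

    # steps 2-3 to a fixed point; new rare haplotypes are registered only at
    # the end of each round so the outcome is independent of input order
    while True:
        new_haps = set()
        next_pending = []
        for ind in pending:
            decomps = enumerate_decompositions(names_of[ind])
            both_known = [d for d in decomps
                          if d[0] in panel and d[1] in panel]
            if len(both_known) == 1:
                h1, h2 = both_known[0]
                prov = (Provenance.HOMOZYGOUS_DIRECT
                        if h1 == h2 else Provenance.INFERRED_FROM_KNOWN)
                resolved[ind] = HaplotypePair(ind, (h1, h2), (prov, prov))
                continue
            if len(both_known) > 1:
                next_pending.append(ind)
                continue
            one_known = [d for d in decomps
                         if (d[0] in panel) != (d[1] in panel)]
            if len(one_known) == 1:
                h1, h2 = one_known[0]
                known_first = h1 in panel
                rare = h2 if known_first else h1
                new_haps.add(rare)
                prov = ((Provenance.INFERRED_FROM_KNOWN, Provenance.SUBTRACTION)
                        if known_first else
                        (Provenance.SUBTRACTION, Provenance.INFERRED_FROM_KNOWN))
                resolved[ind] = HaplotypePair(ind, (h1, h2), prov)
                continue
            next_pending.append(ind)
        if not new_haps and len(next_pending) == len(pending):
            pending = next_pending
            break
        panel |= new_haps
        pending = next_pending

    for ind in pending:
        decomps = enumerate_decompositions(names_of[ind])
        both = [d for d in decomps if d[0] in panel and d[1] in panel]
        unresolved[ind] = both if both else decomps
    return resolved, unresolved


def infer_missing_parent(known_parent_pair: HaplotypePair,
                         offspring_pairs: Iterable) -> tuple:
    """Infer the un-genotyped parent's haplotypes from resolved offspring.

    Each offspring must carry one haplotype transmissible by the known
    parent; the other one is attributed to the missing parent.  The union of
    attributed haplotypes must have at most two members, else a
    :class:`ValueError` lists them (a non-paternity/-maternity signal).
    Offspring where both haplotypes match the known parent are phase-
    ambiguous for this purpose and contribute both candidates jointly (they
    never add a third).

    Returns the inferred unordered haplotype pair; if only one distinct
    haplotype was contributed it is returned twice (homozygous or partially
    unknown - indistinguishable without more data).
    """
    known = set(known_parent_pair.haplotypes)
    contributed = set()
    ambiguous = []
    for off in offspring_pairs:
        h1, h2 = off.haplotypes
        in1, in2 = h1 in known, h2 in known
        if in1 and in2:
            ambiguous.append((h1, h2))
        elif in1:
            contributed.add(h2)
        elif in2:
            contributed.add(h1)
        else:
            raise ValueError(
                f"offspring {off.individual_id} carries no haplotype of the "
                "known parent")
    if len(contributed) > 2:
        raise ValueError(
            "more than two candidate haplotypes for the missing parent: "
            + ", ".join(str(h) for h in sorted(contributed)))
    if not contributed:
        if not ambiguous:
            raise ValueError("no informative offspring")
        # every offspring matches the known parent on both sides: the missing
        # parent carries haplotypes from the known parent's own pair
        cands = {h for pair in ambiguous for h in pair}
        if len(cands) == 1:
            (h,) = cands
            return (h, h)
        raise ValueError("missing parent not identifiable: all offspring "
                         "phase-ambiguous with multiple candidates")
    if len(contributed) == 1:
        (h,) = contributed
        return (h, h)
    return tuple(sorted(contributed))


def map_microsatellites(dual_typed: Dict[str, tuple],
                        msat_only: Dict[str, tuple]):
    """Assign DLA haplotypes from linked microsatellite genotypes.

    ``dual_typed`` maps individual id to ``(msat_genotype, HaplotypePair)``
    where ``msat_genotype`` is a tuple of per-marker unordered allele pairs
    (markers CFA12-3, CFA12-4, CFA12-9 in fixed order).  The marker-allele
    combination -> haplotype map is learned from exact matches in individuals
    homozygous for both data types; a combination mapping to two haplotypes
    raises :class:`ValueError`.

    ``msat_only`` maps individual id to a msat genotype.  Returns
    ``(assignments, unmappable)`` where assignments maps id ->
    ``HaplotypePair`` (provenance ``pedigree_inferred``) and unmappable is a
    list of ids whose combinations are unknown or phase-ambiguous.
    """
    mapping: Dict[tuple, Haplotype] = {}
    for ind in sorted(dual_typed):
        msat, pair = dual_typed[ind]
        hom_msat = all(a == b for a, b in msat)
        h1, h2 = pair.haplotypes
        if hom_msat and h1 == h2:
            combo = tuple(a for a, _ in msat)
            prev = mapping.get(combo)
            if prev is not None and prev != h1:
                raise ValueError(
                    f"microsatellite combination {combo} maps to both "
                    f"{prev} and {h1}")
            mapping[combo] = h1

    assignments, unmappable = {}, []
    for ind in sorted(msat_only):
        msat = msat_only[ind]
        # enumerate phase splits across markers, keep splits where both
        # resulting combinations are in the learned map
        n = len(msat)
        valid = set()
        for mask in range(2 ** n):
            c1 = tuple(msat[i][(mask >> i) & 1] for i in range(n))
            c2 = tuple(msat[i][1 - ((mask >> i) & 1)] for i in range(n))
            if c1 in mapping and c2 in mapping:
                haps = (mapping[c1], mapping[c2])
                valid.add(tuple(sorted(haps)))
        if len(valid) == 1:
            h1, h2 = valid.pop()
            assignments[ind] = HaplotypePair(
                ind, (h1, h2), (Provenance.PEDIGREE_INFERRED,) * 2)
        else:
            unmappable.append(ind)
    return assignments, unmappable
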