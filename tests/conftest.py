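import numpy as np
import pytest

from famsel.types import (AlleleCall, AlleleSequence, Family, GenotypeRecord,
                          Haplotype, Locus, Role)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def geno(drb1=None, dqa1=None, dqb1=None):
    """Build a genotype dict from 'a/b' strings per locus."""
    out = {}
    for locus, spec in ((Locus.DRB1, drb1), (Locus.DQA1, dqa1),
                        (Locus.DQB1, dqb1)):
        if spec is None:
            continue
        a, b = spec.split("/")
        out[locus] = (AlleleCall(locus, a), AlleleCall(locus, b))
    return out


def record(ind, fam, role, genotype=None, breed="Saluki", sex=None):
    return GenotypeRecord(individual_id=ind, family_id=fam, role=Role(role),
                          breed=breed, sex=sex, genotype=genotype or {})


def trio_family(dam_g, sire_g, kid_gs, fam="F1", breed="Saluki"):
    """Family from genotype dicts; offspring ids o1, o2, ..."""
    dam = record("dam", fam, "dam", dam_g, breed=breed, sex="F")
    sire = record("sire", fam, "sire", sire_g, breed=breed, sex="M")
    kids = [record(f"o{i+1}", fam, "offspring", g, breed=breed)
            for i, g in enumerate(kid_gs)]
    return Family(fam, dam, sire, kids)


def synthetic_sequence(locus, name, residues_at, length=95, fill="A"):
    """AlleleSequence with given residues at 1-based codon positions.

    Labelled synthetic: stands in for exon-2 peptides that are not packaged.
    """
    seq = [fill] * length
    for pos, res in residues_at.items():
        seq[pos - 1] = res
    return AlleleSequence(AlleleCall(locus, name), "".join(seq))


def planted_group_sequences(locus, sites, n_groups, per_group, rng,
                            within_jitter=0):
    """Allele sequences in planted groups: each group has its own residue
    pattern on the candidate sites; optional within-group jitter at extra
    non-candidate positions (does not affect PBR features)."""
    seqs, labels = [], []
    patterns = []
    for g in range(n_groups):
        perm = rng.permutation(len(AMINO_ACIDS))
        patterns.append({pos: AMINO_ACIDS[perm[i % 20]]
                         for i, pos in enumerate(sites)})
    for g in range(n_groups):
        for j in range(per_group):
            name = f"s{g}{j:02d}"
            seqs.append(synthetic_sequence(locus, name, patterns[g]))
            labels.append(g)
    return seqs, np.array(labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20160938)
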