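"""Maternal-effect transmission tests.

When the father shares an allele with the mother, the offspring can inherit
from him either the maternal-shared allele or his non-shared one.  Two cross
contexts qualify (mother x father): A1A2 x A1A3 and A1A1 x A1A2; in both the
paternal transmitted allele is unambiguous for every Mendelian-consistent
offspring.  Shared vs non-shared transmission is tested against the 1:1
expectation with the Monte-Carlo chi-squared of
:mod:`famsel.segregation`.  A positive ``direction`` means an excess of
shared transmissions (a histo-compatibility advantage); a negative one an
excess of non-shared (the incompatibility-advantage expectation).

Separately, ``het_mother_pooled`` pools all heterozygous-mother cross types
(HETxHOM, HETxHET_same, HETxHET_oneshared) into one heterozygosity test
with their respective Mendelian fractions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .segregation import (CrossType, HET_FRACTION, SegregationResult,
                          chisq_mc, classify_cross, combine_crosses,
                          accumulate_cross_counts, _allele_level_map,
                          _supertype_level_map)
from .types import Family, Locus

__all__ = ["TransmissionCount", "paternal_transmission", "het_mother_pooled"]

QUALIFYING = (CrossType.HETxHET_oneshared, CrossType.HOMxHET)


@dataclass
class TransmissionCount:
    """Shared/non-shared paternal transmissions in one cross context."""
    level: str
    locus: Optional[Locus]
    context: CrossType
    n_shared: int
    n_nonshared: int
    chi2: float
    p_mc: float
    B: int
    excluded: int = 0

    @property
    def n(self) -> int:
        return self.n_shared + self.n_nonshared

    @property
    def direction(self) -> float:
        """Signed shared-excess fraction: (shared - nonshared) / n."""
        if self.n == 0:
            return 0.0
        return (self.n_shared - self.n_nonshared) / self.n


def _score_offspring(cross: CrossType, m_pair, p_pair, k_pair
                     ) -> Optional[bool]:
    """True = shared paternal allele transmitted, False = non-shared,
    None = unscorable (Mendelian-inconsistent or missing)."""
    if k_pair is None:
        return None
    shared = (set(m_pair) & set(p_pair)).pop()
    nonshared = next(a for a in p_pair if a != shared)
    if cross is CrossType.HETxHET_oneshared:
        # mother A1A2 x father A1A3: A3 present => non-shared transmitted
        if nonshared in k_pair:
            return False
        if shared in k_pair:
            return True
        return None
    # mother A1A1 x father A1A2
    if sorted(k_pair) == sorted((shared, nonshared)):
        return False
    if k_pair[0] == k_pair[1] == shared:
        return True
    return None


def paternal_transmission(families: Sequence[Family], level: str = "allele",
                          locus: Optional[Locus] = None, *,
                          supertype_model=None, pooled: bool = True,
                          B: int = 2000, seed=None
                          ) -> List[TransmissionCount]:
    """Test paternal shared vs non-shared allele transmission.

    Returns one :class:`TransmissionCount` per qualifying cross context and
    (with ``pooled``) a final pooled row (context ``None`` is not used; the
    pooled row reuses ``HETxHET_oneshared`` context label only when a single
    context is present, otherwise ``context`` is None).
    """
    if level == "allele":
        mapper = _allele_level_map(locus)
    elif level == "supertype":
        if supertype_model is None:
            raise ValueError("supertype level needs a SupertypeModel")
        mapper = _supertype_level_map(locus, supertype_model)
    else:
        raise ValueError("level must be 'allele' or 'supertype'")
    rng = np.random.default_rng(seed)

    counts = {ct: [0, 0, 0] for ct in QUALIFYING}   # shared, nonshared, excl
    for fam in families:
        m_pair, p_pair = mapper(fam.dam), mapper(fam.sire)
        if m_pair is None or p_pair is None:
            continue
        cross = classify_cross(m_pair, p_pair)
        if cross not in QUALIFYING:
            continue
        for kid in fam.offspring:
            res = _score_offspring(cross, m_pair, p_pair, mapper(kid))
            if res is None:
                counts[cross][2] += 1
            elif res:
                counts[cross][0] += 1
            else:
                counts[cross][1] += 1

    out: List[TransmissionCount] = []
    for ct in QUALIFYING:
        shared, nonshared, excl = counts[ct]
        if shared + nonshared == 0:
            continue
        chi2, p = chisq_mc((shared, nonshared), 0.5, B=B, seed=rng)
        out.append(TransmissionCount(level, locus, ct, shared, nonshared,
                                     chi2, p, B, excluded=excl))
    if pooled and out:
        shared = sum(t.n_shared for t in out)
        nonshared = sum(t.n_nonshared for t in out)
        chi2, p = chisq_mc((shared, nonshared), 0.5, B=B, seed=rng)
        out.append(TransmissionCount(
            level, locus, None, shared, nonshared, chi2, p, B,
            excluded=sum(t.excluded for t in out)))
    return out


def het_mother_pooled(families: Sequence[Family], level: str = "allele",
                      locus: Optional[Locus] = None, *,
                      supertype_model=None, B: int = 2000,
                      seed=None) -> SegregationResult:
    """Pooled heterozygosity test over all heterozygous-mother families.

    Offspring counts from HETxHOM, HETxHET_same and HETxHET_oneshared
    crosses are combined with their Mendelian fractions (1/2, 1/2, 3/4)
    into one 1-df chi-squared with a Monte-Carlo p-value.
    """
    if level == "allele":
        mapper = _allele_level_map(locus)
    elif level == "supertype":
        if supertype_model is None:
            raise ValueError("supertype level needs a SupertypeModel")
        mapper = _supertype_level_map(locus, supertype_model)
    else:
        raise ValueError("level must be 'allele' or 'supertype'")
    rng = np.random.default_rng(seed)
    counts = accumulate_cross_counts(families, mapper)
    het_mother = {ct: tuple(counts[ct]) for ct in
                  (CrossType.HETxHOM, CrossType.HETxHET_same,
                   CrossType.HETxHET_oneshared)
                  if sum(counts[ct]) > 0}
    if not het_mother:
        raise ValueError("no informative heterozygous-mother families")
    stat, df, p = combine_crosses(het_mother, mode="pool", B=B, seed=rng)
    o_het = sum(h for h, _ in het_mother.values())
    o_hom = sum(m for _, m in het_mother.values())
    e_het = sum(HET_FRACTION[ct] * (h + m)
                for ct, (h, m) in het_mother.items())
    return SegregationResult(
        level=level, locus=locus, cross=None, obs_het=o_het, obs_hom=o_hom,
        exp_het=e_het, exp_hom=(o_het + o_hom) - e_het, chi2=stat, df=df,
        p_mc=p, B=B, subset="het_mothers", mode="pool")
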