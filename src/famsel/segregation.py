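"""Family-based Mendelian segregation tests.

Offspring heterozygote/homozygote ratios are compared with Mendelian
expectations within four informative mating cross types (mother x father):

====================  ==========================  ================
cross type            parental genotypes          expected het
====================  ==========================  ================
HOMxHET               A1A1 x A1A2                 1/2
HETxHOM               A1A2 x A1A1                 1/2
HETxHET_same          A1A2 x A1A2                 1/2
HETxHET_oneshared     A1A2 x A1A3                 3/4
====================  ==========================  ================

Any other parental configuration is uninformative for heterozygosity.
Deviations are tested per cross type with a 1-df Pearson chi-squared and a
Monte-Carlo p-value (binomial resampling at the Mendelian fraction), and
combined over cross types either by pooling observed/expected counts into
one 1-df test (default) or by summing the chi-squared statistics.  The same
machinery runs at allele, three-locus-haplotype, supertype and PBR-site
levels, over breed/sex/purity subsets, with Storey q-values for the
per-site multiple tests.  Allele identity is deliberately discarded within
cross types: counts are pooled over whichever alleles play the A1/A2/A3
roles.
"""
from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import Family, Locus, COMPOSITE_DQB1

__all__ = [
    "CrossType", "classify_cross", "expected_counts", "chisq_mc",
    "combine_crosses", "site_genotype", "run_level_analysis", "qvalues",
    "SegregationResult", "family_has_composite",
]

DEFAULT_B = 2000


class CrossType(str, enum.Enum):
    HOMxHET = "HOMxHET"                    # A1A1 x A1A2
    HETxHOM = "HETxHOM"                    # A1A2 x A1A1
    HETxHET_same = "HETxHET_same"          # A1A2 x A1A2
    HETxHET_oneshared = "HETxHET_oneshared"  # A1A2 x A1A3
    uninformative = "uninformative"


#: Mendelian heterozygote fraction per informative cross type.
HET_FRACTION = {
    CrossType.HOMxHET: 0.5,
    CrossType.HETxHOM: 0.5,
    CrossType.HETxHET_same: 0.5,
    CrossType.HETxHET_oneshared: 0.75,
}


def classify_cross(maternal_pair, paternal_pair) -> CrossType:
    """Classify a mother x father genotype pair at any analysis level.

    Pairs are unordered 2-tuples of hashable labels (allele names, supertype
    classes, residues...).  Only configurations where parents share at least
    one label and offspring heterozygosity is informative qualify.
    """
    m1, m2 = maternal_pair
    p1, p2 = paternal_pair
    m_hom, p_hom = m1 == m2, p1 == p2
    shared = set(maternal_pair) & set(paternal_pair)
    if not shared:
        return CrossType.uninformative
    if m_hom and p_hom:
        return CrossType.uninformative      # A1A1 x A1A1: all offspring equal
    if m_hom and not p_hom:
        return CrossType.HOMxHET if m1 in (p1, p2) else CrossType.uninformative
    if not m_hom and p_hom:
        return CrossType.HETxHOM if p1 in (m1, m2) else CrossType.uninformative
    # both heterozygous
    if set(maternal_pair) == set(paternal_pair):
        return CrossType.HETxHET_same
    if len(shared) == 1:
        return CrossType.HETxHET_oneshared
    return CrossType.uninformative


def expected_counts(cross: CrossType, n_offspring: int) -> Tuple[float, float]:
    """Mendelian (expected het, expected hom) for *n_offspring*."""
    if cross not in HET_FRACTION:
        raise ValueError(f"cross type {cross} is uninformative")
    f = HET_FRACTION[cross]
    return (f * n_offspring, (1 - f) * n_offspring)


def _chi2_stat(obs_het: float, obs_hom: float, frac: float) -> float:
    n = obs_het + obs_hom
    e_het, e_hom = frac * n, (1 - frac) * n
    return (obs_het - e_het) ** 2 / e_het + (obs_hom - e_hom) ** 2 / e_hom


@dataclass
class SegregationResult:
    """One test row: a cross type (or pooled combination) at one level."""
    level: str
    locus: Optional[Locus]
    cross: Optional[CrossType]          # None for combined rows
    obs_het: int
    obs_hom: int
    exp_het: float
    exp_hom: float
    chi2: float
    df: int
    p_mc: float
    B: int
    subset: str = "all"
    site_index: Optional[int] = None
    codon_position: Optional[int] = None
    q_value: Optional[float] = None
    mode: Optional[str] = None          # "pool"/"sum" for combined rows

    @property
    def n(self) -> int:
        return self.obs_het + self.obs_hom


def chisq_mc(obs: Tuple[int, int], exp_fraction: float,
             B: int = DEFAULT_B,
             seed: Optional[int | np.random.Generator] = None
             ) -> Tuple[float, float]:
    """Pearson chi-squared for (het, hom) counts with a Monte-Carlo p-value.

    The statistic is the usual two-cell chi-squared against expectation
    ``exp_fraction``; the p-value is ``(1 + #{chi2_sim >= chi2_obs}) /
    (B + 1)`` over B binomial resamples of the heterozygote count at the
    expected fraction, so p is never exactly zero.  Returns ``(chi2, p)``.
    """
    obs_het, obs_hom = obs
    n = obs_het + obs_hom
    if n < 1:
        raise ValueError("need at least one offspring")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    chi2_obs = _chi2_stat(obs_het, obs_hom, exp_fraction)
    sim_het = rng.binomial(n, exp_fraction, size=B)
    e_het, e_hom = exp_fraction * n, (1 - exp_fraction) * n
    chi2_sim = ((sim_het - e_het) ** 2 / e_het
                + ((n - sim_het) - e_hom) ** 2 / e_hom)
    p = (1 + int(np.sum(chi2_sim >= chi2_obs - 1e-12))) / (B + 1)
    return float(chi2_obs), float(p)


def combine_crosses(per_cross: Dict[CrossType, Tuple[int, int]],
                    mode: str = "pool", B: int = DEFAULT_B,
                    seed: Optional[int | np.random.Generator] = None
                    ) -> Tuple[float, int, float]:
    """Combine per-cross-type (het, hom) tables into one test.

    ``mode="pool"`` (default) sums observed and expected counts over cross
    types into a single 1-df chi-squared; the Monte-Carlo null resamples
    each cross type at its own fraction and n before pooling.
    ``mode="sum"`` adds the per-type chi-squared statistics (df = number of
    types), with the analogous Monte-Carlo null.  Returns ``(stat, df, p)``.
    """
    tables = [(ct, het, hom) for ct, (het, hom) in per_cross.items()
              if het + hom > 0]
    if not tables:
        raise ValueError("no informative cross type with offspring")
    rng = np.random.default_rng(seed)
    ns = np.array([het + hom for _, het, hom in tables])
    fracs = np.array([HET_FRACTION[ct] for ct, _, _ in tables])
    obs_het = np.array([het for _, het, _ in tables])

    sims = rng.binomial(ns[:, None], fracs[:, None], size=(len(tables), B))
    if mode == "pool":
        e_het = float(np.sum(ns * fracs))
        e_hom = float(np.sum(ns * (1 - fracs)))
        o_het, o_hom = int(obs_het.sum()), int((ns - obs_het).sum())
        stat = (o_het - e_het) ** 2 / e_het + (o_hom - e_hom) ** 2 / e_hom
        sim_het = sims.sum(axis=0)
        sim_stat = ((sim_het - e_het) ** 2 / e_het
                    + ((ns.sum() - sim_het) - e_hom) ** 2 / e_hom)
        df = 1
    elif mode == "sum":
        stat = float(sum(_chi2_stat(het, hom, HET_FRACTION[ct])
                         for ct, het, hom in tables))
        e_het = ns[:, None] * fracs[:, None]
        e_hom = ns[:, None] * (1 - fracs[:, None])
        sim_stat = ((sims - e_het) ** 2 / e_het
                    + ((ns[:, None] - sims) - e_hom) ** 2 / e_hom).sum(axis=0)
        df = len(tables)
    else:
        raise ValueError("mode must be 'pool' or 'sum'")
    p = (1 + int(np.sum(sim_stat >= stat - 1e-12))) / (B + 1)
    return float(stat), df, float(p)


# ---------------------------------------------------------------------------
# level mapping

def site_genotype(allele_pair, locus: Locus, codon: int,
                  allele_seqs: dict) -> Optional[Tuple[str, str]]:
    """Amino-acid pair at one PBR codon implied by an allele pair.

    ``allele_seqs`` maps ``(Locus, allele_name) -> AlleleSequence``.
    Identical residues mean site-homozygous even when the alleles differ.
    Returns ``None`` (caller excludes and reports) when a sequence is
    missing — including for the composite duplicated-DQB1 allele, which has
    no single-copy sequence.
    """
    residues = []
    for name in allele_pair:
        seq = allele_seqs.get((locus, name))
        if seq is None:
            return None
        residues.append(seq.residue(codon))
    return tuple(sorted(residues))


def family_has_composite(family: Family) -> bool:
    """True when any member carries the duplicated-DQB1 composite allele."""
    members = [family.dam, family.sire, *family.offspring]
    for rec in members:
        pair = rec.genotype.get(Locus.DQB1)
        if pair and any(c.composite or c.name == COMPOSITE_DQB1 for c in pair):
            return True
    return False


def _apply_dup_policy(families: Sequence[Family], dup_policy: str):
    if dup_policy == "composite":
        return list(families)
    if dup_policy == "exclude_dup_families":
        return [f for f in families if not family_has_composite(f)]
    if dup_policy == "only_dup_families":
        return [f for f in families if family_has_composite(f)]
    raise ValueError(f"unknown dup-policy {dup_policy!r}")


def _allele_level_map(locus):
    def mapper(rec):
        return rec.allele_names(locus)
    return mapper


def _supertype_level_map(locus, model):
    def mapper(rec):
        pair = rec.allele_names(locus)
        if pair is None:
            return None
        return model.map_pair(pair)
    return mapper


def _site_level_map(locus, codon, allele_seqs):
    def mapper(rec):
        pair = rec.allele_names(locus)
        if pair is None:
            return None
        return site_genotype(pair, locus, codon, allele_seqs)
    return mapper


def _haplotype_level_map(haplotype_pairs):
    def mapper(rec):
        hp = haplotype_pairs.get(rec.individual_id)
        if hp is None:
            return None
        h1, h2 = hp.haplotypes
        return (str(h1), str(h2))
    return mapper


def accumulate_cross_counts(families: Sequence[Family],
                            level_map: Callable) -> Dict[CrossType, List[int]]:
    """Observed (het, hom) offspring counts per informative cross type.

    ``level_map(record)`` returns the individual's unordered label pair at
    the analysis level, or None for missing.  Offspring whose pair is
    missing, or inconsistent with the parental cross (no label shared with
    the parents' union), are skipped.
    """
    counts = {ct: [0, 0] for ct in HET_FRACTION}
    for fam in families:
        m_pair = level_map(fam.dam)
        p_pair = level_map(fam.sire)
        if m_pair is None or p_pair is None:
            continue
        cross = classify_cross(m_pair, p_pair)
        if cross is CrossType.uninformative:
            continue
        parent_labels = set(m_pair) | set(p_pair)
        for kid in fam.offspring:
            k_pair = level_map(kid)
            if k_pair is None or not set(k_pair) <= parent_labels:
                continue
            het = k_pair[0] != k_pair[1]
            counts[cross][0 if het else 1] += 1
    return counts


def _subset_families(families, by: Optional[str], breed_info=None):
    """Split families into labelled subsets: None/'breed'/'sex'/'purity'."""
    if by is None:
        return {"all": list(families)}
    subsets: Dict[str, list] = {}
    if by == "breed":
        for f in families:
            subsets.setdefault(f.dam.breed or "unknown", []).append(f)
    elif by == "purity":
        purebred = breed_info or {}
        for f in families:
            label = ("purebred"
                     if purebred.get(f.dam.breed, "mixed" not in
                                     f.dam.breed.lower())
                     else "mixed")
            subsets.setdefault(label, []).append(f)
    elif by == "sex":
        # offspring-level split: families retained, offspring filtered
        for label in ("F", "M"):
            filtered = []
            for f in families:
                kids = [k for k in f.offspring if k.sex == label]
                if kids:
                    filtered.append(Family(f.family_id, f.dam, f.sire, kids))
            subsets[label] = filtered
    else:
        raise ValueError(f"unknown subset key {by!r}")
    return subsets


def run_level_analysis(families: Sequence[Family], level: str,
                       locus: Optional[Locus] = None, *,
                       supertype_model=None, allele_seqs: Optional[dict] = None,
                       haplotype_pairs: Optional[dict] = None,
                       codons: Optional[Sequence[int]] = None,
                       by: Optional[str] = None, breed_info=None,
                       dup_policy: str = "composite",
                       combine_mode: str = "pool",
                       B: int = DEFAULT_B, seed=None) -> List[SegregationResult]:
    """Run segregation tests at one analysis level.

    ``level`` is ``allele``, ``haplotype``, ``supertype`` or ``site``.
    Site-level analyses always exclude duplicated-DQB1 families and emit one
    block of rows per codon in *codons* plus Storey q-values on the combined
    p-values.  Subsets (``by``) produce independent result rows.
    """
    rng = np.random.default_rng(seed)
    if level in ("allele", "supertype", "site") and locus is None:
        raise ValueError(f"{level}-level analysis needs a locus")
    if level == "supertype" and supertype_model is None:
        raise ValueError("supertype level needs a SupertypeModel")
    if level == "haplotype" and haplotype_pairs is None:
        raise ValueError("haplotype level needs resolved haplotype pairs")
    if level == "site":
        if allele_seqs is None or not codons:
            raise ValueError("site level needs allele sequences and codons")
        dup_policy = "exclude_dup_families"
    if level == "supertype" and locus is Locus.DQB1:
        dup_policy = "exclude_dup_families"

    families = _apply_dup_policy(families, dup_policy)
    results: List[SegregationResult] = []
    for subset_label, fams in sorted(_subset_families(
            families, by, breed_info).items()):
        if not fams:
            warnings.warn(f"subset {subset_label!r} is empty")
            continue
        if level == "site":
            combined_ps = []
            site_rows: List[List[SegregationResult]] = []
            for idx, codon in enumerate(codons, start=1):
                mapper = _site_level_map(locus, codon, allele_seqs)
                rows = _test_block(fams, mapper, level, locus, subset_label,
                                   combine_mode, B, rng)
                for r in rows:
                    r.site_index, r.codon_position = idx, codon
                if rows:
                    combined_ps.append(rows[-1].p_mc)
                    site_rows.append(rows)
            qs = qvalues([p for p in combined_ps])
            for rows, q in zip(site_rows, qs):
                rows[-1].q_value = float(q)
            results.extend(r for rows in site_rows for r in rows)
            continue
        if level == "allele":
            mapper = _allele_level_map(locus)
        elif level == "supertype":
            mapper = _supertype_level_map(locus, supertype_model)
        else:
            mapper = _haplotype_level_map(haplotype_pairs)
        results.extend(_test_block(fams, mapper, level, locus, subset_label,
                                   combine_mode, B, rng))
    return results


def _test_block(fams, mapper, level, locus, subset_label, combine_mode, B,
                rng) -> List[SegregationResult]:
    counts = accumulate_cross_counts(fams, mapper)
    rows = []
    nonempty = {ct: (het, hom) for ct, (het, hom) in counts.items()
                if het + hom > 0}
    for ct, (het, hom) in nonempty.items():
        frac = HET_FRACTION[ct]
        chi2, p = chisq_mc((het, hom), frac, B=B, seed=rng)
        e_het, e_hom = expected_counts(ct, het + hom)
        rows.append(SegregationResult(
            level=level, locus=locus, cross=ct, obs_het=het, obs_hom=hom,
            exp_het=e_het, exp_hom=e_hom, chi2=chi2, df=1, p_mc=p, B=B,
            subset=subset_label))
    if nonempty:
        stat, df, p = combine_crosses(nonempty, mode=combine_mode, B=B,
                                      seed=rng)
        o_het = sum(h for h, _ in nonempty.values())
        o_hom = sum(m for _, m in nonempty.values())
        e_het = sum(expected_counts(ct, h + m)[0]
                    for ct, (h, m) in nonempty.items())
        e_hom = sum(expected_counts(ct, h + m)[1]
                    for ct, (h, m) in nonempty.items())
        rows.append(SegregationResult(
            level=level, locus=locus, cross=None, obs_het=o_het,
            obs_hom=o_hom, exp_het=e_het, exp_hom=e_hom, chi2=stat, df=df,
            p_mc=p, B=B, subset=subset_label, mode=combine_mode))
    return rows


# ---------------------------------------------------------------------------
# multiple testing

def qvalues(p_values: Sequence[float], *, pi0: Optional[float] = None,
            lambdas: Optional[np.ndarray] = None) -> np.ndarray:
    """Storey q-values with smoother pi0 estimation.

    pi0 (the null proportion) is estimated by fitting a cubic smoothing
    spline to pi0(lambda) over a lambda grid and evaluating at the largest
    lambda.  With fewer than 10 p-values the estimate is unstable, so pi0
    falls back to 1 (Benjamini-Hochberg-equivalent) with a warning.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    if pi0 is None:
        if m < 10:
            if m > 1:
                warnings.warn("fewer than 10 p-values; using pi0 = 1 "
                              "(BH-equivalent)")
            pi0 = 1.0
        else:
            if lambdas is None:
                lambdas = np.arange(0.05, 0.95, 0.05)
            pi0_l = np.array([np.mean(p > lam) / (1 - lam)
                              for lam in lambdas])
            from scipy.interpolate import UnivariateSpline
            spl = UnivariateSpline(lambdas, pi0_l, k=3)
            pi0 = float(np.clip(spl(lambdas[-1]), 1e-8, 1.0))
    order = np.argsort(p)[::-1]          # descending
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order):
        rank = m - rank_from_top          # number of p <= p[i]
        val = min(pi0 * m * p[i] / rank, prev)
        q[i] = val
        prev = val
    return q
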