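"""Synthetic breed-structured dog families with known haplotype truth.

Parents are drawn as two three-locus haplotypes each from per-breed
frequency panels (default: the packaged study panel); litter sizes follow a
truncated negative binomial with mean 3.9 on 1-16 puppies; transmission is
Mendelian unless a distortion mode is configured:

* ``anti_homozygote``: offspring homozygous at the target level survive
  with probability 1 - s (viability selection; the heterozygote fraction in
  1:1 crosses becomes 1/(2-s));
* ``maternal_shared_bias``: in qualifying crosses the father transmits the
  maternal-shared allele with probability (1+b)/2 (b < 0 models an
  incompatibility advantage, b > 0 a compatibility advantage).

Rare recombinant transmissions swap locus blocks between a parent's two
haplotypes.  Every offspring's parental haplotype origins are recorded in a
truth table so inference can be checked against the generative state.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .types import (AlleleCall, Family, GenotypeRecord, Haplotype, Locus,
                    Role, COMPOSITE_DQB1)
from .datasets import breed_panels

__all__ = ["LitterSizeModel", "SelectionMode", "SimulationConfig",
           "sample_offspring", "simulate_cross", "simulate_families",
           "families_to_records"]

LOCI = (Locus.DRB1, Locus.DQA1, Locus.DQB1)


# ---------------------------------------------------------------------------
# litter sizes

@dataclass(frozen=True)
class LitterSizeModel:
    """Truncated negative binomial litter-size distribution.

    The study design gives only the litter mean (3.9) and range (1-16); a
    negative binomial with moderate overdispersion (``r`` successes),
    truncated to that support, matches both.  ``p`` is solved so the
    truncated mean equals ``mean``.
    """
    mean: float = 3.9
    support: Tuple[int, int] = (1, 16)
    r: float = 4.0
    p: float = field(init=False, default=0.0)

    def __post_init__(self):
        lo, hi = self.support
        ks = np.arange(lo, hi + 1)

        def trunc_mean(p):
            w = stats.nbinom.pmf(ks, self.r, p)
            return float(np.sum(ks * w) / np.sum(w)) - self.mean

        object.__setattr__(self, "p", brentq(trunc_mean, 1e-6, 1 - 1e-6))

    def pmf(self) -> np.ndarray:
        lo, hi = self.support
        ks = np.arange(lo, hi + 1)
        w = stats.nbinom.pmf(ks, self.r, self.p)
        return w / w.sum()

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        lo, hi = self.support
        ks = np.arange(lo, hi + 1)
        return rng.choice(ks, size=size, p=self.pmf())


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SelectionMode:
    """Transmission-distortion setting.

    ``kind`` is ``"none"``, ``"anti_homozygote"`` (uses ``s``) or
    ``"maternal_shared_bias"`` (uses ``b``).  ``locus`` is the target locus
    (``None`` = whole-haplotype identity for anti_homozygote).  ``key``
    optionally maps an allele name to a coarser label (supertype class,
    PBR-site residue) at which homozygosity is judged.
    """
    kind: str = "none"
    s: float = 0.0
    b: float = 0.0
    locus: Optional[Locus] = None
    key: Optional[Callable[[str], object]] = None

    def __post_init__(self):
        if self.kind not in ("none", "anti_homozygote",
                             "maternal_shared_bias"):
            raise ValueError(f"unknown selection kind {self.kind!r}")
        if not 0 <= self.s < 1:
            raise ValueError("s must be in [0, 1)")
        if not -1 < self.b < 1:
            raise ValueError("b must be in (-1, 1)")
        if self.kind == "maternal_shared_bias" and self.locus is None:
            raise ValueError("maternal_shared_bias needs a target locus")

    def label(self, hap: Haplotype):
        if self.locus is None:
            return hap
        allele = hap.allele(self.locus)
        return self.key(allele) if self.key else allele


@dataclass
class SimulationConfig:
    """Study-condition parameters for the family simulator.

    Defaults emulate the study design: the packaged per-breed haplotype
    panel, litter mean 3.9 on support 1-16, no distortion, no recombination,
    no missing data, duplicated-DQB1 composite haplotypes included.
    ``seed`` is mandatory.
    """
    seed: int
    panel: Optional[Dict[str, Dict[Haplotype, float]]] = None
    n_families: Dict[str, int] | int = 8
    litter_model: LitterSizeModel = field(default_factory=LitterSizeModel)
    selection: SelectionMode = field(default_factory=SelectionMode)
    recombinant_rate: float = 0.0
    missing_rate: float = 0.0
    include_composite: bool = True

    def __post_init__(self):
        if self.panel is None:
            self.panel = breed_panels()
        if not self.include_composite:
            self.panel = {
                breed: _renormalize({h: f for h, f in haps.items()
                                     if COMPOSITE_DQB1 not in h.dqb1})
                for breed, haps in self.panel.items()}
        for breed, haps in self.panel.items():
            if not haps:
                raise ValueError(f"empty haplotype panel for breed {breed!r}")
            total = sum(haps.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"panel frequencies for {breed!r} sum to {total}, not 1")
        if not 0 <= self.recombinant_rate < 1:
            raise ValueError("recombinant_rate must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    def families_per_breed(self) -> Dict[str, int]:
        if isinstance(self.n_families, int):
            return {b: self.n_families for b in sorted(self.panel)}
        return dict(self.n_families)


def _renormalize(d):
    total = sum(d.values())
    if total <= 0:
        return d
    return {k: v / total for k, v in d.items()}


# ---------------------------------------------------------------------------
# transmission

def _transmit(parent: Tuple[Haplotype, Haplotype], rng: np.random.Generator,
              recombinant_rate: float) -> Haplotype:
    h1, h2 = parent
    if recombinant_rate > 0 and rng.random() < recombinant_rate:
        a, b = (h1, h2) if rng.random() < 0.5 else (h2, h1)
        if rng.random() < 0.5:                       # break DRB1 | DQA1-DQB1
            return Haplotype(a.drb1, b.dqa1, b.dqb1)
        return Haplotype(a.drb1, a.dqa1, b.dqb1)     # break DRB1-DQA1 | DQB1
    return h1 if rng.random() < 0.5 else h2


def sample_offspring(dam: Tuple[Haplotype, Haplotype],
                     sire: Tuple[Haplotype, Haplotype],
                     mode: SelectionMode, rng: np.random.Generator,
                     recombinant_rate: float = 0.0
                     ) -> Tuple[Haplotype, Haplotype]:
    """Draw one offspring's (maternal, paternal) haplotypes.

    Each parent transmits one of its haplotypes with probability 1/2, then
    the selection mode reshapes the outcome: anti-homozygote selection
    rejects level-homozygous offspring with probability s (redraw);
    maternal-shared bias tilts the paternal draw in qualifying crosses.
    """
    if mode.kind == "maternal_shared_bias":
        m_lab = tuple(mode.label(h) for h in dam)
        p_lab = tuple(mode.label(h) for h in sire)
        shared = set(m_lab) & set(p_lab)
        # qualifying contexts: A1A2xA1A3 and A1A1xA1A2 — father heterozygous
        # with exactly one maternal-shared label; A1A2xA1A2 is excluded
        qualifying = len(shared) == 1 and p_lab[0] != p_lab[1]
        if qualifying:
            sh = shared.pop()
            maternal = _transmit(dam, rng, recombinant_rate)
            idx_shared = 0 if p_lab[0] == sh else 1
            take_shared = rng.random() < (1 + mode.b) / 2
            paternal = sire[idx_shared if take_shared else 1 - idx_shared]
            return maternal, paternal
        return (_transmit(dam, rng, recombinant_rate),
                _transmit(sire, rng, recombinant_rate))

    while True:
        maternal = _transmit(dam, rng, recombinant_rate)
        paternal = _transmit(sire, rng, recombinant_rate)
        if mode.kind == "anti_homozygote":
            if (mode.label(maternal) == mode.label(paternal)
                    and rng.random() < mode.s):
                continue                              # selected against
        return maternal, paternal


def simulate_cross(dam: Tuple[Haplotype, Haplotype],
                   sire: Tuple[Haplotype, Haplotype], n_offspring: int,
                   mode: SelectionMode, rng: np.random.Generator,
                   recombinant_rate: float = 0.0) -> List[Tuple]:
    """n offspring haplotype pairs from one fixed parental pair."""
    return [sample_offspring(dam, sire, mode, rng, recombinant_rate)
            for _ in range(n_offspring)]


# ---------------------------------------------------------------------------
# full families

def _genotype_from_haps(h1: Haplotype, h2: Haplotype) -> dict:
    geno = {}
    for locus in LOCI:
        a, b = h1.allele(locus), h2.allele(locus)
        geno[locus] = (
            AlleleCall(locus, a, composite=(locus is Locus.DQB1
                                            and a == COMPOSITE_DQB1)),
            AlleleCall(locus, b, composite=(locus is Locus.DQB1
                                            and b == COMPOSITE_DQB1)))
    return geno


def simulate_families(config: SimulationConfig):
    """Generate families under *config*.

    Returns ``(families, truth)``: :class:`famsel.types.Family` objects and
    a truth dataframe with one row per individual recording its breed and
    true haplotype pair (offspring rows also carry the transmitted maternal
    and paternal haplotypes).  Output is byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    families: List[Family] = []
    truth_rows = []
    fam_no = 0
    for breed in sorted(config.families_per_breed()):
        n_fam = config.families_per_breed()[breed]
        haps = sorted(config.panel[breed])
        freqs = np.array([config.panel[breed][h] for h in haps])
        litter_sizes = config.litter_model.sample(rng, size=n_fam)
        for i in range(n_fam):
            fam_no += 1
            fam_id = f"F{fam_no:04d}"
            idx = rng.choice(len(haps), size=4, p=freqs)
            dam_h = (haps[idx[0]], haps[idx[1]])
            sire_h = (haps[idx[2]], haps[idx[3]])
            dam = GenotypeRecord(f"{fam_id}_dam", fam_id, Role.DAM, breed,
                                 "F", _genotype_from_haps(*dam_h))
            sire = GenotypeRecord(f"{fam_id}_sire", fam_id, Role.SIRE, breed,
                                  "M", _genotype_from_haps(*sire_h))
            truth_rows.append((fam_id, dam.individual_id, breed, "dam",
                               str(dam_h[0]), str(dam_h[1]), None, None))
            truth_rows.append((fam_id, sire.individual_id, breed, "sire",
                               str(sire_h[0]), str(sire_h[1]), None, None))
            kids = []
            for j in range(int(litter_sizes[i])):
                mat, pat = sample_offspring(dam_h, sire_h, config.selection,
                                            rng, config.recombinant_rate)
                kid_id = f"{fam_id}_o{j + 1}"
                geno = _genotype_from_haps(mat, pat)
                if config.missing_rate > 0:
                    geno = {loc: pair for loc, pair in geno.items()
                            if rng.random() >= config.missing_rate}
                sex = "F" if rng.random() < 0.5 else "M"
                kids.append(GenotypeRecord(kid_id, fam_id, Role.OFFSPRING,
                                           breed, sex, geno))
                truth_rows.append((fam_id, kid_id, breed, "offspring",
                                   str(mat), str(pat), str(mat), str(pat)))
            families.append(Family(fam_id, dam, sire, kids))
    truth = pd.DataFrame(truth_rows, columns=[
        "family_id", "individual_id", "breed", "role", "haplotype1",
        "haplotype2", "maternal_transmitted", "paternal_transmitted"])
    return families, truth


def families_to_records(families: Sequence[Family]) -> List[GenotypeRecord]:
    """Flatten families into records (parents deduplicated by id)."""
    out, seen = [], set()
    for fam in families:
        for rec in (fam.dam, fam.sire, *fam.offspring):
            if rec.individual_id not in seen:
                seen.add(rec.individual_id)
                out.append(rec)
    return out
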