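# Methods

## The question and the test

A foetus is a semi-allograft; maternal–foetal immune interactions can in
principle favour MHC-heterozygous or maternally histo-incompatible
offspring before birth.  In pedigree data such selection leaves a
signature: offspring genotype ratios that deviate from Mendelian
expectations.  `famsel` tests for that signature in nuclear dog families
genotyped at the three class II loci DLA-DRB1, DLA-DQA1 and DLA-DQB1
(tightly linked on chromosome 12, inherited as three-locus haplotype
blocks).

Only four parental configurations (mother × father) are informative for
offspring heterozygosity once allele identity is discarded:

| cross type        | genotypes   | P(het offspring) |
|-------------------|-------------|------------------|
| HOMxHET           | A₁A₁ × A₁A₂ | 1/2              |
| HETxHOM           | A₁A₂ × A₁A₁ | 1/2              |
| HETxHET_same      | A₁A₂ × A₁A₂ | 1/2              |
| HETxHET_oneshared | A₁A₂ × A₁A₃ | 3/4              |

Counts are accumulated over offspring within each cross type (allele
identity deliberately pooled: whichever alleles play the A₁/A₂/A₃ roles,
the counts enter the same table; this trades allele-specific resolution
for power, which matters in breed-structured data where individual allele
frequencies are low).  Each table is tested with the 1-df Pearson χ²;
because per-type counts can be small, p-values are Monte-Carlo:
p = (1 + #{χ²_sim ≥ χ²_obs}) / (B + 1) over B binomial resamples of the
heterozygote count at the Mendelian fraction (default B = 2000; the +1
keeps p > 0).  Cross types are combined by pooling observed and expected
counts into one 1-df χ² (default, matching a combined 1-df report); the
Σχ² alternative with df = #types is also available (`mode="sum"`), since
either construction is defensible.

The same machinery runs at four analysis levels — allele, three-locus
haplotype (each haplotype treated as one allele), supertype (alleles
mapped through a `SupertypeModel`, which can render crosses
uninformative when parental alleles share a class), and single PBR codon
(residue pairs; two different alleles with the same residue are
site-homozygous) — and over breed, sex and purebred/mixed subsets.
Per-site scans within a locus are corrected with Storey q-values (π₀ by
the smoother method: cubic spline of π₀(λ) on λ ∈ {0.05,…,0.90},
evaluated at the largest λ; with fewer than 10 p-values π₀ falls back to
1, i.e. Benjamini–Hochberg, flagged by a warning).

### Duplicated DQB1

Some haplotypes carry two DQB1 copies (alleles 01303 + 01701).  Since it
is unknown whether both are expressed, the pair is handled as one
composite allele `013017`; analyses can run with the composite
(`dup_policy="composite"`), excluding carrier families, or on carrier
families only.  Site-level and DQB1-supertype analyses always exclude
carrier families (a composite allele has no single-copy residue string).

## Haplotype inference

Three steps, iterated to a fixed point: (1) individuals homozygous at all
three loci define haplotypes directly; (2) heterozygous individuals with
exactly one decomposition into two known haplotypes are resolved;
(3) individuals with no known-known decomposition but exactly one
known + remainder decomposition register the remainder as a new rare
haplotype.  Newly found haplotypes are committed only between rounds, so
the fixed point does not depend on input order.  Individuals with two or
more valid decompositions are returned unresolved with their candidate
sets — ambiguity is data, never guessed.  Pedigree inference
(`infer_missing_parent`) attributes each offspring's
non-maternally-transmissible haplotype to an un-genotyped sire (or vice
versa) and errors if more than two candidates accumulate (a non-paternity
signal).  Microsatellite-to-haplotype maps are learned only from
exact-match combinations in doubly-genotyped, doubly-homozygous
individuals; no fuzzy matching.

Limitation: step 3 is a heuristic.  When *neither* true haplotype of an
individual is yet known, a unique known + remainder decomposition can
register a spurious rare haplotype.  On simulated panel populations this
affects ≲ 0.5% of individuals (tests assert > 95% truth recovery); the
exhaustive-enumeration guarantee — any individual unambiguous against the
true panel is recovered exactly — is tested separately.

## Supertype classification

Alleles are represented by the residues at their polymorphic PBR codons
(candidate lists: 19 codons for DRB1, 15 for DQB1, 10 for DQA1 — the
DQA1 set is monomorphic in study-scale allele sets and drops out).  Each
residue is encoded by the five z-descriptors (z1 hydrophobicity, z2
steric bulk, z3 polarity, z4/z5 electronic effects; the extended
20-amino-acid z-scale table is embedded and checksum-guarded).
Descriptors are standardised to mean 0 / sd 1 — by default over the
20-residue reference table (so features are comparable across datasets),
optionally over the observed allele×site values.  Euclidean distances
over all site×descriptor columns feed Ward clustering.  The textbook
Lance–Williams Ward on squared distances ("D2") is the default; the
legacy unsquared variant ("D") is available because hierarchical-
clustering environments have historically differed, and the choice can
move cluster boundaries.

The class count k is the smallest number of clusters before a steep
increase in merge cost: the largest ratio h_{m+1}/h_m over the last 10
merges, k = clusters just below that merge.  A zero-to-positive step
counts as an infinite jump (duplicate-PBR alleles always co-cluster); if
no ratio reaches 2.0 the choice is flagged as weakly determined and an
explicit override is recommended (the CLI documents the override flag).
Classes are numbered by size rank.  Per-site influence is the sum of
squared PCA loadings of a site's five descriptor columns over the first
three PCs, computed on the standardised feature matrix as-is (no
re-centering; a `center=True` option gives the conventional PCA).  Both
the within-analysis site index and the codon position are always
reported together, because "site i" depends on which candidate codons
happen to be polymorphic in the allele set at hand.

The packaged fixture supports structural checks only (45 haplotypes, 28
DRB1 / 11 DQA1 / 23 DQB1 alleles); reproducing published class counts
for full allele registries would require those registries' sequences,
which are not distributed here.

## Maternal effect

In crosses where the father carries exactly one maternal-shared allele
(A₁A₂ × A₁A₃ and A₁A₁ × A₁A₂), every Mendelian-consistent offspring
reveals whether the father transmitted the shared or the non-shared
allele.  Counts are tested against 1:1 per context and pooled; a signed
direction column (positive = shared excess, i.e. a histo-compatibility
advantage; negative = incompatibility advantage) makes the sign
convention explicit.  The maternal allele A₂ never enters the
classification.  Separately, all heterozygous-mother cross types are
pooled (fractions ½, ½, ¾) into one 1-df test of whether maternal
heterozygosity shapes offspring heterozygosity.

## Selection coefficient and power

For 1:1-expectation crosses, s = 1 − N_ii/(N_ij + 1): s = 0 at
N_ii = N_ij + 1, s = 1 when homozygotes are absent.  The generative model
behind the power analysis is viability selection: Mendelian ½ het / ½ hom,
homozygotes surviving with probability 1 − s, renormalised to
P(het) = 1/(2 − s).  (The estimator does not dictate a generative model;
this renormalised-viability form is this package's choice and is the one
the simulator implements, so estimator and generator are mutually
consistent — the recovery tests confirm median ŝ within ±0.05 of truth at
n = 5000.)  Power is computed by binomial simulation against the
asymptotic χ²₁ critical value, or by the noncentral-χ² approximation with
λ = 4n(p₁ − ½)²; the two agree within 0.05 at study scales.  The minimal
detectable s scans a 0.01 grid for the smallest s reaching the target
power (default 0.80 at α = 0.05; the power target is this package's
default, stated explicitly because "detectable" is meaningless without
one).  At per-cross-type sample sizes of 50–300 offspring the minimal
detectable s falls between ≈0.6 and ≈0.3 — only very strong selection is
visible at realistic family-study scales.

## Simulator

`simulate_families` draws each parent as two haplotypes from per-breed
frequency panels.  Defaults are the study conditions: the packaged
45-haplotype panel over 10 purebred and 4 mixed-breed groups; litter
sizes from a negative binomial (r = 4) truncated to 1–16 with p solved so
the truncated mean is exactly 3.9; no distortion, recombination or
missing data unless configured.  Distortion modes: anti-homozygote
rejection sampling at any level (allele, haplotype, or any coarsening via
a key function) and maternal-shared bias (father transmits the shared
allele with probability (1 + b)/2 in qualifying crosses; b may be
negative).  Recombinant transmissions swap locus blocks at one of the two
inter-locus boundaries.  A truth table records every individual's
haplotypes and every offspring's parental transmissions, so inference and
tests can be validated against the generative state.  Output is
byte-identical for a fixed seed.

What the simulator does *not* emulate: genotyping error, mutation,
population structure beyond breed-level frequencies, linkage-map realism
beyond the three-locus block, litter-size/selection interactions, or
multi-generation dynamics.  Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated model,
not that real data are free of those complications.

### The packaged haplotype panel

The 45 haplotype triples, their per-row frequency values and the
per-breed sample sizes are transcribed from the source study.  The
placement of each frequency value in its breed column was reconstructed
by constraint satisfaction (values in a row occupy strictly increasing
columns; each breed column sums to one; each frequency times 2n gene
copies is an integer; total copy deviation zero), because the archived
table text does not preserve column alignment.  The reconstruction is
exact under those constraints but is not guaranteed unique; per-breed
panels should be read as a faithful panel of that population's structure,
not as an archival record of which breed carried which rare haplotype.

## Numerical choices and calibration

* Monte-Carlo p-values use (1 + r)/(B + 1) with mandatory seeds.  The
  estimator is discrete and (under ties) conservative: with two-cell
  tables it has probability atoms, the largest at p = 1 (the central
  outcome).  Null calibration is therefore tested in the direction that
  matters — rejection rate at α = 0.05 within [0.03, 0.07] over 1000
  Mendelian replicates, and a one-sided Kolmogorov–Smirnov check that
  p-values are never anti-conservative.  A two-sided uniformity test
  would reject on discreteness alone at large replicate counts.
* Monte-Carlo agreement with exact enumeration is asserted within
  3 binomial standard deviations plus the estimator's 1/(B + 1)
  resolution on every table with n ≤ 12.
* Expected counts are exact fraction × n, never rounded; χ² at fraction ½
  reduces to (het − hom)²/n (verified as an identity).
* Ward merge ties break deterministically (lowest condensed-index pair,
  the scipy convention); pipeline output is invariant to allele input
  order.
* Offspring are treated as independent trials within and across families,
  as in the counts the tests consume; a family-bootstrap robustness
  p-value is a possible extension, deliberately not the default.
* Test problem sizes (e.g. 112-family simulations, 1000 calibration
  replicates, 200-seed recovery runs) were chosen to mirror the study
  scale while keeping the default suite fast.

## Known limitations

* No statistical (EM/likelihood) phasing: ambiguous individuals stay
  unresolved by design, and recombination-aware phasing is out of scope.
* Allele-identity-specific distortion (e.g. transmission ratio distortion
  of one particular allele) is invisible to the pooled cross-type tests.
* The supertype class count is an elbow heuristic; biologically
  meaningful class numbers need functional peptide-binding data.
* Site-level tests treat codons independently; no haplotype structure of
  residues within the PBR is modelled.
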