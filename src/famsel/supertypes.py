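"""MHC supertype classification from peptide-binding-region physicochemistry.

Alleles of the beta-chain loci (DRB1, DQB1) are encoded by the five
z-descriptors (z1 hydrophobicity, z2 steric bulk, z3 polarity, z4/z5
electronic effects) of the residues at the polymorphic peptide-binding
region (PBR) codons, standardised to mean zero / unit standard deviation.
Euclidean distances over all descriptor x site columns feed Ward
hierarchical clustering; the number of supertype classes is the smallest
cluster count before a steep increase in merge cost, and a PCA on the
feature matrix scores each site's influence on the clustering.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .types import AlleleSequence, Locus

__all__ = [
    "Z_SCALES", "PBR_SITES", "polymorphic_sites", "standardized_z_table",
    "build_feature_matrix", "euclidean_distances", "ward_cluster", "choose_k",
    "assign_supertypes", "site_influence_pca", "SupertypeModel",
    "SupertypeClassifier",
]

# ---------------------------------------------------------------------------
# z-descriptor scale (extended five-component z-scores for the 20 canonical
# amino acids: hydrophobicity, steric bulk, polarity, two electronic terms)

Z_SCALES: Dict[str, Tuple[float, float, float, float, float]] = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}

#: SHA-256 of the canonical serialisation of Z_SCALES; guards against silent
#: edits of the embedded physicochemical constants.
Z_SCALES_SHA256 = \
    "9ba1d13088f01cbb02c95c44f4ddde1fd255c494e890824b9ff6048ab1604b41"


def _z_checksum() -> str:
    body = ";".join(f"{aa}:" + ",".join(f"{v:.2f}" for v in Z_SCALES[aa])
                    for aa in sorted(Z_SCALES))
    return hashlib.sha256(body.encode()).hexdigest()


# Candidate PBR codon positions (1-based within the exon-2 peptide) per locus.
# The DQA1 candidate set is retained for the structural check that the locus
# drops out (monomorphic) on study allele sets.
PBR_SITES: Dict[Locus, Tuple[int, ...]] = {
    Locus.DRB1: (9, 11, 13, 26, 28, 30, 38, 47, 56, 57, 60, 61, 67, 70, 71,
                 74, 78, 86, 90),
    Locus.DQB1: (9, 13, 26, 28, 30, 37, 38, 47, 57, 67, 70, 71, 74, 77, 85),
    Locus.DQA1: (9, 22, 24, 31, 52, 53, 58, 61, 65, 68),
}


def standardized_z_table(population: Optional[np.ndarray] = None) -> dict:
    """z-scales standardised to mean 0 / sd 1 per descriptor.

    By default the standardisation population is the 20-amino-acid reference
    table itself; pass an (n, 5) array of observed z-values to standardise
    over the data instead.
    """
    table = np.array([Z_SCALES[aa] for aa in sorted(Z_SCALES)])
    pop = table if population is None else np.asarray(population, float)
    mean = pop.mean(axis=0)
    sd = pop.std(axis=0, ddof=0)
    return {aa: (np.array(Z_SCALES[aa]) - mean) / sd for aa in sorted(Z_SCALES)}


def polymorphic_sites(sequences: Sequence, sites: Sequence[int]) -> List[int]:
    """Candidate codon positions with >1 residue across *sequences*."""
    out = []
    for pos in sites:
        residues = {seq.residue(pos) for seq in sequences}
        if len(residues) > 1:
            out.append(pos)
    return out


def build_feature_matrix(sequences: Sequence, sites: Sequence[int],
                         *, standardize: str = "table"):
    """Allele x (polymorphic site x 5 descriptors) feature matrix.

    Monomorphic candidate sites are dropped.  ``standardize`` is ``"table"``
    (per-descriptor over the 20-residue scale table, the default) or
    ``"observed"`` (over the realised allele x site values).  Returns
    ``(matrix, polymorphic_positions)``; raises :class:`ValueError` when no
    candidate site is polymorphic or a residue is non-canonical.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two alleles")
    for seq in sequences:
        for pos in sites:
            res = seq.residue(pos)
            if res not in Z_SCALES:
                raise ValueError(
                    f"non-canonical residue {res!r} at codon {pos} in "
                    f"{seq.allele.locus.value}*{seq.allele.name}")
    poly = polymorphic_sites(sequences, sites)
    if not poly:
        raise ValueError("no polymorphic sites among the candidate PBR codons")

    if standardize == "table":
        ztab = standardized_z_table()
    elif standardize == "observed":
        raw = np.array([[Z_SCALES[s.residue(p)] for p in poly]
                        for s in sequences])          # (n, sites, 5)
        ztab = standardized_z_table(raw.reshape(-1, 5))
    else:
        raise ValueError("standardize must be 'table' or 'observed'")

    matrix = np.array([
        np.concatenate([ztab[s.residue(p)] for p in poly])
        for s in sequences
    ])
    return matrix, poly


def euclidean_distances(matrix: np.ndarray) -> np.ndarray:
    """Symmetric pairwise Euclidean distance matrix over matrix rows."""
    matrix = np.asarray(matrix, float)
    if matrix.size == 0:
        raise ValueError("empty feature matrix")
    return squareform(pdist(matrix, metric="euclidean"))


def ward_cluster(distances: np.ndarray, *, variant: str = "D2") -> np.ndarray:
    """Ward agglomeration on a distance matrix; returns a scipy linkage.

    ``variant="D2"`` runs the Lance-Williams Ward update on squared
    distances (textbook Ward; heights are merge costs on the original
    scale).  ``variant="D"`` applies the update to the unsquared distances
    (legacy behaviour of some implementations); implemented by feeding
    sqrt-distances through the squared-distance machinery and squaring the
    resulting heights.
    """
    d = np.asarray(distances, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distances must be a square matrix")
    if d.shape[0] < 2:
        raise ValueError("need at least two items")
    cond = squareform(d, checks=False)
    if variant == "D2":
        return linkage(cond, method="ward")
    if variant == "D":
        Z = linkage(np.sqrt(cond), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
        return Z
    raise ValueError("variant must be 'D2' or 'D'")


def choose_k(merge_heights: Sequence[float], *, top: int = 10,
             steep_ratio: float = 2.0, override: Optional[int] = None) -> int:
    """Cluster count from the elbow of the agglomeration-cost sequence.

    Scans the ``top`` last merges for the largest relative jump
    ``h[m+1]/h[m]`` and returns the number of clusters just below that
    merge.  If no jump reaches ``steep_ratio`` a warning is issued (and the
    argmax-based k is still returned); equal heights throughout give k=1
    with a warning.  ``override`` short-circuits everything.
    """
    if override is not None:
        return int(override)
    h = np.asarray(merge_heights, float)
    if h.size < 2:
        raise ValueError("need at least two merges")
    n = h.size + 1
    if np.allclose(h, h[0]):
        warnings.warn("all merge heights equal; no cluster structure, k=1")
        return 1
    lo = max(0, h.size - top)
    prev, nxt = h[lo:-1], h[lo + 1:]
    # relative merge-cost jump; a zero-to-positive step is an infinite jump,
    # zero-to-zero is no jump at all
    ratios = np.where(prev > 0, np.divide(nxt, prev, where=prev > 0, out=np.ones_like(nxt)),
                      np.where(nxt > 0, np.inf, 1.0))
    # on ties take the merge closest to the root (smallest k)
    i = lo + (ratios.size - 1 - int(np.argmax(ratios[::-1])))
    if np.isfinite(ratios[i - lo]) and ratios[i - lo] < steep_ratio:
        warnings.warn(
            f"largest merge-cost jump is only x{ratios[i - lo]:.2f} "
            f"(< {steep_ratio}); cluster count is weakly determined, "
            "consider an explicit override")
    return n - 1 - i


@dataclass
class SupertypeModel:
    """Allele -> supertype class map plus the artefacts that produced it."""
    locus: Locus
    classes: Dict[str, int]                  # allele name -> class (1..k)
    k: int
    linkage: np.ndarray
    merge_heights: np.ndarray
    polymorphic_positions: List[int]
    site_influence: Optional["pd.DataFrame"] = None   # noqa: F821
    explained_variance: Optional[np.ndarray] = None

    def map_pair(self, pair):
        """Map an unordered allele-name pair to its supertype pair."""
        a, b = (self.classes.get(pair[0]), self.classes.get(pair[1]))
        if a is None or b is None:
            return None
        return (a, b) if a <= b else (b, a)


def assign_supertypes(allele_names: Sequence[str], Z: np.ndarray,
                      k: int) -> Dict[str, int]:
    """Cut the dendrogram at *k* clusters; classes labelled by size rank.

    The largest class is 1; ties broken by first occurrence in input order.
    """
    n = len(allele_names)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} alleles")
    raw = fcluster(Z, t=k, criterion="maxclust")
    sizes = {}
    first = {}
    for i, c in enumerate(raw):
        sizes[c] = sizes.get(c, 0) + 1
        first.setdefault(c, i)
    order = sorted(sizes, key=lambda c: (-sizes[c], first[c]))
    relabel = {c: r + 1 for r, c in enumerate(order)}
    return {name: relabel[c] for name, c in zip(allele_names, raw)}


def site_influence_pca(matrix: np.ndarray, positions: Sequence[int],
                       *, n_components: int = 3, center: bool = False):
    """Per-site influence on the leading principal components.

    The influence of a site is the sum of squared loadings of its five
    descriptor columns over the first ``n_components`` PCs (fewer, with a
    warning, if the matrix supports fewer).  The matrix is used as
    standardised (no re-centering) unless ``center``.  Returns
    ``(influence_df, explained_variance_ratio)`` with the dataframe sorted
    by descending influence and carrying both the within-analysis site index
    and the codon position.
    """
    import pandas as pd

    X = np.asarray(matrix, float)
    if center:
        X = X - X.mean(axis=0)
    # principal axes via SVD; prcomp-style loadings = right singular vectors
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    nz = int(np.sum(s > 1e-12))
    ncomp = min(n_components, nz)
    if ncomp < n_components:
        warnings.warn(f"only {ncomp} informative principal components "
                      f"available (requested {n_components})")
    loadings = vt[:ncomp].T                       # (features, ncomp)
    var = s ** 2
    evr = var / var.sum() if var.sum() > 0 else var
    infl = (loadings ** 2).sum(axis=1)
    per_site = infl.reshape(len(positions), 5).sum(axis=1)
    df = pd.DataFrame({
        "site_index": np.arange(1, len(positions) + 1),
        "codon_position": list(positions),
        "influence": per_site,
    }).sort_values("influence", ascending=False).reset_index(drop=True)
    return df, evr[:ncomp]


class SupertypeClassifier(BaseEstimator):
    """Sklearn-style estimator: cluster MHC alleles into supertypes.

    Parameters follow the pipeline defaults: ``standardize`` the z-scales
    over the reference table or the observed values, Ward ``variant`` D2 or
    D, ``k`` fixed or chosen from the merge-cost elbow (``k=None``).

    Fitted attributes: ``model_`` (:class:`SupertypeModel`), ``labels_``,
    ``classes_map_``, ``k_``, ``linkage_``, ``site_influence_``.
    """

    def __init__(self, k: Optional[int] = None, standardize: str = "table",
                 variant: str = "D2", steep_ratio: float = 2.0,
                 top_merges: int = 10):
        self.k = k
        self.standardize = standardize
        self.variant = variant
        self.steep_ratio = steep_ratio
        self.top_merges = top_merges

    def fit(self, sequences: Sequence, y=None):
        sequences = list(sequences)
        if not sequences:
            raise ValueError("no sequences")
        locus = sequences[0].allele.locus
        if any(s.allele.locus is not locus for s in sequences):
            raise ValueError("all sequences must come from one locus")
        sites = PBR_SITES[locus]
        X, poly = build_feature_matrix(sequences, sites,
                                       standardize=self.standardize)
        D = euclidean_distances(X)
        Z = ward_cluster(D, variant=self.variant)
        heights = Z[:, 2]
        k = choose_k(heights, top=self.top_merges,
                     steep_ratio=self.steep_ratio, override=self.k)
        names = [s.allele.name for s in sequences]
        classes = assign_supertypes(names, Z, k)
        infl, evr = site_influence_pca(X, poly)
        self.model_ = SupertypeModel(
            locus=locus, classes=classes, k=k, linkage=Z,
            merge_heights=heights, polymorphic_positions=poly,
            site_influence=infl, explained_variance=evr)
        self.feature_matrix_ = X
        self.linkage_ = Z
        self.k_ = k
        self.classes_map_ = classes
        self.labels_ = np.array([classes[n] for n in names])
        self.site_influence_ = infl
        self._pbr_strings = {
            "".join(s.residue(p) for p in poly): classes[s.allele.name]
            for s in sequences}
        self._poly = poly
        return self

    def predict(self, sequences: Sequence) -> np.ndarray:
        """Supertype class for alleles by exact PBR-residue match."""
        if not hasattr(self, "model_"):
            raise ValueError("classifier is not fitted")
        out = []
        for s in sequences:
            name = s.allele.name
            if name in self.classes_map_:
                out.append(self.classes_map_[name])
                continue
            key = "".join(s.residue(p) for p in self._poly)
            cls = self._pbr_strings.get(key)
            if cls is None:
                raise ValueError(
                    f"allele {name} has an unseen PBR residue string; "
                    "refit including it")
            out.append(cls)
        return np.array(out)

    def fit_predict(self, sequences: Sequence, y=None) -> np.ndarray:
        return self.fit(sequences).labels_


if _z_checksum() != Z_SCALES_SHA256:   # pragma: no cover - tamper guard
    raise ImportError("embedded z-scale table failed its checksum")
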