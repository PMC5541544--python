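"""Functional diversity from mixed-type species traits.

Six traits (three numeric: max body length, population doubling time, trophic
level; three categorical: vertical position, aggregation behaviour, food
niche) are combined with Gower dissimilarity, embedded into a Euclidean trait
space by principal coordinates analysis (with the Cailliez correction when
the Gower matrix is non-Euclidean), and summarized per year as the
biomass-weighted functional dispersion

    FDis = sum_j a_j ||x_j - c|| / sum_j a_j,     c = sum_j a_j x_j / sum_j a_j

— the abundance-weighted mean distance of species to the abundance-weighted
centroid.  Community-weighted trait means (numeric traits) and biomass shares
per level (categorical traits) complete the picture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import (CATEGORICAL_TRAITS, NUMERIC_TRAITS, CommunityMatrix,
                        IndicatorSeries, validate_traits)
from .composition import DissimilarityMatrix

__all__ = [
    "TraitSpace",
    "gower_dissimilarity",
    "pcoa_embed",
    "fdis",
    "annual_fdis",
    "community_weighted_trait_means",
]


@dataclass
class TraitSpace:
    """Euclidean embedding of species in functional trait space."""

    species: list
    coordinates: np.ndarray  # species x axes
    correction: str  # 'none' or 'cailliez'
    negative_eigenvalue_mass: float

    def distances(self) -> np.ndarray:
        return squareform(pdist(self.coordinates))

    def subset(self, keep) -> "TraitSpace":
        idx = [self.species.index(s) for s in keep]
        return TraitSpace([self.species[i] for i in idx], self.coordinates[idx],
                          self.correction, self.negative_eigenvalue_mass)


def gower_dissimilarity(traits: pd.DataFrame, numeric=None,
                        categorical=None) -> DissimilarityMatrix:
    """Gower dissimilarity over mixed numeric and categorical traits.

    Numeric traits contribute |difference| / range (ranges over the full
    species pool, so yearly subsets stay comparable); categorical traits
    contribute 0/1 mismatch; the overall value is the unweighted mean across
    traits.  A numeric trait with zero range carries no information and is
    dropped with a warning.
    """
    df = validate_traits(traits) if numeric is None and categorical is None \
        else traits.set_index("species") if "species" in traits.columns else traits
    numeric = NUMERIC_TRAITS if numeric is None else numeric
    categorical = CATEGORICAL_TRAITS if categorical is None else categorical
    species = df.index.tolist()
    n = len(species)
    parts = []
    for c in numeric:
        v = df[c].to_numpy(dtype=float)
        rng = v.max() - v.min()
        if rng == 0:
            warnings.warn(f"numeric trait {c} has zero range; dropped", stacklevel=2)
            continue
        parts.append(np.abs(v[:, None] - v[None, :]) / rng)
    for c in categorical:
        v = df[c].to_numpy()
        parts.append((v[:, None] != v[None, :]).astype(float))
    if not parts:
        raise ValueError("no usable traits")
    return DissimilarityMatrix(species, np.mean(parts, axis=0))


def _double_centre(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d2 @ J


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making d + c (off-diagonal) Euclidean."""
    n = d.shape[0]
    delta1 = _double_centre(d**2)
    delta2 = _double_centre(d)
    zero = np.zeros((n, n))
    eye = np.eye(n)
    top = np.hstack([zero, 2 * delta1])
    bot = np.hstack([-eye, -4 * delta2])
    eig = np.linalg.eigvals(np.vstack([top, bot]))
    return float(np.max(eig.real))


def pcoa_embed(d: DissimilarityMatrix, correction: str = "auto",
               neg_tol: float = 1e-8) -> TraitSpace:
    """Principal coordinates embedding of a dissimilarity matrix.

    Double-centred eigendecomposition; when the relative mass of negative
    eigenvalues exceeds ``neg_tol`` (the matrix is non-Euclidean, as Gower
    matrices often are) the Cailliez constant is added to off-diagonal
    dissimilarities and the embedding recomputed, after which pairwise
    Euclidean distances reproduce the corrected dissimilarities.
    """
    dm = d.values

    def embed(mat):
        B = _double_centre(mat**2)
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        neg_mass = float(np.sum(np.abs(w[w < 0])) / np.sum(np.abs(w))) if np.sum(np.abs(w)) else 0.0
        keep = w > max(neg_tol * max(abs(w[0]), 1.0), 0.0)
        X = V[:, keep] * np.sqrt(w[keep])
        return X, neg_mass

    X, neg_mass = embed(dm)
    applied = "none"
    if correction in ("auto", "cailliez") and neg_mass > neg_tol:
        c = _cailliez_constant(dm)
        if c > 0:
            dm = dm + c * (1 - np.eye(dm.shape[0]))
            X, neg_mass = embed(dm)
            applied = "cailliez"
    return TraitSpace(list(d.labels), X, applied, neg_mass)


def fdis(space: TraitSpace, weights) -> float:
    """Abundance-weighted functional dispersion in an embedded trait space.

    Zero iff all weight rests on species sharing identical coordinates.
    Invariant to rescaling the weights and to rigid rotation of the space.
    """
    a = np.asarray(weights, dtype=float)
    if (a < 0).any():
        raise ValueError("weights must be non-negative")
    tot = a.sum()
    if tot == 0:
        raise ValueError("all-zero weights")
    a = a / tot
    X = space.coordinates
    c = a @ X
    dist = np.sqrt(np.sum((X - c) ** 2, axis=1))
    return float(a @ dist)


def annual_fdis(cm: CommunityMatrix, space: TraitSpace,
                subset=None, name: str = "fdis") -> IndicatorSeries:
    """Per-year functional dispersion from an annual community matrix.

    Rows are normalized to relative-biomass weights; ``subset`` restricts the
    species pool (e.g. the non-commercial community) while keeping the trait
    space geometry fixed.
    """
    species = [s for s in cm.species if s in set(space.species)]
    if subset is not None:
        species = [s for s in species if s in set(subset)]
    missing = set(cm.species) - set(space.species)
    if subset is None and missing:
        raise ValueError(f"species lack traits: {sorted(missing)}")
    sub_space = space.subset(species)
    years = np.asarray(cm.row_labels, dtype=int)
    vals = np.array([fdis(sub_space, cm.data.loc[y, species].to_numpy(dtype=float))
                     for y in years])
    return IndicatorSeries(name=name, years=years, values=vals,
                           subset="all" if subset is None else "subset")


def community_weighted_trait_means(cm: CommunityMatrix,
                                   traits: pd.DataFrame) -> dict:
    """Biomass-weighted annual trait summaries.

    Returns {'numeric': DataFrame years x numeric traits of weighted means,
    'categorical': {trait: DataFrame years x levels of biomass shares}}; the
    shares of each categorical trait sum to one every year.
    """
    tr = validate_traits(traits)
    species = [s for s in cm.species if s in tr.index]
    w = cm.data[species].to_numpy(dtype=float)
    sums = w.sum(axis=1, keepdims=True)
    w = np.divide(w, sums, out=np.zeros_like(w), where=sums > 0)
    years = cm.row_labels

    num = {}
    for c in NUMERIC_TRAITS:
        v = tr.loc[species, c].to_numpy(dtype=float)
        num[c] = w @ v
    numeric = pd.DataFrame(num, index=years)

    categorical = {}
    for c in CATEGORICAL_TRAITS:
        levels = sorted(tr.loc[species, c].unique())
        shares = np.zeros((len(years), len(levels)))
        lv = tr.loc[species, c].to_numpy()
        for j, level in enumerate(levels):
            shares[:, j] = w[:, lv == level].sum(axis=1)
        categorical[c] = pd.DataFrame(shares, index=years, columns=levels)
    return {"numeric": numeric, "categorical": categorical}
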