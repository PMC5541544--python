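"""Compositional dissimilarity, ordination and recovery scaling.

Community composition per year is the relative-biomass vector across species.
Years are compared by Bray-Curtis dissimilarity (whose complement is the
quantitative Sorensen similarity), displayed with a 2-D non-metric
multidimensional scaling (NMDS), and tracked against a pre-collapse reference
year with a 0-100 recovery scaling anchored at 100 for the reference year's
value and 0 at the series minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .datatypes import CommunityMatrix, IndicatorSeries

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "bray_curtis",
    "bray_curtis_pair",
    "sorensen_similarity",
    "nmds",
    "relative_change_series",
    "composition_trajectory",
]


@dataclass
class DissimilarityMatrix:
    """Square symmetric dissimilarities in [0, 1] with zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = v.shape[0]
        if v.shape != (n, n) or len(self.labels) != n:
            raise ValueError("labels and matrix dimensions disagree")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class OrdinationResult:
    """NMDS configuration: centred coordinates rotated to principal axes."""

    coordinates: pd.DataFrame
    stress: float  # Kruskal stress-1
    converged: bool
    n_starts: int
    seed: int
    stress_history: list = field(default_factory=list)


def bray_curtis_pair(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = np.sum(x + y)
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero compositions")
    return float(np.sum(np.abs(x - y)) / denom)


def bray_curtis(cm: CommunityMatrix) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarities between the matrix rows.

    All-zero rows are excluded with a warning (the dissimilarity to an empty
    composition is undefined).
    """
    vals = cm.values
    labels = cm.row_labels
    nonzero = vals.sum(axis=1) > 0
    if (~nonzero).any():
        warnings.warn(f"{int((~nonzero).sum())} all-zero row(s) excluded",
                      stacklevel=2)
        vals = vals[nonzero]
        labels = [l for l, ok in zip(labels, nonzero) if ok]
    return DissimilarityMatrix(labels, squareform(pdist(vals, metric="braycurtis")))


def sorensen_similarity(x, y) -> float:
    """Quantitative Sorensen similarity = 1 - Bray-Curtis dissimilarity."""
    return 1.0 - bray_curtis_pair(x, y)


# ---------------------------------------------------------------------------
# Non-metric multidimensional scaling


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    t = np.sum(d**2)
    if t == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / t))


def _disparities(diss: np.ndarray, d: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Monotone (primary/weak-tie) fit of configuration distances to the
    dissimilarity order: within tied dissimilarities, distances may order
    freely (they are pre-sorted), so ties do not force equal disparities."""
    dhat = np.empty_like(d)
    dhat[order] = isotonic_regression(d[order]).x
    return dhat


def _tie_order(diss: np.ndarray, d: np.ndarray) -> np.ndarray:
    return np.lexsort((d, diss))


def _guttman(X: np.ndarray, dhat: np.ndarray, iu) -> np.ndarray:
    """One majorization (Guttman transform) step toward disparities dhat."""
    n = X.shape[0]
    d = pdist(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat / d, 0.0)
    B = np.zeros((n, n))
    B[iu] = -ratio
    B += B.T
    np.fill_diagonal(B, -B.sum(axis=1))
    return (B @ X) / n


def _classical_mds(diss_sq: np.ndarray, k: int) -> np.ndarray:
    n = diss_sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (diss_sq**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    w = np.clip(w[idx], 0, None)
    return V[:, idx] * np.sqrt(w)


def nmds(d: DissimilarityMatrix, k: int = 2, n_starts: int = 20, seed: int = 0,
         max_iter: int = 300, tol: float = 1e-7) -> OrdinationResult:
    """Kruskal non-metric MDS of a dissimilarity matrix into ``k`` dimensions.

    Minimizes Kruskal stress-1 by alternating monotone (isotonic) regression
    of configuration distances on dissimilarities with Guttman majorization
    steps; a backtracking safeguard (step halving toward the previous
    configuration) guarantees the recorded stress sequence never increases.
    Runs ``n_starts`` random initializations plus one metric (classical MDS)
    start and keeps the best.  The result is centred and rotated to its
    principal axes; coordinates are identifiable only up to rotation and
    reflection, so downstream use should rely on distances or stress.
    """
    diss_sq = d.values
    n = diss_sq.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} points for a {k}-D ordination")
    diss = d.condensed()
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)

    inits = [_classical_mds(diss_sq, k)]
    for _ in range(n_starts):
        inits.append(rng.uniform(-1, 1, size=(n, k)) * diss.max())

    best = None
    for X in inits:
        X = X.copy()
        dd = pdist(X)
        order = _tie_order(diss, dd)
        dhat = _disparities(diss, dd, order)
        stress = _stress1(dd, dhat)
        history = [stress]
        converged = False
        for _ in range(max_iter):
            X_new = _guttman(X, dhat, iu)
            # safeguarded step: accept only a non-increasing stress-1
            accepted = False
            for _half in range(8):
                dd_new = pdist(X_new)
                order = _tie_order(diss, dd_new)
                dhat_new = _disparities(diss, dd_new, order)
                s_new = _stress1(dd_new, dhat_new)
                if s_new <= stress + 1e-15:
                    accepted = True
                    break
                X_new = 0.5 * (X_new + X)
            if not accepted:
                converged = True
                break
            drop = stress - s_new
            X, dhat, stress = X_new, dhat_new, s_new
            history.append(stress)
            if drop <= tol * max(stress, 1e-12):
                converged = True
                break
        if best is None or stress < best[0]:
            best = (stress, X, converged, history)

    stress, X, converged, history = best
    X = X - X.mean(axis=0)
    # rotate to principal axes
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    coords = pd.DataFrame(X, index=d.labels,
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(coords, stress, converged, n_starts, seed, history)


# ---------------------------------------------------------------------------
# Recovery scaling


def relative_change_series(series: IndicatorSeries,
                           reference_year: int) -> IndicatorSeries:
    """Scale an annual series to 0-100 recovery units.

    scaled_t = 100 * (x_t - min(x)) / (x_ref - min(x)): 100 at the reference
    year's value, 0 at the series minimum.  Degenerate when the reference
    value is the minimum.
    """
    x = series.values
    ref = series.at(reference_year)
    lo = float(np.min(x))
    if ref == lo:
        raise ValueError("reference value equals series minimum; scaling degenerate")
    scaled = 100.0 * (x - lo) / (ref - lo)
    return IndicatorSeries(name=f"{series.name}_scaled", years=series.years,
                           values=scaled, subset=series.subset)


def composition_trajectory(cm: CommunityMatrix, reference_year: int,
                           rescale: bool = True) -> IndicatorSeries:
    """Similarity of each year's composition to the reference year's.

    Rows of ``cm`` (indexed by year) must be normalized relative biomass.  The
    per-year quantitative Sorensen similarity to the reference composition is
    computed, then rescaled to recovery units unless ``rescale=False``.
    """
    if not cm.normalized:
        raise ValueError("composition trajectory needs normalized rows")
    years = np.asarray(cm.row_labels, dtype=int)
    if reference_year not in years:
        raise KeyError(f"reference year {reference_year} not in matrix")
    ref = cm.data.loc[reference_year].to_numpy(dtype=float)
    sims = np.array([sorensen_similarity(cm.data.loc[y].to_numpy(dtype=float), ref)
                     for y in years])
    raw = IndicatorSeries(name="composition_similarity", years=years, values=sims)
    return relative_change_series(raw, reference_year) if rescale else raw
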