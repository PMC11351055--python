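"""How plastic-like are the biotic phases (and vice versa)?

Two complementary views: a PCA of standardized LFER system coefficients
(phases as observations, coefficients as variables) showing which phases
experience similar intermolecular interactions, and pairwise Pearson
correlations among per-chemical log K columns and -log LC50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DataError, DegenerateColumnError
from .lfer_engine import PhaseSystem

_COEFF_ORDER = ("c", "e", "s", "a", "b", "v", "l")


def coefficient_matrix(
    systems: Sequence[PhaseSystem], include_constant: bool = True
) -> pd.DataFrame:
    """Phases x coefficients matrix from a registry.

    Only coefficients present in every system become columns; the
    constant term c can be excluded (it carries no interaction
    information) via ``include_constant=False``.
    """
    if not systems:
        raise DataError("empty registry")
    names = [n for n in _COEFF_ORDER if all(getattr(s, n) is not None for s in systems)]
    if not include_constant:
        names = [n for n in names if n != "c"]
    if not names:
        raise DataError("no coefficient shared by all systems")
    data = {n: [getattr(s, n) for s in systems] for n in names}
    index = pd.Index([s.phase for s in systems], name="phase")
    if index.has_duplicates:
        raise DataError("duplicate phase names in coefficient matrix")
    return pd.DataFrame(data, index=index)


def standardize_coefficients(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standardization to mean 0, sample sd 1 (ddof=1)."""
    if matrix.shape[0] < 2:
        raise DataError("standardization needs at least 2 phases")
    sd = matrix.std(axis=0, ddof=1)
    degenerate = list(matrix.columns[(sd == 0) | sd.isna()])
    if degenerate:
        raise DegenerateColumnError(degenerate, context="standardize_coefficients")
    return (matrix - matrix.mean(axis=0)) / sd


@dataclass(frozen=True)
class PcaResult:
    """PCA of a standardized coefficient matrix.

    ``scores @ loadings.T`` reconstructs the standardized matrix;
    ``explained_variance_pct`` sums to 100 over all components; ``cos2``
    rows (squared cosines: the share of each phase's squared distance to
    the origin captured per component) sum to 1.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_pct: np.ndarray
    cos2: pd.DataFrame


def pca(standardized: pd.DataFrame) -> PcaResult:
    """Principal components of a standardized matrix via SVD.

    Components are ordered by decreasing explained variance with a
    deterministic sign convention: the largest-magnitude loading of each
    component is positive.
    """
    x = standardized.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise DataError("PCA needs at least 2 phases")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # Deterministic signs: flip so the largest |loading| per component is +.
    for j in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    total = float(np.sum(s**2))
    explained = (s**2 / total * 100.0) if total > 0 else np.zeros_like(s)
    row_ss = np.sum(scores**2, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2 = np.where(row_ss > 0, scores**2 / row_ss, 0.0)
    comp_names = [f"PC{j + 1}" for j in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=standardized.index, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=standardized.columns, columns=comp_names),
        explained_variance_pct=explained,
        cos2=pd.DataFrame(cos2, index=standardized.index, columns=comp_names),
    )


def pc_distances(scores: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Pairwise Euclidean distances in the first ``k`` component coordinates.

    k defaults to 2, the plane of the usual biplot.
    """
    if k < 1 or k > scores.shape[1]:
        raise DataError(f"k={k} out of range for {scores.shape[1]} components")
    coords = scores.iloc[:, :k].to_numpy(dtype=float)
    dist = squareform(pdist(coords, metric="euclidean"))
    return pd.DataFrame(dist, index=scores.index, columns=scores.index)


def pairwise_pearson(columns: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix across variables (chemicals as rows)."""
    if columns.shape[0] < 3:
        raise DataError("pairwise correlation needs at least 3 chemicals")
    sd = columns.std(axis=0, ddof=1)
    degenerate = list(columns.columns[(sd == 0) | sd.isna()])
    if degenerate:
        raise DegenerateColumnError(degenerate, context="pairwise_pearson")
    return columns.corr(method="pearson")
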