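"""Interactome geometry: distance profiles, classical MDS, pre-screen clustering.

Every case IP run contributes one dimension to a protein's quantitative
profile (ensemble-mean, tag-normalized log2 LFQ). Pairwise Euclidean
distances over those profiles are embedded into three dimensions by classical
(Torgerson) multidimensional scaling — double-centering of the squared
distance matrix followed by an eigendecomposition — which is deterministic and
exact whenever the distances have intrinsic dimension at most three. The
pre-screen support routine reproduces the condition-selection view:
hierarchical clustering of experiments with missing intensities filled as 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .differential import collate_significant
from .ingest import ExperimentDesign, IntensityMatrix


def build_profile_matrix(
    mean_matrix: IntensityMatrix,
    design: ExperimentDesign,
    results: pd.DataFrame,
    min_tests: int = 1,
) -> pd.DataFrame:
    """Protein x case-experiment profile matrix for distance analysis.

    Rows are proteins passing at least ``min_tests`` (target_set, condition)
    significance tests; columns are all case IP runs across targets, so each
    replicate contributes one dimension.
    """
    tally = collate_significant(results)
    selected = tally.loc[tally["n_tests_passed"] >= min_tests, "protein_id"]
    if selected.empty:
        raise ValueError(
            f"no protein passed >= {min_tests} significance tests; nothing to embed"
        )
    case_cols: list[str] = []
    for ts in design.target_sets:
        case_cols.extend(design.case_experiments(ts))
    profiles = mean_matrix.values.loc[list(selected), case_cols]
    if profiles.isna().any().any():
        raise ValueError("profile matrix has missing cells; use ensemble means")
    return profiles


def euclidean_distances(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between protein profiles (rows)."""
    if profiles.isna().any().any():
        raise ValueError("distance computation requires a complete matrix")
    d = squareform(pdist(profiles.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def classical_mds(
    distances: pd.DataFrame | np.ndarray, dims: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Torgerson scaling of a distance matrix into ``dims`` coordinates.

    Double-centers -D^2/2, eigendecomposes, and keeps the top ``dims``
    positive-eigenvalue axes scaled by sqrt(eigenvalue). Axis signs are
    canonicalized (the coordinate of largest magnitude on each axis is made
    positive) so repeated runs are byte-identical. Returns the coordinate
    frame and the full eigenvalue spectrum, sorted descending.
    """
    if isinstance(distances, pd.DataFrame):
        index = distances.index
        D = distances.to_numpy(dtype=float)
    else:
        D = np.asarray(distances, dtype=float)
        index = pd.RangeIndex(D.shape[0])
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    n_pos = int((eigvals > 1e-12 * max(eigvals.max(), 1.0)).sum())
    k = min(dims, n_pos)
    if k < dims:
        warnings.warn(
            f"only {k} positive eigenvalue(s); returning a rank-{k} embedding",
            stacklevel=2,
        )
    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    for j in range(k):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    frame = pd.DataFrame(
        coords, index=index, columns=[f"dim{i+1}" for i in range(k)]
    )
    return frame, eigvals


def embedding_distances(coords: pd.DataFrame) -> pd.DataFrame:
    """Pairwise distances among embedded coordinates (for exactness checks)."""
    d = squareform(pdist(coords.to_numpy(dtype=float)))
    return pd.DataFrame(d, index=coords.index, columns=coords.index)


def hierarchical_cluster(
    m: IntensityMatrix, zero_fill: bool = True, method: str = "average"
) -> np.ndarray:
    """Average-linkage Euclidean merge tree over experiment columns.

    With ``zero_fill`` (the pre-screen convention) missing intensities are
    set to 0 before distances are computed. Returns the scipy linkage matrix.
    """
    if m.values.shape[1] < 2:
        raise ValueError("need at least 2 experiments to cluster")
    vals = m.values.fillna(0.0) if zero_fill else m.values
    if vals.isna().any().any():
        raise ValueError("missing values present; enable zero_fill or impute first")
    return linkage(vals.to_numpy(dtype=float).T, method=method, metric="euclidean")
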