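"""Unsupervised divergence profiling of morphological features.

Features from all (well, timepoint) records are z-scored and pooled into a
single PCA; per-timepoint slices of the first two component scores then
quantify how the two culture conditions separate as morphogenesis
progresses — centroid distance and silhouette score per timepoint. A
rolling mean over ten timepoints gives the divergence trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .morphometry import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class StandardizedFeatures:
    """Z-scored feature matrix plus per-row metadata (well, timepoint, condition)."""

    matrix: np.ndarray
    feature_names: list[str]
    meta: pd.DataFrame  # columns well_id, timepoint, condition; aligned with matrix rows


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_records, k)
    loadings: np.ndarray  # (n_features, k)
    explained_variance_ratio: np.ndarray
    feature_names: list[str]


@dataclass
class SeparationTrajectory:
    """Per-timepoint separation of the two conditions in PC1/PC2 space."""

    timepoints: np.ndarray
    centroid_distance: np.ndarray
    silhouette: np.ndarray

    def rolling_distance(self, window: int = 10) -> np.ndarray:
        """Centred rolling mean of the centroid distance (edges truncated)."""
        return (
            pd.Series(self.centroid_distance)
            .rolling(window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )


def standardize(table: FeatureTable) -> StandardizedFeatures:
    """Z-score each shape feature over all non-empty records.

    Empty-flagged records are excluded; zero-variance features are dropped
    with a logged warning (they carry no profiling information).
    """
    df = table.to_dataframe()
    df = df[~df["empty"].astype(bool)].reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("standardization needs at least 2 non-empty records")
    names = [n for n in table.feature_names if n in df.columns]
    X = df[names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("non-empty records contain missing feature values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.warning("dropping zero-variance features: %s", dropped)
    if not keep.any():
        raise ValueError("all features have zero variance")
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    return StandardizedFeatures(
        matrix=Z,
        feature_names=[n for n, k in zip(names, keep) if k],
        meta=df[["well_id", "timepoint", "condition"]].copy(),
    )


def run_pca(matrix: np.ndarray, k: int) -> PCAResult:
    """Covariance-eigendecomposition PCA with a deterministic sign convention.

    Each component is flipped so its largest-magnitude loading is positive,
    making results reproducible across runs and record orderings.
    """
    matrix = np.asarray(matrix, dtype=float)
    if k > matrix.shape[1]:
        raise ValueError(f"k={k} exceeds the {matrix.shape[1]} retained features")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(matrix)
    loadings = pca.components_.T.copy()  # (features, k)
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        feature_names=[],
    )


def separation_over_time(
    result: PCAResult, features: StandardizedFeatures
) -> SeparationTrajectory:
    """Condition separation per timepoint on the first two PC scores.

    At each timepoint with both conditions present, computes the Euclidean
    distance between condition centroids and the silhouette score of the
    condition labelling. Timepoints with a single condition are omitted with
    a warning.
    """
    meta = features.meta
    conditions = sorted(meta["condition"].dropna().unique())
    if len(conditions) != 2:
        raise ValueError(f"separation requires exactly 2 conditions, got {conditions}")
    if result.scores.shape[1] < 2:
        raise ValueError("separation needs at least 2 PCA components")
    pc = result.scores[:, :2]

    tps, dists, sils = [], [], []
    for tp in np.sort(meta["timepoint"].unique()):
        sel = meta["timepoint"].to_numpy() == tp
        labels = meta.loc[sel, "condition"].to_numpy()
        present = set(labels)
        if len(present) < 2:
            logger.warning("timepoint %s has a single condition; omitted", tp)
            continue
        pts = pc[sel]
        c0 = pts[labels == conditions[0]].mean(axis=0)
        c1 = pts[labels == conditions[1]].mean(axis=0)
        dist = float(np.linalg.norm(c0 - c1))
        if min((labels == c).sum() for c in conditions) >= 2:
            sil = float(silhouette_score(pts, labels))
        else:
            sil = float("nan")
        tps.append(int(tp))
        dists.append(dist)
        sils.append(sil)
    return SeparationTrajectory(
        timepoints=np.array(tps),
        centroid_distance=np.array(dists),
        silhouette=np.array(sils),
    )


def profile_table(table: FeatureTable, k: int = 2) -> tuple[StandardizedFeatures, PCAResult, SeparationTrajectory]:
    """Convenience: standardize, fit PCA, and compute the separation trajectory."""
    std = standardize(table)
    res = run_pca(std.matrix, k=min(k, std.matrix.shape[1]))
    res.feature_names = std.feature_names
    traj = separation_over_time(res, std)
    return std, res, traj
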