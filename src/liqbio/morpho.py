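"""Morphometric embedding, Ward clustering and per-class density profiles.

Cellular rare events are summarized by eight standardized features (cell and
nuclear area and eccentricity, four median channel intensities), embedded in
two dimensions with tSNE for visualization, grouped bottom-up by Ward-linkage
agglomerative clustering on Euclidean distances, and profiled per channel-type
class with kernel density estimates whose peak counts support statements
about within-class heterogeneity (e.g. bimodal marker expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.integrate import trapezoid
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from sklearn.manifold import TSNE

from .core import FEATURE_COLUMNS, LEV_CLASSES


def build_feature_matrix(events: pd.DataFrame,
                         class_column: str = "event_class",
                         ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Standardized events x features matrix for cellular rare events.

    LEV rows are excluded (the morphometric analysis covers nucleated rare
    events); each retained column is z-scored to mean 0, SD 1. Columns with
    zero variance cannot be standardized and are dropped; their names are
    returned so the caller can record the degeneracy.

    Returns ``(matrix, classes, dropped_columns)`` where ``classes`` is the
    per-row channel-type annotation aligned with the matrix index.
    """
    lev_names = {c.value for c in LEV_CLASSES}
    cellular = events[~events[class_column].isin(lev_names)]
    if len(cellular) < 2:
        raise ValueError("feature matrix requires at least 2 cellular events")
    X = cellular[FEATURE_COLUMNS].astype(float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    dropped = [c for c in X.columns if sds[c] == 0 or not np.isfinite(sds[c])]
    kept = [c for c in X.columns if c not in dropped]
    Z = (X[kept] - means[kept]) / sds[kept]
    return Z, cellular[class_column].copy(), dropped


def embed_2d(matrix: pd.DataFrame | np.ndarray, perplexity: float = 30.0,
             seed: int = 42) -> np.ndarray:
    """Two-dimensional tSNE coordinates, deterministic under a fixed seed.

    Perplexity must satisfy perplexity < (n - 1) / 3; callers with small
    matrices should shrink it first. Coordinates are visualization-only: no
    downstream computation consumes them.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("embedding requires at least 5 events")
    if perplexity >= (n - 1) / 3:
        raise ValueError(
            f"perplexity {perplexity} too large for n={n}; need < (n-1)/3")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(X)


def clamp_perplexity(n: int, perplexity: float = 30.0) -> float:
    """Default perplexity, shrunk below the (n-1)/3 bound when n is small."""
    return min(perplexity, max(2.0, (n - 1) / 3 - 1e-6))


@dataclass
class ClusterResult:
    """Ward agglomeration output: labels in 1..k and the merge history."""

    labels: np.ndarray
    linkage_matrix: np.ndarray
    k: int
    embedding: np.ndarray | None = field(default=None)

    def merge_history(self) -> list[frozenset[int]]:
        """Member sets of each newly formed cluster, in merge order."""
        n = self.linkage_matrix.shape[0] + 1
        members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        history = []
        for step, (a, b, _, _) in enumerate(self.linkage_matrix[:, :4]):
            merged = members[int(a)] | members[int(b)]
            members[n + step] = merged
            history.append(merged)
        return history


def agglomerate(matrix: pd.DataFrame | np.ndarray, k: int = 6) -> ClusterResult:
    """Ward-linkage agglomerative clustering on Euclidean distances.

    Merges the pair minimizing the increase in within-cluster variance at
    each step and cuts the merge tree at ``k`` clusters; labels are 1..k.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..n={n}")
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(labels=labels, linkage_matrix=Z, k=k)


def density_profiles(matrix: pd.DataFrame, classes: pd.Series,
                     features: list[str] | None = None,
                     grid_size: int = 256,
                     prominence: float = 0.05) -> dict[str, dict[str, dict]]:
    """Per-class Gaussian-KDE profiles per feature, with peak counts.

    For every class with at least 2 events and every feature, returns the
    evaluation grid, the density (normalized to unit area), and the number of
    local maxima above the prominence floor (relative to the density peak) —
    the quantity behind bimodality statements. Classes with a single event
    are skipped with a warning; features that are constant within a class get
    a degenerate single-peak summary without a KDE.
    """
    if features is None:
        features = list(matrix.columns)
    out: dict[str, dict[str, dict]] = {}
    for cls in pd.unique(classes):
        sub = matrix.loc[classes[classes == cls].index, features]
        if len(sub) < 2:
            warnings.warn(f"class {cls!r} has a single event; skipped")
            continue
        per_feature: dict[str, dict] = {}
        for feat in features:
            vals = sub[feat].to_numpy(dtype=float)
            if np.ptp(vals) == 0:
                per_feature[feat] = {"grid": [float(vals[0])],
                                     "density": [np.inf], "n_peaks": 1,
                                     "degenerate": True}
                continue
            kde = gaussian_kde(vals)
            pad = 3 * vals.std(ddof=0)
            grid = np.linspace(vals.min() - pad, vals.max() + pad, grid_size)
            dens = kde(grid)
            peaks, _ = find_peaks(dens, prominence=prominence * dens.max())
            per_feature[feat] = {
                "grid": grid.tolist(), "density": dens.tolist(),
                "n_peaks": int(len(peaks)), "degenerate": False,
            }
        out[str(cls)] = per_feature
    return out


def profile_summary(profiles: dict[str, dict[str, dict]]) -> pd.DataFrame:
    """Flat table of peak counts per class and feature."""
    rows = [
        {"event_class": cls, "feature": feat, "n_peaks": d["n_peaks"]}
        for cls, feats in profiles.items() for feat, d in feats.items()
    ]
    return pd.DataFrame(rows)
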