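"""Cluster analysis in the (wingbeat frequency, wing-to-body ratio) plane.

A Gaussian mixture model and K-means are fitted independently for cluster
counts k = 1..10; each yields a BIC curve, and the cluster count is chosen
at the knee of the curve (maximal perpendicular distance to the chord
joining the curve's endpoints). Events are then hard-assigned from the GMM
at the selected k, and clusters are relabelled 1..k by ascending mean
wingbeat frequency so that labels are reproducible across runs.

K-means does not define a likelihood, so its BIC uses the equal-spherical-
variance Gaussian convention (as in X-means): all clusters share one
variance estimated from the pooled within-cluster sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

__all__ = [
    "ClusteringResult",
    "ElbowResult",
    "feature_matrix",
    "bic_curves",
    "kmeans_bic",
    "select_k_elbow",
    "assign",
    "run_clustering",
]

DEFAULT_K_RANGE = range(1, 11)


@dataclass(frozen=True)
class ElbowResult:
    """Knee of a model-selection curve.

    ``has_elbow`` is False for curves with no discernible bend (close to the
    straight chord everywhere); ``k`` then falls back to the smallest
    candidate.
    """

    k: int
    has_elbow: bool
    distances: np.ndarray


@dataclass
class ClusteringResult:
    k_selected: int
    bic_gmm: np.ndarray
    bic_kmeans: np.ndarray
    assignments: np.ndarray  # labels 1..k, ascending mean frequency
    centers: pd.DataFrame  # per-cluster mean (wingbeat_hz, ratio), raw units
    agreement: bool  # GMM and K-means elbows coincide
    elbow_gmm: ElbowResult | None = None
    elbow_kmeans: ElbowResult | None = None


def feature_matrix(events: pd.DataFrame) -> np.ndarray:
    """Standardised (frequency, ratio) feature matrix.

    Frequency spans hundreds of Hz while the ratio spans less than one, so
    both columns are scaled to zero mean and unit variance before any model
    fitting; assignments are therefore invariant to affine rescaling of the
    raw units.
    """
    if len(events) < 2:
        raise ValueError("need at least 2 events to build features")
    X = events[["wingbeat_hz", "ratio"]].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature column; cannot standardise")
    return (X - X.mean(axis=0)) / sd


def kmeans_bic(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    """BIC of a K-means partition under an equal-spherical-variance
    Gaussian likelihood (lower is better, matching the GMM convention)."""
    n, d = X.shape
    if n <= k:
        raise ValueError("need more points than clusters")
    centers = np.stack([X[labels == j].mean(axis=0) for j in range(k)])
    sse = float(np.sum((X - centers[labels]) ** 2))
    var = max(sse / (d * (n - k)), np.finfo(float).tiny)
    sizes = np.bincount(labels, minlength=k).astype(float)
    nz = sizes[sizes > 0]
    loglik = (
        float(np.sum(nz * np.log(nz / n)))
        - 0.5 * n * d * np.log(2.0 * np.pi * var)
        - 0.5 * d * (n - k)
    )
    n_params = (k - 1) + k * d + 1
    return -2.0 * loglik + n_params * np.log(n)


def bic_curves(
    X: np.ndarray,
    k_range: range = DEFAULT_K_RANGE,
    seed: int = 0,
    restarts: int = 10,
    tol: float = 1e-4,
    reg_covar: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """BIC versus cluster count for GMM (full covariance) and K-means.

    Both fits use ``restarts`` random initialisations and are deterministic
    for a fixed seed. A singular GMM fit is retried once with a stronger
    covariance regulariser.
    """
    bic_g, bic_k = [], []
    for k in k_range:
        try:
            gmm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=restarts,
                tol=tol,
                reg_covar=reg_covar,
                random_state=seed,
                max_iter=200,
            ).fit(X)
        except ValueError:
            gmm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=restarts,
                tol=tol,
                reg_covar=1e-3,
                random_state=seed,
                max_iter=200,
            ).fit(X)
        bic_g.append(gmm.bic(X))
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
        bic_k.append(kmeans_bic(X, km.labels_, k))
    return np.asarray(bic_g), np.asarray(bic_k)


def select_k_elbow(
    bic: np.ndarray, k_range: range = DEFAULT_K_RANGE, flat_tol: float = 0.05
) -> ElbowResult:
    """Knee of a BIC curve by maximal distance to the endpoint chord.

    Curve and k-axis are normalised to [0, 1] (kneedle-style) so the result
    does not depend on the BIC scale; the knee is the point farthest from
    the chord joining the first and last points, with two guards. First, if
    the global minimum sits at the smallest k, no split improves the score
    and there is no elbow. Second, the knee is only accepted at or before
    the global minimum: adding clusters past the minimum brings no
    improvement, so a bend in the rising tail is not a knee. Ties break
    toward smaller k. A curve nowhere farther than ``flat_tol`` from the
    chord (featureless, near-linear) has no elbow and falls back to the
    smallest k.
    """
    bic = np.asarray(bic, dtype=float)
    ks = np.asarray(list(k_range))
    if bic.size != ks.size:
        raise ValueError("bic vector length does not match k_range")
    if bic.size < 3:
        raise ValueError("need at least 3 points to locate an elbow")
    imin = int(np.argmin(bic))
    if imin == 0:
        return ElbowResult(int(ks[0]), False, np.zeros(bic.size))
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    span = bic.max() - bic.min()
    y = (bic - bic.min()) / span
    # distance from (x_i, y_i) to the line through the two endpoints
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
    cand = dist[: imin + 1]
    if cand.max() <= flat_tol:
        return ElbowResult(int(ks[0]), False, dist)
    # tie-break toward smaller k (tolerance absorbs float noise in exact ties)
    best = int(np.flatnonzero(cand >= cand.max() - 1e-12)[0])
    return ElbowResult(int(ks[best]), True, dist)


def assign(
    events: pd.DataFrame,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    tol: float = 1e-4,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Hard cluster assignment from the GMM at the selected k.

    Each event gets the component of maximal posterior responsibility;
    components are relabelled 1..k by ascending mean wingbeat frequency so
    that cluster 1 is always the slowest-flapping group.

    Returns ``(labels, centers)`` where ``centers`` holds per-cluster mean
    frequency and ratio in raw units.
    """
    X = feature_matrix(events)
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=restarts,
        tol=tol,
        random_state=seed,
        max_iter=200,
    ).fit(X)
    raw_labels = gmm.predict(X)
    freq = events["wingbeat_hz"].to_numpy(dtype=float)
    means = np.array(
        [
            freq[raw_labels == j].mean() if np.any(raw_labels == j) else np.inf
            for j in range(k)
        ]
    )
    order = np.argsort(means)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw_labels]
    centers = (
        pd.DataFrame(
            {
                "cluster": labels,
                "wingbeat_hz": freq,
                "ratio": events["ratio"].to_numpy(dtype=float),
            }
        )
        .groupby("cluster")
        .mean()
        .reset_index()
    )
    return labels, centers


def run_clustering(
    events: pd.DataFrame,
    k_max: int = 10,
    seed: int = 0,
    restarts: int = 10,
    tol: float = 1e-4,
) -> ClusteringResult:
    """Full cluster analysis: BIC curves, elbow selection, assignment."""
    X = feature_matrix(events)
    k_range = range(1, k_max + 1)
    bic_g, bic_k = bic_curves(X, k_range, seed=seed, restarts=restarts, tol=tol)
    elbow_g = select_k_elbow(bic_g, k_range)
    elbow_k = select_k_elbow(bic_k, k_range)
    k_sel = elbow_g.k
    labels, centers = assign(events, k_sel, seed=seed, restarts=restarts, tol=tol)
    return ClusteringResult(
        k_selected=k_sel,
        bic_gmm=bic_g,
        bic_kmeans=bic_k,
        assignments=labels,
        centers=centers,
        agreement=elbow_g.k == elbow_k.k,
        elbow_gmm=elbow_g,
        elbow_kmeans=elbow_k,
    )
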