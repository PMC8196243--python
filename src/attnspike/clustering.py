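"""Feature-based subdivision of units into functional classes.

Units are described by waveform width (P2T), firing rate, Fano factor,
inter-spike-interval irregularity (CV, CV2, Lv) and attentional modulation
(AUROC).  Redundant features are removed by a greedy explained-variance
pre-screen, and k-means with spherical-Gaussian AIC/BIC model selection
picks the number of clusters.  Cluster-membership stability across
realizations flags unreliable assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "isi_irregularity",
    "standardize_features",
    "prescreen_features",
    "ClusterModel",
    "kmeans_select_k",
    "stability_threshold",
]

CLUSTER_FEATURES = ["p2t_us", "fr", "ff", "cv", "cv2", "lv", "auroc"]


def isi_irregularity(trains: list[np.ndarray]) -> tuple[float, float, float]:
    """ISI irregularity measures (CV, CV2, Lv) from per-trial spike trains.

    ISIs never span trial boundaries.  CV = sd(ISI)/mean(ISI) over the
    pooled ISIs; CV2 and Lv average over neighboring ISI pairs within
    trials:

        CV2 = mean_i 2|ISI_{i+1} - ISI_i| / (ISI_{i+1} + ISI_i)
        Lv  = mean_i 3 (ISI_i - ISI_{i+1})^2 / (ISI_i + ISI_{i+1})^2

    Returns NaNs when fewer than 3 ISIs are available.
    """
    isis = [np.diff(np.sort(np.asarray(t, dtype=float))) for t in trains]
    pooled = np.concatenate([i for i in isis if i.size > 0]) if isis else np.array([])
    if pooled.size < 3:
        return (np.nan, np.nan, np.nan)
    cv = float(pooled.std(ddof=1) / pooled.mean())
    num_cv2, num_lv, n_pairs = 0.0, 0.0, 0
    for i in isis:
        if i.size < 2:
            continue
        a, b = i[:-1], i[1:]
        s = a + b
        num_cv2 += np.sum(2.0 * np.abs(b - a) / s)
        num_lv += np.sum(3.0 * (a - b) ** 2 / s**2)
        n_pairs += a.size
    if n_pairs == 0:
        return (cv, np.nan, np.nan)
    return (cv, float(num_cv2 / n_pairs), float(num_lv / n_pairs))


def standardize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Min-max standardization: each feature's observed min -> 0, max -> 1."""
    z = features.copy()
    for c in z.columns:
        lo, hi = z[c].min(), z[c].max()
        if hi == lo:
            raise ValueError(f"feature {c!r} is constant; cannot standardize")
        z[c] = (z[c] - lo) / (hi - lo)
    return z


def prescreen_features(
    features: pd.DataFrame, variance_threshold: float = 0.90
) -> list[str]:
    """Greedy forward selection of features explaining >= ``variance_threshold``
    of the variance of the full standardized feature matrix.

    At each step the feature whose addition maximizes the total R^2 of a
    linear reconstruction of all standardized features is retained.
    Constant features are excluded with a warning.  Deterministic given the
    input.
    """
    if features.shape[1] < 2 or features.shape[0] < 10:
        raise ValueError("prescreen needs >= 2 features and >= 10 units")
    cols = []
    for c in features.columns:
        if features[c].nunique() <= 1:
            warnings.warn(f"feature {c!r} is constant; excluded", stacklevel=2)
        else:
            cols.append(c)
    z = standardize_features(features[cols]).to_numpy()
    zc = z - z.mean(axis=0)
    sst = float(np.sum(zc**2))
    selected: list[int] = []
    remaining = list(range(len(cols)))
    explained = 0.0
    while explained < variance_threshold and remaining:
        best_j, best_r2 = None, -np.inf
        for j in remaining:
            idx = selected + [j]
            basis = zc[:, idx]
            # residual of projecting all features on the candidate basis
            coef, *_ = np.linalg.lstsq(basis, zc, rcond=None)
            sse = float(np.sum((zc - basis @ coef) ** 2))
            r2 = 1.0 - sse / sst
            if r2 > best_r2 + 1e-12:
                best_j, best_r2 = j, r2
        selected.append(best_j)
        remaining.remove(best_j)
        explained = best_r2
    return [cols[j] for j in selected]


@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    wcss: float
    aic: float
    bic: float
    criteria: pd.DataFrame
    realization_assignments: np.ndarray = field(repr=False)  # (realizations, n)
    k_aic: int = 0
    k_bic: int = 0


def _kmeans_information_criteria(
    wcss: float, cluster_sizes: np.ndarray, n: int, d: int, k: int
) -> tuple[float, float]:
    """Spherical equal-variance Gaussian-mixture AIC/BIC for a k-means
    solution (classification likelihood with mixing proportions).

    Without the mixing-proportion term the criteria are not consistent:
    splitting a true cluster always gains more log-likelihood than the
    parameter penalty.
    """
    sigma2 = max(wcss / (n * d), 1e-300)
    nj = np.asarray(cluster_sizes, dtype=float)
    nj = nj[nj > 0]
    ll = -0.5 * n * d * (np.log(2 * np.pi * sigma2) + 1.0) + np.sum(nj * np.log(nj / n))
    n_params = k * d + k  # centroids + mixing weights and shared variance
    return -2.0 * ll + 2.0 * n_params, -2.0 * ll + np.log(n) * n_params


def kmeans_select_k(
    z: pd.DataFrame | np.ndarray,
    k_range: range | list[int] = range(3, 9),
    realizations: int = 500,
    replicas: int = 50,
    seed: int | None = None,
) -> ClusterModel:
    """K-means over a range of k with AIC/BIC model selection.

    For each k, every realization runs ``replicas`` random initializations
    and keeps the best by within-cluster sum of squares; the best realization
    provides the final model at that k.  The returned model is at the argmin
    of the information criteria (ties between AIC and BIC resolved toward
    the smaller, more parsimonious k, with both optima recorded).
    """
    z = np.asarray(z, dtype=float)
    if np.isnan(z).any():
        raise ValueError("feature matrix contains missing values; exclude those units")
    n, d = z.shape
    if n < max(k_range):
        raise ValueError("fewer units than the largest k requested")
    if np.all(z == z[0]):
        raise ValueError("degenerate input: all feature vectors identical")
    if seed is None:
        raise ValueError("a seed is required")
    root = np.random.SeedSequence(seed)

    rows = []
    best_models = {}
    real_assign = {}
    for k in k_range:
        k_ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(k,))
        states = k_ss.generate_state(realizations)
        best = None
        assigns = np.empty((realizations, n), dtype=np.int32)
        for r in range(realizations):
            km = KMeans(
                n_clusters=k,
                n_init=replicas,
                init="random",
                random_state=int(states[r] % (2**32 - 1)),
            ).fit(z)
            assigns[r] = km.labels_
            if best is None or km.inertia_ < best.inertia_:
                best = km
        sizes = np.bincount(best.labels_, minlength=k)
        aic, bic = _kmeans_information_criteria(best.inertia_, sizes, n, d, k)
        rows.append(dict(k=k, wcss=float(best.inertia_), aic=aic, bic=bic))
        best_models[k] = best
        real_assign[k] = assigns
    criteria = pd.DataFrame(rows)
    k_aic = int(criteria.loc[criteria.aic.idxmin(), "k"])
    k_bic = int(criteria.loc[criteria.bic.idxmin(), "k"])
    k_best = k_aic if k_aic == k_bic else min(k_aic, k_bic)
    km = best_models[k_best]
    aic, bic = _kmeans_information_criteria(
        km.inertia_, np.bincount(km.labels_, minlength=k_best), n, d, k_best
    )
    return ClusterModel(
        k=k_best,
        assignments=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        wcss=float(km.inertia_),
        aic=aic,
        bic=bic,
        criteria=criteria,
        realization_assignments=real_assign[k_best],
        k_aic=k_aic,
        k_bic=k_bic,
    )


def _match_labels(labels: np.ndarray, reference: np.ndarray, k: int) -> np.ndarray:
    """Relabel ``labels`` to best match ``reference`` (Hungarian on overlap)."""
    k_lab = max(k, labels.max() + 1)
    cont = np.zeros((k_lab, k_lab))
    for a, b in zip(labels, reference):
        cont[a, b] += 1
    row, col = linear_sum_assignment(-cont)
    mapping = dict(zip(row, col))
    return np.array([mapping[a] for a in labels])


def stability_threshold(
    realization_assignments: np.ndarray,
    final_assignments: np.ndarray,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Fraction of realizations in which each unit lands in its final cluster.

    Realization labelings are matched to the final assignment by maximum
    overlap; units whose co-clustering fraction falls below ``threshold``
    are flagged unstable (core membership is a subset of full membership).
    """
    ra = np.asarray(realization_assignments)
    if ra.ndim != 2 or ra.shape[0] < 2:
        raise ValueError("need assignments from >= 2 realizations")
    final = np.asarray(final_assignments)
    k = int(final.max()) + 1
    hits = np.zeros(final.size)
    for r in range(ra.shape[0]):
        matched = _match_labels(ra[r], final, k)
        hits += matched == final
    frac = hits / ra.shape[0]
    return pd.DataFrame(
        {"cluster": final, "stability": frac, "stable": frac >= threshold}
    )
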