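"""Phenotype grouping from spot-trait profiles.

The ten measured traits (colour excluded) are z-scored, summarised by PCA on
their correlation matrix, and clustered with k-means into coat-pattern
phenotypes.  The number of groups is selected by the gap statistic
(uniform-over-feature-range reference distribution, first-SE-max rule); the
full gap curve is always returned because real data can show several
defensible optima, and overlapping groups can be lumped afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

DEFAULT_KMEANS_SEED = 20120101
DEFAULT_RESTARTS = 50


@dataclass
class TraitMatrix:
    """Animals × traits, column z-scored (mean 0, SD 1, n−1 denominator)."""

    X: np.ndarray
    animal_ids: list
    trait_names: list[str]


@dataclass
class PCAResult:
    """Eigendecomposition of the trait correlation matrix."""

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: np.ndarray        # traits × dims, columns are eigenvectors
    scores: np.ndarray          # animals × dims
    contributions: np.ndarray   # % contribution of trait to dim, traits × dims
    trait_names: list[str]


@dataclass
class ClusterModel:
    """A fitted k-means partition."""

    k: int
    centers: np.ndarray
    assignment: np.ndarray
    within_ss: float
    seed: int
    n_restarts: int


@dataclass
class GapCurve:
    """Gap statistic per candidate k and the selected number of groups."""

    k_values: np.ndarray
    log_wk: np.ndarray
    expected_log_wk: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    chosen_k: int
    B: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "log_Wk": self.log_wk,
                             "E_log_Wk": self.expected_log_wk,
                             "gap": self.gap, "s_k": self.s_k})


def standardize(raw: pd.DataFrame, trait_columns: list[str] | None = None) -> TraitMatrix:
    """Column-wise z-scores (SD with n−1 denominator) of the trait table."""
    if trait_columns is None:
        trait_columns = list(raw.columns)
    if len(raw) < 2:
        raise ValueError("need at least 2 animals")
    X = raw[trait_columns].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(trait_columns, sd):
        if s == 0:
            raise ValueError(f"trait {name!r} is constant and cannot be z-scored")
    Z = (X - X.mean(axis=0)) / sd
    return TraitMatrix(X=Z, animal_ids=list(raw.index), trait_names=list(trait_columns))


def pca(tm: TraitMatrix) -> PCAResult:
    """PCA via eigendecomposition of the correlation matrix.

    Dimensions are ordered by decreasing eigenvalue; each loading vector is
    flipped so its largest-magnitude entry is positive; the contribution of a
    trait to a dimension is 100 × loading².
    """
    Z = tm.X
    n = Z.shape[0]
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    percent = 100.0 * eigval / eigval.sum()
    scores = Z @ eigvec
    contrib = 100.0 * eigvec ** 2
    return PCAResult(eigenvalues=eigval, percent_variance=percent,
                     loadings=eigvec, scores=scores, contributions=contrib,
                     trait_names=list(tm.trait_names))


def kmeans_fit(
    X: np.ndarray,
    k: int,
    seed: int = DEFAULT_KMEANS_SEED,
    n_restarts: int = DEFAULT_RESTARTS,
) -> ClusterModel:
    """Best of ``n_restarts`` k-means++ runs (Lloyd iterations) by within-SS."""
    X = np.asarray(X, dtype=float)
    if k > len(X):
        raise ValueError("k cannot exceed the number of animals")
    if k == 1:
        center = X.mean(axis=0, keepdims=True)
        wss = float(((X - center) ** 2).sum())
        return ClusterModel(k=1, centers=center,
                            assignment=np.zeros(len(X), dtype=int),
                            within_ss=wss, seed=seed, n_restarts=n_restarts)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                max_iter=300, algorithm="lloyd",
                random_state=seed % (2 ** 32)).fit(X)
    return ClusterModel(k=k, centers=km.cluster_centers_,
                        assignment=km.labels_.astype(int),
                        within_ss=float(km.inertia_), seed=seed,
                        n_restarts=n_restarts)


def gap_statistic(
    X: np.ndarray,
    k_max: int = 8,
    B: int = 50,
    seed: int = DEFAULT_KMEANS_SEED,
    n_restarts: int = 10,
) -> GapCurve:
    """Gap statistic over k = 1..k_max.

    Reference datasets are drawn uniformly over each feature's observed
    range.  gap(k) = mean_b log W*_kb − log W_k and
    s_k = sd_b(log W*_kb)·√(1 + 1/B); the chosen k is the smallest with
    gap(k) ≥ gap(k+1) − s_{k+1} (first-SE-max rule), else k_max.
    """
    X = np.asarray(X, dtype=float)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if B < 10:
        raise ValueError("need at least 10 reference datasets")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)
    log_wk = np.array([np.log(kmeans_fit(X, int(k), seed=seed,
                                         n_restarts=n_restarts).within_ss)
                       for k in ks])
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_logs = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(2 ** 31))
        for j, k in enumerate(ks):
            ref_logs[b, j] = np.log(kmeans_fit(ref, int(k), seed=ref_seed,
                                               n_restarts=n_restarts).within_ss)
    exp_log = ref_logs.mean(axis=0)
    gap = exp_log - log_wk
    s_k = ref_logs.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    chosen = int(ks[-1])
    for j in range(k_max - 1):
        if gap[j] >= gap[j + 1] - s_k[j + 1]:
            chosen = int(ks[j])
            break
    return GapCurve(k_values=ks, log_wk=log_wk, expected_log_wk=exp_log,
                    gap=gap, s_k=s_k, chosen_k=chosen, B=B, seed=seed)


def lump_groups(model: ClusterModel, merge_map: dict[int, int]) -> ClusterModel:
    """Merge clusters according to ``merge_map`` (old label → new label).

    Every old label must be mapped (surjection onto the new label set).  New
    centres are the size-weighted means of the merged centres, and the merged
    within-SS follows from the parallel-axis decomposition, so no data matrix
    is needed.
    """
    old_labels = set(range(model.k))
    if set(merge_map) != old_labels:
        raise ValueError("merge_map must map every existing cluster label")
    new_labels = sorted(set(merge_map.values()))
    relabel = {lab: i for i, lab in enumerate(new_labels)}
    sizes = np.bincount(model.assignment, minlength=model.k).astype(float)
    new_k = len(new_labels)
    centers = np.zeros((new_k, model.centers.shape[1]))
    weights = np.zeros(new_k)
    for old in range(model.k):
        j = relabel[merge_map[old]]
        centers[j] += sizes[old] * model.centers[old]
        weights[j] += sizes[old]
    centers /= np.maximum(weights, 1.0)[:, None]
    extra = 0.0
    for old in range(model.k):
        j = relabel[merge_map[old]]
        extra += sizes[old] * float(((model.centers[old] - centers[j]) ** 2).sum())
    assignment = np.array([relabel[merge_map[a]] for a in model.assignment])
    return ClusterModel(k=new_k, centers=centers, assignment=assignment,
                        within_ss=model.within_ss + extra, seed=model.seed,
                        n_restarts=model.n_restarts)
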