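"""Class-imbalance handling.

Two unrelated imbalance problems are covered:

* structural-class training folds are balanced by SMOTE: each minority
  class is oversampled by ``(x - y) / y * 100`` percent, ``x`` the majority
  count and ``y`` the class count, so every class ends at the majority
  count; synthetic points are drawn on segments between a sample and one of
  its five nearest same-class neighbors;
* the binding dataset has only positive pairs, so negatives are drawn from
  the unseen protein-ligand pairs, either uniformly at random or via
  k-means clustering of the positive pair features with per-cluster
  balancing.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "smote_percentage",
    "smote_oversample",
    "SmoteOversampler",
    "balance_training_set",
    "random_negative_pairs",
    "cluster_negative_pairs",
    "NegativePairExhaustionError",
]


class NegativePairExhaustionError(RuntimeError):
    """A cluster (or the pair complement) ran out of candidate unseen pairs."""


def smote_percentage(x: int, y: int) -> float:
    """Oversampling percentage bringing a class of ``y`` up to ``x``: (x-y)/y*100."""
    if y < 1:
        raise ValueError("class count y must be >= 1")
    if x < y:
        raise ValueError("majority count x must be >= class count y")
    return (x - y) / y * 100.0


def smote_oversample(
    X: np.ndarray, percent: float, k: int = 5, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Generate ``round(percent/100 * n)`` synthetic rows by SMOTE interpolation.

    Each synthetic point is ``s + u * (nn - s)`` with ``s`` a class sample
    (samples are cycled in order so coverage is even), ``nn`` one of its
    ``k`` nearest same-class neighbors chosen uniformly, and ``u`` uniform
    on [0, 1]. Original rows are never modified.
    """
    X = np.asarray(X, dtype=float)
    if percent < 0:
        raise ValueError("percent must be >= 0")
    n = len(X)
    n_synthetic = int(round(percent / 100.0 * n))
    if n_synthetic == 0:
        return np.empty((0, X.shape[1] if X.ndim == 2 else 0))
    if n < 2:
        raise ValueError("SMOTE needs at least 2 samples to interpolate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kk = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=kk + 1).fit(X)
    neighbor_idx = nn.kneighbors(X, return_distance=False)[:, 1:]  # drop self
    base = np.arange(n_synthetic) % n
    chosen = neighbor_idx[base, rng.integers(0, kk, size=n_synthetic)]
    u = rng.uniform(0.0, 1.0, size=n_synthetic)[:, None]
    return X[base] + u * (X[chosen] - X[base])


class SmoteOversampler(BaseEstimator):
    """SMOTE resampler with an imbalanced-learn-style ``fit_resample``.

    Every minority class is oversampled to the majority count using
    ``k_neighbors`` nearest same-class neighbors. ``fit_resample`` returns
    the augmented ``(X, y)``; the boolean mask of synthetic rows is kept in
    ``synthetic_mask_`` so callers can audit that no synthetic instance
    leaks into evaluation data.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        majority = counts.max()
        X_parts, y_parts = [X], [y]
        for cls, count in zip(classes, counts):
            if count == majority:
                continue
            percent = smote_percentage(majority, count)
            synthetic = smote_oversample(X[y == cls], percent, k=self.k_neighbors, seed=rng)
            X_parts.append(synthetic)
            y_parts.append(np.full(len(synthetic), cls, dtype=y.dtype))
        X_out = np.concatenate(X_parts)
        y_out = np.concatenate(y_parts)
        self.synthetic_mask_ = np.concatenate(
            [np.zeros(len(X), dtype=bool), np.ones(len(X_out) - len(X), dtype=bool)]
        )
        return X_out, y_out


def balance_training_set(X_train, y_train, seed: int = 0, k: int = 5):
    """SMOTE-balance a training partition.

    Returns ``(X, y, synthetic_mask)``. Balancing is applied to the training
    partition only by construction — the function never sees test indices.
    """
    sampler = SmoteOversampler(k_neighbors=k, random_state=seed)
    X_out, y_out = sampler.fit_resample(X_train, y_train)
    return X_out, y_out, sampler.synthetic_mask_


def random_negative_pairs(positive_pairs, protein_ids, ligand_ids, n: int, seed: int = 0):
    """Sample ``n`` distinct unseen (protein, ligand) pairs uniformly.

    The sample is drawn from the complement of the positive set over the
    full protein x ligand cross product.
    """
    protein_ids = list(protein_ids)
    ligand_ids = list(ligand_ids)
    positives = set(map(tuple, positive_pairs))
    complement_size = len(protein_ids) * len(ligand_ids) - len(positives)
    if n > complement_size:
        raise NegativePairExhaustionError(
            f"requested {n} negative pairs but only {complement_size} unseen pairs exist"
        )
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    chosen: list[tuple[str, str]] = []
    seen = set(positives)
    # rejection sampling; falls back to exhaustive enumeration if unlucky
    attempts = 0
    while len(chosen) < n and attempts < 50 * n + 1000:
        p = protein_ids[rng.integers(len(protein_ids))]
        l = ligand_ids[rng.integers(len(ligand_ids))]
        attempts += 1
        if (p, l) in seen:
            continue
        seen.add((p, l))
        chosen.append((p, l))
    if len(chosen) < n:
        pool = [
            (p, l)
            for p in protein_ids
            for l in ligand_ids
            if (p, l) not in positives and (p, l) not in set(chosen)
        ]
        idx = rng.choice(len(pool), size=n - len(chosen), replace=False)
        chosen.extend(pool[i] for i in idx)
    return chosen


def cluster_negative_pairs(
    positive_pairs,
    protein_features: dict,
    ligand_features: dict,
    n_clusters: int = 10,
    seed: int = 0,
    max_attempts_factor: int = 200,
):
    """Clustering-based undersampling of negative pairs.

    The positive pair-feature vectors (protein block + ligand block) are
    k-means clustered; unseen pairs are drawn at random, assigned to the
    nearest centroid, and accepted while that cluster still has fewer
    negatives than positives — so each cluster ends balanced.

    Raises
    ------
    NegativePairExhaustionError
        Naming the unfilled clusters, if candidates run out.
    """
    positive_pairs = [tuple(p) for p in positive_pairs]
    if len(positive_pairs) < n_clusters:
        raise ValueError("need at least n_clusters positive pairs")
    pair_matrix = np.asarray(
        [
            np.concatenate([protein_features[p], ligand_features[l]])
            for p, l in positive_pairs
        ]
    )
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    positive_labels = km.fit_predict(pair_matrix)
    need = np.bincount(positive_labels, minlength=n_clusters)

    protein_ids = sorted(protein_features)
    ligand_ids = sorted(ligand_features)
    positives = set(positive_pairs)
    rng = np.random.default_rng(seed)
    have = np.zeros(n_clusters, dtype=int)
    chosen: list[tuple[str, str]] = []
    seen = set(positives)
    max_attempts = max_attempts_factor * int(need.sum())
    attempts = 0
    while (have < need).any():
        if attempts >= max_attempts:
            unfilled = [int(c) for c in np.nonzero(have < need)[0]]
            raise NegativePairExhaustionError(
                f"clusters {unfilled} could not be filled with unseen pairs"
            )
        attempts += 1
        p = protein_ids[rng.integers(len(protein_ids))]
        l = ligand_ids[rng.integers(len(ligand_ids))]
        if (p, l) in seen:
            continue
        vec = np.concatenate([protein_features[p], ligand_features[l]])
        cluster = int(km.predict(vec[None, :])[0])
        seen.add((p, l))
        if have[cluster] < need[cluster]:
            have[cluster] += 1
            chosen.append((p, l))
    return chosen
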