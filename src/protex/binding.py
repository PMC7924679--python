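"""Similarity-based protein-ligand binding prediction.

The predictor decides whether a protein ``p`` and a ligand ``l`` bind by
exploiting the assumption that similar proteins bind similar ligands:

* ligand side — find the ``k`` training proteins nearest to ``p`` in
  feature space, collect the ligands that bind them (the *related
  ligands*), and measure how far ``l`` is from that set;
* protein side — symmetrically, measure how far ``p`` is from the proteins
  related to ``l``'s nearest ligands.

Each distance is computed in every *category* — a (side, metric,
aggregation) triple with metric Euclidean or Manhattan and aggregation
either distance-to-centroid (``cluster_mean``) or mean of member distances
(``mean_of_distances``) — eight categories in all. A category votes for a
positive bind when its distance falls below its fitted threshold; the final
call is the majority over non-abstaining votes, ties going to positive.

Thresholds are fitted per category as the grand mean of the category
distances of all training pairs (positive and negative), so they sit
between the typical "binding" distance and the typical "non-binding" one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "DistanceCategory",
    "ALL_CATEGORIES",
    "UndecidablePairError",
    "k_nearest",
    "related_items",
    "category_distance",
    "SimilarityBindingClassifier",
]

METRICS = ("euclidean", "manhattan")
AGGREGATIONS = ("cluster_mean", "mean_of_distances")
SIDES = ("ligand", "protein")


@dataclass(frozen=True)
class DistanceCategory:
    """One vote channel: which side is measured, with which metric, how aggregated."""

    side: str
    metric: str
    aggregation: str

    def __post_init__(self) -> None:
        if self.side not in SIDES or self.metric not in METRICS or self.aggregation not in AGGREGATIONS:
            raise ValueError(f"invalid category {self!r}")


ALL_CATEGORIES: tuple[DistanceCategory, ...] = tuple(
    DistanceCategory(s, m, a) for s, m, a in product(SIDES, METRICS, AGGREGATIONS)
)


class UndecidablePairError(ValueError):
    """Raised when every category abstains (no related structures on either side)."""


def _metric_distance(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if metric == "euclidean":
        return float(np.sqrt(np.sum(diff**2)))
    if metric == "manhattan":
        return float(np.sum(np.abs(diff)))
    raise ValueError(f"unknown metric {metric!r}")


def k_nearest(query: np.ndarray, ids, matrix: np.ndarray, k: int, metric: str) -> list:
    """Ids of the ``k`` stored vectors nearest to ``query``.

    Ties are broken by stable id order (the order of ``ids``).
    """
    if k > len(ids):
        raise ValueError(f"asked for {k} neighbors but only {len(ids)} vectors are stored")
    query = np.asarray(query, dtype=float)
    diff = np.asarray(matrix, dtype=float) - query[None, :]
    if metric == "euclidean":
        dists = np.sqrt(np.sum(diff**2, axis=1))
    elif metric == "manhattan":
        dists = np.sum(np.abs(diff), axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    order = np.argsort(dists, kind="stable")[:k]
    return [ids[i] for i in order]


def related_items(anchor_ids, pair_list, anchor_side: str) -> list:
    """Partners appearing in ``pair_list`` with any anchor, deduplicated.

    ``anchor_side="protein"`` returns the ligands paired with the anchor
    proteins; ``"ligand"`` returns the proteins paired with the anchor
    ligands. Order follows the stored pair list (stable).
    """
    anchors = set(anchor_ids)
    out: list = []
    seen: set = set()
    for p, l in pair_list:
        partner = l if anchor_side == "protein" else p
        member = p if anchor_side == "protein" else l
        if member in anchors and partner not in seen:
            seen.add(partner)
            out.append(partner)
    return out


def category_distance(query: np.ndarray, related: np.ndarray, metric: str, aggregation: str) -> float:
    """Distance from a query vector to a non-empty set of related vectors."""
    related = np.atleast_2d(np.asarray(related, dtype=float))
    if related.size == 0:
        raise ValueError("related set is empty")
    if aggregation == "cluster_mean":
        return _metric_distance(query, related.mean(axis=0), metric)
    if aggregation == "mean_of_distances":
        return float(np.mean([_metric_distance(query, r, metric) for r in related]))
    raise ValueError(f"unknown aggregation {aggregation!r}")


class SimilarityBindingClassifier(BaseEstimator, ClassifierMixin):
    """Similarity-based binding predictor with per-category thresholds.

    Parameters
    ----------
    k : int, default 3
        Number of nearest neighbors used to build related sets.
    categories : sequence of DistanceCategory, optional
        Vote channels; defaults to all eight.
    threshold_protocol : {"pooled", "opposite"}, default "pooled"
        ``pooled`` derives related sets from the positive interaction list
        for every training pair (exactly as prediction does) and averages
        the distances of positive and negative pairs together, placing each
        threshold between the binding and non-binding distance scales.
        ``opposite`` derives each training pair's related sets from the
        interaction list of the opposite label instead.
    vote_scheme : {"categories", "sides"}, default "categories"
        ``categories`` takes the majority over all category votes; ``sides``
        first aggregates each side's categories into a single vote, then
        takes the majority of the two.
    tie_break : {"positive", "negative"}, default "positive"
        Label assigned on a tied vote.

    Fitted attributes
    -----------------
    thresholds_ : dict[DistanceCategory, float]
    classes_ : ndarray of [0, 1] (1 = binds)
    """

    def __init__(
        self,
        k: int = 3,
        categories=None,
        threshold_protocol: str = "pooled",
        vote_scheme: str = "categories",
        tie_break: str = "positive",
    ):
        self.k = k
        self.categories = categories
        self.threshold_protocol = threshold_protocol
        self.vote_scheme = vote_scheme
        self.tie_break = tie_break

    # -- internal helpers ---------------------------------------------------

    def _categories(self):
        return tuple(self.categories) if self.categories is not None else ALL_CATEGORIES

    def _store(self, side: str):
        if side == "protein":
            return self._protein_ids, self._protein_matrix
        return self._ligand_ids, self._ligand_matrix

    def _feature(self, side: str, item_id):
        store = self._protein_features if side == "protein" else self._ligand_features
        return store[item_id]

    def _related_vectors(self, pair, category: DistanceCategory, pair_list):
        """Related set and query vector for one pair under one category."""
        p, l = pair
        if category.side == "ligand":
            ids, matrix = self._store("protein")
            anchors = k_nearest(self._feature("protein", p), ids, matrix, self.k, category.metric)
            related = related_items(anchors, pair_list, "protein")
            query = self._feature("ligand", l)
            related_vecs = [self._feature("ligand", r) for r in related]
        else:
            ids, matrix = self._store("ligand")
            anchors = k_nearest(self._feature("ligand", l), ids, matrix, self.k, category.metric)
            related = related_items(anchors, pair_list, "ligand")
            query = self._feature("protein", p)
            related_vecs = [self._feature("protein", r) for r in related]
        return query, related_vecs

    # -- estimator API ------------------------------------------------------

    def fit(self, pairs, y, protein_features: dict, ligand_features: dict):
        """Fit thresholds from labelled training pairs.

        ``pairs`` is a sequence of (protein_id, ligand_id); ``y`` holds 1
        for binding (positive) and 0 for non-binding pairs; the feature
        dicts map ids to feature vectors and act as the model's feature
        store — they must also cover any structure passed to
        :meth:`predict` later.
        """
        pairs = [tuple(p) for p in pairs]
        y = np.asarray(y, dtype=int)
        if len(pairs) != len(y):
            raise ValueError("pairs and y must have equal length")
        if not (y == 1).any():
            raise ValueError("training data must contain positive pairs")
        if self.threshold_protocol not in ("pooled", "opposite"):
            raise ValueError(f"unknown threshold_protocol {self.threshold_protocol!r}")
        for p, l in pairs:
            if p not in protein_features:
                raise KeyError(f"no feature vector stored for protein {p!r}")
            if l not in ligand_features:
                raise KeyError(f"no feature vector stored for ligand {l!r}")
        if self.threshold_protocol == "opposite" and not (y == 0).any():
            raise ValueError(
                "threshold_protocol='opposite' needs negative training pairs; "
                "generate them with random_negative_pairs or cluster_negative_pairs"
            )

        self._protein_features = {k_: np.asarray(v, dtype=float) for k_, v in protein_features.items()}
        self._ligand_features = {k_: np.asarray(v, dtype=float) for k_, v in ligand_features.items()}
        self.positive_pairs_ = [p for p, lab in zip(pairs, y) if lab == 1]
        self.negative_pairs_ = [p for p, lab in zip(pairs, y) if lab == 0]
        self._protein_ids = sorted({p for p, _ in pairs})
        self._ligand_ids = sorted({l for _, l in pairs})
        if len(self._protein_ids) < self.k or len(self._ligand_ids) < self.k:
            raise ValueError("fewer training structures than k on one side")
        self._protein_matrix = np.asarray([self._protein_features[p] for p in self._protein_ids])
        self._ligand_matrix = np.asarray([self._ligand_features[l] for l in self._ligand_ids])

        self.thresholds_ = {}
        for category in self._categories():
            distances = []
            for pair, label in zip(pairs, y):
                if self.threshold_protocol == "pooled":
                    pair_list = self.positive_pairs_
                else:
                    pair_list = self.negative_pairs_ if label == 1 else self.positive_pairs_
                query, related = self._related_vectors(pair, category, pair_list)
                if related:
                    distances.append(
                        category_distance(query, related, category.metric, category.aggregation)
                    )
            if not distances:
                raise ValueError(f"no related sets found while fitting category {category}")
            self.thresholds_[category] = float(np.mean(distances))
        self.classes_ = np.array([0, 1])
        return self

    def decision_details(self, pair) -> dict:
        """Per-category distances, thresholds and votes for one pair.

        Votes are True (positive), False (negative) or None (abstained:
        the category found no related structures).
        """
        details = {}
        for category in self._categories():
            query, related = self._related_vectors(pair, category, self.positive_pairs_)
            if not related:
                details[category] = {"distance": np.nan, "threshold": self.thresholds_[category], "vote": None}
                continue
            d = category_distance(query, related, category.metric, category.aggregation)
            details[category] = {
                "distance": d,
                "threshold": self.thresholds_[category],
                "vote": bool(d < self.thresholds_[category]),
            }
        return details

    def predict_pair(self, pair) -> int:
        """Predict one pair: 1 binds, 0 does not.

        Raises
        ------
        UndecidablePairError
            If every category abstains.
        """
        details = self.decision_details(pair)
        if self.vote_scheme == "sides":
            votes = []
            for side in SIDES:
                side_votes = [
                    v["vote"] for c, v in details.items() if c.side == side and v["vote"] is not None
                ]
                if side_votes:
                    votes.append(sum(side_votes) * 2 >= len(side_votes))
        elif self.vote_scheme == "categories":
            votes = [v["vote"] for v in details.values() if v["vote"] is not None]
        else:
            raise ValueError(f"unknown vote_scheme {self.vote_scheme!r}")
        if not votes:
            raise UndecidablePairError(f"no category could vote for pair {pair!r}")
        positive = sum(votes)
        negative = len(votes) - positive
        if positive == negative:
            return 1 if self.tie_break == "positive" else 0
        return int(positive > negative)

    def predict(self, pairs, undecidable: str = "raise") -> np.ndarray:
        """Predict an array of pairs; see :meth:`predict_pair`.

        ``undecidable`` may be ``"raise"`` or a fallback label (0 or 1).
        """
        out = []
        for pair in pairs:
            try:
                out.append(self.predict_pair(tuple(pair)))
            except UndecidablePairError:
                if undecidable == "raise":
                    raise
                out.append(int(undecidable))
        return np.asarray(out, dtype=int)
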