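"""Cosine-distance nearest-neighbor classification and jackknife evaluation.

The distance between two feature vectors is ``1 - cos(a, b)``, i.e. one
minus the inner product over the product of the vector moduli; it lies in
``[0, 2]`` and is smaller for more similar direction.  A query is assigned
the class of the training sample at minimal distance, ties broken toward
the smallest training-row index.

Evaluation is by jackknife (leave-one-out) cross-validation: each sample
is in turn singled out and predicted from the remaining samples.  Two
standardization modes are provided:

* ``"refit"`` (default for :func:`jackknife`) — standardization statistics
  are re-fitted on each leave-one-out training fold, so no information
  about the held-out sample leaks into the transform;
* ``"paper"`` — statistics are fitted once on the full matrix and reused
  for every fold, the protocol classically used with this predictor (its
  mild optimism is a known caveat).

Four-class prediction is hierarchical: a first binary stage separates
short/medium from long/extra-long half-life; a second stage, with its own
optimized feature subset, refines within the chosen branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import HalfLife, StandardizationParams, standardize

log = logging.getLogger(__name__)

#: Distance assigned when a vector has zero norm (direction undefined).
ZERO_NORM_DISTANCE = 2.0


def nn_distance(a: np.ndarray, b: np.ndarray) -> float:
    """``1 - cosine similarity`` of two feature subvectors, in [0, 2].

    A zero-norm vector has no direction; the distance is then defined as
    the maximal value 2 (with a logged warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("nn_distance needs two equal-length 1-D vectors")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        log.warning("zero-norm feature vector: distance defined as %s", ZERO_NORM_DISTANCE)
        return ZERO_NORM_DISTANCE
    d = 1.0 - float(a @ b) / (na * nb)
    return min(max(d, 0.0), 2.0)


def cosine_distances(queries: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Pairwise ``1 - cos`` distances, queries x train, vectorized.

    Zero-norm rows on either side yield :data:`ZERO_NORM_DISTANCE`.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    train = np.atleast_2d(np.asarray(train, dtype=float))
    qn = np.linalg.norm(queries, axis=1)
    tn = np.linalg.norm(train, axis=1)
    denom = np.outer(np.where(qn > 0, qn, 1.0), np.where(tn > 0, tn, 1.0))
    d = 1.0 - (queries @ train.T) / denom
    d = np.clip(d, 0.0, 2.0)
    bad = np.outer(qn == 0, np.ones(len(tn), dtype=bool)) | np.outer(
        np.ones(len(qn), dtype=bool), tn == 0
    )
    if bad.any():
        log.warning("zero-norm feature vectors encountered in distance matrix")
        d[bad] = ZERO_NORM_DISTANCE
    return d


@dataclass
class TrainingSet:
    """A fitted stage model: raw feature subset matrix, labels, transform."""

    X: np.ndarray  # (n, k) raw values restricted to feature_idx
    labels: np.ndarray  # (n,) integer labels
    feature_idx: np.ndarray  # (k,) positions in the full feature vector
    params: StandardizationParams
    Z: np.ndarray  # standardized X
    ids: list[str] | None = None

    @classmethod
    def fit(
        cls,
        matrix: np.ndarray,
        labels: np.ndarray,
        feature_idx: np.ndarray | list[int] | None = None,
        ids: list[str] | None = None,
    ) -> "TrainingSet":
        """Restrict a raw matrix to a feature subset and fit standardization."""
        matrix = np.asarray(matrix, dtype=float)
        labels = np.asarray(labels)
        if matrix.shape[0] != len(labels):
            raise ValueError("one label per training row required")
        if feature_idx is None:
            feature_idx = np.arange(matrix.shape[1])
        feature_idx = np.asarray(feature_idx, dtype=int)
        X = matrix[:, feature_idx]
        Z, params = standardize(X)
        return cls(X=X, labels=labels, feature_idx=feature_idx, params=params, Z=Z, ids=ids)

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class StagePrediction:
    label: object
    nn_index: int
    nn_id: str | None
    distance: float


def nn_predict(query: np.ndarray, train: TrainingSet) -> StagePrediction:
    """Label a raw query subvector by its nearest (standardized) neighbor."""
    if len(train) == 0:
        raise ValueError("empty training set")
    z = train.params.apply(np.asarray(query, dtype=float)[train.feature_idx]
                           if len(query) != train.X.shape[1]
                           else np.asarray(query, dtype=float))
    d = cosine_distances(z[None, :], train.Z)[0]
    i = int(np.argmin(d))  # first minimum: smallest row index on ties
    return StagePrediction(
        label=train.labels[i],
        nn_index=i,
        nn_id=train.ids[i] if train.ids else None,
        distance=float(d[i]),
    )


@dataclass
class JackknifeResult:
    """Leave-one-out success rates, overall and per class."""

    predictions: np.ndarray
    labels: np.ndarray

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.predictions == self.labels))

    def per_class(self) -> dict[object, tuple[int, int]]:
        """class -> (number correct, number total)."""
        out = {}
        for c in np.unique(self.labels):
            mask = self.labels == c
            out[c.item() if hasattr(c, "item") else c] = (
                int((self.predictions[mask] == c).sum()),
                int(mask.sum()),
            )
        return out


def jackknife(
    matrix: np.ndarray,
    labels: np.ndarray,
    mode: str = "refit",
) -> JackknifeResult:
    """Leave-one-out evaluation of the nearest-neighbor classifier.

    ``matrix`` holds raw (unstandardized) feature values restricted to the
    subset under evaluation.  ``mode`` selects per-fold standardization
    refitting (``"refit"``) or a single global fit (``"paper"``).
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("jackknife needs at least 2 samples")
    if mode not in ("refit", "paper"):
        raise ValueError(f"unknown standardization mode {mode!r}")
    preds = np.empty(n, dtype=labels.dtype)
    if mode == "paper":
        Z, _ = standardize(matrix)
        d = cosine_distances(Z, Z)
        np.fill_diagonal(d, np.inf)
        preds = labels[np.argmin(d, axis=1)]
    else:
        idx = np.arange(n)
        for i in range(n):
            fold = idx != i
            if fold.sum() == 1:
                # single-row fold: every column is constant, transform to zero
                params = StandardizationParams(
                    mean=matrix[fold][0], sd=np.zeros(matrix.shape[1])
                )
                Zt = np.zeros_like(matrix[fold])
            else:
                Zt, params = standardize(matrix[fold])
            zq = params.apply(matrix[i])
            d = cosine_distances(zq[None, :], Zt)[0]
            preds[i] = labels[fold][int(np.argmin(d))]
    return JackknifeResult(predictions=preds, labels=labels)


@dataclass
class PredictionResult:
    """Hierarchical prediction: coarse branch, fine class, stage provenance."""

    coarse: str
    fine: HalfLife
    stages: dict[str, StagePrediction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.fine.coarse == self.coarse, "fine label inconsistent with branch"


@dataclass
class HierarchicalModel:
    """Three nearest-neighbor stages, each with its own feature subset.

    Stage 1 separates short/medium (0) from long/extra-long (1); stage 2a
    refines short vs medium; stage 2b long vs extra-long.
    """

    stage1: TrainingSet
    stage2a: TrainingSet
    stage2b: TrainingSet

    @classmethod
    def fit(
        cls,
        matrix: np.ndarray,
        classes: np.ndarray,
        subset1: np.ndarray,
        subset2a: np.ndarray,
        subset2b: np.ndarray,
        ids: list[str] | None = None,
    ) -> "HierarchicalModel":
        """Fit the three stages from a full raw feature matrix and classes."""
        classes = np.asarray(classes, dtype=int)
        coarse = (classes >= HalfLife.LONG).astype(int)
        sm = classes <= HalfLife.MEDIUM
        le = ~sm
        sub_ids = (lambda m: [i for i, keep in zip(ids, m) if keep]) if ids else (lambda m: None)
        return cls(
            stage1=TrainingSet.fit(matrix, coarse, subset1, ids),
            stage2a=TrainingSet.fit(matrix[sm], classes[sm], subset2a, sub_ids(sm)),
            stage2b=TrainingSet.fit(matrix[le], classes[le], subset2b, sub_ids(le)),
        )

    def predict(self, query: np.ndarray) -> PredictionResult:
        return hierarchical_predict(query, self.stage1, self.stage2a, self.stage2b)


def hierarchical_predict(
    query: np.ndarray,
    stage1: TrainingSet,
    stage2a: TrainingSet,
    stage2b: TrainingSet,
) -> PredictionResult:
    """Two-stage prediction of the four half-life classes.

    ``query`` is the raw full-length feature vector; each stage extracts its
    own feature subset and standardizes with its own training statistics.
    A short/medium stage-1 call routes to stage 2a, otherwise stage 2b.
    """
    for name, st in (("stage1", stage1), ("stage2a", stage2a), ("stage2b", stage2b)):
        if st is None:
            raise ValueError(f"missing fitted model for {name}")
    query = np.asarray(query, dtype=float)
    s1 = nn_predict(query[stage1.feature_idx], stage1)
    if int(s1.label) == 0:
        s2 = nn_predict(query[stage2a.feature_idx], stage2a)
        stages = {"stage1": s1, "stage2a": s2}
    else:
        s2 = nn_predict(query[stage2b.feature_idx], stage2b)
        stages = {"stage1": s1, "stage2b": s2}
    fine = HalfLife(int(s2.label))
    return PredictionResult(coarse=fine.coarse, fine=fine, stages=stages)
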