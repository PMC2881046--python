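"""mRMR (maximum relevance, minimum redundancy) feature ranking.

Features are first discretized into three states per column — below
``mean - sd``, within ``mean +/- sd``, above ``mean + sd`` — and mutual
information (MI) between discrete vectors is estimated with the plug-in
(empirical frequency) estimator, in bits.

The ranking is the greedy forward MID ("difference") variant: the first
feature maximizes relevance ``D = MI(f, target)``; each later round picks
the candidate maximizing ``D - R``, where ``R`` is the mean MI between the
candidate and the already-selected features.  Ties break toward the
smallest feature index so the ranking is deterministic.  The pure-relevance
("MaxRel") ordering is reported alongside but does not drive feature
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizedMatrix:
    """Three-state integer codes per feature, plus per-row class labels."""

    codes: np.ndarray  # (n, m) int8 in {0, 1, 2}
    labels: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        if self.codes.ndim != 2 or len(self.labels) != self.codes.shape[0]:
            raise ValueError("codes must be (n, m) with one label per row")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("need at least 2 distinct class labels")


def discretize(matrix: np.ndarray, labels: np.ndarray | None = None) -> DiscretizedMatrix | np.ndarray:
    """Three-state discretization of each column at thresholds mean +/- sd.

    Code 0 below ``mean - sd``, 1 inside the closed band, 2 above
    ``mean + sd``.  With ``labels`` given, returns a
    :class:`DiscretizedMatrix`; otherwise the raw code matrix.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("discretization needs a matrix with at least 2 rows")
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    codes = np.ones(matrix.shape, dtype=np.int8)
    codes[matrix < mu - sd] = 0
    codes[matrix > mu + sd] = 2
    if labels is None:
        return codes
    return DiscretizedMatrix(codes=codes, labels=np.asarray(labels))


def mutual_information(x: np.ndarray, y: np.ndarray, base: float = 2.0) -> float:
    """Plug-in mutual information between two discrete vectors.

    ``sum_ij p(i,j) log[p(i,j) / (p(i) p(j))]`` over the empirical joint
    distribution, with ``0 log 0 = 0``.  Base 2 (bits) by default; the base
    only rescales MI and cannot change an mRMR ranking.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("mutual information needs two equal-length 1-D vectors")
    n = len(x)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum()) / np.log(base)
    return max(mi, 0.0)  # guard tiny negative rounding


@dataclass
class MRMRRanking:
    """Greedy mRMR feature ordering.

    ``order[r]`` is the feature index selected at round ``r + 1``;
    ``score[r]`` its relevance-minus-redundancy at selection;
    ``relevance[j]`` is MI(feature j, target) for every feature;
    ``maxrel_order`` is the pure-relevance ordering.
    """

    order: np.ndarray
    score: np.ndarray
    relevance: np.ndarray
    maxrel_order: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.order)


def mrmr_rank(data: DiscretizedMatrix, base: float = 2.0) -> MRMRRanking:
    """Rank all features by greedy forward mRMR (difference form).

    Round 1 selects the feature of maximal relevance; round r selects
    ``argmax_f [ MI(f, target) - mean_{s in selected} MI(f, s) ]``.
    Pairwise feature MI is computed lazily and cached, so the cost is
    O(m^2) MI evaluations in the worst case.
    """
    codes, labels = data.codes, data.labels
    m = codes.shape[1]
    relevance = np.array(
        [mutual_information(codes[:, j], labels, base=base) for j in range(m)]
    )
    maxrel_order = np.lexsort((np.arange(m), -relevance))

    selected: list[int] = []
    remaining = np.ones(m, dtype=bool)
    redundancy_sum = np.zeros(m)
    order = np.empty(m, dtype=int)
    score = np.empty(m)
    for r in range(m):
        if not selected:
            crit = relevance.copy()
        else:
            crit = relevance - redundancy_sum / len(selected)
        crit[~remaining] = -np.inf
        best = int(np.argmax(crit))  # argmax takes the first max: smallest index
        order[r] = best
        score[r] = crit[best]
        remaining[best] = False
        selected.append(best)
        if r < m - 1:
            cand = np.flatnonzero(remaining)
            for j in cand:
                redundancy_sum[j] += mutual_information(
                    codes[:, j], codes[:, best], base=base
                )
    return MRMRRanking(
        order=order, score=score, relevance=relevance, maxrel_order=maxrel_order
    )
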