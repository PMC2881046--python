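"""Incremental feature selection (IFS) over an mRMR ranking.

Nested feature sets ``S_i`` (the first ``i`` features of the mRMR order)
are each evaluated by jackknife cross-validation of the nearest-neighbor
classifier; the curve of accuracy versus set size usually rises to a peak
and then degrades as noise features dilute the cosine distance.  The set
at the peak is the optimal subset; ties at the peak resolve to the
smallest set size (parsimony).

In the global-standardization evaluation mode the leave-one-out cosine
distances for all nested sets are obtained from incrementally updated Gram
matrices (adding one feature adds a rank-one term), so a full curve over
``m`` features costs O(m n^2) rather than O(m^2 n^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import HalfLife, standardize
from .mrmr import MRMRRanking
from .nna import jackknife

TASKS = ("coarse", "short_vs_medium", "long_vs_extra_long")


def build_ifs_sets(ranking: MRMRRanking | np.ndarray) -> list[np.ndarray]:
    """Nested prefixes of the ranking: ``S_i`` = first i ranked features."""
    order = ranking.order if isinstance(ranking, MRMRRanking) else np.asarray(ranking)
    if len(order) == 0:
        raise ValueError("empty ranking")
    return [order[:i].copy() for i in range(1, len(order) + 1)]


def task_subset(
    matrix: np.ndarray, classes: np.ndarray, task: str
) -> tuple[np.ndarray, np.ndarray]:
    """Row filter and binary labels for one hierarchical stage.

    ``coarse`` keeps all rows with labels short/medium=0 vs
    long/extra-long=1; the stage-2 tasks keep only their branch's rows with
    the two fine classes as labels.
    """
    classes = np.asarray(classes, dtype=int)
    if task == "coarse":
        return np.asarray(matrix), (classes >= HalfLife.LONG).astype(int)
    if task == "short_vs_medium":
        mask = classes <= HalfLife.MEDIUM
    elif task == "long_vs_extra_long":
        mask = classes >= HalfLife.LONG
    else:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    return np.asarray(matrix)[mask], classes[mask]


@dataclass
class IFSCurve:
    """Jackknife accuracy for each evaluated nested set size."""

    sizes: np.ndarray  # evaluated set sizes, ascending
    accuracies: np.ndarray
    order: np.ndarray  # the ranking the sets were built from

    @property
    def peak_index(self) -> int:
        """Position of the peak; first (smallest size) on ties."""
        return int(np.argmax(self.accuracies))

    @property
    def peak_size(self) -> int:
        return int(self.sizes[self.peak_index])

    @property
    def peak_accuracy(self) -> float:
        return float(self.accuracies[self.peak_index])


def _loo_accuracy_curve_global(Z: np.ndarray, labels: np.ndarray, order: np.ndarray,
                               sizes: np.ndarray) -> np.ndarray:
    """Leave-one-out NN accuracy for nested column prefixes of Z[:, order].

    Maintains the Gram matrix of the growing subset; standardization is the
    (already applied) global fit, matching jackknife mode="paper".
    """
    n = Z.shape[0]
    G = np.zeros((n, n))
    accs = np.empty(len(sizes))
    size_set = {int(s): k for k, s in enumerate(sizes)}
    for i, f in enumerate(order, start=1):
        col = Z[:, f]
        G += np.outer(col, col)
        if i in size_set:
            sq = np.clip(np.diag(G).copy(), 0.0, None)
            norms = np.sqrt(sq)
            denom = np.outer(np.where(norms > 0, norms, 1.0),
                             np.where(norms > 0, norms, 1.0))
            d = 1.0 - G / denom
            bad = np.outer(norms == 0, np.ones(n, bool)) | np.outer(np.ones(n, bool), norms == 0)
            d[bad] = 2.0
            np.fill_diagonal(d, np.inf)
            preds = labels[np.argmin(d, axis=1)]
            accs[size_set[i]] = np.mean(preds == labels)
    return accs


def ifs_evaluate(
    matrix: np.ndarray,
    labels: np.ndarray,
    ranking: MRMRRanking | np.ndarray,
    task: str | None = None,
    mode: str = "paper",
    stride: int = 1,
) -> IFSCurve:
    """Evaluate every nested mRMR prefix by jackknife and locate the peak.

    Parameters
    ----------
    matrix, labels
        Raw feature matrix and labels.  With ``task`` given, ``labels`` are
        four-class half-life labels and the rows/labels of that stage's
        sub-dataset are extracted first; with ``task=None`` the labels are
        used as-is.
    ranking
        mRMR ordering computed on the same (sub-)dataset.
    mode
        ``"paper"`` — one global standardization, evaluated via incremental
        Gram updates; ``"refit"`` — per-fold standardization refit (slower).
    stride
        Evaluate every ``stride``-th set size plus the full set, then refine
        exactly around the provisional peak.  1 (default) evaluates all
        sizes.
    """
    order = ranking.order if isinstance(ranking, MRMRRanking) else np.asarray(ranking, dtype=int)
    if len(order) == 0:
        raise ValueError("empty ranking")
    if task is not None:
        matrix, labels = task_subset(matrix, labels, task)
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if matrix.shape[0] < 2 or len(np.unique(labels)) < 2:
        raise ValueError("IFS evaluation needs >=2 rows and >=2 classes")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    m = len(order)
    sizes = np.unique(np.append(np.arange(1, m + 1, stride), m))

    def evaluate(sz: np.ndarray) -> np.ndarray:
        if mode == "paper":
            Z, _ = standardize(matrix)
            return _loo_accuracy_curve_global(Z, labels, order, sz)
        return np.array(
            [jackknife(matrix[:, order[:i]], labels, mode=mode).accuracy for i in sz]
        )

    accs = evaluate(sizes)
    if stride > 1:
        peak = int(sizes[np.argmax(accs)])
        fine = np.arange(max(1, peak - stride + 1), min(m, peak + stride - 1) + 1)
        fine = np.setdiff1d(fine, sizes)
        if len(fine):
            fine_accs = evaluate(fine)
            sizes = np.concatenate([sizes, fine])
            accs = np.concatenate([accs, fine_accs])
            srt = np.argsort(sizes)
            sizes, accs = sizes[srt], accs[srt]
    return IFSCurve(sizes=sizes, accuracies=accs, order=order)


def select_optimal(curve: IFSCurve) -> np.ndarray:
    """The feature subset at the curve's peak (smallest size on a plateau)."""
    return curve.order[: curve.peak_size].copy()
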