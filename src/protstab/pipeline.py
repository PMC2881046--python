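"""End-to-end glue: records + metadata -> features -> trained hierarchy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctd import biochemical_vector
from .features import assemble_feature_vector
from .ifs import IFSCurve, ifs_evaluate, select_optimal, task_subset
from .io import _KEGG_COLS, _LOC_COLS
from .mrmr import MRMRRanking, discretize, mrmr_rank
from .nna import HierarchicalModel
from .records import ProteinRecord


def build_feature_matrix(
    records: list[ProteinRecord],
    metadata: pd.DataFrame,
    *,
    annotate: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Encode records and join their metadata into the n x 376 raw matrix.

    Every record must have a metadata row (matched by id).  Rows follow
    record order.
    """
    missing = [r.id for r in records if r.id not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing for {len(missing)} record(s), e.g. {missing[0]!r}")
    rows = []
    for rec in records:
        meta = metadata.loc[rec.id]
        rows.append(
            assemble_feature_vector(
                rec,
                biochemical_vector(rec, annotate=annotate),
                meta[_LOC_COLS].to_numpy(float),
                meta[_KEGG_COLS].to_numpy(float),
                int(meta["complex_count"]),
            )
        )
    return [r.id for r in records], np.vstack(rows)


@dataclass
class TrainedPipeline:
    """A fitted hierarchical predictor with its selection diagnostics."""

    model: HierarchicalModel
    rankings: dict[str, MRMRRanking]
    curves: dict[str, IFSCurve]


def rank_and_select(
    matrix: np.ndarray,
    classes: np.ndarray,
    task: str,
    mode: str = "paper",
    stride: int = 1,
) -> tuple[MRMRRanking, IFSCurve, np.ndarray]:
    """mRMR ranking + IFS curve + optimal subset for one hierarchical stage.

    The stage's sub-dataset is extracted, standardized, discretized and
    ranked; the IFS curve is evaluated on the same sub-dataset.
    """
    sub, y = task_subset(matrix, classes, task)
    from .features import standardize

    Z, _ = standardize(sub)
    ranking = mrmr_rank(discretize(Z, y))
    curve = ifs_evaluate(sub, y, ranking, mode=mode, stride=stride)
    return ranking, curve, select_optimal(curve)


def train_hierarchical(
    matrix: np.ndarray,
    classes: np.ndarray,
    ids: list[str] | None = None,
    mode: str = "paper",
    stride: int = 1,
) -> TrainedPipeline:
    """Run mRMR + IFS for all three stages and fit the hierarchical model."""
    rankings: dict[str, MRMRRanking] = {}
    curves: dict[str, IFSCurve] = {}
    subsets: dict[str, np.ndarray] = {}
    for task in ("coarse", "short_vs_medium", "long_vs_extra_long"):
        ranking, curve, subset = rank_and_select(matrix, classes, task, mode, stride)
        rankings[task], curves[task], subsets[task] = ranking, curve, subset
    model = HierarchicalModel.fit(
        matrix,
        classes,
        subsets["coarse"],
        subsets["short_vs_medium"],
        subsets["long_vs_extra_long"],
        ids=ids,
    )
    return TrainedPipeline(model=model, rankings=rankings, curves=curves)
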