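"""Readers and writers for the pipeline's file formats.

Sequences travel as standard multi-record FASTA; everything else is
header-bearing TSV: annotation tracks (id, ss_track, acc_track), per-protein
metadata (id, psi, loc_1..loc_22, kegg_1..kegg_220, complex_count), labels,
feature matrices (id + V1..V376), standardization parameters, mRMR rankings
and IFS curves.  Model bundles are directories of these TSVs plus a JSON
descriptor.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import (
    FEATURE_NAMES,
    N_LOCATIONS,
    N_PATHWAYS,
    StandardizationParams,
)
from .mrmr import MRMRRanking
from .ifs import IFSCurve
from .nna import HierarchicalModel, TrainingSet
from .records import ProteinRecord, make_record


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


def read_fasta(path: str | Path, *, sanitize: bool = False) -> list[ProteinRecord]:
    """Read a multi-record FASTA into :class:`ProteinRecord` objects.

    Order-preserving; sequences uppercased; the identifier is the first
    whitespace-delimited token.  Duplicate identifiers and empty files are
    rejected.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        records.append(make_record(rec.id, str(rec.seq), sanitize=sanitize))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_tracks(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read the 3-column track TSV: id -> (ss_track, acc_track)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "ss_track", "acc_track"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: track file needs columns {sorted(required)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise FormatError(f"{path}: duplicate identifier {dup!r}")
    return {row.id: (row.ss_track, row.acc_track) for row in df.itertuples()}


def write_tracks(records: list[ProteinRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "ss_track": [r.ss_track or "" for r in records],
            "acc_track": [r.acc_track or "" for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def attach_tracks(
    records: list[ProteinRecord], tracks: dict[str, tuple[str, str]]
) -> list[ProteinRecord]:
    """Return records with their annotation tracks attached by identifier."""
    out = []
    for r in records:
        ss, acc = tracks.get(r.id, (None, None))
        out.append(ProteinRecord(id=r.id, sequence=r.sequence, ss_track=ss or None,
                                 acc_track=acc or None))
    return out


_LOC_COLS = [f"loc_{i}" for i in range(1, N_LOCATIONS + 1)]
_KEGG_COLS = [f"kegg_{i}" for i in range(1, N_PATHWAYS + 1)]


def write_metadata(ids, psi, location_flags, kegg_scores, complex_counts,
                   path: str | Path) -> None:
    df = pd.concat(
        [
            pd.DataFrame({"id": ids, "psi": np.asarray(psi)}),
            pd.DataFrame(np.asarray(location_flags, dtype=int), columns=_LOC_COLS),
            pd.DataFrame(np.asarray(kegg_scores), columns=_KEGG_COLS),
            pd.DataFrame({"complex_count": np.asarray(complex_counts, dtype=int)}),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["id", "psi"] + _LOC_COLS + _KEGG_COLS + ["complex_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing[:5]}...")
    return df.set_index("id", drop=False)


def write_labels(ids, classes, path: str | Path) -> None:
    from .features import HalfLife

    pd.DataFrame(
        {"id": ids, "class": [HalfLife(int(c)).label for c in classes]}
    ).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.Series:
    from .features import HalfLife

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "class"} <= set(df.columns):
        raise FormatError(f"{path}: label file needs columns id, class")
    by_name = {c.label: int(c) for c in HalfLife}
    try:
        values = [by_name[c] for c in df["class"]]
    except KeyError as e:
        raise FormatError(f"{path}: unknown class label {e.args[0]!r}") from None
    return pd.Series(values, index=df["id"], name="class")


def write_feature_matrix(ids, matrix: np.ndarray, path: str | Path,
                         names: list[str] | None = None) -> None:
    names = names or FEATURE_NAMES[: np.asarray(matrix).shape[1]]
    df = pd.DataFrame(np.asarray(matrix), columns=names)
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise FormatError(f"{path}: feature matrix needs an 'id' column")
    return df["id"].tolist(), df.drop(columns="id").to_numpy(dtype=float)


def write_standardization(params: StandardizationParams, path: str | Path) -> None:
    pd.DataFrame(
        [params.mean, params.sd],
        index=["mean", "sd"],
        columns=FEATURE_NAMES[: len(params.mean)],
    ).to_csv(path, sep="\t", float_format="%.17g")


def read_standardization(path: str | Path) -> StandardizationParams:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return StandardizationParams(
        mean=df.loc["mean"].to_numpy(float), sd=df.loc["sd"].to_numpy(float)
    )


def write_ranking(ranking: MRMRRanking, path: str | Path,
                  names: list[str] | None = None) -> None:
    names = names or FEATURE_NAMES
    pd.DataFrame(
        {
            "round": np.arange(1, ranking.n_features + 1),
            "feature_index": ranking.order,
            "feature_name": [names[i] for i in ranking.order],
            "relevance": ranking.relevance[ranking.order],
            "relevance_minus_redundancy": ranking.score,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ranking(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if "feature_index" not in df.columns:
        raise FormatError(f"{path}: ranking file needs a feature_index column")
    return df["feature_index"].to_numpy(int)


def write_ifs_curve(curve: IFSCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"set_size": curve.sizes, "accuracy_overall": curve.accuracies}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Model bundles

def _write_stage(stage: TrainingSet, stage_dir: Path) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(stage_dir / "feature_idx.tsv", stage.feature_idx, fmt="%d")
    ids = stage.ids or [str(i) for i in range(len(stage))]
    write_feature_matrix(
        ids, stage.X, stage_dir / "train.tsv",
        names=[FEATURE_NAMES[i] for i in stage.feature_idx],
    )
    pd.DataFrame({"id": ids, "label": stage.labels}).to_csv(
        stage_dir / "labels.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [stage.params.mean, stage.params.sd], index=["mean", "sd"]
    ).to_csv(stage_dir / "standardization.tsv", sep="\t", float_format="%.17g")


def _read_stage(stage_dir: Path) -> TrainingSet:
    feature_idx = np.loadtxt(stage_dir / "feature_idx.tsv", dtype=int, ndmin=1)
    ids, X = read_feature_matrix(stage_dir / "train.tsv")
    labels = pd.read_csv(stage_dir / "labels.tsv", sep="\t")["label"].to_numpy(int)
    ts = TrainingSet.fit(X, labels, np.arange(X.shape[1]), ids=ids)
    # the stored matrix is already subset; keep the original full-vector indices
    return TrainingSet(X=ts.X, labels=ts.labels, feature_idx=feature_idx,
                       params=ts.params, Z=ts.Z, ids=ids)


def save_model(model: HierarchicalModel, out_dir: str | Path) -> None:
    """Serialize a hierarchical model as TSV stage bundles + descriptor."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("stage1", "stage2a", "stage2b"):
        _write_stage(getattr(model, name), out / name)
    (out / "model.json").write_text(
        json.dumps({"kind": "hierarchical_nna", "stages": ["stage1", "stage2a", "stage2b"]})
        + "\n"
    )


def load_model(model_dir: str | Path) -> HierarchicalModel:
    model_dir = Path(model_dir)
    if not (model_dir / "model.json").exists():
        raise FormatError(f"{model_dir}: not a model bundle (model.json missing)")
    return HierarchicalModel(
        stage1=_read_stage(model_dir / "stage1"),
        stage2a=_read_stage(model_dir / "stage2a"),
        stage2b=_read_stage(model_dir / "stage2b"),
    )
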