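"""Readers and writers for the pipeline's delimited-text and NIfTI formats.

All tabular formats are TSV.  RDMs are square tables with a stimulus-id
header row and index column, missing entries serialized as NA.  Trial and
rating tables are long-format TSVs.  Volumetric inputs (stat maps, masks)
go through nibabel NIfTI images.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import StimulusSet
from .rdm import RDM, ResponseMatrix
from .roi import ROIMask
from .triplets import TRIAL_COLUMNS, TripletDataset

__all__ = [
    "write_design",
    "read_design",
    "write_rdm",
    "read_rdm",
    "write_trials",
    "read_trials",
    "write_ratings_long",
    "read_ratings_long",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_mask_nifti",
    "write_mask_nifti",
]


def write_design(design: StimulusSet, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path) -> StimulusSet:
    return StimulusSet.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_rdm(rdm: RDM, path) -> None:
    df = pd.DataFrame(rdm.values, index=list(rdm.ids), columns=list(rdm.ids))
    df.to_csv(path, sep="\t", na_rep="NA")


def read_rdm(path, source: str = "model", distance_name: str = "") -> RDM:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("RDM file must have identical row and column ids")
    return RDM(df.to_numpy(dtype=float), tuple(df.columns.astype(str)), source, distance_name)


def write_trials(dataset: TripletDataset, path) -> None:
    dataset.trials.to_csv(path, sep="\t", index=False)


def read_trials(path, stimulus_ids=None) -> TripletDataset:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in TRIAL_COLUMNS[:-1]})
    df["rt_ms"] = df["rt_ms"].astype(float)
    if stimulus_ids is None:
        stimulus_ids = sorted(
            set(df["stim_a"]) | set(df["stim_b"]) | set(df["stim_c"])
        )
    return TripletDataset(df, stimulus_ids)


def write_ratings_long(tables: list, path) -> None:
    """Serialize RatingTables to one long TSV
    (participant_id, task, stimulus_id, rating)."""
    frames = []
    for t in tables:
        long = (
            t.ratings.rename_axis(index="participant_id", columns="stimulus_id")
            .stack()
            .rename("rating")
            .reset_index()
        )
        long.insert(1, "task", t.task_name)
        frames.append(long)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_ratings_long(path) -> dict:
    """Read a long ratings TSV into {task_name: RatingTable}."""
    from .ratings import RatingTable

    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str, "stimulus_id": str})
    return {
        str(task): RatingTable.from_long(block, str(task))
        for task, block in df.groupby("task")
    }


def write_feature_matrix(matrix: ResponseMatrix, path) -> None:
    pd.DataFrame(
        matrix.values,
        index=list(matrix.stimulus_ids),
        columns=(
            list(matrix.channel_ids)
            if matrix.channel_ids is not None
            else [f"u{i}" for i in range(matrix.n_channels)]
        ),
    ).to_csv(path, sep="\t")


def read_feature_matrix(path, participant_id: str = "") -> ResponseMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ResponseMatrix(
        df.to_numpy(dtype=float),
        tuple(df.index.astype(str)),
        tuple(df.columns.astype(str)),
        participant_id=participant_id,
    )


def write_mask_nifti(mask: ROIMask, path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), np.eye(4)), str(path))


def read_mask_nifti(path, name: str = "") -> ROIMask:
    import nibabel as nib

    img = nib.load(str(path))
    return ROIMask(np.asarray(img.dataobj) > 0, name=name or Path(path).stem)
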