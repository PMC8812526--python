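"""Cohort serialization: NIfTI-1 volumes plus a TSV index.

Each observation is written as four NIfTI files (FLAIR, T1, brain mask,
manual mask) with the voxel dimensions encoded in a diagonal RAS-like
affine, and the cohort is indexed by a TSV with one row per observation.
Master files for training/validation sets use the same row layout.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputError
from .phantom import Cohort, LesionVolumeModel, PhantomParams, SubjectImage

__all__ = [
    "write_subject",
    "read_subject",
    "write_cohort",
    "read_cohort",
    "write_master_files",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = [
    "participant_id",
    "timepoint",
    "partition",
    "flair_path",
    "t1_path",
    "brainmask_path",
    "manualmask_path",
]


def _affine(voxel_dims: tuple[float, float, float]) -> np.ndarray:
    return np.diag([voxel_dims[0], voxel_dims[1], voxel_dims[2], 1.0])


def _save(volume: np.ndarray, voxel_dims, path: Path, dtype) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=dtype), _affine(voxel_dims))
    nib.save(img, str(path))


def write_subject(subject: SubjectImage, directory: Path) -> dict[str, str]:
    """Write one observation's four volumes; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{subject.participant_id}_{subject.timepoint}"
    paths = {
        "flair_path": f"{stem}_flair.nii.gz",
        "t1_path": f"{stem}_t1.nii.gz",
        "brainmask_path": f"{stem}_brainmask.nii.gz",
        "manualmask_path": f"{stem}_manualmask.nii.gz",
    }
    _save(subject.flair, subject.voxel_dims, directory / paths["flair_path"], np.float32)
    _save(subject.t1, subject.voxel_dims, directory / paths["t1_path"], np.float32)
    _save(subject.brain_mask, subject.voxel_dims, directory / paths["brainmask_path"], np.uint8)
    _save(subject.manual_mask, subject.voxel_dims, directory / paths["manualmask_path"], np.uint8)
    return paths


def read_subject(row: pd.Series, directory: Path) -> SubjectImage:
    directory = Path(directory)

    def load(col: str) -> tuple[np.ndarray, np.ndarray]:
        img = nib.load(str(directory / row[col]))
        return np.asarray(img.dataobj), img.affine

    flair, affine = load("flair_path")
    t1, _ = load("t1_path")
    brain, _ = load("brainmask_path")
    manual, _ = load("manualmask_path")
    voxel_dims = tuple(float(abs(affine[i, i])) for i in range(3))
    return SubjectImage(
        participant_id=str(row["participant_id"]),
        timepoint=str(row["timepoint"]),
        flair=np.asarray(flair, dtype=np.float32),
        t1=np.asarray(t1, dtype=np.float32),
        brain_mask=np.asarray(brain, dtype=bool),
        manual_mask=np.asarray(manual, dtype=bool),
        voxel_dims=voxel_dims,
    )


def write_cohort(cohort: Cohort, directory: Path) -> Path:
    """Write all volumes plus the index TSV; returns the index path.

    A ``provenance.json`` sidecar records the generator parameters so a
    written cohort round-trips including its configuration.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for partition, subject in cohort.observations():
        paths = write_subject(subject, directory)
        rows.append(
            {
                "participant_id": subject.participant_id,
                "timepoint": subject.timepoint,
                "partition": partition,
                **paths,
            }
        )
    index = pd.DataFrame(rows, columns=INDEX_COLUMNS)
    index_path = directory / "cohort_index.tsv"
    index.to_csv(index_path, sep="\t", index=False)
    provenance = {"params": asdict(cohort.params), "model": asdict(cohort.model)}
    (directory / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return index_path


def _params_from_json(d: dict) -> PhantomParams:
    d = dict(d)
    d["grid_shape"] = tuple(d["grid_shape"])
    d["voxel_dims"] = tuple(d["voxel_dims"])
    d["tissue_means"] = {k: tuple(v) for k, v in d["tissue_means"].items()}
    d["tissue_sds"] = {k: tuple(v) for k, v in d["tissue_sds"].items()}
    return PhantomParams(**d)


def read_cohort(directory: Path) -> Cohort:
    """Reconstruct a :class:`Cohort` from a directory written by write_cohort."""
    directory = Path(directory)
    index_path = directory / "cohort_index.tsv"
    if not index_path.exists():
        raise InputError(f"no cohort index at {index_path}")
    index = pd.read_csv(index_path, sep="\t")
    prov = json.loads((directory / "provenance.json").read_text())
    params = _params_from_json(prov["params"])
    model = LesionVolumeModel(**prov["model"])
    resampling, external = [], []
    for _, row in index.iterrows():
        subject = read_subject(row, directory)
        (resampling if row["partition"] == "resampling" else external).append(subject)
    return Cohort(
        resampling_subjects=resampling,
        external_subjects=external,
        params=params,
        model=model,
    )


def write_master_files(
    directory: Path,
    training_rows: pd.DataFrame,
    validation_rows: pd.DataFrame,
    draw_tag: str,
) -> tuple[Path, Path]:
    """Emit the per-draw training and validation master files (TSV).

    Training rows carry the manual-mask column; validation rows do not
    (predictions are compared to the masks downstream, the segmenter never
    sees them).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    train_path = directory / f"master_train_{draw_tag}.tsv"
    val_path = directory / f"master_validate_{draw_tag}.tsv"
    training_rows.to_csv(train_path, sep="\t", index=False)
    validation_rows.drop(columns=["manualmask_path"], errors="ignore").to_csv(
        val_path, sep="\t", index=False
    )
    return train_path, val_path
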