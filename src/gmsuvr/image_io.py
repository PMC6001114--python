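"""NIfTI-1 and TSV input/output, plus cohort grid validation.

Volumes are written as 32-bit float (labels and masks as unsigned integers).
No resampling or registration is offered: volumes that do not share the
cohort grid are an error, not a fixable condition.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .volume import AtlasParcellation, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
    "read_participants",
    "write_participants",
    "write_cohort",
    "read_cohort",
    "check_cohort_grids",
    "GridMismatchError",
]

AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when cohort volumes do not share one grid."""


def read_volume(path: str | Path) -> Volume:
    """Load a 3-D NIfTI-1 volume.

    4-D images are rejected (a trailing singleton dimension is squeezed).
    Non-finite voxels are tolerated but flagged in the description.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3-D image, got shape {data.shape}")
    desc = ""
    hdr_desc = img.header.get("descrip")
    if hdr_desc is not None:
        desc = bytes(hdr_desc).split(b"\x00", 1)[0].decode("ascii", "replace")
    if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
        desc = (desc + " [contains non-finite voxels]").strip()
    return Volume(data=data, affine=np.asarray(img.affine, dtype=float), description=desc)


def write_volume(vol: Volume, path: str | Path, dtype: str | None = None) -> Path:
    """Write a Volume as NIfTI-1.

    Intensity data goes out as float32; integer data (labels, masks) as
    uint16 unless ``dtype`` overrides.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dtype is None:
        dtype = "uint16" if np.issubdtype(vol.data.dtype, np.integer) else "float32"
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    img.header["descrip"] = vol.description.encode("ascii", "replace")[:79]
    nib.save(img, str(path))
    return path


def write_atlas(atlas: AtlasParcellation, nii_path: str | Path, tsv_path: str | Path) -> None:
    """Write label volume (NIfTI) and region-name map (TSV: label, name, is_reference)."""
    write_volume(atlas.labels, nii_path)
    rows = [
        {"label": k, "name": v, "is_reference": int(k == atlas.reference_label)}
        for k, v in sorted(atlas.name_map.items())
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_atlas(nii_path: str | Path, tsv_path: str | Path) -> AtlasParcellation:
    labels = read_volume(nii_path)
    labels = labels.with_data(np.asarray(np.rint(labels.data), dtype=np.int32))
    names = pd.read_csv(tsv_path, sep="\t")
    name_map = {int(r.label): str(r.name) for r in names.itertuples()}
    ref = names.loc[names.is_reference == 1, "label"]
    if len(ref) != 1:
        raise ValueError("atlas name map must designate exactly one reference region")
    return AtlasParcellation(labels=labels, name_map=name_map, reference_label=int(ref.iloc[0]))


def write_participants(subjects: Sequence, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"subject_id": s.subject_id, "group": s.group, "age": s.age, "sex": s.sex}
            for s in subjects
        ]
    ).to_csv(path, sep="\t", index=False)


def read_participants(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(subjects: Sequence, atlas: AtlasParcellation, out_dir: str | Path) -> Path:
    """Write per-subject PET/GM NIfTI pairs, the atlas, and the participants table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_volume(s.pet, out / f"{s.subject_id}_pet.nii.gz")
        write_volume(s.gm_prob, out / f"{s.subject_id}_gm.nii.gz")
    write_atlas(atlas, out / "atlas.nii.gz", out / "atlas_names.tsv")
    write_participants(subjects, out / "participants.tsv")
    scales = {s.subject_id: s.global_scale for s in subjects}
    (out / "global_scales.json").write_text(json.dumps(scales, indent=1))
    return out


def read_cohort(data_dir: str | Path):
    """Load a cohort written by :func:`write_cohort`.

    Returns ``(subjects, atlas)`` with subjects in participants-table order.
    """
    from .synthetic import SubjectRecord  # local import to avoid a cycle

    data_dir = Path(data_dir)
    atlas = read_atlas(data_dir / "atlas.nii.gz", data_dir / "atlas_names.tsv")
    table = read_participants(data_dir / "participants.tsv")
    scales_path = data_dir / "global_scales.json"
    scales = json.loads(scales_path.read_text()) if scales_path.exists() else {}
    subjects = []
    for row in table.itertuples():
        sid = str(row.subject_id)
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=str(row.group),
                age=float(row.age),
                sex=str(row.sex),
                pet=read_volume(data_dir / f"{sid}_pet.nii.gz"),
                gm_prob=read_volume(data_dir / f"{sid}_gm.nii.gz"),
                global_scale=float(scales.get(sid, float("nan"))),
            )
        )
    return subjects, atlas


def check_cohort_grids(subjects: Iterable, atlas: AtlasParcellation) -> list:
    """Validate that every PET, GM and atlas volume shares one grid.

    Shapes must match exactly; affines to an absolute tolerance of 1e-4 per
    entry.  Raises :class:`GridMismatchError` naming the first offender.
    Returns the subject list unchanged on success.
    """
    subjects = list(subjects)
    if not subjects:
        raise ValueError("empty cohort")
    ref = atlas.labels
    for s in subjects:
        for kind, vol in (("pet", s.pet), ("gm_prob", s.gm_prob)):
            if vol.shape != ref.shape:
                raise GridMismatchError(
                    f"subject {s.subject_id} {kind}: shape {vol.shape} != atlas {ref.shape}"
                )
            if not np.allclose(vol.affine, ref.affine, atol=AFFINE_ATOL, rtol=0.0):
                raise GridMismatchError(
                    f"subject {s.subject_id} {kind}: affine differs from atlas "
                    f"beyond {AFFINE_ATOL}"
                )
    return subjects
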