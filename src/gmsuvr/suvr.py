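"""Regional SUVR quantification, classical and gray-matter-masked.

The SUVR of region k for one subject is the mean PET intensity over the
region's voxels divided by the mean over the reference region (whole
cerebellum here):

    SUVR_k = mean_{i in k}(x_i) / mean_{j in ref}(x_j)

In GM-masked mode both means are restricted to the subject's own
gray-matter mask (probability >= threshold), so voxels whose position holds
little gray matter — atrophied or partial-volume tissue — no longer dilute
the regional uptake.  By default the reference region is masked too; a
switch restricts masking to target regions for comparison with earlier
reference-only schemes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .volume import AtlasParcellation, Volume

__all__ = [
    "ALL_VOXELS",
    "GM_MASKED",
    "DEFAULT_GM_THRESHOLD",
    "EmptyRegionError",
    "SUVRTable",
    "gm_mask_from_probability",
    "region_mean",
    "compute_suvr_table",
    "voxelwise_normalize",
    "build_group_gm_mask",
]

log = logging.getLogger(__name__)

ALL_VOXELS = "all_voxels"
GM_MASKED = "gm_masked"
DEFAULT_GM_THRESHOLD = 0.5


class EmptyRegionError(ValueError):
    """A regional mean was requested over an empty voxel set."""


@dataclass
class SUVRTable:
    """Subjects x regions SUVR matrix with its quantification mode.

    ``values`` is indexed by subject id with one column per target region
    (the reference region is never a column); undefined entries — empty
    region/GM intersections — are NaN.
    """

    values: pd.DataFrame
    mode: str
    gm_threshold: float | None = None

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_names(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV with a JSON sidecar carrying mode/threshold."""
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="subject_id")
        sidecar = {"mode": self.mode, "gm_threshold": self.gm_threshold}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SUVRTable":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="subject_id")
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(values=values, mode=meta["mode"], gm_threshold=meta.get("gm_threshold"))


def gm_mask_from_probability(gm_prob: Volume, threshold: float = DEFAULT_GM_THRESHOLD) -> Volume:
    """Binary GM mask: voxel included iff probability >= threshold (inclusive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"gm threshold must lie in (0, 1), got {threshold}")
    data = np.asarray(gm_prob.data)
    if np.nanmin(data) < 0 or np.nanmax(data) > 1:
        raise ValueError("gm_prob values must lie in [0, 1]")
    return gm_prob.with_data((data >= threshold).astype(np.uint8), "GM mask")


def region_mean(pet: Volume, region_mask: Volume | np.ndarray) -> float:
    """Arithmetic mean of PET intensity over the mask's voxels."""
    mask = region_mask.data if isinstance(region_mask, Volume) else region_mask
    mask = np.asarray(mask).astype(bool)
    if mask.shape != pet.shape:
        raise ValueError("mask and pet must share one grid")
    if not mask.any():
        raise EmptyRegionError("regional mean over an empty mask is undefined")
    return float(np.asarray(pet.data, dtype=np.float64)[mask].mean())


def compute_suvr_table(
    subjects: Sequence,
    atlas: AtlasParcellation,
    mode: str = ALL_VOXELS,
    gm_threshold: float = DEFAULT_GM_THRESHOLD,
    mask_reference: bool = True,
    strict: bool = False,
) -> SUVRTable:
    """Per-subject, per-region SUVRs in the requested mode.

    In GM_MASKED mode a region whose intersection with the subject's GM mask
    is empty yields NaN with a warning; an empty reference intersection makes
    the whole row NaN (or raises under ``strict``).
    """
    if mode not in (ALL_VOXELS, GM_MASKED):
        raise ValueError(f"unknown mode {mode!r}")
    region_masks = {name: atlas.region_mask(name) for name in atlas.target_names}
    ref_mask = atlas.region_mask(atlas.reference_label)

    rows = {}
    for s in subjects:
        if mode == GM_MASKED:
            gm = gm_mask_from_probability(s.gm_prob, gm_threshold).data.astype(bool)
        else:
            gm = None
        eff_ref = ref_mask & gm if (gm is not None and mask_reference) else ref_mask
        if not eff_ref.any():
            msg = f"subject {s.subject_id}: reference region has no GM voxels"
            if strict:
                raise EmptyRegionError(msg)
            warnings.warn(msg)
            rows[s.subject_id] = {name: np.nan for name in region_masks}
            continue
        ref = region_mean(s.pet, eff_ref)
        if ref <= 0:
            raise ValueError(f"subject {s.subject_id}: non-positive reference mean {ref}")
        row = {}
        for name, rmask in region_masks.items():
            eff = rmask & gm if gm is not None else rmask
            if not eff.any():
                msg = f"subject {s.subject_id}: region {name!r} has no GM voxels"
                if strict:
                    raise EmptyRegionError(msg)
                warnings.warn(msg)
                row[name] = np.nan
            else:
                row[name] = region_mean(s.pet, eff) / ref
        rows[s.subject_id] = row

    values = pd.DataFrame.from_dict(rows, orient="index")[list(region_masks)]
    values.index.name = "subject_id"
    return SUVRTable(
        values=values,
        mode=mode,
        gm_threshold=gm_threshold if mode == GM_MASKED else None,
    )


def voxelwise_normalize(
    pet: Volume, reference_mask: Volume | np.ndarray, gm_mask: Volume | np.ndarray | None = None
) -> Volume:
    """Divide every voxel by the (optionally GM-restricted) reference mean.

    This is the voxel-level analogue of the SUVR normalisation and feeds the
    voxel-intensity feature sets.
    """
    ref = reference_mask.data if isinstance(reference_mask, Volume) else reference_mask
    ref = np.asarray(ref).astype(bool)
    if gm_mask is not None:
        gm = gm_mask.data if isinstance(gm_mask, Volume) else gm_mask
        ref = ref & np.asarray(gm).astype(bool)
    if not ref.any():
        raise EmptyRegionError("reference mask empty (after GM restriction)")
    denom = region_mean(pet, ref)
    if denom <= 0:
        raise ValueError(f"reference mean must be positive, got {denom}")
    return pet.with_data(
        np.asarray(pet.data, dtype=np.float64) / denom, "cerebellum-referenced intensity"
    )


def build_group_gm_mask(
    subjects: Sequence,
    gm_threshold: float = DEFAULT_GM_THRESHOLD,
    consensus_fraction: float = 0.5,
) -> Volume:
    """Consensus GM mask: voxels that are GM in >= consensus_fraction of subjects.

    Gives every subject the same voxel-feature dimensionality.  With
    ``consensus_fraction = 1`` this is the intersection of subject masks.
    """
    if not 0.0 < consensus_fraction <= 1.0:
        raise ValueError("consensus_fraction must lie in (0, 1]")
    subjects = list(subjects)
    if not subjects:
        raise ValueError("empty cohort")
    counts = np.zeros(subjects[0].gm_prob.shape, dtype=np.int32)
    for s in subjects:
        counts += gm_mask_from_probability(s.gm_prob, gm_threshold).data
    mask = (counts >= consensus_fraction * len(subjects)).astype(np.uint8)
    if not mask.any():
        raise EmptyRegionError("consensus GM mask is empty")
    return subjects[0].gm_prob.with_data(mask, f"consensus GM mask ({consensus_fraction:g})")
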