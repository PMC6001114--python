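"""Core in-memory containers: 3-D volumes and atlas parcellations.

All analysis assumes a single common grid (one shape, one affine) across the
cohort, as produced by spatial normalisation to a standard space.  Voxel
indices are 0-based; world coordinates are millimetres in the affine's frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Volume", "AtlasParcellation"]


@dataclass
class Volume:
    """A 3-D scalar field with a voxel-index -> mm affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities.  Stored as float for intensity images; integer
        arrays are used for label volumes and binary masks.
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-to-world transform.  Must be invertible.
    description : str
        Free-text provenance note (carried into the NIfTI description field,
        truncated to 80 bytes on write).
    """

    data: np.ndarray
    affine: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge length in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "Volume", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )

    def with_data(self, data: np.ndarray, description: str | None = None) -> "Volume":
        """A new Volume on the same grid with replaced voxel data."""
        return replace(
            self,
            data=data,
            description=self.description if description is None else description,
        )


@dataclass
class AtlasParcellation:
    """Integer-labelled parcellation with a region-name map and a reference region.

    ``labels`` holds non-negative integers; 0 means outside the brain.  Every
    nonzero label must appear in ``name_map``.  The reference region (whole
    cerebellum in the default toy atlas) is identified by ``reference_label``
    and is never counted among the target regions.
    """

    labels: Volume
    name_map: dict[int, str] = field(default_factory=dict)
    reference_label: int = 0

    def __post_init__(self) -> None:
        lab = self.labels.data
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("atlas labels must be an integer volume")
        if lab.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        present = set(int(v) for v in np.unique(lab)) - {0}
        missing = present - set(self.name_map)
        if missing:
            raise ValueError(f"labels without a name: {sorted(missing)}")
        if self.reference_label not in present:
            raise ValueError("reference_label has no voxels in the label volume")

    @property
    def target_labels(self) -> list[int]:
        """Nonzero labels excluding the reference region, in label order."""
        return sorted(k for k in self.name_map if k != self.reference_label)

    @property
    def target_names(self) -> list[str]:
        return [self.name_map[k] for k in self.target_labels]

    @property
    def reference_name(self) -> str:
        return self.name_map[self.reference_label]

    def label_of(self, name: str) -> int:
        for k, v in self.name_map.items():
            if v == name:
                return k
        raise KeyError(f"region {name!r} not in atlas")

    def region_mask(self, region: int | str) -> np.ndarray:
        """Boolean voxel mask of one region (by label or by name)."""
        lab = region if isinstance(region, int) else self.label_of(region)
        return self.labels.data == lab

    @property
    def brain_mask(self) -> np.ndarray:
        """Boolean mask of all labelled voxels (targets plus reference)."""
        return self.labels.data > 0
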