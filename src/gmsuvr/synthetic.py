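"""Synthetic amyloid-PET / gray-matter phantom cohort.

Generates co-registered PET and GM-probability volumes for an AD vs non-AD
cohort on a toy atlas, with the statistical structure the downstream
analyses assume:

* elevated GM amyloid uptake in AD target regions,
* gray-matter atrophy in AD target regions (peripheral erosion of the GM
  core), which partial-volume-dilutes the all-voxel regional mean but not
  the GM-restricted one,
* a per-subject global intensity scale (cancels in any uptake ratio),
* shared per-subject amyloid burden plus independent per-region jitter
  (between-subject variability that voxel averaging cannot remove),
* additive Gaussian voxel noise.

Each atlas region is a box: an inner GM core (probability 1.0) surrounded
by a rim of mostly non-GM tissue (probability 0.15), mixed in PET via the
voxel's GM fraction.  The reference cerebellum shares the core/rim
composition (it holds white matter too) but is never atrophied and its
uptake carries no group effect, so at zero effect and zero atrophy the
all-voxel SUVR of every region is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume import AtlasParcellation, Volume

__all__ = [
    "TARGET_REGIONS",
    "REFERENCE_REGION",
    "CohortConfig",
    "SubjectRecord",
    "make_toy_atlas",
    "generate_cohort",
]

# The ten AD-associated target regions, atlas label = position + 1.
TARGET_REGIONS = (
    "medial_temporal",
    "lateral_temporal",
    "precuneus",
    "posterior_cingulate",
    "anterior_cingulate",
    "frontal",
    "occipital",
    "striatum",
    "thalami",
    "parietal",
)
REFERENCE_REGION = "cerebellum"
REFERENCE_LABEL = len(TARGET_REGIONS) + 1

# Region placement on a 3 x 4 x 2 cell lattice (x, y=posterior->anterior,
# z=inferior->superior) and fill fraction of the cell interior.  Fill
# fractions produce a wide size distribution; the frontal box is more than
# ten times the voxel count of the precuneus box on the default grid.
_LAYOUT: dict[str, tuple[tuple[int, int, int], float]] = {
    "medial_temporal": ((0, 1, 0), 0.60),
    "lateral_temporal": ((2, 1, 0), 0.80),
    "precuneus": ((0, 0, 1), 0.35),
    "posterior_cingulate": ((1, 2, 1), 0.45),
    "anterior_cingulate": ((1, 3, 0), 0.60),
    "frontal": ((1, 3, 1), 0.95),
    "occipital": ((2, 0, 1), 0.70),
    "striatum": ((2, 2, 0), 0.55),
    "thalami": ((1, 1, 0), 0.50),
    "parietal": ((0, 2, 1), 0.75),
    "cerebellum": ((1, 0, 0), 0.80),
}

GM_CORE_PROB = 1.0
GM_RIM_PROB = 0.15
GM_CORE_FRACTION = 0.70  # innermost fraction of region voxels that are GM
MIN_REGION_VOXELS = 20

# Per-region AD uptake elevation (added to GM uptake, dimensionless).
# Magnitudes grade from strong (lateral temporal, cingulate, precuneus)
# to negligible (thalami), mirroring the usual amyloid topography.
DEFAULT_REGION_EFFECTS: dict[str, float] = {
    "medial_temporal": 0.15,
    "lateral_temporal": 0.35,
    "precuneus": 0.30,
    "posterior_cingulate": 0.20,
    "anterior_cingulate": 0.30,
    "frontal": 0.20,
    "occipital": 0.15,
    "striatum": 0.15,
    "thalami": 0.05,
    "parietal": 0.20,
}

# Demographics: group sizes, sex counts and age moments of the emulated cohort.
_DEMOGRAPHICS = {
    "AD": {"n": 51, "male": 23, "age_mean": 63.43, "age_sd": 6.32, "age_range": (49.0, 74.0)},
    "NONAD": {"n": 43, "male": 28, "age_mean": 62.91, "age_sd": 8.27, "age_range": (42.0, 79.0)},
}


@dataclass
class CohortConfig:
    """Generator settings; the defaults are the study conditions.

    ``region_effects`` adds to AD gray-matter uptake per region;
    ``atrophy_factor`` is the mean fraction of each target region's GM core
    lost in AD subjects.  Each subject's actual eroded fraction is drawn
    around the group mean (sd ``atrophy_sd``), and the non-AD group gets a
    smaller mean (``nonad_atrophy_factor``) — elderly non-AD cohorts are not
    atrophy-free, and a noiseless AD-only erosion would hand the voxelwise
    classifier an anatomical giveaway no real cohort provides.  Both default
    to fixed multiples of ``atrophy_factor`` so a zero setting yields an
    exact between-group null.  ``burden_sd`` is the sd of a per-subject uptake shift
    shared by all target regions; ``region_jitter_sd`` is independent per
    subject x region (reference included); ``noise_sd`` is voxelwise, scaled
    by the subject's global intensity factor.
    """

    n_ad: int = 51
    n_nonad: int = 43
    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 3.0
    region_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_EFFECTS)
    )
    atrophy_factor: float = 0.25
    nonad_atrophy_factor: float | None = None  # default: 0.4 * atrophy_factor
    atrophy_sd: float | None = None  # default: 0.4 * atrophy_factor
    baseline_gm_uptake: float = 1.0
    nongm_uptake: float = 0.5
    reference_uptake: float = 1.0
    burden_sd: float = 0.12
    region_jitter_sd: float = 0.08
    noise_sd: float = 0.05
    global_scale_range: tuple[float, float] = (0.8, 1.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ad <= 0 or self.n_nonad <= 0:
            raise ValueError("both group sizes must be positive")
        if any(ax < 8 for ax in self.grid_shape):
            raise ValueError("grid axes must be >= 8")
        if self.noise_sd < 0 or self.burden_sd < 0 or self.region_jitter_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0.0 <= self.atrophy_factor < 1.0:
            raise ValueError("atrophy_factor must be in [0, 1)")
        if self.nonad_atrophy_factor is None:
            self.nonad_atrophy_factor = 0.4 * self.atrophy_factor
        if self.atrophy_sd is None:
            self.atrophy_sd = 0.4 * self.atrophy_factor
        if not 0.0 <= self.nonad_atrophy_factor < 1.0 or self.atrophy_sd < 0:
            raise ValueError("atrophy parameters out of range")
        lo, hi = self.global_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("global_scale_range must be a positive interval")

    @classmethod
    def mni_scale(cls, **overrides) -> "CohortConfig":
        """Preset on the full normalised-space grid (121 x 141 x 121 at 1.5 mm)."""
        overrides.setdefault("grid_shape", (121, 141, 121))
        overrides.setdefault("voxel_size_mm", 1.5)
        return cls(**overrides)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "AD" | "NONAD"
    age: float
    sex: str  # "M" | "F"
    pet: Volume
    gm_prob: Volume
    global_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in ("AD", "NONAD"):
            raise ValueError(f"group must be AD or NONAD, got {self.group!r}")
        if self.pet.shape != self.gm_prob.shape:
            raise ValueError("pet and gm_prob must share one grid")


def _affine(voxel_size_mm: float, grid_shape: tuple[int, int, int]) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    # centre the grid at the world origin, neuroimaging style
    aff[:3, 3] = -voxel_size_mm * (np.asarray(grid_shape) - 1) / 2.0
    return aff


def make_toy_atlas(
    grid_shape: tuple[int, int, int] = (40, 48, 40), voxel_size_mm: float = 3.0
) -> AtlasParcellation:
    """Build the toy parcellation: 10 disjoint target boxes plus cerebellum.

    Raises ``ValueError`` when the grid is too small to host all 11 regions
    with at least 20 voxels each.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    labels = np.zeros(grid_shape, dtype=np.int32)
    cells = [np.linspace(0, g, n + 1).astype(int) for g, n in zip(grid_shape, (3, 4, 2))]
    name_map: dict[int, str] = {}
    for idx, name in enumerate((*TARGET_REGIONS, REFERENCE_REGION)):
        (ci, cj, ck), fill = _LAYOUT[name]
        lab = idx + 1
        lo = np.array([cells[0][ci], cells[1][cj], cells[2][ck]])
        hi = np.array([cells[0][ci + 1], cells[1][cj + 1], cells[2][ck + 1]])
        inner = hi - lo - 2  # one-voxel margin keeps neighbouring boxes disjoint
        size = np.maximum(1, np.floor(fill * inner + 0.5).astype(int))
        start = lo + 1 + (inner - size) // 2
        stop = start + size
        if np.any(size > inner) or int(np.prod(size)) < MIN_REGION_VOXELS:
            raise ValueError(
                f"grid {grid_shape} too small: region {name!r} would have "
                f"{int(np.prod(size))} voxels (< {MIN_REGION_VOXELS})"
            )
        block = labels[start[0] : stop[0], start[1] : stop[1], start[2] : stop[2]]
        if np.any(block != 0):
            raise ValueError(f"grid {grid_shape} too small: region {name!r} overlaps")
        block[...] = lab
        name_map[lab] = name
    vol = Volume(labels, _affine(voxel_size_mm, grid_shape), description="toy atlas")
    return AtlasParcellation(labels=vol, name_map=name_map, reference_label=REFERENCE_LABEL)


def _region_voxel_order(atlas: AtlasParcellation, label: int) -> np.ndarray:
    """Flat voxel indices of a region, innermost first.

    Ordering is by Euclidean distance to the region centroid, each axis
    normalised by the region's half-extent, with a stable sort — fully
    determined by the atlas geometry.
    """
    mask = atlas.labels.data == label
    idx = np.flatnonzero(mask)
    coords = np.array(np.unravel_index(idx, atlas.labels.shape), dtype=float).T
    centre = coords.mean(axis=0)
    half = np.maximum((coords.max(axis=0) - coords.min(axis=0)) / 2.0, 0.5)
    d = np.sqrt((((coords - centre) / half) ** 2).sum(axis=1))
    return idx[np.argsort(d, kind="stable")]


def _template_gm(atlas: AtlasParcellation) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Template GM probability and per-region innermost-first voxel orders.

    Every region — reference included — has an innermost ``GM_CORE_FRACTION``
    of voxels at core probability and a rim at rim probability, so with no
    effect and no atrophy the all-voxel SUVR of every region is exactly 1.
    """
    gm = np.zeros(atlas.labels.shape, dtype=np.float32).ravel()
    orders: dict[int, np.ndarray] = {}
    for lab in (*atlas.target_labels, atlas.reference_label):
        order = _region_voxel_order(atlas, lab)
        orders[lab] = order
        n_core = max(1, int(round(GM_CORE_FRACTION * order.size)))
        gm[order[:n_core]] = GM_CORE_PROB
        gm[order[n_core:]] = GM_RIM_PROB
    return gm.reshape(atlas.labels.shape), orders


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[SubjectRecord], AtlasParcellation]:
    """Draw a full synthetic cohort; deterministic given ``config.seed``.

    Per subject, the PET voxel value inside the brain is

        scale * [gm * (u_region + effects) + (1 - gm) * nongm_uptake] + noise

    with ``gm`` the subject's (possibly atrophied) GM probability and
    ``noise ~ N(0, noise_sd * scale)``.  AD atrophy removes the outermost
    ``atrophy_factor`` fraction of each target region's GM core (those
    voxels fall to the rim probability), so the subject's own GM mask
    excludes them while an all-voxel regional mean still averages over them.
    """
    cfg = config if config is not None else CohortConfig()
    atlas = make_toy_atlas(cfg.grid_shape, cfg.voxel_size_mm)
    unknown = set(cfg.region_effects) - set(TARGET_REGIONS)
    if unknown:
        raise ValueError(f"region_effects name unknown regions: {sorted(unknown)}")

    template_gm, orders = _template_gm(atlas)
    rng = np.random.default_rng(cfg.seed)
    shape = atlas.labels.shape
    flat_labels = atlas.labels.data.ravel()
    brain = flat_labels > 0
    label_of = {name: atlas.label_of(name) for name in TARGET_REGIONS}

    subjects: list[SubjectRecord] = []
    groups = ["AD"] * cfg.n_ad + ["NONAD"] * cfg.n_nonad
    sex_pool = {g: _sex_sequence(g, n, rng) for g, n in (("AD", cfg.n_ad), ("NONAD", cfg.n_nonad))}
    counters = {"AD": 0, "NONAD": 0}
    for i, group in enumerate(groups):
        demo = _DEMOGRAPHICS[group]
        age = float(
            np.clip(rng.normal(demo["age_mean"], demo["age_sd"]), *demo["age_range"])
        )
        sex = sex_pool[group][counters[group]]
        counters[group] += 1
        scale = float(rng.uniform(*cfg.global_scale_range))

        gm = template_gm.ravel().copy()
        af_mean = cfg.atrophy_factor if group == "AD" else cfg.nonad_atrophy_factor
        af_subject = float(np.clip(rng.normal(af_mean, cfg.atrophy_sd), 0.0, 0.95))
        if af_subject > 0:
            for name in TARGET_REGIONS:
                order = orders[label_of[name]]
                n_core = max(1, int(round(GM_CORE_FRACTION * order.size)))
                n_lost = int(round(af_subject * n_core))
                if n_lost:
                    gm[order[n_core - n_lost : n_core]] = GM_RIM_PROB

        # regional GM uptake: baseline (+ AD elevation) + shared burden + jitter
        burden = float(rng.normal(0.0, cfg.burden_sd)) if cfg.burden_sd else 0.0
        uptake = np.zeros(flat_labels.max() + 1)
        for name in TARGET_REGIONS:
            u = cfg.baseline_gm_uptake + burden
            if group == "AD":
                u += cfg.region_effects.get(name, 0.0)
            uptake[label_of[name]] = u
        uptake[atlas.reference_label] = cfg.reference_uptake
        if cfg.region_jitter_sd:
            uptake[1:] += rng.normal(0.0, cfg.region_jitter_sd, size=uptake.size - 1)

        pet = np.zeros(flat_labels.size, dtype=np.float64)
        u_vox = uptake[flat_labels[brain]]
        pet[brain] = scale * (gm[brain] * u_vox + (1.0 - gm[brain]) * cfg.nongm_uptake)
        if cfg.noise_sd > 0:
            pet[brain] += rng.normal(0.0, cfg.noise_sd * scale, size=int(brain.sum()))

        sid = f"sub-{i + 1:03d}"
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                age=round(age, 1),
                sex=sex,
                pet=Volume(
                    pet.reshape(shape).astype(np.float32),
                    atlas.labels.affine,
                    description=f"synthetic amyloid PET {sid}",
                ),
                gm_prob=Volume(
                    gm.reshape(shape).astype(np.float32),
                    atlas.labels.affine,
                    description=f"synthetic GM probability {sid}",
                ),
                global_scale=scale,
            )
        )
    return subjects, atlas


def _sex_sequence(group: str, n: int, rng: np.random.Generator) -> list[str]:
    """Sex labels with the emulated cohort's M/F proportions, shuffled."""
    demo = _DEMOGRAPHICS[group]
    n_male = int(round(n * demo["male"] / demo["n"]))
    seq = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(seq)
    return [str(s) for s in seq]
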