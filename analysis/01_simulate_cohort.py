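"""Generate the synthetic amyloid-PET / gray-matter cohort.

Draws the default 51 AD / 43 non-AD phantom cohort on the toy atlas,
writes the NIfTI volumes to scratch/ (bulky, regenerable) and the
participants table to results/, and prints the cohort composition.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

from collections import Counter
from pathlib import Path

from gmsuvr import CohortConfig, generate_cohort, image_io

SEED = 0
RESULTS = Path("results")
SCRATCH = Path("scratch")


def main() -> None:
    cfg = CohortConfig(seed=SEED)
    subjects, atlas = generate_cohort(cfg)
    image_io.check_cohort_grids(subjects, atlas)

    out = image_io.write_cohort(subjects, atlas, SCRATCH / "cohort")
    RESULTS.mkdir(exist_ok=True)
    image_io.write_participants(subjects, RESULTS / "participants.tsv")

    groups = Counter(s.group for s in subjects)
    sexes = Counter((s.group, s.sex) for s in subjects)
    print(f"cohort: {groups['AD']} AD / {groups['NONAD']} non-AD on grid "
          f"{cfg.grid_shape} at {cfg.voxel_size_mm} mm")
    print(f"sex by group: AD {sexes[('AD','M')]}M/{sexes[('AD','F')]}F, "
          f"non-AD {sexes[('NONAD','M')]}M/{sexes[('NONAD','F')]}F")
    sizes = {n: int(atlas.region_mask(n).sum()) for n in atlas.target_names}
    print(f"region sizes (voxels): {sizes}")
    print(f"frontal / precuneus size ratio: "
          f"{sizes['frontal'] / sizes['precuneus']:.1f}")
    print(f"volumes written to {out}; participants table to {RESULTS}/participants.tsv")


if __name__ == "__main__":
    main()
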