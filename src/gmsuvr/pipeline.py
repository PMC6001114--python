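"""End-to-end orchestration: simulate -> quantify -> stats -> classify.

One master seed deterministically derives a seed per stage (via a keyed
hash), so any stage can be re-run standalone with the same result.  All
tabular outputs are TSV; the run summary — juxtaposing the classical and
GM-masked analyses — is JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classify as cl
from . import group_stats as gs
from . import image_io, suvr
from .synthetic import CohortConfig, generate_cohort

__all__ = ["RunConfig", "derive_seed", "run_all"]

log = logging.getLogger(__name__)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed from the master seed: keyed blake2s, folded below 2**31."""
    h = hashlib.blake2s(f"{master_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2**31)


@dataclass
class RunConfig:
    """Full pipeline configuration (serialised verbatim into the run report)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    gm_threshold: float = suvr.DEFAULT_GM_THRESHOLD
    consensus_fraction: float = 0.5
    fwe_method: str = gs.PERMUTATION_MAXT
    alpha: float = 0.05
    n_permutations: int = 1000
    fwhm_mm: float = 8.0
    n_folds: int = 10
    C: float = 1.0
    master_seed: int = 0
    write_volumes: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("cohort", {}) or {}).items()
        })
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the whole analysis; returns (and writes) the summary dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict(), "stages": {}}

    def stage_seed(name: str) -> int:
        s = derive_seed(config.master_seed, name)
        summary["stages"][name] = {"seed": s}
        return s

    # --- simulate ------------------------------------------------------
    cohort_cfg = CohortConfig(**{**asdict(config.cohort), "seed": stage_seed("simulate")})
    subjects, atlas = generate_cohort(cohort_cfg)
    image_io.check_cohort_grids(subjects, atlas)
    labels = [s.group for s in subjects]
    log.info("simulated %d subjects (%d AD / %d non-AD)", len(subjects),
             labels.count("AD"), labels.count("NONAD"))
    image_io.write_participants(subjects, out / "participants.tsv")
    if config.write_volumes:
        image_io.write_cohort(subjects, atlas, out / "cohort")

    # --- quantify ------------------------------------------------------
    table_all = suvr.compute_suvr_table(subjects, atlas, mode=suvr.ALL_VOXELS)
    table_gm = suvr.compute_suvr_table(
        subjects, atlas, mode=suvr.GM_MASKED, gm_threshold=config.gm_threshold
    )
    table_all.to_tsv(out / "suvr_all_voxels.tsv")
    table_gm.to_tsv(out / "suvr_gm_masked.tsv")

    # --- voxelwise stats ----------------------------------------------
    seed_stats = stage_seed("stats")
    brain = atlas.brain_mask
    ad = [s for s in subjects if s.group == "AD"]
    non = [s for s in subjects if s.group == "NONAD"]
    smoothed_ad = [gs.smooth_volume(s.pet, config.fwhm_mm, mask=brain) for s in ad]
    smoothed_non = [gs.smooth_volume(s.pet, config.fwhm_mm, mask=brain) for s in non]
    tres = gs.fwe_threshold(
        smoothed_ad, smoothed_non, brain,
        direction=gs.A_GT_B, method=config.fwe_method, alpha=config.alpha,
        n_permutations=config.n_permutations, seed=seed_stats,
    )
    if config.write_volumes:
        image_io.write_volume(tres.t_map, out / "pet_tmap.nii.gz")
        image_io.write_volume(tres.sig_mask, out / "pet_sigmask.nii.gz")
    coverage = gs.region_coverage(tres.sig_mask, atlas)
    # GM-probability maps: both directions, mirroring the structural analysis
    gm_directions = {}
    for direction in (gs.A_GT_B, gs.B_GT_A):
        gres = gs.fwe_threshold(
            [gs.smooth_volume(s.gm_prob, config.fwhm_mm, mask=brain) for s in ad],
            [gs.smooth_volume(s.gm_prob, config.fwhm_mm, mask=brain) for s in non],
            brain, direction=direction, method=config.fwe_method,
            alpha=config.alpha, n_permutations=config.n_permutations, seed=seed_stats,
        )
        gm_directions[direction] = int(gres.sig_mask.data.sum())

    region_stats = coverage.copy()
    for name, table in (("all_voxels", table_all), ("gm_masked", table_gm)):
        anova = gs.region_anova(table, labels)
        jr = gs.fisher_ratio(table, labels)
        region_stats[f"F_{name}"] = anova["F"]
        region_stats[f"p_{name}"] = anova["p"]
        region_stats[f"J_{name}"] = jr
    region_stats.to_csv(out / "region_stats.tsv", sep="\t")
    json.dump(
        {"alpha": config.alpha, "method": config.fwe_method, "threshold": tres.threshold,
         "df": tres.df, "n_permutations": tres.n_permutations, "seed": seed_stats,
         "n_sig_voxels_pet": int(tres.sig_mask.data.sum()),
         "n_sig_voxels_gm_by_direction": gm_directions},
        (out / "stats_meta.json").open("w"), indent=1,
    )

    # --- classification ------------------------------------------------
    seed_cls = stage_seed("classify")
    consensus = suvr.build_group_gm_mask(subjects, config.gm_threshold, config.consensus_fraction)
    features = cl.build_feature_sets(subjects, atlas, table_all, table_gm, consensus)
    reports = {}
    for kind, feats in features.items():
        kept = set(feats.subject_ids)
        labs = [s.group for s in subjects if s.subject_id in kept]
        rep = cl.crossval_classify(
            feats, labs, n_folds=config.n_folds, C=config.C, seed=seed_cls
        )
        rep.to_json(out / f"classification_{kind}.json")
        np.savetxt(out / f"roc_{kind}.tsv", rep.roc_points, delimiter="\t",
                   header="fpr\ttpr", comments="")
        reports[kind] = rep
        if feats.feature_names is not None:
            w, b, _ = cl.extract_weight_map(feats, labs, C=config.C)
            with (out / f"weights_{kind}.tsv").open("w") as fh:
                fh.write("region\tweight\n")
                for name, wi in zip(feats.feature_names, w):
                    fh.write(f"{name}\t{wi:.6f}\n")

    # --- summary --------------------------------------------------------
    jr_all = region_stats["J_all_voxels"]
    jr_gm = region_stats["J_gm_masked"]
    summary.update(
        {
            "n_subjects": len(subjects),
            "n_ad": labels.count("AD"),
            "n_nonad": labels.count("NONAD"),
            "fwe_threshold": tres.threshold,
            "n_sig_voxels_pet": int(tres.sig_mask.data.sum()),
            "coverage_percent": coverage["coverage_percent"].round(4).to_dict(),
            "fisher_gm_ge_all_regions": int((jr_gm >= jr_all).sum()),
            "anova_F": {
                "all_voxels": region_stats["F_all_voxels"].round(6).to_dict(),
                "gm_masked": region_stats["F_gm_masked"].round(6).to_dict(),
            },
            "fisher_J": {
                "all_voxels": jr_all.round(6).to_dict(),
                "gm_masked": jr_gm.round(6).to_dict(),
            },
            "classification": {
                kind: {
                    "accuracy": rep.accuracy,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "auc": rep.auc,
                }
                for kind, rep in reports.items()
            },
        }
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
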