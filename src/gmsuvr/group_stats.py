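"""Group-difference statistics: voxelwise t-maps with family-wise error
control, region coverage of the significant map, per-region one-way ANOVA,
and the Fisher discriminant ratio.

The voxelwise test is the classical pooled-variance two-sample t (Welch by
flag), one-sided in a stated direction.  Family-wise error over the brain
mask is controlled either by the permutation max-T procedure (exact under
exchangeability of group labels) or by Bonferroni.

The Fisher discriminant ratio of region r,

    J_r = (mu1_r - mu2_r)^2 / (sd1_r^2 + sd2_r^2),

ranks regions by univariate class separation of their SUVRs; group
standard deviations use the n-1 (sample) convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .suvr import SUVRTable
from .volume import AtlasParcellation, Volume

__all__ = [
    "A_GT_B",
    "B_GT_A",
    "PERMUTATION_MAXT",
    "BONFERRONI",
    "TMapResult",
    "fwhm_to_sigma",
    "smooth_volume",
    "pooled_t",
    "voxelwise_t_map",
    "fwe_threshold",
    "region_coverage",
    "region_anova",
    "fisher_ratio",
]

log = logging.getLogger(__name__)

A_GT_B = "A_GT_B"
B_GT_A = "B_GT_A"
PERMUTATION_MAXT = "permutation_maxt"
BONFERRONI = "bonferroni"

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class TMapResult:
    """A thresholded voxelwise t-test with its FWE context."""

    t_map: Volume
    direction: str
    df: int
    alpha: float
    fwe_method: str
    threshold: float
    sig_mask: Volume
    n_permutations: int | None = None
    seed: int | None = None


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: np.ndarray | float) -> np.ndarray:
    """Per-axis Gaussian sigma in voxels for a kernel FWHM in mm."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm must be positive")
    return _FWHM_TO_SIGMA * fwhm_mm / np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))


def smooth_volume(vol: Volume, fwhm_mm: float, mask: np.ndarray | None = None) -> Volume:
    """Gaussian-smooth a volume with an isotropic FWHM in mm.

    Anisotropic voxels get per-axis sigmas.  Boundary handling is
    nearest-edge replication; when ``mask`` is given, smoothing runs inside
    the mask's bounding box (the brain), so empty background does not bleed
    into the edge of the brain.  Constant volumes are preserved exactly.
    """
    sigma = fwhm_to_sigma(fwhm_mm, vol.voxel_sizes)
    data = np.asarray(vol.data, dtype=np.float64)
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            raise ValueError("empty smoothing mask")
        sl = tuple(
            slice(int(ax.min()), int(ax.max()) + 1) for ax in np.nonzero(mask)
        )
        out = data.copy()
        out[sl] = ndimage.gaussian_filter(data[sl], sigma=sigma, mode="nearest")
        return vol.with_data(out, f"{vol.description} [smoothed {fwhm_mm:g}mm]".strip())
    return vol.with_data(
        ndimage.gaussian_filter(data, sigma=sigma, mode="nearest"),
        f"{vol.description} [smoothed {fwhm_mm:g}mm]".strip(),
    )


def pooled_t(a: np.ndarray, b: np.ndarray, welch: bool = False) -> np.ndarray:
    """Two-sample t statistics, columnwise, for samples stacked as rows.

    ``a`` has shape (n_a, V), ``b`` (n_b, V); returns V statistics for
    mean(a) - mean(b).  Voxels with zero variance in both groups yield 0.
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least two subjects per group")
    diff = a.mean(axis=0) - b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    if welch:
        se2 = va / na + vb / nb
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    degenerate = se2 <= 0
    if np.any(degenerate):
        n_bad = int(np.count_nonzero(degenerate))
        log.warning("%d voxel(s) with zero within-group variance; t set to 0", n_bad)
        t = np.where(degenerate, 0.0, t)
    return t


def _stack(volumes, mask: np.ndarray) -> np.ndarray:
    return np.stack([np.asarray(v.data, dtype=np.float64)[mask] for v in volumes])


def voxelwise_t_map(
    group_a,
    group_b,
    brain_mask: np.ndarray | Volume,
    direction: str = A_GT_B,
    welch: bool = False,
) -> Volume:
    """Voxelwise two-sample t over the brain mask, signed for ``direction``.

    Positive values support the stated hypothesis (e.g. group A higher for
    ``A_GT_B``).  Voxels outside the mask are 0.
    """
    if direction not in (A_GT_B, B_GT_A):
        raise ValueError(f"unknown direction {direction!r}")
    mask = brain_mask.data if isinstance(brain_mask, Volume) else brain_mask
    mask = np.asarray(mask).astype(bool)
    group_a, group_b = list(group_a), list(group_b)
    t = pooled_t(_stack(group_a, mask), _stack(group_b, mask), welch=welch)
    if direction == B_GT_A:
        t = -t
    out = np.zeros(mask.shape)
    out[mask] = t
    template = group_a[0]
    return template.with_data(out, f"t-map ({direction}, df={len(group_a) + len(group_b) - 2})")


def _perm_max_t(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    welch: bool,
    batch: int = 0,
) -> np.ndarray:
    """Max-t null distribution over random relabelings (vectorised).

    Pooled-variance statistics for all permutations in a batch come from two
    matrix products (group sums and sums of squares against a permutation
    indicator matrix).
    """
    x = np.vstack([a, b])
    n, v = x.shape
    na = a.shape[0]
    if batch <= 0:
        batch = max(1, int(2e7 // max(v, 1)))
    x2 = x**2
    tot = x.sum(axis=0)
    tot2 = x2.sum(axis=0)
    maxima = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        m = min(batch, n_permutations - done)
        sel = np.zeros((m, n))
        for i in range(m):
            sel[i, rng.choice(n, size=na, replace=False)] = 1.0
        sa = sel @ x
        sa2 = sel @ x2
        nb = n - na
        ma = sa / na
        mb = (tot - sa) / nb
        va = (sa2 - na * ma**2) / (na - 1)
        vb = ((tot2 - sa2) - nb * mb**2) / (nb - 1)
        if welch:
            se2 = va / na + vb / nb
        else:
            se2 = ((na - 1) * va + (nb - 1) * vb) / (n - 2) * (1.0 / na + 1.0 / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ma - mb) / np.sqrt(se2)
        t = np.where(se2 <= 0, 0.0, t)
        maxima[done : done + m] = t.max(axis=1)
        done += m
    return maxima


def fwe_threshold(
    group_a,
    group_b,
    brain_mask: np.ndarray | Volume,
    direction: str = A_GT_B,
    method: str = PERMUTATION_MAXT,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    welch: bool = False,
) -> TMapResult:
    """Threshold a voxelwise t-map controlling the family-wise error rate.

    PERMUTATION_MAXT permutes group labels ``n_permutations`` times, records
    the maximum t over the brain mask each time, and takes the threshold as
    the k-th largest maximum with k = floor(alpha * (n_permutations + 1)) —
    the cut-off at which the permutation p-value of the observed maximum is
    at most alpha.  BONFERRONI uses the one-sided t quantile at
    alpha / n_voxels with df = n_A + n_B - 2.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    mask = brain_mask.data if isinstance(brain_mask, Volume) else brain_mask
    mask = np.asarray(mask).astype(bool)
    group_a, group_b = list(group_a), list(group_b)
    na, nb = len(group_a), len(group_b)
    df = na + nb - 2
    t_map = voxelwise_t_map(group_a, group_b, mask, direction=direction, welch=welch)

    if method == BONFERRONI:
        n_vox = int(mask.sum())
        threshold = float(stats.t.isf(alpha / n_vox, df))
        n_perm_out = None
    elif method == PERMUTATION_MAXT:
        if n_permutations < 100:
            raise ValueError("permutation max-T needs n_permutations >= 100")
        from math import comb

        if comb(na + nb, na) < n_permutations:
            warnings.warn(
                f"only {comb(na + nb, na)} distinct relabelings exist; "
                f"null distribution will repeat"
            )
        a = _stack(group_a, mask)
        b = _stack(group_b, mask)
        if direction == B_GT_A:
            a, b = -a, -b
        rng = np.random.default_rng(seed)
        maxima = _perm_max_t(a, b, n_permutations, rng, welch=welch)
        k = max(1, int(np.floor(alpha * (n_permutations + 1))))
        threshold = float(np.sort(maxima)[-k])
        n_perm_out = n_permutations
    else:
        raise ValueError(f"unknown FWE method {method!r}")

    sig = np.zeros(mask.shape, dtype=np.uint8)
    sig[mask] = (t_map.data[mask] >= threshold).astype(np.uint8)
    return TMapResult(
        t_map=t_map,
        direction=direction,
        df=df,
        alpha=alpha,
        fwe_method=method,
        threshold=threshold,
        sig_mask=t_map.with_data(sig, f"FWE {alpha:g} significance mask"),
        n_permutations=n_perm_out,
        seed=seed if method == PERMUTATION_MAXT else None,
    )


def region_coverage(sig_mask: Volume | np.ndarray, atlas: AtlasParcellation) -> pd.DataFrame:
    """Per-target-region volume and the share covered by significant voxels.

    Columns: n_voxels, volume_mm3, sig_volume_mm3, coverage_percent.
    """
    sig = sig_mask.data if isinstance(sig_mask, Volume) else sig_mask
    sig = np.asarray(sig).astype(bool)
    if sig.shape != atlas.labels.shape:
        raise ValueError("sig_mask and atlas must share one grid")
    vox_mm3 = atlas.labels.voxel_volume_mm3
    rows = {}
    for name in atlas.target_names:
        region = atlas.region_mask(name)
        n = int(region.sum())
        n_sig = int((region & sig).sum())
        rows[name] = {
            "n_voxels": n,
            "volume_mm3": n * vox_mm3,
            "sig_volume_mm3": n_sig * vox_mm3,
            "coverage_percent": 100.0 * n_sig / n,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "region"
    return out


def _group_values(table: SUVRTable, group_labels, region: str):
    labels = np.asarray(list(group_labels))
    vals = table.values[region].to_numpy(dtype=float)
    names = np.unique(labels)
    if names.size != 2:
        raise ValueError(f"need exactly two groups, got {list(names)}")
    out = []
    for g in names:
        v = vals[labels == g]
        kept = v[~np.isnan(v)]
        if kept.size < v.size:
            log.info("region %s group %s: dropped %d missing SUVRs", region, g, v.size - kept.size)
        out.append(kept)
    return out


def region_anova(table: SUVRTable, group_labels) -> pd.DataFrame:
    """One-way ANOVA per region on SUVRs: F with df (1, n-2) and its p-value.

    Regions with fewer than two usable subjects in a group get NaN.
    p-values are uncorrected (per-region), with a Bonferroni-across-regions
    column kept clearly separate.
    """
    rows = {}
    for region in table.region_names:
        a, b = _group_values(table, group_labels, region)
        if min(a.size, b.size) < 2:
            rows[region] = {"F": np.nan, "p": np.nan, "n_used": a.size + b.size}
            continue
        f, p = stats.f_oneway(a, b)
        rows[region] = {"F": float(f), "p": float(p), "n_used": a.size + b.size}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    out.index.name = "region"
    return out


def fisher_ratio(table: SUVRTable, group_labels) -> pd.Series:
    """Fisher discriminant ratio J_r per region (sample-sd convention).

    With both group variances zero: equal means give 0; unequal means are an
    infinite-separation degeneracy reported as NaN with a warning.
    """
    out = {}
    for region in table.region_names:
        a, b = _group_values(table, group_labels, region)
        if min(a.size, b.size) < 2:
            out[region] = np.nan
            continue
        num = (a.mean() - b.mean()) ** 2
        den = a.var(ddof=1) + b.var(ddof=1)
        if den == 0:
            if num == 0:
                out[region] = 0.0
            else:
                warnings.warn(f"region {region!r}: zero variance with unequal means")
                out[region] = np.nan
        else:
            out[region] = float(num / den)
    s = pd.Series(out, name="J_r")
    s.index.name = "region"
    return s
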