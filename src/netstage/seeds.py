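"""Seed definition from group contrasts.

Seeds anchor the covariance-network analyses.  They are located where a
one-sided group contrast (e.g. cognitively normal > probable dementia)
shows both grey-matter atrophy and hypometabolism: per-voxel t maps are
computed on nuisance-residualised data, enhanced with threshold-free
cluster enhancement (TFCE), family-wise-error corrected against a
max-statistic permutation null, thresholded at alpha, summed across the
two modalities, and 4 mm spherical seeds are placed at the local maxima
inside each expected region's search neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .images import ImageMatrix
from .nuisance import residualize

__all__ = [
    "GroupDifferenceMap",
    "SeedRegion",
    "regress_nuisance",
    "tfce",
    "permutation_contrast",
    "sphere_mask",
    "combine_and_peak",
]

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
@dataclass
class SeedRegion:
    """Spherical seed: name, world-mm center, radius, voxel mask."""

    name: str
    center: np.ndarray  # (3,) mm
    radius: float  # mm
    mask: np.ndarray  # 3D bool

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"seed {self.name}: empty voxel mask")


@dataclass
class GroupDifferenceMap:
    """Observed t map with TFCE enhancement and FWE-corrected p values."""

    t: np.ndarray  # 3D
    tfce: np.ndarray  # 3D
    p_fwe: np.ndarray  # 3D, 1 outside the mask
    threshold_mask: np.ndarray  # 3D bool, p_fwe <= alpha
    alpha: float
    n_perm: int
    mask: np.ndarray  # analysis mask

    def thresholded_t(self) -> np.ndarray:
        """t map zeroed outside the significant voxels."""
        return np.where(self.threshold_mask, self.t, 0.0)


# ----------------------------------------------------------------------
def regress_nuisance(
    values: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
) -> np.ndarray:
    """Per-voxel OLS residuals of a subjects x voxels matrix on covariates."""
    return residualize(values, covariates)


def tfce(
    stat_map: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a (positive) statistic map.

    For each voxel v the enhanced value is the Riemann sum
    ``sum_h extent(cluster of v at height h)^E * h^H * dh`` over heights
    ``h = dh, 2*dh, ... <= max``, with clusters defined by face
    connectivity and membership at height h meaning ``stat >= h``.  When
    ``dh`` is not given it defaults to ``max/n_steps`` (the FSL
    convention).  Non-positive maps return zeros; negative values never
    contribute (one-sided use).
    """
    stat = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("stat map contains non-finite values")
    out = np.zeros_like(stat)
    mx = float(stat.max(initial=0.0))
    if mx <= 0:
        return out
    if dh is None:
        dh = mx / n_steps
    if dh <= 0:
        raise ValueError("dh must be positive")
    structure = ndimage.generate_binary_structure(stat.ndim, 1)
    n_heights = int(np.floor(mx / dh + 1e-12))
    for k in range(1, n_heights + 1):
        h = k * dh
        labels, n_clusters = ndimage.label(stat >= h, structure=structure)
        if n_clusters == 0:
            continue
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        incr = sizes.astype(float) ** E * (h**H) * dh
        incr[0] = 0.0
        out += incr[labels]
    return out


def _t_two_sample(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column (A minus B)."""
    nA, nB = A.shape[0], B.shape[0]
    mA, mB = A.mean(axis=0), B.mean(axis=0)
    vA = A.var(axis=0, ddof=1)
    vB = B.var(axis=0, ddof=1)
    sp2 = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
    denom = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mA - mB) / denom
    t[~np.isfinite(t)] = 0.0
    return t


def permutation_contrast(
    group_a: ImageMatrix,
    group_b: ImageMatrix,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    rng: np.random.Generator | int | None = None,
) -> GroupDifferenceMap:
    """One-sided permutation contrast (A > B) with TFCE and FWE control.

    Covariates (stacked A-then-B) are regressed out of the voxel data
    first; the two-sample t map is then computed on the residuals and the
    null distribution built by permuting group labels (Freedman-Lane
    style: the permutation acts on residualised data).  Family-wise error
    is controlled with the maximum-TFCE statistic over permutations, so
    ``p_fwe >= 1/(n_perm+1)`` everywhere.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if group_a.n_subjects < 2 or group_b.n_subjects < 2:
        raise ValueError("need at least 2 subjects per group")
    if group_a.shape3d != group_b.shape3d:
        raise ValueError("groups are on different grids")
    rng = np.random.default_rng(rng)

    nA = group_a.n_subjects
    data = np.vstack([group_a.values, group_b.values])
    data = residualize(data, covariates)
    mask = group_a.mask

    def tfce_of(tvec: np.ndarray) -> np.ndarray:
        vol = np.zeros(mask.shape)
        vol[mask] = tvec
        return tfce(vol, E=E, H=H, n_steps=n_steps)

    t_obs = _t_two_sample(data[:nA], data[nA:])
    tfce_obs = tfce_of(t_obs)

    n = data.shape[0]
    max_null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(n)
        ia, ib = perm[:nA], perm[nA:]
        t_p = _t_two_sample(data[ia], data[ib])
        max_null[p] = tfce_of(t_p).max()

    obs_vals = tfce_obs[mask]
    exceed = (max_null[None, :] >= obs_vals[:, None]).sum(axis=1)
    p_vals = (1.0 + exceed) / (n_perm + 1.0)

    p_fwe = np.ones(mask.shape)
    p_fwe[mask] = p_vals
    t_vol = np.zeros(mask.shape)
    t_vol[mask] = t_obs
    thr = (p_fwe <= alpha) & mask
    return GroupDifferenceMap(
        t=t_vol, tfce=tfce_obs, p_fwe=p_fwe, threshold_mask=thr,
        alpha=alpha, n_perm=n_perm, mask=mask,
    )


# ----------------------------------------------------------------------
def sphere_mask(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    center_mm: np.ndarray,
    radius_mm: float,
) -> np.ndarray:
    """Voxels whose center lies within ``radius_mm`` of ``center_mm``."""
    idx = np.indices(shape).reshape(3, -1).T
    coords = nib.affines.apply_affine(np.asarray(affine, float), idx)
    d = np.linalg.norm(coords - np.asarray(center_mm, float), axis=1)
    return (d <= radius_mm).reshape(shape)


def combine_and_peak(
    t_gmv_thresh: np.ndarray,
    t_fdg_thresh: np.ndarray,
    expected_regions: Mapping[str, Sequence[float]],
    affine: np.ndarray,
    search_radius: float = 12.0,
    seed_radius: float = 4.0,
) -> list[SeedRegion]:
    """Sum two thresholded t maps and place spherical seeds at region peaks.

    ``expected_regions`` maps a region name (e.g. ``HIP_L``) to the mm
    coordinates of its search neighbourhood center.  A region with no
    surviving voxel inside its neighbourhood is reported absent (logged),
    never fabricated.
    """
    t_gmv_thresh = np.asarray(t_gmv_thresh, dtype=float)
    t_fdg_thresh = np.asarray(t_fdg_thresh, dtype=float)
    if t_gmv_thresh.shape != t_fdg_thresh.shape:
        raise ValueError("thresholded maps are on different grids")
    summed = t_gmv_thresh + t_fdg_thresh
    shape = summed.shape
    seeds: list[SeedRegion] = []
    for name, center in expected_regions.items():
        neigh = sphere_mask(shape, affine, np.asarray(center, float), search_radius)
        cand = neigh & (summed > 0)
        if not cand.any():
            log.warning("region %s: no significant voxel in its neighbourhood", name)
            continue
        vals = np.where(cand, summed, -np.inf)
        peak_idx = np.unravel_index(np.argmax(vals), shape)
        peak_mm = nib.affines.apply_affine(np.asarray(affine, float),
                                           np.asarray(peak_idx))
        mask = sphere_mask(shape, affine, peak_mm, seed_radius)
        seeds.append(SeedRegion(name=name, center=peak_mm,
                                radius=seed_radius, mask=mask))
    return seeds


def seeds_to_table(seeds: Sequence[SeedRegion]) -> pd.DataFrame:
    """TSV-ready table of seed name, mm coordinates and radius."""
    return pd.DataFrame(
        {
            "name": [s.name for s in seeds],
            "x_mm": [s.center[0] for s in seeds],
            "y_mm": [s.center[1] for s in seeds],
            "z_mm": [s.center[2] for s in seeds],
            "radius_mm": [s.radius for s in seeds],
        }
    )
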