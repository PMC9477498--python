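"""Seed-based partial least squares covariance networks.

For each seed and modality the per-subject mean signal inside the seed
(Y) is cross-correlated with the whole-brain voxel matrix (X); with both
centered and scaled to unit column norm the correlation vector
``R = Y' X`` holds exact Pearson correlations.  Its SVD
``R = v s u'`` yields latent variables whose brain salience ``u`` is the
covariance-network pattern; for a single seed R is 1 x V and the unique
latent variable has the closed form ``u = R'/||R||``, ``s = ||R||``.

Significance of a latent variable is assessed by permuting subjects in Y
relative to X (statistic: singular value), voxel reliability by the
bootstrap ratio (salience / bootstrap SE over subject resamples), and
individual network scores by projecting each subject's map onto the
salience, ``L_X = X u``, followed by bilateral averaging and z-scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .images import ImageMatrix
from .seeds import SeedRegion

__all__ = [
    "LatentVariable",
    "extract_seed_values",
    "correlation_vector",
    "pls_svd",
    "permute_lv",
    "bootstrap_bsr",
    "compute_network_scores",
    "BILATERAL_REGIONS",
    "MIDLINE_REGIONS",
]

log = logging.getLogger(__name__)

#: Regions whose left/right network scores are averaged into one score.
BILATERAL_REGIONS = ("HIP", "ANG", "INS", "PPC", "DLPFC")
#: Regions with a single midline seed.
MIDLINE_REGIONS = ("PCC", "mPFC")


@dataclass
class LatentVariable:
    """One latent variable of the seed-brain correlation decomposition."""

    u: np.ndarray  # voxel salience, unit norm
    v: np.ndarray  # seed salience
    s: float  # singular value (>= 0)
    p_perm: float | None = None
    bsr: np.ndarray | None = None  # bootstrap-ratio map over voxels
    degenerate: bool = False


# ----------------------------------------------------------------------
def extract_seed_values(images: ImageMatrix, seed: SeedRegion) -> np.ndarray:
    """Per-subject mean signal over the seed voxels (within the image mask)."""
    cols = images.columns_for(seed.mask & images.mask)
    if cols.size == 0:
        raise ValueError(f"seed {seed.name}: no voxels inside the image mask")
    return images.values[:, cols].mean(axis=1)


def _unit_normalize(M: np.ndarray) -> tuple[np.ndarray, int]:
    """Center columns and scale to unit Euclidean norm; count constants."""
    M = M - M.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(M, axis=0)
    constant = int(np.sum(norms == 0))
    norms_safe = np.where(norms == 0, 1.0, norms)
    return M / norms_safe, constant


def correlation_vector(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Pearson correlations of the seed vector with every voxel column.

    ``Y`` may be a vector (one seed) or an ``n x k`` matrix; the result is
    ``k x V``.  Constant voxel columns yield correlation 0 (count logged).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError("Y and X have different numbers of subjects")
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 subjects for correlations")
    Yn, y_const = _unit_normalize(Y)
    Xn, x_const = _unit_normalize(X)
    if y_const:
        raise ValueError("constant seed vector")
    if x_const:
        log.info("correlation_vector: %d constant voxel columns set to r=0", x_const)
    return Yn.T @ Xn


def pls_svd(R: np.ndarray) -> list[LatentVariable]:
    """Decompose a correlation vector/matrix into latent variables.

    Latent variables are ordered by decreasing singular value and their
    number equals ``rank(R)``.  The sign convention makes the seed
    salience of the leading component non-negative, so for a single seed
    ``u = R'/||R||`` exactly.  An all-zero R returns one degenerate LV.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if not np.all(np.isfinite(R)):
        raise ValueError("R contains non-finite values")
    if not R.any():
        k, V = R.shape
        return [
            LatentVariable(u=np.zeros(V), v=np.zeros(k), s=0.0, degenerate=True)
        ]
    v_full, s_full, ut_full = np.linalg.svd(R, full_matrices=False)
    rank = int(np.sum(s_full > s_full[0] * max(R.shape) * np.finfo(float).eps))
    lvs = []
    for i in range(rank):
        u_i = ut_full[i]
        v_i = v_full[:, i]
        # fix sign: dominant seed-salience entry positive
        j = int(np.argmax(np.abs(v_i)))
        if v_i[j] < 0:
            u_i, v_i = -u_i, -v_i
        lvs.append(LatentVariable(u=u_i, v=v_i, s=float(s_full[i])))
    return lvs


def permute_lv(
    Y: np.ndarray,
    X: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> list[LatentVariable]:
    """Permutation test for the latent variables (statistic: singular value).

    The subject order of Y is permuted relative to X; for each latent
    variable ``p = (1 + #{s_perm >= s_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    R = correlation_vector(Y, X)
    lvs = pls_svd(R)
    n = np.asarray(X).shape[0]
    Y = np.asarray(Y, dtype=float)
    s_obs = np.array([lv.s for lv in lvs])
    exceed = np.zeros(len(lvs))
    for _ in range(n_perm):
        Rp = correlation_vector(Y[rng.permutation(n)], X)
        sp = np.linalg.svd(np.atleast_2d(Rp), compute_uv=False)
        k = min(len(lvs), len(sp))
        exceed[:k] += sp[:k] >= s_obs[:k]
    for i, lv in enumerate(lvs):
        lv.p_perm = float((1.0 + exceed[i]) / (n_perm + 1.0))
    return lvs


def bootstrap_bsr(
    Y: np.ndarray,
    X: np.ndarray,
    n_boot: int = 500,
    rng: np.random.Generator | int | None = None,
    max_redraws: int = 100,
) -> np.ndarray:
    """Bootstrap ratio of the leading salience: ``u / SE_boot(u)``.

    Subjects are resampled with replacement; each bootstrap salience is
    sign-aligned to the original (flipped when its correlation with the
    original u is negative) before the elementwise standard error is
    taken.  Degenerate resamples (constant seed values) are redrawn and
    counted in the log.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(rng)
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    u0 = pls_svd(correlation_vector(Y, X))[0].u
    n = X.shape[0]
    boots = np.empty((n_boot, u0.size))
    redraws = 0
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            yb = Y[idx]
            if np.ptp(yb, axis=0).min() > 0:
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        ub = pls_svd(correlation_vector(yb, X[idx]))[0].u
        if ub @ u0 < 0:
            ub = -ub
        boots[b] = ub
    if redraws:
        log.info("bootstrap_bsr: %d degenerate resamples redrawn", redraws)
    se = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = u0 / se
    bsr[~np.isfinite(bsr)] = 0.0
    return bsr


# ----------------------------------------------------------------------
def _region_of(seed_name: str) -> str:
    """Seed name -> region name (strip a _L/_R hemisphere suffix)."""
    if seed_name.endswith(("_L", "_R")):
        return seed_name[:-2]
    return seed_name


def compute_network_scores(
    images_by_modality: Mapping[str, ImageMatrix],
    lvs: Mapping[tuple[str, str], LatentVariable],
    reference_group: np.ndarray | Sequence[bool] | None = None,
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Individual network scores: project maps onto saliences, average
    left/right homologues, z-score.

    Parameters
    ----------
    images_by_modality
        ``{"GMV": ImageMatrix, "FDG": ImageMatrix}`` (rows aligned).
    lvs
        ``{(seed_name, modality): LatentVariable}`` — the significant LV
        per seed per modality.  Missing entries simply drop that column
        (logged).
    reference_group
        Boolean row mask defining the z-scoring reference (``None`` = all
        subjects; a CN-only mask gives the CN-referenced variant).

    Returns
    -------
    DataFrame with one ``{region}_{modality}`` column per region; with
    the canonical 7 regions x 2 modalities this is 14 columns.
    """
    raw: dict[str, dict[str, np.ndarray]] = {}
    for (seed_name, modality), lv in lvs.items():
        if modality not in images_by_modality:
            raise ValueError(f"no images for modality {modality}")
        img = images_by_modality[modality]
        if lv.u.shape[0] != img.n_voxels:
            raise ValueError(
                f"salience length mismatch for {seed_name}/{modality}"
            )
        scores = img.values @ lv.u  # L_X = X u
        raw.setdefault(modality, {}).setdefault(_region_of(seed_name), []).append(
            scores
        )

    n = next(iter(images_by_modality.values())).n_subjects
    if reference_group is None:
        ref = np.ones(n, dtype=bool)
    else:
        ref = np.asarray(reference_group, dtype=bool)
        if ref.shape != (n,):
            raise ValueError("reference_group mask has wrong length")
        if not ref.any():
            raise ValueError("reference_group is empty")

    cols: dict[str, np.ndarray] = {}
    for modality, regions in raw.items():
        for region, score_list in regions.items():
            avg = np.mean(score_list, axis=0)  # bilateral average of raw scores
            mu = avg[ref].mean()
            sd = avg[ref].std(ddof=1)
            if sd == 0:
                raise ValueError(f"constant scores for {region}_{modality}")
            cols[f"{region}_{modality}"] = (avg - mu) / sd

    df = pd.DataFrame(cols)
    order = sorted(df.columns)
    df = df[order]
    if subject_ids is not None:
        df.index = pd.Index(list(subject_ids), name="subject_id")
    return df
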