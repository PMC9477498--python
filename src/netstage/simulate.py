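"""Synthetic cohorts with planted covariance networks and known truth.

The generator emulates the study design the pipeline targets: a
three-stage cohort (CN / MCI / probable AD) crossed with three CSF
pathology strata (A-T-, A-T+, A+), paired grey-matter-volume and
FDG-metabolism voxel maps containing seed-anchored covariance patterns,
and a memory composite generated from the latent network expressions
with stage-varying coefficients plus noise.

Each planted network j is a set of smooth Gaussian blobs (one per
hemisphere for bilateral networks) scaled by a per-subject loading
``l_ij ~ Normal(mu_stage, loading_sd^2)`` whose stage means decrease
CN -> MCI -> AD; subject maps are ``baseline + sum_j l_ij pattern_j +
site offset + iid noise``.  CSF values are drawn strictly inside /
outside the clinical cutoffs so the A/T classifier reproduces the
intended labels exactly.  All randomness flows from ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .images import ImageMatrix
from .staging import ABETA_CUTOFF, PTAU_CUTOFF, order_and_bin

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "DEFAULT_LOCI",
    "default_beta_truth",
    "generate_cohort",
    "generate_memory",
    "write_fixture",
    "read_fixture",
]

STAGES = ("CN", "MCI", "AD")
PATHOLOGIES = ("A-T-", "A-T+", "A+")
MODALITIES = ("GMV", "FDG")

#: Canonical 7 networks and their 12 planted foci (mm, within a 96 mm box):
#: five bilateral pairs plus two midline seeds.
DEFAULT_LOCI: dict[str, list[tuple[float, float, float]]] = {
    "HIP": [(-24.0, -16.0, -20.0), (24.0, -16.0, -20.0)],
    "ANG": [(-36.0, -32.0, 28.0), (36.0, -32.0, 28.0)],
    "INS": [(-32.0, 12.0, 0.0), (32.0, 12.0, 0.0)],
    "DLPFC": [(-28.0, 28.0, 24.0), (28.0, 28.0, 24.0)],
    "PPC": [(-20.0, -36.0, 40.0), (20.0, -36.0, 40.0)],
    "PCC": [(0.0, -32.0, 28.0)],
    "mPFC": [(0.0, 36.0, 12.0)],
}


def default_beta_truth(n_bins: int) -> dict[str, np.ndarray]:
    """True coefficient curves: HIP structural influence decreasing 0.8->0.2
    across bins, every other predictor null."""
    return {"HIP_GMV": np.linspace(0.8, 0.2, n_bins)}


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_per_cell: int = 10  # subjects per (stage x pathology) cell
    grid_dims: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 4.0
    pattern_loci: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_LOCI.items()}
    )
    blob_sigma_mm: float = 6.0
    loading_sd: float = 1.0
    stage_means: dict[str, float] = field(
        default_factory=lambda: {"CN": 0.5, "MCI": 0.0, "AD": -0.5}
    )
    noise_sd: float = 0.5
    site_sd: float = 0.1
    n_sites: int = 3
    baseline: float = 1.0
    bin_size: int = 10
    beta_truth: dict[str, np.ndarray] | None = None  # per-bin curves
    memory_noise_sd: float = 0.5
    rng_seed: int = 0

    @property
    def n_networks(self) -> int:
        return len(self.pattern_loci)

    @property
    def n_subjects(self) -> int:
        return self.n_per_cell * len(STAGES) * len(PATHOLOGIES)

    def affine(self) -> np.ndarray:
        """Voxel->mm transform with the grid centered on the origin."""
        v = self.voxel_size_mm
        aff = np.diag([v, v, v, 1.0])
        aff[:3, 3] = -v * (np.array(self.grid_dims) - 1) / 2.0
        return aff

    def validate(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        n_loci = sum(len(v) for v in self.pattern_loci.values())
        if int(np.prod(self.grid_dims)) < n_loci:
            raise ValueError("grid too small for the requested loci")
        half = self.voxel_size_mm * (np.array(self.grid_dims) - 1) / 2.0
        for name, loci in self.pattern_loci.items():
            for locus in loci:
                if np.any(np.abs(np.asarray(locus)) > half + 1e-9):
                    raise ValueError(
                        f"grid too small for the requested loci: "
                        f"{name} at {locus} outside +/-{half} mm"
                    )


@dataclass
class SyntheticCohort:
    """Phenotypes + paired voxel matrices + planted ground truth."""

    phenotypes: pd.DataFrame
    gmv: ImageMatrix
    fdg: ImageMatrix
    truth: dict  # loadings (DataFrame), beta_truth, loci, bins

    @property
    def n_subjects(self) -> int:
        return len(self.phenotypes)


# ----------------------------------------------------------------------
def _pattern_maps(config: SimConfig) -> dict[str, np.ndarray]:
    """Per-network blob pattern on the full grid (unit peak amplitude)."""
    aff = config.affine()
    idx = np.indices(config.grid_dims).reshape(3, -1).T
    coords = nib.affines.apply_affine(aff, idx)
    patterns = {}
    for name, loci in config.pattern_loci.items():
        pat = np.zeros(coords.shape[0])
        for locus in loci:
            d2 = np.sum((coords - np.asarray(locus, float)) ** 2, axis=1)
            pat += np.exp(-d2 / (2.0 * config.blob_sigma_mm**2))
        patterns[name] = pat.reshape(config.grid_dims)
    return patterns


def _sample_phenotypes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    sid = 0
    for pathology in PATHOLOGIES:
        for stage in STAGES:
            for _ in range(config.n_per_cell):
                sid += 1
                age = float(np.clip(rng.normal(73.0, 7.0), 55.0, 92.0))
                if stage == "CN":
                    mmse = int(rng.integers(27, 31))
                    cdr_global, cdr_sob = 0.0, 0.0
                elif stage == "MCI":
                    mmse = int(rng.integers(24, 31))
                    cdr_global = 0.5
                    cdr_sob = float(rng.integers(1, 6)) * 0.5
                else:
                    mmse = int(rng.integers(18, 27))
                    cdr_global = float(rng.choice([1.0, 2.0]))
                    cdr_sob = float(rng.integers(4, 19)) * 0.5
                if pathology == "A+":
                    abeta = float(rng.uniform(100.0, 180.0))
                    ptau = float(rng.uniform(15.0, 45.0))
                    p_apoe = 0.55
                elif pathology == "A-T+":
                    abeta = float(rng.uniform(205.0, 280.0))
                    ptau = float(rng.uniform(26.0, 45.0))
                    p_apoe = 0.25
                else:
                    abeta = float(rng.uniform(205.0, 280.0))
                    ptau = float(rng.uniform(8.0, 20.0))
                    p_apoe = 0.25
                rows.append(
                    {
                        "subject_id": f"S{sid:04d}",
                        "age": round(age, 2),
                        "gender": "F" if rng.random() < 0.5 else "M",
                        "education": int(np.clip(round(rng.normal(16.0, 2.6)), 8, 20)),
                        "apoe4": "carrier" if rng.random() < p_apoe else "non-carrier",
                        "icv": round(float(rng.normal(1540.0, 150.0)), 1),
                        "site": f"site{int(rng.integers(1, config.n_sites + 1))}",
                        "diagnosis": stage,
                        "mmse": mmse,
                        "cdr_global": cdr_global,
                        "cdr_sob": cdr_sob,
                        "csf_abeta": round(abeta, 1),
                        "csf_ptau": round(ptau, 1),
                        "pathology": pathology,
                    }
                )
    return pd.DataFrame(rows)


def _predictor_names(config: SimConfig) -> list[str]:
    return [f"{net}_{mod}" for net in config.pattern_loci for mod in MODALITIES]


def generate_cohort(config: SimConfig | None = None) -> SyntheticCohort:
    """Draw one synthetic cohort from the configured study conditions.

    Deterministic under a fixed ``rng_seed``: the same configuration
    always returns bit-identical phenotypes, maps and truth.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    phen = _sample_phenotypes(config, rng)
    n = len(phen)
    patterns = _pattern_maps(config)
    mask = np.ones(config.grid_dims, dtype=bool)
    aff = config.affine()

    stage_mu = phen["diagnosis"].map(config.stage_means).to_numpy(float)
    loadings = {}
    for net in config.pattern_loci:
        for mod in MODALITIES:
            loadings[f"{net}_{mod}"] = stage_mu + rng.normal(
                0.0, config.loading_sd, size=n
            )
    load_df = pd.DataFrame(loadings, index=phen["subject_id"])

    site_levels = sorted(phen["site"].unique())
    site_offsets = {
        (s, mod): rng.normal(0.0, config.site_sd, size=config.grid_dims)
        for s in site_levels for mod in MODALITIES
    }
    site_idx = phen["site"].to_numpy()

    images = {}
    pat_flat = {net: patterns[net][mask] for net in patterns}
    for mod in MODALITIES:
        vals = np.full((n, int(mask.sum())), config.baseline)
        for net in patterns:
            vals += np.outer(load_df[f"{net}_{mod}"].to_numpy(), pat_flat[net])
        for s in site_levels:
            rows_s = site_idx == s
            vals[rows_s] += site_offsets[(s, mod)][mask]
        vals += rng.normal(0.0, config.noise_sd, size=vals.shape)
        images[mod] = ImageMatrix(
            values=vals, affine=aff, mask=mask, modality=mod,
            subject_ids=list(phen["subject_id"]),
        )

    cohort = SyntheticCohort(
        phenotypes=phen,
        gmv=images["GMV"],
        fdg=images["FDG"],
        truth={
            "loadings": load_df,
            "loci": {k: list(v) for k, v in config.pattern_loci.items()},
            "beta_truth": None,
            "config": config,
        },
    )
    memory, bins = generate_memory(
        cohort,
        beta_truth=config.beta_truth,
        memory_noise_sd=config.memory_noise_sd,
        rng=rng,
        bin_size=config.bin_size,
        return_bins=True,
    )
    cohort.phenotypes["memory"] = memory.round(4)
    cohort.truth["beta_truth"] = bins["beta_truth"]
    cohort.truth["bins"] = bins["bins"]
    return cohort


def generate_memory(
    cohort: SyntheticCohort,
    beta_truth: dict[str, np.ndarray] | None = None,
    memory_noise_sd: float = 0.5,
    rng: np.random.Generator | int | None = None,
    bin_size: int = 10,
    return_bins: bool = False,
):
    """Memory composite from planted loadings with stage-varying coefficients.

    Within each pathology group the participants are ordered along the
    pseudo-stage axis and binned; the memory score of subject i is
    ``sum_j beta_j(bin_i) * x_ij + eps`` with ``x`` the planted network
    loadings standardised within the pathology group and
    ``eps ~ Normal(0, memory_noise_sd^2)``.  Every ``beta_truth`` curve
    must have one value per bin of every group.
    """
    rng = np.random.default_rng(rng)
    phen = cohort.phenotypes
    load_df = cohort.truth["loadings"]
    memory = pd.Series(np.zeros(len(phen)), index=phen.index, dtype=float)
    bins_by_group: dict[str, pd.DataFrame] = {}
    resolved_beta: dict[str, np.ndarray] | None = None
    for group, sub in phen.groupby("pathology", sort=True):
        ordered = order_and_bin(sub, strategy="split", bin_size=bin_size)
        if "bin" not in ordered.columns:
            raise ValueError("bin assignment could not be computed")
        n_bins = int(ordered["bin"].max())
        beta = beta_truth if beta_truth is not None else default_beta_truth(n_bins)
        for name, curve in beta.items():
            if len(np.asarray(curve)) != n_bins:
                raise ValueError(
                    f"beta_truth[{name!r}] has {len(np.asarray(curve))} values "
                    f"but group {group!r} has {n_bins} bins"
                )
        resolved_beta = {k: np.asarray(v, dtype=float) for k, v in beta.items()}
        x = load_df.loc[ordered["subject_id"]]
        x = (x - x.mean()) / x.std(ddof=1)
        y = np.zeros(len(ordered))
        for name, curve in resolved_beta.items():
            if name not in x.columns:
                raise ValueError(f"beta_truth names unknown predictor {name!r}")
            y += np.asarray(curve)[ordered["bin"].to_numpy() - 1] * x[name].to_numpy()
        y += rng.normal(0.0, memory_noise_sd, size=len(y))
        pos = phen.index[phen["subject_id"].isin(ordered["subject_id"])]
        id_to_y = dict(zip(ordered["subject_id"], y))
        memory.loc[pos] = phen.loc[pos, "subject_id"].map(id_to_y)
        bins_by_group[group] = ordered[["subject_id", "order", "bin"]]
    if return_bins:
        return memory, {"bins": bins_by_group, "beta_truth": resolved_beta}
    return memory


# ----------------------------------------------------------------------
def write_fixture(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Serialise a cohort: one NIfTI per subject per modality, a phenotype
    TSV, and a truth JSON.  Round-trips losslessly through
    :func:`read_fixture` (float32 image tolerance)."""
    if cohort.n_subjects == 0:
        raise ValueError("refusing to write an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    for mod, img in (("gmv", cohort.gmv), ("fdg", cohort.fdg)):
        for row, sid in enumerate(img.subject_ids):
            img.save_subject(row, img_dir / f"{sid}_{mod}.nii")
    phen_path = out / "phenotypes.tsv"
    cohort.phenotypes.to_csv(phen_path, sep="\t", index=False)
    truth = {
        "loci": cohort.truth["loci"],
        "beta_truth": {
            k: np.asarray(v).tolist()
            for k, v in (cohort.truth.get("beta_truth") or {}).items()
        },
        "loadings": {
            "columns": list(cohort.truth["loadings"].columns),
            "subject_id": list(cohort.truth["loadings"].index),
            "values": cohort.truth["loadings"].to_numpy().tolist(),
        },
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth))
    return {"images": img_dir, "phenotypes": phen_path, "truth": truth_path}


def read_fixture(out_dir: str | Path) -> SyntheticCohort:
    """Load a cohort written by :func:`write_fixture`."""
    out = Path(out_dir)
    phen = pd.read_csv(out / "phenotypes.tsv", sep="\t")
    truth_raw = json.loads((out / "truth.json").read_text())
    ids = list(phen["subject_id"])
    imgs = {}
    for mod_key, mod in (("gmv", "GMV"), ("fdg", "FDG")):
        paths = [out / "images" / f"{sid}_{mod_key}.nii" for sid in ids]
        imgs[mod] = ImageMatrix.from_nifti_files(
            paths, modality=mod, subject_ids=ids
        )
    load_df = pd.DataFrame(
        truth_raw["loadings"]["values"],
        index=pd.Index(truth_raw["loadings"]["subject_id"], name="subject_id"),
        columns=truth_raw["loadings"]["columns"],
    )
    truth = {
        "loci": truth_raw["loci"],
        "beta_truth": {k: np.asarray(v) for k, v in truth_raw["beta_truth"].items()},
        "loadings": load_df,
    }
    return SyntheticCohort(
        phenotypes=phen, gmv=imgs["GMV"], fdg=imgs["FDG"], truth=truth
    )
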