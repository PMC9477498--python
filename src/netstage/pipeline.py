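"""End-to-end orchestration: simulate -> seeds -> PLS -> scores ->
group statistics -> SVC.

A :class:`PipelineConfig` carries every stage parameter with defaults at
the published analysis values (CSF cutoffs 192/23, 10 subjects per bin,
5000/1000/500 permutation and bootstrap counts, 100 repetitions with the
>90 selection rule, fivefold CV).  All randomness flows from one master
seed through per-stage derived seeds; every run writes a manifest with
the config hash and the seeds actually used, so reruns with the same
config are reproducible.  Any contiguous subsequence of stages can be
run: each stage reads its inputs from the output directory and fails
with the name of the missing artifact if an upstream stage has not run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import groupstats as gs
from . import pls as pls_mod
from . import seeds as seeds_mod
from . import svc as svc_mod
from .simulate import (
    MODALITIES,
    SimConfig,
    generate_cohort,
    read_fixture,
    write_fixture,
)
from .staging import order_and_bin

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "seeds", "pls", "scores", "groupstats", "svc")

#: Nuisance predictors entering the SVC model alongside the network scores.
SVC_NUISANCE = ("gender", "education", "apoe4", "icv", "site")


class SimulateParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_cell: int = Field(10, ge=1)
    grid: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = Field(4.0, gt=0)
    loading_sd: float = Field(1.0, ge=0)
    noise_sd: float = Field(0.5, gt=0)
    memory_noise_sd: float = Field(0.5, ge=0)
    # network-loading group means across CN -> MCI -> AD
    stage_means: tuple[float, float, float] = (0.5, 0.0, -0.5)


class SeedParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = Field(5000, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    search_radius_mm: float = Field(12.0, gt=0)
    seed_radius_mm: float = Field(4.0, gt=0)
    tfce_e: float = 0.5
    tfce_h: float = 2.0


class PlsParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = Field(1000, ge=1)
    n_boot: int = Field(500, ge=2)
    compute_bsr: bool = True
    lv_alpha: float = Field(0.05, gt=0, lt=1)
    reference_group: Literal["all", "CN"] = "all"


class GroupStatsParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = Field(5000, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)


class SvcParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_rep: int = Field(100, ge=1)
    selection_threshold: int = Field(90, ge=0)
    cv_folds: int = Field(5, ge=2)
    n_lambda: int = Field(50, ge=1)
    lambda_min_ratio: float = Field(1e-3, gt=0, le=1)
    basis_size: int = Field(6, ge=2)
    spline_degree: int = Field(3, ge=1)
    penalty: Literal["group_lasso", "ridge"] = "group_lasso"
    ordering: Literal["split", "merged"] = "split"


class PipelineConfig(BaseModel):
    """Structured configuration for the whole pipeline (YAML-friendly)."""

    model_config = ConfigDict(extra="forbid")
    out_dir: str = "netstage_out"
    seed: int = Field(0, ge=0)
    abeta_cutoff: float = Field(192.0, gt=0)
    ptau_cutoff: float = Field(23.0, gt=0)
    bin_size: int = Field(10, ge=1)
    simulate: SimulateParams = SimulateParams()
    seeds: SeedParams = SeedParams()
    pls: PlsParams = PlsParams()
    groupstats: GroupStatsParams = GroupStatsParams()
    svc: SvcParams = SvcParams()

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed (always < 2^31)."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def validate_config(config: dict | str | Path | PipelineConfig) -> dict:
    """Validate a config (dict, YAML path, or model); return a report.

    The report echoes every effective value including defaults.  Schema
    violations raise ``ValueError`` naming the offending key.
    """
    if isinstance(config, (str, Path)):
        import yaml

        raw = yaml.safe_load(Path(config).read_text()) or {}
    elif isinstance(config, PipelineConfig):
        raw = config.model_dump()
    else:
        raw = config
    try:
        model = PipelineConfig.model_validate(raw)
    except ValidationError as err:
        msgs = [
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ValueError("invalid configuration: " + "; ".join(msgs)) from err
    return {"valid": True, "effective": model.model_dump(),
            "hash": model.config_hash()}


# ----------------------------------------------------------------------
def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run stage '{stage}' first"
        )
    return path


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    return SimConfig(
        n_per_cell=cfg.simulate.n_per_cell,
        grid_dims=tuple(cfg.simulate.grid),
        voxel_size_mm=cfg.simulate.voxel_size_mm,
        loading_sd=cfg.simulate.loading_sd,
        noise_sd=cfg.simulate.noise_sd,
        memory_noise_sd=cfg.simulate.memory_noise_sd,
        stage_means=dict(zip(("CN", "MCI", "AD"), cfg.simulate.stage_means)),
        bin_size=cfg.bin_size,
        rng_seed=cfg.stage_seed("simulate"),
    )


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    cohort = generate_cohort(_sim_config(cfg))
    write_fixture(cohort, out / "sim")


def _expected_regions(loci: dict) -> dict[str, np.ndarray]:
    regions = {}
    for net, points in loci.items():
        pts = [np.asarray(p, float) for p in points]
        if len(pts) == 1:
            regions[net] = pts[0]
        else:
            for p in pts:
                suffix = "_L" if p[0] < 0 else "_R"
                regions[f"{net}{suffix}"] = p
    return regions


def _stage_seeds(cfg: PipelineConfig, out: Path) -> None:
    fixture = _require(out / "sim" / "phenotypes.tsv", "simulate").parent
    cohort = read_fixture(fixture)
    phen = cohort.phenotypes
    is_cn = (phen["diagnosis"] == "CN").to_numpy()
    is_ad = (phen["diagnosis"] == "AD").to_numpy()
    cov = phen[["age", "gender", "education", "apoe4"]]
    rng = np.random.default_rng(cfg.stage_seed("seeds"))
    thresholded = {}
    seed_dir = out / "seeds"
    seed_dir.mkdir(parents=True, exist_ok=True)
    for mod, img in (("GMV", cohort.gmv), ("FDG", cohort.fdg)):
        rows = np.concatenate([np.flatnonzero(is_cn), np.flatnonzero(is_ad)])
        cov_sub = cov.iloc[rows].reset_index(drop=True)
        diff = seeds_mod.permutation_contrast(
            img.subset(np.flatnonzero(is_cn)),
            img.subset(np.flatnonzero(is_ad)),
            covariates=cov_sub,
            n_perm=cfg.seeds.n_perm,
            alpha=cfg.seeds.alpha,
            E=cfg.seeds.tfce_e,
            H=cfg.seeds.tfce_h,
            rng=rng,
        )
        thresholded[mod] = diff.thresholded_t()
        img.save_map(diff.t, seed_dir / f"t_{mod.lower()}.nii")
        img.save_map(diff.p_fwe, seed_dir / f"pfwe_{mod.lower()}.nii")
    regions = _expected_regions(cohort.truth["loci"])
    found = seeds_mod.combine_and_peak(
        thresholded["GMV"],
        thresholded["FDG"],
        regions,
        cohort.gmv.affine,
        search_radius=cfg.seeds.search_radius_mm,
        seed_radius=cfg.seeds.seed_radius_mm,
    )
    seeds_mod.seeds_to_table(found).to_csv(
        seed_dir / "seeds.tsv", sep="\t", index=False
    )


def _load_seeds(out: Path, cohort) -> list[seeds_mod.SeedRegion]:
    table = pd.read_csv(_require(out / "seeds" / "seeds.tsv", "seeds"), sep="\t")
    if table.empty:
        raise ValueError(
            "no seed regions available: seed definition found no "
            "significant voxels (underpowered contrast?)"
        )
    regions = []
    for _, row in table.iterrows():
        center = np.array([row["x_mm"], row["y_mm"], row["z_mm"]])
        mask = seeds_mod.sphere_mask(
            cohort.gmv.shape3d, cohort.gmv.affine, center, row["radius_mm"]
        )
        regions.append(
            seeds_mod.SeedRegion(
                name=row["name"], center=center, radius=row["radius_mm"], mask=mask
            )
        )
    return regions


def _stage_pls(cfg: PipelineConfig, out: Path) -> None:
    fixture = _require(out / "sim" / "phenotypes.tsv", "simulate").parent
    cohort = read_fixture(fixture)
    seed_regions = _load_seeds(out, cohort)
    rng = np.random.default_rng(cfg.stage_seed("pls"))
    pls_dir = out / "pls"
    pls_dir.mkdir(parents=True, exist_ok=True)
    records = []
    arrays = {}
    for mod, img in (("GMV", cohort.gmv), ("FDG", cohort.fdg)):
        for seed in seed_regions:
            Y = pls_mod.extract_seed_values(img, seed)
            lvs = pls_mod.permute_lv(Y, img.values, n_perm=cfg.pls.n_perm, rng=rng)
            lv = lvs[0]
            if cfg.pls.compute_bsr:
                lv.bsr = pls_mod.bootstrap_bsr(
                    Y, img.values, n_boot=cfg.pls.n_boot, rng=rng
                )
                img.save_map(lv.bsr, pls_dir / f"bsr_{seed.name}_{mod.lower()}.nii")
            arrays[f"u_{seed.name}_{mod}"] = lv.u
            records.append(
                {"seed": seed.name, "modality": mod, "s": lv.s, "p_perm": lv.p_perm}
            )
    np.savez_compressed(pls_dir / "saliences.npz", **arrays)
    pd.DataFrame(records).to_csv(pls_dir / "lv_summary.tsv", sep="\t", index=False)


def _stage_scores(cfg: PipelineConfig, out: Path) -> None:
    fixture = _require(out / "sim" / "phenotypes.tsv", "simulate").parent
    cohort = read_fixture(fixture)
    sal_path = _require(out / "pls" / "saliences.npz", "pls")
    summary = pd.read_csv(
        _require(out / "pls" / "lv_summary.tsv", "pls"), sep="\t"
    )
    arrays = np.load(sal_path)
    lvs = {}
    for _, row in summary.iterrows():
        if row["p_perm"] is not None and row["p_perm"] > cfg.pls.lv_alpha:
            log.warning(
                "LV for %s/%s not significant (p=%.3g); column dropped",
                row["seed"], row["modality"], row["p_perm"],
            )
            continue
        u = arrays[f"u_{row['seed']}_{row['modality']}"]
        lvs[(row["seed"], row["modality"])] = pls_mod.LatentVariable(
            u=u, v=np.ones(1), s=row["s"], p_perm=row["p_perm"]
        )
    ref = None
    if cfg.pls.reference_group == "CN":
        ref = (cohort.phenotypes["diagnosis"] == "CN").to_numpy()
    scores = pls_mod.compute_network_scores(
        {"GMV": cohort.gmv, "FDG": cohort.fdg},
        lvs,
        reference_group=ref,
        subject_ids=cohort.phenotypes["subject_id"],
    )
    score_dir = out / "scores"
    score_dir.mkdir(parents=True, exist_ok=True)
    scores.to_csv(score_dir / "network_scores.tsv", sep="\t")


def _stage_groupstats(cfg: PipelineConfig, out: Path) -> None:
    scores = pd.read_csv(
        _require(out / "scores" / "network_scores.tsv", "scores"),
        sep="\t", index_col="subject_id",
    )
    phen = pd.read_csv(
        _require(out / "sim" / "phenotypes.tsv", "simulate"), sep="\t"
    ).set_index("subject_id").loc[scores.index]
    nuisance = phen[["age", "gender", "education", "apoe4", "icv", "site"]]
    rng = np.random.default_rng(cfg.stage_seed("groupstats"))
    results = []
    for factor, labels in (
        ("stage", phen["diagnosis"]),
        ("pathology", phen["pathology"]),
    ):
        results.extend(
            gs.compare_networks(
                scores, labels.to_numpy(), factor=factor, nuisance=nuisance,
                n_perm=cfg.groupstats.n_perm, alpha=cfg.groupstats.alpha, rng=rng,
            )
        )
    stat_dir = out / "groupstats"
    stat_dir.mkdir(parents=True, exist_ok=True)
    gs.results_to_table(results).to_csv(
        stat_dir / "group_comparisons.tsv", sep="\t", index=False
    )


def svc_design(phen: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Network scores + nuisance predictors as one numeric design table.

    Gender and APOE e4 are coded as binaries, scan site as effect-coded
    contrast columns, so every predictor can carry a stage-varying
    coefficient in the penalised model.
    """
    X = scores.copy()
    X["gender"] = (phen["gender"] == "F").astype(float).to_numpy()
    X["education"] = phen["education"].to_numpy(float)
    X["apoe4"] = (phen["apoe4"] == "carrier").astype(float).to_numpy()
    X["icv"] = phen["icv"].to_numpy(float)
    sites = sorted(phen["site"].unique())
    for s in sites[:-1]:  # effect coding: last level = -1 on every column
        col = np.where(
            phen["site"] == s, 1.0, np.where(phen["site"] == sites[-1], -1.0, 0.0)
        )
        X[f"site_{s}"] = col
    return X


def _stage_svc(cfg: PipelineConfig, out: Path) -> None:
    scores = pd.read_csv(
        _require(out / "scores" / "network_scores.tsv", "scores"),
        sep="\t", index_col="subject_id",
    )
    phen = pd.read_csv(
        _require(out / "sim" / "phenotypes.tsv", "simulate"), sep="\t"
    )
    svc_dir = out / "svc"
    svc_dir.mkdir(parents=True, exist_ok=True)
    results = {}
    for group, sub in phen.groupby("pathology", sort=True):
        ordered = order_and_bin(
            sub, strategy=cfg.svc.ordering, bin_size=cfg.bin_size
        )
        n_bins = int(ordered["bin"].max())
        if n_bins < cfg.svc.basis_size:
            log.warning(
                "group %s: only %d bins (< basis size %d); skipped",
                group, n_bins, cfg.svc.basis_size,
            )
            continue
        X_all = svc_design(ordered.set_index("subject_id"),
                           scores.loc[ordered["subject_id"]])
        keep = [c for c in X_all.columns if X_all[c].std(ddof=1) > 0]
        X_all = X_all[keep]
        y = ordered["memory"].to_numpy(float)
        y_std, X_std = svc_mod.standardize_inputs(
            y, X_all, np.full(len(y), group)
        )
        X_std = pd.DataFrame(X_std, columns=X_all.columns)
        basis = svc_mod.build_basis(
            n_bins, cfg.svc.basis_size, cfg.svc.spline_degree
        )
        summary = svc_mod.repeat_and_summarize(
            y_std, X_std, ordered["bin"].to_numpy(), basis,
            n_rep=cfg.svc.n_rep, threshold=cfg.svc.selection_threshold,
            folds=cfg.svc.cv_folds, penalty=cfg.svc.penalty,
            n_lambda=cfg.svc.n_lambda, min_ratio=cfg.svc.lambda_min_ratio,
            base_seed=cfg.stage_seed("svc"),
        )
        tag = group.replace("+", "pos").replace("-", "neg")
        summary.frequency.to_csv(svc_dir / f"{tag}_selection.tsv", sep="\t")
        summary.curve_mean.to_csv(svc_dir / f"{tag}_curve_mean.tsv", sep="\t")
        summary.curve_se.to_csv(svc_dir / f"{tag}_curve_se.tsv", sep="\t")
        results[group] = {
            "kept": summary.kept,
            "n_bins": n_bins,
            "n_subjects": int(len(ordered)),
        }
    (svc_dir / "summary.json").write_text(json.dumps(results, indent=2))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "seeds": _stage_seeds,
    "pls": _stage_pls,
    "scores": _stage_scores,
    "groupstats": _stage_groupstats,
    "svc": _stage_svc,
}


def run_pipeline(
    config: PipelineConfig | dict | str | Path,
    stages: Sequence[str] | None = None,
) -> Path:
    """Run the requested (contiguous) stages; returns the output directory."""
    report = validate_config(config)
    cfg = PipelineConfig.model_validate(report["effective"])
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.seed,
        "stages": stages,
        "stage_seeds": {s: cfg.stage_seed(s) for s in stages},
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        _STAGE_FUNCS[stage](cfg, out)
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
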