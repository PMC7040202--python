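"""Configuration and the staged end-to-end driver.

A single YAML config drives all stages; every JSON output embeds the
resolved-config hash and the seed, so a run is reproducible and idempotent:
re-running a stage with the same config and seed rewrites byte-identical
artifacts.  Logs are line-oriented ``key=value`` records written next to
the outputs (and excluded from the idempotence guarantee).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import io_formats as iof
from .errors import MissingArtifactError, ValidationError
from .features import ExtractionConfig, extract_features, feature_registry
from .phantom import (
    PhantomParams,
    PhantomSampler,
    SurvivalSimParams,
    generate_cohort,
    null_cohort,
)
from .selection import epv_check, select_features, stability_analysis, zscore_fit_apply
from .survival import (
    SignatureModel,
    clinical_and_combined_models,
    compare_baseline,
    evaluate_signature,
    fit_signature,
    hazard_ratio_table,
)

logger = logging.getLogger("ctradiomics.pipeline")


@dataclass
class PipelineConfig:
    """Resolved settings of every stage (see README for the YAML schema)."""

    output_dir: str = "ctradiomics_run"
    seed: int = 0
    # simulate
    n: int = 63
    n_null: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 1.0
    semi_axes_mm: tuple[float, float, float] = (14.0, 11.0, 9.0)
    median_pfs_days: float = 248.0
    censor_bounds: tuple[float, float] = (30.0, 1095.0)
    beta: dict = field(default_factory=lambda: {"sigma2": 1.5, "gamma": 1.2})
    # extract
    n_gray_levels: int = 32
    resample_mm: float | None = 1.0
    wavelet: bool = True
    # select
    pearson_threshold: float = 0.8
    folds: int = 10
    train_fraction: float = 0.5
    stability_splits: int = 0  # 0 = skip the stability pass
    # evaluate
    horizon_days: float = 183.0
    n_boot: int = 2000
    rho: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.pearson_threshold <= 1):
            raise ValidationError("pearson_threshold must be in (0, 1]")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if not (0 < self.train_fraction < 1):
            raise ValidationError("train_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        for key in ("grid_shape", "semi_axes_mm", "censor_bounds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("grid_shape", "semi_axes_mm", "censor_bounds"):
            d[key] = list(d[key])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # derived simulation parameter objects -------------------------------
    def phantom_sampler(self) -> PhantomSampler:
        base = PhantomParams(
            shape=self.grid_shape,
            spacing=(self.spacing_mm,) * 3,
            semi_axes_mm=self.semi_axes_mm,
        )
        return PhantomSampler(base=base)

    def survival_params(self, n: int | None = None, seed_offset: int = 0) -> SurvivalSimParams:
        return SurvivalSimParams(
            n=n if n is not None else self.n,
            lambda0=float(np.log(2) / self.median_pfs_days),
            beta=dict(self.beta),
            censor_bounds=self.censor_bounds,
            seed=self.seed + seed_offset,
        )

    def extraction(self) -> ExtractionConfig:
        return ExtractionConfig(
            n_gray_levels=self.n_gray_levels,
            resample_mm=self.resample_mm,
            wavelet=self.wavelet,
        )


def _setup_log(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (outdir / "run.log").resolve()
        for h in logger.handlers
    ):
        fh = logging.FileHandler(outdir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logger.addHandler(fh)
    logger.setLevel(logging.INFO)


def _log(stage: str, **kv) -> None:
    logger.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in kv.items()))


def _stamp(cfg: PipelineConfig, payload: dict) -> dict:
    payload = dict(payload)
    payload["config_hash"] = cfg.config_hash
    payload["seed"] = cfg.seed
    return payload


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"stage {stage!r} needs {path}; run the producing stage first"
        )
    return path


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig) -> Path:
    """Generate the synthetic cohort(s) and write all volumes and tables."""
    out = Path(cfg.output_dir)
    _setup_log(out)
    t0 = _time.perf_counter()
    cohort_dir = out / "cohort"
    cohort = generate_cohort(cfg.phantom_sampler(), cfg.survival_params(), cohort_label="alk")
    for (img, mask), pid in zip(cohort.volumes, cohort.clinical["patient_id"]):
        iof.write_image(img, cohort_dir / f"{pid}_image.nrrd")
        iof.write_mask(mask, cohort_dir / f"{pid}_mask.nrrd")
    iof.write_clinical(cohort.clinical, cohort_dir / "clinical.csv")
    cohort.truth.to_csv(cohort_dir / "truth.csv", index=False)
    if cfg.n_null > 0:
        nc = null_cohort(
            cfg.survival_params(n=cfg.n_null, seed_offset=1),
            cfg.phantom_sampler(),
            cohort_label="null",
        )
        null_dir = out / "cohort_null"
        for (img, mask), pid in zip(nc.volumes, nc.clinical["patient_id"]):
            iof.write_image(img, null_dir / f"{pid}_image.nrrd")
            iof.write_mask(mask, null_dir / f"{pid}_mask.nrrd")
        iof.write_clinical(nc.clinical, null_dir / "clinical.csv")
        nc.truth.to_csv(null_dir / "truth.csv", index=False)
    _log("simulate", n=cfg.n, n_null=cfg.n_null, seconds=round(_time.perf_counter() - t0, 2))
    return cohort_dir


def stage_extract(cfg: PipelineConfig) -> Path:
    """Extract the 481-feature table for every patient in the cohort."""
    out = Path(cfg.output_dir)
    _setup_log(out)
    t0 = _time.perf_counter()
    cohort_dir = _require(out / "cohort", "extract")
    clinical = iof.read_clinical(_require(cohort_dir / "clinical.csv", "extract"))
    econf = cfg.extraction()
    rows = []
    for pid in clinical["patient_id"]:
        img = iof.read_image(cohort_dir / f"{pid}_image.nrrd")
        mask = iof.read_mask(cohort_dir / f"{pid}_mask.nrrd", img)
        rows.append(extract_features(img, mask, econf, patient_id=pid))
        _log("extract", patient=pid, n_features=len(rows[-1]))
    table = pd.DataFrame(rows)
    table.index.name = "patient_id"
    path = out / "features.csv"
    iof.write_feature_table(table, path)
    _log(
        "extract",
        n_patients=len(table),
        n_features=table.shape[1],
        seconds=round(_time.perf_counter() - t0, 2),
    )
    return path


def _load_features_clinical(cfg: PipelineConfig, stage: str):
    out = Path(cfg.output_dir)
    reg = feature_registry(cfg.extraction())
    feats = iof.read_feature_table(
        _require(out / "features.csv", stage), expected_columns=reg["column"]
    )
    clinical = iof.read_clinical(_require(out / "cohort" / "clinical.csv", stage))
    clinical = clinical.set_index("patient_id").loc[feats.index].reset_index()
    return feats, clinical


def stage_select(cfg: PipelineConfig) -> Path:
    """Split the cohort 1:1 (event-stratified), normalize on the training
    half and run the Pearson + CV-LASSO-Cox discovery chain."""
    out = Path(cfg.output_dir)
    _setup_log(out)
    t0 = _time.perf_counter()
    feats, clinical = _load_features_clinical(cfg, "select")
    event = clinical["event"].to_numpy()
    idx_tr, idx_va = train_test_split(
        np.arange(len(clinical)),
        train_size=cfg.train_fraction,
        stratify=event,
        random_state=cfg.seed,
    )
    idx_tr, idx_va = np.sort(idx_tr), np.sort(idx_va)
    train_ids = clinical["patient_id"].iloc[idx_tr].tolist()
    val_ids = clinical["patient_id"].iloc[idx_va].tolist()

    (feats_tr_n,), state = zscore_fit_apply(feats.iloc[idx_tr])
    res = select_features(
        feats_tr_n,
        clinical["pfs_days"].iloc[idx_tr].to_numpy(),
        event[idx_tr],
        pearson_threshold=cfg.pearson_threshold,
        folds=cfg.folds,
        seed=cfg.seed,
    )
    ok, msg = epv_check(len(res.nonzero), int(event[idx_tr].sum()))
    _log("select", epv=msg)

    payload = _stamp(
        cfg,
        {
            "train_ids": train_ids,
            "validation_ids": val_ids,
            "normalization": {
                "mean": state.mean.to_dict(),
                "sd": state.sd.to_dict(),
                "dropped": state.dropped,
            },
            "selection": res.to_dict(),
            "epv_ok": ok,
        },
    )
    path = out / "selection.json"
    iof.write_json(payload, path)

    if cfg.stability_splits > 0:
        freq = stability_analysis(
            feats,
            clinical["pfs_days"].to_numpy(),
            event,
            n_splits=cfg.stability_splits,
            seed=cfg.seed,
            pearson_threshold=cfg.pearson_threshold,
            folds=cfg.folds,
        )
        freq.rename("selection_frequency").to_csv(out / "selection_frequency.csv")
    _log(
        "select",
        n_surviving=len(res.nonzero),
        chosen_alpha=res.chosen_alpha,
        seconds=round(_time.perf_counter() - t0, 2),
    )
    return path


def stage_fit(cfg: PipelineConfig) -> Path:
    """Fit the multivariate-Cox signature on the training half."""
    out = Path(cfg.output_dir)
    _setup_log(out)
    sel = iof.read_json(_require(out / "selection.json", "fit"))
    feats, clinical = _load_features_clinical(cfg, "fit")
    mean = pd.Series(sel["normalization"]["mean"])
    sd = pd.Series(sel["normalization"]["sd"])
    chosen = list(sel["selection"]["nonzero"])
    if not chosen:
        # LASSO kept nothing: fall back to the path's first-entering feature
        chosen = [sel["selection"]["entry_order"][0]]
        _log("fit", warning="empty_lasso_set_fallback", feature=chosen[0])
    clin = clinical.set_index("patient_id")
    tr = clin.loc[sel["train_ids"]]
    feats_n = (feats[mean.index] - mean) / sd
    model = fit_signature(
        feats_n.loc[sel["train_ids"], chosen],
        tr["pfs_days"].to_numpy(),
        tr["event"].to_numpy(),
    )
    payload = _stamp(cfg, {"model": model.to_dict()})
    path = out / "signature.json"
    iof.write_json(payload, path)
    _log("fit", features=",".join(chosen), cutoff=model.cutoff)
    return path


def stage_evaluate(cfg: PipelineConfig) -> Path:
    """Evaluate the signature on training and validation halves and write
    the report plus plot-ready CSV exports."""
    out = Path(cfg.output_dir)
    _setup_log(out)
    t0 = _time.perf_counter()
    sel = iof.read_json(_require(out / "selection.json", "evaluate"))
    sig = iof.read_json(_require(out / "signature.json", "evaluate"))
    feats, clinical = _load_features_clinical(cfg, "evaluate")
    model = SignatureModel.from_dict(sig["model"])
    mean = pd.Series(sel["normalization"]["mean"])
    sd = pd.Series(sel["normalization"]["sd"])
    feats_n = (feats[mean.index] - mean) / sd
    clin = clinical.set_index("patient_id")

    report: dict = {}
    scores = {}
    for name, ids in (("train", sel["train_ids"]), ("validation", sel["validation_ids"])):
        sub_clin = clin.loc[ids].reset_index()
        sub_feats = feats_n.loc[ids]
        report[name] = evaluate_signature(
            model,
            sub_feats,
            sub_clin,
            horizon=cfg.horizon_days,
            n_boot=cfg.n_boot,
            seed=cfg.seed,
            rho=cfg.rho,
        )
        scores[name] = (sub_clin, model.score(sub_feats))

    split_table = clinical.copy()
    split_table["cohort_label"] = np.where(
        clinical["patient_id"].isin(sel["train_ids"]), "train", "validation"
    )
    report["baseline_comparison"] = (
        compare_baseline(split_table).reset_index().to_dict(orient="records")
    )

    tr_clin, tr_scores = scores["train"]
    va_clin, va_scores = scores["validation"]
    from .survival import encode_clinical  # local import to avoid cycle noise

    factors = encode_clinical(va_clin)
    factors["signature"] = va_scores
    for fname in model.feature_names:
        factors[fname] = feats_n.loc[sel["validation_ids"], fname].to_numpy()
    hr = hazard_ratio_table(
        factors, va_clin["pfs_days"].to_numpy(), va_clin["event"].to_numpy()
    )
    hr.reset_index().to_csv(out / "forest_table.csv", index=False)
    report["hazard_ratios_validation"] = hr.reset_index().to_dict(orient="records")

    models = clinical_and_combined_models(tr_clin, tr_scores, va_clin, va_scores)
    report["models"] = {
        "clinical_covariates": models["clinical_covariates"],
        "clinical_model": models["clinical_model"],
        "combined_model": models["combined_model"],
        "signature_cindex_train": models["signature_cindex_train"],
        "signature_cindex_validation": models["signature_cindex_validation"],
    }

    for name in ("train", "validation"):
        for grp, km in report[name]["km"].items():
            pd.DataFrame(km).to_csv(out / f"km_{name}_{grp}.csv", index=False)

    path = out / "report.json"
    iof.write_json(_stamp(cfg, report), path)
    _log(
        "evaluate",
        cindex_train=round(report["train"]["cindex"], 4),
        cindex_validation=round(report["validation"]["cindex"], 4),
        seconds=round(_time.perf_counter() - t0, 2),
    )
    return path


def run_all(cfg: PipelineConfig) -> Path:
    """simulate -> extract -> select -> fit -> evaluate, in order."""
    stage_simulate(cfg)
    stage_extract(cfg)
    stage_select(cfg)
    stage_fit(cfg)
    return stage_evaluate(cfg)
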