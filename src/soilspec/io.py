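"""File formats, run configuration and the pipeline orchestrator.

Library file format (CSV, UTF-8, header row): metadata columns
``sample_id, land_cover, material, scan_id``, then the property columns
``soc, nitrogen, clay, silt, sand, caco3, ph, cec`` (missing = empty cell),
then one reflectance column per wavelength, named as the nm value with one
decimal ("500.0"), strictly increasing left to right.  One row per scan;
``(sample_id, scan_id)`` must be unique.  Duplicate laboratory analyses
travel in a companion ``<stem>.duplicates.csv`` with columns
``sample_id, soc_replicate``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    METADATA_COLUMNS,
    PROPERTY_COLUMNS,
    SpectralLibrary,
)
from .errors import ConfigError, FormatError
from .synth import SUBSETS, generate_library
from .preprocess import RECIPES, QcReport
from .select import SelectionResult

logger = logging.getLogger("soilspec")

_SCAN_META = METADATA_COLUMNS + ("scan_id",)


def _wavelength_name(wl: float) -> str:
    return f"{wl:.1f}"


def write_library(lib: SpectralLibrary, path: str | Path) -> Path:
    """Write a library to the CSV format (plus duplicates companion file)."""
    path = Path(path)
    wl_names = [_wavelength_name(w) for w in lib.wavelengths]
    rows = []
    for i in range(lib.n_samples):
        meta = lib.properties.iloc[i]
        for s in range(lib.n_scans):
            row = {c: meta[c] for c in METADATA_COLUMNS}
            row["scan_id"] = s
            for c in PROPERTY_COLUMNS:
                row[c] = meta[c]
            rows.append(row)
    df = pd.DataFrame(rows)
    spectra = lib.scans.reshape(-1, lib.wavelengths.size)
    df = pd.concat(
        [df, pd.DataFrame(spectra, columns=wl_names, index=df.index)], axis=1
    )
    df.to_csv(path, index=False, float_format="%.17g")
    dup_path = path.with_suffix(".duplicates.csv")
    if lib.duplicate_lab:
        pd.DataFrame(
            {"sample_id": list(lib.duplicate_lab),
             "soc_replicate": list(lib.duplicate_lab.values())}
        ).to_csv(dup_path, index=False, float_format="%.17g")
    elif dup_path.exists():
        dup_path.unlink()
    return path


def read_library(path: str | Path) -> SpectralLibrary:
    """Read a library CSV, validating the format; failures name the first
    offending column or row."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    missing = [c for c in _SCAN_META + PROPERTY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    wl_names = [c for c in df.columns if c not in _SCAN_META + PROPERTY_COLUMNS]
    try:
        wl = np.array([float(c) for c in wl_names])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength column: {exc}") from None
    bad = np.flatnonzero(np.diff(wl) <= 0)
    if bad.size:
        raise FormatError(
            f"{path}: wavelength columns not strictly increasing at "
            f"{wl_names[bad[0] + 1]!r}"
        )
    if df.duplicated(subset=["sample_id", "scan_id"]).any():
        row = int(df.duplicated(subset=["sample_id", "scan_id"]).idxmax())
        raise FormatError(f"{path}: duplicate (sample_id, scan_id) at row {row + 2}")

    spectra = df[wl_names]
    non_numeric = spectra.apply(
        lambda col: pd.to_numeric(col, errors="coerce")
    )
    if non_numeric.isna().any().any():
        col = non_numeric.columns[non_numeric.isna().any().to_numpy()][0]
        row = int(non_numeric[col].isna().idxmax())
        raise FormatError(f"{path}: non-numeric spectrum value at row {row + 2}, "
                          f"column {col!r}")

    n_scans_per = df.groupby("sample_id", sort=False)["scan_id"].count()
    if n_scans_per.nunique() != 1:
        raise FormatError(f"{path}: unequal scan counts per sample")
    n_scans = int(n_scans_per.iloc[0])

    first = df.sort_values(["sample_id", "scan_id"], kind="stable")
    order = first["sample_id"].drop_duplicates().tolist()
    props = (first.drop_duplicates("sample_id")
             .loc[:, list(METADATA_COLUMNS + PROPERTY_COLUMNS)]
             .reset_index(drop=True))
    scans = np.empty((len(order), n_scans, wl.size))
    grouped = first.groupby("sample_id", sort=False)
    for i, sid in enumerate(order):
        scans[i] = grouped.get_group(sid)[wl_names].to_numpy(float)

    dup_path = path.with_suffix(".duplicates.csv")
    duplicate_lab: dict[str, float] = {}
    if dup_path.exists():
        dup = pd.read_csv(dup_path, dtype={"sample_id": str},
                          float_precision="round_trip")
        duplicate_lab = dict(zip(dup["sample_id"], dup["soc_replicate"].astype(float)))
    return SpectralLibrary(props, wl, scans, duplicate_lab)


def write_qc_report(qc: QcReport, path: str | Path) -> Path:
    path = Path(path)
    qc.to_frame().to_csv(path, index=False)
    return path


def write_selection(result: SelectionResult, sample_ids, path: str | Path) -> Path:
    path = Path(path)
    result.to_frame(sample_ids).to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    subset: str = "mineral"
    n_samples: int = 300
    library_path: str | None = None     # read instead of simulating if set
    pretreatment: str = "SG1"
    predictor_source: str = "spectra"   # {"spectra", "rfe"}
    auxiliary: str = "none"             # {"none", "sand", "clay", "both"}
    family: str = "pls"
    max_latent_variables: int = 20
    rfe_sizes: list[int] | None = None
    train_fraction: float = 2.0 / 3.0
    qc_threshold: float | None = 0.01
    n_partitions: int = 10
    holdout_fraction: float = 0.5
    duplicate_fraction: float = 0.0
    seed: int = 0
    output_dir: str = "soilspec_run"

    def validate(self) -> "RunConfig":
        problems = []
        if self.library_path is None and self.subset not in SUBSETS:
            problems.append(f"subset: {self.subset!r} not in {SUBSETS}")
        if self.pretreatment not in RECIPES:
            problems.append(f"pretreatment: {self.pretreatment!r} not in {RECIPES}")
        if self.predictor_source not in ("spectra", "rfe"):
            problems.append(f"predictor_source: {self.predictor_source!r}")
        if self.auxiliary not in ("none", "sand", "clay", "both"):
            problems.append(f"auxiliary: {self.auxiliary!r}")
        if self.auxiliary != "none" and self.subset == "organic":
            problems.append(
                "auxiliary: texture predictors unavailable for the organic subset"
            )
        if self.family not in ("pls", "random_forest", "svm", "boosted_trees"):
            problems.append(f"family: {self.family!r}")
        if not 0 < self.train_fraction < 1:
            problems.append("train_fraction: must lie in (0, 1)")
        if not 0 < self.holdout_fraction < 1:
            problems.append("holdout_fraction: must lie in (0, 1)")
        if not 0 <= self.duplicate_fraction <= 1:
            problems.append("duplicate_fraction: must lie in [0, 1]")
        if self.n_samples < 3 and self.library_path is None:
            problems.append("n_samples: must be >= 3")
        if self.max_latent_variables < 1:
            problems.append("max_latent_variables: must be >= 1")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _kv(stage: str, **kwargs) -> str:
    pairs = " ".join(f"{k}={v}" for k, v in kwargs.items())
    return f"ts={time.strftime('%Y-%m-%dT%H:%M:%S')} stage={stage} {pairs}"


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute simulate/load -> preprocess -> split -> calibrate -> validate
    and write all artifacts to ``config.output_dir``.

    Returns a mapping of artifact names to paths.  Fully reproducible from
    the config and seed alone; the log records every stage and parameter.
    """
    from .calibrate import (
        FAMILY_REGISTRY, PredictorRecipe, pls_family, train_model,
    )
    from .validate import format_report, performance_report, sel

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [_kv("config", **dataclasses.asdict(config))]
    artifacts: dict[str, Path] = {}

    if config.library_path is not None:
        lib = read_library(config.library_path)
        log_lines.append(_kv("load", path=config.library_path, n=lib.n_samples))
    else:
        lib = generate_library(config.n_samples, config.subset, config.seed,
                               config.duplicate_fraction)
        log_lines.append(_kv("simulate", subset=config.subset,
                             n=lib.n_samples, seed=config.seed))
        artifacts["library"] = write_library(lib, out / "library.csv")

    if config.family == "pls":
        family = pls_family(max_lv=config.max_latent_variables)
    else:
        family = FAMILY_REGISTRY[config.family](seed=config.seed) \
            if config.family != "svm" else FAMILY_REGISTRY[config.family]()
    recipe = PredictorRecipe(config.predictor_source, config.auxiliary)

    model = train_model(
        lib,
        pretreatment=config.pretreatment,
        recipe=recipe,
        family=family,
        rfe_sizes=config.rfe_sizes,
        train_fraction=config.train_fraction,
        n_partitions=config.n_partitions,
        holdout_fraction=config.holdout_fraction,
        qc_threshold=config.qc_threshold,
        seed=config.seed,
    )
    log_lines.append(_kv("calibrate", family=family.name,
                         chosen=model.tuning.chosen,
                         removed_by_qc=len(model.qc.removed)))

    artifacts["qc"] = write_qc_report(model.qc, out / "qc.csv")
    kept_ids = model.qc.mean_sd.index[
        ~model.qc.mean_sd.index.isin(model.qc.removed)]
    artifacts["selection"] = write_selection(
        model.selection, np.asarray(kept_ids), out / "selection.csv")

    manifest = {
        "format_version": 1,
        "family": model.family_name,
        "pretreatment": model.pretreatment,
        "predictor_source": model.recipe.source,
        "auxiliary": model.recipe.auxiliary,
        "fusion": model.recipe.fusion,
        "chosen_params": model.tuning.chosen,
        "wavelengths_nm": [float(w) for w in model.wavelengths],
        "selected_columns": (None if model.selected_columns is None
                             else [int(c) for c in model.selected_columns]),
        "coefficients": (list(map(float, model.estimator.coef_))
                         if hasattr(model.estimator, "coef_") else None),
        "intercept": (float(model.estimator.intercept_)
                      if hasattr(model.estimator, "intercept_") else None),
        "cv": model.tuning.to_frame().to_dict(orient="list"),
        "stats": model.stats.as_dict(),
        "seed": config.seed,
    }
    artifacts["model"] = out / "model.json"
    artifacts["model"].write_text(json.dumps(manifest, indent=1))

    stats_df = pd.DataFrame([model.stats.as_dict()])
    artifacts["stats"] = out / "validation_stats.csv"
    stats_df.to_csv(artifacts["stats"], index=False)

    base_name = "rfe" if recipe.source == "rfe" else "spc"
    pred_name = base_name if recipe.auxiliary == "none" else \
        f"{base_name}+{recipe.auxiliary}"
    report = performance_report([{
        "subset": config.subset.capitalize(), "treatment": config.pretreatment,
        "family": model.family_name, "predictor": pred_name,
        "stats": model.stats,
    }])
    artifacts["report"] = out / "report.txt"
    artifacts["report"].write_text(format_report(report) + "\n")
    report.to_csv(out / "report.csv", index=False)

    if lib.duplicate_lab:
        pmap = dict(zip(lib.properties["sample_id"], lib.properties["soc"]))
        pairs = [(pmap[k], v) for k, v in lib.duplicate_lab.items()]
        sel_value = sel(np.asarray(pairs))
        (out / "reproducibility.txt").write_text(
            f"sel_g_per_kg={sel_value:.6g} n_pairs={len(pairs)}\n")
        artifacts["reproducibility"] = out / "reproducibility.txt"
        log_lines.append(_kv("validate", sel=f"{sel_value:.4f}"))

    log_lines.append(_kv("done", rmsep=f"{model.stats.rmsep:.4f}",
                         rpd=f"{model.stats.rpd:.4f}", r2=f"{model.stats.r2:.4f}"))
    artifacts["log"] = out / "run.log"
    artifacts["log"].write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info(line)
    return artifacts
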