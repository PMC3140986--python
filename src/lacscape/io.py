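"""Dataset tables, run configuration and the end-to-end pipeline.

The canonical dataset is a comma-separated UTF-8 table with a mandatory
header ``strain_id,E_mM,replicate_id,fitness,concentration``; one row per
strain x inducer condition x replicate, with empty cells where a quantity was
not measured in that replicate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ModelParams
from .inference import FitConfig, StrainMeasurement

__all__ = [
    "DatasetError",
    "Dataset",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "run_pipeline",
]

logger = logging.getLogger("lacscape")

REQUIRED_COLUMNS = ["strain_id", "E_mM", "replicate_id", "fitness", "concentration"]


class DatasetError(ValueError):
    pass


@dataclass
class Dataset:
    """Replicate-structured measurement table."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        self.df = self.df[REQUIRED_COLUMNS].reset_index(drop=True)
        for col in ("E_mM", "fitness", "concentration"):
            self.df[col] = self.df[col].astype(float)

    def measurements(self) -> dict:
        """{(strain_id, E): StrainMeasurement} with per-condition replicates."""
        out = {}
        for (sid, E), grp in self.df.groupby(["strain_id", "E_mM"], sort=True):
            out[(sid, float(E))] = StrainMeasurement(
                strain_id=sid,
                E=float(E),
                fitness=grp["fitness"].to_numpy(dtype=float),
                concentration=grp["concentration"].to_numpy(dtype=float),
            )
        return out

    def summary(self) -> pd.DataFrame:
        """Per strain x condition means, standard errors and replicate counts."""
        rows = []
        for (sid, E), m in self.measurements().items():
            rows.append(
                {
                    "strain_id": sid,
                    "E_mM": E,
                    "fitness_mean": m.fitness_mean,
                    "fitness_se": m.fitness_se,
                    "n_fitness": int(np.sum(~np.isnan(m.fitness))),
                    "conc_mean": m.conc_mean,
                    "conc_se": m.conc_se,
                    "n_conc": int(np.sum(~np.isnan(m.concentration))),
                }
            )
        return pd.DataFrame(rows)


def read_dataset(path) -> Dataset:
    """Read and validate a dataset table, reporting offending line numbers."""
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"strain_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing columns {missing}")
    # header is line 1, first data row line 2
    for col in ("E_mM", "replicate_id", "fitness", "concentration"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise DatasetError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r} at line {bad[0] + 2}"
            )
        df[col] = coerced
    both_empty = df.index[df["fitness"].isna() & df["concentration"].isna()]
    if len(both_empty):
        raise DatasetError(
            f"{path}: row with neither fitness nor concentration at line "
            f"{both_empty[0] + 2}"
        )
    dup = df.duplicated(subset=["strain_id", "E_mM", "replicate_id"], keep="first")
    if dup.any():
        line = int(df.index[dup][0]) + 2
        key = df.loc[df.index[dup][0], ["strain_id", "E_mM", "replicate_id"]].tolist()
        raise DatasetError(f"{path}: duplicate replicate key {key} at line {line}")
    return Dataset(df)


def write_dataset(dataset: Dataset, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dataset.df.to_csv(path, index=False, float_format="%.12g")


@dataclass
class RunConfig:
    """Top-level configuration: model parameters, panel design, fit search."""

    model: dict = field(default_factory=dict)
    panel: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    seed: int = 0
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"model", "panel", "fit", "seed", "verbose"}
        unknown = set(raw) - known
        if unknown:
            raise DatasetError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def model_params(self) -> ModelParams:
        return ModelParams.from_mapping(self.model)

    def panel_config(self):
        from .synth import PanelConfig

        cfg = dict(self.panel)
        cfg.setdefault("seed", self.seed)
        for key in ("delta_max_range", "chi0_range", "E_conditions",
                    "dose_response_E", "dose_response_strains"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        return PanelConfig(**cfg)

    def fit_config(self) -> FitConfig:
        cfg = dict(self.fit)
        for key in ("c_delta_grid", "c_T_grid", "c_C_grid"):
            if key in cfg:
                cfg[key] = np.asarray(cfg[key], dtype=float)
        return FitConfig(**cfg)


def run_pipeline(config: RunConfig, outdir) -> Path:
    """simulate -> estimate -> fit -> landscape, writing all artifacts.

    Deterministic given the configuration seed; every stage failure is
    re-raised with a stage tag.  Returns the output directory.
    """
    from . import __version__
    from .inference import build_prediction_table, fit_cost_coefficients
    from .landscape import landscape_grid
    from .model import Genotype
    from .synth import generate_strain_panel, simulate_measurements

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.model_params()
    panel_cfg = config.panel_config()
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "params": params.to_dict(),
        "panel_config": asdict(panel_cfg),
        "stages": [],
    }

    def stage(name):
        logger.info("pipeline stage: %s", name)
        log["stages"].append(name)

    try:
        stage("simulate")
        rng = np.random.default_rng(panel_cfg.seed)
        panel = generate_strain_panel(panel_cfg, rng)
        dataset, manifest = simulate_measurements(panel, params, panel_cfg, rng)
        write_dataset(dataset, outdir / "dataset.csv")
        (outdir / "panel_manifest.json").write_text(json.dumps(manifest, indent=2))

        stage("estimate")
        pump = {s.strain_id: s.genotype.pump_factor for s in panel}
        sat_E = max(panel_cfg.E_conditions)
        rows, estimates = build_prediction_table(
            dataset, params, pump_factors=pump, saturating_E=sat_E, exclude=("ref",)
        )
        est_df = pd.DataFrame(
            [
                {
                    "strain_id": s,
                    "delta_max": e.delta_max,
                    "delta_max_se": e.delta_max_se,
                    "chi0": e.chi0,
                    "chi0_se": e.chi0_se,
                }
                for s, e in sorted(estimates.items())
            ]
        )
        est_df.to_csv(outdir / "phenotype_estimates.csv", index=False, float_format="%.12g")

        stage("fit")
        fit_cfg = config.fit_config()
        fit = fit_cost_coefficients(rows, params, fit_cfg)
        (outdir / "fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
        grid_rows = []
        for i, ct in enumerate(fit.grid_c_T):
            for j, cc in enumerate(fit.grid_c_C):
                grid_rows.append((ct, cc, fit.grid_scores[i, j]))
        pd.DataFrame(grid_rows, columns=["c_T", "c_C", "score"]).to_csv(
            outdir / "score_grid.csv", index=False, float_format="%.12g"
        )

        stage("landscape")
        fitted = params.replace(c_delta=fit.c_delta, c_T=fit.c_T, c_C=fit.c_C)
        dm_grid = np.linspace(0.05, panel_cfg.delta_max_range[1] * 1.5, 25)
        E_grid = np.concatenate([[0.0], np.geomspace(1e-3, 10.0, 24)])
        grid = landscape_grid(
            "genotype-env",
            dm_grid,
            E_grid,
            fitted,
            genotype=Genotype(1.0, panel_cfg.chi0_wt, 1.0),
        )
        grid.to_frame().to_csv(outdir / "landscape_grid.csv", index=False, float_format="%.12g")
        grid.cliff.to_csv(outdir / "cliff_polyline.csv", index=False, float_format="%.12g")
    except Exception as exc:  # noqa: BLE001 - re-tag for the operator
        raise RuntimeError(f"pipeline failed in stage {log['stages'][-1]!r}: {exc}") from exc

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return outdir
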