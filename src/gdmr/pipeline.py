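"""End-to-end demo pipeline: genomes -> pyrograms -> GDMR -> models -> correlations.

Every stage is seeded from one master seed, the artifact directory gets a
manifest with SHA-256 checksums, and identical config + seed yields an
identical manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assay_quant, assay_sim, io, models, pheno_sim, tissue_corr

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    seed: int = 0
    out_dir: str = "gdmr_run"
    n_ccgg: int = 400
    n_gaattc: int = 100
    noise_cv: float = 0.014
    #: fixed methylation fraction for every sample, or None to draw each
    #: sample's fraction from the blood-panel phenotype preset
    methylation: float | None = None
    design_scale: float = 1.0
    alpha: float = 0.05
    model_names: tuple[str, ...] = ("blood", "blood_cbc")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cfg = io.load_config(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise io.SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "model_names" in cfg:
            cfg["model_names"] = tuple(cfg["model_names"])
        return cls(**cfg)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Run the full demo analysis; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    noise = assay_sim.NoiseModel(cv=config.noise_cv)

    # --- phenotype truth ---------------------------------------------------
    stage = "simulate_phenotypes"
    try:
        design = (
            pheno_sim.StudyDesign.default_longitudinal()
            if config.design_scale == 1.0
            else pheno_sim.StudyDesign.scaled_longitudinal(config.design_scale)
        )
        effects = pheno_sim.preset("blood_gdmr")
        cbc = pheno_sim.preset("cbc_counts")
        panel = pheno_sim.simulate_blood_panel(design, effects, rng, cbc_spec=cbc)
        if config.methylation is not None:
            panel["gdmr"] = 100.0 * config.methylation
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- assay simulation + quantification --------------------------------
    stage = "simulate_assay"
    try:
        pyros = []
        for row in panel.itertuples():
            sample_id = f"{row.animal}@{row.date}"
            genome = assay_sim.make_genome(
                config.n_ccgg, config.n_gaattc, row.gdmr / 100.0, rng, exact=True
            )
            pair = assay_sim.simulate_sample(
                genome, noise, rng, sample_id=sample_id, run_id="run1"
            )
            pyros.extend(pair.values())
        pyro_frame = io.pyrograms_to_frame(pyros)
        io.write_pyrograms_csv(pyros, out / "pyrograms.csv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    stage = "quantify"
    try:
        gdmr_table, qc = assay_quant.batch_quantify(pyro_frame)
        gdmr_table.to_csv(out / "gdmr_measured.csv", index=False)
        (out / "qc_report.json").write_text(json.dumps(qc, indent=2, default=str))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- merge measured GDMR back onto the phenotype table -----------------
    stage = "merge"
    try:
        measured = gdmr_table.assign(
            animal=gdmr_table["sample_id"].str.split("@").str[0],
            date=gdmr_table["sample_id"].str.split("@").str[1],
        )[["animal", "date", "gdmr"]].rename(columns={"gdmr": "gdmr_measured"})
        merged = panel.merge(measured, on=["animal", "date"], how="left")
        analysis = merged.drop(columns=["gdmr"]).rename(columns={"gdmr_measured": "gdmr"})
        io.write_phenotypes_csv(merged, out / "phenotypes.csv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- mixed models -------------------------------------------------------
    stage = "fit_models"
    try:
        fits = []
        lsmeans_frames = []
        for name in config.model_names:
            spec = models.MODEL_SPECS[name]
            fit = models.fit_mixed(analysis.dropna(subset=["gdmr"]), spec)
            fits.append(fit)
            for factor in spec.factors:
                ls, _ = models.tukey_letters(fit, factor, config.alpha)
                lsmeans_frames.append(ls.assign(model=name, factor=factor))
            fit.anova.assign(model=name).to_csv(
                out / f"anova_{name}.csv", index=False
            )
        if fits:
            pd.concat(lsmeans_frames).to_csv(out / "lsmeans.csv", index=False)
            models.compare_bic(fits).to_csv(out / "bic.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- blood time-point correlations --------------------------------------
    stage = "correlate"
    try:
        wide = analysis.pivot(index="animal", columns="date", values="gdmr")
        corr = tissue_corr.correlate(wide)
        corr.pairs.to_csv(out / "correlations.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    manifest = _manifest(out, config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _manifest(out: Path, config: RunConfig) -> dict:
    files = {}
    for path in sorted(out.glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    cfg = asdict(config)
    cfg["model_names"] = list(cfg["model_names"])
    return {
        "package_version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "files": files,
    }
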