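"""Configuration-driven end-to-end pipeline.

Wires the stages — synthetic generation (optional), censoring/creatinine
processing, reverse dosimetry, deterministic risk, Monte Carlo
probabilistic risk, and dietary association — into one reproducible run.
All randomness derives from a single master seed through
``numpy.random.SeedSequence`` so each stage is independently
re-runnable; the output manifest records seeds, package version and a
config hash sufficient to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations, dosimetry, montecarlo, processing, risk, synthetic
from .surveydata import ANALYTES, FOOD_GROUPS

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

STAGES = ("simulate", "process", "dose", "risk", "mc", "associate")


@dataclass
class PipelineConfig:
    """Everything needed to run (and re-run) the pipeline."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    #: paths to existing input CSVs; unset → synthetic generation
    participants_csv: str | None = None
    intakes_csv: str | None = None
    biomarkers_csv: str | None = None
    population_spec_yaml: str | None = None
    reference_doses_yaml: str | None = None
    mc_iterations: int = 10_000
    mc_families: tuple[str, ...] = ("normal", "lognormal", "gamma", "weibull")
    gcomp_n_boot: int = 1000
    gcomp_contrast: str = "observed_vs_zero"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "mc_families"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["stages"] = list(self.stages)
        d["mc_families"] = list(self.mc_families)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([master, idx])
    return int(ss.generate_state(1)[0] % (2**31))


def validate_inputs(
    participants: pd.DataFrame | None = None,
    intakes: pd.DataFrame | None = None,
    biomarkers: pd.DataFrame | None = None,
) -> dict[str, list[str]]:
    """Schema and invariant checks; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings: list[str] = []
    if participants is not None:
        need = {"subject_id", "age_group", "age", "sex", "body_weight", "height"}
        missing = need - set(participants.columns)
        if missing:
            errors.append(f"participants: missing columns {sorted(missing)}")
        else:
            if (participants["body_weight"] <= 0).any():
                errors.append("participants: non-positive body weight")
            if (participants["height"] <= 0).any():
                errors.append("participants: non-positive height")
            if ((participants["age"] < 0) | (participants["age"] >= 140)).any():
                errors.append("participants: age outside [0, 140)")
            if participants["subject_id"].duplicated().any():
                errors.append("participants: duplicate subject ids")
            bad_sex = set(participants["sex"]) - {"male", "female"}
            if bad_sex:
                errors.append(f"participants: unknown sex values {sorted(bad_sex)}")
    if intakes is not None:
        missing = set(FOOD_GROUPS) - set(intakes.columns)
        if missing:
            errors.append(
                f"intakes: 12-group schema violated, missing {sorted(missing)}"
            )
        else:
            if (intakes[list(FOOD_GROUPS)] < 0).any().any():
                errors.append("intakes: negative cooked weight")
        if "subject_id" not in intakes.columns:
            errors.append("intakes: missing subject_id")
    if biomarkers is not None:
        need = {"subject_id", "analyte_id", "raw_concentration", "lod", "creatinine"}
        missing = need - set(biomarkers.columns)
        if missing:
            errors.append(f"biomarkers: missing columns {sorted(missing)}")
        else:
            if (biomarkers["raw_concentration"] < 0).any():
                errors.append("biomarkers: negative concentration")
            if (biomarkers["creatinine"] <= 0).any():
                errors.append("biomarkers: non-positive creatinine")
            unknown = set(biomarkers["analyte_id"]) - set(ANALYTES)
            if unknown:
                warnings.append(f"biomarkers: unrecognized analytes {sorted(unknown)}")
    return {"errors": errors, "warnings": warnings}


class StageError(RuntimeError):
    """Raised when one pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "master_seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in STAGES},
        "outputs": {},
    }
    try:
        import importlib.metadata as md

        manifest["version"] = md.version("biomonrisk")
    except Exception:
        manifest["version"] = "unknown"

    def emit(stage: str, name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest["outputs"].setdefault(stage, []).append(str(path))

    spec = None
    participants = intakes = biomarkers = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            spec = (
                synthetic.PopulationSpec.from_yaml(config.population_spec_yaml)
                if config.population_spec_yaml
                else synthetic.default_population_spec(seed=config.seed)
            )
            s = manifest["stage_seeds"]["simulate"]
            participants = synthetic.generate_population(spec, seed=s)
            intakes = synthetic.generate_intakes(participants, spec, seed=s + 1)
            biomarkers = synthetic.generate_biomarkers(
                participants, spec, intakes, seed=s + 2
            )
            emit(stage, "participants", participants)
            emit(stage, "intakes", intakes)
            emit(stage, "biomarkers", biomarkers)
        else:
            stage = "load"
            if config.participants_csv:
                participants = pd.read_csv(config.participants_csv)
            if config.intakes_csv:
                intakes = pd.read_csv(config.intakes_csv)
            if config.biomarkers_csv:
                biomarkers = pd.read_csv(config.biomarkers_csv)

        report = validate_inputs(participants, intakes, biomarkers)
        manifest["validation"] = report
        if report["errors"]:
            raise ValueError("; ".join(report["errors"]))

        processed = edi = None
        if "process" in config.stages:
            stage = "process"
            processed = processing.process_measurements(biomarkers)
            emit(stage, "processed_biomarkers", processed)

        if "dose" in config.stages:
            stage = "dose"
            edi = dosimetry.edi_table(participants, processed)
            emit(stage, "edi", edi)
            emit(stage, "edi_summary", dosimetry.summarize_edi(edi))

        if "risk" in config.stages:
            stage = "risk"
            doses = (
                risk.load_reference_doses(config.reference_doses_yaml)
                if config.reference_doses_yaml
                else dict(risk.DEFAULT_REFERENCE_DOSES)
            )
            emit(stage, "risk", risk.risk_table(edi, doses))

        if "mc" in config.stages:
            stage = "mc"
            doses = (
                risk.load_reference_doses(config.reference_doses_yaml)
                if config.reference_doses_yaml
                else dict(risk.DEFAULT_REFERENCE_DOSES)
            )
            mc_rows = []
            mc_seed = manifest["stage_seeds"]["mc"]
            for group, sub_p in participants.groupby("age_group"):
                results = []
                for analyte in sorted(set(edi["analyte_id"])):
                    vals = edi.loc[
                        (edi["analyte_id"] == analyte)
                        & (edi["age_group"] == group),
                        "ue",
                    ].to_numpy()
                    dist = montecarlo.fit_best_distribution(
                        vals, families=config.mc_families
                    )
                    sampler = _make_sampler(sub_p)
                    res = montecarlo.monte_carlo_edi(
                        dist,
                        sampler,
                        f_ue=dosimetry.DEFAULT_EXCRETION_FRACTIONS[analyte],
                        iterations=config.mc_iterations,
                        seed=mc_seed,
                        analyte_id=analyte,
                        age_group=str(group),
                    )
                    results.append(res)
                mc_rows.append(montecarlo.probabilistic_risk_summary(results, doses))
            emit(stage, "probabilistic_risk", pd.concat(mc_rows, ignore_index=True))

        if "associate" in config.stages:
            stage = "associate"
            a_seed = manifest["stage_seeds"]["associate"]
            spearman_rows, mlr_rows, gcomp_rows = [], [], []
            for group, sub_p in participants.groupby("age_group"):
                ids = set(sub_p["subject_id"])
                proc_g = processed.loc[processed["subject_id"].isin(ids)]
                int_g = intakes.loc[intakes["subject_id"].isin(ids)]
                for analyte in sorted(set(proc_g["analyte_id"])):
                    screen = associations.spearman_matrix(
                        proc_g, int_g, analyte, age_group=str(group)
                    )
                    spearman_rows.extend(screen)
                    significant = [r.food_group for r in screen if r.p_value < 0.05]
                    if significant:
                        mlr, _fit = associations.mlr_food_groups(
                            proc_g, int_g, sub_p, analyte, significant,
                            age_group=str(group),
                        )
                        mlr_rows.extend(mlr)
                    effects = [
                        associations.gcomputation_effect(
                            proc_g, int_g, sub_p, analyte, fg,
                            age_group=str(group),
                            contrast=config.gcomp_contrast,
                            n_boot=config.gcomp_n_boot,
                            seed=a_seed,
                        )
                        for fg in FOOD_GROUPS
                    ]
                    gcomp_rows.extend(associations.effect_weights(effects))
            emit(stage, "spearman", _assoc_frame(spearman_rows))
            emit(stage, "mlr", _assoc_frame(mlr_rows))
            emit(stage, "gcomputation", _gcomp_frame(gcomp_rows))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _make_sampler(participants: pd.DataFrame):
    """Empirical anthropometry sampler: resample observed subjects."""
    frame = participants[["age", "sex", "body_weight", "height"]].reset_index(
        drop=True
    )

    def sampler(n: int, rng: np.random.Generator) -> pd.DataFrame:
        idx = rng.integers(0, len(frame), size=n)
        return frame.iloc[idx].reset_index(drop=True)

    return sampler


def _assoc_frame(rows) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(
            columns=["analyte_id", "food_group", "age_group", "estimate",
                     "ci_low", "ci_high", "p_value", "p_bh", "method"]
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["p_bh"] = associations.benjamini_hochberg(df["p_value"])
    return df


def _gcomp_frame(rows) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["p_bh"] = associations.benjamini_hochberg(df["p_value"])
    return df
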