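"""End-to-end orchestration: generate -> preprocess -> features -> evaluate.

A single validated :class:`RunConfig` (YAML on disk) drives every stage; all
outputs are CSV/JSON under a run directory, and a manifest records the config,
seed, and library versions so a run is bit-for-bit reproducible.  Each stage
can also be executed from the previous stage's serialized outputs (see
:mod:`eegintent.cli`).
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from eegintent import io as eio
from eegintent.channels import CHANNEL_SUBSETS
from eegintent.design import DEFAULT_DROPOUT, DEFAULT_YES_PROB, make_design
from eegintent.evaluate import (
    POSITIVE,
    channel_subset_run,
    default_classifiers,
    evaluate_experiment,
    normalize_task,
    pooled_roc,
)
from eegintent.features import extract_feature_table
from eegintent.preprocess import (
    PreprocessParams,
    RecordingRejectedError,
    epoch_question,
    preprocess_recording,
)
from eegintent.selection import BorutaConfig, VarSelRFConfig, boruta_select, varselrf_select
from eegintent.seeding import child_seed
from eegintent.synth import ArtifactConfig, EffectSpec, synthesize_experiment

_FLOAT_FMT = "%.10g"


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignConfig(_Model):
    n_subjects: int = Field(25, ge=0)
    n_insider: int = Field(10, ge=0)
    n_conflict: int = Field(10, ge=0)
    yes_prob_insider: float = Field(DEFAULT_YES_PROB["insider"], ge=0.0, le=1.0)
    yes_prob_conflict: float = Field(DEFAULT_YES_PROB["conflict"], ge=0.0, le=1.0)
    dropout_prob: float = Field(DEFAULT_DROPOUT, ge=0.0, le=1.0)


class ArtifactModel(_Model):
    line_amplitude_uv: float = Field(2.0, ge=0)
    line_freq_hz: float = Field(50.0, gt=0)
    drift_amplitude_uv: float = Field(5.0, ge=0)
    drift_freq_hz: float = Field(0.3, gt=0)
    blink_rate_hz: float = Field(0.2, ge=0)
    blink_amplitude_uv: float = Field(80.0, ge=0)
    dead_channel_prob: float = Field(0.02, ge=0.0, le=1.0)


class EffectModel(_Model):
    intent_effect: float = Field(0.0, ge=0)
    scenario_effect: float = Field(0.0, ge=0)
    subject_variability: float = Field(0.2, ge=0)
    artifacts: ArtifactModel = Field(default_factory=ArtifactModel)


class RecordingConfig(_Model):
    fs: float = Field(500.0, ge=250.0)
    duration_s: float = Field(30.0, ge=2.0)


class PreprocessConfig(_Model):
    target_fs: float = Field(250.0, gt=0)
    highpass_hz: float = Field(1.0, gt=0)
    highpass_order: int = Field(4, ge=1)
    line_freq_hz: float = Field(50.0, gt=0)
    notch_bandwidth_hz: float = Field(1.0, gt=0)
    flat_variance_uv2: float = Field(1e-10, gt=0)
    min_neighbor_corr: float = Field(0.4, ge=0.0, le=1.0)
    max_bad_fraction: float = Field(0.5, gt=0.0, le=1.0)
    epoch_window_s: float = Field(2.0, gt=0)
    epoch_step_s: float = Field(1.0, gt=0)
    epoch_min_len_s: float = Field(1.0, gt=0)
    amplitude_reject_uv: float | None = None


class BorutaModel(_Model):
    max_iter: int = Field(30, ge=1)
    alpha: float = Field(0.01, gt=0.0, lt=0.5)
    rf_trees: int = Field(50, ge=10)
    importance: str = "oob_permutation"


class VarSelRFModel(_Model):
    drop_fraction: float = Field(0.2, gt=0.0, lt=1.0)
    initial_trees: int = Field(200, ge=10)
    iter_trees: int = Field(200, ge=10)
    importance: str = "oob_permutation"
    min_features: int = Field(2, ge=1)


class FeatureConfig(_Model):
    channels: list[str] | None = None  # None -> all 21


class SelectionModel(_Model):
    boruta: BorutaModel = Field(default_factory=BorutaModel)
    varselrf: VarSelRFModel = Field(default_factory=VarSelRFModel)


class EvaluationModel(_Model):
    tasks: list[str] = Field(default_factory=lambda: ["intent", "scenario_type"])
    selectors: list[str] = Field(default_factory=lambda: ["varselrf", "boruta"])
    classifiers: list[str] = Field(default_factory=lambda: ["knn", "svm_rbf", "nb", "mlp"])
    channel_subsets: dict[str, list[str]] = Field(default_factory=dict)


class RunConfig(_Model):
    design: DesignConfig = Field(default_factory=DesignConfig)
    effects: EffectModel = Field(default_factory=EffectModel)
    recording: RecordingConfig = Field(default_factory=RecordingConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    selection: SelectionModel = Field(default_factory=SelectionModel)
    evaluation: EvaluationModel = Field(default_factory=EvaluationModel)

    # -- translated objects -------------------------------------------------
    def effect_spec(self) -> EffectSpec:
        a = self.effects.artifacts
        return EffectSpec(
            intent_effect=self.effects.intent_effect,
            scenario_effect=self.effects.scenario_effect,
            subject_variability=self.effects.subject_variability,
            artifacts=ArtifactConfig(**a.model_dump()),
        )

    def preprocess_params(self) -> PreprocessParams:
        p = self.preprocess
        return PreprocessParams(
            target_fs=p.target_fs,
            highpass_hz=p.highpass_hz,
            highpass_order=p.highpass_order,
            line_freq_hz=p.line_freq_hz,
            notch_bandwidth_hz=p.notch_bandwidth_hz,
            flat_variance_uv2=p.flat_variance_uv2,
            min_neighbor_corr=p.min_neighbor_corr,
            max_bad_fraction=p.max_bad_fraction,
        )

    def boruta_config(self) -> BorutaConfig:
        return BorutaConfig(**self.selection.boruta.model_dump())

    def varselrf_config(self) -> VarSelRFConfig:
        return VarSelRFConfig(**self.selection.varselrf.model_dump())

    def classifier_specs(self) -> dict:
        all_specs = default_classifiers()
        unknown = [c for c in self.evaluation.classifiers if c not in all_specs]
        if unknown:
            raise ValueError(f"unknown classifier(s) {unknown}; valid: {list(all_specs)}")
        return {c: all_specs[c] for c in self.evaluation.classifiers}

    def selector_names(self) -> dict:
        valid = ("none", "boruta", "varselrf")
        unknown = [s for s in self.evaluation.selectors if s not in valid]
        if unknown:
            raise ValueError(f"unknown selector(s) {unknown}; valid: {valid}")
        return {s: s for s in self.evaluation.selectors}


class ConfigError(ValueError):
    pass


def validate_config(path_or_dict) -> RunConfig:
    """Load and fully validate a run config; all defaults materialized.

    Unknown keys and out-of-range values produce aggregated per-field errors.
    """
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        p = Path(path_or_dict)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text()) or {}
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
        raise ConfigError("invalid run config:\n  " + "\n  ".join(lines)) from exc


# --------------------------------------------------------------- stages

def stage_simulate(config: RunConfig, seed: int, out: Path) -> Path:
    """Write design.csv and one recording (txt+json) per trial."""
    out = Path(out)
    design = make_design(
        n_subjects=config.design.n_subjects,
        n_insider=config.design.n_insider,
        n_conflict=config.design.n_conflict,
        yes_prob_by_type={
            "insider": config.design.yes_prob_insider,
            "conflict": config.design.yes_prob_conflict,
        },
        dropout_prob=config.design.dropout_prob,
        seed=seed,
    )
    eio.save_design(design, out / "design.csv")
    rec_dir = out / "recordings"
    for rec in synthesize_experiment(
        design, config.effect_spec(), seed,
        fs=config.recording.fs, duration=config.recording.duration_s,
    ):
        eio.save_recording(rec, rec_dir)
    return out


def _features_from_recordings(config: RunConfig, recordings) -> tuple[pd.DataFrame, list[dict]]:
    params = config.preprocess_params()
    p = config.preprocess
    epochs = []
    logs: list[dict] = []
    for raw in recordings:
        if not raw.responded:
            logs.append({"subject": raw.subject, "question": raw.question,
                         "status": "excluded_no_response"})
            continue
        try:
            clean = preprocess_recording(raw, params)
        except RecordingRejectedError as exc:
            logs.append({"subject": raw.subject, "question": raw.question,
                         "status": "rejected", "reason": str(exc)})
            continue
        logs.append({"subject": raw.subject, "question": raw.question,
                     "status": "ok", "log": clean.log,
                     "interpolated": clean.interpolated})
        epochs.extend(
            epoch_question(
                clean,
                window=p.epoch_window_s,
                step=p.epoch_step_s,
                min_len=p.epoch_min_len_s,
                amplitude_reject_uv=p.amplitude_reject_uv,
            )
        )
    table = extract_feature_table(epochs, channels=config.features.channels)
    return table, logs


def stage_preprocess_and_features(config: RunConfig, out: Path,
                                  recordings=None) -> pd.DataFrame:
    """Clean + epoch + extract features; writes features.csv and the log."""
    out = Path(out)
    if recordings is None:
        rec_dir = out / "recordings"
        paths = sorted(rec_dir.glob("*.txt"))
        recordings = (eio.load_recording(p) for p in paths)
    table, logs = _features_from_recordings(config, recordings)
    eio.save_feature_table(table, out / "features.csv")
    (out / "preprocess_log.json").write_text(json.dumps(logs, indent=1))
    return table


def stage_select(config: RunConfig, seed: int, out: Path, task: str,
                 table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Exploratory per-subject selection on a full feature table (no CV)."""
    from eegintent.features import feature_columns

    out = Path(out)
    task = normalize_task(task)
    if table is None:
        table = eio.load_feature_table(out / "features.csv")
    tbl = table if task != "intent" else table[table["scenario_type"] == "insider"]
    label_col = "answer" if task == "intent" else "scenario_type"
    frames = []
    for si, subject in enumerate(sorted(tbl["subject"].unique())):
        sub = tbl[tbl["subject"] == subject]
        y = sub[label_col].to_numpy()
        if len(np.unique(y)) < 2:
            continue
        X = sub[feature_columns(sub)]
        dec = boruta_select(X, y, config.boruta_config(), child_seed(seed, 11, si))
        bdf = dec.to_frame()
        bdf.insert(0, "subject", subject)
        bdf.insert(1, "selector", "boruta")
        vsel = set(varselrf_select(X, y, config.varselrf_config(), child_seed(seed, 12, si)))
        vdf = pd.DataFrame({
            "subject": subject, "selector": "varselrf",
            "feature": list(X.columns),
            "status": ["confirmed" if c in vsel else "rejected" for c in X.columns],
            "median_importance": np.nan,
        })
        frames.append(bdf)
        frames.append(vdf)
    result = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["subject", "selector", "feature", "status", "median_importance"])
    result.to_csv(out / f"selection_{task}.csv", index=False, float_format=_FLOAT_FMT)
    return result


def stage_evaluate(config: RunConfig, seed: int, out: Path,
                   table: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Cross-validate every task/cell; write summary, prediction and ROC CSVs."""
    out = Path(out)
    if table is None:
        table = eio.load_feature_table(out / "features.csv")
    selectors = config.selector_names()
    classifiers = config.classifier_specs()
    summaries: dict[str, pd.DataFrame] = {}
    for task in config.evaluation.tasks:
        task = normalize_task(task)
        summary, results = evaluate_experiment(
            table, task, selectors, classifiers, seed,
            boruta_config=config.boruta_config(),
            varselrf_config=config.varselrf_config(),
        )
        summaries[task] = summary
        summary.to_csv(out / f"summary_{task}.csv", float_format=_FLOAT_FMT)
        _write_predictions(results, out / f"predictions_{task}.csv")
        _write_roc(results, task, out / f"roc_{task}.csv")
        for name, chans in config.evaluation.channel_subsets.items():
            chans = list(CHANNEL_SUBSETS.get(name, chans))
            sub_summary, _ = channel_subset_run(
                table, chans, task, selectors, classifiers, seed,
                boruta_config=config.boruta_config(),
                varselrf_config=config.varselrf_config(),
            )
            key = f"{task}_{name}"
            summaries[key] = sub_summary
            sub_summary.to_csv(out / f"summary_{key}.csv", float_format=_FLOAT_FMT)
    return summaries


def _write_predictions(results, path: Path) -> None:
    rows = []
    for (sn, cn), subject_results in sorted(results.items()):
        for r in subject_results:
            for p in r.predictions:
                rows.append({
                    "subject": r.subject, "task": r.task, "selector": sn,
                    "classifier": cn, "question": p.question, "true": p.true,
                    "pred": p.pred, "score": p.score, "n_epochs": p.n_epochs,
                    "n_selected": p.n_selected,
                })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_roc(results, task: str, path: Path) -> None:
    rows = []
    positive = POSITIVE[task]
    for (sn, cn), subject_results in sorted(results.items()):
        evaluable = [r for r in subject_results if r.predictions]
        if not evaluable:
            continue
        try:
            fpr, tpr, thr, auc_val = pooled_roc(evaluable, positive)
        except ValueError:
            continue
        for f, t, th in zip(fpr, tpr, thr):
            rows.append({"selector": sn, "classifier": cn, "fpr": f, "tpr": t,
                         "threshold": th, "auc": auc_val})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig, seed: int, out_dir,
                 save_recordings: bool = False) -> Path:
    """Execute all stages under one run directory and write the manifest.

    By default recordings stream through memory (only design.csv,
    features.csv, summaries, predictions, ROC points and the manifest are
    written); ``save_recordings=True`` additionally serializes every raw
    recording for stage-by-stage re-runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = make_design(
        n_subjects=config.design.n_subjects,
        n_insider=config.design.n_insider,
        n_conflict=config.design.n_conflict,
        yes_prob_by_type={
            "insider": config.design.yes_prob_insider,
            "conflict": config.design.yes_prob_conflict,
        },
        dropout_prob=config.design.dropout_prob,
        seed=seed,
    )
    eio.save_design(design, out / "design.csv")

    recordings = synthesize_experiment(
        design, config.effect_spec(), seed,
        fs=config.recording.fs, duration=config.recording.duration_s,
    )
    if save_recordings:
        recordings = list(recordings)
        for rec in recordings:
            eio.save_recording(rec, out / "recordings")

    table = stage_preprocess_and_features(config, out, recordings=recordings)
    summaries = stage_evaluate(config, seed, out, table=table)

    manifest = {
        "config": config.model_dump(),
        "seed": int(seed),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _versions() -> dict[str, str]:
    import sklearn

    import eegintent

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "eegintent": eegintent.__version__,
    }
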