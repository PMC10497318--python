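"""End-to-end experiment: simulate -> preprocess -> features -> train ->
evaluate -> cross-test, with a serializable report.

Two electrode "arms" are run by default, mirroring a wet-vs-dry electrode
comparison: an Ag/AgCl arm using all five time-domain features and a
conductive-elastomer (CE) arm using RMS/MAV/VAR, each with its own training
hyperparameters.  All subjects' segments are pooled into one dataset per
arm; the last trial of every movement is held out for testing and never
touches training or normalization.  Per-subject SNR is computed from the
raw (offset-removed, un-denoised) segments, so it characterizes the
recordings rather than the denoiser.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess
from .errors import ConfigurationError, SplitError
from .features import FeatureDataset, FEATURE_NAMES, compute_snr, extract, summarize
from .network import (
    EvaluationReport,
    NetworkModel,
    TrainConfig,
    cross_evaluate,
    evaluate,
    init_network,
    train,
)
from .protocol import (
    ELECTRODES,
    ActivationModel,
    ElectrodeProfile,
    ProtocolConfig,
    activation_from_dict,
    electrode_from_dict,
    protocol_from_dict,
)
from .simulate import generate_session


@dataclass
class ArmConfig:
    """One electrode arm: which electrode, which features, how to train."""

    name: str
    electrode: str
    features: tuple[str, ...]
    train: TrainConfig


@dataclass
class ExperimentConfig:
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    activation: ActivationModel = field(default_factory=ActivationModel)
    electrodes: dict[str, ElectrodeProfile] = field(
        default_factory=lambda: dict(ELECTRODES)
    )
    subjects: tuple[tuple[str, int], ...] = ()
    arms: tuple[ArmConfig, ...] = ()
    wavelet: str = "db1"
    denoise_level: int | None = None
    trim: float = 0.0
    cross_norm_source: str = "model"

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ConfigurationError("at least one subject is required")
        for arm in self.arms:
            if arm.electrode not in self.electrodes:
                raise ConfigurationError(
                    f"arm {arm.name!r} references undefined electrode "
                    f"{arm.electrode!r}"
                )


def default_experiment(
    n_subjects: int = 4, master_seed: int = 0, protocol: ProtocolConfig | None = None
) -> ExperimentConfig:
    """Study-default experiment: 4 subjects, two arms with their published
    feature subsets and training hyperparameters."""
    protocol = protocol or ProtocolConfig()
    subjects = tuple(
        (f"S{i + 1}", (int(master_seed) * 1009 + i) % 2**31)
        for i in range(n_subjects)
    )
    arms = (
        ArmConfig(
            name="AgAgCl",
            electrode="AgAgCl",
            features=("RMS", "MAV", "VAR", "WL", "SD"),
            train=TrainConfig(
                learning_rate=0.01,
                batch_size=256,
                max_epochs=542,
                seed=(int(master_seed) * 1009 + 101) % 2**31,
            ),
        ),
        ArmConfig(
            name="CE",
            electrode="CE",
            features=("RMS", "MAV", "VAR"),
            train=TrainConfig(
                learning_rate=0.05,
                batch_size=128,
                max_epochs=180,
                seed=(int(master_seed) * 1009 + 202) % 2**31,
            ),
        ),
    )
    return ExperimentConfig(protocol=protocol, subjects=subjects, arms=arms)


def _config_fingerprint(config: ExperimentConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class _ArmData:
    full_train: FeatureDataset  # all five features, training trials
    full_test: FeatureDataset  # all five features, held-out trial
    model: NetworkModel
    history: dict
    same_report: EvaluationReport
    snr_by_subject: dict[str, float]
    feature_summary: pd.DataFrame


def _prepare_arm(config: ExperimentConfig, arm: ArmConfig) -> _ArmData:
    protocol = config.protocol
    if protocol.trials_per_movement < 2:
        raise SplitError(
            "trial-wise split needs trials_per_movement >= 2: training and "
            "testing on the same single trial is refused"
        )
    electrode = config.electrodes[arm.electrode]
    processed_segments = []
    snr_by_subject: dict[str, float] = {}
    for subject_id, seed in config.subjects:
        trials = generate_session(
            protocol, config.activation, electrode, subject_id, seed
        )
        raw_segments = []
        for trial in trials:
            raw = preprocess.remove_offset(trial)
            raw_segments.extend(preprocess.splice(raw))
            clean = preprocess.remove_offset(
                preprocess.denoise(trial, wavelet=config.wavelet,
                                   level=config.denoise_level)
            )
            processed_segments.extend(preprocess.splice(clean, trim=config.trim))
        snr_by_subject[subject_id] = compute_snr(raw_segments).snr_db

    full = extract(processed_segments, feature_subset=FEATURE_NAMES)
    test_mask = full.df["trial"] == protocol.trials_per_movement
    full_train = full.subset_rows(~test_mask)
    full_test = full.subset_rows(test_mask)

    train_ds = full_train.select(features=arm.features)
    model = init_network(
        len(arm.features) * len(train_ds.channels), seed=arm.train.seed
    )
    model.train_electrode = arm.electrode
    model, history = train(model, train_ds, arm.train)
    same_report = evaluate(
        model,
        full_test.select(features=arm.features),
        provenance=(arm.electrode, arm.electrode),
    )
    return _ArmData(
        full_train=full_train,
        full_test=full_test,
        model=model,
        history=history,
        same_report=same_report,
        snr_by_subject=snr_by_subject,
        feature_summary=summarize(
            FeatureDataset(
                df=pd.concat([full_train.df, full_test.df], ignore_index=True),
                feature_names=full.feature_names,
                channels=full.channels,
            ),
            channel=1,
        ),
    )


def run(config: ExperimentConfig) -> dict:
    """Execute the full experiment; deterministic given the config seeds.

    Returns a JSON-serializable report with per-arm training/validation/test
    accuracy, confusion matrices, per-subject SNR and a feature summary
    table, plus both cross-electrode evaluations.
    """
    arms: dict[str, _ArmData] = {}
    for arm in config.arms:
        arms[arm.name] = _prepare_arm(config, arm)

    report: dict = {
        "config_hash": _config_fingerprint(config),
        "subjects": [list(s) for s in config.subjects],
        "arms": {},
        "cross": {},
    }
    for arm in config.arms:
        data = arms[arm.name]
        hist = data.history
        report["arms"][arm.name] = {
            "electrode": arm.electrode,
            "features": list(arm.features),
            "training_accuracy": hist["final_train_accuracy"],
            "validation_accuracy": hist["best_val_accuracy"],
            "testing_accuracy": data.same_report.accuracy,
            "best_epoch": hist["best_epoch"],
            "evaluation": data.same_report.to_dict(),
            "snr_db_by_subject": data.snr_by_subject,
            "snr_db_mean": float(np.mean(list(data.snr_by_subject.values()))),
            "feature_summary": data.feature_summary.to_dict(orient="records"),
            "n_train": data.full_train.n,
            "n_test": data.full_test.n,
        }
    for arm_model in config.arms:
        for arm_data in config.arms:
            if arm_model.name == arm_data.name:
                continue
            rep = cross_evaluate(
                arms[arm_model.name].model,
                arms[arm_data.name].full_test,
                norm_source=config.cross_norm_source,
                provenance=(arm_model.electrode, arm_data.electrode),
            )
            key = f"{arm_data.name}_data_on_{arm_model.name}_model"
            report["cross"][key] = rep.to_dict()
    return report


def measure_session_snr(
    protocol: ProtocolConfig,
    activation: ActivationModel,
    electrode: ElectrodeProfile,
    seeds,
) -> list[float]:
    """Measured SNR (dB) of one generated session per seed.

    Sessions are offset-removed and spliced, then the contraction/rest power
    ratio is computed; no denoising, so the value characterizes the raw
    recording quality the generator is calibrated to.
    """
    out = []
    for seed in seeds:
        segments = []
        for trial in generate_session(protocol, activation, electrode, "S1", seed):
            segments.extend(preprocess.splice(preprocess.remove_offset(trial)))
        out.append(compute_snr(segments).snr_db)
    return out


# -- rendering / persistence --------------------------------------------------

def _pct(x: float) -> str:
    return f"{100.0 * x:.2f}%"


def _render_confusion(block: dict) -> list[str]:
    labels = block["class_labels"]
    width = max(len(l) for l in labels) + 2
    lines = [" " * width + "".join(f"{l:>{width}}" for l in labels)]
    for lab, row in zip(labels, block["confusion"]):
        lines.append(f"{lab:>{width}}" + "".join(f"{v:>{width}}" for v in row))
    return lines


def report_render(report: dict) -> str:
    """Human-readable text summary; presentation only, the JSON is the record."""
    lines: list[str] = []
    for name, arm in report.get("arms", {}).items():
        lines.append(f"=== Arm {name} (electrode {arm['electrode']}) ===")
        lines.append(f"features: {', '.join(arm['features'])}")
        lines.append(
            "accuracy  train "
            + _pct(arm["training_accuracy"])
            + "  validation "
            + _pct(arm["validation_accuracy"])
            + "  test "
            + _pct(arm["testing_accuracy"])
        )
        snrs = "  ".join(
            f"{s}: {v:.1f} dB" for s, v in arm["snr_db_by_subject"].items()
        )
        lines.append(f"SNR per subject: {snrs} (mean {arm['snr_db_mean']:.1f} dB)")
        lines.append("confusion (rows = true):")
        lines.extend(_render_confusion(arm["evaluation"]))
        lines.append("")
    cross = report.get("cross", {})
    if cross:
        lines.append("=== Cross-electrode testing ===")
        for key, block in cross.items():
            lines.append(f"{key}: accuracy {_pct(block['accuracy'])}")
            lines.extend(_render_confusion(block))
            lines.append("")
    else:
        lines.append("warning: no cross-electrode results in report")
    return "\n".join(lines)


def save_report(report: dict, directory) -> Path:
    """Write report.json plus CSV side-files (confusion matrices, feature
    table, SNR table)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "report.json").write_text(json.dumps(report, indent=2))
    snr_rows = []
    feat_rows = []
    for name, arm in report.get("arms", {}).items():
        labels = arm["evaluation"]["class_labels"]
        pd.DataFrame(
            arm["evaluation"]["confusion"], index=labels, columns=labels
        ).to_csv(directory / f"confusion_{name}.csv")
        for subject, v in arm["snr_db_by_subject"].items():
            snr_rows.append({"arm": name, "subject": subject, "snr_db": v})
        for rec in arm["feature_summary"]:
            feat_rows.append({"arm": name, **rec})
    for key, block in report.get("cross", {}).items():
        labels = block["class_labels"]
        pd.DataFrame(block["confusion"], index=labels, columns=labels).to_csv(
            directory / f"confusion_{key}.csv"
        )
    if snr_rows:
        pd.DataFrame(snr_rows).to_csv(directory / "snr.csv", index=False)
    if feat_rows:
        pd.DataFrame(feat_rows).to_csv(directory / "features_table.csv", index=False)
    (directory / "report.txt").write_text(report_render(report))
    return directory / "report.json"


def experiment_from_yaml(path, master_seed: int = 0) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML mapping, falling back to study
    defaults for anything unspecified."""
    from .protocol import load_yaml

    data = load_yaml(path)
    base = default_experiment(master_seed=master_seed)
    protocol = (
        protocol_from_dict(data["protocol"]) if "protocol" in data else base.protocol
    )
    activation = (
        activation_from_dict(data["activation"])
        if "activation" in data
        else base.activation
    )
    electrodes = dict(ELECTRODES)
    for name, spec in (data.get("electrodes") or {}).items():
        electrodes[name] = electrode_from_dict({"name": name, **spec})
    if "subjects" in data:
        subjects = tuple(
            (str(s["id"]), int(s["seed"])) for s in data["subjects"]
        )
    else:
        subjects = base.subjects
    if "arms" in data:
        arms = tuple(
            ArmConfig(
                name=str(a["name"]),
                electrode=str(a.get("electrode", a["name"])),
                features=tuple(a.get("features", FEATURE_NAMES)),
                train=TrainConfig(**a.get("train", {})),
            )
            for a in data["arms"]
        )
    else:
        arms = base.arms
    return ExperimentConfig(
        protocol=protocol,
        activation=activation,
        electrodes=electrodes,
        subjects=subjects,
        arms=arms,
        wavelet=data.get("wavelet", "db1"),
        denoise_level=data.get("denoise_level"),
        trim=float(data.get("trim", 0.0)),
        cross_norm_source=data.get("cross_norm_source", "model"),
    )
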