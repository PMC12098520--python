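"""End-to-end experiment orchestration.

``run_experiment`` wires synthetic generation → preprocessing →
leave-one-subject-out adversarial training → evaluation into one
reproducible run: every stage draws its randomness from the experiment
seed, the resolved configuration is written next to the outputs, and
each fold leaves a JSON report plus a training-history log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import preprocess as pp
from . import synthetic as syn
from . import training as tr
from .evaluation import (EvalReport, aggregate_folds, bootstrap_ci,
                         evaluate_predictions)
from .network import ConfigurationError

logger = logging.getLogger(__name__)

_ALLOWED_SECTIONS = {"seed", "cohort", "preprocess", "model", "training",
                     "evaluation"}
_ALLOWED_KEYS = {
    "cohort": {"n_subjects", "epochs_per_subject", "stage_distribution",
               "fs", "shift_magnitude"},
    "preprocess": {"size"},
    "model": {"encoder_widths", "decoder_channels", "gru_hidden",
              "head_hidden", "use_se", "use_discriminator", "lambda",
              "lambda_schedule"},
    "training": {"epochs", "batch_size", "learning_rate"},
    "evaluation": {"bootstrap_b", "level"},
}


@dataclass
class ExperimentConfig:
    """Validated experiment configuration (YAML round-trippable)."""

    seed: int = 0
    cohort: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        unknown = set(raw) - _ALLOWED_SECTIONS
        if unknown:
            raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
        for section, allowed in _ALLOWED_KEYS.items():
            bad = set(raw.get(section, {})) - allowed
            if bad:
                raise ConfigurationError(
                    f"unknown keys in [{section}]: {sorted(bad)} "
                    f"(allowed: {sorted(allowed)})")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    # -- resolved pieces -------------------------------------------------
    def cohort_config(self) -> syn.SyntheticCohortConfig:
        c = dict(self.cohort)
        c.setdefault("master_seed", self.seed)
        if "stage_distribution" in c:
            c["stage_distribution"] = tuple(c["stage_distribution"])
        return syn.SyntheticCohortConfig(**c)

    @property
    def tensor_size(self) -> int:
        return int(self.preprocess.get("size", 128))

    def stager_kwargs(self) -> dict:
        m, t = dict(self.model), dict(self.training)
        kwargs = {"input_size": self.tensor_size, "seed": self.seed}
        if "encoder_widths" in m:
            kwargs["encoder_widths"] = tuple(m["encoder_widths"])
        if "head_hidden" in m:
            kwargs["head_hidden"] = tuple(m["head_hidden"])
        for src, dst in (("decoder_channels", "decoder_channels"),
                         ("gru_hidden", "gru_hidden"),
                         ("use_se", "use_se"),
                         ("use_discriminator", "use_discriminator"),
                         ("lambda", "lambda_"),
                         ("lambda_schedule", "lambda_schedule")):
            if src in m:
                kwargs[dst] = m[src]
        for key in ("epochs", "batch_size", "learning_rate"):
            if key in t:
                kwargs[key] = t[key]
        return kwargs


def preprocess_cohort(recordings: list[syn.RawRecording], size: int
                      ) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Un-normalized tensors and integer labels keyed by subject."""
    tensors, labels = {}, {}
    for rec in recordings:
        eps = pp.recording_to_epochs(rec, size=size)
        tensors[rec.subject_id] = np.stack([e.tensor for e in eps]
                                           ).astype(np.float32)
        labels[rec.subject_id] = np.asarray([e.stage_label for e in eps])
    return tensors, labels


def run_fold(fold: tr.FoldSpec, tensors, labels, config: ExperimentConfig
             ) -> tuple[EvalReport, dict, tuple[np.ndarray, np.ndarray]]:
    """Train and evaluate one LOSO fold with leakage-free normalization."""
    ds = tr.build_domain_dataset(fold, tensors, labels)
    x_train, x_test, _ = pp.normalize_dataset(ds.x_train, ds.x_test)
    ds = tr.DomainDataset(x_train, ds.y_train, ds.d_train, x_test, ds.y_test)
    model, history = tr.train_fold(fold, ds, **config.stager_kwargs())
    y_pred = model.predict(ds.x_test)
    ev = config.evaluation
    report = evaluate_predictions(
        ds.y_test, y_pred, bootstrap=True,
        B=int(ev.get("bootstrap_b", 1000)),
        level=float(ev.get("level", 0.95)), seed=config.seed)
    return report, history, (ds.y_test, y_pred)


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Full pipeline; writes reports/configs/logs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    cohort_cfg = config.cohort_config()
    logger.info("generating %d-subject synthetic cohort", cohort_cfg.n_subjects)
    recordings = syn.generate_cohort(cohort_cfg)
    logger.info("preprocessing to %dx%d tensors", config.tensor_size,
                config.tensor_size)
    tensors, labels = preprocess_cohort(recordings, config.tensor_size)

    folds = tr.loso_folds(list(tensors), seed=config.seed)
    reports, pooled_true, pooled_pred = [], [], []
    for fold in folds:
        logger.info("fold %d: test subject %d", fold.fold_index,
                    fold.test_subject)
        report, history, (y_true, y_pred) = run_fold(fold, tensors, labels,
                                                     config)
        report.save(out / f"fold_{fold.fold_index}_report.json")
        with open(out / f"fold_{fold.fold_index}_history.jsonl", "w") as fh:
            for i in range(len(history["l_cla"])):
                fh.write(json.dumps({k: history[k][i] for k in history}) + "\n")
        reports.append(report)
        pooled_true.append(y_true)
        pooled_pred.append(y_pred)

    summary = aggregate_folds(reports)
    ev = config.evaluation
    summary.ci = bootstrap_ci(
        np.concatenate(pooled_true), np.concatenate(pooled_pred),
        B=int(ev.get("bootstrap_b", 1000)),
        level=float(ev.get("level", 0.95)), seed=config.seed)
    summary.ci_level = float(ev.get("level", 0.95))
    summary.ci_b = int(ev.get("bootstrap_b", 1000))
    summary_dict = summary.to_dict()
    summary_dict["seed"] = config.seed
    summary_dict["n_folds"] = len(reports)
    (out / "summary.json").write_text(json.dumps(summary_dict, indent=2))
    logger.info("mean accuracy %.4f, macro-F1 %.4f, kappa %.4f",
                summary.accuracy, summary.macro_f1, summary.kappa)
    return summary_dict
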