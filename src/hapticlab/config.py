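"""YAML run configuration.

A single configuration object seeds every randomized stage, so two runs
from the same file are byte-identical.  Blocks: ``device`` (belt model),
``conditions`` (profile overrides), ``cohort`` (subjects, trials, subject
and synergy-ground-truth parameters), ``analysis`` (filter, SPARC, CCI,
NNMF and significance settings) and a top-level ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import SubjectParams, SynergyGroundTruth, TaskReference
from .device import DeviceModel

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


@dataclass
class CohortConfig:
    n_subjects: int = 9
    n_trials_per_condition: int = 2
    repetitions: int = 5
    mvc: float = 1.0
    subject: SubjectParams = field(default_factory=SubjectParams)
    reference: TaskReference = field(default_factory=TaskReference)


@dataclass
class AnalysisConfig:
    emg_band: tuple = (30.0, 450.0)
    emg_lowpass: float = 6.0
    median_window_s: float = 0.4
    cci_variant: str = "falconer_winter"
    sparc_fc_max: float = 20.0
    sparc_amp_threshold: float = 0.05
    nmf_k_max: int = 6
    nmf_restarts: int = 20
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    nmf_fs: float = 500.0
    vaf_threshold: float = 0.90
    slope_threshold: float = 0.001
    gate_alpha: float = 0.05
    effect_variant: str = "pooled"


@dataclass
class RunConfig:
    seed: int = 0
    device: DeviceModel = field(default_factory=DeviceModel.from_step_characterization)
    condition_overrides: dict = field(default_factory=dict)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    synergy_truth: SynergyGroundTruth = field(default_factory=SynergyGroundTruth)


def _build(cls, data: dict, path: str):
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML (missing blocks take defaults)."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    if overrides:
        data = {**data, **overrides}

    cfg = RunConfig()
    known = {"seed", "device", "conditions", "cohort", "analysis", "synergy_truth"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"top level: unknown keys {sorted(unknown)}")

    if "seed" in data:
        cfg.seed = int(data["seed"])
    if "device" in data:
        cfg.device = _build(DeviceModel, data["device"], "device")
    if "conditions" in data:
        if not isinstance(data["conditions"], dict):
            raise ConfigError("conditions: expected a mapping of overrides")
        cfg.condition_overrides = data["conditions"]
    if "cohort" in data:
        block = dict(data["cohort"])
        if "subject" in block:
            block["subject"] = _build(SubjectParams, block["subject"], "cohort.subject")
        if "reference" in block:
            ref = dict(block["reference"])
            if "phase_durations" in ref:
                ref["phase_durations"] = tuple(ref["phase_durations"])
            block["reference"] = _build(TaskReference, ref, "cohort.reference")
        cfg.cohort = _build(CohortConfig, block, "cohort")
    if "analysis" in data:
        block = dict(data["analysis"])
        if "emg_band" in block:
            block["emg_band"] = tuple(block["emg_band"])
        cfg.analysis = _build(AnalysisConfig, block, "analysis")
    if "synergy_truth" in data:
        block = dict(data["synergy_truth"])
        for key in ("W_true", "phase_levels"):
            if key in block:
                block[key] = np.asarray(block[key], dtype=float)
        cfg.synergy_truth = _build(SynergyGroundTruth, block, "synergy_truth")
    return cfg
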