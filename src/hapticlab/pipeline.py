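"""End-to-end experiment driver: simulate -> metrics -> synergies -> stats.

Functions here glue the generator, the per-phase metrics, the synergy
extraction and the statistics battery into the reproducible pipeline the
command-line interface exposes.  Everything is seeded through the
:class:`~hapticlab.config.RunConfig`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .cohort import FS_EMG, TrialData, generate_pose_trace, iter_session_trials
from .config import RunConfig
from .conditions import CONDITION_NAMES
from .metrics import (
    EnvelopeRecording,
    aggregate_metrics,
    preprocess_emg,
    segment_phases,
    time_to_bounded_error,
    trial_phase_metrics,
)
from .stats import StatReport, default_plans, run_battery
from .synergy import (
    compare_synergies,
    extract_synergies,
    reorder_synergies,
    select_synergy_count,
    vaf_curve,
)

logger = logging.getLogger(__name__)

__all__ = [
    "simulate_session",
    "analyze_trials",
    "analyze_directory",
    "cohort_synergy_analysis",
    "guided_settling_times",
    "AnalysisResult",
]


def simulate_session(config: RunConfig, out_dir, overwrite: bool = False) -> Path:
    """Write the full synthetic session described by ``config``."""
    from .cohort import generate_session

    return generate_session(
        out_dir,
        n_subjects=config.cohort.n_subjects,
        n_trials_per_condition=config.cohort.n_trials_per_condition,
        master_seed=config.seed,
        overwrite=overwrite,
        ref=config.cohort.reference,
        subj=config.cohort.subject,
        truth=config.synergy_truth,
        mvc=config.cohort.mvc,
        repetitions=config.cohort.repetitions,
    )


@dataclass
class AnalysisResult:
    metrics: pd.DataFrame
    report: StatReport
    synergy: dict = field(default_factory=dict)
    skipped_trials: list = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False, float_format="%.9g")
        self.report.to_csv(out)
        summary = self.report.summary_json()
        summary["skipped_trials"] = self.skipped_trials
        if self.synergy:
            summary["synergy"] = {
                cond: {
                    "k_selected": res["k_selected"],
                    "median_vaf_curve": [round(v, 6) for v in res["median_vaf"]],
                }
                for cond, res in self.synergy["per_condition"].items()
            }
            self._write_synergy(out)
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    def _write_synergy(self, out: Path) -> None:
        rows = []
        for cond, res in self.synergy["per_condition"].items():
            for s in res["sets"]:
                for j in range(s.k):
                    for m, w in zip(s.muscles, s.W[:, j]):
                        rows.append(
                            {"condition": cond, "subject": s.subject_id,
                             "synergy": j + 1, "muscle": m, "weight": w}
                        )
        pd.DataFrame(rows).to_csv(
            out / "synergy_weights.csv", index=False, float_format="%.9g"
        )
        sim_rows = []
        for cond, sim in self.synergy.get("similarity", {}).items():
            for j in range(len(sim.median_r)):
                sim_rows.append(
                    {"condition": cond, "synergy": j + 1,
                     "median_r": sim.median_r[j], "median_p": sim.median_p[j]}
                )
        if sim_rows:
            pd.DataFrame(sim_rows).to_csv(
                out / "synergy_similarity.csv", index=False, float_format="%.9g"
            )


def _trial_envelope(trial: TrialData, mvc, config: RunConfig) -> EnvelopeRecording | None:
    if not len(trial.emg_time):
        return None
    a = config.analysis
    return preprocess_emg(
        trial.emg, mvc, FS_EMG,
        band=a.emg_band, lowpass=a.emg_lowpass, median_window_s=a.median_window_s,
    )


def analyze_trials(trials, config: RunConfig, with_synergy: bool = True) -> AnalysisResult:
    """Run metrics + synergies + statistics over an iterable of trials."""
    a = config.analysis
    frames = []
    skipped = []
    envelopes: dict[tuple, list] = {}
    for trial in trials:
        try:
            table = segment_phases(
                trial.events, rest_duration=trial.reference.phase_durations[-1]
            )
            env = _trial_envelope(trial, config.cohort.mvc, config)
            frame = trial_phase_metrics(
                trial, env, table, cci_variant=a.cci_variant,
                sparc_params={"fc_max": a.sparc_fc_max,
                              "amp_threshold": a.sparc_amp_threshold},
            )
        except Exception as exc:  # a corrupt trial must not kill the run
            logger.warning(
                "skipping subject %s trial %s: %s",
                trial.subject_id, trial.trial_id, exc,
            )
            skipped.append(
                {"subject": trial.subject_id, "trial": trial.trial_id,
                 "reason": str(exc)}
            )
            continue
        frames.append(frame)
        if env is not None:
            envelopes.setdefault((trial.subject_id, trial.condition), []).append(env)
    if not frames:
        raise RuntimeError("all trials were skipped; nothing to analyze")

    metrics = aggregate_metrics(frames)
    report = run_battery(
        metrics, default_plans(), gate_alpha=a.gate_alpha,
        effect_variant=a.effect_variant,
    )
    synergy = (
        cohort_synergy_analysis(envelopes, config) if (with_synergy and envelopes) else {}
    )
    return AnalysisResult(metrics, report, synergy, skipped)


def analyze_directory(data_dir, config: RunConfig, with_synergy: bool = True) -> AnalysisResult:
    """Load a written session and analyze it."""
    manifest = hio.read_manifest(data_dir)

    def trials():
        for entry in manifest["trials"]:
            try:
                yield hio.read_trial(data_dir, entry)
            except Exception as exc:
                logger.warning(
                    "skipping unreadable trial %s/%s: %s",
                    entry["subject"], entry["trial"], exc,
                )

    return analyze_trials(trials(), config, with_synergy)


def _concat_envelopes(env_list) -> EnvelopeRecording:
    x = np.vstack([e.envelopes for e in env_list])
    return EnvelopeRecording(x, env_list[0].fs, env_list[0].muscles)


def cohort_synergy_analysis(envelopes: dict, config: RunConfig) -> dict:
    """Cohort-wide synergy extraction, order selection and NH comparison.

    ``envelopes`` maps (subject, condition) to a list of per-trial
    envelope recordings (concatenated per subject before factorization).
    Per condition: per-subject VAF curves, the synergy count selected on
    the across-subject median curve, refits at that count, reordering
    against a seeded reference subject, and Pearson similarity against the
    no-haptics baseline.
    """
    a = config.analysis
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E]))
    conditions = sorted({cond for _, cond in envelopes})
    per_condition: dict = {}
    for cond in conditions:
        subjects = sorted(s for s, c in envelopes if c == cond)
        curves, sets_by_subject = [], {}
        for subject in subjects:
            env = _concat_envelopes(envelopes[(subject, cond)])
            curve, _ = vaf_curve(
                env, a.nmf_k_max, a.nmf_restarts,
                seed=int(rng.integers(0, 2**31 - 1)),
                max_iter=a.nmf_max_iter, tol=a.nmf_tol, fs_nmf=a.nmf_fs,
            )
            curves.append(curve)
            sets_by_subject[subject] = env
        median_curve = np.median(np.vstack(curves), axis=0)
        k_sel = select_synergy_count(
            median_curve, a.vaf_threshold, a.slope_threshold
        )
        sets = []
        for subject in subjects:
            s = extract_synergies(
                sets_by_subject[subject], k_sel, a.nmf_restarts,
                seed=int(rng.integers(0, 2**31 - 1)),
                max_iter=a.nmf_max_iter, tol=a.nmf_tol, fs_nmf=a.nmf_fs,
            )
            s.subject_id, s.condition = subject, cond
            sets.append(s)
        sets, ref_idx = reorder_synergies(
            sets, seed=int(rng.integers(0, 2**31 - 1))
        )
        per_condition[cond] = {
            "subjects": subjects, "curves": curves,
            "median_vaf": list(map(float, median_curve)),
            "k_selected": int(k_sel), "sets": sets, "reference_index": ref_idx,
        }

    similarity = {}
    if "NH" in per_condition:
        base = per_condition["NH"]["sets"]
        for cond in conditions:
            if cond == "NH":
                continue
            cond_sets = per_condition[cond]["sets"]
            if len(cond_sets) == len(base):
                similarity[cond] = compare_synergies(cond_sets, base)
    return {"per_condition": per_condition, "similarity": similarity}


def guided_settling_times(
    config: RunConfig,
    condition: str,
    n_subjects: int | None = None,
    error_fraction: float = 0.1,
) -> tuple[float, np.ndarray]:
    """Settle time of the cohort-median pose-error transient.

    For the grasp conditions the transient is measured from the start of
    phase 2 (feedback onset after the grab) against the grasp reference;
    for the pronosupination conditions from the start of phase 3 (pouring)
    against the reference pouring angle.  All repetitions of all subjects
    are aligned to guidance onset, the across-trace median of |error| is
    taken per time point, and the reported value is the first time after
    which that median curve stays within ``error_fraction`` of the
    reference until the end of the phase (``nan`` if it never does --
    typical without the vibrotactile component).

    Returns ``(settle_time_s, per_subject_settle_times)``; the per-subject
    vector applies the same rule to each subject's own rep-median curve.
    """
    t_rel, median_curve, reference, per_subject_curves = _error_transients(
        config, condition, n_subjects
    )
    bound = error_fraction * reference
    tau = time_to_bounded_error(t_rel, median_curve, bound)
    per_subject = np.array(
        [time_to_bounded_error(t_rel, c, bound) for c in per_subject_curves]
    )
    return float(tau), per_subject


def _error_transients(
    config: RunConfig, condition: str, n_subjects: int | None = None
):
    """Onset-aligned |pose error| transients of the guided DoF.

    Returns ``(t_rel, cohort_median_curve, reference, per_subject_curves)``.
    """
    from .conditions import condition_task

    task = condition_task(condition)
    if task is None:
        raise ValueError("transients are defined for guided conditions only")
    ref = config.cohort.reference
    subj = config.cohort.subject
    n_subjects = n_subjects or config.cohort.n_subjects
    onset_phase = 2 if task == "grasp" else 3
    reference = ref.grasp_ref if task == "grasp" else ref.pronation_ref
    duration = ref.phase_durations[onset_phase - 1]
    n_rel = int(round(duration * 100.0))

    per_subject_curves = []
    for s in range(1, n_subjects + 1):
        seed = np.random.SeedSequence([config.seed, s, 0x7A])
        t, grasp, pron, phase, events = generate_pose_trace(
            condition, ref, subj, seed, config.cohort.repetitions
        )
        signal_ = grasp if task == "grasp" else pron
        segs = []
        for ev in events:
            onset = ev[list(ev)[onset_phase - 1]]
            i0 = int(round(onset * 100.0))
            seg = np.abs(signal_[i0 : i0 + n_rel] - reference)
            if len(seg) == n_rel:
                segs.append(seg)
        per_subject_curves.append(np.median(np.vstack(segs), axis=0))
    per_subject_curves = np.vstack(per_subject_curves)
    t_rel = np.arange(n_rel) / 100.0
    return t_rel, np.median(per_subject_curves, axis=0), reference, per_subject_curves


def median_error_transient(
    config: RunConfig, condition: str, n_subjects: int | None = None
):
    """Across-subject median |pose error| aligned to guidance onset.

    Returns ``(t_rel, median_abs_error, reference)`` -- the desk-scale
    analogue of the study's averaged transient figures.
    """
    t_rel, curve, reference, _ = _error_transients(config, condition, n_subjects)
    return t_rel, curve, reference
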