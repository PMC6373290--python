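"""End-to-end orchestration: trials in, result tables out.

Stages: despike -> low-pass filter -> movement segmentation -> exclusion
rules -> imitator wrist/digit kinematics -> actor-imitator correspondence ->
participant x condition cell means -> repeated-measures ANOVAs and paired
contrasts.  Preprocessing and kinematic extraction never read the condition
labels (they are attached only when rows are tabulated), so relabelling
conditions cannot change any per-trial measurement.

Any stage error on a single trial excludes that trial with reason
``pipeline_error``; the run aborts only on configuration or I/O errors.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .correspondence import N_TRACKERS, score_trial
from .io_trials import (KINEMATIC_VARIABLES, TRACKER_LABELS, IntegrityError,
                        Trial, load_dataset, write_condition_table)
from .kinematics import (SegmentationConfig, digit_relative_pv,
                         extract_wrist_kinematics, segment_movement)
from .preprocess import (EXCLUSION_REASONS, PreprocessConfig,
                         apply_exclusions, preprocess_trial)
from .stats import StatError, bonferroni_gate, paired_t_grm, rm_anova_2x2x2

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(
        default_factory=SegmentationConfig)
    alpha: float = 0.05
    tracker_family: int = N_TRACKERS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            preprocess=PreprocessConfig(**raw.get("preprocess", {})),
            segmentation=SegmentationConfig(**raw.get("kinematics", {})),
            alpha=float(raw.get("alpha", 0.05)),
            tracker_family=int(raw.get("tracker_family", N_TRACKERS)),
        )


@dataclass
class PipelineResult:
    """Bundle of tidy result tables from one pipeline run."""

    trial_kinematics: pd.DataFrame
    correspondence: pd.DataFrame
    condition_means: pd.DataFrame
    correspondence_means: pd.DataFrame
    anova_kinematics: pd.DataFrame
    anova_correspondence: pd.DataFrame
    contrasts: pd.DataFrame
    exclusions: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.trial_kinematics.to_csv(out_dir / "trial_kinematics.csv",
                                     index=False)
        self.correspondence.to_csv(out_dir / "correspondence_trials.csv",
                                   index=False)
        if not self.condition_means.empty:
            write_condition_table(self.condition_means,
                                  out_dir / "condition_means.csv")
        else:
            self.condition_means.to_csv(out_dir / "condition_means.csv",
                                        index=False)
        self.correspondence_means.to_csv(
            out_dir / "correspondence_condition_means.csv", index=False)
        self.anova_kinematics.to_csv(out_dir / "anova_kinematics.csv",
                                     index=False)
        self.anova_correspondence.to_csv(
            out_dir / "anova_correspondence.csv", index=False)
        self.contrasts.to_csv(out_dir / "paired_contrasts.csv", index=False)
        self.exclusions.to_csv(out_dir / "exclusion_summary.csv", index=False)

    @property
    def retention_fraction(self) -> float:
        total = self.exclusions["n_trials"].sum()
        if total == 0:
            return float("nan")
        valid = self.exclusions.loc[
            self.exclusions["outcome"] == "valid", "n_trials"].sum()
        return float(valid / total)


CONDITION_KEYS = ["participant_id", "site", "meaning", "effector"]


def _kinematics_rows(trial: Trial, seg: SegmentationConfig) -> dict:
    summary = extract_wrist_kinematics(trial, "imitator", seg)
    digit = digit_relative_pv(trial, "imitator", seg,
                              window=(summary.onset_idx, summary.offset_idx))
    return {
        "participant_id": trial.participant_id,
        "session_index": trial.session_index,
        "site": trial.site, "meaning": trial.meaning,
        "effector": trial.effector, "gesture_id": trial.gesture_id,
        "role": "imitator",
        "MT": summary.mt_ms, "PV": summary.pv,
        "TPV_MT": summary.tpv_over_mt, "TPD_MT": summary.tpd_over_mt,
        "path_length": summary.path_length,
        "mean_digit_PV": np.nan if digit is None else digit,
        "onset_idx": summary.onset_idx, "offset_idx": summary.offset_idx,
    }


def condition_table(trial_kinematics: pd.DataFrame) -> pd.DataFrame:
    """Long participant x condition x variable cell-mean table."""
    if trial_kinematics.empty:
        return pd.DataFrame(columns=CONDITION_KEYS + ["variable", "cell_mean"])
    melted = trial_kinematics.melt(
        id_vars=CONDITION_KEYS, value_vars=list(KINEMATIC_VARIABLES),
        var_name="variable", value_name="value")
    out = (melted.groupby(CONDITION_KEYS + ["variable"], as_index=False)
           ["value"].mean().rename(columns={"value": "cell_mean"}))
    return out


def correspondence_condition_table(corr: pd.DataFrame) -> pd.DataFrame:
    """Mean Fisher Z and mean lag (ms) per participant, condition, tracker."""
    if corr.empty:
        return pd.DataFrame(columns=CONDITION_KEYS + [
            "tracker", "mean_Z", "mean_lag_ms", "n_trials"])
    grouped = corr.groupby(CONDITION_KEYS + ["tracker"], as_index=False).agg(
        mean_Z=("z_max", "mean"), mean_lag_ms=("lag_ms", "mean"),
        n_trials=("z_max", "size"))
    return grouped


def _anova_frame(table: pd.DataFrame, variables: Iterable[str],
                 alpha: float) -> pd.DataFrame:
    frames = []
    for variable in variables:
        try:
            res = rm_anova_2x2x2(table, variable)
        except (IntegrityError, StatError) as err:
            log.warning("ANOVA skipped for %s: %s", variable, err)
            continue
        frame = res.to_frame()
        frame["significant"] = bonferroni_gate(frame["p"], 1, alpha)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["variable", "effect", "F", "df_num",
                                     "df_den", "p", "partial_eta_sq",
                                     "significant"])
    return pd.concat(frames, ignore_index=True)


def paired_contrasts(table: pd.DataFrame, variable: str,
                     alpha_corrected: float = 0.05 / 8) -> pd.DataFrame:
    """The eight paired contrasts probing a site x meaning x effector
    interaction: site contrasts within each meaning x effector cell, and
    meaning contrasts within each site x effector cell, Bonferroni-gated."""
    sub = table[table["variable"] == variable]
    wide = sub.pivot_table(index="participant_id", values="cell_mean",
                           columns=["site", "meaning", "effector"])
    rows = []

    def run(label: str, a_key, b_key):
        if a_key not in wide.columns or b_key not in wide.columns:
            log.warning("contrast %s skipped: missing condition cell", label)
            return
        pair = wide[[a_key, b_key]].dropna()
        try:
            cmp_ = paired_t_grm(pair[a_key].to_numpy(),
                                pair[b_key].to_numpy(),
                                alpha_corrected=alpha_corrected)
        except StatError as err:
            log.warning("contrast %s skipped: %s", label, err)
            return
        rows.append({"variable": variable, "contrast": label, "t": cmp_.t,
                     "df": cmp_.df, "p": cmp_.p, "g_rm": cmp_.g_rm,
                     "alpha_corrected": alpha_corrected,
                     "significant": cmp_.significant})

    for meaning in ("meaningful", "meaningless"):
        for effector in ("hand", "finger"):
            run(f"pMTG-vs-vertex/{meaning}/{effector}",
                ("pMTG", meaning, effector), ("vertex", meaning, effector))
    for site in ("pMTG", "vertex"):
        for effector in ("hand", "finger"):
            run(f"meaningful-vs-meaningless/{site}/{effector}",
                (site, "meaningful", effector), (site, "meaningless", effector))
    return pd.DataFrame(rows)


def run_pipeline(trials: Iterable[Trial],
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis over an iterable of trials.

    Returns a :class:`PipelineResult`; also writes all tables as CSV when
    ``out_dir`` is given.  Stage counts are conserved:
    trials_in = trials_valid + sum of trials excluded by reason.
    """
    config = config or PipelineConfig()
    seg = config.segmentation

    def hook(speed, sample_rate):
        return segment_movement(speed, seg, sample_rate)

    kin_rows, corr_rows = [], []
    counts = {reason: 0 for reason in EXCLUSION_REASONS}
    n_total = n_valid = 0
    total_spikes = 0
    for trial in trials:
        n_total += 1
        try:
            clean, n_spikes = preprocess_trial(trial, config.preprocess)
            total_spikes += n_spikes
            checked = apply_exclusions(clean, config.preprocess, hook)
            if not checked.is_valid:
                counts[checked.exclusion_reason] += 1
                log.info("trial %s/%s excluded: %s", trial.participant_id,
                         trial.gesture_id, checked.exclusion_reason)
                continue
            kin_rows.append(_kinematics_rows(checked, seg))
            for res in score_trial(checked, seg):
                corr_rows.append({
                    "participant_id": trial.participant_id,
                    "session_index": trial.session_index,
                    "site": trial.site, "meaning": trial.meaning,
                    "effector": trial.effector,
                    "gesture_id": trial.gesture_id,
                    "tracker": res.tracker, "r_max": res.r_max,
                    "z_max": res.z_max, "lag_samples": res.lag_samples,
                    "lag_ms": res.lag_ms,
                })
            n_valid += 1
        except Exception as err:  # noqa: BLE001 — one bad trial never aborts
            counts["pipeline_error"] += 1
            log.warning("trial %s/%s failed (%s); excluded as pipeline_error",
                        trial.participant_id, trial.gesture_id, err)
    if n_total == 0:
        log.warning("empty dataset: no trials to analyse")

    trial_kin = pd.DataFrame(kin_rows)
    corr = pd.DataFrame(corr_rows)
    cond = condition_table(trial_kin)
    corr_cond = correspondence_condition_table(corr)

    anova_kin = _anova_frame(cond, KINEMATIC_VARIABLES, config.alpha)

    tracker_frames = []
    tracker_alpha = config.alpha / config.tracker_family
    for tracker in TRACKER_LABELS:
        sub = corr_cond[corr_cond["tracker"] == tracker]
        if sub.empty:
            continue
        long = sub.melt(id_vars=CONDITION_KEYS,
                        value_vars=["mean_Z", "mean_lag_ms"],
                        var_name="variable", value_name="cell_mean")
        frame = _anova_frame(long, ["mean_Z", "mean_lag_ms"], config.alpha)
        if frame.empty:
            continue
        frame.insert(0, "tracker", tracker)
        frame["alpha_corrected"] = tracker_alpha
        frame["significant"] = bonferroni_gate(frame["p"],
                                               config.tracker_family,
                                               config.alpha)
        tracker_frames.append(frame)
    anova_corr = (pd.concat(tracker_frames, ignore_index=True)
                  if tracker_frames else pd.DataFrame())

    contrasts = (paired_contrasts(cond, "PV",
                                  config.alpha / 8) if not cond.empty
                 else pd.DataFrame())

    excl_rows = [{"outcome": "valid", "n_trials": n_valid}]
    excl_rows += [{"outcome": reason, "n_trials": counts[reason]}
                  for reason in EXCLUSION_REASONS]
    exclusions = pd.DataFrame(excl_rows)
    exclusions["fraction"] = (exclusions["n_trials"] / n_total
                              if n_total else np.nan)
    retained_pct = 100.0 * n_valid / n_total if n_total else float("nan")
    log.info("%d/%d trials retained (%.1f%%); %d spike samples repaired",
             n_valid, n_total, retained_pct, total_spikes)

    result = PipelineResult(
        trial_kinematics=trial_kin, correspondence=corr,
        condition_means=cond, correspondence_means=corr_cond,
        anova_kinematics=anova_kin, anova_correspondence=anova_corr,
        contrasts=contrasts, exclusions=exclusions,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def run_pipeline_on_dir(data_dir: str | Path,
                        config: PipelineConfig | None = None,
                        out_dir: str | Path | None = None) -> PipelineResult:
    """Read canonical trial files from ``data_dir`` and run the pipeline."""
    return run_pipeline(load_dataset(data_dir), config, out_dir)
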