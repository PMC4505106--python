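"""End-to-end analysis: dataset directory -> preprocessing -> laterality ->
behavioral summary -> ANOVAs, Scheffé, moderated regression, simple slopes.

Mirrors the study's full analysis chain, including the error-trial control
(re-running the group x location ANOVA on all-correct participants only,
plus an accuracy x location ANOVA within the youngest group).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import hemodynamics as hemo
from . import inference as inf
from . import nirs_io
from .preprocess import GlobalComponentCriterion, preprocess_recording

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_full_analysis",
    "accuracy_location_anova",
]


def accuracy_location_anova(
    laterality: pd.DataFrame, group: str = "Low"
) -> inf.AnovaResult:
    """Control analysis: 2x2 mixed ANOVA of accuracy (all-correct vs
    some-errors) x location within one group, checking that error trials
    did not drive the laterality pattern."""
    sub = laterality[laterality.group == group].copy()
    sub["accuracy"] = np.where(
        sub.n_correct == sub.n_trials, "all_correct", "some_errors"
    )
    if sub.accuracy.nunique() < 2:
        raise ValueError(f"group {group} has only one accuracy stratum")
    sub = sub.rename(columns={"roi_right_mean": "right", "roi_left_mean": "left"})
    return inf.mixed_anova(sub, group_col="accuracy", within_cols=("right", "left"))


@dataclass
class AnalysisConfig:
    cutoff_hz: float = 0.05
    n_components: int = 16
    criterion: GlobalComponentCriterion = field(
        default_factory=GlobalComponentCriterion
    )
    dv_window: str = "last10"      # "last10" | "full-reverse"
    participant_filter: str = "none"  # "none" | "all-correct"
    run_ica: bool = True
    run_filter: bool = True
    seed: int = 0


@dataclass
class AnalysisReport:
    laterality: pd.DataFrame
    behavior_per_participant: pd.DataFrame
    behavior_per_group: pd.DataFrame
    anova_nirs: inf.AnovaResult
    anova_behavior_rt: inf.AnovaResult
    anova_correct: inf.AnovaResult
    scheffe_rt_reverse: inf.ScheffeResult
    scheffe_correct: inf.ScheffeResult
    simple_effects_nirs: dict[str, inf.AnovaResult]
    regression: inf.HierarchicalRegressionResult
    slopes: inf.SimpleSlopesResult
    component_reports: pd.DataFrame
    n_analyzed: int
    filter_applied: str

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.laterality.to_csv(out / "laterality.csv", index=False)
        self.behavior_per_participant.to_csv(
            out / "behavioral_per_participant.csv", index=False
        )
        self.behavior_per_group.to_csv(out / "behavioral_summary.csv", index=False)
        self.anova_nirs.to_frame().to_csv(out / "anova_nirs.csv", index=False)
        self.anova_behavior_rt.to_frame().to_csv(
            out / "anova_behavior.csv", index=False
        )
        self.anova_correct.to_frame().to_csv(out / "anova_correct.csv", index=False)
        self.scheffe_rt_reverse.contrasts.to_csv(out / "scheffe.csv", index=False)
        steps = []
        for i, s in enumerate(self.regression.steps, start=1):
            df = s.to_frame()
            df.insert(0, "step", i)
            df["r2"] = s.r2
            df["delta_r2"] = s.delta_r2
            df["adj_r2"] = s.adj_r2
            steps.append(df)
        pd.concat(steps).to_csv(out / "regression_steps.csv", index=False)
        self.slopes.table.to_csv(out / "simple_slopes.csv", index=False)
        self.component_reports.to_csv(out / "component_scores.csv", index=False)
        (out / "report.md").write_text(self.to_markdown())

    def to_markdown(self) -> str:
        lines = ["# Analysis report", ""]
        lines.append(f"Participants analyzed: {self.n_analyzed}")
        lines.append(f"Participant filter: {self.filter_applied}")
        lines += ["", "## Behavioral summary (group x condition)", ""]
        lines.append(self.behavior_per_group.round(2).to_markdown(index=False))
        lines += ["", "## Mixed ANOVA on ROI oxy-Hb (group x location)", ""]
        lines.append(self.anova_nirs.to_frame().round(4).to_markdown(index=False))
        lines += ["", "## Simple effects of location per group", ""]
        for g, res in self.simple_effects_nirs.items():
            e = res["location"]
            lines.append(
                f"- {g}: F({e.df[0]:.0f},{e.df[1]:.0f}) = {e.F:.2f}, p = {e.p:.3f}"
            )
        lines += ["", "## Mixed ANOVA on mean correct RT (group x condition)", ""]
        lines.append(
            self.anova_behavior_rt.to_frame().round(4).to_markdown(index=False)
        )
        lines += ["", "## Scheffé contrasts on Reverse RT", ""]
        lines.append(
            self.scheffe_rt_reverse.contrasts.round(4).to_markdown(index=False)
        )
        lines += ["", "## Hierarchical regression: RT ~ age * L-R index", ""]
        for i, s in enumerate(self.regression.steps, start=1):
            lines.append(
                f"Step {i}: R2 = {s.r2:.3f}, dR2 = {s.delta_r2:.3f}, "
                f"adj R2 = {s.adj_r2:.3f}, "
                f"F_change({s.df_change[0]:.0f},{s.df_change[1]:.0f}) = "
                f"{s.f_change:.2f}, p = {s.p_change:.4f}"
            )
            lines.append(s.to_frame().round(4).to_markdown(index=False))
            lines.append("")
        lines += ["## Simple slopes of age at +/-1 SD of the L-R index", ""]
        lines.append(self.slopes.table.round(4).to_markdown(index=False))
        lines.append("")
        return "\n".join(lines)


def _dataset_paths(dataset_dir: Path):
    recs = sorted((dataset_dir / "recordings").glob("*.csv"))
    logs = sorted((dataset_dir / "logs").glob("*.csv"))
    if not recs or not logs:
        raise FileNotFoundError(f"no recordings/logs under {dataset_dir}")
    return recs, logs


def compute_laterality(
    dataset_dir: str | Path, config: AnalysisConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Preprocess every recording and compute per-participant laterality.

    Returns (laterality table, concatenated per-component audit tables).
    """
    dataset_dir = Path(dataset_dir)
    layout = nirs_io.load_layout(dataset_dir / "layout.json")
    design = nirs_io.canonical_block_design()
    rec_paths, _ = _dataset_paths(dataset_dir)
    window = (90.0, 100.0) if config.dv_window == "last10" else (40.0, 100.0)
    results, reports = [], []
    for path in rec_paths:
        rec = nirs_io.load_recording(path, layout)
        cleaned, report = preprocess_recording(
            rec,
            cutoff_hz=config.cutoff_hz,
            criterion=config.criterion,
            n_components=config.n_components,
            run_ica=config.run_ica,
            run_filter=config.run_filter,
        )
        corrected = hemo.baseline_correct(cleaned, design)
        results.append(hemo.roi_laterality(corrected, layout, window))
        if report is not None:
            report = report.copy()
            report.insert(0, "participant_id", rec.participant_id)
            reports.append(report)
    lat = hemo.laterality_table(results)
    comp = pd.concat(reports, ignore_index=True) if reports else pd.DataFrame()
    return lat, comp


def run_full_analysis(
    dataset_dir: str | Path, config: AnalysisConfig = AnalysisConfig()
) -> AnalysisReport:
    """Run the complete pipeline on a dataset directory."""
    dataset_dir = Path(dataset_dir)
    participants = nirs_io.load_participants(dataset_dir / "participants.csv")
    _, log_paths = _dataset_paths(dataset_dir)
    logs = [bhv.load_trial_log(p) for p in log_paths]

    lat, comp_reports = compute_laterality(dataset_dir, config)
    per_part, per_group = bhv.summarize_behavior(logs, participants)

    # participant-level merged table
    meta = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in participants],
            "group": [p.group for p in participants],
            "age_months": [p.age_months for p in participants],
        }
    )
    lat = lat.merge(meta, on="participant_id")

    rev = per_part[per_part.condition == "Reverse"][
        ["participant_id", "n_correct", "n_trials", "mean_correct_rt_ms"]
    ].rename(columns={"mean_correct_rt_ms": "reverse_rt_ms"})
    rep = per_part[per_part.condition == "Repeat"][
        ["participant_id", "mean_correct_rt_ms"]
    ].rename(columns={"mean_correct_rt_ms": "repeat_rt_ms"})
    table = lat.merge(rev, on="participant_id").merge(rep, on="participant_id")

    if config.participant_filter == "all-correct":
        keep = table.n_correct == table.n_trials
        if not keep.any():
            raise ValueError("all-correct filter removed every participant")
        analyzed = table[keep].reset_index(drop=True)
        applied = f"all-correct (kept {keep.sum()} of {len(table)})"
    elif config.participant_filter == "none":
        analyzed = table
        applied = "none"
    else:
        raise ValueError(f"unknown filter {config.participant_filter!r}")

    # NIRS mixed ANOVA: group x location on ROI window means
    nirs_df = analyzed.rename(
        columns={"roi_right_mean": "right", "roi_left_mean": "left"}
    )
    anova_nirs = inf.mixed_anova(nirs_df, within_cols=("right", "left"))
    simple_effects = {
        g: inf.simple_effect_within(
            nirs_df.loc[nirs_df.group == g, "left"].to_numpy(),
            nirs_df.loc[nirs_df.group == g, "right"].to_numpy(),
        )
        for g in ("Low", "Middle", "High")
        if (nirs_df.group == g).sum() >= 2
    }

    # behavioral mixed ANOVA: group x condition on mean correct RT
    beh_df = analyzed.rename(
        columns={"repeat_rt_ms": "Repeat", "reverse_rt_ms": "Reverse"}
    )
    anova_rt = inf.mixed_anova(beh_df, within_cols=("Repeat", "Reverse"))
    by_group_rt = {
        g: beh_df.loc[beh_df.group == g, "Reverse"].to_numpy()
        for g in ("Low", "Middle", "High")
        if (beh_df.group == g).sum() >= 2
    }
    scheffe_rt = inf.scheffe_posthoc(by_group_rt)
    by_group_nc = {
        g: analyzed.loc[analyzed.group == g, "n_correct"].to_numpy(dtype=float)
        for g in ("Low", "Middle", "High")
        if (analyzed.group == g).sum() >= 2
    }
    anova_nc = inf.oneway_anova(by_group_nc)
    scheffe_nc = inf.scheffe_posthoc(by_group_nc, anova_nc)

    regression = inf.hierarchical_regression(
        analyzed.reverse_rt_ms.to_numpy(),
        analyzed.age_months.to_numpy(dtype=float),
        analyzed.lr_index.to_numpy(),
    )
    slopes = inf.simple_slopes(regression)

    return AnalysisReport(
        laterality=analyzed,
        behavior_per_participant=per_part,
        behavior_per_group=per_group,
        anova_nirs=anova_nirs,
        anova_behavior_rt=anova_rt,
        anova_correct=anova_nc,
        scheffe_rt_reverse=scheffe_rt,
        scheffe_correct=scheffe_nc,
        simple_effects_nirs=simple_effects,
        regression=regression,
        slopes=slopes,
        component_reports=comp_reports,
        n_analyzed=len(analyzed),
        filter_applied=applied,
    )
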