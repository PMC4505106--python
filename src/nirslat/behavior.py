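"""Scoring of the mora reversal task.

Each trial presents a three-mora Japanese noun; the participant repeats it
verbatim (Repeat condition) or in reversed mora order (Reverse condition,
e.g. ta-i-ko -> ko-i-ta).  Morae are compared as opaque tokens — kana
normalization is the log producer's job.  Response time is the interval
from stimulus onset to the end of the spoken response, in milliseconds;
mean correct RT is computed over correct trials only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .nirs_io import BlockDesign, ParticipantRecord

__all__ = [
    "Trial",
    "TrialLog",
    "score_trial",
    "compute_rt",
    "summarize_behavior",
    "participant_summary",
    "load_trial_log",
    "save_trial_log",
]

CONDITIONS = ("Repeat", "Reverse")


@dataclass(frozen=True)
class Trial:
    condition: str
    stimulus_morae: tuple[str, ...]
    onset_s: float
    response_morae: tuple[str, ...] | None = None
    response_end_s: float | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        object.__setattr__(self, "stimulus_morae", tuple(self.stimulus_morae))
        if len(self.stimulus_morae) != 3:
            raise ValueError("stimuli are three-mora words")
        if self.response_morae is not None:
            object.__setattr__(self, "response_morae", tuple(self.response_morae))
        if self.response_end_s is not None and self.response_end_s <= self.onset_s:
            raise ValueError("response_end_s must be after onset_s")


@dataclass
class TrialLog:
    participant_id: str
    trials: list[Trial] = field(default_factory=list)

    def validate_against(self, design: BlockDesign) -> None:
        if len(self.trials) != len(design.trial_conditions):
            raise ValueError(
                f"{len(self.trials)} trials, design expects "
                f"{len(design.trial_conditions)}"
            )
        for i, (trial, cond) in enumerate(zip(self.trials, design.trial_conditions)):
            if trial.condition != cond:
                raise ValueError(f"trial {i}: condition {trial.condition} != {cond}")


def score_trial(trial: Trial) -> bool:
    """Correctness of one trial: token-by-token match against the stimulus
    (Repeat) or the reversed stimulus (Reverse); no response is incorrect."""
    if trial.response_morae is None:
        return False
    target = (
        trial.stimulus_morae
        if trial.condition == "Repeat"
        else trial.stimulus_morae[::-1]
    )
    return trial.response_morae == target


def compute_rt(trial: Trial) -> float | None:
    """Response time in ms: onset to end of response; None when absent."""
    if trial.response_end_s is None:
        return None
    return (trial.response_end_s - trial.onset_s) * 1000.0


def participant_summary(log: TrialLog) -> pd.DataFrame:
    """Per-condition n_correct and mean correct RT for one participant.

    Repeat pools both Repeat sections (up to 12 trials); Reverse has up to
    6.  Mean correct RT is NaN when no trial in the condition is correct.
    """
    rows = []
    for cond in CONDITIONS:
        trials = [t for t in log.trials if t.condition == cond]
        correct = [t for t in trials if score_trial(t)]
        rts = [compute_rt(t) for t in correct]
        rts = [r for r in rts if r is not None]
        rows.append(
            {
                "participant_id": log.participant_id,
                "condition": cond,
                "n_trials": len(trials),
                "n_correct": len(correct),
                "mean_correct_rt_ms": float(np.mean(rts)) if rts else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_behavior(
    logs: Sequence[TrialLog], participants: Sequence[ParticipantRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant-level and group-level behavioral tables.

    Returns ``(per_participant, per_group)``: the first has one row per
    participant x condition (n_correct, mean correct RT, group, age); the
    second aggregates mean +/- SD of RT and n_correct per group x
    condition.  Cells with no correct trial stay NaN rather than being
    dropped.
    """
    by_id = {p.participant_id: p for p in participants}
    missing = [log.participant_id for log in logs if log.participant_id not in by_id]
    if missing:
        raise KeyError(f"participants missing from table: {missing}")
    frames = []
    for log in logs:
        df = participant_summary(log)
        p = by_id[log.participant_id]
        df["group"] = p.group
        df["age_months"] = p.age_months
        frames.append(df)
    per_participant = pd.concat(frames, ignore_index=True)
    per_group = (
        per_participant.groupby(["group", "condition"], observed=True)
        .agg(
            n=("participant_id", "size"),
            mean_rt_ms=("mean_correct_rt_ms", "mean"),
            sd_rt_ms=("mean_correct_rt_ms", "std"),
            mean_n_correct=("n_correct", "mean"),
            sd_n_correct=("n_correct", "std"),
        )
        .reset_index()
    )
    return per_participant, per_group


# ---------------------------------------------------------------------------
# trial-log CSV I/O
#
# columns: participant_id, trial_index, condition, stimulus (hyphen-joined
# morae), onset_s, response (hyphen-joined, empty if none), response_end_s


def save_trial_log(log: TrialLog, path: str | Path) -> None:
    rows = []
    for i, t in enumerate(log.trials):
        rows.append(
            {
                "participant_id": log.participant_id,
                "trial_index": i,
                "condition": t.condition,
                "stimulus": "-".join(t.stimulus_morae),
                "onset_s": t.onset_s,
                "response": "-".join(t.response_morae) if t.response_morae else "",
                "response_end_s": (
                    "" if t.response_end_s is None else repr(t.response_end_s)
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def load_trial_log(path: str | Path) -> TrialLog:
    df = pd.read_csv(
        path, dtype={"participant_id": str, "response": str, "response_end_s": str}
    )
    df = df.sort_values("trial_index")
    pid = str(df["participant_id"].iloc[0])
    trials = []
    for row in df.itertuples():
        resp = row.response if isinstance(row.response, str) and row.response else None
        end = (
            float(row.response_end_s)
            if isinstance(row.response_end_s, str) and row.response_end_s
            else None
        )
        trials.append(
            Trial(
                condition=row.condition,
                stimulus_morae=tuple(row.stimulus.split("-")),
                onset_s=float(row.onset_s),
                response_morae=tuple(resp.split("-")) if resp else None,
                response_end_s=end,
            )
        )
    return TrialLog(participant_id=pid, trials=trials)
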