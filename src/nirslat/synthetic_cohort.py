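"""Synthetic cohort generator with planted ground truth.

Emulates the study conditions end-to-end so every pipeline stage is
testable without external data: a block-design session (4 Repeat / 6
Reverse / 8 Repeat trials, 10 s SOA), 16-channel oxy-Hb recordings at
650 ms sampling, and behavioral trial logs.

Signal model per channel c::

    y_c(t) = a_c * r(t) + global_amp * g_c * s(t) + eps_c(t)

where ``r`` is the Reverse-section boxcar convolved with a canonical
double-gamma HRF (evaluated in closed form via gamma CDFs, so planted
values admit exact recovery checks), ``a_c`` is the left / right / middle
activation amplitude, ``s`` is a spatially near-uniform "skin blood flow"
waveform — a very-low-frequency vasomotor oscillation, one tone per
participant drawn from 0.025-0.045 Hz, below the 0.05 Hz low-pass cutoff
so that ICA rejection (not the filter) is what removes it — ``g_c`` are
positive near-uniform loadings (CV < 0.1), and ``eps`` is white sensor
noise.

Behavioral model: each participant's Reverse response time follows

    RT = b0 + b_age * age_c + b_lr * LR_c + b_int * age_c * LR_c + u + e

with ``u`` a participant-level residual and ``e`` small trial jitter;
``age_c`` / ``LR_c`` are centered at declared population means.  Repeat
trials are fast (~1.9 s) and always correct; Reverse accuracy is a
logistic function of age.  Default coefficients reproduce the qualitative
structure of the study (negative age effect, negative age x laterality
interaction, Low > Middle > High response times); magnitudes are free,
documented parameters.

Units for oxy-Hb amplitudes are arbitrary (concentration change); the
instrument's scale is not modelled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .behavior import Trial, TrialLog, save_trial_log
from .nirs_io import (
    BlockDesign,
    ChannelLayout,
    ParticipantRecord,
    Recording,
    canonical_block_design,
    save_layout,
    save_participants,
    save_recording,
)

__all__ = [
    "HRFParams",
    "RTModel",
    "AccuracyModel",
    "GeneratorConfig",
    "SyntheticTruth",
    "canonical_hrf",
    "block_regressor",
    "simulate_recording",
    "simulate_behavior",
    "simulate_cohort",
]


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF: response peaking at ``peak_delay_s``
    with a late undershoot, normalized to unit peak."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self):
        if self.dispersion_s <= 0:
            raise ValueError("dispersion_s must be positive")


@dataclass(frozen=True)
class RTModel:
    """Linear model for Reverse response time (ms) on centered age and
    centered planted laterality, plus their product."""

    b0_ms: float = 3300.0
    b_age: float = -27.0          # ms per month
    b_lr: float = -400.0          # ms per laterality unit
    b_interaction: float = -65.0  # ms per (month x laterality unit)
    resid_sd_ms: float = 1000.0   # participant-level residual
    trial_jitter_sd_ms: float = 150.0
    repeat_mean_ms: float = 1900.0
    repeat_sd_ms: float = 220.0
    min_rt_ms: float = 200.0


@dataclass(frozen=True)
class AccuracyModel:
    """Reverse-trial correctness: Bernoulli with logistic probability in
    centered age; Repeat trials are correct with ``repeat_p`` (default 1)."""

    intercept: float = 2.4
    slope_per_month: float = 0.045
    repeat_p: float = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    n_participants: int = 103
    seed: int = 0
    hrf: HRFParams = field(default_factory=HRFParams)
    # activation amplitude per group (arbitrary oxy-Hb units).  The Low
    # group is bilateral (immature, diffuse activity); Middle and High are
    # strongly left-lateralized.
    amp_left: dict = field(
        default_factory=lambda: {"Low": 0.60, "Middle": 0.60, "High": 0.70}
    )
    amp_right: dict = field(
        default_factory=lambda: {"Low": 0.60, "Middle": 0.08, "High": 0.08}
    )
    amp_sd: float = 0.12          # between-participant SD of the left amplitude
    global_amp: float = 1.0       # skin-blood-flow amplitude (SD units)
    global_freq_band_hz: tuple = (0.025, 0.045)  # one tone per participant
    loading_cv: float = 0.04      # channel-loading spread of the global source
    noise_sd: float = 0.2
    rt_model: RTModel = field(default_factory=RTModel)
    accuracy_model: AccuracyModel = field(default_factory=AccuracyModel)
    age_center_months: float = 118.5
    lr_center: float = 0.37       # population-mean planted laterality
    sampling_interval_s: float = 0.65
    n_samples: int = 246          # floor(160 s / 0.65 s)
    age_range_months: tuple = (84, 153)
    group_stratified: bool = False

    def __post_init__(self):
        if self.n_participants < 4:
            raise ValueError("n_participants must be >= 4")
        for sd in (self.amp_sd, self.noise_sd, self.rt_model.resid_sd_ms):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        for d in (self.amp_left, self.amp_right):
            if not all(np.isfinite(list(d.values()))):
                raise ValueError("amplitudes must be finite")


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside the generated data."""

    config_seed: int
    rt_model: dict
    participants: dict = field(default_factory=dict)
    # per participant: amp_left, amp_right, lr (= left - right),
    # global_loadings, has_global

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_seed": self.config_seed,
                "rt_model": self.rt_model,
                "participants": self.participants,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        doc = json.loads(text)
        return cls(
            config_seed=doc["config_seed"],
            rt_model=doc["rt_model"],
            participants=doc["participants"],
        )


# ---------------------------------------------------------------------------
# hemodynamics


def canonical_hrf(t_s, params: HRFParams = HRFParams()) -> np.ndarray:
    """Double-gamma HRF evaluated at ``t_s`` (s), peak normalized to 1.

    The positive lobe is a gamma density with mode ``peak_delay_s``; the
    undershoot a gamma density with mode ``undershoot_delay_s`` scaled by
    ``undershoot_ratio``.
    """
    t = np.asarray(t_s, dtype=float)
    d = params.dispersion_s
    a1 = params.peak_delay_s / d + 1.0
    a2 = params.undershoot_delay_s / d + 1.0
    raw = stats.gamma.pdf(t, a1, scale=d) - params.undershoot_ratio * stats.gamma.pdf(
        t, a2, scale=d
    )
    grid = np.arange(0, params.undershoot_delay_s + 20 * d, d / 50.0)
    peak = np.max(
        stats.gamma.pdf(grid, a1, scale=d)
        - params.undershoot_ratio * stats.gamma.pdf(grid, a2, scale=d)
    )
    return raw / peak


def _hrf_integral(t_s, params: HRFParams) -> np.ndarray:
    """Closed-form running integral of the unit-peak HRF (via gamma CDFs)."""
    t = np.asarray(t_s, dtype=float)
    d = params.dispersion_s
    a1 = params.peak_delay_s / d + 1.0
    a2 = params.undershoot_delay_s / d + 1.0
    grid = np.arange(0, params.undershoot_delay_s + 20 * d, d / 50.0)
    peak = np.max(
        stats.gamma.pdf(grid, a1, scale=d)
        - params.undershoot_ratio * stats.gamma.pdf(grid, a2, scale=d)
    )
    raw = stats.gamma.cdf(t, a1, scale=d) - params.undershoot_ratio * stats.gamma.cdf(
        t, a2, scale=d
    )
    return np.where(t > 0, raw, 0.0) / peak


def block_regressor(
    t_s, span_s: tuple[float, float], params: HRFParams = HRFParams()
) -> np.ndarray:
    """Boxcar over ``span_s`` convolved with the canonical HRF, evaluated
    exactly at ``t_s`` via the HRF's closed-form integral."""
    lo, hi = span_s
    t = np.asarray(t_s, dtype=float)
    return _hrf_integral(t - lo, params) - _hrf_integral(t - hi, params)


# ---------------------------------------------------------------------------
# per-participant simulation


def _global_waveform(
    times: np.ndarray, config: GeneratorConfig, rng
) -> tuple[np.ndarray, float, float]:
    """Skin-blood-flow waveform: a single very-low-frequency vasomotor
    tone (frequency drawn per participant from ``global_freq_band_hz``),
    standardized to unit SD.  Returns (waveform, freq_hz, phase)."""
    lo, hi = config.global_freq_band_hz
    f0 = float(rng.uniform(lo, hi))
    phase = float(rng.uniform(0, 2 * np.pi))
    s = np.sin(2 * np.pi * f0 * times + phase)
    s = (s - s.mean()) / max(s.std(), 1e-12)
    return s, f0, phase


def plant_amplitudes(
    config: GeneratorConfig, participant: ParticipantRecord, rng
) -> tuple[float, float]:
    """Draw this participant's (left, right) activation amplitudes: group
    base values with between-participant variation on the left side."""
    a_left = config.amp_left[participant.group] + config.amp_sd * rng.standard_normal()
    a_right = config.amp_right[participant.group]
    return float(a_left), float(a_right)


def simulate_recording(
    config: GeneratorConfig,
    participant: ParticipantRecord,
    design: BlockDesign,
    rng: np.random.Generator,
    layout: ChannelLayout = ChannelLayout(),
    amplitudes: tuple[float, float] | None = None,
) -> tuple[Recording, dict]:
    """One participant's oxy-Hb matrix plus their slice of the truth file."""
    if rng is None:
        raise ValueError("an explicit numpy Generator is required for reproducibility")
    times = np.arange(config.n_samples) * config.sampling_interval_s
    r = block_regressor(times, design.reverse_span, config.hrf)
    if amplitudes is None:
        amplitudes = plant_amplitudes(config, participant, rng)
    a_left, a_right = amplitudes
    a_mid = 0.5 * (a_left + a_right)
    amps = np.full(layout.n_channels, a_mid)
    for ch in layout.roi_left:
        amps[ch - 1] = a_left
    for ch in layout.roi_right:
        amps[ch - 1] = a_right

    loadings = 1.0 + config.loading_cv * rng.standard_normal(layout.n_channels)
    loadings = np.clip(loadings, 0.5, None)  # positive, near-uniform
    s, global_freq, global_phase = _global_waveform(times, config, rng)
    noise = config.noise_sd * rng.standard_normal((layout.n_channels, config.n_samples))

    data = (
        amps[:, None] * r[None, :]
        + config.global_amp * loadings[:, None] * s[None, :]
        + noise
    )
    rec = Recording(
        participant_id=participant.participant_id,
        data=data,
        sampling_interval_s=config.sampling_interval_s,
        t0_s=0.0,
    )
    truth = {
        "age_months": participant.age_months,
        "group": participant.group,
        "amp_left": a_left,
        "amp_right": a_right,
        "lr": a_left - a_right,
        "global_loadings": [float(x) for x in loadings],
        "global_freq_hz": global_freq,
        "global_phase": global_phase,
        "has_global": config.global_amp != 0.0,
    }
    return rec, truth


# a small synthetic mora pool; stimuli are 18 three-mora "words" with
# distinct morae so a non-reversed answer is never accidentally correct
_MORAE = [
    "ka", "ki", "ku", "ke", "ko", "sa", "shi", "su", "se", "so",
    "ta", "chi", "tsu", "te", "to", "na", "ni", "nu", "ne", "no",
    "ma", "mi", "mu", "me", "mo", "ra", "ri", "ru", "re", "ro",
]


def _stimulus_pool(rng) -> list[tuple[str, str, str]]:
    pool = []
    for _ in range(18):
        pool.append(tuple(rng.choice(_MORAE, size=3, replace=False)))
    return pool


def simulate_behavior(
    config: GeneratorConfig,
    participant: ParticipantRecord,
    truth: dict,
    design: BlockDesign,
    rng: np.random.Generator,
) -> TrialLog:
    """Trial log for one participant, driven by their planted laterality."""
    m = config.rt_model
    acc = config.accuracy_model
    age_c = participant.age_months - config.age_center_months
    lr_c = truth["lr"] - config.lr_center
    reverse_mean = (
        m.b0_ms + m.b_age * age_c + m.b_lr * lr_c + m.b_interaction * age_c * lr_c
    )
    participant_effect = m.resid_sd_ms * rng.standard_normal()
    p_correct_rev = 1.0 / (1.0 + np.exp(-(acc.intercept + acc.slope_per_month * age_c)))

    stimuli = _stimulus_pool(rng)
    trials = []
    for stim, onset, cond in zip(
        stimuli, design.trial_onsets_s, design.trial_conditions
    ):
        if cond == "Repeat":
            correct = bool(rng.random() < acc.repeat_p)
            rt = m.repeat_mean_ms + m.repeat_sd_ms * rng.standard_normal()
            target = stim
        else:
            correct = bool(rng.random() < p_correct_rev)
            rt = (
                reverse_mean
                + participant_effect
                + m.trial_jitter_sd_ms * rng.standard_normal()
            )
            target = stim[::-1]
        rt = max(rt, m.min_rt_ms)
        if correct:
            response = target
        else:
            # wrong answer: first two tokens of the target transposed
            response = (target[1], target[0], target[2])
        trials.append(
            Trial(
                condition=cond,
                stimulus_morae=stim,
                onset_s=float(onset),
                response_morae=response,
                response_end_s=float(onset) + rt / 1000.0,
            )
        )
    return TrialLog(participant_id=participant.participant_id, trials=trials)


def simulate_behavioral_cohort(
    config: GeneratorConfig, rng: np.random.Generator
) -> "pd.DataFrame":
    """Participant-level behavioral sample for simulation studies.

    Draws, per participant: age, planted laterality (group base + left
    jitter), Reverse correct count k ~ Binomial(6, logistic(age)), and the
    mean correct Reverse RT = linear model + participant residual + mean
    of k trial jitters.  Statistically identical to scoring the trial-level
    generator output, but vectorized (no per-trial bookkeeping), so
    thousands of replicate cohorts run in seconds.  Participants with
    k = 0 have missing RT.
    """
    import pandas as pd

    m = config.rt_model
    acc = config.accuracy_model
    participants = draw_participants(config, rng)
    ages = np.array([p.age_months for p in participants], dtype=float)
    groups = np.array([p.group for p in participants])
    a_left = np.array(
        [config.amp_left[g] for g in groups]
    ) + config.amp_sd * rng.standard_normal(len(ages))
    a_right = np.array([config.amp_right[g] for g in groups])
    lr = a_left - a_right
    age_c = ages - config.age_center_months
    lr_c = lr - config.lr_center
    mean_rt = (
        m.b0_ms
        + m.b_age * age_c
        + m.b_lr * lr_c
        + m.b_interaction * age_c * lr_c
        + m.resid_sd_ms * rng.standard_normal(len(ages))
    )
    p_corr = 1.0 / (1.0 + np.exp(-(acc.intercept + acc.slope_per_month * age_c)))
    n_correct = rng.binomial(6, p_corr)
    with np.errstate(divide="ignore", invalid="ignore"):
        jitter = np.where(
            n_correct > 0,
            m.trial_jitter_sd_ms
            * rng.standard_normal(len(ages))
            / np.sqrt(np.maximum(n_correct, 1)),
            np.nan,
        )
    return pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in participants],
            "age_months": ages,
            "group": groups,
            "lr_true": lr,
            "n_correct": n_correct,
            "mean_reverse_rt_ms": np.where(
                n_correct > 0, mean_rt + jitter, np.nan
            ),
        }
    )


# ---------------------------------------------------------------------------
# whole-cohort generation


def draw_participants(config: GeneratorConfig, rng) -> list[ParticipantRecord]:
    """Ages uniform over the observed span (or group-stratified), sexes
    balanced Bernoulli."""
    lo, hi = config.age_range_months
    n = config.n_participants
    if config.group_stratified:
        bins = [(84, 106), (108, 129), (132, 153)]
        ages = []
        for i in range(n):
            b_lo, b_hi = bins[i % 3]
            ages.append(int(rng.integers(b_lo, b_hi + 1)))
    else:
        ages = [int(a) for a in rng.integers(lo, hi + 1, size=n)]
    sexes = ["F" if rng.random() < 0.5 else "M" for _ in range(n)]
    return [
        ParticipantRecord(participant_id=f"p{i:03d}", age_months=a, sex=s)
        for i, (a, s) in enumerate(zip(ages, sexes))
    ]


def simulate_cohort(
    config: GeneratorConfig,
    out_dir: str | Path,
    overwrite: bool = False,
    design: BlockDesign | None = None,
    layout: ChannelLayout = ChannelLayout(),
) -> Path:
    """Generate a full dataset directory.

    Layout: ``recordings/<id>.csv(+.json)``, ``logs/<id>.csv``,
    ``participants.csv``, ``layout.json``, ``truth.json``, ``config.json``.
    Everything is a pure function of (config, seed).
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is non-empty; pass overwrite=True")
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    (out / "logs").mkdir(parents=True, exist_ok=True)
    if design is None:
        design = canonical_block_design()

    root_rng = np.random.default_rng(config.seed)
    participants = draw_participants(config, root_rng)
    child_seeds = np.random.SeedSequence(config.seed).spawn(len(participants))

    truth = SyntheticTruth(
        config_seed=config.seed, rt_model=asdict(config.rt_model)
    )
    for p, ss in zip(participants, child_seeds):
        rng = np.random.default_rng(ss)
        rec, part_truth = simulate_recording(config, p, design, rng, layout)
        log = simulate_behavior(config, p, part_truth, design, rng)
        save_recording(rec, out / "recordings" / f"{p.participant_id}.csv")
        save_trial_log(log, out / "logs" / f"{p.participant_id}.csv")
        truth.participants[p.participant_id] = part_truth

    save_participants(participants, out / "participants.csv")
    save_layout(layout, out / "layout.json")
    (out / "truth.json").write_text(truth.to_json())
    (out / "config.json").write_text(
        json.dumps(asdict(config), indent=1, sort_keys=True, default=list)
    )
    return out
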