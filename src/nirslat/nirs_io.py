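"""Domain types and file I/O for multichannel oxy-Hb recordings.

The measurement model: a 16-channel continuous-wave NIRS array over the
forehead (6 x 2 probe matrix, 3.0 cm emitter-detector separation, channel 9
on Fpz, bottom corners near F7/F8), sampling oxy-Hb concentration change
every 650 ms for ~160 s while the participant performs a block-design mora
reversal task.  Channels 1-4 cover the right DLPFC (R-ROI) and channels
13-16 the left DLPFC (L-ROI); channel ids are 1-based everywhere at the
interface level.

On-disk formats are deliberately plain: a CSV with one ``chNN`` column per
channel plus a JSON sidecar for sampling metadata, a participant CSV, and a
JSON channel-layout/ROI config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelLayout",
    "Recording",
    "BlockDesign",
    "ParticipantRecord",
    "canonical_block_design",
    "derive_group",
    "load_recording",
    "save_recording",
    "load_layout",
    "save_layout",
    "load_participants",
    "save_participants",
]

GROUPS = ("Low", "Middle", "High")

#: age-group bins in months, completed-years rule: Low 7-8 y, Middle 9-10 y,
#: High 11-12 y
GROUP_BINS = {"Low": (84, 108), "Middle": (108, 132), "High": (132, 156)}


class LayoutError(ValueError):
    """Channel count or ROI definition inconsistent with the probe layout."""


class SidecarError(ValueError):
    """Missing or malformed JSON sidecar for a time-series file."""


@dataclass(frozen=True)
class ChannelLayout:
    """Probe geometry and ROI channel sets (1-based channel ids)."""

    n_channels: int = 16
    probe_matrix: tuple[int, int] = (6, 2)
    emitter_detector_separation_cm: float = 3.0
    anchor_landmarks: dict = field(
        default_factory=lambda: {
            "ch9": "Fpz",
            "bottom_left_probe": "F7",
            "bottom_right_probe": "F8",
        }
    )
    roi_right: frozenset[int] = frozenset({1, 2, 3, 4})
    roi_left: frozenset[int] = frozenset({13, 14, 15, 16})

    def __post_init__(self):
        object.__setattr__(self, "roi_right", frozenset(self.roi_right))
        object.__setattr__(self, "roi_left", frozenset(self.roi_left))
        if not self.roi_left or not self.roi_right:
            raise LayoutError("ROI channel sets must be non-empty")
        if self.roi_left & self.roi_right:
            raise LayoutError("L-ROI and R-ROI must be disjoint")
        valid = set(range(1, self.n_channels + 1))
        if not (self.roi_left <= valid and self.roi_right <= valid):
            raise LayoutError(
                f"ROI channels must be within 1..{self.n_channels}"
            )

    def swap_rois(self) -> "ChannelLayout":
        """Layout with left and right ROI sets exchanged (for symmetry checks)."""
        return replace(self, roi_left=self.roi_right, roi_right=self.roi_left)


@dataclass
class Recording:
    """One participant's oxy-Hb matrix (channels x samples, arbitrary units)."""

    participant_id: str
    data: np.ndarray
    sampling_interval_s: float = 0.65
    t0_s: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("recording must have >=1 channel and >=1 sample")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps t0 + k * sampling_interval_s, seconds."""
        return self.t0_s + np.arange(self.n_samples) * self.sampling_interval_s

    def channel(self, ch: int) -> np.ndarray:
        """Series for 1-based channel id ``ch``."""
        if not 1 <= ch <= self.n_channels:
            raise LayoutError(f"channel {ch} not in 1..{self.n_channels}")
        return self.data[ch - 1]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(
            participant_id=self.participant_id,
            data=np.array(data, dtype=float),
            sampling_interval_s=self.sampling_interval_s,
            t0_s=self.t0_s,
        )


@dataclass(frozen=True)
class BlockDesign:
    """Task timeline: labelled sections plus per-trial onsets and conditions.

    ``sections`` are contiguous half-open intervals; each trial onset lies
    inside its section and consecutive onsets are exactly ``soa_s`` apart.
    """

    sections: tuple[tuple[str, float, float], ...]
    trial_onsets_s: tuple[float, ...]
    soa_s: float
    trials_per_section: tuple[int, ...]

    def __post_init__(self):
        if len(self.sections) != len(self.trials_per_section):
            raise ValueError("one trial count per section required")
        for (_, a0, a1), (_, b0, _) in zip(self.sections, self.sections[1:]):
            if a1 != b0:
                raise ValueError("sections must be contiguous")
            if a1 <= a0:
                raise ValueError("sections must have positive length")
        if len(self.trial_onsets_s) != sum(self.trials_per_section):
            raise ValueError("onset count must match trials_per_section")
        for onset, label in zip(self.trial_onsets_s, self.trial_labels):
            lo, hi = self.section_span(label)
            if not lo <= onset < hi:
                raise ValueError(f"onset {onset} outside section {label}")

    @property
    def trial_labels(self) -> tuple[str, ...]:
        labels = []
        for (name, _, _), n in zip(self.sections, self.trials_per_section):
            labels.extend([name] * n)
        return tuple(labels)

    @property
    def trial_conditions(self) -> tuple[str, ...]:
        """Per-trial condition: Repeat for Repeat1/Repeat2, Reverse otherwise."""
        return tuple(
            "Reverse" if lab == "Reverse" else "Repeat"
            for lab in self.trial_labels
        )

    def section_span(self, label: str) -> tuple[float, float]:
        for name, lo, hi in self.sections:
            if name == label:
                return lo, hi
        raise KeyError(label)

    @property
    def reverse_span(self) -> tuple[float, float]:
        return self.section_span("Reverse")


def canonical_block_design() -> BlockDesign:
    """The fixed task design: 18 trials at 10 s SOA, 4 Repeat / 6 Reverse /
    8 Repeat, Reverse section spanning 40-100 s.

    The final Repeat section extends to 180 s so its eight 10 s-spaced
    trials fit; the NIRS analysis only ever uses the first 160 s.
    """
    soa = 10.0
    return BlockDesign(
        sections=(
            ("Repeat1", 0.0, 40.0),
            ("Reverse", 40.0, 100.0),
            ("Repeat2", 100.0, 180.0),
        ),
        trial_onsets_s=tuple(float(k) * soa for k in range(18)),
        soa_s=soa,
        trials_per_section=(4, 6, 8),
    )


def derive_group(age_months: int) -> str:
    """Age group from age in months: Low [84,108), Middle [108,132),
    High [132,156) — the completed-years binning of 7-8 / 9-10 / 11-12 y."""
    if not 84 <= age_months < 156:
        raise ValueError(f"age {age_months} months outside supported 84..155")
    for group, (lo, hi) in GROUP_BINS.items():
        if lo <= age_months < hi:
            return group
    raise AssertionError("unreachable: bins partition the domain")


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    age_months: int
    sex: str
    group: str = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "group", derive_group(self.age_months))


# ---------------------------------------------------------------------------
# file I/O


def _channel_columns(n_channels: int) -> list[str]:
    return [f"ch{c:02d}" for c in range(1, n_channels + 1)]


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV (one column per channel, full precision)
    plus a JSON sidecar ``<stem>.json`` with sampling metadata."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=_channel_columns(rec.n_channels))
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "participant_id": rec.participant_id,
        "sampling_interval_s": rec.sampling_interval_s,
        "t0_s": rec.t0_s,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(path: str | Path, layout: ChannelLayout | None = None) -> Recording:
    """Read a CSV + JSON-sidecar recording; validate against ``layout``."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SidecarError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if layout is not None and df.shape[1] != layout.n_channels:
        raise LayoutError(
            f"{path}: {df.shape[1]} channels, layout expects {layout.n_channels}"
        )
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if bad.size or coerced.isna().any():
            row = int(bad[0]) if bad.size else int(coerced.isna().idxmax())
            raise ValueError(f"{path}: non-numeric value in {col} at row {row}")
        df[col] = coerced
    return Recording(
        participant_id=str(meta["participant_id"]),
        data=df.to_numpy().T,
        sampling_interval_s=float(meta["sampling_interval_s"]),
        t0_s=float(meta.get("t0_s", 0.0)),
    )


def save_layout(layout: ChannelLayout, path: str | Path) -> None:
    doc = {
        "n_channels": layout.n_channels,
        "probe_matrix": list(layout.probe_matrix),
        "emitter_detector_separation_cm": layout.emitter_detector_separation_cm,
        "anchors": layout.anchor_landmarks,
        "roi_left": sorted(layout.roi_left),
        "roi_right": sorted(layout.roi_right),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_layout(path: str | Path) -> ChannelLayout:
    doc = json.loads(Path(path).read_text())
    return ChannelLayout(
        n_channels=int(doc["n_channels"]),
        probe_matrix=tuple(doc.get("probe_matrix", (6, 2))),
        emitter_detector_separation_cm=float(
            doc.get("emitter_detector_separation_cm", 3.0)
        ),
        anchor_landmarks=doc.get("anchors", {}),
        roi_left=frozenset(doc["roi_left"]),
        roi_right=frozenset(doc["roi_right"]),
    )


def save_participants(participants: Sequence[ParticipantRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in participants],
            "age_months": [p.age_months for p in participants],
            "sex": [p.sex for p in participants],
        }
    ).to_csv(path, index=False)


def load_participants(path: str | Path) -> list[ParticipantRecord]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    return [
        ParticipantRecord(
            participant_id=row.participant_id,
            age_months=int(row.age_months),
            sex=str(row.sex),
        )
        for row in df.itertuples()
    ]
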