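"""Block-design signal summarization: two-anchor baseline correction,
window means, ROI averaging, the L-R laterality index, and grand averages.

Baseline model: per channel, a straight line through two anchor points —
(mean time, mean signal) over the 10 s before the Reverse section and over
the final 10 s of the second Repeat section — is subtracted, so slow drift
that survives the low-pass filter is removed while the sustained Reverse
response between the anchors is kept.  The laterality index is
``mean(L-ROI) - mean(R-ROI)`` over the analysis window (by default the last
10 s of the Reverse section); positive values mean left-lateralized
activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .nirs_io import BlockDesign, ChannelLayout, Recording

__all__ = [
    "LateralityResult",
    "TwoAnchorBaseline",
    "baseline_correct",
    "window_mean",
    "roi_laterality",
    "grand_average",
    "laterality_table",
]


class WindowingError(ValueError):
    """Requested time window has no samples or exceeds the recording."""


@dataclass(frozen=True)
class LateralityResult:
    """Per-participant ROI means over the analysis window and their
    difference ``lr_index = roi_left_mean - roi_right_mean``."""

    participant_id: str
    roi_left_mean: float
    roi_right_mean: float
    lr_index: float
    analysis_window_s: tuple[float, float] = (90.0, 100.0)

    def __post_init__(self):
        if abs(self.lr_index - (self.roi_left_mean - self.roi_right_mean)) > 1e-12:
            raise ValueError("lr_index must equal left - right exactly")


def _window_index(times: np.ndarray, window_s: tuple[float, float]) -> np.ndarray:
    start, end = window_s
    if end <= start:
        raise WindowingError(f"empty window {window_s}")
    mask = (times >= start) & (times < end)
    if not mask.any():
        raise WindowingError(
            f"window [{start}, {end}) contains no samples "
            f"(recording spans {times[0]:.3f}..{times[-1]:.3f} s)"
        )
    return mask


class TwoAnchorBaseline(TransformerMixin, BaseEstimator):
    """Subtract, per channel, the line through the two anchor-window means.

    Anchors default to [30, 40) s (pre-Reverse) and [150, 160) s (end of the
    second Repeat section).  The line passes through (mean anchor time,
    mean anchor signal), so corrected anchor-window means are exactly zero
    and the transform is idempotent.

    Operates on (n_samples, n_channels) arrays with timestamps
    ``t0_s + k * sampling_interval_s``.
    """

    def __init__(
        self,
        anchor_a_s: tuple[float, float] = (30.0, 40.0),
        anchor_b_s: tuple[float, float] = (150.0, 160.0),
        sampling_interval_s: float = 0.65,
        t0_s: float = 0.0,
        least_squares: bool = False,
    ):
        self.anchor_a_s = anchor_a_s
        self.anchor_b_s = anchor_b_s
        self.sampling_interval_s = sampling_interval_s
        self.t0_s = t0_s
        self.least_squares = least_squares

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        times = self.t0_s + np.arange(X.shape[0]) * self.sampling_interval_s
        mask_a = _window_index(times, self.anchor_a_s)
        mask_b = _window_index(times, self.anchor_b_s)
        if self.least_squares:
            # single least-squares line over the pooled anchor samples
            mask = mask_a | mask_b
            t = times[mask]
            A = np.column_stack([np.ones_like(t), t])
            coef, *_ = np.linalg.lstsq(A, X[mask], rcond=None)
            self.intercept_, self.slope_ = coef[0], coef[1]
        else:
            ta, tb = times[mask_a].mean(), times[mask_b].mean()
            ya = X[mask_a].mean(axis=0)
            yb = X[mask_b].mean(axis=0)
            self.slope_ = (yb - ya) / (tb - ta)
            self.intercept_ = ya - self.slope_ * ta
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        times = self.t0_s + np.arange(X.shape[0]) * self.sampling_interval_s
        baseline = self.intercept_[None, :] + times[:, None] * self.slope_[None, :]
        return X - baseline

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def baseline_correct(
    rec: Recording, design: BlockDesign, least_squares: bool = False
) -> Recording:
    """Two-anchor baseline correction of a recording.

    Anchors are the 10 s before the Reverse section and the window ending
    10 s later than ``min(150 s, recording end)`` clipped to the design —
    concretely [reverse_start-10, reverse_start) and [end-10, end) where
    ``end`` is the 160 s analysis span.
    """
    rev_lo, rev_hi = design.reverse_span
    anchor_a = (rev_lo - 10.0, rev_lo)
    # final 10 s of the analyzed part of the second Repeat section
    analysis_end = rev_hi + 60.0
    anchor_b = (analysis_end - 10.0, analysis_end)
    tb = TwoAnchorBaseline(
        anchor_a_s=anchor_a,
        anchor_b_s=anchor_b,
        sampling_interval_s=rec.sampling_interval_s,
        t0_s=rec.t0_s,
        least_squares=least_squares,
    )
    span = rec.times[-1] + rec.sampling_interval_s
    if span < anchor_b[0]:
        raise WindowingError(
            f"recording ends at {span:.2f} s, before anchor {anchor_b}"
        )
    return rec.copy_with(tb.fit_transform(rec.data.T).T)


def window_mean(
    rec: Recording, window_s: tuple[float, float], channels=None
) -> dict[int, float]:
    """Per-channel arithmetic mean over samples with timestamps in
    half-open ``[start, end)``.  ``channels`` are 1-based ids (default all)."""
    mask = _window_index(rec.times, window_s)
    if channels is None:
        channels = range(1, rec.n_channels + 1)
    return {ch: float(rec.channel(ch)[mask].mean()) for ch in channels}


def roi_laterality(
    rec: Recording,
    layout: ChannelLayout,
    window_s: tuple[float, float] = (90.0, 100.0),
) -> LateralityResult:
    """ROI means and L-R index over the analysis window.

    Expects a baseline-corrected recording; the ROI mean is the mean over
    the ROI's channels of their window means (equal channel weights).
    """
    means = window_mean(rec, window_s)
    missing = (layout.roi_left | layout.roi_right) - set(means)
    if missing:
        raise ValueError(f"ROI channels {sorted(missing)} absent from recording")
    left = float(np.mean([means[ch] for ch in sorted(layout.roi_left)]))
    right = float(np.mean([means[ch] for ch in sorted(layout.roi_right)]))
    return LateralityResult(
        participant_id=rec.participant_id,
        roi_left_mean=left,
        roi_right_mean=right,
        lr_index=left - right,
        analysis_window_s=window_s,
    )


def grand_average(
    recs: list[Recording],
    window_s: tuple[float, float] = (30.0, 100.0),
    channels=None,
    roi: set[int] | frozenset[int] | None = None,
) -> pd.DataFrame:
    """Across-participant mean waveform (and SE) over ``window_s``.

    With ``roi`` given, channels in the ROI are averaged within participant
    first; otherwise one column per requested channel is returned.
    All recordings must share the sampling grid.
    """
    if not recs:
        raise ValueError("no recordings")
    base = recs[0]
    for r in recs[1:]:
        if (
            r.sampling_interval_s != base.sampling_interval_s
            or r.t0_s != base.t0_s
            or r.n_samples != base.n_samples
        ):
            raise ValueError("recordings must share one sampling grid")
    mask = _window_index(base.times, window_s)
    t = base.times[mask]
    if roi is not None:
        chans = sorted(roi)
        stack = np.stack(
            [r.data[[c - 1 for c in chans]][:, mask].mean(axis=0) for r in recs]
        )
        mean = stack.mean(axis=0)
        se = stack.std(axis=0, ddof=1) / np.sqrt(len(recs)) if len(recs) > 1 else np.zeros_like(mean)
        return pd.DataFrame({"time_s": t, "mean": mean, "se": se})
    chans = sorted(channels) if channels is not None else list(range(1, base.n_channels + 1))
    stack = np.stack([r.data[[c - 1 for c in chans]][:, mask] for r in recs])
    out = {"time_s": t}
    for i, ch in enumerate(chans):
        out[f"ch{ch:02d}_mean"] = stack[:, i, :].mean(axis=0)
        out[f"ch{ch:02d}_se"] = (
            stack[:, i, :].std(axis=0, ddof=1) / np.sqrt(len(recs))
            if len(recs) > 1
            else np.zeros_like(t)
        )
    return pd.DataFrame(out)


def laterality_table(results: list[LateralityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in results],
            "roi_left_mean": [r.roi_left_mean for r in results],
            "roi_right_mean": [r.roi_right_mean for r in results],
            "lr_index": [r.lr_index for r in results],
        }
    )
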