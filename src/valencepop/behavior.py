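"""Licking and eye-blink quantification.

Licks are point events per trial (seconds relative to CS onset); eye area
is a per-trial series in arbitrary camera units. The blink statistic is the
relative eye-area change dA/A0 about the median baseline area, and a blink
event is a contiguous run of frames in which the eye area is reduced by
more than the threshold (dA/A0 < -threshold). Predictive (anticipatory)
responses are events falling in the CS-onset -> US-onset window, the trace
interval during which the animal can only rely on the CS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BehaviorSeries",
    "eye_area_change",
    "detect_blink_events",
    "predictive_fraction",
    "lick_rate",
]


@dataclass
class BehaviorSeries:
    """Per-trial behavioural streams for one mouse.

    lick_times: one array per trial, event times in s relative to CS onset.
    eye_area: (n_trials, n_frames) area series at `frame_rate`, aligned so
        that CS onset is at `cs_onset_s` from trial start.
    lick_counts / blink_magnitudes: per-trial scalar responses (count of
        licks in the predictive window; depth of the largest eye-area dip).
    """

    lick_times: list[np.ndarray]
    eye_area: np.ndarray
    frame_rate: float
    cs_onset_s: float
    us_onset_s: float
    lick_counts: np.ndarray = field(default_factory=lambda: np.zeros(0))
    blink_magnitudes: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.eye_area = np.asarray(self.eye_area, dtype=float)
        if np.any(self.eye_area < 0):
            raise ValueError("eye areas must be nonnegative")

    @property
    def n_trials(self) -> int:
        return len(self.lick_times)


def eye_area_change(trace: np.ndarray, baseline_frames: int) -> np.ndarray:
    """Relative eye-area change dA/A0 about the baseline median.

    A0 is the median area over the first `baseline_frames` frames (the
    pre-CS baseline); the result is (A(t) - A0) / A0 elementwise.
    """
    trace = np.asarray(trace, dtype=float)
    if baseline_frames < 1 or baseline_frames > trace.shape[-1]:
        raise ValueError("baseline window empty or longer than trace")
    a0 = np.median(trace[..., :baseline_frames], axis=-1, keepdims=True)
    if np.any(a0 <= 0):
        raise ValueError("baseline median eye area must be positive")
    return (trace - a0) / a0


def detect_blink_events(da: np.ndarray, threshold: float = 0.20) -> np.ndarray:
    """Start frames of blink events in a dA/A0 series.

    A frame is blinking when the eye area is reduced by more than
    `threshold`, i.e. dA/A0 < -threshold; contiguous runs of blinking
    frames are merged into a single event and the first frame of each run
    is returned.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    da = np.asarray(da, dtype=float)
    if da.ndim != 1:
        raise ValueError("expected a single dA/A0 series")
    if not np.all(np.isfinite(da)):
        raise ValueError("dA/A0 series must be finite")
    below = da < -threshold
    starts = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))
    return starts


def predictive_fraction(
    events_per_trial: list[np.ndarray],
    window: tuple[float, float],
) -> float:
    """Percentage of trials with >= 1 event inside [window[0], window[1]).

    The window is given in the same time base as the events (seconds from
    CS onset); the conventional choice is CS onset to US onset.
    """
    if len(events_per_trial) == 0:
        raise ValueError("no trials provided")
    lo, hi = window
    hits = sum(
        bool(np.any((np.asarray(ev) >= lo) & (np.asarray(ev) < hi)))
        for ev in events_per_trial
    )
    return 100.0 * hits / len(events_per_trial)


def lick_rate(
    events_per_trial: list[np.ndarray],
    t_start: float,
    t_stop: float,
    bin_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged lick rate in Hz over [t_start, t_stop) in `bin_s` bins.

    Returns (bin_left_edges, rate) with rate = mean count per trial per bin
    divided by the bin width.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(t_start, t_stop + bin_s * 0.5, bin_s)
    counts = np.zeros(len(edges) - 1)
    n = max(len(events_per_trial), 1)
    for ev in events_per_trial:
        c, _ = np.histogram(np.asarray(ev, dtype=float), bins=edges)
        counts += c
    return edges[:-1], counts / n / bin_s
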