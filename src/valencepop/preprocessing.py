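"""Fluorescence normalization and response-window extraction.

Traces enter the pipeline as dF/F values organised neuron x trial x frame.
Two z-score conventions are supported, both standardising each trace by its
own mean and SD over the *entire* peri-event period (the full trial), never
over a short baseline (whose SD can be zero in sparsely active neurons):

* trial-averaged: average dF/F across trials first, then standardise the
  per-neuron mean trace (used for heat maps and ensemble vectors);
* per-trial: standardise each single-trial trace (used for trial-by-trial
  analyses such as noise correlations and reversal trajectories).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrialTensor",
    "ZScoreTensor",
    "compute_dff",
    "zscore_trial_average",
    "zscore_per_trial",
    "extract_response_window",
]

STIMULI = ("CS1", "CS2", "US1", "US2")


@dataclass
class TrialTensor:
    """dF/F values indexed neuron x trial x frame with trial annotations.

    Parameters
    ----------
    values : ndarray, shape (n_neurons, n_trials, n_frames)
    frame_rate : float
        Imaging rate in Hz.
    onset_frame : int
        0-based frame index of stimulus onset; the onset frame belongs to
        the post-stimulus window.
    stimuli : ndarray of str, shape (n_trials,)
        Stimulus label of each trial (e.g. ``"CS1"``).
    stage : str
        Stage label (``"pre"``, ``"post"``, ``"reversal"`` ...).
    mouse_ids : ndarray of int, shape (n_neurons,)
        Identifies which neurons were recorded simultaneously.
    neuron_ids : ndarray of int, shape (n_neurons,)
        Stable identities for cross-stage matching.
    """

    values: np.ndarray
    frame_rate: float
    onset_frame: int
    stimuli: np.ndarray
    stage: str = ""
    mouse_ids: np.ndarray | None = None
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be neuron x trial x frame")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trial tensor contains non-finite values")
        n_neurons, n_trials, n_frames = self.values.shape
        if not 0 <= self.onset_frame < n_frames:
            raise ValueError("onset_frame outside the trial")
        self.stimuli = np.asarray(self.stimuli)
        if self.stimuli.shape != (n_trials,):
            raise ValueError("one stimulus label per trial required")
        if self.mouse_ids is None:
            self.mouse_ids = np.zeros(n_neurons, dtype=int)
        else:
            self.mouse_ids = np.asarray(self.mouse_ids, dtype=int)
            if self.mouse_ids.shape != (n_neurons,):
                raise ValueError("one mouse id per neuron required")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(n_neurons, dtype=int)
        else:
            self.neuron_ids = np.asarray(self.neuron_ids, dtype=int)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    def trials_of(self, stimulus: str) -> np.ndarray:
        """Indices of trials in which `stimulus` was presented."""
        idx = np.flatnonzero(self.stimuli == stimulus)
        if idx.size == 0:
            raise ValueError(f"no trials with stimulus {stimulus!r}")
        return idx

    def select_trials(self, idx: np.ndarray) -> "TrialTensor":
        return TrialTensor(
            self.values[:, idx, :],
            self.frame_rate,
            self.onset_frame,
            self.stimuli[idx],
            self.stage,
            self.mouse_ids,
            self.neuron_ids,
        )


@dataclass
class ZScoreTensor:
    """Standardised traces; ``per_trial`` flags the convention used.

    ``excluded`` marks neurons whose trace was constant (zero SD) and could
    not be standardised; their rows are NaN and downstream analyses skip
    them.
    """

    values: np.ndarray
    frame_rate: float
    onset_frame: int
    per_trial: bool
    stimuli: np.ndarray | None = None
    excluded: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def compute_dff(f: np.ndarray, f0: float | np.ndarray) -> np.ndarray:
    """(F - F0) / F0 with F0 the modelled background fluorescence."""
    f = np.asarray(f, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0):
        raise ValueError("background F0 must be positive")
    return (f - f0) / f0


def _zscore_rows(traces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardise each row over its full length; returns (z, degenerate)."""
    mean = traces.mean(axis=-1, keepdims=True)
    sd = traces.std(axis=-1, keepdims=True)
    degenerate = sd[..., 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (traces - mean) / sd
    z[degenerate] = np.nan
    return z, degenerate


def zscore_trial_average(tensor: TrialTensor, stimulus: str) -> ZScoreTensor:
    """Trial-averaged z-score traces for one stimulus.

    Averages dF/F across the stimulus' trials per neuron, then standardises
    the mean trace by its mean and SD over the whole peri-event period.
    """
    idx = tensor.trials_of(stimulus)
    if idx.size < 2:
        raise ValueError("trial-averaged z-scores need at least 2 trials")
    mean_trace = tensor.values[:, idx, :].mean(axis=1)
    z, degenerate = _zscore_rows(mean_trace)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant trace(s) excluded from "
            "z-scoring", stacklevel=2,
        )
    return ZScoreTensor(z, tensor.frame_rate, tensor.onset_frame,
                        per_trial=False, excluded=degenerate)


def zscore_per_trial(tensor: TrialTensor, stimulus: str | None = None) -> ZScoreTensor:
    """Single-trial z-score traces (no averaging across trials)."""
    if stimulus is None:
        values, stimuli = tensor.values, tensor.stimuli
    else:
        idx = tensor.trials_of(stimulus)
        values, stimuli = tensor.values[:, idx, :], tensor.stimuli[idx]
    z, degenerate = _zscore_rows(values)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant single-trial trace(s) "
            "excluded from z-scoring", stacklevel=2,
        )
    return ZScoreTensor(z, tensor.frame_rate, tensor.onset_frame,
                        per_trial=True, stimuli=stimuli, excluded=degenerate)


def extract_response_window(
    values: np.ndarray,
    onset_frame: int,
    frame_rate: float,
    which: str = "post",
    width_s: float = 1.0,
) -> np.ndarray:
    """Mean over the 1-s (by default) window before or after stimulus onset.

    Windows are half-open frame ranges: post = [onset, onset + w) and
    pre = [onset - w, onset) with w = round(width_s * frame_rate); the onset
    frame belongs to the post window. Works on any array whose last axis is
    frames and reduces that axis.
    """
    values = np.asarray(values, dtype=float)
    w = int(round(width_s * frame_rate))
    if w < 1:
        raise ValueError("window must cover at least one frame")
    n_frames = values.shape[-1]
    if which == "post":
        lo, hi = onset_frame, onset_frame + w
    elif which == "pre":
        lo, hi = onset_frame - w, onset_frame
    else:
        raise ValueError("which must be 'pre' or 'post'")
    if lo < 0 or hi > n_frames:
        raise ValueError(
            f"window [{lo}, {hi}) outside trial of {n_frames} frames")
    return values[..., lo:hi].mean(axis=-1)
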