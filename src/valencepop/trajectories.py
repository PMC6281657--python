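"""End-to-end reversal-learning trajectory analysis.

For each mouse: per-trial z-scored CS responses -> per-trial population
vectors -> PCA (3 components) -> Mahalanobis distance of every trial from
the pre-reversal reference block -> median-normalised, mean-centred,
sign-aligned series. Behaviour per mouse: licking and blinking scalars,
each normalised the same way, variance-standardised, sign-aligned and
averaged into a combined series. Per-mouse series are averaged per trial
across mice, fitted with rise-form Weibull curves, correlated (Pearson)
and searched for change points on the cumulative record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import build_population_vectors, trial_md_trajectory
from .preprocessing import TrialTensor, zscore_per_trial
from .reversal import (
    ChangePointResult,
    NormalizedSeries,
    WeibullFit,
    change_point_lags,
    detect_change_points,
    fit_weibull,
    neural_behavior_correlation,
    normalize_series,
)
from .synthetic import SyntheticDataset

__all__ = ["ReversalTrajectory", "analyze_reversal", "combine_behavior"]


@dataclass
class ReversalTrajectory:
    """Per-trial neural and behavioural reversal trajectories + fits."""

    neural: np.ndarray  # across-mouse average, normalised
    behavior: np.ndarray
    neural_per_mouse: np.ndarray  # (n_mice, n_trials)
    behavior_per_mouse: np.ndarray
    neural_fit: WeibullFit
    behavior_fit: WeibullFit
    pearson_r: float
    pearson_p: float
    neural_change_points: ChangePointResult
    behavior_change_points: ChangePointResult
    lags: np.ndarray  # per-mouse neural - behavioural first change point
    n_reference_trials: int


def combine_behavior(
    channels: list[np.ndarray],
    split: int,
    sources: list[str] | None = None,
) -> NormalizedSeries:
    """Normalise, sign-align, variance-standardise and average channels.

    Each behavioural channel (e.g. per-trial lick counts, blink
    magnitudes) is median-normalised and mean-centred with automatic sign
    alignment about `split`, scaled to unit variance so neither channel
    dominates, then averaged per trial. Channels without variance are
    skipped.
    """
    used = []
    for ch in channels:
        ch = np.asarray(ch, dtype=float)
        if ch.std() == 0:
            continue
        norm = normalize_series(ch, flip="auto", split=split)
        sd = norm.values.std()
        used.append(norm.values / sd)
    if not used:
        raise ValueError("no behavioural channel has variance")
    combined = np.mean(used, axis=0)
    return NormalizedSeries(combined - combined.mean(), False,
                            source="combined")


def analyze_reversal(
    dataset: SyntheticDataset,
    n_reference_trials: int = 10,
    n_components: int = 3,
    change_point_alpha: float = 0.05,
) -> ReversalTrajectory:
    """Run the full trial-by-trial reversal pipeline on one reversal block."""
    tensor = dataset.tensor
    if dataset.behavior is None:
        raise ValueError("reversal dataset carries no behaviour")
    n_trials = tensor.n_trials
    split = n_reference_trials
    ref_idx = np.arange(n_reference_trials)

    neural_rows, behavior_rows, lags = [], [], []
    for m, beh in enumerate(dataset.behavior):
        neurons = np.flatnonzero(tensor.mouse_ids == m)
        sub = TrialTensor(tensor.values[neurons], tensor.frame_rate,
                          tensor.onset_frame, tensor.stimuli, tensor.stage)
        z = zscore_per_trial(sub)
        pvs = build_population_vectors(z, per="trial")
        md = trial_md_trajectory(pvs, ref_idx, n_components=n_components)
        neural = normalize_series(md.distances, flip="auto", split=split,
                                  source="neural MD")
        combined = combine_behavior(
            [beh.lick_counts, beh.blink_magnitudes], split,
            sources=["licking", "blinking"])
        neural_rows.append(neural.values)
        behavior_rows.append(combined.values)
        cp_n = detect_change_points(neural.values, change_point_alpha)
        cp_b = detect_change_points(combined.values, change_point_alpha)
        lags.append(change_point_lags(cp_n.first, cp_b.first))

    neural_avg = np.mean(neural_rows, axis=0)
    behavior_avg = np.mean(behavior_rows, axis=0)
    r, p = neural_behavior_correlation(neural_avg, behavior_avg)
    return ReversalTrajectory(
        neural=neural_avg,
        behavior=behavior_avg,
        neural_per_mouse=np.asarray(neural_rows),
        behavior_per_mouse=np.asarray(behavior_rows),
        neural_fit=fit_weibull(neural_avg),
        behavior_fit=fit_weibull(behavior_avg),
        pearson_r=r,
        pearson_p=p,
        neural_change_points=detect_change_points(neural_avg,
                                                  change_point_alpha),
        behavior_change_points=detect_change_points(behavior_avg,
                                                    change_point_alpha),
        lags=np.asarray(lags),
        n_reference_trials=n_reference_trials,
    )
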