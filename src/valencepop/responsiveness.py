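"""Single-neuron stimulus-responsiveness classification and its population
summaries.

A neuron is responsive to a stimulus when its mean dF/F in the 1 s after
stimulus onset differs from the 1 s before (two-sided Wilcoxon signed-rank
over paired trials, exact distribution at the small trial counts used
here); the direction of the mean post-pre difference labels it excited or
inhibited. Downstream summaries reproduce the category pie fractions, the
per-neuron CS/US response-vector geometry (quadrant occupancy, nearest-
neighbour angles) and the origin/transition bookkeeping between stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocessing import (
    STIMULI,
    TrialTensor,
    extract_response_window,
    zscore_per_trial,
)

__all__ = [
    "ResponseLabel",
    "ResponseProfile",
    "classify_response",
    "profile_population",
    "category_distribution",
    "cs_us_vector_map",
    "nn_angle_stats",
    "origin_transitions",
    "ensemble_overlap",
]


@dataclass
class ResponseLabel:
    label: str  # excited | inhibited | nonresponsive
    p_value: float
    amplitude: float  # mean z in the 1-s post window

    def __post_init__(self) -> None:
        if self.label not in ("excited", "inhibited", "nonresponsive"):
            raise ValueError(f"bad label {self.label!r}")


@dataclass
class ResponseProfile:
    neuron_id: int
    stage: str
    labels: dict[str, ResponseLabel]

    def is_excited(self, stimulus: str) -> bool:
        return self.labels[stimulus].label == "excited"

    def is_inhibited(self, stimulus: str) -> bool:
        return self.labels[stimulus].label == "inhibited"

    def is_nonresponsive_all(self) -> bool:
        return all(lab.label == "nonresponsive" for lab in self.labels.values())


def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p with midranked ties.

    Enumerates the null distribution of W+ (sum of ranks of positive
    differences) over all 2^n equiprobable sign assignments by dynamic
    programming on doubled midranks (integers), and returns
    min(1, 2 * min(P(W <= w), P(W >= w))) — the standard exact two-sided
    convention. Midranks make the distribution correct under tied
    |differences|, where the textbook exact tables do not apply.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    ranks2 = np.rint(2.0 * stats.rankdata(np.abs(d))).astype(int)
    w2_obs = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        counts[r:] += counts[:-r]
    counts /= 2.0 ** n
    le = counts[: w2_obs + 1].sum()
    ge = counts[w2_obs:].sum()
    return float(min(1.0, 2.0 * min(le, ge)))


def classify_response(
    pre_means: np.ndarray,
    post_means: np.ndarray,
    alpha: float = 0.05,
    amplitude: float | None = None,
) -> ResponseLabel:
    """Label one neuron's response to one stimulus from paired trial means.

    Two-sided signed-rank test on post - pre differences; zero differences
    are dropped (Wilcoxon convention) and the exact null distribution
    (midranked ties) is used for n <= 25, the normal approximation with
    tie correction beyond. The label is excited/inhibited by the sign of
    the mean difference when p < alpha, nonresponsive otherwise.
    """
    pre = np.asarray(pre_means, dtype=float)
    post = np.asarray(post_means, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre/post must be equal-length 1-d arrays")
    if pre.size < 5:
        raise ValueError("need at least 5 paired trials")
    diff = post - pre
    amp = float(post.mean() - pre.mean()) if amplitude is None else amplitude
    nz = diff[diff != 0]
    if nz.size == 0:
        return ResponseLabel("nonresponsive", 1.0, amp)
    if nz.size <= 25:
        p = _exact_signed_rank_p(nz)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(nz, zero_method="wilcox",
                                 alternative="two-sided", method="approx")
        p = float(res.pvalue)
    if p < alpha and diff.mean() != 0:
        label = "excited" if diff.mean() > 0 else "inhibited"
    else:
        label = "nonresponsive"
    return ResponseLabel(label, p, amp)


def profile_population(
    tensor: TrialTensor,
    alpha: float = 0.05,
    stimuli: tuple[str, ...] = STIMULI,
) -> list[ResponseProfile]:
    """Classify every neuron against every stimulus of a stage.

    Window means are taken on raw dF/F (classification) while the reported
    amplitude is the mean z in the post window of the per-trial z-scores.
    """
    for stim in stimuli:
        if not np.any(tensor.stimuli == stim):
            raise ValueError(f"stimulus {stim!r} missing from tensor")
    profiles = [ResponseProfile(int(nid), tensor.stage, {})
                for nid in tensor.neuron_ids]
    for stim in stimuli:
        idx = tensor.trials_of(stim)
        raw = tensor.values[:, idx, :]
        pre = extract_response_window(raw, tensor.onset_frame,
                                      tensor.frame_rate, "pre")
        post = extract_response_window(raw, tensor.onset_frame,
                                       tensor.frame_rate, "post")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = zscore_per_trial(tensor, stim)
        zpost = extract_response_window(z.values, tensor.onset_frame,
                                        tensor.frame_rate, "post")
        zamp = np.nanmean(np.where(np.isnan(zpost), 0.0, zpost), axis=1)
        for i in range(tensor.n_neurons):
            profiles[i].labels[stim] = classify_response(
                pre[i], post[i], alpha, amplitude=float(zamp[i]))
    return profiles


def category_distribution(profiles: list[ResponseProfile]) -> dict[str, float]:
    """Fractions of the response-category families.

    Families reported (each normalised within its own denominator):
    per-stimulus excited/inhibited/nonresponsive fractions of all neurons;
    pairwise co-response fractions of all neurons; and the US1-only /
    US2-only / both split among US-responsive (US-excited) neurons.
    """
    if not profiles:
        raise ValueError("empty profile list")
    n = len(profiles)
    out: dict[str, float] = {}
    for stim in STIMULI:
        exc = sum(p.is_excited(stim) for p in profiles)
        inh = sum(p.is_inhibited(stim) for p in profiles)
        out[f"{stim}_excited"] = exc / n
        out[f"{stim}_inhibited"] = inh / n
        out[f"{stim}_nonresponsive"] = (n - exc - inh) / n
    pairs = [("CS1", "CS2"), ("US1", "US2"), ("CS1", "US1"), ("CS2", "US2")]
    for a, b in pairs:
        out[f"{a}&{b}_excited"] = sum(
            p.is_excited(a) and p.is_excited(b) for p in profiles) / n
        out[f"{a}&{b}_inhibited"] = sum(
            p.is_inhibited(a) and p.is_inhibited(b) for p in profiles) / n
    out["all_nonresponsive"] = sum(
        p.is_nonresponsive_all() for p in profiles) / n
    us_resp = [p for p in profiles if p.is_excited("US1") or p.is_excited("US2")]
    if us_resp:
        m = len(us_resp)
        both = sum(p.is_excited("US1") and p.is_excited("US2") for p in us_resp)
        us1_only = sum(p.is_excited("US1") and not p.is_excited("US2")
                       for p in us_resp)
        out["US1_only_of_US_responsive"] = us1_only / m
        out["US2_only_of_US_responsive"] = (m - both - us1_only) / m
        out["US_both_of_US_responsive"] = both / m
    return out


def cs_us_vector_map(
    profiles: list[ResponseProfile],
    valence_pair: tuple[str, str] = ("CS1", "US1"),
) -> dict:
    """Per-neuron (CS, US) response vectors with quadrant fractions and r.

    Uses the stored response amplitudes (mean z in the post window).
    Quadrants are counted counterclockwise with boundary points assigned
    to the quadrant counterclockwise of the axis; exact zero vectors are
    excluded. Also reports the across-neuron Pearson correlation between
    CS and US amplitudes.
    """
    cs, us = valence_pair
    vecs = np.array([[p.labels[cs].amplitude, p.labels[us].amplitude]
                     for p in profiles])
    nonzero = ~np.all(vecs == 0, axis=1)
    if not np.all(nonzero):
        warnings.warn(f"{int((~nonzero).sum())} zero vector(s) excluded",
                      stacklevel=2)
    vecs = vecs[nonzero]
    angles = np.degrees(np.arctan2(vecs[:, 1], vecs[:, 0])) % 360.0
    quad_counts = np.array([
        np.sum((angles >= lo) & (angles < hi))
        for lo, hi in ((0, 90), (90, 180), (180, 270), (270, 360))
    ])
    fractions = quad_counts / max(len(vecs), 1)
    if len(vecs) >= 3 and vecs[:, 0].std() > 0 and vecs[:, 1].std() > 0:
        r, p = stats.pearsonr(vecs[:, 0], vecs[:, 1])
    else:
        r, p = np.nan, np.nan
    return {"vectors": vecs, "angles_deg": angles,
            "quadrant_fractions": fractions,
            "pearson_r": float(r), "pearson_p": float(p)}


def _nn_separations(angles_deg: np.ndarray) -> np.ndarray:
    """Circular nearest-neighbour angular separation per vector (degrees)."""
    a = np.sort(np.asarray(angles_deg) % 360.0)
    n = a.size
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    prev_gap = np.roll(gaps, 1)
    return np.minimum(gaps, prev_gap)[np.argsort(np.argsort(a))] if n > 1 else np.array([])


def nn_angle_stats(
    angles_pre: np.ndarray, angles_post: np.ndarray
) -> dict:
    """Nearest-neighbour angle concentration before vs after learning.

    For each set of vector angles, computes each vector's circular distance
    to its nearest neighbour and the median of those separations; a
    two-sided Wilcoxon rank-sum (normal approximation) compares the two
    separation distributions. Smaller separations mean the vectors have
    concentrated (e.g. into opposing quadrants).
    """
    a_pre, a_post = np.asarray(angles_pre), np.asarray(angles_post)
    if a_pre.size < 3 or a_post.size < 3:
        raise ValueError("need at least 3 vectors per set")
    sep_pre = _nn_separations(a_pre)
    sep_post = _nn_separations(a_post)
    res = stats.ranksums(sep_pre, sep_post)
    return {
        "median_pre": float(np.median(sep_pre)),
        "median_post": float(np.median(sep_post)),
        "separations_pre": sep_pre,
        "separations_post": sep_post,
        "z": float(res.statistic),
        "p": float(res.pvalue),
    }


def origin_transitions(
    profiles_a: list[ResponseProfile],
    profiles_b: list[ResponseProfile],
    category: tuple[str, str],
) -> dict[str, int]:
    """Where the stage-B members of a response category came from in stage A.

    `category` is (stimulus, label), e.g. ("CS1", "inhibited"). Stage-B
    neurons in that category are assigned exactly one source: `same-label`
    (same stimulus and label in stage A), `nonresponsive` (no response to
    any stimulus in A), `new` (no matched stage-A identity), or `other`
    (responsive in A but not same-label). Counts sum to the stage-B
    category size.
    """
    stim, label = category
    by_id_a = {p.neuron_id: p for p in profiles_a}
    if not by_id_a and profiles_b:
        raise ValueError("no matched neurons between stages")
    counts = {"same-label": 0, "nonresponsive": 0, "other": 0, "new": 0}
    for p in profiles_b:
        if p.labels[stim].label != label:
            continue
        src = by_id_a.get(p.neuron_id)
        if src is None:
            counts["new"] += 1
        elif src.labels[stim].label == label:
            counts["same-label"] += 1
        elif src.is_nonresponsive_all():
            counts["nonresponsive"] += 1
        else:
            counts["other"] += 1
    return counts


def ensemble_overlap(
    profiles_a: list[ResponseProfile],
    profiles_b: list[ResponseProfile],
    category_a: tuple[str, ...],
    category_b: tuple[str, ...],
) -> float:
    """Fraction of stage-A members of one excited co-response ensemble that
    belong to another ensemble in stage B (e.g. CS1&US1 pre-reversal that
    are CS2&US1 post-reversal)."""
    by_id_b = {p.neuron_id: p for p in profiles_b}
    members = [p for p in profiles_a
               if all(p.is_excited(s) for s in category_a)]
    if not members:
        return float("nan")
    hits = sum(
        1 for p in members
        if p.neuron_id in by_id_b
        and all(by_id_b[p.neuron_id].is_excited(s) for s in category_b)
    )
    return hits / len(members)
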