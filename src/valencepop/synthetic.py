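"""Ground-truth synthetic generator for valence-conditioning imaging data.

Emulates the study design the analysis pipeline expects: 23-s trials at
10 frames/s with a 10-s baseline, CS onset at frame 100, a 1-s CS, a 2-s
trace interval and the US 3 s after CS onset; 10 trials per stimulus; six
mice with >100 neurons each. Every neuron belongs to a response archetype
(which stimuli excite or inhibit it); evoked responses are exponential-
decay calcium transients riding on a positive dF/F baseline, plus private
Gaussian frame noise and a per-trial shared (common-latent) fluctuation
that produces positive pairwise noise correlations. Reversal datasets remap
each neuron's CS response between a pre- and a post-reversal amplitude
along a sigmoidal latent learning curve that also drives behaviour, so
the neural-behavioural coupling measured downstream is a genuine pipeline
output. All randomness flows from the config seed.

Response amplitudes are stated in z-units: an amplitude of ``a`` yields a
mean dF/F elevation of ``a`` noise SDs in the 1-s post-onset window (when
``noise_sd == 0`` the elevation is ``a`` in raw dF/F).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .behavior import BehaviorSeries
from .preprocessing import STIMULI, TrialTensor

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "paper_mimic_config",
    "synth_transient",
    "generate_stage_dataset",
    "generate_reversal_dataset",
    "generate_reversal_session",
    "generate_learning_pair",
    "generate_behavior",
    "exact_signed_rank_fp_rate",
]

SCHEMA_VERSION = "1"

#: classified category fractions replicated by the pre-learning preset
PRE_TARGETS = {
    "excited": {"CS1": 0.15, "CS2": 0.12, "US1": 0.25, "US2": 0.19},
    "excited_pairs": {
        ("CS1", "CS2"): 0.06, ("US1", "US2"): 0.08,
        ("CS1", "US1"): 0.05, ("CS2", "US2"): 0.04,
    },
    "inhibited": {"CS1": 0.03, "CS2": 0.03, "US1": 0.03, "US2": 0.03},
    "inhibited_pairs": {},
}

# After learning inhibition becomes prominent, CS-excited fractions are
# unchanged, US-excited fractions shrink and CS/US co-responses double.
POST_TARGETS = {
    "excited": {"CS1": 0.15, "CS2": 0.12, "US1": 0.18, "US2": 0.14},
    "excited_pairs": {
        ("CS1", "CS2"): 0.04, ("US1", "US2"): 0.05,
        ("CS1", "US1"): 0.10, ("CS2", "US2"): 0.08,
    },
    "inhibited": {"CS1": 0.08, "CS2": 0.07, "US1": 0.10, "US2": 0.08},
    "inhibited_pairs": {("CS1", "US1"): 0.04, ("CS2", "US2"): 0.03},
}


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    Timing defaults follow the experimental protocol (23-s trials at
    10 Hz, 10-s baseline, 1-s CS, 2-s trace interval, US at +3 s, 10
    trials per stimulus); kinetic and noise parameters (transient tau,
    baseline dF/F, frame noise) are generator choices exposed here, not
    measured quantities.
    """

    n_mice: int = 6
    n_neurons_per_mouse: int = 126
    frame_rate: float = 10.0
    trial_length: float = 23.0
    baseline_length: float = 10.0
    cs_duration: float = 1.0
    trace_delay: float = 2.0
    trials_per_stimulus: int = 10
    archetype_probs: dict = field(default_factory=lambda: {"none": 1.0})
    response_amplitude: float = 2.0
    transient_tau: float = 0.6
    baseline_dff: float = 0.5
    noise_sd: float = 0.05
    shared_noise_fraction: float = 0.2
    reversal_block_lengths: dict = field(
        default_factory=lambda: {
            "punishment_to_reward": (10, 50),
            "reward_to_punishment": (10, 30),
        }
    )
    remap_latency: float = 10.0
    remap_abruptness: float = 4.0
    remap_mode: str = "weibull"
    reversal_responsive_fraction: float = 0.3
    obs_noise_frac: float = 0.05
    behavior_noise_sd: float = 0.05
    behavior_lag_trials: int = 0
    lick_rate_max: float = 21.0
    blink_magnitude_max: float = 0.45
    camera_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mice", "n_neurons_per_mouse", "trials_per_stimulus"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.frame_rate <= 0 or self.transient_tau <= 0:
            raise ValueError("frame_rate and transient_tau must be positive")
        post = self.trial_length - self.baseline_length
        if post < self.cs_duration + self.trace_delay + 1.0:
            raise ValueError(
                "trial too short: baseline + post must cover CS, trace "
                "interval and a 1-s US window")
        total = 0.0
        for key, p in self.archetype_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"archetype probability {key}={p} not in [0,1]")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError("archetype probabilities must sum to 1")
        if not 0.0 <= self.shared_noise_fraction < 1.0:
            raise ValueError("shared_noise_fraction must lie in [0, 1)")
        if self.remap_mode not in ("weibull", "step"):
            raise ValueError("remap_mode must be 'weibull' or 'step'")

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_length * self.frame_rate))

    @property
    def onset_frame(self) -> int:
        return int(round(self.baseline_length * self.frame_rate))

    @property
    def window_frames(self) -> int:
        return int(round(1.0 * self.frame_rate))

    @property
    def amplitude_scale(self) -> float:
        """dF/F value of one z-unit of response amplitude."""
        return self.noise_sd if self.noise_sd > 0 else 1.0


@dataclass
class GroundTruth:
    """What the generator actually injected, for oracle-style testing."""

    archetypes: np.ndarray
    shared_loadings: np.ndarray
    latent: np.ndarray | None = None
    change_point: int | None = None
    amp_pre: np.ndarray | None = None
    amp_post: np.ndarray | None = None
    behavior_latent: np.ndarray | None = None


@dataclass
class SyntheticDataset:
    tensor: TrialTensor
    ground_truth: GroundTruth
    config: GeneratorConfig
    behavior: list[BehaviorSeries] | None = None
    schema_version: str = SCHEMA_VERSION


# ---------------------------------------------------------------------------
# archetype bookkeeping

def parse_archetype(key: str) -> dict[str, int]:
    """'CS1+US1-' -> {'CS1': +1, 'US1': -1}; 'none' -> {}."""
    if key == "none":
        return {}
    out: dict[str, int] = {}
    for i in range(0, len(key), 4):
        token = key[i:i + 4]
        stim, sign = token[:3], token[3]
        if stim not in STIMULI or sign not in "+-":
            raise ValueError(f"malformed archetype key {key!r}")
        out[stim] = 1 if sign == "+" else -1
    return out


def exact_signed_rank_fp_rate(n: int, alpha: float = 0.05) -> float:
    """One-sided false-positive rate of the exact two-sided signed-rank test.

    For continuous null data the exact test rejects on either side with the
    largest achievable tail probability p1 such that 2*p1 < alpha; that p1
    is the rate at which a truly unresponsive neuron is labelled excited
    (and equally inhibited). Computed from the subset-sum distribution of
    ranks 1..n.
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    tail = np.cumsum(counts[::-1])[::-1] / float(2 ** n)  # P(W >= w)
    achievable = tail[2.0 * tail < alpha]
    return float(achievable.max()) if achievable.size else 0.0


def _predicted_classified(probs: dict[str, float], fe: float) -> dict:
    """Expected classified category statistics given generative archetype
    probabilities, a per-stimulus false-positive rate fe on each side and
    near-unit power for true responses (valid for amplitudes >= 2 z-units
    at 10 trials)."""
    exc = {s: 0.0 for s in STIMULI}
    inh = {s: 0.0 for s in STIMULI}
    exc_pairs: dict[tuple, float] = {}
    inh_pairs: dict[tuple, float] = {}
    pair_keys = set()
    for key, p in probs.items():
        arch = parse_archetype(key)
        qe = {s: 1.0 if arch.get(s) == 1 else (0.0 if arch.get(s) == -1 else fe)
              for s in STIMULI}
        qi = {s: 1.0 if arch.get(s) == -1 else (0.0 if arch.get(s) == 1 else fe)
              for s in STIMULI}
        for s in STIMULI:
            exc[s] += p * qe[s]
            inh[s] += p * qi[s]
        for a in STIMULI:
            for b in STIMULI:
                if a < b:
                    pair_keys.add((a, b))
                    exc_pairs[(a, b)] = exc_pairs.get((a, b), 0.0) + p * qe[a] * qe[b]
                    inh_pairs[(a, b)] = inh_pairs.get((a, b), 0.0) + p * qi[a] * qi[b]
    return {"excited": exc, "inhibited": inh,
            "excited_pairs": exc_pairs, "inhibited_pairs": inh_pairs}


def _solve_generative_probs(targets: dict, fe: float) -> dict[str, float]:
    """Fixed-point inversion of the classification channel.

    Finds generative archetype probabilities whose *classified* marginals
    and pairwise overlaps (under the known false-positive rate of the exact
    signed-rank test) equal the target fractions. Pure plumbing: converges
    in a handful of iterations because the channel is identity + O(fe).
    """
    def pair_key(a: str, b: str, sign: str) -> str:
        return f"{a}{sign}{b}{sign}"

    probs: dict[str, float] = {}
    for (a, b), p in targets["excited_pairs"].items():
        probs[pair_key(a, b, "+")] = p
    for (a, b), p in targets["inhibited_pairs"].items():
        probs[pair_key(a, b, "-")] = p
    for s, p in targets["excited"].items():
        single = p - sum(v for (a, b), v in targets["excited_pairs"].items()
                         if s in (a, b))
        probs[f"{s}+"] = max(single, 0.0)
    for s, p in targets["inhibited"].items():
        single = p - sum(v for (a, b), v in targets["inhibited_pairs"].items()
                         if s in (a, b))
        probs[f"{s}-"] = max(single, 0.0)
    probs["none"] = max(0.0, 1.0 - sum(probs.values()))

    for _ in range(200):
        pred = _predicted_classified(probs, fe)
        err = 0.0
        for (a, b), tgt in targets["excited_pairs"].items():
            delta = tgt - pred["excited_pairs"][(a, b)]
            err = max(err, abs(delta))
            probs[pair_key(a, b, "+")] = max(0.0, probs[pair_key(a, b, "+")] + delta)
        for (a, b), tgt in targets["inhibited_pairs"].items():
            delta = tgt - pred["inhibited_pairs"][(a, b)]
            err = max(err, abs(delta))
            probs[pair_key(a, b, "-")] = max(0.0, probs[pair_key(a, b, "-")] + delta)
        pred = _predicted_classified(probs, fe)
        for s, tgt in targets["excited"].items():
            delta = tgt - pred["excited"][s]
            err = max(err, abs(delta))
            probs[f"{s}+"] = max(0.0, probs[f"{s}+"] + delta)
        for s, tgt in targets["inhibited"].items():
            delta = tgt - pred["inhibited"][s]
            err = max(err, abs(delta))
            probs[f"{s}-"] = max(0.0, probs[f"{s}-"] + delta)
        probs["none"] = max(0.0, 1.0 - sum(v for k, v in probs.items()
                                           if k != "none"))
        if err < 1e-12:
            break
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


def _raw_probs(targets: dict) -> dict[str, float]:
    probs: dict[str, float] = {}
    for (a, b), p in targets["excited_pairs"].items():
        probs[f"{a}+{b}+"] = p
    for (a, b), p in targets["inhibited_pairs"].items():
        probs[f"{a}-{b}-"] = p
    for s, p in targets["excited"].items():
        pair = sum(v for (a, b), v in targets["excited_pairs"].items() if s in (a, b))
        probs[f"{s}+"] = max(p - pair, 0.0)
    for s, p in targets["inhibited"].items():
        pair = sum(v for (a, b), v in targets["inhibited_pairs"].items() if s in (a, b))
        probs[f"{s}-"] = max(p - pair, 0.0)
    probs["none"] = max(0.0, 1.0 - sum(probs.values()))
    return probs


def paper_mimic_config(
    stage: str,
    measurement_corrected: bool = True,
    alpha: float = 0.05,
    **overrides,
) -> GeneratorConfig:
    """Preset reproducing the published response-category fractions.

    The published fractions (15%/12% CS-excited, 25%/19% US-excited, rare
    inhibition and the stated overlaps before learning; prominent
    inhibition and doubled CS-US co-responses after) are measurements made
    *through* the signed-rank classifier, which mislabels a truly silent
    neuron as excited at a small but known rate. With
    ``measurement_corrected=True`` (default) the preset inverts that
    channel so the classified fractions of generated data reproduce the
    published ones; with ``False`` the published fractions are used
    directly as generative probabilities. Pre- and post-learning presets
    differ only in archetype_probs and shared_noise_fraction.
    """
    if stage == "pre":
        targets, shared = PRE_TARGETS, 0.2
    elif stage == "post":
        targets, shared = POST_TARGETS, 0.05
    else:
        raise ValueError(f"unknown stage {stage!r}; expected 'pre' or 'post'")
    base = GeneratorConfig(**overrides) if overrides else GeneratorConfig()
    if measurement_corrected:
        fe = exact_signed_rank_fp_rate(base.trials_per_stimulus, alpha)
        probs = _solve_generative_probs(targets, fe)
    else:
        probs = _raw_probs(targets)
    return replace(base, archetype_probs=probs, shared_noise_fraction=shared)


# ---------------------------------------------------------------------------
# trace synthesis

def synth_transient(
    amplitude: float,
    tau: float,
    frame_rate: float,
    duration: float,
) -> np.ndarray:
    """Calcium-transient kernel: instantaneous rise, exponential decay.

    Frame i carries amplitude * exp(-(i / frame_rate) / tau); the kernel
    has duration * frame_rate frames.
    """
    if not math.isfinite(amplitude):
        raise ValueError("amplitude must be finite")
    if tau <= 0 or frame_rate <= 0:
        raise ValueError("tau and frame_rate must be positive")
    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    return amplitude * np.exp(-t / tau)


def _rng_for(config: GeneratorConfig, label: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, zlib.crc32(label.encode()) & 0x7FFFFFFF])


def _allocate_archetypes(
    probs: dict[str, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Largest-remainder proportional allocation, shuffled by the seed.

    Stratified assignment realises the configured fractions exactly (to
    one neuron) at finite n, so category-fraction recovery is limited by
    the classifier, not by multinomial sampling noise.
    """
    keys = sorted(probs)
    quotas = np.array([probs[k] * n for k in keys])
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    labels = np.repeat(np.array(keys, dtype=object), counts)
    rng.shuffle(labels)
    return labels


def _shared_loading(config: GeneratorConfig) -> float:
    """Per-neuron loading on the per-trial common latent.

    The latent is expressed as a constant dF/F offset over the 2-s window
    straddling stimulus onset (a shared state fluctuation around the
    stimulus), so it cancels in the post-minus-pre classification contrast
    but survives in the z-scored trial response. The loading is scaled --
    including the attenuation from full-trace mean subtraction -- so the
    shared fraction of trial-response variance equals the configured
    value.
    """
    f = config.shared_noise_fraction
    if f == 0 or config.noise_sd == 0:
        return 0.0
    w = config.window_frames
    private_sd = config.noise_sd / math.sqrt(w)
    retain = 1.0 - 2.0 * w / config.n_frames
    return private_sd * math.sqrt(f / (1.0 - f)) / retain


def _response_kernel(config: GeneratorConfig) -> tuple[np.ndarray, float]:
    """Unit kernel from onset to trial end and its 1-s-window mean."""
    n_post = config.n_frames - config.onset_frame
    k = synth_transient(1.0, config.transient_tau, config.frame_rate,
                        n_post / config.frame_rate)
    kappa = k[: config.window_frames].mean()
    return k, kappa


def generate_stage_dataset(config: GeneratorConfig, stage: str) -> SyntheticDataset:
    """One imaging stage: 4 stimuli x trials_per_stimulus trials per neuron.

    Each trial trace is baseline dF/F + private Gaussian frame noise +
    (for neurons whose archetype includes the trial's stimulus) a signed
    calcium transient scaled so its 1-s-window mean equals the configured
    amplitude, + the shared per-trial latent expressed through the same
    kernel. Identical (config, seed) reproduce the dataset bitwise.
    """
    rng = _rng_for(config, f"stage:{stage}")
    n_total = config.n_mice * config.n_neurons_per_mouse
    nt = config.trials_per_stimulus
    n_trials = nt * len(STIMULI)
    archetypes = _allocate_archetypes(config.archetype_probs, n_total, rng)
    arch_maps = [parse_archetype(k) for k in archetypes]
    kernel, kappa = _response_kernel(config)
    onset = config.onset_frame
    amp_dff = config.response_amplitude * config.amplitude_scale
    load = _shared_loading(config)

    values = config.baseline_dff + config.noise_sd * rng.standard_normal(
        (n_total, n_trials, config.n_frames))
    stimuli = np.repeat(np.array(STIMULI, dtype=object), nt).astype(str)
    mouse_ids = np.repeat(np.arange(config.n_mice), config.n_neurons_per_mouse)

    for si, stim in enumerate(STIMULI):
        cols = slice(si * nt, (si + 1) * nt)
        # shared latent: one draw per (mouse, trial), same loading for all
        # neurons of the mouse, constant over the 2-s peri-onset window
        if load > 0:
            w = config.window_frames
            g = rng.standard_normal((config.n_mice, nt))
            values[:, cols, onset - w:onset + w] += (
                load * g[mouse_ids][:, :, None])
        signs = np.array([arch.get(stim, 0) for arch in arch_maps])
        resp = np.flatnonzero(signs != 0)
        if resp.size:
            bump = (amp_dff / kappa) * kernel
            values[resp, cols, onset:] += signs[resp][:, None, None] * bump

    tensor = TrialTensor(values, config.frame_rate, onset, stimuli,
                         stage=stage, mouse_ids=mouse_ids)
    truth = GroundTruth(archetypes=archetypes,
                        shared_loadings=np.full(n_total, load))
    return SyntheticDataset(tensor, truth, config)


def generate_learning_pair(
    config_pre: GeneratorConfig, config_post: GeneratorConfig
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Matched pre/post datasets with identity-linked archetype origins.

    The post-learning archetypes are drawn from the pre-learning neuron
    pool with the origin structure seen in tracked populations: neurons
    inhibited after learning come predominantly from the pre-learning
    nonresponsive pool; neurons US-excited after learning come mostly from
    the same US-excited pool; CS-excited neurons have divergent origins.
    """
    pre = generate_stage_dataset(config_pre, "pre")
    rng = _rng_for(config_post, "learning-pair")
    n = pre.tensor.n_neurons
    post_labels = _allocate_archetypes(config_post.archetype_probs, n, rng)

    pre_arch = pre.ground_truth.archetypes
    pre_maps = [parse_archetype(k) for k in pre_arch]
    remaining = np.ones(n, dtype=bool)
    assignment = np.empty(n, dtype=object)

    def weight(post_key: str, i: int) -> float:
        post_map = parse_archetype(post_key)
        pre_map = pre_maps[i]
        if any(v == -1 for v in post_map.values()):
            return 8.0 if not pre_map else 1.0
        for stim, sign in post_map.items():
            if stim.startswith("US") and sign == 1:
                return 6.0 if pre_map.get(stim) == 1 else 1.0
        return 1.0

    order = np.argsort([parse_archetype(k) == {} for k in post_labels],
                       kind="stable")  # assign responsive categories first
    for j in order:
        key = str(post_labels[j])
        pool = np.flatnonzero(remaining)
        w = np.array([weight(key, i) for i in pool])
        pick = pool[rng.choice(pool.size, p=w / w.sum())]
        assignment[pick] = key
        remaining[pick] = False

    post_cfg = replace(config_post, archetype_probs={"none": 1.0})
    post = generate_stage_dataset(post_cfg, "post")
    # overwrite the placeholder responses with the identity-linked archetypes
    kernel, kappa = _response_kernel(post_cfg)
    onset = post_cfg.onset_frame
    amp_dff = post_cfg.response_amplitude * post_cfg.amplitude_scale
    nt = post_cfg.trials_per_stimulus
    for si, stim in enumerate(STIMULI):
        cols = slice(si * nt, (si + 1) * nt)
        signs = np.array([parse_archetype(str(k)).get(stim, 0)
                          for k in assignment])
        resp = np.flatnonzero(signs != 0)
        if resp.size:
            bump = (amp_dff / kappa) * kernel
            post.tensor.values[resp, cols, onset:] += (
                signs[resp][:, None, None] * bump)
    post.ground_truth.archetypes = assignment
    return pre, post


def _latent_curve(config: GeneratorConfig, n_pre: int, n_post: int) -> np.ndarray:
    """Sigmoidal remapping latent L(t) on trial index (0-based).

    L = 0 throughout the pre-reversal block; from the first post-reversal
    trial t0 it follows 1 - exp(-(((t - t0)) / alpha)^beta) (so L(t0) = 0
    exactly), or jumps to 1 at t0 in the abrupt 'step' mode.
    """
    n = n_pre + n_post
    latent = np.zeros(n)
    t = np.arange(n_post, dtype=float)
    if config.remap_mode == "step":
        latent[n_pre:] = 1.0
    else:
        latent[n_pre:] = 1.0 - np.exp(
            -np.power(t / config.remap_latency, config.remap_abruptness))
    return latent


def generate_behavior(
    latent: np.ndarray,
    config: GeneratorConfig,
    side: str,
    rng: np.random.Generator | None = None,
) -> BehaviorSeries:
    """Behaviour driven by a per-trial latent in [0, 1].

    Reward side: anticipatory lick count in the CS->US window is
    Poisson(lick_rate_max * latent). Punishment side: the eye-area trace
    dips during the window by blink_magnitude_max * latent (so dips exceed
    the 20% blink criterion once the latent is high), on a baseline-1
    trace with camera noise. `behavior_noise_sd` jitters the latent per
    trial before it drives either readout.
    """
    latent = np.asarray(latent, dtype=float)
    if np.any((latent < 0) | (latent > 1)):
        raise ValueError("latent values must lie in [0, 1]")
    if side not in ("reward", "punishment"):
        raise ValueError("side must be 'reward' or 'punishment'")
    if rng is None:
        rng = _rng_for(config, f"behavior:{side}")
    n_trials = latent.size
    window = config.cs_duration + config.trace_delay
    noisy = np.clip(
        latent + config.behavior_noise_sd * rng.standard_normal(n_trials),
        0.0, 1.0)

    lick_times: list[np.ndarray] = []
    lick_counts = np.zeros(n_trials)
    eye = 1.0 + config.camera_noise_sd * rng.standard_normal(
        (n_trials, config.n_frames))
    blink_mag = np.zeros(n_trials)
    onset, w = config.onset_frame, int(round(window * config.frame_rate))
    for t in range(n_trials):
        if side == "reward":
            k = rng.poisson(config.lick_rate_max * noisy[t])
            times = np.sort(rng.uniform(0.0, window, size=k))
            lick_counts[t] = k
        else:
            times = np.empty(0)
            blink_mag[t] = config.blink_magnitude_max * noisy[t]
            eye[t, onset:onset + w] -= blink_mag[t]
        lick_times.append(times)
    eye = np.clip(eye, 0.0, None)
    return BehaviorSeries(
        lick_times=lick_times, eye_area=eye, frame_rate=config.frame_rate,
        cs_onset_s=config.baseline_length,
        us_onset_s=config.baseline_length + window,
        lick_counts=lick_counts, blink_magnitudes=blink_mag)


def _draw_reversal_amps(
    config: GeneratorConfig, rng: np.random.Generator, n_total: int
) -> np.ndarray:
    """CS-response amplitudes of one ensemble: a neuron is responsive with
    the configured probability, mostly excited."""
    resp = rng.random(n_total) < config.reversal_responsive_fraction
    sign = np.where(rng.random(n_total) < 0.8, 1.0, -1.0)
    return resp * sign * config.response_amplitude


def _build_reversal_block(
    config: GeneratorConfig,
    rng: np.random.Generator,
    cs: str,
    reversal: str,
    amp_pre: np.ndarray,
    amp_post: np.ndarray,
) -> SyntheticDataset:
    """One reversal block: trial tensor + behaviour from a shared latent."""
    n_pre, n_post = config.reversal_block_lengths[reversal]
    if n_pre < 2 or n_post < 2:
        raise ValueError("reversal blocks need at least 2 trials each")
    n_trials = n_pre + n_post
    n_total = amp_pre.size
    latent = _latent_curve(config, n_pre, n_post)
    delta = np.abs(amp_post - amp_pre)
    kernel, kappa = _response_kernel(config)
    onset = config.onset_frame
    scale = config.amplitude_scale
    load = _shared_loading(config)
    mouse_ids = np.repeat(np.arange(config.n_mice), config.n_neurons_per_mouse)

    amp_t = ((1.0 - latent)[None, :] * amp_pre[:, None]
             + latent[None, :] * amp_post[:, None]
             + config.obs_noise_frac * delta[:, None]
             * rng.standard_normal((n_total, n_trials)))
    values = config.baseline_dff + config.noise_sd * rng.standard_normal(
        (n_total, n_trials, config.n_frames))
    if load > 0:
        w = config.window_frames
        g = rng.standard_normal((config.n_mice, n_trials))
        values[:, :, onset - w:onset + w] += load * g[mouse_ids][:, :, None]
    values[:, :, onset:] += (scale / kappa) * amp_t[:, :, None] * kernel

    stimuli = np.full(n_trials, cs)
    tensor = TrialTensor(values, config.frame_rate, onset, stimuli,
                         stage=f"reversal:{reversal}", mouse_ids=mouse_ids)

    # behaviour may trail the neural remapping by a configurable number of
    # trials (the population signal precedes the behavioural switch)
    lag = int(config.behavior_lag_trials)
    if lag > 0:
        beh_latent = np.concatenate([np.zeros(lag), latent[:-lag]])
    elif lag < 0:
        beh_latent = np.concatenate([latent[-lag:], np.full(-lag, latent[-1])])
    else:
        beh_latent = latent
    lick_side_latent = (beh_latent if reversal == "punishment_to_reward"
                        else 1.0 - beh_latent)
    behavior = []
    for m in range(config.n_mice):
        sub = np.random.default_rng(rng.integers(2 ** 31))
        licks = generate_behavior(lick_side_latent, config, "reward", sub)
        blinks = generate_behavior(1.0 - lick_side_latent, config,
                                   "punishment", sub)
        behavior.append(BehaviorSeries(
            lick_times=licks.lick_times, eye_area=blinks.eye_area,
            frame_rate=config.frame_rate, cs_onset_s=config.baseline_length,
            us_onset_s=config.baseline_length + config.cs_duration
            + config.trace_delay,
            lick_counts=licks.lick_counts,
            blink_magnitudes=blinks.blink_magnitudes))

    truth = GroundTruth(
        archetypes=np.where(amp_pre != 0, "CS+", "none"),
        shared_loadings=np.full(n_total, load),
        latent=latent, change_point=n_pre + 1,
        amp_pre=amp_pre, amp_post=amp_post,
        behavior_latent=lick_side_latent)
    return SyntheticDataset(tensor, truth, config, behavior=behavior)


def generate_reversal_dataset(
    config: GeneratorConfig, reversal: str = "punishment_to_reward"
) -> SyntheticDataset:
    """Trial-by-trial CS responses and behaviour across a valence reversal.

    Each neuron carries a pre-reversal and a post-reversal CS-response
    amplitude (drawn from the reversal ensemble mixture; the two ensembles
    are independent); on trial t its evoked amplitude is the latent-
    weighted interpolation (1 - L(t)) * a_pre + L(t) * a_post plus
    per-trial observation noise of SD obs_noise_frac * |a_post - a_pre|.
    Behaviour (licking on the reward side of the reversal, blinking on the
    punishment side) is driven by the same latent with independent noise,
    per mouse.
    """
    if reversal not in config.reversal_block_lengths:
        raise ValueError(f"unknown reversal {reversal!r}")
    rng = _rng_for(config, f"reversal:{reversal}")
    cs = "CS2" if reversal == "punishment_to_reward" else "CS1"
    n_total = config.n_mice * config.n_neurons_per_mouse
    amp_pre = _draw_reversal_amps(config, rng, n_total)
    amp_post = _draw_reversal_amps(config, rng, n_total)
    return _build_reversal_block(config, rng, cs, reversal, amp_pre, amp_post)


def generate_reversal_session(config: GeneratorConfig) -> dict[str, SyntheticDataset]:
    """Both reversal blocks recorded from one neuron population.

    Mirrors the single-session design: the same neurons are tracked
    through the punishment-to-reward block (CS2) and the reward-to-
    punishment block (CS1). Each CS has its own pre- and post-reversal
    ensemble; the CS1 pre-reversal (reward) ensemble equals the CS2
    post-reversal (reward) ensemble's statistics but is an independent
    draw — identity across blocks is in the neurons, not the ensembles.
    Returns {"punishment_to_reward": ..., "reward_to_punishment": ...}.
    """
    rng = _rng_for(config, "reversal-session")
    n_total = config.n_mice * config.n_neurons_per_mouse
    amps = {name: (_draw_reversal_amps(config, rng, n_total),
                   _draw_reversal_amps(config, rng, n_total))
            for name in ("punishment_to_reward", "reward_to_punishment")}
    out = {}
    for name, (a_pre, a_post) in amps.items():
        cs = "CS2" if name == "punishment_to_reward" else "CS1"
        out[name] = _build_reversal_block(config, rng, cs, name, a_pre, a_post)
    return out
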