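"""Configuration and end-to-end pipeline runner.

The pipeline chains simulate -> preprocess -> behaviour -> responsiveness
-> population geometry -> reversal trajectories -> decoding/clustering on
paper-mimic synthetic data, writing tidy CSV tables, a machine-readable
summary.json and a log. Every output table carries the configuration
hash; all randomness flows from the named seed in the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .decoding import cluster_response_types, train_eval_cs_decoder
from .geometry import (
    build_population_vectors,
    ensemble_md,
    noise_correlations,
    pca_reduce,
)
from .preprocessing import (
    STIMULI,
    TrialTensor,
    extract_response_window,
    zscore_per_trial,
    zscore_trial_average,
)
from .responsiveness import (
    category_distribution,
    origin_transitions,
    profile_population,
)
from .synthetic import (
    generate_learning_pair,
    generate_reversal_session,
    paper_mimic_config,
)
from .trajectories import analyze_reversal

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("valencepop")

_REQUIRED_KEYS = ("seed", "window_width_s")


@dataclass
class PipelineConfig:
    seed: int = 0
    window_width_s: float = 1.0
    alpha: float = 0.05
    n_mice: int = 6
    n_neurons_per_mouse: int = 126
    pca_components: dict = field(default_factory=lambda: {
        "ensemble": 2, "reversal": 3, "decoder": 2})
    md_ridge: float = 1e-6
    weibull_form: str = "rise"
    change_point_alpha: float = 0.05
    decoder_folds: int = 10
    decoder_c: float = 1.0
    simulate: dict = field(default_factory=dict)  # GeneratorConfig overrides
    stages: tuple = ("pre", "post")
    reversals: tuple = ("punishment_to_reward", "reward_to_punishment")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        for key in _REQUIRED_KEYS:
            if key not in d:
                raise ValueError(f"config missing required key {key!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.window_width_s <= 0:
            raise ValueError("window_width_s must be positive")
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(d)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    df = df.copy()
    df["config_hash"] = config_hash
    df.to_csv(path, index=False)


def _trial_responses(tensor: TrialTensor, stimulus: str) -> np.ndarray:
    """Per-trial mean z in the 1-s post window, neurons x trials."""
    z = zscore_per_trial(tensor, stimulus)
    values = np.where(np.isnan(z.values), 0.0, z.values)
    return extract_response_window(values, tensor.onset_frame,
                                   tensor.frame_rate, "post")


def _ensemble_mds(tensor: TrialTensor, k: int) -> dict[str, float]:
    """Per-mouse time-point ensemble MDs between stimulus pairs, averaged."""
    pairs = [("CS1", "CS2"), ("US1", "US2"), ("CS1", "US1"), ("CS2", "US2")]
    sums = {f"{a}/{b}": [] for a, b in pairs}
    for m in np.unique(tensor.mouse_ids):
        neurons = np.flatnonzero(tensor.mouse_ids == m)
        sub = TrialTensor(tensor.values[neurons], tensor.frame_rate,
                          tensor.onset_frame, tensor.stimuli, tensor.stage)
        pv_sets = {}
        all_vecs = []
        for stim in STIMULI:
            z = zscore_trial_average(sub, stim)
            pv_sets[stim] = build_population_vectors(z, per="timepoint")
            all_vecs.append(pv_sets[stim].vectors)
        stacked = np.concatenate(all_vecs)
        from .geometry import PopulationVectorSet
        pooled = PopulationVectorSet(
            stacked, np.repeat(STIMULI, [len(v) for v in all_vecs]),
            "timepoint")
        reduced, space = pca_reduce(pooled, min(k, stacked.shape[0],
                                                stacked.shape[1]))
        w = pv_sets["CS1"].vectors.shape[0]
        by_stim = {stim: PopulationVectorSet(
            reduced.vectors[i * w:(i + 1) * w], np.arange(w), "timepoint")
            for i, stim in enumerate(STIMULI)}
        for a, b in pairs:
            sums[f"{a}/{b}"].append(ensemble_md(by_stim[a], by_stim[b]))
    return {key: float(np.mean(v)) for key, v in sums.items()}


def _decoder_stage_trials(session: dict, stage: str, n: int = 10):
    """Trial PVs + labels for one decoder stage of the reversal session."""
    pr = session["punishment_to_reward"]   # CS2 block
    rp = session["reward_to_punishment"]   # CS1 block
    n_pre_pr = pr.ground_truth.change_point - 1
    n_pre_rp = rp.ground_truth.change_point - 1
    if stage == "before":
        # reminder trials under the original contingencies
        reward = ("rp", np.arange(n_pre_rp - n, n_pre_rp))
        punish = ("pr", np.arange(n_pre_pr - n, n_pre_pr))
    elif stage == "after":
        reward = ("pr", np.arange(n_pre_pr, n_pre_pr + n))
        punish = ("rp", np.arange(n_pre_rp, n_pre_rp + n))
    elif stage == "end":
        reward = ("pr", np.arange(pr.tensor.n_trials - n, pr.tensor.n_trials))
        punish = ("rp", np.arange(rp.tensor.n_trials - n, rp.tensor.n_trials))
    else:
        raise ValueError(f"unknown decoder stage {stage!r}")
    blocks = {"pr": pr, "rp": rp}
    pvs, labels = [], []
    for (tag, idx), lab in ((reward, "CS-reward"), (punish, "CS-punishment")):
        resp = _trial_responses(blocks[tag].tensor,
                                str(blocks[tag].tensor.stimuli[0]))
        pvs.append(resp[:, idx].T)
        labels.extend([lab] * len(idx))
    return np.concatenate(pvs), np.asarray(labels)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured analysis chain; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("valencepop %s | config hash %s | seed %d",
             __version__, h, config.seed)
    summary: dict = {"version": __version__, "config_hash": h,
                     "seed": config.seed}
    try:
        overrides = dict(config.simulate)
        overrides.setdefault("seed", config.seed)
        overrides.setdefault("n_mice", config.n_mice)
        overrides.setdefault("n_neurons_per_mouse", config.n_neurons_per_mouse)
        pre_cfg = paper_mimic_config("pre", alpha=config.alpha, **overrides)
        post_cfg = paper_mimic_config("post", alpha=config.alpha, **overrides)
        log.info("simulating matched pre/post stage datasets")
        pre, post = generate_learning_pair(pre_cfg, post_cfg)

        profiles = {}
        for stage, ds in (("pre", pre), ("post", post)):
            profiles[stage] = profile_population(ds.tensor, config.alpha)
            dist = category_distribution(profiles[stage])
            _write_table(
                pd.DataFrame(sorted(dist.items()),
                             columns=["category", "fraction"]),
                outdir / f"categories_{stage}.csv", h)
            summary[f"categories_{stage}"] = dist
        trans_rows = []
        for stim in STIMULI:
            for label in ("excited", "inhibited"):
                counts = origin_transitions(profiles["pre"], profiles["post"],
                                            (stim, label))
                trans_rows.append({"stimulus": stim, "label": label, **counts})
        _write_table(pd.DataFrame(trans_rows),
                     outdir / "origin_transitions.csv", h)

        log.info("noise correlations")
        nc_rows = []
        for stage, ds in (("pre", pre), ("post", post)):
            for stim in ("CS1", "CS2"):
                resp = _trial_responses(ds.tensor, stim)
                nc = noise_correlations(resp, ds.tensor.mouse_ids, stage)
                nc_rows.append({"stage": stage, "stimulus": stim,
                                "mean_r": nc.mean,
                                **{f"mouse_{m}": v
                                   for m, v in nc.per_mouse_mean.items()}})
                summary[f"noise_corr_{stage}_{stim}"] = nc.mean
        for stim in ("CS1", "CS2"):
            a = [r for r in nc_rows if r["stimulus"] == stim]
            pre_means = [v for k, v in a[0].items() if k.startswith("mouse_")]
            post_means = [v for k, v in a[1].items() if k.startswith("mouse_")]
            t, p = stats.ttest_rel(pre_means, post_means)
            summary[f"noise_corr_paired_t_{stim}"] = {"t": float(t),
                                                      "p": float(p)}
        _write_table(pd.DataFrame(nc_rows), outdir / "noise_correlations.csv", h)

        log.info("ensemble Mahalanobis distances")
        for stage, ds in (("pre", pre), ("post", post)):
            summary[f"ensemble_md_{stage}"] = _ensemble_mds(
                ds.tensor, config.pca_components["ensemble"])

        log.info("reversal trajectories")
        session = generate_reversal_session(pre_cfg)
        for name in config.reversals:
            traj = analyze_reversal(
                session[name],
                n_components=config.pca_components["reversal"],
                change_point_alpha=config.change_point_alpha)
            _write_table(
                pd.DataFrame({
                    "trial": np.arange(1, traj.neural.size + 1),
                    "neural": traj.neural, "behavior": traj.behavior,
                    "neural_fitted": traj.neural_fit.predict(
                        np.arange(traj.neural.size, dtype=float)),
                }), outdir / f"reversal_{name}.csv", h)
            summary[f"reversal_{name}"] = {
                "pearson_r": traj.pearson_r, "pearson_p": traj.pearson_p,
                "neural_r2": traj.neural_fit.r_squared,
                "behavior_r2": traj.behavior_fit.r_squared,
                "neural_change_points":
                    traj.neural_change_points.change_points.tolist(),
                "behavior_change_points":
                    traj.behavior_change_points.change_points.tolist(),
                "lags": traj.lags.tolist(),
            }

        log.info("decoding")
        for stage in ("before", "after", "end"):
            pvs, labels = _decoder_stage_trials(session, stage)
            rep = train_eval_cs_decoder(
                pvs, labels, stage,
                n_components=config.pca_components["decoder"],
                n_folds=config.decoder_folds, c=config.decoder_c,
                seed=config.seed)
            summary[f"decoder_{stage}_accuracy"] = rep.mean_accuracy

        log.info("functional clustering")
        feats = []
        for ds in (pre, post):
            for stim in STIMULI:
                feats.append(_trial_responses(ds.tensor, stim).mean(axis=1))
        assign = cluster_response_types(np.column_stack(feats))
        _write_table(
            pd.DataFrame({"neuron": assign.kept, "cluster": assign.labels}),
            outdir / "clusters.csv", h)
        summary["cluster_sizes"] = np.bincount(
            assign.labels)[1:].tolist()
    except Exception as exc:  # re-raise with stage-tagged diagnostics
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True))
    return summary
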