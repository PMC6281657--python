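import dataclasses

import numpy as np
import pytest

from valencepop.preprocessing import extract_response_window
from valencepop.synthetic import (
    GeneratorConfig,
    exact_signed_rank_fp_rate,
    generate_behavior,
    generate_reversal_dataset,
    generate_stage_dataset,
    paper_mimic_config,
    parse_archetype,
    synth_transient,
)


class TestTransient:
    def test_exponential_decay_value(self):
        k = synth_transient(1.0, 0.5, 10.0, 3.0)
        assert k[0] == pytest.approx(1.0)
        assert k[5] == pytest.approx(np.exp(-1.0))

    def test_zero_amplitude_all_zero(self):
        assert np.all(synth_transient(0.0, 0.5, 10.0, 2.0) == 0.0)

    def test_area_matches_geometric_series(self):
        # sum_{i>=0} A exp(-i/(rate*tau)) = A / (1 - exp(-1/(rate*tau)))
        amp, tau, rate = 2.0, 0.7, 10.0
        k = synth_transient(amp, tau, rate, 400.0)  # effectively infinite
        expected = amp / (1.0 - np.exp(-1.0 / (rate * tau)))
        assert k.sum() == pytest.approx(expected, rel=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            synth_transient(1.0, 0.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            synth_transient(np.inf, 1.0, 10.0, 1.0)


class TestConfig:
    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            GeneratorConfig(archetype_probs={"CS1+": 0.4, "none": 0.4})
        with pytest.raises(ValueError):
            GeneratorConfig(archetype_probs={"CS1+": 1.2, "none": -0.2})

    def test_timing_consistency_enforced(self):
        with pytest.raises(ValueError):
            GeneratorConfig(trial_length=11.0, baseline_length=10.0)

    def test_counts_positive(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_mice=0)


class TestPaperMimicPresets:
    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            paper_mimic_config("mid")

    def test_pre_preset_places_cs1_fraction(self):
        # generative CS1-excited mass is the published 15% minus the
        # classification channel's false-positive inflow
        cfg = paper_mimic_config("pre", measurement_corrected=False)
        mass = sum(p for k, p in cfg.archetype_probs.items()
                   if parse_archetype(k).get("CS1") == 1)
        assert mass == pytest.approx(0.15, abs=1e-9)

    def test_pre_preset_us_split(self):
        cfg = paper_mimic_config("pre", measurement_corrected=False)
        us1_only = us2_only = both = 0.0
        for k, p in cfg.archetype_probs.items():
            arch = parse_archetype(k)
            u1, u2 = arch.get("US1") == 1, arch.get("US2") == 1
            us1_only += p * (u1 and not u2)
            us2_only += p * (u2 and not u1)
            both += p * (u1 and u2)
        total = us1_only + us2_only + both
        assert us1_only / total == pytest.approx(0.472, abs=0.005)
        assert us2_only / total == pytest.approx(0.306, abs=0.005)
        assert both / total == pytest.approx(0.222, abs=0.005)

    def test_pre_and_post_differ_only_in_probs_and_shared_noise(self):
        pre = dataclasses.asdict(paper_mimic_config("pre"))
        post = dataclasses.asdict(paper_mimic_config("post"))
        diff = {k for k in pre if pre[k] != post[k]}
        assert diff == {"archetype_probs", "shared_noise_fraction"}
        assert (paper_mimic_config("pre").shared_noise_fraction
                > paper_mimic_config("post").shared_noise_fraction)


class TestStageDataset:
    def test_seed_determinism_bitwise(self, small_config):
        a = generate_stage_dataset(small_config, "pre")
        b = generate_stage_dataset(small_config, "pre")
        assert np.array_equal(a.tensor.values, b.tensor.values)
        assert np.array_equal(a.ground_truth.archetypes,
                              b.ground_truth.archetypes)

    def test_different_seed_differs(self, small_config):
        a = generate_stage_dataset(small_config, "pre")
        c = generate_stage_dataset(
            dataclasses.replace(small_config, seed=100), "pre")
        assert not np.array_equal(a.tensor.values, c.tensor.values)

    def test_noiseless_excited_neuron_window_mean(self):
        cfg = GeneratorConfig(
            n_mice=1, n_neurons_per_mouse=1, noise_sd=0.0,
            shared_noise_fraction=0.0, response_amplitude=2.0,
            archetype_probs={"CS1+": 1.0})
        ds = generate_stage_dataset(cfg, "pre")
        t = ds.tensor
        cs1 = t.values[0, t.trials_of("CS1"), :]
        post = extract_response_window(cs1, t.onset_frame, t.frame_rate, "post")
        assert np.allclose(post - cfg.baseline_dff, 2.0, atol=1e-9)
        # inhibition mirrors excitation on the positive baseline
        cfg2 = dataclasses.replace(cfg, archetype_probs={"CS1-": 1.0})
        ds2 = generate_stage_dataset(cfg2, "pre")
        post2 = extract_response_window(
            ds2.tensor.values[0, ds2.tensor.trials_of("CS1"), :],
            t.onset_frame, t.frame_rate, "post")
        assert np.allclose(post2 - cfg.baseline_dff, -2.0, atol=1e-9)

    def test_allocation_matches_probabilities_exactly(self):
        cfg = GeneratorConfig(
            n_mice=4, n_neurons_per_mouse=50,
            archetype_probs={"CS1+": 0.25, "US1+": 0.5, "none": 0.25})
        ds = generate_stage_dataset(cfg, "pre")
        arch, counts = np.unique(ds.ground_truth.archetypes,
                                 return_counts=True)
        got = dict(zip(arch, counts))
        assert got == {"CS1+": 50, "US1+": 100, "none": 50}


class TestSharedNoise:
    def test_noise_correlation_recovery_and_monotonicity(self):
        # mean pairwise noise correlation approximately equals the shared
        # variance fraction (200 neurons x 10 trials, averaged over seeds)
        from valencepop.geometry import noise_correlations
        from valencepop.preprocessing import zscore_per_trial

        means = {}
        for f in (0.1, 0.2, 0.3):
            vals = []
            for seed in range(20):
                cfg = GeneratorConfig(n_mice=10, n_neurons_per_mouse=20,
                                      shared_noise_fraction=f, seed=seed)
                ds = generate_stage_dataset(cfg, "pre")
                z = zscore_per_trial(ds.tensor, "CS1")
                resp = extract_response_window(
                    np.nan_to_num(z.values), ds.tensor.onset_frame,
                    ds.tensor.frame_rate, "post")
                vals.append(noise_correlations(resp, ds.tensor.mouse_ids).mean)
            means[f] = float(np.mean(vals))
        for f, m in means.items():
            assert abs(m - f) < 0.02
        assert means[0.1] < means[0.2] < means[0.3]


class TestArchetypeRecovery:
    def test_classifier_recovers_responsive_labels(self):
        from valencepop.responsiveness import profile_population

        cfg = paper_mimic_config("pre", seed=11, n_mice=3,
                                 n_neurons_per_mouse=80)
        ds = generate_stage_dataset(cfg, "pre")
        profiles = profile_population(ds.tensor)
        hits = total = 0
        for prof, key in zip(profiles, ds.ground_truth.archetypes):
            for stim, sign in parse_archetype(str(key)).items():
                want = "excited" if sign == 1 else "inhibited"
                hits += prof.labels[stim].label == want
                total += 1
        assert total > 100
        assert hits / total >= 0.95


class TestFalsePositiveRate:
    def test_exact_rate_for_ten_trials(self):
        # 25 of 1024 sign assignments reach the upper critical value
        assert exact_signed_rank_fp_rate(10, 0.05) == pytest.approx(25 / 1024)

    def test_rate_bounded_by_half_alpha(self):
        for n in (6, 10, 15, 20):
            assert exact_signed_rank_fp_rate(n, 0.05) <= 0.025


class TestBehaviorGeneration:
    def test_zero_latent_no_predictive_licks(self):
        from valencepop.behavior import predictive_fraction

        cfg = GeneratorConfig(behavior_noise_sd=0.0)
        beh = generate_behavior(np.zeros(20), cfg, "reward")
        assert predictive_fraction(beh.lick_times, (0.0, 3.0)) == 0.0

    def test_full_latent_high_rate_saturates(self):
        from valencepop.behavior import predictive_fraction

        cfg = GeneratorConfig(behavior_noise_sd=0.0, lick_rate_max=30.0)
        beh = generate_behavior(np.ones(50), cfg, "reward")
        assert predictive_fraction(beh.lick_times, (0.0, 3.0)) == 100.0

    def test_half_latent_matches_poisson_closed_form(self):
        # P(>= 1 lick) = 1 - exp(-lambda/2) for latent 0.5
        lam = 4.0
        cfg = GeneratorConfig(behavior_noise_sd=0.0, lick_rate_max=lam,
                              seed=5)
        frac = []
        for rep in range(40):
            rng = np.random.default_rng(rep)
            beh = generate_behavior(np.full(50, 0.5), cfg, "reward", rng)
            frac.append(np.mean([len(t) > 0 for t in beh.lick_times]))
        expected = 1.0 - np.exp(-lam / 2)
        assert np.mean(frac) == pytest.approx(expected, abs=0.02)

    def test_latent_outside_unit_interval_rejected(self):
        cfg = GeneratorConfig()
        with pytest.raises(ValueError):
            generate_behavior(np.array([0.5, 1.2]), cfg, "reward")

    def test_punishment_side_dips_below_blink_threshold(self):
        from valencepop.behavior import detect_blink_events, eye_area_change

        cfg = GeneratorConfig(behavior_noise_sd=0.0, camera_noise_sd=0.0)
        beh = generate_behavior(np.ones(5), cfg, "punishment")
        da = eye_area_change(beh.eye_area[0], 100)
        assert len(detect_blink_events(da)) == 1


class TestReversalDataset:
    def test_latent_zero_at_reversal_and_saturates(self):
        cfg = GeneratorConfig(n_mice=1, n_neurons_per_mouse=4, seed=0)
        ds = generate_reversal_dataset(cfg, "punishment_to_reward")
        latent = ds.ground_truth.latent
        n_pre = cfg.reversal_block_lengths["punishment_to_reward"][0]
        assert np.all(latent[:n_pre] == 0.0)
        assert latent[n_pre] == 0.0  # L(t0) = 0 in the smooth form
        assert latent[-1] > 0.99
        assert np.all(np.diff(latent) >= 0)
        assert ds.ground_truth.change_point == n_pre + 1

    def test_step_mode_remaps_at_first_reversal_trial(self):
        cfg = GeneratorConfig(n_mice=1, n_neurons_per_mouse=4,
                              remap_mode="step")
        ds = generate_reversal_dataset(cfg, "punishment_to_reward")
        latent = ds.ground_truth.latent
        assert np.all(latent[:10] == 0.0) and np.all(latent[10:] == 1.0)

    def test_block_lengths_follow_protocol(self):
        cfg = GeneratorConfig(n_mice=1, n_neurons_per_mouse=2)
        pr = generate_reversal_dataset(cfg, "punishment_to_reward")
        rp = generate_reversal_dataset(cfg, "reward_to_punishment")
        assert pr.tensor.n_trials == 60 and rp.tensor.n_trials == 40
        assert str(pr.tensor.stimuli[0]) == "CS2"
        assert str(rp.tensor.stimuli[0]) == "CS1"

    def test_too_short_blocks_rejected(self):
        cfg = GeneratorConfig(
            n_mice=1, n_neurons_per_mouse=2,
            reversal_block_lengths={"punishment_to_reward": (1, 50),
                                    "reward_to_punishment": (10, 30)})
        with pytest.raises(ValueError):
            generate_reversal_dataset(cfg, "punishment_to_reward")

    def test_neural_and_behavioral_latents_agree_at_low_noise(self):
        # with noise off, per-trial neural remapping and behaviour follow
        # the same latent: the raw population response is linear in the
        # latent (r ~ 1) and the full MD pipeline tracks it closely (the
        # distance floor at the reference block adds mild curvature)
        cfg = GeneratorConfig(n_mice=2, n_neurons_per_mouse=30, seed=3,
                              obs_noise_frac=0.0, behavior_noise_sd=0.0,
                              shared_noise_fraction=0.0, noise_sd=0.01)
        ds = generate_reversal_dataset(cfg, "punishment_to_reward")
        t = ds.tensor
        post = extract_response_window(t.values, t.onset_frame, t.frame_rate,
                                       "post")
        amp = ds.ground_truth.amp_post - ds.ground_truth.amp_pre
        proj = (post - post.mean(axis=1, keepdims=True)).T @ amp
        r = np.corrcoef(proj, ds.ground_truth.latent)[0, 1]
        assert r > 0.995
        from valencepop.trajectories import analyze_reversal

        traj = analyze_reversal(ds)
        assert traj.pearson_r > 0.97
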