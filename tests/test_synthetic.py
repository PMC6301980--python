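"""Synthetic-session generator: scheduler, trial timing, planted structure."""

import numpy as np
import pytest
from scipy import stats

from graspdyn import CONDITIONS, FORCES, TaskConfig
from graspdyn.dpca import marginalize
from graspdyn.rates import AlignmentSpec
from graspdyn.synthetic import (
    BehaviorModel,
    Latent,
    LatentSpec,
    default_latents,
    schedule_conditions,
    simulate_emg,
    simulate_population,
    simulate_session,
    simulate_trial,
    simulate_unit_bin_rates,
    null_unit_profiles,
)


class TestScheduler:
    def test_all_success_frequencies_uniform(self, rng):
        # multinomial oracle: each condition frequency within 3 SD of 1/6
        n = 6000
        cfg = TaskConfig(n_trials=n)
        labels = schedule_conditions(cfg, np.ones(n, bool), rng)
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for cond in CONDITIONS:
            freq = sum(lab == cond for lab in labels) / n
            assert abs(freq - 1 / 6) < 3 * se

    def test_failing_condition_overrepresented(self, rng):
        # a condition that always fails stays in the pool
        cfg = TaskConfig(n_trials=4000)
        target = CONDITIONS[2]
        labels = schedule_conditions(cfg, lambda lab: lab != target, rng)
        freq = sum(lab == target for lab in labels) / len(labels)
        assert freq > 1 / 6

    def test_pool_size_bounds(self, rng):
        cfg = TaskConfig(n_trials=2000)
        _, sizes = schedule_conditions(
            cfg, np.ones(2000, bool), rng, return_pool_sizes=True
        )
        assert sizes.min() >= cfg.pool_refill_threshold
        assert sizes.max() <= cfg.pool_size


class TestSimulateTrial:
    def test_invalid_condition_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_trial(TaskConfig(), ("fist", "low"), rng)

    def test_degenerate_at_crosses_band_exactly(self, rng):
        bm = BehaviorModel()
        cond = ("whole_hand", "medium")
        bm.at_mean[cond], bm.at_sd[cond] = 400.0, 0.0
        bm.p_overshoot[cond] = 0.0
        cfg = TaskConfig()
        ev, sig, _ = simulate_trial(cfg, cond, rng, bm)
        t = sig.times()
        band_min = cfg.force_bands["medium"][0]
        first = t[np.argmax(sig.samples >= band_min)]
        assert abs(first - (ev["touch"] + 400.0)) <= 1.0  # 1-ms sampling

    def test_low_force_at_near_zero(self, rng):
        bm = BehaviorModel()
        cond = ("whole_hand", "low")
        bm.at_mean[cond], bm.at_sd[cond] = 0.0, 0.0
        cfg = TaskConfig()
        ev, sig, _ = simulate_trial(cfg, cond, rng, bm)
        t = sig.times()
        first = t[np.argmax((t >= ev["touch"]) & (sig.samples >= 0.0))]
        assert first - ev["touch"] <= 1.0

    def test_mean_at_matches_configured_distribution(self):
        # sampling oracle: truncated-normal mean over many WMF trials
        rng = np.random.default_rng(2)
        bm = BehaviorModel()
        cond = ("whole_hand", "medium")
        mu, sd = bm.at_mean[cond], bm.at_sd[cond]
        a = (0.0 - mu) / sd
        expected = stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd)
        ats = [
            simulate_trial(TaskConfig(), cond, rng, bm)[2]["at"] for _ in range(1000)
        ]
        se = np.std(ats, ddof=1) / np.sqrt(len(ats))
        assert abs(np.mean(ats) - expected) < 3 * se

    def test_events_causally_ordered_and_hold_in_band(self, small_session):
        tt = small_session.successful_trials()
        ev_cols = [f"t_{e}" for e in ("fixation", "cue_on", "cue_off", "go",
                                      "movement", "touch", "force_acquired", "reward")]
        times = tt[ev_cols].to_numpy()
        assert np.all(np.diff(times, axis=1) >= 0)
        for _, row in tt.iterrows():
            sig = small_session.force[row["trial_id"]]
            band = small_session.config.force_bands[row["force"]]
            t = sig.times()
            hold = (t >= row["t_force_acquired"]) & (t <= row["t_reward"])
            assert np.all(sig.samples[hold] >= band[0] - 1e-9)
            assert np.all(sig.samples[hold] <= band[1] + 1e-9)


class TestPopulation:
    def test_constant_rate_matches_poisson_oracle(self, rng):
        # no latents: time-averaged rate within 3 SE of the target
        r = 20.0
        rates, _ = simulate_unit_bin_rates(null_unit_profiles(r), 30, rng)
        per_trial = rates.mean(axis=1)
        se = per_trial.std(ddof=1) / np.sqrt(len(per_trial))
        assert abs(per_trial.mean() - r) < 3 * se

    def test_zero_amplitude_latents_yield_null_units(self, rng):
        lat = default_latents(n_units=4, rng=rng)
        for l in lat.latents:
            l.amplitude = 0.0
        tensor = lat.rate_tensor()
        shares = marginalize(tensor).variance_shares()
        # constant tensor: no variance in any condition marginalization
        assert all(np.isnan(v) or v == 0 for v in shares.values()) or (
            (tensor - tensor.mean(axis=(1, 2, 3), keepdims=True)) ** 2
        ).sum() < 1e-18

    def test_single_marginalization_latent_is_pure(self):
        # planting only a force latent leaves every other marginalization at 0
        spec = AlignmentSpec()
        prof = np.sin(np.linspace(0, np.pi, spec.n_bins))
        lat = LatentSpec(
            [Latent("f", "force", prof, np.repeat([[-1.0], [0.0], [1.0]], 2, 1), 5.0)],
            mixing=np.ones((5, 1)),
            baselines=np.full(5, 50.0),
        )
        shares = marginalize(lat.rate_tensor(spec)).variance_shares()
        assert shares["force"] == pytest.approx(1.0, abs=1e-12)
        for m in ("condition_independent", "grip", "interaction"):
            assert shares[m] == pytest.approx(0.0, abs=1e-12)

    def test_coefficient_centering_enforced(self):
        with pytest.raises(ValueError, match="centering"):
            Latent("bad", "force", np.ones(390), np.ones((3, 2)))

    def test_planted_shares_recorded(self):
        lat = default_latents(n_units=60, rng=np.random.default_rng(0))
        shares = lat.ground_truth_shares()
        assert shares["condition_independent"] == pytest.approx(0.70, abs=0.02)
        assert shares["force"] == pytest.approx(0.15, abs=0.02)

    def test_same_seed_bit_identical_session(self):
        a = simulate_session(TaskConfig(n_trials=20, rng_seed=3), n_units=4)
        b = simulate_session(TaskConfig(n_trials=20, rng_seed=3), n_units=4)
        assert a.trial_table.equals(b.trial_table)
        for sa, sb in zip(a.spikes, b.spikes):
            assert np.array_equal(sa, sb)
        for m in a.emg:
            assert np.array_equal(a.emg[m].samples, b.emg[m].samples)


class TestEMG:
    def test_peak_emg_monotone_in_force(self, small_session):
        from graspdyn.rates import continuous_to_condition_tensor

        lat = small_session.latents
        env = simulate_emg(
            lat, small_session.trial_table, np.random.default_rng(0),
            noise_sd=0.0, envelope=True,
        )
        tt = small_session.successful_trials()
        tens = continuous_to_condition_tensor(env["FDS"], tt)
        peaks = tens.max(axis=-1).mean(axis=1)  # (force,) averaged over grips
        assert peaks[0] < peaks[1] < peaks[2]

    def test_silent_before_go(self, small_session):
        env = simulate_emg(
            small_session.latents, small_session.trial_table,
            np.random.default_rng(0), noise_sd=0.0, envelope=True,
        )
        sig = env["FDS"]
        t = sig.times()
        baseline = 0.05
        for _, row in small_session.successful_trials().iterrows():
            pre = (t >= row["t_cue_on"]) & (t < row["t_go"] - 1)
            assert np.all(sig.samples[pre] <= baseline + 0.02)
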