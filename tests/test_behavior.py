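"""Behavioral metrics, exclusion rules, force-divergence statistics."""

import numpy as np
import pandas as pd
import pytest

from graspdyn.behavior import (
    compare_force_levels,
    compute_response_times,
    exclude_trials,
    overshoot_fraction,
    performance_summary,
)
from graspdyn.signals import ContinuousSignal


def make_table(rows):
    base = {
        "trial_id": 0, "grip": "whole_hand", "force": "medium",
        "t_fixation": 0.0, "t_cue_on": 450.0, "t_cue_off": 1250.0,
        "t_go": 1850.0, "t_movement": 2100.0, "t_touch": 2320.0,
        "t_force_acquired": 2700.0, "t_reward": 3700.0,
        "success": True, "failure_stage": "", "n_touches": 1,
    }
    out = []
    for i, r in enumerate(rows):
        d = dict(base)
        d.update(r)
        d["trial_id"] = i
        out.append(d)
    return pd.DataFrame(out)


def ramp_trace(t_touch, slope_n_per_ms, t0=None, n=3000, start=0.0):
    """Force rising linearly from `start` N beginning at touch."""
    t0 = t_touch - 500 if t0 is None else t0
    t = t0 + np.arange(n)
    f = start + np.maximum(t - t_touch, 0) * slope_n_per_ms
    return ContinuousSignal(f, rate=1000.0, unit="N", t0=t0)


class TestResponseTimes:
    def test_rt_mt_subtraction(self):
        tt = make_table([{"t_go": 1000.0, "t_movement": 1268.0, "t_touch": 1484.0}])
        m = compute_response_times(tt)
        assert m.loc[0, "RT"] == pytest.approx(268.0)
        assert m.loc[0, "MT"] == pytest.approx(216.0)

    def test_at_zero_when_force_already_in_band(self):
        tt = make_table([{"force": "low"}])
        traces = {0: ramp_trace(2320.0, 0.01, start=1.0)}  # already >= 0 N
        m = compute_response_times(tt, traces)
        assert m.loc[0, "AT"] == 0.0

    def test_at_from_band_entry(self):
        # 0.01 N/ms ramp reaches the 5 N medium-band minimum 500 ms after touch
        tt = make_table([{}])
        m = compute_response_times(tt, {0: ramp_trace(2320.0, 0.01)})
        assert m.loc[0, "AT"] == pytest.approx(500.0, abs=1.0)

    def test_at_undefined_when_band_never_reached(self):
        tt = make_table([{}])
        flat = ContinuousSignal(np.full(3000, 1.0), 1000.0, "N", t0=1820.0)
        m = compute_response_times(tt, {0: flat})
        assert np.isnan(m.loc[0, "AT"])

    def test_missing_event_gives_nan_not_zero(self):
        tt = make_table([{"t_movement": np.nan}])
        m = compute_response_times(tt)
        assert np.isnan(m.loc[0, "RT"]) and np.isnan(m.loc[0, "MT"])


class TestExclusion:
    def metrics(self, **over):
        base = {"RT": [250.0], "MT": [200.0], "AT": [300.0], "n_touches": [1]}
        base.update({k: [v] for k, v in over.items()})
        base["trial_id"] = [0]
        return pd.DataFrame(base)

    @pytest.mark.parametrize(
        "over,kept",
        [
            ({"RT": 600.0}, False),
            ({"RT": 500.0}, True),  # strict inequality at the boundary
            ({"MT": 350.0}, True),
            ({"MT": 350.1}, False),
            ({"AT": 1500.0}, True),
            ({"AT": 1501.0}, False),
            ({"n_touches": 2}, False),
            ({"AT": np.nan}, True),  # undefined is not a violation here
        ],
    )
    def test_thresholds_strict(self, over, kept):
        keep, _ = exclude_trials(self.metrics(**over))
        assert keep[0] == kept

    def test_toy_table_counts(self):
        # 10 trials, 2 violating one rule each -> 8 retained
        m = pd.DataFrame(
            {
                "trial_id": range(10),
                "RT": [250] * 9 + [700],
                "MT": [200] * 4 + [400] + [200] * 5,
                "AT": [100] * 10,
                "n_touches": [1] * 10,
            }
        )
        keep, log = exclude_trials(m)
        assert keep.sum() == 8
        assert log.counts == {"RT": 1, "MT": 1, "AT": 0, "multi_touch": 0}

    def test_rules_order_independent_and_idempotent(self, rng):
        m = pd.DataFrame(
            {
                "trial_id": range(50),
                "RT": rng.uniform(0, 800, 50),
                "MT": rng.uniform(0, 500, 50),
                "AT": rng.uniform(0, 2000, 50),
                "n_touches": rng.integers(1, 3, 50),
            }
        )
        keep1, _ = exclude_trials(m)
        keep2, _ = exclude_trials(m.iloc[::-1].reset_index(drop=True))
        assert np.array_equal(keep1, keep2[::-1])
        keep3, _ = exclude_trials(m[keep1].reset_index(drop=True))
        assert keep3.all()


class TestForceDivergence:
    def build(self, means, n_per=6, jitter=0.01):
        """Traces whose mean force in (0, 100] ms after touch is means[force]."""
        rng = np.random.default_rng(0)
        rows, traces = [], {}
        tid = 0
        for g in ("whole_hand", "precision"):
            for force, mu in means.items():
                for _ in range(n_per):
                    rows.append({"grip": g, "force": force})
                    val = mu + rng.normal(0, jitter)
                    traces[tid] = ContinuousSignal(
                        np.full(2000, val), 1000.0, "N", t0=1820.0
                    )
                    tid += 1
        tt = make_table(rows)
        return traces, tt

    def test_identical_means_not_significant(self):
        traces, tt = self.build({"low": 3.0, "medium": 3.0, "high": 3.0}, jitter=0.05)
        res = compare_force_levels(traces, tt)
        assert not res["reject"].any()
        assert (res["anova_p"] > 0.05).all()

    def test_planted_low_vs_medium_pattern(self):
        # low << medium = high: low pairs significant, medium-high not
        traces, tt = self.build({"low": 1.0, "medium": 6.0, "high": 6.0}, jitter=0.2)
        res = compare_force_levels(traces, tt)
        for _, row in res.iterrows():
            if set(row["pair"].split("-")) == {"medium", "high"}:
                assert row["tukey_p"] > 0.05
            else:
                assert row["tukey_p"] < 0.001


class TestOvershoot:
    def test_planted_fractions(self):
        rows, traces = [], {}
        for i in range(10):
            rows.append({})
            val = 10.0 if i < 3 else 7.0  # medium band max is 9 N
            traces[i] = ContinuousSignal(np.full(3000, val), 1000.0, "N", t0=1820.0)
        tt = make_table(rows)
        res = overshoot_fraction(traces, tt)
        row = res[(res["grip"] == "whole_hand") & (res["force"] == "medium")].iloc[0]
        assert row["overshoot_fraction"] == pytest.approx(0.3)

    def test_no_overshoots(self):
        tt = make_table([{}])
        traces = {0: ContinuousSignal(np.full(3000, 7.0), 1000.0, "N", t0=1820.0)}
        res = overshoot_fraction(traces, tt)
        row = res[(res["grip"] == "whole_hand") & (res["force"] == "medium")].iloc[0]
        assert row["overshoot_fraction"] == 0.0


class TestPerformanceSummary:
    def test_fractions_and_denominators(self, small_session):
        s = performance_summary(small_session.trial_table)
        for col in ("success_after_cue", "success_after_go", "eye_fixation_errors"):
            assert s[col].between(0, 1).all()
        # fixation errors happen only before go, so the after-go rate is higher
        assert (s["success_after_go"] >= s["success_after_cue"]).all()
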