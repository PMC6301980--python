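"""Behavioral metrics, exclusion rules, performance summaries, and
force-trace statistics for the delayed grasping task.

Metrics per trial: reaction time RT = movement onset - go, movement time
MT = touch - movement onset, and acquisition time AT = first entry of the
force trace into the condition's band - touch (clipped at 0 when the force
is already in band at touch, which routinely happens for the low-force
band whose minimum is 0 N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .signals import ContinuousSignal
from .task import CONDITIONS, FORCES, GRIPS, DEFAULT_FORCE_BANDS

#: exclusion thresholds (strict inequalities), ms
RT_MAX = 500.0
MT_MAX = 350.0
AT_MAX = 1500.0


def compute_response_times(
    trial_table: pd.DataFrame,
    force_traces: dict[int, ContinuousSignal] | None = None,
    force_bands: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-trial RT, MT, AT (ms) and touch count.

    AT is measured from the force trace when available (first sample at or
    above the band minimum after touch, clipped at 0), otherwise from the
    ``t_force_acquired`` event. Missing events leave the metric NaN, never 0.
    """
    bands = force_bands or DEFAULT_FORCE_BANDS
    out = []
    for _, row in trial_table.iterrows():
        rt = row["t_movement"] - row["t_go"]
        mt = row["t_touch"] - row["t_movement"]
        at = np.nan
        tid = row["trial_id"]
        if force_traces is not None and tid in force_traces and np.isfinite(row["t_touch"]):
            sig = force_traces[tid]
            t = sig.times()
            band_min = bands[row["force"]][0]
            after = (t >= row["t_touch"]) & (sig.samples >= band_min)
            if after.any():
                at = max(0.0, float(t[np.argmax(after)] - row["t_touch"]))
        elif np.isfinite(row.get("t_force_acquired", np.nan)) and np.isfinite(row["t_touch"]):
            at = max(0.0, row["t_force_acquired"] - row["t_touch"])
        out.append(
            {
                "trial_id": tid,
                "RT": rt,
                "MT": mt,
                "AT": at,
                "n_touches": row.get("n_touches", 1),
            }
        )
    return pd.DataFrame(out)


@dataclass
class ExclusionLog:
    counts: dict[str, int] = field(default_factory=dict)
    n_excluded: int = 0
    n_total: int = 0


def exclude_trials(
    metrics: pd.DataFrame,
    rt_max: float = RT_MAX,
    mt_max: float = MT_MAX,
    at_max: float = AT_MAX,
) -> tuple[np.ndarray, ExclusionLog]:
    """Keep mask over trials: excluded iff RT > 500 ms, MT > 350 ms,
    AT > 1500 ms (all strict) or more than one sensor touch. NaN metrics do
    not trigger a rule (undefined, not zero). Rules are applied
    independently; the log counts violations per rule."""
    rules = {
        "RT": metrics["RT"].to_numpy() > rt_max,
        "MT": metrics["MT"].to_numpy() > mt_max,
        "AT": metrics["AT"].to_numpy() > at_max,
        "multi_touch": metrics["n_touches"].to_numpy() > 1,
    }
    # NaN comparisons are False, so undefined metrics never trigger a rule
    excl = np.zeros(len(metrics), dtype=bool)
    log = ExclusionLog(n_total=len(metrics))
    for name, viol in rules.items():
        log.counts[name] = int(viol.sum())
        excl |= viol
    log.n_excluded = int(excl.sum())
    return ~excl, log


def performance_summary(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition success fractions on the two denominators:
    trials initiated after cue onset and trials initiated after go
    (excluding trials lost to eye-fixation errors), plus the eye-fixation
    error fraction."""
    rows = []
    for g, f in CONDITIONS:
        sub = trial_table[(trial_table["grip"] == g) & (trial_table["force"] == f)]
        n_cue = len(sub)
        fix = (sub["failure_stage"] == "eye_fixation").sum()
        n_go = n_cue - fix
        succ = sub["success"].sum()
        rows.append(
            {
                "grip": g,
                "force": f,
                "success_after_cue": succ / n_cue if n_cue else np.nan,
                "success_after_go": succ / n_go if n_go else np.nan,
                "eye_fixation_errors": fix / n_cue if n_cue else np.nan,
            }
        )
    return pd.DataFrame(rows)


def mean_force_in_window(
    sig: ContinuousSignal, t_touch: float, window: tuple[float, float] = (0.0, 100.0)
) -> float:
    t = sig.times()
    m = (t >= t_touch + window[0]) & (t < t_touch + window[1])
    if not m.any():
        raise ValueError("empty force window")
    return float(sig.samples[m].mean())


def compare_force_levels(
    force_traces: dict[int, ContinuousSignal],
    trial_table: pd.DataFrame,
    window: tuple[float, float] = (0.0, 100.0),
) -> pd.DataFrame:
    """Early force divergence: per grip type, a one-way ANOVA across force
    levels on the mean force in the first 100 ms after touch, followed by
    Tukey-Kramer pairwise comparisons (valid for unequal trial counts).

    Returns one row per (grip, pair) with the Tukey-Kramer p-value, plus
    the grip's ANOVA p."""
    rows = []
    for g in GRIPS:
        vals, labs = [], []
        for _, row in trial_table.iterrows():
            if row["grip"] != g or row["trial_id"] not in force_traces:
                continue
            if not np.isfinite(row["t_touch"]):
                continue
            vals.append(
                mean_force_in_window(force_traces[row["trial_id"]], row["t_touch"], window)
            )
            labs.append(row["force"])
        vals, labs = np.array(vals), np.array(labs)
        groups = [vals[labs == f] for f in FORCES]
        if any(len(gr) < 2 for gr in groups):
            raise ValueError(f"need >=2 trials per force level for grip {g!r}")
        anova_p = stats.f_oneway(*groups).pvalue
        tk = pairwise_tukeyhsd(vals, labs)
        res = tk.summary().data[1:]
        for r in res:
            rows.append(
                {
                    "grip": g,
                    "pair": f"{r[0]}-{r[1]}",
                    "anova_p": anova_p,
                    "tukey_p": float(r[3]),
                    "mean_diff": float(r[2]),
                    "reject": bool(r[6]),
                }
            )
    return pd.DataFrame(rows)


def overshoot_fraction(
    force_traces: dict[int, ContinuousSignal],
    trial_table: pd.DataFrame,
    force_bands: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per condition, the fraction of successful trials whose force exceeds
    the band maximum at any sample between touch and reward."""
    bands = force_bands or DEFAULT_FORCE_BANDS
    rows = []
    for g, f in CONDITIONS:
        sub = trial_table[
            (trial_table["grip"] == g)
            & (trial_table["force"] == f)
            & trial_table["success"]
        ]
        n, n_over = 0, 0
        for _, row in sub.iterrows():
            if row["trial_id"] not in force_traces:
                continue
            sig = force_traces[row["trial_id"]]
            t = sig.times()
            m = (t >= row["t_touch"]) & (t <= row["t_reward"])
            n += 1
            if np.any(sig.samples[m] > bands[f][1]):
                n_over += 1
        rows.append(
            {"grip": g, "force": f, "n": n, "overshoot_fraction": n_over / n if n else np.nan}
        )
    return pd.DataFrame(rows)
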