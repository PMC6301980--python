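"""Synthetic delayed-grasping sessions with planted ground truth.

Generates complete sessions — trial tables with event times, inhomogeneous
Poisson spike trains, surface-EMG traces, and grip-force traces — whose
condition structure (condition-independent, force, grip, interaction) is
planted through low-dimensional latents, so every downstream analysis stage
can be validated against known ground truth.

Timing follows the task: fixation 400-500 ms, cue 800 ms, memory 500-700 ms,
go, reach, handle touch, force acquisition, 1 s hold, reward. Conditions are
drawn from a pool of 30 (5 copies of each of the six conditions); successful
draws are removed, failures stay, and the pool is topped up with one copy of
each condition whenever it drops below 25 — so a condition the subject fails
more often is re-presented more often.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rates import ALIGN_EVENTS, AlignmentSpec, kernel_pad, smooth_spike_matrix
from .signals import ContinuousSignal
from .task import CONDITIONS, FORCES, GRIPS, TaskConfig

MUSCLES = ("FDS", "EDC")


@dataclass
class BehaviorModel:
    """Per-trial response-time distributions (ms, truncated normals).

    Defaults reproduce typical macaque delayed-grasping statistics:
    RT 268 +/- 69 ms; MT 216 +/- 32 (whole-hand) / 220 +/- 42 (precision);
    AT mean/SD per condition increasing with force level, near zero for low
    force (the force sensor already registers before the touch sensors do).
    """

    rt_mean: float = 268.0
    rt_sd: float = 69.0
    mt_mean: dict[str, float] = field(
        default_factory=lambda: {"whole_hand": 216.0, "precision": 220.0}
    )
    mt_sd: dict[str, float] = field(
        default_factory=lambda: {"whole_hand": 32.0, "precision": 42.0}
    )
    at_mean: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("whole_hand", "low"): 113.0,
            ("whole_hand", "medium"): 467.0,
            ("whole_hand", "high"): 555.0,
            ("precision", "low"): 85.0,
            ("precision", "medium"): 561.0,
            ("precision", "high"): 718.0,
        }
    )
    at_sd: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("whole_hand", "low"): 230.0,
            ("whole_hand", "medium"): 295.0,
            ("whole_hand", "high"): 381.0,
            ("precision", "low"): 215.0,
            ("precision", "medium"): 329.0,
            ("precision", "high"): 360.0,
        }
    )
    #: probability of an overshoot (force transiently above the band maximum
    #: during acquisition) per condition
    p_overshoot: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("whole_hand", "low"): 0.22,
            ("whole_hand", "medium"): 0.68,
            ("whole_hand", "high"): 0.34,
            ("precision", "low"): 0.14,
            ("precision", "medium"): 0.48,
            ("precision", "high"): 0.34,
        }
    )
    p_eye_fixation_error: float = 0.10
    p_execution_error: float = 0.03
    p_double_touch: float = 0.02
    intertrial_ms: float = 1500.0


def schedule_conditions(
    config: TaskConfig,
    outcomes: np.ndarray,
    rng: np.random.Generator | None = None,
    return_pool_sizes: bool = False,
):
    """Draw a condition sequence from the refilled pool.

    ``outcomes`` is the per-trial success flag (True = the drawn item is
    removed from the pool), or a callable mapping the drawn condition to a
    success flag. The pool starts with ``pool_size // 6`` copies of each
    condition; whenever its size drops below ``pool_refill_threshold`` one
    copy of each condition is added, so it can never empty.
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    pool = list(CONDITIONS) * (config.pool_size // len(CONDITIONS))
    if callable(outcomes):
        flags = None
        n = config.n_trials
    else:
        flags = list(outcomes)
        n = len(flags)
    labels, sizes = [], []
    for k in range(n):
        sizes.append(len(pool))
        i = int(rng.integers(len(pool)))
        labels.append(pool[i])
        success = outcomes(pool[i]) if flags is None else flags[k]
        if success:
            pool.pop(i)
            if len(pool) < config.pool_refill_threshold:
                pool.extend(CONDITIONS)
    if return_pool_sizes:
        return labels, np.array(sizes)
    return labels


def _trunc_normal(rng, mean, sd, lo=0.0):
    while True:
        v = rng.normal(mean, sd)
        if v >= lo:
            return v


def simulate_trial(
    config: TaskConfig,
    condition: tuple[str, str],
    rng: np.random.Generator,
    behavior: BehaviorModel | None = None,
    t_start: float = 0.0,
) -> tuple[dict[str, float], ContinuousSignal, dict]:
    """Simulate one successful trial: event times and the force trace.

    The force trace is a logistic rise to a plateau inside the condition's
    band, crossing the band minimum exactly at touch + AT. On overshoot
    trials a transient above the band maximum is inserted during
    acquisition; force acquisition is then the final band entry, after
    which the trace stays in band for the full hold.
    """
    behavior = behavior or BehaviorModel()
    grip, force = condition
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    band = config.force_bands[force]
    ev = {"fixation": t_start}
    ev["cue_on"] = ev["fixation"] + rng.uniform(*config.fixation_range)
    ev["cue_off"] = ev["cue_on"] + config.cue_duration
    ev["go"] = ev["cue_off"] + rng.uniform(*config.memory_range)
    ev["movement"] = ev["go"] + _trunc_normal(rng, behavior.rt_mean, behavior.rt_sd, 80.0)
    ev["touch"] = ev["movement"] + _trunc_normal(
        rng, behavior.mt_mean[grip], behavior.mt_sd[grip], 50.0
    )
    at = _trunc_normal(rng, behavior.at_mean[condition], behavior.at_sd[condition], 0.0)
    overshoot = rng.random() < behavior.p_overshoot.get(condition, 0.0)

    # force trace at 1 kHz from well before touch
    t0 = ev["touch"] - 400.0
    width = band[1] - band[0]
    plateau = band[0] + rng.uniform(0.3, 0.8) * width
    thr = max(band[0], 0.3)
    # slower targets are approached more gradually; crossing stays at touch+AT
    tau = max(40.0, at / 3.0)
    t_cross = ev["touch"] + at
    t50 = t_cross + tau * np.log(plateau / thr - 1.0) if plateau > thr else t_cross
    # provisional duration covers acquisition + hold + margin
    n = int(at + config.hold_duration + 1500)
    t = t0 + np.arange(n)
    trace = plateau / (1.0 + np.exp(-(t - t50) / tau))
    if overshoot:
        peak_t = t_cross + 140.0
        amp = (band[1] - plateau) + rng.uniform(0.3, 1.0)
        trace = trace + amp * np.exp(-0.5 * ((t - peak_t) / 50.0) ** 2)
    # final band entry = force acquisition
    inside = (trace >= band[0]) & (trace <= band[1]) & (t >= ev["touch"])
    out_after = np.nonzero(~inside & (t >= t_cross))[0]
    last_out = out_after[out_after < np.searchsorted(t, t_cross + 1000)]
    t_fa = t_cross if len(last_out) == 0 else float(t[last_out[-1]] + 1)
    ev["force_acquired"] = t_fa
    ev["reward"] = t_fa + config.hold_duration
    end = int(np.searchsorted(t, ev["reward"] + 200.0))
    sig = ContinuousSignal(trace[:end], rate=1000.0, unit="N", t0=t0)
    info = {"overshoot": overshoot, "at": at}
    return ev, sig, info


@dataclass
class Latent:
    """One planted latent: a time profile on the composite timeline and
    per-condition coefficients (force x grip) confined to one
    marginalization by centering."""

    name: str
    marginalization: str
    profile: np.ndarray  # (n_bins,) on the composite 10-ms timeline
    coeffs: np.ndarray  # (3 force, 2 grip)
    amplitude: float = 1.0  # spikes/s scale

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        m = self.marginalization
        tol = 1e-9
        if m == "condition_independent":
            ok = np.allclose(c, c.flat[0])
        elif m == "force":
            ok = np.allclose(c.mean(axis=0), 0, atol=tol) and np.allclose(
                c, c[:, :1]
            )
        elif m == "grip":
            ok = np.allclose(c.mean(axis=1), 0, atol=tol) and np.allclose(
                c, c[:1, :]
            )
        elif m == "interaction":
            ok = np.allclose(c.mean(axis=0), 0, atol=tol) and np.allclose(
                c.mean(axis=1), 0, atol=tol
            )
        else:
            raise ValueError(f"unknown marginalization {m!r}")
        if not ok:
            raise ValueError(
                f"coefficients of latent {self.name!r} violate the "
                f"{m} centering constraints"
            )
        self.coeffs = c

    def pattern(self) -> np.ndarray:
        """(force, grip, bins) condition pattern, amplitude included."""
        p = self.profile
        if self.marginalization == "condition_independent":
            p = p - p.mean()  # keep the grand mean in the baselines
        return self.amplitude * self.coeffs[:, :, None] * p[None, None, :]


@dataclass
class LatentSpec:
    """Planted latents, per-unit mixing weights, and baselines."""

    latents: list[Latent]
    mixing: np.ndarray  # (units, latents)
    baselines: np.ndarray  # (units,) spikes/s
    #: positive weights of each muscle on the condition-independent and
    #: force latents (EMG shares those latents with the population)
    emg_mixing: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.baselines < 0):
            raise ValueError("baselines must be nonnegative")

    @property
    def n_units(self) -> int:
        return len(self.baselines)

    def rate_tensor(self, spec: AlignmentSpec | None = None) -> np.ndarray:
        """Noiseless (units, force, grip, bins) rates, rectified at 0."""
        spec = spec or AlignmentSpec()
        n_bins = spec.n_bins
        out = np.broadcast_to(
            self.baselines[:, None, None, None],
            (self.n_units, len(FORCES), len(GRIPS), n_bins),
        ).copy()
        for li, lat in enumerate(self.latents):
            out += self.mixing[:, li, None, None, None] * lat.pattern()
        return np.maximum(out, 0.0)

    def ground_truth_shares(self, spec: AlignmentSpec | None = None) -> dict[str, float]:
        """Marginalization variance shares of the rectified noiseless tensor."""
        from .dpca import marginalize

        return marginalize(self.rate_tensor(spec)).variance_shares()


def _bump(centers: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((centers - mu) / sigma) ** 2)


def default_latents(
    n_units: int = 100,
    shares: tuple[float, float, float, float] = (0.70, 0.15, 0.10, 0.05),
    baseline: tuple[float, float] = (15.0, 30.0),
    modulation_sd: float = 5.0,
    rng: np.random.Generator | None = None,
    spec: AlignmentSpec | None = None,
) -> LatentSpec:
    """One latent per marginalization with amplitudes chosen so the planted
    variance shares equal ``shares`` (before rectification).

    Profiles: a broad condition-independent reach/grasp profile peaking at
    touch; a force profile growing through late cue/memory and maximal in
    the hold epoch; a grip profile peaking at touch; an interaction profile
    in the hold epoch. ``modulation_sd`` sets the RMS of the planted
    modulation in spikes/s.
    """
    rng = rng or np.random.default_rng(0)
    spec = spec or AlignmentSpec()
    sls = spec.segment_slices()
    cc, tc, rc = spec.bin_centers()
    nb = spec.n_bins

    def compose(cue, touch, reward):
        p = np.zeros(nb)
        p[sls[0]], p[sls[1]], p[sls[2]] = cue, touch, reward
        return p

    prof_ci = compose(
        0.3 * _bump(cc, 500.0, 300.0),
        1.0 * _bump(tc, 0.0, 250.0),
        0.8 * _bump(rc, -700.0, 300.0) + 0.3 * _bump(rc, 100.0, 120.0),
    )
    prof_force = compose(
        0.25 * _bump(cc, 700.0, 350.0),
        0.8 * _bump(tc, 300.0, 300.0),
        1.0 * _bump(rc, -500.0, 350.0),
    )
    prof_grip = compose(
        0.4 * _bump(cc, 600.0, 300.0),
        1.0 * _bump(tc, 0.0, 200.0),
        0.5 * _bump(rc, -850.0, 250.0),
    )
    prof_int = compose(
        np.zeros_like(cc), 0.6 * _bump(tc, 350.0, 250.0), 1.0 * _bump(rc, -400.0, 300.0)
    )
    c_force = np.repeat(np.array([[-1.1], [0.1], [1.0]]), 2, axis=1)
    c_grip = np.repeat(np.array([[-1.0, 1.0]]), 3, axis=0)
    c_int = np.array([[1.0, -1.0], [-1.0, 1.0], [0.0, 0.0]])
    latents = [
        Latent("reach", "condition_independent", prof_ci, np.ones((3, 2))),
        Latent("force", "force", prof_force, c_force),
        Latent("grip", "grip", prof_grip, c_grip),
        Latent("grip_x_force", "interaction", prof_int, c_int),
    ]
    mixing = rng.normal(size=(n_units, len(latents)))
    # amplitude per latent so realized shares match the targets exactly
    # (pre-rectification): marg variance = ||w_l||^2 amp_l^2 * SS(pattern_l)
    total = n_units * 3 * 2 * nb * modulation_sd**2
    for li, (lat, sh) in enumerate(zip(latents, shares)):
        ss = float((lat.pattern() ** 2).sum())
        w2 = float((mixing[:, li] ** 2).sum())
        lat.amplitude = np.sqrt(sh * total / (w2 * ss))
    baselines = rng.uniform(*baseline, size=n_units)
    emg_mixing = {
        "FDS": np.array([1.0, 0.6]),
        "EDC": np.array([0.8, 0.45]),
    }
    return LatentSpec(latents, mixing, baselines, emg_mixing)


def _latent_realtime(
    lat: Latent, ev: dict[str, float], t: np.ndarray, spec: AlignmentSpec
) -> np.ndarray:
    """Evaluate a latent's composite-timeline profile in real (session) time
    for one trial, blending linearly across window gaps and overlaps."""
    centers = spec.bin_centers()
    sls = spec.segment_slices()
    segs = [lat.profile[sl] for sl in sls]
    abs_win = [
        (ev[e] + spec.windows[e][0], ev[e] + spec.windows[e][1]) for e in ALIGN_EVENTS
    ]
    vals = [
        np.interp(t - ev[e], c, s)
        for e, c, s in zip(ALIGN_EVENTS, centers, segs)
    ]
    out = np.empty_like(t, dtype=float)
    c0, c1 = abs_win[0]
    t0, t1 = abs_win[1]
    r0, r1 = abs_win[2]
    out[:] = vals[0]
    # cue->touch gap
    if t0 > c1:
        m = (t >= c1) & (t < t0)
        w = (t[m] - c1) / (t0 - c1)
        out[m] = (1 - w) * segs[0][-1] + w * segs[1][0]
    m = (t >= t0) & (t < min(t1, r0))
    out[m] = vals[1][m]
    if r0 < t1:  # overlap: blend touch- into reward-aligned values
        m = (t >= r0) & (t < t1)
        w = (t[m] - r0) / (t1 - r0)
        out[m] = (1 - w) * vals[1][m] + w * vals[2][m]
    elif r0 > t1:  # gap
        m = (t >= t1) & (t < r0)
        w = (t[m] - t1) / (r0 - t1)
        out[m] = (1 - w) * segs[1][-1] + w * segs[2][0]
    m = t >= max(r0, t1)
    out[m] = vals[2][m]
    return out


def trial_rate_matrix(
    latents: LatentSpec,
    ev: dict[str, float],
    condition: tuple[str, str],
    t: np.ndarray,
    spec: AlignmentSpec,
) -> np.ndarray:
    """Noiseless (units, len(t)) firing rates for one trial."""
    grip, force = condition
    fi, gi = FORCES.index(force), GRIPS.index(grip)
    drive = np.zeros((len(latents.latents), len(t)))
    for li, lat in enumerate(latents.latents):
        p = _latent_realtime(lat, ev, t, spec)
        if lat.marginalization == "condition_independent":
            p = p - lat.profile.mean()
        drive[li] = lat.amplitude * lat.coeffs[fi, gi] * p
    rates = latents.baselines[:, None] + latents.mixing @ drive
    return np.maximum(rates, 0.0)


def simulate_population(
    latents: LatentSpec,
    trial_table: pd.DataFrame,
    rng: np.random.Generator,
    spec: AlignmentSpec | None = None,
) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike times (1 ms resolution) per unit.

    Rates are baseline + mixing . latents, rectified at 0, evaluated over
    each trial's analysis support (cue window to reward window, padded by
    the smoothing support).
    """
    spec = spec or AlignmentSpec()
    pad = kernel_pad(spec)
    spikes: list[list[np.ndarray]] = [[] for _ in range(latents.n_units)]
    for _, row in trial_table.iterrows():
        if not row["success"]:
            continue
        ev = {e: row[f"t_{e}"] for e in ("fixation", "cue_on", "cue_off", "go",
                                         "movement", "touch", "force_acquired",
                                         "reward")}
        lo = ev["cue_on"] + spec.windows["cue_on"][0] - pad
        hi = ev["reward"] + spec.windows["reward"][1] + pad
        t = np.arange(lo, hi)
        rates = trial_rate_matrix(latents, ev, (row["grip"], row["force"]), t, spec)
        draw = rng.random(rates.shape) < rates / 1000.0
        for u in range(latents.n_units):
            spikes[u].append(t[draw[u]])
    return [np.sort(np.concatenate(s)) if s else np.array([]) for s in spikes]


def simulate_emg(
    latents: LatentSpec,
    trial_table: pd.DataFrame,
    rng: np.random.Generator,
    spec: AlignmentSpec | None = None,
    noise_sd: float = 0.02,
    envelope: bool = False,
) -> dict[str, ContinuousSignal]:
    """Session-long 1 kHz EMG per muscle: a rectified, movement-gated
    mixture of the condition-independent and force latents plus noise.

    EMG is silent before the go signal, peaks around touch, and its peak is
    monotone in force level. By default the returned signal is the envelope
    amplitude-modulating a broadband noise carrier (so the standard
    band-pass / rectify / smooth / normalize chain applies); with
    ``envelope=True`` the noiseless envelope itself is returned.
    """
    spec = spec or AlignmentSpec()
    t_end = float(trial_table["t_reward"].max() + 1500.0)
    t = np.arange(0.0, t_end)
    lat_ci = next(l for l in latents.latents if l.marginalization == "condition_independent")
    lat_f = next(l for l in latents.latents if l.marginalization == "force")
    out = {}
    base = {m: np.full_like(t, 0.05) for m in latents.emg_mixing}
    for _, row in trial_table.iterrows():
        if not row["success"] or not np.isfinite(row["t_reward"]):
            continue
        ev = {e: row[f"t_{e}"] for e in ("fixation", "cue_on", "cue_off", "go",
                                         "movement", "touch", "force_acquired",
                                         "reward")}
        fi = FORCES.index(row["force"])
        lo = int(max(ev["go"], 0))
        hi = int(min(ev["reward"] + 400, t_end))
        tt = t[lo:hi]
        gate = 1.0 / (1.0 + np.exp(-(tt - (ev["movement"] - 20.0)) / 15.0))
        ci = _latent_realtime(lat_ci, ev, tt, spec) / max(lat_ci.profile.max(), 1e-12)
        ff = _latent_realtime(lat_f, ev, tt, spec) / max(lat_f.profile.max(), 1e-12)
        for m, w in latents.emg_mixing.items():
            drive = w[0] * ci + w[1] * (1.2 + lat_f.coeffs[fi, 0]) * ff
            base[m][lo:hi] += np.maximum(drive, 0.0) * gate
    for m in latents.emg_mixing:
        x = base[m]
        if noise_sd > 0:
            x = np.abs(x + rng.normal(0, noise_sd, size=x.shape))
        if envelope:
            out[m] = ContinuousSignal(x, rate=1000.0, unit="norm_emg", t0=0.0)
        else:
            carrier = rng.normal(0.0, 1.0, size=x.shape)
            out[m] = ContinuousSignal(x * carrier, rate=1000.0, unit="uV", t0=0.0)
    return out


@dataclass
class SyntheticSession:
    """A complete synthetic session plus its planted ground truth."""

    config: TaskConfig
    trial_table: pd.DataFrame
    spikes: list[np.ndarray]
    emg: dict[str, ContinuousSignal]
    force: dict[int, ContinuousSignal]
    latents: LatentSpec
    ground_truth: dict

    def successful_trials(self) -> pd.DataFrame:
        return self.trial_table[self.trial_table["success"]]


def simulate_session(
    config: TaskConfig | None = None,
    latents: LatentSpec | None = None,
    behavior: BehaviorModel | None = None,
    n_units: int = 100,
    rng_seed: int | None = None,
    spec: AlignmentSpec | None = None,
    with_spikes: bool = True,
    with_emg: bool = True,
) -> SyntheticSession:
    """Generate a full synthetic session. Same seed, same session."""
    config = config or TaskConfig()
    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    behavior = behavior or BehaviorModel()
    spec = spec or AlignmentSpec()
    if latents is None:
        latents = default_latents(n_units=n_units, rng=rng, spec=spec)

    # outcomes drawn up front so the scheduler is exercised exactly as specified
    fix_err = rng.random(config.n_trials) < behavior.p_eye_fixation_error
    exec_err = rng.random(config.n_trials) < behavior.p_execution_error
    success = ~(fix_err | exec_err)
    labels = schedule_conditions(config, success, rng)

    rows = []
    force_traces: dict[int, ContinuousSignal] = {}
    t_clock = 0.0
    for i, (cond, ok) in enumerate(zip(labels, success)):
        ev, trace, info = simulate_trial(config, cond, rng, behavior, t_start=t_clock)
        n_touch = 1 + int(rng.random() < behavior.p_double_touch)
        row = {
            "trial_id": i,
            "grip": cond[0],
            "force": cond[1],
            **{f"t_{e}": ev[e] for e in ev},
            "success": bool(ok),
            "failure_stage": "",
            "n_touches": n_touch,
        }
        if not ok:
            stage = "eye_fixation" if fix_err[i] else "execution"
            row["failure_stage"] = stage
            if stage == "eye_fixation":
                # broke fixation before go: no movement-related events
                cut = ev["go"]
                for e in ("movement", "touch", "force_acquired", "reward"):
                    row[f"t_{e}"] = np.nan
            else:
                row["t_force_acquired"] = np.nan
                row["t_reward"] = np.nan
            t_clock = cut if not ok and stage == "eye_fixation" else ev["touch"]
            t_clock += behavior.intertrial_ms
        else:
            force_traces[i] = trace
            t_clock = ev["reward"] + behavior.intertrial_ms
        rows.append(row)
    table = pd.DataFrame(rows)

    spikes = (
        simulate_population(latents, table, rng, spec)
        if with_spikes
        else [np.array([])] * latents.n_units
    )
    emg = simulate_emg(latents, table, rng, spec) if with_emg else {}
    gt = {
        "variance_shares": latents.ground_truth_shares(spec),
        "n_units": latents.n_units,
        "seed": seed,
    }
    return SyntheticSession(config, table, spikes, emg, force_traces, latents, gt)


def simulate_unit_bin_rates(
    profiles_hz: np.ndarray,
    trials_per_condition: int,
    rng: np.random.Generator,
    spec: AlignmentSpec | None = None,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Fast path for test-calibration studies: Poisson spike trains for one
    unit directly on the composite timeline, smoothed and decimated by the
    standard rate-estimation kernel.

    ``profiles_hz``: (6, total_ms) 1-ms rate profiles per condition in the
    canonical condition order. Returns (rates (trials, bins), labels).
    """
    spec = spec or AlignmentSpec()
    pad = kernel_pad(spec)
    seg_ms = spec.segment_lengths_ms()
    bounds = np.cumsum([0] + seg_ms)
    n_cond = len(CONDITIONS)
    n_tr = trials_per_condition * n_cond
    labels = [cond for cond in CONDITIONS for _ in range(trials_per_condition)]
    prof = np.repeat(profiles_hz, trials_per_condition, axis=0)  # (trials, ms)
    parts = []
    for si in range(3):
        a, b = bounds[si], bounds[si + 1]
        seg = prof[:, a:b]
        seg = np.concatenate(
            [np.repeat(seg[:, :1], pad, axis=1), seg, np.repeat(seg[:, -1:], pad, axis=1)],
            axis=1,
        )
        sp = (rng.random(seg.shape) < seg / 1000.0).astype(float)
        parts.append(smooth_spike_matrix(sp, spec, pad=pad))
    return np.concatenate(parts, axis=1), labels


def simulate_population_bin_rates(
    rate_tensor_hz: np.ndarray,
    trials_per_condition: int,
    rng: np.random.Generator,
    spec: AlignmentSpec | None = None,
) -> np.ndarray:
    """Trial-resolved noisy rates for a whole population directly on the
    composite timeline.

    ``rate_tensor_hz``: noiseless (units, force, grip, bins) rates (e.g.
    from :meth:`LatentSpec.rate_tensor`). Per unit and condition, 1-ms
    Poisson spike trains are drawn and pushed through the standard
    smoothing/decimation, giving (units, force, grip, bins, trials).
    """
    spec = spec or AlignmentSpec()
    u, nf, ng, nb = rate_tensor_hz.shape
    out = np.empty((u, nf, ng, nb, trials_per_condition))
    for ui in range(u):
        prof = np.repeat(
            rate_tensor_hz[ui].transpose(1, 0, 2).reshape(nf * ng, nb), 10, axis=1
        )
        rates, _ = simulate_unit_bin_rates(prof, trials_per_condition, rng, spec)
        out[ui] = rates.reshape(ng, nf, trials_per_condition, nb).transpose(1, 0, 3, 2)
    return out


def null_unit_profiles(
    baseline_hz: float = 20.0, spec: AlignmentSpec | None = None
) -> np.ndarray:
    """Condition-identical flat rate profiles (the permutation-test null)."""
    spec = spec or AlignmentSpec()
    return np.full((len(CONDITIONS), sum(spec.segment_lengths_ms())), baseline_hz)


def force_effect_profiles(
    baseline_hz: float = 20.0,
    effect_hz: float = 0.0,
    spec: AlignmentSpec | None = None,
) -> np.ndarray:
    """Profiles with a force effect confined to the hold epoch: force levels
    at baseline, baseline + effect, baseline + 2*effect during the hold
    (from force acquisition to reward, i.e. the reward-aligned window up to
    reward onset)."""
    spec = spec or AlignmentSpec()
    seg_ms = spec.segment_lengths_ms()
    prof = np.full((len(CONDITIONS), sum(seg_ms)), baseline_hz)
    # hold epoch within the reward-aligned segment: -1000..0 ms
    a = seg_ms[0] + seg_ms[1]
    hold = slice(a, a + 1000)
    for ci, (g, f) in enumerate(CONDITIONS):
        prof[ci, hold] += FORCES.index(f) * effect_hz
    return prof
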