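"""End-to-end orchestration: generator -> behavior -> conditioning ->
rates -> tuning -> dPCA -> EMG correlation, from a single config with
deterministic per-stage seeds."""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import io as gio
from .dpca import DPCAConfig, decode_over_time, explained_variance, fit_dpca, marginalize
from .emgcorr import ShiftSearchSpec, average_marginalizations, correlate_components
from .rates import AlignmentSpec, continuous_to_condition_tensor, mask_and_interpolate, spikes_to_rates
from .signals import SmoothingSpec, gaussian_smooth, preprocess_emg
from .synthetic import simulate_session
from .task import CONDITIONS, TaskConfig
from .tuning import ClusterTestConfig, EFFECTS, population_fractions, preferred_force, test_unit

STAGES = ("simulate", "behavior", "condition", "rates", "tuning", "dpca", "emgcorr")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str = "graspdyn_out"
    rng_seed: int = 0
    n_units: int = 40
    n_trials: int = 240
    stages: tuple[str, ...] = STAGES
    task: TaskConfig = field(default_factory=TaskConfig)
    alignment: AlignmentSpec = field(default_factory=AlignmentSpec)
    tuning: ClusterTestConfig = field(default_factory=ClusterTestConfig)
    dpca: DPCAConfig = field(default_factory=DPCAConfig)
    shift: ShiftSearchSpec = field(default_factory=ShiftSearchSpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        sub = {
            "task": TaskConfig, "alignment": AlignmentSpec,
            "tuning": ClusterTestConfig, "dpca": DPCAConfig,
            "shift": ShiftSearchSpec,
        }
        kwargs = {}
        for k, v in raw.items():
            kwargs[k] = sub[k](**v) if k in sub else v
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        text = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; every stage writes its
    outputs (TSV/HDF5/JSON) under ``out_dir`` and the returned report maps
    stage -> summary. Downstream stages refuse to run without their inputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.rng_seed,
        "stages": {},
    }
    enabled = set(config.stages)
    session = None

    def need(stage: str, obj, what: str):
        if obj is None:
            raise RuntimeError(f"stage {stage!r} is missing its input: {what}")

    if "simulate" in enabled:
        t0 = time.time()
        task = TaskConfig(**{**config.task.__dict__,
                             "n_trials": config.n_trials,
                             "rng_seed": stage_seed(config.rng_seed, "simulate")})
        session = simulate_session(task, n_units=config.n_units, spec=config.alignment)
        gio.write_trial_table(session.trial_table, out / "trial_table.tsv")
        gio.write_session_h5(out / "session.h5", session.spikes, session.emg, session.force)
        gio.write_json(session.ground_truth, out / "ground_truth.json")
        report["stages"]["simulate"] = {
            "n_trials": len(session.trial_table),
            "n_successful": int(session.trial_table["success"].sum()),
            "n_units": session.latents.n_units,
            "seconds": round(time.time() - t0, 2),
        }

    keep_table = None
    if "behavior" in enabled:
        need("behavior", session, "a simulated session")
        tt = session.successful_trials()
        metrics = bh.compute_response_times(tt, session.force, session.config.force_bands)
        keep, log = bh.exclude_trials(metrics)
        keep_table = tt[keep]
        summary = bh.performance_summary(session.trial_table)
        force_cmp = bh.compare_force_levels(session.force, keep_table)
        over = bh.overshoot_fraction(session.force, keep_table, session.config.force_bands)
        metrics.to_csv(out / "trial_metrics.tsv", sep="\t", index=False)
        summary.to_csv(out / "performance_summary.tsv", sep="\t", index=False)
        force_cmp.to_csv(out / "force_divergence.tsv", sep="\t", index=False)
        over.to_csv(out / "overshoot_fractions.tsv", sep="\t", index=False)
        report["stages"]["behavior"] = {
            "excluded": log.counts,
            "n_kept": int(keep.sum()),
            "median_RT": float(np.nanmedian(metrics["RT"])),
        }

    emg_clean = None
    if "condition" in enabled:
        need("condition", session, "a simulated session")
        fix_windows = [
            (row["t_fixation"], row["t_cue_on"])
            for _, row in session.successful_trials().iterrows()
        ]
        emg_clean = {
            m: preprocess_emg(sig, fix_windows) for m, sig in session.emg.items()
        }
        force_smooth = {
            k: gaussian_smooth(sig, SmoothingSpec(sigma=10.0))
            for k, sig in session.force.items()
        }
        gio.write_session_h5(out / "conditioned.h5", emg=emg_clean, force=force_smooth)
        report["stages"]["condition"] = {"muscles": sorted(emg_clean)}

    tensor = None
    timeline = None
    if "rates" in enabled:
        need("rates", session, "a simulated session")
        table = keep_table if keep_table is not None else session.successful_trials()
        raw = spikes_to_rates(session.spikes, table, config.alignment)
        med_at = {}
        for g, f in CONDITIONS:
            sub = table[(table["grip"] == g) & (table["force"] == f)]
            med_at[(g, f)] = float((sub["t_force_acquired"] - sub["t_touch"]).median())
        tensor, timeline = mask_and_interpolate(raw, med_at)
        gio.write_rate_tensor_h5(out / "rates.h5", tensor)
        report["stages"]["rates"] = {
            "n_bins": tensor.spec.n_bins,
            "interpolated": timeline.interpolated,
            "median_AT_ms": {f"{g}|{f}": med_at[(g, f)] for g, f in CONDITIONS},
        }

    results = None
    if "tuning" in enabled:
        need("tuning", tensor, "the rate tensor")
        cfg = config.tuning
        breaks = (170,) if (timeline and timeline.interpolated) else cfg.segment_breaks
        cfg = ClusterTestConfig(**{**cfg.__dict__, "segment_breaks": breaks,
                                   "rng_seed": stage_seed(config.rng_seed, "tuning")})
        rng = np.random.default_rng(cfg.rng_seed)
        results = [
            test_unit(tensor.trial_resolved[u], tensor.labels, cfg, rng)
            for u in range(tensor.trial_resolved.shape[0])
        ]
        avg = tensor.trial_averaged()
        rows = []
        for u, res in enumerate(results):
            preferred_force(avg[u].mean(axis=1), res)
            for eff in EFFECTS:
                for c in res.clusters[eff]:
                    rows.append({"unit": u, "effect": eff, "start": c.start,
                                 "end": c.end, "summed_F": c.summed_F,
                                 "significant": c.significant})
        pd.DataFrame(rows, columns=["unit", "effect", "start", "end",
                                    "summed_F", "significant"]).to_csv(
            out / "tuning_clusters.tsv", sep="\t", index=False)
        fracs = population_fractions(results)
        pd.DataFrame(fracs).to_csv(out / "tuning_fractions.tsv", sep="\t", index=False)
        report["stages"]["tuning"] = {
            eff: int(sum(r.any_significant(eff) for r in results)) for eff in EFFECTS
        }

    model = None
    if "dpca" in enabled:
        need("dpca", tensor, "the rate tensor")
        dcfg = DPCAConfig(**{**config.dpca.__dict__,
                             "rng_seed": stage_seed(config.rng_seed, "dpca")})
        t5 = tensor.stacked_5d()
        model = fit_dpca(t5, dcfg)
        ev = explained_variance(model)
        gio.write_json(ev, out / "dpca_variance.json")
        dec = {}
        for factor in ("grip", "force"):
            try:
                r = decode_over_time(model, t5, factor, dcfg)
            except ValueError:
                continue
            dec[factor] = {
                "mean_accuracy": float(r.accuracy.mean()),
                "significant_intervals": r.significant_intervals(),
            }
        gio.write_json(dec, out / "dpca_decoding.json")
        report["stages"]["dpca"] = {
            "lambda": model.chosen_lambda,
            "marginalization_variance": model.marginalization_variance,
            "decoding": dec,
        }

    if "emgcorr" in enabled:
        need("emgcorr", model, "a fitted dPCA model")
        need("emgcorr", session, "a simulated session")
        table = keep_table if keep_table is not None else session.successful_trials()
        emg_src = emg_clean if emg_clean is not None else session.emg
        margs = [
            marginalize(continuous_to_condition_tensor(sig, table, config.alignment))
            for sig in emg_src.values()
        ]
        avg_marg = average_marginalizations(margs)
        res = correlate_components(avg_marg, model, tensor.trial_averaged(),
                                   config.shift)
        rows = [
            {"factor": f, "component": i + 1, "r2": v}
            for f, vals in res.r2.items()
            for i, v in enumerate(vals)
        ]
        pd.DataFrame(rows).to_csv(out / "emg_correlation.tsv", sep="\t", index=False)
        report["stages"]["emgcorr"] = {
            "shift_ms": res.chosen_shift_ms,
            "r2": res.r2,
        }

    gio.write_json(report, out / "report.json")
    return report
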