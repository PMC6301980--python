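"""On-disk formats: trial tables as TSV, continuous signals and spike times
as HDF5 (with sampling-rate attributes), ground truth and reports as JSON,
plus schema validation with line-level diagnostics."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .signals import ContinuousSignal
from .task import EVENTS, FORCES, GRIPS

TRIAL_COLUMNS = (
    ["trial_id", "grip", "force"]
    + [f"t_{e}" for e in EVENTS]
    + ["success", "failure_stage", "n_touches"]
)


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=TRIAL_COLUMNS, na_rep="NA")


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["failure_stage"] = df["failure_stage"].fillna("")
    return df


def write_session_h5(
    path: str | Path,
    spikes: list[np.ndarray] | None = None,
    emg: dict[str, ContinuousSignal] | None = None,
    force: dict[int, ContinuousSignal] | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        if spikes is not None:
            g = f.create_group("spikes")
            for u, st in enumerate(spikes):
                d = g.create_dataset(f"unit_{u:04d}", data=np.asarray(st, dtype=float))
                d.attrs["unit"] = "ms"
        for name, group in (("emg", emg), ("force", force)):
            if not group:
                continue
            g = f.create_group(name)
            for key, sig in group.items():
                d = g.create_dataset(str(key), data=sig.samples)
                d.attrs["rate"] = sig.rate
                d.attrs["unit"] = sig.unit
                d.attrs["t0"] = sig.t0


def read_session_h5(path: str | Path):
    spikes, emg, force = [], {}, {}
    with h5py.File(path, "r") as f:
        if "spikes" in f:
            for k in sorted(f["spikes"]):
                spikes.append(f["spikes"][k][...])
        for name, store in (("emg", emg), ("force", force)):
            if name not in f:
                continue
            for k in f[name]:
                d = f[name][k]
                key = int(k) if name == "force" else k
                store[key] = ContinuousSignal(
                    d[...], rate=float(d.attrs["rate"]), unit=str(d.attrs["unit"]),
                    t0=float(d.attrs["t0"]),
                )
    return spikes, emg, force


def write_rate_tensor_h5(path: str | Path, tensor) -> None:
    """Store a RateTensor with dimension labels and bin centers."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("trial_resolved", data=tensor.trial_resolved)
        d.attrs["dims"] = "unit,trial,bin"
        f.create_dataset("trial_averaged", data=tensor.trial_averaged()).attrs[
            "dims"
        ] = "unit,force,grip,bin"
        f.create_dataset(
            "bin_centers", data=np.concatenate(tensor.spec.bin_centers())
        )
        lab = np.array([f"{g}|{fo}" for g, fo in tensor.labels], dtype="S")
        f.create_dataset("trial_labels", data=lab)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=1, default=default, sort_keys=True))


def validate_trial_table(path: str | Path) -> list[str]:
    """Schema check for a trial-table TSV; returns a list of problems
    (empty = pass), each naming the offending row where applicable."""
    problems = []
    try:
        df = read_trial_table(path)
    except Exception as e:  # noqa: BLE001
        return [f"unreadable TSV: {e}"]
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        problems.append(f"missing columns: {sorted(missing)}")
        return problems
    for i, row in df.iterrows():
        if row["grip"] not in GRIPS:
            problems.append(f"row {i}: grip {row['grip']!r} not in {GRIPS}")
        if row["force"] not in FORCES:
            problems.append(f"row {i}: force {row['force']!r} not in {FORCES}")
        times = [row[f"t_{e}"] for e in EVENTS]
        finite = [t for t in times if np.isfinite(t)]
        if row["success"] and len(finite) != len(times):
            problems.append(f"row {i}: successful trial with missing event time")
        if any(np.diff(finite) < 0):
            problems.append(f"row {i}: event times out of causal order")
    return problems


def validate_session_h5(path: str | Path) -> list[str]:
    problems = []
    try:
        with h5py.File(path, "r") as f:
            for name in ("emg", "force"):
                if name not in f:
                    continue
                for k in f[name]:
                    for attr in ("rate", "unit", "t0"):
                        if attr not in f[name][k].attrs:
                            problems.append(f"{name}/{k}: missing attribute {attr!r}")
    except Exception as e:  # noqa: BLE001
        return [f"unreadable HDF5: {e}"]
    return problems


def validate_io(paths: dict[str, str | Path]) -> dict[str, list[str]]:
    """Validate a bundle of outputs; keys ``trial_table`` and/or
    ``session_h5``. Returns per-file problem lists (all empty = pass)."""
    report = {}
    if "trial_table" in paths:
        report["trial_table"] = validate_trial_table(paths["trial_table"])
    if "session_h5" in paths:
        report["session_h5"] = validate_session_h5(paths["session_h5"])
    return report
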