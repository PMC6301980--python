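"""Time-shifted correlation between EMG marginalizations and demixed
principal components.

For each brain area, the time shift maximizing R^2 between a reference
condition-independent dPC and the EMG condition-independent marginalization
is found on a -500..+500 ms grid (10-ms steps, matching the analysis bins);
that single shift is then applied to all other (factor, component) pairs.
Per factor, the condition time courses are concatenated (three segments for
force, two for grip) before computing one squared Pearson correlation.

Sign convention: a positive shift means the neural signal precedes (leads)
the muscle signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dpca import DPCAModel, MarginalizationSet

FACTORS = ("condition_independent", "force", "grip")


@dataclass
class ShiftSearchSpec:
    range_ms: float = 500.0
    step_ms: float = 10.0
    #: which condition-independent dPC fixes the shift (1-based; areas where
    #: the largest component is muscle-unrelated may use the second)
    reference_component: int = 1
    min_overlap_frac: float = 0.5

    def shifts_bins(self) -> np.ndarray:
        if self.range_ms % self.step_ms:
            raise ValueError("step must divide the shift range")
        n = int(self.range_ms // self.step_ms)
        return np.arange(-n, n + 1)


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ValueError("zero-variance series")
    return float(((a * b).sum() / denom) ** 2)


def _shifted_pairs(
    neural: np.ndarray, emg: np.ndarray, shift: int
) -> tuple[np.ndarray, np.ndarray]:
    """Crop to the masked overlap after shifting; ``shift`` in bins, positive
    = neural leads (neural[t] pairs with emg[t + shift])."""
    n = neural.shape[-1]
    if shift >= 0:
        return neural[..., : n - shift], emg[..., shift:]
    return neural[..., -shift:], emg[..., : n + shift]


def shift_scan(
    neural: np.ndarray, emg: np.ndarray, spec: ShiftSearchSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """R^2 per shift on the grid for a pair of (conditions x bins) or (bins,)
    series. Condition rows are shifted jointly and concatenated before the
    correlation. Returns (shifts in ms, R^2 per shift)."""
    spec = spec or ShiftSearchSpec()
    neural = np.atleast_2d(neural)
    emg = np.atleast_2d(emg)
    if neural.shape != emg.shape:
        raise ValueError("series shapes differ")
    shifts = spec.shifts_bins()
    n = neural.shape[-1]
    if n - shifts.max() < spec.min_overlap_frac * n:
        raise ValueError("overlap after shifting would be below the minimum")
    r2 = np.empty(len(shifts))
    for i, s in enumerate(shifts):
        a, b = _shifted_pairs(neural, emg, int(s))
        r2[i] = _r2(a.ravel(), b.ravel())
    return shifts * spec.step_ms, r2


@dataclass
class CorrelationResult:
    chosen_shift_ms: float  # positive = neural leads muscle
    #: factor -> per component (largest, second largest) R^2
    r2: dict[str, list[float]] = field(default_factory=dict)
    reference_component: int = 1


def _factor_courses(model: DPCAModel, tensor: np.ndarray, factor: str, rank: int):
    comps = model.components_of(factor)
    if rank >= len(comps):
        return None
    tc = model.time_courses(comps[rank], tensor)  # (force, grip, bins)
    if factor == "condition_independent":
        return tc.mean(axis=(0, 1))[None, :]
    if factor == "force":
        return tc.mean(axis=1)  # (3, bins)
    if factor == "grip":
        return tc.mean(axis=0)  # (2, bins)
    raise ValueError(factor)


def _emg_courses(margs: MarginalizationSet, factor: str) -> np.ndarray:
    arr = margs.combined(factor)
    arr = arr.reshape((-1,) + arr.shape[-3:])[0]  # (force, grip, bins)
    if factor == "condition_independent":
        return arr[0, 0][None, :]
    if factor == "force":
        return arr[:, 0, :]  # (3, bins)
    if factor == "grip":
        return arr[0, :, :]  # (2, bins)
    raise ValueError(factor)


def average_marginalizations(sets: list[MarginalizationSet]) -> MarginalizationSet:
    """Average the marginalizations of several muscles term by term."""
    keys = sets[0].terms.keys()
    return MarginalizationSet(
        {k: np.mean([s.terms[k] for s in sets], axis=0) for k in keys}
    )


def correlate_components(
    emg_margs: MarginalizationSet,
    model: DPCAModel,
    tensor: np.ndarray,
    spec: ShiftSearchSpec | None = None,
) -> CorrelationResult:
    """R^2 between the muscle-averaged EMG marginalizations and the two
    largest dPCs per factor, at a single shift fixed on the reference
    condition-independent component.

    ``tensor``: the trial-averaged (units, force, grip, bins) rates the
    model was fitted on (components are re-projected onto it).
    """
    spec = spec or ShiftSearchSpec()
    ref = _factor_courses(model, tensor, "condition_independent",
                          spec.reference_component - 1)
    if ref is None:
        raise ValueError("model lacks the reference condition-independent component")
    emg_ci = _emg_courses(emg_margs, "condition_independent")
    shifts_ms, r2 = shift_scan(ref, emg_ci, spec)
    best = int(np.argmax(r2))
    shift_bins = int(round(shifts_ms[best] / spec.step_ms))

    result = CorrelationResult(float(shifts_ms[best]), {},
                               spec.reference_component)
    for factor in FACTORS:
        emg_tc = _emg_courses(emg_margs, factor)
        vals = []
        for rank in (0, 1):
            tc = _factor_courses(model, tensor, factor, rank)
            if tc is None:
                vals.append(np.nan)
                continue
            a, b = _shifted_pairs(tc, emg_tc, shift_bins)
            try:
                vals.append(_r2(a.ravel(), b.ravel()))
            except ValueError:  # a factor absent from one of the signals
                vals.append(np.nan)
        result.r2[factor] = vals
    return result
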