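"""Firing-rate estimation on the three-alignment composite timeline.

Spike trains are binned at 1 ms, smoothed with a unit-sum Gaussian
(sigma = 50 ms), and sampled on three event-aligned windows: cue onset
(-400..+1300 ms), handle touch (-500..+500 ms), and reward onset
(-1000..+200 ms). The windows are concatenated into one composite timeline
and decimated to 10-ms analysis bins (390 bins total).

When the median force-acquisition time (AT) of a condition is short, the
end of the touch-aligned window and the start of the reward-aligned window
cover the same data; that span is masked for display and replaced by linear
interpolation for statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import SmoothingSpec
from .task import CONDITIONS, FORCES, GRIPS

#: events each alignment window is locked to
ALIGN_EVENTS = ("cue_on", "touch", "reward")


@dataclass
class AlignmentSpec:
    """The composite-timeline geometry.

    ``windows`` maps alignment event -> (start, stop) in ms relative to the
    event. Defaults give segment lengths 1700 + 1000 + 1200 = 3900 ms,
    i.e. 390 analysis bins of 10 ms.
    """

    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "cue_on": (-400.0, 1300.0),
            "touch": (-500.0, 500.0),
            "reward": (-1000.0, 200.0),
        }
    )
    rate_sigma: float = 50.0
    bin_ms: float = 10.0

    def segment_lengths_ms(self) -> list[int]:
        return [int(b - a) for a, b in (self.windows[e] for e in ALIGN_EVENTS)]

    def segment_bins(self) -> list[int]:
        return [int(n // self.bin_ms) for n in self.segment_lengths_ms()]

    @property
    def n_bins(self) -> int:
        return sum(self.segment_bins())

    def segment_slices(self) -> list[slice]:
        bounds = np.cumsum([0] + self.segment_bins())
        return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    def bin_centers(self) -> list[np.ndarray]:
        """Per segment, bin-center times in ms relative to the alignment event."""
        out = []
        for ev in ALIGN_EVENTS:
            a, b = self.windows[ev]
            out.append(np.arange(a + self.bin_ms / 2, b, self.bin_ms))
        return out


@dataclass
class CompositeTimeline:
    """Bin centers, segment labels and the display/interpolation mask."""

    spec: AlignmentSpec
    #: per condition (grip, force) -> boolean display mask over bins
    display_mask: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    interpolated: bool = False

    def segment_of_bin(self) -> np.ndarray:
        lab = np.empty(self.spec.n_bins, dtype=int)
        for i, sl in enumerate(self.spec.segment_slices()):
            lab[sl] = i
        return lab


@dataclass
class RateTensor:
    """Trial-resolved and trial-averaged firing rates (spikes/s) on the
    composite 10-ms timeline.

    ``trial_resolved``: (units, trials, bins); ``labels``: list of
    (grip, force) per trial. The averaged tensor (units, force, grip, bins)
    is the within-condition mean of the trial-resolved rates.
    """

    trial_resolved: np.ndarray
    labels: list[tuple[str, str]]
    spec: AlignmentSpec

    def __post_init__(self) -> None:
        if self.trial_resolved.shape[1] != len(self.labels):
            raise ValueError("trial count mismatch between rates and labels")

    def condition_trials(self, grip: str, force: str) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.labels) if lab == (grip, force)])

    def trial_averaged(self) -> np.ndarray:
        """(units, force, grip, bins) condition means."""
        u, _, b = self.trial_resolved.shape
        out = np.empty((u, len(FORCES), len(GRIPS), b))
        for fi, f in enumerate(FORCES):
            for gi, g in enumerate(GRIPS):
                idx = self.condition_trials(g, f)
                if len(idx) == 0:
                    raise ValueError(f"no trials for condition ({g}, {f})")
                out[:, fi, gi] = self.trial_resolved[:, idx].mean(axis=1)
        return out

    def stacked_5d(self) -> np.ndarray:
        """(units, force, grip, bins, trials) with trial counts equalized by
        truncation to the smallest per-condition count."""
        counts = [len(self.condition_trials(g, f)) for g, f in CONDITIONS]
        r = min(counts)
        u, _, b = self.trial_resolved.shape
        out = np.empty((u, len(FORCES), len(GRIPS), b, r))
        for fi, f in enumerate(FORCES):
            for gi, g in enumerate(GRIPS):
                idx = self.condition_trials(g, f)[:r]
                out[:, fi, gi, :, :] = np.moveaxis(self.trial_resolved[:, idx], 1, -1)
        return out


def smooth_spike_matrix(
    spikes_1ms: np.ndarray, spec: AlignmentSpec, pad: int | None = None
) -> np.ndarray:
    """Smooth 1-ms binary spike rows into rates (spikes/s) and decimate at
    10-ms bin centers.

    ``spikes_1ms``: (..., n_ms) with n_ms = segment length + 2*pad; ``pad``
    extends the window by the kernel support on each side so that the bins
    inside the window are free of boundary bias. Returns (..., n_bins) for
    one segment of length ``n_ms - 2*pad``.
    """
    kernel = SmoothingSpec(sigma=spec.rate_sigma).kernel(1000.0)
    half = len(kernel) // 2
    if pad is None:
        pad = half
    from scipy.signal import fftconvolve

    rate = fftconvolve(spikes_1ms * 1000.0, kernel[(None,) * (spikes_1ms.ndim - 1)], mode="same", axes=-1)
    n_ms = spikes_1ms.shape[-1] - 2 * pad
    centers = pad + np.arange(spec.bin_ms / 2, n_ms, spec.bin_ms).astype(int)
    return rate[..., centers]


def kernel_pad(spec: AlignmentSpec) -> int:
    """Samples of padding needed on each side of an alignment window."""
    return len(SmoothingSpec(sigma=spec.rate_sigma).kernel(1000.0)) // 2


def spikes_to_rates(
    spikes: list[np.ndarray],
    trial_table,
    spec: AlignmentSpec | None = None,
) -> RateTensor:
    """Build the composite-timeline rate tensor from spike-time lists.

    Parameters
    ----------
    spikes : list of ndarray
        Per unit, spike times in ms on the session clock.
    trial_table : pandas.DataFrame
        One row per trial with columns ``grip``, ``force`` and event-time
        columns ``t_cue_on``, ``t_touch``, ``t_reward`` (ms). Trials with a
        missing alignment event are dropped (and counted).
    """
    spec = spec or AlignmentSpec()
    pad = kernel_pad(spec)
    ev_cols = [f"t_{e}" for e in ALIGN_EVENTS]
    ok = trial_table[ev_cols].notna().all(axis=1)
    tt = trial_table[ok]
    labels = list(zip(tt["grip"], tt["force"]))

    seg_bins = spec.segment_bins()
    n_units = len(spikes)
    out = np.empty((n_units, len(tt), spec.n_bins))
    for u, st in enumerate(spikes):
        st = np.asarray(st, dtype=float)
        for ti, (_, row) in enumerate(tt.iterrows()):
            col = 0
            for ev, nb in zip(ALIGN_EVENTS, seg_bins):
                a, b = spec.windows[ev]
                t_ev = row[f"t_{ev}"]
                lo = t_ev + a - pad
                n_ms = int(b - a) + 2 * pad
                idx = np.floor(st - lo).astype(int)
                idx = idx[(idx >= 0) & (idx < n_ms)]
                train = np.zeros(n_ms)
                np.add.at(train, idx, 1.0)
                out[u, ti, col : col + nb] = smooth_spike_matrix(train, spec, pad=pad)
                col += nb
    return RateTensor(out, labels, spec)


def continuous_to_condition_tensor(
    sig, trial_table, spec: AlignmentSpec | None = None
) -> np.ndarray:
    """Average a continuous signal (EMG, force) into the (force, grip, bins)
    condition tensor on the composite timeline.

    Per trial and alignment window the signal is sampled at the 10-ms bin
    centers (nearest sample); trials missing an alignment event are skipped.
    """
    from .task import FORCES, GRIPS  # local to avoid cycle at import time

    spec = spec or AlignmentSpec()
    t = sig.times()
    centers = spec.bin_centers()
    acc = np.zeros((len(FORCES), len(GRIPS), spec.n_bins))
    cnt = np.zeros((len(FORCES), len(GRIPS), 1))
    for _, row in trial_table.iterrows():
        if not all(np.isfinite(row[f"t_{e}"]) for e in ALIGN_EVENTS):
            continue
        fi, gi = FORCES.index(row["force"]), GRIPS.index(row["grip"])
        vals = []
        for ev, c in zip(ALIGN_EVENTS, centers):
            idx = np.clip(
                np.round((row[f"t_{ev}"] + c - sig.t0) * sig.rate / 1000.0).astype(int),
                0,
                sig.n_samples - 1,
            )
            vals.append(sig.samples[..., idx])
        acc[fi, gi] += np.concatenate(vals, axis=-1)
        cnt[fi, gi] += 1
    if np.any(cnt == 0):
        raise ValueError("a condition has no complete trials")
    return acc / cnt


def overlap_mask(
    spec: AlignmentSpec, median_at_ms: float
) -> np.ndarray:
    """Boolean mask over composite bins covering the duplicated span between
    the touch- and reward-aligned segments.

    When the median AT is below 500 ms, the first part of the reward-aligned
    window (from reward-1000 ms up to reward-(median AT + 500) ms) repeats
    information already present after touch; those bins are masked. For
    median AT >= 500 ms the mask is empty.
    """
    mask = np.zeros(spec.n_bins, dtype=bool)
    if median_at_ms >= 500.0:
        return mask
    sl = spec.segment_slices()[2]
    centers = spec.bin_centers()[2]
    mask[sl] = centers < -(median_at_ms + 500.0)
    return mask


def mask_and_interpolate(
    tensor: RateTensor, median_at: dict[tuple[str, str], float]
) -> tuple[RateTensor, CompositeTimeline]:
    """Apply the overlap rule per condition.

    Returns a new tensor whose masked span is replaced, per trial, by linear
    interpolation between the boundary bin values (used for statistics), and
    a :class:`CompositeTimeline` carrying the per-condition display masks.
    """
    spec = tensor.spec
    timeline = CompositeTimeline(spec)
    rr = tensor.trial_resolved.copy()
    any_interp = False
    for cond in CONDITIONS:
        g, f = cond
        mask = overlap_mask(spec, median_at.get(cond, np.inf))
        timeline.display_mask[cond] = mask
        if not mask.any():
            continue
        any_interp = True
        idx = tensor.condition_trials(g, f)
        if len(idx) == 0:
            continue
        first, last = np.nonzero(mask)[0][[0, -1]]
        left, right = first - 1, last + 1
        w = np.arange(1, last - first + 2) / (last - first + 2)
        seg = (
            rr[:, idx, left, None] * (1 - w)
            + rr[:, idx, right, None] * w
        )
        rr[:, idx[:, None], np.arange(first, last + 1)[None, :]] = seg
    timeline.interpolated = any_interp
    return RateTensor(rr, tensor.labels, spec), timeline
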