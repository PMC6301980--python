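"""Continuous-signal conditioning: Gaussian smoothing, EMG preprocessing,
median high-pass for broadband data, and PCA common-artifact cancellation.

All filters are zero-phase (non-causal): the Butterworth stages run
forward-backward (``sosfiltfilt``), which doubles the effective order, and
the Gaussian / median kernels are symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal


@dataclass
class ContinuousSignal:
    """A uniformly sampled signal with physical units.

    Parameters
    ----------
    samples : ndarray
        Sample values, shape (n,) or (n_channels, n).
    rate : float
        Sampling rate in Hz.
    unit : str
        Physical unit, e.g. ``"N"``, ``"uV"``, ``"norm_emg"``, ``"spikes/s"``.
    t0 : float
        Time of the first sample in ms (session clock).
    """

    samples: np.ndarray
    rate: float
    unit: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + np.arange(self.n_samples) * 1000.0 / self.rate

    def replace(self, samples: np.ndarray, unit: str | None = None) -> "ContinuousSignal":
        return ContinuousSignal(samples, self.rate, self.unit if unit is None else unit, self.t0)


@dataclass
class SmoothingSpec:
    """Gaussian smoothing kernel: ``sigma`` in ms, truncated at
    ``support * sigma`` on each side and renormalized to unit sum (so
    constants are preserved exactly)."""

    sigma: float = 10.0
    support: float = 2.5

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def kernel(self, rate: float) -> np.ndarray:
        """Unit-sum truncated Gaussian sampled at ``rate`` Hz."""
        sigma_samp = self.sigma * rate / 1000.0
        half = int(np.ceil(self.support * sigma_samp))
        x = np.arange(-half, half + 1)
        k = np.exp(-0.5 * (x / sigma_samp) ** 2)
        return k / k.sum()


def smooth_array(x: np.ndarray, kernel: np.ndarray, axis: int = -1) -> np.ndarray:
    """Convolve along ``axis`` with reflected edges; output length preserved."""
    half = len(kernel) // 2
    pad = [(0, 0)] * x.ndim
    pad[axis] = (half, half)
    xp = np.pad(x, pad, mode="reflect")
    out = ndimage.convolve1d(xp, kernel, axis=axis, mode="nearest")
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(half, half + x.shape[axis])
    return out[tuple(sl)]


def gaussian_smooth(sig: ContinuousSignal, spec: SmoothingSpec | None = None) -> ContinuousSignal:
    """Smooth with a truncated, renormalized Gaussian kernel (default
    sigma = 10 ms). Edges are handled by reflection; length is preserved."""
    spec = spec or SmoothingSpec()
    k = spec.kernel(sig.rate)
    if len(k) > sig.n_samples:
        raise ValueError("smoothing support longer than signal")
    return sig.replace(smooth_array(sig.samples, k))


def preprocess_emg(
    raw: ContinuousSignal,
    fixation_windows: list[tuple[float, float]] | None,
    band: tuple[float, float] = (25.0, 250.0),
    order: int = 6,
    smoothing: SmoothingSpec | None = None,
) -> ContinuousSignal:
    """Standard EMG conditioning: 25-250 Hz 6th-order Butterworth band-pass
    (zero-phase), rectification, Gaussian smoothing (sigma = 10 ms), and
    normalization by the mean smoothed activity over the trials' fixation
    epochs.

    ``fixation_windows`` is a list of (start, stop) times in ms on the
    signal's clock; ``None`` skips the normalization step (diagnostics).
    """
    if raw.rate <= 2 * band[1]:
        raise ValueError("sampling rate too low for the band-pass upper edge")
    sos = signal.butter(order, band, btype="bandpass", fs=raw.rate, output="sos")
    x = signal.sosfiltfilt(sos, raw.samples, axis=-1)
    x = np.abs(x)
    smoothing = smoothing or SmoothingSpec()
    x = smooth_array(x, smoothing.kernel(raw.rate))
    if fixation_windows is None:
        return raw.replace(x, unit="norm_emg")

    t = raw.t0 + np.arange(x.shape[-1]) * 1000.0 / raw.rate
    mask = np.zeros(x.shape[-1], dtype=bool)
    for a, b in fixation_windows:
        mask |= (t >= a) & (t < b)
    if not mask.any():
        raise ValueError("no samples fall inside the fixation windows")
    base = x[..., mask].mean(axis=-1, keepdims=True)
    if np.any(base == 0):
        raise ValueError("fixation-epoch mean is zero; cannot normalize")
    return raw.replace(x / base, unit="norm_emg")


def median_window_samples(window_ms: float, rate: float) -> int:
    """Median-filter window in samples: nearest odd count (medians need an
    odd window), e.g. 3.33 ms at 30 kHz -> 99."""
    return 2 * int(round((window_ms * rate / 1000.0 - 1) / 2)) + 1


def median_highpass(sig: ContinuousSignal, window_ms: float = 3.33) -> ContinuousSignal:
    """Subtract a running median (high-pass for broadband data).

    The window is ``window_ms`` converted to the nearest odd sample count
    (3.33 ms at 30 kHz -> 99 samples); edges use shrinking windows.
    """
    n = median_window_samples(window_ms, sig.rate)
    if n < 3:
        raise ValueError("median window must span at least 3 samples")
    if n > sig.n_samples:
        raise ValueError("median window longer than signal")
    x = sig.samples
    med = ndimage.median_filter(x, size=(1,) * (x.ndim - 1) + (n,), mode="nearest")
    # shrink the window at the edges instead of padding
    half = n // 2
    med = np.array(med)
    for i in range(half):
        med[..., i] = np.median(x[..., : i + half + 1], axis=-1)
        med[..., -(i + 1)] = np.median(x[..., -(i + half + 1):], axis=-1)
    return sig.replace(x - med)


def lowpass(sig: ContinuousSignal, cutoff: float = 5000.0, order: int = 4) -> ContinuousSignal:
    """Zero-phase Butterworth low-pass (default 5000 Hz, 4th order)."""
    sos = signal.butter(order, cutoff, btype="lowpass", fs=sig.rate, output="sos")
    return sig.replace(signal.sosfiltfilt(sos, sig.samples, axis=-1))


def pca_artifact_cancel(
    channels: ContinuousSignal, coeff_threshold: float = 0.36
) -> ContinuousSignal:
    """Remove common-mode artifacts shared across an electrode array.

    Channels are normalized to unit variance, decomposed by PCA, and every
    principal dimension whose loading vector has no coefficient exceeding
    ``coeff_threshold`` in magnitude is treated as a common artifact and
    subtracted. Dimensions with any loading above the threshold carry
    channel-specific signal and are retained, so no individual channel can
    be eliminated.
    """
    x = channels.samples
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd
    # principal axes of the channel covariance
    cov = z @ z.T / z.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    artifact = np.abs(evecs).max(axis=0) <= coeff_threshold
    v = evecs[:, artifact]
    z_clean = z - v @ (v.T @ z)
    return channels.replace(z_clean * sd + mean)
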