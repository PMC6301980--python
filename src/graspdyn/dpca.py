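"""Demixed principal component analysis and marginalization algebra.

A condition-labeled tensor x(unit, force, grip, time) is decomposed into
eight averaged terms (grand mean; time; force; grip; time-force; time-grip;
force-grip; time-force-grip), which sum back to the tensor exactly. The
combined marginalizations are

* condition-independent = x_t
* force                 = x_f + x_tf
* grip                  = x_g + x_tg
* interaction           = x_fg + x_tfg

dPCA finds, per combined marginalization X_phi, a rank-limited pair of
decoder F and encoder D minimizing ||X_phi - D F X||^2 + mu ||D F||^2 with
X the full centered trial-averaged matrix — a reduced-rank ridge regression
with a closed-form solution. Decoding significance uses a stratified
Monte Carlo leave-group-out linear classifier against a label-shuffle
chance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import FORCES, GRIPS

MARGINALIZATIONS = ("condition_independent", "force", "grip", "interaction")

#: averaging axes of the (force, grip, time) condition axes for each of the
#: eight terms; tensor axes here are (unit, force, grip, time)
_TERMS = ("mean", "t", "f", "g", "tf", "tg", "fg", "tfg")


@dataclass
class MarginalizationSet:
    """The eight averaged terms, each broadcast back to full tensor shape,
    plus the four combined marginalizations."""

    terms: dict[str, np.ndarray]

    def combined(self, which: str) -> np.ndarray:
        if which == "condition_independent":
            return self.terms["t"]
        if which == "force":
            return self.terms["f"] + self.terms["tf"]
        if which == "grip":
            return self.terms["g"] + self.terms["tg"]
        if which == "interaction":
            return self.terms["fg"] + self.terms["tfg"]
        raise KeyError(which)

    def reconstruct(self) -> np.ndarray:
        return sum(self.terms.values())

    def centered(self) -> np.ndarray:
        """Input minus the grand mean."""
        return self.reconstruct() - self.terms["mean"]

    def variance_shares(self) -> dict[str, float]:
        """Share of total (grand-mean-centered) variance per combined
        marginalization. On a balanced design the four shares sum to 1."""
        tot = float((self.centered() ** 2).sum())
        return {
            m: float((self.combined(m) ** 2).sum()) / tot for m in MARGINALIZATIONS
        }


def marginalize(tensor: np.ndarray) -> MarginalizationSet:
    """Decompose a (..., force, grip, time) tensor into the eight averaged
    terms. Leading axes (e.g. unit) are carried through untouched.

    Each term is centered over every axis it was averaged on, so the terms
    are mutually orthogonal on a balanced design and sum back to the input
    exactly.
    """
    x = np.asarray(tensor, dtype=float)
    f_ax, g_ax, t_ax = x.ndim - 3, x.ndim - 2, x.ndim - 1

    def avg(arr, axes):
        return arr.mean(axis=axes, keepdims=True)

    xbar = avg(x, (f_ax, g_ax, t_ax))
    xc = x - xbar
    xt = avg(xc, (f_ax, g_ax))
    xf = avg(xc, (t_ax, g_ax))
    xg = avg(xc, (t_ax, f_ax))
    resid = xc - xt - xf - xg
    xtf = avg(resid, (g_ax,))
    xtg = avg(resid, (f_ax,))
    xfg = avg(resid, (t_ax,))
    xtfg = resid - xtf - xtg - xfg
    full = np.broadcast_to
    shape = x.shape
    terms = {
        "mean": full(xbar, shape).copy(),
        "t": full(xt, shape).copy(),
        "f": full(xf, shape).copy(),
        "g": full(xg, shape).copy(),
        "tf": full(xtf, shape).copy(),
        "tg": full(xtg, shape).copy(),
        "fg": full(xfg, shape).copy(),
        "tfg": xtfg,
    }
    return MarginalizationSet(terms)


@dataclass
class DPCAConfig:
    n_components: int = 30
    lambdas: np.ndarray = field(
        default_factory=lambda: np.concatenate([[0.0], np.logspace(-7, -2.5, 10)])
    )
    lambda_repetitions: int = 10
    cv_iterations: int = 100
    n_shuffles: int = 100
    consecutive_bins: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if not np.any(self.lambdas == 0):
            raise ValueError("lambda grid must include 0")


@dataclass
class Component:
    marginalization: str
    index: int  # rank within its marginalization (0 = largest)
    encoder: np.ndarray  # (units,)
    decoder: np.ndarray  # (units,)
    explained_variance: float  # fraction of total centered variance


@dataclass
class DPCAModel:
    components: list[Component]
    #: noise-corrected signal-variance shares per combined marginalization
    marginalization_variance: dict[str, float]
    #: raw shares of the trial-averaged tensor (no noise-floor subtraction)
    marginalization_variance_raw: dict[str, float]
    total_variance: float
    mean_rates: np.ndarray  # per-unit grand mean removed before fitting
    chosen_lambda: float
    shape: tuple[int, int, int, int]  # units, force, grip, time

    def components_of(self, marg: str) -> list[Component]:
        return sorted(
            (c for c in self.components if c.marginalization == marg),
            key=lambda c: -c.explained_variance,
        )

    def time_courses(self, comp: Component, tensor: np.ndarray) -> np.ndarray:
        """Project a (units, force, grip, time) tensor onto the component's
        decoder -> (force, grip, time)."""
        x = tensor - self.mean_rates[:, None, None, None]
        return np.einsum("u,ufgt->fgt", comp.decoder, x)


def _flatten(t: np.ndarray) -> np.ndarray:
    return t.reshape(t.shape[0], -1)


def _fit_axes(
    Xphi: np.ndarray, X: np.ndarray, mu: float, rank: int
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form reduced-rank ridge: returns (D, F) with D (units, rank)
    encoder columns and F (rank, units) decoder rows."""
    U = X.shape[0]
    G = X @ X.T + mu * np.eye(U)
    # pinv handles rank-deficient data at mu = 0
    A = Xphi @ X.T @ np.linalg.pinv(G, hermitian=True)
    # rank reduction: project onto the top left-singular space of A X
    M = A @ X
    uu, ss, _ = np.linalg.svd(M, full_matrices=False)
    r = min(rank, np.sum(ss > max(ss[0], 1e-300) * 1e-12)) if ss.size else 0
    D = uu[:, :r]
    F = D.T @ A
    return D, F


def _holdout_split(
    tensor_5d: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Hold out one random trial per (unit, condition); returns
    (train mean tensor, test tensor), both (units, force, grip, time)."""
    u, nf, ng, t, r = tensor_5d.shape
    pick = rng.integers(0, r, size=(u, nf, ng))
    idx = np.broadcast_to(pick[..., None, None], (u, nf, ng, t, 1))
    test = np.take_along_axis(tensor_5d, idx, axis=-1)[..., 0]
    train = (tensor_5d.sum(axis=-1) - test) / (r - 1)
    return train, test


def select_lambda(
    tensor_5d: np.ndarray, config: DPCAConfig, rng: np.random.Generator
) -> float:
    """Pick the ridge parameter by held-out-trial reconstruction error,
    averaged over ``lambda_repetitions`` random holdouts."""
    errs = np.zeros(len(config.lambdas))
    u = tensor_5d.shape[0]
    rank = min(config.n_components, u)
    for _ in range(config.lambda_repetitions):
        train, test = _holdout_split(tensor_5d, rng)
        Xtr = _flatten(train - train.mean(axis=(1, 2, 3), keepdims=True))
        Xte = _flatten(test - train.mean(axis=(1, 2, 3), keepdims=True))
        margs = marginalize(train - train.mean(axis=(1, 2, 3), keepdims=True))
        norm2 = float((Xtr**2).sum())
        for li, lam in enumerate(config.lambdas):
            mu = (lam * np.sqrt(norm2)) ** 2
            recon = np.zeros_like(Xte)
            for m in MARGINALIZATIONS:
                Xphi = _flatten(margs.combined(m))
                D, F = _fit_axes(Xphi, Xtr, mu, rank)
                recon += D @ (F @ Xte)
            errs[li] += float(((Xte - recon) ** 2).sum())
    return float(config.lambdas[int(np.argmin(errs))])


def _noise_floor(
    tensor_5d: np.ndarray, rng: np.random.Generator, n_splits: int = 10
) -> tuple[dict[str, float], float]:
    """Noise sums-of-squares of the trial-averaged tensor, per combined
    marginalization, estimated by split-half differences.

    Half the difference of two half-means has exactly the noise covariance
    of the full trial mean, so marginalizing it gives an unbiased noise
    floor per marginalization even when the noise variance depends on
    condition (Poisson) or is correlated over time (smoothing). Averaged
    over ``n_splits`` random splits.
    """
    r = tensor_5d.shape[-1]
    half = r // 2
    acc = {m: 0.0 for m in MARGINALIZATIONS}
    tot = 0.0
    for _ in range(n_splits):
        order = rng.permutation(r)
        d = (
            tensor_5d[..., order[:half]].mean(axis=-1)
            - tensor_5d[..., order[half : 2 * half]].mean(axis=-1)
        ) * 0.5 * np.sqrt(2 * half / r)
        d = d - d.mean(axis=(1, 2, 3), keepdims=True)
        margs = marginalize(d)
        for m in MARGINALIZATIONS:
            acc[m] += float((margs.combined(m) ** 2).sum())
        tot += float((d**2).sum())
    return {m: v / n_splits for m, v in acc.items()}, tot / n_splits


def fit_dpca(
    tensor_5d: np.ndarray,
    config: DPCAConfig | None = None,
    rng: np.random.Generator | None = None,
    lam: float | None = None,
) -> DPCAModel:
    """Fit dPCA on the trial-averaged tensor derived from a 5-D
    (units, force, grip, time, trials) array.

    The ridge parameter is chosen on ``config.lambdas`` by held-out-trial
    reconstruction unless ``lam`` is given. Components are ordered by
    explained variance; at most ``n_components`` are kept in total.
    """
    config = config or DPCAConfig()
    rng = rng or np.random.default_rng(config.rng_seed)
    if tensor_5d.ndim != 5:
        raise ValueError("expected (units, force, grip, time, trials)")
    avg = tensor_5d.mean(axis=-1)
    mean_rates = avg.mean(axis=(1, 2, 3))
    centered = avg - mean_rates[:, None, None, None]
    X = _flatten(centered)
    total_var = float((X**2).sum())
    if total_var == 0:
        raise ValueError("tensor has no variance")

    if lam is None:
        if tensor_5d.shape[-1] >= 2 and len(config.lambdas) > 1:
            lam = select_lambda(tensor_5d, config, rng)
        else:
            lam = 0.0
    mu = (lam * np.sqrt(total_var)) ** 2

    margs = marginalize(centered)
    rank = min(config.n_components, X.shape[0])
    components: list[Component] = []
    marg_ss: dict[str, float] = {}
    for m in MARGINALIZATIONS:
        Xphi = _flatten(margs.combined(m))
        marg_ss[m] = float((Xphi**2).sum())
        if marg_ss[m] <= 1e-20 * total_var:  # degenerate marginalization
            continue
        D, F = _fit_axes(Xphi, X, mu, rank)
        for i in range(D.shape[1]):
            ev = float(((D[:, i : i + 1] @ (F[i : i + 1] @ X)) ** 2).sum()) / total_var
            components.append(Component(m, i, D[:, i], F[i], ev))
    components.sort(key=lambda c: -c.explained_variance)
    components = components[: config.n_components]

    raw = {m: marg_ss[m] / total_var for m in MARGINALIZATIONS}
    corrected = dict(raw)
    n_trials = tensor_5d.shape[-1]
    if n_trials >= 2:
        noise_ss, noise_tot = _noise_floor(tensor_5d, rng)
        denom = max(total_var - noise_tot, 1e-12)
        corrected = {
            m: max(marg_ss[m] - noise_ss[m], 0.0) / denom for m in MARGINALIZATIONS
        }
    return DPCAModel(
        components, corrected, raw, total_var, mean_rates, float(lam), avg.shape
    )


def explained_variance(model: DPCAModel) -> dict[str, object]:
    """Per-component and per-marginalization explained-variance fractions."""
    per_comp = [
        {
            "marginalization": c.marginalization,
            "rank": c.index,
            "explained_variance": c.explained_variance,
        }
        for c in model.components
    ]
    return {
        "components": per_comp,
        "marginalizations": dict(model.marginalization_variance),
    }


@dataclass
class DecodingResult:
    factor: str
    accuracy: np.ndarray  # (bins,) mean CV accuracy
    shuffle_accuracies: np.ndarray  # (n_shuffles, bins)
    significant: np.ndarray  # (bins,) accuracy > all shuffles
    reported: np.ndarray  # significant filtered to runs >= consecutive_bins

    def significant_intervals(self) -> list[tuple[int, int]]:
        out, start = [], None
        rep = self.reported
        for b in range(len(rep) + 1):
            on = b < len(rep) and rep[b]
            if on and start is None:
                start = b
            if not on and start is not None:
                out.append((start, b - 1))
                start = None
        return out


def make_pseudo_trials(
    projected: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one trial per unit and condition from decoder-projected
    single trials ``projected`` (units, force, grip, time, trials).

    Returns (test, train_mean), both (force, grip, time): the pseudo-trial
    population projection and the mean of the remaining trials. For
    simultaneously recorded units pass the same trial index per unit by
    using a single-unit projected array.
    """
    u, nf, ng, t, r = projected.shape
    pick = rng.integers(0, r, size=(u, nf, ng))
    idx = np.broadcast_to(pick[..., None, None], (u, nf, ng, t, 1))
    picked = np.take_along_axis(projected, idx, axis=-1)[..., 0]
    test = picked.sum(axis=0)
    train = (projected.sum(axis=(0, -1)) - test) / (r - 1)
    return test, train


def _run_lengths_ok(mask: np.ndarray, min_len: int) -> np.ndarray:
    out = np.zeros_like(mask)
    start = None
    for b in range(len(mask) + 1):
        on = b < len(mask) and mask[b]
        if on and start is None:
            start = b
        if not on and start is not None:
            if b - start >= min_len:
                out[start:b] = True
            start = None
    return out


def _factor_decoder(train_avg: np.ndarray, factor: str, lam: float) -> np.ndarray:
    """Leading decoder axis of the factor's marginalization, fit on a
    training-average tensor (units, force, grip, time)."""
    centered = train_avg - train_avg.mean(axis=(1, 2, 3), keepdims=True)
    X = _flatten(centered)
    mu = (lam * np.linalg.norm(X)) ** 2
    Xphi = _flatten(marginalize(centered).combined(factor))
    _, F = _fit_axes(Xphi, X, mu, 1)
    if F.shape[0] == 0:
        raise ValueError(f"training data has no {factor} variance")
    return F[0]


def _cv_accuracy(
    tensor_5d: np.ndarray,
    factor: str,
    lam: float,
    iterations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean accuracy per bin of nearest-class-mean classification of
    held-out pseudo-trials; the decoder axis is refit per fold on the
    training trials only, so held-out data never leaks into the axis."""
    u, nf, ng, t, r = tensor_5d.shape
    total = tensor_5d.sum(axis=-1)  # (units, force, grip, time)
    correct = np.zeros(t)
    n_cases = 0
    for _ in range(iterations):
        pick = rng.integers(0, r, size=(u, nf, ng))
        idx = np.broadcast_to(pick[..., None, None], (u, nf, ng, t, 1))
        test = np.take_along_axis(tensor_5d, idx, axis=-1)[..., 0]
        train_avg = (total - test) / (r - 1)
        dec = _factor_decoder(train_avg, factor, lam)
        mean_u = train_avg.mean(axis=(1, 2, 3))
        tr = np.einsum("u,ufgt->fgt", dec, train_avg - mean_u[:, None, None, None])
        te = np.einsum("u,ufgt->fgt", dec, test - mean_u[:, None, None, None])
        if factor == "force":
            means = tr.mean(axis=1)  # (force, time)
            pred = np.abs(te[:, :, None, :] - means[None, None, :, :]).argmin(axis=2)
            correct += (pred == np.arange(nf)[:, None, None]).sum(axis=(0, 1))
        elif factor == "grip":
            means = tr.mean(axis=0)  # (grip, time)
            pred = np.abs(te[:, :, None, :] - means[None, None, :, :]).argmin(axis=2)
            correct += (pred == np.arange(ng)[None, :, None]).sum(axis=(0, 1))
        else:
            raise ValueError(factor)
        n_cases += nf * ng
    return correct / n_cases


def decode_over_time(
    model: DPCAModel,
    tensor_5d: np.ndarray,
    factor: str,
    config: DPCAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> DecodingResult:
    """Time-resolved decoding of grip or force from pseudo-single-trial
    activity projected on the factor's leading decoder axis.

    Per bin, a stratified Monte Carlo leave-group-out scheme holds out one
    trial per (unit, condition), refits the factor's decoder axis on the
    training trials, classifies the held-out projection by the nearest
    training class mean, and repeats ``cv_iterations`` times. The chance
    distribution repeats the procedure on ``n_shuffles`` label-shuffled
    copies; a bin is significant when the actual accuracy exceeds all
    shuffle accuracies, and reported significance additionally requires at
    least ``consecutive_bins`` consecutive significant bins.
    """
    config = config or DPCAConfig()
    rng = rng or np.random.default_rng(config.rng_seed)
    if factor not in ("grip", "force"):
        raise ValueError(f"cannot decode factor {factor!r}")
    lam = model.chosen_lambda

    acc = _cv_accuracy(tensor_5d, factor, lam, config.cv_iterations, rng)

    u, nf, ng, t, r = tensor_5d.shape
    flat = tensor_5d.transpose(0, 1, 2, 4, 3).reshape(u, nf * ng * r, t)
    shuff_acc = np.empty((config.n_shuffles, t))
    for s in range(config.n_shuffles):
        shuffled = np.empty_like(flat)
        for ui in range(u):
            shuffled[ui] = flat[ui, rng.permutation(nf * ng * r)]
        sh = shuffled.reshape(u, nf, ng, r, t).transpose(0, 1, 2, 4, 3)
        shuff_acc[s] = _cv_accuracy(sh, factor, lam, config.cv_iterations, rng)

    significant = acc > shuff_acc.max(axis=0)
    reported = _run_lengths_ok(significant, config.consecutive_bins)
    return DecodingResult(factor, acc, shuff_acc, significant, reported)
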