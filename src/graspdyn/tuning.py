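"""Cluster-based permutation test for grip, force, and interaction tuning.

Per unit, a two-way ANOVA (grip x force, Type II sums of squares) is run in
10-ms steps along the composite timeline. Adjacent bins with p < 0.01 form
clusters whose F-values are summed. The null distribution per effect is the
maximal summed F over 1000 label permutations; an observed cluster is
significant when its summed F exceeds the 99th percentile of that null.
Permutations are shared across the three effects within a unit.

The ANOVA is vectorized over bins and permutations via cell-sum algebra:
every model in the 2x3 layout fits cell means only, so each sum of squared
errors reduces to quadratic forms in the six per-cell sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .task import FORCES, GRIPS

EFFECTS = ("grip", "force", "interaction")


@dataclass
class ClusterTestConfig:
    step_ms: float = 10.0
    cluster_forming_p: float = 0.01
    n_permutations: int = 1000
    percentile: float = 99.0
    alpha: float = 0.01
    rng_seed: int = 0
    #: bin indices where adjacency is broken (segment boundaries); the
    #: touch/reward boundary is bridged when the overlap was interpolated
    segment_breaks: tuple[int, ...] = (170, 270)

    def __post_init__(self) -> None:
        if abs(self.percentile - 100.0 * (1.0 - self.alpha)) > 1e-9:
            raise ValueError("percentile must equal 100*(1-alpha)")


@dataclass
class Cluster:
    effect: str
    start: int  # first bin (inclusive)
    end: int  # last bin (inclusive)
    summed_F: float
    significant: bool = False

    @property
    def bins(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


@dataclass
class ClusterTestResult:
    clusters: dict[str, list[Cluster]]
    null_thresholds: dict[str, float]
    n_bins: int
    #: per significant force bin, preferred force level (filled by
    #: :func:`preferred_force`)
    preferred: dict[int, str] = field(default_factory=dict)

    def significant_mask(self, effect: str) -> np.ndarray:
        m = np.zeros(self.n_bins, dtype=bool)
        for c in self.clusters[effect]:
            if c.significant:
                m[c.start : c.end + 1] = True
        return m

    def any_significant(self, effect: str) -> bool:
        return any(c.significant for c in self.clusters[effect])


def _cell_codes(labels: list[tuple[str, str]]) -> np.ndarray:
    """Map (grip, force) labels to cell codes 0..5 (grip*3 + force)."""
    gi = {g: i for i, g in enumerate(GRIPS)}
    fi = {f: i for i, f in enumerate(FORCES)}
    return np.array([gi[g] * 3 + fi[f] for g, f in labels])


def two_way_f(
    rates: np.ndarray, cells: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Type II two-way ANOVA F statistics for every column of ``rates``.

    Parameters
    ----------
    rates : (n_trials, n_bins)
    cells : (n_trials,) or (n_perm, n_trials) cell codes 0..5

    Returns
    -------
    F : (n_perm, 3, n_bins) for effects (grip, force, interaction)
    df : the three numerator dfs (1, 2, 2)
    df_err : error df
    """
    cells = np.atleast_2d(cells)
    n_perm, n = cells.shape
    n_bins = rates.shape[1]
    counts = np.bincount(cells[0], minlength=6).astype(float)
    if np.any(counts < 2):
        raise ValueError("every grip x force cell needs at least 2 trials")

    # per-cell sums for all permutations in one GEMM:
    # onehot (n, 6*n_perm) so that C = rates.T @ onehot -> (n_bins, 6*n_perm)
    onehot = np.zeros((n, 6 * n_perm))
    rows = np.tile(np.arange(n), n_perm)
    cols = (cells + 6 * np.arange(n_perm)[:, None]).ravel()
    onehot[rows, cols] = 1.0
    C = (rates.T @ onehot).T.reshape(n_perm, 6, n_bins)

    tot = rates.sum(axis=0)  # (n_bins,)
    ss_tot_raw = (rates**2).sum(axis=0)
    ss_mean = tot**2 / n

    # cell/grip/force sums; counts identical across permutations
    n_c = counts
    n_g = n_c.reshape(2, 3).sum(axis=1)
    n_f = n_c.reshape(2, 3).sum(axis=0)
    G = C.reshape(n_perm, 2, 3, n_bins).sum(axis=2)
    Fo = C.reshape(n_perm, 2, 3, n_bins).sum(axis=1)

    sse_full = ss_tot_raw - (C**2 / n_c[:, None]).sum(axis=1)
    sse_g = ss_tot_raw - (G**2 / n_g[:, None]).sum(axis=1)
    sse_f = ss_tot_raw - (Fo**2 / n_f[:, None]).sum(axis=1)

    # additive model: weighted LS on the 6 cell means
    X = np.zeros((6, 4))
    X[:, 0] = 1.0
    X[3:, 1] = 1.0  # grip dummy
    X[[1, 4], 2] = 1.0  # medium force dummy
    X[[2, 5], 3] = 1.0  # high force dummy
    W = np.diag(n_c)
    H = X @ np.linalg.solve(X.T @ W @ X, X.T @ W)  # 6x6, same for all perms
    ybar = C / n_c[:, None]
    yhat = np.einsum("ij,pjb->pib", H, ybar)
    sse_add = ss_tot_raw - (n_c[:, None] * yhat**2).sum(axis=1)

    df_err = n - 6
    mse = sse_full / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        F_grip = (sse_f - sse_add) / 1.0 / mse
        F_force = (sse_g - sse_add) / 2.0 / mse
        F_int = (sse_add - sse_full) / 2.0 / mse
    F = np.stack([F_grip, F_force, F_int], axis=1)
    return np.nan_to_num(F, nan=0.0, posinf=0.0), (1.0, 2.0, 2.0), float(df_err)


def _max_cluster_sums(F: np.ndarray, supra: np.ndarray, breaks: tuple[int, ...]) -> np.ndarray:
    """Max summed F over contiguous supra-threshold runs, per row.

    ``F``/``supra``: (rows, bins); adjacency breaks at the given bin indices.
    Fully vectorized (cumsum minus forward-filled base at run starts).
    """
    rows, bins = F.shape
    fm = np.where(supra, F, 0.0)
    cs = np.cumsum(fm, axis=1)
    cs0 = np.concatenate([np.zeros((rows, 1)), cs[:, :-1]], axis=1)
    boundary = np.zeros(bins, dtype=bool)
    boundary[list(breaks)] = True
    start = supra & (np.concatenate([np.ones((rows, 1), bool), ~supra[:, :-1]], axis=1) | boundary)
    # forward-fill cs0 at run starts; 0 before any start
    base = np.where(start, cs0, -np.inf)
    base = np.maximum.accumulate(base, axis=1)
    run_sum = np.where(supra & np.isfinite(base), cs - base, 0.0)
    return run_sum.max(axis=1)


def _observed_clusters(
    F: np.ndarray, supra: np.ndarray, breaks: tuple[int, ...], effect: str
) -> list[Cluster]:
    bins = len(F)
    out = []
    start = None
    for b in range(bins + 1):
        boundary = b in breaks or b == bins
        on = b < bins and supra[b]
        if start is not None and (boundary or not on):
            out.append(Cluster(effect, start, b - 1, float(F[start:b].sum())))
            start = None
        if on and start is None:
            start = b
    return out


def null_threshold(null: np.ndarray, percentile: float) -> float:
    """The (n*q)-th order statistic of the permutation null, ties upward."""
    n = len(null)
    k = int(np.ceil(n * percentile / 100.0))
    return float(np.sort(null)[k - 1])


def test_unit(
    rates: np.ndarray,
    labels: list[tuple[str, str]],
    config: ClusterTestConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ClusterTestResult:
    """Run the cluster-based permutation test on one unit.

    Parameters
    ----------
    rates : (n_trials, n_bins)
        Overlap-interpolated 10-ms bin rates.
    labels : per-trial (grip, force).
    """
    config = config or ClusterTestConfig()
    rng = rng or np.random.default_rng(config.rng_seed)
    cells = _cell_codes(labels)
    n = len(cells)

    F_obs, dfs, df_err = two_way_f(rates, cells)
    F_obs = F_obs[0]
    crit = np.array([stats.f.isf(config.cluster_forming_p, d, df_err) for d in dfs])
    supra_obs = F_obs > crit[:, None]

    # shared label permutations across the three effects
    perm = np.argsort(rng.random((config.n_permutations, n)), axis=1)
    cells_perm = cells[perm]
    F_perm, _, _ = two_way_f(rates, cells_perm)

    clusters: dict[str, list[Cluster]] = {}
    thresholds: dict[str, float] = {}
    for ei, effect in enumerate(EFFECTS):
        null = _max_cluster_sums(
            F_perm[:, ei, :], F_perm[:, ei, :] > crit[ei], config.segment_breaks
        )
        thr = null_threshold(null, config.percentile)
        obs = _observed_clusters(F_obs[ei], supra_obs[ei], config.segment_breaks, effect)
        for c in obs:
            c.significant = c.summed_F > thr
        clusters[effect] = obs
        thresholds[effect] = thr
    return ClusterTestResult(clusters, thresholds, rates.shape[1])


def population_fractions(results: list[ClusterTestResult]) -> dict[str, np.ndarray]:
    """Per bin, the fraction of units with a significant cluster covering it."""
    n_bins = {r.n_bins for r in results}
    if len(n_bins) != 1:
        raise ValueError("units were tested on different timelines")
    out = {}
    for effect in EFFECTS:
        masks = np.stack([r.significant_mask(effect) for r in results])
        out[effect] = masks.mean(axis=0)
    return out


def preferred_force(
    psth: np.ndarray, result: ClusterTestResult
) -> dict[int, str]:
    """Per significant force bin, the force level with maximal mean rate.

    ``psth``: (force, bins) condition-averaged rates (averaged over grips).
    Ties break toward the lower force level and are logged on the result.
    """
    mask = result.significant_mask("force")
    pref: dict[int, str] = {}
    for b in np.nonzero(mask)[0]:
        best = int(np.argmax(psth[:, b]))  # argmax takes first max -> lower force
        pref[int(b)] = FORCES[best]
    result.preferred = pref
    return pref
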