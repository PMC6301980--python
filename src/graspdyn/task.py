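"""Task vocabulary and configuration for the delayed grasping paradigm.

The task crosses two grip types (whole-hand, precision) with three grasp-force
levels (low 0-5 N, medium 5-9 N, high 9-12 N), giving six conditions. A trial
runs through fixation -> cue -> memory -> go -> movement -> handle touch ->
force acquisition -> 1 s hold -> reward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GRIPS = ("whole_hand", "precision")
FORCES = ("low", "medium", "high")

#: The six conditions in canonical order: force varies fastest.
CONDITIONS = tuple((g, f) for g in GRIPS for f in FORCES)

#: Short condition codes in the conventional order (W=whole-hand, P=precision;
#: L/M/H force): WLF, WMF, WHF, PLF, PMF, PHF.
CONDITION_CODES = tuple(
    f"{g[0].upper()}{f[0].upper()}F" for g, f in CONDITIONS
)

DEFAULT_FORCE_BANDS = {
    "low": (0.0, 5.0),
    "medium": (5.0, 9.0),
    "high": (9.0, 12.0),
}

#: Trial event names in causal order.
EVENTS = (
    "fixation",
    "cue_on",
    "cue_off",
    "go",
    "movement",
    "touch",
    "force_acquired",
    "reward",
)


def condition_index(grip: str, force: str) -> int:
    """Index of a (grip, force) pair in :data:`CONDITIONS`."""
    return CONDITIONS.index((grip, force))


@dataclass
class TaskConfig:
    """Timing and scheduling parameters of the delayed grasping task.

    Epoch durations are millisecond intervals drawn uniformly per trial.
    ``force_bands`` maps force level to a (min, max) band in newtons; the
    bands must be contiguous and ordered low < medium < high.
    """

    fixation_range: tuple[float, float] = (400.0, 500.0)
    cue_duration: float = 800.0
    memory_range: tuple[float, float] = (500.0, 700.0)
    hold_duration: float = 1000.0
    force_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FORCE_BANDS)
    )
    n_trials: int = 500
    pool_size: int = 30
    pool_refill_threshold: int = 25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size % len(CONDITIONS):
            raise ValueError("pool_size must be divisible by 6")
        if not self.pool_refill_threshold < self.pool_size:
            raise ValueError("pool_refill_threshold must be < pool_size")
        lo, me, hi = (self.force_bands[f] for f in FORCES)
        if not (lo[0] < lo[1] == me[0] < me[1] == hi[0] < hi[1]):
            raise ValueError(
                "force bands must be contiguous and ordered low < medium < high"
            )
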