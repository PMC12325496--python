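"""Multiple-cue judgment task environment.

The task presents stimuli made of two integer cues ``x1, x2`` in {1..4}; each
stimulus carries a numeric criterion on a 1-30 response scale.  Four of the
sixteen cue combinations serve as exemplars whose criterion values (and screen
locations) are learned during training; the remaining stimuli probe
generalization, including extrapolation stimuli whose criterion lies outside
the exemplar range.  This module defines the stimulus grid, criterion
functions, exemplar/distractor sets, trial schedules for the three
experimental phases, and the adaptive staircase used to calibrate stimulus
presentation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

CUE_VALUES = (1, 2, 3, 4)
SCALE_MIN = 1
SCALE_MAX = 30

PHASES = ("location_training", "criterion_training", "test")


class Stimulus(NamedTuple):
    """A two-cue stimulus; both cues are integers in {1, 2, 3, 4}."""

    x1: int
    x2: int

    def __str__(self) -> str:  # compact "21"-style label used in tables
        return f"{self.x1}{self.x2}"


def _check_stimulus(s: Stimulus) -> Stimulus:
    if s[0] != int(s[0]) or s[1] != int(s[1]):
        raise ValueError(f"cue values must be integers, got {tuple(s)}")
    s = Stimulus(int(s[0]), int(s[1]))
    if s.x1 not in CUE_VALUES or s.x2 not in CUE_VALUES:
        raise ValueError(f"cue values must lie in {CUE_VALUES}, got {tuple(s)}")
    return s


def full_grid() -> list[Stimulus]:
    """All 16 cue combinations, in lexicographic (x1, x2) order."""
    return [Stimulus(a, b) for a in CUE_VALUES for b in CUE_VALUES]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    On the 16-point cue grid no criterion value lands exactly on .5, so the
    half-rule never fires there; it is fixed here for arbitrary inputs.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def criterion_multiplicative(s: Stimulus) -> int:
    """Multiplicative criterion c = round((5/3) * x1 * x2 + 2).

    Monotone in each cue and symmetric in (x1, x2); ranges from 4 at (1,1)
    to 29 at (4,4).
    """
    s = _check_stimulus(s)
    return round_half_away((5.0 / 3.0) * s.x1 * s.x2 + 2.0)


def criterion_additive(
    s: Stimulus,
    a0: float,
    a1: float,
    a2: float,
    scale: tuple[int, int] = (SCALE_MIN, SCALE_MAX),
) -> int:
    """Linear-additive criterion round(a0 + a1*x1 + a2*x2), clipped to scale."""
    s = _check_stimulus(s)
    for a in (a0, a1, a2):
        if not math.isfinite(a):
            raise ValueError("additive coefficients must be finite")
    c = round_half_away(a0 + a1 * s.x1 + a2 * s.x2)
    return int(min(max(c, scale[0]), scale[1]))


def reversed_distractor(e: Stimulus) -> Stimulus:
    """Cue-reversed distractor (x2, x1); undefined for symmetric stimuli."""
    e = _check_stimulus(e)
    if e.x1 == e.x2:
        raise ValueError(
            f"stimulus {e} is symmetric: its reversal equals the exemplar"
        )
    return Stimulus(e.x2, e.x1)


DEFAULT_EXEMPLARS = (Stimulus(2, 1), Stimulus(1, 4), Stimulus(3, 2), Stimulus(4, 3))


def default_exemplars() -> dict[Stimulus, int]:
    """The default exemplar set with multiplicative criterion values.

    The four exemplars {(2,1), (1,4), (3,2), (4,3)} cover every cue value
    exactly once on each cue, are all asymmetric (so each has a distinct
    reversed distractor), and leave the extreme stimuli (1,1) and (4,4)
    outside the exemplar criterion range [5, 22], so that those stimuli
    require extrapolation.
    """
    return {e: criterion_multiplicative(e) for e in DEFAULT_EXEMPLARS}


@dataclass(frozen=True)
class Environment:
    """Criterion function plus exemplar set and response-scale bounds."""

    criterion_fn: Callable[[Stimulus], int]
    exemplars: dict[Stimulus, int] = field(default_factory=default_exemplars)
    scale_min: int = SCALE_MIN
    scale_max: int = SCALE_MAX
    name: str = "multiplicative"

    def __post_init__(self) -> None:
        if not self.exemplars:
            raise ValueError("environment needs at least one exemplar")
        for e, c in self.exemplars.items():
            _check_stimulus(e)
            if not (self.scale_min <= c <= self.scale_max):
                raise ValueError(f"exemplar {e} criterion {c} outside scale")

    @classmethod
    def multiplicative(cls) -> "Environment":
        return cls(criterion_fn=criterion_multiplicative)

    @classmethod
    def additive(
        cls, a0: float = 2.0, a1: float = 5.0 / 3.0, a2: float = 5.0 / 3.0
    ) -> "Environment":
        """Linear-additive environment.

        The default coefficients are arbitrary; they are chosen only so that
        the criterion spans a range comparable to the multiplicative
        environment's.
        """
        fn = lambda s: criterion_additive(s, a0, a1, a2)  # noqa: E731
        exemplars = {e: fn(e) for e in DEFAULT_EXEMPLARS}
        return cls(criterion_fn=fn, exemplars=exemplars, name="additive")

    @property
    def exemplar_list(self) -> list[Stimulus]:
        return sorted(self.exemplars)

    def criterion(self, s: Stimulus) -> int:
        return self.criterion_fn(Stimulus(*s))

    def exemplar_criterion_range(self) -> tuple[int, int]:
        vals = list(self.exemplars.values())
        return min(vals), max(vals)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "scale_min": self.scale_min,
            "scale_max": self.scale_max,
            "exemplars": [[e.x1, e.x2, c] for e, c in sorted(self.exemplars.items())],
        }


def environment_from_config(cfg: dict) -> Environment:
    """Build an Environment from a plain config mapping (YAML/JSON-shaped).

    Recognized keys: ``criterion`` ("multiplicative" or "additive"),
    ``coefficients`` (for additive), ``exemplars`` (list of [x1, x2] or
    [x1, x2, criterion]), ``scale_min``/``scale_max``.
    """
    kind = cfg.get("criterion", "multiplicative")
    if kind == "multiplicative":
        fn = criterion_multiplicative
    elif kind == "additive":
        a0, a1, a2 = cfg.get("coefficients", (2.0, 5.0 / 3.0, 5.0 / 3.0))
        fn = lambda s: criterion_additive(s, a0, a1, a2)  # noqa: E731
    else:
        raise ValueError(f"unknown criterion function {kind!r}")
    if "exemplars" in cfg:
        exemplars = {}
        for row in cfg["exemplars"]:
            s = _check_stimulus(Stimulus(row[0], row[1]))
            exemplars[s] = int(row[2]) if len(row) > 2 else fn(s)
    else:
        exemplars = {e: fn(e) for e in DEFAULT_EXEMPLARS}
    return Environment(
        criterion_fn=fn,
        exemplars=exemplars,
        scale_min=int(cfg.get("scale_min", SCALE_MIN)),
        scale_max=int(cfg.get("scale_max", SCALE_MAX)),
        name=kind,
    )


def environment_from_yaml(path) -> Environment:
    with open(path) as fh:
        return environment_from_config(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Trial schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trial list for one phase: (block, stimulus, item role)."""

    phase: str
    trials: pd.DataFrame  # columns: block, trial, x1, x2, role
    seed: int

    def __len__(self) -> int:
        return len(self.trials)


def _phase_items(phase: str, env: Environment) -> list[tuple[Stimulus, str]]:
    if phase == "location_training":
        items = [(e, "exemplar") for e in env.exemplar_list]
        items += [(reversed_distractor(e), "distractor") for e in env.exemplar_list]
        return items
    if phase == "criterion_training":
        return [(e, "exemplar") for e in env.exemplar_list]
    if phase == "test":
        return [(s, "test") for s in full_grid()]
    raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")


def make_schedule(
    phase: str, env: Environment, n_blocks: int, seed: int = 0
) -> TrialSchedule:
    """Blocked schedule with a seeded random order within each block.

    Every scheduled item appears exactly once per block: 8 items (4 exemplars
    + 4 reversed distractors) in location training, 4 exemplars in criterion
    training, all 16 stimuli in the test phase.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    items = _phase_items(phase, env)
    rng = np.random.default_rng(seed)
    rows = []
    trial = 0
    for block in range(1, n_blocks + 1):
        for idx in rng.permutation(len(items)):
            s, role = items[idx]
            trial += 1
            rows.append((block, trial, s.x1, s.x2, role))
    trials = pd.DataFrame(rows, columns=["block", "trial", "x1", "x2", "role"])
    return TrialSchedule(phase=phase, trials=trials, seed=seed)


def schedule_to_csv(schedule: TrialSchedule, path, participant=None) -> None:
    df = schedule.trials.copy()
    df.insert(0, "phase", schedule.phase)
    if participant is not None:
        df.insert(0, "participant", participant)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# 4-down-1-up staircase for presentation-time calibration
# ---------------------------------------------------------------------------

STAIRCASE_STEP_DOWN_MS = 336.60
STAIRCASE_STEP_UP_MS = 400.0


@dataclass(frozen=True)
class StaircaseState:
    duration: float  # current presentation duration, ms
    consecutive_correct: int = 0
    history: tuple[tuple[float, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("staircase duration must be positive")
        if self.consecutive_correct < 0:
            raise ValueError("consecutive_correct must be non-negative")


def staircase_step(
    state: StaircaseState,
    correct: bool,
    step_down: float = STAIRCASE_STEP_DOWN_MS,
    step_up: float = STAIRCASE_STEP_UP_MS,
    n_down: int = 4,
    floor: float = 1.0,
) -> StaircaseState:
    """One 4-down-1-up update: shorten after ``n_down`` consecutive correct
    responses, lengthen after any error; duration floored at ``floor`` ms."""
    history = state.history + ((state.duration, bool(correct)),)
    if not correct:
        return StaircaseState(state.duration + step_up, 0, history)
    streak = state.consecutive_correct + 1
    if streak >= n_down:
        return StaircaseState(max(state.duration - step_down, floor), 0, history)
    return StaircaseState(state.duration, streak, history)


def staircase_presentation_time(block_means: Sequence[float]) -> float:
    """Test-phase presentation time: the mean of per-block staircase means."""
    if len(block_means) == 0:
        raise ValueError("need at least one block mean")
    return float(np.mean(block_means))


def run_staircase(
    responses: Iterable[bool], start: float = 2000.0, **kwargs
) -> StaircaseState:
    """Convenience driver applying :func:`staircase_step` over a response run."""
    state = StaircaseState(start)
    for correct in responses:
        state = staircase_step(state, correct, **kwargs)
    return state
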