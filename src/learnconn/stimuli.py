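"""Color-name association stimulus generation, session planning and scoring.

Stimuli are HSL colors with every channel rescaled to the integer range
0-255.  For each target color a set of five candidate colors is built that
share the target's hue and lightness and differ only in saturation: an
arithmetic grid of saturations with step 35 is laid around the target, every
window of five consecutive grid values containing the target is enumerated,
and one window is drawn uniformly.  Because the grid always has 7 or 8
members, a uniformly distributed target saturation makes the target's
position within its window uniform over the five slots, so the candidate
display carries no positional cue.

A learning or test session presents 10 color-name associations, each four
times (four blocks, each a fresh permutation of the 10 associations), with
the five candidates randomly permuted across screen slots on every trial.
The test score is 10 points per correct choice, 0-400 overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_STEP = 35
LIGHTNESS_MIN = 100
LIGHTNESS_MAX = 200
N_ASSOCIATIONS = 10
N_BLOCKS = 4
N_CANDIDATES = 5
N_TRIALS = N_ASSOCIATIONS * N_BLOCKS

CONDITIONS = ("EL", "TE")


def _check_channel(name: str, value: int) -> int:
    value = int(value)
    if not 0 <= value <= 255:
        raise ValueError(f"{name} must lie in [0, 255], got {value}")
    return value


@dataclass(frozen=True)
class ColorHSL:
    """A color in integer HSL coordinates, each channel in [0, 255]."""

    hue: int
    saturation: int
    lightness: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "hue", _check_channel("hue", self.hue))
        object.__setattr__(self, "saturation", _check_channel("saturation", self.saturation))
        object.__setattr__(self, "lightness", _check_channel("lightness", self.lightness))


@dataclass(frozen=True)
class SaturationGrid:
    """Arithmetic saturation grid around a target value.

    ``values`` is the ascending list of all ``target +- k*step`` that fit in
    the admissible range; the target itself is always a member.
    """

    target_saturation: int
    step: int
    values: tuple[int, ...]

    @property
    def target_position(self) -> int:
        return self.values.index(self.target_saturation)


@dataclass(frozen=True)
class CandidateSet:
    """Five candidate colors sharing hue and lightness, distinct saturations.

    The saturations are five consecutive values of a :class:`SaturationGrid`;
    ``target_index`` locates the target color within the window (0-4).
    """

    colors: tuple[ColorHSL, ...]
    target_index: int

    def __post_init__(self) -> None:
        if len(self.colors) != N_CANDIDATES:
            raise ValueError(f"a candidate set has exactly {N_CANDIDATES} colors")
        hues = {c.hue for c in self.colors}
        lights = {c.lightness for c in self.colors}
        if len(hues) != 1 or len(lights) != 1:
            raise ValueError("candidates must share hue and lightness")
        sats = [c.saturation for c in self.colors]
        if len(set(sats)) != N_CANDIDATES:
            raise ValueError("candidate saturations must be distinct")
        if not 0 <= self.target_index < N_CANDIDATES:
            raise ValueError("target_index must lie in 0-4")

    @property
    def target(self) -> ColorHSL:
        return self.colors[self.target_index]

    @property
    def saturations(self) -> tuple[int, ...]:
        return tuple(c.saturation for c in self.colors)


@dataclass(frozen=True)
class Trial:
    """One presentation: an association and a screen layout of its candidates.

    ``slot_of_candidate[i]`` is the screen slot (0-4, left to right) holding
    candidate ``i`` of the association's :class:`CandidateSet`; the tuple is
    a permutation of 0-4.
    """

    block: int
    association_id: int
    name: str
    candidates: CandidateSet
    slot_of_candidate: tuple[int, ...]

    @property
    def target_slot(self) -> int:
        return self.slot_of_candidate[self.candidates.target_index]


@dataclass(frozen=True)
class SessionPlan:
    """A full 40-trial session (10 associations x 4 blocks) for one condition.

    Exposure timings are carried as metadata only; no presentation engine
    exists.  In the trial-and-error condition a learner may need several
    attempts per trial, which response records capture; the plan itself is
    identical across conditions.
    """

    condition: str
    associations: tuple[tuple[str, CandidateSet], ...]
    trials: tuple[Trial, ...]
    rng_seed: int | None = None
    candidate_exposure_s: float = 9.0
    target_exposure_s: float = 6.0

    def blocks(self) -> list[list[Trial]]:
        return [
            [t for t in self.trials if t.block == b] for b in range(N_BLOCKS)
        ]


@dataclass(frozen=True)
class TestResponseSet:
    """Chosen vs. correct screen slots for the 40 test trials."""

    __test__ = False  # not a pytest class, despite the name

    chosen_slots: tuple[int, ...]
    correct_slots: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chosen_slots) != len(self.correct_slots):
            raise ValueError("chosen and correct slot lists must align")
        for s in (*self.chosen_slots, *self.correct_slots):
            if not 0 <= s < N_CANDIDATES:
                raise ValueError("slots must lie in 0-4")


def build_saturation_grid(
    target_saturation: int,
    step: int = DEFAULT_STEP,
    lo: int = 0,
    hi: int = 255,
) -> SaturationGrid:
    """All saturations ``target +- k*step`` inside ``[lo, hi]``, ascending.

    With the default step of 35 and the full 0-255 range the grid has 7 or 8
    members for every admissible target.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not lo <= target_saturation <= hi:
        raise ValueError(
            f"target saturation {target_saturation} outside [{lo}, {hi}]"
        )
    below = range((target_saturation - lo) // step, 0, -1)
    above = range(1, (hi - target_saturation) // step + 1)
    values = (
        [target_saturation - k * step for k in below]
        + [target_saturation]
        + [target_saturation + k * step for k in above]
    )
    return SaturationGrid(int(target_saturation), int(step), tuple(values))


def enumerate_candidate_windows(grid: SaturationGrid) -> list[tuple[int, ...]]:
    """All windows of 5 consecutive grid values containing the target.

    Windows are returned in ascending order of their first value.
    """
    if len(grid.values) < N_CANDIDATES:
        raise ValueError(
            f"grid has {len(grid.values)} values; at least {N_CANDIDATES} required"
        )
    pos = grid.target_position
    windows = []
    for start in range(len(grid.values) - N_CANDIDATES + 1):
        if start <= pos < start + N_CANDIDATES:
            windows.append(tuple(grid.values[start : start + N_CANDIDATES]))
    return windows


def sample_candidate_set(target: ColorHSL, rng: np.random.Generator) -> CandidateSet:
    """Draw one candidate window uniformly and wrap it as colors.

    The target must satisfy the lightness restriction 100-200 used for all
    study colors (easier targets would make the discrimination trivial).
    """
    if not LIGHTNESS_MIN <= target.lightness <= LIGHTNESS_MAX:
        raise ValueError(
            f"target lightness {target.lightness} outside "
            f"[{LIGHTNESS_MIN}, {LIGHTNESS_MAX}]"
        )
    grid = build_saturation_grid(target.saturation)
    windows = enumerate_candidate_windows(grid)
    window = windows[int(rng.integers(len(windows)))]
    colors = tuple(
        ColorHSL(target.hue, s, target.lightness) for s in window
    )
    return CandidateSet(colors=colors, target_index=window.index(target.saturation))


def target_position_distribution(step: int = DEFAULT_STEP) -> np.ndarray:
    """Exact distribution of the target's window position for uniform targets.

    Brute-force enumeration over all 256 target saturations of the uniform
    window choice; used as the oracle for the no-positional-bias property.
    """
    probs = np.zeros(N_CANDIDATES)
    for s in range(256):
        grid = build_saturation_grid(s, step=step)
        windows = enumerate_candidate_windows(grid)
        for w in windows:
            probs[w.index(s)] += 1.0 / len(windows)
    return probs / 256.0


def sample_target_colors(
    n: int, rng: np.random.Generator
) -> list[ColorHSL]:
    """Draw ``n`` target colors covering the hue palette evenly.

    Hues are stratified: the 0-255 hue axis is split into ``n`` equal bins,
    one integer hue drawn per bin, and the list shuffled.  Lightness is
    uniform on [100, 200]; saturation uniform on [0, 255].
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if n > 256:
        raise ValueError("more than 256 colors cannot have distinct hue bins")
    edges = np.linspace(0, 256, n + 1)
    colors = []
    for i in range(n):
        lo, hi = int(np.ceil(edges[i])), int(np.ceil(edges[i + 1]))
        hue = int(rng.integers(lo, hi))
        sat = int(rng.integers(0, 256))
        light = int(rng.integers(LIGHTNESS_MIN, LIGHTNESS_MAX + 1))
        colors.append(ColorHSL(hue, sat, light))
    order = rng.permutation(n)
    return [colors[i] for i in order]


def build_session_plan(
    named_colors: Sequence[tuple[str, ColorHSL]],
    condition: str,
    rng: np.random.Generator,
    rng_seed: int | None = None,
) -> SessionPlan:
    """Plan a 40-trial session from 10 named target colors.

    Each block presents the 10 associations in a fresh random order, and
    every trial assigns the five candidates to screen slots by a fresh
    permutation, so the target appears in each slot with probability 1/5.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if len(named_colors) != N_ASSOCIATIONS:
        raise ValueError(f"exactly {N_ASSOCIATIONS} associations required")
    names = [name for name, _ in named_colors]
    if len(set(names)) != N_ASSOCIATIONS:
        raise ValueError("color names must be distinct")

    associations = tuple(
        (name, sample_candidate_set(color, rng)) for name, color in named_colors
    )
    trials = []
    for block in range(N_BLOCKS):
        for assoc_id in rng.permutation(N_ASSOCIATIONS):
            name, cand = associations[assoc_id]
            slots = tuple(int(s) for s in rng.permutation(N_CANDIDATES))
            trials.append(
                Trial(
                    block=block,
                    association_id=int(assoc_id),
                    name=name,
                    candidates=cand,
                    slot_of_candidate=slots,
                )
            )
    return SessionPlan(
        condition=condition,
        associations=associations,
        trials=tuple(trials),
        rng_seed=rng_seed,
    )


def score_test(responses: TestResponseSet) -> int:
    """Test score: 10 points per correct choice over the 40 trials."""
    n = len(responses.chosen_slots)
    if n != N_TRIALS:
        raise ValueError(f"a test session has {N_TRIALS} trials, got {n}")
    correct = sum(
        c == k for c, k in zip(responses.chosen_slots, responses.correct_slots)
    )
    return 10 * correct


def plan_to_frame(plan: SessionPlan) -> pd.DataFrame:
    """Tabular form of a session plan, one row per trial."""
    rows = []
    for i, t in enumerate(plan.trials):
        row: dict[str, object] = {
            "trial": i,
            "block": t.block,
            "association_id": t.association_id,
            "name": t.name,
            "condition": plan.condition,
            "target_slot": t.target_slot,
        }
        # candidates listed in screen-slot order, left to right
        by_slot = sorted(
            range(N_CANDIDATES), key=lambda c: t.slot_of_candidate[c]
        )
        for slot, cand_idx in enumerate(by_slot):
            c = t.candidates.colors[cand_idx]
            row[f"slot{slot}_h"] = c.hue
            row[f"slot{slot}_s"] = c.saturation
            row[f"slot{slot}_l"] = c.lightness
        rows.append(row)
    return pd.DataFrame(rows)


def write_plan(plan: SessionPlan, path) -> None:
    """Serialize a plan as TSV with a commented metadata header."""
    frame = plan_to_frame(plan)
    with open(path, "w") as fh:
        fh.write(f"# condition={plan.condition}\n")
        fh.write(f"# rng_seed={plan.rng_seed}\n")
        fh.write(
            f"# candidate_exposure_s={plan.candidate_exposure_s}"
            f" target_exposure_s={plan.target_exposure_s}\n"
        )
        frame.to_csv(fh, sep="\t", index=False)
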