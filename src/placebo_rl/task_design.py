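"""Probabilistic selection task: session designs and trial schedules.

The task repeatedly presents one of three symbol pairs; within each pair one
symbol is rewarded with higher probability than the other.  Sessions come in
a default flavour (contingencies 80/20, 70/30, 60/40 over four blocks) and
two manipulated flavours used on the first day of the conditioning groups:
an easier version (90/10, 90/10, 80/20) and a harder one (60/40, 60/40,
55/45), both over two blocks.  Every pair appears twenty times per block and
the presentation side of the better symbol is exactly counterbalanced within
each block.

Rewards are coded ``1`` (gain) and ``0`` (loss / no reward), consistent with
value estimates initialised at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PAIR_IDS",
    "TASK_LABELS",
    "SymbolPair",
    "SessionDesign",
    "TrialSpec",
    "TrialRecord",
    "make_design",
    "generate_session",
    "sample_feedback",
    "design_from_dict",
    "design_to_dict",
]

PAIR_IDS = ("AB", "CD", "EF")
TASK_LABELS = ("task1_default", "task2_placebo", "task2_nocebo", "task3_default")

#: Trial timing, stored as metadata only (no real-time presentation).
DEFAULT_TIMING = {
    "fixation_s": 0.3,
    "response_deadline_s": 1.7,
    "highlight_s": 0.5,
    "feedback_s": 0.5,
}


@dataclass(frozen=True)
class SymbolPair:
    """One symbol pair with its reward contingencies.

    ``p_better`` / ``p_worse`` are the reward probabilities of the better and
    worse symbol.  All built-in designs use complementary probabilities
    (``p_better + p_worse = 1``), but the type only requires
    ``0 <= p_worse < p_better <= 1``.
    """

    pair_id: str
    p_better: float
    p_worse: float

    def __post_init__(self) -> None:
        if self.pair_id not in PAIR_IDS:
            raise ValueError(f"pair_id must be one of {PAIR_IDS}, got {self.pair_id!r}")
        if not (0.0 <= self.p_worse < self.p_better <= 1.0):
            raise ValueError(
                "require 0 <= p_worse < p_better <= 1, got "
                f"p_better={self.p_better}, p_worse={self.p_worse}"
            )


@dataclass(frozen=True)
class SessionDesign:
    """Structure of one task session."""

    task_label: str
    n_blocks: int
    reps_per_pair_per_block: int
    pairs: tuple[SymbolPair, SymbolPair, SymbolPair]
    timing: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TIMING))

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be a positive integer")
        if self.reps_per_pair_per_block < 1:
            raise ValueError("reps_per_pair_per_block must be a positive integer")
        if len(self.pairs) != 3:
            raise ValueError("a session design has exactly 3 symbol pairs")
        seen = [p.pair_id for p in self.pairs]
        if sorted(seen) != sorted(PAIR_IDS):
            raise ValueError(f"pairs must cover {PAIR_IDS} exactly once, got {seen}")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * 3 * self.reps_per_pair_per_block

    def pair(self, pair_id: str) -> SymbolPair:
        for p in self.pairs:
            if p.pair_id == pair_id:
                return p
        raise KeyError(pair_id)

    def scaled(self, n_blocks: int) -> "SessionDesign":
        """Same contingencies with a different block count (desk-scale runs)."""
        return replace(self, n_blocks=n_blocks)


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial (1-based indices)."""

    block: int
    trial_in_session: int
    pair_id: str
    better_on_left: bool


@dataclass(frozen=True)
class TrialRecord:
    """One observed or simulated trial.

    ``chosen_better`` / ``reward`` / ``rt_ms`` are ``None`` for missed trials
    (no response before the deadline, hence no feedback).
    """

    block: int
    trial_in_session: int
    pair_id: str
    better_on_left: bool
    chosen_better: bool | None
    reward: int | None
    rt_ms: float | None = None

    def __post_init__(self) -> None:
        if self.chosen_better is None:
            if self.reward is not None:
                raise ValueError("reward present but no choice was made")
        else:
            if self.reward not in (0, 1):
                raise ValueError(f"reward must be 0 or 1, got {self.reward!r}")
        if self.rt_ms is not None and self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive when present")

    @property
    def answered(self) -> bool:
        return self.chosen_better is not None


_BUILTIN_CONTINGENCIES = {
    "task1_default": ((0.80, 0.20), (0.70, 0.30), (0.60, 0.40)),
    "task3_default": ((0.80, 0.20), (0.70, 0.30), (0.60, 0.40)),
    "task2_placebo": ((0.90, 0.10), (0.90, 0.10), (0.80, 0.20)),
    "task2_nocebo": ((0.60, 0.40), (0.60, 0.40), (0.55, 0.45)),
}
_BUILTIN_BLOCKS = {
    "task1_default": 4,
    "task3_default": 4,
    "task2_placebo": 2,
    "task2_nocebo": 2,
}


def make_design(task_label: str) -> SessionDesign:
    """Build one of the four built-in session designs.

    ``task1_default``/``task3_default``: 4 blocks x 3 pairs x 20 reps = 240
    trials at the default contingencies.  ``task2_placebo``/``task2_nocebo``:
    2 blocks (120 trials) at the easier / harder manipulated contingencies.
    """
    if task_label not in _BUILTIN_CONTINGENCIES:
        raise ValueError(
            f"unknown task label {task_label!r}; valid labels: {', '.join(TASK_LABELS)}"
        )
    pairs = tuple(
        SymbolPair(pid, pb, pw)
        for pid, (pb, pw) in zip(PAIR_IDS, _BUILTIN_CONTINGENCIES[task_label])
    )
    return SessionDesign(
        task_label=task_label,
        n_blocks=_BUILTIN_BLOCKS[task_label],
        reps_per_pair_per_block=20,
        pairs=pairs,  # type: ignore[arg-type]
    )


def generate_session(design: SessionDesign, seed: int | np.random.Generator) -> list[TrialSpec]:
    """Generate a randomized, side-counterbalanced trial schedule.

    Within each block every pair occurs ``reps_per_pair_per_block`` times,
    with the better symbol on the left in exactly half of those occurrences;
    the within-block trial order is a uniformly random permutation.
    Deterministic for a fixed seed.
    """
    reps = design.reps_per_pair_per_block
    if reps % 2 != 0:
        raise ValueError(
            "reps_per_pair_per_block must be even for exact left/right counterbalancing"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    t = 1
    for block in range(1, design.n_blocks + 1):
        slots: list[tuple[str, bool]] = []
        for pair in design.pairs:
            slots.extend((pair.pair_id, True) for _ in range(reps // 2))
            slots.extend((pair.pair_id, False) for _ in range(reps // 2))
        order = rng.permutation(len(slots))
        for idx in order:
            pid, left = slots[idx]
            trials.append(TrialSpec(block=block, trial_in_session=t, pair_id=pid, better_on_left=left))
            t += 1
    return trials


def sample_feedback(pair: SymbolPair, chose_better: bool, rng: np.random.Generator) -> int:
    """Bernoulli reward for a choice within ``pair`` (1 = gain, 0 = loss)."""
    p = pair.p_better if chose_better else pair.p_worse
    return int(rng.random() < p)


def design_to_dict(design: SessionDesign) -> dict:
    return {
        "task_label": design.task_label,
        "n_blocks": design.n_blocks,
        "reps_per_pair_per_block": design.reps_per_pair_per_block,
        "pairs": {p.pair_id: [p.p_better, p.p_worse] for p in design.pairs},
        "timing": dict(design.timing),
    }


def design_from_dict(d: Mapping) -> SessionDesign:
    """Inverse of :func:`design_to_dict`; also accepts a bare task label."""
    if isinstance(d, str):
        return make_design(d)
    pairs = tuple(
        SymbolPair(pid, *map(float, d["pairs"][pid])) for pid in PAIR_IDS
    )
    return SessionDesign(
        task_label=d["task_label"],
        n_blocks=int(d["n_blocks"]),
        reps_per_pair_per_block=int(d["reps_per_pair_per_block"]),
        pairs=pairs,  # type: ignore[arg-type]
        timing=dict(d.get("timing", DEFAULT_TIMING)),
    )
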