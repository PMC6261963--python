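"""Generative dual-learning-rate reinforcement-learning agent.

The agent maintains a value estimate Q per symbol, initialised at 0.  After
choosing symbol ``a`` and receiving reward r in {0, 1} it updates

    Q(a) <- Q(a) + alpha_G * [r - Q(a)]_+  +  alpha_L * [r - Q(a)]_-

where [x]_+ / [x]_- keep the positive / negative part, i.e. positive
prediction errors are scaled by the gain learning rate alpha_G and negative
ones by the loss learning rate alpha_L.  Choices between the two presented
symbols follow the softmax rule

    P(a) = exp(Q(a) / beta) / (exp(Q(a) / beta) + exp(Q(b) / beta)),

so larger beta makes decisions noisier ("more exploratory").

This module doubles as the synthetic-cohort generator: subject-level
parameters are drawn from the probit-/log-normal group hierarchy, day-2
parameters receive the common day shift plus the group-specific shift on the
transformed scale, and behaviour is simulated through the task schedules of
:mod:`placebo_rl.task_design` following the five-group two-day study flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._params import (
    GROUPS,
    MANIPULATED_GROUPS,
    PARAM_NAMES,
    GroupEffects,
    HyperParams,
    alpha_link,
)
from .task_design import (
    PAIR_IDS,
    SessionDesign,
    TrialRecord,
    generate_session,
    make_design,
    sample_feedback,
)

__all__ = [
    "AgentParams",
    "SessionData",
    "SubjectDataset",
    "CohortSpec",
    "GROUP_SCHEDULES",
    "SUBJECTIVE_CATEGORIES",
    "q_update",
    "choice_prob",
    "simulate_subject",
    "simulate_cohort",
    "pair_symbol_indices",
]

#: Per-group task schedules over the two days of the study flow.
GROUP_SCHEDULES: dict[str, dict[int, tuple[str, ...]]] = {
    "NHG": {1: ("task1_default",), 2: ("task3_default",)},
    "placebo": {1: ("task1_default", "task2_placebo"), 2: ("task3_default",)},
    "nocebo": {1: ("task1_default", "task2_nocebo"), 2: ("task3_default",)},
    "placebo_control": {1: ("task1_default", "task2_placebo"), 2: ("task3_default",)},
    "nocebo_control": {1: ("task1_default", "task2_nocebo"), 2: ("task3_default",)},
}

SUBJECTIVE_CATEGORIES = ("decline", "neutral", "improve")

#: Symbol indices (0..5) of the (better, worse) symbol within each pair.
_PAIR_SYMBOLS = {"AB": (0, 1), "CD": (2, 3), "EF": (4, 5)}


def pair_symbol_indices(pair_id: str) -> tuple[int, int]:
    """(better, worse) symbol index in the 6-symbol value vector."""
    return _PAIR_SYMBOLS[pair_id]


@dataclass(frozen=True)
class AgentParams:
    """Subject-level model parameters on the natural scale."""

    alpha_G: float
    alpha_L: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_G <= 1.0 and 0.0 <= self.alpha_L <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if not self.beta > 0:
            raise ValueError("beta must be strictly positive")


def q_update(q: float, reward: int, params: AgentParams) -> float:
    """Update one value estimate with a 0/1 reward.

    Positive prediction errors are scaled by ``alpha_G``, negative ones by
    ``alpha_L``; a zero prediction error leaves the value unchanged (both
    branches would contribute nothing, and strict inequalities avoid
    applying the update twice at x = 0).
    """
    if reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {reward!r}")
    if not np.isfinite(q):
        raise ValueError("q must be finite")
    pe = reward - q
    if pe > 0:
        return q + params.alpha_G * pe
    if pe < 0:
        return q + params.alpha_L * pe
    return q


def choice_prob(q_a: float, q_b: float, beta: float) -> float:
    """Softmax probability of choosing the symbol with value ``q_a``.

    Computed as a logistic of the scaled value difference, which is
    numerically stable for extreme ``q/beta`` ratios.
    """
    if not beta > 0:
        raise ValueError("beta must be strictly positive")
    d = (q_b - q_a) / beta
    if d >= 0:
        return float(np.exp(-d) / (1.0 + np.exp(-d)))
    return float(1.0 / (1.0 + np.exp(d)))


@dataclass
class SessionData:
    """Records of one task session (one fresh set of symbols)."""

    task_label: str
    records: list[TrialRecord]


@dataclass
class SubjectDataset:
    """All behaviour of one subject: per-day sessions plus subjective reports."""

    subject_id: str
    group: str
    days: dict[int, list[SessionData]]
    subjective: dict[str, str | None] = field(
        default_factory=lambda: {"expected": None, "perceived": None}
    )
    true_params: dict[int, AgentParams] | None = None

    def n_trials(self, day: int | None = None) -> int:
        days = [day] if day is not None else sorted(self.days)
        return sum(len(s.records) for d in days for s in self.days[d])


def _simulate_session(
    design: SessionDesign,
    params: AgentParams,
    rng: np.random.Generator,
    rt_loc: float,
    rt_scale: float,
) -> SessionData:
    """Simulate one session with a fresh Q vector (new symbols each session)."""
    q = np.zeros(6)
    records: list[TrialRecord] = []
    for spec in generate_session(design, rng):
        better, worse = pair_symbol_indices(spec.pair_id)
        p_better = choice_prob(q[better], q[worse], params.beta)
        chose_better = bool(rng.random() < p_better)
        chosen = better if chose_better else worse
        reward = sample_feedback(design.pair(spec.pair_id), chose_better, rng)
        q[chosen] = q_update(q[chosen], reward, params)
        # Synthetic RT: lognormal, capped at the deadline; invented plumbing
        # to exercise the RT regression, not a fitted model component.
        deadline_ms = design.timing.get("response_deadline_s", 1.7) * 1000.0
        rt = float(np.exp(rng.normal(rt_loc, rt_scale)))
        rt = min(rt, deadline_ms - 1.0)
        records.append(
            TrialRecord(
                block=spec.block,
                trial_in_session=spec.trial_in_session,
                pair_id=spec.pair_id,
                better_on_left=spec.better_on_left,
                chosen_better=chose_better,
                reward=reward,
                rt_ms=rt,
            )
        )
    return SessionData(task_label=design.task_label, records=records)


def simulate_subject(
    params_day1: AgentParams,
    params_day2: AgentParams,
    group: str,
    seed: int | np.random.Generator,
    subject_id: str = "S1",
    designs: Mapping[str, SessionDesign] | None = None,
    rt_loc: float = 6.7,
    rt_scale: float = 0.25,
) -> SubjectDataset:
    """Simulate one subject through their group's two-day task schedule.

    Values are re-initialised at zero at the start of every session: each
    task uses a fresh symbol set and the model fits per-day parameters, so
    no value carries across sessions or nights (configurable only by
    simulating sessions manually).  ``designs`` may override the built-in
    session designs, e.g. with block-scaled versions.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; valid groups: {GROUPS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    designs = designs or {}
    params = {1: params_day1, 2: params_day2}
    days: dict[int, list[SessionData]] = {}
    for day, labels in GROUP_SCHEDULES[group].items():
        days[day] = [
            _simulate_session(
                designs.get(label, make_design(label)), params[day], rng, rt_loc, rt_scale
            )
            for label in labels
        ]
    return SubjectDataset(
        subject_id=subject_id,
        group=group,
        days=days,
        true_params={1: params_day1, 2: params_day2},
    )


@dataclass(frozen=True)
class CohortSpec:
    """Generative specification of a synthetic cohort.

    Defaults mirror the study: 16 subjects in each of the five groups, the
    built-in session designs, and subject parameters drawn from the
    probit-/log-normal hierarchy with day-2 shifts applied on the
    transformed scale.  ``subjective_probs`` optionally supplies per-group
    categorical probabilities (decline, neutral, improve) used for both
    questionnaire items; the study provides no generative model for these,
    so they are plain configuration.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {g: 16 for g in GROUPS}
    )
    hyper: HyperParams = field(default_factory=HyperParams)
    effects: GroupEffects = field(default_factory=GroupEffects)
    seed: int = 0
    designs: Mapping[str, SessionDesign] | None = None
    subjective_probs: Mapping[str, Sequence[float]] | None = None
    link: str = "probit"
    rt_loc: float = 6.7
    rt_scale: float = 0.25
    #: generate with a single learning rate (alpha_G = alpha_L per subject)
    single_alpha: bool = False
    #: generate with day-2 parameters identical to day 1 (no shifts, no redraw)
    share_days: bool = False

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 1:
                raise ValueError(f"subject count for {g!r} must be positive")


def _draw_subject_params(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> tuple[AgentParams, AgentParams]:
    """Draw (day-1, day-2) parameters for one subject under the hierarchy."""
    to_nat, _ = alpha_link(spec.link)

    def one_day(day: int, z: dict) -> AgentParams:
        vals = {}
        for theta in PARAM_NAMES:
            loc = spec.hyper.mu(theta)
            if day == 2:
                loc += spec.effects.day2_shift(theta, group)
            vals[theta] = loc + spec.hyper.sigma(theta) * z[theta]
        return AgentParams(
            alpha_G=float(to_nat(vals["alpha_G"])),
            alpha_L=float(to_nat(vals["alpha_L"])),
            beta=float(np.exp(vals["beta"])),
        )

    def draw_z() -> dict:
        z = {theta: rng.normal() for theta in PARAM_NAMES}
        if spec.single_alpha:
            z["alpha_L"] = z["alpha_G"]
        return z

    z1 = draw_z()
    p1 = one_day(1, z1)
    if spec.share_days:
        return p1, p1
    return p1, one_day(2, draw_z())


def simulate_cohort(spec: CohortSpec) -> list[SubjectDataset]:
    """Simulate a full cohort under the generative hierarchy."""
    rng = np.random.default_rng(spec.seed)
    cohort: list[SubjectDataset] = []
    for group in GROUPS:
        n = spec.n_per_group.get(group, 0)
        for i in range(n):
            p1, p2 = _draw_subject_params(spec, group, rng)
            subj = simulate_subject(
                p1,
                p2,
                group,
                rng,
                subject_id=f"{group}_{i + 1:02d}",
                designs=spec.designs,
                rt_loc=spec.rt_loc,
                rt_scale=spec.rt_scale,
            )
            if spec.subjective_probs is not None and group in spec.subjective_probs:
                p = np.asarray(spec.subjective_probs[group], dtype=float)
                p = p / p.sum()
                for q in ("expected", "perceived"):
                    subj.subjective[q] = SUBJECTIVE_CATEGORIES[rng.choice(3, p=p)]
            cohort.append(subj)
    return cohort
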