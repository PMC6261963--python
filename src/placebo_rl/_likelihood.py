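"""Packed trial arrays and numba kernels for the choice likelihood.

The fitted likelihood replays each subject-session's Q trajectory
deterministically from the recorded choices and rewards and scores every
answered trial with the softmax log-probability of the chosen symbol.  Each
task session is one *episode* with a fresh Q vector (every task uses new
stimuli); missed trials are excluded and do not advance Q.

Kernels are batched over parameter vectors (one row per ensemble walker) so
the sampler can evaluate half an ensemble in a single call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .rl_agent import GROUP_SCHEDULES, SubjectDataset, pair_symbol_indices

__all__ = ["PackedCohort", "pack_cohort", "loglik_sum", "loglik_pointwise"]


@dataclass
class PackedCohort:
    """Flat trial arrays for a cohort, episode-indexed.

    ``slot`` indexes subject-days: slot = 2 * subject_index + (day - 1).
    """

    chosen: np.ndarray  # (T,) int8, chosen symbol 0..5
    other: np.ndarray  # (T,) int8, unchosen symbol of the presented pair
    reward: np.ndarray  # (T,) int8 in {0, 1}
    offsets: np.ndarray  # (E + 1,) int64 episode boundaries
    ep_slot: np.ndarray  # (E,) int64 subject-day slot per episode
    subjects: list  # subject ids, cohort order
    subject_group: list  # group label per subject
    groups: tuple  # distinct group labels present (study order)
    obs_subject: np.ndarray  # (T,) int64 subject index per trial
    obs_day: np.ndarray  # (T,) int8 day (1 or 2) per trial

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_slots(self) -> int:
        return 2 * len(self.subjects)

    @property
    def n_trials(self) -> int:
        return int(self.chosen.size)


def pack_cohort(cohort: list[SubjectDataset]) -> PackedCohort:
    if not cohort:
        raise ValueError("cohort is empty")
    chosen, other, reward, offsets, ep_slot = [], [], [], [0], []
    obs_subject, obs_day = [], []
    group_order = [g for g in GROUP_SCHEDULES if any(s.group == g for s in cohort)]
    subjects, subject_group = [], []
    for si, subj in enumerate(cohort):
        subjects.append(subj.subject_id)
        subject_group.append(subj.group)
        for day in sorted(subj.days):
            if day not in (1, 2):
                raise ValueError(f"day must be 1 or 2, got {day}")
            for session in subj.days[day]:
                n_in_ep = 0
                last_t = -1
                for rec in session.records:
                    if rec.trial_in_session <= last_t:
                        raise ValueError(
                            f"records of {subj.subject_id} day {day} not ordered by trial"
                        )
                    last_t = rec.trial_in_session
                    if rec.chosen_better is None:
                        continue  # missed trial: no feedback, no update
                    if rec.reward is None:
                        raise ValueError(
                            f"answered trial without reward for {subj.subject_id} day {day}"
                        )
                    better, worse = pair_symbol_indices(rec.pair_id)
                    c, o = (better, worse) if rec.chosen_better else (worse, better)
                    chosen.append(c)
                    other.append(o)
                    reward.append(int(rec.reward))
                    obs_subject.append(si)
                    obs_day.append(day)
                    n_in_ep += 1
                if n_in_ep:
                    offsets.append(offsets[-1] + n_in_ep)
                    ep_slot.append(2 * si + (day - 1))
    if not chosen:
        raise ValueError("cohort contains no answered trials")
    return PackedCohort(
        chosen=np.asarray(chosen, dtype=np.int8),
        other=np.asarray(other, dtype=np.int8),
        reward=np.asarray(reward, dtype=np.int8),
        offsets=np.asarray(offsets, dtype=np.int64),
        ep_slot=np.asarray(ep_slot, dtype=np.int64),
        subjects=subjects,
        subject_group=subject_group,
        groups=tuple(group_order),
        obs_subject=np.asarray(obs_subject, dtype=np.int64),
        obs_day=np.asarray(obs_day, dtype=np.int8),
    )


@njit(cache=True)
def _log_sigmoid(neg_d):  # log(1 / (1 + exp(-neg_d))) evaluated stably
    if neg_d >= 0.0:
        return -np.log1p(np.exp(-neg_d))
    return neg_d - np.log1p(np.exp(neg_d))


@njit(cache=True)
def _loglik_sum_kernel(aG, aL, beta, chosen, other, reward, offsets, ep_slot, out):
    B = aG.shape[0]
    E = offsets.shape[0] - 1
    for b in range(B):
        total = 0.0
        for e in range(E):
            s = ep_slot[e]
            ag = aG[b, s]
            al = aL[b, s]
            bt = beta[b, s]
            Q = np.zeros(6)
            for t in range(offsets[e], offsets[e + 1]):
                c = chosen[t]
                o = other[t]
                total += _log_sigmoid((Q[c] - Q[o]) / bt)
                pe = reward[t] - Q[c]
                if pe > 0.0:
                    Q[c] = Q[c] + ag * pe
                elif pe < 0.0:
                    Q[c] = Q[c] + al * pe
        out[b] = total


@njit(cache=True)
def _loglik_episode_kernel(aG, aL, beta, chosen, other, reward, offsets, ep_slot, out):
    B = aG.shape[0]
    E = offsets.shape[0] - 1
    for b in range(B):
        for e in range(E):
            s = ep_slot[e]
            ag = aG[b, s]
            al = aL[b, s]
            bt = beta[b, s]
            Q = np.zeros(6)
            total = 0.0
            for t in range(offsets[e], offsets[e + 1]):
                c = chosen[t]
                o = other[t]
                total += _log_sigmoid((Q[c] - Q[o]) / bt)
                pe = reward[t] - Q[c]
                if pe > 0.0:
                    Q[c] = Q[c] + ag * pe
                elif pe < 0.0:
                    Q[c] = Q[c] + al * pe
            out[b, e] = total


@njit(cache=True)
def _loglik_pointwise_kernel(aG, aL, beta, chosen, other, reward, offsets, ep_slot, out):
    B = aG.shape[0]
    E = offsets.shape[0] - 1
    for b in range(B):
        for e in range(E):
            s = ep_slot[e]
            ag = aG[b, s]
            al = aL[b, s]
            bt = beta[b, s]
            Q = np.zeros(6)
            for t in range(offsets[e], offsets[e + 1]):
                c = chosen[t]
                o = other[t]
                out[b, t] = _log_sigmoid((Q[c] - Q[o]) / bt)
                pe = reward[t] - Q[c]
                if pe > 0.0:
                    Q[c] = Q[c] + ag * pe
                elif pe < 0.0:
                    Q[c] = Q[c] + al * pe


def _as_batch(a, n_slots):
    a = np.ascontiguousarray(np.asarray(a, dtype=np.float64))
    if a.ndim == 1:
        a = a[None, :]
    if a.shape[1] != n_slots:
        raise ValueError(f"expected {n_slots} subject-day slots, got {a.shape[1]}")
    return a


def loglik_sum(packed: PackedCohort, alpha_G, alpha_L, beta) -> np.ndarray:
    """Total choice log-likelihood per parameter row.

    ``alpha_G``/``alpha_L``/``beta`` have shape (batch, n_slots) on the
    natural scale, one column per subject-day slot.
    """
    aG = _as_batch(alpha_G, packed.n_slots)
    aL = _as_batch(alpha_L, packed.n_slots)
    bt = _as_batch(beta, packed.n_slots)
    out = np.empty(aG.shape[0])
    _loglik_sum_kernel(
        aG, aL, bt, packed.chosen, packed.other, packed.reward, packed.offsets, packed.ep_slot, out
    )
    return out


def loglik_episode(packed: PackedCohort, alpha_G, alpha_L, beta) -> np.ndarray:
    """Per-episode (subject-session) log-likelihood, shape (batch, n_episodes)."""
    aG = _as_batch(alpha_G, packed.n_slots)
    aL = _as_batch(alpha_L, packed.n_slots)
    bt = _as_batch(beta, packed.n_slots)
    out = np.empty((aG.shape[0], packed.ep_slot.size))
    _loglik_episode_kernel(
        aG, aL, bt, packed.chosen, packed.other, packed.reward, packed.offsets, packed.ep_slot, out
    )
    return out


def loglik_pointwise(packed: PackedCohort, alpha_G, alpha_L, beta) -> np.ndarray:
    """Per-trial choice log-likelihood, shape (batch, n_trials)."""
    aG = _as_batch(alpha_G, packed.n_slots)
    aL = _as_batch(alpha_L, packed.n_slots)
    bt = _as_batch(beta, packed.n_slots)
    out = np.empty((aG.shape[0], packed.n_trials))
    _loglik_pointwise_kernel(
        aG, aL, bt, packed.chosen, packed.other, packed.reward, packed.offsets, packed.ep_slot, out
    )
    return out
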