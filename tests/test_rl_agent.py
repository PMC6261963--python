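"""Forward model: value updates, softmax choice and cohort simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import placebo_rl as p
from placebo_rl.rl_agent import GROUP_SCHEDULES, pair_symbol_indices
from placebo_rl.experiments import performance_map

from conftest import scaled_designs


def test_q_update_worked_examples():
    assert p.q_update(0.0, 1, p.AgentParams(0.5, 0.2, 1.0)) == pytest.approx(0.5)
    assert p.q_update(0.5, 0, p.AgentParams(0.5, 0.2, 1.0)) == pytest.approx(0.4)
    assert p.q_update(0.7, 1, p.AgentParams(0.0, 0.0, 1.0)) == pytest.approx(0.7)
    assert p.q_update(0.5, 0, p.AgentParams(0.0, 0.0, 1.0)) == pytest.approx(0.5)


def test_q_update_rejects_bad_inputs():
    with pytest.raises(ValueError):
        p.q_update(0.0, 2, p.AgentParams(0.5, 0.5, 1.0))
    with pytest.raises(ValueError):
        p.AgentParams(1.5, 0.5, 1.0)
    with pytest.raises(ValueError):
        p.AgentParams(0.5, 0.5, 0.0)


def test_q_trajectory_matches_naive_oracle():
    """20-trial replay agrees with an independently coded loop to 1e-12."""
    rng = np.random.default_rng(3)
    rewards = rng.integers(0, 2, size=20)
    aG, aL = 0.3, 0.1
    params = p.AgentParams(aG, aL, 1.0)
    q = 0.0
    oracle = 0.0
    for r in rewards:
        q = p.q_update(q, int(r), params)
        # oracle: direct positive/negative-part formula
        pe = r - oracle
        oracle = oracle + aG * max(pe, 0.0) + aL * min(pe, 0.0)
        assert q == pytest.approx(oracle, abs=1e-12)


@given(
    q=st.floats(0, 1),
    r=st.integers(0, 1),
    aG=st.floats(0, 1),
    aL=st.floats(0, 1),
)
@settings(deadline=None, max_examples=200, derandomize=True)
def test_q_stays_in_unit_interval(q, r, aG, aL):
    q2 = p.q_update(q, r, p.AgentParams(aG, aL, 1.0))
    assert 0.0 <= q2 <= 1.0


def test_choice_prob_worked_example():
    """Perfect knowledge of the easiest pair at beta = 2 gives ~0.57."""
    assert p.choice_prob(0.8, 0.2, 2.0) == pytest.approx(0.574, abs=5e-4)
    assert round(p.choice_prob(0.8, 0.2, 2.0), 2) == 0.57


@given(
    qa=st.floats(-5, 5),
    qb=st.floats(-5, 5),
    beta=st.floats(0.01, 100),
)
@settings(deadline=None, max_examples=200, derandomize=True)
def test_choice_prob_normalises(qa, qb, beta):
    pa = p.choice_prob(qa, qb, beta)
    pb = p.choice_prob(qb, qa, beta)
    assert pa + pb == pytest.approx(1.0, abs=1e-12)
    assert 0.0 <= pa <= 1.0


def test_choice_prob_limits_and_errors():
    assert p.choice_prob(0.3, 0.3, 5.0) == pytest.approx(0.5)
    assert p.choice_prob(1.0, 0.0, 1e-8) == pytest.approx(1.0)
    assert p.choice_prob(1e6, -1e6, 0.5) == pytest.approx(1.0)  # no overflow
    with pytest.raises(ValueError):
        p.choice_prob(0.5, 0.5, -1.0)


def test_subject_follows_group_schedule():
    params = p.AgentParams(0.3, 0.1, 0.2)
    subj = p.simulate_subject(params, params, "nocebo", seed=0)
    assert [s.task_label for s in subj.days[1]] == ["task1_default", "task2_nocebo"]
    assert [s.task_label for s in subj.days[2]] == ["task3_default"]
    assert subj.n_trials(1) == 360 and subj.n_trials(2) == 240
    with pytest.raises(ValueError, match="unknown group"):
        p.simulate_subject(params, params, "sham", seed=0)


def test_subject_simulation_reproducible():
    params = p.AgentParams(0.4, 0.2, 0.3)
    a = p.simulate_subject(params, params, "NHG", seed=5)
    b = p.simulate_subject(params, params, "NHG", seed=5)
    assert a.days[1][0].records == b.days[1][0].records


def _mean_accuracy(subjects, day=None):
    hits = tot = 0
    for s in subjects:
        days = [day] if day else sorted(s.days)
        for d in days:
            for sess in s.days[d]:
                for r in sess.records:
                    hits += int(r.chosen_better)
                    tot += 1
    return hits / tot


def test_no_learning_agent_is_at_chance():
    params = p.AgentParams(0.0, 0.0, 1.0)
    subs = [
        p.simulate_subject(params, params, "NHG", seed=i, designs=scaled_designs(1))
        for i in range(40)
    ]
    assert _mean_accuracy(subs) == pytest.approx(0.5, abs=0.03)


def test_pure_noise_agent_is_at_chance():
    params = p.AgentParams(0.5, 0.5, 1e3)
    subs = [
        p.simulate_subject(params, params, "NHG", seed=i, designs=scaled_designs(1))
        for i in range(40)
    ]
    assert _mean_accuracy(subs) == pytest.approx(0.5, abs=0.03)


def test_easy_pair_learned_better_than_hard_pair():
    """AB (80/20) accuracy exceeds EF (60/40) for a learning agent."""
    params = p.AgentParams(0.3, 0.3, 0.2)
    by_pair = {"AB": [0, 0], "EF": [0, 0]}
    for i in range(60):
        subj = p.simulate_subject(params, params, "NHG", seed=i, designs=scaled_designs(2))
        for d in (1, 2):
            for sess in subj.days[d]:
                for r in sess.records:
                    if r.pair_id in by_pair:
                        by_pair[r.pair_id][0] += int(r.chosen_better)
                        by_pair[r.pair_id][1] += 1
    acc = {k: h / n for k, (h, n) in by_pair.items()}
    assert acc["AB"] > acc["EF"] + 0.05


def test_accuracy_decreases_with_noise():
    """Expected accuracy is non-increasing in beta at fixed learning rates."""
    grid = performance_map(
        "alpha_G", [0.3], "beta", [0.1, 0.5, 2.0, 20.0], fixed={"alpha_L": 0.3},
        n_reps=300, seed=0,
    )
    acc = grid.accuracy[:, 0]
    assert np.all(np.diff(acc) < 0.02)  # allow Monte-Carlo slack
    assert acc[0] > acc[-1] + 0.1


def test_cohort_degenerate_hierarchy_shares_parameters():
    spec = p.CohortSpec(
        n_per_group={"NHG": 3},
        hyper=p.HyperParams(
            mu_alphaG=0.0, mu_alphaL=0.0, mu_beta=0.0,
            sigma_alphaG=0.0, sigma_alphaL=0.0, sigma_beta=0.0,
        ),
        seed=0,
        designs=scaled_designs(1),
    )
    cohort = p.simulate_cohort(spec)
    for s in cohort:
        # probit^-1(0) = 0.5, exp(0) = 1
        assert s.true_params[1] == p.AgentParams(0.5, 0.5, 1.0)
        assert s.true_params[2] == p.AgentParams(0.5, 0.5, 1.0)


def test_cohort_trial_counts_match_study_design():
    spec = p.CohortSpec(seed=1)  # defaults: 16 per group, built-in designs
    cohort = p.simulate_cohort(spec)
    assert len(cohort) == 80
    for s in cohort:
        extra = 120 if s.group != "NHG" else 0
        assert s.n_trials(1) == 240 + extra
        assert s.n_trials(2) == 240


def test_cohort_day2_shift_applied_on_transformed_scale():
    eff = p.GroupEffects(
        b_day={"alpha_G": 0.0, "alpha_L": 0.0, "beta": 1.0},
        sigma_b=1.0,
    )
    spec = p.CohortSpec(
        n_per_group={"NHG": 6},
        hyper=p.HyperParams(sigma_alphaG=0.0, sigma_alphaL=0.0, sigma_beta=0.0),
        effects=eff,
        seed=0,
        designs=scaled_designs(1),
    )
    cohort = p.simulate_cohort(spec)
    for s in cohort:
        assert s.true_params[2].beta == pytest.approx(np.e * s.true_params[1].beta)


def test_pair_symbols_are_disjoint():
    seen = set()
    for pid in ("AB", "CD", "EF"):
        b, w = pair_symbol_indices(pid)
        seen |= {b, w}
    assert seen == set(range(6))
    assert set(GROUP_SCHEDULES) == set(p.GROUPS)
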