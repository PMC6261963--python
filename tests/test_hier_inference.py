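"""Inverse model: transforms, likelihood replay, diagnostics, hierarchy."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import placebo_rl as p
from placebo_rl._likelihood import loglik_pointwise, pack_cohort
from placebo_rl.hier_inference import prior_predictive_params
from placebo_rl.rl_agent import SessionData
from placebo_rl.task_design import TrialRecord

from conftest import scaled_designs


# -- transforms --------------------------------------------------------------


def test_transform_worked_examples():
    assert p.to_natural(0.0) == pytest.approx(0.5)
    assert p.to_natural_beta(0.0) == pytest.approx(1.0)
    assert p.to_natural(-0.5) == pytest.approx(0.3085, abs=1e-4)


@given(x=st.floats(-5, 5))
@settings(deadline=None, derandomize=True)
def test_transforms_round_trip(x):
    assert p.from_natural(p.to_natural(x)) == pytest.approx(x, abs=1e-9)
    assert p.from_natural_beta(p.to_natural_beta(x)) == pytest.approx(x, abs=1e-12)


# -- likelihood --------------------------------------------------------------

_PAIR_SYMBOLS = {"AB": (0, 1), "CD": (2, 3), "EF": (4, 5)}


def _oracle_loglik(trials, aG, aL, beta):
    """Brute-force replay: explicit softmax and positive/negative parts."""
    q = [0.0] * 6
    out = []
    for pair_id, chose_better, reward in trials:
        b, w = _PAIR_SYMBOLS[pair_id]
        c, o = (b, w) if chose_better else (w, b)
        num = math.exp(q[c] / beta)
        den = num + math.exp(q[o] / beta)
        out.append(math.log(num / den))
        pe = reward - q[c]
        q[c] += aG * max(pe, 0.0) + aL * min(pe, 0.0)
    return np.asarray(out)


def _records(trials):
    return [
        TrialRecord(1, t + 1, pid, True, cb, r) for t, (pid, cb, r) in enumerate(trials)
    ]


@given(
    data=st.lists(
        st.tuples(
            st.sampled_from(["AB", "CD", "EF"]),
            st.booleans(),
            st.integers(0, 1),
        ),
        min_size=1,
        max_size=20,
    ),
    aG=st.floats(0.0, 1.0),
    aL=st.floats(0.0, 1.0),
    beta=st.floats(0.05, 5.0),
)
@settings(deadline=None, max_examples=150, derandomize=True)
def test_trial_loglik_matches_bruteforce_oracle(data, aG, aL, beta):
    got = p.trial_loglik(_records(data), p.AgentParams(aG, aL, beta))
    want = _oracle_loglik(data, aG, aL, beta)
    assert np.allclose(got, want, atol=1e-10)


def test_batched_kernel_agrees_with_trial_loglik():
    """The compiled likelihood used in fitting equals the replay API."""
    rng = np.random.default_rng(0)
    params = p.AgentParams(0.45, 0.15, 0.4)
    subj = p.simulate_subject(params, params, "placebo", seed=1, designs=scaled_designs(1))
    packed = pack_cohort([subj])
    n_slots = packed.n_slots
    aG = np.full(n_slots, params.alpha_G)
    aL = np.full(n_slots, params.alpha_L)
    bt = np.full(n_slots, params.beta)
    kernel = loglik_pointwise(packed, aG, aL, bt)[0]
    api = np.concatenate(
        [p.trial_loglik(subj.days[d], params) for d in sorted(subj.days)]
    )
    assert np.allclose(kernel, api, atol=1e-10)
    del rng


def test_trial_loglik_limits():
    trials = [("AB", bool(i % 2), i % 2) for i in range(30)]
    # huge noise: every choice probability ~0.5
    ll = p.trial_loglik(_records(trials), p.AgentParams(0.5, 0.5, 1e6))
    assert np.allclose(ll, math.log(0.5), atol=1e-4)
    # zero learning rates: values never separate, exactly log 0.5
    ll = p.trial_loglik(_records(trials), p.AgentParams(0.0, 0.0, 0.3))
    assert np.allclose(ll, math.log(0.5), atol=1e-12)


def test_trial_loglik_validates_records():
    recs = _records([("AB", True, 1), ("AB", False, 0)])
    with pytest.raises(ValueError, match="ordered"):
        p.trial_loglik(list(reversed(recs)), p.AgentParams(0.3, 0.3, 0.5))
    missed = [TrialRecord(1, 1, "AB", True, None, None)] + [
        TrialRecord(1, t + 2, "AB", True, True, 1) for t in range(3)
    ]
    ll = p.trial_loglik(missed, p.AgentParams(0.3, 0.3, 0.5))
    assert ll.size == 3  # missed trial excluded


def test_session_reset_between_tasks():
    """Q starts fresh per session: per-session replay equals concatenation."""
    params = p.AgentParams(0.4, 0.2, 0.3)
    subj = p.simulate_subject(params, params, "placebo", seed=3, designs=scaled_designs(1))
    day1 = subj.days[1]
    joint = p.trial_loglik(day1, params)
    parts = np.concatenate([p.trial_loglik(s.records, params) for s in day1])
    assert np.allclose(joint, parts)


# -- model structure ---------------------------------------------------------


def _five_group_cohort():
    spec = p.CohortSpec(
        n_per_group={g: 1 for g in p.GROUPS},
        seed=0,
        designs=scaled_designs(1),
    )
    return p.simulate_cohort(spec)


def test_full_model_parameter_count():
    """6 hypers + 15 shrunk effects + sigma_b + 3 per subject-day."""
    cohort = _five_group_cohort()
    model = p.HierarchicalRLModel(cohort, variant="full")
    n_subj = len(cohort)
    assert model.ndim == 6 + 1 + 15 + 3 * 2 * n_subj
    assert sum(1 for n in model.param_names if n.startswith("b_")) == 15


def test_variant_parameter_sharing():
    cohort = _five_group_cohort()
    m1 = p.HierarchicalRLModel(cohort, variant="single_alpha")
    m2 = p.HierarchicalRLModel(cohort, variant="day_group")
    n = len(cohort)
    assert m1.ndim == 4 + 2 * n  # 2 mus, 2 sigmas, alpha+beta per subject
    assert m2.ndim == 4 + 1 + 10 + 2 * 2 * n  # + sigma_b + 2+8 effects
    with pytest.raises(ValueError, match="variant"):
        p.HierarchicalRLModel(cohort, variant="m4")


def test_nhg_day2_uses_common_day_effect_only():
    """No group-shift parameter exists for the natural history baseline."""
    cohort = _five_group_cohort()
    model = p.HierarchicalRLModel(cohort, variant="full")
    assert not any("[NHG]" in n for n in model.param_names)
    assert "b_day_alpha_G" in model.param_names


def test_log_density_invariant_to_subject_order(tiny_cohort):
    m = p.HierarchicalRLModel(tiny_cohort, variant="full")
    perm = list(reversed(tiny_cohort))
    mp = p.HierarchicalRLModel(perm, variant="full")
    # identical parameters for every subject: order cannot matter
    x = m._init_center()
    assert m.log_prob(x)[0] == pytest.approx(mp.log_prob(mp._init_center())[0], rel=1e-12)


def test_parameterizations_define_same_posterior(tiny_cohort):
    """Centred and non-centred log densities differ only by a constant shift
    along matched points (checked at the shared prior-central point)."""
    mc = p.HierarchicalRLModel(tiny_cohort, parameterization="centered")
    mn = p.HierarchicalRLModel(tiny_cohort, parameterization="noncentered")
    # at the centred point v = loc, the non-centred equivalent is z = 0
    lc = mc.log_prob(mc._init_center())[0]
    ln = mn.log_prob(mn._init_center())[0]
    # densities at corresponding points differ by the reparameterisation
    # Jacobians: log sigma per subject value, log sigma_b per shrunk effect
    n_slots = mc.packed.n_slots
    n_effects = 3 * (1 + len(mc.mgroups))
    jac = 3 * n_slots * math.log(0.2) + n_effects * math.log(0.3)
    assert lc == pytest.approx(ln - jac, rel=1e-9)


# -- diagnostics -------------------------------------------------------------


def test_rhat_same_distribution_near_one():
    rng = np.random.default_rng(0)
    chains = rng.standard_normal((2, 5000))
    assert 1.0 <= p.rhat(chains) < 1.05


def test_rhat_detects_separated_chains():
    rng = np.random.default_rng(0)
    chains = rng.standard_normal((2, 1000))
    chains[1] += 5.0
    assert p.rhat(chains) > 1.1


def test_rhat_constant_chains_and_errors():
    assert p.rhat(np.ones((4, 100))) == 1.0
    with pytest.raises(ValueError, match="2 chains"):
        p.rhat(np.zeros((1, 100)))


def test_hdi_standard_normal():
    rng = np.random.default_rng(1)
    lo, hi = p.hdi(rng.standard_normal(200_000), 0.95)
    assert lo == pytest.approx(-1.96, abs=0.03)
    assert hi == pytest.approx(1.96, abs=0.03)


def test_hdi_point_mass_and_exponential():
    assert p.hdi(np.full(100, 2.5), 0.95) == (2.5, 2.5)
    rng = np.random.default_rng(2)
    lo, hi = p.hdi(rng.exponential(1.0, 100_000), 0.95)
    assert lo < 0.02  # HDI hugs the mode at zero
    assert hi == pytest.approx(3.0, abs=0.15)


def test_hdi_validation():
    with pytest.raises(ValueError, match="mass"):
        p.hdi(np.arange(100.0), 1.5)
    with pytest.raises(ValueError, match="50 draws"):
        p.hdi(np.arange(10.0), 0.95)


# -- priors ------------------------------------------------------------------


def test_prior_predictive_shape():
    """Implied priors put most learning-rate mass below 0.5 and most
    noise-parameter mass below 2."""
    draws = prior_predictive_params(n=20_000, seed=0)
    assert np.mean(draws["alpha"] < 0.5) > 0.6
    assert np.mean(draws["beta"] < 2.0) > 0.9
    assert np.mean(draws["beta"] < 0.8) > 0.5


# -- fitting -----------------------------------------------------------------


def test_fit_reproducible_and_summaries(small_fit, tiny_cohort):
    res = small_fit
    assert res.samples.chains.shape[0] == 4
    assert res.diagnostics.rhat.index.tolist() == res.samples.names
    # deterministic refit
    model = p.HierarchicalRLModel(tiny_cohort, variant="full")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", p.ConvergenceWarning)
        res2 = model.fit(p.SamplerConfig(chains=4, warmup=600, draws=300, thin=2), seed=0)
    assert np.array_equal(res.samples.chains, res2.samples.chains)
    table = res.summarize_effects(formatted=True)
    assert table.shape == (2, 3)  # NHG baseline + placebo rows
    assert list(table.columns) == ["alpha_G", "alpha_L", "beta"]


def test_effect_table_has_five_rows_with_all_groups():
    spec = p.CohortSpec(
        n_per_group={g: 2 for g in p.GROUPS}, seed=3, designs=scaled_designs(1)
    )
    model = p.HierarchicalRLModel(p.simulate_cohort(spec), variant="full")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", p.ConvergenceWarning)
        res = model.fit(p.SamplerConfig(chains=2, warmup=150, draws=120, thin=1), seed=0)
    table = res.summarize_effects(formatted=True)
    assert table.shape == (5, 3)
    assert table.index[0] == "NHG (baseline)"


def test_effect_table_requires_full_variant(tiny_cohort):
    model = p.HierarchicalRLModel(tiny_cohort, variant="single_alpha")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", p.ConvergenceWarning)
        res = model.fit(p.SamplerConfig(chains=2, warmup=100, draws=60, thin=1), seed=0)
    with pytest.raises(ValueError, match="full"):
        res.summarize_effects()


def test_posterior_contracts_with_more_trials():
    """More trials per subject sharpen the group-mean posterior and pull it
    toward the generating value."""
    truth = -0.2
    results = {}
    for blocks in (1, 4):
        spec = p.CohortSpec(
            n_per_group={"NHG": 4},
            hyper=p.HyperParams(
                mu_alphaG=truth, mu_alphaL=truth, mu_beta=-1.2,
                sigma_alphaG=0.15, sigma_alphaL=0.15, sigma_beta=0.15,
            ),
            seed=11,
            single_alpha=True,
            share_days=True,
            designs=scaled_designs(blocks),
        )
        model = p.HierarchicalRLModel(p.simulate_cohort(spec), variant="single_alpha")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", p.ConvergenceWarning)
            res = model.fit(p.SamplerConfig(chains=4, warmup=500, draws=300, thin=1), seed=0)
        results[blocks] = res.samples.flat("mu_alpha")
    assert results[4].std() < results[1].std()
    assert abs(results[4].mean() - truth) < abs(results[1].mean() - truth) + 0.1
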