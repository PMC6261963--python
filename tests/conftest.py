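import warnings

import numpy as np
import pytest

import placebo_rl as p
from placebo_rl.task_design import make_design


def scaled_designs(n_blocks: int):
    """Built-in designs with fewer blocks, for fast fits."""
    return {
        label: make_design(label).scaled(n_blocks)
        for label in ("task1_default", "task3_default", "task2_placebo", "task2_nocebo")
    }


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 NHG + 3 placebo subjects with 60-trial default sessions."""
    spec = p.CohortSpec(
        n_per_group={"NHG": 3, "placebo": 3},
        hyper=p.HyperParams(
            mu_alphaG=-0.3,
            mu_alphaL=-0.8,
            mu_beta=-1.2,
            sigma_alphaG=0.25,
            sigma_alphaL=0.25,
            sigma_beta=0.25,
        ),
        seed=42,
        designs=scaled_designs(1),
        subjective_probs={
            "placebo": (0.05, 0.25, 0.70),
            "nocebo": (0.70, 0.20, 0.10),
            "placebo_control": (0.10, 0.40, 0.50),
            "nocebo_control": (0.10, 0.55, 0.35),
        },
    )
    return p.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_fit(tiny_cohort):
    """A quick, converged-enough full-model fit shared across tests."""
    model = p.HierarchicalRLModel(tiny_cohort, variant="full")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", p.ConvergenceWarning)
        res = model.fit(
            p.SamplerConfig(chains=4, warmup=600, draws=300, thin=2), seed=0
        )
    return res


def fresh_rng(seed=0):
    return np.random.default_rng(seed)
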