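"""Desk-scale validation studies: performance maps, parameter recovery and
model recovery.

The performance map tabulates the Monte-Carlo expected accuracy of a
simulated agent over a grid of model parameters on a stated session design
(the "which parameter settings are optimal" landscape).  Parameter recovery
simulates cohorts from known hyperparameters, fits the hierarchical model
and scores bias, RMSE, interval coverage and subject-level rank
correlation.  Model recovery checks that LOOIC prefers the dual-learning-
rate model on data generated with separated gain/loss learning rates and
does not strongly prefer it on single-learning-rate data.

Defaults are deliberately desk-scale (small cohorts, reduced draw budgets);
study-scale settings are available through the configuration objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from ._params import MANIPULATED_GROUPS, PARAM_NAMES, from_natural, from_natural_beta
from ._sampler import SamplerConfig
from .hier_inference import HierarchicalRLModel, hdi
from .model_selection import pointwise_matrix, psis_loo
from .rl_agent import CohortSpec, simulate_cohort
from .task_design import SessionDesign, generate_session, make_design

__all__ = [
    "PerformanceGrid",
    "RecoveryReport",
    "performance_map",
    "run_parameter_recovery",
    "run_model_recovery",
    "reduced_study_spec",
]


def reduced_study_spec(seed: int = 0) -> "CohortSpec":
    """Desk-scale analogue of the study for convergence checks.

    Two groups (natural history + placebo, 4 subjects each), two-block
    default sessions (120 trials/day; the placebo group's day 1 adds its
    120-trial manipulated session), realistic group-level parameters
    (learning rates centred near 0.38/0.21, beta near 0.3) and a day-2
    gain/loss learning-rate shift of the magnitude seen in behavioural
    practice effects.
    """
    from ._params import HyperParams, GroupEffects
    from .task_design import make_design

    return CohortSpec(
        n_per_group={"NHG": 4, "placebo": 4},
        hyper=HyperParams(
            mu_alphaG=-0.3,
            mu_alphaL=-0.8,
            mu_beta=-1.2,
            sigma_alphaG=0.25,
            sigma_alphaL=0.25,
            sigma_beta=0.25,
        ),
        effects=GroupEffects(b_day={"alpha_G": 0.3, "alpha_L": -0.2, "beta": 0.0}),
        seed=seed,
        designs={
            label: make_design(label).scaled(2)
            for label in ("task1_default", "task3_default")
        },
    )


@njit(cache=True)
def _sim_accuracy(aG, aL, beta, pair_seq, p_better, p_worse, n_reps, seed):
    np.random.seed(seed)
    n_tr = pair_seq.shape[0]
    correct = 0
    for _ in range(n_reps):
        Q = np.zeros(6)
        for t in range(n_tr):
            p = pair_seq[t]
            b = 2 * p
            w = b + 1
            d = (Q[w] - Q[b]) / beta
            if d >= 0.0:
                pb = np.exp(-d) / (1.0 + np.exp(-d))
            else:
                pb = 1.0 / (1.0 + np.exp(d))
            if np.random.random() < pb:
                correct += 1
                c = b
                pr = p_better[p]
            else:
                c = w
                pr = p_worse[p]
            rew = 1.0 if np.random.random() < pr else 0.0
            pe = rew - Q[c]
            if pe > 0.0:
                Q[c] = Q[c] + aG * pe
            elif pe < 0.0:
                Q[c] = Q[c] + aL * pe
    return correct / (n_reps * n_tr)


@dataclass
class PerformanceGrid:
    """Monte-Carlo mean accuracy over a 2-D parameter grid."""

    x_param: str
    x_values: np.ndarray
    y_param: str
    y_values: np.ndarray
    fixed: dict
    accuracy: np.ndarray  # (len(y_values), len(x_values)), values in [0, 1]
    n_reps: int
    seed: int
    design_label: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, yv in enumerate(self.y_values):
            for j, xv in enumerate(self.x_values):
                rows.append(
                    {self.x_param: xv, self.y_param: yv, "accuracy": self.accuracy[i, j]}
                )
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.pcolormesh(self.x_values, self.y_values, self.accuracy, cmap="RdBu_r")
        ax.set_xlabel(self.x_param)
        ax.set_ylabel(self.y_param)
        plt.colorbar(im, ax=ax, label="expected accuracy")
        return ax


def performance_map(
    x_param: str,
    x_values: Sequence[float],
    y_param: str,
    y_values: Sequence[float],
    fixed: Mapping[str, float] | None = None,
    design: SessionDesign | None = None,
    n_reps: int = 200,
    seed: int = 0,
) -> PerformanceGrid:
    """Expected accuracy for each parameter combination on a session design.

    Each cell is the mean proportion of better-symbol choices over
    ``n_reps`` replicate agents playing the (fixed, seeded) trial schedule
    of ``design`` (default: the 240-trial default session).
    """
    x_values = np.asarray(list(x_values), dtype=float)
    y_values = np.asarray(list(y_values), dtype=float)
    if x_values.size == 0 or y_values.size == 0:
        raise ValueError("parameter grid must be non-empty on both axes")
    if x_param not in PARAM_NAMES or y_param not in PARAM_NAMES or x_param == y_param:
        raise ValueError(f"grid axes must be two distinct names from {PARAM_NAMES}")
    fixed = dict(fixed or {})
    third = [p for p in PARAM_NAMES if p not in (x_param, y_param)][0]
    if third not in fixed:
        raise ValueError(f"value for the fixed parameter {third!r} is required")
    design = design or make_design("task1_default")
    schedule = generate_session(design, seed)
    pair_seq = np.asarray(
        [{"AB": 0, "CD": 1, "EF": 2}[t.pair_id] for t in schedule], dtype=np.int64
    )
    p_b = np.asarray([p.p_better for p in design.pairs])
    p_w = np.asarray([p.p_worse for p in design.pairs])
    acc = np.empty((y_values.size, x_values.size))
    for i, yv in enumerate(y_values):
        for j, xv in enumerate(x_values):
            params = {**fixed, x_param: xv, y_param: yv}
            acc[i, j] = _sim_accuracy(
                params["alpha_G"],
                params["alpha_L"],
                params["beta"],
                pair_seq,
                p_b,
                p_w,
                n_reps,
                (seed + 1000003 * i + 7919 * j) % (2**31 - 1),
            )
    return PerformanceGrid(
        x_param=x_param,
        x_values=x_values,
        y_param=y_param,
        y_values=y_values,
        fixed=fixed,
        accuracy=acc,
        n_reps=n_reps,
        seed=seed,
        design_label=design.task_label,
    )


@dataclass
class RecoveryReport:
    """Parameter-recovery results over replicates."""

    table: pd.DataFrame  # one row per (replicate, quantity)
    rank_correlations: pd.DataFrame  # per replicate, subject-level Spearman rho
    failures: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Bias, RMSE and HDI coverage per recovered quantity."""
        g = self.table.groupby("quantity")
        out = pd.DataFrame(
            {
                "bias": g.apply(lambda d: (d["posterior_mean"] - d["truth"]).mean(), include_groups=False),
                "rmse": g.apply(
                    lambda d: float(np.sqrt(((d["posterior_mean"] - d["truth"]) ** 2).mean())),
                    include_groups=False,
                ),
                "coverage": g["covered"].mean(),
            }
        )
        return out


def _truth_map(spec: CohortSpec, model: HierarchicalRLModel) -> dict[str, float]:
    """Generating values keyed by the model's derived-quantity names."""
    truths: dict[str, float] = {}
    var_thetas = model.spec.thetas
    for th in var_thetas:
        gen_th = "alpha_G" if th == "alpha" else th
        truths[f"mu_{th}"] = spec.hyper.mu(gen_th)
        if model.spec.day_structure:
            truths[f"b_day_{th}"] = spec.effects.b_day[gen_th]
            for g in model.mgroups:
                truths[f"b_{th}[{g}]"] = spec.effects.b_group.get((gen_th, g), 0.0)
    return truths


def run_parameter_recovery(
    true_spec: CohortSpec,
    n_replicates: int = 1,
    variant: str = "full",
    config: SamplerConfig | None = None,
    seed: int = 0,
    hdi_mass: float = 0.95,
) -> RecoveryReport:
    """Simulate -> fit -> compare posterior to generating values.

    Each replicate re-simulates the cohort with a fresh seed, fits the
    requested model variant, and records posterior mean and HDI coverage
    for the group-level means and all day/group effects, plus the Spearman
    correlation between true and estimated subject-level parameters.
    Fit failures are recorded per replicate rather than raised.
    """
    rows, rank_rows, failures = [], [], []
    for r in range(n_replicates):
        spec_r = replace(true_spec, seed=(true_spec.seed + 104729 * r) % (2**31 - 1))
        cohort = simulate_cohort(spec_r)
        try:
            model = HierarchicalRLModel(cohort, variant=variant, link=spec_r.link)
            res = model.fit(config=config, seed=seed + r)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            failures.append({"replicate": r, "error": str(exc)})
            continue
        truths = _truth_map(spec_r, model)
        for name, truth in truths.items():
            if name.startswith("mu_"):
                draws = res.samples.flat(name)
            elif name.startswith("b_day_"):
                draws = res.effect_draws(name.removeprefix("b_day_"))
            else:
                th, g = name[2:].split("[")
                draws = res.effect_draws(th.rstrip("_"), g.rstrip("]"))
            lo, hi = hdi(draws, hdi_mass)
            rows.append(
                {
                    "replicate": r,
                    "quantity": name,
                    "truth": truth,
                    "posterior_mean": float(draws.mean()),
                    "hdi_low": lo,
                    "hdi_high": hi,
                    "covered": bool(lo <= truth <= hi),
                }
            )
        est = res.subject_params(day=1)
        true_by_subject = {
            s.subject_id: s.true_params[1] for s in cohort if s.true_params is not None
        }
        for th in ("alpha_G", "alpha_L", "beta"):
            true_vals = [getattr(true_by_subject[s], th) for s in est["subject_id"]]
            rho = stats.spearmanr(true_vals, est[th]).statistic
            rank_rows.append({"replicate": r, "parameter": th, "spearman_rho": float(rho)})
    return RecoveryReport(
        table=pd.DataFrame(rows),
        rank_correlations=pd.DataFrame(rank_rows),
        failures=failures,
    )


def run_model_recovery(
    generating_variant: str,
    n_replicates: int = 1,
    cohort_spec: CohortSpec | None = None,
    config: SamplerConfig | None = None,
    seed: int = 0,
    max_loo_draws: int | None = 1000,
) -> pd.DataFrame:
    """Fit the single- and dual-learning-rate models to simulated data.

    Data are generated either from the full model (``generating_variant=
    'full'``; the default cohort has well-separated gain/loss learning
    rates) or from the single-learning-rate model.  Per replicate the
    returned table records LOOIC for both fits, delta LOOIC (single minus
    full; positive favours the dual-learning-rate model) and the winner.
    """
    if generating_variant not in ("single_alpha", "full"):
        raise ValueError("generating_variant must be 'single_alpha' or 'full'")
    if cohort_spec is None:
        from ._params import HyperParams

        if generating_variant == "full":
            # clearly separated gain/loss learning rates (~0.7 vs ~0.2)
            hyper = HyperParams(
                mu_alphaG=float(from_natural(0.7)),
                mu_alphaL=float(from_natural(0.2)),
                mu_beta=float(from_natural_beta(0.3)),
                sigma_alphaG=0.2,
                sigma_alphaL=0.2,
                sigma_beta=0.2,
            )
            cohort_spec = CohortSpec(
                n_per_group={"NHG": 8}, hyper=hyper, share_days=True
            )
        else:
            hyper = HyperParams(
                mu_alphaG=float(from_natural(0.4)),
                mu_alphaL=float(from_natural(0.4)),
                mu_beta=float(from_natural_beta(0.3)),
                sigma_alphaG=0.2,
                sigma_alphaL=0.2,
                sigma_beta=0.2,
            )
            cohort_spec = CohortSpec(
                n_per_group={"NHG": 8}, hyper=hyper, single_alpha=True, share_days=True
            )
    rows = []
    for r in range(n_replicates):
        spec_r = replace(cohort_spec, seed=(cohort_spec.seed + 15485863 * r) % (2**31 - 1))
        cohort = simulate_cohort(spec_r)
        loos = {}
        for variant in ("single_alpha", "full"):
            try:
                res = HierarchicalRLModel(cohort, variant=variant).fit(
                    config=config, seed=seed + 17 * r
                )
                loos[variant] = psis_loo(pointwise_matrix(res, max_draws=max_loo_draws))
            except Exception as exc:  # noqa: BLE001
                loos[variant] = None
                rows.append({"replicate": r, "error": f"{variant}: {exc}"})
        if loos["single_alpha"] is None or loos["full"] is None:
            continue
        delta = loos["single_alpha"].looic - loos["full"].looic
        rows.append(
            {
                "replicate": r,
                "looic_single_alpha": loos["single_alpha"].looic,
                "looic_full": loos["full"].looic,
                "delta_looic": delta,
                "winner": "full" if delta > 0 else "single_alpha",
                "strong": bool(abs(delta) > 10.0),
            }
        )
    return pd.DataFrame(rows)
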