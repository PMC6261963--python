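"""Hierarchical Bayesian estimation of the dual-learning-rate model.

Subject-level learning rates are modelled on the probit scale and the noise
parameter on the log scale; day-1 parameters are drawn from group-level
normal distributions and day-2 parameters receive a common day shift plus a
group-specific shift on the transformed scale, with all shift effects
shrunk toward zero by a shared Normal(0, sigma_b) distribution:

    probit(alpha_{G,i})      ~ Normal(mu_aG, sigma_aG)                 (day 1)
    probit(alpha_{G,i}^d2)   ~ Normal(mu_aG + b_aG + b_{aG,group_i}, sigma_aG)
    log(beta_i)              ~ Normal(mu_b, sigma_b')                  (day 1)
    b_theta, b_{theta,group} ~ Normal(0, sigma_shrink)

and weakly-informative hyperpriors (see :class:`PriorConfig`).  The model
ladder has three variants: ``single_alpha`` (one learning rate and one noise
parameter per subject, shared across days), ``day_group`` (single learning
rate, parameters vary by day with group-specific day-2 shifts) and ``full``
(separate gain/loss learning rates, all parameters vary by day).

The non-centred parameterisation is used for all subject-level normals and
the shrunk effects (a posterior-equivalent reparameterisation that improves
sampler mixing).  Sampling uses the ensemble machinery in
:mod:`placebo_rl._sampler`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._likelihood import PackedCohort, loglik_pointwise, loglik_sum, pack_cohort
from ._params import (
    GROUPS,
    MANIPULATED_GROUPS,
    PARAM_NAMES,
    GroupEffects,
    HyperParams,
    PriorConfig,
    alpha_link,
    from_natural,
    from_natural_beta,
    to_natural,
    to_natural_beta,
)
from ._sampler import (
    ConvergenceWarning,
    FitDiagnostics,
    SamplerConfig,
    map_estimate,
    run_ensemble,
)
from .rl_agent import AgentParams, SessionData, SubjectDataset
from .task_design import TrialRecord

__all__ = [
    "VARIANTS",
    "ModelSpec",
    "PriorConfig",
    "HyperParams",
    "GroupEffects",
    "SamplerConfig",
    "FitDiagnostics",
    "ConvergenceWarning",
    "PosteriorSamples",
    "HierarchicalRLModel",
    "HierarchicalRLResults",
    "build_model",
    "fit",
    "trial_loglik",
    "to_natural",
    "from_natural",
    "to_natural_beta",
    "from_natural_beta",
    "rhat",
    "hdi",
    "summarize_effects",
    "prior_predictive_params",
]

VARIANTS = ("single_alpha", "day_group", "full")

_LN_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Variant selector for the nested model ladder."""

    variant: str = "full"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    @property
    def thetas(self) -> tuple[str, ...]:
        if self.variant == "full":
            return ("alpha_G", "alpha_L", "beta")
        return ("alpha", "beta")

    @property
    def day_structure(self) -> bool:
        return self.variant != "single_alpha"


@dataclass
class PosteriorSamples:
    """Labelled MCMC draws, shaped (chain, draw, parameter)."""

    names: list[str]
    chains: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chains.ndim != 3 or self.chains.shape[2] != len(self.names):
            raise ValueError("chains must have shape (chain, draw, len(names))")
        self._ix = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def n_draws(self) -> int:
        return self.chains.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chain, draw)."""
        return self.chains[:, :, self._ix[name]]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def flat_matrix(self) -> np.ndarray:
        """All draws flattened over chains, shape (total_draws, n_params)."""
        return self.chains.reshape(-1, len(self.names))

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy (chain, iteration, parameter, value) frame."""
        c, d, p = self.chains.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), d * p),
                "iteration": np.tile(np.repeat(np.arange(d), p), c),
                "parameter": np.tile(self.names, c * d),
                "value": self.chains.reshape(-1),
            }
        )


def _norm_logpdf(x, loc, scale):
    z = (x - loc) / scale
    return -0.5 * z * z - np.log(scale) - _LN_SQRT_2PI


def _halfnormal_logpdf(x, scale):
    return math.log(2.0) - _LN_SQRT_2PI - np.log(scale) - 0.5 * (x / scale) ** 2


def _halfcauchy_logpdf(x, scale):
    return math.log(2.0 / math.pi) - np.log(scale) - np.log1p((x / scale) ** 2)


class HierarchicalRLModel:
    """Generative hierarchical model bound to a cohort (statsmodels-style).

    Parameters
    ----------
    cohort : list of SubjectDataset
        Observed or simulated behaviour.
    variant : str or ModelSpec
        One of ``single_alpha``, ``day_group``, ``full``.
    priors : PriorConfig
    link : str
        Link for the learning rates: ``probit`` (default, as in the model
        equations) or ``logit``.
    shrink_common_day_effects : bool
        If True (default) the 3 common day effects share the Normal(0,
        sigma_b) shrinkage with the 12 group effects (15 shrunk effects in
        the full design); if False only the group effects are shrunk and
        the day effects get an independent Normal(0, b_day_scale) prior.
    parameterization : str
        ``centered`` (default) samples subject-day parameters and effects
        directly; ``noncentered`` samples standardised offsets.  Both are
        posterior-equivalent; centred mixes better here because hundreds
        of trials per subject-day identify the latent parameters strongly.
    """

    def __init__(
        self,
        cohort: Sequence[SubjectDataset],
        variant: str | ModelSpec = "full",
        priors: PriorConfig | None = None,
        link: str = "probit",
        shrink_common_day_effects: bool = True,
        parameterization: str = "centered",
    ) -> None:
        self.spec = variant if isinstance(variant, ModelSpec) else ModelSpec(variant)
        self.priors = priors or PriorConfig()
        self.link = link
        self.shrink_common_day_effects = shrink_common_day_effects
        if parameterization not in ("centered", "noncentered"):
            raise ValueError("parameterization must be 'centered' or 'noncentered'")
        self.parameterization = parameterization
        self._to_nat_alpha, self._from_nat_alpha = alpha_link(link)
        self.cohort = list(cohort)
        self.packed: PackedCohort = pack_cohort(self.cohort)
        self.mgroups = tuple(g for g in MANIPULATED_GROUPS if g in self.packed.groups)
        self._build_index()
        self._slot_day2 = (np.arange(self.packed.n_slots) % 2).astype(bool)
        gcode = []
        for g in self.packed.subject_group:
            gcode.append(self.mgroups.index(g) if g in self.mgroups else -1)
        self._slot_gcode = np.repeat(np.asarray(gcode, dtype=int), 2)

    # -- parameter vector layout -------------------------------------------
    def _build_index(self) -> None:
        spec, packed = self.spec, self.packed
        centered = self.parameterization == "centered"
        names: list[str] = []
        blocks: dict[str, slice] = {}

        def add(key: str, size: int, scalar_names: list[str] | None = None):
            blocks[key] = slice(len(names), len(names) + size)
            names.extend(scalar_names or [key])

        for th in spec.thetas:
            add(f"mu_{th}", 1)
        for th in spec.thetas:
            add(f"log_sigma_{th}", 1)
        if spec.day_structure:
            add("log_sigma_b", 1)
            suffix = "" if centered else "_raw"
            for th in spec.thetas:
                add(f"b_day_{th}", 1, [f"b_day_{th}{suffix}"])
            for th in spec.thetas:
                for g in self.mgroups:
                    add(f"b_{th}[{g}]", 1, [f"b_{th}[{g}]{suffix}"])
        n_z = packed.n_subjects if not spec.day_structure else packed.n_slots
        prefix = "subj" if centered else "z"
        for th in spec.thetas:
            if spec.day_structure:
                sn = [
                    f"{prefix}_{th}[{packed.subjects[i // 2]},d{i % 2 + 1}]"
                    for i in range(packed.n_slots)
                ]
            else:
                sn = [f"{prefix}_{th}[{s}]" for s in packed.subjects]
            add(f"subj_{th}", n_z, sn)
        self.param_names = names
        self._blocks = blocks
        self.ndim = len(names)

    def _get(self, th: np.ndarray, name: str) -> np.ndarray:
        return th[:, self._blocks[name]]

    # -- densities ----------------------------------------------------------
    def _log_prior_and_params(self, th: np.ndarray):
        spec, pri = self.spec, self.priors
        centered = self.parameterization == "centered"
        B = th.shape[0]
        lp = np.zeros(B)
        nat = {}
        if spec.day_structure:
            xb = self._get(th, "log_sigma_b")[:, 0]
            sigma_b = np.exp(xb)
            lp += _halfnormal_logpdf(sigma_b, pri.sigma_b_scale) + xb
        for th_name in spec.thetas:
            mu = self._get(th, f"mu_{th_name}")[:, 0]
            if th_name == "beta":
                lp += _norm_logpdf(mu, pri.mu_beta_loc, pri.mu_beta_scale)
            else:
                lp += _norm_logpdf(mu, pri.mu_alpha_loc, pri.mu_alpha_scale)
            x = self._get(th, f"log_sigma_{th_name}")[:, 0]
            sigma = np.exp(x)
            if th_name == "beta":
                lp += _halfnormal_logpdf(sigma, pri.sigma_beta_scale) + x
            else:
                lp += _halfcauchy_logpdf(sigma, pri.sigma_alpha_scale) + x
            if spec.day_structure:
                bday_val = self._get(th, f"b_day_{th_name}")[:, 0]
                if self.shrink_common_day_effects:
                    if centered:
                        lp += _norm_logpdf(bday_val, 0.0, sigma_b)
                        b_day = bday_val
                    else:
                        lp += _norm_logpdf(bday_val, 0.0, 1.0)
                        b_day = sigma_b * bday_val
                else:
                    lp += _norm_logpdf(bday_val, 0.0, pri.b_day_scale)
                    b_day = bday_val
                bg = np.zeros((B, max(len(self.mgroups), 1)))
                for gi, g in enumerate(self.mgroups):
                    bval = self._get(th, f"b_{th_name}[{g}]")[:, 0]
                    if centered:
                        lp += _norm_logpdf(bval, 0.0, sigma_b)
                        bg[:, gi] = bval
                    else:
                        lp += _norm_logpdf(bval, 0.0, 1.0)
                        bg[:, gi] = sigma_b * bval
                loc = mu[:, None] + self._slot_day2[None, :] * (
                    b_day[:, None]
                    + np.where(
                        self._slot_gcode[None, :] >= 0,
                        bg[:, np.maximum(self._slot_gcode, 0)],
                        0.0,
                    )
                )
            else:
                loc = np.broadcast_to(mu[:, None], (B, self.packed.n_slots)).copy()
            v = self._get(th, f"subj_{th_name}")
            loc_free = loc if spec.day_structure else loc[:, ::2]
            if centered:
                zz = (v - loc_free) / sigma[:, None]
                lp += np.sum(-0.5 * zz * zz - _LN_SQRT_2PI, axis=1) - v.shape[1] * x
                trans = v if spec.day_structure else np.repeat(v, 2, axis=1)
            else:
                lp += np.sum(-0.5 * v * v - _LN_SQRT_2PI, axis=1)
                v_full = v if spec.day_structure else np.repeat(v, 2, axis=1)
                trans = loc + sigma[:, None] * v_full
            if th_name == "beta":
                # clip to keep beta strictly positive under extreme proposals
                nat[th_name] = np.exp(np.clip(trans, -500.0, 500.0))
            else:
                nat[th_name] = self._to_nat_alpha(trans)
        if "alpha" in nat:
            nat["alpha_G"] = nat["alpha"]
            nat["alpha_L"] = nat["alpha"]
        return lp, nat

    def natural_params(self, th: np.ndarray):
        """Natural-scale (alpha_G, alpha_L, beta), each (batch, n_slots)."""
        th = np.atleast_2d(np.asarray(th, dtype=float))
        _, nat = self._log_prior_and_params(th)
        return nat["alpha_G"], nat["alpha_L"], nat["beta"]

    def log_prob(self, th: np.ndarray) -> np.ndarray:
        """Batched log posterior density (up to a constant)."""
        th = np.atleast_2d(np.asarray(th, dtype=float))
        with np.errstate(over="ignore", invalid="ignore"):
            lp, nat = self._log_prior_and_params(th)
            ll = loglik_sum(self.packed, nat["alpha_G"], nat["alpha_L"], nat["beta"])
        out = lp + ll
        out[~np.isfinite(out)] = -np.inf
        return out

    # -- fitting ------------------------------------------------------------
    def _init_center(self) -> np.ndarray:
        pri = self.priors
        x0 = np.zeros(self.ndim)
        for th_name in self.spec.thetas:
            loc = pri.mu_beta_loc if th_name == "beta" else pri.mu_alpha_loc
            x0[self._blocks[f"mu_{th_name}"]] = loc
            x0[self._blocks[f"log_sigma_{th_name}"]] = math.log(0.2)
            if self.parameterization == "centered":
                x0[self._blocks[f"subj_{th_name}"]] = loc
        if self.spec.day_structure:
            x0[self._blocks["log_sigma_b"]] = math.log(0.3)
        return x0

    def map_estimate(self) -> np.ndarray:
        return map_estimate(self.log_prob, self._init_center())

    def fit(self, config: SamplerConfig | None = None, seed: int = 0) -> "HierarchicalRLResults":
        """Sample the posterior; returns results with draws and diagnostics.

        A :class:`ConvergenceWarning` is emitted if any R-hat exceeds 1.1.
        Deterministic for a fixed seed and configuration.
        """
        config = config or SamplerConfig()
        if config.sampler == "gibbs":
            from ._gibbs import run_gibbs

            report, walker_chains, diags = run_gibbs(self, config, seed)
        else:
            report, walker_chains, diags = run_ensemble(
                self.log_prob,
                self.ndim,
                self.param_names,
                config,
                seed,
                self._init_center(),
            )
        samples = PosteriorSamples(
            names=list(self.param_names),
            chains=report,
            meta={
                "seed": seed,
                "variant": self.spec.variant,
                "link": self.link,
                "config": config,
                "subjects": list(self.packed.subjects),
                "groups": list(self.packed.groups),
            },
        )
        return HierarchicalRLResults(self, samples, diags, walker_chains)


def build_model(
    cohort: Sequence[SubjectDataset],
    variant: str | ModelSpec = "full",
    priors: PriorConfig | None = None,
    **kwargs,
) -> HierarchicalRLModel:
    """Construct the generative model object for a cohort (spec operation)."""
    return HierarchicalRLModel(cohort, variant=variant, priors=priors, **kwargs)


def fit(
    model: HierarchicalRLModel, config: SamplerConfig | None = None, seed: int = 0
) -> "HierarchicalRLResults":
    return model.fit(config=config, seed=seed)


class HierarchicalRLResults:
    """Posterior draws, diagnostics and summaries of a fitted model."""

    def __init__(
        self,
        model: HierarchicalRLModel,
        samples: PosteriorSamples,
        diagnostics: FitDiagnostics,
        walker_chains: np.ndarray | None = None,
    ) -> None:
        self.model = model
        self.samples = samples
        self.diagnostics = diagnostics
        self._walker_chains = walker_chains

    # -- derived draws ------------------------------------------------------
    def effect_draws(self, theta: str, group: str | None = None) -> np.ndarray:
        """Flat draws of a day-2 effect on the transformed scale.

        ``group=None`` (or "NHG") gives the common day effect b_theta; a
        manipulated group gives its group-specific coefficient b_theta,group.
        """
        if not self.model.spec.day_structure:
            raise ValueError("effects require a day/group model variant")
        if theta not in self.model.spec.thetas:
            raise KeyError(f"no parameter {theta!r} in variant {self.model.spec.variant}")
        s = self.samples
        centered = self.model.parameterization == "centered"
        if group is None or group == "NHG":
            name = f"b_day_{theta}"
            if centered or not self.model.shrink_common_day_effects:
                return s.flat(name)
            return np.exp(s.flat("log_sigma_b")) * s.flat(f"{name}_raw")
        if group not in self.model.mgroups:
            raise KeyError(f"group {group!r} not in fitted cohort {self.model.mgroups}")
        name = f"b_{theta}[{group}]"
        if centered:
            return s.flat(name)
        return np.exp(s.flat("log_sigma_b")) * s.flat(f"{name}_raw")

    def sigma_draws(self, theta: str) -> np.ndarray:
        return np.exp(self.samples.flat(f"log_sigma_{theta}"))

    def subject_params(self, day: int) -> pd.DataFrame:
        """Posterior-mean natural-scale parameters per subject for one day."""
        flat = self.samples.flat_matrix()
        aG, aL, bt = self.model.natural_params(flat)
        idx = 2 * np.arange(self.model.packed.n_subjects) + (day - 1)
        return pd.DataFrame(
            {
                "subject_id": self.model.packed.subjects,
                "group": self.model.packed.subject_group,
                "alpha_G": aG[:, idx].mean(axis=0),
                "alpha_L": aL[:, idx].mean(axis=0),
                "beta": bt[:, idx].mean(axis=0),
            }
        )

    def pointwise_loglik(self, max_draws: int | None = None, seed: int = 0) -> np.ndarray:
        """Per-trial log-likelihood matrix (draws x trials) for LOO."""
        flat = self.samples.flat_matrix()
        if max_draws is not None and flat.shape[0] > max_draws:
            rng = np.random.default_rng(seed)
            flat = flat[rng.choice(flat.shape[0], max_draws, replace=False)]
        aG, aL, bt = self.model.natural_params(flat)
        return loglik_pointwise(self.model.packed, aG, aL, bt)

    # -- summaries ----------------------------------------------------------
    def summary(self, hdi_mass: float = 0.95) -> pd.DataFrame:
        """Posterior mean, sd and HDI for hypers and effects (+ diagnostics)."""
        rows = []

        def row(name, draws):
            lo, hi = hdi(draws, hdi_mass)
            rows.append({"parameter": name, "mean": draws.mean(), "sd": draws.std(), "hdi_low": lo, "hdi_high": hi})

        s = self.samples
        for th in self.model.spec.thetas:
            row(f"mu_{th}", s.flat(f"mu_{th}"))
            row(f"sigma_{th}", self.sigma_draws(th))
        if self.model.spec.day_structure:
            row("sigma_b", np.exp(s.flat("log_sigma_b")))
            for th in self.model.spec.thetas:
                row(f"b_day_{th}", self.effect_draws(th))
                for g in self.model.mgroups:
                    row(f"b_{th}[{g}]", self.effect_draws(th, g))
        df = pd.DataFrame(rows).set_index("parameter")
        df["rhat_max_overall"] = self.diagnostics.max_rhat
        return df

    def summarize_effects(self, hdi_mass: float = 0.95, formatted: bool = False):
        return summarize_effects(self, hdi_mass=hdi_mass, formatted=formatted)

    def to_csv(self, path) -> None:
        self.samples.to_dataframe().to_csv(path, index=False)


# -- spec-level operations ---------------------------------------------------

def trial_loglik(
    records: Sequence[TrialRecord] | Sequence[SessionData],
    params: AgentParams,
) -> np.ndarray:
    """Pointwise choice log-likelihood for one subject-day.

    Accepts a list of trial records (one session: one Q trajectory from
    zero) or a list of sessions (Q re-initialised per session).  Missed
    trials are excluded from the vector and do not advance Q.
    """
    from .rl_agent import choice_prob, pair_symbol_indices, q_update

    if len(records) and isinstance(records[0], SessionData):
        parts = [trial_loglik(sess.records, params) for sess in records]
        return np.concatenate(parts) if parts else np.empty(0)
    q = np.zeros(6)
    out = []
    last_t = -1
    for rec in records:
        if rec.trial_in_session <= last_t:
            raise ValueError("records must be ordered by trial_in_session")
        last_t = rec.trial_in_session
        if rec.chosen_better is None:
            continue
        if rec.reward is None:
            raise ValueError("answered trial without a recorded reward")
        better, worse = pair_symbol_indices(rec.pair_id)
        c, o = (better, worse) if rec.chosen_better else (worse, better)
        out.append(math.log(choice_prob(q[c], q[o], params.beta)))
        q[c] = q_update(q[c], rec.reward, params)
    return np.asarray(out)


def rhat(samples: np.ndarray | PosteriorSamples) -> pd.Series | float:
    """Split Gelman-Rubin potential scale reduction factor.

    Accepts a (chain, draw) array for a single parameter (returns a float)
    or a PosteriorSamples / (chain, draw, parameter) array (returns a
    Series).  Constant chains return 1 by convention; a single chain is an
    error.
    """
    from ._sampler import _split_rhat

    if isinstance(samples, PosteriorSamples):
        return pd.Series(
            [_split_rhat(samples.chains[:, :, i]) for i in range(len(samples.names))],
            index=samples.names,
        )
    x = np.asarray(samples, dtype=float)
    if x.ndim == 2:
        return _split_rhat(x)
    if x.ndim == 3:
        return pd.Series([_split_rhat(x[:, :, i]) for i in range(x.shape[2])])
    raise ValueError("expected (chain, draw) or (chain, draw, parameter) array")


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of the draws.

    Assumes a unimodal posterior (the narrowest-interval construction is
    only an HDI under unimodality).
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    x = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = x.size
    if n < 50:
        raise ValueError(f"need at least 50 draws for an HDI, got {n}")
    k = max(int(np.ceil(mass * n)), 2)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def summarize_effects(
    results: HierarchicalRLResults, hdi_mass: float = 0.95, formatted: bool = False
):
    """Per-group day-2 effect table (posterior mean and HDI per parameter).

    One row per group; the natural-history baseline row carries the common
    day effects.  Requires a fitted day/group variant with separate
    learning rates (the ``full`` model).
    """
    model = results.model
    if model.spec.variant != "full":
        raise ValueError("effect table requires the fitted 'full' model variant")
    rows = ["NHG (baseline)"] + [g for g in MANIPULATED_GROUPS if g in model.mgroups]
    stats, fmt = {}, {}
    for th in ("alpha_G", "alpha_L", "beta"):
        means, los, his, cells = [], [], [], []
        for label in rows:
            g = None if label.startswith("NHG") else label
            d = results.effect_draws(th, g)
            lo, hi = hdi(d, hdi_mass)
            means.append(d.mean())
            los.append(lo)
            his.append(hi)
            cells.append(f"{d.mean():.2f} [{lo:.2f}, {hi:.2f}]")
        stats[(th, "mean")] = means
        stats[(th, "hdi_low")] = los
        stats[(th, "hdi_high")] = his
        fmt[th] = cells
    if formatted:
        return pd.DataFrame(fmt, index=rows)
    return pd.DataFrame(stats, index=rows)


def prior_predictive_params(
    priors: PriorConfig | None = None,
    n: int = 4000,
    seed: int = 0,
    link: str = "probit",
) -> dict[str, np.ndarray]:
    """Sample subject-level natural parameters implied by the priors.

    Pushes hyperparameter draws through the subject-level distribution and
    the natural-scale transforms; used for prior-predictive checks (the
    implied prior puts most learning-rate mass below 0.5 and most beta mass
    below 2).
    """
    pri = priors or PriorConfig()
    rng = np.random.default_rng(seed)
    to_nat, _ = alpha_link(link)
    mu_a = rng.normal(pri.mu_alpha_loc, pri.mu_alpha_scale, n)
    mu_b = rng.normal(pri.mu_beta_loc, pri.mu_beta_scale, n)
    sig_a = np.abs(pri.sigma_alpha_scale * rng.standard_cauchy(n))
    sig_b = np.abs(rng.normal(0.0, pri.sigma_beta_scale, n))
    alpha = to_nat(mu_a + sig_a * rng.normal(size=n))
    beta = np.exp(mu_b + sig_b * rng.normal(size=n))
    return {"alpha": np.asarray(alpha), "beta": beta}
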