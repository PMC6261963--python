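"""Hierarchical regression analyses of accuracy, reaction time and
subjective reports.

Accuracy (binary, logit link) and reaction time (milliseconds, identity
link) are modelled with treatment-coded fixed effects — trial (z-scored),
symbol pair (baseline AB), day (baseline day 1), group (baseline natural
history group) and the trial x pair, trial x day and day x group
interactions — plus correlated subject-level random effects for the
intercept, trial and pair.  Group contrasts (e.g. placebo vs placebo
control) are posterior distributions of differences between day x group
coefficients.

The three-category subjective reports (decline / neutral / improve) are
modelled with a multinomial-logit ("softmax") regression with factors
task-manipulation (placebo-type vs nocebo-type), question (expected vs
perceived) and group (control vs experimental) plus the group x question
and group x manipulation interactions.  Because raw category coefficients
depend on the reference category, results are reported as implied response
probabilities per group and question, which are invariant to that choice.

Priors are weakly informative: Normal(0, 2.5) on fixed effects (reaction
times are standardised internally, coefficients are reported back in ms)
and half-normal / normal priors on the random-effect Cholesky factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._params import GROUPS, MANIPULATED_GROUPS
from ._sampler import FitDiagnostics, SamplerConfig, run_ensemble
from .hier_inference import hdi
from .rl_agent import SUBJECTIVE_CATEGORIES, SubjectDataset

__all__ = [
    "RegressionSpec",
    "SubjectiveSpec",
    "Contrast",
    "ResponseProbabilities",
    "DesignTable",
    "build_design",
    "BehaviorRegression",
    "BehaviorResults",
    "fit_behavior",
    "SubjectiveRegression",
    "SubjectiveResults",
    "fit_subjective",
    "implied_probabilities",
    "subjective_frame",
]

_LN_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

_DEFAULT_TERMS = ("trial", "pair", "day", "trial:pair", "trial:day", "group", "day:group")


@dataclass(frozen=True)
class RegressionSpec:
    """Fixed- and random-effect structure of a behavioural regression.

    ``terms`` picks fixed effects from {trial, pair, day, trial:pair,
    trial:day, group, day:group}; ``random`` picks subject-level effects
    from {intercept, trial, pair}.  The model ladder of the analysis is the
    base terms, + group, + day:group.
    """

    outcome: str = "accuracy"
    terms: tuple[str, ...] = _DEFAULT_TERMS
    random: tuple[str, ...] = ("intercept", "trial", "pair")
    include_manipulated_sessions: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in ("accuracy", "rt"):
            raise ValueError("outcome must be 'accuracy' or 'rt'")
        bad = set(self.terms) - set(_DEFAULT_TERMS)
        if bad:
            raise ValueError(f"unknown terms {sorted(bad)}")
        bad = set(self.random) - {"intercept", "trial", "pair"}
        if bad:
            raise ValueError(f"unknown random terms {sorted(bad)}")

    @property
    def link(self) -> str:
        return "logit" if self.outcome == "accuracy" else "identity"


@dataclass
class DesignTable:
    """Model-ready arrays for one behavioural regression."""

    y: np.ndarray
    X: pd.DataFrame
    Z: pd.DataFrame
    subject_index: np.ndarray
    subjects: list[str]
    spec: RegressionSpec


_REQUIRED_COLUMNS = (
    "subject_id",
    "group",
    "day",
    "task_label",
    "trial_in_session",
    "pair_id",
    "chosen_better",
    "reward",
)


def build_design(data, spec: RegressionSpec) -> DesignTable:
    """Treatment-coded design with baselines pair AB, day 1, group NHG.

    ``data`` is a long trial table (or a cohort, converted internally).
    Only answered trials enter; by default only the default-contingency
    sessions (tasks 1 and 3) are analysed.  The trial index is z-scored
    over the included rows.
    """
    if not isinstance(data, pd.DataFrame):
        from .io_cli import cohort_to_frame

        data = cohort_to_frame(data)
    missing = [c for c in _REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    df = data.copy()
    df = df[df["chosen_better"].notna()]
    if not spec.include_manipulated_sessions:
        df = df[df["task_label"].isin(["task1_default", "task3_default"])]
    if spec.outcome == "rt":
        if "rt_ms" not in df.columns:
            raise ValueError("trial table is missing required columns: ['rt_ms']")
        df = df[df["rt_ms"].notna()]
    df = df.reset_index(drop=True)
    t = df["trial_in_session"].to_numpy(dtype=float)
    df["trial_z"] = (t - t.mean()) / t.std()

    pair_cd = (df["pair_id"] == "CD").astype(float)
    pair_ef = (df["pair_id"] == "EF").astype(float)
    day2 = (df["day"] == 2).astype(float)
    X = pd.DataFrame({"intercept": np.ones(len(df))})
    if "trial" in spec.terms:
        X["trial_z"] = df["trial_z"]
    if "pair" in spec.terms:
        X["pair_CD"] = pair_cd
        X["pair_EF"] = pair_ef
    if "day" in spec.terms:
        X["day2"] = day2
    if "trial:pair" in spec.terms:
        X["trial_z:pair_CD"] = df["trial_z"] * pair_cd
        X["trial_z:pair_EF"] = df["trial_z"] * pair_ef
    if "trial:day" in spec.terms:
        X["trial_z:day2"] = df["trial_z"] * day2
    groups_present = [g for g in GROUPS[1:] if (df["group"] == g).any()]
    if "group" in spec.terms:
        for g in groups_present:
            X[f"group[{g}]"] = (df["group"] == g).astype(float)
    if "day:group" in spec.terms:
        for g in groups_present:
            X[f"day2:group[{g}]"] = day2 * (df["group"] == g).astype(float)

    Z = pd.DataFrame(index=df.index)
    if "intercept" in spec.random:
        Z["intercept"] = 1.0
    if "trial" in spec.random:
        Z["trial_z"] = df["trial_z"]
    if "pair" in spec.random:
        Z["pair_CD"] = (df["pair_id"] == "CD").astype(float)
        Z["pair_EF"] = (df["pair_id"] == "EF").astype(float)

    subjects = sorted(df["subject_id"].unique().tolist())
    s_ix = df["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    if spec.outcome == "accuracy":
        y = df["chosen_better"].to_numpy(dtype=float)
        if y.min() == y.max():
            warnings.warn("degenerate outcome: all accuracy values identical", UserWarning)
    else:
        y = df["rt_ms"].to_numpy(dtype=float)
    return DesignTable(y=y, X=X, Z=Z, subject_index=s_ix, subjects=subjects, spec=spec)


@dataclass
class Contrast:
    """Posterior distribution of a difference of two day x group effects."""

    group_a: str
    group_b: str
    draws: np.ndarray
    hdi_mass: float = 0.95

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def interval(self) -> tuple[float, float]:
        return hdi(self.draws, self.hdi_mass)

    def __repr__(self) -> str:
        lo, hi = self.interval
        return (
            f"delta({self.group_a} - {self.group_b}) = {self.mean:.2f} "
            f"[{lo:.2f}, {hi:.2f}]"
        )


class BehaviorRegression:
    """Bayesian hierarchical GLM for accuracy or reaction time."""

    def __init__(
        self,
        design: DesignTable,
        beta_scale: float = 2.5,
        re_sd_scale: float = 1.0,
        re_offdiag_scale: float = 0.5,
        resid_scale: float = 1.0,
    ) -> None:
        self.design = design
        self.spec = design.spec
        self.beta_scale = beta_scale
        self.re_sd_scale = re_sd_scale
        self.re_offdiag_scale = re_offdiag_scale
        self.resid_scale = resid_scale
        self._X = design.X.to_numpy(dtype=float)
        self._Zrow = design.Z.to_numpy(dtype=float)
        self._six = design.subject_index
        self.n_subjects = len(design.subjects)
        self.q = self._Zrow.shape[1]
        self.gaussian = self.spec.outcome == "rt"
        y = design.y
        if self.gaussian:
            self.y_mean, self.y_sd = float(y.mean()), float(y.std())
            self._y = (y - self.y_mean) / self.y_sd
        else:
            self.y_mean, self.y_sd = 0.0, 1.0
            self._y = y
        self._build_index()

    @classmethod
    def from_cohort(cls, cohort: Sequence[SubjectDataset], spec: RegressionSpec, **kw):
        return cls(build_design(cohort, spec), **kw)

    from_dataframe = from_cohort  # accepts a long trial table as well

    def _build_index(self) -> None:
        names: list[str] = list(self.design.X.columns)
        self._p = len(names)
        q = self.q
        for j in range(q):
            names.append(f"log_L[{j},{j}]")
        for i in range(q):
            for j in range(i):
                names.append(f"L[{i},{j}]")
        self._n_chol = q + q * (q - 1) // 2
        if self.gaussian:
            names.append("log_sigma_resid")
        for s in self.design.subjects:
            for j in range(q):
                names.append(f"z[{s},{self.design.Z.columns[j]}]")
        self.param_names = names
        self.ndim = len(names)

    def _unpack(self, th):
        B = th.shape[0]
        p, q = self._p, self.q
        beta = th[:, :p]
        pos = p
        logdiag = th[:, pos : pos + q]
        pos += q
        off = th[:, pos : pos + q * (q - 1) // 2]
        pos += q * (q - 1) // 2
        if self.gaussian:
            log_sig = th[:, pos]
            pos += 1
        else:
            log_sig = None
        z = th[:, pos:].reshape(B, self.n_subjects, q)
        L = np.zeros((B, q, q))
        for j in range(q):
            L[:, j, j] = np.exp(logdiag[:, j])
        k = 0
        for i in range(q):
            for j in range(i):
                L[:, i, j] = off[:, k]
                k += 1
        return beta, logdiag, off, log_sig, z, L

    def log_prob(self, th: np.ndarray) -> np.ndarray:
        th = np.atleast_2d(np.asarray(th, dtype=float))
        B = th.shape[0]
        beta, logdiag, off, log_sig, z, L = self._unpack(th)
        lp = np.sum(-0.5 * (beta / self.beta_scale) ** 2, axis=1)
        diag = np.exp(logdiag)
        lp += np.sum(-0.5 * (diag / self.re_sd_scale) ** 2 + logdiag, axis=1)
        if off.size:
            lp += np.sum(-0.5 * (off / self.re_offdiag_scale) ** 2, axis=1)
        lp += np.sum(-0.5 * z * z, axis=(1, 2))
        u = np.einsum("bsq,brq->bsr", z, L)  # u_s = L z_s (non-centred)
        eta = self._X @ beta.T  # (n, B)
        eta = eta.T + np.einsum("bnq,nq->bn", u[:, self._six, :], self._Zrow)
        with np.errstate(over="ignore"):
            if self.gaussian:
                sig = np.exp(log_sig)
                lp += -0.5 * (sig / self.resid_scale) ** 2 + log_sig
                r = eta - self._y[None, :]
                lp += np.sum(
                    -0.5 * (r / sig[:, None]) ** 2 - log_sig[:, None] - _LN_SQRT_2PI, axis=1
                )
            else:
                # Bernoulli-logit: y*eta - log(1 + exp(eta)), stably
                lp += np.sum(
                    self._y[None, :] * eta - np.logaddexp(0.0, eta), axis=1
                )
        lp[~np.isfinite(lp)] = -np.inf
        return lp

    def _init_center(self) -> np.ndarray:
        x0 = np.zeros(self.ndim)
        x0[self._p : self._p + self.q] = math.log(0.3)
        return x0

    def fit(self, config: SamplerConfig | None = None, seed: int = 0) -> "BehaviorResults":
        config = config or SamplerConfig(chains=4, warmup=500, draws=500)
        report, walkers, diags = run_ensemble(
            self.log_prob, self.ndim, self.param_names, config, seed, self._init_center()
        )
        return BehaviorResults(self, report, diags)


class BehaviorResults:
    """Posterior of a behavioural regression; coefficients on outcome scale."""

    def __init__(self, model: BehaviorRegression, chains: np.ndarray, diagnostics: FitDiagnostics):
        self.model = model
        self.chains = chains
        self.diagnostics = diagnostics
        self.param_names = model.param_names

    def coef_draws(self, name: str) -> np.ndarray:
        """Flat draws of one fixed-effect coefficient on the outcome scale."""
        i = self.param_names.index(name)
        d = self.chains[:, :, i].reshape(-1)
        if self.model.gaussian:
            d = d * self.model.y_sd
            if name == "intercept":
                d = d + self.model.y_mean
        return d

    def summary(self, hdi_mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for name in self.model.design.X.columns:
            d = self.coef_draws(name)
            lo, hi = hdi(d, hdi_mass)
            rows.append(
                {"coefficient": name, "mean": d.mean(), "hdi_low": lo, "hdi_high": hi}
            )
        return pd.DataFrame(rows).set_index("coefficient")

    def contrast(self, group_a: str, group_b: str) -> Contrast:
        """delta = (day2 x group_a) - (day2 x group_b) per posterior draw."""

        def eff(g):
            if g == "NHG":
                return np.zeros(self.chains.shape[0] * self.chains.shape[1])
            name = f"day2:group[{g}]"
            if name not in self.param_names:
                raise KeyError(f"coefficient {name!r} not in the fitted model")
            return self.coef_draws(name)

        return Contrast(group_a, group_b, eff(group_a) - eff(group_b))

    def pointwise_loglik(self, max_draws: int | None = 500, seed: int = 0) -> np.ndarray:
        """Per-row log-likelihood matrix (draws x rows) for LOOIC comparison."""
        m = self.model
        flat = self.chains.reshape(-1, m.ndim)
        if max_draws is not None and flat.shape[0] > max_draws:
            rng = np.random.default_rng(seed)
            flat = flat[rng.choice(flat.shape[0], max_draws, replace=False)]
        beta, logdiag, off, log_sig, z, L = m._unpack(flat)
        u = np.einsum("bsq,brq->bsr", z, L)
        eta = (m._X @ beta.T).T + np.einsum("bnq,nq->bn", u[:, m._six, :], m._Zrow)
        if m.gaussian:
            sig = np.exp(log_sig)[:, None]
            r = eta - m._y[None, :]
            return -0.5 * (r / sig) ** 2 - np.log(sig) - _LN_SQRT_2PI - math.log(m.y_sd)
        return m._y[None, :] * eta - np.logaddexp(0.0, eta)


def fit_behavior(
    data,
    spec: RegressionSpec,
    config: SamplerConfig | None = None,
    seed: int = 0,
    **kw,
) -> BehaviorResults:
    """Build the design (if needed) and fit the hierarchical regression."""
    design = data if isinstance(data, DesignTable) else build_design(data, spec)
    return BehaviorRegression(design, **kw).fit(config=config, seed=seed)


# -- subjective reports ------------------------------------------------------

_SUBJ_TERMS = (
    "intercept",
    "manipulation[nocebo]",
    "question[perceived]",
    "experimental",
    "experimental:question[perceived]",
    "experimental:manipulation[nocebo]",
)


@dataclass(frozen=True)
class SubjectiveSpec:
    """Three-category softmax regression for the questionnaire items."""

    reference: str = "neutral"
    prior_scale: float = 2.5

    def __post_init__(self) -> None:
        if self.reference not in SUBJECTIVE_CATEGORIES:
            raise ValueError(f"reference must be one of {SUBJECTIVE_CATEGORIES}")


@dataclass
class ResponseProbabilities:
    """Implied probabilities of (decline, neutral, improve) for one cell."""

    group: str
    question: str
    draws: np.ndarray  # (n_draws, 3), each row sums to 1
    hdi_mass: float = 0.95

    @property
    def mean(self) -> dict[str, float]:
        m = self.draws.mean(axis=0)
        return dict(zip(SUBJECTIVE_CATEGORIES, m))

    def interval(self, category: str) -> tuple[float, float]:
        j = SUBJECTIVE_CATEGORIES.index(category)
        return hdi(self.draws[:, j], self.hdi_mass)

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, cat in enumerate(SUBJECTIVE_CATEGORIES):
            lo, hi = self.interval(cat)
            rows.append(
                {"category": cat, "mean": self.draws[:, j].mean(), "hdi_low": lo, "hdi_high": hi}
            )
        return pd.DataFrame(rows).set_index("category")


def subjective_frame(cohort: Sequence[SubjectDataset]) -> pd.DataFrame:
    """Long table (subject, group, question, response) for manipulated groups."""
    rows = []
    for subj in cohort:
        if subj.group not in MANIPULATED_GROUPS:
            continue
        for question in ("expected", "perceived"):
            resp = subj.subjective.get(question)
            if resp is not None:
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "group": subj.group,
                        "question": question,
                        "response": resp,
                    }
                )
    return pd.DataFrame(rows)


def subjective_design_row(group: str, question: str) -> np.ndarray:
    """Fixed-effect row for one (group, question) cell."""
    if group not in MANIPULATED_GROUPS:
        raise KeyError(f"unknown cell: group {group!r}")
    if question not in ("expected", "perceived"):
        raise KeyError(f"unknown cell: question {question!r}")
    nocebo_arm = 1.0 if group in ("nocebo", "nocebo_control") else 0.0
    perceived = 1.0 if question == "perceived" else 0.0
    experimental = 1.0 if group in ("placebo", "nocebo") else 0.0
    return np.array(
        [
            1.0,
            nocebo_arm,
            perceived,
            experimental,
            experimental * perceived,
            experimental * nocebo_arm,
        ]
    )


def category_probs(coefs: np.ndarray, x: np.ndarray, reference: str) -> np.ndarray:
    """Softmax probabilities (decline, neutral, improve) for cell row ``x``.

    ``coefs`` has shape (draws, 2, n_terms): coefficients of the two
    non-reference categories in canonical category order.  Exactly invariant
    to the reference-category convention by softmax normalisation.
    """
    ref = SUBJECTIVE_CATEGORIES.index(reference)
    eta = np.zeros((coefs.shape[0], 3))
    non_ref = [j for j in range(3) if j != ref]
    for k, j in enumerate(non_ref):
        eta[:, j] = coefs[:, k, :] @ x
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


class SubjectiveRegression:
    """Bayesian softmax regression of the three-category reports."""

    def __init__(self, responses: pd.DataFrame, spec: SubjectiveSpec | None = None) -> None:
        self.spec = spec or SubjectiveSpec()
        df = responses.reset_index(drop=True)
        for col in ("group", "question", "response"):
            if col not in df.columns:
                raise ValueError(f"responses table missing column {col!r}")
        bad = set(df["response"]) - set(SUBJECTIVE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown response categories {sorted(bad)}")
        self.data = df
        self._Xrows = np.stack(
            [subjective_design_row(g, q) for g, q in zip(df["group"], df["question"])]
        )
        self._ycat = df["response"].map({c: i for i, c in enumerate(SUBJECTIVE_CATEGORIES)}).to_numpy()
        counts = df.groupby(["group", "question"]).size()
        if (counts < 1).any():
            warnings.warn("empty design cells; estimates rely on the prior", UserWarning)
        self._ref = SUBJECTIVE_CATEGORIES.index(self.spec.reference)
        self._non_ref = [j for j in range(3) if j != self._ref]
        self.n_terms = self._Xrows.shape[1]
        self.param_names = [
            f"b[{SUBJECTIVE_CATEGORIES[j]}]:{t}" for j in self._non_ref for t in _SUBJ_TERMS
        ]
        self.ndim = len(self.param_names)

    @classmethod
    def from_cohort(cls, cohort: Sequence[SubjectDataset], spec: SubjectiveSpec | None = None):
        return cls(subjective_frame(cohort), spec)

    def log_prob(self, th: np.ndarray) -> np.ndarray:
        th = np.atleast_2d(np.asarray(th, dtype=float))
        B = th.shape[0]
        coefs = th.reshape(B, 2, self.n_terms)
        lp = np.sum(-0.5 * (th / self.spec.prior_scale) ** 2, axis=1)
        eta = np.zeros((B, self._Xrows.shape[0], 3))
        for k, j in enumerate(self._non_ref):
            eta[:, :, j] = coefs[:, k, :] @ self._Xrows.T
        m = eta.max(axis=2, keepdims=True)
        logZ = m[:, :, 0] + np.log(np.exp(eta - m).sum(axis=2))
        lp += np.sum(eta[:, np.arange(eta.shape[1]), self._ycat] - logZ, axis=1)
        return lp

    def fit(self, config: SamplerConfig | None = None, seed: int = 0) -> "SubjectiveResults":
        config = config or SamplerConfig(chains=4, warmup=500, draws=500)
        report, walkers, diags = run_ensemble(
            self.log_prob, self.ndim, self.param_names, config, seed, np.zeros(self.ndim)
        )
        return SubjectiveResults(self, report, diags)


class SubjectiveResults:
    def __init__(self, model: SubjectiveRegression, chains: np.ndarray, diagnostics: FitDiagnostics):
        self.model = model
        self.chains = chains
        self.diagnostics = diagnostics

    def coef_matrix(self) -> np.ndarray:
        """(draws, 2, n_terms) coefficient draws for the non-ref categories."""
        flat = self.chains.reshape(-1, self.model.ndim)
        return flat.reshape(flat.shape[0], 2, self.model.n_terms)

    def implied_probabilities(self, group: str, question: str) -> ResponseProbabilities:
        """Posterior response-probability triple for one group x question cell."""
        x = subjective_design_row(group, question)
        probs = category_probs(self.coef_matrix(), x, self.model.spec.reference)
        return ResponseProbabilities(group=group, question=question, draws=probs)

    def probability_table(self) -> pd.DataFrame:
        rows = []
        for g in MANIPULATED_GROUPS:
            for q in ("expected", "perceived"):
                rp = self.implied_probabilities(g, q)
                for cat in SUBJECTIVE_CATEGORIES:
                    lo, hi = rp.interval(cat)
                    rows.append(
                        {
                            "group": g,
                            "question": q,
                            "category": cat,
                            "mean": rp.mean[cat],
                            "hdi_low": lo,
                            "hdi_high": hi,
                        }
                    )
        return pd.DataFrame(rows)


def fit_subjective(
    responses: pd.DataFrame | Sequence[SubjectDataset],
    spec: SubjectiveSpec | None = None,
    config: SamplerConfig | None = None,
    seed: int = 0,
) -> SubjectiveResults:
    if isinstance(responses, pd.DataFrame):
        model = SubjectiveRegression(responses, spec)
    else:
        model = SubjectiveRegression.from_cohort(responses, spec)
    return model.fit(config=config, seed=seed)


def implied_probabilities(results: SubjectiveResults, group: str, question: str) -> ResponseProbabilities:
    return results.implied_probabilities(group, question)
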