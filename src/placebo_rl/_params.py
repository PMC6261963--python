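"""Shared parameter containers and scale transforms for the hierarchy.

Learning rates live on a probit (standard-normal quantile) scale in the
hierarchy, the noise parameter on a log scale.  ``to_natural`` maps a
probit-scale value to (0, 1) via the standard-normal CDF; ``to_natural_beta``
exponentiates.  A logit link for the learning rates is supported as an
alternative (see the link functions at the bottom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "GROUPS",
    "MANIPULATED_GROUPS",
    "PARAM_NAMES",
    "HyperParams",
    "GroupEffects",
    "PriorConfig",
    "to_natural",
    "from_natural",
    "to_natural_beta",
    "from_natural_beta",
    "alpha_link",
]

GROUPS = ("NHG", "placebo", "nocebo", "placebo_control", "nocebo_control")
MANIPULATED_GROUPS = ("placebo", "nocebo", "placebo_control", "nocebo_control")
PARAM_NAMES = ("alpha_G", "alpha_L", "beta")


def to_natural(alpha_probit):
    """Probit-scale value -> learning rate in (0, 1) via the normal CDF."""
    return special.ndtr(np.asarray(alpha_probit, dtype=float))


def from_natural(alpha):
    """Learning rate in (0, 1) -> probit scale (normal quantile)."""
    return special.ndtri(np.asarray(alpha, dtype=float))


def to_natural_beta(log_beta):
    """Log-scale value -> noise parameter beta > 0."""
    return np.exp(np.asarray(log_beta, dtype=float))


def from_natural_beta(beta):
    return np.log(np.asarray(beta, dtype=float))


def alpha_link(link: str):
    """Return (transformed -> natural, natural -> transformed) for alpha."""
    if link == "probit":
        return special.ndtr, special.ndtri
    if link == "logit":
        return special.expit, special.logit
    raise ValueError(f"link must be 'probit' or 'logit', got {link!r}")


@dataclass(frozen=True)
class HyperParams:
    """Group-level means and scales of the day-1 parameter distributions.

    Means for the learning rates are on the probit scale, for beta on the
    log scale; scales are standard deviations on the same scales.
    """

    mu_alphaG: float = -0.5
    mu_alphaL: float = -0.5
    mu_beta: float = -1.5
    sigma_alphaG: float = 0.3
    sigma_alphaL: float = 0.3
    sigma_beta: float = 0.3

    def __post_init__(self) -> None:
        for name in ("sigma_alphaG", "sigma_alphaL", "sigma_beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def mu(self, theta: str) -> float:
        return {"alpha_G": self.mu_alphaG, "alpha_L": self.mu_alphaL, "beta": self.mu_beta}[theta]

    def sigma(self, theta: str) -> float:
        return {
            "alpha_G": self.sigma_alphaG,
            "alpha_L": self.sigma_alphaL,
            "beta": self.sigma_beta,
        }[theta]


@dataclass(frozen=True)
class GroupEffects:
    """Day-2 shift effects on the transformed scales.

    ``b_day[theta]`` is the day-2 shift common to all groups (the natural
    history group's day-2 distribution is shifted by it alone);
    ``b_group[(theta, group)]`` is the additional shift for each of the four
    manipulated groups.  Under the shrinkage prior these 3 + 12 = 15 effects
    share a common Normal(0, sigma_b) distribution.
    """

    b_day: dict = field(default_factory=lambda: {t: 0.0 for t in PARAM_NAMES})
    b_group: dict = field(
        default_factory=lambda: {(t, g): 0.0 for t in PARAM_NAMES for g in MANIPULATED_GROUPS}
    )
    sigma_b: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be non-negative")
        missing = [t for t in PARAM_NAMES if t not in self.b_day]
        if missing:
            raise ValueError(f"b_day missing entries for {missing}")

    def day2_shift(self, theta: str, group: str) -> float:
        """Total day-2 shift for ``theta`` in ``group`` (0 group term for NHG)."""
        shift = self.b_day[theta]
        if group != "NHG":
            shift += self.b_group.get((theta, group), 0.0)
        return shift

    @classmethod
    def zero(cls) -> "GroupEffects":
        return cls()


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative priors of the hierarchical model.

    Defaults: mu_alpha ~ Normal(-0.5, 0.6) (probit scale, mass on learning
    rates below 0.5), mu_beta ~ Normal(-1.5, 0.8) (log scale, discouraging
    beta above ~2), sigma_alpha ~ HalfCauchy(0.01), sigma_beta ~
    HalfNormal(0.3), sigma_b ~ HalfNormal(1).
    """

    mu_alpha_loc: float = -0.5
    mu_alpha_scale: float = 0.6
    mu_beta_loc: float = -1.5
    mu_beta_scale: float = 0.8
    sigma_alpha_scale: float = 0.01  # HalfCauchy scale, as printed
    sigma_beta_scale: float = 0.3  # HalfNormal scale
    sigma_b_scale: float = 1.0  # HalfNormal scale
    #: prior sd for the common day effects when they are NOT shrunk
    b_day_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "mu_alpha_scale",
            "mu_beta_scale",
            "sigma_alpha_scale",
            "sigma_beta_scale",
            "sigma_b_scale",
            "b_day_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
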