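"""Pointwise predictive evaluation and LOOIC model comparison.

The leave-one-out unit is a single trial, matching the factorisation of the
fitted likelihood (leave-one-subject-out is available via ``groups``).
Importance weights are Pareto-smoothed (PSIS); observations with a Pareto
shape diagnostic above 0.7 are counted and reported, never silently
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .hier_inference import HierarchicalRLResults

__all__ = ["LooResult", "ComparisonResult", "pointwise_matrix", "psis_loo", "compare"]


@dataclass
class LooResult:
    """PSIS-LOO estimate for one fitted model."""

    elpd_loo: float
    looic: float
    se: float
    pareto_k: np.ndarray
    n_draws: int
    n_obs: int
    elpd_pointwise: np.ndarray

    @property
    def n_high_k(self) -> int:
        """Observations with Pareto k above 0.7 (unreliable weights)."""
        return int(np.sum(self.pareto_k > 0.7))


@dataclass
class ComparisonResult:
    """Ranked LOOIC comparison across models fitted to the same data."""

    table: pd.DataFrame  # index: model name; columns: elpd_loo, looic, se, delta_looic, strong
    loos: dict

    def __repr__(self) -> str:  # human-readable log form
        return "LOOIC comparison (delta > 10 flagged strong)\n" + self.table.to_string()


def pointwise_matrix(
    results: HierarchicalRLResults, max_draws: int | None = None, seed: int = 0
) -> np.ndarray:
    """Log-likelihood of every trial under every posterior draw.

    Shape (draws, trials); row s is the concatenated per-trial log-likelihood
    vectors under draw s's subject-day parameters.
    """
    return results.pointwise_loglik(max_draws=max_draws, seed=seed)


def _psis_smooth(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pareto-smoothed, self-normalised log weights via arviz.

    Returns (log_weights (draws, obs), pareto_k (obs,)).
    """
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, k = az.psislw(-matrix.T)  # psislw expects (..., n_samples)
    return np.asarray(lw).T, np.asarray(k)


def psis_loo(matrix: np.ndarray, groups: np.ndarray | None = None) -> LooResult:
    """PSIS leave-one-out expected log predictive density and LOOIC.

    ``matrix`` is (draws, observations).  ``groups`` optionally maps each
    observation to a fold (e.g. a subject) for leave-one-group-out; columns
    in a fold are summed before weighting.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("pointwise matrix must be 2-D (draws, observations)")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("pointwise log-likelihood matrix contains non-finite entries")
    if groups is not None:
        groups = np.asarray(groups)
        cols = [matrix[:, groups == g].sum(axis=1) for g in np.unique(groups)]
        matrix = np.column_stack(cols)
    s, n = matrix.shape
    col_var = matrix.var(axis=0)
    if np.all(col_var < 1e-12):
        # no across-draw uncertainty: LOO reduces to the plain log predictive
        elpd_i = logsumexp(matrix, axis=0) - np.log(s)
        k = np.full(n, -np.inf)
    elif s < 25:
        # too few draws to fit a generalised-Pareto tail: exact (unsmoothed)
        # self-normalised importance weights
        warnings.warn(
            f"only {s} draws; using raw importance weights without smoothing",
            UserWarning,
            stacklevel=2,
        )
        lw = -matrix - logsumexp(-matrix, axis=0, keepdims=True)
        k = np.full(n, np.nan)
        elpd_i = logsumexp(matrix + lw, axis=0)
    else:
        if s < 100:
            warnings.warn(
                f"only {s} draws; PSIS importance weights may be unstable",
                UserWarning,
                stacklevel=2,
            )
        lw, k = _psis_smooth(matrix)
        elpd_i = logsumexp(matrix + lw, axis=0)
        if np.any(k > 0.7):
            warnings.warn(
                f"{int(np.sum(k > 0.7))} observations with Pareto k > 0.7; "
                "their LOO contributions are unreliable",
                UserWarning,
                stacklevel=2,
            )
    elpd = float(elpd_i.sum())
    se = float(np.sqrt(n * np.var(elpd_i)))
    return LooResult(
        elpd_loo=elpd,
        looic=-2.0 * elpd,
        se=se,
        pareto_k=k,
        n_draws=s,
        n_obs=n,
        elpd_pointwise=elpd_i,
    )


def compare(
    fitted: dict[str, HierarchicalRLResults] | dict[str, np.ndarray],
    max_draws: int | None = 1000,
    seed: int = 0,
    strong_threshold: float = 10.0,
) -> ComparisonResult:
    """LOOIC ranking of models fitted to the same observations.

    Accepts fitted results objects or precomputed pointwise matrices.  The
    best model gets delta 0; differences larger than ``strong_threshold``
    (10, the conventional cut for a strong difference) are flagged.
    """
    loos: dict[str, LooResult] = {}
    n_obs = None
    for name, obj in fitted.items():
        mat = obj if isinstance(obj, np.ndarray) else pointwise_matrix(obj, max_draws, seed)
        loo = psis_loo(mat)
        if n_obs is None:
            n_obs = loo.n_obs
        elif loo.n_obs != n_obs:
            raise ValueError(
                f"model {name!r} scores {loo.n_obs} observations, others score "
                f"{n_obs}; LOOIC comparison requires the same observation set"
            )
        loos[name] = loo
    best = max(loos, key=lambda k: loos[k].elpd_loo)
    rows = []
    for name, loo in sorted(loos.items(), key=lambda kv: kv[1].looic):
        delta = loo.looic - loos[best].looic
        rows.append(
            {
                "model": name,
                "elpd_loo": loo.elpd_loo,
                "looic": loo.looic,
                "se": loo.se,
                "delta_looic": delta,
                "strong": bool(abs(delta) > strong_threshold),
                "n_high_pareto_k": loo.n_high_k,
            }
        )
    return ComparisonResult(table=pd.DataFrame(rows).set_index("model"), loos=loos)
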