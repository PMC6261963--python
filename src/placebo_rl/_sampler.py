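"""Ensemble-MCMC driver shared by the hierarchical models.

Posterior sampling uses an ensemble sampler (emcee) with differential-
evolution moves, which requires only batched log-density evaluations.  The
ensemble's walkers are grouped into a configurable number of reporting
chains; convergence is assessed with the rank-normalised split Gelman-Rubin
statistic computed across walkers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import emcee
import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["SamplerConfig", "FitDiagnostics", "ConvergenceWarning", "run_ensemble", "map_estimate"]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning, never silently) when diagnostics fail."""


@dataclass(frozen=True)
class SamplerConfig:
    """Sampler budget and bookkeeping.

    ``chains`` chains with ``draws`` retained draws each (the default
    8 x 1000 = 8000 retained draws after a 1000-sweep warm-up per chain).
    ``sampler`` selects the backend for the hierarchical RL model:
    ``gibbs`` (default; blocked Metropolis-within-Gibbs, independent
    vectorised chains) or ``ensemble`` (emcee differential-evolution
    ensemble, walkers grouped into reporting chains).  ``walkers`` (ensemble
    only) defaults to a multiple of ``chains`` of at least ``2 * ndim + 2``.
    ``thin`` keeps every ``thin``-th sweep/iteration.  ``init='map'``
    (ensemble only) starts in a small ball around a posterior mode;
    ``init='center'`` starts around the priors' central region.
    """

    chains: int = 8
    warmup: int = 1000
    draws: int = 1000
    sampler: str = "gibbs"
    walkers: int | None = None
    thin: int = 5
    init: str = "center"
    init_jitter: float = 0.1
    progress: bool = False

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if min(self.warmup, self.draws, self.thin) < 1:
            raise ValueError("warmup, draws and thin must be positive")
        if self.init not in ("map", "center"):
            raise ValueError("init must be 'map' or 'center'")
        if self.sampler not in ("gibbs", "ensemble"):
            raise ValueError("sampler must be 'gibbs' or 'ensemble'")

    def n_walkers(self, ndim: int) -> int:
        w = self.walkers or max(2 * ndim + 2, 8 * self.chains)
        return int(np.ceil(w / self.chains) * self.chains)


@dataclass
class FitDiagnostics:
    """Per-parameter convergence diagnostics of one fit."""

    rhat: pd.Series
    ess: pd.Series
    divergences: int  # ensemble moves have no divergence notion; kept at 0
    acceptance_fraction: float

    @property
    def max_rhat(self) -> float:
        return float(self.rhat.max())

    @property
    def converged(self) -> bool:
        return bool(self.max_rhat <= 1.1)


def _split_rhat(x: np.ndarray) -> float:
    """Rank-normalised split-R-hat for one parameter, x of shape (chain, draw)."""
    if x.ndim != 2:
        raise ValueError("expected (chain, draw) array")
    m, n = x.shape
    if m < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if n < 4:
        raise ValueError("R-hat requires at least 4 draws per chain")
    if np.ptp(x) == 0:
        return 1.0  # constant chains: defined as 1 by convention
    half = n // 2
    x = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    # rank-normalise (Vehtari et al. folding omitted; bulk variant)
    r = (np.argsort(np.argsort(x, axis=None)).reshape(x.shape) + 0.625) / (x.size + 0.25)
    z = _ndtri(r)
    m2, n2 = z.shape
    chain_means = z.mean(axis=1)
    b = n2 * chain_means.var(ddof=1)
    w = z.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def _ndtri(p):
    from scipy import special

    return special.ndtri(p)


def _ess(x: np.ndarray) -> float:
    """Bulk effective sample size via autocorrelation (Geyer initial positive)."""
    m, n = x.shape
    if np.ptp(x) == 0:
        return float(m * n)
    x = x - x.mean(axis=1, keepdims=True)
    acov = np.zeros(n)
    for c in range(m):
        f = np.fft.rfft(x[c], 2 * n)
        acov += np.fft.irfft(f * np.conj(f), 2 * n)[:n]
    acov /= m * n
    if acov[0] == 0:
        return float(m * n)
    rho = acov / acov[0]
    tau = 1.0
    for t in range(1, n - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2 * pair
    return float(m * n / max(tau, 1.0))


def diagnostics_from_chains(chains: np.ndarray, names: list[str], acceptance: float) -> FitDiagnostics:
    """Compute per-parameter R-hat and ESS from a (chain, draw, dim) array."""
    rhat = pd.Series(
        [_split_rhat(chains[:, :, i]) for i in range(chains.shape[2])], index=names
    )
    ess = pd.Series([_ess(chains[:, :, i]) for i in range(chains.shape[2])], index=names)
    return FitDiagnostics(rhat=rhat, ess=ess, divergences=0, acceptance_fraction=acceptance)


def map_estimate(
    log_prob: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    maxiter: int = 500,
) -> np.ndarray:
    """Posterior mode via L-BFGS-B on the batched log-density (batch of 1)."""

    def neg(x):
        v = float(np.asarray(log_prob(x[None, :]))[0])
        return -v if np.isfinite(v) else 1e12

    res = optimize.minimize(neg, x0, method="L-BFGS-B", options={"maxiter": maxiter})
    return res.x if np.all(np.isfinite(res.x)) else x0


def run_ensemble(
    log_prob: Callable[[np.ndarray], np.ndarray],
    ndim: int,
    names: list[str],
    config: SamplerConfig,
    seed: int,
    init_center: np.ndarray,
    init_scale: np.ndarray | float | None = None,
):
    """Run the ensemble sampler; return (report_chains, walker_chains, diagnostics).

    ``report_chains`` has shape (chains, draws_per_chain, ndim) obtained by
    grouping walkers into ``config.chains`` groups; ``walker_chains``
    (walker, kept_iteration, ndim) is what diagnostics are computed from.
    """
    rng = np.random.RandomState(seed)
    w = config.n_walkers(ndim)
    if init_scale is None:
        init_scale = config.init_jitter
    if config.init == "map":
        center = map_estimate(log_prob, np.asarray(init_center, dtype=float))
    else:
        center = np.asarray(init_center, dtype=float)
    p0 = center[None, :] + np.asarray(init_scale) * rng.randn(w, ndim)
    lp0 = np.asarray(log_prob(p0))
    bad = ~np.isfinite(lp0)
    if bad.any():
        # re-draw offending walkers closer to the center
        for _ in range(20):
            p0[bad] = center[None, :] + 0.2 * np.asarray(init_scale) * rng.randn(
                int(bad.sum()), ndim
            )
            lp0 = np.asarray(log_prob(p0))
            bad = ~np.isfinite(lp0)
            if not bad.any():
                break
        if bad.any():
            worst = [names[i] for i in np.argsort(np.abs(center))[-5:]]
            raise FloatingPointError(
                "non-finite log-density at initialization; largest-magnitude "
                f"initial parameters: {worst}"
            )
    sampler = emcee.EnsembleSampler(
        w,
        ndim,
        log_prob,
        vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler.random_state = rng.get_state()
    n_keep = int(np.ceil(config.draws * config.chains / w))
    n_iter = config.warmup + n_keep * config.thin
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sampler.run_mcmc(p0, n_iter, progress=config.progress)
    chain = sampler.get_chain(discard=config.warmup, thin=config.thin)  # (it, walker, dim)
    walker_chains = np.ascontiguousarray(chain.transpose(1, 0, 2))
    diags = diagnostics_from_chains(
        walker_chains, names, float(np.mean(sampler.acceptance_fraction))
    )
    per_group = w // config.chains
    report = walker_chains.reshape(config.chains, per_group, n_keep, ndim)
    report = report.reshape(config.chains, per_group * n_keep, ndim)
    if not diags.converged:
        warnings.warn(
            f"maximum R-hat {diags.max_rhat:.3f} exceeds 1.1; treat this fit as "
            "unconverged (increase warmup/draws)",
            ConvergenceWarning,
            stacklevel=2,
        )
    return report, walker_chains, diags
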