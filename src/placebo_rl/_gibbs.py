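"""Blocked Metropolis-within-Gibbs sampler for the hierarchical RL model.

The posterior factorises cleanly: given the hyperparameters, the
subject-day parameter blocks are mutually independent and each touches only
its own episodes' likelihood; given the subject-day parameters, the
group-level means and all day/group shift effects have exactly Gaussian
conditionals, and the scale parameters have cheap one-dimensional
conditionals that never touch the trial data.  One sweep therefore does:

1. a parallel random-walk MH update of every subject-day block (one batched
   per-episode likelihood evaluation for all chains and subjects at once),
2. exact Gibbs draws for the mu's and every shift effect b,
3. adaptive 1-D MH updates for log sigma_theta and log sigma_b.

Proposal scales adapt toward standard acceptance targets during warm-up
only and are frozen afterwards.  Chains are genuinely independent (the
whole state is vectorised over chains) and deterministic given the seed.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from ._likelihood import loglik_episode
from ._sampler import ConvergenceWarning, SamplerConfig, diagnostics_from_chains

__all__ = ["run_gibbs"]

_V_TARGET = 0.44  # acceptance target for the 1-D subject-day updates
_S_TARGET = 0.44  # acceptance target for scalar updates


def _halfcauchy_logpdf(s, scale):
    return -np.log1p((s / scale) ** 2)  # constants drop in MH ratios


def _halfnormal_logpdf(s, scale):
    return -0.5 * (s / scale) ** 2


class _GibbsState:
    def __init__(self, model, n_chains: int, rng: np.random.Generator):
        self.model = model
        spec = model.spec
        self.thetas = spec.thetas
        self.K = len(self.thetas)
        self.beta_k = self.K - 1  # beta is always the last theta
        self.day = spec.day_structure
        packed = model.packed
        self.B = n_chains
        self.G = len(model.mgroups)
        if self.day:
            self.U = packed.n_slots
            self.unit_day2 = model._slot_day2.astype(float)  # (U,)
            self.unit_gcode = model._slot_gcode  # (U,)
            self.slot_unit = np.arange(packed.n_slots)
        else:
            self.U = packed.n_subjects
            self.unit_day2 = np.zeros(self.U)
            self.unit_gcode = np.full(self.U, -1)
            self.slot_unit = np.arange(packed.n_slots) // 2
        self.ep_unit = (
            packed.ep_slot if self.day else packed.ep_slot // 2
        )
        self.agg = np.zeros((packed.ep_slot.size, self.U))
        self.agg[np.arange(packed.ep_slot.size), self.ep_unit] = 1.0
        pri = model.priors
        B, K, U, G = self.B, self.K, self.U, self.G
        self.mu = np.empty((B, K))
        self.log_sig = np.empty((B, K))
        for k, th in enumerate(self.thetas):
            loc = pri.mu_beta_loc if th == "beta" else pri.mu_alpha_loc
            self.mu[:, k] = loc + 0.3 * rng.standard_normal(B)
            self.log_sig[:, k] = math.log(0.2) + 0.3 * rng.standard_normal(B)
        self.b_day = 0.1 * rng.standard_normal((B, K)) if self.day else np.zeros((B, K))
        self.b_grp = 0.1 * rng.standard_normal((B, K, max(G, 1))) if self.day else np.zeros((B, K, 1))
        self.log_sig_b = math.log(0.3) + 0.3 * rng.standard_normal(B)
        self.v = self.loc() + 0.3 * rng.standard_normal((B, U, K))
        self.ep_ll = self.episode_loglik(self.v)
        # adaptive proposal scales
        self.v_scale = np.full((B, U, K), 0.15)
        self.s_scale = np.full((B, K), 0.3)
        self.sb_scale = np.full(B, 0.3)
        self.t_scale_mu = np.full(B, 0.05)
        self.t_scale_bday = np.full(B, 0.05)
        self.t_scale_grp = np.full((B, max(G, 1)), 0.08)
        self.r_scale = np.full((B, K), 0.2)
        self.v_acc = 0.0
        self.v_acc_n = 0

    # -- model geometry ------------------------------------------------------
    def loc(self) -> np.ndarray:
        """Prior location of each unit's transformed parameters, (B, U, K)."""
        loc = np.broadcast_to(self.mu[:, None, :], (self.B, self.U, self.K)).copy()
        if self.day:
            # b_grp is (B, K, G); gather per unit, K last
            shift = self.b_day[:, None, :] + np.where(
                (self.unit_gcode >= 0)[None, :, None],
                np.transpose(self.b_grp, (0, 2, 1))[:, np.maximum(self.unit_gcode, 0), :],
                0.0,
            )
            loc += self.unit_day2[None, :, None] * shift
        return loc

    def episode_loglik(self, v: np.ndarray) -> np.ndarray:
        """(B, E) episode log-likelihoods for transformed values ``v``."""
        model = self.model
        vs = v[:, self.slot_unit, :]  # (B, n_slots, K)
        if self.K == 3:
            aG = model._to_nat_alpha(vs[:, :, 0])
            aL = model._to_nat_alpha(vs[:, :, 1])
        else:
            aG = aL = model._to_nat_alpha(vs[:, :, 0])
        beta = np.exp(np.clip(vs[:, :, self.beta_k], -500.0, 500.0))
        return loglik_episode(model.packed, aG, aL, beta)

    # -- sweep components ----------------------------------------------------
    def update_units(self, rng: np.random.Generator, adapt_step: float | None):
        """One-parameter-at-a-time MH over all subject-day blocks in parallel."""
        sig = np.exp(self.log_sig)  # (B, K)
        loc = self.loc()
        for k in range(self.K):
            prop = self.v.copy()
            prop[:, :, k] += self.v_scale[:, :, k] * rng.standard_normal((self.B, self.U))
            ep_ll_prop = self.episode_loglik(prop)
            ll_cur = self.ep_ll @ self.agg  # (B, U)
            ll_prop = ep_ll_prop @ self.agg
            z_cur = (self.v[:, :, k] - loc[:, :, k]) / sig[:, None, k]
            z_prop = (prop[:, :, k] - loc[:, :, k]) / sig[:, None, k]
            log_r = ll_prop - ll_cur - 0.5 * (z_prop**2 - z_cur**2)
            accept = np.log(rng.random((self.B, self.U))) < log_r  # (B, U)
            self.v[:, :, k] = np.where(accept, prop[:, :, k], self.v[:, :, k])
            ep_accept = accept[:, self.ep_unit]
            self.ep_ll = np.where(ep_accept, ep_ll_prop, self.ep_ll)
            self.v_acc += accept.mean()
            self.v_acc_n += 1
            if adapt_step is not None:
                self.v_scale[:, :, k] *= np.exp(adapt_step * (accept - _V_TARGET))
                np.clip(self.v_scale[:, :, k], 1e-3, 3.0, out=self.v_scale[:, :, k])

    def _translate(
        self,
        rng: np.random.Generator,
        mask: np.ndarray,
        scale: np.ndarray,
        dprior_fn,
        apply_fn,
        adapt_step: float | None,
    ) -> np.ndarray:
        """Joint shift of a location parameter and its subject values.

        Proposes v[:, mask, :] += delta (holding the standardised residuals
        fixed, so the subject-level prior is unchanged) together with the
        matching location shift; accepted per chain on the likelihood of the
        affected episodes plus the location parameter's own prior.
        Returns the adapted ``scale`` (modified in place).
        """
        delta = scale[:, None] * rng.standard_normal((self.B, self.K))
        prop = self.v.copy()
        prop[:, mask, :] += delta[:, None, :]
        ep_ll_prop = self.episode_loglik(prop)
        ep_sel = mask[self.ep_unit]
        d_ll = np.sum(ep_ll_prop[:, ep_sel] - self.ep_ll[:, ep_sel], axis=1)
        log_r = d_ll + dprior_fn(delta)
        accept = np.log(rng.random(self.B)) < log_r
        if accept.any():
            self.v = np.where(accept[:, None, None], prop, self.v)
            self.ep_ll = np.where(accept[:, None], ep_ll_prop, self.ep_ll)
            apply_fn(delta, accept)
        if adapt_step is not None:
            scale *= np.exp(adapt_step * (accept - _V_TARGET))
            np.clip(scale, 1e-4, 2.0, out=scale)
        return accept

    def translate_locations(self, rng: np.random.Generator, adapt_step: float | None):
        """Translation moves for mu, the common day effect and group effects."""
        pri = self.model.priors

        all_units = np.ones(self.U, dtype=bool)

        def dprior_mu(delta):
            d = np.zeros(self.B)
            for k, th in enumerate(self.thetas):
                m0 = pri.mu_beta_loc if th == "beta" else pri.mu_alpha_loc
                s0 = pri.mu_beta_scale if th == "beta" else pri.mu_alpha_scale
                new = self.mu[:, k] + delta[:, k]
                d += -0.5 * ((new - m0) ** 2 - (self.mu[:, k] - m0) ** 2) / s0**2
            return d

        def apply_mu(delta, accept):
            self.mu = np.where(accept[:, None], self.mu + delta, self.mu)

        self._translate(rng, all_units, self.t_scale_mu, dprior_mu, apply_mu, adapt_step)
        if not self.day:
            return
        day2 = self.unit_day2.astype(bool)
        sb2 = np.exp(2 * self.log_sig_b)

        def dprior_bday(delta):
            new = self.b_day + delta
            if self.model.shrink_common_day_effects:
                return -0.5 * np.sum(new**2 - self.b_day**2, axis=1) / sb2
            return -0.5 * np.sum(new**2 - self.b_day**2, axis=1) / pri.b_day_scale**2

        def apply_bday(delta, accept):
            self.b_day = np.where(accept[:, None], self.b_day + delta, self.b_day)

        self._translate(rng, day2, self.t_scale_bday, dprior_bday, apply_bday, adapt_step)
        for gi in range(self.G):
            sel = day2 & (self.unit_gcode == gi)
            if not sel.any():
                continue

            def dprior_grp(delta, gi=gi):
                new = self.b_grp[:, :, gi] + delta
                return -0.5 * np.sum(new**2 - self.b_grp[:, :, gi] ** 2, axis=1) / sb2

            def apply_grp(delta, accept, gi=gi):
                self.b_grp[:, :, gi] = np.where(
                    accept[:, None], self.b_grp[:, :, gi] + delta, self.b_grp[:, :, gi]
                )

            self._translate(rng, sel, self.t_scale_grp[:, gi], dprior_grp, apply_grp, adapt_step)

    def rescale_sigmas(self, rng: np.random.Generator, adapt_step: float | None):
        """Joint rescaling of sigma_theta and its subject-level residuals.

        Proposes log sigma_k += delta with v' = loc + (v - loc) * exp(delta),
        keeping the standardised residuals fixed; the subject-level prior
        change cancels against the transform Jacobian, so acceptance uses
        only the likelihood of all episodes and the prior on sigma itself.
        """
        pri = self.model.priors
        loc = self.loc()
        for k, th in enumerate(self.thetas):
            delta = self.r_scale[:, k] * rng.standard_normal(self.B)
            prop = self.v.copy()
            prop[:, :, k] = loc[:, :, k] + (self.v[:, :, k] - loc[:, :, k]) * np.exp(
                delta[:, None]
            )
            ep_ll_prop = self.episode_loglik(prop)
            d_ll = np.sum(ep_ll_prop - self.ep_ll, axis=1)
            x, xp = self.log_sig[:, k], self.log_sig[:, k] + delta
            s, sp = np.exp(x), np.exp(xp)
            if th == "beta":
                dprior = _halfnormal_logpdf(sp, pri.sigma_beta_scale) + xp
                dprior -= _halfnormal_logpdf(s, pri.sigma_beta_scale) + x
            else:
                dprior = _halfcauchy_logpdf(sp, pri.sigma_alpha_scale) + xp
                dprior -= _halfcauchy_logpdf(s, pri.sigma_alpha_scale) + x
            accept = np.log(rng.random(self.B)) < d_ll + dprior
            self.v[:, :, k] = np.where(accept[:, None], prop[:, :, k], self.v[:, :, k])
            self.ep_ll = np.where(accept[:, None], ep_ll_prop, self.ep_ll)
            self.log_sig[:, k] = np.where(accept, xp, x)
            if adapt_step is not None:
                self.r_scale[:, k] *= np.exp(adapt_step * (accept - _S_TARGET))
                np.clip(self.r_scale[:, k], 1e-4, 2.0, out=self.r_scale[:, k])

    def gibbs_mu(self, rng: np.random.Generator):
        pri = self.model.priors
        sig2 = np.exp(2 * self.log_sig)  # (B, K)
        loc = self.loc()
        shift = loc - self.mu[:, None, :]
        w = self.v - shift  # (B, U, K): w ~ N(mu, sigma)
        for k, th in enumerate(self.thetas):
            m0 = pri.mu_beta_loc if th == "beta" else pri.mu_alpha_loc
            s0 = pri.mu_beta_scale if th == "beta" else pri.mu_alpha_scale
            prec = self.U / sig2[:, k] + 1.0 / s0**2
            mean = (w[:, :, k].sum(axis=1) / sig2[:, k] + m0 / s0**2) / prec
            self.mu[:, k] = mean + rng.standard_normal(self.B) / np.sqrt(prec)

    def gibbs_effects(self, rng: np.random.Generator):
        if not self.day:
            return
        pri = self.model.priors
        sig2 = np.exp(2 * self.log_sig)
        sb2 = np.exp(2 * self.log_sig_b)
        day2 = self.unit_day2.astype(bool)
        n_d2 = int(day2.sum())
        gterm = np.transpose(self.b_grp, (0, 2, 1))[:, np.maximum(self.unit_gcode, 0), :]
        gterm = np.where((self.unit_gcode >= 0)[None, :, None], gterm, 0.0)
        for k in range(self.K):
            # common day effect
            w = self.v[:, day2, k] - self.mu[:, k, None] - gterm[:, day2, k]
            pv = sb2 if self.model.shrink_common_day_effects else np.full(self.B, pri.b_day_scale**2)
            prec = n_d2 / sig2[:, k] + 1.0 / pv
            mean = (w.sum(axis=1) / sig2[:, k]) / prec
            self.b_day[:, k] = mean + rng.standard_normal(self.B) / np.sqrt(prec)
            # group-specific effects
            for gi in range(self.G):
                sel = day2 & (self.unit_gcode == gi)
                n_g = int(sel.sum())
                if n_g == 0:
                    continue
                w = self.v[:, sel, k] - self.mu[:, k, None] - self.b_day[:, k, None]
                prec = n_g / sig2[:, k] + 1.0 / sb2
                mean = (w.sum(axis=1) / sig2[:, k]) / prec
                self.b_grp[:, k, gi] = mean + rng.standard_normal(self.B) / np.sqrt(prec)

    def mh_sigmas(self, rng: np.random.Generator, adapt_step: float | None):
        pri = self.model.priors
        loc = self.loc()
        r2 = np.sum((self.v - loc) ** 2, axis=1)  # (B, K)
        for k, th in enumerate(self.thetas):
            x = self.log_sig[:, k]
            xp = x + self.s_scale[:, k] * rng.standard_normal(self.B)

            def post(xv):
                s = np.exp(xv)
                if th == "beta":
                    prior = _halfnormal_logpdf(s, pri.sigma_beta_scale)
                else:
                    prior = _halfcauchy_logpdf(s, pri.sigma_alpha_scale)
                return prior + xv - self.U * xv - r2[:, k] / (2 * s**2)

            log_r = post(xp) - post(x)
            accept = np.log(rng.random(self.B)) < log_r
            self.log_sig[:, k] = np.where(accept, xp, x)
            if adapt_step is not None:
                self.s_scale[:, k] *= np.exp(adapt_step * (accept - _S_TARGET))
                np.clip(self.s_scale[:, k], 1e-3, 3.0, out=self.s_scale[:, k])

    def mh_sigma_b(self, rng: np.random.Generator, adapt_step: float | None):
        if not self.day:
            return
        pri = self.model.priors
        b2 = np.sum(self.b_grp[:, :, : self.G] ** 2, axis=(1, 2))
        n_b = self.K * self.G
        if self.model.shrink_common_day_effects:
            b2 = b2 + np.sum(self.b_day**2, axis=1)
            n_b += self.K
        x = self.log_sig_b
        xp = x + self.sb_scale * rng.standard_normal(self.B)

        def post(xv):
            s = np.exp(xv)
            return _halfnormal_logpdf(s, pri.sigma_b_scale) + xv - n_b * xv - b2 / (2 * s**2)

        log_r = post(xp) - post(x)
        accept = np.log(rng.random(self.B)) < log_r
        self.log_sig_b = np.where(accept, xp, x)
        if adapt_step is not None:
            self.sb_scale *= np.exp(adapt_step * (accept - _S_TARGET))
            np.clip(self.sb_scale, 1e-3, 3.0, out=self.sb_scale)

    def sweep(self, rng: np.random.Generator, adapt_step: float | None):
        self.update_units(rng, adapt_step)
        self.translate_locations(rng, adapt_step)
        self.rescale_sigmas(rng, adapt_step)
        self.gibbs_mu(rng)
        self.gibbs_effects(rng)
        self.mh_sigmas(rng, adapt_step)
        self.mh_sigma_b(rng, adapt_step)

    # -- export --------------------------------------------------------------
    def vector(self) -> np.ndarray:
        """Current state as (B, ndim) in the model's centred layout."""
        model = self.model
        out = np.empty((self.B, model.ndim))
        for k, th in enumerate(self.thetas):
            out[:, model._blocks[f"mu_{th}"]] = self.mu[:, k, None]
            out[:, model._blocks[f"log_sigma_{th}"]] = self.log_sig[:, k, None]
        if self.day:
            out[:, model._blocks["log_sigma_b"]] = self.log_sig_b[:, None]
            for k, th in enumerate(self.thetas):
                out[:, model._blocks[f"b_day_{th}"]] = self.b_day[:, k, None]
                for gi, g in enumerate(model.mgroups):
                    out[:, model._blocks[f"b_{th}[{g}]"]] = self.b_grp[:, k, gi, None]
        for k, th in enumerate(self.thetas):
            out[:, model._blocks[f"subj_{th}"]] = self.v[:, :, k]
        return out


def run_gibbs(model, config: SamplerConfig, seed: int):
    """Sample the model posterior; returns (chains, chains, diagnostics).

    The returned array has shape (config.chains, config.draws, ndim) in the
    model's centred parameter layout.  Requires the centred
    parameterisation (the sampler's conditionals are derived in it).
    """
    if model.parameterization != "centered":
        raise ValueError("the blocked Gibbs sampler requires parameterization='centered'")
    rng = np.random.default_rng(seed)
    state = _GibbsState(model, config.chains, rng)
    kept = np.empty((config.chains, config.draws, model.ndim))
    for t in range(config.warmup):
        adapt = min(0.25, 2.0 / (t + 10) ** 0.6)
        state.sweep(rng, adapt)
    state.v_acc = 0.0
    state.v_acc_n = 0
    for d in range(config.draws):
        for _ in range(config.thin):
            state.sweep(rng, None)
        kept[:, d, :] = state.vector()
    diags = diagnostics_from_chains(
        kept, model.param_names, state.v_acc / max(state.v_acc_n, 1)
    )
    if not diags.converged:
        warnings.warn(
            f"maximum R-hat {diags.max_rhat:.3f} exceeds 1.1; treat this fit as "
            "unconverged (increase warmup/draws)",
            ConvergenceWarning,
            stacklevel=2,
        )
    return kept, kept, diags
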