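"""The three surveillance models and their Model/Results interfaces.

* :class:`DiseaseMappingModel` (DM) — the standard spatiotemporal disease
  mapping model ``log rho_it = alpha + theta_i + phi_i + gamma_t + psi_it``
  with an ICAR spatial field, iid heterogeneity, an RW1 trend and iid
  space-time interactions.  Anomalies are read off informally from the
  interaction exceedance probabilities.
* :class:`STMixModel` — the same structure with the interaction prior
  replaced by a two-component zero-mean normal mixture (small "common"
  variance vs large "unusual" variance), the formal interaction-mixture
  detector.
* :class:`FlexDetectModel` — model choice between a common-trend submodel
  ``alpha + theta_i + gamma_t`` and an area-specific-trend submodel
  ``alpha_i + delta_it`` (one RW1 per area), with a per-area indicator
  ``z_i`` whose posterior frequency of selecting the common model is the
  detection score.  The indicator is sampled without feedback into either
  submodel ("cut"), matching the original model-choice construction.

Each model is built from a :class:`~stsurv.scenarios.CountPanel` and an
:class:`~stsurv.graphs.AreaGraph`; ``fit()`` runs MCMC and returns a Results
object carrying the posterior draws, summaries and detection methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import detection
from .graphs import AreaGraph, icar_quadratic_form
from .mcmc import (
    AdaptiveScale,
    McmcConfig,
    PosteriorSamples,
    gelman_rubin,
    icar_log_density,
    normal_log_density,
    poisson_loglik,
    register_model,
    run_chain,
    rw1_log_density,
)
from .scenarios import CountPanel


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(x) - rate * x


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


class _PanelSampler:
    """Shared precomputations and Metropolis sub-updates for panel samplers."""

    def __init__(self, panel: CountPanel, graph: AreaGraph):
        if panel.n_areas != graph.n_areas:
            raise ValueError(
                f"panel has {panel.n_areas} areas but graph has {graph.n_areas}"
            )
        self.panel = panel
        self.graph = graph
        self.y = panel.y.astype(float)
        self.E = panel.E
        self.n, self.T = panel.y.shape
        self.Yrow = self.y.sum(axis=1)
        self.Ycol = self.y.sum(axis=0)
        self.Ytot = float(self.y.sum())
        self.W = graph.adjacency_matrix()
        self.m = graph.neighbor_counts.astype(float)
        self.colors = graph.coloring()
        self.comps = graph.components()
        self.icar_rank = graph.n_areas - len(self.comps)
        # time colouring for RW1 chain-graph updates
        self.t_even = np.arange(0, self.T, 2)
        self.t_odd = np.arange(1, self.T, 2)
        self.mt = np.where((np.arange(self.T) == 0) | (np.arange(self.T) == self.T - 1), 1.0, 2.0)

    # -- bookkeeping -----------------------------------------------------
    def _init_book(self, state: dict, blocks, scale: float) -> None:
        state["_scales"] = {b: AdaptiveScale(scale) for b in blocks}
        state["_accept"] = {b: 0.0 for b in blocks}
        state["_prop"] = {b: 0.0 for b in blocks}
        state["_nsweeps"] = 0

    def _reg(self, state, blk, frac, n, adapting) -> None:
        state["_accept"][blk] += frac * n
        state["_prop"][blk] += n
        if adapting:
            state["_scales"][blk].register(frac, n)

    # -- generic sub-updates --------------------------------------------
    def _update_cells(self, state, blk, value, M, prior_prec, rng, adapting):
        """Parallel MH on iid-normal cells entering the rate multiplicatively."""
        sc = state["_scales"][blk].scale
        d = sc * rng.standard_normal(value.shape)
        log_ratio = (
            self.y * d
            - M * np.expm1(d)
            - 0.5 * prior_prec * ((value + d) ** 2 - value**2)
        )
        acc = np.log(rng.uniform(size=value.shape)) < log_ratio
        dacc = np.where(acc, d, 0.0)
        value = value + dacc
        M = M * np.exp(dacc)
        self._reg(state, blk, float(acc.mean()), acc.size, adapting)
        return value, M

    def _update_rows_iid(self, state, blk, value, M, prior_prec, rng, adapting):
        """Parallel MH on per-area effects with iid normal prior (or flat)."""
        sc = state["_scales"][blk].scale
        d = sc * rng.standard_normal(self.n)
        S = M.sum(axis=1)
        log_ratio = self.Yrow * d - S * np.expm1(d)
        if prior_prec is not None:
            log_ratio -= 0.5 * prior_prec * ((value + d) ** 2 - value**2)
        acc = np.log(rng.uniform(size=self.n)) < log_ratio
        dacc = np.where(acc, d, 0.0)
        value = value + dacc
        M = M * np.exp(dacc)[:, None]
        self._reg(state, blk, float(acc.mean()), self.n, adapting)
        return value, M

    def _update_theta(self, state, blk, theta, M, tau, rng, adapting):
        """Chromatic MH on the ICAR field (independent sets updated jointly)."""
        sc = state["_scales"][blk].scale
        theta = theta.copy()
        for ids in self.colors:
            s = (self.W @ theta)[ids]
            S = M[ids].sum(axis=1)
            th = theta[ids]
            d = sc * rng.standard_normal(len(ids))
            thp = th + d
            dlp = -0.5 * tau * (
                (self.m[ids] * thp**2 - 2 * thp * s)
                - (self.m[ids] * th**2 - 2 * th * s)
            )
            log_ratio = self.Yrow[ids] * d - S * np.expm1(d) + dlp
            acc = np.log(rng.uniform(size=len(ids))) < log_ratio
            dacc = np.where(acc, d, 0.0)
            theta[ids] = th + dacc
            M[ids] = M[ids] * np.exp(dacc)[:, None]
            self._reg(state, blk, float(acc.mean()), len(ids), adapting)
        return theta, M

    def _update_gamma(self, state, blk, gamma, M, tau, rng, adapting):
        """Even/odd-time MH on the RW1 trend."""
        sc = state["_scales"][blk].scale
        gamma = gamma.copy()
        Scol = M.sum(axis=0)
        for ids in (self.t_even, self.t_odd):
            s = np.zeros(self.T)
            s[1:] += gamma[:-1]
            s[:-1] += gamma[1:]
            g = gamma[ids]
            d = sc * rng.standard_normal(len(ids))
            gp = g + d
            dlp = -0.5 * tau * (
                (self.mt[ids] * gp**2 - 2 * gp * s[ids])
                - (self.mt[ids] * g**2 - 2 * g * s[ids])
            )
            log_ratio = self.Ycol[ids] * d - Scol[ids] * np.expm1(d) + dlp
            acc = np.log(rng.uniform(size=len(ids))) < log_ratio
            dacc = np.where(acc, d, 0.0)
            gamma[ids] = g + dacc
            M[:, ids] = M[:, ids] * np.exp(dacc)[None, :]
            Scol[ids] = Scol[ids] * np.exp(dacc)
            self._reg(state, blk, float(acc.mean()), len(ids), adapting)
        return gamma, M

    def _update_alpha(self, state, blk, alpha, M, rng, adapting):
        """Scalar MH on the intercept (flat prior)."""
        sc = state["_scales"][blk].scale
        d = sc * rng.standard_normal()
        log_ratio = self.Ytot * d - M.sum() * np.expm1(d)
        acc = np.log(rng.uniform()) < log_ratio
        if acc:
            alpha = alpha + d
            M = M * np.exp(d)
        self._reg(state, blk, float(acc), 1, adapting)
        return alpha, M

    def _recenter_icar(self, theta, alpha):
        """Per-component sum-to-zero; the global mean is absorbed into alpha."""
        alpha = alpha + float(theta.mean())
        theta = theta.copy()
        for comp in self.comps:
            theta[comp] -= theta[comp].mean()
        return theta, alpha

    def _alpha_init(self) -> float:
        return float(np.log(self.Ytot / self.E.sum()))


@register_model("dm")
class DmSampler(_PanelSampler):
    """Metropolis-within-Gibbs sampler for the disease-mapping model.

    Precisions of theta, phi, gamma and psi carry Gamma(shape, rate) priors
    (vague but proper by default) with conjugate Gibbs updates; the intercept
    is flat.
    """

    name = "dm"
    _blocks = ("alpha", "theta", "phi", "gamma", "psi")

    def __init__(
        self,
        panel: CountPanel,
        graph: AreaGraph,
        prior_shape: float = 1.0,
        prior_rate: float = 0.01,
        fixed_alpha: float | None = None,
    ):
        super().__init__(panel, graph)
        self.a0 = prior_shape
        self.b0 = prior_rate
        self.fixed_alpha = fixed_alpha

    def init_state(self, rng) -> dict:
        state = {
            "alpha": self.fixed_alpha if self.fixed_alpha is not None else self._alpha_init(),
            "theta": np.zeros(self.n),
            "phi": np.zeros(self.n),
            "gamma": np.zeros(self.T),
            "psi": np.zeros((self.n, self.T)),
            "tau_theta": 10.0,
            "tau_phi": 10.0,
            "tau_gamma": 10.0,
            "tau_psi": 10.0,
        }
        self._init_book(state, self._blocks, 0.1)
        return state

    def _rate(self, state) -> np.ndarray:
        log_rr = (
            state["alpha"]
            + state["theta"][:, None]
            + state["phi"][:, None]
            + state["gamma"][None, :]
            + state["psi"]
        )
        return self.E * np.exp(log_rr)

    def _psi_prior_prec(self, state):
        return state["tau_psi"]

    def sweep(self, state, rng, adapting=False) -> None:
        M = self._rate(state)
        state["psi"], M = self._update_cells(
            state, "psi", state["psi"], M, self._psi_prior_prec(state), rng, adapting
        )
        state["phi"], M = self._update_rows_iid(
            state, "phi", state["phi"], M, state["tau_phi"], rng, adapting
        )
        state["theta"], M = self._update_theta(
            state, "theta", state["theta"], M, state["tau_theta"], rng, adapting
        )
        state["gamma"], M = self._update_gamma(
            state, "gamma", state["gamma"], M, state["tau_gamma"], rng, adapting
        )
        if self.fixed_alpha is None:
            state["alpha"], M = self._update_alpha(
                state, "alpha", state["alpha"], M, rng, adapting
            )
            state["theta"], state["alpha"] = self._recenter_icar(
                state["theta"], state["alpha"]
            )
            mu = float(state["gamma"].mean())
            state["gamma"] = state["gamma"] - mu
            state["alpha"] += mu
        else:
            # pure projection onto the intrinsic-prior gauge (alpha held)
            for comp in self.comps:
                state["theta"][comp] -= state["theta"][comp].mean()
            state["gamma"] = state["gamma"] - state["gamma"].mean()
        self._gibbs_precisions(state, rng)
        state["_nsweeps"] += 1

    def _gibbs_precisions(self, state, rng) -> None:
        a0, b0 = self.a0, self.b0
        q_theta = icar_quadratic_form(state["theta"], self.graph)
        state["tau_theta"] = rng.gamma(a0 + 0.5 * self.icar_rank, 1.0 / (b0 + 0.5 * q_theta))
        state["tau_phi"] = rng.gamma(
            a0 + 0.5 * self.n, 1.0 / (b0 + 0.5 * float(np.sum(state["phi"] ** 2)))
        )
        q_gamma = float(np.sum(np.diff(state["gamma"]) ** 2))
        state["tau_gamma"] = rng.gamma(a0 + 0.5 * (self.T - 1), 1.0 / (b0 + 0.5 * q_gamma))
        state["tau_psi"] = rng.gamma(
            a0 + 0.5 * self.n * self.T,
            1.0 / (b0 + 0.5 * float(np.sum(state["psi"] ** 2))),
        )

    def record(self, state) -> dict:
        return {
            "alpha": state["alpha"],
            "theta": state["theta"].copy(),
            "phi": state["phi"].copy(),
            "gamma": state["gamma"].copy(),
            "psi": state["psi"].copy(),
            "tau_theta": state["tau_theta"],
            "tau_phi": state["tau_phi"],
            "tau_gamma": state["tau_gamma"],
            "tau_psi": state["tau_psi"],
        }

    def log_posterior(self, state) -> float:
        log_rr = np.log(self._rate(state) / self.E)
        lp = poisson_loglik(self.panel, log_rr)
        lp += icar_log_density(state["theta"], state["tau_theta"], self.graph)
        lp += normal_log_density(state["phi"], state["tau_phi"])
        lp += rw1_log_density(state["gamma"], state["tau_gamma"])
        lp += self._psi_prior_logdens(state)
        for k in ("tau_theta", "tau_phi", "tau_gamma", "tau_psi"):
            lp += _gamma_logpdf(state[k], self.a0, self.b0)
        return float(lp)

    def _psi_prior_logdens(self, state) -> float:
        return normal_log_density(state["psi"], state["tau_psi"])


@register_model("stmix")
class StmixSampler(DmSampler):
    """Disease-mapping structure with a two-component mixture interaction.

    ``psi_it ~ (1-p) N(0, sigma1^2) + p N(0, sigma2^2)`` with sigma1 <= sigma2;
    the indicator ``c_it`` (1 = wide/unusual component) and the weight ``p``
    have Bernoulli/Beta full conditionals.  Label switching is controlled by
    the ordering constraint (default: joint rejection of unordered precision
    draws) or, alternatively, by asymmetric informative priors on the two
    component precisions (``label_switching="informative"``).
    """

    name = "stmix"

    def __init__(
        self,
        panel: CountPanel,
        graph: AreaGraph,
        prior_shape: float = 1.0,
        prior_rate: float = 0.01,
        weight_prior: tuple = (1.0, 1.0),
        label_switching: str = "ordered",
        narrow_prior: tuple = (2.0, 0.01),
        wide_prior: tuple = (2.0, 1.0),
    ):
        super().__init__(panel, graph, prior_shape, prior_rate)
        if label_switching not in ("ordered", "informative"):
            raise ValueError("label_switching must be 'ordered' or 'informative'")
        self.weight_prior = weight_prior
        self.label_switching = label_switching
        self.narrow_prior = narrow_prior  # Gamma prior for the narrow-component precision
        self.wide_prior = wide_prior

    def init_state(self, rng) -> dict:
        state = super().init_state(rng)
        del state["tau_psi"]
        state["c"] = np.zeros((self.n, self.T), dtype=bool)
        state["p"] = 0.1
        state["tau_narrow"] = 40.0
        state["tau_wide"] = 2.5
        return state

    def _psi_prior_prec(self, state):
        return np.where(state["c"], state["tau_wide"], state["tau_narrow"])

    def sweep(self, state, rng, adapting=False) -> None:
        M = self._rate(state)
        state["psi"], M = self._update_cells(
            state, "psi", state["psi"], M, self._psi_prior_prec(state), rng, adapting
        )
        state["phi"], M = self._update_rows_iid(
            state, "phi", state["phi"], M, state["tau_phi"], rng, adapting
        )
        state["theta"], M = self._update_theta(
            state, "theta", state["theta"], M, state["tau_theta"], rng, adapting
        )
        state["gamma"], M = self._update_gamma(
            state, "gamma", state["gamma"], M, state["tau_gamma"], rng, adapting
        )
        state["alpha"], M = self._update_alpha(state, "alpha", state["alpha"], M, rng, adapting)
        state["theta"], state["alpha"] = self._recenter_icar(state["theta"], state["alpha"])
        mu = float(state["gamma"].mean())
        state["gamma"] = state["gamma"] - mu
        state["alpha"] += mu
        self._gibbs_mixture(state, rng)
        self._gibbs_precisions(state, rng)
        state["_nsweeps"] += 1

    def _gibbs_mixture(self, state, rng) -> None:
        psi2 = state["psi"] ** 2
        t1, t2 = state["tau_narrow"], state["tau_wide"]
        p = state["p"]
        log_odds = (
            np.log(p) - np.log1p(-p) + 0.5 * (np.log(t2) - np.log(t1)) - 0.5 * (t2 - t1) * psi2
        )
        state["c"] = rng.uniform(size=psi2.shape) < 1.0 / (1.0 + np.exp(-log_odds))
        n_wide = int(state["c"].sum())
        ap, bp = self.weight_prior
        state["p"] = float(
            np.clip(rng.beta(ap + n_wide, bp + psi2.size - n_wide), 1e-12, 1 - 1e-12)
        )
        q_wide = float(psi2[state["c"]].sum())
        q_narrow = float(psi2[~state["c"]].sum())
        n_narrow = psi2.size - n_wide
        if self.label_switching == "ordered":
            a0, b0 = self.a0, self.b0
            # rejection within the Gibbs step: keep sigma1 <= sigma2
            for _ in range(100):
                t1 = rng.gamma(a0 + 0.5 * n_narrow, 1.0 / (b0 + 0.5 * q_narrow))
                t2 = rng.gamma(a0 + 0.5 * n_wide, 1.0 / (b0 + 0.5 * q_wide))
                if t1 >= t2:
                    state["tau_narrow"], state["tau_wide"] = t1, t2
                    break
        else:
            an, bn = self.narrow_prior
            aw, bw = self.wide_prior
            state["tau_narrow"] = rng.gamma(an + 0.5 * n_narrow, 1.0 / (bn + 0.5 * q_narrow))
            state["tau_wide"] = rng.gamma(aw + 0.5 * n_wide, 1.0 / (bw + 0.5 * q_wide))

    def _gibbs_precisions(self, state, rng) -> None:
        a0, b0 = self.a0, self.b0
        q_theta = icar_quadratic_form(state["theta"], self.graph)
        state["tau_theta"] = rng.gamma(a0 + 0.5 * self.icar_rank, 1.0 / (b0 + 0.5 * q_theta))
        state["tau_phi"] = rng.gamma(
            a0 + 0.5 * self.n, 1.0 / (b0 + 0.5 * float(np.sum(state["phi"] ** 2)))
        )
        q_gamma = float(np.sum(np.diff(state["gamma"]) ** 2))
        state["tau_gamma"] = rng.gamma(a0 + 0.5 * (self.T - 1), 1.0 / (b0 + 0.5 * q_gamma))

    def record(self, state) -> dict:
        rec = {
            "alpha": state["alpha"],
            "theta": state["theta"].copy(),
            "phi": state["phi"].copy(),
            "gamma": state["gamma"].copy(),
            "psi": state["psi"].copy(),
            "tau_theta": state["tau_theta"],
            "tau_phi": state["tau_phi"],
            "tau_gamma": state["tau_gamma"],
            "c": state["c"].astype(np.uint8),
            "p": state["p"],
            "sigma1": 1.0 / np.sqrt(state["tau_narrow"]),
            "sigma2": 1.0 / np.sqrt(state["tau_wide"]),
        }
        return rec

    def _psi_prior_logdens(self, state) -> float:
        prec = self._psi_prior_prec(state)
        psi = state["psi"]
        return float(
            np.sum(0.5 * (np.log(prec) - np.log(2 * np.pi)) - 0.5 * prec * psi**2)
        )

    def log_posterior(self, state) -> float:
        log_rr = np.log(self._rate(state) / self.E)
        lp = poisson_loglik(self.panel, log_rr)
        lp += icar_log_density(state["theta"], state["tau_theta"], self.graph)
        lp += normal_log_density(state["phi"], state["tau_phi"])
        lp += rw1_log_density(state["gamma"], state["tau_gamma"])
        lp += self._psi_prior_logdens(state)
        for k in ("tau_theta", "tau_phi", "tau_gamma"):
            lp += _gamma_logpdf(state[k], self.a0, self.b0)
        return float(lp)


@register_model("flexdetect")
class FlexDetectSampler(_PanelSampler):
    """Model-choice sampler: common trend vs area-specific trends.

    Both submodels are always conditioned on the full panel; the per-area
    indicator ``z_i`` (1 = area-specific/unusual) is Gibbs-drawn from the two
    submodels' current Poisson likelihoods and the prior inclusion
    probability ``pi``, with no feedback into the submodel parameters (the
    "cut" construction).  ``pi`` is held at its prior mean (0.95 by default)
    unless ``update_pi=True``.

    The area-specific submodel decomposes each area's trend hierarchically
    as (own overall trend ``gamma2``) + (per-area departure ``delta_i``):
    the departure random walk has a stiff base increment scale, with
    heavy-tailed (Student-t via a Gamma scale mixture, ``robust_nu`` degrees
    of freedom) increments so that abrupt area-specific excursions — step
    changes, isolated spikes — remain cheap while ordinary areas stay glued
    to their shared trend.  Set ``robust_nu=None`` for plain Gaussian
    increments.
    """

    name = "flexdetect"
    _blocks = ("alpha_common", "theta", "gamma_common", "alpha_area", "gamma2", "delta")

    def __init__(
        self,
        panel: CountPanel,
        graph: AreaGraph,
        prior_shape: float = 1.0,
        prior_rate: float = 0.01,
        pi_prior: tuple = (19.0, 1.0),
        update_pi: bool = False,
        delta_prior: tuple = (200.0, 0.25),
        robust_nu: float | None = 4.0,
        audit_every: int = 100,
    ):
        super().__init__(panel, graph)
        self.a0 = prior_shape
        self.b0 = prior_rate
        self.pi_prior = pi_prior
        self.update_pi = update_pi
        self.delta_prior = delta_prior
        self.robust_nu = robust_nu
        self.audit_every = audit_every

    def init_state(self, rng) -> dict:
        state = {
            "alpha_common": self._alpha_init(),
            "theta": np.zeros(self.n),
            "gamma_common": np.zeros(self.T),
            "tau_theta": 10.0,
            "tau_gamma": 10.0,
            "alpha_area": np.where(
                self.Yrow > 0, np.log(np.maximum(self.Yrow, 0.5) / self.E.sum(axis=1)), 0.0
            ),
            "gamma2": np.zeros(self.T),
            "tau_gamma2": 10.0,
            "delta": np.zeros((self.n, self.T)),
            "tau_delta": self.delta_prior[0] / self.delta_prior[1],
            "w": np.ones((self.n, self.T - 1)),
            "z": np.zeros(self.n, dtype=bool),
            "pi": self.pi_prior[0] / (self.pi_prior[0] + self.pi_prior[1]),
        }
        self._init_book(state, self._blocks, 0.1)
        return state

    # -- submodel rates ---------------------------------------------------
    def _rate_common(self, state) -> np.ndarray:
        return self.E * np.exp(
            state["alpha_common"] + state["theta"][:, None] + state["gamma_common"][None, :]
        )

    def _rate_area(self, state) -> np.ndarray:
        return self.E * np.exp(
            state["alpha_area"][:, None] + state["gamma2"][None, :] + state["delta"]
        )

    def sweep(self, state, rng, adapting=False) -> None:
        # common-trend submodel
        M0 = self._rate_common(state)
        state["theta"], M0 = self._update_theta(
            state, "theta", state["theta"], M0, state["tau_theta"], rng, adapting
        )
        state["gamma_common"], M0 = self._update_gamma(
            state, "gamma_common", state["gamma_common"], M0, state["tau_gamma"], rng, adapting
        )
        state["alpha_common"], M0 = self._update_alpha(
            state, "alpha_common", state["alpha_common"], M0, rng, adapting
        )
        state["theta"], state["alpha_common"] = self._recenter_icar(
            state["theta"], state["alpha_common"]
        )
        mu = float(state["gamma_common"].mean())
        state["gamma_common"] -= mu
        state["alpha_common"] += mu

        # area-specific submodel
        M1 = self._rate_area(state)
        state["alpha_area"], M1 = self._update_rows_iid(
            state, "alpha_area", state["alpha_area"], M1, None, rng, adapting
        )
        state["gamma2"], M1 = self._update_gamma(
            state, "gamma2", state["gamma2"], M1, state["tau_gamma2"], rng, adapting
        )
        mu = float(state["gamma2"].mean())
        state["gamma2"] -= mu
        state["alpha_area"] += mu
        state["delta"], M1 = self._update_delta(state, M1, rng, adapting)
        mu_rows = state["delta"].mean(axis=1)
        state["delta"] = state["delta"] - mu_rows[:, None]
        state["alpha_area"] = state["alpha_area"] + mu_rows

        self._gibbs_increment_scales(state, rng)
        self._gibbs_precisions(state, rng)
        self._gibbs_model_choice(state, rng)
        state["_nsweeps"] += 1
        if self.audit_every and state["_nsweeps"] % self.audit_every == 0:
            self._likelihood_audit(state)

    def _update_delta(self, state, M1, rng, adapting):
        """Even/odd-time MH on every area's departure walk simultaneously.

        The walk's increment (t-1, t) carries weight ``w[:, t-1]`` so a
        cell's conditional prior precision is ``tau * (w_left + w_right)``
        with mean pulled toward the weighted neighbour average.
        """
        sc = state["_scales"]["delta"].scale
        delta = state["delta"].copy()
        tau = state["tau_delta"]
        w = state["w"]
        for ids in (self.t_even, self.t_odd):
            wsum = np.zeros((self.n, self.T))
            wsum[:, 1:] += w
            wsum[:, :-1] += w
            s = np.zeros((self.n, self.T))
            s[:, 1:] += w * delta[:, :-1]
            s[:, :-1] += w * delta[:, 1:]
            dl = delta[:, ids]
            d = sc * rng.standard_normal(dl.shape)
            dlp = -0.5 * tau * (
                (wsum[:, ids] * (dl + d) ** 2 - 2 * (dl + d) * s[:, ids])
                - (wsum[:, ids] * dl**2 - 2 * dl * s[:, ids])
            )
            log_ratio = self.y[:, ids] * d - M1[:, ids] * np.expm1(d) + dlp
            acc = np.log(rng.uniform(size=dl.shape)) < log_ratio
            dacc = np.where(acc, d, 0.0)
            delta[:, ids] = dl + dacc
            M1[:, ids] = M1[:, ids] * np.exp(dacc)
            self._reg(state, "delta", float(acc.mean()), acc.size, adapting)
        return delta, M1

    def _gibbs_increment_scales(self, state, rng) -> None:
        if self.robust_nu is None:
            state["w"] = np.ones((self.n, self.T - 1))
            return
        nu = self.robust_nu
        d2 = np.diff(state["delta"], axis=1) ** 2
        state["w"] = rng.gamma((nu + 1.0) / 2.0, 2.0 / (nu + state["tau_delta"] * d2))

    def _gibbs_precisions(self, state, rng) -> None:
        a0, b0 = self.a0, self.b0
        q_theta = icar_quadratic_form(state["theta"], self.graph)
        state["tau_theta"] = rng.gamma(a0 + 0.5 * self.icar_rank, 1.0 / (b0 + 0.5 * q_theta))
        q_gamma = float(np.sum(np.diff(state["gamma_common"]) ** 2))
        state["tau_gamma"] = rng.gamma(a0 + 0.5 * (self.T - 1), 1.0 / (b0 + 0.5 * q_gamma))
        q_gamma2 = float(np.sum(np.diff(state["gamma2"]) ** 2))
        state["tau_gamma2"] = rng.gamma(a0 + 0.5 * (self.T - 1), 1.0 / (b0 + 0.5 * q_gamma2))
        ad, bd = self.delta_prior
        q_delta = float(np.sum(state["w"] * np.diff(state["delta"], axis=1) ** 2))
        state["tau_delta"] = rng.gamma(
            ad + 0.5 * self.n * (self.T - 1), 1.0 / (bd + 0.5 * q_delta)
        )

    def _area_logliks(self, state) -> tuple[np.ndarray, np.ndarray]:
        """Per-area Poisson log-likelihood under each submodel (y! dropped)."""
        M0, M1 = self._rate_common(state), self._rate_area(state)
        ll0 = (self.y * np.log(M0) - M0).sum(axis=1)
        ll1 = (self.y * np.log(M1) - M1).sum(axis=1)
        return ll0, ll1

    def _gibbs_model_choice(self, state, rng) -> None:
        ll0, ll1 = self._area_logliks(state)
        pi = state["pi"]
        logit_common = np.log(pi) - np.log1p(-pi) + ll0 - ll1
        p_common = 1.0 / (1.0 + np.exp(-np.clip(logit_common, -700, 700)))
        state["z"] = rng.uniform(size=self.n) >= p_common  # z=1: area-specific
        if self.update_pi:
            a_pi, b_pi = self.pi_prior
            n_unusual = int(state["z"].sum())
            state["pi"] = float(
                np.clip(
                    rng.beta(a_pi + self.n - n_unusual, b_pi + n_unusual), 1e-12, 1 - 1e-12
                )
            )

    def _likelihood_audit(self, state) -> None:
        """The mixture likelihood at the z-selected risks must equal the
        panel Poisson log-likelihood of the assembled surface."""
        M0, M1 = self._rate_common(state), self._rate_area(state)
        mixed = np.where(state["z"][:, None], M1, M0)
        ll_rows = (self.y * np.log(mixed) - mixed - gammaln(self.y + 1.0)).sum()
        ll_panel = poisson_loglik(self.panel, np.log(mixed / self.E))
        if not np.isclose(ll_rows, ll_panel, rtol=1e-10, atol=1e-6):
            raise RuntimeError(
                f"likelihood audit failed: {ll_rows} != {ll_panel} at sweep "
                f"{state['_nsweeps']}"
            )

    def record(self, state) -> dict:
        return {
            "alpha_common": state["alpha_common"],
            "theta": state["theta"].copy(),
            "gamma_common": state["gamma_common"].copy(),
            "alpha_area": state["alpha_area"].copy(),
            "gamma2": state["gamma2"].copy(),
            "delta": state["delta"].copy(),
            "tau_theta": state["tau_theta"],
            "tau_gamma": state["tau_gamma"],
            "tau_gamma2": state["tau_gamma2"],
            "tau_delta": state["tau_delta"],
            "z": state["z"].astype(np.uint8),
            "pi": state["pi"],
        }

    def log_posterior(self, state) -> float:
        ll0, ll1 = self._area_logliks(state)
        pi = state["pi"]
        lp = float(np.sum(np.where(state["z"], ll1 + np.log1p(-pi), ll0 + np.log(pi))))
        lp += icar_log_density(state["theta"], state["tau_theta"], self.graph)
        lp += rw1_log_density(state["gamma_common"], state["tau_gamma"])
        lp += rw1_log_density(state["gamma2"], state["tau_gamma2"])
        # weighted per-area RW1 densities for the departure walks
        diffs2 = np.diff(state["delta"], axis=1) ** 2
        prec = state["tau_delta"] * state["w"]
        lp += float(np.sum(0.5 * (np.log(prec) - np.log(2 * np.pi)) - 0.5 * prec * diffs2))
        if self.robust_nu is not None:
            nu = self.robust_nu
            lp += float(
                np.sum(
                    0.5 * nu * np.log(0.5 * nu)
                    - gammaln(0.5 * nu)
                    + (0.5 * nu - 1.0) * np.log(state["w"])
                    - 0.5 * nu * state["w"]
                )
            )
        lp += _gamma_logpdf(state["tau_theta"], self.a0, self.b0)
        lp += _gamma_logpdf(state["tau_gamma"], self.a0, self.b0)
        lp += _gamma_logpdf(state["tau_gamma2"], self.a0, self.b0)
        lp += _gamma_logpdf(state["tau_delta"], *self.delta_prior)
        return float(lp)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class _SurveillanceModel:
    """Base class: a surveillance model bound to a count panel and graph."""

    _spec_name: str = ""
    _results_cls: type | None = None

    def __init__(self, panel: CountPanel, graph: AreaGraph, **model_kwargs):
        self.panel = panel
        self.graph = graph
        self.model_kwargs = model_kwargs

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, graph: AreaGraph, **model_kwargs):
        """Build from a long-format frame with columns area, time, observed,
        expected."""
        return cls(CountPanel.from_dataframe(df), graph, **model_kwargs)

    def fit(
        self,
        cfg: McmcConfig | None = None,
        *,
        fast: bool = False,
        seed: int = 0,
    ):
        """Run MCMC and return a Results object.

        ``fast=True`` uses the desk-scale 5 000-sweep configuration; the
        default is 2 chains x 20 000 sweeps with 10 000 burn-in, thinned by
        10.
        """
        if cfg is None:
            cfg = McmcConfig.fast(seed=seed) if fast else McmcConfig(seed=seed)
        samples = run_chain(self._spec_name, self.panel, self.graph, cfg, **self.model_kwargs)
        return self._results_cls(self, samples)


class _SurveillanceResults:
    """Posterior draws plus summaries for a fitted surveillance model."""

    _scalar_blocks: tuple = ()

    def __init__(self, model: _SurveillanceModel, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    @property
    def panel(self) -> CountPanel:
        return self.model.panel

    def gelman_rubin(self) -> dict:
        return gelman_rubin(self.samples)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, 2.5/97.5 percentiles (and PSRF with >=2
        chains) for the scalar parameter blocks."""
        rows = []
        psrf = self.gelman_rubin() if self.samples.n_chains >= 2 else {}
        for name in self._scalar_blocks:
            v = self.samples.get(name).astype(float)
            rows.append(
                {
                    "param": name,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1),
                    "q2.5": np.percentile(v, 2.5),
                    "q97.5": np.percentile(v, 97.5),
                    "rhat": float(np.asarray(psrf.get(name, np.nan)).max()),
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        cfg = self.samples.config
        head = (
            f"<{type(self).__name__}: {self.samples.model}, "
            f"{self.samples.n_chains} chains x {self.samples.n_draws} draws>"
        )
        return head + "\n" + self.summary().round(4).to_string()


class DiseaseMappingResults(_SurveillanceResults):
    _scalar_blocks = ("alpha", "tau_theta", "tau_phi", "tau_gamma", "tau_psi")

    def log_rr_draws(self) -> np.ndarray:
        """Posterior draws of the full log relative-risk surface."""
        s = self.samples
        return (
            s.get("alpha")[:, None, None]
            + s.get("theta")[:, :, None]
            + s.get("phi")[:, :, None]
            + s.get("gamma")[:, None, :]
            + s.get("psi")
        )

    def fitted_relative_risks(self) -> np.ndarray:
        return np.exp(self.log_rr_draws()).mean(axis=0)

    def exceedance(self, component: str = "interaction") -> np.ndarray:
        """Per-unit exceedance probabilities.

        ``component="interaction"`` thresholds P(psi_it > 0 | y) — the
        informal anomaly carrier; ``component="risk"`` thresholds
        P(rho_it > 1 | y) instead.
        """
        if component == "interaction":
            return detection.exceedance_matrix(self.samples.get("psi"))
        if component == "risk":
            return detection.exceedance_matrix(self.log_rr_draws())
        raise ValueError("component must be 'interaction' or 'risk'")

    def detect(self, threshold: float = 0.8, component: str = "interaction"):
        """Exceedance-threshold detection (0.8 standard, 0.9 conservative)."""
        return detection.dm_rule(self.exceedance(component), threshold)

    def plot_area_trend(self, area: int, ax=None):
        """Posterior mean relative-risk trend (95% band) for one area."""
        import matplotlib.pyplot as plt

        rr = np.exp(self.log_rr_draws()[:, area, :])
        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(1, rr.shape[1] + 1)
        ax.plot(t, rr.mean(axis=0), marker="o", label=f"area {area}")
        ax.fill_between(
            t, np.percentile(rr, 2.5, axis=0), np.percentile(rr, 97.5, axis=0), alpha=0.25
        )
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xlabel("time point")
        ax.set_ylabel("relative risk")
        ax.legend()
        return ax


class DiseaseMappingModel(_SurveillanceModel):
    """Standard spatiotemporal disease-mapping model (BYM + RW1 + iid
    interaction); detection by exceedance-probability thresholding."""

    _spec_name = "dm"
    _results_cls = DiseaseMappingResults


class STMixResults(DiseaseMappingResults):
    _scalar_blocks = ("alpha", "tau_theta", "tau_phi", "tau_gamma", "p", "sigma1", "sigma2")

    def mixture_weight(self) -> np.ndarray:
        """Posterior draws of the wide-component weight p."""
        return self.samples.get("p")

    def wide_component_probability(self) -> np.ndarray:
        """Per-unit posterior probability of the wide (unusual) component."""
        return self.samples.get("c").astype(float).mean(axis=0)

    def detect(self, rule: str = "stmix1", consecutive: bool = False):
        """Apply interaction-mixture rule 1 or 2 to the interaction
        exceedance probabilities."""
        exceed = self.exceedance("interaction")
        if rule == "stmix1":
            return detection.stmix_rule1(exceed)
        if rule == "stmix2":
            return detection.stmix_rule2(exceed, consecutive=consecutive)
        raise ValueError("rule must be 'stmix1' or 'stmix2'")


class STMixModel(_SurveillanceModel):
    """Interaction-mixture detector: two-component normal mixture on the
    space-time interaction, classified by exceedance rules."""

    _spec_name = "stmix"
    _results_cls = STMixResults


class FlexDetectResults(_SurveillanceResults):
    _scalar_blocks = ("alpha_common", "tau_theta", "tau_gamma", "tau_delta", "pi")

    def model_probabilities(self) -> np.ndarray:
        """Per-area posterior probability of the common-trend model,
        the draw frequency of z_i = 0."""
        return 1.0 - self.samples.get("z").astype(float).mean(axis=0)

    def detect(self, alpha: float = 0.05):
        """Bayesian FDR flags from the posterior model probabilities."""
        return detection.bayes_fdr_flags(self.model_probabilities(), alpha=alpha)

    def common_trend(self) -> np.ndarray:
        """Posterior mean of the shared temporal trend (risk-ratio scale)."""
        return np.exp(self.samples.get("gamma_common")).mean(axis=0)

    def area_trend(self, area: int) -> np.ndarray:
        """Posterior mean area-specific trend for one area (risk-ratio
        scale, own-level removed): shared part plus the area's departure."""
        s = self.samples
        return np.exp(s.get("gamma2") + s.get("delta")[:, area, :]).mean(axis=0)

    def plot_flagged_trends(self, alpha: float = 0.05, ax=None):
        """Area-specific trends of flagged areas against the common trend."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(1, self.panel.n_times + 1)
        ax.plot(t, self.common_trend(), color="black", lw=2, label="common trend")
        for area in self.detect(alpha=alpha).flagged_areas():
            ax.plot(t, self.area_trend(int(area)), alpha=0.7, label=f"area {area}")
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xlabel("time point")
        ax.set_ylabel("relative risk")
        ax.legend(fontsize="small")
        return ax


class FlexDetectModel(_SurveillanceModel):
    """Trend-mixture detector: per-area choice between a common spatial
    trend model and an independent area-specific trend, with Bayesian FDR
    control on the posterior model probabilities."""

    _spec_name = "flexdetect"
    _results_cls = FlexDetectResults


# functional front-ends returning raw posterior draws


def fit_dm(panel: CountPanel, graph: AreaGraph, cfg: McmcConfig, **kw) -> PosteriorSamples:
    """Fit the disease-mapping model; returns the retained draws."""
    return run_chain("dm", panel, graph, cfg, **kw)


def fit_stmix(panel: CountPanel, graph: AreaGraph, cfg: McmcConfig, **kw) -> PosteriorSamples:
    """Fit the interaction-mixture model; returns the retained draws."""
    return run_chain("stmix", panel, graph, cfg, **kw)


def fit_flexdetect(
    panel: CountPanel, graph: AreaGraph, cfg: McmcConfig, **kw
) -> PosteriorSamples:
    """Fit the trend-mixture model-choice detector; returns the retained
    draws (block ``z`` holds the per-area indicators)."""
    return run_chain("flexdetect", panel, graph, cfg, **kw)
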