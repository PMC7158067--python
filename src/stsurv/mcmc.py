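"""Markov chain Monte Carlo machinery shared by all surveillance models.

The samplers are Metropolis-within-Gibbs: latent Gaussian fields entering the
Poisson log-rate are updated by random-walk Metropolis, vectorised over
conditionally independent coordinates (independent sets of the area graph for
ICAR blocks, even/odd time points for random walks, all cells at once for
exchangeable interactions); precision parameters have conjugate Gamma full
conditionals and are Gibbs-sampled.  Proposal scales adapt by Robbins-Monro
during burn-in only, so the retained chain is Markovian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .graphs import AreaGraph, icar_quadratic_form
from .scenarios import CountPanel

MH_TARGET_ACCEPT = 0.44  # optimal single-site random-walk acceptance


# ---------------------------------------------------------------------------
# configuration and sample containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    ``n_iterations`` counts total sweeps per chain; the first ``burn_in`` are
    discarded and the rest kept every ``thin`` sweeps.  Runs are deterministic
    given ``seed`` (per-chain substreams are spawned from it).
    """

    n_iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    n_chains: int = 2
    seed: int = 0
    adapt: bool = True
    initial_scale: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @classmethod
    def fast(cls, seed: int = 0, n_chains: int = 2) -> "McmcConfig":
        """Desk-scale settings: 5 000 sweeps, 2 500 burn-in, thin 5."""
        return cls(
            n_iterations=5_000, burn_in=2_500, thin=5, n_chains=n_chains, seed=seed
        )

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained draws keyed by latent-block name.

    Each array has shape ``(n_chains, n_draws, *block_shape)``.  Indicator
    blocks hold values in {0, 1}, probability blocks lie in [0, 1], precision
    blocks are strictly positive; :meth:`validate` audits all three.
    """

    draws: dict
    acceptance: dict  # block name -> per-chain mean acceptance rate
    model: str = ""
    config: McmcConfig | None = None

    def __post_init__(self) -> None:
        counts = {k: (v.shape[0], v.shape[1]) for k, v in self.draws.items()}
        if len(set(counts.values())) > 1:
            raise ValueError(f"blocks disagree on (chains, draws): {counts}")
        self.validate()

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        """Retained draws per chain."""
        return next(iter(self.draws.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws for one block, chains stacked: shape (n_chains*n_draws, ...)."""
        v = self.draws[name]
        return v.reshape(-1, *v.shape[2:])

    def validate(self) -> None:
        for name, v in self.draws.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite draws in block {name!r}")
            if name in ("z", "c") and not np.isin(v, (0, 1)).all():
                raise ValueError(f"indicator block {name!r} not in {{0,1}}")
            if name.startswith("tau") or name.startswith("sigma"):
                if not np.all(v > 0):
                    raise ValueError(f"scale block {name!r} must be positive")
            if name in ("p", "pi") and (v.min() < 0 or v.max() > 1):
                raise ValueError(f"probability block {name!r} outside [0,1]")

    def to_dataframe(self) -> pd.DataFrame:
        """Columnar export: one row per retained draw, flattened block columns."""
        cols = {}
        nc, nd = self.n_chains, self.n_draws
        cols["chain"] = np.repeat(np.arange(nc), nd)
        cols["draw"] = np.tile(np.arange(nd), nc)
        for name, v in self.draws.items():
            flat = v.reshape(nc * nd, -1)
            if flat.shape[1] == 1:
                cols[name] = flat[:, 0]
            else:
                for k in range(flat.shape[1]):
                    cols[f"{name}_{k}"] = flat[:, k]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# log-densities
# ---------------------------------------------------------------------------


def poisson_loglik(panel: CountPanel, log_rr) -> float:
    """Poisson log-likelihood of the panel at the given log relative risks.

    ``sum_it [ y_it (log E_it + log_rr_it) - E_it exp(log_rr_it) - log y_it! ]``
    """
    log_rr = np.asarray(log_rr, dtype=float)
    if log_rr.shape != panel.y.shape:
        raise ValueError(
            f"log_rr shape {log_rr.shape} != panel shape {panel.y.shape}"
        )
    y, E = panel.y, panel.E
    return float(
        np.sum(y * (np.log(E) + log_rr) - E * np.exp(log_rr) - gammaln(y + 1.0))
    )


def rw1_log_density(gamma, tau: float) -> float:
    """First-order random-walk log-density (intrinsic, constant gauge dropped).

    ``(T-1)/2 log(tau/2pi) - (tau/2) sum_t (gamma_t - gamma_{t-1})^2``; equals
    the sum of independent normal increment log-densities.
    """
    g = np.asarray(gamma, dtype=float)
    if g.ndim != 1 or len(g) < 2:
        raise ValueError("gamma must be a vector of length >= 2")
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    q = float(np.sum(np.diff(g) ** 2))
    k = len(g) - 1  # rank of the RW1 structure matrix
    return 0.5 * k * (np.log(tau) - np.log(2 * np.pi)) - 0.5 * tau * q


def icar_log_density(theta, tau: float, graph: AreaGraph) -> float:
    """Intrinsic CAR log-density, one sum-to-zero gauge per graph component."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    q = icar_quadratic_form(theta, graph)
    rank = graph.n_areas - len(graph.components())
    return 0.5 * rank * (np.log(tau) - np.log(2 * np.pi)) - 0.5 * tau * q


def normal_log_density(x, tau: float) -> float:
    """iid zero-mean normal log-density with precision ``tau``."""
    x = np.asarray(x, dtype=float)
    return float(
        0.5 * x.size * (np.log(tau) - np.log(2 * np.pi)) - 0.5 * tau * np.sum(x * x)
    )


# ---------------------------------------------------------------------------
# vectorised Metropolis updates
# ---------------------------------------------------------------------------


class AdaptiveScale:
    """Scalar proposal scale with Robbins-Monro adaptation toward 0.44."""

    def __init__(self, scale: float):
        self.scale = scale
        self.accepted = 0.0
        self.proposed = 0

    def register(self, acc_fraction: float, n: int) -> None:
        self.accepted += acc_fraction * n
        self.proposed += n

    def adapt(self, batch: int) -> None:
        if self.proposed == 0:
            return
        rate = self.accepted / self.proposed
        step = min(0.25, 1.0 / np.sqrt(batch + 1.0))
        self.scale *= float(np.exp(step * (rate - MH_TARGET_ACCEPT)))
        self.accepted = 0.0
        self.proposed = 0

    @property
    def rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else np.nan


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------

_MODEL_REGISTRY: dict = {}


def register_model(name: str):
    def deco(cls):
        _MODEL_REGISTRY[name] = cls
        return cls

    return deco


def get_model_sampler(name: str):
    try:
        return _MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model spec {name!r}; registered: {sorted(_MODEL_REGISTRY)}"
        )


def run_chain(
    model_spec,
    panel: CountPanel,
    graph: AreaGraph,
    cfg: McmcConfig,
    **model_kwargs,
) -> PosteriorSamples:
    """Run ``cfg.n_chains`` chains of the registered model sampler.

    ``model_spec`` is either a registered name ("dm", "stmix", "flexdetect")
    or an already-constructed sampler-spec object exposing the sampler
    protocol (``init_state`` / ``sweep`` / ``record``).  Sum-to-zero
    constraints on intrinsic blocks are re-imposed every sweep by the
    samplers.  Deterministic given ``cfg.seed``.
    """
    if isinstance(model_spec, str):
        sampler = get_model_sampler(model_spec)(panel, graph, **model_kwargs)
    else:
        sampler = model_spec
    name = getattr(sampler, "name", type(sampler).__name__)

    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    ]
    per_chain: list[dict] = []
    accept_log: dict[str, list[float]] = {}
    for chain_seed in seeds:
        rng = np.random.default_rng(chain_seed)
        state = sampler.init_state(rng)
        lp = sampler.log_posterior(state)
        if not np.isfinite(lp):
            dump = {
                k: float(np.mean(v))
                for k, v in state.items()
                if isinstance(v, np.ndarray)
            }
            raise RuntimeError(
                f"non-finite log-posterior at initialization of {name!r}: {lp}; "
                f"block means: {dump}"
            )
        records: dict[str, list] = {}
        for it in range(cfg.n_iterations):
            adapting = cfg.adapt and it < cfg.burn_in
            sampler.sweep(state, rng, adapting=adapting)
            if adapting and (it + 1) % 50 == 0:
                for sc in state["_scales"].values():
                    sc.adapt((it + 1) // 50)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                for k, v in sampler.record(state).items():
                    records.setdefault(k, []).append(v)
        per_chain.append({k: np.array(v) for k, v in records.items()})
        for blk in state["_scales"]:
            accept_log.setdefault(blk, []).append(
                state["_accept"][blk] / max(state["_prop"][blk], 1.0)
            )

    draws = {
        k: np.stack([pc[k] for pc in per_chain], axis=0) for k in per_chain[0]
    }
    acceptance = {k: np.array(v) for k, v in accept_log.items()}
    return PosteriorSamples(draws=draws, acceptance=acceptance, model=name, config=cfg)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin(samples: PosteriorSamples) -> dict:
    """Potential-scale-reduction summary per block.

    Uses ``R = sqrt(1 + B / (n W))`` with ``W`` the mean within-chain variance
    and ``B/n`` the variance of chain means: a monotone variant of the
    classical statistic that is exactly 1 for identical chains and grows
    without bound as chains separate.  Returns ``{block: array}`` with one
    value per scalar element of the block.
    """
    if samples.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    out = {}
    for name, v in samples.draws.items():
        nc, nd = v.shape[0], v.shape[1]
        flat = v.reshape(nc, nd, -1).astype(float)
        w = flat.var(axis=1, ddof=1).mean(axis=0)
        b_over_n = flat.mean(axis=1).var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.sqrt(1.0 + np.where(w > 0, b_over_n / w, np.where(b_over_n > 0, np.inf, 0.0)))
        out[name] = r.reshape(v.shape[2:]) if v.ndim > 2 else float(r[0])
    return out
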