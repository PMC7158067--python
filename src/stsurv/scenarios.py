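"""Synthetic surveillance scenarios with known ground truth.

Generates replicate area x time count panels mimicking monthly small-area
hospital-admission data: a smooth spatiotemporal Poisson baseline
``y_it ~ Poisson(E_it * rho_it)`` with

    log rho_it = alpha + theta_i + phi_i + gamma_t + psi_it

(theta spatially structured via the ICAR model, gamma a first-order random
walk, phi and psi exchangeable noise), on top of which a chosen set of
"unusual" areas receives signed log-risk shifts at scheduled time points.
The default configuration is the benchmark scenario used throughout the
package: 211 areas, 15 monthly time points, 15 unusual areas whose risk is
doubled (+log 2) at time points 3 and 10 and halved (-log 2) at 6, 12 and 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graphs import AreaGraph, build_random_planar_graph


@dataclass(frozen=True)
class CountPanel:
    """Observed and expected counts on an area x time grid.

    ``y`` holds nonnegative integer observed counts, ``E`` strictly positive
    expected counts (the Poisson offset); both have shape
    ``(n_areas, n_times)``.
    """

    y: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        E = np.asarray(self.E, dtype=float)
        if y.shape != E.shape or y.ndim != 2:
            raise ValueError(f"y {y.shape} and E {E.shape} must share a 2-d shape")
        if np.any(E <= 0):
            raise ValueError("all expected counts must be strictly positive")
        if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer):
            raise ValueError("observed counts must be nonnegative integers")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "E", E)

    @property
    def n_areas(self) -> int:
        return self.y.shape[0]

    @property
    def n_times(self) -> int:
        return self.y.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format with columns area, time (1-based), observed, expected."""
        areas, times = np.meshgrid(
            np.arange(self.n_areas), np.arange(1, self.n_times + 1), indexing="ij"
        )
        return pd.DataFrame(
            {
                "area": areas.ravel(),
                "time": times.ravel(),
                "observed": self.y.ravel(),
                "expected": self.E.ravel(),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountPanel":
        """Inverse of :meth:`to_dataframe`; times may start at 0 or 1."""
        areas = np.sort(df["area"].unique())
        times = np.sort(df["time"].unique())
        piv_y = df.pivot(index="area", columns="time", values="observed")
        piv_e = df.pivot(index="area", columns="time", values="expected")
        piv_y = piv_y.loc[areas, times]
        piv_e = piv_e.loc[areas, times]
        return cls(y=piv_y.to_numpy().astype(int), E=piv_e.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CountPanel":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass(frozen=True)
class LatentSurface:
    """Latent components of the log relative-risk surface."""

    alpha: float
    theta: np.ndarray  # per-area, spatially structured (ICAR)
    phi: np.ndarray  # per-area, unstructured
    gamma: np.ndarray  # per-time trend (RW1)
    psi: np.ndarray  # area x time interaction

    @property
    def log_rr(self) -> np.ndarray:
        return (
            self.alpha
            + self.theta[:, None]
            + self.phi[:, None]
            + self.gamma[None, :]
            + self.psi
        )


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground-truth labels for one replicate."""

    unusual_areas: frozenset
    signal_schedule: dict  # 1-based time index -> signed log-risk offset
    per_unit_offset: np.ndarray  # area x time

    @property
    def n_areas(self) -> int:
        return self.per_unit_offset.shape[0]

    def labels(self) -> np.ndarray:
        """Boolean per-area vector, True for unusual areas."""
        lab = np.zeros(self.n_areas, dtype=bool)
        lab[list(self.unusual_areas)] = True
        return lab

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"area": np.arange(self.n_areas), "is_unusual": self.labels()}
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated scenario.

    Time indices in ``up_times``/``down_times`` are 1-based to match the
    conventional "time point 3" phrasing; they are converted internally.
    Standard deviations are on the log relative-risk scale.
    """

    n_areas: int = 211
    n_times: int = 15
    n_unusual: int = 15
    signal_magnitude: float = float(np.log(2.0))
    up_times: frozenset = frozenset({3, 10})
    down_times: frozenset = frozenset({6, 12, 15})
    alpha0: float = 0.0
    sd_spatial: float = 0.2
    sd_temporal: float = 0.15
    sd_unstructured: float = 0.05
    sd_interaction: float = 0.05
    expected_range: tuple = (20.0, 60.0)

    def __post_init__(self) -> None:
        if self.up_times & self.down_times:
            raise ValueError("up_times and down_times must be disjoint")
        sched = self.up_times | self.down_times
        if sched and (max(sched) > self.n_times or min(sched) < 1):
            raise ValueError("scheduled times must lie in 1..n_times")
        if self.n_unusual > self.n_areas:
            raise ValueError("n_unusual cannot exceed n_areas")

    @property
    def signal_schedule(self) -> dict:
        sched = {t: self.signal_magnitude for t in sorted(self.up_times)}
        sched.update({t: -self.signal_magnitude for t in sorted(self.down_times)})
        return dict(sorted(sched.items()))


def _icar_sample(graph: AreaGraph, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from the intrinsic CAR model with conditional scale ``sd``.

    The ICAR density is proper only on the subspace orthogonal to the
    component-wise constants; sampling uses the Laplacian eigenbasis with the
    zero eigenvalues removed, which enforces sum-to-zero per component.
    """
    if sd == 0.0:
        return np.zeros(graph.n_areas)
    lap = graph.laplacian().toarray()
    evals, evecs = np.linalg.eigh(lap)
    keep = evals > 1e-9
    z = rng.standard_normal(keep.sum())
    theta = evecs[:, keep] @ (z * sd / np.sqrt(evals[keep]))
    for comp in graph.components():
        theta[comp] -= theta[comp].mean()
    return theta


def generate_baseline(
    config: ScenarioConfig, graph: AreaGraph, seed: int
) -> LatentSurface:
    """Simulate the smooth spatiotemporal baseline surface (no signals).

    theta ~ ICAR(sd_spatial) gauge-fixed to sum to zero per component;
    gamma is a first-order random walk with increment sd ``sd_temporal``,
    centred to sum to zero; phi and psi are iid zero-mean normals.
    Deterministic given ``seed``.
    """
    if graph.n_areas != config.n_areas:
        raise ValueError(
            f"graph has {graph.n_areas} areas, config expects {config.n_areas}"
        )
    rng = np.random.default_rng(seed)
    theta = _icar_sample(graph, config.sd_spatial, rng)
    increments = rng.standard_normal(config.n_times - 1) * config.sd_temporal
    gamma = np.concatenate([[0.0], np.cumsum(increments)])
    gamma -= gamma.mean()
    phi = rng.standard_normal(config.n_areas) * config.sd_unstructured
    psi = (
        rng.standard_normal((config.n_areas, config.n_times)) * config.sd_interaction
    )
    return LatentSurface(
        alpha=config.alpha0, theta=theta, phi=phi, gamma=gamma, psi=psi
    )


def inject_signals(
    surface: LatentSurface, config: ScenarioConfig, seed: int
) -> tuple[LatentSurface, ScenarioTruth]:
    """Add the scheduled +/- signal to ``n_unusual`` randomly chosen areas.

    Chosen areas gain ``+signal_magnitude`` on the log-risk at each up time
    and ``-signal_magnitude`` at each down time; all other units are
    untouched.  Returns the modified surface and the truth labels.
    """
    n_areas, n_times = surface.psi.shape
    if config.n_unusual > n_areas:
        raise ValueError("n_unusual cannot exceed n_areas")
    rng = np.random.default_rng(seed)
    unusual = rng.choice(n_areas, size=config.n_unusual, replace=False)
    offset = np.zeros((n_areas, n_times))
    for t1, delta in config.signal_schedule.items():
        offset[unusual, t1 - 1] = delta
    truth = ScenarioTruth(
        unusual_areas=frozenset(int(u) for u in unusual),
        signal_schedule=config.signal_schedule,
        per_unit_offset=offset,
    )
    shifted = replace(surface, psi=surface.psi + offset)
    return shifted, truth


def sample_counts(surface: LatentSurface, E, seed: int) -> CountPanel:
    """Draw ``y_it ~ Poisson(E_it * exp(log_rr_it))`` independently."""
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("all expected counts must be strictly positive")
    if E.shape != surface.psi.shape:
        raise ValueError(f"E has shape {E.shape}, expected {surface.psi.shape}")
    rng = np.random.default_rng(seed)
    y = rng.poisson(E * np.exp(surface.log_rr))
    return CountPanel(y=y, E=E)


def make_scenario(
    config: ScenarioConfig, seed: int, graph: AreaGraph | None = None
) -> tuple[CountPanel, ScenarioTruth, AreaGraph]:
    """One replicate dataset under ``config``.

    Expected counts are drawn once per area, uniform on
    ``config.expected_range``, and held constant over time.  The master seed
    spawns independent substreams for the graph, baseline, signal placement,
    expected counts and count noise, so replicates with different seeds are
    independently reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_graph, s_base, s_sig, s_exp, s_count = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]
    if graph is None:
        graph = build_random_planar_graph(config.n_areas, seed=s_graph)
    surface = generate_baseline(config, graph, seed=s_base)
    surface, truth = inject_signals(surface, config, seed=s_sig)
    rng = np.random.default_rng(s_exp)
    lo, hi = config.expected_range
    E = np.repeat(rng.uniform(lo, hi, size=config.n_areas)[:, None], config.n_times, 1)
    panel = sample_counts(surface, E, seed=s_count)
    return panel, truth, graph


def make_scenario1(seed: int) -> tuple[CountPanel, ScenarioTruth, AreaGraph]:
    """The default benchmark replicate: 211 areas x 15 time points, 15 unusual
    areas with +log 2 at time points 3 and 10 and -log 2 at 6, 12 and 15."""
    return make_scenario(ScenarioConfig(), seed)
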