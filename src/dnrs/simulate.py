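"""Stochastic regulatory-network simulator with a controlled tipping point.

The canonical fixture is an 18-node gene regulatory network in
Michaelis-Menten/Hill form driven by additive white noise,

    dx_i = [ sum_act  b_ij x_j^h / (Km^h + x_j^h)
           + sum_rep  b_ij Km^h / (Km^h + x_j^h)
           - g_i x_i + c_i + coupling_i * s ] dt + sigma dW_i,

integrated by Euler-Maruyama and clipped at 0.  Six nodes form the DNB
(dynamic network biomarker) block: they activate one another (and
themselves) symmetrically and their basal production is shifted by the
bifurcation parameter s.  The block's basal rate is placed exactly at
the saddle-node (fold) value for s = 0, so for s < 0 the block relaxes
around a low-expression state whose restoring rate vanishes as s -> 0-
(variance and intra-block correlation rise - the DNB signature), and at
s >= 0 the low state no longer exists and the block transits to a high
state.  The remaining 12 nodes form a weakly coupled ring far from any
bifurcation, so their statistics are flat in s.

Each "cell" is an independent noise realization observed after a fixed
burn-in, matching the use of many cells/samples per time point.  The
companion Ornstein-Uhlenbeck surrogate replaces the nonlinear block with
a linear mean-reverting process whose stationary moments are closed form
(variance sigma^2 / (2 lambda(s))), for exact assertions the nonlinear
system cannot support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .io import ExpressionMatrix, PPINetwork, StageSeries

logger = logging.getLogger("dnrs")

__all__ = [
    "RegulatoryNetworkSpec",
    "SweepConfig",
    "GroundTruth",
    "canonical_network",
    "default_s_grid",
    "drift",
    "simulate_stage",
    "generate_sweep",
    "generate_ou_surrogate",
]

BLOWUP_CAP = 1e6


@dataclass(frozen=True)
class RegulatoryNetworkSpec:
    """Topology and kinetic coefficients of the simulated network."""

    node_ids: tuple[str, ...]
    activations: tuple[tuple[str, str, float], ...]  # (source, target, rate)
    repressions: tuple[tuple[str, str, float], ...]
    dnb_members: tuple[str, ...]
    hill_coefficient: float = 2.0
    michaelis_constant: float = 8.0
    degradation_rates: tuple[float, ...] = ()
    basal_rates: tuple[float, ...] = ()
    dnb_coupling: float = 0.8
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node ids")
        dnb = set(self.dnb_members)
        if not dnb or not dnb < set(self.node_ids):
            raise ValueError("dnb_members must be a nonempty proper subset of nodes")
        if self.hill_coefficient <= 0 or self.michaelis_constant <= 0:
            raise ValueError("hill and Michaelis constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        deg = self.degradation_rates or tuple([1.0] * n)
        bas = self.basal_rates or tuple([0.0] * n)
        if len(deg) != n or len(bas) != n:
            raise ValueError("per-node rate vectors must match node count")
        if any(g <= 0 for g in deg):
            raise ValueError("degradation rates must be positive")
        object.__setattr__(self, "degradation_rates", tuple(deg))
        object.__setattr__(self, "basal_rates", tuple(bas))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def ppi_skeleton(self) -> PPINetwork:
        """Undirected PPI scaffold: the regulation pairs, self-edges dropped."""
        return PPINetwork.from_pairs(
            [(a, b) for a, b, _ in self.activations + self.repressions if a != b]
        )


@dataclass(frozen=True)
class GroundTruth:
    """Engineered truth of a sweep: where the fold sits and who the DNB are."""

    bifurcation_index: int
    bifurcation_s: float
    dnb_members: tuple[str, ...]


def default_s_grid() -> tuple[float, ...]:
    """Bifurcation-parameter grid -0.5 ... 0.15 in steps of 0.05 (fold at 0)."""
    return tuple(np.round(np.arange(-0.5, 0.1501, 0.05), 10))


@dataclass(frozen=True)
class SweepConfig:
    """Stage-sweep settings: grid, cells per stage, trials, integration."""

    s_grid: tuple[float, ...] = field(default_factory=default_s_grid)
    n_cells_per_stage: int = 100
    n_trials: int = 50
    dt: float = 0.01
    burn_in: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        g = np.asarray(self.s_grid, dtype=float)
        if len(g) < 2 or np.any(np.diff(g) <= 0):
            raise ValueError("s_grid must be strictly increasing with >= 2 values")
        if not (g[0] < 0 <= g[-1]):
            raise ValueError("s_grid must contain a value < 0 and a value >= 0")
        if self.n_cells_per_stage < 1 or self.n_trials < 1:
            raise ValueError("n_cells_per_stage and n_trials must be >= 1")
        if self.dt <= 0 or self.burn_in <= 0:
            raise ValueError("dt and burn_in must be positive")


# ---------------------------------------------------------------------------
# Canonical 18-node fixture
# ---------------------------------------------------------------------------

def _fold_basal(block_gain: float, km: float) -> float:
    """Basal rate placing the DNB block's saddle-node exactly at s = 0.

    On the synchronized manifold z = x/Km the block obeys
    z' = g z^2/(1+z^2) - z + b/Km with reduced gain g = block_gain/Km;
    the fold condition is tangency: 2 g z = (1+z^2)^2 at the low knee.
    """
    g = block_gain / km
    z_star = brentq(lambda z: (1 + z * z) ** 2 - 2 * g * z, 1e-3, 1.0)
    return km * (z_star - g * z_star**2 / (1 + z_star**2))


def canonical_network() -> RegulatoryNetworkSpec:
    """The reference 18-node fixture with a 6-node DNB block, fold at s = 0.

    DNB nodes G01-G06 activate each other and themselves with total gain
    32 split evenly; their basal rate sits at the fold value for s = 0 and
    the bifurcation parameter enters as +0.8*s.  Non-DNB nodes G07-G18
    form an activation ring plus four weak DNB-to-ring links (so the
    scaffold is connected); no edge feeds back into the DNB block, which
    keeps the fold location exact.
    """
    nodes = tuple(f"G{i + 1:02d}" for i in range(18))
    dnb = nodes[:6]
    ring = nodes[6:]
    block_gain, km = 32.0, 8.0
    acts: list[tuple[str, str, float]] = []
    for src in dnb:
        for dst in dnb:
            acts.append((src, dst, block_gain / len(dnb)))
    for i, dst in enumerate(ring):
        acts.append((ring[i - 1], dst, 4.0))
    acts += [("G01", "G07", 1.0), ("G05", "G13", 1.0)]
    reps = [("G03", "G10", 1.0), ("G06", "G16", 1.0)]
    b_star = _fold_basal(block_gain, km)
    basal = tuple([b_star] * 6 + [1.0] * 12)
    return RegulatoryNetworkSpec(
        node_ids=nodes,
        activations=tuple(acts),
        repressions=tuple(reps),
        dnb_members=dnb,
        hill_coefficient=2.0,
        michaelis_constant=km,
        basal_rates=basal,
        dnb_coupling=0.8,
        noise_sd=0.05,
    )


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def _weight_matrices(spec: RegulatoryNetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    n = spec.n_nodes
    idx = {g: i for i, g in enumerate(spec.node_ids)}
    wa = np.zeros((n, n))
    wr = np.zeros((n, n))
    for src, dst, beta in spec.activations:
        if beta < 0:
            raise ValueError("activation rates must be nonnegative")
        wa[idx[dst], idx[src]] += beta
    for src, dst, beta in spec.repressions:
        if beta < 0:
            raise ValueError("repression rates must be nonnegative")
        wr[idx[dst], idx[src]] += beta
    return wa, wr


def drift(spec: RegulatoryNetworkSpec, x: np.ndarray, s: float) -> np.ndarray:
    """Deterministic drift field; ``x`` is (cells, nodes) or (nodes,)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    wa, wr = _weight_matrices(spec)
    return _drift_precomputed(spec, x, s, wa.T, wr.T)


def _drift_precomputed(spec, x, s, wa_t, wr_t):
    kmh = spec.michaelis_constant ** spec.hill_coefficient
    xh = np.maximum(x, 0.0) ** spec.hill_coefficient
    act = (xh / (kmh + xh)) @ wa_t
    rep = (kmh / (kmh + xh)) @ wr_t
    gamma = np.asarray(spec.degradation_rates)
    basal = np.asarray(spec.basal_rates)
    coupling = np.array(
        [spec.dnb_coupling if g in spec.dnb_members else 0.0 for g in spec.node_ids]
    )
    return act + rep - gamma * x + basal + coupling * s


def simulate_stage(
    spec: RegulatoryNetworkSpec,
    s: float,
    n_cells: int,
    dt: float = 0.01,
    burn_in: float = 50.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    stage_label: str | None = None,
) -> ExpressionMatrix:
    """Euler-Maruyama snapshots of ``n_cells`` independent realizations.

    Every cell starts at x = 1, integrates for ``burn_in`` time units
    with step ``dt`` and is observed once; values are clipped at 0.  A
    trajectory exceeding |x| = 1e6 aborts with advice to reduce ``dt``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    wa, wr = _weight_matrices(spec)
    wa_t, wr_t = wa.T.copy(), wr.T.copy()
    n_steps = max(1, round(burn_in / dt))
    x = np.ones((n_cells, spec.n_nodes))
    sig = spec.noise_sd * math.sqrt(dt)
    for step in range(n_steps):
        x += dt * _drift_precomputed(spec, x, s, wa_t, wr_t)
        if sig > 0.0:
            x += sig * rng.standard_normal(x.shape)
        np.clip(x, 0.0, None, out=x)
        if step % 100 == 0 and np.max(x) > BLOWUP_CAP:
            raise RuntimeError(
                f"simulation blow-up at s={s} (|x| > {BLOWUP_CAP:g}); "
                "use a smaller dt"
            )
    if np.max(x) > BLOWUP_CAP:
        raise RuntimeError(
            f"simulation blow-up at s={s} (|x| > {BLOWUP_CAP:g}); use a smaller dt"
        )
    return ExpressionMatrix(
        list(spec.node_ids), x.T, stage_label or f"s{s:+.2f}"
    )


def generate_sweep(
    spec: RegulatoryNetworkSpec, cfg: SweepConfig
) -> tuple[StageSeries, PPINetwork, GroundTruth]:
    """One stochastic trial: a stage per grid value, plus scaffold and truth.

    All stages of the trial are integrated in one batched Euler-Maruyama
    pass (cells are independent, so stages can share the step loop); the
    ground-truth bifurcation index is the grid position closest to the
    engineered fold at s = 0.
    """
    rng = np.random.default_rng(cfg.seed)
    n_c = cfg.n_cells_per_stage
    s_row = np.repeat(np.asarray(cfg.s_grid, dtype=float), n_c)
    wa, wr = _weight_matrices(spec)
    wa_t, wr_t = wa.T.copy(), wr.T.copy()
    kmh = spec.michaelis_constant ** spec.hill_coefficient
    gamma = np.asarray(spec.degradation_rates)
    basal = np.asarray(spec.basal_rates)
    coupling = np.array(
        [spec.dnb_coupling if g in spec.dnb_members else 0.0 for g in spec.node_ids]
    )
    shift = basal[None, :] + s_row[:, None] * coupling[None, :]
    n_steps = max(1, round(cfg.burn_in / cfg.dt))
    sig = spec.noise_sd * math.sqrt(cfg.dt)
    x = np.ones((len(s_row), spec.n_nodes))
    square = spec.hill_coefficient == 2.0
    for step in range(n_steps):
        xh = x * x if square else x ** spec.hill_coefficient
        sat = xh / (kmh + xh)
        x += cfg.dt * (
            sat @ wa_t + (1.0 - sat) @ wr_t - gamma * x + shift
        )
        if sig > 0.0:
            x += sig * rng.standard_normal(x.shape)
        np.clip(x, 0.0, None, out=x)
        if step % 200 == 0 and np.max(x) > BLOWUP_CAP:
            raise RuntimeError(
                f"simulation blow-up (|x| > {BLOWUP_CAP:g}); use a smaller dt"
            )
    stages = [
        ExpressionMatrix(
            list(spec.node_ids), x[i * n_c: (i + 1) * n_c].T, f"s{s:+.2f}"
        )
        for i, s in enumerate(cfg.s_grid)
    ]
    series = StageSeries(stages)
    grid = np.asarray(cfg.s_grid, dtype=float)
    b_idx = int(np.argmin(np.abs(grid)))
    truth = GroundTruth(b_idx, float(grid[b_idx]), tuple(spec.dnb_members))
    return series, spec.ppi_skeleton(), truth


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck surrogate
# ---------------------------------------------------------------------------

def generate_ou_surrogate(
    n_nodes: int,
    dnb_members: Sequence[int],
    lambda_of_s: Callable[[float], float],
    cfg: SweepConfig,
    noise_sd: float = 0.05,
    baseline: float = 1.0,
) -> tuple[StageSeries, PPINetwork, GroundTruth]:
    """Linear OU test bed sampled exactly from its stationary law.

    DNB nodes (given by index) revert with rate lambda(s) and therefore
    have stationary variance sigma^2 / (2 lambda(s)); the remaining nodes
    revert with rate 1 independent of s (variance sigma^2/2).  No
    integration error: cells are drawn directly from the stationary
    normal distribution.  The scaffold is a complete graph on the DNB
    block, a ring on the rest, and one bridging edge.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    dnb_idx = sorted(set(int(i) for i in dnb_members))
    if not dnb_idx or len(dnb_idx) >= n_nodes or min(dnb_idx) < 0:
        raise ValueError("dnb_members must be a nonempty proper subset of node indices")
    nodes = [f"G{i + 1:02d}" for i in range(n_nodes)]
    rng = np.random.default_rng(cfg.seed)
    sds = np.full(n_nodes, noise_sd / math.sqrt(2.0))
    stages = []
    for s in cfg.s_grid:
        lam = float(lambda_of_s(float(s)))
        if lam <= 0:
            raise ValueError(f"decay rate must be positive, got {lam} at s={s}")
        stage_sd = sds.copy()
        stage_sd[dnb_idx] = noise_sd / math.sqrt(2.0 * lam)
        x = baseline + stage_sd[:, None] * rng.standard_normal(
            (n_nodes, cfg.n_cells_per_stage)
        )
        stages.append(ExpressionMatrix(nodes, x, f"s{s:+.2f}"))
    series = StageSeries(stages)
    non_dnb = [i for i in range(n_nodes) if i not in dnb_idx]
    pairs = [
        (nodes[a], nodes[b])
        for i, a in enumerate(dnb_idx)
        for b in dnb_idx[i + 1:]
    ]
    pairs += [
        (nodes[non_dnb[i - 1]], nodes[j]) for i, j in enumerate(non_dnb)
    ]
    pairs.append((nodes[dnb_idx[0]], nodes[non_dnb[0]]))
    grid = np.asarray(cfg.s_grid, dtype=float)
    b_idx = int(np.argmin(np.abs(grid)))
    truth = GroundTruth(b_idx, float(grid[b_idx]), tuple(nodes[i] for i in dnb_idx))
    return series, PPINetwork.from_pairs(pairs), truth
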