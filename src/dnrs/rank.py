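"""Personalized-PageRank rank engine.

From the directed stage network N(T) a transition system (H, d, tau) is
built:

* H — K x K row-normalized weight matrix: H_ij = w_ij / sum_j w_ij for
  rows with positive outgoing weight.
* d — dangling indicator, d_i = 1 iff node i has no positive outgoing
  weight.
* tau — personalization vector: per-gene standard deviation over the N
  stage-T observations, normalized to sum 1, so teleportation is biased
  toward high-variance genes.

The local score vector s* is the fixed point of

    s(l+1) = alpha * H' s(l) + alpha * (d . s(l)) * tau + (1 - alpha) * tau

By default dangling rows are all-zero in H and their rank mass is
redistributed solely through the (d . s) tau term; this is the unique
reading under which s* stays a probability vector and the iteration
reduces to classical PageRank when d = 0 and tau is uniform.  The
alternative that places a unit self-loop on dangling rows (and therefore
needs per-iterate renormalization, since the dangling mass is counted
twice) is available as ``dangling="selfloop-renormalize"``.

The global score PR(T) is the mean of the top-Q local scores divided by
the overall mean score, with Q the number of top-5% genes; the top-Q
genes are the stage's signaling (candidate biomarker) genes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import ExpressionMatrix, PPINetwork, StageSeries
from .network import DirectedStageNetwork, build_stage_network

logger = logging.getLogger("dnrs")

__all__ = [
    "TransitionSystem",
    "RankResult",
    "build_transition_system",
    "personalized_pagerank",
    "classical_pagerank",
    "global_dnrs",
    "stage_rank",
    "random_transition_system",
]

DANGLING_MODES = ("redistribute", "selfloop-renormalize")


@dataclass
class TransitionSystem:
    """Row-(sub)stochastic transition matrix with dangling and teleport data."""

    H: sp.csr_matrix
    d: np.ndarray
    tau: np.ndarray
    alpha: float = 0.85
    gene_ids: list[str] | None = None
    dangling: str = "redistribute"

    def __post_init__(self) -> None:
        self.H = sp.csr_matrix(self.H, dtype=float)
        self.d = np.asarray(self.d, dtype=float).ravel()
        self.tau = np.asarray(self.tau, dtype=float).ravel()
        k = self.H.shape[0]
        if self.H.shape != (k, k) or len(self.d) != k or len(self.tau) != k:
            raise ValueError("H, d, tau dimensions disagree")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.dangling not in DANGLING_MODES:
            raise ValueError(f"dangling must be one of {DANGLING_MODES}")
        if np.any(self.tau < 0) or not math.isclose(
            float(self.tau.sum()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("tau must be nonnegative and sum to 1")

    @property
    def k(self) -> int:
        return self.H.shape[0]

    def validate_rows(self, tol: float = 1e-12) -> None:
        """Check the row-sum/dangling invariants (used by tests and callers)."""
        rowsum = np.asarray(self.H.sum(axis=1)).ravel()
        dang = self.d.astype(bool)
        if self.dangling == "redistribute":
            if np.any(np.abs(rowsum[~dang] - 1.0) > max(tol, 1e-12)):
                raise ValueError("non-dangling rows of H must sum to 1")
            if np.any(rowsum[dang] != 0.0):
                raise ValueError("dangling rows of H must be all-zero")
        else:
            if np.any(np.abs(rowsum - 1.0) > max(tol, 1e-12)):
                raise ValueError("all rows of H must sum to 1 in self-loop mode")


@dataclass
class RankResult:
    """Local scores s*, global score PR(T) and signaling genes for one stage."""

    stage_label: str
    gene_ids: list[str]
    s_star: np.ndarray
    pr: float
    q: int
    signaling_genes: list[str]
    n_iter: int
    residual: float
    n_edges: int = 0


def build_transition_system(
    net: DirectedStageNetwork,
    expr_T: ExpressionMatrix,
    alpha: float = 0.85,
    dangling: str = "redistribute",
) -> TransitionSystem:
    """Assemble H, d and tau from a stage network and the stage-T matrix."""
    if net.gene_ids != expr_T.gene_ids:
        raise ValueError("network and stage-T expression gene universes differ")
    k = len(net.gene_ids)
    index = {g: i for i, g in enumerate(net.gene_ids)}
    rows, cols, vals = [], [], []
    for u, v, data in net.graph.edges(data=True):
        rows.append(index[u])
        cols.append(index[v])
        vals.append(float(data["w"]))
    W = sp.csr_matrix((vals, (rows, cols)), shape=(k, k))
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    d = (rowsum == 0.0).astype(float)
    inv = np.where(rowsum > 0, 1.0 / np.where(rowsum > 0, rowsum, 1.0), 0.0)
    H = sp.diags(inv) @ W
    if dangling == "selfloop-renormalize":
        H = H.tolil()
        for i in np.flatnonzero(d):
            H[i, i] = 1.0
        H = H.tocsr()
    elif dangling != "redistribute":
        raise ValueError(f"dangling must be one of {DANGLING_MODES}")

    tau = np.std(expr_T.values, axis=1)
    total = float(tau.sum())
    if total == 0.0:
        warnings.warn(
            "all genes constant at stage "
            f"{expr_T.stage_label!r}; using uniform personalization",
            stacklevel=2,
        )
        tau = np.full(k, 1.0 / k)
    else:
        tau = tau / total
    return TransitionSystem(H, d, tau, alpha, list(net.gene_ids), dangling)


def personalized_pagerank(
    ts: TransitionSystem,
    tol: float = 1e-12,
    max_iter: int = 10000,
    return_info: bool = False,
):
    """Power-iterate the personalized PageRank to its fixed point.

    Starts from s(0) = tau and stops when the L1 change drops below
    ``tol``; raises RuntimeError (carrying the residual) if ``max_iter``
    is exhausted first.  The result is nonnegative and sums to 1.
    """
    alpha, tau, d = ts.alpha, ts.tau, ts.d
    HT = ts.H.T.tocsr()
    s = tau.copy()
    if ts.dangling == "selfloop-renormalize":
        s = s / s.sum() if s.sum() else np.full(ts.k, 1.0 / ts.k)
    residual = math.inf
    for it in range(1, max_iter + 1):
        s_new = alpha * (HT @ s) + alpha * float(d @ s) * tau + (1.0 - alpha) * tau
        if ts.dangling == "selfloop-renormalize":
            s_new = s_new / s_new.sum()
        residual = float(np.abs(s_new - s).sum())
        s = s_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"personalized PageRank did not converge in {max_iter} iterations "
            f"(L1 residual {residual:.3e})"
        )
    if return_info:
        return s, it, residual
    return s


def classical_pagerank(
    adjacency: np.ndarray,
    alpha: float = 0.85,
    tol: float = 1e-12,
    max_iter: int = 10000,
) -> np.ndarray:
    """Reference classical PageRank on an unweighted adjacency matrix.

    Row i of the transition matrix A is 1/outdeg(i) on its successors, or
    a unit self-loop when node i has no successors; the iteration is
    s(l+1) = alpha * A' s(l) + (1 - alpha)/K, from the uniform vector.
    Kept as an independent limit-case reference for the personalized
    iteration (d = 0, uniform tau).
    """
    A = np.asarray(adjacency, dtype=float)
    k = A.shape[0]
    if A.shape != (k, k):
        raise ValueError("adjacency must be square")
    A = (A != 0).astype(float)
    out = A.sum(axis=1)
    T = np.zeros_like(A)
    for i in range(k):
        if out[i] > 0:
            T[i] = A[i] / out[i]
        else:
            T[i, i] = 1.0
    s = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        s_new = alpha * (T.T @ s) + (1.0 - alpha) / k
        if float(np.abs(s_new - s).sum()) < tol:
            return s_new
        s = s_new
    raise RuntimeError(f"classical PageRank did not converge in {max_iter} iterations")


def global_dnrs(
    s_star: np.ndarray,
    fraction: float = 0.05,
    gene_ids: list[str] | None = None,
) -> tuple[float, int, list[str]]:
    """Global score: top-Q mean over overall mean, Q = max(1, ceil(f*K)).

    Ties at the Q-th rank are broken lexicographically by gene id so the
    signaling set is byte-reproducible.  Returns (pr, Q, top gene ids).
    """
    s = np.asarray(s_star, dtype=float).ravel()
    k = len(s)
    if k == 0:
        raise ValueError("empty score vector")
    if not 0.0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    ids = gene_ids if gene_ids is not None else [str(i) for i in range(k)]
    if len(ids) != k:
        raise ValueError("gene_ids length mismatch")
    q = max(1, math.ceil(fraction * k))
    order = sorted(range(k), key=lambda i: (-s[i], ids[i]))
    top = order[:q]
    mean_all = float(s.mean())
    if mean_all == 0.0:
        raise ValueError("score vector sums to 0")
    pr = float(s[top].mean()) / mean_all
    return pr, q, [ids[i] for i in top]


def stage_rank(
    series: StageSeries,
    ppi: PPINetwork,
    stage_index: int,
    alpha: float = 0.85,
    fraction: float = 0.05,
    method: str = "gaussian",
    bins: int | None = None,
    tol: float = 1e-12,
    max_iter: int = 10000,
    dangling: str = "redistribute",
) -> RankResult:
    """Full per-stage scoring: network -> transition system -> s* -> PR(T)."""
    net = build_stage_network(series, ppi, stage_index, method, bins)
    ts = build_transition_system(net, series[stage_index], alpha, dangling)
    s_star, n_iter, residual = personalized_pagerank(
        ts, tol=tol, max_iter=max_iter, return_info=True
    )
    pr, q, top = global_dnrs(s_star, fraction, list(series.gene_ids))
    return RankResult(
        stage_label=series[stage_index].stage_label,
        gene_ids=list(series.gene_ids),
        s_star=s_star,
        pr=pr,
        q=q,
        signaling_genes=top,
        n_iter=n_iter,
        residual=residual,
        n_edges=net.n_edges,
    )


def random_transition_system(
    rng: np.random.Generator,
    k_max: int = 50,
    alpha: float = 0.85,
    dangling_fraction: float = 0.3,
) -> TransitionSystem:
    """Random valid TransitionSystem for oracle-based validation runs."""
    k = int(rng.integers(2, k_max + 1))
    dense = rng.random((k, k)) * (rng.random((k, k)) < 0.4)
    np.fill_diagonal(dense, 0.0)
    dang = rng.random(k) < dangling_fraction
    dense[dang] = 0.0
    rowsum = dense.sum(axis=1)
    dang = rowsum == 0.0
    H = np.zeros_like(dense)
    H[~dang] = dense[~dang] / rowsum[~dang, None]
    tau = rng.random(k) + 1e-3
    tau /= tau.sum()
    return TransitionSystem(sp.csr_matrix(H), dang.astype(float), tau, alpha)
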