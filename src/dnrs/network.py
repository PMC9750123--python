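"""Edge orientation and time-specific directed network construction.

For each unordered PPI pair {gi, gj} and each ordered direction, the
direction determination index w quantifies how much averaging gene gj's
profile into gi's improves the association with the binary stage label y
(0 for the earlier stage T-1, 1 for stage T).  With X = U (gi's pooled
profile) and Xhat = (U + V)/2:

    MI form:        w = MI(Xhat; y) - MI(X; y)          (nats)
    Gaussian form:  w = -1/2 * log[(1 - r_hat^2) / (1 - r^2)]

where r_hat = PCC(Xhat, y) and r = PCC(X, y).  The Gaussian form is the
closed-form equivalent under Gaussian/binomial marginals and is the
default.  A directed edge gi -> gj exists in the stage network N(T) iff
w > 0 (and w is well defined).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.metrics import mutual_info_score

from .io import PhenotypeLabel, PPINetwork, StageSeries

logger = logging.getLogger("dnrs")

__all__ = [
    "pcc",
    "direction_index_gaussian",
    "direction_index_mi",
    "default_bins",
    "DirectedStageNetwork",
    "build_stage_network",
    "export_network",
]


def pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation; NaN sentinel if either input is constant.

    The sentinel (rather than an exception) lets callers apply the
    degenerate-pair rule of the network construction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    na = math.sqrt(float(da @ da))
    nb = math.sqrt(float(db @ db))
    if na == 0.0 or nb == 0.0:
        return float("nan")
    r = float(da @ db) / (na * nb)
    return min(1.0, max(-1.0, r))


def _check_pair(u: np.ndarray, v: np.ndarray, y: PhenotypeLabel | np.ndarray):
    if isinstance(y, PhenotypeLabel):
        y = y.y
    else:
        y = PhenotypeLabel(np.asarray(y)).y
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (u.shape == v.shape == y.shape):
        raise ValueError(
            f"u, v, y must share one length; got {u.shape}, {v.shape}, {y.shape}"
        )
    return u, v, y


def direction_index_gaussian(
    u: np.ndarray, v: np.ndarray, y: PhenotypeLabel | np.ndarray
) -> float:
    """Closed-form direction index -1/2 log[(1-r_hat^2)/(1-r^2)].

    Returns NaN (the degenerate sentinel, meaning "no directed edge") when
    either correlation is undefined (zero-variance input) or |r| = 1 makes
    the log ratio infinite.  Identical u and v give exactly 0.
    """
    u, v, y = _check_pair(u, v, y)
    r_hat = pcc((u + v) / 2.0, y)
    r = pcc(u, y)
    if math.isnan(r_hat) or math.isnan(r):
        return float("nan")
    num = 1.0 - r_hat * r_hat
    den = 1.0 - r * r
    if num <= 0.0 or den <= 0.0:
        return float("nan")
    if num == den:  # covers v == u bit-for-bit
        return 0.0
    return -0.5 * math.log(num / den)


def default_bins(n: int) -> int:
    """Default equal-frequency bin count ceil(sqrt(n)) for the MI estimator."""
    return max(2, math.ceil(math.sqrt(n)))


def _equal_frequency_labels(x: np.ndarray, bins: int) -> np.ndarray:
    # interior quantile cut points; duplicates collapse for tied data
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="left")


def direction_index_mi(
    u: np.ndarray,
    v: np.ndarray,
    y: PhenotypeLabel | np.ndarray,
    bins: int | None = None,
) -> float:
    """Plug-in mutual-information direction index MI(Xhat;y) - MI(X;y).

    Continuous profiles are discretized by equal-frequency binning
    (``bins`` defaults to ceil(sqrt(n))); MI is the plug-in estimate
    against the binary label, in nats, with 0*log 0 := 0.
    """
    u, v, y = _check_pair(u, v, y)
    if bins is None:
        bins = default_bins(len(u))
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x_hat = _equal_frequency_labels((u + v) / 2.0, bins)
    x = _equal_frequency_labels(u, bins)
    return float(mutual_info_score(x_hat, y) - mutual_info_score(x, y))


@dataclass
class DirectedStageNetwork:
    """Per-stage directed, w-weighted graph over the aligned gene universe.

    ``graph`` contains every universe gene as a node and a directed edge
    (gi, gj) with attribute ``w`` (> 0) wherever the orientation index is
    positive; both orientations of a PPI pair may coexist.
    """

    stage_label: str
    gene_ids: list[str]
    graph: nx.DiGraph
    n_degenerate: int = 0
    method: str = "gaussian"

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def out_degree(self, gene: str) -> int:
        return self.graph.out_degree(gene)

    def edge_triples(self) -> list[tuple[str, str, float]]:
        """Edges as (source, target, w), stably sorted for reproducibility."""
        return sorted(
            (u, v, d["w"]) for u, v, d in self.graph.edges(data=True)
        )


def build_stage_network(
    series: StageSeries,
    ppi: PPINetwork,
    stage_index: int,
    method: str = "gaussian",
    bins: int | None = None,
) -> DirectedStageNetwork:
    """Rewire the PPI scaffold into the directed network N(T).

    Observations of stages ``stage_index - 1`` and ``stage_index`` are
    pooled, labeled y = 0 / 1 respectively, and each ordered pair of every
    PPI edge receives its own w; the ordered pair is kept iff w > 0 and
    non-degenerate.  ``stage_index`` is 0-based, so the first network is at
    index 1 (the second stage).
    """
    if not 1 <= stage_index < series.n_stages:
        raise IndexError(
            f"stage_index {stage_index} out of range 1..{series.n_stages - 1}"
        )
    if method not in ("gaussian", "mi"):
        raise ValueError(f"unknown method {method!r}")
    prev, curr = series[stage_index - 1], series[stage_index]
    pooled = np.hstack([prev.values, curr.values])
    y = PhenotypeLabel.for_adjacent_stages(prev.n_obs, curr.n_obs)
    if method == "mi" and bins is None:
        bins = default_bins(len(y))

    index = {g: i for i, g in enumerate(series.gene_ids)}
    g = nx.DiGraph()
    g.add_nodes_from(series.gene_ids)
    n_degenerate = 0
    for a, b in ppi.sorted_edges():
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            continue
        u, v = pooled[ia], pooled[ib]
        for src, dst, x1, x2 in ((a, b, u, v), (b, a, v, u)):
            if method == "gaussian":
                w = direction_index_gaussian(x1, x2, y)
            else:
                w = direction_index_mi(x1, x2, y, bins)
            if math.isnan(w):
                n_degenerate += 1
            elif w > 0.0:
                g.add_edge(src, dst, w=w)
    if n_degenerate:
        logger.info(
            "stage %r: %d degenerate ordered pair(s) left unoriented",
            curr.stage_label, n_degenerate,
        )
    return DirectedStageNetwork(
        curr.stage_label, list(series.gene_ids), g, n_degenerate, method
    )


def export_network(net: DirectedStageNetwork, path) -> None:
    """Write N(T) as a 3-column TSV (source, target, w), stably sorted."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tw\n")
        for u, v, w in net.edge_triples():
            fh.write(f"{u}\t{v}\t{w!r}\n")
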