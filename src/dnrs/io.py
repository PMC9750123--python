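"""Domain types and readers/writers for expression matrices, PPI edge lists
and result tables.

Expression matrices are delimited text (TSV or CSV) with genes in rows: a
header row of observation (cell/sample) identifiers and a first column of
gene symbols.  Gene identifiers are opaque, case-sensitive strings; inputs
are expected to be pre-mapped to a single symbol space (no probe/Entrez
translation is attempted here).  PPI networks are two-column edge lists.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .detect import DetectionResult
    from .rank import RankResult

logger = logging.getLogger("dnrs")

__all__ = [
    "ExpressionMatrix",
    "StageSeries",
    "PPINetwork",
    "PhenotypeLabel",
    "read_expression",
    "write_expression",
    "aggregate_duplicates",
    "read_ppi",
    "write_ppi",
    "align_to_common_genes",
    "write_results",
    "read_summary",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x observations expression for one stage/time point.

    ``gene_ids`` may contain duplicates immediately after reading a raw
    file; every analysis entry point requires them unique, which
    :func:`aggregate_duplicates` establishes by element-wise averaging.
    """

    gene_ids: list[str]
    values: np.ndarray
    stage_label: str = ""
    stage_index: int = 0
    obs_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {self.values.shape[0]} rows"
            )
        if self.values.shape[1] < 1:
            raise ValueError("expression matrix needs at least one observation")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"observation column {bad[1]}"
            )
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.obs_ids is not None:
            self.obs_ids = [str(o) for o in self.obs_ids]
            if len(self.obs_ids) != self.values.shape[1]:
                raise ValueError("obs_ids length does not match observation count")

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def has_duplicate_genes(self) -> bool:
        return len(set(self.gene_ids)) != len(self.gene_ids)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]


@dataclass
class StageSeries:
    """Ordered stages sharing one gene universe in identical row order."""

    stages: list[ExpressionMatrix]

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("a stage series needs at least two stages")
        ref = self.stages[0].gene_ids
        if len(set(ref)) != len(ref):
            raise ValueError(
                "duplicate gene ids in stage series; run aggregate_duplicates first"
            )
        for m in self.stages[1:]:
            if m.gene_ids != ref:
                raise ValueError(
                    f"stage {m.stage_label!r} gene ids differ from stage "
                    f"{self.stages[0].stage_label!r}; align/aggregate first"
                )
        for i, m in enumerate(self.stages):
            m.stage_index = i

    @property
    def gene_ids(self) -> list[str]:
        return self.stages[0].gene_ids

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def labels(self) -> list[str]:
        return [m.stage_label for m in self.stages]

    def __len__(self) -> int:
        return len(self.stages)

    def __getitem__(self, i: int) -> ExpressionMatrix:
        return self.stages[i]


@dataclass(frozen=True)
class PPINetwork:
    """Undirected PPI scaffold: a set of unordered gene-symbol pairs."""

    edges: frozenset[tuple[str, str]]  # each stored as a sorted 2-tuple

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PPINetwork":
        edges = set()
        n_self = 0
        for a, b in pairs:
            a, b = str(a), str(b)
            if a == b:
                n_self += 1
                continue
            edges.add((a, b) if a < b else (b, a))
        if n_self:
            logger.info("dropped %d self-loop(s) from PPI edge list", n_self)
        return cls(frozenset(edges))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(n for e in self.edges for n in e)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def subnetwork(self, genes: Iterable[str]) -> "PPINetwork":
        keep = set(genes)
        return PPINetwork(
            frozenset(e for e in self.edges if e[0] in keep and e[1] in keep)
        )

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)


@dataclass(frozen=True)
class PhenotypeLabel:
    """Binary stage label over pooled observations: 0 = stage T-1, 1 = stage T."""

    y: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=int)
        if y.ndim != 1:
            raise ValueError("phenotype label must be a 1-D vector")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("phenotype label must be coded 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("phenotype label needs both classes present")
        object.__setattr__(self, "y", y)

    @classmethod
    def for_adjacent_stages(cls, n_prev: int, n_curr: int) -> "PhenotypeLabel":
        return cls(np.concatenate([np.zeros(n_prev, int), np.ones(n_curr, int)]))

    def __len__(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    genes_in_rows: bool = True,
    stage_label: str | None = None,
    on_duplicates: str = "error",
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    Parameters
    ----------
    path
        TSV (default) or CSV file; the delimiter is chosen from the
        extension (``.csv`` means comma, anything else tab).
    genes_in_rows
        If False the file is observations x genes and is transposed.
    on_duplicates
        ``"error"`` (default) rejects duplicated gene symbols with a
        pointer to :func:`aggregate_duplicates`; ``"mean"`` aggregates
        them in place.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, header=0,
        float_precision="round_trip",
    )
    if df.empty:
        raise ValueError(f"empty expression matrix in {path}")
    if not genes_in_rows:
        df = df.T
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                row = df.index[coerced.isna().argmax()]
                raise ValueError(
                    f"non-numeric expression value at gene {row!r}, column {col!r} in {path}"
                ) from exc
        raise
    gene_ids = [str(g) for g in df.index]
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"NaN/Inf at gene {gene_ids[bad[0]]!r}, column {df.columns[bad[1]]!r} in {path}"
        )
    m = ExpressionMatrix(
        gene_ids, values, stage_label or path.stem,
        obs_ids=[str(c) for c in df.columns],
    )
    if m.has_duplicate_genes:
        if on_duplicates == "mean":
            m = aggregate_duplicates(m)
        else:
            dup = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
            raise ValueError(
                f"duplicate gene symbol(s) {dup[:5]} in {path}; call "
                "aggregate_duplicates (or pass on_duplicates='mean') to average them"
            )
    return m


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix; values round-trip at full precision."""
    path = Path(path)
    df = pd.DataFrame(
        m.values,
        index=pd.Index(m.gene_ids, name="gene"),
        columns=m.obs_ids or [f"obs{i + 1}" for i in range(m.n_obs)],
    )
    df.to_csv(path, sep=_sep_for(path), float_format=lambda v: repr(float(v)))


def aggregate_duplicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse rows sharing a gene symbol to their element-wise mean.

    Gene order in the result follows the first occurrence of each symbol;
    the operation is idempotent.
    """
    if not m.has_duplicate_genes:
        return m
    df = pd.DataFrame(m.values, index=m.gene_ids)
    agg = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(
        list(agg.index), agg.to_numpy(), m.stage_label, m.stage_index, m.obs_ids
    )


_PPI_SPLIT = re.compile(r"[,\t ]+")


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a two-column undirected edge list (extra columns ignored).

    Duplicate pairs (in either order) are merged and self-loops dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _PPI_SPLIT.split(line)
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least two columns, got {line!r}"
                )
            pairs.append((tokens[0], tokens[1]))
    if not pairs:
        logger.warning("PPI edge list %s is empty", path)
        return PPINetwork(frozenset())
    return PPINetwork.from_pairs(pairs)


def write_ppi(ppi: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in ppi.sorted_edges():
            fh.write(f"{a}\t{b}\n")


def align_to_common_genes(
    series: StageSeries, ppi: PPINetwork
) -> tuple[StageSeries, PPINetwork]:
    """Restrict series and PPI scaffold to their common gene universe.

    The common genes keep the series' row order, applied identically to
    every stage, so only measured genes take part in network rewiring.
    """
    ppi_nodes = ppi.nodes
    common = [g for g in series.gene_ids if g in ppi_nodes]
    if not common:
        raise ValueError("no genes shared between expression series and PPI network")
    logger.info(
        "aligned to %d common genes (series %d, PPI %d)",
        len(common), len(series.gene_ids), len(ppi_nodes),
    )
    if common == series.gene_ids and len(ppi_nodes) == len(common):
        return series, ppi
    idx = [series.gene_ids.index(g) for g in common]
    stages = [
        ExpressionMatrix(common, m.values[idx], m.stage_label, m.stage_index, m.obs_ids)
        for m in series.stages
    ]
    return StageSeries(stages), ppi.subnetwork(common)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

_FLOAT = lambda v: repr(float(v))  # noqa: E731 - full-precision round trip


def write_results(
    result: "DetectionResult",
    outdir: str | Path,
    rank_results: Sequence["RankResult"] | None = None,
    params: dict | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write the per-stage summary, per-stage gene tables and run metadata.

    Produces ``summary.tsv`` (stage, pr, t_statistic, p_value, flagged),
    one ``genes_<stage>.tsv`` per scored stage (gene, local_dnrs, rank,
    signaling) and ``metadata.json``; returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary = result.to_frame()
    p = outdir / "summary.tsv"
    summary.to_csv(p, sep="\t", index=False, float_format=_FLOAT, na_rep="NA")
    written.append(p)

    for rr in rank_results or []:
        order = np.argsort(rr.s_star)[::-1]  # stable enough: ranks only reported
        rank_of = np.empty(len(order), int)
        rank_of[order] = np.arange(1, len(order) + 1)
        sig = set(rr.signaling_genes)
        df = pd.DataFrame(
            {
                "gene": rr.gene_ids,
                "local_dnrs": rr.s_star,
                "rank": rank_of,
                "signaling": [int(g in sig) for g in rr.gene_ids],
            }
        )
        p = outdir / f"genes_{_safe(rr.stage_label)}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=_FLOAT)
        written.append(p)

    import numpy, pandas, scipy  # noqa: PLC0415

    from . import __version__

    meta = {
        "parameters": _jsonable(params or {}),
        "seed": seed,
        "versions": {
            "dnrs": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    p = outdir / "metadata.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")


def _safe(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.+-]", "_", label)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
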