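"""Term–article incidence, term–term co-occurrence and heatmap ordering.

The incidence matrix marks which selected terms occur in which articles;
its Gram matrix (incidenceᵀ·incidence) is the term–term adjacency whose
entry (i, j) counts articles mentioning both terms and whose diagonal is
each term's document frequency.  Cross-category matrices (e.g. drug rows
× protein columns) and row normalization (each row divided by its total,
so a drug's protein profile sums to 1) feed the heatmap exports; row and
column orders come from agglomerative hierarchical clustering on
Euclidean distances (complete linkage by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from ._text import norm_term
from .medline import Article

logger = logging.getLogger(__name__)

__all__ = [
    "CooccurrenceModel",
    "build_incidence",
    "build_adjacency",
    "normalize_rows",
    "cross_cooccurrence",
    "cluster_order",
    "write_matrix_tsv",
]


def _check_unique(terms: Sequence[str], what: str = "terms") -> list[str]:
    keys = [norm_term(t) for t in terms]
    if len(set(keys)) != len(keys):
        dupes = sorted({t for t, k in zip(terms, keys) if keys.count(k) > 1})
        raise ValueError(f"duplicate {what}: {dupes}")
    return keys


def build_incidence(articles: Sequence[Article], terms: Sequence[str]) -> np.ndarray:
    """Binary (articles × terms) matrix of qualifier-stripped descriptor presence."""
    keys = _check_unique(terms)
    mat = np.zeros((len(articles), len(terms)), dtype=np.int8)
    col = {k: j for j, k in enumerate(keys)}
    for i, art in enumerate(articles):
        for k in art.descriptor_set():
            j = col.get(k)
            if j is not None:
                mat[i, j] = 1
    return mat


def build_adjacency(incidence: np.ndarray) -> np.ndarray:
    """Term–term co-occurrence counts: incidenceᵀ·incidence in exact integers."""
    inc = np.asarray(incidence, dtype=np.int64)
    if inc.size and not np.isin(inc, (0, 1)).all():
        raise ValueError("incidence matrix must be 0/1-valued")
    return inc.T @ inc


def normalize_rows(counts: np.ndarray) -> np.ndarray:
    """Divide each row by its total; all-zero rows stay zero (and are logged)."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1, keepdims=True)
    zero_rows = np.flatnonzero(totals[:, 0] == 0)
    if zero_rows.size:
        logger.info("normalize_rows: %d all-zero row(s) left as zeros", zero_rows.size)
    safe = np.where(totals == 0, 1.0, totals)
    return counts / safe


def cross_cooccurrence(
    articles: Sequence[Article],
    row_terms: Sequence[str],
    col_terms: Sequence[str],
) -> np.ndarray:
    """Counts of articles mentioning row term i and column term j.

    Row and column lists must each be unique but may overlap each other;
    a term against itself yields its document frequency.
    """
    inc_r = build_incidence(articles, row_terms)
    inc_c = build_incidence(articles, col_terms)
    return inc_r.T.astype(np.int64) @ inc_c.astype(np.int64)


def cluster_order(
    matrix: np.ndarray, method: str = "complete"
) -> tuple[list[int], list[int]]:
    """Dendrogram leaf orders for rows and (independently) columns.

    Agglomerative clustering on Euclidean distances between row vectors
    and between column vectors; ``method`` is any scipy linkage method
    (complete by default, single/average available).  Axes with fewer
    than two entries get the identity permutation.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.isfinite(matrix).all():
        raise ValueError("matrix must be finite")

    def one_axis(m: np.ndarray) -> list[int]:
        if m.shape[0] < 2:
            return list(range(m.shape[0]))
        return [int(i) for i in leaves_list(linkage(pdist(m, metric="euclidean"), method=method))]

    return one_axis(matrix), one_axis(matrix.T)


@dataclass
class CooccurrenceModel:
    """Bundle of incidence, adjacency and normalized adjacency for a term set."""

    terms: list[str]
    articles: list[str]
    incidence: np.ndarray
    adjacency: np.ndarray
    row_normalized: np.ndarray

    @classmethod
    def from_articles(
        cls, articles: Sequence[Article], terms: Sequence[str]
    ) -> "CooccurrenceModel":
        inc = build_incidence(articles, terms)
        adj = build_adjacency(inc)
        return cls(
            terms=list(terms),
            articles=[a.pmid for a in articles],
            incidence=inc,
            adjacency=adj,
            row_normalized=normalize_rows(adj),
        )


def write_matrix_tsv(
    matrix: np.ndarray,
    row_names: Sequence[str],
    col_names: Sequence[str],
    dest,
    header_comment: str | None = None,
) -> None:
    """Write a labeled matrix as TSV (first column = row names)."""
    matrix = np.asarray(matrix)
    if matrix.shape != (len(row_names), len(col_names)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match labels "
            f"({len(row_names)} x {len(col_names)})"
        )
    own = not hasattr(dest, "write")
    handle = Path(dest).open("w", encoding="utf-8") if own else dest

    def fmt(v) -> str:
        if isinstance(v, (int, np.integer)):
            return str(int(v))
        return f"{float(v):.10g}"

    try:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        handle.write("term\t" + "\t".join(col_names) + "\n")
        for name, row in zip(row_names, matrix):
            handle.write(name + "\t" + "\t".join(fmt(v) for v in row) + "\n")
    finally:
        if own:
            handle.close()


def plot_heatmap(
    matrix: np.ndarray,
    row_names: Sequence[str],
    col_names: Sequence[str],
    dest,
    method: str = "complete",
):  # pragma: no cover - optional rendering, exercised manually
    """Optional rendered heatmap (requires the ``plot`` extra).

    The numeric artifact of record is the ordered TSV written by
    :func:`write_matrix_tsv`; this image is presentation only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ro, co = cluster_order(matrix, method=method)
    ordered = np.asarray(matrix)[np.ix_(ro, co)]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * len(col_names)), max(3, 0.3 * len(row_names)))
    )
    im = ax.imshow(ordered, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(co)), [col_names[j] for j in co], rotation=90, fontsize=6)
    ax.set_yticks(range(len(ro)), [row_names[i] for i in ro], fontsize=6)
    fig.colorbar(im, ax=ax, label="normalized count")
    fig.tight_layout()
    fig.savefig(dest, dpi=150)
    plt.close(fig)
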