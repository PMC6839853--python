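"""Tissue-specificity filter: keep interactome edges with co-expressed partners.

An edge survives when the Pearson correlation of its partners' normalized
expression, across the *disease (case) samples* of a dataset, is strictly
greater than 0.7 in at least one dataset.  One normalization variant per
dataset is designated for this computation.  Edges whose partners are never
measured together in any dataset are dropped and counted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .integration import Edge, IntegratedInteractome

log = logging.getLogger(__name__)

RHO_THRESHOLD = 0.7


@dataclass
class EdgeSupport:
    """Per-edge co-expression evidence across datasets."""

    edge: Edge
    rho_by_dataset: dict[str, float] = field(default_factory=dict)
    support: int = 0


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _case_correlations(
    dataset: ExpressionDataset, edges: list[Edge]
) -> dict[Edge, float]:
    """rho per edge over the dataset's case samples (log2 scale)."""
    cases = dataset.case_samples
    if len(cases) < 3:
        raise ValueError(f"{dataset.id}: need >=3 case samples for correlation")
    genes = sorted({g for e in edges for g in e} & set(dataset.genes))
    if not genes:
        return {}
    mat = dataset.log2_matrix().loc[genes, cases].to_numpy()
    centred = mat - mat.mean(axis=1, keepdims=True)
    norm = np.sqrt((centred**2).sum(axis=1))
    idx = {g: i for i, g in enumerate(genes)}
    out: dict[Edge, float] = {}
    n_degenerate = 0
    for e in edges:
        a, b = e
        if a not in idx or b not in idx:
            continue
        ia, ib = idx[a], idx[b]
        if norm[ia] == 0.0 or norm[ib] == 0.0:
            n_degenerate += 1
            continue
        out[e] = float((centred[ia] @ centred[ib]) / (norm[ia] * norm[ib]))
    if n_degenerate:
        log.info("%s: skipped %d edges with zero-variance partners", dataset.id, n_degenerate)
    return out


def filter_coexpressed(
    interactome: IntegratedInteractome | set[Edge],
    datasets: list[ExpressionDataset],
    *,
    rho_threshold: float = RHO_THRESHOLD,
    min_support: int = 1,
) -> tuple[set[Edge], list[EdgeSupport]]:
    """Keep edges co-expressed (rho > threshold, strict) in enough datasets.

    ``datasets`` holds the one designated normalization variant per dataset.
    Returns the surviving edge set and the full per-edge support records
    (including dropped edges, with their per-dataset correlations).
    """
    edges = sorted(interactome.edges if isinstance(interactome, IntegratedInteractome) else interactome)
    supports = {e: EdgeSupport(edge=e) for e in edges}
    for ds in datasets:
        for e, rho in _case_correlations(ds, edges).items():
            supports[e].rho_by_dataset[ds.id] = rho
            if rho > rho_threshold:
                supports[e].support += 1
    kept = {e for e in edges if supports[e].support >= min_support}
    n_unmeasured = sum(1 for e in edges if not supports[e].rho_by_dataset)
    log.info(
        "co-expression filter: %d -> %d edges (rho > %g in >= %d dataset(s)); "
        "%d edges never measured",
        len(edges), len(kept), rho_threshold, min_support, n_unmeasured,
    )
    return kept, [supports[e] for e in edges]


def support_histogram(edge_supports: list[EdgeSupport] | list[int]) -> dict[int, int]:
    """Counts of retained edges by support level (support >= 1 only)."""
    levels = [
        s.support if isinstance(s, EdgeSupport) else int(s) for s in edge_supports
    ]
    out: dict[int, int] = {}
    for lv in levels:
        if lv >= 1:
            out[lv] = out.get(lv, 0) + 1
    return dict(sorted(out.items()))


def write_edge_support_tsv(
    supports: list[EdgeSupport], dataset_ids: list[str], path: str | Path
) -> None:
    rows = []
    for s in supports:
        row = {
            "gene_a": s.edge[0],
            "gene_b": s.edge[1],
            "support": s.support,
        }
        for ds in dataset_ids:
            rho = s.rho_by_dataset.get(ds)
            row[f"rho_{ds}"] = "" if rho is None else f"{rho:.4f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_support_histogram(histogram: dict[int, int], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({str(k): v for k, v in sorted(histogram.items())}, indent=2) + "\n"
    )
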