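"""Multi-source interaction loading, reliability filtering and merging.

Each interaction source carries one kind of reliability evidence: a continuous
confidence score (kept when strictly above that source's median), a binary
core-quality flag, or a publication count (kept at >= ``min_pubs``).  Filtered
sources are merged into one deduplicated, undirected candidate interactome
with per-edge provenance, then restricted to the organelle gene catalog.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass(frozen=True)
class InteractionRecord:
    """One scored/evidenced candidate edge from one source database."""

    protein_a: str
    protein_b: str
    source: str
    score: float | None = None
    pubs: int | None = None
    core_flag: bool | None = None


@dataclass
class IntegratedInteractome:
    """Deduplicated undirected edge set with provenance and stage counts."""

    edges: set[Edge] = field(default_factory=set)
    provenance: dict[Edge, set[str]] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}


def score_cutoff(records: pd.DataFrame) -> float:
    """Median of the source's full confidence-score distribution.

    For even n this is the midpoint of the two central order statistics.
    """
    if len(records) == 0:
        raise ValueError("cannot take the score median of an empty source table")
    if "score" not in records.columns:
        raise ValueError("source table carries no 'score' column")
    scores = records["score"]
    if scores.isna().any():
        bad = list(records.index[scores.isna()][:10])
        raise ValueError(f"missing scores in rows {bad}")
    return float(np.median(scores.to_numpy(dtype=float)))


def filter_scored(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records with score strictly greater than the source median.

    With continuous scores this retains just under half the table; with heavy
    ties it can retain less (strict inequality).
    """
    cutoff = score_cutoff(records)
    return records[records["score"] > cutoff]


def filter_quality(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records whose core-quality flag is set."""
    if "core_flag" not in records.columns:
        raise ValueError("source table carries no 'core_flag' column")
    if records["core_flag"].isna().any():
        raise ValueError("missing core_flag values")
    return records[records["core_flag"].astype(bool)]


def filter_evidence(records: pd.DataFrame, min_pubs: int = 2) -> pd.DataFrame:
    """Keep records with at least ``min_pubs`` publication evidences."""
    if "pubs" not in records.columns:
        raise ValueError("source table carries no 'pubs' column")
    pubs = records["pubs"]
    if pubs.isna().any():
        raise ValueError("missing publication counts")
    if (pubs < 0).any():
        raise ValueError("negative publication counts")
    return records[pubs >= min_pubs]


_FILTERS = {
    "score_median": lambda df, **kw: filter_scored(df),
    "core_flag": lambda df, **kw: filter_quality(df),
    "min_pubs": lambda df, **kw: filter_evidence(df, kw.get("min_pubs", 2)),
}


def apply_source_filter(records: pd.DataFrame, rule: str, *, min_pubs: int = 2) -> pd.DataFrame:
    """Dispatch to the reliability filter named by ``rule``."""
    try:
        fn = _FILTERS[rule]
    except KeyError:
        raise ValueError(f"unknown filter rule {rule!r}") from None
    return fn(records, min_pubs=min_pubs)


def infer_filter_rule(records: pd.DataFrame) -> str:
    """Guess the filter branch from the columns a table carries."""
    for col, rule in (("score", "score_median"), ("core_flag", "core_flag"), ("pubs", "min_pubs")):
        if col in records.columns:
            return rule
    raise ValueError("table has none of score/core_flag/pubs")


def canonical_edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


def merge_sources(filtered_tables: list[pd.DataFrame]) -> IntegratedInteractome:
    """Union already-filtered source tables into one undirected edge set.

    Pair order is canonicalized, self-loops are dropped (the downstream
    degree-based hub analysis assumes a simple graph), and per-edge provenance
    records every contributing source.
    """
    out = IntegratedInteractome()
    n_in = 0
    n_self = 0
    for table in filtered_tables:
        n_in += len(table)
        for a, b, src in zip(table["protein_a"], table["protein_b"], table["source"]):
            if not isinstance(a, str) or not isinstance(b, str) or not a or not b:
                raise ValueError(f"malformed protein symbol in source {src!r}: {(a, b)!r}")
            if a == b:
                n_self += 1
                continue
            e = canonical_edge(a, b)
            out.edges.add(e)
            out.provenance.setdefault(e, set()).add(str(src))
    if n_self:
        log.info("merge_sources: dropped %d self-interactions", n_self)
    out.stage_counts = {
        "records_in": n_in,
        "self_loops_dropped": n_self,
        "merged_edges": len(out.edges),
    }
    log.info("merge_sources: %d records -> %d unique edges", n_in, len(out.edges))
    return out


def restrict_to_catalog(
    interactome: IntegratedInteractome, catalog: set[str] | list[str]
) -> IntegratedInteractome:
    """Keep edges with both endpoints in the organelle catalog."""
    catalog = set(catalog)
    if not catalog:
        raise ValueError("empty catalog")
    kept = {e for e in interactome.edges if e[0] in catalog and e[1] in catalog}
    out = IntegratedInteractome(
        edges=kept,
        provenance={e: set(interactome.provenance.get(e, set())) for e in kept},
        stage_counts=dict(interactome.stage_counts),
    )
    covered = out.genes
    out.stage_counts.update(
        {
            "catalog_edges": len(kept),
            "catalog_genes_covered": len(covered),
        }
    )
    out.stage_counts["catalog_coverage_fraction"] = len(covered) / len(catalog)
    log.info(
        "restrict_to_catalog: %d -> %d edges; %d/%d catalog genes (%.1f%%)",
        len(interactome.edges), len(kept), len(covered), len(catalog),
        100.0 * len(covered) / len(catalog),
    )
    return out


def integrate(
    tables: list[pd.DataFrame],
    catalog: set[str] | list[str],
    *,
    rules: list[str] | None = None,
    min_pubs: int = 2,
) -> IntegratedInteractome:
    """Filter each source by its rule, merge, and restrict to the catalog."""
    if rules is None:
        rules = [infer_filter_rule(t) for t in tables]
    filtered = [
        apply_source_filter(t, rule, min_pubs=min_pubs) for t, rule in zip(tables, rules)
    ]
    n_raw = sum(len(t) for t in tables)
    merged = merge_sources(filtered)
    merged.stage_counts["records_before_filters"] = n_raw
    return restrict_to_catalog(merged, catalog)


# ---------------------------------------------------------------------------
# IO


def read_source_tables(config_path: str | Path) -> tuple[list[pd.DataFrame], list[str]]:
    """Read the ``sources.json`` declaration and the tables it points at.

    The declaration is ``{"sources": [{"name", "path", "filter"}, ...]}`` with
    paths relative to the declaration file.
    """
    config_path = Path(config_path)
    decl = json.loads(config_path.read_text())
    tables, rules = [], []
    for entry in decl["sources"]:
        path = config_path.parent / entry["path"]
        tables.append(pd.read_csv(path, sep="\t"))
        rules.append(entry["filter"])
    return tables, rules


def read_catalog(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_edge_list(interactome: IntegratedInteractome, path: str | Path) -> None:
    rows = [
        {
            "protein_a": a,
            "protein_b": b,
            "sources": ",".join(sorted(interactome.provenance.get((a, b), set()))),
        }
        for a, b in sorted(interactome.edges)
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "sources"]).to_csv(
        path, sep="\t", index=False
    )
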