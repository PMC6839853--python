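"""Hypergeometric over-representation test with Benjamini–Hochberg FDR.

Given a query gene list, a background universe (by default all catalog genes
present in the network) and annotation term sets, each term's overlap k with
the query is scored with the upper-tail hypergeometric probability
P(X >= k), X ~ Hypergeometric(N, K, n), computed in log space.  Terms with
zero overlap are excluded from testing and from the multiple-testing family.
Significance cut: FDR < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

FDR_CUTOFF = 0.01


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    description: str
    k: int          # overlap with query
    K: int          # term size in background
    n: int          # query size
    N: int          # background size
    p_value: float
    fdr: float


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: background size, K: annotated genes in background, n: query size,
    k: annotated genes in the query.  Computed through the survival function
    of the log-space hypergeometric PMF for numerical stability.
    """
    if not (0 <= k <= K <= N and 0 <= k <= n <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    # sum the log-pmf from k to min(K, n) via logsumexp
    upper = min(K, n)
    ks = np.arange(k, upper + 1)
    logpmf = stats.hypergeom.logpmf(ks, N, K, n)
    from scipy.special import logsumexp

    return float(min(1.0, np.exp(logsumexp(logpmf))))


def bh_adjust(p_values, *, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (capped at 1).

    Benjamini–Yekutieli is available with ``method="fdr_by"``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if method not in ("fdr_bh", "fdr_by"):
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]


def enrich(
    query_genes,
    annotation_sets: dict[str, set[str]],
    background,
    *,
    fdr_cutoff: float = FDR_CUTOFF,
    descriptions: dict[str, str] | None = None,
    adjust_method: str = "fdr_bh",
) -> tuple[list[EnrichmentRecord], list[EnrichmentRecord]]:
    """Test every term with nonzero query overlap; return (all, significant).

    Query genes outside the background are dropped with a log entry; term
    sets are intersected with the background.  Records are sorted by FDR
    (ties by p, then term id).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query_genes)
    outside = query - background
    if outside:
        log.info("enrich: dropped %d query genes outside the background", len(outside))
        query &= background
    descriptions = descriptions or {}
    N, n = len(background), len(query)
    tested = []
    for term in sorted(annotation_sets):
        members = set(annotation_sets[term]) & background
        k = len(members & query)
        if k == 0 or not members:
            continue
        p = hypergeometric_pvalue(k, len(members), n, N)
        tested.append((term, k, len(members), p))
    if not tested:
        return [], []
    fdrs = bh_adjust([t[3] for t in tested], method=adjust_method)
    records = [
        EnrichmentRecord(
            term=term,
            description=descriptions.get(term, term),
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            fdr=float(f),
        )
        for (term, k, K, p), f in zip(tested, fdrs)
    ]
    records.sort(key=lambda r: (r.fdr, r.p_value, r.term))
    significant = [r for r in records if r.fdr < fdr_cutoff]
    return records, significant


# ---------------------------------------------------------------------------
# IO


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read tab-separated gene sets: term, description, members...

    Returns (term -> member set, term -> description).
    """
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        terms[parts[0]] = set(parts[2:])
        descriptions[parts[0]] = parts[1]
    return terms, descriptions


def write_enrichment_tsv(records: list[EnrichmentRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "term_id": r.term,
                "description": r.description,
                "observed_gene_count": r.k,
                "term_size": r.K,
                "p_value": f"{r.p_value:.4g}",
                "fdr": f"{r.fdr:.4g}",
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
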