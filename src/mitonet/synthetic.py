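"""Seeded synthetic inputs with planted ground truth.

This module emulates the statistical structure of the study inputs that the
pipeline consumes: a scale-free "truth" interaction network over an organelle
gene catalog, several interaction-source tables carrying confidence scores /
quality flags / publication counts, case-control expression datasets in two
monotone-related normalization variants with co-expressed true-edge partners
and planted differential expression, and annotation term sets with planted
enrichment.  Everything is driven by one :class:`numpy.random.Generator` so a
fixed seed reproduces byte-identical files.

Co-expression model
-------------------
Case and control samples draw their per-gene residuals from a multivariate
normal whose correlation matrix pins every truth edge at ``edge_rho``.  The
matrix is the nearest positive-semidefinite correlation matrix with those
entries fixed, found by Dykstra alternating projections starting from the
distance-decay surface ``edge_rho**d``; non-edge correlations consequently
decay with graph distance, so transitive correlations resemble real
co-expression rather than isolated correlated pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression import (
    CASE,
    CONTROL,
    ExpressionDataset,
    write_expression_tsv,
    write_metadata_tsv,
)


class ConfigurationError(ValueError):
    """Raised when a generation or pipeline configuration is invalid."""


# Internal constants of the generator (not exposed as knobs): the fraction of
# truth edges sampled into each source table, the score / flag / publication
# distributions separating truth from decoy edges, and the variant-B affine
# transform.  They are part of the emulated study conditions.
_SOURCE_TRUTH_FRACTION = 0.7
_SCORE_TRUE = (0.75, 0.12)   # mean, sd of truth-edge confidence scores
_SCORE_DECOY = (0.45, 0.12)
_FLAG_TRUE_P = 0.8           # P(core_flag) for truth edges
_FLAG_DECOY_P = 0.25
_PUBS_TRUE_LAM = 1.6         # pubs = 1 + Poisson(lam)
_PUBS_DECOY_LAM = 0.35
_VARIANT_B_SLOPE = 0.9
_VARIANT_B_OFFSET = 0.3
_VARIANT_B_NOISE_SD = 0.05
_BASELINE_MEAN = 7.0         # log2 baseline intensity
_BASELINE_SD = 1.0


@dataclass
class GenerationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the real study at desk scale: a catalog of 200 organelle
    genes inside a 600-gene universe (standing in for 1158 MitoCarta genes on
    ~20k-gene arrays), seven interaction sources (four score-bearing, one
    quality-flagged, two with publication counts), and six case/control
    datasets whose group sizes match the study's means (12 cases, 8 controls).
    ``noise_sd`` is the total per-observation residual s.d. in log2 units
    (0.25, typical of RMA-normalized arrays); ``edge_rho`` is the population
    correlation of true-edge partners (0.8, above the pipeline's 0.7 cut).
    """

    n_genes: int = 600
    n_catalog: int = 200
    n_sources: int = 7
    scale_free_m: int = 2
    decoy_edge_fraction: float = 0.5
    n_datasets: int = 6
    cases_per_dataset: int = 12
    controls_per_dataset: int = 8
    coverage_fraction: float = 0.9
    edge_rho: float = 0.8
    deg_fraction_up: float = 0.08
    deg_fraction_down: float = 0.08
    effect_fold: float = 2.0
    noise_sd: float = 0.25
    n_terms: int = 20
    term_size: int = 15
    seed: int = 0

    def validate(self) -> None:
        for name in ("decoy_edge_fraction", "coverage_fraction", "edge_rho",
                     "deg_fraction_up", "deg_fraction_down"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.effect_fold < 1.0:
            raise ConfigurationError("effect_fold must be >= 1 (1 means no effect)")
        if self.n_catalog > self.n_genes:
            raise ConfigurationError("n_catalog cannot exceed n_genes")
        if self.scale_free_m < 1:
            raise ConfigurationError("scale_free_m must be >= 1")
        if self.n_catalog < self.scale_free_m + 1:
            raise ConfigurationError("n_catalog must be >= scale_free_m + 1")
        if self.deg_fraction_up + self.deg_fraction_down > 1.0:
            raise ConfigurationError("planted DEG fractions sum to more than 1")
        if self.term_size > self.n_catalog:
            raise ConfigurationError("term_size cannot exceed n_catalog")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study."""

    genes: list[str]
    catalog: list[str]
    graph: nx.Graph = field(repr=False)
    planted_up: set[str] = field(default_factory=set)
    planted_down: set[str] = field(default_factory=set)
    term_memberships: dict[str, set[str]] = field(default_factory=dict)
    measured_genes: dict[str, set[str]] = field(default_factory=dict)

    @property
    def truth_edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges()}


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_truth_network(config: GenerationConfig) -> SyntheticTruth:
    """Grow the scale-free truth network over the organelle catalog.

    Preferential attachment (Barabási–Albert): nodes are added one at a time
    and each new node connects to ``scale_free_m`` existing nodes chosen with
    probability proportional to their current degree, which yields the heavy-
    tailed degree distribution the topology stages assume.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    catalog = genes[: config.n_catalog]
    g = nx.barabasi_albert_graph(config.n_catalog, config.scale_free_m, seed=rng)
    graph = nx.relabel_nodes(g, dict(enumerate(catalog)))
    return SyntheticTruth(genes=genes, catalog=catalog, graph=graph)


def edge_pinned_correlation(
    graph: nx.Graph,
    rho: float,
    *,
    n_iter: int = 150,
    unreachable_distance: int = 30,
) -> tuple[np.ndarray, list]:
    """Correlation matrix with every graph edge pinned at ``rho``.

    Dykstra alternating projections between the PSD cone and the affine set
    {diag = 1, R[edge] = rho}, initialised at ``rho**d`` (d = graph distance).
    Returns the PSD iterate (unit diagonal, edges at ``rho`` to within ~1e-3)
    and the node order.
    """
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if rho == 0.0 or n == 0:
        return np.eye(n), nodes
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), float(unreachable_distance))
    np.fill_diagonal(dist, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(graph):
        i = idx[src]
        for dst, d in lengths.items():
            dist[i, idx[dst]] = d
    r = rho ** dist
    mask = np.zeros((n, n), dtype=bool)
    for u, v in graph.edges():
        mask[idx[u], idx[v]] = mask[idx[v], idx[u]] = True
    correction = np.zeros_like(r)
    x = r
    for _ in range(n_iter):
        y = r + correction
        w, vecs = np.linalg.eigh(y)
        x = (vecs * np.clip(w, 0.0, None)) @ vecs.T
        correction = y - x
        r = x.copy()
        np.fill_diagonal(r, 1.0)
        r[mask] = rho
    # finish on the PSD side and renormalise to unit diagonal
    d = np.sqrt(np.clip(np.diag(x), 1e-12, None))
    out = x / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out, nodes


def _sample_decoy_pairs(
    rng: np.random.Generator, genes: list[str], truth: set[tuple[str, str]], k: int
) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    while len(pairs) < k:
        a, b = rng.choice(len(genes), size=2, replace=False)
        pair = tuple(sorted((genes[a], genes[b])))
        if pair in truth or pair in seen:
            continue
        seen.add(pair)
        pairs.append(pair)
    return pairs


def generate_interaction_sources(
    truth: SyntheticTruth, config: GenerationConfig
) -> list[pd.DataFrame]:
    """Emit one table per source mixing truth edges and decoy pairs.

    The first four sources carry confidence scores (truth edges drawn from a
    higher-mean distribution than decoys), the fifth a binary ``core_flag``,
    and the remaining ones publication counts — one table per reliability
    filter branch.  Decoy pairs are drawn over the whole gene universe, so
    some edges fall outside the catalog and exercise the catalog filter.

    Each table has columns ``protein_a``, ``protein_b``, ``source`` and one of
    ``score`` / ``core_flag`` / ``pubs``, plus an ``is_true`` ground-truth
    column that the pipeline never reads.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    truth_edges = sorted(truth.truth_edges)
    n_true = max(1, round(_SOURCE_TRUTH_FRACTION * len(truth_edges)))
    f = config.decoy_edge_fraction
    n_decoy = 0 if f == 0 else round(n_true * f / (1.0 - f)) if f < 1 else 0
    kinds = ["score"] * min(4, config.n_sources)
    if config.n_sources >= 5:
        kinds.append("core_flag")
    kinds += ["pubs"] * max(0, config.n_sources - 5)
    tables = []
    for i, kind in enumerate(kinds):
        name = f"{kind}_db{i + 1}"
        chosen = rng.choice(len(truth_edges), size=min(n_true, len(truth_edges)), replace=False)
        edges = [truth_edges[j] for j in sorted(chosen)]
        decoys = _sample_decoy_pairs(rng, truth.genes, truth.truth_edges, n_decoy)
        rows = pd.DataFrame(
            {
                "protein_a": [e[0] for e in edges] + [d[0] for d in decoys],
                "protein_b": [e[1] for e in edges] + [d[1] for d in decoys],
                "source": name,
                "is_true": [True] * len(edges) + [False] * len(decoys),
            }
        )
        nt, nd = len(edges), len(decoys)
        if kind == "score":
            score = np.concatenate(
                [
                    rng.normal(*_SCORE_TRUE, size=nt),
                    rng.normal(*_SCORE_DECOY, size=nd),
                ]
            )
            rows["score"] = np.clip(score, 0.001, 0.999)
        elif kind == "core_flag":
            rows["core_flag"] = np.concatenate(
                [
                    rng.random(nt) < _FLAG_TRUE_P,
                    rng.random(nd) < _FLAG_DECOY_P,
                ]
            )
        else:
            rows["pubs"] = np.concatenate(
                [
                    1 + rng.poisson(_PUBS_TRUE_LAM, size=nt),
                    1 + rng.poisson(_PUBS_DECOY_LAM, size=nd),
                ]
            )
        # shuffle rows so nothing downstream can rely on ordering
        rows = rows.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
        tables.append(rows)
    return tables


def generate_expression_datasets(
    truth: SyntheticTruth, config: GenerationConfig
) -> list[tuple[ExpressionDataset, ExpressionDataset]]:
    """Simulate the case/control expression datasets, two variants each.

    Per dataset: a coverage_fraction subset of genes is "on the array"; case
    samples of planted DEGs are shifted by ±log2(effect_fold); catalog-gene
    residuals are drawn from the edge-pinned correlation model (cases and
    controls from independent draws of the same correlation structure, so the
    marginal distributions of the two groups are identical under the null).
    Variant A is the linear-scale matrix ``2**x``; variant B is a strictly
    monotone affine transform of log2(A) plus small observation noise, so the
    two variants agree in direction but can disagree on marginal calls.
    """
    config.validate()
    if config.cases_per_dataset < 3 or config.controls_per_dataset < 3:
        raise ConfigurationError(
            "need at least 3 cases and 3 controls per dataset for "
            "correlation and t-testing"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = truth.genes
    n_genes = len(genes)
    corr, cat_order = edge_pinned_correlation(truth.graph, config.edge_rho)
    chol = np.linalg.cholesky(corr + 1e-8 * np.eye(len(cat_order))) if len(cat_order) else None
    cat_index = {g: i for i, g in enumerate(cat_order)}

    baseline = pd.Series(
        rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=n_genes), index=genes
    )
    # planted effects: disjoint up/down sets among catalog genes
    n_up = round(config.deg_fraction_up * len(truth.catalog))
    n_down = round(config.deg_fraction_down * len(truth.catalog))
    delta = pd.Series(0.0, index=genes)
    if config.effect_fold > 1.0 and (n_up or n_down):
        picked = rng.choice(len(truth.catalog), size=n_up + n_down, replace=False)
        up = [truth.catalog[i] for i in picked[:n_up]]
        down = [truth.catalog[i] for i in picked[n_up:]]
        truth.planted_up = set(up)
        truth.planted_down = set(down)
        delta[up] = np.log2(config.effect_fold)
        delta[down] = -np.log2(config.effect_fold)

    def residuals(n_samples: int, measured: list[str]) -> np.ndarray:
        """iid-in-sample residual matrix (genes x samples) with the catalog
        correlation structure; non-catalog genes independent."""
        out = rng.standard_normal((len(measured), n_samples))
        rows = [i for i, g in enumerate(measured) if g in cat_index]
        if rows and chol is not None and config.edge_rho != 0.0:
            z = rng.standard_normal((len(cat_order), n_samples))
            corr_z = chol @ z
            for i in rows:
                out[i] = corr_z[cat_index[measured[i]]]
        return out * config.noise_sd

    datasets = []
    for d in range(config.n_datasets):
        ds_id = f"DS{d + 1}"
        n_meas = round(config.coverage_fraction * n_genes)
        meas_idx = sorted(rng.choice(n_genes, size=n_meas, replace=False))
        measured = [genes[i] for i in meas_idx]
        truth.measured_genes[ds_id] = set(measured)
        cases = [f"{ds_id}_case{j + 1:02d}" for j in range(config.cases_per_dataset)]
        controls = [f"{ds_id}_ctrl{j + 1:02d}" for j in range(config.controls_per_dataset)]
        mu = baseline[measured].to_numpy()[:, None]
        case_log2 = mu + delta[measured].to_numpy()[:, None] + residuals(len(cases), measured)
        ctrl_log2 = mu + residuals(len(controls), measured)
        log2 = np.concatenate([case_log2, ctrl_log2], axis=1)
        samples = cases + controls
        groups = {s: CASE for s in cases} | {s: CONTROL for s in controls}
        mat_a = pd.DataFrame(2.0 ** log2, index=pd.Index(measured, name="gene"), columns=samples)
        b_vals = (
            _VARIANT_B_OFFSET
            + _VARIANT_B_SLOPE * log2
            + rng.normal(0.0, _VARIANT_B_NOISE_SD, size=log2.shape)
        )
        mat_b = pd.DataFrame(b_vals, index=pd.Index(measured, name="gene"), columns=samples)
        datasets.append(
            (
                ExpressionDataset(id=ds_id, matrix=mat_a, groups=groups, variant="A", scale="linear"),
                ExpressionDataset(id=ds_id, matrix=mat_b, groups=groups, variant="B", scale="log2"),
            )
        )
    return datasets


def generate_annotations(
    truth: SyntheticTruth, config: GenerationConfig
) -> dict[str, set[str]]:
    """Annotation term sets over the catalog; some planted-DEG-enriched.

    One in five terms (at least one, when any term is requested) draws 60% of
    its members from the planted DEGs, the rest uniformly from the catalog —
    the enrichment stage should rank these terms ahead of the random ones.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    terms: dict[str, set[str]] = {}
    if config.n_terms == 0:
        return terms
    planted = sorted(truth.planted_up | truth.planted_down)
    n_enriched = max(1, config.n_terms // 5) if planted else 0
    catalog = truth.catalog
    for t in range(config.n_terms):
        name = f"TERM{t + 1:03d}"
        if t < n_enriched:
            k_planted = min(len(planted), int(np.ceil(0.6 * config.term_size)))
            members = set(
                planted[i]
                for i in rng.choice(len(planted), size=k_planted, replace=False)
            )
            pool = [g for g in catalog if g not in members]
            extra = config.term_size - len(members)
            members |= {
                pool[i] for i in rng.choice(len(pool), size=max(0, extra), replace=False)
            }
        else:
            members = {
                catalog[i]
                for i in rng.choice(len(catalog), size=config.term_size, replace=False)
            }
        terms[name] = members
    return terms


def generate_all(config: GenerationConfig) -> tuple[SyntheticTruth, list[pd.DataFrame],
                                                    list[tuple[ExpressionDataset, ExpressionDataset]],
                                                    dict[str, set[str]]]:
    """Run all four generators in their canonical order."""
    truth = generate_truth_network(config)
    sources = generate_interaction_sources(truth, config)
    datasets = generate_expression_datasets(truth, config)
    annotations = generate_annotations(truth, config)
    return truth, sources, datasets, annotations


# ---------------------------------------------------------------------------
# on-disk layout


def write_gmt(terms: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(terms):
            members = "\t".join(sorted(terms[name]))
            fh.write(f"{name}\t{name} (synthetic)\t{members}\n")


def write_inputs(config: GenerationConfig, outdir: str | Path) -> dict:
    """Generate everything and write the pipeline's input files.

    Returns a manifest dict describing what was written (also saved as
    ``manifest.json``).  Layout::

        catalog.txt                 one gene symbol per line
        sources/<name>.tsv          interaction source tables
        sources.json                source name/path/filter declaration
        expression/<ds>_<v>.tsv     matrices (first column `gene`)
        expression/<ds>_meta.tsv    sample, group
        annotations.gmt
        truth.json                  ground truth for recovery evaluation
    """
    outdir = Path(outdir)
    (outdir / "sources").mkdir(parents=True, exist_ok=True)
    (outdir / "expression").mkdir(parents=True, exist_ok=True)
    truth, sources, datasets, annotations = generate_all(config)

    (outdir / "catalog.txt").write_text("\n".join(truth.catalog) + "\n")
    source_decl = []
    kind_to_filter = {"score": "score_median", "core_flag": "core_flag", "pubs": "min_pubs"}
    for table in sources:
        name = table["source"].iloc[0]
        kind = name.split("_db")[0]
        rel = f"sources/{name}.tsv"
        table.drop(columns=["is_true"]).to_csv(outdir / rel, sep="\t", index=False,
                                               float_format="%.6g")
        source_decl.append({"name": name, "path": rel, "filter": kind_to_filter[kind]})
    (outdir / "sources.json").write_text(json.dumps({"sources": source_decl}, indent=2) + "\n")

    dataset_decl = []
    for ds_a, ds_b in datasets:
        for ds in (ds_a, ds_b):
            rel = f"expression/{ds.id}_{ds.variant}.tsv"
            write_expression_tsv(ds, outdir / rel)
        write_metadata_tsv(ds_a, outdir / f"expression/{ds_a.id}_meta.tsv")
        dataset_decl.append(
            {
                "id": ds_a.id,
                "variant_a": f"expression/{ds_a.id}_A.tsv",
                "variant_b": f"expression/{ds_a.id}_B.tsv",
                "metadata": f"expression/{ds_a.id}_meta.tsv",
                "scale_a": "linear",
                "scale_b": "log2",
            }
        )
    write_gmt(annotations, outdir / "annotations.gmt")
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                "truth_edges": sorted(map(list, truth.truth_edges)),
                "planted_up": sorted(truth.planted_up),
                "planted_down": sorted(truth.planted_down),
                "term_memberships": {t: sorted(m) for t, m in annotations.items()},
                "measured_genes": {d: sorted(m) for d, m in truth.measured_genes.items()},
            },
            indent=2,
        )
        + "\n"
    )
    manifest = {
        "config": asdict(config),
        "catalog": "catalog.txt",
        "sources": source_decl,
        "datasets": dataset_decl,
        "annotations": "annotations.gmt",
        "truth": "truth.json",
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
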