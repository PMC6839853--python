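"""Configuration-driven orchestration of all analysis stages.

``run_pipeline`` executes, in order: source integration -> catalog
restriction -> co-expression filtering -> consensus differential expression
-> network topology -> enrichment -> sample clustering, writing every stage
output plus a manifest (input hashes, parameters, per-stage counts) and a
summary JSON into the run directory.  ``demo`` generates a synthetic study
with :mod:`mitonet.synthetic` and runs the pipeline on it end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import coexpression, diffexp, enrichment, integration, topology
from .clustering import cluster_samples, flag_misclustered_cases, rerun_after_removal, assignment_table
from .expression import ExpressionDataset, read_expression_tsv
from .synthetic import ConfigurationError, GenerationConfig, write_inputs

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for one pipeline run."""

    sources_config: str = "sources.json"
    catalog_path: str = "catalog.txt"
    datasets: list[dict] = field(default_factory=list)  # entries as in input manifest
    annotations_path: str | None = "annotations.gmt"
    output_dir: str = "run"

    min_pubs: int = 2
    rho_threshold: float = 0.7
    min_support: int = 1
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    fdr_cutoff: float = 0.01
    key_hub_min_neighbours: int = 27
    key_hub_min_degs: int = 7
    enrichment_min_datasets: int = 2
    panel_min_datasets: int = 3

    welch: bool = False
    power_law_method: str = "loglog_ls"
    clustering_linkage: str = "average"
    coexpression_variant: str = "B"
    seed: int = 0

    base_dir: str = "."

    def resolve(self, rel: str | Path) -> Path:
        return Path(self.base_dir) / rel


def validate_config(config: PipelineConfig, *, check_paths: bool = True) -> list[str]:
    """Schema/range checks; returns a list of violations (empty = ok)."""
    v: list[str] = []
    for name in ("rho_threshold",):
        val = getattr(config, name)
        if not 0.0 < val < 1.0:
            v.append(f"{name}={val} must lie in (0, 1)")
    if config.fc_threshold <= 1.0:
        v.append(f"fc_threshold={config.fc_threshold} must be > 1")
    if not 0.0 < config.p_threshold < 1.0:
        v.append(f"p_threshold={config.p_threshold} must lie in (0, 1)")
    if not 0.0 < config.fdr_cutoff < 1.0:
        v.append(f"fdr_cutoff={config.fdr_cutoff} must lie in (0, 1)")
    if config.min_support < 1:
        v.append(f"min_support={config.min_support} must be >= 1")
    if config.min_pubs < 1:
        log.warning("min_pubs=%d keeps single-publication evidence (2 is the usual cut)",
                    config.min_pubs)
    if config.power_law_method not in ("loglog_ls", "discrete_mle"):
        v.append(f"unknown power_law_method {config.power_law_method!r}")
    if config.coexpression_variant not in ("A", "B"):
        v.append(f"coexpression_variant must be 'A' or 'B'")
    if config.key_hub_min_neighbours < 0 or config.key_hub_min_degs < 0:
        v.append("key-hub thresholds must be non-negative")
    if check_paths:
        for p in [config.sources_config, config.catalog_path] + (
            [config.annotations_path] if config.annotations_path else []
        ):
            if not config.resolve(p).exists():
                v.append(f"missing input path: {config.resolve(p)}")
        for ds in config.datasets:
            for key in ("variant_a", "variant_b", "metadata"):
                if not config.resolve(ds[key]).exists():
                    v.append(f"missing input path: {config.resolve(ds[key])}")
    return v


def load_config(path: str | Path) -> PipelineConfig:
    """Read a JSON or YAML pipeline configuration."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    if "base_dir" not in data:
        cfg.base_dir = str(path.parent)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_datasets(config: PipelineConfig) -> list[tuple[ExpressionDataset, ExpressionDataset]]:
    pairs = []
    for entry in config.datasets:
        a = read_expression_tsv(
            config.resolve(entry["variant_a"]), config.resolve(entry["metadata"]),
            id=entry["id"], variant="A", scale=entry.get("scale_a", "linear"),
        )
        b = read_expression_tsv(
            config.resolve(entry["variant_b"]), config.resolve(entry["metadata"]),
            id=entry["id"], variant="B", scale=entry.get("scale_b", "log2"),
        )
        pairs.append((a, b))
    return pairs


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the summary dict."""
    violations = validate_config(config)
    if violations:
        raise ConfigurationError("; ".join(violations))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    manifest: dict = {
        "parameters": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(PipelineConfig)
            if f.name not in ("datasets",)
        },
        "inputs": {},
    }
    for p in [config.sources_config, config.catalog_path]:
        manifest["inputs"][str(p)] = _sha256(config.resolve(p))
    if config.annotations_path:
        manifest["inputs"][str(config.annotations_path)] = _sha256(
            config.resolve(config.annotations_path)
        )
    for entry in config.datasets:
        for key in ("variant_a", "variant_b", "metadata"):
            manifest["inputs"][str(entry[key])] = _sha256(config.resolve(entry[key]))

    stage = "integrate"
    try:
        tables, rules = integration.read_source_tables(config.resolve(config.sources_config))
        catalog = integration.read_catalog(config.resolve(config.catalog_path))
        interactome = integration.integrate(
            tables, catalog, rules=rules, min_pubs=config.min_pubs
        )
        integration.write_edge_list(interactome, outdir / "interactome.tsv")
        summary["stages"][stage] = dict(interactome.stage_counts)

        stage = "de"
        pairs = _load_datasets(config)
        consensus = diffexp.consensus_table(
            pairs,
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
            equal_var=not config.welch,
        )
        consensus.to_csv(outdir / "consensus_degs.tsv", sep="\t")
        summary["stages"][stage] = {
            "degs": len(consensus),
            "up": int((consensus["regulation"] == "Up").sum()),
            "down": int((consensus["regulation"] == "Down").sum()),
            "mixed": int((consensus["regulation"] == "Mixed").sum()),
        }

        stage = "coexpress"
        chosen = [a if config.coexpression_variant == "A" else b for a, b in pairs]
        kept_edges, supports = coexpression.filter_coexpressed(
            interactome, chosen,
            rho_threshold=config.rho_threshold, min_support=config.min_support,
        )
        histogram = coexpression.support_histogram(supports)
        coexpression.write_edge_support_tsv(
            supports, [d.id for d in chosen], outdir / "edge_support.tsv"
        )
        coexpression.write_support_histogram(histogram, outdir / "support_histogram.json")
        summary["stages"][stage] = {
            "edges_in": len(interactome.edges),
            "edges_kept": len(kept_edges),
            "support_histogram": {str(k): v for k, v in histogram.items()},
        }

        stage = "topology"
        classes = dict(consensus["regulation"])
        support_counts = {s.edge: s.support for s in supports}
        network = topology.build_graph(kept_edges, classes, supports=support_counts)
        records = topology.rank_hubs(network, top_n=None)
        fit = None
        if network.n_nodes:
            dist = topology.degree_distribution(network)
            if len([k for k, p in dist.items() if k >= 1 and p > 0]) >= 3:
                fit = topology.fit_power_law(dist, method=config.power_law_method)
        topology.hub_table(records[:50]).to_csv(outdir / "hubs.tsv", sep="\t", index=False)
        key = topology.select_key_hubs(
            records,
            min_neighbours=config.key_hub_min_neighbours,
            min_degs=config.key_hub_min_degs,
        )
        topology.hub_table(key).to_csv(outdir / "key_hubs.tsv", sep="\t", index=False)
        topology.export_graph(network, outdir / "network.graphml", "graphml")
        topology.export_graph(network, outdir / "network.xgmml", "xgmml")
        summary["stages"][stage] = topology.topology_summary(network, fit)
        summary["stages"][stage]["key_hubs"] = len(key)

        stage = "enrich"
        if config.annotations_path:
            terms, descriptions = enrichment.read_gmt(config.resolve(config.annotations_path))
            query = sorted(
                consensus.index[consensus["n_selected"] >= config.enrichment_min_datasets]
            )
            background = sorted(set(network.nodes) | set(query))
            all_records, significant = enrichment.enrich(
                query, terms, background,
                fdr_cutoff=config.fdr_cutoff, descriptions=descriptions,
            )
            enrichment.write_enrichment_tsv(all_records, outdir / "enrichment.tsv")
            summary["stages"][stage] = {
                "terms_tested": len(all_records),
                "significant": len(significant),
                "query_size": len(query),
                "background_size": len(background),
            }

        stage = "cluster"
        panel = sorted(consensus.index[consensus["n_selected"] >= config.panel_min_datasets])
        flagged: dict[str, list[str]] = {}
        if len(panel) >= 2:
            rows = []
            for ds_a, ds_b in pairs:
                chosen_ds = ds_a if config.coexpression_variant == "A" else ds_b
                try:
                    assignment = cluster_samples(
                        chosen_ds, panel, linkage_method=config.clustering_linkage
                    )
                except ValueError as exc:
                    log.warning("clustering skipped for %s: %s", ds_a.id, exc)
                    continue
                mis = flag_misclustered_cases(assignment, chosen_ds.groups)
                if mis:
                    flagged[ds_a.id] = mis
                rows.append(assignment_table(assignment, chosen_ds.groups).assign(dataset=ds_a.id))
            if rows:
                import pandas as pd

                pd.concat(rows).to_csv(outdir / "cluster_assignments.tsv", sep="\t", index=False)
            report = rerun_after_removal(
                pairs, flagged,
                min_datasets=config.panel_min_datasets,
                fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
            )
            (outdir / "rerun_report.json").write_text(
                json.dumps(
                    {k: v for k, v in report.items() if not k.endswith("_table")},
                    indent=2,
                )
                + "\n"
            )
            summary["stages"][stage] = {
                "panel_size": len(panel),
                "flagged_samples": {k: len(v) for k, v in flagged.items()},
                "degs_lost": len(report["lost"]),
                "degs_gained": len(report["gained"]),
            }
        else:
            summary["stages"][stage] = {"panel_size": len(panel), "skipped": True}
    except ConfigurationError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageFailure(stage, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def demo(seed: int = 0, outdir: str | Path = "demo_run",
         generation: GenerationConfig | None = None) -> dict:
    """One-command synthetic end-to-end run.

    Generates a synthetic study (inputs under ``<outdir>/inputs``), builds a
    pipeline configuration for it, and runs all stages (outputs under
    ``<outdir>/run``).  Returns the summary dict.
    """
    outdir = Path(outdir)
    gen = generation or GenerationConfig(seed=seed)
    manifest = write_inputs(gen, outdir / "inputs")
    config = PipelineConfig(
        sources_config="sources.json",
        catalog_path="catalog.txt",
        datasets=manifest["datasets"],
        annotations_path="annotations.gmt",
        output_dir=str(outdir / "run"),
        base_dir=str(outdir / "inputs"),
        seed=seed,
    )
    return run_pipeline(config)
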