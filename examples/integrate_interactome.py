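"""Reliability-filter seven interaction sources and merge them.

Score-bearing sources keep interactions strictly above their own score
median, the quality-flagged source keeps core-status interactions, and
publication-count sources keep interactions with at least two papers.  The
union is deduplicated and restricted to the organelle catalog.
"""

from mitonet import GenerationConfig, generate_interaction_sources, generate_truth_network, integrate

config = GenerationConfig(seed=0)
truth = generate_truth_network(config)
sources = generate_interaction_sources(truth, config)

interactome = integrate(sources, truth.catalog)
counts = interactome.stage_counts
print(f"records across sources:   {counts['records_before_filters']}")
print(f"after per-source filters: {counts['records_in']}")
print(f"merged unique edges:      {counts['merged_edges']}")
print(f"catalog-restricted edges: {counts['catalog_edges']} "
      f"({counts['catalog_genes_covered']} catalog genes, "
      f"{100 * counts['catalog_coverage_fraction']:.0f}% coverage)")

truth_kept = len(interactome.edges & truth.truth_edges)
print(f"of these, {truth_kept} are truth edges and "
      f"{len(interactome.edges) - truth_kept} decoys survived filtering")
# The reliability filters should enrich for truth edges: decoys draw lower
# scores/flags/publication counts, so most are removed at their source.
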