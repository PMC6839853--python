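"""Therapy-effect check: hierarchical clustering of samples on a gene panel.

Samples are clustered on the z-scored expression of a selected gene panel
(agglomerative, average linkage, Euclidean distance, tree cut at two groups).
Case samples falling into the control-majority cluster are flagged as
"misclustered" — the signature of a treatment pulling diseased expression
toward the healthy profile — removed, and the consensus differential-
expression analysis is repeated to report which genes are gained or lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .diffexp import consensus_table
from .expression import CASE, CONTROL, ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Two-group sample clustering with case/control composition."""

    labels: dict[str, int]                       # sample -> cluster (1 or 2)
    composition: dict[int, dict[str, int]]       # cluster -> {case: n, control: n}
    misclustered_cases: list[str] = field(default_factory=list)
    control_majority_cluster: int | None = None
    degenerate: bool = False


def cluster_samples(
    dataset: ExpressionDataset,
    gene_panel,
    *,
    linkage_method: str = "average",
    metric: str = "euclidean",
) -> ClusterAssignment:
    """Cluster samples on the panel genes, cut the tree at two groups.

    Rows are restricted to the panel and z-scored per gene (so per-gene
    affine rescaling cannot change the result); zero-variance genes are
    skipped.  Panel genes absent from the matrix are skipped with a log line.
    """
    panel = [g for g in gene_panel if g in set(dataset.genes)]
    missing = len(list(gene_panel)) - len(panel)
    if missing:
        log.info("%s: %d panel genes absent from the matrix", dataset.id, missing)
    if len(panel) < 2:
        raise ValueError(f"{dataset.id}: fewer than 2 panel genes present")
    if dataset.matrix.shape[1] < 4:
        raise ValueError(f"{dataset.id}: need at least 4 samples to cluster")
    mat = dataset.log2_matrix().loc[panel]
    sd = mat.std(axis=1, ddof=0)
    keep = sd > 0
    degenerate = False
    if not keep.any():
        # identical samples: any 2-cut is valid; flag it
        degenerate = True
        z = mat.to_numpy() * 0.0
    else:
        mat = mat[keep]
        z = ((mat.sub(mat.mean(axis=1), axis=0)).div(mat.std(axis=1, ddof=0), axis=0)).to_numpy()
    samples = sorted(dataset.matrix.columns)
    order = [list(dataset.matrix.columns).index(s) for s in samples]
    x = z.T[order]  # samples x genes, in sample-name order for order invariance
    lk = linkage(x, method=linkage_method, metric=metric)
    cut = fcluster(lk, t=2, criterion="maxclust")
    if len(set(cut)) < 2:
        degenerate = True
    labels = {s: int(c) for s, c in zip(samples, cut)}
    composition: dict[int, dict[str, int]] = {}
    for s, c in labels.items():
        composition.setdefault(c, {CASE: 0, CONTROL: 0})[dataset.groups[s]] += 1
    return ClusterAssignment(labels=labels, composition=composition, degenerate=degenerate)


def flag_misclustered_cases(
    assignment: ClusterAssignment, groups: dict[str, str]
) -> list[str]:
    """Case samples sitting in the control-majority cluster.

    The cluster holding the larger number of controls is the control-majority
    cluster; on a tie no removal is proposed and both clusters are reported
    via ``control_majority_cluster = None``.
    """
    controls_per_cluster = {
        c: comp.get(CONTROL, 0) for c, comp in assignment.composition.items()
    }
    ranked = sorted(controls_per_cluster.items(), key=lambda kv: -kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        log.info("control composition tied between clusters; no removal proposed")
        assignment.control_majority_cluster = None
        assignment.misclustered_cases = []
        return []
    majority = ranked[0][0]
    assignment.control_majority_cluster = majority
    flagged = sorted(
        s
        for s, c in assignment.labels.items()
        if c == majority and groups[s] == CASE
    )
    assignment.misclustered_cases = flagged
    return flagged


def rerun_after_removal(
    dataset_pairs: list[tuple[ExpressionDataset, ExpressionDataset]],
    flagged_samples: dict[str, list[str]],
    *,
    min_datasets: int = 1,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> dict:
    """Repeat the consensus DE analysis without the flagged case samples.

    ``flagged_samples`` maps dataset id -> samples to drop.  Datasets left
    with fewer than two cases are excluded with a warning.  Returns a report
    with the original and re-run DEG sets and the genes gained/lost.
    """
    for ds_id, samples in flagged_samples.items():
        pair = next((p for p in dataset_pairs if p[0].id == ds_id), None)
        if pair is None:
            raise ValueError(f"flagged samples for unknown dataset {ds_id!r}")
        non_cases = [s for s in samples if pair[0].groups.get(s) != CASE]
        if non_cases:
            raise ValueError(f"{ds_id}: flagged samples are not cases: {non_cases}")
    original = consensus_table(
        dataset_pairs, fc_threshold=fc_threshold, p_threshold=p_threshold,
        min_datasets=min_datasets,
    )
    reduced_pairs = []
    excluded = []
    for ds_a, ds_b in dataset_pairs:
        drop = set(flagged_samples.get(ds_a.id, []))
        if not drop:
            reduced_pairs.append((ds_a, ds_b))
            continue
        keep = [s for s in ds_a.matrix.columns if s not in drop]
        ra, rb = ds_a.subset_samples(keep), ds_b.subset_samples(keep)
        if len(ra.case_samples) < 2:
            log.warning("%s: removal leaves <2 cases; dataset excluded", ds_a.id)
            excluded.append(ds_a.id)
            continue
        reduced_pairs.append((ra, rb))
    rerun = consensus_table(
        reduced_pairs, fc_threshold=fc_threshold, p_threshold=p_threshold,
        min_datasets=min_datasets,
    )
    before = set(original.index)
    after = set(rerun.index)
    return {
        "original_degs": sorted(before),
        "rerun_degs": sorted(after),
        "lost": sorted(before - after),
        "gained": sorted(after - before),
        "retained_fraction": (len(before & after) / len(before)) if before else 1.0,
        "excluded_datasets": excluded,
        "original_table": original,
        "rerun_table": rerun,
    }


def assignment_table(assignment: ClusterAssignment, groups: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": s,
                "group": groups[s],
                "cluster": c,
                "misclustered": s in set(assignment.misclustered_cases),
            }
            for s, c in sorted(assignment.labels.items())
        ]
    )
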