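"""Per-dataset differential expression and cross-dataset consensus calls.

A gene is differentially expressed in one dataset/variant when its linear
case/control fold change exceeds 1.5 in either direction and its two-sample
t-test p-value is below 0.05 (uncorrected by design: the organelle gene list
is small and the calls feed an integrative analysis, so no multiple-testing
adjustment is applied at this stage).  Each dataset is analysed under two
normalization variants; a gene is *selected* in a dataset when both variants
call it in the same direction.  Study-wide, a gene is a DEG when it is
selected in at least one dataset, or called by complementary variants (A-only
in one dataset, B-only in another, same direction) in at least two datasets.
Consensus classes: Up (up somewhere, down nowhere), Down (mirror), Mixed
(both directions observed), NotDE.

Fold changes are always reported on the linear scale (log2-scale matrices are
exponentiated first) so the 1.5 cut means the same under both normalizations;
t-tests are computed on the log2 scale (linear matrices are log-transformed
first), the usual variance-stabilized scale for array intensities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionDataset

log = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NONE = "none"

FC_THRESHOLD = 1.5
P_THRESHOLD = 0.05


@dataclass(frozen=True)
class GeneDatasetCall:
    gene: str
    dataset: str
    variant: str
    fold_change: float
    p_value: float
    direction: str


@dataclass(frozen=True)
class ConsensusCall:
    gene: str
    n_datasets_up: int
    n_datasets_down: int
    n_selected: int
    regulation: str
    max_fold_change_linear: float | None = None
    max_fold_change_log2: float | None = None


def group_fold_change(case_values, control_values, scale: str = "linear") -> float:
    """Linear-scale ratio of case mean to control mean.

    log2-scale inputs are exponentiated per value first, so the ratio is a
    ratio of linear-scale means under both normalizations.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be nonempty")
    if scale == "log2":
        case = 2.0 ** case
        control = 2.0 ** control
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    if (case <= 0).any() or (control <= 0).any():
        raise ValueError("linear-scale intensities must be positive")
    denom = control.mean()
    if denom == 0:
        raise ValueError("control mean is zero; fold change undefined")
    return float(case.mean() / denom)


def two_sample_t(case_values, control_values, *, equal_var: bool = True) -> float:
    """Two-sided p of the two-sample independent t-test.

    Pooled-variance (classical) by default; Welch with ``equal_var=False``.
    When both groups are constant the convention is p = 1 for equal means
    (t = 0) and p = 0 for unequal means.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("need at least 2 values per group")
    if case.std(ddof=1) == 0.0 and control.std(ddof=1) == 0.0:
        return 1.0 if case.mean() == control.mean() else 0.0
    res = stats.ttest_ind(case, control, equal_var=equal_var)
    return float(res.pvalue)


def call_dataset(
    dataset: ExpressionDataset,
    *,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene calls for one dataset/variant (vectorized over genes).

    Returns a DataFrame indexed by gene with columns ``fold_change``,
    ``p_value`` and ``direction``; semantics per gene are identical to
    :func:`group_fold_change` + :func:`two_sample_t`.
    """
    cases = dataset.case_samples
    controls = dataset.control_samples
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError(f"{dataset.id}: need >=2 samples per group")
    lin = dataset.linear_matrix()
    fc = lin[cases].mean(axis=1) / lin[controls].mean(axis=1)
    logm = dataset.log2_matrix()
    cm = logm[cases].to_numpy()
    km = logm[controls].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(cm, km, axis=1, equal_var=equal_var).pvalue
    # zero-variance convention (vectorized counterpart of two_sample_t)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(cm.mean(axis=1), km.mean(axis=1))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
    direction = np.full(len(fc), NONE, dtype=object)
    sig = p < p_threshold
    direction[np.asarray(fc > fc_threshold) & sig] = UP
    direction[np.asarray(fc < 1.0 / fc_threshold) & sig] = DOWN
    return pd.DataFrame(
        {"fold_change": fc, "p_value": p, "direction": direction},
        index=dataset.genes,
    )


def dataset_selection(calls_a: pd.DataFrame, calls_b: pd.DataFrame, *, dataset: str = "") -> pd.DataFrame:
    """Combine the two normalization variants of one dataset.

    A gene is *selected* (column ``direction``) only when both variants call
    it in the same direction; single-variant calls are retained in ``a_only``
    / ``b_only`` for the cross-dataset complementary rule, and contradictory
    calls (A up, B down) are flagged in ``conflict``.
    """
    common = calls_a.index.intersection(calls_b.index)
    if len(common) < len(calls_a) or len(common) < len(calls_b):
        log.info(
            "dataset %s: variant gene sets differ (%d vs %d); using %d common genes",
            dataset, len(calls_a), len(calls_b), len(common),
        )
    a = calls_a.loc[common, "direction"]
    b = calls_b.loc[common, "direction"]
    agree = (a == b) & (a != NONE)
    conflict = (a != NONE) & (b != NONE) & (a != b)
    out = pd.DataFrame(index=common)
    out["direction"] = np.where(agree, a, NONE)
    out["a_only"] = np.where((a != NONE) & (b == NONE), a, NONE)
    out["b_only"] = np.where((b != NONE) & (a == NONE), b, NONE)
    out["conflict"] = conflict
    n_conf = int(conflict.sum())
    if n_conf:
        log.info("dataset %s: %d genes with contradictory variant calls", dataset, n_conf)
    return out


def cross_dataset_selection(selections: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Study-wide DEG qualification and per-dataset direction counts.

    A gene qualifies when (a) it is selected by both variants in >=1 dataset,
    or (b) it has an A-only call in one dataset and a B-only call in a
    different dataset, in the same direction.  For a qualifying gene, a
    dataset counts toward ``n_up``/``n_down`` when it supports that direction
    either by both-variant agreement or by a single-variant call.
    """
    genes: set[str] = set()
    for sel in selections.values():
        genes |= set(sel.index)
    rows = []
    for gene in sorted(genes):
        strong: dict[str, str] = {}
        weak: dict[str, tuple[str, str]] = {}  # dataset -> (direction, variant)
        for ds, sel in selections.items():
            if gene not in sel.index:
                continue
            row = sel.loc[gene]
            if row["direction"] != NONE:
                strong[ds] = row["direction"]
            elif row["a_only"] != NONE:
                weak[ds] = (row["a_only"], "A")
            elif row["b_only"] != NONE:
                weak[ds] = (row["b_only"], "B")
        qualifies = bool(strong)
        if not qualifies:
            for direction in (UP, DOWN):
                has_a = any(d == direction and v == "A" for d, v in weak.values())
                has_b = any(d == direction and v == "B" for d, v in weak.values())
                if has_a and has_b and sum(d == direction for d, _ in weak.values()) >= 2:
                    qualifies = True
        if not qualifies:
            continue
        directions = dict(strong)
        for ds, (d, _v) in weak.items():
            directions.setdefault(ds, d)
        n_up = sum(d == UP for d in directions.values())
        n_down = sum(d == DOWN for d in directions.values())
        rows.append(
            {
                "gene": gene,
                "n_up": n_up,
                "n_down": n_down,
                "n_selected": n_up + n_down,
                "datasets": sorted(directions),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_up", "n_down", "n_selected", "datasets"]).set_index("gene") if rows else pd.DataFrame(
        columns=["n_up", "n_down", "n_selected", "datasets"]
    )


def classify_regulation(n_up: int, n_down: int) -> str:
    """Consensus class from per-dataset direction counts.

    Up: up-regulated in >=1 dataset and down in none; Down: the mirror case;
    Mixed: both directions observed; NotDE otherwise.
    """
    if n_up < 0 or n_down < 0:
        raise ValueError("direction counts must be non-negative")
    if n_up >= 1 and n_down == 0:
        return "Up"
    if n_down >= 1 and n_up == 0:
        return "Down"
    if n_up >= 1 and n_down >= 1:
        return "Mixed"
    return "NotDE"


def truncate_log2(linear_fc: float) -> float:
    """log2 of a linear fold change, truncated toward zero at 2 decimals.

    The reporting convention for the consensus table: e.g. 7.94 -> 2.98 and
    30.45 -> 4.92 (rounding would give 2.99 / 4.93).  Full precision is kept
    internally; only reported values are truncated.
    """
    if linear_fc <= 0:
        raise ValueError("fold change must be positive")
    v = math.log2(linear_fc)
    return math.trunc(round(v * 100, 6)) / 100.0


def max_fold_change(gene: str, all_calls: list[pd.DataFrame]) -> tuple[float, float]:
    """The gene's fold change of largest magnitude deviation from 1.

    Scanned across all dataset/variant call tables where the gene received a
    directional call; returns (linear, truncated log2).
    """
    best = None
    for calls in all_calls:
        if gene not in calls.index:
            continue
        row = calls.loc[gene]
        if row["direction"] == NONE:
            continue
        fc = float(row["fold_change"])
        if best is None or abs(math.log2(fc)) > abs(math.log2(best)):
            best = fc
    if best is None:
        raise ValueError(f"{gene}: no passing call in any dataset/variant")
    return best, truncate_log2(best)


def consensus_table(
    dataset_pairs: list[tuple[ExpressionDataset, ExpressionDataset]],
    *,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    equal_var: bool = True,
    min_datasets: int = 1,
) -> pd.DataFrame:
    """Run the full consensus pipeline over (variant A, variant B) pairs.

    Returns one row per study-wide DEG selected in >= ``min_datasets``
    datasets, with the consensus-table columns: ``n_up``, ``n_down``,
    ``n_selected``, ``regulation``, ``max_fc_linear``, ``max_fc_log2``.
    """
    all_calls: list[pd.DataFrame] = []
    selections: dict[str, pd.DataFrame] = {}
    for ds_a, ds_b in dataset_pairs:
        if ds_a.id != ds_b.id:
            raise ValueError(f"variant pair ids differ: {ds_a.id} vs {ds_b.id}")
        calls_a = call_dataset(ds_a, fc_threshold=fc_threshold, p_threshold=p_threshold,
                               equal_var=equal_var)
        calls_b = call_dataset(ds_b, fc_threshold=fc_threshold, p_threshold=p_threshold,
                               equal_var=equal_var)
        all_calls += [calls_a, calls_b]
        selections[ds_a.id] = dataset_selection(calls_a, calls_b, dataset=ds_a.id)
    crossed = cross_dataset_selection(selections)
    rows = []
    for gene, rec in crossed.iterrows():
        if rec["n_selected"] < min_datasets:
            continue
        lin, lg2 = max_fold_change(gene, all_calls)
        rows.append(
            {
                "gene": gene,
                "n_up": int(rec["n_up"]),
                "n_down": int(rec["n_down"]),
                "n_selected": int(rec["n_selected"]),
                "regulation": classify_regulation(int(rec["n_up"]), int(rec["n_down"])),
                "max_fc_linear": lin,
                "max_fc_log2": lg2,
            }
        )
    cols = ["gene", "n_up", "n_down", "n_selected", "regulation", "max_fc_linear", "max_fc_log2"]
    out = pd.DataFrame(rows, columns=cols)
    return out.set_index("gene")


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_to_gene: dict[str, str],
    *,
    policy: str = "max-mean",
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    Policies: ``max-mean`` takes the probe with the highest mean intensity;
    ``best-p`` the probe with the smallest case/control t-test p (requires
    ``groups``); ``any-probe-passes`` the probe with the largest |log2 fold
    change| (so a gene passes a fold-change cut whenever any of its probes
    would; requires ``groups``).  Unmapped probes are dropped and counted.
    """
    mapped = [p for p in probe_matrix.index if p in probe_to_gene]
    dropped = len(probe_matrix) - len(mapped)
    if dropped:
        log.info("collapse_probes: dropped %d unmapped probes", dropped)
    sub = probe_matrix.loc[mapped]
    if policy == "max-mean":
        score = sub.mean(axis=1)
    elif policy in ("best-p", "any-probe-passes"):
        if groups is None:
            raise ValueError(f"policy {policy!r} requires group labels")
        cases = [s for s in sub.columns if groups.get(s) == "case"]
        controls = [s for s in sub.columns if groups.get(s) == "control"]
        if policy == "best-p":
            p = stats.ttest_ind(sub[cases], sub[controls], axis=1).pvalue
            score = pd.Series(-np.nan_to_num(p, nan=1.0), index=sub.index)
        else:
            fc = sub[cases].mean(axis=1) / sub[controls].mean(axis=1)
            score = np.abs(np.log2(fc))
    else:
        raise ValueError(f"unknown collapse policy {policy!r}")
    frame = sub.assign(_gene=[probe_to_gene[p] for p in sub.index], _score=score)
    best = frame.sort_values("_score").groupby("_gene").tail(1)
    out = best.drop(columns=["_gene", "_score"])
    out.index = pd.Index(best["_gene"], name="gene")
    return out.sort_index()
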