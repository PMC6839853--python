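"""Fold changes, t-tests, the dual-normalization rules and consensus classes."""

import numpy as np
import pandas as pd
import pytest

from mitonet import (
    GenerationConfig,
    call_dataset,
    classify_regulation,
    collapse_probes,
    consensus_table,
    cross_dataset_selection,
    dataset_selection,
    generate_expression_datasets,
    generate_truth_network,
    group_fold_change,
    max_fold_change,
    truncate_log2,
    two_sample_t,
)
from mitonet.expression import ExpressionDataset


class TestGroupFoldChange:
    def test_linear_ratio(self):
        assert group_fold_change([4, 4], [2, 2], "linear") == pytest.approx(2.0)

    def test_equal_groups_give_unity(self):
        assert group_fold_change([3, 3], [3, 3], "linear") == pytest.approx(1.0)

    def test_log2_inputs_exponentiated_first(self):
        assert group_fold_change([2, 2], [1, 1], "log2") == pytest.approx(2.0)

    def test_nonpositive_linear_rejected(self):
        with pytest.raises(ValueError):
            group_fold_change([1, -1], [1, 1], "linear")


class TestTwoSampleT:
    def test_identical_groups_give_p_one(self):
        assert two_sample_t([5, 5, 5], [5, 5, 5]) == 1.0

    def test_pooled_t_matches_hand_computation(self):
        """case [10,11,12] vs control [1,2,3]: pooled sd 1, se sqrt(2/3),
        t = 9/sqrt(2/3) = 11.0227, df 4, two-sided p = 3.8507e-4."""
        p = two_sample_t([10, 11, 12], [1, 2, 3])
        assert p == pytest.approx(3.8507e-4, rel=1e-3)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1, 2, 3])

    def test_constant_unequal_groups_give_p_zero(self):
        assert two_sample_t([2, 2, 2], [3, 3, 3]) == 0.0

    def test_welch_flag_changes_unbalanced_variances(self):
        case = [10.0, 12, 14, 30]
        control = [9.9, 10.0, 10.1, 10.05]
        assert two_sample_t(case, control) != two_sample_t(case, control, equal_var=False)


def _dataset(case_rows, ctrl_rows, genes, *, id="D", variant="A", scale="linear"):
    case_rows = np.asarray(case_rows, float)
    ctrl_rows = np.asarray(ctrl_rows, float)
    cases = [f"{id}c{i}" for i in range(case_rows.shape[1])]
    ctrls = [f"{id}k{i}" for i in range(ctrl_rows.shape[1])]
    mat = pd.DataFrame(
        np.hstack([case_rows, ctrl_rows]), index=genes, columns=cases + ctrls
    )
    groups = {s: "case" for s in cases} | {s: "control" for s in ctrls}
    return ExpressionDataset(id=id, matrix=mat, groups=groups, variant=variant, scale=scale)


def _calls(directions, fc=None, genes=None):
    genes = genes or [f"g{i}" for i in range(len(directions))]
    fc = fc or [2.0 if d == "up" else 0.4 if d == "down" else 1.0 for d in directions]
    return pd.DataFrame(
        {"fold_change": fc, "p_value": 0.01, "direction": directions}, index=genes
    )


class TestCallDataset:
    def test_direction_consistency_invariant(self, synthetic_study):
        """direction=up <=> FC>1.5 and p<0.05 on every emitted call."""
        for ds_a, ds_b in synthetic_study["datasets"][:2]:
            for ds in (ds_a, ds_b):
                calls = call_dataset(ds)
                up = (calls["fold_change"] > 1.5) & (calls["p_value"] < 0.05)
                down = (calls["fold_change"] < 1 / 1.5) & (calls["p_value"] < 0.05)
                assert ((calls["direction"] == "up") == up).all()
                assert ((calls["direction"] == "down") == down).all()

    def test_no_multiple_testing_adjustment(self):
        """Emitted p-values equal raw per-gene t-test p-values."""
        rng = np.random.default_rng(0)
        ds = _dataset(rng.uniform(1, 9, (50, 5)), rng.uniform(1, 9, (50, 4)),
                      [f"g{i}" for i in range(50)])
        calls = call_dataset(ds)
        log2 = ds.log2_matrix()
        for gene in list(calls.index)[::7]:
            raw = two_sample_t(log2.loc[gene, ds.case_samples], log2.loc[gene, ds.control_samples])
            assert calls.loc[gene, "p_value"] == pytest.approx(raw)


class TestSelectionRules:
    def test_both_variants_same_direction_selected(self):
        sel = dataset_selection(_calls(["up"]), _calls(["up"]))
        assert sel["direction"].iloc[0] == "up"

    def test_single_variant_retained_but_not_selected(self):
        sel = dataset_selection(_calls(["up"]), _calls(["none"]))
        assert sel["direction"].iloc[0] == "none"
        assert sel["a_only"].iloc[0] == "up"

    def test_contradictory_variants_conflict(self):
        sel = dataset_selection(_calls(["up"]), _calls(["down"]))
        assert sel["direction"].iloc[0] == "none"
        assert bool(sel["conflict"].iloc[0])

    def test_one_strong_dataset_qualifies(self):
        sel = dataset_selection(_calls(["up"]), _calls(["up"]))
        crossed = cross_dataset_selection({"d1": sel})
        assert crossed.loc["g0", "n_up"] == 1

    def test_complementary_rule_qualifies(self):
        """A-only up in one dataset + B-only up in another => DEG."""
        d1 = dataset_selection(_calls(["up"]), _calls(["none"]))
        d2 = dataset_selection(_calls(["none"]), _calls(["up"]))
        crossed = cross_dataset_selection({"d1": d1, "d2": d2})
        assert crossed.loc["g0", "n_up"] == 2

    def test_single_lone_call_does_not_qualify(self):
        d1 = dataset_selection(_calls(["up"]), _calls(["none"]))
        crossed = cross_dataset_selection({"d1": d1})
        assert "g0" not in crossed.index

    def test_same_variant_twice_does_not_qualify(self):
        """Two A-only calls are not complementary evidence."""
        d1 = dataset_selection(_calls(["up"]), _calls(["none"]))
        d2 = dataset_selection(_calls(["up"]), _calls(["none"]))
        crossed = cross_dataset_selection({"d1": d1, "d2": d2})
        assert "g0" not in crossed.index


class TestClassification:
    @pytest.mark.parametrize(
        "n_up,n_down,expected",
        [(3, 0, "Up"), (0, 3, "Down"), (3, 1, "Mixed"), (0, 0, "NotDE"), (1, 0, "Up")],
    )
    def test_classes(self, n_up, n_down, expected):
        assert classify_regulation(n_up, n_down) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_regulation(-1, 0)


class TestMaxFoldChange:
    @pytest.mark.parametrize(
        "linear,expected",
        [(30.45, 4.92), (7.94, 2.98), (1.0, 0.0), (0.38, -1.39), (3.22, 1.68)],
    )
    def test_truncation_convention(self, linear, expected):
        assert truncate_log2(linear) == pytest.approx(expected, abs=1e-12)

    def test_largest_deviation_wins(self):
        calls = [
            _calls(["up"], fc=[2.0], genes=["g"]),
            _calls(["down"], fc=[0.2], genes=["g"]),  # |log2 0.2| > |log2 2|
        ]
        lin, lg2 = max_fold_change("g", calls)
        assert lin == 0.2
        assert lg2 == pytest.approx(-2.32)

    def test_no_passing_call_rejected(self):
        with pytest.raises(ValueError):
            max_fold_change("g", [_calls(["none"], genes=["g"])])


class TestCollapseProbes:
    def test_single_probe_identity(self):
        mat = pd.DataFrame([[1.0, 2.0]], index=["p1"], columns=["s1", "s2"])
        out = collapse_probes(mat, {"p1": "GENE"})
        assert list(out.index) == ["GENE"]
        assert np.array_equal(out.values, mat.values)

    def test_max_mean_policy_picks_brightest_probe(self):
        mat = pd.DataFrame(
            [[5.0, 5.0], [50.0, 50.0]], index=["p1", "p2"], columns=["s1", "s2"]
        )
        out = collapse_probes(mat, {"p1": "G", "p2": "G"})
        assert out.loc["G", "s1"] == 50.0

    def test_policies_match_brute_force(self, rng):
        genes = [f"G{i}" for i in range(10)]
        probes, mapping = [], {}
        for g in genes:
            for j in range(3):
                p = f"{g}_p{j}"
                probes.append(p)
                mapping[p] = g
        mat = pd.DataFrame(
            rng.uniform(1, 100, (len(probes), 6)), index=probes,
            columns=[f"s{i}" for i in range(6)],
        )
        groups = {f"s{i}": ("case" if i < 3 else "control") for i in range(6)}
        out = collapse_probes(mat, mapping, policy="max-mean")
        for g in genes:
            rows = mat.loc[[p for p in probes if mapping[p] == g]]
            expected = rows.loc[rows.mean(axis=1).idxmax()]
            assert np.array_equal(out.loc[g].values, expected.values)
        out_fc = collapse_probes(mat, mapping, policy="any-probe-passes", groups=groups)
        for g in genes:
            rows = mat.loc[[p for p in probes if mapping[p] == g]]
            fc = rows[["s0", "s1", "s2"]].mean(axis=1) / rows[["s3", "s4", "s5"]].mean(axis=1)
            expected = rows.loc[np.abs(np.log2(fc)).idxmax()]
            assert np.array_equal(out_fc.loc[g].values, expected.values)

    def test_unmapped_probes_dropped(self):
        mat = pd.DataFrame([[1.0], [2.0]], index=["p1", "px"], columns=["s1"])
        out = collapse_probes(mat, {"p1": "G"})
        assert list(out.index) == ["G"]


class TestPlantedRecovery:
    def test_strong_effects_recovered_with_high_precision_and_recall(self):
        """Planted DEGs at threefold effect: consensus recovers >=90% with
        matching direction and few spurious genes."""
        cfg = GenerationConfig(seed=21, effect_fold=3.0)
        truth = generate_truth_network(cfg)
        pairs = generate_expression_datasets(truth, cfg)
        table = consensus_table(pairs)
        called_up = set(table.index[table["regulation"] == "Up"])
        called_down = set(table.index[table["regulation"] == "Down"])
        tp = len(called_up & truth.planted_up) + len(called_down & truth.planted_down)
        called = len(table)
        planted = len(truth.planted_up) + len(truth.planted_down)
        assert tp / planted >= 0.9      # recall with matching direction
        assert tp / called >= 0.9       # precision
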