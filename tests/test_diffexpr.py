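"""Differential expression: normalisation, tests, BH, calling, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lincnet as ln
from lincnet.diffexpr import DEResult
from lincnet.study import ExpressionStudy

from oracles import bh_stepup, mann_whitney_exact_p, welch_t_p


def make_study(values: dict, groups=("control", "diabetic"), timepoint="20wk",
               scale="log2", biotype="lncRNA"):
    """Tiny study: values maps transcript -> (control samples, case samples)."""
    rows, cols = {}, None
    for tid, (ctrl, case) in values.items():
        rows[tid] = list(ctrl) + list(case)
        cols = ([f"c{i}" for i in range(len(ctrl))] +
                [f"d{i}" for i in range(len(case))])
    intensities = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    design = pd.DataFrame({
        "group": [groups[0]] * len(list(values.values())[0][0])
                 + [groups[1]] * len(list(values.values())[0][1]),
        "timepoint": timepoint,
    }, index=pd.Index(cols, name="sample"))
    biotypes = pd.Series(biotype, index=intensities.index)
    return ExpressionStudy(intensities, design, biotypes, scale=scale)


class TestQuantileNormalize:
    def test_two_sample_hand_example(self):
        intensities = pd.DataFrame({"s1": [1, 2, 3], "s2": [4, 5, 6]},
                                   index=["t1", "t2", "t3"])
        design = pd.DataFrame({"group": ["control", "diabetic"],
                               "timepoint": "6wk"},
                              index=pd.Index(["s1", "s2"], name="sample"))
        study = ExpressionStudy(intensities, design,
                                pd.Series("mRNA", index=intensities.index))
        out = ln.quantile_normalize(study).intensities
        expected = [2.5, 3.5, 4.5]
        assert list(out["s1"]) == expected
        assert list(out["s2"]) == expected

    def test_identical_samples_unchanged_and_idempotent(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(8, 1, size=20)
        intensities = pd.DataFrame({"s1": vals, "s2": vals},
                                   index=[f"t{i}" for i in range(20)])
        design = pd.DataFrame({"group": ["control", "diabetic"],
                               "timepoint": "6wk"},
                              index=pd.Index(["s1", "s2"], name="sample"))
        study = ExpressionStudy(intensities, design,
                                pd.Series("mRNA", index=intensities.index))
        once = ln.quantile_normalize(study)
        np.testing.assert_allclose(once.intensities, intensities)
        twice = ln.quantile_normalize(once)
        np.testing.assert_allclose(twice.intensities, once.intensities)

    def test_marginals_equalised_and_ranks_preserved(self, small_sim):
        study = small_sim[1]
        out = ln.quantile_normalize(study).intensities
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        np.testing.assert_allclose(sorted_cols, sorted_cols[:, [0]] *
                                   np.ones(sorted_cols.shape[1]))
        # rank order within each sample preserved
        orig = study.intensities.to_numpy()
        for j in [0, 5, 17]:
            assert (np.argsort(orig[:, j], kind="stable")
                    == np.argsort(out.to_numpy()[:, j], kind="stable")).all()

    def test_missing_values_rejected_above_threshold(self, small_sim):
        study = small_sim[1]
        bad = study.intensities.copy()
        bad.iloc[0, 0] = np.nan
        broken = ExpressionStudy(bad, study.design, study.biotypes)
        with pytest.raises(ValueError, match="missing"):
            ln.quantile_normalize(broken, max_missing_frac=0.0)
        ok = ln.quantile_normalize(broken, max_missing_frac=0.01)
        assert np.isfinite(ok.intensities.to_numpy()).all()


class TestFoldChange:
    def test_linear_scale_ratio_and_direction(self):
        study = make_study({"t1": ([5, 5], [10, 10]),
                            "t2": ([4, 4], [4, 4])}, scale="linear")
        fc = ln.fold_change(study, "20wk")
        assert fc.loc["t1", "fold_change"] == pytest.approx(2.0)
        assert fc.loc["t1", "direction"] == "up"
        assert fc.loc["t2", "fold_change"] == pytest.approx(1.0)
        assert fc.loc["t2", "direction"] == "none"

    def test_log2_scale_means_give_ratio(self):
        # log2 group means 5.0 vs 4.0 -> linear ratio 2^(5-4) = 2 under the
        # geometric convention; arithmetic on 2^x agrees for constant groups
        study = make_study({"t1": ([4.0, 4.0], [5.0, 5.0])}, scale="log2")
        for mean in ("arithmetic", "geometric"):
            fc = ln.fold_change(study, "20wk", mean=mean)
            assert fc.loc["t1", "fold_change"] == pytest.approx(2.0)

    def test_zero_control_mean_flagged_infinite(self):
        study = make_study({"t1": ([0, 0], [3, 3])}, scale="linear")
        fc = ln.fold_change(study, "20wk")
        assert np.isinf(fc.loc["t1", "fold_change"])
        assert not fc.loc["t1", "valid"]


class TestTestTranscript:
    def test_mann_whitney_exact_small_groups(self):
        study = make_study({"t1": ([1, 2, 3], [4, 5, 6])})
        p = ln.test_transcript(study, "20wk", method="mann_whitney")
        assert p.loc["t1", "p_raw"] == pytest.approx(0.1)

    def test_welch_matches_textbook_formula(self):
        x, y = [1.0, 2.0, 3.5, 2.2], [4.0, 5.5, 6.1, 7.0]
        study = make_study({"t1": (x, y)})
        p = ln.test_transcript(study, "20wk", method="welch_t")
        assert p.loc["t1", "p_raw"] == pytest.approx(welch_t_p(x, y))

    def test_constant_transcript_degenerate(self):
        study = make_study({"t1": ([2, 2, 2], [2, 2, 2]),
                            "t2": ([1, 2, 3], [4, 5, 6])})
        p = ln.test_transcript(study, "20wk")
        assert p.loc["t1", "p_raw"] == 1.0
        assert bool(p.loc["t1", "degenerate"])
        assert not bool(p.loc["t2", "degenerate"])

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 4), (5, 5), (6, 6),
                                       (3, 6), (4, 5)])
    def test_exact_path_agrees_with_full_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = list(rng.normal(size=n1))
            y = list(rng.normal(size=n2))
            study = make_study({"t": (x, y)})
            p = ln.test_transcript(study, "20wk").loc["t", "p_raw"]
            assert p == pytest.approx(mann_whitney_exact_p(x, y))

    def test_unknown_method_rejected(self):
        study = make_study({"t1": ([1, 2], [3, 4])})
        with pytest.raises(ValueError, match="method"):
            ln.test_transcript(study, "20wk", method="anova")


class TestAdjustBH:
    def test_worked_example(self):
        np.testing.assert_allclose(ln.adjust_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_trivial_cases(self):
        assert ln.adjust_bh([0.3]) == pytest.approx([0.3])
        np.testing.assert_allclose(ln.adjust_bh([1.0, 1.0, 1.0]), 1.0)
        assert ln.adjust_bh([]).size == 0

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(derandomize=True, max_examples=200)
    def test_matches_stepup_definition(self, pvals):
        np.testing.assert_allclose(ln.adjust_bh(pvals), bh_stepup(pvals),
                                   atol=1e-12)

    def test_monotone_in_rank_and_at_least_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        adj = ln.adjust_bh(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestCallDeregulated:
    def _de(self, fold_changes, p_values):
        n = len(fold_changes)
        table = pd.DataFrame({
            "biotype": "lncRNA",
            "fold_change": fold_changes,
            "log2_fc": np.log2(fold_changes),
            "direction": ["up" if f > 1 else "down" if f < 1 else "none"
                          for f in fold_changes],
            "p_raw": p_values,
            "p_adj": ln.adjust_bh(p_values),
            "valid": True,
        }, index=[f"t{i}" for i in range(n)])
        return DEResult(table, timepoint="20wk", test="mann_whitney")

    def test_inclusive_boundaries(self):
        de = ln.call_deregulated(self._de([2.0, 0.5, 1.9], [0.05, 0.05, 0.01]))
        t = de.table
        assert bool(t.loc["t0", "deregulated"])   # exactly fc 2.0, p 0.05
        assert bool(t.loc["t1", "deregulated"])   # exactly 1/fc_min
        assert not bool(t.loc["t2", "deregulated"])
        assert de.counts() == (1, 1, 2)

    def test_nothing_passes(self):
        de = ln.call_deregulated(self._de([1.2, 0.9], [0.5, 0.9]))
        assert de.counts() == (0, 0, 0)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match="fc_min"):
            ln.call_deregulated(self._de([2.0], [0.01]), fc_min=1.0)

    def test_up_down_partition_planted_sim(self, small_config, small_sim):
        _, study, truth, _ = small_sim
        de = ln.run_de(study, "20wk")
        up, down, total = de.counts("lncRNA")
        assert up + down == total
        called = set(de.deregulated_ids("lncRNA"))
        planted = truth.de_ids("20wk", "lncRNA")
        assert len(called & planted) / len(planted) >= 0.9


class TestOverlap:
    def _result(self, flags):
        table = pd.DataFrame({
            "biotype": "lncRNA",
            "fold_change": [2.5 if d == "up" else 0.3 for d, _ in flags.values()],
            "direction": [d for d, _ in flags.values()],
            "p_raw": 0.01, "p_adj": 0.01, "valid": True,
            "deregulated": [f for _, f in flags.values()],
        }, index=list(flags))
        return DEResult(table, timepoint="x", test="mann_whitney")

    def test_toy_overlap_partition(self):
        de_a = self._result({"a": ("up", True), "b": ("up", True),
                             "c": ("down", True), "d": ("up", False)})
        de_b = self._result({"a": ("up", False), "b": ("up", True),
                             "c": ("down", True), "d": ("down", True)})
        ov = ln.overlap_sets(de_a, de_b)
        assert ov.n_overlap == 2 and ov.n_up == 1 and ov.n_down == 1
        assert ov.n_up + ov.n_down == ov.n_overlap

    def test_identical_results_full_overlap(self):
        de = self._result({"a": ("up", True), "b": ("down", True)})
        ov = ln.overlap_sets(de, de)
        assert ov.ids == ["a", "b"]

    def test_disjoint_id_spaces_rejected(self):
        de_a = self._result({"a": ("up", True)})
        de_b = self._result({"z": ("up", True)})
        with pytest.raises(ValueError, match="share no transcript"):
            ln.overlap_sets(de_a, de_b)


class TestHierarchicalCluster:
    def test_identical_rows_merge_first(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        study = make_study({"a": (base[:2], base[2:]),
                            "b": (base[:2], base[2:]),
                            "c": ([4, 1], [3, 0])})
        res = ln.hierarchical_cluster(study, ["a", "b", "c"],
                                      cluster_samples=False)
        first_merge = set(res.row_linkage[0, :2].astype(int))
        assert first_merge == {0, 1}

    def test_two_block_rows_separate_in_leaf_order(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 12)
        rows = {}
        for i in range(5):
            rows[f"x{i}"] = t + rng.normal(0, 0.01, 12)
            rows[f"y{i}"] = -t + rng.normal(0, 0.01, 12)
        study = make_study({k: (v[:6], v[6:]) for k, v in rows.items()})
        res = ln.hierarchical_cluster(study, list(rows),
                                      cluster_samples=False)
        labels = ["x" if name.startswith("x") else "y"
                  for name in res.row_order]
        # one contiguous run per block
        assert len([1 for a, b in zip(labels, labels[1:]) if a != b]) == 1

    def test_empty_subset_rejected(self, small_sim):
        with pytest.raises(ValueError, match="empty"):
            ln.hierarchical_cluster(small_sim[1], [])


class TestVolcano:
    def test_columns_consistent_with_calling(self):
        table = pd.DataFrame({
            "biotype": "lncRNA", "fold_change": [2.0, 1.0],
            "log2_fc": [1.0, 0.0], "direction": ["up", "none"],
            "p_raw": [0.05, 0.5], "p_adj": [0.1, 0.5], "valid": True,
        }, index=["a", "b"])
        de = ln.call_deregulated(
            DEResult(table, timepoint="x", test="mann_whitney"))
        v = ln.volcano_table(de)
        assert v.loc["a", "log2_fc"] == pytest.approx(1.0)
        assert v.loc["a", "neg_log10_p"] == pytest.approx(1.30103, abs=1e-5)
        # flags re-derivable from the stored thresholds
        re_flag = ((de.table["p_raw"] <= de.p_max)
                   & ((de.table["fold_change"] >= de.fc_min)
                      | (de.table["fold_change"] <= 1 / de.fc_min)))
        assert (v["deregulated"] == re_flag).all()
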