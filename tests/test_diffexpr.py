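import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from srnagrep.counts import merge_counts
from srnagrep.datasets import example_serum_exosome_de
from srnagrep.diffexpr import (
    DetectionRule,
    HitCriteria,
    SampleDesign,
    bh_adjust,
    call_hits,
    de_analysis,
    detection_sets,
    log2_fold_change,
    normalize,
    permutation_test,
    size_factors_median_of_ratios,
)


def _design(n=5):
    samples = [f"control_{i}" for i in range(n)] + [f"case_{i}" for i in range(n)]
    return SampleDesign(samples, {s: s.split("_")[0] for s in samples})


def _table(data, samples):
    return pd.DataFrame(
        data, index=pd.Index([f"f{i}" for i in range(len(data))], name="feature_id"),
        columns=samples, dtype=np.int64,
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        table = _table([[10, 10], [20, 20]], ["s1", "s2"])
        assert np.allclose(size_factors_median_of_ratios(table), 1.0)

    def test_hand_computed_median_of_ratios(self):
        # features (10,20) and (20,40): geomeans sqrt(200), sqrt(800);
        # per-sample ratios are both 1/sqrt(2) and sqrt(2)
        table = _table([[10, 20], [20, 40]], ["s1", "s2"])
        factors = size_factors_median_of_ratios(table)
        assert factors["s1"] == pytest.approx(0.7071, abs=1e-4)
        assert factors["s2"] == pytest.approx(1.4142, abs=1e-4)

    def test_feature_with_zero_excluded_from_reference(self):
        # f1 has a zero, so factors come from f0 alone
        table = _table([[10, 40], [0, 100]], ["s1", "s2"])
        factors = size_factors_median_of_ratios(table)
        assert factors["s1"] == pytest.approx(10 / 20)
        assert factors["s2"] == pytest.approx(40 / 20)

    def test_no_all_positive_feature_advises_pseudocount(self):
        table = _table([[0, 5], [5, 0]], ["s1", "s2"])
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors_median_of_ratios(table)
        factors = size_factors_median_of_ratios(table, pseudocount=1)
        assert (factors > 0).all()


class TestNormalize:
    def test_unit_factors_leave_table_unchanged(self):
        table = _table([[1, 2], [3, 4]], ["s1", "s2"])
        factors = pd.Series([1.0, 1.0], index=["s1", "s2"])
        assert normalize(table, factors).equals(table.astype(float))

    def test_proportional_columns_become_identical(self):
        table = _table([[10, 20], [30, 60], [5, 10]], ["s1", "s2"])
        normed = normalize(table, size_factors_median_of_ratios(table))
        assert np.allclose(normed["s1"], normed["s2"])

    def test_scaling_a_sample_leaves_normalized_data_invariant(self):
        # median-of-ratios absorbs a per-sample depth change: normalized
        # columns agree up to one common constant (the geometric-mean shift),
        # so fold changes are unaffected
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 500, size=(30, 10))
        design = _design()
        table = _table(counts, design.sample_ids)
        scaled = table.copy()
        scaled["case_0"] = scaled["case_0"] * 7
        n1 = normalize(table, size_factors_median_of_ratios(table))
        n2 = normalize(scaled, size_factors_median_of_ratios(scaled))
        ratio = n2.to_numpy() / n1.to_numpy()
        assert np.allclose(ratio, ratio.flat[0])
        lfc1 = log2_fold_change(n1, design, pseudocount=0)
        lfc2 = log2_fold_change(n2, design, pseudocount=0)
        assert np.allclose(lfc1, lfc2)

    def test_zero_factor_rejected(self):
        table = _table([[1, 2]], ["s1", "s2"])
        with pytest.raises(ValueError):
            normalize(table, pd.Series([0.0, 1.0], index=["s1", "s2"]))


class TestLog2FoldChange:
    def test_equal_means_give_zero(self):
        design = _design(2)
        normed = pd.DataFrame([[4.0, 4.0, 4.0, 4.0]], columns=design.sample_ids)
        assert log2_fold_change(normed, design).iloc[0] == 0

    def test_closed_form_with_pseudocount(self):
        design = _design(2)
        normed = pd.DataFrame([[1.0, 1.0, 8.0, 8.0]], columns=design.sample_ids)
        expected = math.log2(8.5 / 1.5)
        assert log2_fold_change(normed, design).iloc[0] == pytest.approx(
            expected, abs=1e-4
        )
        assert expected == pytest.approx(2.5025, abs=1e-4)

    def test_all_zero_case_group(self):
        design = _design(2)
        normed = pd.DataFrame([[10.0, 10.0, 0.0, 0.0]], columns=design.sample_ids)
        assert log2_fold_change(normed, design).iloc[0] == pytest.approx(
            math.log2(0.5 / 10.5), abs=1e-3
        )


class TestPermutationTest:
    def test_constant_feature_has_p_one(self):
        design = _design()
        normed = pd.DataFrame([[7.0] * 10], columns=design.sample_ids)
        assert permutation_test(normed, design).iloc[0] == 1.0

    def test_complete_separation_reaches_the_floor(self):
        design = _design()
        normed = pd.DataFrame(
            [[1, 2, 3, 4, 5, 100, 200, 300, 400, 500]],
            columns=design.sample_ids, dtype=float,
        )
        p = permutation_test(normed, design).iloc[0]
        assert p == pytest.approx(2 / 252, abs=1e-9)

    def test_pvalues_lie_on_the_even_grid(self, rng):
        design = _design()
        normed = pd.DataFrame(
            rng.lognormal(size=(50, 10)), columns=design.sample_ids
        )
        p = permutation_test(normed, design)
        k = p * 252
        assert np.allclose(k, np.round(k))
        assert (np.round(k) % 2 == 0).all()  # mask and complement tie
        assert (p >= 2 / 252 - 1e-12).all()

    def test_exact_matches_explicit_enumeration_on_small_design(self, rng):
        # independent oracle: enumerate 2v2 relabelings by hand
        from itertools import combinations

        design = _design(2)
        values = rng.lognormal(size=(6, 4))
        normed = pd.DataFrame(values, columns=design.sample_ids)
        p = permutation_test(normed, design, pseudocount=0.5)
        logs = np.log2(values + 0.5)
        for f in range(6):
            obs = logs[f, 2:].mean() - logs[f, :2].mean()
            stats = [
                logs[f, list(idx)].mean()
                - logs[f, [i for i in range(4) if i not in idx]].mean()
                for idx in combinations(range(4), 2)
            ]
            expected = np.mean([abs(s) >= abs(obs) - 1e-12 for s in stats])
            assert p.iloc[f] == pytest.approx(expected, abs=1e-12)

    def test_null_pvalues_are_approximately_uniform(self):
        rng = np.random.default_rng(42)
        design = _design()
        normed = pd.DataFrame(
            rng.lognormal(size=(2000, 10)), columns=design.sample_ids
        )
        p = permutation_test(normed, design).to_numpy()
        # discrete grid: P(p <= 0.05) = 12/252; binomial 3-sigma band
        rate = (p <= 0.05).mean()
        expected = 12 / 252
        sd = math.sqrt(expected * (1 - expected) / 2000)
        assert abs(rate - expected) < 3 * sd
        from scipy.stats import kstest

        assert kstest(p, "uniform").statistic < 0.05

    def test_sampled_mode_agrees_with_exact(self):
        rng = np.random.default_rng(3)
        design = _design()
        normed = pd.DataFrame(
            rng.lognormal(size=(20, 10)), columns=design.sample_ids
        )
        exact = permutation_test(normed, design, mode="exact")
        sampled = permutation_test(
            normed, design, mode="sampled", n_perm=4000, seed=11
        )
        assert np.abs(exact - sampled).max() < 0.05

    def test_exact_cap_enforced(self):
        design = _design()
        normed = pd.DataFrame(np.ones((1, 10)), columns=design.sample_ids)
        with pytest.raises(ValueError, match="cap"):
            permutation_test(normed, design, exact_cap=100)


def _bh_brute_force(p):
    """Literal step-up definition, independent of the vectorized version."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    for rank_i in range(m):
        candidates = [
            min(1.0, p[order[rank_j]] * m / (rank_j + 1))
            for rank_j in range(rank_i, m)
        ]
        out[order[rank_i]] = min(candidates)
    return out


class TestBhAdjust:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_output_bounded_by_input_and_one(self, rng):
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p).all() and (adj <= 1).all()

    @given(st.integers(0, 2**31 - 1))
    def test_equals_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        p = rng.uniform(size=n)
        assert np.allclose(bh_adjust(p), _bh_brute_force(list(p)), atol=0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCallHits:
    def test_worked_example_yields_exactly_five_hits(self):
        """Published seven-miRNA table, two adjusted-p methods at alpha 0.05,
        |log2FC| > 3, one supporting method suffices."""
        results = example_serum_exosome_de()
        results = results[results["method"].isin(["deseq2", "limma"])]
        hits = call_hits(results, HitCriteria())
        called = set(hits.loc[hits["hit"], "feature_id"])
        assert called == {
            "miR-127-3p", "miR-409-3p", "miR-540-3p", "miR-410-3p", "miR-541-5p",
        }
        assert "miR-329-5p" not in called and "miR-30d-3p" not in called

    def test_all_padj_one_gives_no_hits(self):
        results = pd.DataFrame(
            {
                "feature_id": ["a", "b"],
                "method": ["permutation"] * 2,
                "log2fc": [5.0, -6.0],
                "padj": [1.0, 1.0],
            }
        )
        assert not call_hits(results)["hit"].any()

    def test_small_fold_change_is_never_significant(self):
        results = pd.DataFrame(
            {
                "feature_id": ["a"],
                "method": ["permutation"],
                "log2fc": [2.9],
                "padj": [1e-9],
            }
        )
        assert not call_hits(results)["hit"].any()

    def test_missing_padj_never_supports(self):
        results = example_serum_exosome_de()
        edger_only = results[results["method"] == "edger"]
        assert not call_hits(edger_only)["hit"].any()

    def test_unknown_method_errors(self):
        results = pd.DataFrame(
            {"feature_id": ["a"], "method": ["mystery"], "log2fc": [4.0],
             "padj": [0.01]}
        )
        with pytest.raises(ValueError, match="mystery"):
            call_hits(results)

    def test_monotone_in_alpha_and_lfc_threshold(self):
        results = example_serum_exosome_de()
        strict = call_hits(
            results, HitCriteria(lfc_threshold=3.0)
        ).set_index("feature_id")["hit"]
        relaxed_alpha = call_hits(
            results,
            HitCriteria(
                method_alphas={"deseq2": 0.2, "limma": 0.2, "edger": 0.2},
                lfc_threshold=3.0,
            ),
        ).set_index("feature_id")["hit"]
        relaxed_lfc = call_hits(
            results, HitCriteria(lfc_threshold=2.0)
        ).set_index("feature_id")["hit"]
        assert (relaxed_alpha | ~strict).all()  # strict => relaxed
        assert (relaxed_lfc | ~strict).all()


class TestDetectionSets:
    def test_three_of_five_rule(self):
        design = _design()
        counts = _table(
            [
                [0, 0, 0, 0, 0, 3, 1, 2, 0, 0],  # f0: 3/5 case, 0/5 control
                [0, 0, 0, 0, 0, 3, 1, 0, 0, 0],  # f1: only 2/5 case
                [1, 1, 1, 0, 0, 2, 2, 2, 0, 0],  # f2: both groups
            ],
            design.sample_ids,
        )
        sets = detection_sets(counts, design, DetectionRule(3, 5))
        assert sets.case_only == {"f0"}
        assert sets.detected_case == {"f0", "f2"}
        assert "f1" not in sets.detected_case
        assert sets.shared == {"f2"}
        # set identity: |detected| == |shared| + |unique|
        assert len(sets.detected_case) == len(sets.shared) + len(sets.case_only)
        assert len(sets.detected_control) == len(sets.shared) + len(sets.control_only)

    def test_group_size_mismatch_warns_and_uses_actual_n(self, caplog):
        design = _design(3)
        counts = _table([[1, 1, 1, 0, 0, 0]], design.sample_ids)
        with caplog.at_level("WARNING"):
            sets = detection_sets(counts, design, DetectionRule(3, 5))
        assert sets.detected_control == {"f0"}
        assert any("rule expects" in r.message for r in caplog.records)


def test_de_analysis_pipeline_shape_and_columns():
    rng = np.random.default_rng(7)
    design = _design()
    table = _table(rng.integers(1, 1000, size=(40, 10)), design.sample_ids)
    results = de_analysis(table, design, mode="exact")
    assert list(results.columns) == ["feature_id", "method", "log2fc", "pvalue", "padj"]
    assert (results["method"] == "permutation").all()
    assert len(results) == 40
    # padj >= pvalue up to one ulp of the p*m/j rounding
    assert ((results["padj"] >= results["pvalue"] - 1e-12) &
            (results["padj"] <= 1)).all()
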