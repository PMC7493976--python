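"""RPKM, quantile normalization, t statistics and the lost/gained caller."""

import numpy as np
import pandas as pd
import pytest

from ctcfrep.atlas import PeakCall, PeakDataset, build_union_atlas, compute_occupancy
from ctcfrep.config import PipelineConfig
from ctcfrep.specificity import (CohortDesign, call_cancer_specific_sites,
                                 compute_rpkm, differential_accessibility_score,
                                 differential_binding, quantile_normalize)
from ctcfrep.stattests import benjamini_hochberg


class TestRpkm:
    def test_formula(self):
        counts = pd.DataFrame({"d1": [30]}, index=["s1"])
        out = compute_rpkm(counts, [150.0], [10_000_000.0])
        assert out.iloc[0, 0] == pytest.approx(20.0)

    def test_zero_reads_zero_rpkm(self):
        counts = pd.DataFrame({"d1": [0]}, index=["s1"])
        assert compute_rpkm(counts, [150.0], [1e7]).iloc[0, 0] == 0.0

    def test_doubling_library_halves_column(self):
        counts = pd.DataFrame({"d1": [10, 20], "d2": [10, 20]},
                              index=["s1", "s2"])
        a = compute_rpkm(counts, [150.0, 300.0], [1e7, 2e7])
        assert np.allclose(a["d1"].to_numpy(), 2 * a["d2"].to_numpy())

    def test_zero_library_size_raises(self):
        counts = pd.DataFrame({"d1": [1]}, index=["s1"])
        with pytest.raises(ValueError):
            compute_rpkm(counts, [150.0], [0.0])


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = quantile_normalize(m)
        assert out["a"].tolist() == [1.5, 3.5]
        assert out["b"].tolist() == [1.5, 3.5]

    def test_identical_columns_are_fixed_point(self):
        m = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_sorted_columns_identical_after_normalization(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.gamma(2, 2, size=(50, 6)))
        out = quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_ties_receive_mean_of_reference_values(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        out = quantile_normalize(m)
        ref = [1.0, 1.5, 2.5]  # row means of sorted columns
        assert out["a"].tolist() == [1.25, 1.25, 2.5]
        assert out["b"].tolist() == ref

    def test_rank_order_preserved_per_column(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(30, 4)))
        out = quantile_normalize(m)
        for col in m:
            assert (m[col].rank() == out[col].rank()).all()

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestDifferentialBinding:
    def test_pooled_t_worked_example(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]],
                         columns=["a1", "a2", "a3", "b1", "b2", "b3"],
                         index=["s1"])
        r = differential_binding(m, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert r.loc["s1", "t_statistic"] == pytest.approx(-2.449, abs=1e-3)
        assert r.loc["s1", "p_value"] == pytest.approx(0.0705, abs=1e-4)
        assert r.loc["s1", "effect_size"] == pytest.approx(-2.0, abs=1e-9)

    def test_identical_groups_give_null_result(self):
        m = pd.DataFrame([[2.0, 3.0, 2.0, 3.0]],
                         columns=["a1", "a2", "b1", "b2"], index=["s1"])
        r = differential_binding(m, ["a1", "a2"], ["b1", "b2"])
        assert r.loc["s1", "t_statistic"] == 0.0
        assert r.loc["s1", "p_value"] == 1.0

    def test_zero_variance_unequal_means_flagged_degenerate(self):
        m = pd.DataFrame([[1.0, 1.0, 2.0, 2.0]],
                         columns=["a1", "a2", "b1", "b2"], index=["s1"])
        r = differential_binding(m, ["a1", "a2"], ["b1", "b2"])
        assert r.loc["s1", "degenerate"]
        assert r.loc["s1", "p_value"] == 0.0

    def test_sign_matches_mean_difference(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(40, 6)),
                         columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        r = differential_binding(m, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        diff = m[["a1", "a2", "a3"]].mean(axis=1) - m[["b1", "b2", "b3"]].mean(axis=1)
        assert (np.sign(r["t_statistic"]) == np.sign(diff)).all()

    def test_small_group_rejected(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a1", "b1", "b2"])
        with pytest.raises(ValueError):
            differential_binding(m, ["a1"], ["b1", "b2"])


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04, 0.05])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.05, 0.05])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3]), [0.3])


def _toy_caller_inputs(cancer_values):
    """One site, 2 cancer + 2 matched-normal + 6 other datasets.

    Occupancy: absent in cancer, present in both normals and all others,
    so the lost frequency criteria hold; ``cancer_values`` controls the
    mean-signal criterion.
    """
    cfg = PipelineConfig(min_peaks_per_dataset=1)
    ids_cancer = ["c1", "c2"]
    ids_normal = ["n1", "n2"]
    ids_other = [f"o{i}" for i in range(1, 7)]
    datasets = []
    for ds in ids_cancer:
        datasets.append(PeakDataset(ds, [PeakCall(ds, "chr2", 99_000, 8.0)]))
    for ds in ids_normal + ids_other:
        datasets.append(PeakDataset(ds, [PeakCall(ds, "chr1", 1000, 8.0)]))
    atlas = compute_occupancy(build_union_atlas(datasets, cfg), datasets, cfg)
    design = CohortDesign(pd.DataFrame({
        "dataset_id": ids_cancer + ids_normal + ids_other,
        "cohort": ["T"] * 2 + ["N"] * 2 + ["O"] * 6,
        "cancer_type": ["T"] * 2 + [""] * 8,
        "matched_normal_for": [""] * 2 + ["T"] * 2 + [""] * 6,
    }))
    site_id = [s.site_id for s in atlas.sites if s.chrom == "chr1"][0]
    other_site = [s.site_id for s in atlas.sites if s.chrom == "chr2"][0]
    matrix = pd.DataFrame(
        [cancer_values + [8.0, 9.0] + [8.0, 9.0, 10.0, 8.0, 9.0, 10.0],
         [5.0, 5.0] + [5.0] * 8],
        index=[site_id, other_site],
        columns=ids_cancer + ids_normal + ids_other)
    return atlas, datasets, matrix, design, cfg, site_id


class TestCaller:
    def test_lost_conjunction_satisfied(self):
        atlas, ds, m, design, cfg, sid = _toy_caller_inputs([3.0, 3.5])
        calls = call_cancer_specific_sites(atlas, ds, m, design, "T", cfg)
        assert calls.loc[sid, "call"] == "lost"

    def test_high_cancer_signal_blocks_lost_with_ledger(self):
        atlas, ds, m, design, cfg, sid = _toy_caller_inputs([6.0, 6.5])
        calls = call_cancer_specific_sites(atlas, ds, m, design, "T", cfg)
        assert calls.loc[sid, "call"] == "none"
        assert not calls.loc[sid, "lost_cancer_rpkm"]
        assert calls.loc[sid, ["lost_cancer_freq", "lost_overall_freq",
                               "lost_normal_freq", "lost_t_vs_others",
                               "lost_t_vs_normal"]].all()

    def test_missing_matched_normal_disables_calls(self):
        atlas, ds, m, design, cfg, sid = _toy_caller_inputs([3.0, 3.5])
        design.table.loc[design.table["matched_normal_for"] == "T",
                         "matched_normal_for"] = ""
        calls = call_cancer_specific_sites(atlas, ds, m, design, "T", cfg)
        assert calls.attrs["status"] == "disabled_no_matched_normal"
        assert (calls["call"] == "none").all()

    def test_column_order_invariance(self):
        atlas, ds, m, design, cfg, sid = _toy_caller_inputs([3.0, 3.5])
        c1 = call_cancer_specific_sites(atlas, ds, m, design, "T", cfg)
        m2 = m[list(reversed(m.columns))]
        c2 = call_cancer_specific_sites(atlas, ds, m2, design, "T", cfg)
        assert (c1["call"] == c2["call"]).all()


class TestAccessibility:
    def test_fold_change_hand_example(self):
        m = pd.DataFrame([[4.0, 6.0, 1.0, 1.0, 2.0]],
                         columns=["c1", "c2", "o1", "o2", "o3"], index=["s1"])
        score = differential_accessibility_score(m, ["c1", "c2"],
                                                 ["o1", "o2", "o3"])
        assert score.loc["s1"] == pytest.approx(3.75)

    def test_identical_strata_give_unity(self):
        m = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]],
                         columns=["c1", "c2", "o1", "o2"], index=["s1"])
        assert differential_accessibility_score(
            m, ["c1", "c2"], ["o1", "o2"]).loc["s1"] == 1.0

    def test_empty_stratum_raises(self):
        m = pd.DataFrame([[1.0, 2.0]], columns=["c1", "o1"], index=["s1"])
        with pytest.raises(ValueError):
            differential_accessibility_score(m, [], ["o1"])
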