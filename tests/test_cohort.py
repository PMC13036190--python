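import numpy as np
import pandas as pd
import pytest

from dualreg.classify import Thresholds
from dualreg.cohort import (DEFAULT_STAGE_MAP, StageMarkerDetector,
                            SubgroupDefinition, correlation_analysis,
                            cross_dataset_correlation,
                            exclusive_genotype_subgroups, map_stage_tokens,
                            pca_reduce, rowscale_for_heatmap, select_subgroups,
                            stage_stratified_dea, subgroup_log2fc_profiles)
from dualreg.io import ExpressionCohort
from dualreg.simulate import (CohortSimulationConfig, GroupShift,
                              simulate_cohort)


def _cohort(meta_rows, n_genes=5, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(len(meta_rows))]
    expr = pd.DataFrame(rng.uniform(0, 100, size=(len(samples), n_genes)),
                        index=samples, columns=[f"g{j}" for j in range(n_genes)])
    defaults = {"LKB1_mut": False, "SMARCA4_mut": False, "TP53_mut": False,
                "KRAS_mut": False, "stage": "early"}
    meta = pd.DataFrame([{**defaults, **row} for row in meta_rows], index=samples)
    return ExpressionCohort(expression=expr, metadata=meta)


class TestSubgroups:
    def test_flag_matching(self):
        cohort = _cohort([
            {"LKB1_mut": True},
            {"SMARCA4_mut": True},
            {},
        ])
        defs = exclusive_genotype_subgroups(("WT", "LKB1"))
        groups = select_subgroups(cohort, defs)
        assert groups == {"WT": ["s2"], "LKB1": ["s0"]}

    def test_overlap_disallowed_names_sample(self):
        cohort = _cohort([{"LKB1_mut": True}])
        defs = [SubgroupDefinition("any1"), SubgroupDefinition("any2")]
        with pytest.raises(ValueError, match="s0"):
            select_subgroups(cohort, defs)
        groups = select_subgroups(cohort, defs, allow_overlap=True)
        assert groups["any1"] == groups["any2"] == ["s0"]

    def test_empty_subgroup_warns_not_errors(self, caplog):
        cohort = _cohort([{}])
        defs = exclusive_genotype_subgroups(("WT", "TP53"))
        with caplog.at_level("WARNING"):
            groups = select_subgroups(cohort, defs)
        assert groups["TP53"] == []
        assert any("empty" in rec.message for rec in caplog.records)

    def test_simulated_group_sizes_recovered_exactly(self):
        sizes = {("WT", "early"): 7, ("LKB1", "early"): 4,
                 ("SMARCA4", "late"): 3, ("TP53", "late"): 5}
        cohort, _ = simulate_cohort(CohortSimulationConfig(
            genes=50, group_sizes=sizes, seed=2))
        groups = select_subgroups(cohort, exclusive_genotype_subgroups())
        assert len(groups["WT"]) == 7
        assert len(groups["LKB1"]) == 4
        assert len(groups["SMARCA4"]) == 3
        assert len(groups["TP53"]) == 5

    def test_unknown_flag_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SubgroupDefinition("bad", flags={"EGFR_mut": True})


class TestStageMapping:
    @pytest.mark.parametrize("raw,expected", [
        ("Stage IA", "early"), ("II", "early"), ("stage iiib", "late"),
        ("IV", "late"), ("not-a-stage", "unknown"),
    ])
    def test_ajcc_tokens(self, raw, expected):
        assert map_stage_tokens([raw]).iloc[0] == expected

    def test_substage_coverage(self):
        assert all(v in ("early", "late") for v in DEFAULT_STAGE_MAP.values())


class TestPCA:
    def test_rank_one_matrix_needs_one_component(self):
        base = np.outer([1, 2, 3, 4.0], np.linspace(1, 2, 6))
        matrix = pd.DataFrame(2.0 ** base - 1)  # rank-1 after log2(x+1)
        scores, evr = pca_reduce(matrix, variance_target=0.8)
        assert scores.shape[1] == 1
        assert evr[0] == pytest.approx(1.0)

    def test_planted_two_factor_structure(self, rng):
        n, g = 40, 200
        factors = rng.normal(size=(n, 2)) * [6, 3]
        loadings = rng.normal(size=(2, g))
        log2x = 8 + factors @ loadings + rng.normal(scale=0.1, size=(n, g))
        matrix = pd.DataFrame(np.exp2(log2x) - 1).clip(lower=0)
        scores, evr = pca_reduce(matrix, variance_target=0.95, max_components=10)
        assert evr[:2].sum() >= 0.95
        assert scores.shape[1] == 2

    def test_isotropic_noise_hits_component_cap(self, rng):
        matrix = pd.DataFrame(rng.uniform(1, 2, size=(30, 100)))
        scores, evr = pca_reduce(matrix, variance_target=0.9, max_components=5)
        assert scores.shape[1] == 5
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pca_reduce(pd.DataFrame(np.ones((2, 4))))


class TestCorrelation:
    def test_identical_and_negated_profiles(self):
        v = pd.Series([1.0, 2, 3, 5], index=list("abcd"))
        mat = correlation_analysis({"x": v, "y": v.copy(), "z": -v})
        assert mat.loc["x", "y"] == pytest.approx(1.0)
        assert mat.loc["x", "z"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(mat), 1.0)

    def test_matches_textbook_pearson(self, rng):
        profiles = {f"p{i}": pd.Series(rng.normal(size=10),
                                       index=[f"g{j}" for j in range(10)])
                    for i in range(4)}
        mat = correlation_analysis(profiles)
        for a in profiles:
            for b in profiles:
                x, y = profiles[a].to_numpy(), profiles[b].to_numpy()
                xc, yc = x - x.mean(), y - y.mean()
                manual = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
                assert mat.loc[a, b] == pytest.approx(manual, abs=1e-12)

    def test_constant_profile_reported_missing(self):
        mat = correlation_analysis({
            "c": pd.Series([1.0, 1.0, 1.0]),
            "v": pd.Series([1.0, 2.0, 3.0]),
            "w": pd.Series([3.0, 1.0, 2.0]),
        })
        assert np.isnan(mat.loc["c", "v"])
        assert mat.loc["c", "c"] == 1.0
        assert not np.isnan(mat.loc["v", "w"])

    def test_shared_shift_pair_correlates_highest(self):
        sizes = {("WT", "early"): 20, ("LKB1", "early"): 20,
                 ("SMARCA4", "early"): 20, ("TP53", "early"): 20}
        shifts = (GroupShift("LKB1", "early", 60, 2.0),
                  GroupShift("SMARCA4", "early", 60, 2.0),
                  GroupShift("TP53", "early", 60, 2.0))
        cohort, truth = simulate_cohort(CohortSimulationConfig(
            genes=800, group_sizes=sizes, group_shifts=shifts, seed=9))
        # make LKB1 and SMARCA4 share their shifted genes
        expr = cohort.expression.copy()
        logx = np.log2(expr + 1)
        lkb1_genes = sorted(truth.shifted_genes("LKB1", "early"))
        sm_genes = sorted(truth.shifted_genes("SMARCA4", "early"))
        sm_samples = cohort.metadata.index[cohort.metadata["SMARCA4_mut"]]
        logx.loc[sm_samples, lkb1_genes] += 2.0
        logx.loc[sm_samples, sm_genes] -= 2.0
        cohort2 = ExpressionCohort(expression=np.exp2(logx) - 1,
                                   metadata=cohort.metadata)
        groups = select_subgroups(cohort2, exclusive_genotype_subgroups())
        profiles = subgroup_log2fc_profiles(cohort2, groups)
        mat = correlation_analysis(profiles)
        pairs = {(a, b): mat.loc[a, b] for a in profiles for b in profiles if a < b}
        assert max(pairs, key=pairs.get) == ("LKB1", "SMARCA4")


class TestCrossDatasetCorrelation:
    def test_equal_profiles_give_r_one(self, rng):
        genes = [f"g{i}" for i in range(100)]
        v = pd.Series(rng.normal(size=100), index=genes)
        block = cross_dataset_correlation({"cellline": v}, {"subgroup": v.copy()})
        assert block.loc["cellline", "subgroup"] == pytest.approx(1.0)

    def test_independent_profiles_near_zero(self):
        genes = [f"g{i}" for i in range(1000)]
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = pd.Series(rng.normal(size=1000), index=genes)
            b = pd.Series(rng.normal(size=1000), index=genes)
            r = cross_dataset_correlation({"c": a}, {"s": b}).iloc[0, 0]
            hits += abs(r) < 0.1
        assert hits >= 19  # |r| < 0.1 in >= 95% of seeds

    def test_planted_partner_is_max_r(self):
        sizes = {("WT", "early"): 25, ("LKB1", "early"): 25,
                 ("TP53", "early"): 25}
        shifts = (GroupShift("LKB1", "early", 80, 2.0),
                  GroupShift("TP53", "early", 80, 2.0))
        cohort, truth = simulate_cohort(CohortSimulationConfig(
            genes=1000, group_sizes=sizes, group_shifts=shifts, seed=4))
        groups = select_subgroups(cohort, exclusive_genotype_subgroups(
            ("WT", "LKB1", "TP53")))
        subgroup_profiles = subgroup_log2fc_profiles(cohort, groups)
        # cell-line contrast profile sharing the LKB1 subgroup's shift genes
        contrast = pd.Series(0.0, index=cohort.genes)
        for gene, shift in truth.group_shifts[("LKB1", "early")].items():
            contrast.loc[gene] = shift
        block = cross_dataset_correlation({"LKB1_line": contrast},
                                          subgroup_profiles)
        assert block.loc["LKB1_line"].idxmax() == "LKB1"

    def test_too_few_shared_genes_rejected(self):
        a = pd.Series([1.0] * 10, index=[f"g{i}" for i in range(10)])
        b = pd.Series([1.0] * 10, index=[f"h{i}" for i in range(10)])
        with pytest.raises(ValueError, match="0 shared"):
            cross_dataset_correlation({"c": a}, {"s": b})


class TestStageDEA:
    def test_identical_groups_give_no_markers(self):
        rng = np.random.default_rng(1)
        block = rng.uniform(10, 100, size=(10, 50))
        expr = pd.DataFrame(np.vstack([block, block]),
                            index=[f"s{i}" for i in range(20)],
                            columns=[f"g{j}" for j in range(50)])
        meta = pd.DataFrame({
            "LKB1_mut": [False] * 10 + [True] * 10,
            "SMARCA4_mut": False, "TP53_mut": False, "KRAS_mut": False,
            "stage": "early",
        }, index=expr.index)
        det = stage_stratified_dea(ExpressionCohort(expr, meta))
        assert len(det.markers_) == 0

    def test_planted_shift_recovery_with_fdr_control(self):
        cohort, truth = simulate_cohort(CohortSimulationConfig(
            genes=2000,
            group_sizes={("WT", "late"): 30, ("LKB1", "late"): 30},
            group_shifts=(GroupShift("LKB1", "late", 50, 2.0),),
            seed=5))
        det = stage_stratified_dea(cohort, Thresholds())
        markers = det.markers_.query("genotype == 'LKB1' and stage == 'late'")
        planted = truth.shifted_genes("LKB1", "late")
        recovered = set(markers["gene"]) & planted
        false_pos = set(markers["gene"]) - planted
        assert len(recovered) >= 45
        assert len(false_pos) <= 0.05 * 1950

    def test_tiny_groups_run_without_crash(self):
        cohort, _ = simulate_cohort(CohortSimulationConfig(
            genes=50, group_sizes={("WT", "early"): 2, ("LKB1", "early"): 2},
            seed=3))
        det = stage_stratified_dea(cohort, min_group_size=2)
        assert ("LKB1", "early") in det.group_sizes_
        # power near zero at n=2: rank-sum minimum two-sided p is 2/C(4,2)=1/3
        assert len(det.markers_) == 0

    def test_undersized_group_skipped_with_warning(self, caplog):
        cohort, _ = simulate_cohort(CohortSimulationConfig(
            genes=50, group_sizes={("WT", "early"): 5, ("LKB1", "early"): 1},
            seed=3))
        with caplog.at_level("WARNING"):
            det = stage_stratified_dea(cohort)
        assert det.group_sizes_ == {}
        assert any("skipped" in rec.message for rec in caplog.records)

    def test_sklearn_interface(self):
        det = StageMarkerDetector(lfc_min=1.0)
        assert det.get_params()["lfc_min"] == 1.0


class TestRowscale:
    def test_minmax_maps_row_to_unit_interval(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0]])
        out = rowscale_for_heatmap(matrix, mode="minmax")
        np.testing.assert_allclose(out.iloc[0], [0.0, 0.5, 1.0])

    def test_constant_rows_map_to_zero(self):
        matrix = pd.DataFrame([[5.0, 5.0, 5.0]])
        for mode in ("minmax", "zscore"):
            assert (rowscale_for_heatmap(matrix, mode=mode) == 0).all().all()

    def test_zscore_rows_standardized(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(6, 20)))
        out = rowscale_for_heatmap(matrix, mode="zscore")
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            rowscale_for_heatmap(pd.DataFrame([[1.0]]), mode="rank")
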