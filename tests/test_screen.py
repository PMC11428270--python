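import math

import numpy as np
import pytest

from cafscreen import (
    ScreenConfig,
    ScreenError,
    anchor_correlation,
    build_design,
    classify_tier,
    count_probes_at_threshold,
    housekeeping_normalize,
    rank_by_expression,
    screen_genes,
)
from cafscreen.normalize import NormalizationConfig
from cafscreen.simulate import SimulationParams, simulate_cohort

import _oracles as oracle
from conftest import make_matrix, paired_annotation

CFG = ScreenConfig(anchor_probe="anchor")


def _design(n_tumors, matrix):
    return build_design(paired_annotation(n_tumors), matrix)


def _paired_matrix(stroma_rows, epi_rows, probes):
    """Interleave stroma/epithelium columns as T01_str, T01_epi, ..."""
    stroma = np.asarray(stroma_rows, dtype=float)
    epi = np.asarray(epi_rows, dtype=float)
    nt = stroma.shape[1]
    vals = np.empty((stroma.shape[0], 2 * nt))
    vals[:, 0::2] = stroma
    vals[:, 1::2] = epi
    samples = []
    for i in range(nt):
        samples.extend([f"T{i + 1:02d}_str", f"T{i + 1:02d}_epi"])
    return make_matrix(vals, probes=probes, samples=samples)


class TestSeRatio:
    def test_identical_profiles_give_one_in_both_modes(self):
        from cafscreen import se_ratio

        m = _paired_matrix([[3.0, 7.0, 2.0]], [[3.0, 7.0, 2.0]], ["g"])
        d = _design(3, m)
        assert se_ratio(m, d, "g", "mean_of_paired_ratios") == 1.0
        assert se_ratio(m, d, "g", "ratio_of_means") == 1.0

    def test_two_tumor_instance_matches_hand_oracle_per_mode(self):
        from cafscreen import se_ratio

        # stroma (2, 9), epithelium (1, 3): paired ratios 2 and 3
        m = _paired_matrix([[2.0, 9.0]], [[1.0, 3.0]], ["g"])
        d = _design(2, m)
        assert se_ratio(m, d, "g", "mean_of_paired_ratios") == pytest.approx(
            oracle.se_mean_of_paired_ratios([2.0, 9.0], [1.0, 3.0]), abs=1e-12
        )
        assert se_ratio(m, d, "g", "ratio_of_means") == pytest.approx(
            oracle.se_ratio_of_means([2.0, 9.0], [1.0, 3.0]), abs=1e-12
        )
        # and the hand values themselves
        assert oracle.se_mean_of_paired_ratios([2.0, 9.0], [1.0, 3.0]) == 2.5
        assert oracle.se_ratio_of_means([2.0, 9.0], [1.0, 3.0]) == 2.75

    def test_noise_free_planting_recovers_rho_exactly_in_both_modes(self):
        from cafscreen import se_ratio
        from cafscreen.simulate import HOUSEKEEPING_PROBE

        params = SimulationParams(
            n_tumors=6,
            n_background_genes=5,
            n_block_genes=0,
            noise_sigma_log2=0.0,
            planted_se_rho={"background": np.full(5, 12.0)},
            seed=5,
        )
        matrix, ann, truth, _ = simulate_cohort(params)
        norm = housekeeping_normalize(matrix)
        d = build_design(ann, matrix)
        for probe in truth.genes.query("block == 'background'")["probe_id"]:
            if probe == HOUSEKEEPING_PROBE:
                continue
            for mode in ("mean_of_paired_ratios", "ratio_of_means"):
                assert se_ratio(norm, d, probe, mode) == pytest.approx(12.0, rel=1e-12)

    def test_zero_epithelium_tumor_skipped_with_warning(self, caplog):
        from cafscreen import se_ratio

        m = _paired_matrix([[2.0, 9.0]], [[1.0, 0.0]], ["g"])
        d = _design(2, m)
        with caplog.at_level("WARNING"):
            assert se_ratio(m, d, "g", "mean_of_paired_ratios") == 2.0
        assert any("T02" in rec.message for rec in caplog.records)

    def test_all_tumors_skipped_is_undefined(self):
        from cafscreen import se_ratio

        m = _paired_matrix([[2.0, 9.0]], [[0.0, 0.0]], ["g"])
        d = _design(2, m)
        assert math.isnan(se_ratio(m, d, "g", "mean_of_paired_ratios"))


class TestAnchorCorrelation:
    def test_anchor_vs_itself_is_one(self):
        m = make_matrix([[1.0, 5.0, 2.0, 8.0]], probes=["anchor"])
        assert anchor_correlation(m, m.sample_ids, "anchor", "anchor") == 1.0

    def test_negative_linear_dependence_is_minus_one(self):
        anchor = np.array([1.0, 5.0, 2.0, 8.0])
        m = make_matrix([anchor, 10.0 - 0.5 * anchor], probes=["anchor", "g"])
        assert anchor_correlation(m, m.sample_ids, "g", "anchor") == pytest.approx(-1.0, abs=1e-12)

    def test_five_sample_vectors_match_direct_formula_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        m = make_matrix([x, y], probes=["g", "anchor"])
        expected = oracle.pearson(x, y)
        assert expected == pytest.approx(0.8, abs=1e-12)  # frozen oracle value
        assert anchor_correlation(m, m.sample_ids, "g", "anchor") == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged_undefined(self):
        m = make_matrix([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]], probes=["g", "anchor"])
        assert math.isnan(anchor_correlation(m, m.sample_ids, "g", "anchor"))

    def test_fewer_than_three_samples_is_error(self):
        m = make_matrix([[1.0, 2.0], [2.0, 1.0]], probes=["g", "anchor"])
        with pytest.raises(ScreenError, match="3 stroma samples"):
            anchor_correlation(m, m.sample_ids, "g", "anchor")


class TestClassifyTier:
    @pytest.mark.parametrize(
        "se,expected",
        [
            (10.0, "CAFG"),  # "10 or beyond" is inclusive
            (5.0, "semi_CAFG"),  # "5 or beyond and below 10"
            (4.999, "L_CAFG"),
            (17.2, "CAFG"),  # the anchor marker's own stromal SE in CRC
            (3.6, "L_CAFG"),  # POSTN's breast SE
            (9.999, "semi_CAFG"),
        ],
    )
    def test_boundaries_and_reported_values(self, se, expected):
        assert classify_tier(se, CFG) == expected

    def test_undefined_se_gives_no_tier(self):
        assert classify_tier(math.nan, CFG) is None

    def test_partition_of_positive_axis(self):
        rng = np.random.default_rng(7)
        for se in np.exp(rng.uniform(np.log(1e-3), np.log(1e3), 200)):
            assert classify_tier(float(se), CFG) in ("CAFG", "semi_CAFG", "L_CAFG")


class TestScreenGenes:
    def test_noise_free_block_fully_correlated_and_anchor_is_one(self, anchor_probe):
        params = SimulationParams(
            n_tumors=10, n_background_genes=10, n_block_genes=6, noise_sigma_log2=0.0, seed=3
        )
        matrix, ann, truth, pmap = simulate_cohort(params)
        norm = housekeeping_normalize(matrix)
        d = build_design(ann, matrix)
        cfg = ScreenConfig(anchor_probe=anchor_probe)
        table = screen_genes(norm, d, cfg, pmap).set_index("probe_id")
        block = truth.genes.query("block == 'anchor_block'")["probe_id"]
        assert (table.loc[block, "anchor_r"] >= 0.99).all()
        assert table.loc[anchor_probe, "anchor_r"] == pytest.approx(1.0, abs=1e-12)

    def test_full_table_equals_probewise_oracle(self, small_cohort, anchor_probe, hk_probe):
        params, (matrix, ann, truth, pmap) = small_cohort
        norm = housekeeping_normalize(matrix)
        d = build_design(ann, matrix)
        ref_sample = d.stroma_samples[0]
        for mode in ("mean_of_paired_ratios", "ratio_of_means"):
            cfg = ScreenConfig(anchor_probe=anchor_probe, reference_sample=ref_sample, ratio_mode=mode)
            table = screen_genes(norm, d, cfg, pmap).set_index("probe_id")
            expected = oracle.screen_table(
                matrix.data, hk_probe, d.stroma_samples, d.epithelium_samples,
                anchor_probe, mode, reference_sample=ref_sample,
            )
            assert len(table) == len(expected)
            for probe, row in expected.items():
                got = table.loc[probe]
                assert got["se_ratio"] == pytest.approx(row["se_ratio"], abs=1e-9)
                if math.isnan(row["anchor_r"]):
                    assert math.isnan(got["anchor_r"])
                else:
                    assert got["anchor_r"] == pytest.approx(row["anchor_r"], abs=1e-9)
                assert got["tier"] == row["tier"]
                assert got["rank_by_expression"] == row["rank_by_expression"]

    def test_missing_anchor_is_error(self):
        m = _paired_matrix([[1.0, 2.0, 3.0]], [[1.0, 1.0, 1.0]], ["g"])
        d = _design(3, m)
        with pytest.raises(ScreenError, match="anchor"):
            screen_genes(m, d, ScreenConfig(anchor_probe="nope"))


class TestRankByExpression:
    def test_forced_ordering(self):
        m = make_matrix([[5.0], [3.0], [9.0]], probes=["a", "b", "c"], samples=["ref"])
        assert rank_by_expression(m, "ref") == ["c", "a", "b"]

    def test_ties_break_lexicographically(self):
        m = make_matrix([[5.0], [5.0], [9.0]], probes=["b", "a", "c"], samples=["ref"])
        assert rank_by_expression(m, "ref") == ["c", "a", "b"]

    def test_hundred_probe_order_equals_oracle_sort(self):
        rng = np.random.default_rng(11)
        vals = rng.choice(np.arange(50.0), size=100)  # force some ties
        probes = [f"p{i:03d}" for i in range(100)]
        m = make_matrix(vals.reshape(-1, 1), probes=probes, samples=["ref"])
        expected = [p for p, _ in sorted(zip(probes, vals), key=lambda t: (-t[1], t[0]))]
        assert rank_by_expression(m, "ref") == expected

    def test_missing_sample_is_error(self):
        m = make_matrix([[1.0]], probes=["a"], samples=["s"])
        with pytest.raises(ScreenError, match="ref"):
            rank_by_expression(m, "ref")


class TestCountProbesAtThreshold:
    def test_uncorrelated_cohort_counts_zero(self):
        rng = np.random.default_rng(13)
        m = make_matrix(rng.uniform(1, 10, size=(6, 20)),
                        probes=["anchor"] + [f"g{i}" for i in range(5)])
        assert count_probes_at_threshold(m, m.sample_ids, "anchor", 0.99) == 0

    def test_noise_free_planting_counts_k(self, anchor_probe):
        k = 7
        params = SimulationParams(
            n_tumors=8, n_background_genes=10, n_block_genes=k + 1, noise_sigma_log2=0.0,
            loading_lambda={"anchor_block": np.ones(k + 1)},  # exact scalings of the anchor
            seed=9,
        )
        matrix, ann, _, _ = simulate_cohort(params)
        norm = housekeeping_normalize(matrix)
        d = build_design(ann, matrix)
        assert count_probes_at_threshold(norm, d.stroma_samples, anchor_probe, 0.99) == k

    def test_stochastic_cohort_equals_brute_force_recount(self, small_cohort, anchor_probe, hk_probe):
        _, (matrix, ann, _, _) = small_cohort
        norm = housekeeping_normalize(matrix)
        d = build_design(ann, matrix)
        for r_min in (0.9, 0.8, 0.6):
            expected = oracle.count_at_threshold(
                matrix.data, hk_probe, d.stroma_samples, anchor_probe, r_min
            )
            assert count_probes_at_threshold(norm, d.stroma_samples, anchor_probe, r_min) == expected


class TestScreenConfigValidation:
    def test_bad_correlation_ordering_rejected(self):
        with pytest.raises(ScreenError):
            ScreenConfig(anchor_probe="a", r_weak=0.9, r_mid=0.8, r_strong=0.6)

    def test_bad_se_thresholds_rejected(self):
        with pytest.raises(ScreenError):
            ScreenConfig(anchor_probe="a", se_mid=10.0, se_high=5.0)
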