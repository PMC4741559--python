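import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_matrix
from straincgh.cgh import (
    auto_penalty,
    call_region_events,
    divergence_profile,
    genome_sorted,
    renormalize,
    segment_profile,
    subtelomeric_regions,
    validate_annotation,
)


class TestRenormalize:
    def test_row_means_become_zero(self):
        matrix = random_matrix(np.random.default_rng(0), 20, 5, nan_frac=0.1)
        out = renormalize(matrix)
        assert np.nanmax(np.abs(out.mean(axis=1, skipna=True))) < 1e-12

    def test_per_gene_bias_cancels_exactly(self):
        rng = np.random.default_rng(1)
        matrix = random_matrix(rng, 15, 4)
        bias = pd.Series(rng.normal(size=15) * 10, index=matrix.index)
        assert renormalize(matrix.add(bias, axis=0)).equals(
            renormalize(matrix)
            .add(bias, axis=0)
            .sub(bias, axis=0)
        ) or np.allclose(
            renormalize(matrix.add(bias, axis=0)).to_numpy(),
            renormalize(matrix).to_numpy(),
            atol=1e-12,
            rtol=0,
        )

    def test_subtract_row_mean_example(self):
        matrix = pd.DataFrame([[0.5, 0.1, 0.0]], index=["g"], columns=list("abc"))
        out = renormalize(matrix)
        assert out.loc["g"].tolist() == pytest.approx([0.3, -0.1, -0.2])

    def test_idempotent(self):
        matrix = random_matrix(np.random.default_rng(2), 10, 6, nan_frac=0.2)
        once = renormalize(matrix)
        twice = renormalize(once)
        assert np.allclose(
            once.to_numpy(), twice.to_numpy(), atol=1e-12, rtol=0, equal_nan=True
        )

    def test_all_missing_gene_dropped_with_warning(self):
        matrix = random_matrix(np.random.default_rng(3), 5, 3)
        matrix.iloc[2] = np.nan
        with pytest.warns(UserWarning, match="missing in every strain"):
            out = renormalize(matrix)
        assert matrix.index[2] not in out.index
        assert out.shape == (4, 3)

    def test_requires_two_strains(self):
        matrix = pd.DataFrame({"only": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="two strains"):
            renormalize(matrix)


class TestDivergenceProfile:
    def test_window_one_is_identity(self, tiny_annotation):
        matrix = random_matrix(np.random.default_rng(4), 5, 4)
        matrix.index = ["g1", "g2", "g3", "g4", "g5"]
        profile = divergence_profile(matrix, tiny_annotation, window=1)
        assert np.allclose(profile["sd"], profile["smoothed_sd"])

    def test_population_sd_convention(self, tiny_annotation):
        matrix = random_matrix(np.random.default_rng(5), 5, 4)
        matrix.index = ["g1", "g2", "g3", "g4", "g5"]
        profile = divergence_profile(matrix, tiny_annotation, window=1)
        expected = np.std(matrix.to_numpy(), axis=1, ddof=0)  # divide by n
        by_gene = profile.set_index("gene_id").loc[matrix.index, "sd"].to_numpy()
        assert np.allclose(by_gene, expected)

    def test_constant_sd_preserved(self, tiny_annotation):
        # values chosen so every gene has identical cross-strain spread
        matrix = pd.DataFrame(
            np.tile([-1.0, 0.0, 1.0], (5, 1)),
            index=["g1", "g2", "g3", "g4", "g5"],
            columns=list("abc"),
        )
        profile = divergence_profile(matrix, tiny_annotation, window=3)
        assert np.allclose(profile["smoothed_sd"], profile["sd"])

    def test_hand_convolution_with_edge_shrink(self):
        annotation = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(5)],
                "chromosome": 1,
                "start": np.arange(5) * 100 + 1,
                "end": np.arange(5) * 100 + 100,
                "subtelomeric": 0,
            }
        )
        # craft per-gene sd sequence [0, 0, 3, 0, 0]: two equal strains give
        # sd 0, strains (0, 6) give sd 3
        matrix = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [0.0, 6.0], [0.0, 0.0], [0.0, 0.0]],
            index=annotation["gene_id"],
            columns=["a", "b"],
        )
        profile = divergence_profile(matrix, annotation, window=3)
        assert profile["sd"].tolist() == pytest.approx([0, 0, 3, 0, 0])
        assert profile["smoothed_sd"].tolist() == pytest.approx([0, 1, 1, 1, 0])

    def test_window_never_crosses_chromosomes(self, tiny_annotation):
        # chromosome 2 carries a huge sd; chromosome 1 must be unaffected
        matrix = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [0.0, 90.0], [0.0, 90.0]],
            index=["g1", "g2", "g3", "g4", "g5"],
            columns=["a", "b"],
        )
        profile = divergence_profile(matrix, tiny_annotation, window=5)
        chr1 = profile[profile["chromosome"] == 1]["smoothed_sd"]
        assert np.allclose(chr1, 0.0)

    def test_full_window_center_equals_chromosome_mean(self, tiny_annotation):
        matrix = random_matrix(np.random.default_rng(6), 5, 4)
        matrix.index = ["g1", "g2", "g3", "g4", "g5"]
        profile = divergence_profile(matrix, tiny_annotation, window=5)
        chr1 = profile[profile["chromosome"] == 1]
        # center gene of the 3-gene chromosome sees the whole chromosome;
        # the edge genes shrink to width 1 and equal their raw sd
        assert chr1["smoothed_sd"].iloc[1] == pytest.approx(chr1["sd"].mean())
        assert chr1["smoothed_sd"].iloc[0] == pytest.approx(chr1["sd"].iloc[0])
        assert chr1["smoothed_sd"].iloc[2] == pytest.approx(chr1["sd"].iloc[2])

    def test_strain_permutation_invariance(self, tiny_annotation):
        matrix = random_matrix(np.random.default_rng(7), 5, 6)
        matrix.index = ["g1", "g2", "g3", "g4", "g5"]
        shuffled = matrix[list(matrix.columns[::-1])]
        a = divergence_profile(matrix, tiny_annotation, window=3)
        b = divergence_profile(shuffled, tiny_annotation, window=3)
        assert np.allclose(a["sd"], b["sd"]) and np.allclose(
            a["smoothed_sd"], b["smoothed_sd"]
        )

    def test_gene_needs_two_observations(self, tiny_annotation):
        matrix = random_matrix(np.random.default_rng(8), 5, 3)
        matrix.index = ["g1", "g2", "g3", "g4", "g5"]
        matrix.loc["g2", ["s0", "s1"]] = np.nan  # only one observation left
        profile = divergence_profile(matrix, tiny_annotation, window=1)
        assert np.isnan(profile.set_index("gene_id").loc["g2", "sd"])

    @pytest.mark.parametrize("window", [0, 2, 4, -3])
    def test_invalid_window_rejected(self, tiny_annotation, window):
        matrix = random_matrix(np.random.default_rng(9), 5, 3)
        matrix.index = ["g1", "g2", "g3", "g4", "g5"]
        with pytest.raises(ValueError, match="odd"):
            divergence_profile(matrix, tiny_annotation, window=window)


class TestSegmentation:
    def test_constant_vector_single_segment(self):
        segs = segment_profile(np.full(9, 2.5))
        assert len(segs) == 1
        assert (segs[0].first, segs[0].last) == (0, 8)
        assert segs[0].mean == pytest.approx(2.5)

    def test_two_level_vector_cost_comparison(self):
        # one segment costs SSE 2.5; two segments cost an extra penalty but
        # remove the SSE, so any penalty below 2.5 prefers the split
        x = np.r_[np.zeros(5), np.ones(5)]
        segs = segment_profile(x, penalty=2.0)
        assert [(s.first, s.last) for s in segs] == [(0, 4), (5, 9)]
        assert [s.mean for s in segs] == pytest.approx([0.0, 1.0])
        segs = segment_profile(x, penalty=3.0)
        assert len(segs) == 1

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            n = int(rng.integers(1, 13))
            x = rng.normal(size=n)
            penalty = float(rng.uniform(0.05, 2.0))
            segs = segment_profile(x, penalty=penalty)
            cost = penalty * len(segs)
            for s in segs:
                seg = x[s.first : s.last + 1]
                cost += float(np.sum((seg - seg.mean()) ** 2))
            assert cost == pytest.approx(
                oracles.segmentation_best_cost(x, penalty), abs=1e-9
            )

    def test_segments_partition_the_range(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        segs = segment_profile(x, penalty=0.5)
        assert segs[0].first == 0 and segs[-1].last == 39
        for a, b in zip(segs, segs[1:]):
            assert b.first == a.last + 1

    def test_rejects_empty_and_nan(self):
        with pytest.raises(ValueError, match="non-empty"):
            segment_profile([])
        with pytest.raises(ValueError, match="NaN"):
            segment_profile([1.0, np.nan])
        with pytest.raises(ValueError, match="positive"):
            segment_profile([1.0, 2.0], penalty=0.0)

    def test_auto_penalty_positive_and_scales_with_noise(self):
        rng = np.random.default_rng(12)
        assert auto_penalty(np.full(50, 3.0)) > 0
        quiet = auto_penalty(rng.normal(0, 0.1, 200))
        loud = auto_penalty(rng.normal(0, 1.0, 200))
        assert 0 < quiet < loud


class TestCallRegionEvents:
    @pytest.fixture()
    def zero_matrix(self, tiny_annotation):
        return pd.DataFrame(
            np.zeros((5, 3)),
            index=tiny_annotation["gene_id"],
            columns=["a", "b", "c"],
        )

    def test_all_zero_matrix_all_neutral(self, zero_matrix, tiny_annotation):
        regions = {"r1": (1, 1, 300), "r2": (2, 1, 200)}
        calls = call_region_events(zero_matrix, tiny_annotation, regions)
        assert (calls["call"] == "neutral").all()

    def test_boundary_mean_is_gain(self, zero_matrix, tiny_annotation):
        matrix = zero_matrix.copy()
        matrix.loc[["g4", "g5"], "a"] = 0.2  # region mean exactly +threshold
        calls = call_region_events(
            matrix, tiny_annotation, {"r2": (2, 1, 200)}, threshold=0.2
        )
        assert calls.set_index("strain_id").loc["a", "call"] == "gain"
        assert calls.set_index("strain_id").loc["b", "call"] == "neutral"

    def test_loss_called_symmetrically(self, zero_matrix, tiny_annotation):
        matrix = zero_matrix.copy()
        matrix.loc[["g1", "g2", "g3"], "b"] = -0.5
        calls = call_region_events(
            matrix, tiny_annotation, {"r1": (1, 1, 300)}, threshold=0.2
        )
        assert calls.set_index("strain_id").loc["b", "call"] == "loss"

    def test_empty_region_reported_missing(self, zero_matrix, tiny_annotation):
        calls = call_region_events(
            zero_matrix, tiny_annotation, {"void": (1, 10_000, 20_000)}
        )
        assert (calls["call"] == "missing").all()
        assert calls["mean_log2"].isna().all()

    def test_planted_event_called_for_event_group_only(self):
        from straincgh.simulate import CNVEvent, SimulationConfig, simulate_cohort

        config = SimulationConfig(
            seed=0,
            n_chromosomes=2,
            genes_per_chromosome=30,
            chromosome_length_bp=90_000,
            group_sizes=(2, 3),
            cnv_events=(CNVEvent(0, 1, 1, 30_000, +1.0),),
            noise_sd=1e-9,
            reference_bias_sd=0.0,
            n_terms=2,
            genes_per_term=5,
        )
        cohort = simulate_cohort(config)
        calls = call_region_events(
            cohort.matrix, cohort.annotation, {"ev": (1, 1, 30_000)}, threshold=0.2
        )
        by_strain = calls.set_index("strain_id")["call"]
        for strain, group in cohort.truth_partition.items():
            assert by_strain[strain] == ("gain" if group == 0 else "neutral")


class TestAnnotationHelpers:
    def test_genome_sort_key(self, tiny_annotation):
        shuffled = tiny_annotation.sample(frac=1, random_state=0)
        assert genome_sorted(shuffled)["gene_id"].tolist() == [
            "g1", "g2", "g3", "g4", "g5",
        ]

    def test_validate_rejects_duplicates_and_bad_coords(self, tiny_annotation):
        dup = pd.concat([tiny_annotation, tiny_annotation.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            validate_annotation(dup)
        bad = tiny_annotation.copy()
        bad.loc[0, "start"] = 500
        with pytest.raises(ValueError, match="start > end"):
            validate_annotation(bad)

    def test_subtelomeric_regions_cover_flagged_genes(self, small_cohort):
        regions = subtelomeric_regions(small_cohort.annotation)
        ann = small_cohort.annotation
        flagged = ann[ann["subtelomeric"] == 1]
        mid = (flagged["start"] + flagged["end"]) / 2.0
        covered = 0
        for _, row in flagged.iterrows():
            m = (row["start"] + row["end"]) / 2.0
            for chrom, start, end in regions.values():
                if chrom == row["chromosome"] and start <= m <= end:
                    covered += 1
                    break
        assert covered == len(flagged)
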