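import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coidenoise.denoise import (
    DenoiseParams,
    MergeCandidate,
    beta_threshold,
    corrected_distance,
    count_positional_differences,
    denoise,
    pair_distance,
    select_mother,
)
from coidenoise.entropy import EntropyProfile
from coidenoise.sequence_io import DatasetError
from coidenoise.simulate import SimulationParams, score_recovery, simulate

from .conftest import random_dataset, us
from .reference import naive_classic_denoise

PAPER_PROFILE = EntropyProfile(0.473, 0.227, 1.021, frame_offset=1)


class TestBetaThreshold:
    @pytest.mark.parametrize(
        "alpha,d,expected",
        [(5, 1, 1 / 64), (2, 2, 1 / 32), (3, 0, 0.5), (7, 0, 0.5)],
    )
    def test_direct_evaluation(self, alpha, d, expected):
        assert beta_threshold(alpha, d) == pytest.approx(expected)

    def test_real_valued_distance_accepted(self):
        assert beta_threshold(5, 0.396) == pytest.approx(1 / 2 ** (5 * 0.396 + 1))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            beta_threshold(5, -0.1)


class TestPositionalDifferences:
    def test_identical(self):
        assert count_positional_differences("ACGACG", "ACGACG", 1) == (0, 0, 0)

    def test_third_position_differences_frame1(self):
        # Columns 3 and 6 differ; with frame_offset=1 both are position 3.
        assert count_positional_differences("AAAAAA", "AATAAT", 1) == (0, 0, 2)

    def test_same_columns_reassigned_by_frame2(self):
        # With frame_offset=2, columns 3 and 6 are codon position 1.
        assert count_positional_differences("AAAAAA", "AATAAT", 2) == (2, 0, 0)

    def test_sums_to_hamming(self):
        a, b = "ACGTACGTA", "ACCTACGAA"
        d = count_positional_differences(a, b, 3)
        assert sum(d) == sum(x != y for x, y in zip(a, b))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            count_positional_differences("ACG", "ACGT", 1)


class TestCorrectedDistance:
    def test_one_difference_per_position_is_three(self):
        for profile in [PAPER_PROFILE, EntropyProfile(0.9, 0.1, 1.3), EntropyProfile(1, 1, 1)]:
            assert corrected_distance(1, 1, 1, profile) == pytest.approx(3.0)

    def test_third_position_difference_weighs_more(self):
        assert corrected_distance(0, 0, 1, PAPER_PROFILE) == pytest.approx(1.780, abs=5e-4)

    def test_second_position_difference_weighs_less(self):
        assert corrected_distance(0, 1, 0, PAPER_PROFILE) == pytest.approx(0.396, abs=5e-4)

    def test_zero_entropy_profile_rejected(self):
        with pytest.raises(ValueError):
            corrected_distance(1, 0, 0, EntropyProfile(0, 0, 0))


class TestPairDistance:
    def test_identical_zero_under_all_metrics(self):
        for params in [
            DenoiseParams(),
            DenoiseParams(distance_metric="levenshtein"),
            DenoiseParams(entropy_correction=True, profile=PAPER_PROFILE),
        ]:
            assert pair_distance("ACGT", "ACGT", params) == 0.0

    def test_substitutions_match_levenshtein_on_equal_length(self):
        a, b = "AAAAAA", "AATAAT"
        assert pair_distance(a, b, DenoiseParams()) == 2.0
        assert pair_distance(a, b, DenoiseParams(distance_metric="levenshtein")) == 2.0

    def test_corrected_single_third_position_substitution(self):
        params = DenoiseParams(entropy_correction=True, profile=PAPER_PROFILE)
        assert pair_distance("AAA", "AAT", params) == pytest.approx(1.780, abs=5e-4)

    def test_levenshtein_handles_unequal_lengths(self):
        assert pair_distance("ACGT", "ACG", DenoiseParams(distance_metric="levenshtein")) == 1.0

    def test_positional_rejects_unequal_lengths(self):
        with pytest.raises(ValueError):
            pair_distance("ACGT", "ACG", DenoiseParams())

    def test_correction_requires_positional_metric(self):
        with pytest.raises(ValueError):
            DenoiseParams(
                entropy_correction=True, profile=PAPER_PROFILE, distance_metric="levenshtein"
            )


class TestDenoiseRule:
    def test_low_skew_daughter_merges(self):
        # skew 0.01 <= beta(1) = 0.015625
        ds = [us("AAAAAA", 100, "A"), us("AAAAAT", 1, "B")]
        result = denoise(ds, DenoiseParams(alpha=5, frame_offset=1))
        assert len(result.esvs) == 1
        assert result.esvs[0].total_reads == 101
        assert result.merge_map[0].mother_id == "A"

    def test_high_skew_daughter_kept(self):
        # skew 0.02 > beta(1) = 0.015625
        ds = [us("AAAAAA", 100, "A"), us("AAAAAT", 2, "B")]
        result = denoise(ds, DenoiseParams(alpha=5, frame_offset=1))
        assert len(result.esvs) == 2

    def test_entropy_correction_merges_position2_keeps_position3(self):
        # Same abundances; the single difference sits at codon position 2 vs 3.
        params = DenoiseParams(alpha=5, entropy_correction=True, profile=PAPER_PROFILE)
        pos2 = [us("AAAAAA", 100, "A"), us("ATAAAA", 2, "B")]  # col 2 = position 2
        pos3 = [us("AAAAAA", 100, "A"), us("AATAAA", 2, "B")]  # col 3 = position 3
        assert len(denoise(pos2, params).esvs) == 1  # d_corr=0.396, beta=0.127 >= 0.02
        assert len(denoise(pos3, params).esvs) == 2  # d_corr=1.780, beta=0.00105 < 0.02

    def test_empty_input(self):
        result = denoise([], DenoiseParams())
        assert result.esvs == () and result.merge_map == ()

    def test_non_dereplicated_rejected(self):
        with pytest.raises(DatasetError):
            denoise([us("ACGT", 5, "a"), us("ACGT", 1, "b")], DenoiseParams())


class TestSelectMother:
    def test_single_candidate_under_all_criteria(self):
        c = MergeCandidate("m", d=1.0, skew=0.01, ratio=0.64, mother_count=100)
        for crit in ("skew", "distance", "ratio"):
            assert select_mother([c], crit) is c

    def test_three_criteria_disagree_as_constructed(self):
        # alpha=5: beta(1)=0.015625, beta(2)=0.000244140625
        c1 = MergeCandidate("near", d=1.0, skew=0.010, ratio=0.010 / 0.015625, mother_count=10)
        c2 = MergeCandidate("far", d=2.0, skew=0.0003, ratio=0.0003 / 0.000244140625, mother_count=40)
        assert select_mother([c1, c2], "skew").mother_id == "far"
        assert select_mother([c1, c2], "distance").mother_id == "near"
        assert select_mother([c1, c2], "ratio").mother_id == "near"

    def test_tie_break_prefers_more_abundant_mother(self):
        c1 = MergeCandidate("small", d=1.0, skew=0.01, ratio=0.5, mother_count=100)
        c2 = MergeCandidate("big", d=1.0, skew=0.01, ratio=0.5, mother_count=500)
        assert select_mother([c1, c2], "skew").mother_id == "big"

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_mother([], "skew")


@settings(max_examples=40, deadline=None)
@given(
    seed=st.integers(0, 10**6),
    mode=st.sampled_from(["classic", "two_phase"]),
    criterion=st.sampled_from(["skew", "distance", "ratio"]),
)
def test_read_conservation_and_partition(seed, mode, criterion):
    """Every input sequence lands exactly once (centroid or merge row) and
    reads are conserved, in every mode/criterion."""
    rng = random.Random(seed)
    ds = random_dataset(rng, rng.randint(1, 40), length=24)
    result = denoise(ds, DenoiseParams(alpha=rng.choice([1, 2, 5]), mode=mode, criterion=criterion))
    assert result.total_reads == sum(s.count for s in ds)
    centroid_ids = {e.centroid.id for e in result.esvs}
    daughter_ids = {r.daughter_id for r in result.merge_map}
    assert centroid_ids | daughter_ids == {s.id for s in ds}
    assert not centroid_ids & daughter_ids
    assert len(result.merge_map) == len(daughter_ids)
    # Merge graph is a forest onto the centroids.
    members = [m for e in result.esvs for m in e.members]
    assert sorted(members) == sorted(daughter_ids)


def test_classic_matches_naive_reference_on_random_instances():
    """The optimised classic mode is indistinguishable from the literal
    O(n^2) rule application."""
    rng = random.Random(999)
    for _ in range(25):
        ds = random_dataset(rng, rng.randint(2, 80), length=30)
        alpha = rng.choice([1, 2, 5, 8])
        result = denoise(ds, DenoiseParams(alpha=alpha, frame_offset=1))
        totals, merged_into = naive_classic_denoise(ds, alpha)
        assert {e.centroid.id: e.total_reads for e in result.esvs} == totals
        assert {r.daughter_id: r.mother_id for r in result.merge_map} == merged_into


def test_esv_count_non_decreasing_in_alpha():
    ds, _ = simulate(SimulationParams(seed=21, n_species=10, n_reads=2000, error_rate=0.002))
    for mode in ("classic", "two_phase"):
        counts = [
            len(denoise(ds, DenoiseParams(alpha=a, mode=mode)).esvs) for a in (1, 2, 3, 5, 8, 10)
        ]
        assert counts == sorted(counts)


def test_entropy_correction_asymmetry_exhaustive():
    """Whenever a pair differing at position 3 merges, the identical pair
    with the difference moved to position 2 merges too (e2 < e3)."""
    for alpha in range(1, 11):
        for mother, daughter in [(1000, d) for d in (1, 2, 5, 20, 100, 500)]:
            params = DenoiseParams(
                alpha=alpha, entropy_correction=True, profile=PAPER_PROFILE
            )
            pos3 = denoise([us("AAAAAA", mother, "M"), us("AATAAA", daughter, "D")], params)
            pos2 = denoise([us("AAAAAA", mother, "M"), us("ATAAAA", daughter, "D")], params)
            if len(pos3.esvs) == 1:
                assert len(pos2.esvs) == 1


def test_true_haplotypes_recovered_exactly_on_safe_noiseless_data():
    ds, truth = simulate(SimulationParams(seed=5, n_species=20, denoise_safe=True))
    for mode, crit in [("classic", "skew"), ("two_phase", "skew"), ("two_phase", "distance"), ("two_phase", "ratio")]:
        score = score_recovery(denoise(ds, DenoiseParams(mode=mode, criterion=crit)), truth)
        assert score.recall == 1.0 and score.precision == 1.0


def test_two_phase_skew_equals_classic_without_chains():
    """When no selected mother is itself merged, the two formulations agree;
    chain instances are allowed to diverge and are simply skipped."""
    rng = random.Random(4242)
    compared = 0
    for _ in range(40):
        ds = random_dataset(rng, rng.randint(2, 50), length=24)
        two = denoise(ds, DenoiseParams(alpha=2, mode="two_phase", criterion="skew"))
        daughters = {r.daughter_id for r in two.merge_map}
        if any(r.mother_id in daughters for r in two.merge_map):
            continue  # chain event: divergence permitted
        classic = denoise(ds, DenoiseParams(alpha=2, mode="classic"))
        assert {(e.centroid.id, e.total_reads) for e in two.esvs} == {
            (e.centroid.id, e.total_reads) for e in classic.esvs
        }
        compared += 1
    assert compared >= 10
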