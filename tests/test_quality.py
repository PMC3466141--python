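import numpy as np
import pytest

from matchqual.errors import InsufficientDataError, SpecError
from matchqual.quality import (
    PairDistanceSet,
    compute_pair_distances,
    match_quality_report,
    pair_distance,
    permutation_test_partially_paired,
    rank_sum_statistic,
)
from matchqual.varspec import EDUCATION_LEVELS, VariableSpec

from conftest import paired_cohort


class TestPairDistance:
    @pytest.mark.parametrize(
        "scale,a,b,expected",
        [
            ("continuous", 64, 64, 0.0),
            ("continuous", 1, 10, 9.0),
            ("binary", "male", "male", 0.0),
            ("binary", "male", "female", 1.0),
            ("nominal", "white", "other", 1.0),
        ],
    )
    def test_scales(self, scale, a, b, expected):
        assert pair_distance(a, b, VariableSpec("v", scale)) == expected

    def test_ordinal_rank_distance(self, education_spec):
        assert pair_distance("post-HS", "less-than-HS", education_spec) == 2.0
        assert pair_distance("HS-grad", "post-HS", education_spec) == 1.0

    def test_missing_propagates(self, age_spec):
        assert pair_distance(None, 5, age_spec) is None
        assert pair_distance(5, None, age_spec) is None

    def test_undeclared_ordinal_level_is_spec_error(self, education_spec):
        with pytest.raises(SpecError, match="PhD"):
            pair_distance("PhD", "HS-grad", education_spec)


class TestRankSum:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2], [3, 4], 3.0),
            ([1, 1], [1, 2], 4.0),  # midranks of pooled {1,1,1,2} are (2,2,2,4)
            ([5, 5, 5], [5, 5, 5], 10.5),  # identical multisets: n(2n+1)/2
        ],
    )
    def test_midrank_sums(self, a, b, expected):
        assert rank_sum_statistic(a, b) == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            rank_sum_statistic([], [1.0])


class TestPermutationTest:
    def test_four_perfect_pairs_exact(self):
        d = PairDistanceSet(
            "x", {i: 0.0 for i in range(4)}, {i: 5.0 for i in range(4)}
        )
        res = permutation_test_partially_paired(d, method="exact")
        assert res.p_one_sided == pytest.approx(1 / 16)
        assert res.method == "exact_enumeration"
        assert res.n_permutations == 16
        assert res.n_paired == 4 and res.n_peer_only == 0 and res.n_listed_only == 0

    def test_all_identical_distances_give_p_one(self):
        d = PairDistanceSet(
            "x", {i: 2.0 for i in range(4)}, {i: 2.0 for i in range(4)}
        )
        assert permutation_test_partially_paired(d, method="exact").p_one_sided == 1.0

    def test_monte_carlo_near_exact(self):
        d = PairDistanceSet(
            "x", {i: 0.0 for i in range(4)}, {i: 5.0 for i in range(4)}
        )
        n_perm = 100000
        res = permutation_test_partially_paired(
            d, n_permutations=n_perm, seed=12, method="monte_carlo"
        )
        se = np.sqrt(0.0625 * 0.9375 / n_perm)
        assert abs(res.p_one_sided - 0.0625) <= 3 * se + 1 / (n_perm + 1)

    def test_one_empty_group_is_insufficient(self):
        d = PairDistanceSet("x", {0: 1.0}, {})
        with pytest.raises(InsufficientDataError):
            permutation_test_partially_paired(d)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            PairDistanceSet("x", {0: -1.0}, {0: 1.0})


class TestComputePairDistances:
    def test_partially_paired_structure(self, age_spec):
        cohort = paired_cohort(
            survivor_vals=[60.0, 62.0, 64.0],
            peer_vals=[61.0, None, 63.0],
            listed_vals=[60.0, 62.0, None],
        )
        d = compute_pair_distances(cohort, age_spec)
        assert d.peer_distances == {"S000": 1.0, "S002": 1.0}
        assert d.listed_distances == {"S000": 0.0, "S001": 0.0}

    @pytest.mark.parametrize("rule,expected", [
        ("first", 2.0),       # first enrolled peer defines the pair
        ("mean_distance", 3.0),
        ("all", (2.0, 4.0)),
    ])
    def test_two_peer_rules(self, age_spec, rule, expected):
        from conftest import make_participant
        from matchqual.cohort import CohortTable

        parts = [
            make_participant("S1", "survivor", age=60.0),
            make_participant("P1", "peer", "S1", age=62.0),
            make_participant("P2", "peer", "S1", age=64.0),
            make_participant("L1", "listed", "S1", age=60.0),
        ]
        cohort = CohortTable.from_participants(parts)
        d = compute_pair_distances(cohort, age_spec, peer_rule=rule)
        assert d.peer_distances["S1"] == expected


class TestMatchQualityReport:
    def test_perfect_peers_poor_listed_reject_everywhere(self):
        n = 12
        cohort = paired_cohort(
            survivor_vals=[60.0 + i for i in range(n)],
            peer_vals=[60.0 + i for i in range(n)],
            listed_vals=[75.0 + i for i in range(n)],
        )
        frame = match_quality_report(
            cohort, [VariableSpec("age", "continuous")], n_permutations=2000, seed=0
        )
        assert (frame["p_one_sided"] < 0.05).all()

    def test_four_pair_fixture_row(self):
        cohort = paired_cohort(
            survivor_vals=[60.0] * 4,
            peer_vals=[60.0] * 4,
            listed_vals=[65.0] * 4,
        )
        frame = match_quality_report(
            cohort, [VariableSpec("age", "continuous")], method="exact", seed=0
        )
        assert len(frame) == 1
        assert frame.loc[0, "p_one_sided"] == pytest.approx(0.0625)

    def test_missing_group_flagged_not_dropped(self, age_spec):
        cohort = paired_cohort(
            survivor_vals=[60.0, 61.0],
            peer_vals=[60.0, 61.0],
            listed_vals=[None, None],
        )
        frame = match_quality_report(cohort, [age_spec], n_permutations=100, seed=0)
        assert frame.loc[0, "flag"] == "insufficient_data"
        assert np.isnan(frame.loc[0, "p_one_sided"])

    def test_cluster_swap_rule_runs_with_two_peers(self, age_spec):
        from conftest import make_participant
        from matchqual.cohort import CohortTable

        parts = []
        for i in range(6):
            sid = f"S{i}"
            parts.append(make_participant(sid, "survivor", age=60.0 + i))
            parts.append(make_participant(f"Pa{i}", "peer", sid, age=61.0 + i))
            parts.append(make_participant(f"Pb{i}", "peer", sid, age=62.0 + i))
            parts.append(make_participant(f"L{i}", "listed", sid, age=63.0 + i))
        cohort = CohortTable.from_participants(parts)
        frame = match_quality_report(
            cohort, [age_spec], peer_rule="all", method="exact", seed=0
        )
        assert 0.0 <= frame.loc[0, "p_one_sided"] <= 1.0
        assert frame.loc[0, "n_peer"] == 12
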