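import numpy as np
import pytest

from matchqual.errors import InsufficientDataError
from matchqual.marginal import (
    marginal_report,
    marginal_test_categorical,
    marginal_test_continuous,
)
from matchqual.quality import compute_pair_distances
from matchqual.varspec import VariableSpec

from conftest import paired_cohort


def keyed(values):
    return {i: v for i, v in enumerate(values)}


class TestContinuous:
    def test_equal_margins_despite_poor_pairs(self, toy_pairs, age_spec):
        """Marginal equality does not imply pair-level match."""
        survivors, comparisons = toy_pairs
        res = marginal_test_continuous(keyed(survivors), keyed(comparisons), method="exact")
        assert res.summary_index["mean"] == pytest.approx(5.5)
        assert res.summary_comparison["mean"] == pytest.approx(5.5)
        assert res.p_two_sided == 1.0
        cohort = paired_cohort(survivors, comparisons, [None] * 4)
        dists = compute_pair_distances(cohort, age_spec)
        assert all(d == 9.0 for d in dists.peer_distances.values())

    def test_identical_vectors_give_p_one(self):
        res = marginal_test_continuous(keyed([3, 1, 4, 1]), keyed([3, 1, 4, 1]), method="exact")
        assert res.p_two_sided == 1.0

    def test_separated_paired_sets_exact(self):
        res = marginal_test_continuous(
            keyed([1, 2, 3, 4]), keyed([11, 12, 13, 14]), method="exact"
        )
        assert res.p_two_sided == pytest.approx(2 / 16)
        assert res.method == "exact_enumeration"

    def test_two_sided_p_invariant_under_group_swap(self, rng):
        idx = keyed(rng.normal(0, 1, 6).round(2))
        cmp_ = keyed(rng.normal(0.5, 1, 5).round(2))
        a = marginal_test_continuous(idx, cmp_, method="exact")
        b = marginal_test_continuous(cmp_, idx, method="exact")
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_too_few_complete_cases(self):
        with pytest.raises(InsufficientDataError):
            marginal_test_continuous({0: 1.0}, keyed([1, 2, 3]))


class TestCategorical:
    def test_identical_compositions_paired(self):
        vals = ["m"] * 7 + ["f"] * 3
        res = marginal_test_categorical(keyed(vals), keyed(vals), method="exact")
        assert res.p_two_sided == 1.0

    def test_disjoint_categories_five_pairs(self):
        res = marginal_test_categorical(
            keyed(["A"] * 5), keyed(["B"] * 5), method="exact"
        )
        assert res.p_two_sided == pytest.approx(2 / 32)

    def test_single_pooled_category_degenerate(self):
        res = marginal_test_categorical(keyed(["A"] * 5), keyed(["A"] * 5))
        assert res.p_two_sided == 1.0
        assert res.degenerate
        assert res.warnings


class TestMarginalReport:
    def test_all_identical_cohort_never_rejects(self):
        cohort = paired_cohort([64.0] * 5, [64.0] * 5, [64.0] * 5)
        frame = marginal_report(cohort, n_permutations=200, seed=0)
        ok = frame[frame["flag"].isin(["", "degenerate"])]
        assert (ok["p_two_sided"] == 1.0).all()

    def test_row_per_variable_and_group_pair(self):
        cohort = paired_cohort([60.0, 61.0, 62.0], [59.0, 60.0, 61.0], [60.0, 61.0, 62.0])
        specs = [VariableSpec("age", "continuous"), VariableSpec("sex", "binary")]
        frame = marginal_report(cohort, specs, n_permutations=200, seed=0)
        assert len(frame) == 4
        assert set(frame["group_pair"]) == {"survivor_vs_peer", "survivor_vs_listed"}

    def test_unmatched_survivors_still_counted(self):
        # survivors without a peer stay in the margin as unpaired observations
        cohort = paired_cohort(
            [60.0, 61.0, 62.0, 63.0],
            [59.0, None, None, None],
            [60.0, 61.0, 62.0, 63.0],
        )
        frame = marginal_report(
            cohort, [VariableSpec("age", "continuous")], n_permutations=200, seed=0
        )
        peer_row = frame[frame["group_pair"] == "survivor_vs_peer"].iloc[0]
        assert peer_row["n_index"] == 4
        assert peer_row["n_comparison"] == 1

    def test_peer_age_shift_hits_peer_margin_not_listed(self):
        """A younger-peer generator should flag the peer age margin far more."""
        from matchqual.simulate import GeneratorConfig, generate_cohort

        cfg = GeneratorConfig(n_survivors=80)
        p_peer, p_listed = [], []
        for seed in range(10):
            cohort = generate_cohort(cfg, seed=1000 + seed)
            frame = marginal_report(
                cohort, [VariableSpec("age", "continuous")], n_permutations=500, seed=seed
            )
            p_peer.append(float(frame.loc[frame["group_pair"] == "survivor_vs_peer", "p_two_sided"].iloc[0]))
            p_listed.append(float(frame.loc[frame["group_pair"] == "survivor_vs_listed", "p_two_sided"].iloc[0]))
        assert np.mean(np.asarray(p_peer) < 0.05) > np.mean(np.asarray(p_listed) < 0.05)
        assert np.median(p_peer) < np.median(p_listed)
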