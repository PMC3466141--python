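import numpy as np
import pytest

from matchqual.cohort import COLUMNS
from matchqual.errors import ConfigError
from matchqual.simulate import (
    GeneratorConfig,
    generate_cohort,
    generate_null_cohort,
    generate_recruitment_ledger,
    generate_shifted_cohort,
    nomination_counts,
)

VALUE_COLUMNS = [c for c in COLUMNS if c not in ("subject_id", "group", "survivor_link")]


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig(n_survivors=30)
        a = generate_cohort(cfg, seed=5).to_frame()
        b = generate_cohort(cfg, seed=5).to_frame()
        assert a.equals(b)

    def test_hard_constraints_always_hold(self):
        cohort = generate_cohort(GeneratorConfig(), seed=17)
        for mset in cohort.matched_sets:
            surv = cohort.participants[mset.survivor_id]
            if mset.listed_id:
                listed = cohort.participants[mset.listed_id]
                assert listed.sex == surv.sex
                assert abs(listed.age - surv.age) <= 5.0 + 1e-9
        assert all(
            p.cancer_history is False
            for p in cohort.participants.values()
            if p.group != "survivor"
        )

    def test_perfect_fidelity_copies_every_variable(self):
        cfg = GeneratorConfig.perfect_peer_fidelity(n_survivors=40)
        cohort = generate_cohort(cfg, seed=3)
        n_peers = 0
        for mset in cohort.matched_sets:
            surv = cohort.participants[mset.survivor_id]
            for pid in mset.peer_ids:
                n_peers += 1
                peer = cohort.participants[pid]
                for col in VALUE_COLUMNS:
                    if col == "cancer_history":
                        continue
                    assert getattr(peer, col) == getattr(surv, col), col
        assert n_peers > 0

    def test_nomination_and_completion_calibration(self):
        # quick check at 60 seeds; the full 200-seed check is in acceptance
        cfg = GeneratorConfig()
        counts = [nomination_counts(cfg, seed=s) for s in range(60)]
        mean_nom = np.mean([c["n_nominators"] for c in counts])
        mean_peers = np.mean([c["n_completed_peers"] for c in counts])
        assert abs(mean_nom - 61) < 2.5
        assert abs(mean_peers - 44) < 3.0

    def test_nomination_counts_match_cohort(self):
        cfg = GeneratorConfig(n_survivors=50)
        nc = nomination_counts(cfg, seed=9)
        cohort = generate_cohort(cfg, seed=9)
        assert nc["n_completed_peers"] == len(cohort.group("peer"))


class TestNullAndShifted:
    def test_shift_zero_reduces_to_null_generator(self):
        cfg = GeneratorConfig(n_survivors=25)
        a = generate_null_cohort(cfg, seed=7).to_frame()
        b = generate_shifted_cohort(cfg, shift=0.0, seed=7).to_frame()
        assert a.equals(b)

    def test_small_cohort_reproducible(self):
        cfg = GeneratorConfig(n_survivors=4, missing_rate=0.0)
        a = generate_null_cohort(cfg, seed=1).to_frame()
        b = generate_null_cohort(cfg, seed=1).to_frame()
        assert a.equals(b)

    def test_shift_displaces_listed_ages_only(self):
        cfg = GeneratorConfig(n_survivors=200, missing_rate=0.0)
        shifted = generate_shifted_cohort(cfg, shift=10.0, seed=3)
        diffs_listed, diffs_peer = [], []
        for mset in shifted.matched_sets:
            surv = shifted.participants[mset.survivor_id]
            if mset.listed_id:
                diffs_listed.append(shifted.participants[mset.listed_id].age - surv.age)
            for pid in mset.peer_ids:
                diffs_peer.append(shifted.participants[pid].age - surv.age)
        assert np.mean(diffs_listed) > 8.0
        assert abs(np.mean(diffs_peer)) < 2.0

    def test_negative_shift_rejected(self):
        with pytest.raises(ConfigError):
            generate_shifted_cohort(GeneratorConfig(), shift=-1.0, seed=0)


class TestConfig:
    def test_probability_bounds_checked(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(peer_nomination_prob=1.5)
        with pytest.raises(ConfigError):
            GeneratorConfig(n_survivors=0)
        with pytest.raises(ConfigError):
            GeneratorConfig(listed_match_window_years=0.0)

    def test_from_yaml_merges_defaults(self, tmp_path):
        path = tmp_path / "gen.yaml"
        path.write_text(
            "n_survivors: 12\nmarginals:\n  age: {mean: 50.0}\n", encoding="utf-8"
        )
        cfg = GeneratorConfig.from_yaml(path)
        assert cfg.n_survivors == 12
        assert cfg.marginals["age"]["mean"] == 50.0
        assert cfg.marginals["age"]["sd"] == 10.09  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "gen.yaml"
        path.write_text("n_survivor: 12\n", encoding="utf-8")
        with pytest.raises(ConfigError, match="n_survivor"):
            GeneratorConfig.from_yaml(path)


class TestRecruitmentLedger:
    def test_funnel_conservation(self):
        ledgers = generate_recruitment_ledger(GeneratorConfig(), seed=11)
        for led in ledgers.values():
            assert led.n_completed + sum(led.stage_counts.values()) == led.n_candidates
            assert led.n_completed <= led.n_usable_numbers <= led.n_candidates

    def test_fixed_seed_reproducible(self):
        a = generate_recruitment_ledger(GeneratorConfig(), seed=2)
        b = generate_recruitment_ledger(GeneratorConfig(), seed=2)
        assert a == b

    def test_all_success_config(self):
        cfg = GeneratorConfig()
        for arm in cfg.funnel.values():
            arm["p_usable"] = 1.0
            arm["p_complete"] = 1.0
        ledgers = generate_recruitment_ledger(cfg, seed=0)
        for led in ledgers.values():
            assert led.n_completed == led.n_candidates
            assert all(v == 0 for v in led.stage_counts.values())

    def test_survivor_completion_calibrated(self):
        rates = []
        for s in range(100):
            led = generate_recruitment_ledger(GeneratorConfig(), seed=s)["survivor"]
            rates.append(led.n_completed)
        # E[completed] = 378 * P(usable) * P(complete | usable) = 100
        assert abs(np.mean(rates) - 100.0) < 4.0
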