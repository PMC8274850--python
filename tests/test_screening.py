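from dataclasses import replace

import numpy as np
import pytest

from screencea import synthetic_data as sd
from screencea.natural_history import PersonHistory, person_rng, simulate_cohort
from screencea.screening import (
    Strategy,
    apply_strategy,
    as_screened,
    run_arm,
    schedule_screens,
)


def _person(death=90.0, entry=40.0):
    return PersonHistory(0, entry, death, [])


def _colonoscopy(start, stop, interval, **kw):
    return Strategy(
        label=f"Colonoscopy, {start}-{stop}, {interval}",
        modality="colonoscopy",
        start_age=float(start),
        stop_age=float(stop),
        interval=float(interval) if interval else None,
        test=kw.pop("test", sd.colonoscopy_test()),
        surveillance=kw.pop("surveillance", sd.crc_surveillance()),
    )


class TestSchedule:
    @pytest.mark.parametrize(
        "start,stop,interval,death,expected",
        [
            (50, 75, 10, 90.0, [50.0, 60.0, 70.0]),
            (45, 75, 15, 90.0, [45.0, 60.0, 75.0]),
            (50, 75, 10, 65.0, [50.0, 60.0]),
            (55, 85, 5, 56.0, [55.0]),
        ],
    )
    def test_routine_grid(self, start, stop, interval, death, expected):
        assert schedule_screens(_colonoscopy(start, stop, interval), _person(death)) == expected

    def test_once_only_death_before(self):
        strat = Strategy(
            label="Endoscopy, 60", modality="endoscopy", start_age=60.0, stop_age=60.0,
            interval=None, test=sd.endoscopy_test(),
        )
        assert schedule_screens(strat, _person(59.0)) == []
        assert schedule_screens(strat, _person(61.0)) == [60.0]

    def test_no_screening_empty(self):
        assert schedule_screens(sd.no_screening(), _person(90.0)) == []


class TestApplyStrategy:
    def test_empty_schedule_is_identity(self, crc_params, small_cohort):
        strat = _colonoscopy(50, 75, 10)
        h = next(p for p in small_cohort if p.observed_death_age < 50.0)
        out = apply_strategy(h, strat, crc_params, person_rng(0, 0, 2))
        assert out.events == []
        assert out.observed_death_age == h.observed_death_age
        assert out.cancer_death_age == h.cancer_death_age

    def test_perfect_annual_screening_intercepts_everything(self, crc_params, life_table):
        perfect = replace(
            sd.colonoscopy_test(),
            sensitivity={k: 1.0 for k in sd.colonoscopy_test().sensitivity},
        )
        strat = _colonoscopy(20, 110, 1, test=perfect)
        cohort = simulate_cohort(500, crc_params, life_table, seed=21, entry_age=20.0)
        arm = run_arm(cohort, strat, 21, crc_params)
        for sh in arm:
            # no lesion arising in the screened window survives to clinical cancer
            assert sh.diagnosis_age is None or sh.screen_detected

    def test_zero_sensitivity_leaves_outcomes_unchanged(self, crc_params, small_cohort):
        blind = replace(
            sd.colonoscopy_test(),
            sensitivity={k: 0.0 for k in sd.colonoscopy_test().sensitivity},
        )
        strat = _colonoscopy(50, 75, 10, test=blind)
        arm = run_arm(small_cohort, strat, 7, crc_params)
        for h, sh in zip(small_cohort, arm):
            assert sh.observed_death_age == h.observed_death_age
            assert sh.cancer_death_age == h.cancer_death_age
            assert not sh.removed_lesions
            kinds = {e.kind for e in sh.events}
            assert kinds <= {"screen", "false_positive", "positive", "complication"}

    def test_events_within_screening_window_and_life(self, crc_params, small_cohort,
                                                     colonoscopy_50_75_10):
        arm = run_arm(small_cohort, colonoscopy_50_75_10, 7, crc_params)
        for sh in arm:
            for e in sh.events:
                assert 50.0 <= e.age <= 75.0 + 1e-9 or e.kind in (
                    "surveillance", "positive", "precursor_removed",
                    "screen_detected_cancer", "complication", "false_positive",
                )
                assert e.age <= sh.observed_death_age

    def test_screening_never_shortens_life_without_test_mortality(
        self, crc_params, small_cohort, colonoscopy_50_75_10
    ):
        arm = run_arm(small_cohort, colonoscopy_50_75_10, 7, crc_params)
        # other-cause death is untouched; cancer death can only be averted or
        # delayed/advanced by the redraw, but never past the other-cause age
        for h, sh in zip(small_cohort, arm):
            assert sh.observed_death_age <= h.other_cause_death_age + 1e-12


class TestRunArm:
    def test_no_screening_arm_equals_cohort(self, small_cohort):
        arm = run_arm(small_cohort, sd.no_screening(), 7)
        for h, sh in zip(small_cohort, arm):
            assert sh.base is h
            assert sh.events == []
            assert sh.observed_death_age == h.observed_death_age

    def test_same_seed_identical_arm(self, crc_params, small_cohort, colonoscopy_50_75_10):
        a = run_arm(small_cohort[:300], colonoscopy_50_75_10, 7, crc_params)
        b = run_arm(small_cohort[:300], colonoscopy_50_75_10, 7, crc_params)
        assert [x.observed_death_age for x in a] == [x.observed_death_age for x in b]
        assert [len(x.events) for x in a] == [len(x.events) for x in b]

    def test_common_random_numbers_pair_arms(self, crc_params, small_cohort):
        # natural histories are shared across arms; divergence only through
        # screening actions
        a = run_arm(small_cohort, _colonoscopy(50, 75, 10), 7, crc_params)
        b = run_arm(small_cohort, _colonoscopy(55, 75, 10), 7, crc_params)
        for x, y in zip(a, b):
            assert x.base is y.base
            if not x.events and not y.events:
                assert x.observed_death_age == y.observed_death_age

    def test_perfect_screening_gains_life_years(self, crc_params, life_table):
        perfect = replace(
            sd.colonoscopy_test(),
            sensitivity={k: 1.0 for k in sd.colonoscopy_test().sensitivity},
            complication_prob=0.0,
        )
        cohort = simulate_cohort(4000, crc_params, life_table, seed=17)
        arm = run_arm(cohort, _colonoscopy(45, 85, 5, test=perfect), 17, crc_params)
        gained = np.mean([sh.observed_death_age - h.observed_death_age
                          for h, sh in zip(cohort, arm)])
        assert gained > 0

    def test_shorter_interval_never_loses_life_years(self, crc_params, life_table):
        cohort = simulate_cohort(4000, crc_params, life_table, seed=19)
        ly = {}
        for interval in (15, 10, 5):
            arm = run_arm(cohort, _colonoscopy(45, 85, interval), 19, crc_params)
            ly[interval] = np.mean([sh.observed_death_age for sh in arm])
        assert ly[5] >= ly[10] - 0.02
        assert ly[10] >= ly[15] - 0.02


class TestCytosponge:
    def test_triage_cost_and_product_sensitivity(self, eac_params, life_table):
        cohort = simulate_cohort(3000, eac_params, life_table, seed=23, entry_age=60.0)
        cyto, endo = sd.default_strategy_grid("eac_like")
        assert cyto.modality == "cytosponge_then_endoscopy"
        arm_c = run_arm(cohort, cyto, 23, eac_params)
        arm_e = run_arm(cohort, endo, 23, eac_params)
        # every positive cytosponge triggers a triage endoscopy event
        for sh in arm_c:
            kinds = [e.kind for e in sh.events]
            if "precursor_removed" in kinds or "screen_detected_cancer" in kinds:
                assert "positive" in kinds
        # two-step testing detects no more than single-step endoscopy on average
        removed_c = np.mean([len(sh.removed_lesions) for sh in arm_c])
        removed_e = np.mean([len(sh.removed_lesions) for sh in arm_e])
        assert removed_c <= removed_e + 1e-9
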