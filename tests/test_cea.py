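import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_efficient
from screencea import synthetic_data as sd
from screencea.cea import (
    CEPoint,
    COST_SAVING,
    DOMINATED,
    acer,
    efficient_frontier,
    frontier_from_table,
    icer_table,
    load_table1_fixture,
    scenario_sweep,
    sensitivity_suite,
)
from screencea.economics import CancerCareParams


def _pt(label, cost, qaly):
    return CEPoint(label=label, cost=cost, qaly=qaly)


class TestACER:
    def test_cost_saving_flag(self):
        # net savings with QALYs gained: flagged, not reported as a ratio
        assert acer(_pt("s", -1.66e6, 83.0), _pt("ref", 0.0, 0.0)) == COST_SAVING

    def test_ratio_from_published_cells(self):
        a = acer(_pt("cyto", 976_200.0, 32.4), _pt("ref", 0.0, 0.0))
        assert a == pytest.approx(30_130, abs=50)

    def test_zero_cost_difference(self):
        assert acer(_pt("s", 0.0, 5.0), _pt("ref", 0.0, 0.0)) == 0.0

    def test_no_gain_is_dominated(self):
        assert acer(_pt("s", 10.0, 0.0), _pt("ref", 0.0, 0.0)) == DOMINATED


class TestFrontier:
    def test_textbook_extended_dominance(self):
        pts = [_pt("a", 0.0, 0.0), _pt("b", 10.0, 1.0), _pt("c", 12.0, 3.0)]
        report = efficient_frontier(pts)
        assert report.labels == {
            "a": "reference", "b": "extendedly_dominated", "c": "efficient",
        }
        assert report.icers["c"] == pytest.approx(4.0)
        assert brute_force_efficient(pts) == {"a", "c"}

    def test_single_strategy_vs_comparator(self):
        report = efficient_frontier([_pt("ref", 0.0, 0.0), _pt("s", 10.0, 2.0)],
                                    comparator_label="ref")
        assert report.labels["s"] == "efficient"
        assert report.icers["s"] == pytest.approx(5.0)
        assert report.acers["s"] == pytest.approx(5.0)  # frontier of 2: ICER == ACER

    def test_strong_dominance(self):
        pts = [_pt("a", 0.0, 0.0), _pt("b", 5.0, 3.0), _pt("worse", 6.0, 2.0)]
        report = efficient_frontier(pts)
        assert report.labels["worse"] == "strongly_dominated"

    def test_duplicate_points_tie_break_lexicographic(self):
        pts = [_pt("zeta", 5.0, 2.0), _pt("alpha", 5.0, 2.0), _pt("ref", 0.0, 0.0)]
        report = efficient_frontier(pts)
        assert report.labels["alpha"] == "efficient"
        assert report.labels["zeta"] == "strongly_dominated"

    def test_icers_strictly_increase_along_frontier(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pts = [_pt(f"s{i}", c, q)
                   for i, (c, q) in enumerate(zip(rng.uniform(0, 100, 10),
                                                  rng.uniform(0, 50, 10)))]
            report = efficient_frontier(pts)
            icers = [report.icers[p.label] for p in report.efficient[1:]]
            assert np.all(np.diff(icers) > 0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            pts = [_pt(f"s{i}", float(c), float(q))
                   for i, (c, q) in enumerate(zip(rng.uniform(-10, 100, n),
                                                  rng.uniform(0, 50, n)))]
            report = efficient_frontier(pts)
            assert report.efficient_labels() == brute_force_efficient(pts), pts


class TestPublishedTable:
    def test_loader_units_and_shape(self):
        t = load_table1_fixture()
        assert set(t.disease) == {"crc", "eac"}
        assert len(t.query("disease=='crc' and scenario=='default'")) == 21
        assert len(t.query("disease=='eac' and scenario=='default'")) == 3
        row = t.query("disease=='eac' and scenario=='default' and strategy=='Endoscopy, 60'")
        assert row.cost.iloc[0] == pytest.approx(1_618_300.0)  # $ thousands -> $
        row = t.query("disease=='crc' and scenario=='default' and strategy=='Colonoscopy, 50-75, 10'")
        assert row.cost.iloc[0] == pytest.approx(-1.66e6)  # $ millions -> $

    def test_default_crc_frontier_is_the_published_set(self):
        report = frontier_from_table(load_table1_fixture(), "crc", "default")
        assert report.efficient_labels() == {
            "Colonoscopy, 55-75, 15",
            "Colonoscopy, 55-75, 10",
            "Colonoscopy, 50-75, 10",
            "Colonoscopy, 45-75, 10",
            "Colonoscopy, 45-75, 5",
        }
        # the cost-saving reference strongly dominates no screening
        assert report.labels["No screening"] == "strongly_dominated"

    def test_published_icer_examples(self):
        t = load_table1_fixture()
        crc = frontier_from_table(t, "crc", "default")
        assert crc.icers["Colonoscopy, 45-75, 10"] == pytest.approx(71_400, rel=0.01)
        eac = frontier_from_table(t, "eac", "default")
        assert eac.icers["Endoscopy, 60"] == pytest.approx(107_000, rel=0.01)
        pairs = icer_table(eac)
        assert [p[0] for p in pairs] == ["Cytosponge, 60", "Endoscopy, 60"]


@pytest.fixture(scope="module")
def tiny_sweep(life_table, crc_params, cost_curve, utility_curve, care,
               colonoscopy_50_75_10):
    strategies = [sd.no_screening(), colonoscopy_50_75_10]
    return scenario_sweep(
        800, crc_params, life_table, strategies, cost_curve, utility_curve, care,
        seed=31, entry_age=40.0,
    )


class TestScenarioSweep:
    def test_rr_one_cells_coincide(self, tiny_sweep):
        # at rr=1 every component toggle describes the same all-average
        # scenario, represented exactly once by the 'average' cell
        rr_one = tiny_sweep.query("rr == 1.0")
        assert set(rr_one.scenario) == {"default", "average"}
        avg = tiny_sweep.query("scenario=='average' and strategy!='No screening'")
        assert len(avg) == 1

    def test_default_cell_has_no_background(self, tiny_sweep, life_table, crc_params,
                                            cost_curve, utility_curve, care,
                                            colonoscopy_50_75_10):
        from screencea.economics import ScenarioAssumptions, summarize_arm
        from screencea.natural_history import simulate_cohort
        from screencea.screening import run_arm

        cohort = simulate_cohort(800, crc_params, life_table, 1.0, 31, entry_age=40.0)
        arm = run_arm(cohort, colonoscopy_50_75_10, 31, crc_params)
        res = summarize_arm(arm, None, None, care, ScenarioAssumptions.default(),
                            label="Colonoscopy, 50-75, 10")
        row = tiny_sweep.query("scenario=='default' and strategy=='Colonoscopy, 50-75, 10'")
        assert row.cost.iloc[0] == pytest.approx(res.cost, rel=1e-12)
        assert row.qaly.iloc[0] == pytest.approx(res.qaly, rel=1e-12)

    def test_combined_acer_dominates_single_components(self, tiny_sweep):
        s = tiny_sweep[tiny_sweep.strategy != "No screening"]
        for rr in (1.125, 1.25, 1.375, 1.5):
            combined = s.query("components=='costs+disutility+mortality' and rr==@rr")
            combined = combined[combined.scenario.str.startswith("combined")]
            acer_comb = combined.acer.iloc[0]
            for comp in ("costs", "disutility", "mortality"):
                single = s.query("components==@comp and rr==@rr")
                assert acer_comb >= single.acer.iloc[0] - 1e-9

    def test_sensitivity_identities(self, life_table, crc_params, cost_curve,
                                    utility_curve, care, colonoscopy_50_75_10):
        strategies = [sd.no_screening(), colonoscopy_50_75_10]
        suite = sensitivity_suite(
            500, crc_params, life_table, strategies, cost_curve, utility_curve, care,
            seed=37, entry_age=40.0, rr_grid=(1.0, 1.25),
        )
        undisc = suite["undiscounted"]
        base = scenario_sweep(
            500, crc_params, life_table, strategies, cost_curve, utility_curve, care,
            seed=37, entry_age=40.0, rr_grid=(1.0, 1.25),
        )
        merged = undisc.merge(base, on=["scenario", "strategy"], suffixes=("_u", "_d"))
        assert (merged.ly_u >= merged.ly_d - 1e-9).all()
        assert (merged.qaly_u >= merged.qaly_d - 1e-9).all()

        # excess-only at rr=1 equals no background costs at all
        excess = suite["excess_only"]
        avg_row = excess.query("scenario=='average' and strategy=='No screening'")
        plain = base.query("scenario=='default' and strategy=='No screening'")
        # same histories, so the only cost left in the average/excess cell is care
        assert avg_row.cost.iloc[0] == pytest.approx(plain.cost.iloc[0], rel=1e-6)
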